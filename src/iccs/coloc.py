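"""Colocalization fractions from fitted correlation amplitudes.

M1 is the fraction of channel-a particles that carry both labels,
M2 the converse, computed as amplitude ratios:

    M1 = r(0,0)_ab / r(0,0)_bb        M2 = r(0,0)_ab / r(0,0)_aa

and the single per-ROI summary is their arithmetic mean,
f_ICCS = (M1 + M2) / 2.  Because each M is a ratio of amplitudes from the
same pair of channels, it is invariant to rescaling either channel's
intensity — unlike the pixelwise Pearson coefficient, which degrades when
the two channels have very different particle densities.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

from .correlation import GaussianFitResult

DEFAULT_MIN_AMP_OVER_STDERR = 2.0
DEFAULT_MIN_AMP_OVER_OFFSET = 1.0


@dataclass
class ColocResult:
    """Interaction fractions and particle numbers for one ROI."""

    m1: float
    m2: float
    f_iccs: float
    n_a: float
    n_b: float
    n_ab: float
    accepted: bool
    flags: list[str] = field(default_factory=list)
    audit: dict[str, Any] = field(default_factory=dict)


def snr_gate(
    fit: GaussianFitResult,
    min_amplitude_over_stderr: float = DEFAULT_MIN_AMP_OVER_STDERR,
    min_amplitude_over_offset: float = DEFAULT_MIN_AMP_OVER_OFFSET,
) -> tuple[bool, GaussianFitResult]:
    """Accept a fit only if its amplitude is resolvable above noise.

    A fit passes when the amplitude is positive, exceeds
    ``min_amplitude_over_stderr`` times its standard error, and is at least
    ``min_amplitude_over_offset`` times the magnitude of the long-range
    offset.  Rejection reasons are appended to the fit's flags.
    """
    flags = list(fit.flags)
    ok = True
    if fit.amplitude <= 0:
        flags.append("low-snr:non-positive-amplitude")
        ok = False
    else:
        if fit.amplitude_stderr > 0 and (
            fit.amplitude / fit.amplitude_stderr < min_amplitude_over_stderr
        ):
            flags.append("low-snr:amplitude-vs-stderr")
            ok = False
        if fit.amplitude < min_amplitude_over_offset * abs(fit.offset):
            flags.append("low-snr:amplitude-vs-offset")
            ok = False
    annotated = replace(fit, accepted=ok, flags=flags)
    return ok, annotated


def coloc_fractions(
    fit_aa: GaussianFitResult,
    fit_bb: GaussianFitResult,
    fit_ab: GaussianFitResult,
) -> ColocResult:
    """Combine the three fitted amplitudes into M1, M2 and f_ICCS.

    Requires positive autocorrelation amplitudes (otherwise no particle
    number exists).  A negative cross-correlation amplitude means no
    detectable co-fluctuation and maps to zero fractions with a flag;
    fractions above 1 (possible with noisy amplitudes) are reported raw
    and flagged rather than clamped.

    Acceptance follows the autocorrelation gates: ICCS is feasible whenever
    both channels individually pass the signal-to-noise criteria, and a
    rejected cross fit then reports zero colocalization (flagged) instead
    of discarding the ROI.
    """
    r_aa, r_bb, r_ab = fit_aa.amplitude, fit_bb.amplitude, fit_ab.amplitude
    if r_aa <= 0 or r_bb <= 0:
        raise ValueError("non-positive autocorrelation amplitude: no particle-number estimate")
    flags: list[str] = []
    if r_ab < 0:
        m1 = m2 = 0.0
        n_ab = 0.0
        flags.append("negative-cross")
    else:
        m1 = r_ab / r_bb
        m2 = r_ab / r_aa
        n_ab = r_ab / (r_aa * r_bb)
        if m1 > 1 or m2 > 1:
            flags.append("clamped-range")
    accepted = True
    for name, fit in (("aa", fit_aa), ("bb", fit_bb)):
        if fit.accepted is False:
            accepted = False
            flags.append(f"rejected-{name}")
        flags.extend(f"{name}:{fl}" for fl in fit.flags)
    if fit_ab.accepted is False:
        m1 = m2 = n_ab = 0.0
        flags.append("low-snr-cross")
    flags.extend(f"ab:{fl}" for fl in fit_ab.flags)
    return ColocResult(
        m1=m1,
        m2=m2,
        f_iccs=(m1 + m2) / 2.0,
        n_a=1.0 / r_aa,
        n_b=1.0 / r_bb,
        n_ab=n_ab,
        accepted=accepted,
        flags=flags,
    )


def pearson_coefficient(pixels_a: np.ndarray, pixels_b: np.ndarray) -> float:
    """Pixelwise Pearson correlation of two intensity grids.

    Provided as a comparator: unlike the amplitude-ratio fractions, Pearson
    is depressed when the channels have unequal particle densities even if
    every particle of the sparse channel is colocalized.
    """
    a = np.asarray(pixels_a, dtype=np.float64).ravel()
    b = np.asarray(pixels_b, dtype=np.float64).ravel()
    if a.shape != b.shape:
        raise ValueError("pixel grids must have the same shape")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance in a channel")
    return float(np.corrcoef(a, b)[0, 1])
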