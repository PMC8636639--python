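"""Spatial auto-/cross-correlation of intensity fluctuations and Gaussian fits.

The normalized spatial correlation of two channels a, b over an ROI is

    r(xi, eta)_ab = < dI_a(x, y) * dI_b(x + xi, y + eta) > / (<I>_a * <I>_b)

with dI = I - <I> the zero-mean fluctuation field.  Its zero-lag amplitude
is the inverse of the mean number of (co-)fluctuating particles per beam
focal area, so a 2D Gaussian

    r(xi, eta) = r(0,0) * exp(-((xi - u)^2 + (eta - v)^2) / w0^2) + r_inf

is fitted to the central portion of the surface to estimate r(0,0) free of
the uncorrelated-noise spike that sits on the exact zero-lag sample.

Shifts are periodic (circular), computed via FFT; fitting is restricted to
small lags (a quarter of the ROI by default) where wrap-around bias is
negligible and random long-range correlations do not leak into the fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

DEFAULT_PSF_RADIUS_INIT = 3.0  # px, starting guess for the beam e^-2 radius
PEAK_SHIFT_BOUND = 2.0  # px, |u|,|v| bound; larger shifts indicate misregistration
MAX_FIT_RESTARTS = 5


@dataclass
class FluctuationField:
    """Zero-mean intensity fluctuations dI(x, y) over an ROI and its mean."""

    delta: np.ndarray
    mean_intensity: float


@dataclass
class CorrelationSurface:
    """Normalized correlation values r(xi, eta) on a centered square lag grid.

    ``values`` has shape ``(2 * max_lag + 1,) * 2`` with index
    ``(max_lag, max_lag)`` holding the zero-lag sample.  ``pair`` is one of
    ``"aa"``, ``"bb"``, ``"ab"``.
    """

    values: np.ndarray
    pair: str
    max_lag: int

    @property
    def zero_lag_sample(self) -> float:
        """The raw r(0,0) sample (noise spike included, no fitting)."""
        return float(self.values[self.max_lag, self.max_lag])

    def lag_grids(self) -> tuple[np.ndarray, np.ndarray]:
        lags = np.arange(-self.max_lag, self.max_lag + 1)
        return np.meshgrid(lags, lags, indexing="ij")


@dataclass
class GaussianFitResult:
    """Parameters of the 2D Gaussian fit to a correlation surface."""

    amplitude: float
    beam_radius: float
    peak_u: float
    peak_v: float
    offset: float
    amplitude_stderr: float
    residual_norm: float
    accepted: bool | None = None  # set by the SNR gate, not by the fit
    zero_lag_excluded: bool = False
    flags: list[str] = field(default_factory=list)


def compute_fluctuations(pixels: np.ndarray) -> FluctuationField:
    """Subtract the ROI spatial mean: dI(x, y) = I(x, y) - <I>."""
    pixels = np.asarray(pixels, dtype=np.float64)
    if pixels.size == 0:
        raise ValueError("empty pixel grid")
    mean = float(pixels.mean())
    if mean <= 0:
        raise ValueError("ROI mean intensity is zero; dark region unusable for ICCS")
    return FluctuationField(delta=pixels - mean, mean_intensity=mean)


def spatial_correlation(
    f_a: FluctuationField, f_b: FluctuationField, pair: str | None = None
) -> CorrelationSurface:
    """Normalized spatial correlation of two fluctuation fields.

    The average runs over all pixel positions with periodic (wrap-around)
    shifting, evaluated with FFTs.  The returned surface is trimmed to the
    largest symmetric lag window so that r(xi, eta) and r(-xi, -eta) are
    both present for every retained lag.
    """
    da, db = f_a.delta, f_b.delta
    if da.shape != db.shape:
        raise ValueError(f"fluctuation field shapes differ: {da.shape} vs {db.shape}")
    h, w = da.shape
    corr = np.fft.ifft2(np.conj(np.fft.fft2(da)) * np.fft.fft2(db)).real / (h * w)
    corr /= f_a.mean_intensity * f_b.mean_intensity
    corr = np.fft.fftshift(corr)
    max_lag = min((h - 1) // 2, (w - 1) // 2)
    ctr_r, ctr_c = h // 2, w // 2
    values = corr[
        ctr_r - max_lag : ctr_r + max_lag + 1, ctr_c - max_lag : ctr_c + max_lag + 1
    ]
    if pair is None:
        pair = "aa" if f_a is f_b else "ab"
    return CorrelationSurface(values=np.ascontiguousarray(values), pair=pair, max_lag=max_lag)


def crop_correlation(surface: CorrelationSurface, max_lag: int) -> CorrelationSurface:
    """Central ``(2 * max_lag + 1)^2`` window of the surface, values unchanged.

    Cropping limits the contribution of random correlations at large lags
    to the subsequent Gaussian fit.
    """
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    if max_lag > surface.max_lag:
        raise ValueError(
            f"max_lag {max_lag} exceeds available lag range {surface.max_lag}"
        )
    c = surface.max_lag
    values = surface.values[c - max_lag : c + max_lag + 1, c - max_lag : c + max_lag + 1]
    return CorrelationSurface(values=values.copy(), pair=surface.pair, max_lag=max_lag)


def _gauss2d(coords, amplitude, beam_radius, u, v, offset):
    xi, eta = coords
    return amplitude * np.exp(-((xi - u) ** 2 + (eta - v) ** 2) / beam_radius**2) + offset


def fit_gaussian(
    surface: CorrelationSurface,
    exclude_zero_lag: bool = False,
    init: Sequence[float] | None = None,
    fix_peak: bool = False,
) -> GaussianFitResult:
    """Least-squares fit of the 2D Gaussian model to a correlation surface.

    Parameters
    ----------
    exclude_zero_lag
        Omit the (0, 0) sample from the residuals.  Per-pixel white/shot
        noise is uncorrelated between pixels so its entire contribution sits
        on that one sample; excluding it yields a noise-free amplitude
        estimate for autocorrelations.
    init
        Optional ``(amplitude, beam_radius, u, v, offset)`` starting point.
    fix_peak
        Pin the peak to (0, 0) instead of fitting (u, v) within +/-2 px.

    Returns the fitted parameters, the standard error of the amplitude from
    the fit covariance, and the residual norm.  The ``accepted`` flag is
    left unset; apply the SNR gate to populate it.
    """
    if surface.max_lag < 3:
        raise ValueError("surface must retain max_lag >= 3 to constrain 5 parameters")
    xi, eta = surface.lag_grids()
    values = surface.values
    if np.ptp(values) == 0:
        raise ValueError("degenerate correlation surface: all values equal")

    mask = np.ones(values.shape, dtype=bool)
    if exclude_zero_lag:
        mask[surface.max_lag, surface.max_lag] = False
    coords = (xi[mask], eta[mask])
    data = values[mask]

    edge = np.concatenate([values[0], values[-1], values[1:-1, 0], values[1:-1, -1]])
    edge_median = float(np.median(edge))
    c = surface.max_lag
    ring = [values[c - 1, c], values[c + 1, c], values[c, c - 1], values[c, c + 1]]
    amp0 = float(np.mean(ring)) - edge_median
    if init is not None:
        p0 = list(init)
    else:
        p0 = [amp0, DEFAULT_PSF_RADIUS_INIT, 0.0, 0.0, edge_median]

    peak_bound = 1e-9 if fix_peak else PEAK_SHIFT_BOUND
    lower = [-np.inf, 1e-3, -peak_bound, -peak_bound, -np.inf]
    upper = [np.inf, 4.0 * surface.max_lag, peak_bound, peak_bound, np.inf]

    rng = np.random.default_rng(0)
    last_err: Exception | None = None
    for attempt in range(MAX_FIT_RESTARTS):
        trial = list(p0)
        if attempt > 0:
            trial[0] = p0[0] * (1 + 0.3 * rng.standard_normal())
            trial[1] = max(0.5, p0[1] * (1 + 0.3 * rng.standard_normal()))
        trial = [float(np.clip(t, lo, hi)) for t, lo, hi in zip(trial, lower, upper)]
        try:
            popt, pcov = curve_fit(
                _gauss2d,
                coords,
                data,
                p0=trial,
                bounds=(lower, upper),
                xtol=1e-10,
                ftol=1e-12,
                maxfev=20000,
            )
            last_err = None
            break
        except (RuntimeError, ValueError) as err:  # pragma: no cover - rare
            last_err = err
    if last_err is not None:
        raise RuntimeError(f"Gaussian fit did not converge: {last_err}")

    residuals = data - _gauss2d(coords, *popt)
    stderr = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else np.inf
    result = GaussianFitResult(
        amplitude=float(popt[0]),
        beam_radius=float(popt[1]),
        peak_u=float(popt[2]),
        peak_v=float(popt[3]),
        offset=float(popt[4]),
        amplitude_stderr=stderr,
        residual_norm=float(np.linalg.norm(residuals)),
        zero_lag_excluded=exclude_zero_lag,
    )
    if max(abs(result.peak_u), abs(result.peak_v)) >= 0.95 * PEAK_SHIFT_BOUND:
        result.flags.append("displaced-peak")
    return result


def particle_number(fit: GaussianFitResult) -> float:
    """Mean particle count per beam focal area: the inverse fit amplitude."""
    if fit.amplitude <= 0:
        raise ValueError("non-positive amplitude: failed or noise-dominated fit")
    return 1.0 / fit.amplitude
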