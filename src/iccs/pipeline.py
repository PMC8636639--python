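"""ROI-level ICCS orchestration, batch analysis and group statistics.

``analyze_roi`` runs the full chain on one region: background estimation
and subtraction, fluctuation fields per channel, the three correlation
surfaces (aa, bb, ab), cropping, Gaussian fitting with SNR gating, and the
amplitude-ratio colocalization fractions.  ``analyze_batch`` maps the
chain over a manifest of images grouped by experimental condition and
summarizes accepted ROIs per group with mean +/- SD, Welch's t-test for
two groups and one-way ANOVA (with Bonferroni-corrected pairwise Welch
tests) for more.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import __version__
from .coloc import (
    DEFAULT_MIN_AMP_OVER_OFFSET,
    DEFAULT_MIN_AMP_OVER_STDERR,
    ColocResult,
    coloc_fractions,
    snr_gate,
)
from .correlation import (
    compute_fluctuations,
    crop_correlation,
    fit_gaussian,
    spatial_correlation,
)
from .image_io import ROI, BackgroundEstimate, TwoChannelImage, estimate_background, read_image, subtract_background

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """All tunable knobs of the ROI analysis, serializable to YAML/JSON."""

    roi_size: int = 64
    max_lag: int = 16
    background_percentile: float = 0.10
    min_amplitude_over_stderr: float = DEFAULT_MIN_AMP_OVER_STDERR
    min_amplitude_over_offset: float = DEFAULT_MIN_AMP_OVER_OFFSET
    exclude_zero_lag_auto: bool = True
    exclude_zero_lag_cross: bool = False
    fix_peak_cross: bool = True  # channels are pre-registered; see methods note
    channel_a: int = 0
    channel_b: int = 1
    base_seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "AnalysisConfig":
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class GroupComparison:
    group_1: str
    group_2: str | None
    test: str
    statistic: float
    p_value: float


@dataclass
class GroupSummary:
    label: str
    values: list[float]
    mean: float
    sd: float
    n: int
    comparisons: list[GroupComparison] = field(default_factory=list)


def _failed_result(flag: str) -> ColocResult:
    return ColocResult(
        m1=np.nan, m2=np.nan, f_iccs=np.nan, n_a=np.nan, n_b=np.nan, n_ab=np.nan,
        accepted=False, flags=[flag],
    )


def analyze_roi(
    image: TwoChannelImage,
    roi: ROI,
    config: AnalysisConfig | None = None,
    background: BackgroundEstimate | None = None,
) -> ColocResult:
    """Full ICCS chain on one ROI; failures yield a flagged, not-accepted result.

    The zero-lag sample is excluded from the autocorrelation fits (each
    channel's detector noise correlates with itself) but kept in the
    cross-correlation fit, where noise is uncorrelated across channels.
    All intermediate fit parameters are retained in ``result.audit``.
    """
    config = config or AnalysisConfig()
    try:
        roi.validate(image.shape)
        if background is None:
            background = estimate_background(image, roi, config.background_percentile)
        corrected = subtract_background(image, background)
        f_a = compute_fluctuations(corrected.pixels_a[roi.slices])
        f_b = compute_fluctuations(corrected.pixels_b[roi.slices])
    except (ValueError, ZeroDivisionError) as err:
        logger.warning("ROI %s unusable: %s", roi, err)
        return _failed_result(f"empty-roi:{err}")

    max_lag = min(config.max_lag, min(roi.height, roi.width) // 4)
    fits = {}
    try:
        for pair, (fa, fb), exclude, fix_peak in (
            ("aa", (f_a, f_a), config.exclude_zero_lag_auto, False),
            ("bb", (f_b, f_b), config.exclude_zero_lag_auto, False),
            ("ab", (f_a, f_b), config.exclude_zero_lag_cross, config.fix_peak_cross),
        ):
            surface = crop_correlation(spatial_correlation(fa, fb, pair=pair), max_lag)
            fit = fit_gaussian(surface, exclude_zero_lag=exclude, fix_peak=fix_peak)
            _, fits[pair] = snr_gate(
                fit, config.min_amplitude_over_stderr, config.min_amplitude_over_offset
            )
        result = coloc_fractions(fits["aa"], fits["bb"], fits["ab"])
    except (ValueError, RuntimeError) as err:
        logger.warning("ROI %s analysis failed: %s", roi, err)
        result = _failed_result(f"fit-failed:{err}")

    result.audit = {
        "roi": str(roi),
        "background": {"a": background.value_a, "b": background.value_b,
                       "method": background.method},
        "mean_intensity": {"a": f_a.mean_intensity, "b": f_b.mean_intensity},
        "max_lag": max_lag,
        "fits": {
            pair: {
                "amplitude": f.amplitude,
                "beam_radius": f.beam_radius,
                "peak_u": f.peak_u,
                "peak_v": f.peak_v,
                "offset": f.offset,
                "amplitude_stderr": f.amplitude_stderr,
                "residual_norm": f.residual_norm,
                "accepted": f.accepted,
                "zero_lag_excluded": f.zero_lag_excluded,
                "flags": f.flags,
            }
            for pair, f in fits.items()
        },
    }
    return result


def _result_row(path: str, group: str, roi: ROI, result: ColocResult) -> dict:
    fits = result.audit.get("fits", {})
    row = {
        "path": path,
        "group": group,
        "roi": str(roi),
        "m1": result.m1,
        "m2": result.m2,
        "f_iccs": result.f_iccs,
        "n_a": result.n_a,
        "n_b": result.n_b,
        "n_ab": result.n_ab,
        "accepted": result.accepted,
        "flags": ";".join(result.flags),
    }
    for pair in ("aa", "bb", "ab"):
        f = fits.get(pair, {})
        row[f"amp_{pair}"] = f.get("amplitude", np.nan)
        row[f"omega_{pair}"] = f.get("beam_radius", np.nan)
    return row


def analyze_batch(
    manifest: list[tuple[str | Path, str, list[ROI]]],
    config: AnalysisConfig | None = None,
) -> tuple[pd.DataFrame, list[GroupSummary]]:
    """Analyze every (image, group, ROI) entry and summarize groups.

    Unreadable files are skipped with a warning; failed ROIs are retained
    in the table, flagged, and excluded from group summaries so acceptance
    rates stay auditable.
    """
    config = config or AnalysisConfig()
    if not manifest:
        raise ValueError("empty manifest")
    rows = []
    for path, group, rois in manifest:
        try:
            image = read_image(path, (config.channel_a, config.channel_b))
        except (FileNotFoundError, IndexError, ValueError) as err:
            logger.warning("skipping unreadable file %s: %s", path, err)
            continue
        for roi in rois:
            result = analyze_roi(image, roi, config)
            rows.append(_result_row(str(path), group, roi, result))
    results = pd.DataFrame(rows)
    if results.empty:
        raise ValueError("no analyzable entries in manifest")
    results = results.sort_values(["group", "path", "roi"], kind="stable").reset_index(drop=True)
    return results, group_summaries(results)


def group_summaries(results: pd.DataFrame) -> list[GroupSummary]:
    """Per-group mean +/- SD of f_ICCS over accepted ROIs, plus significance tests."""
    summaries: dict[str, GroupSummary] = {}
    for label in sorted(results["group"].unique()):
        sub = results[(results["group"] == label) & results["accepted"]]
        values = [float(v) for v in sub["f_iccs"] if np.isfinite(v)]
        summaries[label] = GroupSummary(
            label=label,
            values=values,
            mean=float(np.mean(values)) if values else np.nan,
            sd=float(np.std(values, ddof=1)) if len(values) > 1 else np.nan,
            n=len(values),
        )
    testable = [s for s in summaries.values() if s.n >= 2]
    for s in summaries.values():
        if s.n < 2 and len(summaries) > 1:
            logger.warning("group %r has < 2 accepted ROIs; excluded from tests", s.label)
    comparisons: list[GroupComparison] = []
    if len(testable) == 2:
        g1, g2 = testable
        stat, p = stats.ttest_ind(g1.values, g2.values, equal_var=False)
        comparisons.append(GroupComparison(g1.label, g2.label, "welch-t", float(stat), float(p)))
    elif len(testable) > 2:
        stat, p = stats.f_oneway(*[s.values for s in testable])
        comparisons.append(GroupComparison("all", None, "anova", float(stat), float(p)))
        pairs = [(a, b) for i, a in enumerate(testable) for b in testable[i + 1:]]
        for g1, g2 in pairs:
            stat, p = stats.ttest_ind(g1.values, g2.values, equal_var=False)
            p_adj = min(1.0, float(p) * len(pairs))  # Bonferroni
            comparisons.append(
                GroupComparison(g1.label, g2.label, "welch-t-bonferroni", float(stat), p_adj)
            )
    for s in summaries.values():
        s.comparisons = comparisons
    return list(summaries.values())


def report(
    results: pd.DataFrame,
    summaries: list[GroupSummary],
    config: AnalysisConfig,
    output_dir: str | Path,
    plots: bool = False,
) -> dict[str, Path]:
    """Write per-ROI CSV, group-summary CSV and JSON run metadata.

    Output is deterministic: identical inputs and config produce
    byte-identical files.  With ``plots=True`` a per-group strip/box plot
    of the accepted f_ICCS values is also written.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    roi_csv = out / "roi_results.csv"
    results.to_csv(roi_csv, index=False, float_format="%.10g")
    paths["roi_results"] = roi_csv

    summary_rows = []
    for s in summaries:
        summary_rows.append({"group": s.label, "mean_f_iccs": s.mean, "sd_f_iccs": s.sd, "n": s.n})
    summary_csv = out / "group_summary.csv"
    pd.DataFrame(summary_rows).to_csv(summary_csv, index=False, float_format="%.10g")
    paths["group_summary"] = summary_csv

    comparisons = summaries[0].comparisons if summaries else []
    meta = {
        "software": "iccs",
        "version": __version__,
        "config": config.to_dict(),
        "n_rois": int(len(results)),
        "n_accepted": int(results["accepted"].sum()),
        "comparisons": [dataclasses.asdict(c) for c in comparisons],
    }
    meta_json = out / "run_metadata.json"
    meta_json.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    paths["metadata"] = meta_json

    if plots:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(4, 3))
        labels = [s.label for s in summaries]
        ax.boxplot([s.values for s in summaries], tick_labels=labels)
        ax.set_ylabel("f_ICCS")
        fig.tight_layout()
        plot_path = out / "group_f_iccs.png"
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)
        paths["plot"] = plot_path
    return paths
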