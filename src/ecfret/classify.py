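"""Dynamic/static trace classification and FRET-efficiency population analysis.

A trace switching between FRET states shows anticorrelated donor and
acceptor intensities; the classifier thresholds a scale-invariant
anticorrelation statistic (covariance of the two corrected, filtered
channels divided by the squared mean total intensity). Non-dynamic traces
are split into static-high and static-low by their median FRET efficiency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .tracepipe import ProcessedTrace

DYNAMIC = "dynamic"
STATIC_HIGH = "static_high"
STATIC_LOW = "static_low"

ANTICORR_THRESHOLD = -0.01   # classification threshold on the statistic
MEDIAN_E_SPLIT = 0.4         # static high/low split on median E

HIST_RANGE = (-0.2, 1.2)
HIST_BIN_WIDTH = 0.04


def anticorrelation_statistic(proc: ProcessedTrace, use_raw: bool = False,
                              min_frames: int = 50) -> float:
    """Donor-acceptor anticorrelation normalized by squared mean total intensity.

    c = (1/N) sum_t (I_D(t) - <I_D>) (I_A(t) - <I_A>) / <I_D + I_A>^2,
    computed on the corrected, Chung-Kennedy-filtered green-segment
    intensities. Dimensionless, sign-preserving and invariant under scaling
    both channels or adding a common offset. NaN when the mean total
    intensity is ~zero (trace should be flagged).
    """
    d = proc.I_D if use_raw else proc.I_D_ck
    a = proc.I_A if use_raw else proc.I_A_ck
    if d.size < min_frames:
        raise ValueError(f"need at least {min_frames} green frames")
    total = float(np.mean(d + a))
    if abs(total) < 1e-9:
        return float("nan")
    cov = float(np.mean((d - d.mean()) * (a - a.mean())))
    return cov / total ** 2


@dataclass
class ClassificationResult:
    trace_id: str
    statistic: float
    label: str                # dynamic | static_high | static_low
    median_E: float


def classify_trace(proc: ProcessedTrace,
                   threshold: float = ANTICORR_THRESHOLD,
                   split: float = MEDIAN_E_SPLIT,
                   use_raw: bool = False) -> ClassificationResult:
    """Label a trace dynamic (c < threshold) or static high/low (median E vs split).

    Ties at exactly the threshold are classified static (strict inequality
    for dynamic).
    """
    c = anticorrelation_statistic(proc, use_raw=use_raw)
    e = proc.E_ck[~proc.undefined]
    med = float(np.median(e)) if e.size else float("nan")
    if np.isfinite(c) and c < threshold:
        label = DYNAMIC
    else:
        label = STATIC_HIGH if med > split else STATIC_LOW
    return ClassificationResult(proc.trace_id, c, label, med)


def dynamic_fraction(experiments: list[tuple[int, int]]
                     ) -> tuple[float, float, int]:
    """Weighted mean +- SD of per-experiment dynamic percentages.

    ``experiments`` is a list of (n_dynamic, n_total); weights are n_total
    (frequency-weight convention). Returns (mean %, SD %, n_experiments);
    SD is NaN for a single experiment. Zero-total experiments are excluded
    with a warning.
    """
    kept = [(d, n) for d, n in experiments if n > 0]
    if len(kept) < len(experiments):
        warnings.warn("excluded experiment(s) with zero traces")
    if not kept:
        raise ValueError("no experiments with traces")
    p = np.array([100.0 * d / n for d, n in kept])
    w = np.array([n for _, n in kept], float)
    mean = float(np.sum(w * p) / w.sum())
    if len(kept) < 2 or w.sum() <= 1:
        return mean, float("nan"), len(kept)
    sd = float(np.sqrt(np.sum(w * (p - mean) ** 2) / (w.sum() - 1)))
    return mean, sd, len(kept)


@dataclass
class EfficiencyHistogram:
    """Frame-level FRET-efficiency histogram pooled over selected traces."""

    bin_edges: np.ndarray
    counts: np.ndarray
    n_traces: int
    condition: str = ""

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bin_left": self.bin_edges[:-1],
                             "count": self.counts})


def efficiency_histogram(procs: list[ProcessedTrace], condition: str = "",
                         bin_width: float = HIST_BIN_WIDTH,
                         e_range: tuple[float, float] = HIST_RANGE
                         ) -> EfficiencyHistogram:
    """Pool per-frame filtered E values of selected traces into a histogram."""
    if not procs:
        raise ValueError("need at least one trace")
    values = np.concatenate([p.E_ck[~p.undefined] for p in procs])
    n_bins = int(round((e_range[1] - e_range[0]) / bin_width))
    edges = np.round(e_range[0] + bin_width * np.arange(n_bins + 1), 10)
    # clip so that clamped excursions land in the outermost bins
    counts, _ = np.histogram(np.clip(values, e_range[0], e_range[1] - 1e-9),
                             bins=edges)
    return EfficiencyHistogram(edges, counts, len(procs), condition)


@dataclass
class PeakRatioResult:
    ratio: float               # dissociated / associated amplitude ratio
    flag: str = ""             # "", "no_dissociated_peak", "no_associated_peak"
    amplitudes: tuple[float, float] = (np.nan, np.nan)  # (dissociated, associated)
    centers: tuple[float, float] = (np.nan, np.nan)
    fit_ok: bool = True
    params: dict = field(default_factory=dict)


def peak_ratio(hist: EfficiencyHistogram,
               init_centers: tuple[float, float] = (0.08, 0.60),
               center_bound: float = 0.1,
               use_areas: bool = False) -> PeakRatioResult:
    """Dissociated/associated peak ratio from a two-Gaussian mixture fit.

    Peak centers are initialized at the dissociated and associated state
    efficiencies and bounded to +-``center_bound`` of the initialization.
    The ratio uses fitted peak amplitudes by default (peak-to-peak); with
    ``use_areas`` it uses amplitude * width. When one population is absent
    the ratio is 0 or +inf with a flag rather than an exception.
    """
    if hist.counts.sum() == 0:
        raise ValueError("histogram is empty")
    x = hist.centers
    y = hist.counts.astype(float)

    def model(x, a1, c1, s1, a2, c2, s2):
        return (a1 * np.exp(-0.5 * ((x - c1) / s1) ** 2)
                + a2 * np.exp(-0.5 * ((x - c2) / s2) ** 2))

    c_lo, c_hi = init_centers
    ymax = y.max()
    p0 = [max(y[np.abs(x - c_lo) < 0.1].max(initial=ymax * 0.1), 1e-3), c_lo, 0.05,
          max(y[np.abs(x - c_hi) < 0.1].max(initial=ymax * 0.1), 1e-3), c_hi, 0.05]
    bounds = ([0, c_lo - center_bound, 0.01, 0, c_hi - center_bound, 0.01],
              [2 * ymax + 1, c_lo + center_bound, 0.4,
               2 * ymax + 1, c_hi + center_bound, 0.4])
    try:
        popt, _ = curve_fit(model, x, y, p0=p0, bounds=bounds, maxfev=20_000)
        fit_ok = True
    except RuntimeError:
        popt, fit_ok = p0, False
    a_diss, c_diss, s_diss, a_assoc, c_assoc, s_assoc = popt
    if use_areas:
        a_diss, a_assoc = a_diss * s_diss, a_assoc * s_assoc

    floor = 0.01 * max(a_diss + a_assoc, 1e-12)
    flag = ""
    if a_assoc <= floor and a_diss <= floor:
        ratio, flag = float("nan"), "no_peaks"
    elif a_assoc <= floor:
        ratio, flag = float("inf"), "no_associated_peak"
    elif a_diss <= floor:
        ratio, flag = 0.0, "no_dissociated_peak"
    else:
        ratio = a_diss / a_assoc
    return PeakRatioResult(ratio=float(ratio), flag=flag,
                           amplitudes=(float(a_diss), float(a_assoc)),
                           centers=(float(c_diss), float(c_assoc)),
                           fit_ok=fit_ok,
                           params=dict(zip(("a1", "c1", "s1", "a2", "c2", "s2"),
                                           map(float, popt))))


def results_table(results: list[ClassificationResult],
                  condition: str = "") -> pd.DataFrame:
    return pd.DataFrame([{
        "trace_id": r.trace_id, "c": r.statistic, "label": r.label,
        "median_E": r.median_E, "condition": condition,
    } for r in results])
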