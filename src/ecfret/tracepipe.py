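"""Trace-processing chain for two-channel smFRET TIRF recordings.

Order of operations: running-median prefilter (3 frames on signal, 7 on
background), background subtraction, donor->acceptor crosstalk correction,
direct-acceptor-excitation correction, FRET efficiency, single-pair
selection on the red ALEX segments and the first/last 10 s of donor
excitation, and Chung-Kennedy edge-preserving denoising.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .traces import GREEN, RED_HEAD, RED_TAIL, Trace

E_CLAMP = (-0.2, 1.2)


@dataclass
class CorrectionFactors:
    """Spectral correction factors estimated from single-dye calibration samples."""

    lk: float           # donor -> acceptor channel crosstalk (leakage)
    dir: float          # acceptor direct excitation under the donor laser
    gamma: float = 1.0  # detection-correction factor; balanced detection assumed

    def __post_init__(self) -> None:
        if self.lk < 0 or self.dir < 0:
            raise ValueError("lk and dir must be >= 0")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")


@dataclass
class SelectionCriteria:
    """Intensity constraints identifying single donor/acceptor pairs.

    ``total_window`` bounds the mean corrected total green-segment intensity
    in the first and last ``eval_seconds`` of donor excitation (one donor, no
    donor bleach, no aggregates); ``acceptor_window`` bounds the mean
    background-subtracted I_AA in both red segments (one live acceptor).
    ``max_acceptor_drop``: reject when the red-tail acceptor signal falls
    below this fraction of the red-head signal (photobleach guard).
    """

    total_window: tuple[float, float]
    acceptor_window: tuple[float, float]
    eval_seconds: float = 10.0
    max_acceptor_drop: float = 0.5

    def __post_init__(self) -> None:
        if self.total_window[1] <= self.total_window[0] or \
           self.acceptor_window[1] <= self.acceptor_window[0]:
            raise ValueError("selection windows must have positive width")
        if self.eval_seconds <= 0:
            raise ValueError("evaluation window must be positive")

    @classmethod
    def from_calibration(cls, donor_only: list[Trace],
                         acceptor_only: list[Trace],
                         n_sd: float = 2.5, **kw) -> "SelectionCriteria":
        """Windows as mean +- n_sd * SD of the single-dye calibration populations."""
        tot = np.array([np.mean((t.I_D - t.bg_D)[t.green]) for t in donor_only])
        acc = np.array([np.mean((t.I_AA - t.bg_A)[~t.green]) for t in acceptor_only])
        sd_tot = max(tot.std(ddof=1), 0.02 * abs(tot.mean()))
        sd_acc = max(acc.std(ddof=1), 0.02 * abs(acc.mean()))
        return cls(
            total_window=(tot.mean() - n_sd * sd_tot, tot.mean() + n_sd * sd_tot),
            acceptor_window=(acc.mean() - n_sd * sd_acc, acc.mean() + n_sd * sd_acc),
            **kw,
        )


@dataclass
class SelectionVerdict:
    accepted: bool
    reasons: list[str] = field(default_factory=list)


@dataclass
class ProcessedTrace:
    """Corrected, filtered green-segment record of one trace."""

    trace_id: str
    time: np.ndarray          # s, green frames only
    I_D: np.ndarray           # corrected donor intensity
    I_A: np.ndarray           # corrected acceptor intensity
    I_D_ck: np.ndarray        # Chung-Kennedy filtered channels
    I_A_ck: np.ndarray
    E_raw: np.ndarray         # clamped to E_CLAMP for reporting
    E_ck: np.ndarray
    undefined: np.ndarray     # frames where total intensity was ~0
    verdict: SelectionVerdict | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return len(self.time)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_s": self.time, "I_D": self.I_D, "I_A": self.I_A,
            "E_raw": self.E_raw, "E_ck": self.E_ck,
            "selected": bool(self.verdict.accepted) if self.verdict else True,
            "reason": ";".join(self.verdict.reasons) if self.verdict else "",
        })


def _running_median(x: np.ndarray, window: int) -> np.ndarray:
    """Centered running median with windows shrinking at the edges."""
    return (pd.Series(x).rolling(window, center=True, min_periods=1)
            .median().to_numpy())


def median_prefilter(trace: Trace, signal_window: int = 3,
                     background_window: int = 7) -> Trace:
    """Running-median prefilter: 3 frames on signals, 7 on background series."""
    return Trace(
        trace_id=trace.trace_id,
        time=trace.time,
        I_D=_running_median(trace.I_D, signal_window),
        I_A=_running_median(trace.I_A, signal_window),
        I_AA=_running_median(trace.I_AA, signal_window),
        segment=trace.segment,
        bg_D=_running_median(trace.bg_D, background_window),
        bg_A=_running_median(trace.bg_A, background_window),
        metadata=dict(trace.metadata),
    )


def estimate_corrections(donor_only: list[Trace], acceptor_only: list[Trace],
                         gamma: float = 1.0) -> CorrectionFactors:
    """Leakage and direct-excitation factors from single-dye calibration traces.

    lk  = median over donor-only traces of <I_A - bg> / <I_D - bg> on green
    frames; dir = median over acceptor-only traces of <I_A - bg> on green
    frames over <I_AA - bg> on red frames.
    """
    if not donor_only or not acceptor_only:
        raise ValueError("both calibration sets must be non-empty")
    lks = []
    for t in donor_only:
        g = t.green
        lks.append(np.mean((t.I_A - t.bg_A)[g]) / np.mean((t.I_D - t.bg_D)[g]))
    dirs = []
    for t in acceptor_only:
        g = t.green
        dirs.append(np.mean((t.I_A - t.bg_A)[g]) / np.mean((t.I_AA - t.bg_A)[~g]))
    return CorrectionFactors(lk=float(np.median(lks)),
                             dir=float(np.median(dirs)), gamma=gamma)


def chung_kennedy(series: np.ndarray, window: int = 10, p: float = 1.0,
                  eps: float = 1e-12) -> np.ndarray:
    """Chung-Kennedy edge-preserving filter (two-predictor form, K = M).

    Each point is replaced by a blend of the mean of the ``window`` points
    strictly before it (forward predictor) and the mean of the ``window``
    points strictly after it (backward predictor); the blend weights are the
    inverse p-th power of each predictor's mean squared prediction error over
    a comparison window of the same length. Near a level change the
    predictor straddling the step accumulates a large error and is switched
    off, so steps stay sharp while flat stretches are averaged. Edge windows
    shrink; output length equals input length. ``eps`` floors the error
    estimate so that noiseless segments do not divide by zero.
    """
    x = np.asarray(series, float)
    n = x.size
    K = int(window)
    if n <= 2 * K:
        raise ValueError("series must be longer than twice the window")

    csum = np.concatenate([[0.0], np.cumsum(x)])
    idx = np.arange(n)

    # forward predictor: mean of x[t-K .. t-1]
    lo = np.maximum(idx - K, 0)
    nf = idx - lo
    fwd = np.where(nf > 0, (csum[idx] - csum[lo]) / np.maximum(nf, 1), np.nan)
    # backward predictor: mean of x[t+1 .. t+K]
    hi = np.minimum(idx + 1 + K, n)
    nb = hi - (idx + 1)
    bwd = np.where(nb > 0, (csum[hi] - csum[idx + 1]) / np.maximum(nb, 1), np.nan)

    ef = (x - fwd) ** 2   # nan at t=0
    eb = (x - bwd) ** 2   # nan at t=n-1

    def trailing_nanmean(e: np.ndarray) -> np.ndarray:
        v = np.nan_to_num(e)
        ok = (~np.isnan(e)).astype(float)
        cv = np.concatenate([[0.0], np.cumsum(v)])
        ck = np.concatenate([[0.0], np.cumsum(ok)])
        lo = np.maximum(idx - K + 1, 0)
        cnt = ck[idx + 1] - ck[lo]
        return np.where(cnt > 0, (cv[idx + 1] - cv[lo]) / np.maximum(cnt, 1), np.nan)

    def leading_nanmean(e: np.ndarray) -> np.ndarray:
        return trailing_nanmean(e[::-1])[::-1]

    mse_f = trailing_nanmean(ef)
    mse_b = leading_nanmean(eb)

    wf = np.where(np.isnan(fwd) | np.isnan(mse_f), 0.0,
                  1.0 / (np.nan_to_num(mse_f) + eps) ** p)
    wb = np.where(np.isnan(bwd) | np.isnan(mse_b), 0.0,
                  1.0 / (np.nan_to_num(mse_b) + eps) ** p)
    fwd0 = np.nan_to_num(fwd)
    bwd0 = np.nan_to_num(bwd)
    wsum = wf + wb
    return np.where(wsum > 0, (wf * fwd0 + wb * bwd0) / np.maximum(wsum, eps), x)


def correct_trace(trace: Trace, cf: CorrectionFactors,
                  prefilter: bool = True, ck_window: int = 10,
                  ck_p: float = 1.0) -> ProcessedTrace:
    """Background, crosstalk and direct-excitation corrections + E computation.

    I_D' = I_D - bg_D;  I_A' = (I_A - bg_A) - lk * I_D' - dir * <I_AA - bg_A>
    (the direct-excitation term uses the trace's own mean red-segment I_AA);
    E = I_A' / (gamma * I_D' + I_A'). E series are clamped to [-0.2, 1.2]
    for reporting; frames with ~zero total intensity are flagged undefined.
    """
    tr = median_prefilter(trace) if prefilter else trace
    green = tr.green
    red = ~green
    I_D = (tr.I_D - tr.bg_D)[green]
    mean_iaa = float(np.mean((tr.I_AA - tr.bg_A)[red]))
    I_A = (tr.I_A - tr.bg_A)[green] - cf.lk * I_D - cf.dir * mean_iaa

    def efficiency(d: np.ndarray, a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        total = cf.gamma * d + a
        undef = np.abs(total) < 1e-9
        e = np.where(undef, np.nan, a / np.where(undef, 1.0, total))
        return np.clip(e, *E_CLAMP), undef

    E_raw, undef = efficiency(I_D, I_A)
    I_D_ck = chung_kennedy(I_D, window=ck_window, p=ck_p)
    I_A_ck = chung_kennedy(I_A, window=ck_window, p=ck_p)
    E_ck, undef_ck = efficiency(I_D_ck, I_A_ck)

    return ProcessedTrace(
        trace_id=trace.trace_id,
        time=trace.time[green],
        I_D=I_D, I_A=I_A, I_D_ck=I_D_ck, I_A_ck=I_A_ck,
        E_raw=E_raw, E_ck=E_ck,
        undefined=undef | undef_ck,
        metadata=dict(trace.metadata),
    )


def select_single_pair(trace: Trace, criteria: SelectionCriteria,
                       cf: CorrectionFactors | None = None) -> SelectionVerdict:
    """Accept traces consistent with one donor + one live acceptor, no bleaching.

    (i) mean background-subtracted I_AA in the red head and tail must both
    fall inside the acceptor single-dye window, and the tail signal must not
    drop below ``max_acceptor_drop`` of the head (acceptor present,
    unbleached, single); (ii) the mean corrected total green intensity in
    the first and last ``eval_seconds`` of donor excitation must fall inside
    the single-pair window (single donor, no donor bleach). Every failed
    check is recorded as a reason code.
    """
    cf = cf or CorrectionFactors(lk=0.0, dir=0.0)
    reasons: list[str] = []
    head = trace.mask(RED_HEAD)
    tail = trace.mask(RED_TAIL)
    green = trace.green

    iaa_head = float(np.mean((trace.I_AA - trace.bg_A)[head]))
    iaa_tail = float(np.mean((trace.I_AA - trace.bg_A)[tail]))
    lo, hi = criteria.acceptor_window
    if iaa_head > 0 and iaa_tail < criteria.max_acceptor_drop * iaa_head:
        reasons.append("acceptor_end_low")
    if not (lo <= iaa_head <= hi):
        reasons.append("acceptor_head_window")
    if not (lo <= iaa_tail <= hi) and "acceptor_end_low" not in reasons:
        reasons.append("acceptor_tail_window")

    I_D = trace.I_D - trace.bg_D
    mean_iaa = max(iaa_head, 0.0)
    I_A = (trace.I_A - trace.bg_A) - cf.lk * I_D - cf.dir * mean_iaa
    total = (cf.gamma * I_D + I_A)[green]
    t_green = trace.time[green]
    first = t_green <= t_green[0] + criteria.eval_seconds
    last = t_green >= t_green[-1] - criteria.eval_seconds
    lo, hi = criteria.total_window
    if not (lo <= float(np.mean(total[first])) <= hi) or \
       not (lo <= float(np.mean(total[last])) <= hi):
        reasons.append("intensity_window")

    return SelectionVerdict(accepted=not reasons, reasons=reasons)


def process_trace(trace: Trace, cf: CorrectionFactors,
                  criteria: SelectionCriteria | None = None,
                  ck_window: int = 10, ck_p: float = 1.0) -> ProcessedTrace:
    """Full per-trace pipeline: prefilter, correct, filter, select."""
    proc = correct_trace(trace, cf, prefilter=True, ck_window=ck_window,
                         ck_p=ck_p)
    if criteria is not None:
        proc.verdict = select_single_pair(trace, criteria, cf)
    return proc
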