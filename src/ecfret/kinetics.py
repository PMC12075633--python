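"""Dwell-time kinetics, survival-of-first-event analysis and dose-response fits.

Change points in an efficiency series are found by recursive binary
segmentation with a local multi-scale t statistic: the noise scale is a
step-robust block-mean estimate (median filtering and Chung-Kennedy
smoothing leave autocorrelated noise, so naive per-frame variances would
over-segment), the split score compares flanking windows so short dwells
inside long segments stay detectable, and a Bonferroni scan correction
controls the per-trace false-positive rate. Segment means are merged into
two kinetic states (associated = high E, dissociated = low E). Dwell times
between transitions are exponential for Markov kinetics; only interior
dwells (both ends observed) enter the fits, with a truncated-exponential
maximum-likelihood estimator correcting for the finite observation window
and a missed-event (dead-time) correction for dwells merged across
unresolvably short excursions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lmfit import Parameters, minimize as lm_minimize
from scipy import optimize, stats

from .simulate import ASSOCIATED, DISSOCIATED

#: default midpoint between the dissociated (0.08) and associated (0.60)
#: state efficiencies, used when a trace yields a single segment
FALLBACK_STATE_SPLIT = 0.34


# ---------------------------------------------------------------------------
# change-point detection
# ---------------------------------------------------------------------------

@dataclass
class Segment:
    start: int      # first frame (inclusive)
    stop: int       # last frame (exclusive)
    mean: float
    state: str = ""

    @property
    def n_frames(self) -> int:
        return self.stop - self.start


@dataclass
class TransitionResult:
    """Change points and two-state path of one trace."""

    change_points: np.ndarray      # frame indices where a new state begins
    states: np.ndarray             # per-frame state label
    segments: list[Segment]
    trace_id: str = ""

    @property
    def n_transitions(self) -> int:
        return len(self.change_points)


def _robust_longrun_variance(x: np.ndarray, block: int) -> tuple[float, float]:
    """Step-robust long-run variance of a (possibly autocorrelated) series.

    The variance of an n-point mean of filtered noise is ~ lrv / n. The lrv
    is estimated from the scatter of differences of adjacent block means
    (median absolute deviation, so occasional level changes do not inflate
    it): var(block mean) = (1.4826 MAD / sqrt(2))^2, lrv = block * var.
    Returns (lrv, number of blocks).
    """
    n_blocks = x.size // block
    if n_blocks < 4:
        return float(np.var(x)), max(n_blocks, 2)
    means = x[: n_blocks * block].reshape(n_blocks, block).mean(axis=1)
    d = np.diff(means)
    mad = float(np.median(np.abs(d - np.median(d))))
    var_bm = (1.4826 * mad) ** 2 / 2.0
    return block * var_bm, n_blocks


def _local_split_scores(x: np.ndarray, min_dwell: int,
                        scan_window: int) -> tuple[np.ndarray, np.ndarray, int]:
    """Standardized local mean-change score at every candidate split.

    For a split between frames k-1 and k the score compares the means of
    flanking windows on either side, over a geometric ladder of window sizes
    from ``min_dwell`` up to ``scan_window`` (the per-candidate score is the
    maximum over scales). Local multi-scale windows keep short dwells
    detectable inside long segments, where a global two-half statistic
    dilutes them away. Returns (candidate indices, scores, number of
    scales); scores are |delta mean| / sqrt(1/n_left + 1/n_right), the noise
    scale is applied by the caller.
    """
    m = x.size
    cs = np.concatenate([[0.0], np.cumsum(x)])
    ks = np.arange(min_dwell, m - min_dwell + 1)
    scales = []
    w = max(min_dwell, 2)
    while w < scan_window:
        scales.append(w)
        w *= 2
    scales.append(scan_window)
    best = np.zeros(ks.size)
    for w in scales:
        n1 = np.minimum(ks, w)
        n2 = np.minimum(m - ks, w)
        mean_l = (cs[ks] - cs[ks - n1]) / n1
        mean_r = (cs[ks + n2] - cs[ks]) / n2
        score = np.abs(mean_r - mean_l) / np.sqrt(1.0 / n1 + 1.0 / n2)
        best = np.maximum(best, score)
    return ks, best, len(scales)


def _split_pvalue(score: float, n_candidates: int, lrv: float,
                  n_blocks: int) -> float:
    """Scan-corrected (Bonferroni) two-sided p-value for the best local score."""
    if lrv < 1e-18:
        return 0.0 if score > 1e-9 else 1.0
    t = score / np.sqrt(lrv)
    df = max(n_blocks - 2.0, 2.0)
    p = float(2.0 * stats.t.sf(abs(t), df))
    return min(1.0, p * max(n_candidates, 1))


def detect_transitions(e_series: np.ndarray, alpha: float = 0.001,
                       min_dwell: int = 3, noise_block: int = 10,
                       scan_window: int = 20, state_gap: float = 0.15,
                       fallback_split: float = FALLBACK_STATE_SPLIT,
                       trace_id: str = "") -> TransitionResult:
    """Recursive binary segmentation of an efficiency series into two states.

    At each segment the split maximizing a local two-window t statistic
    (up to ``scan_window`` frames on either side of the candidate point) is
    accepted if its autocorrelation-robust, scan-corrected p-value is below
    ``alpha`` and both halves span at least ``min_dwell`` frames. The noise
    scale is estimated once per trace from block-mean differences
    (``noise_block`` frames) with a median absolute deviation, so it is
    robust both to filter-induced autocorrelation and to the level changes
    being detected. Segment means are then clustered into two states (1-D
    2-means, threshold at the midpoint of the cluster centers); clusterings
    whose centers differ by less than ``state_gap`` are collapsed to a
    single state, and adjacent same-state segments are merged.
    Deterministic.
    """
    x = np.asarray(e_series, float)
    x = np.where(np.isfinite(x), x, np.nanmedian(x))
    n = x.size
    if n < 2 * min_dwell:
        raise ValueError("series shorter than twice the minimum dwell")

    lrv, n_blocks = _robust_longrun_variance(x, noise_block)
    breakpoints: list[int] = []

    def best_split(lo: int, hi: int) -> tuple[int, float] | None:
        seg = x[lo:hi]
        if seg.size < 2 * min_dwell:
            return None
        ks, scores, n_scales = _local_split_scores(seg, min_dwell, scan_window)
        i = int(np.argmax(scores))
        return int(ks[i]), _split_pvalue(float(scores[i]), ks.size * n_scales,
                                         lrv, n_blocks)

    def recurse(lo: int, hi: int) -> None:
        res = best_split(lo, hi)
        if res is None:
            return
        k, p = res
        if p >= alpha:
            return
        breakpoints.append(lo + k)
        recurse(lo, lo + k)
        recurse(lo + k, hi)

    recurse(0, n)
    bps = sorted(breakpoints)
    edges = [0] + bps + [n]
    segments = [Segment(a, b, float(x[a:b].mean())) for a, b in
                zip(edges[:-1], edges[1:])]

    # two-state merge
    if len(segments) == 1:
        segments[0].state = (ASSOCIATED if segments[0].mean > fallback_split
                             else DISSOCIATED)
    else:
        means = np.array([s.mean for s in segments])
        weights = np.array([s.n_frames for s in segments], float)
        c_lo, c_hi = means.min(), means.max()
        for _ in range(50):  # weighted 1-D 2-means
            assign = np.abs(means - c_lo) <= np.abs(means - c_hi)
            if assign.all() or (~assign).all():
                break
            new_lo = np.average(means[assign], weights=weights[assign])
            new_hi = np.average(means[~assign], weights=weights[~assign])
            if np.isclose(new_lo, c_lo) and np.isclose(new_hi, c_hi):
                c_lo, c_hi = new_lo, new_hi
                break
            c_lo, c_hi = new_lo, new_hi
        if c_hi - c_lo < state_gap:
            # amplitude too small for a two-state interpretation
            overall = float(np.average(means, weights=weights))
            state = ASSOCIATED if overall > fallback_split else DISSOCIATED
            segments = [Segment(0, n, overall, state)]
        else:
            midpoint = 0.5 * (c_lo + c_hi)
            for s in segments:
                s.state = ASSOCIATED if s.mean > midpoint else DISSOCIATED
            # merge adjacent same-state segments
            merged = [segments[0]]
            for s in segments[1:]:
                last = merged[-1]
                if s.state == last.state:
                    w = last.n_frames + s.n_frames
                    last.mean = (last.mean * last.n_frames
                                 + s.mean * s.n_frames) / w
                    last.stop = s.stop
                else:
                    merged.append(s)
            segments = merged

    states = np.empty(n, object)
    for s in segments:
        states[s.start:s.stop] = s.state
    cps = np.array([s.start for s in segments[1:]], int)
    return TransitionResult(cps, states, segments, trace_id=trace_id)


# ---------------------------------------------------------------------------
# dwell harvesting
# ---------------------------------------------------------------------------

@dataclass
class DwellSet:
    """State-resolved dwell durations with censoring flags.

    ``censoring`` is 'complete' for interior dwells (both bounding
    transitions observed), 'first'/'last' for the leading and trailing
    dwells of each trace, which are censored and excluded from rate fits.
    ``start`` is the dwell start time relative to the observation window,
    used for per-dwell right-truncation bounds in the fits.
    """

    durations: np.ndarray
    states: np.ndarray
    censoring: np.ndarray
    starts: np.ndarray
    trace_ids: np.ndarray
    window: float               # observation window length (s)
    frame_time: float

    def complete(self, state: str) -> tuple[np.ndarray, np.ndarray]:
        """(durations, start times) of interior dwells in the given state."""
        m = (self.states == state) & (self.censoring == "complete")
        return self.durations[m], self.starts[m]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"trace_id": self.trace_ids, "state": self.states,
                             "duration_s": self.durations,
                             "start_s": self.starts,
                             "censoring": self.censoring})


def harvest_dwells(results: list[TransitionResult], frame_time: float,
                   ) -> DwellSet:
    """Collect dwells from per-trace state sequences; flag first/last censored.

    A trace with fewer than two transitions contributes zero complete dwells
    (its only dwells touch the window edges and have unknown duration).
    """
    durations, states, cens, starts, ids = [], [], [], [], []
    window = 0.0
    for res in results:
        n = len(res.states)
        window = max(window, n * frame_time)
        segs = res.segments
        for i, s in enumerate(segs):
            durations.append(s.n_frames * frame_time)
            states.append(s.state)
            starts.append(s.start * frame_time)
            ids.append(res.trace_id)
            if i == 0:
                cens.append("first")
            elif i == len(segs) - 1:
                cens.append("last")
            else:
                cens.append("complete")
    return DwellSet(np.array(durations), np.array(states, object),
                    np.array(cens, object), np.array(starts),
                    np.array(ids, object), window=window,
                    frame_time=frame_time)


# ---------------------------------------------------------------------------
# exponential dwell fits
# ---------------------------------------------------------------------------

@dataclass
class ExpFit:
    """One-phase exponential fit of a dwell population."""

    tau: float                 # mean dwell (s)
    rate: float                # 1/tau (s^-1)
    se_rate: float
    ci_tau: tuple[float, float]
    n: int
    method: str
    amplitude: float = np.nan  # histogram fits only
    flags: list[str] = field(default_factory=list)


def _truncated_mle(t: np.ndarray, a: float, b: np.ndarray) -> tuple[float, float]:
    """MLE rate of an exponential left-truncated at a, right-truncated at b_i."""

    def score(k: float) -> float:
        ea, eb = np.exp(-k * a), np.exp(-k * b)
        # b may be +inf (no right truncation): b * exp(-k b) -> 0
        beb = np.zeros_like(eb)
        fin = ~np.isinf(b)
        beb[fin] = b[fin] * eb[fin]
        corr = (-a * ea + beb) / np.maximum(ea - eb, 1e-300)
        return float(np.sum(1.0 / k - t - corr))

    lo, hi = 1e-4, 50.0
    if score(lo) < 0:       # even the smallest rate overshoots
        k_hat = lo
    elif score(hi) > 0:
        k_hat = hi
    else:
        k_hat = optimize.brentq(score, lo, hi, xtol=1e-10)
    # observed information via numeric derivative of the score
    h = max(1e-6, 1e-4 * k_hat)
    info = -(score(k_hat + h) - score(k_hat - h)) / (2 * h)
    se = 1.0 / np.sqrt(info) if info > 0 else float("nan")
    return k_hat, se


def fit_exponential_dwells(durations: np.ndarray, method: str = "mle",
                           min_dwell_s: float = 0.6,
                           window_s: float | None = None,
                           starts: np.ndarray | None = None,
                           min_n: int = 20) -> ExpFit:
    """Exponential fit of interior dwell durations.

    ``mle`` (default): truncated-exponential maximum likelihood with left
    truncation at the detection limit ``min_dwell_s`` and per-dwell right
    truncation at the time remaining in the observation window after the
    dwell starts (``window_s - starts``; falls back to ``window_s``).
    ``lsq``: least-squares fit of A exp(-t/tau) to the dwell histogram, the
    convention of classical trace-analysis software (biased low near the
    window length). ``naive``: plain sample mean, for comparison only.
    """
    t = np.asarray(durations, float)
    if t.size < min_n:
        raise ValueError(f"need at least {min_n} complete dwells, got {t.size}")
    flags = []
    if t.std() < 0.1 * t.mean():
        flags.append("non-exponential")

    if method == "naive":
        tau = float(t.mean())
        se_tau = tau / np.sqrt(t.size)
        rate = 1.0 / tau
        se_rate = se_tau * rate ** 2
    elif method == "mle":
        a = float(min_dwell_s)
        if window_s is None:
            b = np.full(t.size, np.inf)
        elif starts is not None:
            b = np.maximum(window_s - np.asarray(starts, float), t + 1e-9)
        else:
            b = np.full(t.size, float(window_s))
        rate, se_rate = _truncated_mle(t, a, b)
        tau = 1.0 / rate
    elif method == "lsq":
        edges = np.arange(0.0, t.max() + 2.0, max(t.max() / 25.0, 1e-3))
        counts, edges = np.histogram(t, bins=edges)
        centers = 0.5 * (edges[:-1] + edges[1:])
        keep = counts > 0
        popt, pcov = optimize.curve_fit(
            lambda x, A, tau: A * np.exp(-x / tau), centers[keep],
            counts[keep], p0=[counts.max(), t.mean()],
            bounds=([0, 1e-6], [np.inf, np.inf]), maxfev=10_000)
        A, tau = popt
        se_tau = float(np.sqrt(pcov[1, 1]))
        rate = 1.0 / tau
        se_rate = se_tau * rate ** 2
        fit = ExpFit(float(tau), float(rate), float(se_rate),
                     (tau - 1.96 * se_tau, tau + 1.96 * se_tau), t.size,
                     "lsq", amplitude=float(A), flags=flags)
        return fit
    else:
        raise ValueError(f"unknown method {method!r}")

    se_tau = se_rate / rate ** 2 if rate > 0 else float("nan")
    return ExpFit(float(tau), float(rate), float(se_rate),
                  (float(tau - 1.96 * se_tau), float(tau + 1.96 * se_tau)),
                  t.size, method, flags=flags)


def fit_dwellset(dwells: DwellSet, state: str, method: str = "mle",
                 min_n: int = 20) -> ExpFit:
    """Truncation-aware exponential fit of one state's interior dwells."""
    t, starts = dwells.complete(state)
    return fit_exponential_dwells(
        t, method=method, min_dwell_s=3 * dwells.frame_time,
        window_s=dwells.window, starts=starts, min_n=min_n)


def fit_two_state_rates(dwells: DwellSet, min_resolved_frames: int = 10,
                        dead_time_frames: int = 5, min_n: int = 20
                        ) -> tuple[ExpFit, ExpFit]:
    """Dead-time-corrected exponential rates of both states.

    Two detector artefacts bias per-state fits: (i) detection of a dwell is
    only reliable above ~``min_resolved_frames`` (the median prefilter and
    frame averaging suppress shorter events), so shorter dwells are
    discarded and the likelihood is left-truncated there; (ii) a dwell of
    the opposite state short enough to escape detection merges its two
    neighbours into one long observed dwell. A geometric sum of exponential
    dwells is again exponential with rate k * q, q = exp(-k_other * d), so
    the merge bias is removed by jointly solving
    k_assoc = k_assoc_obs * exp(k_diss * d) (and vice versa) with an
    effective dead time d of ``dead_time_frames`` frames. Returns
    (associated-state fit, dissociated-state fit) with corrected rates.
    """
    a = min_resolved_frames * dwells.frame_time
    d = dead_time_frames * dwells.frame_time
    fits = {}
    for state in (ASSOCIATED, DISSOCIATED):
        t, starts = dwells.complete(state)
        keep = t >= a
        fits[state] = fit_exponential_dwells(
            t[keep], min_dwell_s=a, window_s=dwells.window,
            starts=starts[keep], min_n=min_n)
    k_a, k_b = fits[ASSOCIATED].rate, fits[DISSOCIATED].rate
    for _ in range(100):
        k_a2 = fits[ASSOCIATED].rate * np.exp(min(k_b * d, 0.5))
        k_b2 = fits[DISSOCIATED].rate * np.exp(min(k_a * d, 0.5))
        if abs(k_a2 - k_a) < 1e-12 and abs(k_b2 - k_b) < 1e-12:
            break
        k_a, k_b = k_a2, k_b2
    out = []
    for state, k in ((ASSOCIATED, k_a), (DISSOCIATED, k_b)):
        f = fits[state]
        scale = k / f.rate
        tau = 1.0 / k
        se_rate = f.se_rate * scale
        se_tau = se_rate / k ** 2
        out.append(ExpFit(tau, k, se_rate,
                          (tau - 1.96 * se_tau, tau + 1.96 * se_tau),
                          f.n, "mle_deadtime", flags=list(f.flags)))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# survival of the first event
# ---------------------------------------------------------------------------

@dataclass
class FirstEventCurve:
    """Fraction of traces without a first transition vs time since activation."""

    times: np.ndarray          # s, event times (sorted)
    survival: np.ndarray       # fraction without event, starts at 1
    half_life: float           # ln 2 / rate (s)
    rate: float
    se_rate: float
    n_events: int
    n_censored: int

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        """Empirical survival S(t); S(0) = 1, non-increasing."""
        t = np.asarray(t, float)
        idx = np.searchsorted(self.times, t, side="right")
        return self.survival[idx]


def first_event_analysis(event_times: list[float | None],
                         window: float) -> FirstEventCurve:
    """Time-to-first-transition survival analysis after activation.

    ``event_times`` holds, per trace, the time from activation to the first
    high-to-low transition, or None when no event occurred inside the
    recording (right-censored at ``window``). The exponential decay rate is
    the censored MLE n_events / (sum of event times + censored exposure).
    """
    events = np.sort(np.array([t for t in event_times if t is not None], float))
    n_cens = sum(1 for t in event_times if t is None)
    n_total = events.size + n_cens
    if n_total == 0:
        raise ValueError("no traces supplied")
    # survival curve: S just after each event time; prepend S(0-) = 1
    surv = 1.0 - np.arange(1, events.size + 1) / n_total
    surv = np.concatenate([[1.0], surv])
    if events.size == 0:
        return FirstEventCurve(events, surv, float("nan"), float("nan"),
                               float("nan"), 0, n_cens)
    exposure = events.sum() + n_cens * window
    rate = events.size / exposure
    se_rate = rate / np.sqrt(events.size)
    return FirstEventCurve(events, surv, float(np.log(2) / rate), float(rate),
                           float(se_rate), int(events.size), int(n_cens))


def first_dissociation_time(result: TransitionResult, frame_time: float,
                            t0: float = 0.0) -> float | None:
    """Time from t0 to the first associated -> dissociated transition, or None."""
    for cp in result.change_points:
        if result.states[cp] == DISSOCIATED and result.states[cp - 1] == ASSOCIATED:
            t = cp * frame_time
            if t >= t0:
                return t - t0
    return None


def compare_decay_rates(fit_a, fit_b) -> tuple[float, float]:
    """Two-tailed unpaired t test on two fitted rates with Welch df.

    Accepts :class:`ExpFit` / :class:`FirstEventCurve` objects or
    (rate, se_rate, n) tuples. Returns (t statistic, p value).
    """

    def unpack(f):
        if isinstance(f, tuple):
            return float(f[0]), float(f[1]), int(f[2])
        n = getattr(f, "n", None) or getattr(f, "n_events", None)
        return float(f.rate), float(f.se_rate), int(n)

    r1, se1, n1 = unpack(fit_a)
    r2, se2, n2 = unpack(fit_b)
    if not (np.isfinite(se1) and np.isfinite(se2)) or se1 <= 0 or se2 <= 0:
        raise ValueError("both fits must carry finite standard errors")
    t = (r1 - r2) / np.hypot(se1, se2)
    df = (se1 ** 2 + se2 ** 2) ** 2 / (se1 ** 4 / (n1 - 1) + se2 ** 4 / (n2 - 1))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return float(t), p


# ---------------------------------------------------------------------------
# dose-response
# ---------------------------------------------------------------------------

@dataclass
class DoseResponseFit:
    ec50: float
    floor: float
    ceiling: float
    readout: str
    ci_ec50: tuple[float, float]
    flags: list[str] = field(default_factory=list)
    ec50_stderr: float = np.nan


def _hyperbola(x, floor, ceiling, ec50):
    return floor + (ceiling - floor) * x / (ec50 + x)


def fit_ec50(doses: np.ndarray, response: np.ndarray,
             readout: str = "dynamic_fraction",
             ci_level: float = 0.95) -> DoseResponseFit:
    """Least-squares single-site hyperbola fit with profile-likelihood EC50 CI.

    y = floor + (ceiling - floor) * x / (EC50 + x); Hill coefficient fixed
    at 1. Doses must include 0 (or near-0) and a near-saturating level.
    Constant responses are returned with a 'no_dose_dependence' flag and an
    unbounded CI rather than an exception.
    """
    x = np.asarray(doses, float)
    y = np.asarray(response, float)
    if x.size < 4:
        raise ValueError("need at least 4 dose levels")

    span = y.max() - y.min()
    resid_scale = np.std(np.diff(np.sort(y))) if y.size > 2 else 0.0
    if span < 1e-12 or span < 2.0 * resid_scale / np.sqrt(2):
        return DoseResponseFit(float("nan"), float(y.mean()), float(y.mean()),
                               readout, (0.0, float("inf")),
                               flags=["no_dose_dependence"])

    params = Parameters()
    params.add("floor", value=float(y[np.argmin(x)]))
    params.add("ceiling", value=float(y[np.argmax(x)]))
    half = y.min() + 0.5 * span
    x_pos = x[x > 0]
    ec50_init = float(np.interp(half, np.sort(y), x[np.argsort(y)])) \
        if np.all(np.diff(y[np.argsort(x)]) >= 0) else float(np.median(x_pos))
    params.add("ec50", value=max(ec50_init, x_pos.min() * 0.1), min=1e-12)

    def resid(p):
        return _hyperbola(x, p["floor"], p["ceiling"], p["ec50"]) - y

    out = lm_minimize(resid, params)
    pf = out.params
    ec50 = float(pf["ec50"].value)
    flags = []
    rho, _ = stats.spearmanr(x, y)
    if np.isfinite(rho) and rho < 0 and pf["ceiling"].value > pf["floor"].value:
        flags.append("non_monotone")

    # profile likelihood CI on EC50
    chi2_best = float(np.sum(out.residual ** 2))
    target = chi2_best * (1 + stats.chi2.ppf(ci_level, 1)
                          / max(x.size - 3, 1))

    def profile_chi2(log_ec50: float) -> float:
        pp = Parameters()
        pp.add("floor", value=pf["floor"].value)
        pp.add("ceiling", value=pf["ceiling"].value)
        e = np.exp(log_ec50)
        r = lm_minimize(lambda q: _hyperbola(x, q["floor"], q["ceiling"], e) - y,
                        pp)
        return float(np.sum(r.residual ** 2))

    lo_bound, hi_bound = float("nan"), float("nan")
    try:
        lo_bound = np.exp(optimize.brentq(
            lambda l: profile_chi2(l) - target,
            np.log(ec50) - 8, np.log(ec50), xtol=1e-6))
    except ValueError:
        lo_bound = 0.0
    try:
        hi_bound = np.exp(optimize.brentq(
            lambda l: profile_chi2(l) - target,
            np.log(ec50), np.log(ec50) + 8, xtol=1e-6))
    except ValueError:
        hi_bound = float("inf")

    stderr = pf["ec50"].stderr if pf["ec50"].stderr is not None else np.nan
    return DoseResponseFit(ec50, float(pf["floor"].value),
                           float(pf["ceiling"].value), readout,
                           (float(lo_bound), float(hi_bound)), flags=flags,
                           ec50_stderr=float(stderr))


# ---------------------------------------------------------------------------
# between-condition statistics
# ---------------------------------------------------------------------------

@dataclass
class WelchAnovaResult:
    F: float
    df1: float
    df2: float
    p_omnibus: float           # right-tailed
    pairwise: pd.DataFrame     # two-tailed studentized-range p values


def welch_anova_tukey(groups: list[tuple[float, float, int]],
                      labels: list[str] | None = None,
                      pairwise: bool = True) -> WelchAnovaResult:
    """Welch's ANOVA + Tukey-HSD pairwise comparisons from group summaries.

    ``groups`` is a list of (mean, sd, n) per condition. The omnibus test is
    Welch's heteroscedastic F (right-tailed); pairwise comparisons use the
    studentized range on Welch-style per-pair error terms and degrees of
    freedom (Games-Howell form), two-tailed.
    """
    k = len(groups)
    if k < 2:
        raise ValueError("need at least 2 groups")
    means = np.array([g[0] for g in groups], float)
    sds = np.array([g[1] for g in groups], float)
    ns = np.array([g[2] for g in groups], float)
    if np.any(ns < 2):
        raise ValueError("every group needs n >= 2")
    if np.any(sds <= 0):
        raise ValueError("zero within-group variance")
    labels = labels or [f"g{i}" for i in range(k)]

    w = ns / sds ** 2
    W = w.sum()
    mbar = float(np.sum(w * means) / W)
    A = float(np.sum(w * (means - mbar) ** 2) / (k - 1))
    h = float(np.sum((1 - w / W) ** 2 / (ns - 1)))
    B = 1.0 + 2.0 * (k - 2) / (k ** 2 - 1) * h
    F = A / B
    df1 = k - 1
    df2 = (k ** 2 - 1) / (3.0 * h) if h > 0 else float("inf")
    p_omni = float(stats.f.sf(F, df1, df2))

    rows = []
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)] if pairwise \
        else []
    for i, j in pairs:
        se2 = sds[i] ** 2 / ns[i] + sds[j] ** 2 / ns[j]
        q = abs(means[i] - means[j]) / np.sqrt(se2 / 2.0)
        df = se2 ** 2 / ((sds[i] ** 2 / ns[i]) ** 2 / (ns[i] - 1)
                         + (sds[j] ** 2 / ns[j]) ** 2 / (ns[j] - 1))
        p = float(stats.studentized_range.sf(q, k, df))
        rows.append({"group_a": labels[i], "group_b": labels[j],
                     "q": float(q), "df": float(df), "p": p})
    return WelchAnovaResult(float(F), float(df1), float(df2), p_omni,
                            pd.DataFrame(rows))
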