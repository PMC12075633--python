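"""Confocal PIE/ALEX burst analysis of freely diffusing molecules.

Single molecules crossing the confocal volume produce photon bursts; an
all-photon sliding-window search flags photons whose local rate exceeds a
multiple of the background rate. Per burst, donor-excitation photon counts
in the two detectors give the FRET efficiency E and the acceptor-excitation
counts give the stoichiometry S, which separates doubly-labeled molecules
(intermediate S) from donor-only (S ~ 1) and acceptor-only (S ~ 0) species.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import DET_ACCEPTOR, DET_DONOR, EXC_ACCEPTOR, EXC_DONOR, PhotonStream
from .tracepipe import CorrectionFactors

STREAMS = ("dd", "da", "aa", "all")


def _stream_mask(stream: PhotonStream, key: str) -> np.ndarray:
    if key == "dd":
        return (stream.detector == DET_DONOR) & (stream.excitation == EXC_DONOR)
    if key == "da":
        return (stream.detector == DET_ACCEPTOR) & (stream.excitation == EXC_DONOR)
    if key == "aa":
        return (stream.detector == DET_ACCEPTOR) & (stream.excitation == EXC_ACCEPTOR)
    if key == "all":
        return np.ones(stream.n_photons, bool)
    raise KeyError(key)


@dataclass
class BackgroundEstimate:
    """Per-window, per-stream background rates (Hz)."""

    window: float
    edges: np.ndarray                       # window edges (s)
    rates: dict                             # stream key -> per-window rates
    flags: dict                             # stream key -> carry-forward flags

    def rate_at(self, t: np.ndarray, stream: str = "all") -> np.ndarray:
        idx = np.clip(np.searchsorted(self.edges, t, side="right") - 1, 0,
                      len(self.rates[stream]) - 1)
        return self.rates[stream][idx]


def _delay_tail_rate(delays: np.ndarray) -> float:
    """Background rate from the exponential tail of inter-photon delays.

    Burst photons produce a spike of short delays; delays longer than the
    mean delay are background-dominated. For an exponential, the mean excess
    over a threshold equals 1/rate (memorylessness), so
    rate = 1 / (mean(tail) - threshold).
    """
    if delays.size < 3:
        return float("nan")
    thresh = float(delays.mean())
    tail = delays[delays > thresh]
    if tail.size < 2:
        return float("nan")
    return 1.0 / (float(tail.mean()) - thresh)


def estimate_background(stream: PhotonStream, window: float = 30.0,
                        min_photons: int = 50) -> BackgroundEstimate:
    """Background rate per 30 s window from exponential delay-tail fits.

    Windows with fewer than ``min_photons`` photons carry the previous
    window's rate forward with a flag.
    """
    if stream.duration < window:
        raise ValueError("stream shorter than one background window")
    n_win = int(np.ceil(stream.duration / window))
    edges = np.arange(n_win + 1) * window
    rates: dict[str, np.ndarray] = {}
    flags: dict[str, np.ndarray] = {}
    for key in STREAMS:
        ts = stream.timestamps[_stream_mask(stream, key)]
        r = np.full(n_win, np.nan)
        fl = np.zeros(n_win, bool)
        for i in range(n_win):
            sel = ts[(ts >= edges[i]) & (ts < edges[i + 1])]
            if sel.size >= min_photons:
                est = _delay_tail_rate(np.diff(sel))
                if np.isfinite(est):
                    r[i] = est
                    continue
            fl[i] = True
            r[i] = r[i - 1] if i > 0 else np.nan
        # leading empty windows take the first defined rate
        if np.isnan(r).any() and np.isfinite(r).any():
            first = np.flatnonzero(np.isfinite(r))[0]
            r[:first] = r[first]
        rates[key] = r
        flags[key] = fl
    return BackgroundEstimate(window, edges, rates, flags)


@dataclass
class Burst:
    start: float
    stop: float
    n_dd: int                 # donor detector, donor excitation
    n_da: int                 # acceptor detector, donor excitation
    n_aa: int                 # acceptor detector, acceptor excitation
    E: float = np.nan         # corrected FRET efficiency
    S: float = np.nan         # corrected stoichiometry

    @property
    def size(self) -> int:
        return self.n_dd + self.n_da + self.n_aa


def burst_search(stream: PhotonStream, bg: BackgroundEstimate, m: int = 10,
                 F: float = 6.0) -> list[Burst]:
    """All-photon sliding-window burst search (rate over m consecutive photons).

    A photon is in-burst when the local rate of the m-photon window starting
    at it, (m-1)/(t[i+m-1]-t[i]), exceeds F times the local all-photon
    background rate; maximal runs of in-burst photons form bursts.
    Deterministic for fixed inputs.
    """
    ts = stream.timestamps
    n = ts.size
    if n < m:
        return []
    span = ts[m - 1:] - ts[: n - m + 1]
    local_rate = (m - 1) / np.maximum(span, 1e-12)
    bg_rate = bg.rate_at(ts[: n - m + 1], "all")
    hot = local_rate > F * bg_rate
    in_burst = np.zeros(n, bool)
    for i in np.flatnonzero(hot):
        in_burst[i:i + m] = True

    bursts: list[Burst] = []
    if not in_burst.any():
        return bursts
    d = np.diff(in_burst.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    stops = np.flatnonzero(d == -1) + 1
    if in_burst[0]:
        starts = np.concatenate([[0], starts])
    if in_burst[-1]:
        stops = np.concatenate([stops, [n]])
    det, exc = stream.detector, stream.excitation
    for a, b in zip(starts, stops):
        dd = int(np.sum((det[a:b] == DET_DONOR) & (exc[a:b] == EXC_DONOR)))
        da = int(np.sum((det[a:b] == DET_ACCEPTOR) & (exc[a:b] == EXC_DONOR)))
        aa = int(np.sum((det[a:b] == DET_ACCEPTOR) & (exc[a:b] == EXC_ACCEPTOR)))
        bursts.append(Burst(float(ts[a]), float(ts[b - 1]), dd, da, aa))
    return bursts


def estimate_corrections_from_bursts(bursts: list[Burst],
                                     s_donor_only: float = 0.9,
                                     s_acceptor_only: float = 0.1,
                                     min_photons: int = 40
                                     ) -> CorrectionFactors:
    """Leakage and direct-excitation factors from single-dye burst populations.

    Uses the uncorrected stoichiometry to isolate donor-only (S > 0.9) and
    acceptor-only (S < 0.1) bursts of the same acquisition: leakage is the
    median n_DA/n_DD of donor-only bursts, direct excitation the median
    n_DA/n_AA of acceptor-only bursts (standard ALEX correction scheme).
    """
    big = [b for b in bursts if b.size >= min_photons]
    lks, dirs = [], []
    for b in big:
        s_raw = (b.n_dd + b.n_da) / b.size if b.size else np.nan
        if s_raw > s_donor_only and b.n_dd > 0:
            lks.append(b.n_da / b.n_dd)
        elif s_raw < s_acceptor_only and b.n_aa > 0:
            dirs.append(b.n_da / b.n_aa)
    if not lks or not dirs:
        raise ValueError("need donor-only and acceptor-only burst populations")
    return CorrectionFactors(lk=float(np.median(lks)), dir=float(np.median(dirs)))


@dataclass
class BurstHistogram:
    bin_edges: np.ndarray
    frequency: np.ndarray      # normalized to sum 1 (empty selection: zeros)
    n_bursts: int
    bursts: list[Burst] = field(default_factory=list)

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def mode(self) -> float:
        return float(self.centers[np.argmax(self.frequency)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bin_left": self.bin_edges[:-1],
                             "frequency": self.frequency})


def es_select_and_histogram(bursts: list[Burst], cf: CorrectionFactors,
                            min_photons: int = 40,
                            s_range: tuple[float, float] = (0.25, 0.85),
                            bin_width: float = 0.04,
                            e_range: tuple[float, float] = (-0.2, 1.2)
                            ) -> BurstHistogram:
    """Corrected E-S selection and normalized FRET-efficiency histogram.

    E = (n_DA - lk n_DD - dir n_AA) / (n_DA - lk n_DD - dir n_AA + n_DD);
    S = (n_DD + n_DA') / (n_DD + n_DA' + n_AA) with the same corrected
    acceptor counts. Bursts below ``min_photons`` total photons (acceptor
    excitation included) or outside the stoichiometry range are dropped.
    """
    selected = []
    for b in bursts:
        if b.size < min_photons:
            continue
        f_da = b.n_da - cf.lk * b.n_dd - cf.dir * b.n_aa
        denom_e = f_da + cf.gamma * b.n_dd
        denom_s = f_da + cf.gamma * b.n_dd + b.n_aa
        if denom_e <= 0 or denom_s <= 0:
            continue
        b.E = float(f_da / denom_e)
        b.S = float((f_da + cf.gamma * b.n_dd) / denom_s)
        if s_range[0] <= b.S <= s_range[1]:
            selected.append(b)

    n_bins = int(round((e_range[1] - e_range[0]) / bin_width))
    edges = np.round(e_range[0] + bin_width * np.arange(n_bins + 1), 10)
    if not selected:
        return BurstHistogram(edges, np.zeros(n_bins), 0, [])
    e_vals = np.clip([b.E for b in selected], e_range[0], e_range[1] - 1e-9)
    counts, _ = np.histogram(e_vals, bins=edges)
    return BurstHistogram(edges, counts / counts.sum(), len(selected), selected)


def burst_table(bursts: list[Burst]) -> pd.DataFrame:
    return pd.DataFrame([{
        "start_s": b.start, "stop_s": b.stop, "n_dd": b.n_dd, "n_da": b.n_da,
        "n_aa": b.n_aa, "E": b.E, "S": b.S,
    } for b in bursts])
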