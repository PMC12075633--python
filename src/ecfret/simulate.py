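"""Forward simulator of the single-molecule FRET experiment.

Models a modular membrane transporter whose substrate-binding subunit
associates with (high FRET, E ~ 0.60) and dissociates from (low FRET,
E ~ 0.08) its ATPase module as a two-state continuous-time Markov chain.
Dissociation is ATP-driven through a single-site rectangular hyperbola
``k_diss(ATP) = k_diss_max * [ATP] / (K_atp + [ATP])``; association is
ATP-independent. On top of the hidden state path the simulator layers the
photophysics of a two-channel TIRF recording with alternating-laser
excitation (ALEX): donor/acceptor crosstalk, direct acceptor excitation,
single-step photobleaching, constant-mean background and Gaussian camera
noise, plus the experimental population structure (membrane-orientation
"responsive" fraction, inactive complexes, donor-only and acceptor-only
spots).

All public entry points take an explicit seed or ``numpy.random.Generator``;
there is no module-level random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .traces import GREEN, RED_HEAD, RED_TAIL, Trace, alex_segments

ASSOCIATED = "associated"
DISSOCIATED = "dissociated"

SPOT_PAIR = "pair"
SPOT_DONOR_ONLY = "donor_only"
SPOT_ACCEPTOR_ONLY = "acceptor_only"

# photon-stream codes
DET_DONOR = 0
DET_ACCEPTOR = 1
EXC_DONOR = 0
EXC_ACCEPTOR = 1


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class KineticScenario:
    """Generative parameters of the two-state switching + photophysics model.

    Rates are s^-1, concentrations are uM, intensities are camera counts per
    frame. Defaults are the study conditions: saturating Mg-ATP drives
    dissociation at ``k_diss_max`` = 0.125 s^-1 (8 s mean associated dwell),
    re-association at ``k_assoc`` = 0.05 s^-1 (20 s mean dissociated dwell),
    half-saturation at 380 uM ATP, and a 5 s / 90 s / 5 s red-green-red ALEX
    movie layout at 200 ms frames.
    """

    k_assoc: float = 0.05          # association rate from the dissociated state
    k_diss_max: float = 0.125      # maximal ATP-driven dissociation rate
    K_atp: float = 380.0           # half-saturation ATP concentration (uM)
    atp: float = 10_000.0          # ATP concentration (uM); study default 10 mM
    E_assoc: float = 0.60
    E_diss: float = 0.08
    frac_responsive: float = 0.5   # orientation: fraction that can see external ATP
    frac_inactive: float = 0.2     # complexes that never switch
    frac_donor_only: float = 0.1
    frac_acceptor_only: float = 0.1
    total_intensity: float = 500.0  # mean total counts per frame
    noise_sd: float = 50.0          # additive Gaussian noise per channel
    leakage: float = 0.10           # donor -> acceptor channel crosstalk
    direct_exc: float = 0.05        # acceptor direct excitation under donor laser
    bleach_rate_d: float = 0.0      # per-second photobleaching rates
    bleach_rate_a: float = 0.0
    bg_D_mean: float = 50.0
    bg_A_mean: float = 50.0
    bg_drift: float = 0.0           # counts/s linear background drift (off by default)
    frame_time: float = 0.2         # s
    n_frames_red_head: int = 25
    n_frames_green: int = 450
    n_frames_red_tail: int = 25
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("k_assoc", "k_diss_max", "bleach_rate_d", "bleach_rate_a",
                     "leakage", "direct_exc", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("E_assoc", "E_diss"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("frac_responsive", "frac_inactive",
                     "frac_donor_only", "frac_acceptor_only"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.frac_donor_only + self.frac_acceptor_only > 1.0:
            raise ValueError("frac_donor_only + frac_acceptor_only must be <= 1")
        if min(self.n_frames_red_head, self.n_frames_green,
               self.n_frames_red_tail) <= 0:
            raise ValueError("frame counts must be positive")
        if self.atp < 0 or self.K_atp < 0:
            raise ValueError("concentrations must be >= 0")

    @property
    def k_diss(self) -> float:
        """Effective dissociation rate at this scenario's ATP concentration."""
        if self.atp == 0.0:
            return 0.0
        if self.K_atp == 0.0:
            return self.k_diss_max
        return self.k_diss_max * self.atp / (self.K_atp + self.atp)

    @property
    def n_frames(self) -> int:
        return (self.n_frames_red_head + self.n_frames_green
                + self.n_frames_red_tail)

    @property
    def duration(self) -> float:
        return self.n_frames * self.frame_time

    @property
    def green_window(self) -> tuple[float, float]:
        """(start, end) time in s of the donor-excitation segment."""
        t0 = self.n_frames_red_head * self.frame_time
        return t0, t0 + self.n_frames_green * self.frame_time


@dataclass
class GroundTruth:
    """Hidden truth of one simulated molecule (simulation oracle)."""

    initial_state: str                 # associated | dissociated
    transition_times: np.ndarray       # s, strictly increasing
    duration: float
    spot_class: str = SPOT_PAIR
    responsive: bool = True
    inactive: bool = False
    bleach_time_d: float | None = None
    bleach_time_a: float | None = None

    def __post_init__(self) -> None:
        self.transition_times = np.asarray(self.transition_times, float)
        if np.any(np.diff(self.transition_times) <= 0):
            raise ValueError("transition times must be strictly increasing")

    def state_at(self, t: np.ndarray) -> np.ndarray:
        """Hidden state label at each query time."""
        n_before = np.searchsorted(self.transition_times, np.asarray(t, float),
                                   side="right")
        flipped = n_before % 2 == 1
        starts_assoc = self.initial_state == ASSOCIATED
        assoc = ~flipped if starts_assoc else flipped
        return np.where(assoc, ASSOCIATED, DISSOCIATED)

    def associated_occupancy(self, edges: np.ndarray) -> np.ndarray:
        """Fraction of each interval [edges[i], edges[i+1]) spent associated."""
        edges = np.asarray(edges, float)
        knots = np.concatenate([[0.0], self.transition_times, [max(self.duration, edges[-1])]])
        assoc0 = self.initial_state == ASSOCIATED
        # slope of cumulative associated time in each inter-knot interval
        slopes = np.array([(i % 2 == 0) == assoc0 for i in range(len(knots) - 1)],
                          float)
        cum = np.concatenate([[0.0], np.cumsum(slopes * np.diff(knots))])
        c_edges = np.interp(edges, knots, cum)
        return np.diff(c_edges) / np.diff(edges)

    def transitions_in(self, t0: float, t1: float) -> np.ndarray:
        ts = self.transition_times
        return ts[(ts >= t0) & (ts < t1)]


def simulate_state_path(scenario: KineticScenario, duration: float, seed=None,
                        pre_equilibrated: bool = False,
                        t_activation: float = 0.0,
                        spot_class: str | None = None) -> GroundTruth:
    """Simulate one molecule's hidden two-state path and photophysics events.

    Waiting times are exponential with rate ``k_diss(atp)`` out of the
    associated state and ``k_assoc`` out of the dissociated state.
    Non-responsive (wrong membrane orientation) and inactive molecules stay
    associated for the whole duration. With ``pre_equilibrated`` the initial
    state is drawn from the stationary distribution; otherwise the molecule
    starts associated. ``t_activation`` delays the onset of the
    ATP-dependent dissociation rate (ATP arrival in the flow cell).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = _rng(seed if seed is not None else scenario.seed)

    if spot_class is None:
        u = rng.random()
        if u < scenario.frac_donor_only:
            spot_class = SPOT_DONOR_ONLY
        elif u < scenario.frac_donor_only + scenario.frac_acceptor_only:
            spot_class = SPOT_ACCEPTOR_ONLY
        else:
            spot_class = SPOT_PAIR

    responsive = rng.random() < scenario.frac_responsive
    inactive = rng.random() < scenario.frac_inactive

    k_diss = scenario.k_diss if (responsive and not inactive) else 0.0
    k_assoc = scenario.k_assoc

    if pre_equilibrated and (k_diss + k_assoc) > 0 and k_diss > 0:
        p_assoc = k_assoc / (k_assoc + k_diss)
        state = ASSOCIATED if rng.random() < p_assoc else DISSOCIATED
    else:
        state = ASSOCIATED
    initial_state = state

    transitions: list[float] = []
    t = 0.0
    while True:
        if state == ASSOCIATED:
            if k_diss == 0.0:
                break
            if t < t_activation:
                # no dissociation before ATP arrival; memoryless afterwards
                wait = (t_activation - t) + rng.exponential(1.0 / k_diss)
            else:
                wait = rng.exponential(1.0 / k_diss)
        else:
            if k_assoc == 0.0:
                break
            wait = rng.exponential(1.0 / k_assoc)
        t += wait
        if t >= duration:
            break
        transitions.append(t)
        state = DISSOCIATED if state == ASSOCIATED else ASSOCIATED

    def _bleach(rate: float) -> float | None:
        if rate <= 0:
            return None
        tb = rng.exponential(1.0 / rate)
        return tb if tb < duration else None

    return GroundTruth(
        initial_state=initial_state,
        transition_times=np.array(transitions),
        duration=duration,
        spot_class=spot_class,
        responsive=responsive,
        inactive=inactive,
        bleach_time_d=_bleach(scenario.bleach_rate_d),
        bleach_time_a=_bleach(scenario.bleach_rate_a),
    )


def render_trace(truth: GroundTruth, scenario: KineticScenario,
                 trace_id: str = "trace", seed=None,
                 metadata: dict | None = None) -> Trace:
    """Render the observable two-channel ALEX trace for one hidden path.

    Per green frame the ideal donor/acceptor counts follow the
    occupancy-weighted FRET efficiency of the hidden state (sub-frame
    averaging at the camera frame time); crosstalk adds ``leakage * I_D`` to
    the acceptor channel, direct excitation adds ``direct_exc * total`` while
    the acceptor is alive. Red segments carry the acceptor signal under
    direct acceptor excitation (``I_AA``). Photobleaching truncates the
    relevant dye's emission; Gaussian noise and constant-mean background are
    added last.
    """
    sc = scenario
    rng = _rng(seed if seed is not None else sc.seed)
    n = sc.n_frames
    if truth.duration < sc.duration - 1e-9:
        raise ValueError("ground-truth path does not cover the movie")

    time = np.arange(n) * sc.frame_time
    edges = np.arange(n + 1) * sc.frame_time
    segment = alex_segments(sc.n_frames_red_head, sc.n_frames_green,
                            sc.n_frames_red_tail)
    green = segment == GREEN
    red = ~green

    # alive fraction of each frame for each dye (single-step bleaching)
    def alive_frac(t_bleach: float | None) -> np.ndarray:
        if t_bleach is None:
            return np.ones(n)
        return np.clip((t_bleach - edges[:-1]) / sc.frame_time, 0.0, 1.0)

    alive_d = alive_frac(truth.bleach_time_d)
    alive_a = alive_frac(truth.bleach_time_a)

    occ = truth.associated_occupancy(edges)
    E = occ * sc.E_assoc + (1.0 - occ) * sc.E_diss

    tot = sc.total_intensity
    if truth.spot_class == SPOT_PAIR:
        p_both = np.minimum(alive_d, alive_a)
        I_D0 = tot * (p_both * (1.0 - E) + (alive_d - p_both))
        I_A_fret = tot * p_both * E
    elif truth.spot_class == SPOT_DONOR_ONLY:
        alive_a = np.zeros(n)
        I_D0 = tot * alive_d
        I_A_fret = np.zeros(n)
    else:  # acceptor only
        alive_d = np.zeros(n)
        I_D0 = np.zeros(n)
        I_A_fret = np.zeros(n)

    I_A0 = I_A_fret + sc.leakage * I_D0 + sc.direct_exc * tot * alive_a
    I_AA0 = tot * alive_a

    bg_D = np.maximum(sc.bg_D_mean + sc.bg_drift * time, 0.0)
    bg_A = np.maximum(sc.bg_A_mean + sc.bg_drift * time, 0.0)

    noise = (lambda: rng.normal(0.0, sc.noise_sd, n)) if sc.noise_sd > 0 \
        else (lambda: np.zeros(n))

    I_D = np.where(green, I_D0, 0.0) + bg_D + noise()
    I_A = np.where(green, I_A0, 0.0) + bg_A + noise()
    I_AA = np.where(red, I_AA0, 0.0) + bg_A + noise()

    return Trace(trace_id=trace_id, time=time, I_D=I_D, I_A=I_A, I_AA=I_AA,
                 segment=segment, bg_D=bg_D, bg_A=bg_A,
                 metadata=metadata or {})


def simulate_trace(scenario: KineticScenario, trace_id: str = "trace",
                   seed=None, pre_equilibrated: bool = False,
                   t_activation: float = 0.0,
                   spot_class: str | None = None,
                   metadata: dict | None = None) -> tuple[Trace, GroundTruth]:
    """State path + rendering for one full movie; returns (trace, truth)."""
    rng = _rng(seed if seed is not None else scenario.seed)
    truth = simulate_state_path(scenario, scenario.duration, rng,
                                pre_equilibrated=pre_equilibrated,
                                t_activation=t_activation,
                                spot_class=spot_class)
    trace = render_trace(truth, scenario, trace_id=trace_id, seed=rng,
                         metadata=metadata)
    return trace, truth


# ---------------------------------------------------------------------------
# classification benchmark
# ---------------------------------------------------------------------------

def simulate_benchmark(n_traces: int = 500, seed=None,
                       scenario: KineticScenario | None = None,
                       frac_static_high: float = 0.30,
                       frac_static_low: float = 0.20,
                       max_transitions: int = 5
                       ) -> tuple[list[Trace], list[str]]:
    """Labeled synthetic benchmark for the dynamic/static classifier.

    Mixture of static-high (constantly associated), static-low (constantly
    dissociated) and dynamic traces. Dynamic hidden paths are two-state
    Markov paths at the scenario rates, rejection-sampled to show between 1
    and ``max_transitions`` transitions inside the donor-excitation window.
    All traces are doubly-labeled spots without photobleaching, i.e. the
    population that survives single-pair selection. Returns the traces and
    their ground-truth labels (``dynamic`` / ``static_high`` / ``static_low``).
    """
    rng = _rng(seed)
    sc = scenario or KineticScenario()
    sc = replace(sc, frac_responsive=1.0, frac_inactive=0.0,
                 frac_donor_only=0.0, frac_acceptor_only=0.0,
                 bleach_rate_d=0.0, bleach_rate_a=0.0)
    g0, g1 = sc.green_window
    traces, labels = [], []
    for i in range(n_traces):
        u = rng.random()
        if u < frac_static_high:
            truth = GroundTruth(ASSOCIATED, np.array([]), sc.duration)
            label = "static_high"
        elif u < frac_static_high + frac_static_low:
            truth = GroundTruth(DISSOCIATED, np.array([]), sc.duration)
            label = "static_low"
        else:
            while True:
                truth = simulate_state_path(sc, sc.duration, rng,
                                            pre_equilibrated=True,
                                            spot_class=SPOT_PAIR)
                k = len(truth.transitions_in(g0, g1))
                if 1 <= k <= max_transitions:
                    break
            label = "dynamic"
        traces.append(render_trace(truth, sc, trace_id=f"bench_{i:04d}",
                                   seed=rng, metadata={"truth_label": label}))
        labels.append(label)
    return traces, labels


# ---------------------------------------------------------------------------
# dose-response panels
# ---------------------------------------------------------------------------

def simulate_dose_response(scenario: KineticScenario, atp_grid, n_traces: int,
                           seed=None
                           ) -> dict[float, list[tuple[Trace, GroundTruth]]]:
    """One trace set per ATP level, sharing all non-ATP parameters."""
    atp_grid = np.asarray(atp_grid, float)
    if atp_grid.size < 4:
        raise ValueError("need at least 4 ATP levels")
    if np.any(atp_grid < 0):
        raise ValueError("ATP grid must be non-negative")
    rng = _rng(seed)
    panel: dict[float, list[tuple[Trace, GroundTruth]]] = {}
    for atp in atp_grid:
        sc = replace(scenario, atp=float(atp))
        panel[float(atp)] = [
            simulate_trace(sc, trace_id=f"atp{atp:g}_{i:04d}", seed=rng,
                           metadata={"atp_uM": float(atp)})
            for i in range(n_traces)
        ]
    return panel


# ---------------------------------------------------------------------------
# image stacks
# ---------------------------------------------------------------------------

def simulate_movie(traces: list[Trace], shape: tuple[int, int] = (64, 64),
                   psf_sigma: float = 1.2, centers=None,
                   min_separation: float = 6.0, bg: float = 20.0,
                   noise_sd: float = 2.0, seed=None
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Render traces into a dual-view image stack (left donor / right acceptor).

    Each spot is a 2-D Gaussian whose integrated mass per frame equals the
    trace's background-subtracted channel signal; the acceptor view carries
    ``I_A`` during green frames and ``I_AA`` during red segments. A uniform
    background plus Gaussian noise is added. Returns ``(stack, centers)``
    with stack shape (n_frames, H, 2*W) and true spot centers (row, col) in
    donor-view coordinates.
    """
    rng = _rng(seed)
    H, W = shape
    n_frames = traces[0].n_frames if traces else 0
    # keep spots clear of the edge for both the PSF and downstream photometry
    # (default annulus outer radius 8 px)
    margin = max(int(np.ceil(4 * psf_sigma)) + 1, 9)
    if centers is None:
        centers = []
        tries = 0
        while len(centers) < len(traces):
            cand = rng.uniform([margin, margin], [H - margin, W - margin])
            if all(np.hypot(*(cand - c)) >= min_separation for c in centers):
                centers.append(cand)
            tries += 1
            if tries > 10_000:
                raise RuntimeError("could not place spots with the requested separation")
        centers = np.array(centers) if centers else np.empty((0, 2))
    else:
        centers = np.asarray(centers, float)
        if len(centers) != len(traces):
            raise ValueError("one center per trace required")
        for c in centers:
            if not (margin <= c[0] < H - margin and margin <= c[1] < W - margin):
                raise ValueError("spot center too close to the field edge")
        for i in range(len(centers)):
            for j in range(i + 1, len(centers)):
                if np.hypot(*(centers[i] - centers[j])) < min_separation:
                    raise ValueError("spots closer than the separation limit")

    if not traces:
        stack = rng.normal(bg, noise_sd, (1, H, 2 * W)) if noise_sd > 0 \
            else np.full((1, H, 2 * W), bg)
        return stack.astype(np.float32), np.empty((0, 2))

    stack = np.full((n_frames, H, 2 * W), float(bg))
    yy, xx = np.mgrid[0:H, 0:W].astype(float)
    for tr, (cy, cx) in zip(traces, centers):
        psf = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * psf_sigma ** 2))
        psf /= 2 * np.pi * psf_sigma ** 2
        green = tr.green
        donor_sig = np.where(green, tr.I_D - tr.bg_D, 0.0)
        acc_sig = np.where(green, tr.I_A - tr.bg_A, tr.I_AA - tr.bg_A)
        stack[:, :, :W] += donor_sig[:, None, None] * psf[None]
        stack[:, :, W:] += acc_sig[:, None, None] * psf[None]
    if noise_sd > 0:
        stack += rng.normal(0.0, noise_sd, stack.shape)
    return stack.astype(np.float32), centers


# ---------------------------------------------------------------------------
# confocal photon streams
# ---------------------------------------------------------------------------

@dataclass
class PhotonStream:
    """Time-tagged photons from a confocal PIE/ALEX acquisition."""

    timestamps: np.ndarray      # s, sorted ascending
    detector: np.ndarray        # DET_DONOR / DET_ACCEPTOR
    excitation: np.ndarray      # EXC_DONOR / EXC_ACCEPTOR period of each photon
    duration: float             # s

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, float)
        self.detector = np.asarray(self.detector, np.int8)
        self.excitation = np.asarray(self.excitation, np.int8)
        if np.any(np.diff(self.timestamps) < 0):
            raise ValueError("timestamps must be sorted ascending")
        if self.timestamps.size and self.duration < self.timestamps[-1]:
            raise ValueError("duration must cover the last timestamp")

    @property
    def n_photons(self) -> int:
        return self.timestamps.size


def simulate_photon_stream(n_bursts: int = 0, duration: float = 60.0,
                           E_true: float = 0.5, S_true: float = 0.5,
                           burst_rate: float = 50_000.0,
                           burst_duration: float = 1e-3,
                           bg_rate_dd: float = 1_000.0,
                           bg_rate_da: float = 1_000.0,
                           bg_rate_aa: float = 1_000.0,
                           leakage: float = 0.0, direct_exc: float = 0.0,
                           seed=None
                           ) -> tuple[PhotonStream, np.ndarray]:
    """Simulate a PIE photon stream with diffusion-like bursts.

    Bursts are intervals of elevated Poisson photon rate placed uniformly in
    the acquisition. Donor-excitation photons inside a burst land on the
    acceptor detector with probability ``E_true`` plus the leakage and
    direct-excitation terms; acceptor-period photons arrive at a rate set by
    ``S_true``. Poisson background runs in all three detection streams for
    the full duration. Returns the stream and the true burst intervals
    (n_bursts, 2).
    """
    for r in (burst_rate, bg_rate_dd, bg_rate_da, bg_rate_aa):
        if r < 0:
            raise ValueError("rates must be >= 0")
    rng = _rng(seed)

    times, dets, excs = [], [], []

    def add(ts, det, exc):
        times.append(ts)
        dets.append(np.full(ts.size, det, np.int8))
        excs.append(np.full(ts.size, exc, np.int8))

    # background
    for rate, det, exc in ((bg_rate_dd, DET_DONOR, EXC_DONOR),
                           (bg_rate_da, DET_ACCEPTOR, EXC_DONOR),
                           (bg_rate_aa, DET_ACCEPTOR, EXC_ACCEPTOR)):
        if rate > 0:
            n = rng.poisson(rate * duration)
            add(rng.uniform(0, duration, n), det, exc)

    starts = np.sort(rng.uniform(0, duration - burst_duration, n_bursts))
    intervals = np.column_stack([starts, starts + burst_duration]) \
        if n_bursts else np.empty((0, 2))
    p_da = E_true + leakage * (1 - E_true) + direct_exc
    rate_aa = burst_rate * (1 - S_true) / S_true if S_true > 0 else 0.0
    for t0, t1 in intervals:
        n_d = rng.poisson(burst_rate * (t1 - t0))
        ts = rng.uniform(t0, t1, n_d)
        is_da = rng.random(n_d) < p_da
        add(ts[~is_da], DET_DONOR, EXC_DONOR)
        add(ts[is_da], DET_ACCEPTOR, EXC_DONOR)
        n_aa = rng.poisson(rate_aa * (t1 - t0))
        add(rng.uniform(t0, t1, n_aa), DET_ACCEPTOR, EXC_ACCEPTOR)

    ts = np.concatenate(times) if times else np.empty(0)
    det = np.concatenate(dets) if dets else np.empty(0, np.int8)
    exc = np.concatenate(excs) if excs else np.empty(0, np.int8)
    order = np.argsort(ts, kind="stable")
    stream = PhotonStream(ts[order], det[order], exc[order], duration)
    return stream, intervals
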