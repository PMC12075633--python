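"""Deterministic auxiliary computations around the single-molecule assay.

Forster-relation conversions between FRET efficiency and fluorophore
distance, Calpha distances from PDB structures, Gompertz growth-lag fits of
bacterial growth curves, and ATPase turnover from NADH absorbance decay in
the coupled-enzyme assay.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.PDB import PDBParser
from lmfit import Model

#: NADH molar extinction coefficient at 340 nm (per uM per cm)
EPS_NADH_340 = 6.22e-3


# ---------------------------------------------------------------------------
# Forster relation
# ---------------------------------------------------------------------------

@dataclass
class ForsterPair:
    R0: float      # Forster radius (Angstrom): distance at E = 0.5
    r: float       # inter-fluorophore distance (Angstrom)

    def __post_init__(self) -> None:
        if self.R0 <= 0 or self.r < 0:
            raise ValueError("R0 must be > 0 and r >= 0")


def fret_from_distance(pair: ForsterPair) -> float:
    """E = 1 / (1 + (r/R0)^6); strictly decreasing in r."""
    return 1.0 / (1.0 + (pair.r / pair.R0) ** 6)


def distance_from_fret(E: float, R0: float) -> float:
    """Exact inversion of the Forster relation; requires 0 < E < 1."""
    if not 0.0 < E < 1.0:
        raise ValueError("E must lie strictly between 0 and 1")
    return R0 * (1.0 / E - 1.0) ** (1.0 / 6.0)


# ---------------------------------------------------------------------------
# structure distances
# ---------------------------------------------------------------------------

def calpha_distance(structure_file, chain_a: str, resseq_a: int,
                    chain_b: str, resseq_b: int) -> float:
    """Euclidean Calpha-Calpha distance (Angstrom) between two residues.

    Uses the first model of a PDB-format file; when alternate locations are
    present, altloc A is taken. Raises a descriptive error naming the
    chain:residue when a residue or its Calpha atom is missing.
    """
    parser = PDBParser(QUIET=True)
    model = next(iter(parser.get_structure("s", structure_file)))

    def ca(chain_id: str, resseq: int) -> np.ndarray:
        if chain_id not in model:
            raise KeyError(f"chain {chain_id} not in structure")
        chain = model[chain_id]
        for res in chain:
            if res.id[1] == resseq and "CA" in res:
                atom = res["CA"]
                if atom.is_disordered():
                    atom = atom.disordered_get("A")
                return atom.get_coord()
        raise KeyError(f"no Calpha for {chain_id}:{resseq}")

    return float(np.linalg.norm(ca(chain_a, resseq_a) - ca(chain_b, resseq_b)))


# ---------------------------------------------------------------------------
# Gompertz growth fits
# ---------------------------------------------------------------------------

@dataclass
class GompertzFit:
    A: float        # asymptotic amplitude (OD units above baseline)
    mu_max: float   # maximal growth rate (h^-1, OD units per h)
    lag: float      # lag time lambda (h)
    flags: list[str] = field(default_factory=list)
    stderr: dict = field(default_factory=dict)


def gompertz(t, A, mu_max, lag):
    """Modified (Zwietering) Gompertz: y = A exp(-exp(mu_max e / A (lag - t) + 1))."""
    return A * np.exp(-np.exp(mu_max * np.e / A * (lag - t) + 1.0))


def fit_gompertz(time: np.ndarray, od: np.ndarray,
                 baseline: float | None = None) -> GompertzFit:
    """Multi-start least-squares Gompertz fit of a growth curve.

    ``time`` in hours, strictly increasing; ``od`` is baseline-subtracted
    internally (baseline = first reading unless given). Flat or decreasing
    curves are returned with a 'no_growth' flag instead of a fit.
    """
    t = np.asarray(time, float)
    y = np.asarray(od, float)
    if t.size < 10:
        raise ValueError("need at least 10 time points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time must be strictly increasing")
    base = float(y[:3].mean()) if baseline is None else baseline
    yy = y - base
    span = float(yy.max())
    # growth = clear rise from the early to the late readings
    noise = max(float(np.std(y[:5], ddof=1)), 1e-9)
    rise = float(y[-3:].mean() - y[:3].mean())
    if span <= 0 or rise < 4.0 * noise / np.sqrt(3) or np.all(np.diff(y) <= 0):
        return GompertzFit(np.nan, np.nan, np.nan, flags=["no_growth"])

    slope = np.gradient(yy, t)
    mu0 = max(float(slope.max()), 1e-3)
    model = Model(gompertz)
    best = None
    for lag0 in np.linspace(t[0], t[0] + 0.8 * (t[-1] - t[0]), 6):
        params = model.make_params(A=span, mu_max=mu0, lag=max(lag0, 1e-3))
        params["A"].min = 1e-9
        params["mu_max"].min = 1e-9
        params["lag"].min = 0.0
        try:
            res = model.fit(yy, params, t=t)
        except Exception:
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
    if best is None:
        return GompertzFit(np.nan, np.nan, np.nan, flags=["fit_failed"])
    p = best.params
    stderr = {k: (p[k].stderr if p[k].stderr is not None else np.nan)
              for k in ("A", "mu_max", "lag")}
    return GompertzFit(float(p["A"].value), float(p["mu_max"].value),
                       float(p["lag"].value), stderr=stderr)


# ---------------------------------------------------------------------------
# ATPase turnover from NADH absorbance
# ---------------------------------------------------------------------------

def pathlength_from_absorbance(A977: float, A900: float) -> float:
    """Optical pathlength (cm) of a plate well from the water absorbance band:
    (A977 - A900) / 0.18."""
    return (A977 - A900) / 0.18


@dataclass
class ATPaseAssay:
    """Coupled-enzyme ATPase assay record (NADH consumption tracks hydrolysis)."""

    time_s: np.ndarray
    a340: np.ndarray
    pathlength_cm: float
    volume_L: float
    protein_mol: float
    orientation_factor: float = 0.5   # only right-side-out complexes see ATP
    epsilon: float = EPS_NADH_340     # per uM per cm

    def __post_init__(self) -> None:
        if self.pathlength_cm <= 0:
            raise ValueError("pathlength must be positive")
        if self.volume_L <= 0 or self.protein_mol <= 0:
            raise ValueError("volume and protein amount must be positive")


def nadh_consumption_rate(assay: ATPaseAssay,
                          window: tuple[float, float] | None = None) -> float:
    """NADH consumption rate (uM/s) from the linear regime of the A340 decay."""
    t, a = assay.time_s, assay.a340
    if window is not None:
        m = (t >= window[0]) & (t <= window[1])
        t, a = t[m], a[m]
    slope = float(np.polyfit(t, a, 1)[0])
    if slope >= -1e-12:
        return 0.0
    return -slope / (assay.epsilon * assay.pathlength_cm)


def atpase_turnover(assay: ATPaseAssay,
                    window: tuple[float, float] | None = None
                    ) -> tuple[float, list[str]]:
    """ATP turnover per transporter (s^-1), orientation-corrected.

    turnover = rate(uM/s) * volume / (protein mol * orientation factor);
    one NADH consumed per ATP hydrolyzed in the coupled assay. A
    non-decreasing A340 yields turnover 0 with a 'no_activity' flag.
    """
    rate = nadh_consumption_rate(assay, window)
    if rate <= 0:
        return 0.0, ["no_activity"]
    mol_per_s = rate * 1e-6 * assay.volume_L
    return mol_per_s / (assay.protein_mol * assay.orientation_factor), []


def normalize_transport_signal(signal: np.ndarray,
                               i_start: int = 0) -> np.ndarray:
    """Normalize a bulk transport-sensor time course to the first reading
    after nucleotide addition."""
    ref = signal[i_start]
    if ref == 0:
        raise ValueError("reference reading is zero")
    return np.asarray(signal, float) / ref
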