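"""Core trace containers and text I/O.

A :class:`Trace` holds the per-frame two-channel intensities of one
surface-immobilized molecule recorded under alternating-laser excitation
(ALEX): donor and acceptor intensity under donor excitation (``I_D``,
``I_A``), acceptor intensity under direct acceptor excitation (``I_AA``,
meaningful only in the red segments), per-frame background estimates and a
segment label partitioning the movie into a red head (direct acceptor
excitation), the green donor-excitation body, and a red tail.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: canonical ALEX segment labels, in temporal order
RED_HEAD = "red_head"
GREEN = "green"
RED_TAIL = "red_tail"

_SEGMENTS = (RED_HEAD, GREEN, RED_TAIL)

#: file columns for the tab-delimited trace format
TRACE_COLUMNS = ["time_s", "I_D", "I_A", "I_AA", "segment", "bg_D", "bg_A"]


def alex_segments(n_red_head: int, n_green: int, n_red_tail: int) -> np.ndarray:
    """Per-frame segment labels for the standard red/green/red movie layout."""
    if min(n_red_head, n_green, n_red_tail) <= 0:
        raise ValueError("all segment frame counts must be positive")
    return np.array(
        [RED_HEAD] * n_red_head + [GREEN] * n_green + [RED_TAIL] * n_red_tail,
        dtype=object,
    )


@dataclass
class Trace:
    """One molecule's per-frame two-channel ALEX intensity record."""

    trace_id: str
    time: np.ndarray          # s, per frame
    I_D: np.ndarray           # donor channel under donor excitation (counts)
    I_A: np.ndarray           # acceptor channel under donor excitation (counts)
    I_AA: np.ndarray          # acceptor channel under acceptor excitation (counts)
    segment: np.ndarray       # per-frame label in {red_head, green, red_tail}
    bg_D: np.ndarray          # donor-channel background series (counts)
    bg_A: np.ndarray          # acceptor-channel background series (counts)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        arrays = [self.time, self.I_D, self.I_A, self.I_AA, self.segment,
                  self.bg_D, self.bg_A]
        n = len(self.time)
        if any(len(a) != n for a in arrays):
            raise ValueError("all per-frame series must share one length")
        labels = set(np.unique(self.segment))
        if not labels <= set(_SEGMENTS):
            raise ValueError(f"unknown segment labels: {labels - set(_SEGMENTS)}")
        # segments must be contiguous blocks in canonical order
        order = [s for s in _SEGMENTS if s in labels]
        boundaries = np.flatnonzero(self.segment[:-1] != self.segment[1:])
        if len(boundaries) != len(order) - 1:
            raise ValueError("segment labels must partition frames contiguously")
        if np.any(self.bg_D < 0) or np.any(self.bg_A < 0):
            raise ValueError("background series must be non-negative")

    @property
    def n_frames(self) -> int:
        return len(self.time)

    @property
    def frame_time(self) -> float:
        return float(np.median(np.diff(self.time))) if self.n_frames > 1 else np.nan

    def mask(self, segment: str) -> np.ndarray:
        return self.segment == segment

    @property
    def green(self) -> np.ndarray:
        return self.mask(GREEN)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_s": self.time, "I_D": self.I_D, "I_A": self.I_A,
            "I_AA": self.I_AA, "segment": self.segment,
            "bg_D": self.bg_D, "bg_A": self.bg_A,
        })


def write_trace(trace: Trace, path: str | Path) -> None:
    """Write one trace as a tab-delimited text table."""
    trace.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_trace(path: str | Path, trace_id: str | None = None,
               metadata: dict | None = None) -> Trace:
    """Read a trace from the tab-delimited text format."""
    df = pd.read_csv(path, sep="\t")
    missing = set(TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trace file {path} lacks columns {sorted(missing)}")
    return Trace(
        trace_id=trace_id or Path(path).stem,
        time=df["time_s"].to_numpy(float),
        I_D=df["I_D"].to_numpy(float),
        I_A=df["I_A"].to_numpy(float),
        I_AA=df["I_AA"].to_numpy(float),
        segment=df["segment"].to_numpy(object),
        bg_D=df["bg_D"].to_numpy(float),
        bg_A=df["bg_A"].to_numpy(float),
        metadata=metadata or {},
    )


def write_trace_set(traces: list[Trace], out_dir: str | Path) -> Path:
    """Write a set of traces plus a sidecar metadata table; returns the sidecar path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for tr in traces:
        fname = f"{tr.trace_id}.tsv"
        write_trace(tr, out_dir / fname)
        rows.append({"trace_id": tr.trace_id, "file": fname,
                     "condition": tr.metadata.get("condition", ""),
                     "atp_uM": tr.metadata.get("atp_uM", np.nan),
                     "truth_file": tr.metadata.get("truth_file", "")})
    sidecar = out_dir / "traces_index.tsv"
    pd.DataFrame(rows).to_csv(sidecar, sep="\t", index=False)
    return sidecar


def read_trace_set(in_dir: str | Path) -> list[Trace]:
    """Read every trace listed in a directory's sidecar metadata table."""
    in_dir = Path(in_dir)
    index = pd.read_csv(in_dir / "traces_index.tsv", sep="\t")
    traces = []
    for row in index.itertuples(index=False):
        meta = {"condition": row.condition, "atp_uM": row.atp_uM}
        traces.append(read_trace(in_dir / row.file, trace_id=row.trace_id,
                                 metadata=meta))
    return traces
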