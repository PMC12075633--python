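"""Spot detection and trace extraction from dual-view TIRF image stacks.

The stack carries the donor view on the left half of each frame and the
acceptor view on the right (image splitter geometry); channels are assumed
pre-aligned up to an integer pixel offset. Spots are local maxima of the
time-averaged donor image during donor excitation; per-spot traces are
aperture sums with an annulus background estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .traces import GREEN, Trace, alex_segments


@dataclass
class SpotDetection:
    """One detected spot with its photometry geometry (0-based pixel coords)."""

    center: tuple[int, int]                 # (row, col) in the donor view
    aperture_radius: int = 3
    annulus: tuple[int, int] = (5, 8)       # inner, outer radius
    channel_offset: tuple[int, int] = (0, 0)  # donor -> acceptor view offset

    def __post_init__(self) -> None:
        if self.annulus[0] <= self.aperture_radius:
            raise ValueError("annulus inner radius must exceed the aperture radius")
        if self.annulus[1] <= self.annulus[0]:
            raise ValueError("annulus outer radius must exceed the inner radius")


def _disk_offsets(radius: float) -> np.ndarray:
    r = int(np.ceil(radius))
    dy, dx = np.mgrid[-r:r + 1, -r:r + 1]
    keep = dy ** 2 + dx ** 2 <= radius ** 2
    return np.column_stack([dy[keep], dx[keep]])


def detect_spots(stack: np.ndarray, threshold: float,
                 min_separation: float = 5.0,
                 layout: tuple[int, int, int] = (25, 450, 25),
                 aperture_radius: int = 3, annulus: tuple[int, int] = (5, 8),
                 saturation: float = 65535.0) -> list[SpotDetection]:
    """Threshold local-maxima detection on the time-averaged donor image.

    Averages the donor (left) view over the donor-excitation frames, keeps
    local maxima above ``threshold``, and suppresses the dimmer of any pair
    closer than ``min_separation``. Spots whose annulus would leave the
    frame are dropped. Saturated frames are flagged with a warning, never
    dropped. Detections are returned ordered by (row, column).
    """
    n_head, n_green, n_tail = layout
    if stack.shape[0] < n_head + n_green + n_tail:
        raise ValueError("stack shorter than the ALEX layout")
    if n_green < 1:
        raise ValueError("need at least one donor-excitation frame")
    H, W2 = stack.shape[1], stack.shape[2]
    W = W2 // 2
    green = slice(n_head, n_head + n_green)
    if np.any(stack[green] >= saturation):
        warnings.warn("saturated frames present in the donor-excitation segment")
    avg = stack[green, :, :W].mean(axis=0)

    local_max = ndimage.maximum_filter(avg, size=3, mode="nearest")
    peaks = np.argwhere((avg >= local_max) & (avg > threshold))
    if peaks.size == 0:
        return []
    bright = avg[peaks[:, 0], peaks[:, 1]]
    order = np.argsort(-bright, kind="stable")
    kept: list[np.ndarray] = []
    for i in order:
        p = peaks[i]
        if all(np.hypot(*(p - q)) >= min_separation for q in kept):
            kept.append(p)

    margin = annulus[1]
    detections = [
        SpotDetection(center=(int(r), int(c)), aperture_radius=aperture_radius,
                      annulus=annulus, channel_offset=(0, W))
        for r, c in kept
        if margin <= r < H - margin and margin <= c < W - margin
    ]
    detections.sort(key=lambda d: d.center)
    return detections


def extract_trace(stack: np.ndarray, spot: SpotDetection,
                  layout: tuple[int, int, int] = (25, 450, 25),
                  frame_time: float = 0.2,
                  trace_id: str | None = None) -> Trace:
    """Aperture-photometry trace for one spot in both channels.

    Per frame: aperture sums in the donor and acceptor views; the
    background series are annulus means scaled to the aperture pixel count.
    The acceptor-view aperture sum serves as I_A during donor excitation and
    as I_AA during the red segments.
    """
    n_head, n_green, n_tail = layout
    n_frames = n_head + n_green + n_tail
    H, W2 = stack.shape[1], stack.shape[2]
    r0, c0 = spot.center
    off_r, off_c = spot.channel_offset

    ap = _disk_offsets(spot.aperture_radius)
    ann_out = _disk_offsets(spot.annulus[1])
    ann_in = {tuple(o) for o in _disk_offsets(spot.annulus[0])}
    ann = np.array([o for o in ann_out if tuple(o) not in ann_in])

    for (rr, cc) in ((r0, c0), (r0 + off_r, c0 + off_c)):
        rows = rr + ann_out[:, 0]
        cols = cc + ann_out[:, 1]
        if rows.min() < 0 or rows.max() >= H or cols.min() < 0 or cols.max() >= W2:
            raise ValueError("spot photometry region overlaps the frame edge")

    def photometry(rr: int, cc: int) -> tuple[np.ndarray, np.ndarray]:
        ap_sum = stack[:n_frames, rr + ap[:, 0], cc + ap[:, 1]].sum(axis=1)
        ann_mean = stack[:n_frames, rr + ann[:, 0], cc + ann[:, 1]].mean(axis=1)
        return ap_sum.astype(float), (ann_mean * len(ap)).astype(float)

    I_D, bg_D = photometry(r0, c0)
    acc, bg_A = photometry(r0 + off_r, c0 + off_c)

    segment = alex_segments(n_head, n_green, n_tail)
    time = np.arange(n_frames) * frame_time
    return Trace(
        trace_id=trace_id or f"spot_r{r0}c{c0}",
        time=time, I_D=I_D, I_A=acc.copy(), I_AA=acc.copy(),
        segment=segment, bg_D=np.maximum(bg_D, 0.0),
        bg_A=np.maximum(bg_A, 0.0),
        metadata={"center": (r0, c0)},
    )


def gaussian_aperture_fraction(psf_sigma: float, aperture_radius: float) -> float:
    """Mass of a 2-D Gaussian PSF inside a circular aperture (analytic)."""
    return 1.0 - float(np.exp(-aperture_radius ** 2 / (2.0 * psf_sigma ** 2)))
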