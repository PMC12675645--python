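"""Template-matching tumor tracker based on normalized cross-correlation.

The similarity is the energy-normalized cross-correlation

    NCC(u, v) = sum I(u+i, v+j) T(i, j)
                / sqrt(sum I(u+i, v+j)^2) / sqrt(sum T(i, j)^2)

*without* mean subtraction — for strictly positive images its value lies in
(0, 1], reaching 1 only when the window is a positive multiple of the
template (Cauchy–Schwarz).  A zero-mean variant is available behind the
``zero_mean`` flag but is not the default.

Tracking is integer-pixel argmax over a search window centered on the
previous position, with a fixed template taken from frame 1.  Ties are
resolved in favour of the previous position when it attains the maximum
(so flat sequences stay put), otherwise by the first maximum in row-major
scan order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Template", "Trajectory", "ncc", "track_sequence"]


@dataclass(frozen=True)
class Template:
    """Fixed template patch with its center position in frame-1 coordinates."""

    patch: np.ndarray  # (h, w)
    anchor: tuple[int, int]  # (row, col) of the patch center in frame 1

    def __post_init__(self):
        p = np.asarray(self.patch)
        if p.ndim != 2 or min(p.shape) < 1:
            raise ValueError("template patch must be a non-empty 2D array")
        if not np.any(p):
            raise ValueError("template patch has zero energy")

    @classmethod
    def from_roi(cls, frame: np.ndarray, row0: int, col0: int, h: int, w: int) -> "Template":
        patch = np.array(frame[row0 : row0 + h, col0 : col0 + w], dtype=np.float64)
        return cls(patch=patch, anchor=(row0 + h // 2, col0 + w // 2))

    @property
    def shape(self) -> tuple[int, int]:
        return np.asarray(self.patch).shape


@dataclass
class Trajectory:
    """Per-frame (row, col) pixel positions of the matched template center."""

    positions: np.ndarray  # (n_frames, 2), integer or float px
    pixel_to_mm: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.float64)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must be (n, 2)")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")

    def positions_mm(self) -> np.ndarray:
        return self.positions * np.asarray(self.pixel_to_mm)

    def __len__(self) -> int:
        return len(self.positions)


def ncc(frame: np.ndarray, template: Template, u: int, v: int, zero_mean: bool = False) -> float:
    """NCC of the template against the window whose top-left is (u, v)."""
    patch = np.asarray(template.patch, dtype=np.float64)
    h, w = patch.shape
    frame = np.asarray(frame, dtype=np.float64)
    if u < 0 or v < 0 or u + h > frame.shape[0] or v + w > frame.shape[1]:
        raise ValueError("template window lies outside the frame")
    win = frame[u : u + h, v : v + w]
    if zero_mean:
        win = win - win.mean()
        patch = patch - patch.mean()
    denom = np.sqrt((win * win).sum()) * np.sqrt((patch * patch).sum())
    if denom == 0:
        raise ValueError("zero-energy window")
    return float((win * patch).sum() / denom)


def _ncc_map(frame: np.ndarray, patch: np.ndarray, zero_mean: bool) -> np.ndarray:
    """NCC at every valid top-left position (vectorized sliding windows)."""
    frame = np.asarray(frame, dtype=np.float64)
    patch = np.asarray(patch, dtype=np.float64)
    win = sliding_window_view(frame, patch.shape)
    n = patch.size
    if zero_mean:
        wmean = win.mean(axis=(2, 3))
        pz = patch - patch.mean()
        num = np.tensordot(win, pz, axes=([2, 3], [0, 1]))
        wsq = (win * win).sum(axis=(2, 3)) - n * wmean * wmean
        wsq = np.maximum(wsq, 0.0)
        denom = np.sqrt(wsq) * np.sqrt((pz * pz).sum())
    else:
        num = np.tensordot(win, patch, axes=([2, 3], [0, 1]))
        denom = np.sqrt((win * win).sum(axis=(2, 3))) * np.sqrt((patch * patch).sum())
    out = np.full(num.shape, -np.inf)
    ok = denom > 0
    out[ok] = num[ok] / denom[ok]
    return out


def track_sequence(
    frames,
    template: Template,
    search_radius: int = 20,
    zero_mean: bool = False,
    pixel_to_mm: tuple[float, float] = (1.0, 1.0),
) -> Trajectory:
    """Track the template through a sequence at integer-pixel precision.

    Per frame the matched position is the argmax of the NCC over a
    ``(2*search_radius + 1)^2`` window centered on the previous position
    (clipped to the frame with a warning when it would leave it).
    """
    h, w = template.shape
    prev_tl = (template.anchor[0] - h // 2, template.anchor[1] - w // 2)
    centers = []
    for frame in frames:
        frame = np.asarray(frame)
        max_u, max_v = frame.shape[0] - h, frame.shape[1] - w
        u0, u1 = prev_tl[0] - search_radius, prev_tl[0] + search_radius
        v0, v1 = prev_tl[1] - search_radius, prev_tl[1] + search_radius
        if u0 < 0 or v0 < 0 or u1 > max_u or v1 > max_v:
            warnings.warn("search window clipped at the frame border", stacklevel=2)
        u0c, u1c = max(u0, 0), min(u1, max_u)
        v0c, v1c = max(v0, 0), min(v1, max_v)
        nmap = _ncc_map(frame, template.patch, zero_mean)[u0c : u1c + 1, v0c : v1c + 1]
        best = np.max(nmap)
        pu, pv = prev_tl[0] - u0c, prev_tl[1] - v0c
        if (
            0 <= pu < nmap.shape[0]
            and 0 <= pv < nmap.shape[1]
            and nmap[pu, pv] == best
        ):
            tl = prev_tl
        else:
            flat = int(np.argmax(nmap))  # first maximum in row-major order
            tl = (u0c + flat // nmap.shape[1], v0c + flat % nmap.shape[1])
        prev_tl = tl
        centers.append((tl[0] + h // 2, tl[1] + w // 2))
    return Trajectory(positions=np.asarray(centers, dtype=float), pixel_to_mm=pixel_to_mm)
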