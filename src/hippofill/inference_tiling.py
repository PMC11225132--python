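"""Sliding-window decomposition of volumes and seam-free reassembly.

Volumetric networks see fixed-size tiles (the deployed window here is 96^3
voxels); a full scan is covered by a lexicographically ordered grid of patch
origins with the last patch per axis clamped so it ends at the volume edge.
Stitching recombines per-patch outputs, averaging (or taking the max of)
contributions where patches overlap. Volumes smaller than the window are
zero-padded to window size and cropped back after stitching.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import product

import numpy as np

__all__ = ["PatchGrid", "plan_tiles", "extract_patches", "stitch"]


def _as_triple(v) -> tuple[int, int, int]:
    if np.isscalar(v):
        v = (v, v, v)
    t = tuple(int(x) for x in v)
    if len(t) != 3:
        raise ValueError(f"expected scalar or 3-vector, got {v!r}")
    return t  # type: ignore[return-value]


@dataclass(frozen=True)
class PatchGrid:
    """Plan of patch origins covering a volume with a fixed window size."""

    volume_shape: tuple[int, int, int]
    window: tuple[int, int, int]
    stride: tuple[int, int, int]
    origins: tuple[tuple[int, int, int], ...] = field(default=())

    def __len__(self) -> int:
        return len(self.origins)

    @property
    def padded_shape(self) -> tuple[int, int, int]:
        """Volume shape after zero-padding axes shorter than the window."""
        return tuple(max(s, w) for s, w in zip(self.volume_shape, self.window))  # type: ignore[return-value]

    def to_json(self) -> str:
        return json.dumps(
            {
                "volume_shape": self.volume_shape,
                "window": self.window,
                "stride": self.stride,
                "origins": [list(o) for o in self.origins],
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "PatchGrid":
        d = json.loads(s)
        return cls(
            volume_shape=tuple(d["volume_shape"]),
            window=tuple(d["window"]),
            stride=tuple(d["stride"]),
            origins=tuple(tuple(o) for o in d["origins"]),
        )


def _axis_origins(dim: int, window: int, stride: int) -> list[int]:
    if window >= dim:
        return [0]
    starts = list(range(0, dim - window + 1, stride))
    if starts[-1] != dim - window:  # clamp final patch to end at the edge
        starts.append(dim - window)
    return starts


def plan_tiles(shape, window=(96, 96, 96), stride=None) -> PatchGrid:
    """Plan a sliding-window grid covering every voxel of ``shape``.

    ``stride`` defaults to the window (no overlap). Origins are ordered
    lexicographically. Axes shorter than the window yield a single patch over
    the zero-padded axis.
    """
    shape = _as_triple(shape)
    window = _as_triple(window)
    stride = window if stride is None else _as_triple(stride)
    if min(shape) < 1:
        raise ValueError("volume shape must be positive")
    if min(window) < 1 or min(stride) < 1:
        raise ValueError("window and stride must be positive")
    if any(st > w for st, w in zip(stride, window)):
        raise ValueError("stride must not exceed window")
    padded = tuple(max(s, w) for s, w in zip(shape, window))
    axes = [_axis_origins(d, w, st) for d, w, st in zip(padded, window, stride)]
    origins = tuple(product(*axes))
    return PatchGrid(volume_shape=shape, window=window, stride=stride, origins=origins)


def extract_patches(volume: np.ndarray, grid: PatchGrid) -> list[np.ndarray]:
    """Crop the planned patches out of a volume (zero-padding short axes)."""
    volume = np.asarray(volume)
    if volume.shape != grid.volume_shape:
        raise ValueError(f"volume shape {volume.shape} does not match plan {grid.volume_shape}")
    padded = grid.padded_shape
    if padded != volume.shape:
        buf = np.zeros(padded, dtype=volume.dtype)
        buf[tuple(slice(0, s) for s in volume.shape)] = volume
        volume = buf
    w = grid.window
    return [volume[o[0]:o[0] + w[0], o[1]:o[1] + w[1], o[2]:o[2] + w[2]].copy() for o in grid.origins]


def stitch(patches: list[np.ndarray], grid: PatchGrid, blend: str = "mean") -> np.ndarray:
    """Reassemble per-patch scalar grids into a full volume.

    Overlaps combine by ``blend``: 'mean' averages contributions, 'max' keeps
    the largest. Stitching the crops of a volume reproduces it exactly.
    """
    if len(patches) != len(grid.origins):
        raise ValueError(f"{len(patches)} patches supplied for {len(grid.origins)} planned")
    w = grid.window
    for p in patches:
        if tuple(np.shape(p)) != w:
            raise ValueError(f"patch shape {np.shape(p)} does not match window {w}")
    if blend not in ("mean", "max"):
        raise ValueError("blend must be 'mean' or 'max'")
    padded = grid.padded_shape
    if blend == "mean":
        # extended-precision accumulator: k identical float64 contributions
        # average back to the exact input value, keeping round-trips bit-exact
        acc = np.zeros(padded, dtype=np.longdouble)
        cnt = np.zeros(padded, dtype=np.int64)
        for o, p in zip(grid.origins, patches):
            sl = tuple(slice(o[i], o[i] + w[i]) for i in range(3))
            acc[sl] += p
            cnt[sl] += 1
        out = (acc / cnt).astype(np.float64)
    else:
        out = np.full(padded, -np.inf, dtype=np.float64)
        for o, p in zip(grid.origins, patches):
            sl = tuple(slice(o[i], o[i] + w[i]) for i in range(3))
            np.maximum(out[sl], p, out=out[sl])
    return out[tuple(slice(0, s) for s in grid.volume_shape)]
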