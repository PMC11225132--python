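"""Domain containers and NIfTI / CSV input-output.

Axis convention: axis 0 is the slice (axial) axis, axes 1 and 2 are the
in-plane row and column axes. Slice-wise operations default to axis 0 but
accept an override. Voxel spacing is carried in millimetres and is the basis
for every physical distance the package reports.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "MaskVolume",
    "IntensityVolume",
    "ComponentLabeling",
    "FillingParams",
    "MetricReport",
    "CohortTable",
    "read_mask",
    "write_mask",
    "read_image",
    "write_image",
    "write_cohort_table",
]

#: Metric columns reported for every case, in presentation order.
METRIC_NAMES = ("dice", "iou", "osr", "usr", "asd", "hd")


def _validate_spacing(spacing: Sequence[float]) -> tuple[float, float, float]:
    sp = tuple(float(s) for s in spacing)
    if len(sp) != 3:
        raise ValueError(f"spacing must have 3 components, got {len(sp)}")
    if any(not math.isfinite(s) or s <= 0 for s in sp):
        raise ValueError(f"spacing components must be positive and finite, got {sp}")
    return sp  # type: ignore[return-value]


@dataclass(frozen=True)
class MaskVolume:
    """A 3D binary foreground mask with physical voxel spacing (mm).

    ``grid`` holds exactly the values 0 and 1 (uint8). ``spacing`` gives the
    voxel edge lengths along (slice, row, column).
    """

    grid: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid)
        if grid.ndim != 3 or min(grid.shape) < 1:
            raise ValueError(f"mask grid must be 3D with positive dims, got shape {grid.shape}")
        vals = np.unique(grid)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("mask grid must contain only 0 and 1")
        object.__setattr__(self, "grid", grid.astype(np.uint8, copy=False))
        object.__setattr__(self, "spacing", _validate_spacing(self.spacing))

    @property
    def shape(self) -> tuple[int, ...]:
        return self.grid.shape

    def foreground_count(self) -> int:
        """Number of foreground voxels (the mask's 'area')."""
        return int(self.grid.sum())

    def is_empty(self) -> bool:
        return not bool(self.grid.any())

    def with_grid(self, grid: np.ndarray) -> "MaskVolume":
        """Same spacing, new binary grid."""
        return MaskVolume(grid=grid, spacing=self.spacing)


@dataclass(frozen=True)
class IntensityVolume:
    """A 3D grey-level volume (arbitrary MR units) with voxel spacing (mm)."""

    grid: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=np.float64)
        if grid.ndim != 3 or min(grid.shape) < 1:
            raise ValueError(f"image grid must be 3D with positive dims, got shape {grid.shape}")
        if not np.isfinite(grid).all():
            raise ValueError("image grid must contain finite values only")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "spacing", _validate_spacing(self.spacing))

    @property
    def shape(self) -> tuple[int, ...]:
        return self.grid.shape

    def with_grid(self, grid: np.ndarray) -> "IntensityVolume":
        return IntensityVolume(grid=grid, spacing=self.spacing)


@dataclass(frozen=True)
class ComponentLabeling:
    """Integer-labelled decomposition of a binary mask into connected components.

    Label 0 is background; foreground labels are 1..n_components, assigned in
    raster-scan order of first component occurrence (deterministic). ``sizes``
    is indexed by label-1.
    """

    labels: np.ndarray
    n_components: int
    sizes: np.ndarray
    connectivity: int

    def component_mask(self, label: int) -> np.ndarray:
        if not 1 <= label <= self.n_components:
            raise ValueError(f"label {label} out of range 1..{self.n_components}")
        return self.labels == label


@dataclass(frozen=True)
class FillingParams:
    """Parameters of the slice-wise filling technique.

    theta
        Bridging threshold in voxels: two in-plane regions are connected when
        some point pair P1=(x1,y1), P2=(x2,y2) satisfies
        ``|x2-x1| + |y2-y1| <= theta - 1``, i.e. when the closest-point
        Manhattan distance plus the two endpoint voxels stays within theta+1.
        theta=1 bridges nothing beyond touching regions; theta=3 bridges a
        one-voxel gap (closest-point distance 2).
    slice_axis
        Axis along which 2D slices are taken (0 = axial by default).
    connectivity_2d
        In-plane neighbourhood (4 or 8) for component labelling.
    fill_holes
        Whether enclosed in-plane background regions are filled after bridging.
    """

    theta: int = 3
    slice_axis: int = 0
    connectivity_2d: int = 8
    fill_holes: bool = True

    def __post_init__(self) -> None:
        if self.theta < 0:
            raise ValueError("theta must be >= 0")
        if self.slice_axis not in (0, 1, 2):
            raise ValueError("slice_axis must be 0, 1 or 2")
        if self.connectivity_2d not in (4, 8):
            raise ValueError("connectivity_2d must be 4 or 8")


@dataclass(frozen=True)
class MetricReport:
    """Per-case segmentation scores and the voxel counts behind them.

    Ratios (dice, iou, osr, usr) are unitless; asd and hd are in millimetres.
    ``r_s = tp + fn`` is the ground-truth foreground count and
    ``t_s = tp + fp`` the predicted one. Surface distances are NaN when either
    mask is empty; ``degenerate_flags`` records which conventions fired.
    """

    dice: float
    iou: float
    osr: float
    usr: float
    asd: float
    hd: float
    tp: int
    fp: int
    fn: int
    r_s: int
    t_s: int
    degenerate_flags: tuple[str, ...] = ()
    case_id: str | None = None

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["degenerate_flags"] = list(self.degenerate_flags)
        return d


@dataclass
class CohortTable:
    """One MetricReport per case plus per-metric mean / sample-std summaries.

    Distance metrics (asd, hd) exclude degenerate (NaN) cases from the
    summary; ``n_excluded`` counts them per metric. std uses the n-1
    (sample) denominator and is 0 for a single case.
    """

    rows: list[MetricReport]
    summary: pd.DataFrame = field(init=False)
    n_excluded: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("cohort must contain at least one case")
        self.summary, self.n_excluded = _summarize(self.rows)

    def to_frame(self) -> pd.DataFrame:
        """Per-case rows as a DataFrame (one row per case)."""
        recs = []
        for i, r in enumerate(self.rows):
            rec = {"case_id": r.case_id if r.case_id is not None else f"case_{i:03d}"}
            rec.update({m: getattr(r, m) for m in METRIC_NAMES})
            rec.update({k: getattr(r, k) for k in ("tp", "fp", "fn", "r_s", "t_s")})
            rec["degenerate_flags"] = ";".join(r.degenerate_flags)
            recs.append(rec)
        return pd.DataFrame(recs)

    def metric_values(self, metric: str, drop_nan: bool = True) -> np.ndarray:
        vals = np.array([getattr(r, metric) for r in self.rows], dtype=float)
        return vals[~np.isnan(vals)] if drop_nan else vals


def _summarize(rows: list[MetricReport]) -> tuple[pd.DataFrame, dict[str, int]]:
    means, stds, ns, excluded = {}, {}, {}, {}
    for m in METRIC_NAMES:
        vals = np.array([getattr(r, m) for r in rows], dtype=float)
        ok = vals[~np.isnan(vals)]
        excluded[m] = int(np.isnan(vals).sum())
        ns[m] = len(ok)
        means[m] = float(np.mean(ok)) if len(ok) else float("nan")
        stds[m] = float(np.std(ok, ddof=1)) if len(ok) > 1 else 0.0
    summary = pd.DataFrame({"mean": means, "std": stds, "n": ns})
    return summary, excluded


# ---------------------------------------------------------------------------
# NIfTI I/O


def _affine_from_spacing(spacing: Sequence[float]) -> np.ndarray:
    return np.diag(list(spacing) + [1.0])


def _load_nifti(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"non-3D volume: {path} has {data.ndim} dimensions")
    data = np.asarray(data, dtype=np.float64)
    if not np.isfinite(data).all():
        raise ValueError(f"volume {path} contains non-finite values")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, spacing  # type: ignore[return-value]


def read_mask(path: str | Path) -> MaskVolume:
    """Read a NIfTI volume as a binary mask (values > 0.5 become foreground)."""
    data, spacing = _load_nifti(path)
    return MaskVolume(grid=(data > 0.5).astype(np.uint8), spacing=spacing)


def write_mask(mask: MaskVolume, path: str | Path) -> None:
    """Write a mask as uint8 NIfTI; grid and spacing round-trip bit-exactly."""
    img = nib.Nifti1Image(mask.grid.astype(np.uint8), _affine_from_spacing(mask.spacing))
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))


def read_image(path: str | Path) -> IntensityVolume:
    """Read a NIfTI volume as a grey-level image."""
    data, spacing = _load_nifti(path)
    return IntensityVolume(grid=data, spacing=spacing)


def write_image(vol: IntensityVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(vol.grid.astype(np.float32), _affine_from_spacing(vol.spacing))
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def write_cohort_table(table: CohortTable, path: str | Path) -> None:
    """Write per-case rows plus a final 'mean ± std' summary row as CSV."""
    frame = table.to_frame()
    summary_rec: dict = {"case_id": "summary"}
    for m in METRIC_NAMES:
        summary_rec[m] = (
            f"{table.summary.loc[m, 'mean']:.4f} ± {table.summary.loc[m, 'std']:.4f}"
        )
    frame = pd.concat([frame, pd.DataFrame([summary_rec])], ignore_index=True)
    frame.to_csv(path, index=False)
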