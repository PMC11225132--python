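"""Training-side procedures: intensity windowing, elastic augmentation, weighted loss.

These are the data-side ingredients of a volumetric segmentation training
loop, implemented as standalone deterministic functions (no network here):

* intensity windowing of the grey values to [0, 500], the range giving the
  best background/ROI contrast for T1 brain MR;
* geometric augmentation — rotation, scaling and a smooth dense deformation
  field obtained by sampling random control vectors on a coarse grid (one
  every 32 voxels per direction, by default) from a normal distribution and
  interpolating them with cubic B-splines — applied identically to image and
  label, plus grey-value shift/scale on the image only;
* a weighted cross-entropy loss that up-weights the foreground to counter the
  extreme class imbalance of a small bilateral structure in a whole head scan.

Every stochastic operation is a pure function of its inputs and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core_io import IntensityVolume, MaskVolume

__all__ = [
    "DeformationField",
    "AugmentationConfig",
    "intensity_window",
    "sample_deformation_field",
    "warp",
    "augment_pair",
    "weighted_cross_entropy",
]


@dataclass(frozen=True)
class DeformationField:
    """Per-voxel displacement vectors (voxel units) for one volume shape.

    ``displacement`` has shape (3, *volume_shape). The dense field is the
    cubic B-spline interpolation of ``control_vectors``, a coarse grid of
    i.i.d. N(0, sigma^2) vectors with one control point every
    ``control_spacing`` voxels per axis; the control grid has
    ceil((dim-1)/control_spacing) + 1 points per axis so it covers (or
    overshoots) the volume. sigma = 0 yields the identically zero field.
    """

    displacement: np.ndarray
    control_spacing: int
    control_vectors: np.ndarray
    sigma: float
    seed: int | None = None

    @property
    def volume_shape(self) -> tuple[int, ...]:
        return self.displacement.shape[1:]

    def is_zero(self) -> bool:
        return not bool(self.displacement.any())


@dataclass(frozen=True)
class AugmentationConfig:
    """Ranges for one random augmentation draw (all sampled uniformly).

    rotation_deg: per-axis (min, max) rotation in degrees about each of the
    three volume axes; scale: (min, max) isotropic scale factor; grey_shift /
    grey_scale: additive and multiplicative grey-value ranges (image only);
    deformation_sigma: std of the elastic control vectors in voxels (0
    disables); control_spacing in voxels.
    """

    rotation_deg: tuple[float, float] = (0.0, 0.0)
    scale: tuple[float, float] = (1.0, 1.0)
    grey_shift: tuple[float, float] = (0.0, 0.0)
    grey_scale: tuple[float, float] = (1.0, 1.0)
    deformation_sigma: float = 0.0
    control_spacing: int = 32

    def __post_init__(self) -> None:
        for name in ("rotation_deg", "scale", "grey_shift", "grey_scale"):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise ValueError(f"{name} range must be ordered, got ({lo}, {hi})")
        if self.scale[0] <= 0:
            raise ValueError("scale factors must be positive")
        if self.deformation_sigma < 0:
            raise ValueError("deformation_sigma must be >= 0")


def intensity_window(
    vol: IntensityVolume, lo: float = 0.0, hi: float = 500.0, mode: str = "rescale"
) -> IntensityVolume:
    """Transform grey values to the range [lo, hi] (default [0, 500]).

    mode='rescale' (default) affinely maps the input min/max onto [lo, hi];
    a constant volume maps to lo. mode='clip' clamps values outside [lo, hi]
    without rescaling. Both are monotone.
    """
    if hi <= lo:
        raise ValueError("hi must exceed lo")
    g = vol.grid
    if mode == "clip":
        return vol.with_grid(np.clip(g, lo, hi))
    if mode != "rescale":
        raise ValueError("mode must be 'rescale' or 'clip'")
    gmin, gmax = float(g.min()), float(g.max())
    if gmax == gmin:
        return vol.with_grid(np.full_like(g, lo, dtype=np.float64))
    return vol.with_grid(lo + (g - gmin) * ((hi - lo) / (gmax - gmin)))


def _control_points(dim: int, spacing: int) -> int:
    return int(np.ceil((dim - 1) / spacing)) + 1 if dim > 1 else 2


def sample_deformation_field(
    shape,
    control_spacing: int = 32,
    sigma: float = 4.0,
    seed: int | np.random.Generator | None = None,
) -> DeformationField:
    """Draw a smooth dense deformation field for a volume of ``shape``.

    Random 3-vectors are sampled on a coarse grid (one control point every
    ``control_spacing`` voxels per direction) from N(0, sigma^2) and
    interpolated to a dense per-voxel field with cubic B-splines. The dense
    field reproduces the control vectors at the control points.
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or min(shape) < 1:
        raise ValueError(f"shape must be a positive 3-vector, got {shape}")
    if control_spacing < 1:
        raise ValueError("control_spacing must be >= 1")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_ctrl = tuple(_control_points(d, control_spacing) for d in shape)
    control = rng.normal(0.0, sigma, size=(3, *n_ctrl)) if sigma > 0 else np.zeros((3, *n_ctrl))
    if sigma == 0:
        dense = np.zeros((3, *shape))
    else:
        # dense voxel coordinates in control-grid units
        coords = np.meshgrid(
            *[np.arange(d, dtype=np.float64) / control_spacing for d in shape], indexing="ij"
        )
        coords = np.stack(coords)
        dense = np.stack(
            [ndimage.map_coordinates(control[c], coords, order=3, mode="nearest") for c in range(3)]
        )
    return DeformationField(
        displacement=dense,
        control_spacing=control_spacing,
        control_vectors=control,
        sigma=float(sigma),
        seed=seed if isinstance(seed, int) else None,
    )


def _displaced_coords(shape: tuple[int, ...], field: DeformationField | None) -> np.ndarray:
    coords = np.stack(np.meshgrid(*[np.arange(d, dtype=np.float64) for d in shape], indexing="ij"))
    if field is not None:
        if field.volume_shape != shape:
            raise ValueError(f"field shape {field.volume_shape} does not match volume {shape}")
        coords = coords + field.displacement
    return coords


def warp(
    vol: IntensityVolume | MaskVolume,
    field: DeformationField,
    mode: str | None = None,
) -> IntensityVolume | MaskVolume:
    """Resample a volume through a deformation field.

    mode='image' uses trilinear interpolation, mode='label' nearest-neighbour
    (output stays strictly binary). Defaults to the mode matching the input
    type. Samples displaced outside the volume take value 0. A zero field
    returns a bit-identical copy.
    """
    if mode is None:
        mode = "label" if isinstance(vol, MaskVolume) else "image"
    if mode == "label" and not isinstance(vol, MaskVolume):
        raise TypeError("label mode requires a MaskVolume")
    if mode == "image" and not isinstance(vol, IntensityVolume):
        raise TypeError("image mode requires an IntensityVolume")
    if mode not in ("image", "label"):
        raise ValueError("mode must be 'image' or 'label'")
    coords = _displaced_coords(vol.shape, field)
    order = 1 if mode == "image" else 0
    out = ndimage.map_coordinates(
        vol.grid.astype(np.float64), coords, order=order, mode="constant", cval=0.0
    )
    if mode == "label":
        return vol.with_grid((out > 0.5).astype(np.uint8))
    return vol.with_grid(out)


def _rotation_matrix_z(deg: float) -> np.ndarray:
    """Rotation about axis 0 in the (axis1, axis2) plane.

    Positive angles rotate counter-clockwise in array index space so that a
    +90 degree rotation equals np.rot90(vol, k=1, axes=(1, 2)).
    """
    th = np.deg2rad(deg)
    c, s = np.cos(th), np.sin(th)
    # snap right-angle rotations to exact 0/±1 entries so they sample the
    # grid at exactly integer coordinates
    if abs(c) < 1e-12:
        c = 0.0
    if abs(s) < 1e-12:
        s = 0.0
    if abs(abs(c) - 1) < 1e-12:
        c = np.sign(c)
    if abs(abs(s) - 1) < 1e-12:
        s = np.sign(s)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def _rotation_matrix(axis: int, deg: float) -> np.ndarray:
    """Rotation about ``axis``; +90 degrees equals np.rot90 in the other two axes."""
    base = _rotation_matrix_z(deg)
    perm = {0: (0, 1, 2), 1: (1, 2, 0), 2: (2, 0, 1)}[axis]
    m = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            m[perm[i], perm[j]] = base[i, j]
    return m


def _geometric_coords(
    shape: tuple[int, ...],
    rotation_deg: tuple[float, float, float],
    scale: float,
    field: DeformationField | None,
) -> np.ndarray:
    """Output-to-input sampling coordinates for rotation+scale about the centre
    followed by elastic displacement."""
    centre = (np.array(shape, dtype=np.float64) - 1.0) / 2.0
    rot = np.eye(3)
    for axis in (0, 1, 2):
        rot = rot @ _rotation_matrix(axis, rotation_deg[axis])
    # inverse map: input = R^-1 (out - c)/s ... sampling uses inverse transform
    inv = np.linalg.inv(rot) / scale
    coords = _displaced_coords(shape, field)
    rel = coords - centre.reshape(3, 1, 1, 1)
    sampled = np.einsum("ij,j...->i...", inv, rel) + centre.reshape(3, 1, 1, 1)
    return sampled


def augment_pair(
    img: IntensityVolume,
    gt: MaskVolume,
    cfg: AugmentationConfig = AugmentationConfig(),
    seed: int | np.random.Generator | None = None,
) -> tuple[IntensityVolume, MaskVolume]:
    """One random augmentation draw applied consistently to an image/label pair.

    The geometric part (rotation about each axis, isotropic scale, elastic
    deformation) is identical for both members; the grey-value shift/scale
    touches the image only. Deterministic given the seed.
    """
    if img.shape != gt.shape:
        raise ValueError(f"image shape {img.shape} does not match label {gt.shape}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    angles = tuple(rng.uniform(*cfg.rotation_deg) for _ in range(3))
    scale = float(rng.uniform(*cfg.scale))
    shift = float(rng.uniform(*cfg.grey_shift))
    gscale = float(rng.uniform(*cfg.grey_scale))
    field = (
        sample_deformation_field(img.shape, cfg.control_spacing, cfg.deformation_sigma, rng)
        if cfg.deformation_sigma > 0
        else None
    )
    identity_geometry = (
        all(a == 0.0 for a in angles) and scale == 1.0 and field is None
    )
    if identity_geometry:
        img_out, gt_out = img.grid.copy(), gt.grid.copy()
    else:
        coords = _geometric_coords(img.shape, angles, scale, field)
        img_out = ndimage.map_coordinates(img.grid, coords, order=1, mode="constant", cval=0.0)
        gt_out = ndimage.map_coordinates(
            gt.grid.astype(np.float64), coords, order=0, mode="constant", cval=0.0
        )
        gt_out = (gt_out > 0.5).astype(np.uint8)
    img_out = img_out * gscale + shift
    return img.with_grid(img_out), gt.with_grid(gt_out)


def weighted_cross_entropy(
    probs: np.ndarray,
    gt: MaskVolume,
    w_bg: float = 0.1,
    w_fg: float = 1.0,
    eps: float = 1e-7,
) -> float:
    """Class-weighted binary cross-entropy averaged over all voxels.

    loss = -(sum_fg w_fg*log(p) + sum_bg w_bg*log(1-p)) / N with p clamped to
    [eps, 1-eps]. Up-weighting the foreground counters the imbalance between
    the small ROI and the background.
    """
    probs = np.asarray(probs, dtype=np.float64)
    if probs.shape != gt.shape:
        raise ValueError(f"probs shape {probs.shape} does not match mask {gt.shape}")
    p = np.clip(probs, eps, 1.0 - eps)
    fg = gt.grid.astype(bool)
    loss = -(w_fg * np.log(p[fg]).sum() + w_bg * np.log1p(-p[~fg]).sum())
    return float(loss / probs.size)
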