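"""Synthetic bilateral hippocampus-like phantoms with controllable failure modes.

A phantom case stands in for one patient volume: a pair of curved, mirrored
ellipsoidal bodies (the foreground occupies well under 5% of the volume, like
the hippocampus in a head scan), a grey-level image built from a smooth
background plus foreground contrast and Gaussian noise, and a "prediction"
derived from the ground truth by applying the corruption modes the repair
pipeline targets:

* ``discontinuous`` — a thin in-plane slab is deleted from each structure, so
  every axial slice through it shows two fragments separated by a small gap
  that slice-wise bridging can close;
* ``hollow`` — interior voxels are removed leaving a shell, producing enclosed
  in-plane background that hole filling repairs;
* ``noise_clusters`` — small false-positive blobs are scattered far from the
  structures, the target of the largest-component filter;
* ``boundary_jitter`` — random surface voxels are toggled, an irreducible
  error floor.

Geometric realism is not the goal; the phantoms reproduce the topological
failure modes, not hippocampal anatomy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .core_io import IntensityVolume, MaskVolume
from .metrics import surface_voxels

__all__ = ["PhantomCase", "generate_gt", "corrupt", "generate_cohort", "cohort_manifest"]

VALID_MODES = ("discontinuous", "hollow", "noise_clusters", "boundary_jitter")

#: in-plane gap width (voxels) deleted by the ``discontinuous`` mode; a 1-voxel
#: gap gives closest-point Manhattan distance 2, bridgeable at theta = 3
DISCONTINUITY_GAP = 1


@dataclass(frozen=True)
class PhantomCase:
    """One synthetic patient: image, ground truth, corrupted prediction."""

    image: IntensityVolume
    gt: MaskVolume
    pred: MaskVolume
    corruption: dict
    seed: int | None
    case_id: str = "case"


def _banana_mask(
    shape: tuple[int, int, int],
    centre: np.ndarray,
    semi_axes: np.ndarray,
    bend: float,
) -> np.ndarray:
    """Arc-bent ellipsoid: the in-plane column centre shifts quadratically with
    the position along the long (slice) axis, giving a banana-like body."""
    zz, yy, xx = np.meshgrid(*[np.arange(s, dtype=np.float64) for s in shape], indexing="ij")
    u = (zz - centre[0]) / semi_axes[0]
    x_shift = bend * semi_axes[2] * u**2
    v = (yy - centre[1]) / semi_axes[1]
    w = (xx - centre[2] - x_shift) / semi_axes[2]
    return (u**2 + v**2 + w**2 <= 1.0).astype(np.uint8)


def generate_gt(
    shape=(64, 64, 64),
    spacing=(1.0, 1.0, 1.0),
    seed: int | np.random.Generator | None = None,
) -> tuple[IntensityVolume, MaskVolume]:
    """Generate a grey image and its bilateral two-component ground truth.

    The mask holds two mirrored arc-bent ellipsoids straddling the mid-sagittal
    column plane; foreground stays below 5% of the volume. The image is a
    smooth random background plus foreground contrast plus Gaussian noise.
    Deterministic given the seed.
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or min(shape) < 32:
        raise ValueError(f"shape must be >= 32 per axis, got {shape}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    dims = np.array(shape, dtype=np.float64)
    # long axis along axis 0 (axial stack), lateral separation along axis 2
    semi = np.array(
        [
            rng.uniform(0.18, 0.24) * dims[0],
            rng.uniform(0.07, 0.10) * dims[1],
            rng.uniform(0.06, 0.09) * dims[2],
        ]
    )
    bend = rng.uniform(0.5, 1.0)
    offset = rng.uniform(0.22, 0.27) * dims[2]  # lateral offset from midline
    centre_z = dims[0] / 2 + rng.uniform(-0.04, 0.04) * dims[0]
    centre_y = dims[1] / 2 + rng.uniform(-0.06, 0.06) * dims[1]
    mid_x = dims[2] / 2

    left = _banana_mask(shape, np.array([centre_z, centre_y, mid_x - offset]), semi, bend)
    right = left[:, :, ::-1]  # mirror about the mid-column plane: bilateral symmetry
    grid = (left | right).astype(np.uint8)
    gt = MaskVolume(grid=grid, spacing=spacing)

    background = ndimage.gaussian_filter(rng.normal(100.0, 40.0, size=shape), sigma=8.0)
    contrast = rng.uniform(40.0, 70.0)
    noise = rng.normal(0.0, 5.0, size=shape)
    image = IntensityVolume(grid=background + contrast * grid + noise, spacing=spacing)
    return image, gt


def _delete_slab(grid: np.ndarray, comp_mask: np.ndarray, rng: np.random.Generator) -> None:
    """Split one component by zeroing a thin in-plane slab of rows through it."""
    rows = np.unique(np.argwhere(comp_mask)[:, 1])
    mid = rows[len(rows) // 2]
    lo = int(np.clip(mid + rng.integers(-1, 2), rows[0] + 1, rows[-1] - DISCONTINUITY_GAP))
    grid[:, lo : lo + DISCONTINUITY_GAP, :][comp_mask[:, lo : lo + DISCONTINUITY_GAP, :] > 0] = 0


def corrupt(
    gt: MaskVolume,
    modes=("hollow",),
    magnitude: float = 1.0,
    seed: int | np.random.Generator | None = None,
) -> tuple[MaskVolume, dict]:
    """Derive a corrupted prediction from a ground-truth mask.

    Modes are applied in the canonical order hollow -> discontinuous ->
    noise_clusters -> boundary_jitter; magnitude scales the noise-cluster
    count and jitter rate. Returns the prediction and a provenance record.
    Deterministic given the seed.
    """
    if gt.is_empty():
        raise ValueError("cannot corrupt an empty ground truth")
    modes = tuple(modes)
    for m in modes:
        if m not in VALID_MODES:
            raise ValueError(f"unknown corruption mode {m!r}; valid: {VALID_MODES}")
    if magnitude < 0:
        raise ValueError("magnitude must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    grid = gt.grid.copy()
    record: dict = {"modes": list(modes), "magnitude": magnitude}

    if "hollow" in modes and magnitude > 0:
        interior = ndimage.binary_erosion(
            grid.astype(bool), structure=ndimage.generate_binary_structure(3, 1), iterations=2
        )
        grid[interior] = 0
        record["hollow_removed"] = int(interior.sum())

    if "discontinuous" in modes and magnitude > 0:
        lab, n = ndimage.label(grid.astype(bool), structure=np.ones((3, 3, 3), bool))
        for k in range(1, n + 1):
            _delete_slab(grid, lab == k, rng)
        record["discontinuous_gap"] = DISCONTINUITY_GAP

    if "noise_clusters" in modes and magnitude > 0:
        n_blobs = max(1, round(3 * magnitude))
        # keep blobs well away from the structures
        forbidden = ndimage.binary_dilation(gt.grid.astype(bool), iterations=6)
        placed = 0
        attempts = 0
        shape = np.array(grid.shape)
        while placed < n_blobs and attempts < 200:
            attempts += 1
            c = rng.integers(3, shape - 3)
            r = int(rng.integers(1, 3))
            if forbidden[tuple(c)]:
                continue
            zz, yy, xx = np.ogrid[
                -c[0] : shape[0] - c[0], -c[1] : shape[1] - c[1], -c[2] : shape[2] - c[2]
            ]
            blob = zz**2 + yy**2 + xx**2 <= r**2
            if (blob & forbidden).any():
                continue
            grid[blob] = 1
            placed += 1
        record["noise_clusters_placed"] = placed

    if "boundary_jitter" in modes and magnitude > 0:
        rate = min(1.0, 0.2 * magnitude)
        surf = surface_voxels(MaskVolume(grid=grid, spacing=gt.spacing))
        toggle = surf[rng.random(len(surf)) < rate]
        grid[tuple(toggle.T)] ^= 1
        record["jittered"] = int(len(toggle))

    return MaskVolume(grid=grid, spacing=gt.spacing), record


def generate_cohort(
    n: int = 25,
    shape=(64, 64, 64),
    modes=("hollow", "discontinuous", "noise_clusters"),
    seed: int = 0,
    spacing=(1.0, 1.0, 1.0),
    magnitude: float = 1.0,
) -> list[PhantomCase]:
    """Generate a reproducible cohort of n phantom cases.

    Per-case generators are spawned from one seed sequence, so any cohort is a
    pure function of (n, shape, modes, seed, spacing, magnitude).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    children = np.random.SeedSequence(seed).spawn(n)
    cases = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        image, gt = generate_gt(shape, spacing, rng)
        pred, record = corrupt(gt, modes, magnitude, rng)
        cases.append(
            PhantomCase(
                image=image,
                gt=gt,
                pred=pred,
                corruption=record,
                seed=seed,
                case_id=f"case_{i:03d}",
            )
        )
    return cases


def cohort_manifest(cases: list[PhantomCase]) -> pd.DataFrame:
    """Per-case metadata table (one row per phantom)."""
    rows = []
    for c in cases:
        rows.append(
            {
                "case_id": c.case_id,
                "shape": "x".join(map(str, c.gt.shape)),
                "gt_voxels": c.gt.foreground_count(),
                "pred_voxels": c.pred.foreground_count(),
                "modes": ";".join(c.corruption.get("modes", [])),
                "magnitude": c.corruption.get("magnitude"),
            }
        )
    return pd.DataFrame(rows)
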