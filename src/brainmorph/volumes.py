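"""Volume containers, brain-mask construction, patch grids and parcellations.

Everything downstream operates in a fixed normalized space: an MNI-like
181 x 217 x 181 voxel grid at 1 mm isotropic resolution, holding per-tissue
probability maps (gray matter, white matter, CSF).  This module provides

* :class:`TissueMaps` -- the per-subject GM/WM/CSF probability volumes;
* :func:`build_brain_mask` -- tissue conjunction + morphological closing +
  interior-cavity filling;
* :func:`make_patch_grid` / :class:`PatchGrid` -- the centered crop and the
  regular 16^3 patch partition used by the patch-based extractors;
* :func:`synthetic_parcellation` / :func:`load_parcellation` -- a 116-region
  labeled atlas, either generated (seeded Voronoi tessellation of the brain
  mask) or loaded from a user-supplied NIfTI label volume.

Conventions: 0-based voxel indices, half-open patch intervals, patch
enumeration row-major over grid axes (axis 0 slowest, axis 2 fastest).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

#: Default normalized-space grid (matches the 1 mm MNI template bounding box).
DEFAULT_SHAPE: tuple[int, int, int] = (181, 217, 181)

#: Default crop applied before patch partitioning (removes non-brain margins).
DEFAULT_CROP_SHAPE: tuple[int, int, int] = (144, 192, 128)

#: Default cubic patch edge length in voxels.
DEFAULT_PATCH_SIZE: int = 16

#: Default number of atlas regions.
DEFAULT_N_REGIONS: int = 116

# RAS affine with the origin at the usual MNI anterior-commissure voxel.
MNI_LIKE_AFFINE = np.array(
    [
        [1.0, 0.0, 0.0, -90.0],
        [0.0, 1.0, 0.0, -126.0],
        [0.0, 0.0, 1.0, -72.0],
        [0.0, 0.0, 0.0, 1.0],
    ]
)

PROB_TOL = 1e-4


class VolumeError(ValueError):
    """Raised for invalid volumes, grids or parcellations."""


@dataclass
class TissueMaps:
    """Per-subject tissue probability maps on the normalized grid.

    Attributes
    ----------
    gm, wm, csf
        3-D arrays of tissue probabilities in ``[0, 1]``; at every voxel
        ``gm + wm + csf <= 1`` (up to a small tolerance).
    voxel_size
        Isotropic voxel edge length in mm.
    space_tag
        Free-text label of the normalized space.
    """

    gm: np.ndarray
    wm: np.ndarray
    csf: np.ndarray
    voxel_size: float = 1.0
    space_tag: str = "MNI-like"

    def __post_init__(self) -> None:
        self.gm = np.asarray(self.gm)
        self.wm = np.asarray(self.wm)
        self.csf = np.asarray(self.csf)

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(self.gm.shape)

    def validate(self, expected_shape: tuple[int, ...] | None = None) -> "TissueMaps":
        if not (self.gm.shape == self.wm.shape == self.csf.shape):
            raise VolumeError(
                f"tissue map shapes differ: gm {self.gm.shape}, "
                f"wm {self.wm.shape}, csf {self.csf.shape}"
            )
        if self.gm.ndim != 3:
            raise VolumeError(f"tissue maps must be 3-D, got ndim={self.gm.ndim}")
        if expected_shape is not None and self.shape != tuple(expected_shape):
            raise VolumeError(
                f"tissue maps have shape {self.shape}, expected {tuple(expected_shape)}"
            )
        for name, arr in (("gm", self.gm), ("wm", self.wm), ("csf", self.csf)):
            lo, hi = float(arr.min()), float(arr.max())
            if lo < -PROB_TOL or hi > 1 + PROB_TOL:
                raise VolumeError(f"{name} probabilities outside [0, 1]: [{lo}, {hi}]")
        total_max = float((self.gm + self.wm + self.csf).max())
        if total_max > 1 + PROB_TOL:
            raise VolumeError(f"gm+wm+csf exceeds 1 at some voxel (max {total_max})")
        return self

    def total(self) -> np.ndarray:
        """Summed tissue probability (the brain-mask source image)."""
        return self.gm + self.wm + self.csf


@dataclass
class BrainMask:
    """Binary brain mask produced by :func:`build_brain_mask`."""

    mask: np.ndarray
    n_voxels: int = 0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.n_voxels = int(self.mask.sum())


@dataclass
class Parcellation:
    """Integer-labeled 3-D atlas: 0 = background, 1..R = regions."""

    labels: np.ndarray
    n_regions: int
    region_names: list[str] | None = None
    label_map: dict[int, int] | None = None  # original label -> dense 1..R

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise VolumeError("parcellation labels must be an integer array")

    def validate(self, mask: BrainMask | None = None) -> "Parcellation":
        present = np.unique(self.labels)
        if present.min() < 0 or present.max() > self.n_regions:
            raise VolumeError(
                f"labels outside [0, {self.n_regions}]: range "
                f"[{present.min()}, {present.max()}]"
            )
        nonzero = present[present > 0]
        if len(nonzero) != self.n_regions:
            missing = sorted(set(range(1, self.n_regions + 1)) - set(nonzero.tolist()))
            raise VolumeError(f"empty region labels: {missing[:10]}")
        if mask is not None and bool(((self.labels > 0) & ~mask.mask).any()):
            raise VolumeError("parcellation has labeled voxels outside the brain mask")
        return self

    def region_sizes(self) -> np.ndarray:
        """Voxel count per region, index 0 = region 1."""
        return np.bincount(self.labels.ravel(), minlength=self.n_regions + 1)[1:]


@dataclass(frozen=True)
class PatchGrid:
    """Centered crop + regular cubic patch partition of a volume.

    ``grid_dims * patch_size == crop_shape`` elementwise and patches are
    enumerated row-major over grid axes (axis 0 slowest, axis 2 fastest), so
    feature indices are stable across subjects.
    """

    volume_shape: tuple[int, int, int]
    crop_shape: tuple[int, int, int]
    crop_offset: tuple[int, int, int]
    patch_size: int
    grid_dims: tuple[int, int, int]
    n_patches: int = field(default=0)

    def crop(self, volume: np.ndarray) -> np.ndarray:
        """Return the centered crop window of ``volume``."""
        if tuple(volume.shape) != self.volume_shape:
            raise VolumeError(
                f"volume shape {volume.shape} does not match grid source "
                f"shape {self.volume_shape}"
            )
        o, c = self.crop_offset, self.crop_shape
        return volume[o[0] : o[0] + c[0], o[1] : o[1] + c[1], o[2] : o[2] + c[2]]

    def patch_blocks(self, volume: np.ndarray) -> np.ndarray:
        """Reshape the cropped volume to ``(n_patches, p, p, p)`` in grid order."""
        p = self.patch_size
        g = self.grid_dims
        blocks = self.crop(volume).reshape(g[0], p, g[1], p, g[2], p)
        return blocks.transpose(0, 2, 4, 1, 3, 5).reshape(self.n_patches, p, p, p)

    def patch_index(self, i: int, j: int, k: int) -> int:
        """Flat patch index of grid cell (i, j, k)."""
        g = self.grid_dims
        return (i * g[1] + j) * g[2] + k


def make_patch_grid(
    volume_shape: tuple[int, int, int] = DEFAULT_SHAPE,
    crop_shape: tuple[int, int, int] = DEFAULT_CROP_SHAPE,
    patch_size: int = DEFAULT_PATCH_SIZE,
) -> PatchGrid:
    """Build the centered crop + patch partition for ``volume_shape``.

    The crop offset is ``floor((volume - crop) / 2)`` per axis.  With the
    defaults -- a 181x217x181 volume cropped to 144x192x128 with 16^3
    patches -- this yields a 9x12x8 grid of 864 patches at offset
    (18, 12, 26).
    """
    volume_shape = tuple(int(s) for s in volume_shape)
    crop_shape = tuple(int(s) for s in crop_shape)
    patch_size = int(patch_size)
    if len(volume_shape) != 3 or len(crop_shape) != 3:
        raise VolumeError("volume_shape and crop_shape must be 3-D")
    if patch_size <= 0:
        raise VolumeError("patch_size must be positive")
    for ax, (v, c) in enumerate(zip(volume_shape, crop_shape)):
        if c > v:
            raise VolumeError(
                f"crop_shape {crop_shape} exceeds volume_shape {volume_shape} on axis {ax}"
            )
        if c % patch_size != 0:
            raise VolumeError(
                f"crop_shape[{ax}]={c} is not divisible by patch_size={patch_size}"
            )
    offset = tuple((v - c) // 2 for v, c in zip(volume_shape, crop_shape))
    grid_dims = tuple(c // patch_size for c in crop_shape)
    n_patches = int(np.prod(grid_dims))
    return PatchGrid(
        volume_shape=volume_shape,
        crop_shape=crop_shape,
        crop_offset=offset,
        patch_size=patch_size,
        grid_dims=grid_dims,
        n_patches=n_patches,
    )


def build_brain_mask(
    maps: TissueMaps, threshold: float = 0.5, closing: bool = True
) -> BrainMask:
    """Conjunct GM+WM+CSF, threshold, close and fill interior cavities.

    A voxel enters the raw mask when its summed tissue probability is at
    least ``threshold``.  Binary closing (6-connected structuring element)
    smooths the surface, then any background cavity not 6-connected to the
    volume border is filled.

    Raises
    ------
    VolumeError
        If ``threshold`` is outside (0, 1) or the thresholded mask is empty.
    """
    if not 0 < threshold < 1:
        raise VolumeError(f"threshold must be in (0, 1), got {threshold}")
    maps.validate()
    raw = maps.total() >= threshold
    if not raw.any():
        raise VolumeError(
            f"empty brain mask: no voxel has summed tissue probability >= {threshold}"
        )
    out = ndimage.binary_closing(raw) | raw if closing else raw
    # binary_fill_holes fills background components unreachable from the
    # border under the default 6-connected structure.
    out = ndimage.binary_fill_holes(out)
    return BrainMask(mask=out)


def _nearest_seed_labels(
    coords: np.ndarray, seeds: np.ndarray, chunk: int = 200_000
) -> np.ndarray:
    """Label each coordinate by its nearest seed (squared Euclidean).

    Ties are broken toward the lowest seed index because ``argmin`` returns
    the first minimum.
    """
    coords = coords.astype(np.float64)
    seeds = seeds.astype(np.float64)
    seed_sq = (seeds**2).sum(axis=1)
    labels = np.empty(len(coords), dtype=np.int32)
    for start in range(0, len(coords), chunk):
        block = coords[start : start + chunk]
        # ||v - s||^2 = ||v||^2 - 2 v.s + ||s||^2; ||v||^2 is constant per row.
        d2 = seed_sq[None, :] - 2.0 * (block @ seeds.T)
        labels[start : start + chunk] = np.argmin(d2, axis=1) + 1
    return labels


def synthetic_parcellation(
    mask: BrainMask, n_regions: int = DEFAULT_N_REGIONS, seed: int = 0
) -> Parcellation:
    """Seeded-Voronoi tessellation of the brain mask into ``n_regions`` labels.

    ``n_regions`` seed voxels are drawn uniformly without replacement from the
    mask; every mask voxel is then assigned the label of its nearest seed
    (Euclidean distance, ties toward the lowest label).  Each seed labels at
    least itself, so all regions are non-empty.  Deterministic given ``seed``.
    """
    if mask.n_voxels == 0:
        raise VolumeError("cannot parcellate an empty mask")
    if n_regions < 1 or n_regions > mask.n_voxels:
        raise VolumeError(
            f"n_regions={n_regions} must be in [1, mask voxel count={mask.n_voxels}]"
        )
    rng = np.random.default_rng(seed)
    coords = np.argwhere(mask.mask)
    seed_idx = rng.choice(len(coords), size=n_regions, replace=False)
    seeds = coords[seed_idx]
    labels = np.zeros(mask.mask.shape, dtype=np.int32)
    labels[tuple(coords.T)] = _nearest_seed_labels(coords, seeds)
    return Parcellation(labels=labels, n_regions=n_regions).validate(mask)


def save_volume(
    data: np.ndarray, path: str | Path, affine: np.ndarray | None = None
) -> Path:
    """Write a 3-D array as a NIfTI-1 file (float arrays as float32)."""
    path = Path(path)
    if np.issubdtype(np.asarray(data).dtype, np.floating):
        data = np.asarray(data, dtype=np.float32)
    img = nib.Nifti1Image(data, MNI_LIKE_AFFINE if affine is None else affine)
    nib.save(img, str(path))
    return path


def load_volume(path: str | Path) -> np.ndarray:
    img = nib.load(str(path))
    return np.asarray(img.dataobj)


def load_tissue_maps(
    gm_path: str | Path, wm_path: str | Path, csf_path: str | Path
) -> TissueMaps:
    """Read GM/WM/CSF probability volumes and validate the container."""
    return TissueMaps(
        gm=np.asarray(load_volume(gm_path), dtype=np.float32),
        wm=np.asarray(load_volume(wm_path), dtype=np.float32),
        csf=np.asarray(load_volume(csf_path), dtype=np.float32),
    ).validate()


def save_parcellation(parc: Parcellation, path: str | Path) -> Path:
    return save_volume(parc.labels.astype(np.int32), path)


def load_parcellation(
    path: str | Path, expected_shape: tuple[int, ...] | None = None
) -> Parcellation:
    """Load a NIfTI label volume as a dense 1..R parcellation.

    Distinct nonzero labels are relabeled densely to 1..R in increasing
    order of the original label value; the mapping is recorded in
    ``label_map``.  Floating-point label volumes are rejected.
    """
    img = nib.load(str(path))
    dtype = img.get_data_dtype()
    if not np.issubdtype(dtype, np.integer):
        raise VolumeError(
            f"parcellation {path} has non-integer dtype {dtype}; "
            "label volumes must be stored as integers"
        )
    labels = np.asarray(img.dataobj).astype(np.int64)
    if expected_shape is not None and labels.shape != tuple(expected_shape):
        raise VolumeError(
            f"parcellation shape {labels.shape} != expected {tuple(expected_shape)}"
        )
    if labels.min() < 0:
        raise VolumeError("parcellation contains negative labels")
    originals = np.unique(labels)
    originals = originals[originals > 0]
    if len(originals) == 0:
        raise VolumeError(f"parcellation {path} has no nonzero labels")
    label_map = {int(orig): i + 1 for i, orig in enumerate(originals)}
    lut = np.zeros(int(originals.max()) + 1, dtype=np.int32)
    for orig, dense in label_map.items():
        lut[orig] = dense
    dense_labels = lut[labels]
    return Parcellation(
        labels=dense_labels, n_regions=len(originals), label_map=label_map
    ).validate()


def save_mask(mask: BrainMask, path: str | Path) -> Path:
    return save_volume(mask.mask.astype(np.uint8), path)


def manifest_entry(path: Path) -> dict:
    """Small provenance record for an output file."""
    return {"path": str(path), "bytes": path.stat().st_size}


def write_json(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
    return path
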