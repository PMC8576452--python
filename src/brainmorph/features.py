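"""Four volumetric feature representations of one brain: VOR, PBM, LEP, DTL.

Each extractor maps a subject's tissue maps to a fixed-length vector:

* **VOR** (volume of regions): GM volume per atlas region, normalized by the
  subject's total GM volume — 116 features under the default parcellation.
* **PBM** (patch-based morphometry): GM volume per 16^3 patch of the centered
  144x192x128 crop, normalized by total GM — 864 features.
* **LEP** (local energy pattern): per patch, HOG descriptors of the 16 slices
  along each of the three orthogonal views (axial / coronal / sagittal),
  averaged per view and concatenated — 36 x 3 x 864 = 93,312 features.
  z-scoring is deliberately NOT applied here; it is a training-fold-fitted
  transform in the evaluation harness.
* **DTL** (deep transfer features): a five-stage stride-2 3-D convolutional
  stack applied to the center-cropped 160x192x128 GM volume, ending in 64
  channels — a 5x6x4x64 map flattened to 7,680 features.  Weights default to
  a seeded random bank (He-scaled, zero biases) and can be loaded from an
  ``.npz`` file.

Extractors are scikit-learn transformers: ``fit`` validates configuration
and sets fitted attributes, ``transform`` maps a sequence of
:class:`~brainmorph.volumes.TissueMaps` to an ``(n_subjects, dim)`` array.
They compose with sklearn pipelines and model selection.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from skimage.feature import hog as _skimage_hog
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .volumes import Parcellation, PatchGrid, TissueMaps, VolumeError, make_patch_grid

METHOD_DIMS = {"VOR": 116, "PBM": 864, "LEP": 93312, "DTL": 7680}


class FeatureError(ValueError):
    """Raised for invalid feature-extraction inputs."""


@dataclass
class HogConfig:
    """HOG parameterization for one 16x16 patch slice.

    Defaults (9 unsigned orientation bins, 8x8-pixel cells, 2x2-cell blocks)
    are the unique standard configuration giving a 36-dimensional descriptor
    on a 16x16 slice: one block of 4 cells x 9 bins.
    """

    n_orientations: int = 9
    cell_size: tuple[int, int] = (8, 8)
    cells_per_block: tuple[int, int] = (2, 2)
    block_norm: str = "L2-Hys"
    signed_gradients: bool = False

    @property
    def slice_shape(self) -> tuple[int, int]:
        return (
            self.cell_size[0] * self.cells_per_block[0],
            self.cell_size[1] * self.cells_per_block[1],
        )

    @property
    def n_features(self) -> int:
        return (
            self.n_orientations * self.cells_per_block[0] * self.cells_per_block[1]
        )


@dataclass
class FeatureVector:
    """One subject's feature vector tagged with its extraction method."""

    values: np.ndarray
    method: str
    dim: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).ravel()
        self.dim = int(self.values.size)
        if not np.all(np.isfinite(self.values)):
            raise FeatureError(f"{self.method} features contain non-finite values")


@dataclass
class FeatureMatrix:
    """Subjects x features array with aligned subject ids and a method tag."""

    values: np.ndarray
    subject_ids: list[str]
    method: str

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=np.float64))
        if self.values.shape[0] != len(self.subject_ids):
            raise FeatureError(
                f"{self.values.shape[0]} rows vs {len(self.subject_ids)} subject ids"
            )
        if not np.all(np.isfinite(self.values)):
            raise FeatureError("feature matrix contains non-finite values")

    @property
    def dim(self) -> int:
        return self.values.shape[1]

    def to_csv(self, path: str | Path) -> Path:
        """Write subjects x features CSV plus a JSON sidecar."""
        path = Path(path)
        df = pd.DataFrame(self.values, index=pd.Index(self.subject_ids, name="subject_id"))
        df.columns = [f"f{j}" for j in range(self.dim)]
        df.to_csv(path, float_format="%.10g")
        cfg_hash = hashlib.sha256(self.values.tobytes()).hexdigest()[:16]
        sidecar = {"method": self.method, "dim": self.dim, "data_hash": cfg_hash}
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2) + "\n")
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        path = Path(path)
        df = pd.read_csv(path, index_col="subject_id")
        sidecar_path = Path(str(path) + ".json")
        method = "unknown"
        if sidecar_path.exists():
            method = json.loads(sidecar_path.read_text()).get("method", "unknown")
        return cls(
            values=df.to_numpy(dtype=np.float64),
            subject_ids=[str(s) for s in df.index],
            method=method,
        )


def hog_slice(slice_2d: np.ndarray, cfg: HogConfig | None = None) -> np.ndarray:
    """HOG descriptor of one patch slice (36 values under defaults).

    Centered gradients, unsigned orientation binning into ``n_orientations``
    bins per cell, block normalization over the 2x2-cell block.  A constant
    slice yields the all-zero descriptor.
    """
    cfg = cfg or HogConfig()
    slice_2d = np.asarray(slice_2d, dtype=np.float64)
    if slice_2d.shape != cfg.slice_shape:
        raise FeatureError(
            f"expected slice shape {cfg.slice_shape}, got {slice_2d.shape}"
        )
    desc = _skimage_hog(
        slice_2d,
        orientations=cfg.n_orientations,
        pixels_per_cell=cfg.cell_size,
        cells_per_block=cfg.cells_per_block,
        block_norm=cfg.block_norm,
        feature_vector=True,
    )
    return np.asarray(desc, dtype=np.float64)


def _as_maps_list(X) -> list[TissueMaps]:
    if isinstance(X, TissueMaps):
        return [X]
    out = list(X)
    if not out:
        raise FeatureError("empty input: need at least one TissueMaps")
    for m in out:
        if not isinstance(m, TissueMaps):
            raise FeatureError(f"expected TissueMaps, got {type(m).__name__}")
    return out


class _VolumeFeatureExtractor(TransformerMixin, BaseEstimator):
    """Base class: transform a sequence of TissueMaps to (n, dim)."""

    method: str = ""

    def fit(self, X, y=None):
        maps = _as_maps_list(X)
        self._check_config(maps[0])
        self.n_features_out_ = self._dim()
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "n_features_out_")
        maps = _as_maps_list(X)
        out = np.empty((len(maps), self.n_features_out_), dtype=np.float64)
        for i, m in enumerate(maps):
            out[i] = self.transform_one(m)
        return out

    def transform_one(self, maps: TissueMaps) -> np.ndarray:
        raise NotImplementedError

    def _check_config(self, maps: TissueMaps) -> None:
        raise NotImplementedError

    def _dim(self) -> int:
        raise NotImplementedError

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "n_features_out_")
        return np.asarray(
            [f"{self.method.lower()}{j}" for j in range(self.n_features_out_)]
        )


class VORExtractor(_VolumeFeatureExtractor):
    """Atlas-region GM volumes normalized by total GM (116 features).

    Feature r is the summed GM probability over voxels labeled r, divided by
    the summed GM probability over the whole volume.
    """

    method = "VOR"

    def __init__(self, parcellation: Parcellation | None = None):
        self.parcellation = parcellation

    def _check_config(self, maps: TissueMaps) -> None:
        if self.parcellation is None:
            raise FeatureError("VORExtractor requires a parcellation")
        if self.parcellation.labels.shape != maps.gm.shape:
            raise VolumeError(
                f"parcellation shape {self.parcellation.labels.shape} != "
                f"GM shape {maps.gm.shape}"
            )

    def _dim(self) -> int:
        return self.parcellation.n_regions

    def transform_one(self, maps: TissueMaps) -> np.ndarray:
        self._check_config(maps)
        gm = np.asarray(maps.gm, dtype=np.float64)
        total = float(gm.sum())
        if total <= 0:
            raise FeatureError("total GM volume is zero")
        sums = np.bincount(
            self.parcellation.labels.ravel(),
            weights=gm.ravel(),
            minlength=self.parcellation.n_regions + 1,
        )[1:]
        return sums / total


class PBMExtractor(_VolumeFeatureExtractor):
    """Per-patch GM volumes normalized by total GM (864 features).

    Feature p is the summed GM probability inside patch p of the centered
    crop, divided by the total GM of the full uncropped volume.
    """

    method = "PBM"

    def __init__(self, grid: PatchGrid | None = None):
        self.grid = grid

    def _effective_grid(self, maps: TissueMaps) -> PatchGrid:
        if self.grid is not None:
            return self.grid
        return make_patch_grid(maps.gm.shape)

    def _check_config(self, maps: TissueMaps) -> None:
        grid = self._effective_grid(maps)
        if tuple(maps.gm.shape) != grid.volume_shape:
            raise VolumeError(
                f"GM shape {maps.gm.shape} != grid source shape {grid.volume_shape}"
            )

    def _dim(self) -> int:
        if self.grid is None:
            return make_patch_grid().n_patches
        return self.grid.n_patches

    def transform_one(self, maps: TissueMaps) -> np.ndarray:
        grid = self._effective_grid(maps)
        gm = np.asarray(maps.gm, dtype=np.float64)
        total = float(gm.sum())
        if total <= 0:
            raise FeatureError("total GM volume is zero")
        patch_sums = grid.patch_blocks(gm).sum(axis=(1, 2, 3))
        return patch_sums / total


#: view name -> slicing axis (fixed convention, see docs)
VIEW_AXES = {"axial": 2, "coronal": 1, "sagittal": 0}
#: concatenation order of the three views within one patch
VIEW_ORDER = ("axial", "coronal", "sagittal")


class LEPExtractor(_VolumeFeatureExtractor):
    """Slice-averaged 3-view HOG per patch, concatenated (93,312 features).

    For each 16^3 patch of the GM map and each orthogonal view, the HOG
    descriptors of the 16 slices along that view's axis are averaged to 36
    values; the three views are concatenated to 108 values per patch, and
    patches are concatenated in grid order.  No z-scoring here — that is a
    training-fold transform in the evaluation harness.
    """

    method = "LEP"

    def __init__(self, grid: PatchGrid | None = None, hog: HogConfig | None = None):
        self.grid = grid
        self.hog = hog

    def _effective(self, maps: TissueMaps) -> tuple[PatchGrid, HogConfig]:
        grid = self.grid if self.grid is not None else make_patch_grid(maps.gm.shape)
        cfg = self.hog if self.hog is not None else HogConfig()
        return grid, cfg

    def _check_config(self, maps: TissueMaps) -> None:
        grid, cfg = self._effective(maps)
        if tuple(maps.gm.shape) != grid.volume_shape:
            raise VolumeError(
                f"GM shape {maps.gm.shape} != grid source shape {grid.volume_shape}"
            )
        if (grid.patch_size, grid.patch_size) != cfg.slice_shape:
            raise FeatureError(
                f"patch size {grid.patch_size} incompatible with HOG slice "
                f"shape {cfg.slice_shape}"
            )

    def _dim(self) -> int:
        grid = self.grid if self.grid is not None else make_patch_grid()
        cfg = self.hog if self.hog is not None else HogConfig()
        return cfg.n_features * len(VIEW_ORDER) * grid.n_patches

    @staticmethod
    def patch_descriptor(patch: np.ndarray, cfg: HogConfig) -> np.ndarray:
        """108-dim descriptor of one cubic patch: per-view slice-averaged HOG."""
        parts = []
        for view in VIEW_ORDER:
            axis = VIEW_AXES[view]
            n_slices = patch.shape[axis]
            acc = np.zeros(cfg.n_features, dtype=np.float64)
            for s in range(n_slices):
                sl = np.take(patch, s, axis=axis)
                acc += hog_slice(sl, cfg)
            parts.append(acc / n_slices)
        return np.concatenate(parts)

    def transform_one(self, maps: TissueMaps) -> np.ndarray:
        grid, cfg = self._effective(maps)
        self._check_config(maps)
        gm = np.asarray(maps.gm, dtype=np.float64)
        blocks = grid.patch_blocks(gm)
        out = np.empty((grid.n_patches, cfg.n_features * len(VIEW_ORDER)))
        for p in range(grid.n_patches):
            out[p] = self.patch_descriptor(blocks[p], cfg)
        return out.ravel()


#: DTL conv-stack defaults: input shape and per-stage output channels
DTL_INPUT_SHAPE = (160, 192, 128)
DTL_CHANNELS = (8, 16, 32, 64, 64)


def center_fit(volume: np.ndarray, target: tuple[int, int, int]) -> np.ndarray:
    """Center-crop and/or zero-pad a 3-D array to ``target`` shape."""
    out = np.asarray(volume)
    for ax, t in enumerate(target):
        s = out.shape[ax]
        if s > t:
            start = (s - t) // 2
            out = np.take(out, np.arange(start, start + t), axis=ax)
        elif s < t:
            before = (t - s) // 2
            pad = [(0, 0)] * out.ndim
            pad[ax] = (before, t - s - before)
            out = np.pad(out, pad)
    return out


class DTLExtractor(_VolumeFeatureExtractor):
    """Five-stage stride-2 3-D conv features of the GM volume (7,680 dims).

    The GM map is center-fitted to 160x192x128, then passed through five
    stages of 2x2x2 stride-2 convolution + ReLU with channel widths
    (8, 16, 32, 64, 64), producing a 5x6x4x64 feature map flattened to
    7,680 values.  Weights are a seeded random bank by default (He-scaled
    normals, zero biases) or loaded from an ``.npz`` with arrays
    ``W0..W4`` / ``b0..b4``.
    """

    method = "DTL"

    def __init__(
        self,
        weights_source: str = "seeded_random",
        seed: int = 0,
        weights_file: str | Path | None = None,
        input_shape: tuple[int, int, int] = DTL_INPUT_SHAPE,
        channels: tuple[int, ...] = DTL_CHANNELS,
    ):
        self.weights_source = weights_source
        self.seed = seed
        self.weights_file = weights_file
        self.input_shape = input_shape
        self.channels = channels

    def _stage_shapes(self) -> list[tuple[int, int, int]]:
        shapes = [tuple(self.input_shape)]
        for _ in self.channels:
            prev = shapes[-1]
            if any(s % 2 != 0 for s in prev):
                raise FeatureError(
                    f"stage input shape {prev} not divisible by 2; "
                    f"input_shape {self.input_shape} incompatible with "
                    f"{len(self.channels)} stride-2 stages"
                )
            shapes.append(tuple(s // 2 for s in prev))
        return shapes

    def _build_weights(self) -> tuple[list[np.ndarray], list[np.ndarray]]:
        cin_list = (1,) + tuple(self.channels[:-1])
        if self.weights_source == "file" or self.weights_file is not None:
            if self.weights_file is None:
                raise FeatureError("weights_source='file' requires weights_file")
            with np.load(self.weights_file) as npz:
                weights, biases = [], []
                for i, (cin, cout) in enumerate(zip(cin_list, self.channels)):
                    try:
                        w = np.asarray(npz[f"W{i}"], dtype=np.float64)
                        b = np.asarray(npz[f"b{i}"], dtype=np.float64)
                    except KeyError as exc:
                        raise FeatureError(
                            f"weights file missing array {exc.args[0]}"
                        ) from exc
                    if w.shape != (2, 2, 2, cin, cout) or b.shape != (cout,):
                        raise FeatureError(
                            f"stage {i} weight shape {w.shape} incompatible with "
                            f"architecture (expected {(2, 2, 2, cin, cout)})"
                        )
                    weights.append(w)
                    biases.append(b)
            return weights, biases
        if self.weights_source != "seeded_random":
            raise FeatureError(
                f"unknown weights_source {self.weights_source!r}; "
                "use 'seeded_random' or 'file'"
            )
        rng = np.random.default_rng(self.seed)
        weights, biases = [], []
        for cin, cout in zip(cin_list, self.channels):
            fan_in = 8 * cin
            weights.append(
                rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(2, 2, 2, cin, cout))
            )
            biases.append(np.zeros(cout))
        return weights, biases

    def _check_config(self, maps: TissueMaps) -> None:
        shapes = self._stage_shapes()
        self._weights_, self._biases_ = self._build_weights()
        self._final_shape_ = shapes[-1] + (self.channels[-1],)

    def _dim(self) -> int:
        final = self._stage_shapes()[-1]
        return int(np.prod(final)) * self.channels[-1]

    def feature_map(self, maps: TissueMaps) -> np.ndarray:
        """Run the conv stack; returns the (D, H, W, C) final feature map."""
        if not hasattr(self, "_weights_"):
            self._check_config(maps)
        x = center_fit(np.asarray(maps.gm, dtype=np.float64), self.input_shape)
        x = x[..., None]  # single input channel
        for w, b in zip(self._weights_, self._biases_):
            d, h, wd, cin = x.shape
            # 2x2x2 stride-2 convolution as a reshape + tensor contraction
            blocks = x.reshape(d // 2, 2, h // 2, 2, wd // 2, 2, cin)
            x = np.einsum("iajbkcf,abcfo->ijko", blocks, w) + b
            np.maximum(x, 0.0, out=x)  # ReLU
        return x

    def transform_one(self, maps: TissueMaps) -> np.ndarray:
        return self.feature_map(maps).ravel()


_EXTRACTOR_CLASSES = {
    "VOR": VORExtractor,
    "PBM": PBMExtractor,
    "LEP": LEPExtractor,
    "DTL": DTLExtractor,
}


def make_extractor(method: str, **kwargs) -> _VolumeFeatureExtractor:
    """Instantiate an extractor by method name (case-insensitive)."""
    key = method.upper()
    if key not in _EXTRACTOR_CLASSES:
        raise FeatureError(
            f"unknown method {method!r}; choose from {sorted(_EXTRACTOR_CLASSES)}"
        )
    return _EXTRACTOR_CLASSES[key](**kwargs)


# thin functional wrappers ---------------------------------------------------


def extract_vor(maps: TissueMaps, parcellation: Parcellation) -> FeatureVector:
    ext = VORExtractor(parcellation).fit([maps])
    return FeatureVector(ext.transform_one(maps), method="VOR")


def extract_pbm(maps: TissueMaps, grid: PatchGrid | None = None) -> FeatureVector:
    ext = PBMExtractor(grid).fit([maps])
    return FeatureVector(ext.transform_one(maps), method="PBM")


def extract_lep(
    maps: TissueMaps,
    grid: PatchGrid | None = None,
    cfg: HogConfig | None = None,
) -> FeatureVector:
    ext = LEPExtractor(grid, cfg).fit([maps])
    return FeatureVector(ext.transform_one(maps), method="LEP")


def extract_dtl(maps: TissueMaps, **kwargs) -> FeatureVector:
    ext = DTLExtractor(**kwargs).fit([maps])
    return FeatureVector(ext.transform_one(maps), method="DTL")


def extract_features(
    maps_seq: Sequence[TissueMaps],
    subject_ids: Sequence[str],
    extractor: _VolumeFeatureExtractor,
) -> FeatureMatrix:
    """Apply one extractor to a cohort, preserving subject order."""
    maps_list = _as_maps_list(maps_seq)
    if len(maps_list) != len(subject_ids):
        raise FeatureError("maps and subject_ids lengths differ")
    extractor.fit(maps_list)
    return FeatureMatrix(
        values=extractor.transform(maps_list),
        subject_ids=[str(s) for s in subject_ids],
        method=extractor.method,
    )
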