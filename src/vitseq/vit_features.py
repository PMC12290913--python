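"""Per-slice feature encoding and feature persistence.

Each subject's ordered slice folder becomes one feature matrix of shape
(n_slices x feature_dim) via a pluggable slice encoder. The default encoder
is a deterministic stub — a seeded random linear projection of per-patch
mean intensities — which shares the geometry of a ViT-Base/16 front end
(224x224 input cut into 16-pixel patches, 14x14 grid) without needing
pretrained weights. Features are persisted per subject as
``<subject>_scan_data.npy`` / ``<subject>_scan_labels.npy`` in a flat
directory, with a JSON sidecar recording the encoder configuration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .errors import DataError, FormatError, ParameterError, ShapeError
from .slice_prep import PLANES

CLASS_NAMES = ("NC", "MCI", "AD")
#: Fixed label encoding used everywhere downstream.
CLASS_CODES = {"NC": 0, "MCI": 1, "AD": 2}

DEFAULT_IMAGE_SIDE = 224
DEFAULT_PATCH_SIDE = 16

_SLICE_SUFFIXES = (".png", ".jpg", ".jpeg")


# ---------------------------------------------------------------------------
# Patch geometry
# ---------------------------------------------------------------------------

@dataclass
class PatchGrid:
    """Non-overlapping square patches of an image, row-major order."""

    patches: np.ndarray  # (n_patches, patch_side**2 * channels)
    grid_shape: tuple[int, int]
    patch_side: int
    channels: int = 1
    squeeze: bool = True  # original image had no channel axis

    @property
    def n_patches(self) -> int:
        return self.grid_shape[0] * self.grid_shape[1]


def patchify(image: np.ndarray, patch_side: int = DEFAULT_PATCH_SIDE) -> PatchGrid:
    """Cut an image into non-overlapping ``patch_side`` squares.

    A 224x224 input with 16-pixel patches yields the standard 14x14 grid of
    196 patches. Each patch is flattened in row-major pixel order with the
    channel axis (if any) innermost.
    """
    if patch_side <= 0:
        raise ParameterError(f"patch_side must be positive, got {patch_side}")
    arr = np.asarray(image, dtype=np.float64)
    squeeze = arr.ndim == 2
    if squeeze:
        arr = arr[:, :, None]
    if arr.ndim != 3:
        raise ParameterError(f"expected a 2D or HxWxC image, got shape {image.shape}")
    h, w, c = arr.shape
    if h % patch_side or w % patch_side:
        raise ParameterError(
            f"image sides ({h}, {w}) are not divisible by patch_side {patch_side}"
        )
    rows, cols = h // patch_side, w // patch_side
    patches = (
        arr.reshape(rows, patch_side, cols, patch_side, c)
        .transpose(0, 2, 1, 3, 4)
        .reshape(rows * cols, patch_side * patch_side * c)
    )
    return PatchGrid(patches, (rows, cols), patch_side, c, squeeze)


def unpatchify(grid: PatchGrid) -> np.ndarray:
    """Exact inverse of :func:`patchify`."""
    rows, cols = grid.grid_shape
    p, c = grid.patch_side, grid.channels
    patches = np.asarray(grid.patches, dtype=np.float64)
    if patches.ndim != 2 or patches.shape[0] != rows * cols:
        raise FormatError(
            f"expected {rows * cols} patch rows, got array of shape {patches.shape}"
        )
    if patches.shape[1] != p * p * c:
        raise FormatError(
            f"patch vectors of length {patches.shape[1]} inconsistent with "
            f"patch_side {p} and {c} channel(s)"
        )
    img = (
        patches.reshape(rows, cols, p, p, c)
        .transpose(0, 2, 1, 3, 4)
        .reshape(rows * p, cols * p, c)
    )
    return img[:, :, 0] if grid.squeeze else img


# ---------------------------------------------------------------------------
# Slice encoders
# ---------------------------------------------------------------------------

class SliceEncoder:
    """Interface of a per-slice feature encoder (a pure function of the image)."""

    name: str
    feature_dim: int
    image_side: int = DEFAULT_IMAGE_SIDE

    def encode(self, image: np.ndarray) -> np.ndarray:  # (side, side, 3) -> (dim,)
        raise NotImplementedError


class StubProjectionEncoder(SliceEncoder):
    """Seeded random linear projection of per-patch mean intensities.

    Computes the mean intensity of each of the 196 patches (averaged over
    pixels and channels) and maps the resulting vector through a fixed
    Gaussian matrix drawn once from the seed. Cheap, deterministic and
    order-sensitive: permuting patches or changing a single pixel changes
    the output.
    """

    name = "stub_projection"

    def __init__(
        self,
        feature_dim: int = 64,
        seed: int = 0,
        image_side: int = DEFAULT_IMAGE_SIDE,
        patch_side: int = DEFAULT_PATCH_SIDE,
    ):
        if feature_dim <= 0:
            raise ParameterError(f"feature_dim must be positive, got {feature_dim}")
        self.feature_dim = feature_dim
        self.seed = seed
        self.image_side = image_side
        self.patch_side = patch_side
        n_patches = (image_side // patch_side) ** 2
        rng = np.random.default_rng(seed)
        # scale keeps output variance comparable to input variance
        self.projection = rng.standard_normal((n_patches, feature_dim)) / np.sqrt(
            n_patches
        )

    def encode(self, image: np.ndarray) -> np.ndarray:
        grid = patchify(image, self.patch_side)
        patch_means = grid.patches.mean(axis=1)
        return patch_means @ self.projection


class PretrainedViTEncoder(SliceEncoder):
    """Frozen pretrained ViT-Base/16 backend (optional; needs timm or transformers).

    The slice feature is the encoder's pooled/class-token output. This
    backend is pluggable and never required by the test suite.
    """

    name = "pretrained_vit"

    def __init__(self, model_name: str = "vit_base_patch16_224"):
        try:
            import timm  # noqa: F401
        except ImportError as exc:
            raise ParameterError(
                "the pretrained ViT backend requires the optional 'timm' "
                "dependency; install it or use backend='stub'"
            ) from exc
        import timm

        self._model = timm.create_model(model_name, pretrained=True, num_classes=0)
        self._model.eval()
        self.feature_dim = self._model.num_features

    def encode(self, image: np.ndarray) -> np.ndarray:
        import torch

        x = torch.from_numpy(np.ascontiguousarray(image, dtype=np.float32))
        x = x.permute(2, 0, 1)[None]
        with torch.no_grad():
            return self._model(x).numpy()[0]


def make_encoder(
    name: str,
    feature_dim: int = 64,
    seed: int = 0,
    image_side: int = DEFAULT_IMAGE_SIDE,
    patch_side: int = DEFAULT_PATCH_SIDE,
) -> SliceEncoder:
    if name in ("stub", "stub_projection"):
        return StubProjectionEncoder(
            feature_dim=feature_dim, seed=seed, image_side=image_side, patch_side=patch_side
        )
    if name in ("pretrained", "pretrained_vit"):
        return PretrainedViTEncoder()
    raise ParameterError(f"unknown encoder backend {name!r}")


def encode_slice(image: np.ndarray, backend: SliceEncoder) -> np.ndarray:
    """Encode one slice to a feature vector.

    Grayscale input is replicated to three channels first, matching how
    natural-image-pretrained encoders expect their input.
    """
    arr = np.asarray(image, dtype=np.float64)
    side = backend.image_side
    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    if arr.shape != (side, side, 3):
        raise ParameterError(
            f"expected a ({side}, {side}) grayscale or ({side}, {side}, 3) "
            f"image, got shape {np.asarray(image).shape}"
        )
    vec = np.asarray(backend.encode(arr), dtype=np.float64)
    if vec.shape != (backend.feature_dim,) or not np.all(np.isfinite(vec)):
        raise FormatError(
            f"backend {backend.name!r} returned an invalid feature vector"
        )
    return vec


# ---------------------------------------------------------------------------
# Feature sequences and persistence
# ---------------------------------------------------------------------------

@dataclass
class FeatureSequence:
    """One subject's ordered slice-feature matrix plus its diagnosis label."""

    features: np.ndarray  # (n_slices, feature_dim)
    label: str
    subject_id: str
    plane: str | None = "axial"

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        if self.features.ndim != 2 or self.features.shape[1] < 1:
            raise ShapeError(
                f"features must be (n_slices, feature_dim), got {self.features.shape}"
            )
        if not np.all(np.isfinite(self.features)):
            raise DataError(f"non-finite feature values for subject {self.subject_id}")
        if self.label not in CLASS_NAMES:
            raise DataError(f"unknown label {self.label!r}; expected one of {CLASS_NAMES}")
        if self.plane is not None and self.plane not in PLANES:
            raise ParameterError(f"unknown plane {self.plane!r}")

    @property
    def label_code(self) -> int:
        return CLASS_CODES[self.label]


def extract_subject_features(
    slice_dir: str | Path,
    backend: SliceEncoder,
    label: str,
    seq_len: int | None = 50,
    subject_id: str | None = None,
) -> FeatureSequence:
    """Encode a prepared slice folder into one ordered feature matrix.

    Slices are read in filename order (the writer zero-pads indices so this
    equals anatomical order); row i of the result is the encoding of the
    i-th slice.
    """
    slice_dir = Path(slice_dir)
    files = sorted(
        p for p in slice_dir.iterdir() if p.suffix.lower() in _SLICE_SUFFIXES
    ) if slice_dir.is_dir() else []
    if not slice_dir.is_dir() or not files:
        raise IOError(f"no slice images found in {slice_dir}")
    if seq_len is not None and len(files) != seq_len:
        raise ShapeError(
            f"{slice_dir}: found {len(files)} slices, configured sequence "
            f"length is {seq_len}"
        )
    plane = slice_dir.name if slice_dir.name in PLANES else None
    if subject_id is None:
        subject_id = slice_dir.parent.name if plane else slice_dir.name
    rows = []
    for path in files:
        try:
            img = np.asarray(Image.open(path).convert("L"), dtype=np.float64) / 255.0
        except Exception as exc:
            raise IOError(f"cannot read slice image {path}: {exc}") from exc
        rows.append(encode_slice(img, backend))
    return FeatureSequence(np.stack(rows), label, subject_id, plane)


def save_features(seq: FeatureSequence, out_dir: str | Path) -> list[Path]:
    """Persist one subject as flat ``<id>_scan_data.npy`` / ``<id>_scan_labels.npy``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    data_path = out_dir / f"{seq.subject_id}_scan_data.npy"
    label_path = out_dir / f"{seq.subject_id}_scan_labels.npy"
    np.save(data_path, seq.features)
    np.save(label_path, np.int64(seq.label_code))
    return [data_path, label_path]


def load_features(in_dir: str | Path, subject_id: str) -> FeatureSequence:
    """Inverse of :func:`save_features` for one subject."""
    in_dir = Path(in_dir)
    data_path = in_dir / f"{subject_id}_scan_data.npy"
    label_path = in_dir / f"{subject_id}_scan_labels.npy"
    if not data_path.exists():
        raise FormatError(f"missing feature file {data_path}")
    if not label_path.exists():
        raise FormatError(f"missing companion label file {label_path}")
    code = int(np.load(label_path))
    if code not in CLASS_CODES.values():
        raise FormatError(f"{label_path}: invalid label code {code}")
    return FeatureSequence(
        np.load(data_path), CLASS_NAMES[code], subject_id, plane=None
    )


def list_subjects(in_dir: str | Path) -> list[str]:
    return sorted(
        p.name[: -len("_scan_data.npy")]
        for p in Path(in_dir).glob("*_scan_data.npy")
    )


def load_feature_dataset(in_dir: str | Path) -> list[FeatureSequence]:
    subjects = list_subjects(in_dir)
    if not subjects:
        raise FormatError(f"no *_scan_data.npy files found in {in_dir}")
    return [load_features(in_dir, sid) for sid in subjects]


def save_feature_metadata(out_dir: str | Path, backend: SliceEncoder) -> Path:
    """JSON sidecar recording the encoder configuration of a feature directory."""
    meta = {
        "backend": backend.name,
        "feature_dim": backend.feature_dim,
        "seed": getattr(backend, "seed", None),
    }
    path = Path(out_dir) / "features_meta.json"
    path.write_text(json.dumps(meta, indent=2))
    return path
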