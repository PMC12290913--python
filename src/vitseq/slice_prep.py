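"""Slice extraction from registered 3D volumes.

Converts a skull-stripped, template-registered T1 volume into the on-disk
layout consumed by the feature extractor: one folder per subject, one
sub-folder per sectioning plane, holding the central-k slices resized to the
encoder's input resolution and saved as 8-bit grayscale PNGs in anatomical
order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
from PIL import Image
from skimage.transform import resize as _skimage_resize

from .errors import FormatError, InsufficientSlicesError, ParameterError

logger = logging.getLogger(__name__)

PLANES = ("sagittal", "coronal", "axial")

#: NIfTI orientation codes -> the plane obtained by sectioning along that axis.
_AXCODE_TO_PLANE = {
    "L": "sagittal",
    "R": "sagittal",
    "A": "coronal",
    "P": "coronal",
    "S": "axial",
    "I": "axial",
}


@dataclass
class VolumeImage:
    """A 3D scalar intensity grid with voxel spacing and orientation.

    ``axis_labels[i]`` names the anatomical plane produced by slicing along
    array axis ``i``; the three labels are always a permutation of
    sagittal / coronal / axial.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    axis_labels: tuple[str, str, str] = ("sagittal", "coronal", "axial")

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise FormatError(f"volume must be 3D, got {self.data.ndim}D")
        if min(self.data.shape) < 1:
            raise FormatError("all volume dimensions must be >= 1")
        if any(s <= 0 for s in self.spacing):
            raise ParameterError(f"voxel spacing must be positive: {self.spacing}")
        if sorted(self.axis_labels) != sorted(PLANES):
            raise ParameterError(
                f"axis_labels must be a permutation of {PLANES}: {self.axis_labels}"
            )


@dataclass
class SliceStack:
    """An ordered stack of 2D grayscale slices from one subject and plane."""

    slices: list[np.ndarray]
    plane: str
    source_indices: list[int]
    subject_id: str = "subject"

    def __post_init__(self) -> None:
        if not self.slices:
            raise FormatError("slice stack must be nonempty")
        if self.plane not in PLANES:
            raise ParameterError(f"unknown plane {self.plane!r}; expected one of {PLANES}")
        if len(self.source_indices) != len(self.slices):
            raise FormatError("one source index per slice required")
        diffs = np.diff(self.source_indices)
        if len(diffs) and not np.all(diffs == 1):
            raise FormatError("source_indices must be strictly increasing and consecutive")
        shapes = {s.shape for s in self.slices}
        if len(shapes) != 1:
            raise FormatError(f"all slices must share one shape, got {shapes}")

    def __len__(self) -> int:
        return len(self.slices)


def load_volume(path: str | Path) -> VolumeImage:
    """Read a 3D NIfTI file into a :class:`VolumeImage`.

    Spacing comes from the header zooms and the plane-to-axis mapping from
    the affine orientation codes; volumes whose orientation cannot be
    determined are assumed RAS with a logged warning. Intensities are passed
    through unmodified.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # unreadable / not NIfTI
        raise FormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D volume, got {data.ndim}D data")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    try:
        axcodes = nib.aff2axcodes(img.affine)
        axis_labels = tuple(_AXCODE_TO_PLANE[c] for c in axcodes)
        if sorted(axis_labels) != sorted(PLANES):
            raise KeyError(axcodes)
    except (KeyError, TypeError):
        logger.warning("%s: missing/degenerate orientation, assuming RAS", path)
        axis_labels = ("sagittal", "coronal", "axial")
    return VolumeImage(np.asarray(data, dtype=np.float64), spacing, axis_labels)


def save_volume(volume: VolumeImage, path: str | Path) -> Path:
    """Write a volume as NIfTI with its spacing declared in the affine."""
    path = Path(path)
    affine = np.diag([*volume.spacing, 1.0])
    nib.save(nib.Nifti1Image(volume.data.astype(np.float32), affine), str(path))
    return path


def extract_plane_slices(
    volume: VolumeImage, plane: str, subject_id: str = "subject"
) -> SliceStack:
    """Section a volume along one anatomical plane, one slice per index."""
    if plane not in PLANES:
        raise ParameterError(f"unknown plane {plane!r}; expected one of {PLANES}")
    axis = volume.axis_labels.index(plane)
    n = volume.data.shape[axis]
    slices = [np.take(volume.data, i, axis=axis) for i in range(n)]
    return SliceStack(slices, plane, list(range(n)), subject_id)


def select_central(stack: SliceStack, k: int = 50) -> SliceStack:
    """Keep the ``k`` contiguous slices centered on the stack midpoint.

    With ``N`` input slices the window starts at ``(N - k) // 2``, so when
    ``N - k`` is odd the extra discarded slice comes from the top of the
    stack. Source indices are preserved from the input.
    """
    if k <= 0:
        raise ParameterError(f"k must be positive, got {k}")
    n = len(stack)
    if n < k:
        raise InsufficientSlicesError(n, k)
    start = (n - k) // 2
    return SliceStack(
        stack.slices[start : start + k],
        stack.plane,
        stack.source_indices[start : start + k],
        stack.subject_id,
    )


def resize_slice(slice_: np.ndarray, side: int = 224) -> np.ndarray:
    """Bilinearly resize a 2D slice to ``side x side`` pixels.

    The output is clamped to the input's intensity range so interpolation
    never overshoots.
    """
    if side <= 0:
        raise ParameterError(f"side must be positive, got {side}")
    arr = np.asarray(slice_, dtype=np.float64)
    if arr.ndim != 2 or arr.size == 0:
        raise ParameterError(f"expected a nonempty 2D slice, got shape {arr.shape}")
    if arr.shape == (side, side):
        return arr.copy()
    out = _skimage_resize(
        arr, (side, side), order=1, anti_aliasing=False, preserve_range=True
    )
    return np.clip(out, arr.min(), arr.max())


def save_slice_folder(stack: SliceStack, root: str | Path) -> list[Path]:
    """Write a prepared stack as ``root/<subject>/<plane>/slice_<idx>.png``.

    Each slice is min-max scaled to 8-bit grayscale independently; indices in
    filenames are zero-padded so lexicographic order equals anatomical order.
    Returns the written paths in that order.
    """
    out_dir = Path(root) / stack.subject_id / stack.plane
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create slice folder under {root}: {exc}") from exc
    pad = max(3, len(str(max(stack.source_indices))))
    paths: list[Path] = []
    for idx, sl in zip(stack.source_indices, stack.slices):
        paths.append(out_dir / f"slice_{idx:0{pad}d}.png")
        Image.fromarray(quantize_slice(sl), mode="L").save(paths[-1])
    return paths


def quantize_slice(slice_: np.ndarray) -> np.ndarray:
    """Per-slice min-max mapping to uint8; a constant slice maps to 0."""
    arr = np.asarray(slice_, dtype=np.float64)
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        return np.zeros(arr.shape, dtype=np.uint8)
    return np.round((arr - lo) / (hi - lo) * 255.0).astype(np.uint8)


def prepare_subject(
    volume: VolumeImage,
    out_root: str | Path,
    subject_id: str,
    plane: str = "axial",
    k: int = 50,
    side: int = 224,
) -> list[Path]:
    """Full per-subject preparation: section, central-select, resize, save."""
    stack = extract_plane_slices(volume, plane, subject_id)
    stack = select_central(stack, k)
    resized = [resize_slice(s, side) for s in stack.slices]
    stack = SliceStack(resized, plane, stack.source_indices, subject_id)
    return save_slice_folder(stack, out_root)
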