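"""Synthetic phantoms and feature-sequence datasets with known class structure.

Real cohort data (e.g. ADNI) cannot ship with the package, so every
downstream stage is exercised on two synthetic families instead:

* **Intensity phantoms** — concentric ellipsoids (a bright "brain" shell
  with a dark internal cavity) whose cavity radius grows NC < MCI < AD,
  mimicking the direction of ventricular enlargement under atrophy. These
  exercise the volume -> slices -> features path.
* **Feature sequences** — class-conditional Gaussian sequences of shape
  (seq_len x feature_dim) whose class means sit ``separation`` noise
  standard deviations apart along orthogonal axes, plus a slice-position-
  dependent sinusoidal component of amplitude ``positional_signal`` so that
  slice order carries information. These exercise folding, training and
  evaluation with analytically known difficulty.

Both are seeded: one global seed expands into per-subject sub-seeds as
``seed + subject_index``, so individual subjects are reproducible in
isolation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ParameterError
from .slice_prep import VolumeImage, save_volume
from .vit_features import CLASS_NAMES, FeatureSequence, save_features

#: Default cavity radius as a fraction of the brain radius, ordered to mimic
#: atrophy: larger ventricles with disease progression.
VENTRICLE_SCALE_PRESET = {"NC": 0.15, "MCI": 0.25, "AD": 0.35}

_BRAIN_RADIUS = 0.85  # fraction of the half-extent of the grid
_BRAIN_INTENSITY = 0.8
_CAVITY_INTENSITY = 0.05


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic class-conditional phantom volume."""

    class_label: str
    shape: tuple[int, int, int] = (32, 32, 32)
    ventricle_scale: float | None = None  # None -> class preset
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_NAMES:
            raise ParameterError(
                f"unknown class {self.class_label!r}; expected one of {CLASS_NAMES}"
            )
        if len(self.shape) != 3 or any(int(s) < 8 for s in self.shape):
            raise ParameterError(
                f"phantom shape must be a triple with components >= 8: {self.shape}"
            )
        if self.noise_sd < 0:
            raise ParameterError(f"noise_sd must be non-negative: {self.noise_sd}")
        if self.ventricle_scale is not None and self.ventricle_scale < 0:
            raise ParameterError(
                f"ventricle_scale must be non-negative: {self.ventricle_scale}"
            )

    @property
    def resolved_ventricle_scale(self) -> float:
        if self.ventricle_scale is not None:
            return self.ventricle_scale
        return VENTRICLE_SCALE_PRESET[self.class_label]


@dataclass(frozen=True)
class SyntheticFeatureSpec:
    """Parameters of a class-conditional slice-feature-sequence dataset."""

    n_per_class: int = 20
    seq_len: int = 50
    feature_dim: int = 64
    separation: float = 6.0  # between-class mean offset, in noise-sd units
    positional_signal: float = 1.0  # amplitude of the slice-index component
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ParameterError("n_per_class must be a positive integer")
        if self.seq_len < 1:
            raise ParameterError("seq_len must be a positive integer")
        if self.feature_dim < len(CLASS_NAMES):
            raise ParameterError(
                f"feature_dim must be >= {len(CLASS_NAMES)} so class mean "
                f"directions can be orthogonal; got {self.feature_dim}"
            )
        if self.separation < 0 or self.positional_signal < 0:
            raise ParameterError("separation and positional_signal must be >= 0")


def _normalized_coords(shape: tuple[int, int, int]) -> list[np.ndarray]:
    """Per-axis coordinates scaled to [-1, 1] across the grid."""
    axes = []
    for i, n in enumerate(shape):
        c = (np.arange(n) - (n - 1) / 2.0) / ((n - 1) / 2.0)
        shp = [1, 1, 1]
        shp[i] = n
        axes.append(c.reshape(shp))
    return axes


def make_phantom_volume(spec: PhantomSpec) -> VolumeImage:
    """Render one phantom: bright ellipsoidal brain, dark internal cavity.

    The cavity radius is ``ventricle_scale`` times the brain radius; additive
    Gaussian noise with sd ``noise_sd`` is applied and the result clipped to
    [0, 1]. Identical specs produce bitwise-identical volumes.
    """
    shape = tuple(int(s) for s in spec.shape)
    u, v, w = _normalized_coords(shape)
    r2_brain = (u / _BRAIN_RADIUS) ** 2 + (v / _BRAIN_RADIUS) ** 2 + (w / _BRAIN_RADIUS) ** 2
    data = np.where(r2_brain <= 1.0, _BRAIN_INTENSITY, 0.0)
    vs = spec.resolved_ventricle_scale
    if vs > 0:
        cavity_r = _BRAIN_RADIUS * vs
        r2_cav = (u / cavity_r) ** 2 + (v / cavity_r) ** 2 + (w / cavity_r) ** 2
        data = np.where(r2_cav <= 1.0, _CAVITY_INTENSITY, data)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        data = data + rng.normal(0.0, spec.noise_sd, size=shape)
    return VolumeImage(np.clip(data, 0.0, 1.0), spacing=(1.0, 1.0, 1.0))


def brain_mask(spec: PhantomSpec) -> np.ndarray:
    """Boolean mask of the ellipsoidal brain region for a given spec."""
    u, v, w = _normalized_coords(tuple(int(s) for s in spec.shape))
    r2 = (u / _BRAIN_RADIUS) ** 2 + (v / _BRAIN_RADIUS) ** 2 + (w / _BRAIN_RADIUS) ** 2
    return r2 <= 1.0


def make_phantom_cohort(
    n_per_class: int,
    shape: tuple[int, int, int] = (32, 32, 32),
    noise_sd: float = 0.02,
    seed: int = 0,
) -> list[tuple[str, PhantomSpec]]:
    """Balanced cohort of phantom specs, subject ids ``<label>_<j>``."""
    cohort = []
    idx = 0
    for label in CLASS_NAMES:
        for j in range(n_per_class):
            spec = PhantomSpec(
                class_label=label, shape=shape, noise_sd=noise_sd, seed=seed + idx
            )
            cohort.append((f"{label}_{j:03d}", spec))
            idx += 1
    return cohort


def write_phantom_cohort(
    cohort: list[tuple[str, PhantomSpec]], out_dir: str | Path
) -> list[Path]:
    """Write each phantom as ``<subject>.nii.gz`` with 1 mm isotropic spacing."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    return [
        save_volume(make_phantom_volume(spec), out_dir / f"{sid}.nii.gz")
        for sid, spec in cohort
    ]


def make_feature_dataset(spec: SyntheticFeatureSpec) -> list[FeatureSequence]:
    """Generate a balanced, seeded list of labelled feature sequences.

    Class ``c`` sequences are ``separation * e_c`` (orthogonal unit
    directions ``e_c`` = the first three coordinate axes) plus the positional
    waveform ``positional_signal * sin(2*pi*t/seq_len)`` (added to every
    feature dimension) plus unit-sd Gaussian noise. Subject ``g`` (global
    index, class-major order) uses sub-seed ``seed + g``.
    """
    L, D = spec.seq_len, spec.feature_dim
    t = np.arange(L)
    positional = spec.positional_signal * np.sin(2.0 * np.pi * t / L)[:, None]
    sequences: list[FeatureSequence] = []
    g = 0
    for c, label in enumerate(CLASS_NAMES):
        mean = np.zeros(D)
        mean[c] = spec.separation
        for j in range(spec.n_per_class):
            rng = np.random.default_rng(spec.seed + g)
            x = mean[None, :] + positional + rng.standard_normal((L, D))
            sequences.append(
                FeatureSequence(x, label, subject_id=f"{label}_{j:03d}")
            )
            g += 1
    return sequences


def write_feature_dataset(
    sequences: list[FeatureSequence], out_dir: str | Path
) -> list[Path]:
    """Persist a dataset in the scan_data / scan_labels file convention."""
    paths: list[Path] = []
    for seq in sequences:
        paths.extend(save_features(seq, out_dir))
    return paths
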