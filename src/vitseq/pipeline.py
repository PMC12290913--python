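"""End-to-end orchestration of the slice-classification workflow.

Mirrors the three-script structure of the original workflow — feature
extraction, fold splitting, train/evaluate — plus synthetic-fixture
generation, behind a single :class:`PipelineConfig`. Each stage reads the
previous stage's directory, so stages can be run one at a time (the CLI
exposes them as subcommands) or chained with :func:`run_demo`. Every stage
logs its inputs/outputs and records a manifest with content hashes of its
prerequisites; one global seed propagates to every stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import shutil
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import evaluation, fixtures, fold_split, sequence_transformer, slice_prep, vit_features
from .errors import DependencyError, StageError
from .sequence_transformer import ModelConfig
from .vit_features import CLASS_NAMES

logger = logging.getLogger(__name__)

STAGES = ("make-fixtures", "prepare-slices", "extract-features", "split-folds", "train-eval")


@dataclass
class PipelineConfig:
    """One document configuring every stage of the pipeline.

    ``source`` selects what the fixtures stage generates: ``"features"``
    (synthetic feature sequences, fast path) or ``"phantoms"`` (synthetic
    volumes pushed through slicing and the slice encoder, full path).
    ``model`` holds keyword overrides for :class:`ModelConfig`.
    """

    workdir: Path = Path("vitseq_work")
    source: str = "features"
    n_per_class: int = 20
    seq_len: int = 50
    feature_dim: int = 64
    separation: float = 6.0
    positional_signal: float = 1.0
    phantom_shape: tuple[int, int, int] = (64, 64, 64)
    phantom_noise_sd: float = 0.02
    plane: str = "axial"
    k_slices: int = 50
    image_side: int = 224
    backend: str = "stub"
    n_folds: int = 10
    val_frac: float = 0.2
    model: dict = field(default_factory=dict)
    seed: int = 17

    def __post_init__(self) -> None:
        self.workdir = Path(self.workdir)
        if self.source not in ("features", "phantoms"):
            raise ValueError(f"source must be 'features' or 'phantoms': {self.source!r}")

    # stage directories -----------------------------------------------------
    @property
    def phantoms_dir(self) -> Path:
        return self.workdir / "phantoms"

    @property
    def slices_dir(self) -> Path:
        return self.workdir / "prepared_data"

    @property
    def features_dir(self) -> Path:
        return self.workdir / "features"

    @property
    def folds_dir(self) -> Path:
        return self.workdir / "kfold_splits"

    @property
    def results_dir(self) -> Path:
        return self.workdir / "results"

    @property
    def effective_seq_len(self) -> int:
        return self.k_slices if self.source == "phantoms" else self.seq_len

    def model_config(self, fold_seed_offset: int = 0) -> ModelConfig:
        kwargs = dict(
            feature_dim=self.feature_dim,
            seq_len=self.effective_seq_len,
            n_classes=len(CLASS_NAMES),
            seed=self.seed + fold_seed_offset,
        )
        kwargs.update(self.model)
        kwargs["seed"] = kwargs["seed"] + fold_seed_offset if "seed" in self.model else kwargs["seed"]
        return ModelConfig(**kwargs)

    # (de)serialization -----------------------------------------------------
    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        d = dataclasses.asdict(self)
        d["workdir"] = str(self.workdir)
        d["phantom_shape"] = list(self.phantom_shape)
        path.write_text(json.dumps(d, indent=2))
        return path

    @classmethod
    def from_json(cls, path: str | Path, **overrides) -> "PipelineConfig":
        d = json.loads(Path(path).read_text())
        d.update(overrides)
        if "phantom_shape" in d:
            d["phantom_shape"] = tuple(d["phantom_shape"])
        return cls(**d)


# ---------------------------------------------------------------------------
# Stage plumbing
# ---------------------------------------------------------------------------

def _hash_tree(root: Path, limit: int = 512) -> dict[str, str]:
    """Short sha256 content hashes of (up to ``limit``) files under a path."""
    hashes = {}
    files = sorted(p for p in root.rglob("*") if p.is_file())[:limit]
    for p in files:
        h = hashlib.sha256(p.read_bytes()).hexdigest()[:12]
        hashes[str(p.relative_to(root))] = h
    return hashes


def _require(stage: str, *paths: Path) -> None:
    missing = [str(p) for p in paths if not p.exists()]
    if missing:
        raise DependencyError(
            f"stage '{stage}' requires outputs that do not exist: {missing}"
        )


def _fresh_dir(path: Path, overwrite: bool) -> Path:
    if path.exists() and any(path.iterdir()):
        if not overwrite:
            raise FileExistsError(
                f"{path} already contains outputs; pass overwrite/--overwrite "
                "to replace them"
            )
        shutil.rmtree(path)
    path.mkdir(parents=True, exist_ok=True)
    return path


def _write_manifest(config: PipelineConfig, stage: str, inputs: dict, outputs: list, t0: float) -> dict:
    manifest = {
        "stage": stage,
        "seed": config.seed,
        "inputs": inputs,
        "outputs": [str(p) for p in outputs],
        "wall_time_s": round(time.perf_counter() - t0, 3),
    }
    mdir = config.workdir / "manifests"
    mdir.mkdir(parents=True, exist_ok=True)
    (mdir / f"{stage}.json").write_text(json.dumps(manifest, indent=2))
    logger.info(
        "stage %s: %d inputs, %d outputs, %.2fs",
        stage, len(inputs), len(outputs), manifest["wall_time_s"],
    )
    return manifest


def _label_of(subject_id: str) -> str:
    label = subject_id.split("_")[0]
    if label not in CLASS_NAMES:
        raise DependencyError(
            f"cannot infer diagnosis label from subject id {subject_id!r}"
        )
    return label


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_make_fixtures(config: PipelineConfig, overwrite: bool = False) -> dict:
    t0 = time.perf_counter()
    if config.source == "phantoms":
        out = _fresh_dir(config.phantoms_dir, overwrite)
        cohort = fixtures.make_phantom_cohort(
            config.n_per_class,
            shape=config.phantom_shape,
            noise_sd=config.phantom_noise_sd,
            seed=config.seed,
        )
        outputs = fixtures.write_phantom_cohort(cohort, out)
    else:
        out = _fresh_dir(config.features_dir, overwrite)
        spec = fixtures.SyntheticFeatureSpec(
            n_per_class=config.n_per_class,
            seq_len=config.seq_len,
            feature_dim=config.feature_dim,
            separation=config.separation,
            positional_signal=config.positional_signal,
            seed=config.seed,
        )
        outputs = fixtures.write_feature_dataset(fixtures.make_feature_dataset(spec), out)
    return _write_manifest(config, "make-fixtures", {}, outputs, t0)


def stage_prepare_slices(config: PipelineConfig, overwrite: bool = False) -> dict:
    t0 = time.perf_counter()
    _require("prepare-slices", config.phantoms_dir)
    inputs = _hash_tree(config.phantoms_dir)
    out = _fresh_dir(config.slices_dir, overwrite)
    outputs: list[Path] = []
    for nii in sorted(config.phantoms_dir.glob("*.nii*")):
        sid = nii.name.split(".nii")[0]
        volume = slice_prep.load_volume(nii)
        outputs.extend(
            slice_prep.prepare_subject(
                volume, out, sid, config.plane, config.k_slices, config.image_side
            )
        )
    return _write_manifest(config, "prepare-slices", inputs, outputs, t0)


def stage_extract_features(config: PipelineConfig, overwrite: bool = False) -> dict:
    t0 = time.perf_counter()
    _require("extract-features", config.slices_dir)
    inputs = _hash_tree(config.slices_dir)
    out = _fresh_dir(config.features_dir, overwrite)
    backend = vit_features.make_encoder(
        config.backend,
        feature_dim=config.feature_dim,
        seed=config.seed,
        image_side=config.image_side,
    )
    outputs: list[Path] = []
    for subject_dir in sorted(p for p in config.slices_dir.iterdir() if p.is_dir()):
        sid = subject_dir.name
        seq = vit_features.extract_subject_features(
            subject_dir / config.plane,
            backend,
            _label_of(sid),
            seq_len=config.k_slices,
            subject_id=sid,
        )
        outputs.extend(vit_features.save_features(seq, out))
    outputs.append(vit_features.save_feature_metadata(out, backend))
    return _write_manifest(config, "extract-features", inputs, outputs, t0)


def stage_split_folds(config: PipelineConfig, overwrite: bool = False) -> dict:
    t0 = time.perf_counter()
    _require("split-folds", config.features_dir)
    inputs = _hash_tree(config.features_dir)
    out = _fresh_dir(config.folds_dir, overwrite)
    sequences = vit_features.load_feature_dataset(config.features_dir)
    folds = fold_split.make_folds(
        sequences, n_folds=config.n_folds, val_frac=config.val_frac, seed=config.seed
    )
    fold_split.write_fold_files(folds, sequences, out, seed=config.seed)
    outputs = sorted(out.iterdir())
    return _write_manifest(config, "split-folds", inputs, outputs, t0)


def stage_train_eval(config: PipelineConfig, overwrite: bool = False) -> evaluation.EvalReport:
    t0 = time.perf_counter()
    _require("train-eval", config.folds_dir, config.folds_dir / "manifest.json")
    inputs = _hash_tree(config.folds_dir)
    out = _fresh_dir(config.results_dir, overwrite)
    manifest = json.loads((config.folds_dir / "manifest.json").read_text())
    results = []
    for i in range(1, manifest["n_folds"] + 1):
        data = fold_split.load_fold(config.folds_dir, i)
        mc = config.model_config(fold_seed_offset=i)
        model = sequence_transformer.train_fold(data["train"], data["valid"], mc)
        _, y_pred = sequence_transformer.predict(model, data["test"][0])
        results.append(evaluation.evaluate_fold(i, data["test"][1], y_pred))
        sequence_transformer.save_model(model, out / f"model_fold{i}")
        logger.info(
            "fold %d: test accuracy %.3f (%d epochs)",
            i, results[-1].metrics.accuracy, len(model.history),
        )
    report = evaluation.aggregate(results)
    evaluation.report_to_json(report, out / "report.json")
    evaluation.report_to_csv(report, out / "report.csv")
    _write_manifest(config, "train-eval", inputs, sorted(out.iterdir()), t0)
    return report


_STAGE_FUNCS = {
    "make-fixtures": stage_make_fixtures,
    "prepare-slices": stage_prepare_slices,
    "extract-features": stage_extract_features,
    "split-folds": stage_split_folds,
    "train-eval": stage_train_eval,
}


def run_stage(stage: str, config: PipelineConfig, overwrite: bool = False):
    """Execute exactly one pipeline stage, with stage-tagged error reporting."""
    if stage not in _STAGE_FUNCS:
        raise DependencyError(f"unknown stage {stage!r}; expected one of {STAGES}")
    try:
        return _STAGE_FUNCS[stage](config, overwrite=overwrite)
    except (DependencyError, FileExistsError):
        raise
    except Exception as exc:
        raise StageError(stage, exc) from exc


def run_demo(config: PipelineConfig, overwrite: bool = True) -> evaluation.EvalReport:
    """Run the whole workflow on synthetic data and return the evaluation.

    With ``source="features"`` (default): generate feature sequences, split
    into folds, train and evaluate. With ``source="phantoms"``: additionally
    exercise the imaging path (phantom volumes -> slice folders -> encoded
    features). Deterministic for a fixed config and seed.
    """
    stages = ["make-fixtures"]
    if config.source == "phantoms":
        stages += ["prepare-slices", "extract-features"]
    stages += ["split-folds", "train-eval"]
    result = None
    for stage in stages:
        result = run_stage(stage, config, overwrite=overwrite)
    return result
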