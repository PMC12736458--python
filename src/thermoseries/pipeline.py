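"""End-to-end pipeline: cohort -> descriptors -> tensor -> classifiers ->
metrics, plus the classifier adapters used by cross-validation.

The TSF path consumes raw (unstandardized, unaugmented) descriptor series.
The LSTM path standardizes fold-locally and triples its training partition
by augmentation; an inner stratified split of the training fold provides
the early-stopping validation set, so held-out subjects are never touched.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.model_selection import train_test_split

from . import __version__
from .assembly import (
    CohortTensor,
    FeatureSetSpec,
    assemble_tensor,
    expand_training_set,
    save_cohort_csv,
    select_features,
    standardize,
)
from .bioheat import Environment
from .evaluation import CVResult, cross_validate, mean_roc
from .features import sequence_descriptors
from .io import read_sequence, write_json_atomic, write_sequence
from .lstm import LSTMClassifier, LSTMConfig
from .phantom import PhantomConfig, ThermogramSequence, generate_cohort
from .tsf import ForestConfig, TimeSeriesForest

__all__ = [
    "RunConfig",
    "TSFPipeline",
    "LSTMPipeline",
    "cohort_tensor",
    "run_pipeline",
    "PipelineError",
]


class PipelineError(RuntimeError):
    """A pipeline stage failed; message carries stage and subject context."""


@dataclass
class TSFPipeline:
    """Forest adapter: no standardization, no augmentation."""

    config: ForestConfig = field(default_factory=ForestConfig)
    forest: TimeSeriesForest | None = None

    def fit(self, train: CohortTensor, seed: int) -> None:
        cfg = ForestConfig(
            n_trees=self.config.n_trees,
            min_interval=self.config.min_interval,
            k=self.config.k,
            max_depth=self.config.max_depth,
            seed=seed,
            margin_tiebreak=self.config.margin_tiebreak,
        )
        self.forest = TimeSeriesForest(cfg).fit(train.values, train.labels)

    def predict_scores(self, test: CohortTensor) -> np.ndarray:
        return self.forest.predict_scores(test.values)

    def predict_labels(self, test: CohortTensor) -> np.ndarray:
        return self.forest.predict(test.values)


@dataclass
class LSTMPipeline:
    """LSTM adapter: fold-local standardization, 3x training augmentation,
    inner validation split for early stopping."""

    config: LSTMConfig = field(default_factory=LSTMConfig)
    augment: bool = True
    val_fraction: float = 0.2
    model: LSTMClassifier | None = None
    _moments = None

    def fit(self, train: CohortTensor, seed: int) -> None:
        idx = np.arange(train.n_subjects)
        tr_idx, val_idx = train_test_split(
            idx,
            test_size=self.val_fraction,
            stratify=train.labels,
            random_state=seed,
        )
        inner_train, inner_val = train.subset(tr_idx), train.subset(val_idx)
        inner_train, (inner_val,), self._moments = standardize(inner_train, inner_val)
        if self.augment:
            inner_train = expand_training_set(inner_train, seed=seed)
        cfg = LSTMConfig(
            hidden=self.config.hidden,
            dense=self.config.dense,
            dropout=self.config.dropout,
            batch_norm=self.config.batch_norm,
            learning_rate=self.config.learning_rate,
            batch_size=self.config.batch_size,
            max_epochs=self.config.max_epochs,
            patience=self.config.patience,
            seed=seed,
        )
        self.model = LSTMClassifier(cfg, train.n_features)
        self.model.fit(
            inner_train.values, inner_train.labels, inner_val.values, inner_val.labels
        )

    def predict_scores(self, test: CohortTensor) -> np.ndarray:
        test = self._moments.apply(test)
        return self.model.predict_proba(test.values)

    def predict_labels(self, test: CohortTensor) -> np.ndarray:
        return (self.predict_scores(test) >= 0.5).astype(int)


def cohort_tensor(
    sequences: list[ThermogramSequence],
    env: Environment | None = None,
    **descriptor_kwargs,
) -> CohortTensor:
    """Extract per-frame descriptors for every subject and assemble the
    N x M x V tensor."""
    subjects = []
    for seq in sequences:
        try:
            df = sequence_descriptors(seq, env, **descriptor_kwargs)
        except Exception as exc:
            raise PipelineError(
                f"descriptor extraction failed for subject {seq.subject_id}: {exc}"
            ) from exc
        subjects.append((seq.subject_id, seq.label, df))
    return assemble_tensor(subjects)


@dataclass(frozen=True)
class RunConfig:
    """End-to-end run configuration (one input source: synthetic or a
    directory of sequence folders)."""

    synthetic: bool = True
    input_dir: str | None = None
    output_dir: str = "thermoseries_out"
    classifier: str = "both"  # tsf | lstm | both
    feature_set: str = "FS1"
    folds: int = 5
    seed: int = 0
    phantom: PhantomConfig | None = None
    forest: ForestConfig = field(default_factory=ForestConfig)
    lstm: LSTMConfig = field(default_factory=LSTMConfig)
    no_plots: bool = False
    write_sequences: bool = False

    def __post_init__(self) -> None:
        if self.synthetic == (self.input_dir is not None):
            raise ValueError("exactly one input source: --synthetic or an input dir")
        if self.classifier not in {"tsf", "lstm", "both"}:
            raise ValueError(f"unknown classifier {self.classifier!r}")


def _cv_payload(cv: CVResult) -> dict:
    fpr, tpr, tpr_sd = mean_roc(cv)
    return {
        "per_fold": cv.metric_matrix().to_dict(orient="list"),
        "summary": {
            k: {"mean": float(v["mean"]), "sd": float(v["sd"])}
            for k, v in cv.summary().iterrows()
        },
        "mean_confusion_normalized": cv.mean_confusion_normalized().tolist(),
        "mean_roc": {"fpr": fpr.tolist(), "tpr": tpr.tolist(), "tpr_sd": tpr_sd.tolist()},
    }


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full pipeline and write artifacts to the output dir.

    Returns the metrics payload that is also written to ``metrics.json``.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    if cfg.synthetic:
        phantom = cfg.phantom or PhantomConfig(seed=cfg.seed)
        sequences = generate_cohort(phantom)
        if cfg.write_sequences:
            seq_dir = out / "sequences"
            for seq in sequences:
                write_sequence(seq, seq_dir / seq.subject_id)
    else:
        root = Path(cfg.input_dir)
        subdirs = sorted(p for p in root.iterdir() if p.is_dir())
        if not subdirs:
            raise PipelineError(f"no sequence directories under {root}")
        sequences = [read_sequence(p) for p in subdirs]

    tensor = cohort_tensor(sequences)
    save_cohort_csv(tensor, out / "features.csv", out / "features_meta.json")
    tensor = select_features(tensor, FeatureSetSpec.named(cfg.feature_set))

    results: dict[str, dict] = {}
    cvs: dict[str, CVResult] = {}
    if cfg.classifier in {"tsf", "both"}:
        cvs["tsf"] = cross_validate(
            lambda: TSFPipeline(cfg.forest), tensor, folds=cfg.folds, seed=cfg.seed
        )
        results["tsf"] = _cv_payload(cvs["tsf"])
    if cfg.classifier in {"lstm", "both"}:
        cvs["lstm"] = cross_validate(
            lambda: LSTMPipeline(cfg.lstm), tensor, folds=cfg.folds, seed=cfg.seed
        )
        results["lstm"] = _cv_payload(cvs["lstm"])

    payload = {
        "feature_set": cfg.feature_set,
        "n_subjects": tensor.n_subjects,
        "n_frames": tensor.n_frames,
        "features": list(tensor.feature_names),
        "classifiers": results,
    }
    write_json_atomic(out / "metrics.json", payload)
    write_json_atomic(out / "manifest.json", _manifest(cfg))

    if not cfg.no_plots:
        _render_plots(out, cvs)
    return payload


def _manifest(cfg: RunConfig) -> dict:
    return {
        "thermoseries_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": cfg.seed,
        "classifier": cfg.classifier,
        "feature_set": cfg.feature_set,
        "folds": cfg.folds,
        "synthetic": cfg.synthetic,
        "input_dir": cfg.input_dir,
        "forest": {
            "n_trees": cfg.forest.n_trees,
            "min_interval": cfg.forest.min_interval,
            "k": cfg.forest.k,
        },
        "lstm": {
            "hidden": list(cfg.lstm.hidden),
            "dense": cfg.lstm.dense,
            "dropout": cfg.lstm.dropout,
            "batch_norm": cfg.lstm.batch_norm,
            "learning_rate": cfg.lstm.learning_rate,
            "batch_size": cfg.lstm.batch_size,
            "max_epochs": cfg.lstm.max_epochs,
            "patience": cfg.lstm.patience,
        },
    }


def _render_plots(out: Path, cvs: dict[str, CVResult]) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for name, cv in cvs.items():
        fig, axes = plt.subplots(1, 2, figsize=(9, 4))
        cm = cv.mean_confusion_normalized()
        im = axes[0].imshow(cm, vmin=0, vmax=1, cmap="Blues")
        axes[0].set_xticks([0, 1], ["control", "cancer"])
        axes[0].set_yticks([0, 1], ["control", "cancer"])
        axes[0].set_xlabel("predicted")
        axes[0].set_ylabel("true")
        for (r, c), v in np.ndenumerate(cm):
            axes[0].text(c, r, f"{v:.2f}", ha="center", va="center")
        fig.colorbar(im, ax=axes[0])
        axes[0].set_title(f"{name.upper()} mean normalized confusion")
        fpr, tpr, sd = mean_roc(cv)
        axes[1].plot(fpr, tpr, label="mean ROC")
        axes[1].fill_between(fpr, np.clip(tpr - sd, 0, 1), np.clip(tpr + sd, 0, 1), alpha=0.3)
        axes[1].plot([0, 1], [0, 1], "k--", lw=0.8)
        axes[1].set_xlabel("false positive rate")
        axes[1].set_ylabel("true positive rate")
        axes[1].set_title(f"{name.upper()} vertically averaged ROC")
        axes[1].legend()
        fig.tight_layout()
        fig.savefig(out / f"{name}_evaluation.png", dpi=120)
        plt.close(fig)
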