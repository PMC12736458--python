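"""Cohort tensor assembly, feature-set selection, standardization and
training-set augmentation.

The cohort is an N x M x V array: N subjects, M=20 frames, V=5 per-frame
descriptors.  Feature sets FS1-FS4 are the descriptor subsets compared in
the classification experiments.  Augmentation (Gaussian noise of sd 0.05
plus 1-2 frame forward shifts with edge repetition) triples the training
partition and is never applied to held-out subjects.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES
from .phantom import CANCER, CONTROL

__all__ = [
    "CohortTensor",
    "FeatureSetSpec",
    "FEATURE_SETS",
    "StandardizationMoments",
    "assemble_tensor",
    "select_features",
    "standardize",
    "augment_noise",
    "augment_shift",
    "expand_training_set",
    "save_cohort_csv",
    "load_cohort_csv",
]

#: Descriptor subsets, in the order they are compared.
FEATURE_SETS: dict[str, tuple[str, ...]] = {
    "FS1": ("q", "Tmax", "Tmean", "sigma", "d"),
    "FS2": ("q", "Tmax", "Tmean", "sigma"),
    "FS3": ("q", "Tmax", "Tmean"),
    "FS4": ("q", "Tmax", "sigma"),
}

LABEL_CODES = {CONTROL: 0, CANCER: 1}


@dataclass(frozen=True)
class FeatureSetSpec:
    name: str
    features: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.features:
            raise ValueError("feature set must be nonempty")
        if len(set(self.features)) != len(self.features):
            raise ValueError(f"duplicate feature in set {self.name}: {self.features}")

    @classmethod
    def named(cls, name: str) -> "FeatureSetSpec":
        if name not in FEATURE_SETS:
            raise ValueError(f"unknown feature set {name!r}; choose from {list(FEATURE_SETS)}")
        return cls(name, FEATURE_SETS[name])


@dataclass(frozen=True)
class CohortTensor:
    """N x M x V feature tensor with labels and subject ids."""

    values: np.ndarray  # (N, M, V)
    labels: np.ndarray  # (N,) int, 1 = cancer
    feature_names: tuple[str, ...]
    subject_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        n, m, v = self.values.shape
        if len(self.labels) != n or len(self.subject_ids) != n:
            raise ValueError("labels/subject_ids must match the number of subjects")
        if v != len(self.feature_names):
            raise ValueError("feature_names must match the last tensor axis")
        if np.isnan(self.values).any():
            raise ValueError("cohort tensor contains NaNs after assembly")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def n_features(self) -> int:
        return self.values.shape[2]

    def univariate(self, feature: str) -> np.ndarray:
        """The N x M series of a single descriptor."""
        return self.values[:, :, self.feature_names.index(feature)]

    def subset(self, indices) -> "CohortTensor":
        indices = np.asarray(indices)
        return CohortTensor(
            self.values[indices],
            self.labels[indices],
            self.feature_names,
            tuple(self.subject_ids[i] for i in indices),
        )


def assemble_tensor(
    subjects: list[tuple[str, str, pd.DataFrame]],
    feature_names: tuple[str, ...] = FEATURE_NAMES,
) -> CohortTensor:
    """Stack per-subject descriptor tables into the cohort tensor.

    ``subjects`` is a list of (subject_id, label, table) where each table
    has one row per frame and the descriptor columns.  All subjects must
    share the same frame count; ragged inputs raise an error naming them.
    """
    if not subjects:
        raise ValueError("no subjects to assemble")
    lengths = {sid: len(df) for sid, _, df in subjects}
    m = max(lengths.values())
    ragged = [sid for sid, ln in lengths.items() if ln != m]
    if ragged:
        raise ValueError(
            f"subjects with frame counts differing from {m}: {ragged}"
        )
    missing_cols = [
        sid
        for sid, _, df in subjects
        if any(fname not in df.columns for fname in feature_names)
    ]
    if missing_cols:
        raise ValueError(f"subjects missing descriptor columns: {missing_cols}")
    values = np.stack(
        [df.loc[:, list(feature_names)].to_numpy(dtype=float) for _, _, df in subjects]
    )
    labels = np.array([LABEL_CODES[label] for _, label, _ in subjects], dtype=int)
    sids = tuple(sid for sid, _, _ in subjects)
    return CohortTensor(values, labels, tuple(feature_names), sids)


def select_features(tensor: CohortTensor, spec: FeatureSetSpec) -> CohortTensor:
    """Reduce V to the spec's features, in the spec's listed order."""
    unknown = [f for f in spec.features if f not in tensor.feature_names]
    if unknown:
        raise ValueError(f"unknown features {unknown}; have {tensor.feature_names}")
    idx = [tensor.feature_names.index(f) for f in spec.features]
    return CohortTensor(
        tensor.values[:, :, idx], tensor.labels, spec.features, tensor.subject_ids
    )


@dataclass(frozen=True)
class StandardizationMoments:
    mean: np.ndarray  # (V,)
    sd: np.ndarray  # (V,)
    feature_names: tuple[str, ...]

    def apply(self, tensor: CohortTensor) -> CohortTensor:
        if tensor.feature_names != self.feature_names:
            raise ValueError("tensor features do not match fitted moments")
        return replace(tensor, values=(tensor.values - self.mean) / self.sd)

    def invert(self, tensor: CohortTensor) -> CohortTensor:
        return replace(tensor, values=tensor.values * self.sd + self.mean)


def standardize(
    train: CohortTensor, *others: CohortTensor
) -> tuple[CohortTensor, tuple[CohortTensor, ...], StandardizationMoments]:
    """Per-feature z-scoring with moments fitted on the training partition
    only (leakage-safe); the same moments are applied to the held-out
    tensors.  Zero-variance features get an sd floor of 1e-12 with a
    warning."""
    flat = train.values.reshape(-1, train.n_features)
    mean = flat.mean(axis=0)
    sd = flat.std(axis=0)
    zero = sd < 1e-12
    if zero.any():
        names = [train.feature_names[i] for i in np.flatnonzero(zero)]
        warnings.warn(f"zero-variance features {names}; sd floored at 1e-12")
        sd = np.where(zero, 1e-12, sd)
    moments = StandardizationMoments(mean, sd, train.feature_names)
    return moments.apply(train), tuple(moments.apply(t) for t in others), moments


def augment_noise(sequence: np.ndarray, sd: float = 0.05, rng=None) -> np.ndarray:
    """Add i.i.d. zero-mean Gaussian noise (default sd 0.05) to every value
    of an M x V sequence."""
    if sd < 0:
        raise ValueError("noise sd must be >= 0")
    rng = np.random.default_rng(rng)
    return sequence + rng.normal(0.0, sd, size=sequence.shape) if sd > 0 else sequence.copy()


def augment_shift(sequence: np.ndarray, s: int) -> np.ndarray:
    """Shift an M x V sequence forward by ``s`` frames, repeating the
    earliest available measurement in the vacated leading positions."""
    m = sequence.shape[0]
    if s >= m:
        raise ValueError(f"shift {s} must be smaller than sequence length {m}")
    if s < 0:
        raise ValueError("shift must be >= 0")
    if s == 0:
        return sequence.copy()
    out = np.empty_like(sequence)
    out[:s] = sequence[0]
    out[s:] = sequence[: m - s]
    return out


def expand_training_set(train: CohortTensor, seed, noise_sd: float = 0.05) -> CohortTensor:
    """Triple the training partition: each sequence contributes itself, one
    noise-augmented copy and one shift-augmented copy (shift drawn from
    {1, 2}).  Labels are copied; augmented ids carry a suffix so held-out
    disjointness stays checkable."""
    if train.n_subjects == 0:
        raise ValueError("empty training partition")
    rng = np.random.default_rng(seed)
    values, labels, sids = [], [], []
    for i in range(train.n_subjects):
        seq = train.values[i]
        lab = int(train.labels[i])
        sid = train.subject_ids[i]
        shift = int(rng.integers(1, 3))
        for suffix, aug in (
            ("", seq.copy()),
            ("#noise", augment_noise(seq, noise_sd, rng)),
            (f"#shift{shift}", augment_shift(seq, shift)),
        ):
            values.append(aug)
            labels.append(lab)
            sids.append(sid + suffix)
    return CohortTensor(
        np.stack(values), np.array(labels), train.feature_names, tuple(sids)
    )


def save_cohort_csv(tensor: CohortTensor, csv_path, meta_path=None) -> None:
    """Persist the tensor as a long-format CSV (subject, label, frame,
    feature, value) plus a JSON metadata sidecar."""
    n, m, v = tensor.values.shape
    subj = np.repeat(list(tensor.subject_ids), m * v)
    lab = np.repeat(tensor.labels, m * v)
    frame = np.tile(np.repeat(np.arange(m), v), n)
    feat = np.tile(list(tensor.feature_names), n * m)
    df = pd.DataFrame(
        {
            "subject": subj,
            "label": lab,
            "frame": frame,
            "feature": feat,
            "value": tensor.values.ravel(),
        }
    )
    df.to_csv(csv_path, index=False)
    if meta_path is not None:
        meta = {
            "n_subjects": n,
            "n_frames": m,
            "feature_names": list(tensor.feature_names),
            "label_codes": LABEL_CODES,
        }
        with open(meta_path, "w") as fh:
            json.dump(meta, fh, indent=2)


def load_cohort_csv(csv_path) -> CohortTensor:
    """Round-trip reader for :func:`save_cohort_csv`."""
    df = pd.read_csv(csv_path)
    sids = list(dict.fromkeys(df["subject"]))  # preserve order
    features = tuple(dict.fromkeys(df["feature"]))
    m = df["frame"].max() + 1
    values = np.empty((len(sids), m, len(features)))
    labels = np.empty(len(sids), dtype=int)
    fidx = {f: j for j, f in enumerate(features)}
    for i, sid in enumerate(sids):
        sub = df[df["subject"] == sid]
        labels[i] = sub["label"].iloc[0]
        for _, row in sub.iterrows():
            values[i, int(row["frame"]), fidx[row["feature"]]] = row["value"]
    return CohortTensor(values, labels, features, tuple(sids))
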