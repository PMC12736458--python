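"""Synthetic dynamic-thermography phantom cohorts.

Generates post-cold-stress thermogram sequences with the statistical
structure the analysis assumes: each subject is 20 frames of a 2-D
temperature grid plus a fixed region-of-interest (RoI) mask.  A frame is
composed additively from

* a spatially constant rewarming baseline following the exponential
  recovery law with class-specific (T0, Tinf, tau);
* a localized hotspot obeying the buried spherical-source surface law,
  centered at a class-dependent offset from the RoI center (asymmetry);
* a smooth spatial heterogeneity field (Gaussian-blurred white noise,
  fixed across the frames of a sequence, scaled to a class-specific sd);
* i.i.d. Gaussian sensor noise, redrawn per frame.

The hotspot intensity rises with the rewarming factor ``1 - exp(-t/tau)``
above a floor, so the intensity series carries class information over time.
Control subjects have a near-zero hotspot ("hot spots absent"), a smaller
heterogeneity sd and slower, cooler recovery kinetics; cancer subjects the
opposite.  Class kinetics default to the fitted group curves
(control: 32.14 / 32.63 degC, tau 57.76 s; cancer: 32.69 / 33.80 degC,
tau 56.26 s).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .bioheat import (
    DEFAULT_FRAME_INTERVAL_S,
    Environment,
    HeatSourceParams,
    RecoveryKinetics,
    recovery_curve,
)

__all__ = [
    "ClassPhantom",
    "PhantomConfig",
    "ThermalFrame",
    "ThermogramSequence",
    "generate_frame",
    "generate_sequence",
    "generate_cohort",
    "CONTROL",
    "CANCER",
]

CONTROL = "control"
CANCER = "cancer"

PLAUSIBLE_RANGE = (20.0, 40.0)  # degC clamp for composed frames


@dataclass(frozen=True)
class ThermalFrame:
    """One 2-D grid of surface temperatures (degC) with its pixel pitch."""

    values: np.ndarray  # (H, W) float degC
    pitch: float  # m / pixel

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class ThermogramSequence:
    """A subject's dynamic sequence: M frames, one shared RoI mask, a label."""

    frames: np.ndarray  # (M, H, W) degC
    mask: np.ndarray  # (H, W) bool
    times: np.ndarray  # (M,) s
    label: str  # CONTROL or CANCER
    subject_id: str
    pitch: float

    def __post_init__(self) -> None:
        if self.frames.shape[1:] != self.mask.shape:
            raise ValueError("mask shape must match frame shape")
        if self.frames.shape[0] != self.times.shape[0]:
            raise ValueError("one acquisition time per frame required")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def frame(self, t_index: int) -> ThermalFrame:
        return ThermalFrame(self.frames[t_index], self.pitch)


@dataclass(frozen=True)
class ClassPhantom:
    """Per-class generative parameters."""

    kinetics: RecoveryKinetics
    source: HeatSourceParams
    center_offset: tuple[int, int] = (0, 0)  # (row, col) pixels from RoI center
    heterogeneity_sd: float = 0.9  # degC, sd of the smooth spatial field


def _default_control() -> ClassPhantom:
    return ClassPhantom(
        kinetics=RecoveryKinetics(32.14, 32.63, 57.76),
        source=HeatSourceParams(q=0.008, d=0.02),  # "hot spots absent": near-zero
        center_offset=(0, 0),
        heterogeneity_sd=0.90,
    )


def _default_cancer() -> ClassPhantom:
    return ClassPhantom(
        kinetics=RecoveryKinetics(32.69, 33.80, 56.26),
        source=HeatSourceParams(q=0.132, d=0.02),
        center_offset=(8, 8),  # asymmetric focal hotspot
        heterogeneity_sd=0.95,
    )


@dataclass(frozen=True)
class PhantomConfig:
    """Cohort-level phantom configuration.

    Defaults emulate the study conditions: 20 frames at 15 s spacing
    (5 minutes of recovery), a 96x96 grid at 1 mm/pixel so the fixed
    profiling radius a = 0.0168 m spans ~17 pixels, 25 subjects per class,
    and 0.05 degC sensor noise.
    """

    grid_size: int = 96
    pitch: float = 1e-3  # m / pixel
    n_frames: int = 20
    frame_interval: float = DEFAULT_FRAME_INTERVAL_S
    n_per_class: int = 25
    noise_sd: float = 0.05  # degC
    blur_px: float = 4.0  # heterogeneity field correlation scale
    q_floor: float = 0.3  # fraction of peak intensity present at t=0
    control: ClassPhantom = field(default_factory=_default_control)
    cancer: ClassPhantom = field(default_factory=_default_cancer)
    environment: Environment = field(default_factory=Environment)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("need at least one subject per class")
        # the fixed profiling radius must fit inside the RoI around either
        # class hotspot center
        a_px = 0.0168 / self.pitch
        max_off = max(
            max(abs(o) for o in self.control.center_offset),
            max(abs(o) for o in self.cancer.center_offset),
        )
        if a_px + max_off * math.sqrt(2) >= self.mask_radius_px:
            raise ValueError(
                "grid too small: profiling radius does not fit inside the RoI"
            )

    @property
    def mask_radius_px(self) -> float:
        return 0.47 * self.grid_size

    def class_params(self, label: str) -> ClassPhantom:
        if label == CONTROL:
            return self.control
        if label == CANCER:
            return self.cancer
        raise ValueError(f"unknown class label {label!r}")

    def roi_mask(self) -> np.ndarray:
        """Disk-shaped RoI mask centered on the grid."""
        n = self.grid_size
        c = (n - 1) / 2.0
        rr, cc = np.ogrid[:n, :n]
        return (rr - c) ** 2 + (cc - c) ** 2 <= self.mask_radius_px**2

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


def _hotspot_center(cfg: PhantomConfig, label: str) -> tuple[int, int]:
    c = (cfg.grid_size - 1) // 2
    off = cfg.class_params(label).center_offset
    return (c + off[0], c + off[1])


def _source_intensity(cfg: PhantomConfig, label: str, t: float) -> float:
    """Hotspot intensity at time t: floor plus rewarming-scaled rise."""
    p = cfg.class_params(label)
    rise = 1.0 - math.exp(-t / p.kinetics.tau)
    return p.source.q * (cfg.q_floor + (1.0 - cfg.q_floor) * rise)


def heterogeneity_field(cfg: PhantomConfig, label: str, rng: np.random.Generator) -> np.ndarray:
    """Smooth zero-mean spatial field with the class heterogeneity sd.

    Gaussian blur of white noise, rescaled so the field's sd over the RoI
    equals the configured class value.
    """
    sd = cfg.class_params(label).heterogeneity_sd
    if sd == 0.0:
        return np.zeros((cfg.grid_size, cfg.grid_size))
    white = rng.standard_normal((cfg.grid_size, cfg.grid_size))
    smooth = gaussian_filter(white, sigma=cfg.blur_px, mode="reflect")
    mask = cfg.roi_mask()
    smooth -= smooth[mask].mean()
    s = smooth[mask].std()
    return smooth * (sd / s) if s > 0 else smooth


def generate_frame(
    t: float,
    cfg: PhantomConfig,
    label: str,
    rng: np.random.Generator,
    heterogeneity: np.ndarray | None = None,
) -> ThermalFrame:
    """Compose one frame at recovery time ``t`` (s).

    ``heterogeneity`` is the per-sequence fixed field; drawn fresh from
    ``rng`` when omitted.
    """
    if t < 0:
        raise ValueError("recovery time must be >= 0")
    p = cfg.class_params(label)
    mask = cfg.roi_mask()
    center = _hotspot_center(cfg, label)
    if not mask[center]:
        raise ValueError(f"hotspot center {center} lies outside the RoI mask")

    baseline = recovery_curve(t, p.kinetics)

    rr, cc = np.indices((cfg.grid_size, cfg.grid_size))
    r_m = np.hypot(rr - center[0], cc - center[1]) * cfg.pitch
    q_t = _source_intensity(cfg, label, t)
    bump = q_t / (4.0 * math.pi * cfg.environment.h0 * (p.source.d**2 + r_m**2))

    if heterogeneity is None:
        heterogeneity = heterogeneity_field(cfg, label, rng)

    noise = (
        rng.normal(0.0, cfg.noise_sd, size=(cfg.grid_size, cfg.grid_size))
        if cfg.noise_sd > 0
        else 0.0
    )
    values = baseline + bump + heterogeneity + noise
    np.clip(values, *PLAUSIBLE_RANGE, out=values)
    return ThermalFrame(values, cfg.pitch)


def generate_sequence(cfg: PhantomConfig, label: str, seed) -> ThermogramSequence:
    """Generate one subject's M-frame sequence, deterministic given seed.

    The heterogeneity field is drawn once and reused across frames (spatial
    structure persists); sensor noise is redrawn per frame.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    het = heterogeneity_field(cfg, label, rng)
    times = cfg.times()
    frames = np.stack(
        [generate_frame(t, cfg, label, rng, heterogeneity=het).values for t in times]
    )
    sid = f"{label}-{ss.entropy}"
    return ThermogramSequence(
        frames=frames,
        mask=cfg.roi_mask(),
        times=times,
        label=label,
        subject_id=sid,
        pitch=cfg.pitch,
    )


def generate_cohort(cfg: PhantomConfig) -> list[ThermogramSequence]:
    """Balanced cohort: n control + n cancer sequences, deterministically
    shuffled by the config seed, with readable subject ids attached."""
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(2 * cfg.n_per_class)
    sequences = []
    for i in range(cfg.n_per_class):
        for j, label in enumerate((CONTROL, CANCER)):
            child = children[2 * i + j]
            seq = generate_sequence(cfg, label, child)
            seq = replace(seq, subject_id=f"{label}-{i:03d}")
            sequences.append(seq)
    order = np.random.default_rng(ss.spawn(1)[0]).permutation(len(sequences))
    return [sequences[i] for i in order]
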