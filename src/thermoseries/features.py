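"""Per-frame physiological descriptors via the D-I-R inversion.

For every frame the pipeline locates the hottest RoI pixel, samples the
radial temperature profile at a fixed metric distance ``a`` from it, and
algebraically inverts the spherical-source surface law to recover the
source depth and intensity:

    d = a * sqrt((T(a) - Te) / (Tmax - T(a)))
    q = 4 pi h0 (T(a) - Te) (Tmax - Te) a**2 / (Tmax - T(a))
    R = (q / (Qm * At)) ** (1/3)

Together with the RoI maximum, mean and spatial standard deviation these
give the V=5 per-frame feature vector (Tmax, Tmean, sigma, q, d); R is kept
as an auxiliary output.  The surround temperature Te is estimated from the
frame itself (10th percentile of masked temperatures by default, a
surround-tissue proxy) or supplied as a constant override.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bioheat import Environment
from .phantom import ThermalFrame, ThermogramSequence

__all__ = [
    "DEFAULT_RADIUS_M",
    "FEATURE_NAMES",
    "RadialProfile",
    "FeatureVector",
    "DegenerateProfileError",
    "BoundaryError",
    "locate_hotspot",
    "estimate_te",
    "sample_profile",
    "estimate_depth",
    "estimate_intensity",
    "estimate_radius",
    "frame_descriptors",
    "sequence_descriptors",
]

#: Fixed radial profiling distance (m), ~1.7 cm.
DEFAULT_RADIUS_M = 0.0168

#: Feature order of the per-frame vector.
FEATURE_NAMES = ("Tmax", "Tmean", "sigma", "q", "d")


class DegenerateProfileError(ValueError):
    """Radial profile violates Tmax > T(a) > Te; inversion undefined."""


class BoundaryError(ValueError):
    """Requested radius exceeds the RoI extent around the hotspot."""

    def __init__(self, message: str, max_radius: float):
        super().__init__(message)
        self.max_radius = max_radius


@dataclass(frozen=True)
class RadialProfile:
    """Hotspot-centered profile summary used by the inversion."""

    center: tuple[int, int]  # (row, col)
    tmax: float  # degC at the hotspot
    t_a: float  # degC at metric radius a
    te: float  # surround reference degC
    a: float  # m


@dataclass(frozen=True)
class FeatureVector:
    """Per-frame descriptors; q/d/r are NaN when the profile is degenerate."""

    tmax: float
    tmean: float
    sigma: float
    q: float
    d: float
    r: float
    degenerate: bool = False

    def as_tuple(self) -> tuple[float, ...]:
        return (self.tmax, self.tmean, self.sigma, self.q, self.d)


def locate_hotspot(frame: ThermalFrame, mask: np.ndarray) -> tuple[tuple[int, int], float]:
    """Argmax of temperature within the mask.

    Ties are broken toward the smallest row-major index.
    """
    if not np.any(mask):
        raise ValueError("RoI mask is empty")
    masked = np.where(mask, frame.values, -np.inf)
    flat = int(np.argmax(masked))  # first maximum in row-major order
    center = np.unravel_index(flat, masked.shape)
    return (int(center[0]), int(center[1])), float(masked[center])


def estimate_te(frame: ThermalFrame, mask: np.ndarray, percentile: float = 10.0) -> float:
    """Surround-temperature proxy: low percentile of masked temperatures."""
    return float(np.percentile(frame.values[mask], percentile))


def sample_profile(
    frame: ThermalFrame,
    mask: np.ndarray,
    center: tuple[int, int],
    a: float = DEFAULT_RADIUS_M,
    mode: str = "annulus",
    te: float | None = None,
    te_percentile: float = 10.0,
) -> RadialProfile:
    """Sample T(a) around ``center`` at metric radius ``a``.

    ``annulus`` mode (default) averages masked pixels whose distance to the
    center lies within half a pixel pitch of ``a``; ``line`` mode averages
    the two horizontal samples at column offsets of +/- a.  ``te`` overrides
    the frame-based surround estimate.
    """
    if a <= 0:
        raise ValueError("profiling radius a must be positive")
    pitch = frame.pitch
    rr, cc = np.indices(frame.shape)
    dist = np.hypot(rr - center[0], cc - center[1]) * pitch

    if mode == "annulus":
        band = (np.abs(dist - a) <= pitch / 2.0) & mask
        if not np.any(band):
            max_r = float(dist[mask].max())
            raise BoundaryError(
                f"no masked pixels at radius {a} m (max achievable {max_r:.4f} m)",
                max_r,
            )
        t_a = float(frame.values[band].mean())
    elif mode == "line":
        off = round(a / pitch)
        samples = []
        for col in (center[1] - off, center[1] + off):
            if 0 <= col < frame.shape[1] and mask[center[0], col]:
                samples.append(frame.values[center[0], col])
        if not samples:
            max_r = float(dist[mask].max())
            raise BoundaryError(
                f"line samples at radius {a} m fall outside the RoI "
                f"(max achievable {max_r:.4f} m)",
                max_r,
            )
        t_a = float(np.mean(samples))
    else:
        raise ValueError(f"unknown profile mode {mode!r}")

    tmax = float(frame.values[center])
    te_val = float(te) if te is not None else estimate_te(frame, mask, te_percentile)
    return RadialProfile(center=center, tmax=tmax, t_a=t_a, te=te_val, a=a)


def _check_profile(profile: RadialProfile) -> None:
    if not (profile.tmax > profile.t_a):
        raise DegenerateProfileError(
            f"Tmax ({profile.tmax}) must exceed T(a) ({profile.t_a})"
        )
    if not (profile.t_a > profile.te):
        raise DegenerateProfileError(
            f"T(a) ({profile.t_a}) must exceed Te ({profile.te})"
        )


def estimate_depth(profile: RadialProfile) -> float:
    """Source depth d (m) from the radial profile."""
    _check_profile(profile)
    ratio = (profile.t_a - profile.te) / (profile.tmax - profile.t_a)
    return profile.a * math.sqrt(ratio)


def estimate_intensity(profile: RadialProfile, env: Environment) -> float:
    """Source intensity q (W) from the radial profile."""
    _check_profile(profile)
    return (
        4.0
        * math.pi
        * env.h0
        * (profile.t_a - profile.te)
        * (profile.tmax - profile.te)
        * profile.a**2
        / (profile.tmax - profile.t_a)
    )


def estimate_radius(q: float, env: Environment) -> float:
    """Source radius R (m) from the intensity (cube-root law)."""
    if q < 0:
        raise ValueError("intensity q must be >= 0")
    return (q / (env.qm * env.at)) ** (1.0 / 3.0)


def frame_descriptors(
    frame: ThermalFrame,
    mask: np.ndarray,
    env: Environment | None = None,
    a: float = DEFAULT_RADIUS_M,
    mode: str = "annulus",
    te: float | None = None,
    te_percentile: float = 10.0,
) -> FeatureVector:
    """Full V=5 descriptor vector for one frame.

    Tmax/Tmean/sigma come directly from the masked temperatures (sigma with
    N-1 denominator); q and d via the D-I-R chain.  Degenerate profiles
    (no thermal contrast) yield NaN q/d/r with the ``degenerate`` flag set.
    """
    env = env or Environment()
    center, tmax = locate_hotspot(frame, mask)
    roi = frame.values[mask]
    tmean = float(roi.mean())
    sigma = float(roi.std(ddof=1)) if roi.size > 1 else 0.0
    try:
        profile = sample_profile(
            frame, mask, center, a=a, mode=mode, te=te, te_percentile=te_percentile
        )
        d = estimate_depth(profile)
        q = estimate_intensity(profile, env)
        r = estimate_radius(q, env)
        return FeatureVector(tmax, tmean, sigma, q, d, r)
    except (DegenerateProfileError, BoundaryError):
        return FeatureVector(tmax, tmean, sigma, np.nan, np.nan, np.nan, degenerate=True)


def sequence_descriptors(
    seq: ThermogramSequence,
    env: Environment | None = None,
    a: float = DEFAULT_RADIUS_M,
    mode: str = "annulus",
    te: float | None = None,
    te_percentile: float = 10.0,
    collapse_depth: bool = False,
) -> pd.DataFrame:
    """Descriptor table for a whole sequence (one row per frame).

    Degenerate frames carry the previous frame's q/d/R forward (leading
    degenerates are back-filled from the first valid frame) so every series
    keeps length M; the ``flag`` column records which rows were filled.
    If no frame at all is invertible, q falls back to 0 and d to ``a``.
    ``collapse_depth`` replaces the per-frame depth by its per-subject
    median (the depth of a real source does not change over 5 minutes).
    """
    rows = []
    for idx in range(seq.n_frames):
        fv = frame_descriptors(
            seq.frame(idx), seq.mask, env, a=a, mode=mode, te=te,
            te_percentile=te_percentile,
        )
        rows.append(
            {
                "frame": idx,
                "t": float(seq.times[idx]),
                "Tmax": fv.tmax,
                "Tmean": fv.tmean,
                "sigma": fv.sigma,
                "q": fv.q,
                "d": fv.d,
                "R": fv.r,
                "flag": "degenerate" if fv.degenerate else "",
            }
        )
    df = pd.DataFrame(rows)
    inv = ["q", "d", "R"]
    df[inv] = df[inv].ffill().bfill()
    if df["q"].isna().all():
        df["q"] = 0.0
        df["d"] = a
        df["R"] = 0.0
        df["flag"] = "all-degenerate"
    if collapse_depth:
        df["d"] = df["d"].median()
    return df
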