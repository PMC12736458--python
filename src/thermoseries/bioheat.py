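"""Closed-form bio-heat forward model and exponential thermal-recovery kinetics.

Two small physical models underpin the whole pipeline:

1. The steady surface-temperature law over a buried spherical heat source.
   A source of intensity ``q`` (W) at depth ``d`` (m) below the skin raises
   the surface temperature at radial distance ``a`` (m) from the projection
   of the source to::

       T(a) = Te + q / (4 pi h0 (deff**2 + a**2))

   where ``Te`` is the surround (reference) temperature, ``h0`` the heat
   transfer coefficient (W m^-2 degC^-1), and ``deff`` is ``d`` for the
   point-source form or ``d + R`` when the finite source radius ``R`` is
   included.  This law is the forward half of the D-I-R (depth-intensity-
   radius) inversion implemented in :mod:`thermoseries.features`.

2. The exponential rewarming law after cold stress (a modified Newton
   cooling curve)::

       T(t) = Tinf - (Tinf - T0) * exp(-t / tau)

   with ``T0`` the temperature immediately after the stimulus, ``Tinf`` the
   asymptotic recovery temperature and ``tau`` (s) the recovery time
   constant.  Faster recovery (smaller ``tau``) is the malignancy marker the
   downstream classifiers exploit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "Environment",
    "HeatSourceParams",
    "RecoveryKinetics",
    "RecoveryFit",
    "FitError",
    "surface_temperature",
    "recovery_curve",
    "fit_recovery",
]

#: Default frame spacing of the dynamic sequence: 20 frames over 5 minutes.
DEFAULT_FRAME_INTERVAL_S = 15.0


class FitError(RuntimeError):
    """Nonlinear recovery fit failed to converge.

    Carries the initialization used and its residual sum of squares so the
    caller can inspect or fall back.
    """

    def __init__(self, message: str, init: tuple[float, float, float], rss_init: float):
        super().__init__(message)
        self.init = init
        self.rss_init = rss_init


@dataclass(frozen=True)
class Environment:
    """Thermal environment and tissue constants.

    Parameters
    ----------
    te : float
        Surround / reference temperature (degC) entering the surface law.
    h0 : float
        Heat transfer coefficient (W m^-2 degC^-1).
    qm : float
        Metabolic constant (W m^-3) used by the radius estimate.
    at : float
        Cell-volume scaling constant, treated as dimensionless.
    """

    te: float = 30.0
    h0: float = 8.77
    qm: float = 418.6
    at: float = 1.0

    def __post_init__(self) -> None:
        if not (self.h0 > 0):
            raise ValueError(f"h0 must be positive, got {self.h0}")
        if not (self.qm > 0):
            raise ValueError(f"qm must be positive, got {self.qm}")
        if not (self.at > 0):
            raise ValueError(f"at must be positive, got {self.at}")


@dataclass(frozen=True)
class HeatSourceParams:
    """Buried spherical heat source: intensity ``q`` (W), depth ``d`` (m),
    radius ``r`` (m; 0 for the point-source form)."""

    q: float
    d: float
    r: float = 0.0

    def __post_init__(self) -> None:
        if not (self.q >= 0):
            raise ValueError(f"source intensity q must be >= 0, got {self.q}")
        if not (self.d > 0):
            raise ValueError(f"source depth d must be > 0, got {self.d}")
        if not (self.r >= 0):
            raise ValueError(f"source radius r must be >= 0, got {self.r}")


@dataclass(frozen=True)
class RecoveryKinetics:
    """Exponential rewarming parameters (T0, Tinf in degC, tau in s)."""

    t0: float
    t_inf: float
    tau: float

    def __post_init__(self) -> None:
        if not (self.tau > 0):
            raise ValueError(f"recovery time constant tau must be > 0, got {self.tau}")


@dataclass(frozen=True)
class RecoveryFit:
    """Result of a least-squares recovery fit.

    ``tau_identifiable`` is False for degenerate (flat) inputs, in which
    case ``tau`` is NaN and :attr:`kinetics` raises.
    """

    t0: float
    t_inf: float
    tau: float
    rss: float
    tau_identifiable: bool = True

    @property
    def kinetics(self) -> RecoveryKinetics:
        if not self.tau_identifiable:
            raise ValueError("tau is unidentifiable for this fit (flat input)")
        return RecoveryKinetics(self.t0, self.t_inf, self.tau)


def surface_temperature(
    a,
    src: HeatSourceParams,
    env: Environment,
    use_radius: bool = False,
):
    """Surface temperature (degC) at radial distance ``a`` (m) from the
    source projection.

    ``use_radius=False`` gives the point-source form (effective depth
    ``d``); ``use_radius=True`` uses ``d + R``.  Accepts scalar or array
    ``a`` and is strictly decreasing in ``a``.
    """
    a_arr = np.asarray(a, dtype=float)
    if not np.all(np.isfinite(a_arr)):
        raise ValueError("radial distance a must be finite")
    if np.any(a_arr < 0):
        raise ValueError("radial distance a must be >= 0")
    deff = src.d + src.r if use_radius else src.d
    if deff <= 0:
        raise ValueError(f"effective depth must be positive, got {deff}")
    out = env.te + src.q / (4.0 * math.pi * env.h0 * (deff**2 + a_arr**2))
    return float(out) if np.isscalar(a) or a_arr.ndim == 0 else out


def recovery_curve(t, kin: RecoveryKinetics):
    """Exponential rewarming temperature at time(s) ``t`` (s)."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time t must be >= 0")
    out = kin.t_inf - (kin.t_inf - kin.t0) * np.exp(-t_arr / kin.tau)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def _model(t, t0, t_inf, tau):
    return t_inf - (t_inf - t0) * np.exp(-t / tau)


def fit_recovery(times, temps, max_nfev: int = 10_000) -> RecoveryFit:
    """Least-squares fit of the exponential rewarming model.

    Initialization: ``T0`` from the first sample, ``Tinf`` from the last,
    ``tau`` = span/3, with ``tau`` bounded in (0, 100*span].  The returned
    fit never has a larger residual sum of squares than this initialization
    (falls back to it otherwise).  A flat input yields
    ``T0 = Tinf = value`` with ``tau`` flagged unidentifiable.
    """
    times = np.asarray(times, dtype=float)
    temps = np.asarray(temps, dtype=float)
    if times.ndim != 1 or times.shape != temps.shape:
        raise ValueError("times and temps must be 1-D arrays of equal length")
    if times.size < 4:
        raise ValueError(f"need at least 4 samples, got {times.size}")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")

    if np.ptp(temps) == 0.0:
        v = float(temps[0])
        return RecoveryFit(v, v, float("nan"), 0.0, tau_identifiable=False)

    span = float(times[-1] - times[0])
    p0 = (float(temps[0]), float(temps[-1]), span / 3.0)
    rss_init = float(np.sum((_model(times, *p0) - temps) ** 2))
    bounds = ([-np.inf, -np.inf, 1e-9], [np.inf, np.inf, 100.0 * span])
    try:
        popt, _ = curve_fit(
            _model, times, temps, p0=p0, bounds=bounds, max_nfev=max_nfev
        )
    except RuntimeError as exc:  # iteration budget exhausted
        raise FitError(f"recovery fit did not converge: {exc}", p0, rss_init) from exc
    rss = float(np.sum((_model(times, *popt) - temps) ** 2))
    if rss > rss_init:  # pathological: keep the (better) initialization
        popt, rss = p0, rss_init
    return RecoveryFit(float(popt[0]), float(popt[1]), float(popt[2]), rss)
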