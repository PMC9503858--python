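"""Two-compartment single-time-point pharmacokinetics.

Normalized time-activity curves with fixed, experience-derived shapes:

* high-uptake compartment, mono-exponential::

      u_high(t) = 2^(-t / t_half_M)

* low-uptake compartment, bi-exponential::

      u_low(t) = w_S 2^(-t / t_half_S) + w_F 2^(-t / t_half_F)

Both are scaled to the single WBS measurement by solving the linear system

      S_high + S_low = A0
      S_high u_high(t̄) / (S_low u_low(t̄)) = rho,

where rho is the measured high/low counts-per-second ratio from the
segmented geometric-mean image.  Since both compartments share one
acquisition, the counts ratio equals the cps ratio and no absolute camera
calibration is ever needed (self-calibration).  Cumulated activities follow
in closed form by integrating the scaled curves over all time.

All user-facing parameters are half-lives in hours; mean lives
τ = t_half / ln 2 are internal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

LN2 = math.log(2.0)

#: Lu-177 DOTA-TATE default profile: high 69 h; low slow/fast 61 h / 2.4 h
#: with weights 1/6 and 5/6.
LU177_DOTATATE = None  # assigned below, needs the class


@dataclass(frozen=True)
class CompartmentKinetics:
    """Effective half-lives (hours) and weights of the two-compartment model.

    Parameters
    ----------
    t_half_M_h
        Effective half-life of the high-uptake compartment (mono-exponential).
    t_half_S_h, t_half_F_h
        Slow and fast effective half-lives of the low-uptake compartment.
    w_S, w_F
        Low-compartment slow/fast weights; must sum to 1.
    """

    t_half_M_h: float
    t_half_S_h: float
    t_half_F_h: float
    w_S: float = 1.0 / 6.0
    w_F: float = 5.0 / 6.0

    def __post_init__(self) -> None:
        for name in ("t_half_M_h", "t_half_S_h", "t_half_F_h"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.t_half_S_h < self.t_half_F_h:
            raise ValueError("slow half-life must be >= fast half-life")
        if self.w_S < 0 or self.w_F < 0:
            raise ValueError("weights must be non-negative")
        if abs(self.w_S + self.w_F - 1.0) > 1e-12:
            raise ValueError("weights must sum to 1")


#: named presets; the radioiodine profile prints only the high-compartment
#: half-life — low-compartment parameters are mandatory study config.
LU177_DOTATATE = CompartmentKinetics(t_half_M_h=69.0, t_half_S_h=61.0, t_half_F_h=2.4)
I131_HIGH_T_HALF_H = 16.0

PRESETS: dict[str, CompartmentKinetics] = {"lu177_dotatate": LU177_DOTATATE}


@dataclass(frozen=True)
class ScaleFactors:
    """Reconstructed initial compartment activities (MBq)."""

    S_high_MBq: float
    S_low_MBq: float
    A0_MBq: float
    t_obs_h: float
    rho: float

    def __post_init__(self) -> None:
        if self.S_high_MBq < 0 or self.S_low_MBq < 0:
            raise ValueError("scale factors must be non-negative")
        total = self.S_high_MBq + self.S_low_MBq
        if abs(total - self.A0_MBq) > 1e-9 * max(self.A0_MBq, 1.0):
            raise ValueError("scale factors must sum to the administered activity")


@dataclass(frozen=True)
class CumulatedActivitySet:
    """Time-integrated activities (MBq·h) per source region."""

    A_tilde_high: float
    A_tilde_low: float
    A_tilde_BM: float = 0.0
    A_tilde_SL: float = 0.0

    def __post_init__(self) -> None:
        for name in ("A_tilde_high", "A_tilde_low", "A_tilde_BM", "A_tilde_SL"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class StpError:
    """Single-time-point cumulated-activity error for a mono-exponential decay."""

    tau_true_h: float
    tau_eff_h: float
    t_obs_h: float
    E_abs_MBq_h: float
    E_rel: float
    w_tbar: float


def u_high(t, kinetics: CompartmentKinetics):
    """Normalized high-uptake activity 2^(-t/t_half_M); u_high(0) = 1."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    out = np.exp2(-t / kinetics.t_half_M_h)
    return float(out) if out.ndim == 0 else out


def u_low(t, kinetics: CompartmentKinetics):
    """Normalized low-uptake activity, bi-exponential; u_low(0) = 1."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    out = kinetics.w_S * np.exp2(-t / kinetics.t_half_S_h) + kinetics.w_F * np.exp2(
        -t / kinetics.t_half_F_h
    )
    return float(out) if out.ndim == 0 else out


def solve_scale_factors(
    A0_MBq: float, rho: float, t_obs_h: float, kinetics: CompartmentKinetics
) -> ScaleFactors:
    """Solve the two-equation scale-factor system from the measured ratio.

    With q = rho * u_low(t̄) / u_high(t̄):
    S_high = A0 q / (1 + q), S_low = A0 / (1 + q).
    """
    if A0_MBq <= 0:
        raise ValueError("A0 must be positive")
    if rho < 0:
        raise ValueError("rho must be non-negative")
    if t_obs_h < 0:
        raise ValueError("t_obs must be non-negative")
    q = rho * u_low(t_obs_h, kinetics) / u_high(t_obs_h, kinetics)
    # both factors from q directly: subtracting from A0 loses precision
    # when one compartment dominates
    s_high = A0_MBq * q / (1.0 + q)
    s_low = A0_MBq / (1.0 + q)
    return ScaleFactors(
        S_high_MBq=s_high, S_low_MBq=s_low, A0_MBq=A0_MBq, t_obs_h=t_obs_h, rho=rho
    )


def cumulated_activity_high(scale: ScaleFactors | float, kinetics: CompartmentKinetics) -> float:
    """∫ S_high u_high dt = S_high t_half_M / ln 2, in MBq·h."""
    s = scale.S_high_MBq if isinstance(scale, ScaleFactors) else float(scale)
    return s * kinetics.t_half_M_h / LN2


def cumulated_activity_low(scale: ScaleFactors | float, kinetics: CompartmentKinetics) -> float:
    """∫ S_low u_low dt = S_low (w_S t_half_S + w_F t_half_F) / ln 2, in MBq·h."""
    s = scale.S_low_MBq if isinstance(scale, ScaleFactors) else float(scale)
    return s * (kinetics.w_S * kinetics.t_half_S_h + kinetics.w_F * kinetics.t_half_F_h) / LN2


def cumulated_activities(
    scale: ScaleFactors, kinetics: CompartmentKinetics
) -> CumulatedActivitySet:
    """Closed-form cumulated activities for both compartments."""
    return CumulatedActivitySet(
        A_tilde_high=cumulated_activity_high(scale, kinetics),
        A_tilde_low=cumulated_activity_low(scale, kinetics),
    )


def single_timepoint_error(
    tau_true_h: float, tau_eff_h: float, t_obs_h: float, A0_MBq: float
) -> StpError:
    """Error of the single-time-point approximation for a mono-exponential.

    The true activity A(t) = A0 exp(-t/τ) is replaced by the effective curve
    A_eff(t) = S u(t) with u(t) = exp(-t/τ_eff), scaled so the two curves
    agree at the observation time t̄: S = A(t̄)/u(t̄) = A0 w(t̄).  The error
    of the cumulated activity is then

        E = ∫A - ∫A_eff = A0 (τ - τ_eff w(t̄)),

    with w(t̄) = exp(-t̄/τ_true)/exp(-t̄/τ_eff).  E_rel = E / (A0 τ_true).
    """
    if min(tau_true_h, tau_eff_h, t_obs_h, A0_MBq) <= 0:
        raise ValueError("all parameters must be positive")
    w = math.exp(-t_obs_h / tau_true_h) / math.exp(-t_obs_h / tau_eff_h)
    e_abs = A0_MBq * (tau_true_h - tau_eff_h * w)
    return StpError(
        tau_true_h=tau_true_h,
        tau_eff_h=tau_eff_h,
        t_obs_h=t_obs_h,
        E_abs_MBq_h=e_abs,
        E_rel=e_abs / (A0_MBq * tau_true_h),
        w_tbar=w,
    )
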