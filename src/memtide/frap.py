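"""FRAP recovery analysis: D_t, mobile/immobile fraction.

Fluorescence recovery after photobleaching of surface-labelled membrane
proteins is normalized as F = (f - f_o)/(f_pre - f_o) (f_o: first
postbleach intensity, f_pre: prebleach mean) and fit to the hyperbolic
recovery model

    F(t) = (F0 + F_inf * (t / t_half)) / (1 + t / t_half),

whose midpoint identity F(t_half) = (F0 + F_inf)/2 defines the half-time
of recovery.  The tracer diffusion constant is D_t = A_bleach/(4*t_half)
and the mobile fraction is F_inf - F0; the immobile fraction 1 - mobile
feeds the obstacle area fraction phi used by the tension-diffusion model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from lmfit import Model

from .exceptions import DomainError, FitError

__all__ = [
    "A_BLEACH_DEFAULT",
    "FrapCurve",
    "FrapFit",
    "recovery_model",
    "normalize_frap",
    "fit_recovery",
    "diffusion_constant",
    "mobile_immobile",
]

#: Photobleached membrane area, um^2: a 2.4 um spot through a ~0.85 um
#: optical section bleaches a 2.4 x 0.85 um rectangle of membrane.
A_BLEACH_DEFAULT = 2.4 * 0.85


@dataclass
class FrapCurve:
    """A normalized FRAP recovery curve (time measured from the bleach)."""

    time: np.ndarray            # s, postbleach
    F: np.ndarray               # normalized intensity
    f_pre: float | None = None  # a.u.
    f_o: float | None = None    # a.u.

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if self.time.shape != self.F.shape:
            raise DomainError("time and F must have matching shapes")
        if np.any(np.diff(self.time) <= 0):
            raise DomainError("time must be strictly increasing")


@dataclass(frozen=True)
class FrapFit:
    """Fitted recovery parameters and derived quantities."""

    F0: float
    F_inf: float
    t_half: float               # s
    A_bleach: float             # um^2
    mobile_fraction: float
    D_t: float                  # um^2/s

    @property
    def immobile_fraction(self) -> float:
        return 1.0 - self.mobile_fraction


def recovery_model(t, F0, F_inf, t_half):
    """Hyperbolic recovery F(t) = (F0 + F_inf*(t/t_half))/(1 + t/t_half)."""
    x = np.asarray(t, dtype=float) / t_half
    return (F0 + F_inf * x) / (1.0 + x)


def normalize_frap(raw, f_pre: float, f_o: float, time=None) -> FrapCurve:
    """Normalize a raw (background-subtracted) recovery trace.

    F = (f - f_o)/(f_pre - f_o): 0 at the first postbleach intensity, 1 at
    the prebleach level.
    """
    raw = np.asarray(raw, dtype=float)
    if np.isclose(f_pre, f_o):
        raise DomainError("f_pre == f_o: cannot normalize")
    F = (raw - f_o) / (f_pre - f_o)
    if time is None:
        time = np.arange(raw.size, dtype=float)
    return FrapCurve(time=time, F=F, f_pre=f_pre, f_o=f_o)


def fit_recovery(curve: FrapCurve, A_bleach: float = A_BLEACH_DEFAULT) -> FrapFit:
    """Fit the hyperbolic recovery model to a normalized curve.

    Initialization is deterministic: F0 from the first postbleach point,
    F_inf from the tail mean, t_half from the first crossing of the
    midpoint (F0 + F_inf)/2.
    """
    t, F = curve.time, curve.F
    if t.size < 10:
        raise FitError("need >= 10 postbleach points")
    f0_init = float(F[0])
    finf_init = float(np.mean(F[-max(3, F.size // 5):]))
    mid = 0.5 * (f0_init + finf_init)
    above = np.nonzero(F >= mid)[0]
    thalf_init = float(t[above[0]]) if above.size and t[above[0]] > 0 \
        else float(t[t.size // 2])
    thalf_init = max(thalf_init, 1e-3)

    model = Model(recovery_model)
    params = model.make_params(F0=f0_init, F_inf=finf_init,
                               t_half=thalf_init)
    params["t_half"].set(min=1e-6)
    result = model.fit(F, params, t=t)
    if not result.success:
        raise FitError(
            "FRAP recovery fit failed; initial guesses were "
            f"F0={f0_init:.3g}, F_inf={finf_init:.3g}, "
            f"t_half={thalf_init:.3g}s: {result.message}")
    F0 = float(result.params["F0"].value)
    F_inf = float(result.params["F_inf"].value)
    t_half = float(result.params["t_half"].value)
    mobile, _ = mobile_immobile(F0=F0, F_inf=F_inf)
    return FrapFit(F0=F0, F_inf=F_inf, t_half=t_half, A_bleach=A_bleach,
                   mobile_fraction=mobile,
                   D_t=diffusion_constant(t_half, A_bleach))


def diffusion_constant(t_half: float, A_bleach: float = A_BLEACH_DEFAULT) -> float:
    """Tracer diffusion constant D_t = A_bleach / (4 * t_half), um^2/s."""
    if t_half <= 0:
        raise DomainError("t_half must be positive")
    if A_bleach <= 0:
        raise DomainError("A_bleach must be positive")
    return A_bleach / (4.0 * t_half)


def mobile_immobile(fit: FrapFit | None = None, *, F0: float | None = None,
                    F_inf: float | None = None) -> tuple[float, float]:
    """Mobile fraction F_inf - F0 and immobile fraction 1 - mobile.

    Values outside [0, 1] (possible with noisy fits) are clipped with a
    warning rather than silently propagated.
    """
    if fit is not None:
        F0, F_inf = fit.F0, fit.F_inf
    if F0 is None or F_inf is None:
        raise DomainError("provide a FrapFit or both F0 and F_inf")
    mobile = F_inf - F0
    if not 0.0 <= mobile <= 1.0:
        warnings.warn(f"mobile fraction {mobile:.3g} outside [0, 1]; "
                      "clipping", stacklevel=2)
        mobile = float(np.clip(mobile, 0.0, 1.0))
    return mobile, 1.0 - mobile
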