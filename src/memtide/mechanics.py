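"""Tether and optical-trap mechanics.

Membrane tethers pulled from a cell by a trapped bead report the local
membrane tension sigma (pN/um) through the holding force

    f = 2*pi*sqrt(2*kappa*sigma),

where kappa (pN*um) is the membrane bending modulus.  The tether radius
follows from the same energetics, r = 2*pi*kappa/f = sqrt(kappa/(2*sigma)).
This module collects those conversions, the hydrodynamic trap-stiffness
calibration, the step-extension response characterisation, and the
fluorescence-based tension readout (sigma ~ 1/I^2).

Unit system (package-wide): pN, um, s.  Tension pN/um, bending modulus
pN*um, 3D viscosity pN*s/um^2, density pN*s^2/um^4.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from lmfit import Parameters, minimize as lm_minimize

from .exceptions import DomainError, FitError

__all__ = [
    "KAPPA_DEFAULT",
    "WATER_VISCOSITY",
    "WATER_DENSITY",
    "TRACKING_ERROR_UM",
    "TetherState",
    "MembraneConstants",
    "TrapCalibration",
    "ForceTrace",
    "StepResponseFit",
    "tension_from_force",
    "force_from_tension",
    "radius_from_force",
    "radius_from_tension",
    "force_from_displacement",
    "force_uncertainty",
    "tension_uncertainty",
    "drag_coefficient",
    "hydrodynamic_force",
    "calibrate_trap",
    "reynolds_number",
    "fit_step_response",
    "tension_from_fluorescence",
]

#: Membrane bending modulus for neuronal growth cones, pN*um.
KAPPA_DEFAULT = 0.27

#: Viscosity of water at room temperature, pN*s/um^2 (= 1e-3 Pa*s).
WATER_VISCOSITY = 1.0e-3

#: Density of water, pN*s^2/um^4 (= 1e3 kg/m^3... in these units 1e-9).
WATER_DENSITY = 1.0e-9

#: RMS bead-centroid tracking error at ~33 Hz bright-field sampling, um.
TRACKING_ERROR_UM = 0.017


# ---------------------------------------------------------------------------
# conversions
# ---------------------------------------------------------------------------

def tension_from_force(f, kappa: float = KAPPA_DEFAULT):
    """Membrane tension from tether force: sigma = f^2 / (8 pi^2 kappa).

    Parameters
    ----------
    f : float or array
        Tether force, pN.  Must be >= 0.
    kappa : float
        Bending modulus, pN*um.  Must be > 0.

    Returns
    -------
    sigma : float or array, pN/um.
    """
    f = np.asarray(f, dtype=float)
    if np.any(f < 0):
        raise DomainError("tether force must be non-negative")
    if kappa <= 0:
        raise DomainError("bending modulus kappa must be positive")
    sigma = f * f / (8.0 * np.pi**2 * kappa)
    return float(sigma) if sigma.ndim == 0 else sigma


def force_from_tension(sigma, kappa: float = KAPPA_DEFAULT):
    """Tether force from membrane tension: f = 2 pi sqrt(2 kappa sigma)."""
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma < 0):
        raise DomainError("membrane tension must be non-negative")
    if kappa <= 0:
        raise DomainError("bending modulus kappa must be positive")
    f = 2.0 * np.pi * np.sqrt(2.0 * kappa * sigma)
    return float(f) if f.ndim == 0 else f


def radius_from_force(f, kappa: float = KAPPA_DEFAULT):
    """Tether radius from force: r = 2 pi kappa / f (f > 0)."""
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0):
        raise DomainError("tether radius is undefined at zero force")
    if kappa <= 0:
        raise DomainError("bending modulus kappa must be positive")
    r = 2.0 * np.pi * kappa / f
    return float(r) if r.ndim == 0 else r


def radius_from_tension(sigma, kappa: float = KAPPA_DEFAULT):
    """Tether radius from tension: r = sqrt(kappa / (2 sigma)) (sigma > 0)."""
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise DomainError("tether radius is undefined at zero tension")
    r = np.sqrt(kappa / (2.0 * sigma))
    return float(r) if r.ndim == 0 else r


def force_from_displacement(dr, k_trap: float):
    """Trap force on the bead, f = k_trap * dr.

    ``dr`` is the deviation of the bead centroid from its zero-force
    position (um); ``k_trap`` is the calibrated trap stiffness (pN/um).
    """
    dr = np.asarray(dr, dtype=float)
    if np.any(dr < 0):
        raise DomainError("bead displacement magnitude must be non-negative")
    if k_trap <= 0:
        raise DomainError("trap stiffness must be positive")
    f = k_trap * dr
    return float(f) if f.ndim == 0 else f


def force_uncertainty(tracking_error: float = TRACKING_ERROR_UM,
                      k_trap: float = 75.0) -> float:
    """Force uncertainty delta_f = k_trap * (bead tracking RMS error).

    With the default 17 nm tracking error and 75 pN/um stiffness this is
    ~1.3 pN, the single-sample noise floor of a force trace.
    """
    return force_from_displacement(tracking_error, k_trap)


def tension_uncertainty(f: float, delta_f: float = 1.3,
                        kappa: float = KAPPA_DEFAULT) -> float:
    """Propagate a force error through sigma = f^2/(8 pi^2 kappa).

    d(sigma)/df = f/(4 pi^2 kappa), so delta_sigma = f*delta_f/(4 pi^2 kappa).
    Used as the default detectability threshold for probe-tether responses.
    """
    if f < 0 or delta_f < 0:
        raise DomainError("force and its uncertainty must be non-negative")
    return f * delta_f / (4.0 * np.pi**2 * kappa)


# ---------------------------------------------------------------------------
# trap calibration
# ---------------------------------------------------------------------------

def drag_coefficient(fluid_viscosity: float, bead_radius: float) -> float:
    """Stokes drag gamma = 6 pi eta R for a sphere of *radius* R (um).

    Note the argument is the bead radius; bead sizes are usually quoted as
    diameters (e.g. 1.9 or 3.2 um beads), so divide by two first.
    """
    if fluid_viscosity <= 0 or bead_radius <= 0:
        raise DomainError("viscosity and bead radius must be positive")
    return 6.0 * np.pi * fluid_viscosity * bead_radius


def hydrodynamic_force(gamma: float, w_d: float, A_pp: float):
    """Peak hydrodynamic force on a trapped bead under stage oscillation.

    For sinusoidal stage motion with angular frequency ``w_d`` (rad/s) and
    peak-to-peak amplitude ``A_pp`` (um), in the low-frequency regime
    w_d * (gamma/k_trap) << 1, f_hydro = gamma * w_d * A_pp / 2.
    """
    if gamma < 0 or w_d < 0 or A_pp < 0:
        raise DomainError("all inputs must be non-negative")
    return gamma * w_d * A_pp / 2.0


def calibrate_trap(records) -> float:
    """Trap stiffness from oscillation records.

    Parameters
    ----------
    records : sequence of (A_bead, f_hydro) pairs
        Bead oscillation amplitude (um) against the applied hydrodynamic
        force (pN), over at least two distinct drive conditions.

    Returns
    -------
    k_trap : float, pN/um
        Inverse slope of the linear fit of A_bead versus f_hydro
        (A_bead = f_hydro / k_trap).
    """
    arr = np.atleast_2d(np.asarray(records, dtype=float))
    if arr.shape[0] < 2 or arr.shape[1] != 2:
        raise FitError("need >= 2 (A_bead, f_hydro) records")
    a_bead, f_hydro = arr[:, 0], arr[:, 1]
    if np.ptp(f_hydro) == 0:
        raise FitError("degenerate records: all f_hydro equal")
    slope, _ = np.polyfit(f_hydro, a_bead, 1)
    if slope <= 0:
        raise FitError("non-positive A_bead vs f_hydro slope")
    return 1.0 / slope


def reynolds_number(v_l: float, D_bead: float,
                    rho: float = WATER_DENSITY,
                    eta: float = WATER_VISCOSITY):
    """Reynolds number Re = v * D * rho / eta of the bead flow.

    ``D_bead`` is the bead *diameter* (um).  For um/s speeds and um beads in
    water, Re ~ 1e-6: inertia is negligible in every trap experiment here.
    """
    if D_bead <= 0 or rho <= 0 or eta <= 0:
        raise DomainError("diameter, density and viscosity must be positive")
    if np.any(np.asarray(v_l) < 0):
        raise DomainError("speed must be non-negative")
    return v_l * D_bead * rho / eta


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MembraneConstants:
    """Membrane material constants. kappa: bending modulus, pN*um."""

    kappa: float = KAPPA_DEFAULT

    def __post_init__(self):
        if self.kappa <= 0:
            raise DomainError("kappa must be positive")


@dataclass(frozen=True)
class TetherState:
    """Force, tension, radius and length of one tether at an instant.

    Any subset of fields may be populated; when force, tension and radius
    are all present they must be mutually consistent with a single bending
    modulus (f*r = 2*pi*kappa and sigma = f/(4*pi*r)).
    """

    force: float | None = None        # pN
    tension: float | None = None      # pN/um
    radius: float | None = None       # um
    length: float | None = None       # um

    def __post_init__(self):
        if self.force is not None and self.force < 0:
            raise DomainError("force must be >= 0")
        if self.tension is not None and self.tension < 0:
            raise DomainError("tension must be >= 0")
        if self.tension is not None and self.tension > 0:
            if self.radius is not None and self.radius <= 0:
                raise DomainError("radius must be > 0 at finite tension")
        if None not in (self.force, self.tension, self.radius):
            # sigma = f/(4 pi r) is the consistency relation implied by
            # f = 2 pi sqrt(2 kappa sigma) and r = sqrt(kappa/(2 sigma))
            expected = self.force / (4.0 * np.pi * self.radius)
            if not np.isclose(self.tension, expected, rtol=1e-6, atol=1e-12):
                raise DomainError(
                    f"inconsistent tether state: tension {self.tension} != "
                    f"f/(4 pi r) = {expected}")

    @classmethod
    def from_force(cls, f: float, kappa: float = KAPPA_DEFAULT,
                   length: float | None = None) -> "TetherState":
        return cls(force=f, tension=tension_from_force(f, kappa),
                   radius=radius_from_force(f, kappa) if f > 0 else None,
                   length=length)

    @property
    def implied_kappa(self) -> float:
        """kappa = f*r/(2*pi) when force and radius are populated."""
        if self.force is None or self.radius is None:
            raise DomainError("force and radius required")
        return self.force * self.radius / (2.0 * np.pi)


@dataclass(frozen=True)
class TrapCalibration:
    """Calibrated optical-trap parameters.

    ``bead_radius`` is a radius, in um: quoted bead sizes (1.9, 3.2 um) are
    diameters and must be halved.  ``drag_gamma`` defaults to Stokes drag
    6*pi*eta*R.  The hydrodynamic calibration is only valid in the
    low-frequency regime w_d*(gamma/k_trap) << 1; a violation triggers a
    warning and sets ``low_frequency_regime`` False.
    """

    k_trap: float                       # pN/um
    bead_radius: float = 1.5            # um (3 um diameter bead)
    fluid_viscosity: float = WATER_VISCOSITY
    drag_gamma: float | None = None     # pN*s/um
    drive_frequency: float = 0.0        # Hz
    peak_to_peak_amplitude: float = 0.0  # um
    regime_tolerance: float = 0.1
    low_frequency_regime: bool = field(init=False, default=True)

    def __post_init__(self):
        if self.k_trap <= 0:
            raise DomainError("k_trap must be positive")
        if self.drag_gamma is None:
            object.__setattr__(
                self, "drag_gamma",
                drag_coefficient(self.fluid_viscosity, self.bead_radius))
        w_d = 2.0 * np.pi * self.drive_frequency
        wt = w_d * self.drag_gamma / self.k_trap
        if wt >= self.regime_tolerance:
            object.__setattr__(self, "low_frequency_regime", False)
            warnings.warn(
                f"w_d*tau = {wt:.3g} violates the low-frequency calibration "
                "regime (should be << 1)", stacklevel=2)

    @property
    def relaxation_time(self) -> float:
        """tau = gamma / k_trap, s."""
        return self.drag_gamma / self.k_trap


@dataclass
class ForceTrace:
    """A time series of bead displacement / force / tension.

    time must be strictly increasing; force = k_trap * displacement holds
    elementwise when both channels and a stiffness are given.
    """

    time: np.ndarray                       # s
    displacement: np.ndarray | None = None  # um, |dr| from zero-force pos.
    force: np.ndarray | None = None        # pN
    tension: np.ndarray | None = None      # pN/um
    sampling_rate: float | None = None     # Hz
    k_trap: float | None = None            # pN/um

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        if self.time.ndim != 1 or self.time.size < 2:
            raise DomainError("time must be a 1D array with >= 2 samples")
        if np.any(np.diff(self.time) <= 0):
            raise DomainError("time must be strictly increasing")
        for name in ("displacement", "force", "tension"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != self.time.shape:
                    raise DomainError(f"{name} shape differs from time")
                setattr(self, name, v)
        if (self.force is not None and self.displacement is not None
                and self.k_trap is not None):
            if not np.allclose(self.force, self.k_trap * self.displacement,
                               rtol=1e-6, atol=1e-9):
                raise DomainError("force != k_trap * displacement")

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.time)))


# ---------------------------------------------------------------------------
# step-response characterisation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StepResponseFit:
    """Double-exponential fit of a normalized step response.

    f~(t) = 1 - a1*exp(-t/tau1) - a2*exp(-t/tau2), time constants sorted
    ascending with their matched amplitudes.
    """

    amplitudes: tuple[float, float]
    time_constants: tuple[float, float]
    f0: float
    f_max: float
    residual_rms: float

    def evaluate(self, t):
        a1, a2 = self.amplitudes
        t1, t2 = self.time_constants
        t = np.asarray(t, dtype=float)
        return 1.0 - a1 * np.exp(-t / t1) - a2 * np.exp(-t / t2)


def _step_model(t, a1, a2, tau1, tau2):
    return 1.0 - a1 * np.exp(-t / tau1) - a2 * np.exp(-t / tau2)


def fit_step_response(time, force, f0: float | None = None,
                      f_max: float | None = None) -> StepResponseFit:
    """Fit a double exponential to a tether-force step response.

    The trace is normalized to f~ = (f - f0)/(f_max - f0) (0 at the step,
    1 at the new plateau) and fit to
    f~(t) = 1 - a1 exp(-t/tau1) - a2 exp(-t/tau2), with amplitudes
    constrained non-negative and summing to at most 1.05.  Time is measured
    from the step onset.

    Parameters
    ----------
    time, force : arrays
        Response from the moment of the step extension onward.
    f0, f_max : float, optional
        Baseline and plateau forces; default to the first sample and the
        mean of the final 10% of samples.

    Returns
    -------
    StepResponseFit with time constants sorted ascending.
    """
    t = np.asarray(time, dtype=float)
    f = np.asarray(force, dtype=float)
    if t.shape != f.shape or t.size < 8:
        raise FitError("need matched time/force arrays with >= 8 samples")
    t = t - t[0]
    if f0 is None:
        f0 = float(f[0])
    if f_max is None:
        f_max = float(np.mean(f[-max(3, f.size // 10):]))
    if np.isclose(f_max, f0):
        raise DomainError("flat trace: f_max == f0, cannot normalize")
    fn = (f - f0) / (f_max - f0)

    # initialize from a single-exponential time scale (first half-rise)
    above = np.nonzero(fn >= 0.5)[0]
    t_half = t[above[0]] if above.size else t[t.size // 2]
    tau_s = max(t_half / np.log(2.0), 1e-3)

    params = Parameters()
    params.add("total", value=min(max(1.0 - fn[0], 0.1), 1.05),
               min=1e-6, max=1.05)
    params.add("w", value=0.5, min=0.0, max=1.0)
    params.add("a1", expr="total * w")
    params.add("a2", expr="total * (1 - w)")
    params.add("tau1", value=tau_s / 5.0, min=1e-6)
    params.add("tau2", value=tau_s * 2.0, min=1e-6)

    def residual(p):
        return _step_model(t, p["a1"], p["a2"], p["tau1"], p["tau2"]) - fn

    out = lm_minimize(residual, params, method="least_squares")
    if not out.success:
        raise FitError(f"step-response fit failed: {out.message}")
    p = out.params
    pairs = sorted([(p["tau1"].value, p["a1"].value),
                    (p["tau2"].value, p["a2"].value)])
    taus = (pairs[0][0], pairs[1][0])
    amps = (pairs[0][1], pairs[1][1])
    rms = float(np.sqrt(np.mean(out.residual**2)))
    return StepResponseFit(amplitudes=amps, time_constants=taus,
                           f0=f0, f_max=f_max, residual_rms=rms)


# ---------------------------------------------------------------------------
# fluorescence-based tension
# ---------------------------------------------------------------------------

def tension_from_fluorescence(I_t, reference: tuple[float, float]):
    """Tension from integrated tether fluorescence.

    Tether fluorescence integrates over the tube circumference, I ~ r, and
    sigma = kappa/(2 r^2) ~ 1/I^2, so a single reference pair (I_ref,
    sigma_ref) calibrates the readout: sigma = sigma_ref * (I_ref / I)^2.
    """
    I_ref, sigma_ref = reference
    if I_ref <= 0 or sigma_ref <= 0:
        raise DomainError("reference intensity and tension must be positive")
    I_t = np.asarray(I_t, dtype=float)
    if np.any(I_t <= 0):
        raise DomainError("tether intensity must be positive")
    sigma = sigma_ref * (I_ref / I_t) ** 2
    return float(sigma) if sigma.ndim == 0 else sigma
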