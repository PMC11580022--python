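"""Seeded synthetic-data generators with known ground truth.

Every experiment the pipeline analyses can be generated here under a fixed
integer seed: double-tether probe traces (forward-simulated tension
propagation plus tether lag and tracking noise), FRAP recovery curves,
tether-dragging tracks with programmed stick-slip stalls, and stimulation
traces coupling a calcium transient to a tension drop and recovery.

Scenario presets bundle the parameters of the cell types studied:

- ``bipolar_terminal``: fast tension propagation (D_sigma = 24 um^2/s, a
  regime where a pull is sensed within seconds over ~10 um), immobile
  fraction 0.39, low sliding onset force (~8 pN), D_t = 0.019 um^2/s.
- ``bipolar_soma``: as the terminal but immobile fraction 0.37,
  D_t = 0.011 um^2/s.
- ``chromaffin``: no detectable propagation (D_sigma = 0.01 um^2/s),
  immobile fraction 0.60, high onset force (~24 pN), D_t = 0.010 um^2/s.
- ``hela``: the slow-propagation literature value D_sigma = 0.024 um^2/s.

Tracking noise is additive Gaussian on bead position with the 17 nm RMS
default, so force traces carry per-sample noise of k_trap * 0.017
(~1.3 pN at the default 75 pN/um stiffness).  All randomness derives from
``GeneratorConfig.seed``; the same seed reproduces bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import io as mio
from .activity import ExoEndoParams, simulate_exo_endo
from .diffusion import MembraneModel, PullProtocol, simulate_probe_response
from .frap import A_BLEACH_DEFAULT, recovery_model
from .mechanics import force_from_tension

__all__ = [
    "SCENARIOS",
    "ScenarioPreset",
    "GeneratorConfig",
    "gen_double_tether",
    "gen_frap",
    "gen_drag_track",
    "gen_stimulus",
]


@dataclass(frozen=True)
class ScenarioPreset:
    """Parameter bundle for one cell type."""

    D_sigma: float          # um^2/s
    immobile_fraction: float
    D_t: float              # um^2/s
    onset_force: float      # pN, tangential force for free sliding
    stall_peak: float       # pN, force a stalled tether sustains
    sigma0: float           # pN/um resting tension


SCENARIOS: dict[str, ScenarioPreset] = {
    "bipolar_terminal": ScenarioPreset(24.0, 0.39, 0.019, 8.0, 8.0, 5.0),
    "bipolar_soma": ScenarioPreset(24.0, 0.37, 0.011, 8.0, 8.0, 5.0),
    "chromaffin": ScenarioPreset(0.01, 0.60, 0.010, 24.0, 24.0, 5.0),
    "hela": ScenarioPreset(0.024, 0.50, 0.010, 24.0, 24.0, 5.0),
}


class GeneratorConfig(BaseModel):
    """Seeded generator settings (defaults match the study conditions)."""

    model_config = {"extra": "forbid"}

    seed: int = 0
    sampling_rate: float = Field(default=30.0, gt=0)   # Hz (alt 14, 4.2, 1)
    tracking_noise_sd: float = Field(default=0.017, ge=0)  # um RMS
    k_trap: float = Field(default=75.0, gt=0)          # pN/um (73-271)
    scenario: Literal["bipolar_terminal", "bipolar_soma",
                      "chromaffin", "hela"] = "bipolar_terminal"

    @property
    def preset(self) -> ScenarioPreset:
        return SCENARIOS[self.scenario]

    @property
    def force_noise_sd(self) -> float:
        """Per-sample force noise, pN: k_trap x tracking error."""
        return self.k_trap * self.tracking_noise_sd

    def rng(self, stream: int = 0) -> np.random.Generator:
        """Deterministic child generator for a named stream."""
        return np.random.default_rng(np.random.SeedSequence(
            entropy=self.seed, spawn_key=(stream,)))


def _maybe_write(out_dir, name: str, df: pd.DataFrame, truth: dict,
                 schema: str):
    if out_dir is None:
        return None
    out_dir = Path(out_dir)
    mio.write_trace(df, out_dir / f"{name}.csv", schema=schema)
    mio.write_json(truth, out_dir / f"{name}_truth.json")
    return out_dir / f"{name}.csv"


# ---------------------------------------------------------------------------
# double tether
# ---------------------------------------------------------------------------

def gen_double_tether(config: GeneratorConfig,
                      D_sigma: float | None = None,
                      d: float = 8.0,
                      protocol: PullProtocol | None = None,
                      sigma0: float | None = None,
                      lag_tau: float = 1.0,
                      E: float | None = None,
                      geometry=None,
                      out_dir=None) -> tuple[pd.DataFrame, dict]:
    """Generate a probe-tether force trace for a double-tether experiment.

    The probe tension is the forward-simulated diffusive response at
    distance d, lag-filtered with the tether response time, offset by the
    resting tension, converted to force, and noised with the tracking
    error.  ``geometry`` defaults to the infinite plane; pass a
    ReflectingDisc to emulate a bounded terminal-scale membrane.
    Returns (force-trace DataFrame, truth dict).
    """
    preset = config.preset
    if D_sigma is None:
        D_sigma = preset.D_sigma
    if sigma0 is None:
        sigma0 = preset.sigma0
    if protocol is None:
        protocol = PullProtocol(start_time=10.0)
    model = (MembraneModel.from_dsigma(D_sigma) if E is None
             else MembraneModel.from_dsigma(D_sigma, E=E))

    dt = 1.0 / config.sampling_rate
    t_end = protocol.start_time + protocol.duration + 10.0
    times = np.arange(0.0, t_end, dt)
    kwargs = {} if geometry is None else {"geometry": geometry}
    resp = simulate_probe_response(protocol, model, d, times=times,
                                   lag_tau=lag_tau, **kwargs)
    sigma = np.maximum(sigma0 + resp.delta_sigma, 1e-6)
    force_clean = force_from_tension(sigma)
    rng = config.rng(stream=1)
    force = force_clean + rng.normal(0.0, config.force_noise_sd,
                                     size=times.size)
    force = np.maximum(force, 0.0)
    df = pd.DataFrame({
        "time_s": times,
        "dr_um": force / config.k_trap,
        "force_pN": force,
        "tension_pN_per_um": force**2 / (8.0 * np.pi**2 * 0.27),
    })
    truth = {
        "D_sigma_um2_s": D_sigma, "d_um": d, "sigma0_pN_per_um": sigma0,
        "E_pN_per_um": model.E, "lag_tau_s": lag_tau, "seed": config.seed,
        "geometry": "plane" if geometry is None else repr(geometry),
        "scenario": config.scenario, "k_trap_pN_per_um": config.k_trap,
        "protocol": {
            "extend_speed_um_s": protocol.extend_speed,
            "extend_distance_um": protocol.extend_distance,
            "hold_s": protocol.hold_time,
            "retract_speed_um_s": protocol.retract_speed,
            "tether_radius_um": protocol.tether_radius,
            "start_s": protocol.start_time,
        },
    }
    _maybe_write(out_dir, "double_tether", df, truth, "force_trace")
    return df, truth


# ---------------------------------------------------------------------------
# FRAP
# ---------------------------------------------------------------------------

def gen_frap(config: GeneratorConfig,
             D_t: float | None = None,
             immobile_fraction: float | None = None,
             A_bleach: float = A_BLEACH_DEFAULT,
             F0: float = 0.05,
             noise_sd: float = 0.03,
             f_pre: float = 1000.0,
             f_o: float = 120.0,
             out_dir=None) -> tuple[pd.DataFrame, dict]:
    """Generate a FRAP recovery curve with known D_t and immobile fraction.

    The half-time is set by inverting D_t = A_bleach/(4*t_half); the
    plateau by the immobile fraction (mobile = F_inf - F0 = 1 - immobile).
    Acquisition follows the two-phase schedule: 30 frames every 1.29 s,
    then 30 frames every 60 s, with 4 prebleach frames.
    """
    preset = config.preset
    if D_t is None:
        D_t = preset.D_t
    if immobile_fraction is None:
        immobile_fraction = preset.immobile_fraction
    if D_t <= 0:
        raise ValueError("D_t must be positive")
    t_half = A_bleach / (4.0 * D_t)
    F_inf = F0 + (1.0 - immobile_fraction)

    t_fast = np.arange(30) * 1.29
    t_slow = t_fast[-1] + 60.0 * np.arange(1, 31)
    t_post = np.concatenate([t_fast, t_slow])
    F_clean = recovery_model(t_post, F0, F_inf, t_half)
    rng = config.rng(stream=2)
    F_noisy = F_clean + rng.normal(0.0, noise_sd, size=t_post.size)

    t_pre = -1.29 * np.arange(4, 0, -1)
    pre = np.full(4, f_pre) + rng.normal(0.0, noise_sd * (f_pre - f_o),
                                         size=4)
    raw_post = f_o + F_noisy * (f_pre - f_o)
    df = pd.DataFrame({
        "time_s": np.concatenate([t_pre, t_post]),
        "intensity_au": np.concatenate([pre, raw_post]),
    })
    truth = {
        "D_t_um2_s": D_t, "t_half_s": t_half,
        "immobile_fraction": immobile_fraction,
        "F0": F0, "F_inf": F_inf, "A_bleach_um2": A_bleach,
        "f_pre": f_pre, "f_o": f_o, "noise_sd": noise_sd,
        "seed": config.seed, "scenario": config.scenario,
    }
    _maybe_write(out_dir, "frap", df, truth, "frap")
    if out_dir is not None:
        mio.write_json({"f_pre": f_pre, "f_o": f_o, "background": 0.0,
                        "A_bleach_um2": A_bleach},
                       Path(out_dir) / "frap_sidecar.json")
    return df, truth


# ---------------------------------------------------------------------------
# tether dragging
# ---------------------------------------------------------------------------

def gen_drag_track(config: GeneratorConfig,
                   motif: Literal["free_slide", "stick_slip",
                                  "immobile"] = "stick_slip",
                   cell_radius: float = 5.0,
                   n_contour: int = 72,
                   tether_length: float = 3.0,
                   out_dir=None) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate a tether-dragging track on a circular cell.

    The tether base moves along the circumference of a circular contour
    with a programmed speed profile; the bead sits ``tether_length`` from
    the base at an angle theta chosen so f*sin(theta) follows the
    programmed tangential-force profile.

    Motifs: ``free_slide`` (constant sliding at the onset force),
    ``stick_slip`` (slide / stall-with-force-ramp alternation, stall peaks
    at the preset onset force and the chromaffin-like 24 pN), ``immobile``
    (one full-record stall).  Stall plateaus hold the peak force for the
    final 1.5 s of each stall so smoothed boundary shifts do not clip the
    peak.

    Returns (frames DataFrame, contours long-format DataFrame, truth).
    """
    preset = config.preset
    fps = config.sampling_rate
    dt = 1.0 / fps
    slide_speed = 2.0                    # um/s along the circumference
    slide_force = min(4.0, preset.onset_force)   # f_par while sliding
    total_force = 26.0                   # pN, constant trap force

    if motif == "free_slide":
        segs = [("move", 20.0, preset.onset_force)]
        stall_peaks: list[float] = []
    elif motif == "stick_slip":
        stall_peaks = [preset.stall_peak, 24.0]
        segs = [("move", 5.0, slide_force),
                ("stall", 6.0, stall_peaks[0]),
                ("move", 5.0, slide_force),
                ("stall", 6.0, stall_peaks[1]),
                ("move", 4.0, slide_force)]
    elif motif == "immobile":
        segs = [("stall", 20.0, preset.stall_peak)]
        stall_peaks = [preset.stall_peak]
    else:
        raise ValueError(f"unknown motif '{motif}'")

    times, phi_list, fpar_list = [], [], []
    t = 0.0
    phi = 0.0
    stall_windows = []
    for kind, dur, f_level in segs:
        n = int(round(dur * fps))
        tt = t + dt * np.arange(n)
        if kind == "move":
            phis = phi + (slide_speed / cell_radius) * dt * np.arange(n)
            fpar = np.full(n, f_level)
            phi = phis[-1] + (slide_speed / cell_radius) * dt
        else:
            phis = np.full(n, phi)
            # ramp from the sliding force to the peak, hold peak 1.5 s
            ramp_n = max(int(round((dur - 1.5) * fps)), 1)
            fpar = np.concatenate([
                np.linspace(slide_force, f_level, ramp_n),
                np.full(n - ramp_n, f_level)])
            stall_windows.append((t, t + dur, f_level))
        times.append(tt)
        phi_list.append(phis)
        fpar_list.append(fpar)
        t += dur
    times = np.concatenate(times)
    phi_arr = np.concatenate(phi_list)
    fpar = np.concatenate(fpar_list)

    theta = np.arcsin(np.clip(fpar / total_force, 0.0, 1.0))
    base = cell_radius * np.column_stack([np.cos(phi_arr), np.sin(phi_arr)])
    normal = np.column_stack([np.cos(phi_arr), np.sin(phi_arr)])
    tangent = np.column_stack([-np.sin(phi_arr), np.cos(phi_arr)])
    # bead direction: rotate the outward normal by theta toward the tangent
    bead_dir = (np.cos(theta)[:, None] * normal
                + np.sin(theta)[:, None] * tangent)
    bead = base + tether_length * bead_dir

    rng = config.rng(stream=3)
    noise = config.tracking_noise_sd
    base_n = base + rng.normal(0.0, noise, size=base.shape)
    bead_n = bead + rng.normal(0.0, noise, size=bead.shape)

    frames = pd.DataFrame({
        "time_s": times,
        "base_x_um": base_n[:, 0], "base_y_um": base_n[:, 1],
        "bead_x_um": bead_n[:, 0], "bead_y_um": bead_n[:, 1],
        "force_pN": np.full(times.size, total_force),
    })
    ang = 2.0 * np.pi * np.arange(n_contour) / n_contour
    recs = []
    for i in range(times.size):
        cx = cell_radius * np.cos(ang) + rng.normal(0, noise, n_contour)
        cy = cell_radius * np.sin(ang) + rng.normal(0, noise, n_contour)
        recs.append(pd.DataFrame({
            "frame": np.full(n_contour, i, dtype=int),
            "idx": np.arange(n_contour),
            "x_um": cx, "y_um": cy}))
    contours = pd.concat(recs, ignore_index=True)

    truth = {
        "motif": motif, "cell_radius_um": cell_radius,
        "slide_speed_um_s": slide_speed, "total_force_pN": total_force,
        "stall_windows": [{"t_start_s": a, "t_end_s": b, "f_peak_pN": f}
                          for (a, b, f) in stall_windows],
        "stall_peaks_pN": stall_peaks,
        "seed": config.seed, "scenario": config.scenario,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        mio.write_trace(frames, out_dir / "frames.csv", schema="drag_frames")
        mio.write_trace(contours, out_dir / "contours.csv",
                        schema="drag_contours")
        mio.write_json(truth, out_dir / "drag_truth.json")
    return frames, contours, truth


# ---------------------------------------------------------------------------
# stimulation
# ---------------------------------------------------------------------------

def gen_stimulus(config: GeneratorConfig,
                 endo_efficiency: float = 1.0,
                 photolysis: bool = True,
                 sigma0: float = 10.0,
                 duration: float = 80.0,
                 t_on: float = 10.0,
                 ca_peak: float = 3.5,
                 tension_noise_sd: float = 0.15,
                 dff_noise_sd: float = 0.05,
                 sample_rate: float = 1.0,
                 params: ExoEndoParams | None = None,
                 out_dir=None) -> tuple[pd.DataFrame, dict]:
    """Generate a coupled calcium/tension stimulation trace.

    A 1 s photolysis pulse at ``t_on`` triggers a calcium transient
    (difference-of-exponentials, peak ``ca_peak``) and the exo-endo
    tension dip/recovery with the given endocytic efficiency, sampled at
    the two-channel acquisition rate (1 frame/s per channel by default).
    ``photolysis=False`` produces the flat no-stimulation control.
    """
    if params is None:
        params = ExoEndoParams(endo_efficiency=endo_efficiency)
    elif params.endo_efficiency != endo_efficiency:
        raise ValueError("params.endo_efficiency conflicts with argument")

    fine = simulate_exo_endo(params, sigma0=sigma0, duration=duration,
                             t_on=t_on, dt=0.02)
    times = np.arange(0.0, duration, 1.0 / sample_rate)
    if photolysis:
        tension = np.interp(times, fine.time, fine.tension)
        ts = times - t_on
        shape = np.where(ts > 0,
                         np.exp(-np.maximum(ts, 0.0) / 3.0)
                         - np.exp(-np.maximum(ts, 0.0) / 0.3), 0.0)
        peak_val = np.max(shape) if np.max(shape) > 0 else 1.0
        dff = ca_peak * shape / peak_val
        expected = None
        try:
            from .activity import StimulusTrace, recovered_fraction
            clean = StimulusTrace(time=times, tension=tension,
                                  stimulus_window=(t_on, t_on + 1.0))
            expected = recovered_fraction(clean, window=50.0)
        except Exception:
            pass
    else:
        tension = np.full(times.size, sigma0)
        dff = np.zeros(times.size)
        expected = None

    rng = config.rng(stream=4)
    tension_n = tension + rng.normal(0.0, tension_noise_sd, times.size)
    dff_n = dff + rng.normal(0.0, dff_noise_sd, times.size)
    df = pd.DataFrame({"time_s": times, "tension_pN_per_um": tension_n,
                       "dF_over_F": dff_n})
    truth = {
        "endo_efficiency": endo_efficiency if photolysis else None,
        "photolysis": photolysis, "sigma0_pN_per_um": sigma0,
        "t_on_s": t_on, "ca_peak_dff": ca_peak if photolysis else 0.0,
        "expected_recovered_fraction": expected,
        "endo_tau_s": params.endo_tau,
        "area_added_fraction": params.area_added_fraction,
        "seed": config.seed, "scenario": config.scenario,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        mio.write_trace(df, out_dir / "stimulus.csv", schema="stimulus")
        mio.write_json({"t_on_s": t_on, "t_off_s": t_on + 1.0},
                       out_dir / "stimulus_sidecar.json")
        mio.write_json(truth, out_dir / "stimulus_truth.json")
    return df, truth
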