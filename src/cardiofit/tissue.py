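"""1D monodomain cable (plus a coarse 2D sheet mode) for coupling experiments.

Purpose: parameter sets with matched single-cell APs but different membrane
resistance diverge once cells are electrotonically coupled, and decoupling
(scaling the intracellular conductivity down) moves the tissue AP back
toward the single-cell AP.  The cable is the desk-scale geometry for that
demonstration; the sheet mode exists for center-stimulated 2D runs at
coarser resolution.

Monodomain reaction-diffusion, explicit operator splitting: a forward-Euler
diffusion step on V followed by the jitted single-cell ionic step per node.
The effective voltage diffusivity is D = sigma / (chi * C_m) with sigma the
intracellular conductivity, chi the surface-to-volume ratio and C_m the
specific membrane capacitance (the latter two are not model parameters of
the cell model itself and are exposed in :class:`CableConfig`).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import _tnnp_core as _core
from .ionic_model import ParameterVector, TNNPModel
from .protocols import APTrace, apd90, pace

__all__ = ["CableConfig", "CableResult", "simulate_cable", "coupling_sweep",
           "simulate_sheet", "CableUnstableError"]


class CableUnstableError(RuntimeError):
    """The explicit scheme diverged (|V_m| exceeded 200 mV)."""


@dataclass
class CableConfig:
    """Geometry, numerics and stimulus of the 1D cable.

    Defaults: 1 cm fiber, 100 um nodes, 25 us time step, longitudinal
    intracellular conductivity 0.174 S/m, chi = 1400 /cm, C_m = 1 uF/cm^2.
    ``coupling_scale`` multiplies the conductivity (the decoupling knob).
    """

    length_cm: float = 1.0
    dx_um: float = 100.0
    dt_us: float = 25.0
    sigma_s_per_m: float = 0.174
    chi_per_cm: float = 1400.0
    cm_uf_per_cm2: float = 1.0
    coupling_scale: float = 1.0
    stim_site: str = "left"            # "left" | "center"
    stim_width_nodes: int = 5
    stim_amp: float = -104.0           # pA/pF, transmembrane
    stim_dur_ms: float = 2.0
    pre_pace_beats: int = 3
    cycle_length: float = 1000.0

    def __post_init__(self) -> None:
        if self.dx_um <= 0 or self.dt_us <= 0:
            raise ValueError("dx and dt must be positive")
        if self.lam > 0.5:
            raise ValueError(
                f"explicit diffusion number D*dt/dx^2 = {self.lam:.3f} > 0.5: "
                "unstable; refine dt or coarsen dx")

    @property
    def n_nodes(self) -> int:
        return int(round(self.length_cm / (self.dx_um * 1e-4))) + 1

    @property
    def diffusivity_cm2_per_ms(self) -> float:
        sigma_s_per_cm = self.sigma_s_per_m * 1e-2 * self.coupling_scale
        d_cm2_per_s = sigma_s_per_cm / (self.chi_per_cm * self.cm_uf_per_cm2 * 1e-6)
        return d_cm2_per_s * 1e-3

    @property
    def lam(self) -> float:
        dx_cm = self.dx_um * 1e-4
        return self.diffusivity_cm2_per_ms * (self.dt_us * 1e-3) / dx_cm ** 2


@dataclass
class CableResult:
    """Per-node traces, activation map and conduction velocity."""

    traces: dict[int, APTrace]
    activation_ms: np.ndarray
    cv_cm_per_s: float
    config: CableConfig

    def interior_apd90(self) -> float:
        node = sorted(self.traces)[len(self.traces) // 2]
        return apd90(self.traces[node])


def _initial_states(model: TNNPModel, p: ParameterVector,
                    config: CableConfig) -> np.ndarray:
    """Every node starts from the single-cell state after pre-pacing."""
    if config.pre_pace_beats > 0:
        res = pace(model, p,
                   duration=config.pre_pace_beats * config.cycle_length
                   + config.cycle_length,
                   cycle_length=config.cycle_length, sample_dt=1.0)
        y0 = res.pre_state
    else:
        y0 = model.initial_state()
    return np.tile(y0, (config.n_nodes, 1))


def simulate_cable(model: TNNPModel, p: ParameterVector, config: CableConfig,
                   duration: float = 600.0,
                   record_nodes: Sequence[int] | None = None,
                   sample_dt: float = 1.0) -> CableResult:
    """Stimulate the cable once and record the propagated beat.

    Conduction velocity is measured between two interior nodes (at 40% and
    60% of the fiber for an end stimulus) from their activation times (first
    upward crossing of 0 mV).
    """
    if not isinstance(model, TNNPModel):
        raise TypeError("the cable integrator is implemented for the TNNP model")
    n = config.n_nodes
    states = _initial_states(model, p, config)
    dt = config.dt_us * 1e-3
    every = max(1, int(round(sample_dt / dt)))
    n_steps = int(round(duration / dt))
    n_samp = n_steps // every + 1
    out_v = np.empty((n_samp, n))
    act = np.full(n, -1.0)

    if config.stim_site == "left":
        lo, hi = 0, config.stim_width_nodes
    elif config.stim_site == "center":
        mid = n // 2
        half = config.stim_width_nodes // 2
        lo, hi = mid - half, mid + half + 1
    else:
        raise ValueError(f"unknown stim_site {config.stim_site!r}")

    status = _core.cable(states, p.as_array(), 0.0, duration, dt, config.lam,
                         0.0, config.stim_dur_ms, config.stim_amp, lo, hi,
                         every, out_v, act, 0.0)
    if status != 0:
        raise CableUnstableError(
            "cable integration diverged; check coupling scale and time step")

    times = every * dt * np.arange(n_samp)
    if record_nodes is None:
        record_nodes = sorted({n // 4, n // 2, 3 * n // 4})
    traces = {int(k): APTrace(times, out_v[:, k], np.array([0.0]))
              for k in record_nodes}

    i1, i2 = int(0.4 * n), int(0.6 * n)
    if act[i1] > 0 and act[i2] > 0 and act[i2] != act[i1]:
        dx_cm = config.dx_um * 1e-4
        cv = abs((i2 - i1) * dx_cm / (act[i2] - act[i1])) * 1000.0
    else:
        cv = float("nan")
    return CableResult(traces, act, cv, config)


def coupling_sweep(model: TNNPModel, p: ParameterVector, config: CableConfig,
                   scales: Sequence[float], duration: float = 600.0) -> pd.DataFrame:
    """APD90 and conduction velocity at a fixed interior node per coupling scale."""
    if len(scales) < 2:
        raise ValueError("need at least two coupling scales")
    rows = []
    for s in scales:
        cfg = replace(config, coupling_scale=float(s))
        res = simulate_cable(model, p, cfg, duration=duration)
        rows.append({"scale": float(s), "apd90_ms": res.interior_apd90(),
                     "cv_cm_per_s": res.cv_cm_per_s})
    return pd.DataFrame(rows)


def simulate_sheet(model: TNNPModel, p: ParameterVector,
                   size_cm: float = 1.0, dx_um: float = 200.0,
                   dt_us: float = 25.0, sigma_l: float = 0.174,
                   sigma_t: float = 0.019, chi_per_cm: float = 1400.0,
                   cm_uf_per_cm2: float = 1.0, coupling_scale: float = 1.0,
                   duration: float = 600.0, stim_amp: float = -104.0,
                   stim_dur_ms: float = 2.0, pre_pace_beats: int = 3,
                   sample_dt: float = 1.0) -> APTrace:
    """Coarse center-stimulated 2D monodomain sheet; returns the trace of a
    node halfway between center and edge along the fiber direction.

    Python-loop diffusion over a coarse grid — intended for qualitative
    sheet-level checks, not production tissue simulation.
    """
    n = int(round(size_cm / (dx_um * 1e-4))) + 1
    dt = dt_us * 1e-3
    dx_cm = dx_um * 1e-4

    def lam(sig):
        d = (sig * 1e-2 * coupling_scale) / (chi_per_cm * cm_uf_per_cm2 * 1e-6) * 1e-3
        return d * dt / dx_cm ** 2

    lx, ly = lam(sigma_l), lam(sigma_t)
    if lx + ly > 0.5:
        raise CableUnstableError("2D explicit scheme unstable at this resolution")

    cfg1d = CableConfig(pre_pace_beats=pre_pace_beats)
    if pre_pace_beats > 0:
        y0 = pace(model, p, duration=(pre_pace_beats + 1) * cfg1d.cycle_length,
                  cycle_length=cfg1d.cycle_length).pre_state
    else:
        y0 = model.initial_state()
    states = np.tile(y0, (n * n, 1))
    parr = p.as_array()
    mid = n // 2
    rec = mid * n + (mid + n // 4)     # halfway to the edge along x
    every = max(1, int(round(sample_dt / dt)))
    n_steps = int(round(duration / dt))
    rec_v = [states[rec, 0]]
    V = states[:, 0].reshape(n, n)
    for i in range(n_steps):
        t = i * dt
        Vp = np.pad(V, 1, mode="edge")
        V = V + lx * (Vp[1:-1, 2:] - 2 * V + Vp[1:-1, :-2]) \
              + ly * (Vp[2:, 1:-1] - 2 * V + Vp[:-2, 1:-1])
        states[:, 0] = V.ravel()
        amp = stim_amp if t < stim_dur_ms else 0.0
        for k in range(n * n):
            i_stim = amp if (abs(k // n - mid) <= 1 and abs(k % n - mid) <= 1) else 0.0
            _core.step(states[k], parr, dt, i_stim, False)
        V = states[:, 0].reshape(n, n)
        if (i + 1) % every == 0:
            rec_v.append(states[rec, 0])
        if np.abs(V).max() > 200.0:
            raise CableUnstableError("sheet integration diverged")
    times = every * dt * np.arange(len(rec_v))
    return APTrace(times, np.array(rec_v), np.array([0.0]))
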