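"""The two objective functions of the multi-objective fitting problem.

Objective 1 — normalized AP-shape error: the mean over the comparison window
of the squared voltage residual divided by the control AP amplitude (APA),

    f_ap = mean_t [ (V_target(t) - V_fit(t))^2 ] / APA^2 .

Because the headline fit qualities are quoted on the mV scale, the mV-scale
root-mean-square error is computed alongside and carried with every
evaluation (``rmse_mv``); both refer to the same residual.

Objective 2 — normalized R_m error over the n target voltage points,

    f_rm = sum_i |R_target,i - R_fit,i| / R_base,i ,

each point normalized by the base (control-parameter) model's R_m at that
voltage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .ionic_model import ModelInterface, ParameterVector, TNNPModel
from .protocols import (APTrace, ClampSpec, NoCrossingError, PaceResult,
                        SubthresholdStimulusError, measure_rm, pace)

__all__ = [
    "TargetDataset", "ObjectiveValues", "EvalConfig",
    "mse_ap", "rm_error", "evaluate_individual", "PENALTY",
]

#: objective value assigned to individuals whose simulation fails outright;
#: dominated by any viable individual, keeps the Pareto machinery total.
PENALTY = 1.0e6


@dataclass
class TargetDataset:
    """Fitting target: one AP trace plus R_m at a few voltages.

    trace : window-relative target AP (t = 0 at stimulus onset).
    rm_voltages / rm_values : the (V, R_m) target points, same order.
    apa : AP amplitude of the *control* parameterization (normalizes f_ap).
    rm_base : base-model R_m at each voltage (normalizes f_rm).
    p_true : generating parameters when known (recovery scoring), else None.
    """

    trace: APTrace
    rm_voltages: np.ndarray
    rm_values: np.ndarray
    apa: float
    rm_base: np.ndarray
    p_true: dict | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.rm_voltages = np.asarray(self.rm_voltages, dtype=float)
        self.rm_values = np.asarray(self.rm_values, dtype=float)
        self.rm_base = np.asarray(self.rm_base, dtype=float)
        if not (len(self.rm_voltages) == len(self.rm_values) == len(self.rm_base)):
            raise ValueError("rm_voltages, rm_values and rm_base must align")
        if self.apa <= 0:
            raise ValueError("APA must be positive")
        if np.any(self.rm_base == 0):
            raise ValueError("base-model R_m values must be nonzero")
        vmin, vmax = self.trace.voltages.min(), self.trace.voltages.max()
        if np.any((self.rm_voltages < vmin) | (self.rm_voltages > vmax)):
            raise ValueError(
                f"R_m voltages must lie within the target AP's range "
                f"[{vmin:.1f}, {vmax:.1f}] mV")

    # -- serialization: JSON bundle referencing a CSV trace ---------------

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.trace.to_csv(d / "target.csv")
        np.savetxt(d / "rm_points.csv",
                   np.column_stack([self.rm_voltages, self.rm_values, self.rm_base]),
                   delimiter=",", header="V_mV,Rm_target,Rm_base", comments="")
        (d / "meta.json").write_text(json.dumps({
            "trace_csv": "target.csv",
            "rm_points_csv": "rm_points.csv",
            "apa": self.apa,
            "stim_times_ms": self.trace.stim_times.tolist(),
            "p_true": self.p_true,
            "meta": self.meta,
        }, indent=2))

    @classmethod
    def load(cls, directory) -> "TargetDataset":
        d = Path(directory)
        m = json.loads((d / "meta.json").read_text())
        trace = APTrace.from_csv(d / m["trace_csv"], stim_times=m["stim_times_ms"])
        pts = np.loadtxt(d / m["rm_points_csv"], delimiter=",", skiprows=1, ndmin=2)
        return cls(trace, pts[:, 0], pts[:, 1], m["apa"], pts[:, 2],
                   p_true=m.get("p_true"), meta=m.get("meta", {}))


@dataclass(frozen=True)
class ObjectiveValues:
    """Both objectives plus the mV-scale RMSE carried for reporting."""

    f_ap: float
    f_rm: float
    rmse_mv: float
    penalized: bool = False

    def __post_init__(self) -> None:
        if self.f_ap < 0 or (np.isfinite(self.f_rm) and self.f_rm < 0):
            raise ValueError("objective values must be non-negative")


def mse_ap(target: APTrace, fit: APTrace, apa: float) -> tuple[float, float]:
    """Normalized AP error and mV-scale RMSE on the target's time grid.

    Both traces are aligned to their own first stimulus (or first sample when
    unstimulated) and the fit is resampled onto the target's grid, which must
    be covered entirely.
    """
    if apa <= 0:
        raise ValueError("APA must be positive")

    def rel(tr: APTrace) -> APTrace:
        # align on the stimulus that opens the trace window (the last
        # stimulus at or before the first sample), else on the first sample
        before = [s for s in tr.stim_times if s <= tr.times[0] + 1e-6]
        t0 = max(before) if before else tr.times[0]
        return tr.shifted(-t0)

    tgt, ft = rel(target), rel(fit)
    grid = tgt.times
    if grid[0] < ft.times[0] - 1e-6 or grid[-1] > ft.times[-1] + 1e-6:
        raise ValueError(
            f"fit window [{ft.times[0]:.1f}, {ft.times[-1]:.1f}] does not cover "
            f"the target window [{grid[0]:.1f}, {grid[-1]:.1f}] after alignment")
    resid = tgt.voltages - ft.resample(grid)
    mse = float(np.mean(resid ** 2))
    return mse / apa ** 2, float(np.sqrt(mse))


def rm_error(target: TargetDataset, fitted_rm: Sequence[float]) -> float:
    """Normalized absolute R_m mismatch, summed over the target points."""
    fitted = np.asarray(fitted_rm, dtype=float)
    if fitted.shape != target.rm_values.shape:
        raise ValueError(
            f"expected {len(target.rm_values)} fitted R_m values, got {len(fitted)}")
    return float(np.sum(np.abs(target.rm_values - fitted) / np.abs(target.rm_base)))


@dataclass
class EvalConfig:
    """Simulation protocol shared by target generation and GA evaluation.

    The pacing protocol follows the pre-pace-to-steady-state convention:
    stimuli of ``stim_amp`` pA/pF for ``stim_dur`` ms every ``cycle_length``
    ms, ``pre_pace_ms`` of pre-pacing, objectives evaluated on the following
    full beat resampled at ``sample_dt``.
    """

    model: ModelInterface = field(default_factory=TNNPModel)
    pre_pace_ms: float = 3000.0
    cycle_length: float = 1000.0
    stim_amp: float = -52.0
    stim_dur: float = 1.0
    sample_dt: float = 1.0
    clamp_delta_v: float = 10.0
    clamp_duration: float = 5.0
    clamp_delay: float = 5.0
    objectives: str = "ap+rm"          # "ap" skips the R_m protocol entirely

    @property
    def duration(self) -> float:
        return self.pre_pace_ms + self.cycle_length

    def run_pace(self, p: ParameterVector) -> PaceResult:
        return pace(self.model, p, duration=self.duration,
                    cycle_length=self.cycle_length, stim_amp=self.stim_amp,
                    stim_dur=self.stim_dur, sample_dt=self.sample_dt)

    def run_rm(self, p: ParameterVector, baseline: PaceResult,
               voltages: np.ndarray) -> np.ndarray:
        """R_m at each requested voltage; NaN where the voltage is unreachable."""
        out = np.empty(len(voltages))
        for i, v in enumerate(voltages):
            try:
                m = measure_rm(self.model, p, baseline, ClampSpec(
                    onset_voltage=float(v), delta_v=self.clamp_delta_v,
                    duration=self.clamp_duration, delay=self.clamp_delay))
                out[i] = m.r_m
            except NoCrossingError:
                out[i] = np.nan
        return out


def evaluate_individual(p: ParameterVector, target: TargetDataset,
                        config: EvalConfig) -> ObjectiveValues:
    """Run the full protocol for one parameter set and score both objectives.

    Failure containment: a subthreshold stimulus, a diverging integration or
    a missing repolarization yields the documented worst-case penalty pair
    rather than an exception — the optimizer must never crash on a bad
    individual.  Target R_m voltages that the candidate AP never reaches
    contribute as if the fitted R_m were zero.
    """
    try:
        base = config.run_pace(p)
        f_ap, rmse = mse_ap(target.trace, base.trace, target.apa)
        if config.objectives == "ap":
            return ObjectiveValues(f_ap, float("nan"), rmse)
        fitted = config.run_rm(p, base, target.rm_voltages)
        fitted = np.where(np.isnan(fitted), 0.0, fitted)
        return ObjectiveValues(f_ap, rm_error(target, fitted), rmse)
    except (SubthresholdStimulusError, FloatingPointError, RuntimeError,
            ValueError, ArithmeticError):
        return ObjectiveValues(PENALTY, PENALTY, PENALTY, penalized=True)
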