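"""Single-cell pacing and the simulated voltage-clamp membrane-resistance protocol.

The R_m protocol: at a chosen instant during a paced action potential the
membrane is clamped to 10 mV above, then (in a second branch launched from the
identical saved state) 10 mV below, the instantaneous voltage.  The total
ionic current in each branch is read a fixed delay after clamp onset (default
5 ms, after the fast transients settle) and R_m is the slope of the two-point
V-I relation:

    R_m = (V_+10 - V_-10) / (I_+10 - I_-10)   [mV / (pA/pF)]

With +/-10 mV steps the numerator is 20 mV.  All resistances in this package
are in mV/(pA/pF), numerically GOhm*pF.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .ionic_model import ModelInterface, ParameterVector

__all__ = [
    "APTrace", "ClampSpec", "RmMeasurement", "PaceResult",
    "pace", "quiescent_baseline", "apd90", "rm_slope", "measure_rm",
    "rm_delay_sensitivity", "DelaySensitivity",
    "SubthresholdStimulusError", "NoCrossingError", "InfiniteResistanceError",
    "NoRepolarizationError",
]


class SubthresholdStimulusError(RuntimeError):
    """The pacing stimulus failed to elicit an AP (peak V_m < 0 mV)."""


class NoCrossingError(RuntimeError):
    """A voltage-specified clamp onset is never reached in the requested phase."""


class InfiniteResistanceError(ZeroDivisionError):
    """The two clamp branches returned identical currents (flat V-I slope)."""


class NoRepolarizationError(RuntimeError):
    """The trace never repolarizes to the 90% level."""


@dataclass
class APTrace:
    """Uniformly sampled (time, V_m) record.

    times : ms, strictly increasing uniform grid (absolute or window-relative).
    stim_times : onsets of the pacing stimuli that produced the trace.
    """

    times: np.ndarray
    voltages: np.ndarray
    stim_times: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.voltages = np.asarray(self.voltages, dtype=float)
        self.stim_times = np.atleast_1d(np.asarray(self.stim_times, dtype=float))
        if self.times.shape != self.voltages.shape:
            raise ValueError("times and voltages must have the same length")
        if len(self.times) < 2:
            raise ValueError("a trace needs at least two samples")
        dts = np.diff(self.times)
        if np.any(dts <= 0) or not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-9):
            raise ValueError("times must form a strictly increasing uniform grid")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def shifted(self, offset: float) -> "APTrace":
        return APTrace(self.times + offset, self.voltages.copy(),
                       self.stim_times + offset)

    def resample(self, new_times: np.ndarray) -> np.ndarray:
        """Linear interpolation of V onto ``new_times`` (must lie inside)."""
        new_times = np.asarray(new_times, dtype=float)
        if new_times[0] < self.times[0] - 1e-9 or new_times[-1] > self.times[-1] + 1e-9:
            raise ValueError(
                f"requested window [{new_times[0]}, {new_times[-1]}] not covered by "
                f"trace [{self.times[0]}, {self.times[-1]}]"
            )
        return np.interp(new_times, self.times, self.voltages)

    # -- serialization ----------------------------------------------------

    def to_csv(self, path) -> None:
        pd.DataFrame({"t_ms": self.times, "V_mV": self.voltages}).to_csv(
            path, index=False)

    @classmethod
    def from_csv(cls, path, stim_times=()) -> "APTrace":
        df = pd.read_csv(path)
        return cls(df["t_ms"].to_numpy(), df["V_mV"].to_numpy(), np.asarray(stim_times))

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({
            "t_ms": self.times.tolist(),
            "V_mV": self.voltages.tolist(),
            "stim_times_ms": self.stim_times.tolist(),
        }))

    @classmethod
    def from_json(cls, path) -> "APTrace":
        d = json.loads(Path(path).read_text())
        return cls(np.array(d["t_ms"]), np.array(d["V_mV"]),
                   np.array(d.get("stim_times_ms", [])))


@dataclass
class ClampSpec:
    """Specification of one +/-delta_v voltage-clamp R_m measurement.

    The onset is either an absolute time (``onset_time``, ms) or a target
    voltage (``onset_voltage``, mV) resolved on the baseline trace within the
    requested ``phase``:

    * ``"upstroke"`` — first upward crossing between max dV/dt and the peak;
    * ``"plateau"`` / ``"repolarization"`` — last downward crossing after the
      peak (the epicardial notch makes plateau-level voltages cross first
      during the spike-notch transient, so the last crossing is the one on
      the dome/repolarization).
    """

    onset_time: float | None = None
    onset_voltage: float | None = None
    phase: str = "repolarization"
    delta_v: float = 10.0
    duration: float = 5.0
    delay: float = 5.0

    def __post_init__(self) -> None:
        if (self.onset_time is None) == (self.onset_voltage is None):
            raise ValueError("specify exactly one of onset_time / onset_voltage")
        if self.phase not in ("upstroke", "plateau", "repolarization"):
            raise ValueError(f"unknown phase {self.phase!r}")
        if not (0 < self.delay <= self.duration):
            raise ValueError("require duration >= delay > 0")


@dataclass
class RmMeasurement:
    """Result of one paired-clamp R_m measurement."""

    clamp_time: float        # ms (absolute)
    v_ref: float             # membrane voltage at clamp onset (mV)
    i_plus: float            # I_m at the delay in the +delta branch (pA/pF)
    i_minus: float           # I_m at the delay in the -delta branch (pA/pF)
    r_m: float               # mV/(pA/pF)
    delay: float             # ms
    delta_v: float = 10.0


@dataclass
class PaceResult:
    """Final paced beat plus the saved state at its onset (for clamp reuse)."""

    trace: APTrace           # final-beat (or final-window) trace, absolute times
    pre_state: np.ndarray    # full model state at t_beat
    t_beat: float            # onset time of the final beat (ms)
    stim_times: np.ndarray
    stim_amp: float
    stim_dur: float
    states: np.ndarray | None = None   # optional (n_samples, n_state) record


def pace(model: ModelInterface, p: ParameterVector, duration: float = 4000.0,
         cycle_length: float = 1000.0, stim_amp: float = -52.0,
         stim_dur: float = 1.0, sample_dt: float = 1.0,
         keep_states: bool = False, require_ap: bool = True) -> PaceResult:
    """Pace from the model's initial state and return the final beat.

    Stimuli are delivered at t = 0, CL, 2 CL, ... ; the final beat is the
    window [K*CL, duration] with K the last stimulated cycle.  The state at
    the final beat's onset is saved so clamp branches can be launched from it.
    """
    if duration < cycle_length:
        raise ValueError("duration must cover at least one cycle length")
    n_beats = int(np.ceil(duration / cycle_length - 1e-9))
    stim_times = cycle_length * np.arange(n_beats)
    t_beat = stim_times[-1]

    y = model.initial_state()
    y = model.integrate(y, p, 0.0, t_beat, stim_times, stim_amp, stim_dur)
    pre_state = y.copy()
    times, states = model.record(y, p, t_beat, duration, stim_times,
                                 stim_amp, stim_dur, sample_dt=sample_dt)
    trace = APTrace(times, states[:, 0], stim_times)
    if require_ap and trace.voltages.max() < 0.0:
        raise SubthresholdStimulusError(
            f"no AP elicited: peak V_m = {trace.voltages.max():.1f} mV < 0 mV"
        )
    return PaceResult(trace, pre_state, t_beat, stim_times, stim_amp, stim_dur,
                      states if keep_states else None)


def quiescent_baseline(model: ModelInterface, p: ParameterVector,
                       duration: float = 100.0, sample_dt: float = 1.0) -> PaceResult:
    """Unstimulated hold at the model's initial state (oracle/testing aid)."""
    y = model.initial_state()
    times, states = model.record(y, p, 0.0, duration, np.array([]), 0.0, 1.0,
                                 sample_dt=sample_dt)
    trace = APTrace(times, states[:, 0], np.array([]))
    return PaceResult(trace, model.initial_state(), 0.0, np.array([]), 0.0, 1.0)


def apd90(trace: APTrace) -> float:
    """Action potential duration to 90% repolarization.

    Measured from the instant of maximum dV/dt to the first subsequent
    interpolated crossing of V_90 = peak - 0.9 * (peak - rest), where rest is
    the voltage at the start of the trace.
    """
    v = trace.voltages
    t = trace.times
    dv = np.gradient(v, t)
    i_up = int(np.argmax(dv))
    if dv[i_up] <= 0 or v.max() - v[0] < 10.0:
        raise NoRepolarizationError("no identifiable upstroke in trace")
    i_peak = i_up + int(np.argmax(v[i_up:]))
    v_rest = v[0]
    v90 = v[i_peak] - 0.9 * (v[i_peak] - v_rest)
    below = np.where(v[i_peak:] <= v90)[0]
    if len(below) == 0:
        raise NoRepolarizationError(
            f"trace never repolarizes to the 90% level ({v90:.1f} mV)")
    k = i_peak + below[0]
    if k == i_peak:
        t90 = t[k]
    else:
        # linear interpolation between the bracketing samples
        f = (v[k - 1] - v90) / (v[k - 1] - v[k])
        t90 = t[k - 1] + f * (t[k] - t[k - 1])
    return float(t90 - t[i_up])


def rm_slope(v_plus: float, i_plus: float, v_minus: float, i_minus: float,
             *, sentinel: float | None = None) -> float:
    """Slope of the two-point V-I relation, mV/(pA/pF).

    Identical currents mean an (unresolvable) infinite resistance: raises
    :class:`InfiniteResistanceError` unless a ``sentinel`` value is supplied.
    """
    if v_plus == v_minus:
        raise ValueError("clamp voltages must differ")
    di = i_plus - i_minus
    if di == 0.0:
        if sentinel is not None:
            return sentinel
        raise InfiniteResistanceError(
            "identical branch currents; pass sentinel=... to map this to a value")
    return (v_plus - v_minus) / di


def _resolve_onset(trace: APTrace, clamp: ClampSpec) -> float:
    """Map a ClampSpec onto an absolute onset time on the baseline trace."""
    if clamp.onset_time is not None:
        if not (trace.times[0] <= clamp.onset_time <= trace.times[-1]):
            raise ValueError(
                f"onset {clamp.onset_time} ms outside trace window "
                f"[{trace.times[0]}, {trace.times[-1]}]")
        return float(clamp.onset_time)

    v = trace.voltages
    t = trace.times
    vt = clamp.onset_voltage
    dv = np.gradient(v, t)
    i_up = int(np.argmax(dv))
    i_peak = i_up + int(np.argmax(v[i_up:]))
    if clamp.phase == "upstroke":
        seg = slice(i_up, i_peak + 1)
        idx = np.where((v[seg][:-1] < vt) & (v[seg][1:] >= vt))[0]
        if len(idx) == 0:
            raise NoCrossingError(
                f"{vt} mV never reached on the upstroke "
                f"(range {v[seg].min():.1f} to {v[seg].max():.1f} mV)")
        k = i_up + idx[0]
    else:
        idx = np.where((v[i_peak:-1] >= vt) & (v[i_peak + 1:] < vt))[0]
        if len(idx) == 0:
            raise NoCrossingError(
                f"{vt} mV never crossed downward after the peak "
                f"(post-peak range {v[i_peak:].min():.1f} to {v[i_peak:].max():.1f} mV)")
        k = i_peak + idx[-1]
    # interpolate the crossing instant between samples k and k+1
    f = (v[k] - vt) / (v[k] - v[k + 1])
    return float(t[k] + f * (t[k + 1] - t[k]))


def measure_rm(model: ModelInterface, p: ParameterVector, baseline: PaceResult,
               clamp: ClampSpec) -> RmMeasurement:
    """Run the paired +/-delta_v clamp from the saved baseline state.

    Both branches are launched from the *identical* state reached at clamp
    onset; during the clamp V_m is held fixed (the capacitive current
    vanishes) while every other state variable evolves, and I_m is the total
    ionic current at the measurement delay.
    """
    onset = _resolve_onset(baseline.trace, clamp)
    y_on = model.integrate(baseline.pre_state, p, baseline.t_beat, onset,
                           baseline.stim_times, baseline.stim_amp,
                           baseline.stim_dur)
    v_ref = float(y_on[0])
    i_branch = {}
    for sgn in (+1.0, -1.0):
        delays, cur, _ = model.clamp(y_on, p, clamp.duration,
                                     v_ref + sgn * clamp.delta_v,
                                     sample_dt=clamp.delay)
        k = int(round(clamp.delay / (delays[1] - delays[0])))
        i_branch[sgn] = float(cur[k])
    r = rm_slope(v_ref + clamp.delta_v, i_branch[+1.0],
                 v_ref - clamp.delta_v, i_branch[-1.0])
    return RmMeasurement(onset, v_ref, i_branch[+1.0], i_branch[-1.0], r,
                         clamp.delay, clamp.delta_v)


@dataclass
class DelaySensitivity:
    """Delay-sensitivity table for the R_m protocol (5 vs 10 ms by default)."""

    table: pd.DataFrame
    mean_percent_error: float
    mean_percent_error_excluding_first_two: float


def rm_delay_sensitivity(model: ModelInterface, p: ParameterVector,
                         baseline: PaceResult, clamps: Sequence[ClampSpec],
                         delays: tuple[float, float] = (5.0, 10.0)
                         ) -> DelaySensitivity:
    """R_m at two delays for each clamp, with per-row percent differences.

    Percent error is |R_m(d2) - R_m(d1)| / R_m(d1) * 100 with the shorter
    delay as the baseline column.
    """
    if len(clamps) == 0:
        raise ValueError("need at least one clamp")
    d1, d2 = delays
    rows = []
    for c in clamps:
        m1 = measure_rm(model, p, baseline, ClampSpec(
            onset_time=c.onset_time, onset_voltage=c.onset_voltage,
            phase=c.phase, delta_v=c.delta_v, duration=max(c.duration, d1),
            delay=d1))
        m2 = measure_rm(model, p, baseline, ClampSpec(
            onset_time=c.onset_time, onset_voltage=c.onset_voltage,
            phase=c.phase, delta_v=c.delta_v, duration=max(c.duration, d2),
            delay=d2))
        rows.append({
            "time_ms": m1.clamp_time,
            "voltage_mV": m1.v_ref,
            f"rm_{d1:g}ms": m1.r_m,
            f"rm_{d2:g}ms": m2.r_m,
            "percent_error": abs(m2.r_m - m1.r_m) / abs(m1.r_m) * 100.0,
        })
    df = pd.DataFrame(rows)
    pe = df["percent_error"].to_numpy()
    mean_all = float(pe.mean())
    mean_excl = float(pe[2:].mean()) if len(pe) > 2 else float("nan")
    return DelaySensitivity(df, mean_all, mean_excl)
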