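"""Ionic cell models: the TNNP 2004 epicardial human ventricular model and a
linear-leak membrane used as an analytic oracle.

Conventions
-----------
* state vector convention: index 0 is always the membrane voltage ``V_m`` (mV);
* currents are densities in pA/pF;
* membrane resistance is therefore reported in mV/(pA/pF), numerically equal
  to GOhm * pF (1 mV/(pA/pF) on a 100 pF cell is 10 MOhm).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Iterator, Mapping

import numpy as np
from scipy.integrate import solve_ivp

from . import _tnnp_core as _core

__all__ = [
    "ParameterVector",
    "ModelInterface",
    "TNNPModel",
    "LinearLeakModel",
    "linear_leak_model",
    "chord_conductance",
    "NonFiniteStateError",
    "DrivingForceError",
]


class NonFiniteStateError(ValueError):
    """A state variable became non-finite; the message names the variable."""


class DrivingForceError(ZeroDivisionError):
    """Chord conductance requested at (numerically) zero driving force."""


@dataclass(frozen=True)
class ParameterVector:
    """The 16 scalable TNNP parameters (published control values as defaults).

    Conductances ``g_*`` are nS/pF (``g_CaL`` keeps the model's published
    GHK-prefactor units), pump/exchanger turnover rates ``k_*`` are pA/pF,
    SR release/uptake/leak rates are mM/ms (``V_leak`` 1/ms).
    """

    g_Na: float = 14.838
    g_bNa: float = 0.00029
    g_CaL: float = 0.000175
    g_bCa: float = 0.000592
    g_to: float = 0.294
    g_Kr: float = 0.096
    g_Ks: float = 0.245
    g_K1: float = 5.405
    g_pK: float = 0.0146
    k_NaK: float = 1.362
    k_NaCa: float = 1000.0
    a_rel: float = 0.016464
    c_rel: float = 0.008232
    V_leak: float = 0.00008
    V_max_up: float = 0.000425
    k_pCa: float = 0.825

    names = _core.PARAM_NAMES

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(
                    f"parameter {f.name} must be strictly positive and finite, got {v!r}"
                )

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in self.names], dtype=float)

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "ParameterVector":
        if len(arr) != len(cls.names):
            raise ValueError(f"expected {len(cls.names)} parameters, got {len(arr)}")
        return cls(**{n: float(v) for n, v in zip(cls.names, arr)})

    @classmethod
    def control(cls) -> "ParameterVector":
        return cls()

    def replace(self, **kwargs: float) -> "ParameterVector":
        return replace(self, **kwargs)

    def with_subset(self, names: Iterator[str], values: np.ndarray) -> "ParameterVector":
        """Override a named subset of parameters (GA genome -> full vector)."""
        upd = dict(zip(names, map(float, values)))
        unknown = set(upd) - set(self.names)
        if unknown:
            raise KeyError(f"unknown parameter name(s): {sorted(unknown)}")
        return replace(self, **upd)

    def to_dict(self) -> dict[str, float]:
        return {n: getattr(self, n) for n in self.names}

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "ParameterVector":
        return cls(**dict(d))


def chord_conductance(i_x: float, v_m: float, e_x: float, *, eps: float = 1e-9) -> float:
    """Chord conductance i_x / (V_m - E_x) in nS/pF.

    Raises :class:`DrivingForceError` when the driving force V_m - E_x is
    within ``eps`` of zero.
    """
    df = v_m - e_x
    if abs(df) <= eps:
        raise DrivingForceError(
            f"driving force V_m - E_x = {df:g} mV is below eps={eps:g}"
        )
    return i_x / df


def _check_finite(y: np.ndarray, names) -> None:
    if not np.all(np.isfinite(y)):
        bad = [names[i] for i in np.where(~np.isfinite(np.asarray(y)))[0]]
        raise NonFiniteStateError(f"non-finite state variable(s): {', '.join(bad)}")


class ModelInterface:
    """Pluggable cell-model interface.

    Subclasses provide ``rhs``/``ionic_current``/``initial_state`` and may
    override the integration hooks with fast implementations.  The generic
    hooks integrate with LSODA (rtol 1e-6, atol 1e-8), which is adequate for
    small analytic models.
    """

    n_state: int
    state_names: tuple
    name: str = "model"

    def initial_state(self) -> np.ndarray:
        raise NotImplementedError

    def rhs(self, t: float, y: np.ndarray, p: ParameterVector, i_stim: float) -> np.ndarray:
        raise NotImplementedError

    def ionic_current(self, y: np.ndarray, p: ParameterVector) -> float:
        raise NotImplementedError

    # -- integration hooks ------------------------------------------------
    # All take/return raw state arrays; t in ms.  ``stim_times`` is an array
    # of stimulus onsets, each delivering ``stim_amp`` pA/pF for ``stim_dur`` ms.

    def integrate(self, y, p, t0, t1, stim_times, stim_amp, stim_dur, dt=0.02):
        y = np.array(y, dtype=float)
        self._solve_segments(y, p, t0, t1, stim_times, stim_amp, stim_dur)
        _check_finite(y, self.state_names)
        return y

    def record(self, y, p, t0, t1, stim_times, stim_amp, stim_dur,
               sample_dt=1.0, dt=0.02):
        """Integrate while recording the full state on a uniform grid.

        Returns ``(times, states)`` with ``states[k]`` the state at
        ``times[k]``; ``y`` is not modified.
        """
        y = np.array(y, dtype=float)
        times = t0 + sample_dt * np.arange(int(round((t1 - t0) / sample_dt)) + 1)
        states = np.empty((len(times), self.n_state))
        states[0] = y
        for k in range(1, len(times)):
            self._solve_segments(y, p, times[k - 1], times[k],
                                 stim_times, stim_amp, stim_dur)
            states[k] = y
        _check_finite(states[-1], self.state_names)
        return times, states

    def clamp(self, y, p, duration, v_clamp, sample_dt=1.0, dt=0.02):
        """Hold V_m at ``v_clamp``; return total ionic current on a grid.

        Returns ``(delays, currents, y_end)`` where ``delays`` starts at 0
        (instant after the voltage step).
        """
        y = np.array(y, dtype=float)
        y[0] = v_clamp
        delays = sample_dt * np.arange(int(round(duration / sample_dt)) + 1)
        cur = np.empty(len(delays))
        cur[0] = self.ionic_current(y, p)

        def f(t, yy):
            yy = yy.copy()
            yy[0] = v_clamp
            d = self.rhs(t, yy, p, 0.0)
            d[0] = 0.0
            return d

        for k in range(1, len(delays)):
            sol = solve_ivp(f, (delays[k - 1], delays[k]), y, method="LSODA",
                            rtol=1e-6, atol=1e-8)
            y = sol.y[:, -1]
            y[0] = v_clamp
            cur[k] = self.ionic_current(y, p)
        return delays, cur, y

    def _solve_segments(self, y, p, t0, t1, stim_times, stim_amp, stim_dur):
        """LSODA integration split at stimulus edges (in-place on ``y``)."""
        edges = [t0]
        for s in np.atleast_1d(stim_times):
            for e in (s, s + stim_dur):
                if t0 < e < t1:
                    edges.append(e)
        edges.append(t1)
        edges = sorted(set(edges))
        for a, b in zip(edges[:-1], edges[1:]):
            mid = 0.5 * (a + b)
            amp = 0.0
            for s in np.atleast_1d(stim_times):
                if s <= mid < s + stim_dur:
                    amp = stim_amp
            sol = solve_ivp(lambda t, yy: self.rhs(t, yy, p, amp), (a, b), y,
                            method="LSODA", rtol=1e-6, atol=1e-8)
            if not sol.success:
                raise RuntimeError(f"integration failed on [{a}, {b}]: {sol.message}")
            y[:] = sol.y[:, -1]


class TNNPModel(ModelInterface):
    """ten Tusscher-Noble-Noble-Panfilov (2004) epicardial ventricular cell.

    ``method`` selects the integrator used by the hooks: ``"rl"`` (default)
    is the jitted fixed-step Rush-Larsen/Euler scheme published with the
    model; ``"adaptive"`` is LSODA with rtol 1e-6 / atol 1e-8.
    """

    n_state = _core.N_STATE
    state_names = _core.STATE_NAMES
    current_names = _core.CURRENT_NAMES
    name = "tnnp2004-epi"

    def __init__(self, method: str = "rl", dt: float = 0.02):
        if method not in ("rl", "adaptive"):
            raise ValueError(f"unknown integration method {method!r}")
        self.method = method
        self.dt = float(dt)

    def initial_state(self) -> np.ndarray:
        return np.array(_core.INITIAL_STATE)

    @staticmethod
    def _p(p) -> np.ndarray:
        return p.as_array() if isinstance(p, ParameterVector) else np.asarray(p, float)

    def rhs(self, t, y, p, i_stim):
        y = np.asarray(y, dtype=float)
        _check_finite(y, self.state_names)
        return _core.rhs(t, y, self._p(p), i_stim)

    def ionic_current(self, y, p):
        return _core.total_current(np.asarray(y, dtype=float), self._p(p))

    def current_components(self, y, p) -> dict[str, float]:
        """Named individual membrane currents (pA/pF) at a frozen state."""
        vals = _core.currents(np.asarray(y, dtype=float), self._p(p))
        return dict(zip(self.current_names, vals))

    # -- fast hooks -------------------------------------------------------

    def integrate(self, y, p, t0, t1, stim_times, stim_amp, stim_dur, dt=None):
        if self.method == "adaptive":
            return super().integrate(y, p, t0, t1, stim_times, stim_amp, stim_dur)
        y = np.array(y, dtype=float)
        _core.integrate(y, self._p(p), t0, t1, dt or self.dt,
                        np.atleast_1d(np.asarray(stim_times, float)),
                        stim_amp, stim_dur)
        _check_finite(y, self.state_names)
        return y

    def record(self, y, p, t0, t1, stim_times, stim_amp, stim_dur,
               sample_dt=1.0, dt=None):
        if self.method == "adaptive":
            return super().record(y, p, t0, t1, stim_times, stim_amp, stim_dur,
                                  sample_dt=sample_dt)
        dt = dt or self.dt
        every = int(round(sample_dt / dt))
        if abs(every * dt - sample_dt) > 1e-9:
            raise ValueError(f"sample_dt={sample_dt} must be a multiple of dt={dt}")
        n = int(round((t1 - t0) / dt))
        out = np.empty((n // every + 1, self.n_state))
        y = np.array(y, dtype=float)
        _core.record(y, self._p(p), t0, t1, dt,
                     np.atleast_1d(np.asarray(stim_times, float)),
                     stim_amp, stim_dur, every, out)
        _check_finite(out[-1], self.state_names)
        times = t0 + sample_dt * np.arange(out.shape[0])
        return times, out

    def clamp(self, y, p, duration, v_clamp, sample_dt=1.0, dt=None):
        if self.method == "adaptive":
            return super().clamp(y, p, duration, v_clamp, sample_dt=sample_dt)
        dt = dt or self.dt
        every = int(round(sample_dt / dt))
        if abs(every * dt - sample_dt) > 1e-9:
            raise ValueError(f"sample_dt={sample_dt} must be a multiple of dt={dt}")
        n = int(round(duration / dt))
        out = np.empty(n // every + 1)
        y = np.array(y, dtype=float)
        _core.clamp(y, self._p(p), duration, dt, v_clamp, every, out)
        delays = sample_dt * np.arange(out.shape[0])
        return delays, out, y


class LinearLeakModel(ModelInterface):
    """Single-state ohmic membrane: I_m = g (V_m - E_rev).

    The measured membrane resistance of this model is exactly 1/g in
    mV/(pA/pF), independent of clamp onset, delay and step size — the
    analytic oracle for the R_m protocol.
    """

    n_state = 1
    state_names = ("V_m",)
    name = "linear-leak"

    def __init__(self, g: float, e_rev: float = -80.0):
        if not np.isfinite(g) or g <= 0:
            raise ValueError(f"leak conductance must be > 0, got {g!r}")
        self.g = float(g)
        self.e_rev = float(e_rev)

    def initial_state(self) -> np.ndarray:
        return np.array([self.e_rev])

    def rhs(self, t, y, p, i_stim):
        _check_finite(y, self.state_names)
        return np.array([-(self.g * (y[0] - self.e_rev) + i_stim)])

    def ionic_current(self, y, p):
        return self.g * (y[0] - self.e_rev)


def linear_leak_model(g: float, e_rev: float = -80.0) -> LinearLeakModel:
    """Factory mirroring the functional interface of the model registry."""
    return LinearLeakModel(g, e_rev)
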