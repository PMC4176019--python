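"""Packaged constants and the synthetic target-data generator.

The experimental rabbit recordings the method was originally exercised on
are unpublished, so this module generates *synthetic* target bundles from a
known parameterization of the ionic model: a target AP trace sampled at
1 kHz plus R_m at a handful of stated voltages, optionally corrupted with
multiplicative Gaussian noise.  Because the generating parameters are
recorded, recovery can be scored exactly.
"""

from __future__ import annotations

import json
from importlib import resources
from typing import Mapping, Sequence

import numpy as np

from .ionic_model import ModelInterface, ParameterVector, TNNPModel
from .moga import ParetoResult
from .objectives import EvalConfig, TargetDataset
from .protocols import APTrace

__all__ = [
    "search_bounds", "percent_change_sets", "apply_percent_changes",
    "invert_percent_changes", "published_parameter_sets", "generate_target",
    "recovery_score", "SELF_FIT_RM_VOLTAGES", "EXPERIMENT_LIKE_RM_VOLTAGES",
]

#: the three voltages at which R_m is matched in the model self-fit protocol
SELF_FIT_RM_VOLTAGES = (22.57, 8.084, -59.87)

#: voltage sets emulating the shape of the experimental bundles (4-5 points
#: spanning plateau to rest)
EXPERIMENT_LIKE_RM_VOLTAGES = {
    "set1": (24.0, -1.0, -23.0, -28.0, -81.0),
    "set2": (32.0, 28.0, -21.0, -78.0),
}


def _load_json(name: str) -> dict:
    with resources.files("cardiofit.data").joinpath(name).open() as fh:
        return json.load(fh)


def search_bounds() -> dict[str, tuple[float, float]]:
    """Physiological search ranges for the bounded (fittable) parameters."""
    raw = _load_json("search_bounds.json")["bounds"]
    return {k: (v["min"], v["max"]) for k, v in raw.items()}


def percent_change_sets() -> dict[str, dict[str, float]]:
    """The two published percent-change sets (signed %, per parameter)."""
    raw = _load_json("percent_change_sets.json")
    return {k: dict(v) for k, v in raw.items() if k != "comment"}


def apply_percent_changes(control: ParameterVector,
                          changes: Mapping[str, float]) -> ParameterVector:
    """p_new = p_control * (1 + change/100), per named parameter."""
    unknown = set(changes) - set(control.names)
    if unknown:
        raise KeyError(f"unknown parameter name(s): {sorted(unknown)}")
    return control.replace(**{
        n: getattr(control, n) * (1.0 + c / 100.0) for n, c in changes.items()
    })


def invert_percent_changes(changes: Mapping[str, float]) -> dict[str, float]:
    """The percent changes that undo ``changes`` exactly."""
    return {n: -c / (1.0 + c / 100.0) for n, c in changes.items()}


def published_parameter_sets() -> tuple[ParameterVector, ParameterVector]:
    """The two published parameter sets as absolute values."""
    control = ParameterVector.control()
    sets = percent_change_sets()
    return (apply_percent_changes(control, sets["set1"]),
            apply_percent_changes(control, sets["set2"]))


def generate_target(model: ModelInterface | None = None,
                    p_true: ParameterVector | None = None,
                    rm_voltages: Sequence[float] = SELF_FIT_RM_VOLTAGES,
                    noise: float = 0.0,
                    seed: int | None = None,
                    eval_config: EvalConfig | None = None) -> TargetDataset:
    """Simulate a target dataset from known parameters.

    The target trace is the final paced beat, window-relative and resampled
    at the evaluation grid; R_m targets come from the simulated clamp
    protocol at the requested voltages.  ``noise`` is the relative SD of
    multiplicative Gaussian noise applied per voltage sample and per R_m
    point.  The normalization constants (APA and base-model R_m) always come
    from the *control* parameterization.
    """
    config = eval_config or EvalConfig()
    if model is not None:
        config = EvalConfig(**{**config.__dict__, "model": model})
    p_true = p_true or ParameterVector.control()
    control = ParameterVector.control()

    base = config.run_pace(p_true)
    rm_true = config.run_rm(p_true, base, np.asarray(rm_voltages, float))
    if np.any(np.isnan(rm_true)):
        bad = np.asarray(rm_voltages)[np.isnan(rm_true)]
        raise ValueError(
            f"target R_m voltage(s) {bad.tolist()} unreachable; AP range is "
            f"[{base.trace.voltages.min():.1f}, {base.trace.voltages.max():.1f}] mV")

    if p_true.to_dict() == control.to_dict():
        ctrl_base, rm_base = base, rm_true.copy()
    else:
        ctrl_base = config.run_pace(control)
        rm_base = config.run_rm(control, ctrl_base, np.asarray(rm_voltages, float))
        if np.any(np.isnan(rm_base)):
            raise ValueError("base-model R_m unreachable at a target voltage")
    apa = float(ctrl_base.trace.voltages.max() - ctrl_base.trace.voltages.min())

    t_rel = base.trace.times - base.t_beat
    volts = base.trace.voltages.copy()
    rm_vals = rm_true.copy()
    if noise > 0.0:
        rng = np.random.default_rng(seed)
        volts = volts * (1.0 + noise * rng.standard_normal(volts.shape))
        rm_vals = rm_vals * (1.0 + noise * rng.standard_normal(rm_vals.shape))
    trace = APTrace(t_rel, volts, np.array([0.0]))
    return TargetDataset(
        trace, np.asarray(rm_voltages, float), rm_vals, apa, rm_base,
        p_true=p_true.to_dict(),
        meta={"seed": seed, "noise": noise, "model": config.model.name,
              "synthetic": True},
    )


def recovery_score(result: ParetoResult, p_true: ParameterVector) -> dict[str, float]:
    """Per-parameter relative error |p_fit - p_true| / p_true of the best fit."""
    names = result.config.fitted_parameters
    out = {}
    for name, v in zip(names, result.best.genome):
        truth = getattr(p_true, name)
        out[name] = abs(v - truth) / truth
    return out
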