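"""Summary statistics over simulation traces.

Learning curves, the empirical generalization function (test-phase
commands by tested direction), the normalized context-dependent decay
function (relearning commands at the trained direction, normalized by the
end-of-training command), retest divergence for the single-test-direction
design, and the signal-dependent-noise decomposition of the mean squared
error.
"""

from __future__ import annotations

import math
from collections import OrderedDict
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .engine import RunEnsemble, SimulationTrace

__all__ = [
    "learning_curve",
    "generalization_function",
    "decay_function",
    "retest_divergence",
    "noise_error_decomposition",
    "optimal_command",
]


def _traces(obj) -> list[SimulationTrace]:
    if isinstance(obj, RunEnsemble):
        if not obj.traces:
            raise ValueError("ensemble contains no traces")
        return obj.traces
    if isinstance(obj, SimulationTrace):
        return [obj]
    raise TypeError("expected a SimulationTrace or RunEnsemble")


def learning_curve(ensemble) -> pd.DataFrame:
    """Per-trial mean and SD of the movement error across runs."""
    traces = _traces(ensemble)
    values = np.array([[r.error for r in tr.records] for tr in traces])
    mean = values.mean(axis=0)
    sd = (values.std(axis=0, ddof=1) if len(traces) > 1
          else np.full(values.shape[1], np.nan))
    return pd.DataFrame({"trial": np.arange(values.shape[1]),
                         "mean": mean, "sd": sd})


def _per_cycle_values(
    trace: SimulationTrace, phase: str, n_average: int
) -> "OrderedDict[float, float]":
    """Mean executed command over the first n trials of ``phase`` per cycle,
    keyed by the cycle's tested direction."""
    by_cycle: dict[int, list] = {}
    test_dir: dict[int, float] = {}
    for r in trace.records:
        if r.cycle is None:
            continue
        if r.phase == "test":
            test_dir.setdefault(r.cycle, r.target_direction)
        if r.phase == phase:
            by_cycle.setdefault(r.cycle, []).append(r.executed_command)
    if not by_cycle or not test_dir:
        raise ValueError("protocol has no cycled test phases")
    out: "OrderedDict[float, float]" = OrderedDict()
    for cycle in sorted(by_cycle):
        direction = round(test_dir[cycle], 12)
        out[direction] = float(np.mean(by_cycle[cycle][:n_average]))
    return out


def _aggregate(per_run: list[Mapping[float, float]]) -> pd.DataFrame:
    directions = sorted(per_run[0])
    rows = []
    for d in directions:
        vals = np.array([m[d] for m in per_run])
        sd = vals.std(ddof=1) if len(vals) > 1 else np.nan
        rows.append({"direction": d, "mean": vals.mean(), "sd": sd})
    return pd.DataFrame(rows)


def generalization_function(obj, n_average: int = 10) -> pd.DataFrame:
    """Test-phase command by tested direction (the generalization curve).

    For every cycle of the cycled design, the executed commands of the
    first ``n_average`` error-clamp test trials are averaged (early trials
    only, so that within-block decay does not contaminate the curve).
    Returns one row per tested direction with ensemble mean and SD.
    """
    return _aggregate(
        [_per_cycle_values(tr, "test", n_average) for tr in _traces(obj)]
    )


def decay_function(obj, n_average: int = 10) -> pd.DataFrame:
    """Normalized relearning command by tested direction (decay curve).

    For each cycle, the executed commands at ``theta = 0`` over the first
    ``n_average`` relearning trials are averaged and divided by ``x0``,
    the executed command on the final training trial.  Values near 1 mean
    the memory survived the preceding test block; the dip at the trained
    direction is the signature of context-dependent decay.
    """
    per_run = []
    for tr in _traces(obj):
        x0 = None
        for r in tr.records:
            if r.phase == "training":
                x0 = r.executed_command
        if x0 is None:
            raise ValueError("protocol has no training phase")
        if x0 == 0:
            raise ValueError("degenerate normalization: end-of-training command is 0")
        vals = _per_cycle_values(tr, "relearning", n_average)
        per_run.append({d: v / x0 for d, v in vals.items()})
    return _aggregate(per_run)


def retest_divergence(traces, n_average: int = 10) -> dict[float, float]:
    """Mean retest command at ``theta = 0`` keyed by test-phase direction.

    ``traces`` is a mapping ``theta_test -> trace`` or an iterable of
    single-test-direction traces.  All traces must share model kind,
    parameters, basis seed and basis configuration, so that the retest
    values differ only through the direction tested in between.
    """
    if isinstance(traces, Mapping):
        trace_list = list(traces.values())
    else:
        trace_list = list(traces)
    if not trace_list:
        raise ValueError("no traces given")
    ref = trace_list[0]
    for tr in trace_list[1:]:
        if (tr.model_kind != ref.model_kind or tr.params != ref.params
                or repr(tr.basis_seed) != repr(ref.basis_seed)
                or tr.basis_config != ref.basis_config):
            raise ValueError(
                "traces must share model kind, parameters, basis seed and "
                "basis configuration"
            )
    out: dict[float, float] = {}
    for tr in trace_list:
        theta_test = None
        retest = []
        for r in tr.records:
            if r.phase == "test" and theta_test is None:
                theta_test = round(r.target_direction, 12)
            if r.phase == "retest":
                retest.append(r.executed_command)
        if theta_test is None or not retest:
            raise ValueError("trace lacks test or retest phases")
        out[theta_test] = float(np.mean(retest[:n_average]))
    return dict(sorted(out.items()))


def noise_error_decomposition(p: float, x: float, lambda2: float) -> dict[str, float]:
    """Mean-squared-error decomposition under signal-dependent noise.

    If the executed command is ``y = x + xi`` with noise variance
    ``lambda2 * x^2`` (SD proportional to the command itself), then

        <e^2> = (p - x)^2 + lambda2 * x^2,

    a constant (bias) error plus a variable error.  Minimizing this total
    over ``x`` is exactly what the effort-penalized learning rules do.
    """
    if not (math.isfinite(p) and math.isfinite(x)):
        raise ValueError("p and x must be finite")
    if not (math.isfinite(lambda2) and lambda2 >= 0):
        raise ValueError("lambda2 must be non-negative and finite")
    constant = (p - x) ** 2
    variable = lambda2 * x * x
    return {
        "constant_error": constant,
        "variable_error": variable,
        "mean_squared_error": constant + variable,
    }


def optimal_command(p: float, lambda2: float) -> float:
    """Minimizer of ``(p - x)^2 + lambda2 x^2`` over ``x``.

    Completing the square gives ``x* = p / (1 + lambda2)`` -- identical to
    the training asymptote of the effort-penalized learners, linking
    effort minimization to mean-squared-error minimization under
    signal-dependent noise.
    """
    if not (math.isfinite(lambda2) and lambda2 >= 0):
        raise ValueError("lambda2 must be non-negative and finite")
    return p / (1.0 + lambda2)
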