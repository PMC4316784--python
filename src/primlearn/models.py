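"""Trial-by-trial learning rules for motor adaptation.

Three model families share one master update.  Writing the per-trial cost
as

    E_t = e_t^2 / 2  +  (lambda1 / 2) sum_i W_i^2  +  (lambda2 / 2) x_t^2,

gradient descent on the primitive weights gives

    W_i' = (1 - eta*lambda1) W_i - eta*lambda2 x(theta_t) A_i(theta_t)
           + eta e_t A_i(theta_t).

The ``lambda1`` term is *weight decay*: every weight shrinks each trial,
regardless of which primitives were recruited, so memory loss is
context independent.  The ``lambda2`` term is *effort minimization*: the
decay of each weight is gated by its recruitment ``A_i(theta_t)``, so
memory embedded in primitives that are not recruited on a trial is fully
retained -- the origin of context-dependent decay.  The state-space model
drops the basis entirely and applies the same error-plus-effort tradeoff
to a scalar command.

Multiplying the weight update by ``A_i(theta)`` and summing over *i*
turns it into a recursion purely in command space,

    x'(theta) = (1 - eta*lambda1) x(theta)
                - eta*lambda2 G(theta_t, theta) x(theta_t)
                + eta e_t G(theta_t, theta),

which this module also provides (:func:`recursive_command_update`) as an
analytic cross-check of the weight-space simulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .basis import PrimitiveBasis, activities, generalization_empirical

__all__ = [
    "LearnerParams",
    "WEIGHT_DECAY_PRIMITIVE",
    "EFFORT_PRIMITIVE",
    "STATE_SPACE_EFFORT",
    "MODEL_KINDS",
    "default_params",
    "motor_command",
    "update_weights",
    "update_state_space",
    "recursive_command_update",
    "fixed_point_command",
]

WEIGHT_DECAY_PRIMITIVE = "weight_decay_primitive"
EFFORT_PRIMITIVE = "effort_primitive"
STATE_SPACE_EFFORT = "state_space_effort"
MODEL_KINDS = (WEIGHT_DECAY_PRIMITIVE, EFFORT_PRIMITIVE, STATE_SPACE_EFFORT)


@dataclass(frozen=True)
class LearnerParams:
    """Learning rate and regularization strengths.

    Attributes
    ----------
    eta : float
        Learning rate (> 0).  For primitive models this is the
        population-level rate; the engine applies ``eta / N`` per
        primitive so the command-level dynamics are independent of the
        population size.
    lambda1 : float
        Weight-decay regularizer (>= 0); context-independent forgetting.
    lambda2 : float
        Effort regularizer (>= 0); context-dependent forgetting.
    """

    eta: float
    lambda1: float = 0.0
    lambda2: float = 0.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.eta) and self.eta > 0):
            raise ValueError("eta must be positive and finite")
        if not (math.isfinite(self.lambda1) and self.lambda1 >= 0):
            raise ValueError("lambda1 must be non-negative and finite")
        if not (math.isfinite(self.lambda2) and self.lambda2 >= 0):
            raise ValueError("lambda2 must be non-negative and finite")


def default_params(model_kind: str) -> LearnerParams:
    """Reference parameters for each model family.

    Primitive models use eta = 0.5 with per-trial forgetting products
    eta*lambda1 = 0.0015 (weight decay) or eta*lambda2 = 0.03 (effort);
    the state-space model uses eta = 0.04 with eta*lambda2 = 0.0015.
    """
    if model_kind == WEIGHT_DECAY_PRIMITIVE:
        return LearnerParams(eta=0.5, lambda1=0.0015 / 0.5, lambda2=0.0)
    if model_kind == EFFORT_PRIMITIVE:
        return LearnerParams(eta=0.5, lambda1=0.0, lambda2=0.03 / 0.5)
    if model_kind == STATE_SPACE_EFFORT:
        return LearnerParams(eta=0.04, lambda1=0.0, lambda2=0.0015 / 0.04)
    raise ValueError(f"unknown model kind: {model_kind!r}")


def motor_command(weights, basis: PrimitiveBasis, theta: float) -> float:
    """Read out the command ``x(theta) = sum_i W_i A_i(theta)``."""
    w = np.asarray(weights, dtype=float)
    if w.shape != (basis.n_primitives,):
        raise ValueError(
            f"weight vector of length {w.size} does not match "
            f"basis of {basis.n_primitives} primitives"
        )
    return float(w @ activities(basis, theta))


def _gradient_step(w, a, x, error, params: LearnerParams) -> np.ndarray:
    # Shared by update_weights and the engine (which caches activities).
    return (
        (1.0 - params.eta * params.lambda1) * w
        - (params.eta * params.lambda2 * x) * a
        + (params.eta * error) * a
    )


def update_weights(
    weights, basis: PrimitiveBasis, theta_t: float, error: float,
    params: LearnerParams,
) -> np.ndarray:
    """One gradient-descent step on the primitive weights.

    The command ``x(theta_t)`` entering the effort term is computed from
    the *current* weights, matching the within-trial order: recruit,
    generate command, observe error, update.  In an error-clamp trial the
    caller passes ``error = 0`` and the decay/effort terms still apply.
    """
    if not math.isfinite(error):
        raise ValueError("error must be finite")
    w = np.asarray(weights, dtype=float)
    if w.shape != (basis.n_primitives,):
        raise ValueError("weight vector does not match basis size")
    a = activities(basis, theta_t)
    x = float(w @ a)
    return _gradient_step(w, a, x, error, params)


def update_state_space(command: float, error: float, params: LearnerParams) -> float:
    """State-space update ``x' = (1 - eta*lambda2) x + eta e``."""
    if not (math.isfinite(command) and math.isfinite(error)):
        raise ValueError("command and error must be finite")
    return (1.0 - params.eta * params.lambda2) * command + params.eta * error


def recursive_command_update(
    commands_by_angle: Mapping[float, float],
    basis: PrimitiveBasis,
    theta_t: float,
    error: float,
    params: LearnerParams,
) -> dict[float, float]:
    """Advance probed commands one trial purely in command space.

    ``commands_by_angle`` must contain an entry for ``theta_t`` (the
    direction actually trained this trial).  Every probed command evolves
    as

        x'(theta) = (1 - eta*lambda1) x(theta)
                    - eta*lambda2 G(theta_t, theta) x(theta_t)
                    + eta e G(theta_t, theta).

    This recursion is algebraically equivalent to the weight-space update
    and serves as its independent oracle.
    """
    if not math.isfinite(error):
        raise ValueError("error must be finite")
    if theta_t not in commands_by_angle:
        raise ValueError(
            "commands_by_angle must contain an entry for theta_t"
        )
    x_t = commands_by_angle[theta_t]
    keep = 1.0 - params.eta * params.lambda1
    out: dict[float, float] = {}
    for theta, x in commands_by_angle.items():
        g = generalization_empirical(basis, theta_t, theta)
        out[theta] = keep * x - (params.eta * params.lambda2 * x_t) * g \
            + (params.eta * error) * g
    return out


def fixed_point_command(
    p: float,
    params: LearnerParams,
    basis: PrimitiveBasis | None,
    theta_t: float,
    model_kind: str,
) -> float:
    """Training-phase asymptote of ``x(theta_t)`` under a constant perturbation.

    Setting the per-trial increment to zero gives ``x* = p / (1 + lambda2)``
    for both effort models (the effort penalty trades off against the
    residual error ``e* = lambda2 x*``), and
    ``x* = p G / (lambda1 + G)`` with ``G = G(theta_t, theta_t)`` for the
    weight-decay model trained at a single constant direction.
    """
    if model_kind in (EFFORT_PRIMITIVE, STATE_SPACE_EFFORT):
        return p / (1.0 + params.lambda2)
    if model_kind == WEIGHT_DECAY_PRIMITIVE:
        if basis is None:
            raise ValueError("weight-decay fixed point requires a basis")
        g = generalization_empirical(basis, theta_t, theta_t)
        return p * g / (params.lambda1 + g)
    raise ValueError(f"unknown model kind: {model_kind!r}")
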