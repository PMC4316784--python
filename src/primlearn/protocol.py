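"""Deterministic trial schedules for the simulated experiments.

Two canonical designs are provided, plus a loader for user-defined
schedules given as YAML/JSON.

Simulation 1 (single test direction): 100 training trials at ``theta = 0``
under a constant perturbation ``p``, then 100 error-clamp test trials at a
chosen direction ``theta_test``, then 50 error-clamp retest trials back at
``theta = 0``.  Comparing retest commands across choices of ``theta_test``
reveals whether memory decay during the test block depended on the tested
direction.

Simulation 2 (full generalization/decay curves): 200 training trials at
``theta = 0``, followed by K cycles, each consisting of 20 error-clamp
test trials at ``theta'_k = -pi + 2 pi k / K`` and 100 relearning trials
at ``theta = 0``.  The integers k form a seeded random permutation of
``{0, ..., K-1}`` so that every direction on the grid is tested exactly
once.
"""

from __future__ import annotations

import json
import math
import os
import re
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "PHASES",
    "TrialSpec",
    "Protocol",
    "parse_angle",
    "build_simulation1",
    "build_simulation2",
    "load_protocol",
    "ProtocolConfigError",
]

PHASES = ("training", "test", "retest", "relearning")

_PI_RE = re.compile(
    r"^\s*([+-]?)\s*(\d+(?:\.\d*)?)?\s*\*?\s*pi\s*(?:/\s*(\d+(?:\.\d*)?))?\s*$",
    re.IGNORECASE,
)


def parse_angle(value) -> float:
    """Parse an angle given in radians or as a fraction of pi.

    Accepts plain numbers (``0.5``, ``-1.2``) and symbolic forms such as
    ``"pi/4"``, ``"-pi/12"``, ``"2pi/3"`` or ``"0.5pi"``, evaluated
    exactly as multiples of ``math.pi``.
    """
    if isinstance(value, (int, float)):
        return float(value)
    text = str(value)
    m = _PI_RE.match(text)
    if m is not None:
        sign = -1.0 if m.group(1) == "-" else 1.0
        coef = float(m.group(2)) if m.group(2) else 1.0
        denom = float(m.group(3)) if m.group(3) else 1.0
        return sign * coef * math.pi / denom
    try:
        return float(text)
    except ValueError:
        raise ValueError(f"cannot parse angle: {value!r}") from None


class ProtocolConfigError(ValueError):
    """A protocol configuration file failed validation."""


@dataclass(frozen=True)
class TrialSpec:
    """One scheduled trial.

    ``error_clamp`` marks trials in which the movement error is forcibly
    recorded as zero, isolating forgetting from adaptation; the learner's
    decay terms still apply on such trials.
    """

    index: int
    target_direction: float
    perturbation: float
    error_clamp: bool
    phase: str
    cycle: int | None = None

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ValueError(
                f"phase must be one of {PHASES}, got {self.phase!r}"
            )
        if not math.isfinite(self.target_direction):
            raise ValueError("target_direction must be finite")
        if not math.isfinite(self.perturbation):
            raise ValueError("perturbation must be finite")


@dataclass(frozen=True)
class Protocol:
    """An ordered, validated sequence of trials."""

    name: str
    trials: tuple[TrialSpec, ...]

    def __post_init__(self) -> None:
        if len(self.trials) == 0:
            raise ValueError("protocol must contain at least one trial")
        for i, t in enumerate(self.trials):
            if t.index != i:
                raise ValueError(
                    f"trial indices must be consecutive from 0; "
                    f"position {i} has index {t.index}"
                )
        object.__setattr__(self, "trials", tuple(self.trials))

    def __len__(self) -> int:
        return len(self.trials)


def build_simulation1(theta_test: float, p: float) -> Protocol:
    """Single-test-direction design: 100 train + 100 test + 50 retest."""
    trials = []
    i = 0
    for _ in range(100):
        trials.append(TrialSpec(i, 0.0, p, False, "training"))
        i += 1
    for _ in range(100):
        trials.append(TrialSpec(i, float(theta_test), p, True, "test"))
        i += 1
    for _ in range(50):
        trials.append(TrialSpec(i, 0.0, p, True, "retest"))
        i += 1
    return Protocol(name="simulation1", trials=tuple(trials))


def build_simulation2(K: int, p: float, seed) -> Protocol:
    """Cycled design: 200 train, then K x (20 clamp test + 100 relearn).

    The tested directions ``-pi + 2 pi k / K`` are visited in a seeded
    random order, each exactly once.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    rng = np.random.default_rng(seed)
    ks = rng.permutation(K)
    trials = []
    i = 0
    for _ in range(200):
        trials.append(TrialSpec(i, 0.0, p, False, "training"))
        i += 1
    for cycle, k in enumerate(ks):
        theta_prime = -math.pi + 2.0 * math.pi * int(k) / K
        for _ in range(20):
            trials.append(TrialSpec(i, theta_prime, p, True, "test", cycle))
            i += 1
        for _ in range(100):
            trials.append(TrialSpec(i, 0.0, p, False, "relearning", cycle))
            i += 1
    return Protocol(name="simulation2", trials=tuple(trials))


def load_protocol(config) -> Protocol:
    """Assemble a protocol from a configuration document.

    ``config`` may be a dict, a YAML/JSON string, or a path to a file.
    Expected structure::

        name: my-design
        phases:
          - {label: training, n_trials: 100, theta: 0, p: "pi/6", clamp: false}
          - {label: test, n_trials: 100, theta: "pi/6", p: "pi/6", clamp: true}

    Angles accept radians or fractions of pi.  An optional ``cycle``
    field per phase carries a cycle index.
    """
    if isinstance(config, dict):
        doc = config
    else:
        text = None
        if isinstance(config, (str, os.PathLike)) and os.path.exists(str(config)):
            with open(config, "r", encoding="utf-8") as fh:
                text = fh.read()
        else:
            text = str(config)
        try:
            doc = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise ProtocolConfigError(f"cannot parse protocol config: {exc}")
    if not isinstance(doc, dict):
        raise ProtocolConfigError("protocol config must be a mapping")
    phases = doc.get("phases")
    if not phases:
        raise ProtocolConfigError("protocol config must declare a non-empty 'phases' list")
    trials = []
    i = 0
    for pos, phase in enumerate(phases):
        if not isinstance(phase, dict):
            raise ProtocolConfigError(f"phases[{pos}] must be a mapping")
        label = phase.get("label")
        if label not in PHASES:
            raise ProtocolConfigError(
                f"phases[{pos}].label must be one of {PHASES}, got {label!r}"
            )
        try:
            n_trials = int(phase["n_trials"])
        except (KeyError, TypeError, ValueError):
            raise ProtocolConfigError(f"phases[{pos}].n_trials must be a positive integer")
        if n_trials < 1:
            raise ProtocolConfigError(f"phases[{pos}].n_trials must be >= 1")
        try:
            theta = parse_angle(phase.get("theta", 0.0))
            p = parse_angle(phase.get("p", 0.0))
        except ValueError as exc:
            raise ProtocolConfigError(f"phases[{pos}]: {exc}")
        clamp = bool(phase.get("clamp", False))
        cycle = phase.get("cycle")
        cycle = int(cycle) if cycle is not None else None
        for _ in range(n_trials):
            trials.append(TrialSpec(i, theta, p, clamp, label, cycle))
            i += 1
    return Protocol(name=str(doc.get("name", "custom")), trials=tuple(trials))
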