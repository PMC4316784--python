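"""Gaussian motor-primitive basis and direction generalization.

A reaching direction ``theta`` on the circle recruits a population of N
motor primitives.  Primitive *i* responds with a Gaussian tuning curve

    A_i(theta) = exp(-||theta - phi_i||^2 / (2 sigma^2)),

centred on its preferred direction (PD) ``phi_i``, where ``||.||`` is the
wrapped (periodic) angular distance.  The overlap of two recruitment
patterns,

    G(theta_t, theta) = sum_i A_i(theta_t) A_i(theta),

is the generalization function: it measures how much learning acquired
while reaching toward ``theta_t`` transfers to reaches toward ``theta``.
For PDs drawn uniformly on the circle and narrow tuning, ``G/N``
approaches a Gaussian in the wrapped direction difference (see
:func:`generalization_closed_form`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PrimitiveBasis",
    "wrap_angle",
    "sample_basis",
    "activities",
    "generalization_empirical",
    "generalization_closed_form",
]

_TWO_PI = 2.0 * math.pi


def wrap_angle(theta):
    """Wrap an angle (radians) onto the half-open interval ``[-pi, pi)``.

    All angular differences that enter a tuning curve are reduced modulo
    2*pi, so tuning and generalization are periodic in direction.  The
    boundary follows the half-open convention: ``wrap_angle(pi) == -pi``.

    Parameters
    ----------
    theta : float or array_like
        Angle(s) in radians.  Must be finite.

    Returns
    -------
    float or ndarray
        The wrapped angle(s), congruent to ``theta`` mod 2*pi.
    """
    arr = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("angle must be finite")
    wrapped = np.mod(arr + np.pi, _TWO_PI) - np.pi
    # np.mod can round up to the modulus itself for arguments a hair below
    # zero; fold that edge back so the result stays inside [-pi, pi).
    wrapped = np.where(wrapped >= np.pi, wrapped - _TWO_PI, wrapped)
    if arr.ndim == 0:
        return float(wrapped)
    return wrapped


@dataclass(frozen=True)
class PrimitiveBasis:
    """A population of Gaussian direction-tuned motor primitives.

    Attributes
    ----------
    n_primitives : int
        Population size N (>= 1).
    sigma : float
        Angular tuning width in radians (> 0), shared by all primitives.
    preferred_directions : ndarray
        The N preferred directions ``phi_i``, each in ``[-pi, pi)``.
    """

    n_primitives: int
    sigma: float
    preferred_directions: np.ndarray

    def __post_init__(self) -> None:
        if self.n_primitives < 1:
            raise ValueError("n_primitives must be >= 1")
        if not (math.isfinite(self.sigma) and self.sigma > 0):
            raise ValueError("sigma must be positive and finite")
        pds = np.asarray(self.preferred_directions, dtype=float)
        if pds.shape != (self.n_primitives,):
            raise ValueError(
                f"expected {self.n_primitives} preferred directions, "
                f"got shape {pds.shape}"
            )
        if not np.all(np.isfinite(pds)):
            raise ValueError("preferred directions must be finite")
        if np.any(pds < -np.pi) or np.any(pds >= np.pi):
            raise ValueError("preferred directions must lie in [-pi, pi)")
        pds.setflags(write=False)
        object.__setattr__(self, "preferred_directions", pds)


def sample_basis(n_primitives: int, sigma: float, seed) -> PrimitiveBasis:
    """Draw a basis with PDs i.i.d. uniform on ``[-pi, pi)``.

    ``seed`` may be anything accepted by :func:`numpy.random.default_rng`
    (an int, a ``SeedSequence``, ...).  The same seed always reproduces
    bitwise-identical preferred directions.
    """
    if n_primitives < 1:
        raise ValueError("n_primitives must be >= 1")
    if not (math.isfinite(sigma) and sigma > 0):
        raise ValueError("sigma must be positive and finite")
    rng = np.random.default_rng(seed)
    pds = rng.uniform(-np.pi, np.pi, size=n_primitives)
    return PrimitiveBasis(n_primitives, float(sigma), pds)


def activities(basis: PrimitiveBasis, theta: float) -> np.ndarray:
    """Recruitment pattern ``A_i(theta)`` of every primitive at ``theta``.

    Each activity is ``exp(-d_i^2 / (2 sigma^2))`` with ``d_i`` the wrapped
    difference between ``theta`` and the primitive's PD, so values lie in
    ``(0, 1]`` and equal 1 exactly at the PD.
    """
    diffs = wrap_angle(theta - basis.preferred_directions)
    return np.exp(-(diffs * diffs) / (2.0 * basis.sigma**2))


def generalization_empirical(
    basis: PrimitiveBasis, theta_train: float, theta_test: float
) -> float:
    """Inner product of the recruitment patterns at two directions.

    ``G(theta_train, theta_test) = sum_i A_i(theta_train) A_i(theta_test)``.
    Symmetric in its two angle arguments.
    """
    return float(
        activities(basis, theta_train) @ activities(basis, theta_test)
    )


def generalization_closed_form(sigma: float, delta_theta: float) -> float:
    """Large-N limit of ``G/N`` for uniformly distributed PDs.

    For PDs uniform on the circle, the expectation of
    ``A(theta_t) A(theta)`` over one primitive is

        (1 / 2 pi) * Integral  exp(-(||theta_t - phi||^2
                                     + ||theta - phi||^2) / (2 sigma^2)) dphi.

    In the narrow-tuning regime (sigma well below pi) the wrapped distances
    can be replaced by plain differences and the Gaussian integral gives

        (sigma / (2 sqrt(pi))) * exp(-d^2 / (4 sigma^2)),

    with ``d`` the wrapped difference ``theta_t - theta``.  The function is
    maximal at ``d = 0``, even in ``d``, and depends only on ``sigma``.
    Corrections from the periodic boundary are of order
    ``exp(-pi^2 / (2 sigma^2))`` and negligible for ``sigma <= pi/4``.
    """
    if not (math.isfinite(sigma) and sigma > 0):
        raise ValueError("sigma must be positive and finite")
    d = wrap_angle(delta_theta)
    return float(
        sigma / (2.0 * math.sqrt(math.pi)) * math.exp(-(d * d) / (4.0 * sigma**2))
    )
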