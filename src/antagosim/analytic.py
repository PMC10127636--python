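"""Closed-form results used as oracles for the stochastic machinery.

Covers half-normal moments, the coefficient of variation of a sum of m
independent half-normal effects, and the equilibrium of a symmetric
competitive community.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from antagosim.model import InvalidParameterError


class NoStableCoexistenceError(ValueError):
    """The symmetric community has no positive coexistence equilibrium."""


@dataclass(frozen=True)
class HalfNormalMoments:
    """Mean and variance of |Normal(0, scale^2)|."""

    scale: float
    mean: float
    variance: float


def half_normal_moments(sigma: float) -> HalfNormalMoments:
    """Closed-form moments of the half-normal with scale ``sigma``.

    mean = sigma * sqrt(2/pi), variance = sigma^2 * (1 - 2/pi).
    """
    if not sigma > 0:
        raise InvalidParameterError(f"sigma must be > 0, got {sigma}")
    mean = sigma * math.sqrt(2.0 / math.pi)
    variance = sigma * sigma * (1.0 - 2.0 / math.pi)
    return HalfNormalMoments(scale=sigma, mean=mean, variance=variance)


def cv_combined_effect(sigma: float, m: int) -> float:
    """Coefficient of variation of the summed effect of m antagonists.

    For beta = sum of m i.i.d. half-normal(sigma) impacts, E(beta) =
    E(theta) * m and Var(beta) = Var(theta) * m, so

        CV(beta) = sqrt(Var(theta) * m) / (E(theta) * m)

    which for the half-normal simplifies to sqrt(pi/2 - 1) / sqrt(m),
    independent of sigma and strictly decreasing in m.
    """
    if int(m) != m or m < 1:
        raise InvalidParameterError(f"m must be an integer >= 1, got {m}")
    mom = half_normal_moments(sigma)
    return math.sqrt(mom.variance * m) / (mom.mean * m)


def symmetric_equilibrium(n: int, a: float) -> float:
    """Per-species equilibrium density of a symmetric competitive community.

    For the n x n interaction matrix with diagonal 1 and all off-diagonals
    ``a`` (0 <= a < 1), every species settles at ``1 / (1 + (n - 1) * a)``.
    """
    if int(n) != n or n < 1:
        raise InvalidParameterError(f"n must be an integer >= 1, got {n}")
    if a < 0:
        raise InvalidParameterError(f"a must be >= 0, got {a}")
    if n >= 2 and a >= 1:
        raise NoStableCoexistenceError(
            f"no stable coexistence for n={n} with off-diagonal a={a} >= 1"
        )
    return 1.0 / (1.0 + (n - 1) * a)
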