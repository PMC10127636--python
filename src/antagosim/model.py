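"""Community assembly: random interaction matrices, growth rates, and the ODE right-hand side.

A community consists of ``n`` focal species (indices ``0..n-1``) and ``m``
antagonists (indices ``n..n+m-1``).  The interaction matrix ``alpha`` is read
row-wise: ``alpha[i, j]`` scales the effect of species ``j``'s density on
species ``i``'s logistic growth bracket, so the per-capita growth of species
``i`` is ``r[i] * (1 - sum_j alpha[i, j] * x[j])``.

Block structure of ``alpha`` (N = n + m):

* focal x focal     — diagonal 1, off-diagonals ~ Uniform(0, A/n)
* focal x antag     — antagonist impacts ~ half-normal with scale sigma
* antag x focal     — 0 (antagonists are insensitive to focal densities)
* antag x antag     — 1 everywhere (diagonal included)

All growth rates are half-normal draws with scale 1, resampled away from
exact zero.  Draws happen in a fixed order (focal block, focal growth rates,
antagonist impacts, antagonist growth rates) from a single generator seeded
by ``CommunitySpec.seed``, so the focal part of a system depends only on
``(n, A, seed)`` and the ``m = 0`` reduction of any spec reproduces it
bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np


class InvalidParameterError(ValueError):
    """A model parameter violates its domain constraint."""


@dataclass(frozen=True)
class CommunitySpec:
    """Scalar parameters defining one random community draw.

    Attributes
    ----------
    n : int
        Number of focal species (>= 1).
    m : int
        Number of antagonists (>= 0).
    sigma : float
        Scale of the half-normal antagonist-impact distribution (> 0).
    A : float
        Focal interspecific interaction modifier; off-diagonal focal
        coefficients are Uniform(0, A/n) (> 0).
    seed : int
        Nonnegative seed making the draw reproducible.
    """

    n: int
    m: int
    sigma: float
    A: float
    seed: int = 0

    def __post_init__(self) -> None:
        if int(self.n) != self.n or self.n < 1:
            raise InvalidParameterError(f"n must be an integer >= 1, got {self.n}")
        if int(self.m) != self.m or self.m < 0:
            raise InvalidParameterError(f"m must be an integer >= 0, got {self.m}")
        if not self.sigma > 0:
            raise InvalidParameterError(f"sigma must be > 0, got {self.sigma}")
        if not self.A > 0:
            raise InvalidParameterError(f"A must be > 0, got {self.A}")
        if int(self.seed) != self.seed or self.seed < 0:
            raise InvalidParameterError(f"seed must be a nonnegative integer, got {self.seed}")

    def without_antagonists(self) -> "CommunitySpec":
        """The paired baseline spec: same focal parameters and seed, m = 0."""
        return replace(self, m=0)


@dataclass(frozen=True)
class AssembledSystem:
    """A realized interaction matrix and growth-rate vector.

    ``alpha`` is (N, N) with N = n_focal + m_antagonist; ``r`` has length N.
    Focal species occupy indices ``0..n_focal-1``.
    """

    alpha: np.ndarray
    r: np.ndarray
    n_focal: int
    m_antagonist: int = 0

    def __post_init__(self) -> None:
        alpha = np.asarray(self.alpha, dtype=float)
        r = np.asarray(self.r, dtype=float)
        object.__setattr__(self, "alpha", alpha)
        object.__setattr__(self, "r", r)
        N = self.n_focal + self.m_antagonist
        if alpha.shape != (N, N):
            raise InvalidParameterError(
                f"alpha must be {(N, N)} for n={self.n_focal}, m={self.m_antagonist}; "
                f"got {alpha.shape}"
            )
        if r.shape != (N,):
            raise InvalidParameterError(f"r must have length {N}, got shape {r.shape}")
        if not np.all(r > 0):
            raise InvalidParameterError("all growth rates must be strictly positive")

    @property
    def size(self) -> int:
        """Total number of species, N = n + m."""
        return self.n_focal + self.m_antagonist

    def focal_subsystem(self) -> "AssembledSystem":
        """Drop the antagonist rows/columns, keeping the focal draw intact."""
        n = self.n_focal
        return AssembledSystem(
            alpha=self.alpha[:n, :n].copy(),
            r=self.r[:n].copy(),
            n_focal=n,
            m_antagonist=0,
        )


def sample_focal_block(n: int, A: float, rng: np.random.Generator) -> np.ndarray:
    """Draw the n x n focal competition block.

    Diagonal entries are exactly 1; each off-diagonal entry is an independent
    Uniform(0, A/n) draw.
    """
    if int(n) != n or n < 1:
        raise InvalidParameterError(f"n must be an integer >= 1, got {n}")
    if not A > 0:
        raise InvalidParameterError(f"A must be > 0, got {A}")
    block = rng.uniform(0.0, A / n, size=(n, n))
    np.fill_diagonal(block, 1.0)
    return block


def sample_antagonist_impacts(
    n: int, m: int, sigma: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw the n x m block of antagonist impacts on focal species.

    Entries are independent half-normal draws with scale ``sigma``
    (|Normal(0, sigma^2)|).  ``m = 0`` yields an empty (n, 0) block.
    """
    if int(n) != n or n < 1:
        raise InvalidParameterError(f"n must be an integer >= 1, got {n}")
    if int(m) != m or m < 0:
        raise InvalidParameterError(f"m must be an integer >= 0, got {m}")
    if not sigma > 0:
        raise InvalidParameterError(f"sigma must be > 0, got {sigma}")
    if m == 0:
        return np.empty((n, 0), dtype=float)
    return np.abs(rng.normal(0.0, sigma, size=(n, m)))


def sample_growth_rates(N: int, rng: np.random.Generator) -> np.ndarray:
    """Draw N strictly positive growth rates, half-normal with scale 1.

    Exact-zero draws (possible in floating point, probability ~0) are
    resampled so the result is strictly positive.
    """
    if int(N) != N or N < 1:
        raise InvalidParameterError(f"N must be an integer >= 1, got {N}")
    r = np.abs(rng.normal(0.0, 1.0, size=N))
    while np.any(r == 0.0):  # pragma: no cover - measure-zero event
        zeros = r == 0.0
        r[zeros] = np.abs(rng.normal(0.0, 1.0, size=int(zeros.sum())))
    return r


def assemble_system(spec: CommunitySpec) -> AssembledSystem:
    """Realize the full (n+m) x (n+m) system from a spec.

    The draw order (focal block, focal growth rates, antagonist impacts,
    antagonist growth rates) guarantees that the focal block and focal growth
    rates depend only on ``(n, A, seed)``, so ``assemble_system(spec)`` and
    ``assemble_system(spec.without_antagonists())`` share an identical focal
    subsystem.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    n, m = spec.n, spec.m
    N = n + m

    focal = sample_focal_block(n, spec.A, rng)
    r = np.empty(N, dtype=float)
    r[:n] = sample_growth_rates(n, rng)

    alpha = np.empty((N, N), dtype=float)
    alpha[:n, :n] = focal
    if m > 0:
        alpha[:n, n:] = sample_antagonist_impacts(n, m, spec.sigma, rng)
        alpha[n:, :n] = 0.0
        alpha[n:, n:] = 1.0
        r[n:] = sample_growth_rates(m, rng)
    return AssembledSystem(alpha=alpha, r=r, n_focal=n, m_antagonist=m)


def lv_derivative(state: np.ndarray, system: AssembledSystem) -> np.ndarray:
    """Right-hand side of the competitive Lotka-Volterra dynamics.

    Returns ``r_i * x_i * (1 - sum_j alpha[i, j] * x_j)`` componentwise.
    """
    x = np.asarray(state, dtype=float)
    if x.shape != (system.size,):
        raise InvalidParameterError(
            f"state must have length {system.size}, got shape {x.shape}"
        )
    return system.r * x * (1.0 - system.alpha @ x)
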