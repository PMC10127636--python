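"""Divergence and diversity statistics on composition vectors.

Bray-Curtis here is the relative-abundance form ``1 - sum_i min(p_i, q_i)``.
Kendall rank correlation counts concordant/discordant species pairs; two
normalisations are exposed (see :func:`kendall_rank`).  Shannon diversity
uses the natural log; Pielou evenness ``J = H / log(S)`` is base-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_NORM_TOL = 1e-9

KENDALL_VARIANTS = ("standard_tau_a", "paper_literal")


class InvalidCompositionError(ValueError):
    """Input is not a valid relative-abundance vector (or pair thereof)."""


@dataclass(frozen=True)
class DivergenceMetrics:
    bray_curtis: float
    kendall: float
    kendall_variant: str = "standard_tau_a"


@dataclass(frozen=True)
class DiversitySummary:
    shannon_H: float
    richness_S: int
    evenness_J: float


def _as_proportions(p, *, check_normalized: bool = True) -> np.ndarray:
    arr = np.asarray(getattr(p, "proportions", p), dtype=float)
    if arr.ndim != 1:
        raise InvalidCompositionError(f"composition must be 1-D, got shape {arr.shape}")
    if np.any(arr < 0):
        raise InvalidCompositionError("composition entries must be >= 0")
    if check_normalized and abs(arr.sum() - 1.0) > _NORM_TOL:
        raise InvalidCompositionError(
            f"composition must sum to 1 within {_NORM_TOL}, got {arr.sum()!r}"
        )
    return arr


def bray_curtis(p, q) -> float:
    """Bray-Curtis dissimilarity between two relative-abundance vectors.

    ``1 - sum_i min(p_i, q_i)``; 0 for identical compositions, 1 for
    disjoint support.  Both inputs must be normalized and of equal length.

    Computed through the algebraically identical form ``sum_i |p_i - q_i| / 2``
    (identical for normalized vectors), which returns exactly 0 for p == q
    regardless of rounding in the normalisation.
    """
    pa = _as_proportions(p)
    qa = _as_proportions(q)
    if pa.shape != qa.shape:
        raise InvalidCompositionError(
            f"length mismatch: {pa.shape[0]} vs {qa.shape[0]}"
        )
    return float(np.abs(pa - qa).sum() / 2.0)


def kendall_rank(p, q, variant: str = "standard_tau_a") -> float:
    """Kendall rank correlation between two abundance vectors.

    Over all ``n(n-1)/2`` unordered species pairs, ``nc`` pairs are
    concordant (the two species are ordered the same way in both vectors)
    and ``nd`` discordant; ties count toward neither.

    ``variant="standard_tau_a"`` returns ``(nc - nd) / (n(n-1)/2)`` (tau-a,
    bounded in [-1, 1]).  ``variant="paper_literal"`` returns
    ``(nc - nd) / n``, a non-standard normalisation by the species count
    that can exceed 1 in magnitude for n >= 4; it is provided for exact
    replication of the printed formula.
    """
    if variant not in KENDALL_VARIANTS:
        raise InvalidCompositionError(
            f"unknown variant {variant!r}; expected one of {KENDALL_VARIANTS}"
        )
    pa = _as_proportions(p, check_normalized=False)
    qa = _as_proportions(q, check_normalized=False)
    if pa.shape != qa.shape:
        raise InvalidCompositionError(
            f"length mismatch: {pa.shape[0]} vs {qa.shape[0]}"
        )
    n = pa.shape[0]
    if n < 2:
        raise InvalidCompositionError("kendall_rank requires at least 2 species")
    i, j = np.triu_indices(n, k=1)
    s = np.sign(pa[i] - pa[j]) * np.sign(qa[i] - qa[j])
    nc = int(np.count_nonzero(s > 0))
    nd = int(np.count_nonzero(s < 0))
    if variant == "paper_literal":
        return (nc - nd) / n
    return (nc - nd) / (n * (n - 1) / 2)


def shannon_diversity(p) -> float:
    """Shannon diversity H = -sum p_i log(p_i), natural log, 0*log(0) = 0."""
    pa = _as_proportions(p)
    pos = pa[pa > 0]
    return float(-np.sum(pos * np.log(pos)))


def evenness(p) -> float:
    """Pielou evenness J = H / log(S) with S the vector length (S >= 2).

    The ratio is clamped into [0, 1]: rounding in log can push a uniform
    composition a few ulp above 1.
    """
    pa = _as_proportions(p)
    S = pa.shape[0]
    if S < 2:
        raise InvalidCompositionError("evenness is undefined for S < 2 (log S = 0)")
    return float(min(1.0, max(0.0, shannon_diversity(pa) / np.log(S))))


def diversity_summary(p) -> DiversitySummary:
    """Shannon H, realized richness (species with nonzero abundance), and J.

    J is computed against the vector length S, matching :func:`evenness`.
    """
    pa = _as_proportions(p)
    return DiversitySummary(
        shannon_H=shannon_diversity(pa),
        richness_S=int(np.count_nonzero(pa)),
        evenness_J=evenness(pa),
    )
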