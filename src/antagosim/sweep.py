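"""Paired with/without-antagonist runs across a (n, m, sigma, A) grid.

Every replicate draws ONE focal community (competition block plus focal
growth rates), simulates it twice — once with its m antagonists attached,
once without — from identical focal initial conditions, and scores the two
focal compositions with Bray-Curtis dissimilarity and Kendall rank
correlation.  Tiles (parameter combinations) aggregate replicates into
means, excluding and counting degenerate replicates (all focal species
extinct, or solver failure).

Seeding is counter-based: each (tile, replicate) gets its own seed derived
from the root seed and its grid coordinates, so results are independent of
execution order and identical under serial or parallel execution.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from joblib import Parallel, delayed

from antagosim.dynamics import (
    DegenerateCommunityError,
    IntegrationFailureError,
    IntegrationSettings,
    focal_relative_abundances,
    integrate,
)
from antagosim.metrics import DivergenceMetrics, bray_curtis, kendall_rank
from antagosim.model import AssembledSystem, CommunitySpec, InvalidParameterError, assemble_system

logger = logging.getLogger(__name__)

PAIRING_MODES = ("paired", "independent")


@dataclass(frozen=True)
class SweepGrid:
    """Parameter grid plus execution settings for one sweep."""

    n_values: Sequence[int]
    m_values: Sequence[int]
    sigma_values: Sequence[float]
    A_values: Sequence[float]
    replicates: int = 2000
    root_seed: int = 0
    settings: IntegrationSettings = field(default_factory=IntegrationSettings)

    def __post_init__(self) -> None:
        for name in ("n_values", "m_values", "sigma_values", "A_values"):
            vals = getattr(self, name)
            if len(vals) == 0:
                raise InvalidParameterError(f"{name} must be nonempty")
            object.__setattr__(self, name, tuple(vals))
        if int(self.replicates) != self.replicates or self.replicates < 1:
            raise InvalidParameterError(
                f"replicates must be a positive integer, got {self.replicates}"
            )

    def tiles(self) -> list[tuple[int, int, float, float]]:
        """Lexicographic tile order in (n, m, sigma, A); m = 0 tiles are
        skipped because they are the implicit baseline of every paired run."""
        return sorted(
            (n, m, sigma, A)
            for n, m, sigma, A in itertools.product(
                self.n_values, self.m_values, self.sigma_values, self.A_values
            )
            if m >= 1
        )


@dataclass(frozen=True)
class TileSummary:
    """Mean divergence metrics for one parameter combination."""

    n: int
    m: int
    sigma: float
    A: float
    mean_bray_curtis: float
    mean_kendall: float
    replicates_used: int
    degenerate_count: int


def derive_seed(root_seed: int, tile_index: int, replicate: int) -> int:
    """Counter-based per-replicate seed, independent of execution order."""
    words = np.random.SeedSequence(
        root_seed, spawn_key=(tile_index, replicate)
    ).generate_state(2)
    return int(words[0]) << 32 | int(words[1])


def _divergence(
    antagonist_arm: AssembledSystem,
    baseline_arm: AssembledSystem,
    settings: IntegrationSettings,
    kendall_variant: str,
) -> DivergenceMetrics:
    """Integrate both arms from equal initial densities and score the focal
    compositions.  Shared by :func:`paired_run` and the fixture registry."""
    x0_full = np.full(antagonist_arm.size, settings.initial_density)
    x0_base = np.full(baseline_arm.size, settings.initial_density)
    state_full = integrate(antagonist_arm, x0_full, settings)
    state_base = integrate(baseline_arm, x0_base, settings)
    p = focal_relative_abundances(state_full, antagonist_arm, settings)
    q = focal_relative_abundances(state_base, baseline_arm, settings)
    return DivergenceMetrics(
        bray_curtis=bray_curtis(p, q),
        kendall=kendall_rank(p, q, variant=kendall_variant),
        kendall_variant=kendall_variant,
    )


def paired_run(
    spec: CommunitySpec,
    settings: IntegrationSettings = IntegrationSettings(),
    kendall_variant: str = "standard_tau_a",
    pairing_mode: str = "paired",
) -> DivergenceMetrics:
    """One replicate: simulate a community with and without its antagonists.

    In ``paired`` mode (default) the baseline arm is the same focal draw
    with the antagonist rows/columns removed.  In ``independent`` mode the
    baseline is a fresh antagonist-free draw from a seed derived from
    ``spec.seed`` (sensitivity analysis only).
    """
    if spec.m < 1:
        raise InvalidParameterError("paired_run requires spec.m >= 1")
    if pairing_mode not in PAIRING_MODES:
        raise InvalidParameterError(
            f"unknown pairing_mode {pairing_mode!r}; expected one of {PAIRING_MODES}"
        )
    full = assemble_system(spec)
    if pairing_mode == "paired":
        baseline = full.focal_subsystem()
    else:
        alt_seed = int(
            np.random.SeedSequence(spec.seed, spawn_key=(1,)).generate_state(1)[0]
        )
        baseline = assemble_system(
            CommunitySpec(n=spec.n, m=0, sigma=spec.sigma, A=spec.A, seed=alt_seed)
        )
    return _divergence(full, baseline, settings, kendall_variant)


def run_tile(
    n: int,
    m: int,
    sigma: float,
    A: float,
    tile_index: int,
    replicates: int,
    root_seed: int,
    settings: IntegrationSettings,
    kendall_variant: str = "standard_tau_a",
    pairing_mode: str = "paired",
) -> TileSummary:
    """All replicates of one tile, with per-replicate derived seeds."""
    bc_sum = 0.0
    kd_sum = 0.0
    used = 0
    degenerate = 0
    for rep in range(replicates):
        seed = derive_seed(root_seed, tile_index, rep)
        spec = CommunitySpec(n=n, m=m, sigma=sigma, A=A, seed=seed)
        try:
            metrics = paired_run(spec, settings, kendall_variant, pairing_mode)
        except (DegenerateCommunityError, IntegrationFailureError) as exc:
            degenerate += 1
            logger.debug(
                "degenerate replicate: tile=%d rep=%d (n=%d m=%d sigma=%g A=%g): %s",
                tile_index, rep, n, m, sigma, A, exc,
            )
            continue
        bc_sum += metrics.bray_curtis
        kd_sum += metrics.kendall
        used += 1
    return TileSummary(
        n=n,
        m=m,
        sigma=sigma,
        A=A,
        mean_bray_curtis=bc_sum / used if used else float("nan"),
        mean_kendall=kd_sum / used if used else float("nan"),
        replicates_used=used,
        degenerate_count=degenerate,
    )


def run_sweep(
    grid: SweepGrid,
    kendall_variant: str = "standard_tau_a",
    pairing_mode: str = "paired",
    n_jobs: int = 1,
    progress: bool = False,
) -> list[TileSummary]:
    """Execute every m >= 1 tile of the grid; deterministic output order.

    Per-replicate seeds are derived from (root_seed, tile index, replicate
    index), so ``n_jobs > 1`` produces results identical to serial runs.
    """
    tiles = grid.tiles()
    if not tiles:
        raise InvalidParameterError("grid contains no tiles with m >= 1")
    iterator: Iterable = enumerate(tiles)
    if progress:
        from tqdm import tqdm  # local import: optional dependency at runtime

        iterator = tqdm(list(iterator), desc="tiles")
    jobs = (
        delayed(run_tile)(
            n, m, sigma, A, idx, grid.replicates, grid.root_seed,
            grid.settings, kendall_variant, pairing_mode,
        )
        for idx, (n, m, sigma, A) in iterator
    )
    if n_jobs == 1:
        results = [job[0](*job[1], **job[2]) for job in jobs]
    else:
        results = Parallel(n_jobs=n_jobs)(jobs)
    return list(results)
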