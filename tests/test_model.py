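import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from antagosim import (
    AssembledSystem,
    CommunitySpec,
    InvalidParameterError,
    assemble_system,
    lv_derivative,
    sample_antagonist_impacts,
    sample_focal_block,
    sample_growth_rates,
)

HALF_NORMAL_MEAN = math.sqrt(2.0 / math.pi)  # scale-1 half-normal mean


class TestCommunitySpec:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n": 0}, {"n": -1}, {"n": 2.5},
            {"m": -1}, {"m": 1.5},
            {"sigma": 0.0}, {"sigma": -0.3},
            {"A": 0.0}, {"A": -1.0},
            {"seed": -1},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        base = {"n": 3, "m": 2, "sigma": 0.3, "A": 0.5, "seed": 0}
        base.update(kwargs)
        with pytest.raises(InvalidParameterError):
            CommunitySpec(**base)

    def test_without_antagonists_keeps_focal_parameters(self):
        spec = CommunitySpec(n=3, m=2, sigma=0.3, A=0.5, seed=7)
        base = spec.without_antagonists()
        assert base.m == 0
        assert (base.n, base.sigma, base.A, base.seed) == (3, 0.3, 0.5, 7)


class TestSampleFocalBlock:
    def test_n1_is_identity(self, rng):
        block = sample_focal_block(1, 0.7, rng)
        assert block.shape == (1, 1)
        assert block[0, 0] == 1.0

    def test_structure_and_bounds(self, rng):
        n, A = 10, 0.5
        block = sample_focal_block(n, A, rng)
        assert np.all(np.diag(block) == 1.0)
        off = block[~np.eye(n, dtype=bool)]
        assert np.all(off >= 0.0) and np.all(off <= A / n)

    def test_offdiagonal_mean_matches_uniform(self):
        # mean of Uniform(0, b) is b/2; 3 MC standard errors at ~1e6 draws
        n, A = 10, 0.5
        rng = np.random.default_rng(0)
        draws = np.concatenate(
            [sample_focal_block(n, A, rng)[~np.eye(n, dtype=bool)] for _ in range(11112)]
        )
        b = A / n
        se = (b / math.sqrt(12.0)) / math.sqrt(draws.size)
        assert abs(draws.mean() - b / 2.0) < 5 * se

    def test_deterministic_given_seed(self):
        a = sample_focal_block(5, 0.3, np.random.default_rng(42))
        b = sample_focal_block(5, 0.3, np.random.default_rng(42))
        np.testing.assert_array_equal(a, b)

    @pytest.mark.parametrize("n,A", [(0, 0.5), (-1, 0.5), (3, 0.0), (3, -0.1)])
    def test_invalid_parameters(self, n, A, rng):
        with pytest.raises(InvalidParameterError):
            sample_focal_block(n, A, rng)


class TestSampleAntagonistImpacts:
    def test_m0_empty_block(self, rng):
        block = sample_antagonist_impacts(4, 0, 0.3, rng)
        assert block.shape == (4, 0)

    def test_nonnegative(self, rng):
        block = sample_antagonist_impacts(10, 10, 0.3, rng)
        assert np.all(block >= 0.0)

    def test_half_normal_mean_sigma1(self):
        rng = np.random.default_rng(1)
        draws = sample_antagonist_impacts(1000, 1000, 1.0, rng).ravel()
        se = math.sqrt(1.0 - 2.0 / math.pi) / math.sqrt(draws.size)
        assert abs(draws.mean() - HALF_NORMAL_MEAN) < 5 * se

    def test_half_normal_variance_sigma03(self):
        rng = np.random.default_rng(2)
        draws = sample_antagonist_impacts(1000, 1000, 0.3, rng).ravel()
        expected = 0.09 * (1.0 - 2.0 / math.pi)
        assert abs(np.var(draws) - expected) < 5e-4

    def test_negative_m_rejected(self, rng):
        with pytest.raises(InvalidParameterError):
            sample_antagonist_impacts(3, -1, 0.3, rng)


class TestSampleGrowthRates:
    def test_strictly_positive(self, rng):
        assert np.all(sample_growth_rates(1000, rng) > 0.0)

    def test_half_normal_mean(self):
        rng = np.random.default_rng(3)
        draws = sample_growth_rates(1_000_000, rng)
        se = math.sqrt(1.0 - 2.0 / math.pi) / math.sqrt(draws.size)
        assert abs(draws.mean() - HALF_NORMAL_MEAN) < 5 * se

    def test_deterministic_given_seed(self):
        a = sample_growth_rates(10, np.random.default_rng(9))
        b = sample_growth_rates(10, np.random.default_rng(9))
        np.testing.assert_array_equal(a, b)

    def test_invalid_n(self, rng):
        with pytest.raises(InvalidParameterError):
            sample_growth_rates(0, rng)


class TestAssembleSystem:
    def test_m0_structure(self):
        system = assemble_system(CommunitySpec(n=2, m=0, sigma=0.3, A=0.5, seed=0))
        assert system.alpha.shape == (2, 2)
        assert np.all(np.diag(system.alpha) == 1.0)
        off = system.alpha[~np.eye(2, dtype=bool)]
        assert np.all((off >= 0) & (off <= 0.25))

    def test_block_structure_n3_m2(self):
        system = assemble_system(CommunitySpec(n=3, m=2, sigma=0.3, A=0.5, seed=1))
        alpha = system.alpha
        assert alpha.shape == (5, 5)
        assert np.all(np.diag(alpha) == 1.0)
        np.testing.assert_array_equal(alpha[3:, :3], 0.0)  # focal -> antagonist
        np.testing.assert_array_equal(alpha[3:, 3:], 1.0)  # antagonist block
        assert np.all(alpha[:3, 3:] >= 0.0)  # impacts
        assert np.all(system.r > 0.0)

    def test_paired_baseline_shares_focal_draw(self):
        spec = CommunitySpec(n=3, m=2, sigma=0.3, A=0.5, seed=77)
        full = assemble_system(spec)
        base = assemble_system(spec.without_antagonists())
        np.testing.assert_array_equal(full.alpha[:3, :3], base.alpha)
        np.testing.assert_array_equal(full.r[:3], base.r)

    def test_determinism_and_seed_sensitivity(self):
        spec = CommunitySpec(n=4, m=3, sigma=0.3, A=0.5, seed=5)
        a = assemble_system(spec)
        b = assemble_system(spec)
        np.testing.assert_array_equal(a.alpha, b.alpha)
        np.testing.assert_array_equal(a.r, b.r)
        other = assemble_system(CommunitySpec(n=4, m=3, sigma=0.3, A=0.5, seed=6))
        assert not np.array_equal(a.alpha, other.alpha)

    @given(
        n=st.integers(1, 8),
        m=st.integers(0, 5),
        sigma=st.floats(0.05, 2.0),
        A=st.floats(0.05, 1.0),
        seed=st.integers(0, 2**32 - 1),
    )
    def test_invariants_hold_for_any_spec(self, n, m, sigma, A, seed):
        system = assemble_system(CommunitySpec(n=n, m=m, sigma=sigma, A=A, seed=seed))
        alpha = system.alpha
        N = n + m
        assert alpha.shape == (N, N)
        assert np.all(np.diag(alpha) == 1.0)
        focal_off = alpha[:n, :n][~np.eye(n, dtype=bool)]
        assert np.all((focal_off >= 0) & (focal_off <= A / n))
        if m:
            assert np.all(alpha[n:, :n] == 0.0)
            assert np.all(alpha[n:, n:] == 1.0)
            assert np.all(alpha[:n, n:] >= 0.0)
        assert np.all(system.r > 0.0)


class TestLvDerivative:
    def test_zero_state_is_fixed_point(self):
        system = assemble_system(CommunitySpec(n=3, m=2, sigma=0.3, A=0.5, seed=0))
        np.testing.assert_array_equal(
            lv_derivative(np.zeros(5), system), np.zeros(5)
        )

    def test_single_species_hand_value(self):
        system = AssembledSystem(alpha=np.array([[1.0]]), r=np.array([1.0]), n_focal=1)
        assert lv_derivative(np.array([0.5]), system)[0] == pytest.approx(0.25)

    def test_equilibrium_condition_gives_zero(self):
        # any state with alpha @ x = 1 rowwise zeroes the bracket
        a = 0.5
        system = AssembledSystem(
            alpha=np.array([[1.0, a], [a, 1.0]]), r=np.array([0.7, 1.3]), n_focal=2
        )
        x_star = np.full(2, 1.0 / (1.0 + a))
        np.testing.assert_allclose(
            lv_derivative(x_star, system), np.zeros(2), atol=1e-15
        )

    def test_dimension_mismatch(self):
        system = assemble_system(CommunitySpec(n=2, m=0, sigma=0.3, A=0.5, seed=0))
        with pytest.raises(InvalidParameterError):
            lv_derivative(np.zeros(3), system)

    @given(seed=st.integers(0, 10_000), zero_idx=st.integers(0, 4))
    def test_extinction_is_absorbing(self, seed, zero_idx):
        system = assemble_system(CommunitySpec(n=3, m=2, sigma=0.3, A=0.5, seed=seed))
        x = np.random.default_rng(seed).uniform(0.0, 2.0, size=5)
        x[zero_idx] = 0.0
        assert lv_derivative(x, system)[zero_idx] == 0.0
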