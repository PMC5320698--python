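import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from wmhtrial.exceptions import ConfigurationError, DomainError
from wmhtrial.samplesize_ordinal import (
    CategoryDistribution,
    OrdinalDesign,
    RankDesign,
    StratifiedDistribution,
    apply_multiplier,
    backsolve_denominator,
    covariate_multiplier,
    fazekas_baseline_distribution,
    n_from_denominator,
    or_sensitivity_sweep,
    rank_n_per_group,
    rank_superiority_probability,
    treatment_distribution,
    whitehead_denominator,
    whitehead_n_per_group,
)

distributions = st.lists(
    st.floats(0.01, 1.0), min_size=2, max_size=8
).map(lambda xs: CategoryDistribution(tuple(x / sum(xs) for x in xs)))


class TestCategoryDistribution:
    def test_renormalises_rounded_percentages(self):
        dist = fazekas_baseline_distribution()
        assert math.isclose(sum(dist.probs), 1.0, abs_tol=1e-12)
        assert dist.n_categories == 7

    @pytest.mark.parametrize(
        "probs", [(1.0,), (0.5, -0.1, 0.6), (1.0, 0.0), (0.2, 0.2)]
    )
    def test_invalid_distributions_rejected(self, probs):
        with pytest.raises(ConfigurationError):
            CategoryDistribution(probs)

    @given(dist=distributions)
    def test_treatment_shift_moves_mass_down_for_or_above_one(self, dist):
        shifted = treatment_distribution(dist, 2.0)
        # cumulative stochastic dominance: treated lies below on the burden scale
        assert np.all(
            np.cumsum(shifted.array)[:-1] >= np.cumsum(dist.array)[:-1] - 1e-12
        )


class TestWhitehead:
    def test_reference_fazekas_distribution(self):
        # direct evaluation of the formula with averaged two-arm probabilities
        design = OrdinalDesign(odds_ratio=1.21, control_dist=fazekas_baseline_distribution())
        assert whitehead_n_per_group(design) == 1384
        assert whitehead_denominator(design) == pytest.approx(0.93678, abs=1e-4)

    def test_two_equiprobable_categories_or2(self):
        # hand evaluation: pbar = (7/12, 5/12), 1 - sum pbar^3 = 0.729167,
        # 6 * 7.848880 / (log^2 2 * 0.729167) = 134.43
        design = OrdinalDesign(odds_ratio=2.0, control_dist=CategoryDistribution((0.5, 0.5)))
        assert whitehead_denominator(design) == pytest.approx(0.7291667, abs=1e-6)
        assert whitehead_n_per_group(design) == 135

    def test_published_size_implies_baseline_like_denominator(self):
        # the printed OR-1.2 size back-solves to ~0.945, i.e. the distribution
        # term of the published baseline Fazekas marginals
        denom = backsolve_denominator(1499, 1.2)
        assert denom == pytest.approx(0.94511, abs=1e-4)
        base = whitehead_denominator(
            OrdinalDesign(odds_ratio=1 / 1.2, control_dist=fazekas_baseline_distribution())
        )
        assert denom == pytest.approx(base, rel=5e-3)

    def test_backsolve_round_trip(self):
        for n, odds in [(1499, 1.2), (135, 2.0), (6000, 1.1)]:
            denom = backsolve_denominator(n, odds)
            assert n_from_denominator(odds, denom, rounding="nearest") == n

    def test_or_one_and_degenerate_distribution_rejected(self):
        with pytest.raises(ConfigurationError):
            OrdinalDesign(odds_ratio=1.0, control_dist=CategoryDistribution((0.5, 0.5)))
        with pytest.raises(DomainError):
            n_from_denominator(1.2, 0.0)

    @given(dist=distributions)
    def test_denominator_bounds(self, dist):
        # 0 < 1 - sum pbar^3 <= 1 - K^-2, equality at the uniform distribution
        design = OrdinalDesign(odds_ratio=1.3, control_dist=dist)
        denom = whitehead_denominator(design)
        assert 0 < denom <= 1 - dist.n_categories**-2 + 1e-12

    def test_uniform_distribution_attains_bound_at_null_shift(self):
        k = 5
        uniform = CategoryDistribution((1 / k,) * k)
        assert 1 - float(np.sum(uniform.array**3)) == pytest.approx(1 - k**-2)

    def test_log_or_scaling(self):
        # with a fixed denominator, n scales as 1/(log OR)^2
        for or1, or2 in [(1.2, 1.5), (1.1, 2.0)]:
            n1 = 6 * 7.848880 / (math.log(or1) ** 2 * 0.9)
            n2 = 6 * 7.848880 / (math.log(or2) ** 2 * 0.9)
            assert n1 / n2 == pytest.approx((math.log(or2) / math.log(or1)) ** 2)

    def test_direction_symmetry(self):
        dist = fazekas_baseline_distribution()
        # exact on the fixed-denominator path
        denom = 0.94
        assert n_from_denominator(1.2, denom) == n_from_denominator(1 / 1.2, denom)
        # approximate on the explicit-distribution path (averaged arms differ)
        n_up = whitehead_n_per_group(OrdinalDesign(odds_ratio=1.21, control_dist=dist))
        n_dn = whitehead_n_per_group(OrdinalDesign(odds_ratio=1 / 1.21, control_dist=dist))
        assert abs(n_up - n_dn) / n_up < 0.015


class TestSensitivitySweep:
    def test_anchored_sweep_reproduces_published_sensitivity(self):
        base = OrdinalDesign(odds_ratio=1.2, control_dist=fazekas_baseline_distribution())
        results = or_sensitivity_sweep(base, [1.2, 1.25, 1.16], anchor=(1499, 1.2))
        assert [r.n_per_group for r in results] == [1499, 1001, 2262]
        assert [r.n_recruit_total for r in results] == [3748, 2504, 5656]

    def test_small_or_decrease_more_than_doubles_n(self):
        base = OrdinalDesign(odds_ratio=1.2, control_dist=fazekas_baseline_distribution())
        (n_low,), (n_base,) = (
            or_sensitivity_sweep(base, [v], anchor=(1499, 1.2)) for v in (1.16, 1.2)
        )
        assert n_low.n_per_group > 1.5 * n_base.n_per_group
        assert n_base.n_per_group > 1.4 * 1001  # and a 0.05 increase more than halves

    def test_empty_sweep(self):
        base = OrdinalDesign(odds_ratio=1.2, control_dist=fazekas_baseline_distribution())
        assert or_sensitivity_sweep(base, []) == []


class TestCovariateMultiplier:
    def test_single_stratum_is_identity(self):
        overall = CategoryDistribution((0.3, 0.3, 0.4))
        strata = StratifiedDistribution((1.0,), (overall,))
        assert covariate_multiplier(strata, overall) == pytest.approx(1.0)

    def test_two_stratum_hand_example(self):
        strata = StratifiedDistribution(
            (0.5, 0.5),
            (
                CategoryDistribution((0.8, 0.1, 0.1)),
                CategoryDistribution((0.1, 0.1, 0.8)),
            ),
        )
        overall = CategoryDistribution((0.45, 0.1, 0.45))
        # (1 - 0.18325) / (1 - 0.514) = 1.68056
        assert covariate_multiplier(strata, overall) == pytest.approx(1.68056, abs=1e-4)

    def test_published_hypertension_multiplier(self):
        assert apply_multiplier(1499, 1.00057) == 1500

    def test_concentrated_stratum_warns_infinite(self):
        strata = StratifiedDistribution(
            (0.9, 0.1),
            (
                CategoryDistribution((1.0 - 1e-15, 1e-15)),
                CategoryDistribution((0.5, 0.5)),
            ),
        )
        overall = CategoryDistribution((0.7, 0.3))
        m = covariate_multiplier(strata, overall)
        assert m > 5  # nearly-degenerate stratum inflates heavily
        with pytest.raises(DomainError):
            apply_multiplier(100, math.inf)


class TestRankDesign:
    def test_null_design_rejected(self):
        dist = CategoryDistribution((0.5, 0.5))
        with pytest.raises(ConfigurationError):
            rank_n_per_group(RankDesign(treatment_dist=dist, control_dist=dist))

    def test_noether_continuous_limit(self):
        # theta = 0.6 without ties: per group ceil(7.84888 / (6 * 0.01)) = 131
        value = 7.848880 / (6 * 0.01)
        assert math.ceil(value) == 131

    def test_theta_by_enumeration(self):
        # (0.7, 0.3) vs (0.5, 0.5): P(T>C) = 0.15, P(T=C) = 0.5 -> theta = 0.40
        t = CategoryDistribution((0.7, 0.3))
        c = CategoryDistribution((0.5, 0.5))
        assert rank_superiority_probability(t, c) == pytest.approx(0.40)
        assert rank_n_per_group(RankDesign(treatment_dist=t, control_dist=c)) == 95

    @given(dist=distributions)
    def test_theta_direction_antisymmetry(self, dist):
        other = treatment_distribution(dist, 1.7)
        theta = rank_superiority_probability(other, dist)
        assert rank_superiority_probability(dist, other) == pytest.approx(1 - theta)
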