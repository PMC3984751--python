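import numpy as np
import pytest

from epistab import featexp, simgen, stabsel
from epistab.genio import PhenotypeVector
from epistab.scadglm import PenaltySpec
from epistab.stabsel import (
    InfeasibleThresholdError,
    StabilityConfig,
    default_q,
    expected_false_bound,
    fdr_bound,
    permutation_calibration,
    pi_threshold,
    run_stability,
    subsample_indices,
    two_stage,
)

SCAD = PenaltySpec("scad")
LASSO = PenaltySpec("lasso")


class TestThresholdAlgebra:
    @pytest.mark.parametrize(
        "p, expected", [(53628, 231), (100, 10), (1, 1), (3, 1)]
    )
    def test_default_q(self, p, expected):
        assert default_q(p) == expected

    def test_pi_threshold_arithmetic(self):
        assert pi_threshold(200, 53628, 0.1) == pytest.approx(
            (1 + 200 / 5362.8) / 2
        )
        assert pi_threshold(200, 53628, 0.1) == pytest.approx(0.51865, abs=1e-5)

    def test_pi_threshold_boundary_and_degenerate(self):
        p, alpha = 1000, 0.1
        assert pi_threshold(p * alpha, p, alpha) == pytest.approx(1.0)
        assert pi_threshold(0, p, alpha) == pytest.approx(0.5)

    def test_pi_threshold_infeasible(self):
        with pytest.raises(InfeasibleThresholdError):
            pi_threshold(150, 1000, 0.1)

    def test_expected_false_bound_arithmetic(self):
        assert expected_false_bound(100, 10000, 0.75) == pytest.approx(2.0)
        assert expected_false_bound(0, 10000, 0.75) == 0.0
        # decreasing in pi_thr
        assert expected_false_bound(100, 10000, 0.9) < expected_false_bound(
            100, 10000, 0.6
        )

    def test_fdr_bound_arithmetic_and_linearity(self):
        assert fdr_bound(100, 10000, 0.75) == pytest.approx(0.02)
        assert fdr_bound(200, 10000, 0.75) == pytest.approx(2 * fdr_bound(100, 10000, 0.75))

    def test_threshold_is_algebraic_inverse(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            p = int(rng.integers(50, 100_000))
            alpha = rng.uniform(0.01, 0.5)
            q_lambda = rng.uniform(0.1, p * alpha)
            thr = pi_threshold(q_lambda, p, alpha)
            assert fdr_bound(q_lambda, p, thr) == pytest.approx(alpha, abs=1e-12)


class TestSubsampling:
    def test_exact_stratified_counts(self):
        y = np.r_[np.ones(1000), np.zeros(1000)].astype(int)
        cfg = StabilityConfig(B=20, subsample_fraction=0.5, seed=3)
        for idx in subsample_indices(y, cfg):
            assert y[idx].sum() == 500
            assert (1 - y[idx]).sum() == 500
            assert len(np.unique(idx)) == len(idx)

    def test_deterministic_given_seed(self):
        y = np.r_[np.ones(40), np.zeros(60)].astype(int)
        cfg = StabilityConfig(B=10, seed=9)
        a = subsample_indices(y, cfg)
        b = subsample_indices(y, cfg)
        for ia, ib in zip(a, b):
            np.testing.assert_array_equal(ia, ib)

    def test_membership_rate_matches_binomial(self):
        y = np.r_[np.ones(100), np.zeros(100)].astype(int)
        cfg = StabilityConfig(B=500, subsample_fraction=0.5, seed=1)
        counts = np.zeros(200)
        for idx in subsample_indices(y, cfg):
            counts[idx] += 1
        sd = np.sqrt(500 * 0.25)
        assert abs(counts.mean() - 250) < 3 * sd / np.sqrt(200)

    def test_empty_class_error(self):
        y = np.r_[np.ones(2), np.zeros(100)].astype(int)
        with pytest.raises(ValueError):
            subsample_indices(y, StabilityConfig(B=2, subsample_fraction=0.1))


@pytest.fixture(scope="module")
def strong_main_effect():
    """m=12 SNPs, one strong main effect (OR 3), n=1000."""
    spec = simgen.BlockLDSpec.scaled(12, within_block_rho=0.0)
    G = simgen.simulate_genotypes(spec, 1000, seed=101)
    rng = np.random.default_rng(102)
    eta = -0.6 + np.log(3.0) * G.values[:, 4]
    y = rng.binomial(1, 1 / (1 + np.exp(-eta)))
    F = featexp.standardize(featexp.expand_interactions(G))
    return F, PhenotypeVector(y), 4


class TestRunStability:
    def test_strong_main_effect_is_stable(self, strong_main_effect):
        F, y, causal = strong_main_effect
        hits = 0
        for seed in range(5):
            res = run_stability(
                F, y, None, SCAD, StabilityConfig(B=60, alpha=0.2, seed=seed)
            )
            hits += res.selection_prob[causal] >= 0.9 and causal in res.stable_set
        assert hits >= 5 * 0.8

    def test_max_over_lambda_below_union_freq(self, strong_main_effect):
        F, y, _ = strong_main_effect
        res = run_stability(F, y, None, LASSO, StabilityConfig(B=30, seed=2))
        assert (res.selection_prob <= res.union_freq + 1e-12).all()

    def test_union_budget_enforced(self, strong_main_effect):
        F, y, _ = strong_main_effect
        cfg = StabilityConfig(B=25, q=5, alpha=0.2, seed=0)
        res = run_stability(F, y, None, SCAD, cfg)
        assert (res.per_subsample_unions <= 5).all()
        assert res.q_lambda_hat == pytest.approx(res.per_subsample_unions.mean())

    def test_single_subsample_degenerate(self, strong_main_effect):
        F, y, _ = strong_main_effect
        res = run_stability(F, y, None, SCAD, StabilityConfig(B=1, seed=4, alpha=0.5))
        assert set(np.unique(res.selection_prob)) <= {0.0, 1.0}
        union = np.flatnonzero(res.union_freq > 0)
        assert set(res.stable_set) <= set(union)

    def test_null_expected_false_selections_below_bound(self):
        """Mean stable-set size on pure-noise data stays below the
        exchangeability bound on E[V] (scaled-down null suite)."""
        spec = simgen.BlockLDSpec.scaled(12, within_block_rho=0.0)
        sizes, bounds = [], []
        for r in range(8):
            G = simgen.simulate_genotypes(spec, 300, seed=500 + r)
            y = np.random.default_rng(600 + r).binomial(1, 0.5, 300)
            F = featexp.standardize(featexp.expand_interactions(G))
            res = run_stability(
                F, y, None, SCAD, StabilityConfig(B=50, alpha=0.2, seed=700 + r)
            )
            sizes.append(len(res.stable_set))
            bounds.append(
                expected_false_bound(res.q_lambda_hat, F.n_features, res.pi_thr)
            )
        assert np.mean(sizes) <= np.mean(bounds)

    def test_reproducible_and_q_infeasibility(self, strong_main_effect):
        F, y, _ = strong_main_effect
        cfg = StabilityConfig(B=10, seed=11, alpha=0.2)
        r1 = run_stability(F, y, None, SCAD, cfg)
        r2 = run_stability(F, y, None, SCAD, cfg)
        np.testing.assert_array_equal(r1.selection_prob, r2.selection_prob)
        # q above p*alpha makes the threshold infeasible
        with pytest.raises(InfeasibleThresholdError):
            run_stability(
                F, y, None, SCAD,
                StabilityConfig(B=5, q=F.n_features // 2, alpha=0.01, seed=0),
            )


class TestPermutationCalibration:
    def test_reports_are_probabilities_and_reproducible(self, strong_main_effect):
        F, y, _ = strong_main_effect
        cfg = StabilityConfig(B=20, alpha=0.2, seed=21)
        t1 = permutation_calibration(F, y, None, SCAD, cfg, n_perm=3)
        t2 = permutation_calibration(F, y, None, SCAD, cfg, n_perm=3)
        assert ((t1.selection_prob >= 0) & (t1.selection_prob <= 1)).all()
        assert t1.equals(t2)

    def test_mostly_conservative_under_null(self, strong_main_effect):
        F, y, _ = strong_main_effect
        cfg = StabilityConfig(B=30, alpha=0.2, seed=33)
        table = permutation_calibration(F, y, None, SCAD, cfg, n_perm=6)
        assert table.exceeds_threshold.mean() <= 0.5


@pytest.fixture(scope="module")
def interaction_cohorts():
    """Two cohorts with the same planted interaction; a third with the
    interaction sign flipped; a fourth pure-noise."""
    spec = simgen.BlockLDSpec.scaled(10, within_block_rho=0.0)
    scen = simgen.ScenarioConfig.from_scenario("C", 3.0, spec)
    rng = np.random.default_rng(900)
    out = {}
    for name, flip, null in (
        ("d1", False, False), ("d2", False, False),
        ("flip", True, False), ("null", False, True),
    ):
        seed = int(rng.integers(1e6))
        G = simgen.simulate_genotypes(spec, 1200, seed=seed)
        j, k = scen.causal_pair
        inter = np.log(3.0) * G.values[:, j] * G.values[:, k]
        mains = np.log(1.3) * (G.values[:, j] + G.values[:, k])
        eta = mains + (-inter if flip else inter)
        if null:
            eta = np.zeros(G.n_samples)
        y = np.random.default_rng(seed + 1).binomial(
            1, 1 / (1 + np.exp(-(eta - np.median(eta))))
        )
        F = featexp.standardize(featexp.expand_interactions(G))
        out[name] = (F, PhenotypeVector(y))
    out["pair_col"] = featexp.interaction_column(10, *scen.causal_pair)
    return out

class TestTwoStage:
    def test_self_replication_confirms_pair(self, interaction_cohorts):
        F1, y1 = interaction_cohorts["d1"]
        res = two_stage(
            F1, y1, None, F1, y1, None, SCAD,
            StabilityConfig(B=40, alpha=0.2, seed=5),
        )
        assert interaction_cohorts["pair_col"] in res.confirmed_pairs
        assert set(res.confirmed_pairs) <= (
            set(res.discovery.stable_set) & set(res.replication.stable_set)
        )

    def test_sign_flip_blocks_confirmation(self, interaction_cohorts):
        F1, y1 = interaction_cohorts["d1"]
        F3, y3 = interaction_cohorts["flip"]
        res = two_stage(
            F1, y1, None, F3, y3, None, SCAD,
            StabilityConfig(B=40, alpha=0.2, seed=6),
        )
        assert interaction_cohorts["pair_col"] not in res.confirmed_pairs

    def test_null_replication_confirms_nothing(self, interaction_cohorts):
        F1, y1 = interaction_cohorts["d1"]
        F4, y4 = interaction_cohorts["null"]
        res = two_stage(
            F1, y1, None, F4, y4, None, SCAD,
            StabilityConfig(B=40, alpha=0.2, seed=7),
        )
        assert len(res.confirmed_pairs) == 0
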