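import numpy as np
import pandas as pd
import pytest

from clockaudit.coherence import (
    audit_model,
    rectify_model,
    residual_separation,
    tradeoff_experiment,
    univariate_stats,
)
from clockaudit.io import BetaMatrix, ClockAuditError, ClockModel
from clockaudit.synthetic import CohortSpec, generate_cohort
from conftest import make_beta, make_metadata


class TestUnivariateStats:
    def test_perfect_correlation(self):
        ages = np.array([20.0, 40.0, 60.0, 80.0])
        beta = make_beta((ages / 100)[:, None], cpg_ids=["cg1"])
        stats = univariate_stats(beta, make_metadata(ages), subset="all")
        assert stats.at["cg1", "pearson_r"] == pytest.approx(1.0)

    def test_constant_cpg_degenerate(self):
        ages = np.array([20.0, 40.0, 60.0])
        beta = make_beta(np.full((3, 1), 0.5), cpg_ids=["cg1"])
        stats = univariate_stats(beta, make_metadata(ages), subset="all")
        assert stats.at["cg1", "pearson_r"] == 0.0
        assert bool(stats.at["cg1", "degenerate"])

    def test_constant_ages_error(self):
        beta = make_beta([[0.1], [0.2], [0.3]], cpg_ids=["cg1"])
        with pytest.raises(ClockAuditError, match="constant ages"):
            univariate_stats(beta, make_metadata([50, 50, 50]), subset="all")

    def test_too_few_samples_error(self):
        beta = make_beta([[0.1], [0.2]], cpg_ids=["cg1"])
        with pytest.raises(ClockAuditError, match=">= 3"):
            univariate_stats(beta, make_metadata([30, 40]), subset="all")

    def test_healthy_subset_excludes_disease(self):
        ages = np.array([20.0, 40.0, 60.0, 80.0, 30.0, 70.0])
        status = ["healthy"] * 4 + ["disease"] * 2
        vals = np.column_stack([ages / 100])
        vals[4:, 0] = 0.99  # disease outliers would break the correlation
        beta = make_beta(vals, cpg_ids=["cg1"])
        stats = univariate_stats(beta, make_metadata(ages, status),
                                 subset="healthy")
        assert stats.at["cg1", "pearson_r"] == pytest.approx(1.0)
        assert stats.at["cg1", "n_used"] == 4

    def test_age_independent_archetype_uncorrelated(self, big_cohort):
        stats = univariate_stats(big_cohort.beta, big_cohort.metadata,
                                 subset="healthy")
        cg4 = big_cohort.cpgs_of("archetype_4")[0]
        assert abs(stats.at[cg4, "pearson_r"]) < 0.1


class TestAuditModel:
    def test_hand_arithmetic_oracle(self, hand_model, hand_stats):
        report = audit_model(hand_model, hand_stats, neutral_band=0.0)
        assert sorted(report.misaligned_cpgs()) == ["cg2", "cg3"]
        assert report.pct_misaligned == pytest.approx(50.0)
        assert report.pct_weight_misaligned == pytest.approx(100 * 3.0 / 4.5)

    def test_all_coherent(self, hand_stats):
        model = ClockModel("m", 0.0, {"cg1": 1.0, "cg2": 2.0,
                                      "cg3": -1.0, "cg4": -0.5})
        report = audit_model(model, hand_stats)
        assert report.pct_misaligned == 0.0
        assert report.pct_weight_misaligned == 0.0

    def test_max_normalization(self, hand_model, hand_stats):
        report = audit_model(hand_model, hand_stats)
        norm = report.per_cpg["max_norm_coefficient"]
        assert norm.abs().max() == pytest.approx(1.0)
        assert norm["cg3"] == pytest.approx(1.0)  # coefficient +2 is the largest

    def test_unmatched_excluded_from_denominators(self, hand_model):
        stats = pd.DataFrame({"pearson_r": [0.5, 0.5]}, index=["cg1", "cg2"])
        report = audit_model(hand_model, stats)
        assert report.n_unmatched == 2
        assert report.n_audited == 2
        assert report.pct_misaligned == pytest.approx(50.0)
        assert report.total_abs_weight == pytest.approx(2.0)

    def test_partition_invariant(self, hand_model, hand_stats):
        report = audit_model(hand_model, hand_stats, neutral_band=0.55)
        assert (report.n_audited
                == report.n_coherent + report.n_misaligned + report.n_neutral)

    def test_neutral_band(self, hand_model):
        stats = pd.DataFrame({"pearson_r": [0.5, -0.05, -0.5, 0.0]},
                             index=["cg1", "cg2", "cg3", "cg4"])
        report = audit_model(hand_model, stats, neutral_band=0.1)
        flags = report.per_cpg["flag"]
        assert flags["cg1"] == "coherent"
        assert flags["cg2"] == "neutral"      # |r| below the band
        assert flags["cg3"] == "misaligned"
        assert flags["cg4"] == "neutral"      # r exactly 0

    def test_zero_overlap_error(self, hand_model):
        stats = pd.DataFrame({"pearson_r": [0.5]}, index=["cgZ"])
        with pytest.raises(ClockAuditError, match="no overlap"):
            audit_model(hand_model, stats)

    def test_joint_sign_symmetry(self, rng):
        cpgs = [f"cg{i}" for i in range(30)]
        coefs = dict(zip(cpgs, rng.normal(size=30)))
        stats = pd.DataFrame({"pearson_r": rng.uniform(-1, 1, 30)}, index=cpgs)
        a = audit_model(ClockModel("m", 0.0, coefs), stats)
        flipped = ClockModel("m", 0.0, {c: -w for c, w in coefs.items()})
        b = audit_model(flipped, -stats)
        assert a.misaligned_cpgs() == b.misaligned_cpgs()

    def test_random_signs_near_half_misaligned(self, rng):
        n = 2000
        cpgs = [f"cg{i}" for i in range(n)]
        coefs = dict(zip(cpgs, rng.choice([-1.0, 1.0], n)))
        stats = pd.DataFrame({"pearson_r": rng.choice([-0.5, 0.5], n)},
                             index=cpgs)
        report = audit_model(ClockModel("m", 0.0, coefs), stats)
        assert report.pct_misaligned == pytest.approx(50.0, abs=5.0)


class TestRectifyModel:
    def test_fixed_point_when_clean(self, hand_stats):
        model = ClockModel("m", 3.0, {"cg1": 1.0, "cg3": -1.0})
        out = rectify_model(model, hand_stats, mode="drop")
        assert out.coefficients == model.coefficients
        assert out.intercept == model.intercept

    def test_drop_keeps_two_of_four(self, hand_model, hand_stats):
        out = rectify_model(hand_model, hand_stats, mode="drop")
        assert out.n_features == 2
        assert sorted(out.coefficients) == ["cg1", "cg4"]

    def test_rectified_model_is_audit_clean(self, hand_model, hand_stats):
        out = rectify_model(hand_model, hand_stats, mode="drop")
        assert audit_model(out, hand_stats).pct_misaligned == 0.0

    def test_all_misaligned_error(self, hand_stats):
        model = ClockModel("m", 0.0, {"cg2": -1.0, "cg3": 1.0})
        with pytest.raises(ClockAuditError, match="misaligned"):
            rectify_model(model, hand_stats, mode="drop")

    def test_intercept_refit(self, hand_model, hand_stats, rng):
        beta = make_beta(rng.uniform(size=(20, 4)),
                         cpg_ids=["cg1", "cg2", "cg3", "cg4"])
        ages = pd.Series(rng.uniform(20, 80, 20), index=beta.data.index)
        out = rectify_model(hand_model, hand_stats, mode="drop",
                            beta=beta, ages=ages)
        w = np.array([out.coefficients.get(c, 0.0) for c in beta.data.columns])
        resid = ages - (out.intercept + beta.data.to_numpy() @ w)
        assert resid.mean() == pytest.approx(0.0, abs=1e-9)

    def test_sign_constrained_refit_clean(self, rng):
        n = 100
        ages = rng.uniform(20, 80, n)
        vals = np.column_stack([
            0.2 + 0.004 * ages + rng.normal(0, 0.02, n),
            0.8 - 0.005 * ages / 10 + rng.normal(0, 0.02, n),
            rng.uniform(0.2, 0.8, n),
        ]).clip(0, 1)
        beta = make_beta(vals, cpg_ids=["cg1", "cg2", "cg3"])
        meta = make_metadata(ages)
        stats = univariate_stats(beta, meta, subset="all")
        model = ClockModel("m", 0.0, {"cg1": -5.0, "cg2": 10.0, "cg3": 1.0})
        out = rectify_model(model, stats, mode="sign-constrained-refit",
                            beta=beta, ages=meta["age"])
        assert audit_model(out, stats).pct_misaligned == 0.0


class TestResidualSeparation:
    def test_identical_groups(self):
        ages = np.repeat([30.0, 50.0, 70.0], 4)
        status = ["healthy", "disease"] * 6
        beta = make_beta((ages / 100)[:, None], cpg_ids=["cg1"])
        model = ClockModel("m", 0.0, {"cg1": 100.0})  # exact predictor
        sep = residual_separation(model, beta, make_metadata(ages, status))
        assert sep.difference == pytest.approx(0.0)
        assert sep.effect_size == pytest.approx(0.0)
        assert sep.mae == pytest.approx(0.0)

    def test_planted_shift_recovered(self, rng):
        n = 400
        ages = rng.uniform(20, 80, n)
        status = np.where(np.arange(n) < n // 2, "healthy", "disease")
        vals = ages / 100 + np.where(status == "disease", 0.05, 0.0)
        vals += rng.normal(0, 0.01, n)
        beta = make_beta(vals.clip(0, 1)[:, None], cpg_ids=["cg1"])
        model = ClockModel("m", 0.0, {"cg1": 100.0})
        sep = residual_separation(model, beta, make_metadata(ages, status))
        assert sep.difference == pytest.approx(5.0, abs=0.5)
        assert sep.p_value < 1e-6

    def test_one_group_too_small(self):
        ages = np.array([30.0, 40.0, 50.0, 60.0])
        beta = make_beta((ages / 100)[:, None], cpg_ids=["cg1"])
        meta = make_metadata(ages, ["healthy"] * 3 + ["disease"])
        with pytest.raises(ClockAuditError, match=">= 3"):
            residual_separation(ClockModel("m", 0.0, {"cg1": 1.0}), beta, meta)


class TestTradeoff:
    def test_null_cohort_shows_no_separation(self):
        from clockaudit.synthetic import CellMixSpec
        no_shift = CellMixSpec(
            disease_shift=dict.fromkeys(CellMixSpec().cell_types, 0.0))
        cohort = generate_cohort(CohortSpec(n_samples=400, disease_fraction=0.4,
                                            seed=5, disease_beta_shift=0.0,
                                            cell_mix=no_shift))
        result = tradeoff_experiment(cohort, seed=5)
        assert abs(result.original.effect_size) < 0.5
        assert abs(result.rectified.effect_size) < 0.5

    def test_direction_single_replicate(self):
        cohort = generate_cohort(CohortSpec(n_samples=1000, disease_fraction=0.3,
                                            seed=21))
        result = tradeoff_experiment(cohort, seed=21)
        assert result.n_misaligned_dropped >= 1
        assert result.rectified.effect_size >= result.original.effect_size
        assert result.rectified.mae >= result.original.mae
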