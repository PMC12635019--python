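import numpy as np
import pandas as pd
import pytest

from clockaudit.cellfractions import (
    BIN_LABELS,
    bin_delta,
    compare_models_vif,
    deconvolve,
    fraction_correlations,
    model_cpg_beta,
    vif_audit,
)
from clockaudit.io import BetaMatrix, ClockAuditError, ClockModel
from clockaudit.synthetic import CELL_TYPES
from conftest import make_beta


def _reference(rng, n_cpgs=40):
    vals = rng.uniform(0.05, 0.95, size=(12, n_cpgs))
    return pd.DataFrame(vals, index=list(CELL_TYPES),
                        columns=[f"cg{j + 1}" for j in range(n_cpgs)])


class TestDeconvolve:
    def test_noiseless_two_component_mixture(self, rng):
        ref = _reference(rng)
        mix = (0.7 * ref.loc["Neutrophils"] + 0.3 * ref.loc["CD4T_naive"])
        beta = make_beta(mix.to_numpy()[None, :], cpg_ids=list(ref.columns))
        frac, resid = deconvolve(beta, ref)
        assert frac.at["S0", "Neutrophils"] == pytest.approx(0.7, abs=1e-6)
        assert frac.at["S0", "CD4T_naive"] == pytest.approx(0.3, abs=1e-6)
        others = frac.drop(columns=["Neutrophils", "CD4T_naive"])
        assert others.to_numpy().max() < 1e-6
        assert resid.iloc[0] < 1e-9

    def test_pure_profile(self, rng):
        ref = _reference(rng)
        beta = make_beta(ref.loc[["NK"]].to_numpy(), cpg_ids=list(ref.columns))
        frac, _ = deconvolve(beta, ref)
        assert frac.at["S0", "NK"] == pytest.approx(1.0, abs=1e-6)

    def test_noisy_recovery(self, rng):
        ref = _reference(rng, n_cpgs=60)
        n = 200
        true = rng.dirichlet(np.full(12, 2.0), size=n)
        bulk = (true @ ref.to_numpy() + rng.normal(0, 0.02, (n, 60))).clip(0, 1)
        beta = make_beta(bulk, cpg_ids=list(ref.columns))
        frac, _ = deconvolve(beta, ref)
        mafe = np.abs(frac.to_numpy() - true).mean()
        assert mafe < 0.05

    def test_simplex_constraint(self, rng):
        ref = _reference(rng)
        bulk = rng.uniform(0.2, 0.8, size=(20, 40))
        frac, _ = deconvolve(make_beta(bulk, cpg_ids=list(ref.columns)), ref)
        vals = frac.to_numpy()
        assert (vals >= 0).all()
        np.testing.assert_allclose(vals.sum(axis=1), 1.0, atol=1e-9)

    def test_too_few_shared_cpgs(self, rng):
        ref = _reference(rng, n_cpgs=11)
        beta = make_beta(rng.uniform(size=(3, 11)), cpg_ids=list(ref.columns))
        with pytest.raises(ClockAuditError, match="shared"):
            deconvolve(beta, ref)

    def test_degenerate_reference(self, rng):
        ref = _reference(rng)
        ref.loc["Basophils"] = ref.loc["Eosinophils"]
        beta = make_beta(rng.uniform(size=(3, 40)), cpg_ids=list(ref.columns))
        with pytest.raises(ClockAuditError, match="degenerate"):
            deconvolve(beta, ref)


class TestFractionCorrelations:
    def _fractions(self, rng, n):
        raw = rng.dirichlet(np.full(12, 5.0), size=n)
        return pd.DataFrame(raw, index=[f"S{i}" for i in range(n)],
                            columns=list(CELL_TYPES))

    def test_monotone_transform_gives_rho_one(self, rng):
        frac = self._fractions(rng, 50)
        beta = make_beta((frac["Neutrophils"] ** 2).to_numpy()[:, None],
                         cpg_ids=["cg1"])
        rho, _ = fraction_correlations(beta, frac)
        assert rho.at["cg1", "Neutrophils"] == pytest.approx(1.0)

    def test_independent_cpg_uncorrelated(self, rng):
        frac = self._fractions(rng, 2000)
        beta = make_beta(rng.uniform(size=(2000, 1)), cpg_ids=["cg1"])
        rho, summary = fraction_correlations(beta, frac)
        assert rho.loc["cg1"].abs().max() < 0.1
        assert summary["share_below_threshold"] == 1.0

    def test_constant_column_flagged(self, rng):
        frac = self._fractions(rng, 30)
        frac["Basophils"] = 0.01
        beta = make_beta(rng.uniform(size=(30, 2)))
        rho, summary = fraction_correlations(beta, frac)
        assert rho["Basophils"].isna().all()
        assert summary["constant_cell_types"] == ["Basophils"]
        assert rho["NK"].notna().all()

    def test_too_few_samples(self, rng):
        frac = self._fractions(rng, 4)
        beta = make_beta(rng.uniform(size=(4, 2)))
        with pytest.raises(ClockAuditError, match=">= 5"):
            fraction_correlations(beta, frac)


class TestVIFAudit:
    def test_orthogonal_design(self):
        # exactly orthogonal CpGs and an orthogonal fraction column
        x1 = np.array([0.2, 0.8, 0.2, 0.8] * 4)
        x2 = np.array([0.2, 0.2, 0.8, 0.8] * 4)
        f = np.array([0.1, 0.9, 0.9, 0.1] * 4)
        beta = make_beta(np.column_stack([x1, x2]), cpg_ids=["cgA", "cgB"])
        frac = pd.DataFrame({"Neutrophils": f}, index=beta.data.index)
        audit = vif_audit(beta, frac)
        np.testing.assert_allclose(audit.baseline.to_numpy(), 1.0, atol=1e-10)
        np.testing.assert_allclose(audit.delta.to_numpy(), 0.0, atol=1e-10)

    def test_two_variable_closed_form(self, rng):
        x1 = rng.normal(size=500)
        x2 = 0.6 * x1 + rng.normal(size=500)
        lo, hi = min(x1.min(), x2.min()), max(x1.max(), x2.max())
        b = (np.column_stack([x1, x2]) - lo) / (hi - lo)
        beta = make_beta(b, cpg_ids=["cgA", "cgB"])
        frac = pd.DataFrame({"NK": rng.uniform(size=500)},
                            index=beta.data.index)
        audit = vif_audit(beta, frac)
        r = np.corrcoef(b[:, 0], b[:, 1])[0, 1]
        oracle = 1.0 / (1.0 - r ** 2)
        assert audit.baseline["cgA"] == pytest.approx(oracle, abs=1e-8)
        assert audit.baseline["cgB"] == pytest.approx(oracle, abs=1e-8)

    def test_delta_nonnegative(self, cohort):
        frac = cohort.true_fractions
        beta = BetaMatrix(cohort.beta.data[cohort.cpgs_of("mixture")])
        audit = vif_audit(beta, frac)
        finite = audit.delta.to_numpy()
        assert np.nanmin(finite) >= -1e-9

    def test_bin_arithmetic(self):
        assert bin_delta(0.01) == "small"
        assert bin_delta(0.03) == "moderate"
        assert bin_delta(0.07) == "large"
        assert bin_delta(0.5) == "very large"
        assert bin_delta(0.025) == "moderate"   # lower edge is inclusive
        assert bin_delta(0.1) == "very large"

    def test_perfect_collinearity_sentinel(self, rng):
        x = rng.uniform(0.2, 0.8, 30)
        beta = make_beta(np.column_stack([x, x / 2]), cpg_ids=["cgA", "cgB"])
        frac = pd.DataFrame({"NK": rng.uniform(size=30)}, index=beta.data.index)
        audit = vif_audit(beta, frac)
        assert np.isinf(audit.baseline).all()
        assert audit.n_infinite == 2

    def test_high_dimensional_subsample(self, rng, caplog):
        n, p = 30, 40
        beta = make_beta(rng.uniform(size=(n, p)))
        frac = pd.DataFrame({"NK": rng.uniform(size=n)}, index=beta.data.index)
        audit = vif_audit(beta, frac, seed=0)
        assert len(audit.baseline) == max(2, n // 5)

    def test_bad_thresholds(self, rng):
        beta = make_beta(rng.uniform(size=(30, 2)))
        frac = pd.DataFrame({"NK": rng.uniform(size=30)}, index=beta.data.index)
        with pytest.raises(ClockAuditError, match="ascending"):
            vif_audit(beta, frac, thresholds=(0.1, 0.05, 0.2))


class TestCompareModels:
    def test_duplicate_model_identical(self, cohort):
        cpgs = cohort.cpgs_of("mixture")[:10]
        model = ClockModel("dup", 0.0, dict.fromkeys(cpgs, 1.0))
        dist = compare_models_vif([model, model], cohort.beta,
                                  cohort.true_fractions)
        a = dist[dist["model"] == "dup"].reset_index(drop=True)
        # both entries collapse to the same rows
        assert len(a) == 2 * 12 * len(BIN_LABELS)
        first, second = a.iloc[: len(a) // 2], a.iloc[len(a) // 2:]
        np.testing.assert_allclose(first["share"].to_numpy(),
                                   second["share"].to_numpy())

    def test_mixture_model_more_collinear_with_fractions(self, cohort):
        mix_model = ClockModel(
            "mix", 0.0, dict.fromkeys(cohort.cpgs_of("mixture")[:12], 1.0))
        indep_model = ClockModel(
            "indep", 0.0,
            dict.fromkeys((cohort.cpgs_of("normal", "uniform",
                                          "homeostatic"))[:12], 1.0))
        dist = compare_models_vif([mix_model, indep_model], cohort.beta,
                                  cohort.true_fractions)
        big = dist[dist["bin"].isin(["large", "very large"])]
        mix_share = big[big["model"] == "mix"]["share"].mean()
        indep_share = big[big["model"] == "indep"]["share"].mean()
        assert mix_share > indep_share

    def test_independent_model_mostly_small_bins(self, cohort):
        indep_model = ClockModel(
            "indep", 0.0,
            dict.fromkeys((cohort.cpgs_of("normal", "uniform",
                                          "homeostatic"))[:12], 1.0))
        audit = vif_audit(model_cpg_beta(indep_model, cohort.beta),
                          cohort.true_fractions)
        share_small = audit.bin_distribution()["small"].mean()
        assert share_small >= 0.9
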