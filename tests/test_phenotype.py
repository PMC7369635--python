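"""Trait transform, age models, estimator gate, SRM map and its variants."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from srmtx import phenotype, synthetic
from srmtx.exceptions import (
    DegenerateInputError,
    EstimationError,
    InvalidConfigError,
)
from tests.conftest import make_trait_frame


def _trait_frame(t1, t2):
    n = len(t1)
    return pd.DataFrame(
        {
            "subject_id": [f"sub{i:04d}" for i in range(n)],
            "score_t1": t1,
            "score_t2": t2,
        }
    )


class TestTraitTransform:
    def test_mean_then_square_root(self):
        out = phenotype.combine_and_transform_trait(_trait_frame([0.16], [0.24]))
        assert out.loc[0, "combined_score"] == pytest.approx(0.20)
        assert out.loc[0, "transformed_score"] == pytest.approx(0.4472135955)

    def test_zero_maps_to_zero(self):
        out = phenotype.combine_and_transform_trait(_trait_frame([0.0], [0.0]))
        assert out.loc[0, "combined_score"] == 0.0
        assert out.loc[0, "transformed_score"] == 0.0

    def test_single_missing_timepoint_uses_observed(self):
        out = phenotype.combine_and_transform_trait(
            _trait_frame([np.nan, 0.3], [0.4, np.nan])
        )
        assert out["combined_score"].tolist() == pytest.approx([0.4, 0.3])

    def test_both_missing_dropped(self):
        out = phenotype.combine_and_transform_trait(
            _trait_frame([np.nan, 0.3], [np.nan, 0.5])
        )
        assert len(out) == 1 and out.loc[0, "subject_id"] == "sub0001"

    def test_negative_score_rejected(self):
        with pytest.raises(DegenerateInputError):
            phenotype.combine_and_transform_trait(_trait_frame([-0.1], [0.2]))

    @given(
        st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30)
    )
    def test_square_of_transform_recovers_combined(self, scores):
        out = phenotype.combine_and_transform_trait(
            _trait_frame(scores, scores[::-1])
        )
        assert np.allclose(
            out["transformed_score"] ** 2, out["combined_score"], atol=1e-12
        )


class TestAgeModel:
    def test_constant_mt(self):
        ages = pd.Series([15.0, 18.0, 21.0, 24.0])
        mt = pd.DataFrame({"r1": [2.0] * 4})
        fit = phenotype.fit_regional_age_model(mt, ages)
        assert fit.mt14["r1"] == pytest.approx(2.0, abs=1e-12)
        assert fit.dmt["r1"] == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(fit.residuals, 0.0, atol=1e-12)

    def test_exact_linear_model(self):
        ages = np.array([14.0, 16.0, 20.0, 25.0])
        mt = pd.DataFrame({"r1": 1.0 + 0.5 * (ages - 14.0)})
        fit = phenotype.fit_regional_age_model(mt, ages)
        assert fit.mt14["r1"] == pytest.approx(1.0, abs=1e-10)
        assert fit.dmt["r1"] == pytest.approx(0.5, abs=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        n = 200
        ages = rng.uniform(14, 25, n)
        mt = pd.DataFrame(
            {
                f"r{j}": 1.0 + 0.1 * j + (0.02 * j) * (ages - 14)
                + 0.1 * rng.standard_normal(n)
                for j in range(5)
            }
        )
        fit = phenotype.fit_regional_age_model(mt, ages)
        x = np.column_stack([np.ones(n), ages - 14.0])
        xtx_inv = np.linalg.inv(x.T @ x)
        for j, col in enumerate(mt.columns):
            beta = xtx_inv @ x.T @ mt[col].to_numpy()
            assert fit.mt14[col] == pytest.approx(beta[0], abs=1e-10)
            assert fit.dmt[col] == pytest.approx(beta[1], abs=1e-10)
        # residual orthogonality to the age regressor
        resid = fit.residuals.to_numpy()
        assert np.abs(resid.mean(axis=0)).max() < 1e-8
        assert np.abs((ages - 14.0) @ resid).max() / n < 1e-8

    def test_zero_age_variance_rejected(self):
        with pytest.raises(EstimationError):
            phenotype.fit_regional_age_model(
                pd.DataFrame({"r1": [1.0, 2.0, 3.0]}), np.array([16.0] * 3)
            )


class TestEstimatorGate:
    def test_normal_inputs_mostly_select_pearson(self):
        # both-variable Lilliefors gate at alpha=.05: P(pearson) ~ 0.95^2
        rng = np.random.default_rng(2024)
        picks = [
            phenotype.select_estimator(
                rng.standard_normal(500), rng.standard_normal(500)
            )
            for _ in range(400)
        ]
        assert picks.count("pearson") / len(picks) >= 0.85

    def test_skewed_input_selects_spearman(self):
        rng = np.random.default_rng(7)
        x = rng.exponential(1.0, 500) ** 2
        y = rng.standard_normal(500)
        assert phenotype.select_estimator(x, y) == "spearman"

    def test_constant_input_rejected(self):
        with pytest.raises(DegenerateInputError):
            phenotype.select_estimator(np.ones(20), np.arange(20.0))

    def test_rank_transformed_data_pearson_equals_spearman(self, rng):
        x = rng.standard_normal(50)
        y = rng.standard_normal(50)
        rx = pd.Series(x).rank().to_numpy()
        ry = pd.Series(y).rank().to_numpy()
        r_p, _ = phenotype.correlate(rx, ry, "pearson")
        r_s, _ = phenotype.correlate(x, y, "spearman")
        assert r_p == pytest.approx(r_s, abs=1e-12)


class TestSRMMap:
    def test_hand_oracle_pearson(self):
        r, _ = phenotype.correlate(
            np.array([1, 2, 3, 4, 5.0]), np.array([1, 3, 2, 5, 4.0]), "pearson"
        )
        assert r == pytest.approx(0.8, abs=1e-12)

    def test_trait_equal_to_one_region_residuals(self, rng):
        n = 60
        resid = pd.DataFrame(
            rng.standard_normal((n, 5)),
            index=[f"sub{i:04d}" for i in range(n)],
            columns=[f"r{j}" for j in range(5)],
        )
        resid -= resid.mean()
        fit = phenotype.AgeModelFit(
            mt14=pd.Series(0.0, index=resid.columns),
            dmt=pd.Series(0.0, index=resid.columns),
            residuals=resid,
        )
        trait = make_trait_frame(np.abs(resid["r0"].to_numpy()) ** 0.5)
        trait["transformed_score"] = resid["r0"].to_numpy()
        srm = phenotype.compute_srm(fit, trait)
        row = srm.set_index("region").loc["r0"]
        assert row["r"] == pytest.approx(1.0, abs=1e-10)
        assert row["q"] < 0.05 and row["sig_fdr"]

    def test_constant_trait_rejected(self, rng):
        resid = pd.DataFrame(
            rng.standard_normal((20, 3)),
            index=[f"sub{i:04d}" for i in range(20)],
        )
        fit = phenotype.AgeModelFit(
            mt14=pd.Series(0.0, index=resid.columns),
            dmt=pd.Series(0.0, index=resid.columns),
            residuals=resid,
        )
        with pytest.raises(DegenerateInputError):
            phenotype.compute_srm(fit, make_trait_frame(np.full(20, 0.4)))

    def test_fdr_dominates_p_and_is_monotone(self, default_dataset):
        subjects = default_dataset.subjects
        fit = phenotype.fit_regional_age_model(
            default_dataset.mt, subjects["age"]
        )
        trait = phenotype.combine_and_transform_trait(default_dataset.trait)
        srm = phenotype.compute_srm(fit, trait)
        tested = srm.dropna(subset=["p"])
        assert (tested["q"] >= tested["p"] - 1e-15).all()
        by_p = tested.sort_values("p")
        assert (np.diff(by_p["q"]) >= -1e-15).all()

    def test_small_region_flagged_not_tested(self, rng):
        resid = pd.DataFrame(
            rng.standard_normal((30, 2)),
            index=[f"sub{i:04d}" for i in range(30)],
            columns=["r0", "r1"],
        )
        resid.loc[resid.index[5:], "r1"] = np.nan
        fit = phenotype.AgeModelFit(
            mt14=pd.Series(0.0, index=resid.columns),
            dmt=pd.Series(0.0, index=resid.columns),
            residuals=resid,
        )
        trait = make_trait_frame(np.abs(rng.standard_normal(30)))
        srm = phenotype.compute_srm(fit, trait)
        row = srm.set_index("region").loc["r1"]
        assert row["estimator"] == "none" and np.isnan(row["p"])


class TestGlobalAssociation:
    def test_trait_equal_to_global_residual(self, rng):
        n = 80
        ages = pd.Series(rng.uniform(14, 25, n))
        mt = pd.DataFrame(
            rng.standard_normal((n, 6)) + 1.0,
            index=[f"sub{i:04d}" for i in range(n)],
        )
        fit = phenotype.fit_regional_age_model(
            mt.mean(axis=1).to_frame("g"), ages
        )
        trait = make_trait_frame(np.zeros(n))
        trait["transformed_score"] = fit.residuals["g"].to_numpy()
        r2, p = phenotype.global_association(mt, trait, ages)
        assert r2 == pytest.approx(1.0, abs=1e-10)

    def test_single_region_consistent_with_srm(self, rng):
        n = 100
        ages = pd.Series(rng.uniform(14, 25, n))
        mt = pd.DataFrame(
            {"only": rng.standard_normal(n)},
            index=[f"sub{i:04d}" for i in range(n)],
        )
        trait = make_trait_frame(np.abs(rng.standard_normal(n)))
        r2, p = phenotype.global_association(mt, trait, ages)
        fit = phenotype.fit_regional_age_model(mt, ages)
        srm = phenotype.compute_srm(fit, trait)
        assert r2 == pytest.approx(srm.loc[0, "r"] ** 2, abs=1e-12)
        assert p == pytest.approx(srm.loc[0, "p"], abs=1e-12)

    def test_null_calibration(self):
        # independent trait: rejection at alpha=.05 close to .05
        rejections = 0
        n_rep = 300
        for rep in range(n_rep):
            rng = np.random.default_rng(5000 + rep)
            n = 100
            ages = pd.Series(rng.uniform(14, 25, n))
            mt = pd.DataFrame(
                rng.standard_normal((n, 4)) + 1.0,
                index=[f"sub{i:04d}" for i in range(n)],
            )
            trait = make_trait_frame(np.abs(rng.standard_normal(n)))
            _, p = phenotype.global_association(mt, trait, ages)
            rejections += p < 0.05
        assert 0.02 <= rejections / n_rep <= 0.09


class TestCovariateAdjustment:
    def test_age_only_matches_unadjusted_for_age_orthogonal_trait(self, rng):
        # equality of the partial and MT-residual correlations is exact when
        # the trait carries no age signal; construct one orthogonal to age
        n = 120
        subjects = synthetic.generate_subjects(n, (14, 25), seed=3)
        ages = subjects["age"].to_numpy()
        x = np.column_stack([np.ones(n), ages - 14.0])
        raw = rng.standard_normal(n)
        orth = raw - x @ np.linalg.lstsq(x, raw, rcond=None)[0]
        mt = pd.DataFrame(
            rng.standard_normal((n, 6)) + 1.0,
            index=subjects["subject_id"].to_numpy(),
        )
        mt.columns = [f"r{j}" for j in range(6)]
        trait = make_trait_frame(np.zeros(n))
        trait["transformed_score"] = orth
        fit = phenotype.fit_regional_age_model(mt, ages)
        plain = phenotype.compute_srm(fit, trait)
        adjusted = phenotype.covariate_adjusted_srm(mt, trait, subjects, ["age"])
        assert np.allclose(plain["r"], adjusted["r"], atol=1e-10)

    def test_constant_covariate_rejected(self, rng):
        n = 40
        subjects = synthetic.generate_subjects(n, (14, 25), seed=1)
        subjects["flat"] = 1.0
        mt = pd.DataFrame(
            rng.standard_normal((n, 3)),
            index=subjects["subject_id"].to_numpy(),
        )
        trait = make_trait_frame(np.abs(rng.standard_normal(n)))
        with pytest.raises(EstimationError, match="flat|intercept"):
            phenotype.covariate_adjusted_srm(mt, trait, subjects, ["flat"])

    def test_planted_confounder_removed_by_adjustment(self, rng):
        n = 500
        subjects = synthetic.generate_subjects(n, (14, 25), seed=9)
        confounder = rng.standard_normal(n)
        subjects["ses"] = confounder
        trait_vals = confounder + 0.5 * rng.standard_normal(n)
        mt = pd.DataFrame(
            {"r0": confounder + 0.5 * rng.standard_normal(n),
             "r1": rng.standard_normal(n)},
            index=subjects["subject_id"].to_numpy(),
        )
        trait = make_trait_frame(np.zeros(n))
        trait["transformed_score"] = trait_vals
        fit = phenotype.fit_regional_age_model(mt, subjects["age"])
        plain = phenotype.compute_srm(fit, trait).set_index("region")
        adjusted = phenotype.covariate_adjusted_srm(
            mt, trait, subjects, ["ses"]
        ).set_index("region")
        assert plain.loc["r0", "r"] > 0.3
        assert abs(adjusted.loc["r0", "r"]) < 0.15


class TestEulerQC:
    def test_floor_rule_flags_expected_count(self, default_dataset):
        qc = phenotype.euler_qc(
            default_dataset.subjects, default_dataset.mt, 0.10
        )
        assert int(qc.excluded.sum()) == 24  # floor(0.10 * 248)

    def test_worst_euler_flagged_first(self, small_dataset):
        qc = phenotype.euler_qc(small_dataset.subjects, small_dataset.mt, 0.10)
        subjects = small_dataset.subjects.set_index("subject_id")
        flagged = subjects.loc[qc.excluded[qc.excluded].index, "euler_number"]
        kept = subjects.loc[qc.excluded[~qc.excluded].index, "euler_number"]
        assert flagged.max() <= kept.min()

    def test_zero_fraction_rejected(self, small_dataset):
        with pytest.raises(InvalidConfigError):
            phenotype.euler_qc(small_dataset.subjects, small_dataset.mt, 0.0)

    def test_independent_euler_calibrated(self):
        rejections = 0
        n_rep = 200
        for rep in range(n_rep):
            rng = np.random.default_rng(9000 + rep)
            n = 100
            subjects = pd.DataFrame(
                {
                    "subject_id": [f"sub{i:04d}" for i in range(n)],
                    "euler_number": -2 * rng.poisson(30, n),
                }
            )
            mt = pd.DataFrame(
                rng.standard_normal((n, 5)),
                index=subjects["subject_id"].to_numpy(),
            )
            qc = phenotype.euler_qc(subjects, mt, 0.10)
            rejections += qc.p_before < 0.05
        assert 0.01 <= rejections / n_rep <= 0.09
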