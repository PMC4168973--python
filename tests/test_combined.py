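import numpy as np
import pandas as pd
import pytest

from pathsurv.combined import (
    encode_clinical_features,
    fit_combined_model,
    stack_blocks,
    standardize_features,
)
from pathsurv.coxnet import FeatureMatrix, fit_cox_newton
from pathsurv.io import ClinicalTable, SurvivalOutcome
from pathsurv.model import PrognosisModel
from pathsurv.simulate import SimulationConfig, simulate_cohort


def make_clinical(rows):
    return ClinicalTable(pd.DataFrame(rows).T)


class TestEncodeClinical:
    def test_canonical_codes_pass_through(self):
        clin = make_clinical({
            "S1": {"grade": 2, "tumor_size_category": 2, "lymph_node": 1, "p53": 0, "er": 1, "pg": 0},
            "S2": {"grade": 3, "tumor_size_category": 4, "lymph_node": 0, "p53": 1, "er": 0, "pg": 1},
        })
        fm = encode_clinical_features(clin)
        assert fm.data.loc["tumor_size_category", "S1"] == 2
        assert fm.data.loc["lymph_node", "S1"] == 1
        assert all(b == "clinical" for b in fm.blocks.values())

    def test_missing_values_propagate(self):
        clin = make_clinical({
            "S1": {"grade": np.nan, "lymph_node": 1},
            "S2": {"grade": 2, "lymph_node": 0},
        })
        fm = encode_clinical_features(clin)
        assert np.isnan(fm.data.loc["grade", "S1"])

    def test_out_of_domain_code_rejected(self):
        with pytest.raises(ValueError, match="grade"):
            make_clinical({"S1": {"grade": 7}})


class TestStandardize:
    def test_three_point_feature(self):
        fm = FeatureMatrix(pd.DataFrame({"s1": [1.0], "s2": [2.0], "s3": [3.0]}, index=["f"]))
        out, params = standardize_features(fm)
        np.testing.assert_allclose(out.data.loc["f"].to_numpy(), [-1, 0, 1])
        assert params.means["f"] == 2.0

    def test_constant_feature_dropped_and_recorded(self):
        fm = FeatureMatrix(pd.DataFrame([[1.0, 1.0], [0.5, 2.5]], index=["const", "ok"], columns=["a", "b"]))
        out, params = standardize_features(fm)
        assert "const" not in out.data.index
        assert params.dropped == ["const"]

    def test_output_moments(self):
        rng = np.random.default_rng(1)
        fm = FeatureMatrix(pd.DataFrame(rng.normal(3, 2, (5, 40)),
                                        index=[f"f{i}" for i in range(5)],
                                        columns=[f"s{j}" for j in range(40)]))
        out, _ = standardize_features(fm)
        np.testing.assert_allclose(out.data.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.data.std(axis=1, ddof=1), 1.0, atol=1e-12)


class TestCombinedModel:
    def test_empty_clinical_block_reduces_to_genomic_fit(self, small_pds, small_cohort):
        _, _, _, surv, _ = small_cohort
        lambdas = None
        combined = fit_combined_model(small_pds, None, surv, n_repeats=3, seed=9, lambdas=lambdas)
        genomic = PrognosisModel.from_pds(small_pds, surv).fit(n_repeats=3, seed=9).risk_model
        assert combined.feature_names == genomic.feature_names
        np.testing.assert_allclose(combined.weights, genomic.weights, atol=1e-10)
        assert combined.pi_threshold == pytest.approx(genomic.pi_threshold)

    def test_block_stacking_order_invariance_of_pi(self, small_pds, small_cohort):
        # PI is a dot product over features: stacking order cannot matter
        _, _, clin, surv, _ = small_cohort
        fm = encode_clinical_features(clin)
        model = fit_combined_model(small_pds, fm, surv, n_repeats=3, seed=1)
        from pathsurv.prognosis import compute_prognostic_index

        stacked = stack_blocks(small_pds, fm)
        pi1 = compute_prognostic_index(model, stacked)
        reordered = stacked.data.iloc[::-1]
        pi2 = compute_prognostic_index(model, FeatureMatrix(reordered))
        np.testing.assert_allclose(pi1.to_numpy(), pi2.to_numpy(), atol=1e-12)

    def test_clinical_only_signal_selected(self):
        # hazard driven purely by the lymph-node covariate: the selector
        # should find it in nearly every replicate
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            cfg = SimulationConfig(
                n_samples=200, n_pathways=8, genes_per_pathway=8,
                n_causal_pathways=0, clinical_effect=1.5, seed=7000 + seed,
            )
            expr, sets, clin, surv, _ = simulate_cohort(cfg)
            from pathsurv.pds import compute_pds_matrix

            pds = compute_pds_matrix(expr, sets)
            fm = encode_clinical_features(clin)
            model = fit_combined_model(pds, fm, surv, n_repeats=3, seed=seed)
            sel = [f for f, w in zip(model.feature_names, model.weights) if w != 0]
            if "lymph_node" in sel:
                hits += 1
        assert hits >= 0.9 * n_seeds

    def test_both_blocks_informative_selects_from_both(self):
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            cfg = SimulationConfig(
                n_samples=200, n_pathways=8, genes_per_pathway=8,
                n_causal_pathways=2, effect_size=1.0, clinical_effect=1.2,
                seed=8000 + seed,
            )
            expr, sets, clin, surv, truth = simulate_cohort(cfg)
            from pathsurv.pds import compute_pds_matrix

            pds = compute_pds_matrix(expr, sets)
            model = fit_combined_model(pds, encode_clinical_features(clin), surv, n_repeats=3, seed=seed)
            sel = [f for f, w in zip(model.feature_names, model.weights) if w != 0]
            blocks = {model.blocks[f] for f in sel}
            if {"genomic", "clinical"} <= blocks:
                hits += 1
        assert hits >= 0.8 * n_seeds

    def test_lambda_zero_orthogonal_blocks_match_blockwise_newton(self):
        # small orthogonal design: unpenalized combined coefficients agree
        # with the stacked Newton MLE
        rng = np.random.default_rng(5)
        n = 80
        q, _ = np.linalg.qr(rng.standard_normal((n, 4)))
        X = q * np.sqrt(n)  # orthogonal columns, unit-ish variance
        beta = np.array([0.6, -0.4, 0.3, 0.0])
        t = -np.log(rng.random(n)) / (0.3 * np.exp(X @ beta))
        c = rng.uniform(0, 10, n)
        time, event = np.minimum(t, c), (t <= c).astype(int)
        ids = [f"s{i}" for i in range(n)]
        surv = SurvivalOutcome(pd.DataFrame({"time": time, "event": event}, index=ids))
        genomic = pd.DataFrame(X[:, :2].T, index=["g1", "g2"], columns=ids)
        clinical = FeatureMatrix(pd.DataFrame(X[:, 2:].T, index=["c1", "c2"], columns=ids),
                                 blocks={"c1": "clinical", "c2": "clinical"})
        model = fit_combined_model(genomic, clinical, surv, n_repeats=1, n_folds=3,
                                   seed=0, lambdas=np.array([0.0]))
        stacked, params = standardize_features(stack_blocks(genomic, clinical))
        Xs, tt, ee = stacked.align(surv)
        mle = fit_cox_newton(Xs, tt, ee)
        full = pd.Series(0.0, index=stacked.feature_names)
        full[model.feature_names] = model.weights
        np.testing.assert_allclose(full.to_numpy(), mle.coefficients, atol=1e-3)

    def test_too_few_complete_cases_rejected(self, small_pds, small_cohort):
        _, _, clin, surv, _ = small_cohort
        mangled = clin.data.copy()
        mangled.loc[mangled.index[5:], "grade"] = np.nan  # only 5 complete cases
        with pytest.raises(ValueError, match="complete-case"):
            fit_combined_model(small_pds, encode_clinical_features(ClinicalTable(mangled)), surv, n_repeats=2)
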