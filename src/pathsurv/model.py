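"""Model-object interface to the prognosis pipeline.

``PrognosisModel`` is built from a feature matrix (PDS rows, clinical rows,
or both) and a survival outcome; ``fit()`` runs lambda selection and the
penalized Cox fit and returns a ``PrognosisResults`` carrying the selected
features, coefficients, hazard ratios, the PI threshold and diagnostics, with
``summary()``, ``predict_index()``, ``assign_risk()`` and ``evaluate()``.

Typical use::

    pds = compute_pds_matrix(expr, gene_sets)
    model = PrognosisModel.from_pds(pds, survival)
    res = model.fit(seed=0, n_repeats=50)
    print(res.summary())
    assignment = res.assign_risk(pds.data)
    metrics = res.evaluate(pds.data, survival)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .combined import stack_blocks, standardize_features
from .coxnet import (
    FeatureMatrix,
    LambdaSelection,
    PenalizedCoxFit,
    UnivariateCoxResult,
    fit_cox_path,
    fit_univariate_cox,
    select_lambda,
)
from .evaluation import KMCurve, LogRankResult, ROCResult, km_estimate, roc_auc, weighted_logrank_test
from .io import ClinicalTable, ExpressionMatrix, GeneSetCollection, SurvivalOutcome
from .pds import PDSConfig, PDSMatrix, compute_pds_matrix
from .prognosis import RiskAssignment, RiskModel, compute_prognostic_index, dichotomize, select_pi_threshold

__all__ = ["PrognosisModel", "PrognosisResults"]


@dataclass
class EvaluationReport:
    """Risk-group evaluation on one cohort."""

    logrank: LogRankResult
    logrank_unweighted: LogRankResult
    roc: ROCResult
    km_high: KMCurve | None
    km_low: KMCurve | None
    n_high: int
    n_low: int

    @property
    def auc(self) -> float:
        return self.roc.auc

    @property
    def p_value(self) -> float:
        return self.logrank.p_value


class PrognosisModel:
    """Penalized Cox prognosis model over pathway and/or clinical features.

    Parameters
    ----------
    features : FeatureMatrix
        Features x samples, raw (unstandardized) scale.
    survival : SurvivalOutcome
        Relapse-free survival aligned by sample id.
    """

    def __init__(self, features: FeatureMatrix, survival: SurvivalOutcome):
        missing = [s for s in features.sample_ids if s not in set(survival.sample_ids)]
        if missing:
            raise ValueError(f"samples without survival outcome: {missing[:5]}")
        self.features = features
        self.survival = survival.loc(features.sample_ids)

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_pds(cls, pds: PDSMatrix, survival: SurvivalOutcome, clinical: ClinicalTable | None = None) -> "PrognosisModel":
        """Build from a PDS matrix, optionally stacking encoded clinical
        covariates as a second block (complete-case on clinical)."""
        from .combined import encode_clinical_features

        clin_fm = encode_clinical_features(clinical) if clinical is not None else None
        return cls(stack_blocks(pds, clin_fm), survival)

    @classmethod
    def from_expression(
        cls,
        expr: ExpressionMatrix,
        gene_sets: GeneSetCollection,
        survival: SurvivalOutcome,
        pds_config: PDSConfig | None = None,
        clinical: ClinicalTable | None = None,
    ) -> "PrognosisModel":
        """Transform expression to PDS, then build the model."""
        pds = compute_pds_matrix(expr, gene_sets, pds_config)
        model = cls.from_pds(pds, survival, clinical=clinical)
        model.pds = pds
        return model

    # -- fitting ------------------------------------------------------------

    def fit(
        self,
        n_repeats: int = 250,
        n_folds: int = 5,
        seed: int | None = None,
        lambdas: np.ndarray | None = None,
    ) -> "PrognosisResults":
        """Standardize, select lambda by repeated CV, fit, set the PI cutoff."""
        std, params = standardize_features(self.features)
        X, time, event = std.align(self.survival)
        selection = select_lambda(X, time, event, n_repeats=n_repeats, n_folds=n_folds, seed=seed, lambdas=lambdas)
        path = fit_cox_path(X, time, event, selection.lambdas[: selection.chosen_index + 1], feature_names=std.feature_names)
        fit = path[-1]
        relapse_fraction = float(event.mean())
        # the portable model keeps only the selected (nonzero-weight) features
        sel = fit.selected_features or []
        keep = [std.feature_names.index(f) for f in sel]
        risk_model = RiskModel(
            feature_names=sel,
            weights=fit.coefficients.to_numpy()[keep],
            pi_threshold=0.0,
            relapse_fraction=relapse_fraction,
            feature_means=params.means.to_numpy()[keep],
            feature_sds=params.sds.to_numpy()[keep],
            blocks={f: std.blocks.get(f, "") for f in sel},
            provenance={"lambda": selection.chosen_lambda, "n_repeats": n_repeats, "n_folds": n_folds, "seed": seed},
        )
        train_pi = compute_prognostic_index(risk_model, self.features)
        risk_model.pi_threshold = select_pi_threshold(train_pi, relapse_fraction)
        return PrognosisResults(model=self, risk_model=risk_model, fit=fit, selection=selection, train_pi=train_pi)


@dataclass
class PrognosisResults:
    """Fitted prognosis model: estimates, cutoff, diagnostics, predictors."""

    model: PrognosisModel
    risk_model: RiskModel
    fit: PenalizedCoxFit
    selection: LambdaSelection
    train_pi: pd.Series
    _univariate: dict[str, UnivariateCoxResult] = field(default_factory=dict, repr=False)

    @property
    def params(self) -> pd.Series:
        """Coefficients on the standardized scale (sparse; zeros not selected)."""
        return self.fit.coefficients

    @property
    def selected_features(self) -> list[str]:
        return self.fit.selected_features

    @property
    def hazard_ratios(self) -> pd.Series:
        return np.exp(self.params[self.params != 0.0]).rename("HR")

    @property
    def pi_threshold(self) -> float:
        return self.risk_model.pi_threshold

    def univariate(self, feature: str) -> UnivariateCoxResult:
        """Univariate Cox fit of one (standardized) feature; cached."""
        if feature not in self._univariate:
            std, _ = standardize_features(self.model.features)
            row = std.data.loc[feature]
            self._univariate[feature] = fit_univariate_cox(row, self.model.survival, name=feature)
        return self._univariate[feature]

    def summary(self) -> str:
        """Selected features with coefficients, hazard ratios and univariate
        Wald p-values, sorted by coefficient."""
        rows = []
        for f in sorted(self.selected_features, key=lambda f: -self.params[f]):
            uni = self.univariate(f)
            rows.append(
                {
                    "feature": f,
                    "block": self.risk_model.blocks.get(f, ""),
                    "coefficient": self.params[f],
                    "hazard_ratio": float(np.exp(self.params[f])),
                    "univariate_p": uni.p_value,
                }
            )
        df = pd.DataFrame(rows)
        n = self.model.features.data.shape[1]
        lines = [
            "Penalized Cox prognosis model",
            f"  samples: {n}   events: {int(self.model.survival.event.sum())}",
            f"  lambda: {self.risk_model.provenance.get('lambda'):.6g}   "
            f"selected features: {len(self.selected_features)}/{len(self.params)}",
            f"  PI threshold: {self.pi_threshold:.6g} "
            f"(high-risk fraction {self.risk_model.relapse_fraction:.3f})",
            "",
            df.to_string(index=False, float_format=lambda v: f"{v:.6g}") if len(df) else "  (no features selected)",
        ]
        return "\n".join(lines)

    # -- prediction / evaluation -------------------------------------------

    def predict_index(self, features: FeatureMatrix | pd.DataFrame) -> pd.Series:
        """PI on a (raw-scale) cohort using the training standardization."""
        return compute_prognostic_index(self.risk_model, features)

    def assign_risk(self, features: FeatureMatrix | pd.DataFrame, rethreshold_fraction: float | None = None) -> RiskAssignment:
        """Dichotomize a cohort at the training threshold (or, optionally,
        re-threshold at the given fraction of this cohort)."""
        pi = self.predict_index(features)
        thr = self.pi_threshold if rethreshold_fraction is None else select_pi_threshold(pi, rethreshold_fraction)
        return dichotomize(pi, thr)

    def evaluate(
        self,
        features: FeatureMatrix | pd.DataFrame,
        survival: SurvivalOutcome,
        rethreshold_fraction: float | None = None,
    ) -> EvaluationReport:
        """KM / weighted log-rank / ROC evaluation of the dichotomized cohort.

        The ROC uses PI as the score against the binary relapse flag.  When a
        risk group is empty the log-rank is reported as p = 1, statistic 0.
        """
        assign = self.assign_risk(features, rethreshold_fraction=rethreshold_fraction)
        ids = list(assign.pi.index)
        surv = survival.loc(ids)
        high = assign.high_mask.to_numpy()
        t, e = surv.time, surv.event
        if high.all() or (~high).all():
            lr = LogRankResult(0.0, 1.0, "gehan_wilcoxon", int(high.sum()), int((~high).sum()))
            lr_uw = LogRankResult(0.0, 1.0, "logrank", int(high.sum()), int((~high).sum()))
            km_h = km_estimate((t, e)) if high.all() else None
            km_l = km_estimate((t, e)) if (~high).all() else None
        else:
            lr = weighted_logrank_test((t[high], e[high]), (t[~high], e[~high]))
            lr_uw = weighted_logrank_test((t[high], e[high]), (t[~high], e[~high]), weighting="logrank")
            km_h = km_estimate((t[high], e[high]))
            km_l = km_estimate((t[~high], e[~high]))
        roc = roc_auc(assign.pi.to_numpy(), e)
        return EvaluationReport(
            logrank=lr, logrank_unweighted=lr_uw, roc=roc, km_high=km_h, km_low=km_l,
            n_high=int(high.sum()), n_low=int((~high).sum()),
        )
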