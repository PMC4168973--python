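"""Combined clinical + genomic modelling.

Clinical covariates are encoded ordinally (grade 1-3, tumor size category
1-4) or binary (lymph node, p53, ER, PG), then the clinical and PDS blocks
are re-standardized independently so every feature is on a standard-normal
scale and subject to the same L1 selection pressure.  The stacked matrix goes
through exactly the same lambda-selection and penalized-fit code path as the
genomic-only model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coxnet import FeatureMatrix, fit_cox_path, select_lambda
from .io import ClinicalTable, SurvivalOutcome
from .pds import PDSMatrix
from .prognosis import RiskModel, compute_prognostic_index, select_pi_threshold

logger = logging.getLogger(__name__)

__all__ = ["StandardizationParams", "encode_clinical_features", "standardize_features", "fit_combined_model"]


@dataclass
class StandardizationParams:
    """Training-derived per-feature mean and sd; zero-variance features are
    dropped and recorded."""

    means: pd.Series
    sds: pd.Series
    dropped: list[str]


def encode_clinical_features(clinical: ClinicalTable) -> FeatureMatrix:
    """ClinicalTable -> features x samples matrix with block label 'clinical'.

    Codes are already canonical in ClinicalTable (grade ordinal 1-3, size
    category ordinal 1-4, binaries 0/1); missing values propagate as NaN and
    are resolved by complete-case filtering at fit time.  Columns that are
    entirely missing are omitted.
    """
    df = clinical.data.T  # canonical fields x samples
    keep = df.index[df.notna().any(axis=1)]
    df = df.loc[keep]
    return FeatureMatrix(df.astype(float), blocks={f: "clinical" for f in df.index}, allow_missing=True)


def standardize_features(features: FeatureMatrix) -> tuple[FeatureMatrix, StandardizationParams]:
    """Center/scale each feature (row) to mean 0, sample sd 1.

    Zero-variance features are dropped with a warning and recorded in the
    returned parameters, which are kept for test-time reuse.
    """
    df = features.data
    if df.shape[1] < 2:
        raise ValueError("need >= 2 samples to standardize")
    means = df.mean(axis=1)
    sds = df.std(axis=1, ddof=1)
    dropped = list(df.index[(sds == 0) | sds.isna()])
    if dropped:
        logger.warning("standardize_features: dropping zero-variance feature(s) %s", dropped)
    keep = df.index.difference(dropped, sort=False)
    z = df.loc[keep].sub(means[keep], axis=0).div(sds[keep], axis=0)
    out = FeatureMatrix(
        z, standardized=True, blocks={f: features.blocks.get(f, "") for f in keep},
        allow_missing=features.allow_missing,
    )
    return out, StandardizationParams(means=means[keep], sds=sds[keep], dropped=dropped)


def stack_blocks(pds_matrix: PDSMatrix | FeatureMatrix | pd.DataFrame, clinical_features: FeatureMatrix | None) -> FeatureMatrix:
    """Stack genomic (PDS) and clinical blocks on shared samples.

    Samples missing any offered clinical feature are dropped (complete-case
    training).  Returns an unstandardized FeatureMatrix with block labels.
    """
    if isinstance(pds_matrix, PDSMatrix):
        genomic = pds_matrix.data
    elif isinstance(pds_matrix, FeatureMatrix):
        genomic = pds_matrix.data
    else:
        genomic = pd.DataFrame(pds_matrix)
    blocks = {f: "genomic" for f in genomic.index}
    if clinical_features is None or clinical_features.data.empty:
        stacked = genomic.copy()
    else:
        clin = clinical_features.data
        shared = [s for s in genomic.columns if s in clin.columns]
        clin = clin[shared]
        complete = clin.columns[clin.notna().all(axis=0)]
        if len(complete) < len(shared):
            logger.info("stack_blocks: dropped %d sample(s) with missing clinical values", len(shared) - len(complete))
        stacked = pd.concat([genomic[complete], clin[complete]])
        blocks.update({f: "clinical" for f in clin.index})
    return FeatureMatrix(stacked.astype(float), blocks=blocks)


def fit_combined_model(
    pds_matrix: PDSMatrix | FeatureMatrix | pd.DataFrame,
    clinical_features: FeatureMatrix | None,
    survival: SurvivalOutcome,
    n_repeats: int = 250,
    n_folds: int = 5,
    seed: int | None = None,
    lambdas: np.ndarray | None = None,
) -> RiskModel:
    """Fit the combined clinical + genomic prognosis model.

    The clinical and genomic blocks are standardized independently (each
    feature to standard normal), stacked, and passed through lambda selection
    and the penalized Cox fit; the PI threshold matches the training relapse
    fraction.  With an empty clinical block this reduces exactly to the
    genomic-only fit.
    """
    stacked = stack_blocks(pds_matrix, clinical_features)
    if stacked.data.shape[1] < 10:
        raise ValueError(f"only {stacked.data.shape[1]} complete-case samples (< 10)")
    std, params = standardize_features(stacked)
    X, time, event = std.align(survival)
    selection = select_lambda(X, time, event, n_repeats=n_repeats, n_folds=n_folds, seed=seed, lambdas=lambdas)
    path = fit_cox_path(X, time, event, selection.lambdas[: selection.chosen_index + 1], feature_names=std.feature_names)
    fit = path[-1]
    relapse_fraction = float(event.mean())
    sel = fit.selected_features or []
    keep = [std.feature_names.index(f) for f in sel]
    model = RiskModel(
        feature_names=sel,
        weights=fit.coefficients.to_numpy()[keep],
        pi_threshold=0.0,
        relapse_fraction=relapse_fraction,
        feature_means=params.means.to_numpy()[keep],
        feature_sds=params.sds.to_numpy()[keep],
        blocks={f: std.blocks.get(f, "") for f in sel},
        provenance={"lambda": selection.chosen_lambda, "n_repeats": n_repeats, "n_folds": n_folds, "seed": seed},
    )
    unstd = stack_blocks(pds_matrix, clinical_features)
    pi = compute_prognostic_index(model, unstd)
    model.pi_threshold = select_pi_threshold(pi, relapse_fraction)
    return model
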