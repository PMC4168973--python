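"""Pathway Deregulation Scores (PDS) via principal curves.

For each pathway, the member genes' standardized expression is reduced by PCA
and a principal curve is fitted through the samples in that space.  Each
sample's arc-length position along the curve, measured from a "normal
condition" origin end and min-max scaled, is its PDS: 0 at the origin, 1 at
the far extreme, higher meaning more deregulated.  Supplying normal-sample
ids anchors the origin at the curve end nearest their median position; for
tumor-only cohorts (no normal reference) the default rule orients the curve
by a deterministic reference gene so the direction is reproducible across
cohorts, and a "most typical sample" rule is available as an alternative.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .curves import DegenerateInputError, fit_principal_curve, project_to_curve
from .io import ExpressionMatrix, GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = ["PDSConfig", "PathwayScoringReport", "PDSMatrix", "compute_pathway_pds", "compute_pds_matrix"]


@dataclass
class PDSConfig:
    """Knobs of the pathway scoring pipeline.

    min_genes: smallest usable gene count after mapping and variance filtering.
    min_gene_std: genes with log2-scale sd below this are dropped as flat.
    pca_var_target: keep the fewest components reaching this cumulative
        explained variance, capped at min(max_pca_dims, #genes, #samples - 1).
    span / max_iter / tol: principal-curve smoother and stopping controls.
    normal_samples: optional ids anchoring the curve origin.
    """

    min_genes: int = 3
    min_gene_std: float = 0.1
    pca_var_target: float = 0.85
    max_pca_dims: int = 10
    span: float = 0.3
    max_iter: int = 50
    tol: float = 1e-3
    normal_samples: tuple[str, ...] | None = None
    anchor_rule: str = "reference_gene"  # or "typical_sample" (normals override both)


@dataclass
class PathwayScoringReport:
    pathway: str
    genes_requested: int
    genes_used: int
    pca_dims: int
    variance_explained: float
    converged: bool
    anchor_end: str  # "start" | "end"
    anchor_rule: str  # "normals" | "typical_sample"


@dataclass
class PDSMatrix:
    """Pathway x sample deregulation scores in [0, 1] with provenance."""

    data: pd.DataFrame
    reports: dict[str, PathwayScoringReport] = field(default_factory=dict)
    skipped: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = self.data.to_numpy()
        if vals.size and (np.isnan(vals).any() or vals.min() < -1e-12 or vals.max() > 1 + 1e-12):
            raise ValueError("PDS values must be finite and within [0, 1]")

    @property
    def pathway_names(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def to_tsv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.index.name = "pathway"
        out.to_csv(path, sep="\t", float_format="%.10g")

    def reports_to_json(self, path: str | Path) -> None:
        payload = {
            "reports": {k: asdict(v) for k, v in self.reports.items()},
            "skipped": self.skipped,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _pca_scores(z: np.ndarray, var_target: float, max_dims: int) -> tuple[np.ndarray, int, float]:
    """Project samples (rows of z) onto leading PCs; fix signs deterministically.

    Returns (scores, n_dims, cumulative variance explained).  Each component's
    sign is chosen so its largest-magnitude loading is positive.
    """
    n, g = z.shape
    zc = z - z.mean(axis=0)
    u, s, vt = np.linalg.svd(zc, full_matrices=False)
    var = s**2
    total = var.sum()
    frac = var / total if total > 0 else np.ones_like(var) / len(var)
    cum = np.cumsum(frac)
    cap = max(1, min(max_dims, g, n - 1))
    k = int(np.searchsorted(cum, var_target) + 1)
    k = min(k, cap)
    signs = np.sign(vt[np.arange(k), np.argmax(np.abs(vt[:k]), axis=1)])
    signs[signs == 0] = 1.0
    scores = (u[:, :k] * s[:k]) * signs
    return scores, k, float(cum[k - 1])


class PathwaySkipped(Exception):
    """Internal: pathway cannot be scored; message is the reason."""


def compute_pathway_pds(
    expr: ExpressionMatrix,
    genes: Sequence[str],
    config: PDSConfig | None = None,
    pathway: str = "",
) -> tuple[pd.Series, PathwayScoringReport]:
    """Score one pathway: returns per-sample PDS in [0, 1] and a report.

    Raises PathwaySkipped when fewer than ``min_genes`` usable genes remain.
    """
    cfg = config or PDSConfig()
    requested = len(genes)
    present = [g for g in genes if g in expr.data.index]
    if len(present) < cfg.min_genes:
        raise PathwaySkipped(f"only {len(present)}/{requested} gene(s) mapped (need {cfg.min_genes})")
    sub = expr.data.loc[present]                      # genes x samples
    sds = sub.std(axis=1, ddof=1)
    keep = sds[sds >= cfg.min_gene_std].index
    if len(keep) < cfg.min_genes:
        raise PathwaySkipped(
            f"only {len(keep)}/{requested} gene(s) pass sd >= {cfg.min_gene_std} (need {cfg.min_genes})"
        )
    sub = sub.loc[keep]
    sorted_keep_ids = list(keep)
    z = ((sub.T - sub.mean(axis=1)) / sub.std(axis=1, ddof=1)).to_numpy()  # samples x genes

    n_samples = z.shape[0]
    if n_samples < 3:
        raise PathwaySkipped(f"need >= 3 samples, got {n_samples}")
    scores, k, var_explained = _pca_scores(z, cfg.pca_var_target, cfg.max_pca_dims)

    if k == 1:
        # one-dimensional feature space: the curve is the real line itself,
        # lambda is the coordinate and the orthogonal distance is zero
        lam = scores[:, 0]
        converged = True
    else:
        try:
            curve = fit_principal_curve(scores, span=cfg.span, max_iter=cfg.max_iter, tol=cfg.tol)
        except DegenerateInputError as exc:
            raise PathwaySkipped(str(exc)) from None
        lam, _ = project_to_curve(scores, curve)
        converged = curve.converged

    lam_min, lam_max = float(lam.min()), float(lam.max())
    if lam_max - lam_min <= 0:
        raise PathwaySkipped("all samples project to a single curve location")

    # anchor the origin end.  With normal samples the origin is the curve end
    # nearer their median position.  Tumor-only cohorts have no biological
    # origin, so the default "reference_gene" rule makes the direction merely
    # reproducible: lambda is oriented to increase with the standardized
    # expression of a deterministic reference gene (the alphabetically first
    # member gene whose |correlation with lambda| is at least 0.3, falling
    # back to the best-correlated gene).  Because the reference is named, the
    # orientation transfers to any cohort sharing the pathway's genes and
    # trained Cox weights keep their meaning.  "typical_sample" anchors at
    # the end nearer the sample with the smallest mean |z| instead; it reads
    # as "distance from the most normal-looking patient" but its direction
    # can flip between cohorts when that sample sits mid-curve.
    sample_ids = list(expr.data.columns)
    if cfg.normal_samples:
        normal_idx = [i for i, s in enumerate(sample_ids) if s in set(cfg.normal_samples)]
        if not normal_idx:
            raise PathwaySkipped("none of the supplied normal samples are in the matrix")
        lam_ref = float(np.median(lam[normal_idx]))
        rule = "normals"
    elif cfg.anchor_rule == "reference_gene":
        lam_c = lam - lam.mean()
        denom = np.linalg.norm(lam_c)
        corrs = (z - z.mean(axis=0)).T @ lam_c
        norms = np.linalg.norm(z - z.mean(axis=0), axis=0) * denom
        corrs = np.divide(corrs, norms, out=np.zeros_like(corrs), where=norms > 0)
        gene_order = np.argsort(np.asarray(sorted_keep_ids, dtype=object))
        ref = next((g for g in gene_order if abs(corrs[g]) >= 0.3), int(np.argmax(np.abs(corrs))))
        lam_ref = lam_min if corrs[ref] >= 0 else lam_max
        rule = "reference_gene"
    elif cfg.anchor_rule == "typical_sample":
        typical = int(np.argmin(np.abs(z).mean(axis=1)))
        lam_ref = float(lam[typical])
        rule = "typical_sample"
    else:
        raise ValueError(f"unknown anchor_rule {cfg.anchor_rule!r}")
    if lam_ref <= (lam_min + lam_max) / 2:
        pds = (lam - lam_min) / (lam_max - lam_min)
        anchor = "start"
    else:
        pds = (lam_max - lam) / (lam_max - lam_min)
        anchor = "end"

    report = PathwayScoringReport(
        pathway=pathway,
        genes_requested=requested,
        genes_used=len(keep),
        pca_dims=k,
        variance_explained=var_explained,
        converged=converged,
        anchor_end=anchor,
        anchor_rule=rule,
    )
    return pd.Series(pds, index=sample_ids, name=pathway), report


def compute_pds_matrix(
    expr: ExpressionMatrix,
    gene_sets: GeneSetCollection,
    config: PDSConfig | None = None,
    seed: int | None = None,
) -> PDSMatrix:
    """Score every pathway in the collection; deterministic for fixed config.

    Pathways that cannot be scored are recorded in ``skipped`` with the
    reason; an entirely unscoreable collection is an error.  ``seed`` is
    recorded for provenance (the scoring pipeline itself is deterministic).
    """
    cfg = config or PDSConfig()
    rows: list[pd.Series] = []
    reports: dict[str, PathwayScoringReport] = {}
    skipped: dict[str, str] = {}
    for name, genes in gene_sets:
        try:
            series, report = compute_pathway_pds(expr, genes, cfg, pathway=name)
        except PathwaySkipped as exc:
            skipped[name] = str(exc)
            logger.info("pathway %s skipped: %s", name, exc)
            continue
        rows.append(series)
        reports[name] = report
        if not report.converged:
            logger.warning("pathway %s: principal curve did not converge", name)
    if not rows:
        raise ValueError(f"no scoreable pathway among {len(gene_sets)} (all skipped)")
    data = pd.DataFrame(rows)
    return PDSMatrix(data=data, reports=reports, skipped=skipped)
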