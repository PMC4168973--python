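"""Synthetic cohorts with pathway-structured expression and PH relapse.

Each pathway p has a per-sample latent deregulation score t_p ~ N(0, 1).
Gene g in pathway p expresses x = mu_g + a_g * t_p + eps with loadings a_g
drawn from a configured range with random sign and eps ~ N(0, sigma^2), on a
log2-like scale (baselines around 7).  Relapse times follow an exponential
proportional-hazards model with linear predictor sum_p gamma_p t_p +
gamma_c * lymph_node, drawn by inverse transform; censoring is independent
uniform on (0, horizon).  Gene sets are written reflecting true membership,
optionally with cross-pathway overlap in the annotation.  Defaults give a
cohort of 300 patients, 40 pathways of 15 genes, 4 causal pathways with unit
log-hazard effects, noise sd 0.5 and roughly 30% censoring.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import ClinicalTable, ExpressionMatrix, GeneSetCollection, SurvivalOutcome

__all__ = ["SimulationConfig", "GroundTruth", "simulate_cohort", "write_fixtures"]


@dataclass
class SimulationConfig:
    """Generator settings; defaults define the reference study conditions."""

    n_samples: int = 300
    n_pathways: int = 40
    genes_per_pathway: int = 15
    n_causal_pathways: int = 4
    effect_size: float = 1.0          # gamma_p, log-HR per unit latent score
    clinical_effect: float = 0.0      # gamma_c on lymph-node status
    loading_range: tuple[float, float] = (0.5, 1.5)
    noise_sd: float = 0.5             # sigma, log2 scale
    baseline_hazard: float = 0.35     # events per year at linear predictor 0
    censoring_horizon: float = 15.0   # years; uniform censoring on (0, horizon)
    overlap_fraction: float = 0.0     # extra cross-pathway genes in the annotation
    clinical_missing_fraction: float = 0.0
    seed: int = 0
    population_seed: int | None = None  # fixes truth (causal set, loadings) across cohorts

    def __post_init__(self) -> None:
        if self.n_causal_pathways > self.n_pathways:
            raise ValueError("n_causal_pathways cannot exceed n_pathways")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.censoring_horizon <= 0:
            raise ValueError("censoring_horizon must be positive")
        if not 0 <= self.overlap_fraction < 1:
            raise ValueError("overlap_fraction must be in [0, 1)")


@dataclass
class GroundTruth:
    causal_pathways: list[str]
    latent_scores: pd.DataFrame       # pathways x samples
    linear_predictor: pd.Series

    def to_json(self, path: str | Path) -> None:
        payload = {
            "causal_pathways": self.causal_pathways,
            "latent_scores": {p: self.latent_scores.loc[p].round(10).to_dict() for p in self.latent_scores.index},
            "linear_predictor": self.linear_predictor.round(10).to_dict(),
        }
        Path(path).write_text(json.dumps(payload, indent=2))


#: marginal prevalences emulating a mixed node-positive/negative cohort
CLINICAL_PREVALENCES = {
    "grade": ([1, 2, 3], [0.26, 0.52, 0.22]),
    "tumor_size_category": ([1, 2, 3, 4], [0.06, 0.40, 0.52, 0.02]),
    "lymph_node": ([0, 1], [0.66, 0.34]),
    "p53": ([0, 1], [0.77, 0.23]),
    "er": ([0, 1], [0.15, 0.85]),
    "pg": ([0, 1], [0.76, 0.24]),
}


def simulate_cohort(
    config: SimulationConfig | None = None,
) -> tuple[ExpressionMatrix, GeneSetCollection, ClinicalTable, SurvivalOutcome, GroundTruth]:
    """Draw one cohort; bit-identical for a fixed config (seeded)."""
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)
    # the population truth (gene baselines, loadings, causal identity, set
    # overlap) can be pinned across cohorts so a fresh cohort shares it
    pop_rng = np.random.default_rng(cfg.seed if cfg.population_seed is None else cfg.population_seed)
    n, P, G = cfg.n_samples, cfg.n_pathways, cfg.genes_per_pathway

    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    pathway_names = [f"PW_{p + 1:03d}" for p in range(P)]
    gene_ids = [f"PW{p + 1:03d}_G{g + 1:03d}" for p in range(P) for g in range(G)]

    mu = pop_rng.normal(7.0, 1.0, size=P * G)
    loadings = pop_rng.uniform(*cfg.loading_range, size=P * G) * pop_rng.choice([-1.0, 1.0], size=P * G)
    causal_idx = pop_rng.choice(P, size=cfg.n_causal_pathways, replace=False)
    t = rng.standard_normal((P, n))                       # latent scores
    noise = rng.normal(0.0, cfg.noise_sd, size=(P * G, n))
    expr_vals = mu[:, None] + loadings[:, None] * np.repeat(t, G, axis=0) + noise
    expr = ExpressionMatrix(pd.DataFrame(expr_vals, index=gene_ids, columns=sample_ids))

    entries: dict[str, list[str]] = {
        name: gene_ids[p * G : (p + 1) * G] for p, name in enumerate(pathway_names)
    }
    if cfg.overlap_fraction > 0:
        n_extra = int(round(cfg.overlap_fraction * G))
        for p, name in enumerate(pathway_names):
            own = set(entries[name])
            others = [g for g in gene_ids if g not in own]
            extra = pop_rng.choice(others, size=min(n_extra, len(others)), replace=False)
            entries[name] = entries[name] + list(extra)
    gene_sets = GeneSetCollection(entries, source="simulated")

    clin = pd.DataFrame(index=sample_ids, columns=list(CLINICAL_PREVALENCES), dtype=float)
    for field_name, (levels, probs) in CLINICAL_PREVALENCES.items():
        clin[field_name] = rng.choice(levels, size=n, p=probs).astype(float)
    if cfg.clinical_missing_fraction > 0:
        mask = rng.random(clin.shape) < cfg.clinical_missing_fraction
        clin = clin.mask(mask)
    clinical = ClinicalTable(clin)

    gamma = np.zeros(P)
    gamma[causal_idx] = cfg.effect_size
    lp = gamma @ t + cfg.clinical_effect * np.nan_to_num(clin["lymph_node"].to_numpy())
    u = rng.random(n)
    event_time = -np.log(u) / (cfg.baseline_hazard * np.exp(lp))
    censor_time = rng.uniform(0.0, cfg.censoring_horizon, size=n)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(float)
    time = np.maximum(time, 1e-6)
    survival = SurvivalOutcome(pd.DataFrame({"time": time, "event": event}, index=sample_ids))

    truth = GroundTruth(
        causal_pathways=[pathway_names[i] for i in sorted(causal_idx)],
        latent_scores=pd.DataFrame(t, index=pathway_names, columns=sample_ids),
        linear_predictor=pd.Series(lp, index=sample_ids, name="linear_predictor"),
    )
    return expr, gene_sets, clinical, survival, truth


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_fixtures(
    cohort: tuple[ExpressionMatrix, GeneSetCollection, ClinicalTable, SurvivalOutcome, GroundTruth],
    out_dir: str | Path,
) -> dict[str, str]:
    """Write the five cohort files; returns {relative name: sha256}.

    The written expression/GMT/clinical/survival files are re-readable by the
    io module with value identity.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    expr, gene_sets, clinical, survival, truth = cohort
    expr.to_tsv(out / "expression.tsv")
    gene_sets.to_gmt(out / "pathways.gmt")
    clinical.to_csv(out / "clinical.csv")
    survival.to_csv(out / "survival.csv")
    truth.to_json(out / "ground_truth.json")
    names = ["expression.tsv", "pathways.gmt", "clinical.csv", "survival.csv", "ground_truth.json"]
    manifest = {name: _sha256(out / name) for name in names}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
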