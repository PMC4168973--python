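"""Prognostic index, relapse-ratio-matched threshold, and risk groups.

The prognostic index PI_J = sum_i w_i X_iJ is the linear predictor (log
relative hazard) of the fitted Cox model.  The training cohort is split so
that the high-risk group size matches the training relapse fraction (for a
23% relapse cohort this is the 3rd-quartile cut: high vs low at 3-to-1); the
same threshold is then applied unchanged to test cohorts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .coxnet import FeatureMatrix

__all__ = ["RiskModel", "RiskAssignment", "compute_prognostic_index", "select_pi_threshold", "dichotomize"]


@dataclass
class RiskModel:
    """Portable prognosis model: features, Cox weights, scaling, PI cutoff."""

    feature_names: list[str]
    weights: np.ndarray
    pi_threshold: float
    relapse_fraction: float
    feature_means: np.ndarray | None = None  # training standardization, applied at predict time
    feature_sds: np.ndarray | None = None
    blocks: dict[str, str] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.feature_names) != len(self.weights):
            raise ValueError("feature names and weights must align 1:1")
        if not np.isfinite(self.pi_threshold):
            raise ValueError("threshold must be finite")
        for arr in (self.feature_means, self.feature_sds):
            if arr is not None and len(arr) != len(self.feature_names):
                raise ValueError("scaling parameters must align with features")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "feature_names": self.feature_names,
            "weights": self.weights.tolist(),
            "pi_threshold": self.pi_threshold,
            "relapse_fraction": self.relapse_fraction,
            "feature_means": None if self.feature_means is None else np.asarray(self.feature_means).tolist(),
            "feature_sds": None if self.feature_sds is None else np.asarray(self.feature_sds).tolist(),
            "blocks": self.blocks,
            "provenance": self.provenance,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "RiskModel":
        d = json.loads(Path(path).read_text())
        return cls(
            feature_names=d["feature_names"],
            weights=np.asarray(d["weights"], dtype=float),
            pi_threshold=d["pi_threshold"],
            relapse_fraction=d["relapse_fraction"],
            feature_means=None if d.get("feature_means") is None else np.asarray(d["feature_means"], float),
            feature_sds=None if d.get("feature_sds") is None else np.asarray(d["feature_sds"], float),
            blocks=d.get("blocks", {}),
            provenance=d.get("provenance", {}),
        )


@dataclass
class RiskAssignment:
    """Per-sample PI and risk group; high iff PI >= threshold (ties go high)."""

    pi: pd.Series
    threshold: float

    @property
    def group(self) -> pd.Series:
        return pd.Series(np.where(self.pi >= self.threshold, "high", "low"), index=self.pi.index)

    @property
    def high_mask(self) -> pd.Series:
        return self.pi >= self.threshold

    def to_tsv(self, path: str | Path) -> None:
        out = pd.DataFrame({"PI": self.pi, "group": self.group})
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t")


def compute_prognostic_index(
    model: RiskModel, features: FeatureMatrix | pd.DataFrame | Mapping[str, np.ndarray]
) -> pd.Series:
    """PI_J = sum_i w_i X_iJ, with the training standardization re-applied.

    ``features`` holds features in rows and samples in columns (raw scale when
    the model stores scaling parameters).  Every model feature must be
    present; a missing one is an error naming it.
    """
    df = features.data if isinstance(features, FeatureMatrix) else pd.DataFrame(features)
    missing = [f for f in model.feature_names if f not in df.index]
    if missing:
        raise KeyError(f"feature(s) required by the model are missing: {missing}")
    x = df.loc[model.feature_names].to_numpy(dtype=float)  # features x samples
    if model.feature_means is not None and model.feature_sds is not None:
        x = (x - model.feature_means[:, None]) / model.feature_sds[:, None]
    pi = model.weights @ x
    return pd.Series(pi, index=df.columns, name="PI")


def select_pi_threshold(train_pi: np.ndarray | pd.Series, relapse_fraction: float) -> float:
    """The k-th largest training PI with k = round(n * relapse_fraction).

    Matching the high-risk group size to the training relapse fraction, so a
    quarter-relapse cohort is cut at the 3rd quartile of PI (3-to-1 split).
    """
    pi = np.asarray(train_pi, dtype=float)
    if not 0 < relapse_fraction < 1:
        raise ValueError("relapse_fraction must be in (0, 1)")
    n = len(pi)
    k = int(round(n * relapse_fraction))
    if k < 1:
        raise ValueError(f"n * relapse_fraction = {n * relapse_fraction:.3g} < 1: no high-risk group")
    return float(np.sort(pi)[::-1][k - 1])


def dichotomize(pi: pd.Series | np.ndarray, threshold: float) -> RiskAssignment:
    """Assign high risk iff PI >= threshold.

    The threshold is the training threshold; it is never recomputed on test
    cohorts in the headline workflow (per-dataset re-thresholding is an
    explicit opt-in elsewhere).
    """
    if not isinstance(pi, pd.Series):
        pi = pd.Series(np.asarray(pi, dtype=float))
    if not np.isfinite(pi.to_numpy()).all():
        raise ValueError("PI values must be finite")
    return RiskAssignment(pi=pi.astype(float), threshold=float(threshold))
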