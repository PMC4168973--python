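"""Input readers, validated containers and expression preprocessing.

Expression matrices are log2-scale, genes (or probes) in rows and samples in
columns.  Gene sets travel in GMT.  Clinical covariates and relapse-free
survival come from delimited tables with a configurable column mapping.
Preprocessing covers many-to-one probe collapsing and between-array quantile
normalization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "GeneSetCollection",
    "ClinicalTable",
    "SurvivalOutcome",
    "read_expression_table",
    "read_gmt",
    "collapse_probes_to_genes",
    "quantile_normalize",
    "read_clinical_survival",
]

#: canonical clinical fields and their admissible coded values (NaN = missing)
CLINICAL_DOMAINS: dict[str, set[float]] = {
    "grade": {1.0, 2.0, 3.0},
    "tumor_size_category": {1.0, 2.0, 3.0, 4.0},
    "lymph_node": {0.0, 1.0},
    "p53": {0.0, 1.0},
    "er": {0.0, 1.0},
    "pg": {0.0, 1.0},
}


class ValidationError(ValueError):
    """Raised when an input table violates a container invariant."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    s = pd.Index(ids)
    if s.has_duplicates:
        dupes = s[s.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what} id(s): {dupes[:5]}")


@dataclass
class ExpressionMatrix:
    """Log2 expression, genes x samples, finite values, unique ids."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        _check_unique(df.index, "gene")
        _check_unique(df.columns, "sample")
        values = df.to_numpy()
        if values.size and not np.isfinite(values.astype(float, copy=False)).all():
            bad = np.argwhere(~np.isfinite(values.astype(float)))
            r, c = bad[0]
            raise ValidationError(
                f"non-finite expression value at gene {df.index[r]!r}, sample {df.columns[c]!r}"
            )
        self.data = df.astype(float)
        self.data.index = self.data.index.astype(str)
        self.data.columns = self.data.columns.astype(str)
        self.data.index.name = None
        self.data.columns.name = None

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def to_tsv(self, path: str | Path, id_label: str = "gene_id") -> None:
        out = self.data.copy()
        out.index.name = id_label
        out.to_csv(path, sep="\t", float_format="%.10g")


@dataclass
class GeneSetCollection:
    """Named pathway -> member gene ids (unique within a set, order kept)."""

    entries: dict[str, list[str]]
    source: str = ""
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.entries.items():
            if not genes:
                raise ValidationError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValidationError(f"gene set {name!r} has duplicate gene ids")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries.items())

    def names(self) -> list[str]:
        return list(self.entries)

    def subset(self, names: Sequence[str]) -> "GeneSetCollection":
        return GeneSetCollection(
            {n: list(self.entries[n]) for n in names},
            source=self.source,
            descriptions={n: self.descriptions.get(n, "") for n in names},
        )

    def to_gmt(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, genes in self.entries.items():
                desc = self.descriptions.get(name, "na") or "na"
                fh.write("\t".join([name, desc, *genes]) + "\n")


@dataclass
class ClinicalTable:
    """Per-sample clinical covariates on canonical ordinal/binary codes.

    Columns: grade (1-3), tumor_size_category (1-4 for <10, 10-20, 20-50,
    >50 mm), lymph_node, p53, er, pg (0/1).  Missing values are NaN.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample")
        df = self.data.reindex(columns=list(CLINICAL_DOMAINS)).astype(float)
        for col, domain in CLINICAL_DOMAINS.items():
            vals = df[col].dropna()
            bad = vals[~vals.isin(list(domain))]
            if len(bad):
                raise ValidationError(
                    f"clinical field {col!r}: value {bad.iloc[0]} for sample "
                    f"{bad.index[0]!r} outside domain {sorted(domain)}"
                )
        df.index = df.index.astype(str)
        df.index.name = None
        self.data = df

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def to_csv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.index.name = "sample_id"
        out.to_csv(path)


@dataclass
class SurvivalOutcome:
    """Right-censored relapse-free survival: time (> 0, years) and event flag."""

    data: pd.DataFrame  # columns: time, event

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample")
        df = self.data[["time", "event"]].astype(float)
        if (df["time"] <= 0).any():
            bad = df.index[df["time"] <= 0][0]
            raise ValidationError(f"non-positive survival time for sample {bad!r}")
        if not df["event"].isin([0.0, 1.0]).all():
            bad = df.index[~df["event"].isin([0.0, 1.0])][0]
            raise ValidationError(f"event flag outside {{0,1}} for sample {bad!r}")
        df.index = df.index.astype(str)
        df.index.name = None
        self.data = df

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def time(self) -> np.ndarray:
        return self.data["time"].to_numpy()

    @property
    def event(self) -> np.ndarray:
        return self.data["event"].to_numpy().astype(int)

    @property
    def event_fraction(self) -> float:
        return float(self.data["event"].mean())

    def loc(self, sample_ids: Sequence[str]) -> "SurvivalOutcome":
        return SurvivalOutcome(self.data.loc[list(sample_ids)].copy())

    def to_csv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.index.name = "sample_id"
        out.to_csv(path)


# ---------------------------------------------------------------------------
# readers


def _sep_for(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_expression_table(path: str | Path, orientation: str = "genes_by_samples") -> ExpressionMatrix:
    """Read a delimited expression table into a validated ExpressionMatrix.

    The first row holds sample ids, the first column row ids.  ``orientation``
    may be ``genes_by_samples`` (default) or ``samples_by_genes`` (transposed
    on read).  Duplicate header ids and non-numeric cells are rejected with
    the offending row/column named.
    """
    sep = _sep_for(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    _check_unique(header, "header")
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.columns = header
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any() and not df[col].isna().all():
            bad_rows = df.index[coerced.isna() & df[col].notna()]
            if len(bad_rows):
                raise ValidationError(
                    f"non-numeric value {df.loc[bad_rows[0], col]!r} at row "
                    f"{bad_rows[0]!r}, column {col!r} in {path}"
                )
        df[col] = coerced
    if orientation == "samples_by_genes":
        df = df.T
    elif orientation != "genes_by_samples":
        raise ValueError(f"unknown orientation {orientation!r}")
    return ExpressionMatrix(df)


def read_gmt(path: str | Path, source: str = "") -> GeneSetCollection:
    """Parse a GMT file (name, description, then member gene ids per line)."""
    entries: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not any(ln.strip() for ln in lines):
        logger.warning("GMT file %s is empty", path)
        return GeneSetCollection({}, source=source)
    for i, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValidationError(f"GMT line {i} has {len(fields)} field(s); need name, description, >=1 gene")
        name, desc, *genes = fields
        genes = [g for g in genes if g]
        deduped = list(dict.fromkeys(genes))
        if len(deduped) != len(genes):
            logger.warning("GMT set %s: %d duplicate gene id(s) removed", name, len(genes) - len(deduped))
        if name in entries:
            raise ValidationError(f"GMT line {i}: duplicate set name {name!r}")
        entries[name] = deduped
        descriptions[name] = desc
    return GeneSetCollection(entries, source=source, descriptions=descriptions)


def collapse_probes_to_genes(
    probe_matrix: ExpressionMatrix,
    probe_to_gene: Mapping[str, str],
    method: str = "mean_log2",
) -> ExpressionMatrix:
    """Collapse a probe-level log2 matrix to one row per gene.

    Multi-probe genes are summarized per sample by the arithmetic mean of the
    probes' log2 values (``mean_log2``, the default; equal to the log2 of the
    geometric mean of the raw intensities) or by the literal geometric mean of
    the log2 values (``geomean_log2``, requires positive log2 values).
    Unmapped probes are dropped and counted in the log.
    """
    if not probe_to_gene:
        raise ValidationError("empty probe-to-gene map")
    df = probe_matrix.data
    mapped = df.index[df.index.isin(probe_to_gene.keys())]
    n_dropped = df.shape[0] - len(mapped)
    if n_dropped:
        logger.info("collapse_probes_to_genes: dropped %d unmapped probe(s)", n_dropped)
    if not len(mapped):
        raise ValidationError("no probe in the matrix is covered by the map")
    sub = df.loc[mapped]
    genes = pd.Index([probe_to_gene[p] for p in mapped], name="gene_id")
    if method == "mean_log2":
        collapsed = sub.groupby(genes).mean()
    elif method == "geomean_log2":
        if (sub.to_numpy() <= 0).any():
            raise ValidationError("geomean_log2 requires strictly positive log2 values")
        collapsed = np.exp(np.log(sub).groupby(genes).mean())
    else:
        raise ValueError(f"unknown collapse method {method!r}")
    return ExpressionMatrix(collapsed)


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Between-array quantile normalization.

    Every sample column is mapped onto the common reference distribution (the
    across-sample mean of the sorted columns); ties within a column receive
    the mean of the quantile values they span, via average ranks.
    """
    df = matrix.data
    if df.shape[1] < 2:
        logger.warning("quantile_normalize: single sample, returning input unchanged")
        return ExpressionMatrix(df.copy())
    x = df.to_numpy(dtype=float)
    n = x.shape[0]
    reference = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    grid = np.arange(1, n + 1, dtype=float)
    for j in range(x.shape[1]):
        ranks = rankdata(x[:, j], method="average")
        out[:, j] = np.interp(ranks, grid, reference)
    return ExpressionMatrix(pd.DataFrame(out, index=df.index, columns=df.columns))


# ---------------------------------------------------------------------------
# clinical / survival

DEFAULT_CLINICAL_CONFIG: dict = {
    "sample_id": "sample_id",
    "time": "time",
    "event": "event",
    "time_unit": "years",
    "fields": {
        "grade": "grade",
        "tumor_size_category": "tumor_size_category",
        "lymph_node": "lymph_node",
        "p53": "p53",
        "er": "er",
        "pg": "pg",
    },
}

_STRING_CODES: dict[str, dict[str, float]] = {
    "lymph_node": {"positive": 1, "negative": 0},
    "er": {"positive": 1, "negative": 0},
    "pg": {"positive": 1, "negative": 0},
    "p53": {"mutated": 1, "wild type": 0, "wildtype": 0, "positive": 1, "negative": 0},
    "tumor_size_category": {"<10": 1, "10-20": 2, "10–20": 2, "20-50": 3, "20–50": 3, ">50": 4},
}

_MISSING_TOKENS = {"", "na", "nan", "none", "null", "missing"}


def _parse_clinical_value(field_name: str, raw) -> float:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return np.nan
    text = str(raw).strip()
    if text.lower() in _MISSING_TOKENS:
        return np.nan
    codes = _STRING_CODES.get(field_name, {})
    key = text.lower()
    if key in codes:
        return float(codes[key])
    try:
        return float(text)
    except ValueError:
        raise ValidationError(f"cannot interpret {raw!r} for clinical field {field_name!r}") from None


def read_clinical_table(path: str | Path) -> ClinicalTable:
    """Read a clinical-only CSV/TSV on canonical column names."""
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    parsed = pd.DataFrame(index=df.index, columns=list(CLINICAL_DOMAINS), dtype=float)
    for col in CLINICAL_DOMAINS:
        if col in df.columns:
            parsed[col] = [_parse_clinical_value(col, v) for v in df[col]]
    return ClinicalTable(parsed)


def read_survival_table(path: str | Path) -> SurvivalOutcome:
    """Read a survival-only CSV/TSV with columns time and event."""
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    return SurvivalOutcome(df[["time", "event"]].astype(float))


def read_clinical_survival(
    path: str | Path, config: Mapping | str | Path | None = None
) -> tuple[ClinicalTable, SurvivalOutcome]:
    """Read a delimited clinical + survival table.

    ``config`` maps the file's column names onto the canonical fields (a dict
    or a YAML file path); unspecified entries fall back to the canonical names
    themselves.  "NA"/empty cells become missing.  Times are converted to
    years when ``time_unit`` is ``months`` or ``days``.
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    cfg = {**DEFAULT_CLINICAL_CONFIG, **(dict(config or {}))}
    cfg["fields"] = {**DEFAULT_CLINICAL_CONFIG["fields"], **dict((config or {}).get("fields", {}))}

    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    df.columns = [c.strip() for c in df.columns]
    if cfg["sample_id"] not in df.columns:
        raise ValidationError(f"sample id column {cfg['sample_id']!r} not found in {path}")
    df = df.set_index(cfg["sample_id"])

    clin = pd.DataFrame(index=df.index, columns=list(CLINICAL_DOMAINS), dtype=float)
    for canonical, source_col in cfg["fields"].items():
        if source_col in df.columns:
            clin[canonical] = [_parse_clinical_value(canonical, v) for v in df[source_col]]

    for col, label in [(cfg["time"], "time"), (cfg["event"], "event")]:
        if col not in df.columns:
            raise ValidationError(f"required column {col!r} ({label}) not found in {path}")
    time = pd.to_numeric(df[cfg["time"]], errors="raise").astype(float)
    scale = {"years": 1.0, "months": 1.0 / 12.0, "days": 1.0 / 365.25}.get(cfg.get("time_unit", "years"))
    if scale is None:
        raise ValueError(f"unknown time_unit {cfg['time_unit']!r}")
    surv = pd.DataFrame({"time": time * scale, "event": pd.to_numeric(df[cfg["event"]]).astype(float)})
    return ClinicalTable(clin), SurvivalOutcome(surv)
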