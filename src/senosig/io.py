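"""Cohort tabular artifacts: expression matrices, clinical tables, gene lists.

Readers validate hard and fail loudly: duplicate identifiers, negative or
non-numeric intensities, non-positive follow-up times and unknown category
labels are rejected with the offending row/column named.  Missing covariate
cells are preserved as nulls and never imputed.
"""

from __future__ import annotations

import io as _io
import logging
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Cell contents treated as missing in categorical columns (case-insensitive).
MISSING_TOKENS = frozenset({"", "na", "nan"})

#: Canonical clinical covariates and their allowed category labels.
DEFAULT_VOCABULARY: dict[str, tuple[str, ...]] = {
    "sex": ("female", "male"),
    "t_stage": ("1", "2", "3", "4"),
    "n_stage": ("0", "1", "2", "3"),
    "m_stage": ("0", "1"),
    "stage": ("1", "2", "3", "4"),
    "grade": ("1", "2", "3"),
    "location": ("proximal", "distal"),
    "msi": ("stable", "stable_or_low", "high"),
}

COVARIATE_COLUMNS = tuple(DEFAULT_VOCABULARY)


class ValidationError(ValueError):
    """An input artifact violated a structural invariant."""


def _sep_for(path: Path) -> str:
    suffixes = [s.lower() for s in path.suffixes]
    return "," if ".csv" in suffixes else "\t"


class ExpressionMatrix:
    """Samples x genes matrix of nonnegative expression intensities.

    Wraps a pandas DataFrame (index = sample ids, columns = gene or probe
    ids) and enforces: unique ids, finite nonnegative values, at least two
    samples and one gene.
    """

    def __init__(self, values: pd.DataFrame):
        values = values.astype(float)
        idx_dup = values.index[values.index.duplicated()].unique()
        if len(idx_dup):
            raise ValidationError(f"duplicate sample ids: {list(idx_dup)}")
        col_dup = values.columns[values.columns.duplicated()].unique()
        if len(col_dup):
            raise ValidationError(f"duplicate gene ids: {list(col_dup)}")
        if values.shape[0] < 2 or values.shape[1] < 1:
            raise ValidationError(
                f"need >= 2 samples and >= 1 gene, got {values.shape}"
            )
        arr = values.to_numpy()
        if not np.isfinite(arr).all():
            i, j = np.argwhere(~np.isfinite(arr))[0]
            raise ValidationError(
                f"non-finite value at sample {values.index[i]!r}, "
                f"gene {values.columns[j]!r}"
            )
        if (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative intensity {arr[i, j]!r} at sample "
                f"{values.index[i]!r}, gene {values.columns[j]!r}"
            )
        self.data = values
        self.data.index.name = "sample_id"

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    @property
    def gene_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_genes(self) -> int:
        return self.data.shape[1]

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(sample_ids)])

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ExpressionMatrix({self.n_samples} samples x {self.n_genes} genes)"


def _check_duplicate_header(path: Path, sep: str) -> None:
    opener = _io.open
    if path.suffix == ".gz":
        import gzip

        opener = gzip.open  # type: ignore[assignment]
    with opener(path, "rt") as fh:  # type: ignore[arg-type]
        header = fh.readline().rstrip("\n").split(sep)
    body = header[1:]  # first field is the id column
    seen: set[str] = set()
    for name in body:
        if name in seen:
            raise ValidationError(f"duplicate column id {name!r} in {path}")
        seen.add(name)


def read_expression(
    path: str | Path, orientation: str = "samples_by_genes"
) -> ExpressionMatrix:
    """Read a TSV/CSV expression matrix (optionally gzip-compressed).

    ``orientation`` declares the file layout; the returned matrix is always
    canonical samples x genes.
    """
    if orientation not in ("samples_by_genes", "genes_by_samples"):
        raise ValueError(f"unknown orientation {orientation!r}")
    path = Path(path)
    sep = _sep_for(path)
    _check_duplicate_header(path, sep)
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        if df[col].dtype == object:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                row = df.index[bad.to_numpy().nonzero()[0][0]]
                raise ValidationError(
                    f"non-numeric cell at row {row!r}, column {col!r}"
                )
            df[col] = coerced
    if df.isna().to_numpy().any():
        i, j = np.argwhere(df.isna().to_numpy())[0]
        raise ValidationError(
            f"empty cell at row {df.index[i]!r}, column {df.columns[j]!r}"
        )
    if orientation == "genes_by_samples":
        df = df.T
    return ExpressionMatrix(df)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    """Write TSV/CSV; floats printed with up to 10 significant digits so a
    write/read round trip is exact for such values."""
    path = Path(path)
    expr.data.to_csv(path, sep=_sep_for(path), float_format="%.10g")


class ClinicalTable:
    """Per-sample survival outcome plus nullable clinical covariates.

    Required: ``sample_id`` (unique), ``time`` (months, > 0), ``event``
    (0/1).  ``dataset_id`` defaults to a single pseudo-dataset when absent.
    Categorical covariates are validated against a vocabulary and kept as
    strings; missing cells stay null.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        vocabulary: Optional[Mapping[str, Sequence[str]]] = None,
    ):
        vocab = dict(DEFAULT_VOCABULARY if vocabulary is None else vocabulary)
        df = data.copy()
        if df.index.name != "sample_id":
            if "sample_id" not in df.columns:
                raise ValidationError("missing required column 'sample_id'")
            df = df.set_index("sample_id")
        df.index = df.index.astype(str)
        dup = df.index[df.index.duplicated()].unique()
        if len(dup):
            raise ValidationError(f"duplicate sample ids: {list(dup)}")
        for col in ("time", "event"):
            if col not in df.columns:
                raise ValidationError(f"missing required column {col!r}")
        df["time"] = pd.to_numeric(df["time"], errors="raise").astype(float)
        if (df["time"] <= 0).any() or not np.isfinite(df["time"]).all():
            bad = df.index[(df["time"] <= 0) | ~np.isfinite(df["time"])][0]
            raise ValidationError(f"non-positive follow-up time for sample {bad!r}")
        ev = pd.to_numeric(df["event"], errors="raise")
        if not ev.isin([0, 1]).all():
            bad = df.index[~ev.isin([0, 1])][0]
            raise ValidationError(f"event not in {{0,1}} for sample {bad!r}")
        df["event"] = ev.astype(int)
        if "dataset_id" not in df.columns:
            df["dataset_id"] = "cohort"
        df["dataset_id"] = df["dataset_id"].astype(str)
        for col, levels in vocab.items():
            if col not in df.columns:
                continue
            cleaned = _clean_categorical(df[col], col, levels)
            df[col] = cleaned
        self.data = df
        self.vocabulary = vocab

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    @property
    def time(self) -> np.ndarray:
        return self.data["time"].to_numpy()

    @property
    def event(self) -> np.ndarray:
        return self.data["event"].to_numpy()

    @property
    def dataset_ids(self) -> pd.Series:
        return self.data["dataset_id"]

    def covariates_present(self) -> list[str]:
        return [c for c in COVARIATE_COLUMNS if c in self.data.columns]

    def subset(self, sample_ids: Sequence[str]) -> "ClinicalTable":
        return ClinicalTable(
            self.data.loc[list(sample_ids)].reset_index(), self.vocabulary
        )

    def __len__(self) -> int:
        return len(self.data)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"ClinicalTable({len(self)} samples, "
            f"{int(self.data['event'].sum())} events)"
        )


def _clean_categorical(
    series: pd.Series, name: str, levels: Sequence[str]
) -> pd.Series:
    def clean(value: object) -> object:
        if value is None or (isinstance(value, float) and np.isnan(value)):
            return None
        text = str(value).strip()
        if text.lower() in MISSING_TOKENS:
            return None
        # integer-coded levels may arrive as floats from pandas ("3.0")
        if text.endswith(".0") and text[:-2] in levels:
            text = text[:-2]
        if text not in levels:
            raise ValidationError(
                f"unknown label {text!r} for {name!r}; allowed: {list(levels)}"
            )
        return text

    return series.map(clean).astype(object)


def read_clinical(
    path: str | Path,
    vocabulary: Optional[Mapping[str, Sequence[str]]] = None,
    columns: Optional[Mapping[str, str]] = None,
) -> ClinicalTable:
    """Read a clinical TSV/CSV.

    ``columns`` optionally maps canonical names (``sample_id``, ``time``,
    ``event``, ``dataset_id``, covariates) to the file's column headers, as
    declared in a run-config YAML.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    if columns:
        rename = {src: canon for canon, src in columns.items() if src in df.columns}
        df = df.rename(columns=rename)
    return ClinicalTable(df, vocabulary)


def write_clinical(clin: ClinicalTable, path: str | Path) -> None:
    clin.data.to_csv(path, sep=_sep_for(Path(path)), na_rep="", float_format="%.10g")


def _round2(x: float) -> float:
    """Round half away from zero to 2 decimals (printed-table convention)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), ROUND_HALF_UP))


def clinical_summary(clin: ClinicalTable) -> pd.DataFrame:
    """Per-covariate category counts and percentages of non-missing records.

    Returns a tidy frame with columns ``feature``, ``category``, ``count``,
    ``percent`` (2 decimals, computed over non-missing records of that
    feature only).  Features entirely missing yield no rows.
    """
    if len(clin) == 0:
        raise ValidationError("empty clinical table")
    rows = []
    for feature in clin.covariates_present():
        col = clin.data[feature]
        observed = col[col.notna()]
        total = len(observed)
        if total == 0:
            continue
        counts = observed.value_counts()
        for category in clin.vocabulary.get(feature, counts.index):
            if category not in counts:
                continue
            n = int(counts[category])
            rows.append(
                {
                    "feature": feature,
                    "category": category,
                    "count": n,
                    "percent": _round2(100.0 * n / total),
                }
            )
    return pd.DataFrame(rows, columns=["feature", "category", "count", "percent"])


@dataclass(frozen=True)
class GeneListEntry:
    """One signature gene, optionally with its chosen probe and fixed weight."""

    gene_id: str
    probe_id: Optional[str] = None
    fixed_weight: Optional[int] = None

    def __post_init__(self) -> None:
        if self.fixed_weight is not None and self.fixed_weight not in (-1, 1):
            raise ValidationError(
                f"fixed weight for {self.gene_id!r} must be -1 or +1, "
                f"got {self.fixed_weight!r}"
            )


def read_gene_list(path: str | Path) -> list[GeneListEntry]:
    """Read a signature gene list (TSV, or XLSX first sheet).

    Expected columns: ``gene`` (required), ``probe``, ``weight`` — the shape
    of a published supplementary gene/probe/weight table.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path, sheet_name=0)
    else:
        df = pd.read_csv(path, sep=_sep_for(path))
    df.columns = [str(c).strip().lower() for c in df.columns]
    aliases = {"gene_id": "gene", "gene_symbol": "gene", "probe_id": "probe",
               "probe_set": "probe", "fixed_weight": "weight"}
    df = df.rename(columns=aliases)
    if "gene" not in df.columns:
        raise ValidationError("gene list needs a 'gene' column")
    entries: list[GeneListEntry] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        gene = str(row["gene"]).strip()
        if gene in seen:
            raise ValidationError(f"duplicate gene id {gene!r} in gene list")
        seen.add(gene)
        probe = None
        if "probe" in df.columns and pd.notna(row.get("probe")):
            probe = str(row["probe"]).strip()
        weight = None
        if "weight" in df.columns and pd.notna(row.get("weight")):
            weight = int(row["weight"])
        entries.append(GeneListEntry(gene, probe, weight))
    if not entries:
        raise ValidationError("empty gene list")
    return entries


class ProbeMap:
    """Probe -> gene map with a single 'chosen' (most dependable) probe per
    gene, the shape produced by probe-ranking methods such as JetSet."""

    def __init__(self, data: pd.DataFrame):
        df = data.copy()
        for col in ("probe_id", "gene_id", "chosen"):
            if col not in df.columns:
                raise ValidationError(f"probe map missing column {col!r}")
        df["probe_id"] = df["probe_id"].astype(str)
        df["gene_id"] = df["gene_id"].astype(str)
        if df["chosen"].dtype == object:
            df["chosen"] = df["chosen"].map(
                lambda v: str(v).strip().lower() in ("1", "true", "yes")
            )
        df["chosen"] = df["chosen"].astype(bool)
        dup = df["probe_id"][df["probe_id"].duplicated()].unique()
        if len(dup):
            raise ValidationError(f"duplicate probe ids: {list(dup)}")
        chosen = df[df["chosen"]]
        dup_gene = chosen["gene_id"][chosen["gene_id"].duplicated()].unique()
        if len(dup_gene):
            raise ValidationError(
                f"more than one chosen probe for gene(s): {list(dup_gene)}"
            )
        self.data = df

    def chosen_probes(self) -> pd.Series:
        """gene_id -> chosen probe_id."""
        chosen = self.data[self.data["chosen"]]
        return pd.Series(
            chosen["probe_id"].to_numpy(), index=chosen["gene_id"], name="probe_id"
        )


def read_probe_map(path: str | Path) -> ProbeMap:
    return ProbeMap(pd.read_csv(Path(path), sep=_sep_for(Path(path))))


def read_platform_probes(path: str | Path) -> set[str]:
    """Plain-text platform probe list, one id per line."""
    with open(path) as fh:
        probes = {line.strip() for line in fh if line.strip()}
    if not probes:
        raise ValidationError(f"empty platform probe list: {path}")
    return probes
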