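"""Readers and writers for every external format the pipeline touches.

All tabular formats are plain TSV. Expression tables are genes x samples
with the gene identifier in the first column; protein-interaction edges come
as three whitespace-separated columns in the STRING export dialect
(``protein1 protein2 score``); gene sets are GMT; clinical covariates and
MAF-style mutation records are TSV with named columns.

Gene and sample identifiers are treated as opaque case-sensitive strings;
no symbol/alias resolution is attempted. Writers emit a single ``#``-prefixed
header comment recording the package version so outputs are self-describing,
and every reader/writer pair round-trips losslessly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

TUMOR = "tumor"
NORMAL = "normal"

MICROSATELLITE_LEVELS = ("mss", "msi-l", "msi-h")

#: Variant classifications accepted in mutation tables (MAF vocabulary subset).
VARIANT_CLASSIFICATIONS = (
    "Missense_Mutation",
    "Nonsense_Mutation",
    "Silent",
    "Frame_Shift_Del",
    "Frame_Shift_Ins",
    "In_Frame_Del",
    "In_Frame_Ins",
    "Splice_Site",
    "Translation_Start_Site",
    "Nonstop_Mutation",
)

#: Columns a clinical table must carry (beyond the patient id in column 1).
CLINICAL_COLUMNS = (
    "survival_time",
    "event",
    "sex",
    "pathologic_stage",
    "retrospective_indicator",
    "race",
    "year_of_diagnosis",
    "age_at_diagnosis",
    "microsatellite_status",
)

_MUTATION_COLUMNS = (
    "Hugo_Symbol",
    "Tumor_Sample_Barcode",
    "Variant_Classification",
    "Variant_Type",
)


def _version_comment() -> str:
    from . import __version__

    return f"# ssnmark v{__version__}"


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with tumor/normal sample labels.

    ``values`` is a DataFrame indexed by gene id with sample ids as columns;
    ``sample_class`` maps every sample id to ``"tumor"`` or ``"normal"``.
    """

    values: pd.DataFrame
    sample_class: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise FormatError(f"duplicate gene id {dup!r}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise FormatError(f"duplicate sample id {dup!r}")
        self.sample_class = self.sample_class.reindex(self.values.columns)
        missing = self.sample_class.index[self.sample_class.isna()]
        if len(missing):
            raise ValidationError(f"samples missing a tumor/normal label: {list(missing[:5])}")
        bad = set(self.sample_class.unique()) - {TUMOR, NORMAL}
        if bad:
            raise ValidationError(f"unknown sample classes: {sorted(bad)}")
        if not np.all(np.isfinite(self.values.to_numpy(dtype=float))):
            raise ValidationError("expression values must be finite")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def samples_of_class(self, label: str) -> list[str]:
        return list(self.sample_class.index[self.sample_class == label])

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[list(sample_ids)], self.sample_class.loc[list(sample_ids)])

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(gene_ids)], self.sample_class)


@dataclass
class ScoredEdgeList:
    """Undirected scored edges; pairs stored in sorted order, no self-loops."""

    scores: dict[tuple[str, str], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[tuple[str, str], int] = {}
        for (a, b), s in self.scores.items():
            if a == b:
                continue
            key = (a, b) if a <= b else (b, a)
            if int(s) < 0:
                raise ValidationError(f"negative score on edge {key}")
            clean[key] = max(clean.get(key, 0), int(s))
        self.scores = clean

    @property
    def edges(self) -> set[tuple[str, str]]:
        return set(self.scores)

    def __len__(self) -> int:
        return len(self.scores)

    def __contains__(self, pair) -> bool:
        a, b = pair
        return ((a, b) if a <= b else (b, a)) in self.scores


@dataclass
class GeneSetCollection:
    """Named gene sets plus the size N of the reference gene universe.

    ``universe_size`` is the N of the hypergeometric over-representation
    test and must be supplied explicitly by the caller — it is a modelling
    choice, never inferred from the file.
    """

    sets: dict[str, set[str]]
    universe_size: int | None = None
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class ClinicalTable:
    """Per-patient survival outcome and covariates.

    Missing covariate values are preserved as NaN; downstream multivariate
    models apply complete-case filtering rather than imputation.
    """

    data: pd.DataFrame  # indexed by patient id

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise FormatError("duplicate patient ids")
        missing_cols = [c for c in CLINICAL_COLUMNS if c not in self.data.columns]
        if missing_cols:
            raise FormatError(f"clinical table missing columns: {missing_cols}")
        t = self.data["survival_time"]
        if (t.dropna() < 0).any():
            raise ValidationError("negative survival_time")
        ev = self.data["event"].dropna()
        if not set(ev.astype(int).unique()) <= {0, 1}:
            raise ValidationError("event must be 0 (censored) or 1 (death)")
        ms = self.data["microsatellite_status"].dropna()
        bad = set(ms.unique()) - set(MICROSATELLITE_LEVELS)
        if bad:
            raise ValidationError(f"unknown microsatellite status: {sorted(bad)}")

    @property
    def patient_ids(self) -> list[str]:
        return list(self.data.index)

    def complete_cases(self, columns=None) -> "ClinicalTable":
        """Patients with no missing value in ``columns`` (default: all)."""
        cols = list(columns) if columns is not None else list(self.data.columns)
        return ClinicalTable(self.data.dropna(subset=cols))


@dataclass
class MutationTable:
    """MAF-style somatic mutation records (4 required columns)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _MUTATION_COLUMNS if c not in self.data.columns]
        if missing:
            raise FormatError(f"mutation table missing columns: {missing}")
        bad = set(self.data["Variant_Classification"].unique()) - set(VARIANT_CLASSIFICATIONS)
        if bad:
            raise ValidationError(f"unknown variant classifications: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.data)


# ---------------------------------------------------------------------------
# expression


def read_expression_table(path, class_map: dict[str, str]) -> ExpressionMatrix:
    """Read a genes x samples TSV (first column gene id, header sample ids).

    ``class_map`` assigns every sample id a ``"tumor"``/``"normal"`` label.
    Rows with unparseable numeric values are rejected with a FormatError.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype=str)
    df.index = df.index.astype(str)
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"unparseable expression value in {path}: {exc}") from exc
    labels = pd.Series({s: class_map.get(s) for s in values.columns})
    if labels.isna().any():
        unlabeled = list(labels.index[labels.isna()])
        raise ValidationError(f"samples missing from class_map: {unlabeled[:5]}")
    return ExpressionMatrix(values, labels)


def write_expression_table(expr: ExpressionMatrix, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_version_comment() + " expression genes x samples\n")
        expr.values.to_csv(fh, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# scored edges


def read_scored_edges(path, min_score: int = 300) -> ScoredEdgeList:
    """Read a STRING-style edge export and keep edges with score > ``min_score``.

    The score filter is a strict inequality. Duplicate and reversed pairs
    collapse to one undirected edge keeping the maximum score; self-loops
    are dropped.
    """
    scores: dict[tuple[str, str], int] = {}
    first_content = True
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if first_content:
                first_content = False
                if not _is_int(fields[-1]):
                    continue  # header row
            if len(fields) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns, got {len(fields)}")
            a, b, raw = fields
            if not _is_int(raw):
                raise FormatError(f"{path}:{lineno}: non-integer score {raw!r}")
            score = int(raw)
            if a == b:
                continue
            key = (a, b) if a <= b else (b, a)
            scores[key] = max(scores.get(key, -1), score)
    kept = {pair: s for pair, s in scores.items() if s > min_score}
    return ScoredEdgeList(kept)


def write_scored_edges(edges: ScoredEdgeList, path) -> None:
    with open(path, "w") as fh:
        fh.write(_version_comment() + " scored edge list\n")
        fh.write("protein1\tprotein2\tscore\n")
        for (a, b), s in sorted(edges.scores.items()):
            fh.write(f"{a}\t{b}\t{s}\n")


def _is_int(s: str) -> bool:
    try:
        int(s)
        return True
    except ValueError:
        return False


# ---------------------------------------------------------------------------
# gene sets (GMT)


def read_gmt(path, universe_size: int | None = None) -> GeneSetCollection:
    """Read a GMT file: per line ``name<TAB>description<TAB>gene1<TAB>...``."""
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs >=3 fields")
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} has no genes")
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = set(genes)
            descriptions[name] = desc
    return GeneSetCollection(sets, universe_size, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# clinical


def read_clinical_table(path) -> ClinicalTable:
    """Read a TSV of per-patient survival outcome and covariates.

    First column is the patient id. Missing fields stay missing (NaN);
    negative survival times raise a ValidationError.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str)
    return ClinicalTable(df)


def write_clinical_table(clinical: ClinicalTable, path) -> None:
    with open(path, "w") as fh:
        fh.write(_version_comment() + " clinical covariates\n")
        clinical.data.to_csv(fh, sep="\t", index_label="patient_id")


# ---------------------------------------------------------------------------
# mutations


def read_mutation_table(path) -> MutationTable:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    return MutationTable(df)


def write_mutation_table(mutations: MutationTable, path) -> None:
    with open(path, "w") as fh:
        fh.write(_version_comment() + " mutation records\n")
        mutations.data.to_csv(fh, sep="\t", index=False)


def summarize_mutations(mutations: MutationTable) -> dict[str, pd.Series]:
    """Plain mutation summary: counts per classification and variant type,
    and genes ranked by the number of distinct mutated samples."""
    df = mutations.data
    if df.empty:
        empty = pd.Series(dtype=int)
        return {"by_classification": empty, "by_type": empty, "gene_ranking": empty}
    by_class = df["Variant_Classification"].value_counts()
    by_type = df["Variant_Type"].value_counts()
    gene_rank = (
        df.groupby("Hugo_Symbol")["Tumor_Sample_Barcode"].nunique().sort_values(ascending=False)
    )
    return {"by_classification": by_class, "by_type": by_type, "gene_ranking": gene_rank}
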