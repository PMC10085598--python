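"""Data model and readers/writers for the tabular formats the pipeline touches.

Conventions
-----------
* Expression is a genes x samples matrix of continuous, already-normalized
  (log-scale) values.  Gene identifiers are case-sensitive symbols; no alias
  resolution is attempted.
* Missing clinical categories are encoded as the explicit string ``unknown``
  and excluded pairwise from statistical tests, while percentages are
  reported over the full cohort size.
* All tables round-trip bit-identically through their write/read pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

UNKNOWN = "unknown"

GENDER_VOCAB = ("male", "female", UNKNOWN)

#: Variant classes counted as non-silent in mutation-frequency summaries.
NONSILENT_CLASSES = ("missense", "nonsense", "splice_site")

DEFAULT_CLASSIFICATION_MAP: dict[str, str] = {
    "Missense_Mutation": "missense",
    "Nonsense_Mutation": "nonsense",
    "Splice_Site": "splice_site",
    "Silent": "silent",
    "missense": "missense",
    "nonsense": "nonsense",
    "splice_site": "splice_site",
    "silent": "silent",
}


class FormatError(ValueError):
    """Raised when an input file violates the expected dialect."""


@dataclass
class ExpressionMatrix:
    """Genes x samples continuous expression values.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows indexed by gene symbol, columns by sample id.  Assumed to hold
        log-scale normalized expression; the only transform offered at load
        time is an optional ``log2(x+1)``.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        idx, cols = self.values.index, self.values.columns
        if idx.duplicated().any():
            raise ValueError(f"duplicate gene ids: {sorted(idx[idx.duplicated()])[:5]}")
        if cols.duplicated().any():
            raise ValueError(f"duplicate sample ids: {sorted(cols[cols.duplicated()])[:5]}")
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        present = [g for g in genes if g in self.values.index]
        missing = sorted(set(genes) - set(present))
        if missing:
            logger.warning("subset_genes: %d genes absent from matrix: %s",
                           len(missing), missing[:10])
        if not present:
            raise ValueError("no requested genes present in the matrix")
        return ExpressionMatrix(self.values.loc[present])

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[:, list(samples)])


@dataclass
class ClinicalTable:
    """Per-sample survival and covariates.

    ``data`` columns: sample_id, os_time (months), os_event {0,1}, age,
    gender, t_stage, n_stage, m_stage, tnm_stage, grade.  Categorical
    missingness is the explicit category ``unknown``; numeric missingness is
    NaN.
    """

    data: pd.DataFrame

    CATEGORICAL = ("gender", "t_stage", "n_stage", "m_stage", "tnm_stage", "grade")

    def __post_init__(self) -> None:
        df = self.data
        if df["sample_id"].duplicated().any():
            raise ValueError("duplicate sample ids in clinical table")
        known = df["os_event"].notna()
        times = df.loc[known & df["os_event"].isin([0, 1]), "os_time"]
        if (times.dropna() <= 0).any():
            raise ValueError("os_time must be positive where os_event is defined")
        if "gender" in df.columns:
            bad = set(df["gender"].dropna()) - set(GENDER_VOCAB)
            if bad:
                raise ValueError(f"gender values outside vocabulary: {bad}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"])

    def aligned(self, sample_ids: Sequence[str]) -> pd.DataFrame:
        return self.data.set_index("sample_id").loc[list(sample_ids)].reset_index()


@dataclass
class MutationTable:
    """MAF-like records of (sample_id, gene, variant_classification)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        for col in ("sample_id", "gene", "variant_classification"):
            if col not in df.columns:
                raise ValueError(f"mutation table missing column {col!r}")
        empty = (df["gene"].astype(str).str.len() == 0) | (df["sample_id"].astype(str).str.len() == 0)
        if empty.any():
            raise ValueError("mutation records with empty gene or sample id")


@dataclass
class CopyNumberTable:
    """Gene-level copy-number calls: one record per (gene, sample), state in {-2..2}."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        for col in ("gene", "sample_id", "cn_state"):
            if col not in df.columns:
                raise ValueError(f"copy-number table missing column {col!r}")
        if df.duplicated(subset=["gene", "sample_id"]).any():
            raise ValueError("duplicate (gene, sample) copy-number records")
        if not df["cn_state"].isin([-2, -1, 0, 1, 2]).all():
            raise ValueError("cn_state outside {-2,-1,0,1,2}")


@dataclass
class GeneSetCollection:
    """Named, non-empty sets of gene symbols with optional descriptions."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValueError(f"gene set {name!r} has duplicate genes")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)


@dataclass
class RegulatorPanel:
    """Ordered m6A regulator genes with writer/eraser/reader role annotations."""

    roles: dict[str, str]

    VALID_ROLES = ("writer", "eraser", "reader")

    def __post_init__(self) -> None:
        bad = {r for r in self.roles.values() if r not in self.VALID_ROLES}
        if bad:
            raise ValueError(f"invalid regulator roles: {bad}")

    @property
    def genes(self) -> list[str]:
        return list(self.roles)

    def by_role(self, role: str) -> list[str]:
        return [g for g, r in self.roles.items() if r == role]


#: Conventional 23-gene m6A regulator panel: 8 writers, 2 erasers, 13 readers.
DEFAULT_REGULATOR_PANEL = RegulatorPanel({
    "METTL3": "writer", "METTL14": "writer", "METTL16": "writer", "WTAP": "writer",
    "VIRMA": "writer", "ZC3H13": "writer", "RBM15": "writer", "RBM15B": "writer",
    "FTO": "eraser", "ALKBH5": "eraser",
    "YTHDC1": "reader", "YTHDC2": "reader", "YTHDF1": "reader", "YTHDF2": "reader",
    "YTHDF3": "reader", "HNRNPC": "reader", "HNRNPA2B1": "reader",
    "IGF2BP1": "reader", "IGF2BP2": "reader", "IGF2BP3": "reader",
    "FMR1": "reader", "LRPPRC": "reader", "RBMX": "reader",
})


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _sep_for(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_expression(path: str | Path, drop_incomplete: bool = True,
                    log2_transform: bool = False) -> ExpressionMatrix:
    """Read a delimited gene x sample expression matrix.

    First column holds gene ids, the header row sample ids.  Rows with any
    missing value are dropped (and counted in the log) when
    ``drop_incomplete`` is set.  Duplicate gene ids are collapsed by keeping
    the row with the highest mean.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty expression file") from exc
    if df.shape[1] == 0:
        raise FormatError(f"{path}: no sample columns")
    for col in df.columns:
        nonnum = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if nonnum.any():
            row = df.index[nonnum.argmax()]
            raise FormatError(f"{path}: non-numeric value at gene {row!r}, sample {col!r}")
        df[col] = pd.to_numeric(df[col])
    if drop_incomplete:
        incomplete = df.isna().any(axis=1)
        if incomplete.any():
            logger.info("read_expression: dropped %d incomplete rows", int(incomplete.sum()))
            df = df.loc[~incomplete]
    if df.index.duplicated().any():
        means = df.mean(axis=1)
        keep = (pd.DataFrame({"gene": df.index, "mean": means.values, "pos": range(len(df))})
                .sort_values(["gene", "mean", "pos"], ascending=[True, False, True])
                .drop_duplicates("gene"))
        n_dropped = len(df) - len(keep)
        logger.info("read_expression: collapsed %d duplicate gene rows (kept highest mean)", n_dropped)
        df = df.iloc[sorted(keep["pos"])]
    if log2_transform:
        df = np.log2(df + 1.0)
    df.index = df.index.astype(str)
    df.index.name = "gene"
    return ExpressionMatrix(df)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    df = expr.values.copy()
    df.index.name = "gene"
    df.to_csv(path, sep=_sep_for(path))


CLINICAL_COLUMNS = ["sample_id", "os_time", "os_event", "age", "gender",
                    "t_stage", "n_stage", "m_stage", "tnm_stage", "grade"]


def read_clinical(path: str | Path) -> ClinicalTable:
    df = pd.read_csv(path, sep=_sep_for(path))
    for col in CLINICAL_COLUMNS:
        if col not in df.columns:
            df[col] = UNKNOWN if col in ClinicalTable.CATEGORICAL else np.nan
    for col in ClinicalTable.CATEGORICAL:
        df[col] = df[col].fillna(UNKNOWN).astype(str)
    df["sample_id"] = df["sample_id"].astype(str)
    return ClinicalTable(df[CLINICAL_COLUMNS])


def write_clinical(clin: ClinicalTable, path: str | Path) -> None:
    clin.data.to_csv(path, sep=_sep_for(path), index=False)


def read_maf(path: str | Path,
             classification_map: Mapping[str, str] | None = None,
             sample_col: str = "sample_id", gene_col: str = "gene",
             class_col: str = "variant_classification") -> MutationTable:
    """Read a MAF-like delimited mutation table.

    Classifications not covered by ``classification_map`` are mapped to
    ``"other"`` and counted in the log; records with an empty gene or sample
    id are rejected with a count.
    """
    cmap = dict(DEFAULT_CLASSIFICATION_MAP if classification_map is None else classification_map)
    df = pd.read_csv(path, sep=_sep_for(path))
    for col in (sample_col, gene_col, class_col):
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    df = df.rename(columns={sample_col: "sample_id", gene_col: "gene",
                            class_col: "variant_classification"})
    df["gene"] = df["gene"].fillna("").astype(str)
    df["sample_id"] = df["sample_id"].fillna("").astype(str)
    bad = (df["gene"] == "") | (df["sample_id"] == "")
    if bad.any():
        logger.warning("read_maf: rejected %d records with empty gene/sample", int(bad.sum()))
        df = df.loc[~bad]
    known = df["variant_classification"].isin(cmap)
    if (~known).any():
        logger.info("read_maf: %d records with unrecognized classification mapped to 'other'",
                    int((~known).sum()))
    df["variant_classification"] = df["variant_classification"].map(cmap).fillna("other")
    return MutationTable(df[["sample_id", "gene", "variant_classification"]].reset_index(drop=True))


def write_maf(muts: MutationTable, path: str | Path) -> None:
    muts.data.to_csv(path, sep=_sep_for(path), index=False)


def read_copynumber(path: str | Path) -> CopyNumberTable:
    df = pd.read_csv(path, sep=_sep_for(path))
    df["gene"] = df["gene"].astype(str)
    df["sample_id"] = df["sample_id"].astype(str)
    df["cn_state"] = df["cn_state"].astype(int)
    return CopyNumberTable(df[["gene", "sample_id", "cn_state"]])


def write_copynumber(cn: CopyNumberTable, path: str | Path) -> None:
    cn.data.to_csv(path, sep=_sep_for(path), index=False)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT gene-set file: ``name <tab> description <tab> gene...``."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has <3 fields")
            name, desc, genes = fields[0], fields[1], fields[2:]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            deduped = list(dict.fromkeys(g for g in genes if g))
            sets[name] = deduped
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")
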