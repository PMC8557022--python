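"""Readers and writers for the plain-text formats the pipeline exchanges.

Matrices (betas, detection p, counts, M-values) travel as TSV with features
on rows and a header row of sample ids.  Interval tracks use BED6
(0-based half-open).  Gene sets use GMT.  Clock coefficients use the
two-column CSV convention with an ``(Intercept)`` row.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .errors import InvalidArgumentError

REQUIRED_SHEET_COLS = ("group", "age", "sex")
GROUPS = ("case", "control")


# ---------------------------------------------------------------- matrices

def read_matrix(path, index_name: str = "feature_id") -> pd.DataFrame:
    """Read a feature x sample TSV matrix (first column = feature id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = index_name
    return df


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


# ------------------------------------------------------------ sample sheet

def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    """Check the sample-sheet contract; returns the sheet unchanged.

    Required columns: ``group`` (case/control), ``age`` (>0 years), ``sex``
    (F/M).  Additional numeric columns are treated as covariates.  Sample
    ids (the index) must be unique and both groups must be non-empty.
    """
    for col in REQUIRED_SHEET_COLS:
        if col not in sheet.columns:
            raise InvalidArgumentError(f"sample sheet missing column '{col}'")
    if sheet.index.duplicated().any():
        raise InvalidArgumentError("sample ids must be unique")
    bad = set(sheet["group"]) - set(GROUPS)
    if bad:
        raise InvalidArgumentError(f"unknown group labels: {sorted(bad)}")
    for g in GROUPS:
        if (sheet["group"] == g).sum() == 0:
            raise InvalidArgumentError(f"group '{g}' is empty")
    if (sheet["age"] <= 0).any():
        raise InvalidArgumentError("ages must be positive")
    return sheet


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", index_col=0)
    sheet.index.name = "sample_id"
    return validate_sample_sheet(sheet)


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    sheet.to_csv(path, sep="\t")


# --------------------------------------------------------------- manifest

MANIFEST_COLS = [
    "chrom", "pos", "gene", "feature",
    "snp_associated", "non_cpg", "sex_chrom",
]


def read_manifest(path) -> pd.DataFrame:
    ann = pd.read_csv(
        path, sep="\t", index_col=0,
        dtype={"chrom": str, "gene": str, "feature": str},
    )
    ann.index.name = "probe_id"
    ann["gene"] = ann["gene"].fillna("")
    for col in ("snp_associated", "non_cpg", "sex_chrom"):
        ann[col] = ann[col].astype(bool)
    return ann


def write_manifest(ann: pd.DataFrame, path) -> None:
    ann.to_csv(path, sep="\t")


# -------------------------------------------------------------- PPI edges

def read_ppi(path) -> pd.DataFrame:
    ppi = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
    need = {"gene_a", "gene_b", "confidence"}
    if not need.issubset(ppi.columns):
        raise InvalidArgumentError(f"PPI table needs columns {sorted(need)}")
    return ppi


def write_ppi(ppi: pd.DataFrame, path) -> None:
    ppi.to_csv(path, sep="\t", index=False)


# -------------------------------------------------------------------- BED

def read_bed(path) -> pd.DataFrame:
    """Read BED (first 4+ columns); returns chrom/start/end/name."""
    bed = pd.read_csv(path, sep="\t", header=None, comment="#")
    bed = bed.iloc[:, :4]
    bed.columns = ["chrom", "start", "end", "name"]
    bed["chrom"] = bed["chrom"].astype(str)
    return bed


def write_bed6(df: pd.DataFrame, path) -> None:
    """Write chrom/start/end/name(/score/strand) as BED6."""
    out = df.copy()
    if "score" not in out.columns:
        out["score"] = 0
    if "strand" not in out.columns:
        out["strand"] = "."
    out[["chrom", "start", "end", "name", "score", "strand"]].to_csv(
        path, sep="\t", header=False, index=False
    )


# -------------------------------------------------------------------- GMT

def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT gene-set collection: name <tab> description <tab> genes..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def write_gmt(sets: dict[str, set[str]], path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "na", *sorted(genes)]) + "\n")


# ------------------------------------------------------------------- JSON

def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
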