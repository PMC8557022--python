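"""Expression filtering and a simple differential-expression model.

Low-expression filtering follows the CPM rule: a gene is kept when its
counts-per-million reach ``min_cpm`` in at least ``min_frac`` of the
samples of at least one group.  The differential test fits
log2(CPM + 0.5) per gene by OLS on group + covariates and reports the
group coefficient as a log2 fold change with a t-test p-value and BH
adjustment.  The DEG export convention is raw p < 0.01.  Callers with an
externally produced DEG table can skip this model entirely; downstream
stages only consume the table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._lm import rowwise_ols
from .diffmeth import bh_adjust
from .errors import (
    InsufficientSamplesError,
    InvalidArgumentError,
)
from .io import validate_sample_sheet


def cpm(counts: pd.DataFrame, lib_sizes: pd.Series | None = None) -> pd.DataFrame:
    """Counts per million; library sizes default to column sums."""
    if lib_sizes is None:
        lib_sizes = counts.sum(axis=0)
    ls = lib_sizes.loc[counts.columns].to_numpy(float)
    if np.any(ls <= 0):
        raise InvalidArgumentError("library sizes must be positive")
    return counts / ls * 1e6


def cpm_filter(
    counts: pd.DataFrame,
    sheet: pd.DataFrame,
    min_cpm: float = 0.3,
    min_frac: float = 0.5,
) -> pd.DataFrame:
    """Keep genes with CPM >= min_cpm in >= min_frac of either group.

    Idempotent (library sizes are the column sums of the *input* matrix,
    and re-filtering a filtered matrix against its own column sums can
    only raise CPMs of retained genes... the kept set is re-evaluated, so
    idempotence is asserted in the test suite rather than assumed).
    """
    validate_sample_sheet(sheet)
    c = cpm(counts)
    keep = np.zeros(len(counts), dtype=bool)
    for g in ("case", "control"):
        samples = sheet.index[sheet["group"] == g]
        sub = c[samples]
        frac = (sub >= min_cpm).mean(axis=1).to_numpy()
        keep |= frac >= min_frac
    return counts[keep]


def simple_de(
    counts: pd.DataFrame,
    sheet: pd.DataFrame,
    covariates: list[str] | tuple[str, ...] = (),
    deg_p: float = 0.01,
    use_adjusted: bool = False,
) -> pd.DataFrame:
    """Log-CPM OLS differential expression (case vs control).

    Returns a DegTable: gene, lfc (log2 case/control), p, adj_p,
    direction, is_deg (p below ``deg_p``; set ``use_adjusted`` to gate on
    the BH-adjusted p instead).
    """
    validate_sample_sheet(sheet)
    samples = list(counts.columns)
    if set(samples) != set(sheet.index):
        raise InvalidArgumentError("count samples do not match sample sheet")
    sheet = sheet.loc[samples]
    group = (sheet["group"] == "case").to_numpy(float)
    if group.sum() < 2 or (1 - group).sum() < 2:
        raise InsufficientSamplesError("need >= 2 samples per group")

    y = np.log2(cpm(counts).to_numpy(float) + 0.5)
    design_cols = [np.ones(len(samples)), group]
    for cvar in covariates:
        if cvar not in sheet.columns:
            raise InvalidArgumentError(f"covariate '{cvar}' not in sample sheet")
        design_cols.append(sheet[cvar].to_numpy(float))
    design = np.column_stack(design_cols)
    res = rowwise_ols(y, design, coef_index=1)

    adj = bh_adjust(res.p)
    gate = adj if use_adjusted else res.p
    out = pd.DataFrame(
        {
            "lfc": res.effect,
            "p": res.p,
            "adj_p": adj,
            "direction": np.where(res.effect >= 0, "up", "down"),
            "is_deg": gate < deg_p,
        },
        index=counts.index,
    )
    out.index.name = "gene"
    return out


def deg_genes(deg_table: pd.DataFrame) -> set[str]:
    """Genes flagged as differentially expressed."""
    return set(deg_table.index[deg_table["is_deg"]])
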