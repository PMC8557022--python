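"""Probe-level quality filtering and beta/M-value conversion.

Standard 450K-style probe QC: drop probes flagged as SNP-associated,
probes with an unreliable detection p-value in any sample, non-CpG
probes, and probes on the sex chromosomes.  Betas are modelled on the
M = log2(beta / (1 - beta)) scale for linear modelling.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .errors import InconsistentInputError, InvalidArgumentError


@dataclass
class QcReport:
    """Counts of probes removed, attributed in filter order (each once)."""

    removed_snp: int
    removed_detp: int
    removed_noncpg: int
    removed_sexchrom: int
    remaining: int

    @property
    def total_input(self) -> int:
        return (
            self.removed_snp + self.removed_detp + self.removed_noncpg
            + self.removed_sexchrom + self.remaining
        )

    def to_dict(self) -> dict:
        return asdict(self)


def filter_probes(
    beta: pd.DataFrame,
    detp: pd.DataFrame,
    ann: pd.DataFrame,
    detp_threshold: float = 0.05,
    min_failing_samples: int = 1,
) -> tuple[pd.DataFrame, QcReport]:
    """Apply the four probe filters in fixed order and report counts.

    Order: (1) SNP-associated, (2) detection p > `detp_threshold` in at
    least `min_failing_samples` samples, (3) non-CpG, (4) sex-chromosome.
    A probe failing several rules is counted only under the first.  The
    surviving probe *set* is order-invariant; only the attribution of the
    removal counts depends on the order.
    """
    probes = beta.index
    if not (set(probes) <= set(ann.index)):
        raise InconsistentInputError("beta matrix has probes absent from annotation")
    if list(detp.index) != list(probes) or list(detp.columns) != list(beta.columns):
        raise InconsistentInputError(
            "detection-p matrix must share probe ids and sample ids with betas"
        )
    ann = ann.loc[probes]

    snp = ann["snp_associated"].to_numpy(bool)
    fail = (detp.to_numpy(float) > detp_threshold).sum(axis=1) >= min_failing_samples
    noncpg = ann["non_cpg"].to_numpy(bool)
    sexchr = ann["sex_chrom"].to_numpy(bool)

    removed = np.zeros(len(probes), dtype=bool)
    counts = []
    for mask in (snp, fail, noncpg, sexchr):
        new = mask & ~removed
        counts.append(int(new.sum()))
        removed |= new

    keep = ~removed
    report = QcReport(
        removed_snp=counts[0],
        removed_detp=counts[1],
        removed_noncpg=counts[2],
        removed_sexchrom=counts[3],
        remaining=int(keep.sum()),
    )
    return beta.loc[keep], report


def beta_to_m(beta: pd.DataFrame, eps: float = 1e-3) -> pd.DataFrame:
    """Convert betas to M-values, clipping betas to [eps, 1-eps] first."""
    if not (0.0 < eps < 0.5):
        raise InvalidArgumentError("eps must lie in (0, 0.5)")
    b = np.clip(beta.to_numpy(float), eps, 1.0 - eps)
    m = np.log2(b / (1.0 - b))
    return pd.DataFrame(m, index=beta.index, columns=beta.columns)


def m_to_beta(m: pd.DataFrame) -> pd.DataFrame:
    """Inverse of :func:`beta_to_m` (exact for betas inside the clip range)."""
    x = np.exp2(m.to_numpy(float))
    return pd.DataFrame(x / (1.0 + x), index=m.index, columns=m.columns)
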