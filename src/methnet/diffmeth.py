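"""Differential methylation: per-CpG linear models and kernel DMR calling.

Site-level analysis fits, per probe, an OLS model of the M-value on group
plus covariates, optionally with empirical-Bayes variance moderation, and
reports the case-minus-control effect with a Benjamini-Hochberg adjusted
p-value.  The effect size used throughout for filtering is delta-beta, the
case-control difference of mean betas (the interpretable methylation
fraction scale).

Region calling smooths the per-probe squared t statistic along each
chromosome with a Gaussian kernel, flags probes significant either by site
FDR or by an extreme smoothed statistic, merges nearby significant probes
into candidate regions, scores each region by Fisher's combination of
member p-values, and keeps regions passing a region-level FDR and a
minimum absolute mean delta-beta (default 10%).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._lm import moderate, rowwise_ols
from .errors import (
    InconsistentInputError,
    InsufficientSamplesError,
    InvalidArgumentError,
)
from .io import validate_sample_sheet


@dataclass
class DmrParams:
    """Tuning parameters for region calling.

    lambda_bp
        Gaussian kernel bandwidth and merge distance, base pairs.
    min_cpgs
        Minimum CpGs for a candidate region to be reported.
    site_fdr
        Site-level significance: BH-adjusted p <= site_fdr, or smoothed
        statistic above its (1 - site_fdr) quantile.
    site_nominal_p
        Raw-p gate on the smoothed-statistic track: a probe flagged only
        by smoothing must also reach this nominal p, so the kernel does
        not sweep plainly null neighbours of a strong locus into regions.
    region_fdr
        BH threshold on the Fisher-combined region p-values.
    min_mean_delta_beta
        Minimum |mean delta-beta| for a reported region.
    """

    lambda_bp: float = 1000.0
    min_cpgs: int = 2
    site_fdr: float = 0.05
    site_nominal_p: float = 0.05
    region_fdr: float = 0.05
    min_mean_delta_beta: float = 0.10

    def validate(self) -> "DmrParams":
        if self.lambda_bp <= 0:
            raise InvalidArgumentError("lambda_bp must be > 0")
        for name in ("site_fdr", "site_nominal_p", "region_fdr", "min_mean_delta_beta"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise InvalidArgumentError(f"{name} must lie in (0, 1)")
        if self.min_cpgs < 1:
            raise InvalidArgumentError("min_cpgs must be >= 1")
        return self


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise InvalidArgumentError("p must be a 1-d vector")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise InvalidArgumentError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest p downwards
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def fit_dms(
    m_values: pd.DataFrame,
    beta: pd.DataFrame,
    sheet: pd.DataFrame,
    covariates: list[str] | tuple[str, ...] = (),
    moderate_var: bool = True,
    ann: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-probe differential methylation between cases and controls.

    Fits M ~ group + covariates by OLS for every probe; the reported
    ``effect`` is the case-minus-control coefficient in M-units, ``t`` its
    (optionally moderated) statistic, ``delta_beta`` the difference of
    group mean betas.  Returns a DmsTable sorted like the input, with
    chrom/pos attached when an annotation is supplied.
    """
    validate_sample_sheet(sheet)
    samples = list(m_values.columns)
    if set(samples) != set(sheet.index):
        raise InconsistentInputError("M-value samples do not match sample sheet")
    if list(beta.index) != list(m_values.index) or list(beta.columns) != samples:
        raise InconsistentInputError("beta and M matrices must align")
    sheet = sheet.loc[samples]
    group = (sheet["group"] == "case").to_numpy(float)
    if group.sum() < 2 or (1 - group).sum() < 2:
        raise InsufficientSamplesError("need >= 2 samples per group")
    for c in covariates:
        if c not in sheet.columns:
            raise InvalidArgumentError(f"covariate '{c}' not in sample sheet")

    design_cols = [np.ones(len(samples)), group]
    for c in covariates:
        design_cols.append(sheet[c].to_numpy(float))
    design = np.column_stack(design_cols)

    res = rowwise_ols(m_values.to_numpy(float), design, coef_index=1)
    if moderate_var:
        t, p, df, _, _ = moderate(res)
    else:
        t, p, df = res.t, res.p, float(res.df_resid)

    case = group.astype(bool)
    b = beta.to_numpy(float)
    delta_beta = b[:, case].mean(axis=1) - b[:, ~case].mean(axis=1)

    out = pd.DataFrame(
        {
            "effect": res.effect,
            "delta_beta": delta_beta,
            "t": t,
            "df": df,
            "p": p,
            "adj_p": bh_adjust(p),
        },
        index=m_values.index,
    )
    out.index.name = "probe_id"
    if ann is not None:
        out.insert(0, "chrom", ann.loc[out.index, "chrom"].to_numpy())
        out.insert(1, "pos", ann.loc[out.index, "pos"].to_numpy())
    return out


def _smooth_chrom(pos: np.ndarray, stat: np.ndarray, lam: float) -> np.ndarray:
    """Nadaraya-Watson smooth of `stat` over `pos` with Gaussian kernel sd=lam.

    Contributions beyond 4*lam are negligible and skipped via windowing.
    """
    n = len(pos)
    out = np.empty(n)
    window = 4.0 * lam
    lo = np.searchsorted(pos, pos - window, side="left")
    hi = np.searchsorted(pos, pos + window, side="right")
    for i in range(n):
        d = (pos[lo[i]:hi[i]] - pos[i]) / lam
        w = np.exp(-0.5 * d * d)
        out[i] = np.dot(w, stat[lo[i]:hi[i]]) / w.sum()
    return out


def call_dmrs(
    dms: pd.DataFrame,
    ann: pd.DataFrame,
    params: DmrParams | None = None,
) -> pd.DataFrame:
    """Kernel-based DMR calling from a site-level DmsTable.

    Steps: smooth t^2 per chromosome (bandwidth ``lambda_bp``); flag a
    probe significant if its BH-adjusted p <= site_fdr OR its smoothed
    statistic exceeds the (1 - site_fdr) quantile of all smoothed
    statistics; merge significant probes within ``lambda_bp`` bp; keep
    candidates with >= min_cpgs members; combine member raw p-values by
    Fisher's method, BH across regions; keep fdr < region_fdr and
    |mean delta-beta| >= min_mean_delta_beta.

    Coordinates in the returned table are 0-based half-open.
    """
    params = (params or DmrParams()).validate()
    missing = set(dms.index) - set(ann.index)
    if missing:
        raise InconsistentInputError(
            f"{len(missing)} DMS probes missing from annotation"
        )
    tab = dms.copy()
    tab["chrom"] = ann.loc[tab.index, "chrom"].to_numpy()
    tab["pos"] = ann.loc[tab.index, "pos"].to_numpy()
    try:
        tab = tab.sort_values(["chrom", "pos"])
    except TypeError as exc:  # unsortable position/chrom dtypes
        raise InconsistentInputError("DMS table is not sortable by (chrom, pos)") from exc

    # 1) smoothed squared statistic per chromosome
    smoothed = np.empty(len(tab))
    for _, idx in tab.groupby("chrom", sort=False).indices.items():
        pos = tab["pos"].to_numpy(float)[idx]
        t2 = tab["t"].to_numpy(float)[idx] ** 2
        smoothed[idx] = _smooth_chrom(pos, t2, params.lambda_bp)
    tab["smoothed"] = smoothed

    # 2) two-track significance (smoothing track gated by nominal raw p)
    cut = np.quantile(smoothed, 1.0 - params.site_fdr)
    sig = (tab["adj_p"].to_numpy() <= params.site_fdr) | (
        (smoothed > cut) & (tab["p"].to_numpy() <= params.site_nominal_p)
    )
    tab["sig"] = sig

    # 3-6) merge, size filter, Fisher combination, thresholds
    rows = []
    for chrom, sub in tab[tab["sig"]].groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy(float)
        breaks = np.where(np.diff(pos) > params.lambda_bp)[0]
        starts = np.r_[0, breaks + 1]
        ends = np.r_[breaks, len(pos) - 1]
        for s, e in zip(starts, ends):
            members = sub.iloc[s : e + 1]
            if len(members) < params.min_cpgs:
                continue
            praw = np.clip(members["p"].to_numpy(float), 1e-300, 1.0)
            x2 = -2.0 * np.log(praw).sum()
            p_region = stats.chi2.sf(x2, 2 * len(praw))
            db = members["delta_beta"].to_numpy(float)
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(members["pos"].min()) - 1,  # 0-based half-open
                    "end": int(members["pos"].max()),
                    "n_cpgs": len(members),
                    "mean_delta_beta": db.mean(),
                    "max_delta_beta": db[np.argmax(np.abs(db))],
                    "p_region": p_region,
                    "probes": ",".join(members.index),
                }
            )
    if not rows:
        return _empty_dmr_table()
    regions = pd.DataFrame(rows)
    regions["fdr"] = bh_adjust(regions["p_region"].to_numpy())
    keep = (regions["fdr"] < params.region_fdr) & (
        regions["mean_delta_beta"].abs() >= params.min_mean_delta_beta
    )
    regions = regions[keep].reset_index(drop=True)
    regions["direction"] = np.where(regions["mean_delta_beta"] > 0, "hyper", "hypo")
    regions.index = [
        f"dmr_{r.chrom}_{r.start}_{r.end}" for r in regions.itertuples()
    ]
    regions.index.name = "dmr_id"
    cols = [
        "chrom", "start", "end", "n_cpgs", "mean_delta_beta", "max_delta_beta",
        "direction", "p_region", "fdr", "probes",
    ]
    return regions[cols]


def _empty_dmr_table() -> pd.DataFrame:
    out = pd.DataFrame(
        columns=[
            "chrom", "start", "end", "n_cpgs", "mean_delta_beta",
            "max_delta_beta", "direction", "p_region", "fdr", "probes",
        ]
    )
    out.index.name = "dmr_id"
    return out


def map_dmrs_to_genes(dmrs: pd.DataFrame, ann: pd.DataFrame) -> dict[str, list[str]]:
    """Union of member-probe gene annotations per gene, with DMR provenance.

    Returns ``{gene: [dmr_id, ...]}``; intergenic-only regions contribute
    nothing (those are handled by the TF-annotation branch instead).
    """
    out: dict[str, list[str]] = {}
    for dmr_id, row in dmrs.iterrows():
        probes = str(row["probes"]).split(",") if row["probes"] else []
        genes: set[str] = set()
        for p in probes:
            g = ann.loc[p, "gene"] if p in ann.index else ""
            if isinstance(g, str) and g:
                genes.update(x for x in g.split(";") if x)
        for g in sorted(genes):
            out.setdefault(g, []).append(dmr_id)
    return out


def dmr_report_tsv(dmrs: pd.DataFrame) -> pd.DataFrame:
    """Reporting view with 1-based inclusive coordinates."""
    rep = dmrs.copy()
    if len(rep):
        rep["start"] = rep["start"] + 1  # 1-based inclusive
    return rep


def dmrs_to_bed(dmrs: pd.DataFrame) -> pd.DataFrame:
    """BED6 view: name=direction, score=-log10(fdr) (0-based half-open)."""
    with np.errstate(divide="ignore"):
        score = -np.log10(np.clip(dmrs["fdr"].to_numpy(float), 1e-300, 1.0)) if len(dmrs) else []
    return pd.DataFrame(
        {
            "chrom": dmrs["chrom"],
            "start": dmrs["start"],
            "end": dmrs["end"],
            "name": dmrs["direction"],
            "score": score,
            "strand": ".",
        }
    )
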