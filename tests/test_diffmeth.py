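"""Site-level differential methylation and kernel DMR calling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as st

from methnet import diffmeth, methqc, syndata
from methnet.diffmeth import DmrParams, bh_adjust
from methnet.errors import (
    InsufficientSamplesError,
    InvalidArgumentError,
    InvalidDesignError,
)


# ------------------------------------------------------------------ BH

def _bh_oracle(p):
    """Literal step-up definition: adj_(i) = min_{j >= i} min(1, p_(j)*m/j)."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    sorted_p = p[order]
    adj_sorted = [
        min(1.0, min(sorted_p[j] * m / (j + 1) for j in range(i, m)))
        for i in range(m)
    ]
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def test_bh_hand_example():
    assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)


def test_bh_single_value_identity():
    assert bh_adjust([0.5])[0] == 0.5


def test_bh_matches_bruteforce_on_random_vectors():
    rng = np.random.default_rng(42)
    for _ in range(1000):
        p = rng.random(rng.integers(1, 30))
        assert np.allclose(bh_adjust(p), _bh_oracle(p), atol=1e-12)


def test_bh_matches_statsmodels():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(7)
    p = rng.random(500)
    ref = multipletests(p, method="fdr_bh")[1]
    assert np.allclose(bh_adjust(p), ref, atol=1e-12)


def test_bh_monotone_and_validates():
    rng = np.random.default_rng(3)
    p = rng.random(200)
    adj = bh_adjust(p)
    order = np.argsort(p)
    assert (np.diff(adj[order]) >= -1e-15).all()
    with pytest.raises(InvalidArgumentError):
        bh_adjust([0.5, 1.5])


# ------------------------------------------------------------- fit_dms

def _matrices(case_vals, ctrl_vals):
    samples = [f"c{i}" for i in range(len(case_vals))] + [
        f"k{i}" for i in range(len(ctrl_vals))
    ]
    sheet = pd.DataFrame(
        {
            "group": ["case"] * len(case_vals) + ["control"] * len(ctrl_vals),
            "age": 70.0,
            "sex": "F",
        },
        index=pd.Index(samples, name="sample_id"),
    )
    m = pd.DataFrame([list(case_vals) + list(ctrl_vals)],
                     index=pd.Index(["p1"], name="probe_id"), columns=samples)
    beta = methqc.m_to_beta(m)
    return m, beta, sheet


def test_fit_dms_hand_ols_example():
    """Cases (1.0,1.2,0.8,1.0) vs controls (0,0.2,-0.2,0): t=8.660, df=6."""
    m, beta, sheet = _matrices([1.0, 1.2, 0.8, 1.0], [0.0, 0.2, -0.2, 0.0])
    out = diffmeth.fit_dms(m, beta, sheet, moderate_var=False)
    assert out.loc["p1", "effect"] == pytest.approx(1.0, abs=1e-12)
    assert out.loc["p1", "t"] == pytest.approx(8.660254, abs=1e-5)
    assert out.loc["p1", "df"] == 6


def test_fit_dms_identical_groups_null():
    m, beta, sheet = _matrices([0.5, 0.7, 0.3, 0.5], [0.5, 0.7, 0.3, 0.5])
    out = diffmeth.fit_dms(m, beta, sheet, moderate_var=False)
    assert abs(out.loc["p1", "effect"]) < 1e-12
    assert out.loc["p1", "p"] == pytest.approx(1.0, abs=1e-9)


def test_fit_dms_matches_statsmodels_with_covariates():
    """Unmoderated per-probe t equals a textbook OLS fit on 100 probes."""
    import statsmodels.api as sm

    rng = np.random.default_rng(9)
    sheet = syndata.gen_sample_sheet(seed=9)
    samples = list(sheet.index)
    m = pd.DataFrame(
        rng.normal(size=(100, len(samples))),
        index=pd.Index([f"p{i}" for i in range(100)], name="probe_id"),
        columns=samples,
    )
    beta = methqc.m_to_beta(m)
    out = diffmeth.fit_dms(m, beta, sheet, covariates=["age"], moderate_var=False)

    x = np.column_stack([
        np.ones(len(samples)),
        (sheet["group"] == "case").to_numpy(float),
        sheet["age"].to_numpy(float),
    ])
    for probe in m.index[:100]:
        fit = sm.OLS(m.loc[probe].to_numpy(), x).fit()
        assert out.loc[probe, "t"] == pytest.approx(fit.tvalues[1], abs=1e-9)
        assert out.loc[probe, "p"] == pytest.approx(fit.pvalues[1], abs=1e-9)


def test_fit_dms_rejects_bad_designs():
    m, beta, sheet = _matrices([1.0, 1.2], [0.3])
    with pytest.raises(InsufficientSamplesError):
        diffmeth.fit_dms(m, beta, sheet)
    m, beta, sheet = _matrices([1.0, 1.2, 0.8], [0.0, 0.2, -0.2])
    sheet["const"] = 1.0  # collinear with the intercept
    with pytest.raises(InvalidDesignError):
        diffmeth.fit_dms(m, beta, sheet, covariates=["const"])


def test_fit_dms_null_calibration():
    """No planted signal: uniform p and nominal type-I error at 5000 probes."""
    sheet = syndata.gen_sample_sheet(seed=3)
    man = syndata.gen_manifest(5000, n_chrom=2, seed=3)
    beta, _ = syndata.gen_methylation(
        man, sheet, None, noise_sd=0.15, detp_fail_fraction=0.0, seed=4
    )
    out = diffmeth.fit_dms(methqc.beta_to_m(beta), beta, sheet, ["age"])
    assert st.kstest(out["p"], "uniform").pvalue > 0.01
    assert abs((out["p"] < 0.05).mean() - 0.05) < 0.01


# ------------------------------------------------------------ call_dmrs

def _planted_run(seed, plant=True):
    sheet = syndata.gen_sample_sheet(seed=seed)
    man = syndata.gen_manifest(2000, n_chrom=2, mean_spacing=200, seed=seed)
    truth = syndata.SyntheticTruth()
    if plant:
        truth.dmr_regions = syndata.plant_dmrs(
            man, n_regions=1, probes_per_region=5, delta_beta=0.2,
            hyper_fraction=1.0, seed=seed,
        )
    beta, _ = syndata.gen_methylation(
        man, sheet, truth, noise_sd=0.15, detp_fail_fraction=0.0, seed=seed + 1
    )
    dms = diffmeth.fit_dms(methqc.beta_to_m(beta), beta, sheet, ["age"], ann=man)
    return truth, man, dms


def test_planted_region_recovered_as_one_hyper_dmr():
    truth, man, dms = _planted_run(321)
    dmrs = diffmeth.call_dmrs(dms, man)
    region = truth.dmr_regions[0]
    hits = [
        row for _, row in dmrs.iterrows()
        if row["chrom"] == region.chrom
        and len(set(row["probes"].split(",")) & set(region.probes)) >= 4
    ]
    assert len(hits) == 1
    assert hits[0]["direction"] == "hyper"


def test_two_clusters_five_kb_apart_stay_distinct():
    """Two planted runs separated by >> lambda emerge as two regions."""
    samples = [f"c{i}" for i in range(8)] + [f"k{i}" for i in range(8)]
    sheet = pd.DataFrame(
        {"group": ["case"] * 8 + ["control"] * 8, "age": 70.0, "sex": "M"},
        index=pd.Index(samples, name="sample_id"),
    )
    pos = np.r_[np.arange(5) * 200 + 1000, np.arange(5) * 200 + 7000]
    probes = [f"p{i}" for i in range(10)]
    man = pd.DataFrame(
        {"chrom": "chr1", "pos": pos, "gene": "", "feature": "intergenic",
         "snp_associated": False, "non_cpg": False, "sex_chrom": False},
        index=pd.Index(probes, name="probe_id"),
    )
    rng = np.random.default_rng(0)
    base = 0.4 + rng.normal(0, 0.01, size=(10, 16))
    base[:, :8] += 0.2  # both clusters shifted in cases
    beta = pd.DataFrame(base, index=man.index, columns=samples)
    dms = diffmeth.fit_dms(methqc.beta_to_m(beta), beta, sheet, ann=man)
    dmrs = diffmeth.call_dmrs(dms, man, DmrParams(lambda_bp=1000.0))
    assert len(dmrs) == 2
    assert dmrs["start"].min() < 3000 < dmrs["start"].max()


def test_null_replicates_produce_almost_no_regions():
    counts = []
    for rep in range(50):
        _, man, dms = _planted_run(900 + rep, plant=False)
        counts.append(len(diffmeth.call_dmrs(dms, man)))
    assert np.mean(counts) <= 0.5


def test_reported_regions_satisfy_all_thresholds_post_hoc():
    truth, man, dms = _planted_run(77)
    params = DmrParams()
    dmrs = diffmeth.call_dmrs(dms, man, params)
    assert len(dmrs) >= 1
    for _, row in dmrs.iterrows():
        assert row["start"] < row["end"]
        assert row["n_cpgs"] >= params.min_cpgs
        assert abs(row["mean_delta_beta"]) >= params.min_mean_delta_beta
        assert row["fdr"] < params.region_fdr
        assert row["direction"] == ("hyper" if row["mean_delta_beta"] > 0 else "hypo")
        member_pos = man.loc[row["probes"].split(","), "pos"]
        assert (member_pos - 1 >= row["start"]).all()
        assert (member_pos <= row["end"]).all()
    # regions disjoint within a chromosome
    for _, sub in dmrs.groupby("chrom"):
        s = sub.sort_values("start")
        assert (s["start"].to_numpy()[1:] >= s["end"].to_numpy()[:-1]).all()


def test_hyper_hypo_split_sums_to_total(bundle):
    dms = diffmeth.fit_dms(
        methqc.beta_to_m(bundle["beta"]), bundle["beta"], bundle["sheet"],
        ["age"], ann=bundle["manifest"],
    )
    dmrs = diffmeth.call_dmrs(dms, bundle["manifest"])
    n_hyper = (dmrs["direction"] == "hyper").sum()
    n_hypo = (dmrs["direction"] == "hypo").sum()
    assert n_hyper + n_hypo == len(dmrs)


def test_invalid_params_rejected():
    with pytest.raises(InvalidArgumentError):
        DmrParams(lambda_bp=-1).validate()
    with pytest.raises(InvalidArgumentError):
        DmrParams(min_mean_delta_beta=1.5).validate()


def test_map_dmrs_to_genes_union_and_intergenic():
    man = pd.DataFrame(
        {"chrom": "chr1", "pos": [100, 200, 300], "gene": ["A", "A;B", ""],
         "feature": ["body", "body", "intergenic"],
         "snp_associated": False, "non_cpg": False, "sex_chrom": False},
        index=pd.Index(["p1", "p2", "p3"], name="probe_id"),
    )
    dmrs = pd.DataFrame(
        {"chrom": ["chr1", "chr1"], "start": [99, 299], "end": [250, 310],
         "probes": ["p1,p2", "p3"]},
        index=pd.Index(["d1", "d2"], name="dmr_id"),
    )
    genes = diffmeth.map_dmrs_to_genes(dmrs, man)
    assert genes == {"A": ["d1"], "B": ["d1"]}
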