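"""Synthetic-data generators: determinism, planted truth, calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as st

from methnet import syndata
from methnet.errors import InvalidArgumentError


# ------------------------------------------------------------ manifest

def test_manifest_positions_sorted_within_chromosome():
    ann = syndata.gen_manifest(100, n_chrom=2, seed=1)
    assert len(ann) == 100
    for _, sub in ann.groupby("chrom"):
        assert (np.diff(sub["pos"]) > 0).all()


def test_manifest_deterministic():
    a = syndata.gen_manifest(100, n_chrom=2, seed=1)
    b = syndata.gen_manifest(100, n_chrom=2, seed=1)
    pd.testing.assert_frame_equal(a, b)


def test_manifest_flag_rate_within_binomial_bounds():
    """SNP-flag count lies inside the central 99.9% binomial interval."""
    ann = syndata.gen_manifest(1000, flag_fractions={"snp": 0.1}, seed=7)
    k = int(ann["snp_associated"].sum())
    lo, hi = st.binom.ppf([0.0005, 0.9995], 1000, 0.1)
    assert lo <= k <= hi


def test_manifest_rejects_bad_arguments():
    with pytest.raises(InvalidArgumentError):
        syndata.gen_manifest(0)
    with pytest.raises(InvalidArgumentError):
        syndata.gen_manifest(10, flag_fractions={"snp": 1.5})


# --------------------------------------------------------- methylation

def test_noiseless_planted_shift_is_exact():
    sheet = syndata.gen_sample_sheet(seed=2)
    man = syndata.gen_manifest(50, n_chrom=1, seed=2)
    probe = man.index[10]
    truth = syndata.SyntheticTruth(dms_effects={probe: 0.2})
    beta, _ = syndata.gen_methylation(
        man, sheet, truth, noise_sd=0.0, detp_fail_fraction=0.0, seed=3
    )
    case = sheet.index[sheet["group"] == "case"]
    ctrl = sheet.index[sheet["group"] == "control"]
    diff = beta.loc[probe, case].mean() - beta.loc[probe, ctrl].mean()
    assert diff == pytest.approx(0.2, abs=1e-12)


def test_betas_inside_open_unit_interval():
    sheet = syndata.gen_sample_sheet(seed=4)
    man = syndata.gen_manifest(500, seed=4)
    beta, detp = syndata.gen_methylation(man, sheet, None, seed=5)
    assert (beta.to_numpy() > 0).all() and (beta.to_numpy() < 1).all()
    assert ((detp.to_numpy() >= 0) & (detp.to_numpy() <= 1)).all()


def test_no_signal_t_pvalues_uniform():
    """Per-probe two-sample t p-values pass a KS uniformity check."""
    sheet = syndata.gen_sample_sheet(seed=6)
    man = syndata.gen_manifest(5000, seed=6)
    beta, _ = syndata.gen_methylation(
        man, sheet, None, noise_sd=0.15, detp_fail_fraction=0.0, seed=7
    )
    case = beta[sheet.index[sheet["group"] == "case"]].to_numpy()
    ctrl = beta[sheet.index[sheet["group"] == "control"]].to_numpy()
    p = st.ttest_ind(case, ctrl, axis=1).pvalue
    assert st.kstest(p, "uniform").pvalue > 0.01


def test_planted_probe_outside_manifest_rejected():
    sheet = syndata.gen_sample_sheet(seed=1)
    man = syndata.gen_manifest(10, seed=1)
    truth = syndata.SyntheticTruth(dms_effects={"cg_not_there": 0.2})
    with pytest.raises(InvalidArgumentError):
        syndata.gen_methylation(man, sheet, truth)


# ----------------------------------------------------------------- PPI

def test_dense_planted_module_has_all_internal_edges():
    genes = [f"g{i}" for i in range(20)]
    module = set(genes[:6])
    ppi = syndata.gen_ppi(genes, edge_prob=0.0, planted_module=module,
                          module_density=1.0, seed=1)
    assert len(ppi) == 15  # C(6,2)
    assert (ppi["confidence"] >= 0.7).all()
    touched = set(ppi["gene_a"]) | set(ppi["gene_b"])
    assert touched == module


def test_ppi_deterministic_and_duplicate_names_rejected():
    genes = [f"g{i}" for i in range(30)]
    a = syndata.gen_ppi(genes, 0.1, seed=2)
    b = syndata.gen_ppi(genes, 0.1, seed=2)
    pd.testing.assert_frame_equal(a, b)
    with pytest.raises(InvalidArgumentError):
        syndata.gen_ppi(["x", "x"], 0.1)


# ----------------------------------------------------------- expression

def test_zero_base_mean_gives_all_zero_counts():
    sheet = syndata.gen_sample_sheet(seed=3)
    counts = syndata.gen_expression(
        ["a", "b"], sheet, base_means=np.array([0.0, 100.0]), seed=3
    )
    assert (counts.loc["a"] == 0).all()
    assert counts.loc["b"].sum() > 0


def test_planted_lfc_scales_case_means():
    sheet = syndata.gen_sample_sheet(seed=8)
    counts = syndata.gen_expression(
        ["a", "b"], sheet, planted_degs={"a": 2.0},
        base_means=np.array([500.0, 500.0]), dispersion=0.01,
        lib_size_log_sd=0.0, seed=8,
    )
    case = sheet.index[sheet["group"] == "case"]
    ctrl = sheet.index[sheet["group"] == "control"]
    ratio = counts.loc["a", case].mean() / counts.loc["a", ctrl].mean()
    assert ratio == pytest.approx(4.0, rel=0.25)


def test_expression_determinism_and_validation():
    sheet = syndata.gen_sample_sheet(seed=9)
    a = syndata.gen_expression(["x", "y"], sheet, seed=9)
    b = syndata.gen_expression(["x", "y"], sheet, seed=9)
    pd.testing.assert_frame_equal(a, b)
    with pytest.raises(InvalidArgumentError):
        syndata.gen_expression(["x"], sheet, dispersion=-0.1)
    with pytest.raises(InvalidArgumentError):
        syndata.gen_expression(["x"], sheet, planted_degs={"zzz": 1.0})


# --------------------------------------------------------- TF resources

def _tf_setup(overlap_fraction, seed=5, modes=("activation", "repression", "unknown")):
    man = syndata.gen_manifest(300, n_chrom=2, seed=seed)
    regions = syndata.plant_dmrs(man, 3, 4, 0.2, seed=seed)
    bed, targets = syndata.gen_tf_resources(
        man, regions, ["TF1", "TF2"], {"GA", "GB"},
        overlap_fraction=overlap_fraction, modes=modes, seed=seed,
    )
    return man, regions, bed, targets


def test_full_overlap_fraction_covers_every_planted_region():
    from methnet.tfreg import annotate_dmrs_to_tfs

    _, regions, bed, _ = _tf_setup(1.0)
    dmrs = pd.DataFrame(
        [{"chrom": r.chrom, "start": r.start - 1, "end": r.end, "probes": ""}
         for r in regions],
        index=pd.Index([f"d{i}" for i in range(len(regions))], name="dmr_id"),
    )
    support = annotate_dmrs_to_tfs(dmrs, bed)
    covered = {d for dmr_ids in support.values() for d in dmr_ids}
    assert covered == set(dmrs.index)


def test_zero_overlap_fraction_yields_no_support():
    from methnet.tfreg import annotate_dmrs_to_tfs

    _, regions, bed, _ = _tf_setup(0.0)
    dmrs = pd.DataFrame(
        [{"chrom": r.chrom, "start": r.start - 1, "end": r.end, "probes": ""}
         for r in regions],
        index=pd.Index([f"d{i}" for i in range(len(regions))], name="dmr_id"),
    )
    assert annotate_dmrs_to_tfs(dmrs, bed) == {}


def test_restricted_modes_respected():
    _, _, _, targets = _tf_setup(1.0, modes=("repression",))
    assert (targets["mode"] == "repression").all()


def test_empty_tf_names_rejected():
    man = syndata.gen_manifest(100, seed=1)
    with pytest.raises(InvalidArgumentError):
        syndata.gen_tf_resources(man, [], [], set())


# --------------------------------------------------------------- bundle

def test_bundle_regeneration_is_byte_identical(tmp_path):
    a = syndata.write_bundle(syndata.simulate_bundle(seed=5), tmp_path / "a")
    b = syndata.write_bundle(syndata.simulate_bundle(seed=5), tmp_path / "b")
    for key in a:
        assert open(a[key], "rb").read() == open(b[key], "rb").read(), key


def test_validate_truth_catches_dangling_identifiers(bundle):
    syndata.validate_truth(
        bundle["truth"], bundle["manifest"], ppi=bundle["ppi"],
        counts=bundle["counts"], beta=bundle["beta"],
    )
    broken = syndata.SyntheticTruth(dms_effects={"nope": 0.1})
    with pytest.raises(InvalidArgumentError):
        syndata.validate_truth(broken, bundle["manifest"])


def test_sample_sheet_matches_study_design():
    sheet = syndata.gen_sample_sheet(seed=0)
    assert (sheet.groupby("group").size() == 8).all()
    assert (sheet["age"] >= 50).all()
    case_sex = sheet[sheet["group"] == "case"]["sex"].value_counts()
    ctrl_sex = sheet[sheet["group"] == "control"]["sex"].value_counts()
    assert case_sex.to_dict() == ctrl_sex.to_dict() == {"M": 5, "F": 3}
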