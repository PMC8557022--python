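"""Planted-truth benchmark experiments for the pipeline's core claims.

Each function regenerates synthetic data under the package's study
conditions (8 cases vs 8 controls, 2000 probes, five-probe regions with a
0.2 beta shift, 0.15 M-unit noise), runs the relevant stage from scratch
and measures recovery or calibration.  These back both the test suite and
the reproduction script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as st

from . import clock as clockmod
from . import diffmeth, exprde, fem, methqc, syndata

STUDY_N_PROBES = 2000
STUDY_NOISE_SD = 0.15
STUDY_DELTA_BETA = 0.2
STUDY_PROBES_PER_REGION = 5


def _subseeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def _dmr_replicate(seed: int, plant: bool):
    sheet = syndata.gen_sample_sheet(seed=seed)
    man = syndata.gen_manifest(
        STUDY_N_PROBES, n_chrom=2, mean_spacing=200, seed=seed
    )
    truth = syndata.SyntheticTruth()
    if plant:
        truth.dmr_regions = syndata.plant_dmrs(
            man, n_regions=1, probes_per_region=STUDY_PROBES_PER_REGION,
            delta_beta=STUDY_DELTA_BETA, hyper_fraction=1.0, seed=seed,
        )
    beta, _ = syndata.gen_methylation(
        man, sheet, truth, noise_sd=STUDY_NOISE_SD,
        detp_fail_fraction=0.0, seed=seed + 1,
    )
    dms = diffmeth.fit_dms(methqc.beta_to_m(beta), beta, sheet, ["age"], ann=man)
    return truth, diffmeth.call_dmrs(dms, man)


def dmr_recovery(n_reps: int = 20, seed: int = 0) -> dict:
    """Planted-region sensitivity and false regions per null replicate."""
    seeds = _subseeds(seed, 2 * n_reps)
    hits = 0
    for i in range(n_reps):
        truth, dmrs = _dmr_replicate(seeds[i], plant=True)
        region = truth.dmr_regions[0]
        hits += any(
            row["chrom"] == region.chrom
            and len(set(row["probes"].split(",")) & set(region.probes)) >= 4
            and row["direction"] == "hyper"
            for _, row in dmrs.iterrows()
        )
    false_counts = [
        len(_dmr_replicate(seeds[n_reps + i], plant=False)[1])
        for i in range(n_reps)
    ]
    return {
        "sensitivity": hits / n_reps,
        "false_regions_per_null": float(np.mean(false_counts)),
        "n_reps": n_reps,
    }


def _fem_replicate(seed: int, n_perm: int):
    rng = np.random.default_rng(seed)
    genes = [f"g{i:03d}" for i in range(100)]
    module = set(genes[:6])
    ppi = syndata.gen_ppi(
        genes, edge_prob=0.05, planted_module=module, module_density=1.0,
        seed=seed + 1,
    )
    vals = np.abs(rng.normal(0.0, 1.0, 100))
    vals[:6] = rng.normal(4.0, 0.5, 6)
    stats = pd.DataFrame(
        {"stat": vals, "n_probes": 1, "signed_mean_delta_beta": -vals},
        index=pd.Index(genes, name="gene"),
    )
    mods = fem.detect_modules(stats, ppi, n_perm=n_perm, seed=seed)
    top = mods[0]
    jac = len(set(top.members) & module) / len(set(top.members) | module)
    return jac, top.emp_p


def fem_recovery(n_reps: int = 20, n_perm: int = 199, seed: int = 0) -> dict:
    """Planted-module recovery: Jaccard vs truth and permutation p."""
    seeds = _subseeds(seed + 1, n_reps)
    jacs, oks = [], 0
    for s in seeds:
        jac, emp_p = _fem_replicate(s, n_perm)
        jacs.append(jac)
        oks += jac >= 0.6 and emp_p <= 0.05
    return {
        "recovery_rate": oks / n_reps,
        "mean_jaccard": float(np.mean(jacs)),
        "n_reps": n_reps,
    }


def fem_null_fpr(n_runs: int = 200, n_perm: int = 99, seed: int = 0) -> dict:
    """Fraction of fully null runs reporting any module with emp_p < 0.05."""
    genes = [f"g{i:03d}" for i in range(50)]
    ppi = syndata.gen_ppi(genes, edge_prob=0.08, seed=seed + 7)
    seeds = _subseeds(seed + 2, n_runs)
    hits = 0
    for s in seeds:
        rng = np.random.default_rng(s)
        stats = pd.DataFrame(
            {
                "stat": np.abs(rng.normal(0, 1, len(genes))),
                "n_probes": 1,
                "signed_mean_delta_beta": rng.normal(0, 0.1, len(genes)),
            },
            index=pd.Index(genes, name="gene"),
        )
        mods = fem.detect_modules(stats, ppi, n_perm=n_perm, seed=s)
        hits += any(m.emp_p < 0.05 for m in mods)
    return {"fpr": hits / n_runs, "n_runs": n_runs}


def clock_roundtrip_error(seed: int = 0) -> dict:
    """Max |DNAm age - chronological age| for a noiseless planted clock."""
    bundle = syndata.simulate_bundle(seed=seed)
    ages = clockmod.predict_age(bundle["beta"], bundle["truth"].clock)
    err = float(np.max(np.abs(ages - bundle["sheet"]["age"])))
    return {"max_abs_error_years": err, "n_samples": len(ages)}


def null_calibration(seed: int = 0, n_probes: int = 5000, n_genes: int = 2000) -> dict:
    """KS uniformity of site-level and expression p-values under no signal."""
    s1, s2, s3 = _subseeds(seed + 3, 3)
    sheet = syndata.gen_sample_sheet(seed=s1)
    man = syndata.gen_manifest(n_probes, n_chrom=2, seed=s1)
    beta, _ = syndata.gen_methylation(
        man, sheet, None, noise_sd=STUDY_NOISE_SD, detp_fail_fraction=0.0,
        seed=s2,
    )
    dms = diffmeth.fit_dms(methqc.beta_to_m(beta), beta, sheet, ["age"])
    counts = syndata.gen_expression(
        [f"g{i}" for i in range(n_genes)], sheet, {}, dispersion=0.1, seed=s3
    )
    de = exprde.simple_de(counts, sheet)
    return {
        "dms_ks_p": float(st.kstest(dms["p"], "uniform").pvalue),
        "dms_type_i_at_0_05": float((dms["p"] < 0.05).mean()),
        "de_ks_p": float(st.kstest(de["p"], "uniform").pvalue),
        "n_probes": n_probes,
        "n_genes": n_genes,
    }
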