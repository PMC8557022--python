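"""End-to-end orchestration of one brain-region analysis run.

``run_all`` executes the stages in order — QC, site-level differential
methylation, DMR calling, methylation modules, epigenetic age,
expression DE, cross-source network integration, TF regulatory network,
cohort statistics — from a single validated config, writing each stage's
outputs and a JSON run manifest (stage output paths, row counts, seed)
into the run directory.  Identical config + seed yields byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import clock as clockmod
from . import diffmeth, exprde, fem, io, methqc, netint, tfreg
from .cohortstats import table1_from_sheet
from .errors import InvalidArgumentError, MethnetError


@dataclass
class RunConfig:
    """All input paths and thresholds for one region's run."""

    # inputs
    beta: str = ""
    detp: str = ""
    manifest: str = ""
    sheet: str = ""
    counts: str = ""
    ppi: str = ""
    clock_coeffs: str = ""
    tf_clusters: str = ""
    tf_targets: str = ""
    gene_sets: str = ""
    deg_table: str = ""          # optional externally produced DegTable
    # covariates
    dms_covariates: list[str] = field(default_factory=lambda: ["age"])
    de_covariates: list[str] = field(default_factory=list)
    # thresholds
    detp_threshold: float = 0.05
    dms_adj_p: float = 0.05
    dms_export_p: float = 0.0005
    dmr_lambda: float = 1000.0
    dmr_fdr: float = 0.05
    dmr_min_delta_beta: float = 0.10
    ppi_min_conf: float = 0.7
    hub_percentile: float = 95.0
    enrich_min_size: int = 5
    enrich_fdr: float = 0.05
    deg_p: float = 0.01
    cpm_min: float = 0.3
    cpm_min_frac: float = 0.5
    fem_n_perm: int = 1000
    fem_emp_p: float = 0.05
    # misc
    seed: int = 0
    moderate: bool = True
    intergenic_only_tfs: bool = False

    _DOMAIN = {
        "detp_threshold": (0.0, 1.0),
        "dms_adj_p": (0.0, 1.0),
        "dms_export_p": (0.0, 1.0),
        "dmr_fdr": (0.0, 1.0),
        "dmr_min_delta_beta": (0.0, 1.0),
        "ppi_min_conf": (0.0, 1.0),
        "hub_percentile": (0.0, 100.0),
        "enrich_fdr": (0.0, 1.0),
        "deg_p": (0.0, 1.0),
        "cpm_min_frac": (0.0, 1.0),
        "fem_emp_p": (0.0, 1.0),
    }

    def validate(self) -> "RunConfig":
        for name, (lo, hi) in self._DOMAIN.items():
            v = float(getattr(self, name))
            if not (lo <= v <= hi):
                raise InvalidArgumentError(
                    f"config value {name}={v} outside [{lo}, {hi}]"
                )
        if self.dmr_lambda <= 0:
            raise InvalidArgumentError("dmr_lambda must be > 0")
        if self.cpm_min < 0:
            raise InvalidArgumentError("cpm_min must be >= 0")
        if self.fem_n_perm < 1:
            raise InvalidArgumentError("fem_n_perm must be >= 1")
        return self

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(open(path)) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - known
        if bad:
            raise InvalidArgumentError(f"unknown config keys: {sorted(bad)}")
        return cls(**data).validate()

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def _require(path: str, stage: str) -> str:
    if not path or not Path(path).exists():
        raise MethnetError(f"stage '{stage}': missing input file '{path}'")
    return path


def run_all(config: RunConfig, outdir) -> dict:
    """Run every stage; returns the JSON-serialisable run manifest."""
    cfg = config.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": cfg.seed, "stages": {}}

    def record(stage: str, **entries):
        manifest["stages"][stage] = entries

    # ---- qc ----------------------------------------------------------
    beta = io.read_matrix(_require(cfg.beta, "qc"), "probe_id")
    detp = io.read_matrix(_require(cfg.detp, "qc"), "probe_id")
    ann = io.read_manifest(_require(cfg.manifest, "qc"))
    sheet = io.read_sample_sheet(_require(cfg.sheet, "qc"))
    beta_f, qc_report = methqc.filter_probes(beta, detp, ann, cfg.detp_threshold)
    io.write_matrix(beta_f, out / "beta_filtered.tsv")
    io.write_json(qc_report.to_dict(), out / "qc_report.json")
    record("qc", beta_filtered="beta_filtered.tsv",
           report="qc_report.json", **qc_report.to_dict())

    # ---- dms ---------------------------------------------------------
    m_values = methqc.beta_to_m(beta_f)
    dms = diffmeth.fit_dms(
        m_values, beta_f, sheet, covariates=cfg.dms_covariates,
        moderate_var=cfg.moderate, ann=ann,
    )
    dms.to_csv(out / "dms.tsv", sep="\t")
    export = dms[dms["p"] < cfg.dms_export_p]
    export.to_csv(out / "dms_candidates.tsv", sep="\t")
    record("dms", table="dms.tsv", n_tested=len(dms),
           n_significant=int((dms["adj_p"] <= cfg.dms_adj_p).sum()),
           n_exported=len(export))

    # ---- dmr ---------------------------------------------------------
    params = diffmeth.DmrParams(
        lambda_bp=cfg.dmr_lambda, site_fdr=cfg.dmr_fdr,
        region_fdr=cfg.dmr_fdr, min_mean_delta_beta=cfg.dmr_min_delta_beta,
    )
    dmrs = diffmeth.call_dmrs(dms, ann, params)
    diffmeth.dmr_report_tsv(dmrs).to_csv(out / "dmrs.tsv", sep="\t")
    io.write_bed6(diffmeth.dmrs_to_bed(dmrs), out / "dmrs.bed")
    dmr_gene_map = diffmeth.map_dmrs_to_genes(dmrs, ann)
    (out / "dmr_genes.txt").write_text(
        "\n".join(sorted(dmr_gene_map)) + ("\n" if dmr_gene_map else "")
    )
    n_hyper = int((dmrs["direction"] == "hyper").sum()) if len(dmrs) else 0
    record("dmr", table="dmrs.tsv", bed="dmrs.bed",
           n_regions=len(dmrs), n_hyper=n_hyper, n_hypo=len(dmrs) - n_hyper,
           n_genes=len(dmr_gene_map))

    # ---- fem ---------------------------------------------------------
    ppi = io.read_ppi(_require(cfg.ppi, "fem"))
    stats_tab = fem.gene_stats(dms, ann)
    modules = fem.detect_modules(
        stats_tab, ppi, n_perm=cfg.fem_n_perm, seed=cfg.seed
    )
    io.write_json([m.to_dict() for m in modules], out / "modules.json")
    fem_genes = fem.module_genes(modules, cfg.fem_emp_p)
    record("fem", modules="modules.json", n_modules=len(modules),
           n_significant=sum(m.emp_p <= cfg.fem_emp_p for m in modules),
           n_genes=len(fem_genes))

    # ---- clock -------------------------------------------------------
    model = clockmod.ClockModel.from_csv(_require(cfg.clock_coeffs, "clock"))
    dnam = clockmod.predict_age(beta, model)
    ages = clockmod.age_acceleration(dnam, sheet["age"])
    ages.to_csv(out / "ages.tsv", sep="\t")
    aa_cmp = clockmod.compare_groups_aa(ages, sheet)
    io.write_json(aa_cmp, out / "aa_compare.json")
    record("clock", ages="ages.tsv",
           compare="aa_compare.json",
           aa_diff_p=aa_cmp["aa_diff"]["p"],
           aa_residual_p=aa_cmp["aa_residual"]["p"])

    # ---- de ----------------------------------------------------------
    if cfg.deg_table:
        deg_tab = pd.read_csv(_require(cfg.deg_table, "de"), sep="\t", index_col=0)
        if "is_deg" not in deg_tab.columns:
            deg_tab["is_deg"] = deg_tab["p"] < cfg.deg_p
    else:
        counts = io.read_matrix(_require(cfg.counts, "de"), "gene_id")
        filtered = exprde.cpm_filter(counts, sheet, cfg.cpm_min, cfg.cpm_min_frac)
        deg_tab = exprde.simple_de(
            filtered, sheet, covariates=cfg.de_covariates, deg_p=cfg.deg_p
        )
    deg_tab.to_csv(out / "degs.tsv", sep="\t")
    degs = exprde.deg_genes(deg_tab)
    record("de", table="degs.tsv", n_tested=len(deg_tab),
           n_degs=len(degs))

    # ---- integrate ---------------------------------------------------
    dmr_genes = set(dmr_gene_map)
    try:
        net = netint.build_integrated_network(
            ppi, degs, dmr_genes, fem_genes, cfg.ppi_min_conf
        )
        edges = pd.DataFrame(
            [
                {"gene_a": a, "gene_b": b,
                 "confidence": d["confidence"]}
                for a, b, d in net.edges(data=True)
            ]
        )
        edges.to_csv(out / "network_edges.tsv", sep="\t", index=False)
        ct = netint.mark_selected(
            netint.compute_centralities(net), cfg.hub_percentile
        )
        ct.to_csv(out / "centralities.tsv", sep="\t")
        hubs, provenance = netint.select_hubs(
            ct[list(netint.METRICS)], cfg.hub_percentile
        )
        io.write_json(
            {h: provenance[h] for h in sorted(hubs)}, out / "hubs.json"
        )
        enr_n = 0
        if cfg.gene_sets:
            sets = io.read_gmt(_require(cfg.gene_sets, "integrate"))
            universe = set(net.nodes)
            enr = netint.hypergeom_enrich(
                hubs & universe, sets, universe,
                cfg.enrich_min_size, cfg.enrich_fdr,
            )
            enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
            enr_n = int(enr["significant"].sum()) if len(enr) else 0
        record("integrate", edges="network_edges.tsv",
               centralities="centralities.tsv",
               n_nodes=net.number_of_nodes(), n_edges=net.number_of_edges(),
               n_hubs=len(hubs),
               hub_sources=netint.hub_source_breakdown(hubs, net),
               n_enriched=enr_n)
    except netint.EmptyNetworkError:
        record("integrate", n_nodes=0, n_edges=0, n_hubs=0, note="empty network")

    # ---- tfnet -------------------------------------------------------
    clusters = io.read_bed(_require(cfg.tf_clusters, "tfnet"))
    targets = pd.read_csv(_require(cfg.tf_targets, "tfnet"), sep="\t")
    support = tfreg.annotate_dmrs_to_tfs(
        dmrs, clusters, intergenic_only=cfg.intergenic_only_tfs, ann=ann
    )
    regnet = tfreg.build_regulatory_network(support, targets, deg_tab)
    regnet.edges.to_csv(out / "regnet.tsv", sep="\t", index=False)
    (out / "regnet.dot").write_text(regnet.to_dot() + "\n")
    io.write_json(
        {"unmatched_tfs": regnet.unmatched_tfs}, out / "regnet_side.json"
    )
    record("tfnet", table="regnet.tsv", dot="regnet.dot",
           n_tfs=len(support), n_edges=len(regnet.edges),
           n_unmatched_tfs=len(regnet.unmatched_tfs))

    # ---- cohort ------------------------------------------------------
    table1 = table1_from_sheet(sheet)
    table1.to_csv(out / "table1.tsv", sep="\t", index=False)
    record("cohort", table="table1.tsv", n_rows=len(table1))

    io.write_json(manifest, out / "run_manifest.json")
    return manifest


def compare_runs(run_dirs: list[str]) -> pd.DataFrame:
    """Shared TFs and TF->target pairs across several run directories."""
    seen_tfs: dict[str, list[str]] = {}
    seen_pairs: dict[tuple[str, str], list[str]] = {}
    for d in run_dirs:
        name = Path(d).name
        reg = pd.read_csv(Path(d) / "regnet.tsv", sep="\t")
        for tf in set(reg["tf"]):
            seen_tfs.setdefault(tf, []).append(name)
        for tf, tgt in set(zip(reg["tf"], reg["target"])):
            seen_pairs.setdefault((tf, tgt), []).append(name)
    rows = [
        {"kind": "tf", "tf": tf, "target": "", "runs": ",".join(runs),
         "n_runs": len(runs)}
        for tf, runs in sorted(seen_tfs.items()) if len(runs) > 1
    ] + [
        {"kind": "tf_target", "tf": tf, "target": tgt,
         "runs": ",".join(runs), "n_runs": len(runs)}
        for (tf, tgt), runs in sorted(seen_pairs.items()) if len(runs) > 1
    ]
    return pd.DataFrame(rows, columns=["kind", "tf", "target", "runs", "n_runs"])
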