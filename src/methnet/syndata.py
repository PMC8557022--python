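"""Synthetic data with planted truth for every pipeline stage.

Generates a probe manifest with realistic spacing, a bimodal beta-value
matrix with planted site- and region-level group shifts, a detection-p
matrix, negative-binomial read counts with planted fold changes, a random
PPI graph with one planted dense module, a linear epigenetic clock
consistent with the chronological ages, and TF binding clusters /
TF-target tables overlapping the planted DMRs.  Everything is a pure
function of its arguments including the seed, so regeneration is
byte-identical, and all planted identifiers resolve against the generated
resources (checked by :func:`validate_truth`).

Defaults encode the study conditions the pipeline is designed around:
eight cases vs eight matched controls aged 50+, 450K-like bimodal betas,
2000 probes, five-probe planted regions with a 0.2 beta-scale shift and
0.15 M-unit measurement noise.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clock import ClockModel
from .errors import InvalidArgumentError
from .io import validate_sample_sheet

_BETA_MIX = ((2.0, 10.0), (10.0, 2.0))  # unmethylated / methylated modes
_BETA_MIX_W = 0.6                       # weight of the unmethylated mode
_CLIP = (0.001, 0.999)


@dataclass
class DmrTruth:
    chrom: str
    start: int          # 1-based first probe position
    end: int            # 1-based last probe position (inclusive)
    direction: str      # hyper / hypo
    delta_beta: float   # magnitude of the case shift on the beta scale
    probes: list[str] = field(default_factory=list)

    @property
    def signed_delta(self) -> float:
        return self.delta_beta if self.direction == "hyper" else -self.delta_beta


@dataclass
class SyntheticTruth:
    """Planted ground truth tying all generated resources together."""

    dms_effects: dict[str, float] = field(default_factory=dict)  # probe -> signed d-beta
    dmr_regions: list[DmrTruth] = field(default_factory=list)
    module_genes: set[str] = field(default_factory=set)
    deg_genes: dict[str, float] = field(default_factory=dict)    # gene -> lfc
    clock: ClockModel | None = None
    seed: int = 0

    @property
    def dms_probes(self) -> set[str]:
        return set(self.dms_effects)

    def probe_shifts(self) -> dict[str, float]:
        """All planted per-probe beta shifts (sites plus region members)."""
        shifts = dict(self.dms_effects)
        for region in self.dmr_regions:
            for p in region.probes:
                shifts[p] = region.signed_delta
        return shifts

    def to_json_dict(self) -> dict:
        return {
            "seed": self.seed,
            "dms_effects": self.dms_effects,
            "dmr_regions": [dataclasses.asdict(r) for r in self.dmr_regions],
            "module_genes": sorted(self.module_genes),
            "deg_genes": self.deg_genes,
            "clock": None
            if self.clock is None
            else {
                "intercept": self.clock.intercept,
                "adult_age": self.clock.adult_age,
                "coefficients": self.clock.coefficients,
            },
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "SyntheticTruth":
        clock = None
        if d.get("clock"):
            clock = ClockModel(
                intercept=d["clock"]["intercept"],
                coefficients=d["clock"]["coefficients"],
                adult_age=d["clock"]["adult_age"],
            )
        return cls(
            dms_effects=dict(d.get("dms_effects", {})),
            dmr_regions=[DmrTruth(**r) for r in d.get("dmr_regions", [])],
            module_genes=set(d.get("module_genes", [])),
            deg_genes=dict(d.get("deg_genes", {})),
            clock=clock,
            seed=int(d.get("seed", 0)),
        )


# --------------------------------------------------------------- sample sheet

def gen_sample_sheet(
    n_cases: int = 8,
    n_controls: int = 8,
    mean_age: float = 75.0,
    sd_age: float = 13.0,
    min_age: float = 50.0,
    female_fraction: float = 3.0 / 8.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Case-control sheet matched in age and sex distribution by design."""
    rng = np.random.default_rng(seed)
    rows = []
    for group, n in (("case", n_cases), ("control", n_controls)):
        n_f = int(round(female_fraction * n))
        sexes = ["F"] * n_f + ["M"] * (n - n_f)
        for i in range(n):
            age = min_age - 1
            while age < min_age:
                age = rng.normal(mean_age, sd_age)
            rows.append(
                {
                    "sample_id": f"{group}_{i + 1:02d}",
                    "group": group,
                    "age": round(float(age), 1),
                    "sex": sexes[i],
                }
            )
    sheet = pd.DataFrame(rows).set_index("sample_id")
    return validate_sample_sheet(sheet)


# ------------------------------------------------------------------ manifest

def gen_manifest(
    n_probes: int,
    n_chrom: int = 2,
    mean_spacing: float = 500.0,
    flag_fractions: dict[str, float] | None = None,
    gene_fraction: float = 0.7,
    promoter_fraction: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Probe annotation with strictly increasing positions per chromosome.

    Probes are split evenly over ``n_chrom`` chromosomes with exponential
    inter-probe spacing (mean ``mean_spacing`` bp).  Consecutive probes are
    grouped into genes (symbols ``G0001``...) with ``gene_fraction`` of
    groups annotated; the rest are intergenic.  ``flag_fractions`` sets the
    Bernoulli rates of the ``snp``, ``non_cpg`` and ``sex`` flags.
    """
    if n_probes < 1:
        raise InvalidArgumentError("n_probes must be >= 1")
    flags = {"snp": 0.0, "non_cpg": 0.0, "sex": 0.0}
    if flag_fractions:
        for k, v in flag_fractions.items():
            if k not in flags:
                raise InvalidArgumentError(f"unknown flag '{k}'")
            if not (0.0 <= v <= 1.0):
                raise InvalidArgumentError("flag fractions must lie in [0, 1]")
            flags[k] = v
    rng = np.random.default_rng(seed)

    per_chrom = np.full(n_chrom, n_probes // n_chrom)
    per_chrom[: n_probes % n_chrom] += 1
    chroms, positions = [], []
    for c in range(n_chrom):
        k = int(per_chrom[c])
        if k == 0:
            continue
        gaps = np.maximum(1, np.round(rng.exponential(mean_spacing, size=k))).astype(int)
        pos = np.cumsum(gaps) + int(rng.integers(1, 1000))
        chroms += [f"chr{c + 1}"] * k
        positions.append(pos)
    positions = np.concatenate(positions)

    probe_ids = [f"cg{i:08d}" for i in range(1, n_probes + 1)]

    # gene blocks of geometric length; a fraction annotated, rest intergenic
    genes = np.empty(n_probes, dtype=object)
    features = np.empty(n_probes, dtype=object)
    i, gene_no = 0, 0
    while i < n_probes:
        block = int(rng.geometric(0.25))  # mean 4 probes per block
        block = min(block, n_probes - i)
        if rng.random() < gene_fraction:
            gene_no += 1
            name = f"G{gene_no:04d}"
            for j in range(block):
                genes[i + j] = name
                features[i + j] = (
                    "promoter" if rng.random() < promoter_fraction else "body"
                )
        else:
            for j in range(block):
                genes[i + j] = ""
                features[i + j] = "intergenic"
        i += block

    ann = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": positions,
            "gene": genes,
            "feature": features,
            "snp_associated": rng.random(n_probes) < flags["snp"],
            "non_cpg": rng.random(n_probes) < flags["non_cpg"],
            "sex_chrom": rng.random(n_probes) < flags["sex"],
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    return ann


# --------------------------------------------------------------- methylation

def _logit2(b: np.ndarray) -> np.ndarray:
    return np.log2(b / (1.0 - b))


def _expit2(m: np.ndarray) -> np.ndarray:
    x = np.exp2(m)
    return x / (1.0 + x)


def gen_methylation(
    manifest: pd.DataFrame,
    sheet: pd.DataFrame,
    planted: SyntheticTruth | None = None,
    noise_sd: float = 0.15,
    detp_fail_fraction: float = 0.001,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Beta and detection-p matrices with planted case shifts.

    Baselines are drawn from a two-component Beta mixture (Beta(2,10) and
    Beta(10,2), 60/40); per-sample noise is Gaussian on the M scale with
    SD ``noise_sd``; planted probes are shifted by the stated delta-beta in
    cases on the beta scale and clipped to (0.001, 0.999).  Baselines of
    planted probes are drawn from a range that keeps the shift inside the
    clip bounds, so with zero noise the planted group difference is exact.
    """
    planted = planted or SyntheticTruth()
    shifts = planted.probe_shifts()
    missing = set(shifts) - set(manifest.index)
    if missing:
        raise InvalidArgumentError(
            f"planted probes/regions outside manifest: {sorted(missing)[:5]}"
        )
    rng = np.random.default_rng(seed)
    probes = list(manifest.index)
    samples = list(sheet.index)
    case = (sheet["group"] == "case").to_numpy()
    n_p, n_s = len(probes), len(samples)

    comp = rng.random(n_p) >= _BETA_MIX_W
    a = np.where(comp, _BETA_MIX[1][0], _BETA_MIX[0][0])
    b = np.where(comp, _BETA_MIX[1][1], _BETA_MIX[0][1])
    base = rng.beta(a, b)

    # planted baselines: keep base and base+shift well inside (0,1)
    shift = np.zeros(n_p)
    for i, p in enumerate(probes):
        if p in shifts:
            d = shifts[p]
            lo = 0.05 + max(0.0, -d)
            hi = 0.95 - max(0.0, d)
            base[i] = rng.uniform(lo, hi)
            shift[i] = d

    base = np.clip(base, *_CLIP)
    m0 = _logit2(base)[:, None]
    if noise_sd > 0:
        m = m0 + rng.normal(0.0, noise_sd, size=(n_p, n_s))
        betas = _expit2(m)
    else:
        betas = np.repeat(base[:, None], n_s, axis=1)
    betas = betas + shift[:, None] * case[None, :]
    betas = np.clip(betas, *_CLIP)

    detp = rng.beta(1.0, 400.0, size=(n_p, n_s))
    if detp_fail_fraction > 0:
        fail = rng.random((n_p, n_s)) < detp_fail_fraction
        detp = np.where(fail, rng.uniform(0.06, 1.0, size=(n_p, n_s)), detp)

    beta_df = pd.DataFrame(betas, index=pd.Index(probes, name="probe_id"),
                           columns=samples)
    detp_df = pd.DataFrame(detp, index=beta_df.index, columns=samples)
    return beta_df, detp_df


def plant_dmrs(
    manifest: pd.DataFrame,
    n_regions: int = 5,
    probes_per_region: int = 5,
    delta_beta: float = 0.2,
    hyper_fraction: float = 0.5,
    seed: int = 0,
) -> list[DmrTruth]:
    """Choose runs of consecutive manifest probes as planted regions."""
    rng = np.random.default_rng(seed)
    regions: list[DmrTruth] = []
    used: set[str] = set()
    by_chrom = manifest.groupby("chrom", sort=False).indices
    chrom_names = list(by_chrom)
    attempts = 0
    while len(regions) < n_regions and attempts < 1000:
        attempts += 1
        chrom = chrom_names[int(rng.integers(len(chrom_names)))]
        idx = by_chrom[chrom]
        if len(idx) < probes_per_region:
            continue
        start = int(rng.integers(0, len(idx) - probes_per_region + 1))
        run = manifest.iloc[idx[start : start + probes_per_region]]
        if used & set(run.index):
            continue
        used.update(run.index)
        direction = "hyper" if rng.random() < hyper_fraction else "hypo"
        regions.append(
            DmrTruth(
                chrom=chrom,
                start=int(run["pos"].min()),
                end=int(run["pos"].max()),
                direction=direction,
                delta_beta=delta_beta,
                probes=list(run.index),
            )
        )
    if len(regions) < n_regions:
        raise InvalidArgumentError("could not place the requested planted regions")
    return regions


# ---------------------------------------------------------------------- PPI

def gen_ppi(
    genes: list[str],
    edge_prob: float = 0.05,
    planted_module: set[str] | frozenset[str] = frozenset(),
    module_density: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Random PPI edge table with one planted dense high-confidence module.

    Background edges appear independently with ``edge_prob`` and carry
    confidences uniform on [0.4, 1.0]; internal edges of the planted
    module appear with ``module_density`` and confidences uniform on
    [0.7, 1.0].
    """
    if len(set(genes)) != len(genes):
        raise InvalidArgumentError("duplicate gene names")
    if not set(planted_module) <= set(genes):
        raise InvalidArgumentError("planted module must be a subset of genes")
    rng = np.random.default_rng(seed)
    genes = list(genes)
    module = set(planted_module)
    rows = []
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            a, b = genes[i], genes[j]
            internal = a in module and b in module
            if internal:
                if rng.random() < module_density:
                    rows.append((a, b, rng.uniform(0.7, 1.0)))
            elif rng.random() < edge_prob:
                rows.append((a, b, rng.uniform(0.4, 1.0)))
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "confidence"])


# -------------------------------------------------------------------- clock

def gen_clock(
    manifest: pd.DataFrame,
    n_clock_probes: int = 50,
    adult_age: float = 20.0,
    max_age: float = 120.0,
    seed: int = 0,
) -> ClockModel:
    """Planted linear clock whose probes live in the manifest.

    All clock-probe betas are set to the same value per sample by the
    companion rule (:func:`apply_clock_truth`), so the linear predictor
    equals F(chronological age) exactly regardless of how the total weight
    is split across probes.
    """
    if n_clock_probes > len(manifest):
        raise InvalidArgumentError("n_clock_probes exceeds manifest size")
    if n_clock_probes < 1:
        raise InvalidArgumentError("n_clock_probes must be >= 1")
    rng = np.random.default_rng(seed)
    probes = list(
        manifest.index[rng.choice(len(manifest), n_clock_probes, replace=False)]
    )
    ref = ClockModel(intercept=0.0, coefficients={"_": 1.0}, adult_age=adult_age)
    f_lo = float(ref.transform_age(0.0))
    f_hi = float(ref.transform_age(max_age))
    total_w = (f_hi - f_lo) / 0.98
    split = rng.dirichlet(np.ones(n_clock_probes)) if n_clock_probes > 1 else np.ones(1)
    coefs = {p: float(w * total_w) for p, w in zip(probes, split)}
    intercept = f_lo - 0.01 * total_w
    return ClockModel(intercept=intercept, coefficients=coefs, adult_age=adult_age)


def apply_clock_truth(
    beta: pd.DataFrame, model: ClockModel, sheet: pd.DataFrame,
    max_age: float = 120.0,
) -> pd.DataFrame:
    """Overwrite clock-probe betas so the predictor hits F(age) per sample."""
    f_lo = float(model.transform_age(0.0))
    f_hi = float(model.transform_age(max_age))
    ages = sheet.loc[beta.columns, "age"].to_numpy(float)
    target = 0.01 + 0.98 * (model.transform_age(ages) - f_lo) / (f_hi - f_lo)
    out = beta.copy()
    for p in model.coefficients:
        out.loc[p] = target
    return out


# --------------------------------------------------------------- expression

def gen_expression(
    genes: list[str],
    sheet: pd.DataFrame,
    planted_degs: dict[str, float] | None = None,
    dispersion: float = 0.1,
    base_mean_log_mu: float = 4.0,
    base_mean_log_sd: float = 1.5,
    lib_size_log_sd: float = 0.2,
    base_means: np.ndarray | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Negative-binomial count matrix with planted log2 fold changes.

    Gene base means are log-normal (or supplied explicitly through
    ``base_means``, one value per gene; a zero mean gives an all-zero
    row); per-sample library-size factors are log-normal; case means are
    scaled by 2**lfc at planted genes.  ``dispersion`` is the NB
    overdispersion (variance = mu + disp * mu^2); zero gives Poisson
    counts.
    """
    planted_degs = planted_degs or {}
    if not set(planted_degs) <= set(genes):
        raise InvalidArgumentError("planted DEGs must be a subset of genes")
    if dispersion < 0:
        raise InvalidArgumentError("dispersion must be >= 0")
    rng = np.random.default_rng(seed)
    genes = list(genes)
    samples = list(sheet.index)
    case = (sheet["group"] == "case").to_numpy()

    if base_means is None:
        base = rng.lognormal(base_mean_log_mu, base_mean_log_sd, size=len(genes))
    else:
        base = np.asarray(base_means, dtype=float)
        if base.shape != (len(genes),) or (base < 0).any():
            raise InvalidArgumentError("base_means must be non-negative, one per gene")
    lib = (
        rng.lognormal(0.0, lib_size_log_sd, size=len(samples))
        if lib_size_log_sd > 0 else np.ones(len(samples))
    )
    lfc = np.array([planted_degs.get(g, 0.0) for g in genes])
    mu = base[:, None] * lib[None, :]
    mu = mu * np.where(case[None, :], np.exp2(lfc)[:, None], 1.0)

    if dispersion == 0:
        counts = rng.poisson(mu)
    else:
        r = 1.0 / dispersion
        p = r / (r + mu)
        counts = np.where(mu > 0, rng.negative_binomial(r, np.clip(p, 1e-12, 1.0)), 0)
    return pd.DataFrame(
        counts.astype(int), index=pd.Index(genes, name="gene_id"), columns=samples
    )


# ------------------------------------------------------------- TF resources

def gen_tf_resources(
    manifest: pd.DataFrame,
    dmr_truth: list[DmrTruth],
    tf_names: list[str],
    deg_genes: set[str] | list[str],
    overlap_fraction: float = 1.0,
    target_fraction: float = 0.5,
    modes: tuple[str, ...] = ("activation", "repression", "unknown"),
    n_decoy_clusters: int = 10,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """TF binding clusters (BED-style) and TF->target rows tied to truth.

    A fraction ``overlap_fraction`` of planted regions get a binding
    cluster overlapping them (TF drawn from ``tf_names``); decoy clusters
    land away from any planted region.  Each used TF targets a
    ``target_fraction`` Bernoulli subset of ``deg_genes`` (at least one),
    with interaction modes drawn from ``modes``.
    """
    if not tf_names:
        raise InvalidArgumentError("tf_names must be non-empty")
    rng = np.random.default_rng(seed)
    deg_genes = sorted(deg_genes)
    max_pos = {c: int(g["pos"].max()) for c, g in manifest.groupby("chrom")}
    for r in dmr_truth:
        if r.chrom not in max_pos or r.end > max_pos[r.chrom] + 10_000:
            raise InvalidArgumentError(
                f"planted region {r.chrom}:{r.start}-{r.end} outside manifest space"
            )

    clusters = []
    used_tfs: set[str] = set()
    for r in dmr_truth:
        if rng.random() >= overlap_fraction:
            continue
        tf = tf_names[int(rng.integers(len(tf_names)))]
        used_tfs.add(tf)
        pad_l = int(rng.integers(0, 200))
        pad_r = int(rng.integers(0, 200))
        # BED 0-based half-open covering the region
        clusters.append(
            {"chrom": r.chrom, "start": max(0, r.start - 1 - pad_l),
             "end": r.end + pad_r, "name": tf}
        )
    occupied = [(r.chrom, r.start, r.end) for r in dmr_truth]
    for _ in range(n_decoy_clusters):
        chrom = list(max_pos)[int(rng.integers(len(max_pos)))]
        width = int(rng.integers(200, 2000))
        start = int(rng.integers(0, max(1, max_pos[chrom])))
        end = start + width
        if any(c == chrom and start < e and s < end for c, s, e in occupied):
            continue
        clusters.append(
            {"chrom": chrom, "start": start, "end": end,
             "name": tf_names[int(rng.integers(len(tf_names)))]}
        )
    bed = pd.DataFrame(clusters, columns=["chrom", "start", "end", "name"])

    rows = []
    for tf in sorted(used_tfs) or tf_names[:1]:
        picks = [g for g in deg_genes if rng.random() < target_fraction]
        if not picks and deg_genes:
            picks = [deg_genes[int(rng.integers(len(deg_genes)))]]
        for g in picks:
            rows.append(
                {"tf": tf, "target": g,
                 "mode": modes[int(rng.integers(len(modes)))]}
            )
    targets = pd.DataFrame(rows, columns=["tf", "target", "mode"])
    return bed, targets


# --------------------------------------------------------------- validation

def validate_truth(
    truth: SyntheticTruth,
    manifest: pd.DataFrame,
    ppi: pd.DataFrame | None = None,
    counts: pd.DataFrame | None = None,
    beta: pd.DataFrame | None = None,
) -> None:
    """Assert that every planted identifier resolves against its resource."""
    probes = set(manifest.index)
    bad = set(truth.probe_shifts()) - probes
    if bad:
        raise InvalidArgumentError(f"planted probes not in manifest: {sorted(bad)[:5]}")
    if truth.clock is not None:
        bad = set(truth.clock.coefficients) - probes
        if bad:
            raise InvalidArgumentError(f"clock probes not in manifest: {sorted(bad)[:5]}")
    if ppi is not None and truth.module_genes:
        graph_genes = set(ppi["gene_a"]) | set(ppi["gene_b"])
        bad = truth.module_genes - graph_genes
        if bad:
            raise InvalidArgumentError(f"module genes not in PPI: {sorted(bad)[:5]}")
    if counts is not None:
        bad = set(truth.deg_genes) - set(counts.index)
        if bad:
            raise InvalidArgumentError(f"planted DEGs not in counts: {sorted(bad)[:5]}")
    if beta is not None:
        bad = set(truth.probe_shifts()) - set(beta.index)
        if bad:
            raise InvalidArgumentError(f"planted probes not in betas: {sorted(bad)[:5]}")


# ------------------------------------------------------------------- bundle

@dataclass
class SimConfig:
    """Study-condition defaults for a full synthetic input bundle."""

    n_cases: int = 8
    n_controls: int = 8
    n_probes: int = 2000
    n_chrom: int = 2
    mean_spacing: float = 500.0
    noise_sd: float = 0.15
    n_dms: int = 10
    dms_delta_beta: float = 0.2
    n_dmrs: int = 5
    probes_per_dmr: int = 5
    dmr_delta_beta: float = 0.2
    n_genes_expr: int = 2000
    n_planted_degs: int = 40
    deg_lfc: float = 1.5
    dispersion: float = 0.1
    ppi_edge_prob: float = 0.01
    pathway_edge_prob: float = 0.15
    module_size: int = 6
    module_density: float = 1.0
    n_clock_probes: int = 50
    n_tfs: int = 8
    flag_fractions: dict = field(
        default_factory=lambda: {"snp": 0.03, "non_cpg": 0.05, "sex": 0.02}
    )

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        import yaml

        data = yaml.safe_load(open(path)) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - known
        if bad:
            raise InvalidArgumentError(f"unknown simulation keys: {sorted(bad)}")
        return cls(**data)


def simulate_bundle(config: SimConfig | None = None, seed: int = 0) -> dict:
    """Generate every pipeline input with one planted truth.

    Returns a dict with keys: sheet, manifest, beta, detp, counts, ppi,
    clock, tf_clusters, tf_targets, gene_sets, truth.  Deterministic in
    (config, seed).
    """
    cfg = config or SimConfig()
    rng = np.random.default_rng(seed)
    subseeds = rng.integers(0, 2**31 - 1, size=12)

    sheet = gen_sample_sheet(cfg.n_cases, cfg.n_controls, seed=int(subseeds[0]))
    manifest = gen_manifest(
        cfg.n_probes, cfg.n_chrom, cfg.mean_spacing,
        flag_fractions=cfg.flag_fractions, seed=int(subseeds[1]),
    )

    clean = manifest[
        ~(manifest["snp_associated"] | manifest["non_cpg"] | manifest["sex_chrom"])
    ]
    dmr_truth = plant_dmrs(
        clean, cfg.n_dmrs, cfg.probes_per_dmr, cfg.dmr_delta_beta,
        seed=int(subseeds[2]),
    )
    taken = {p for r in dmr_truth for p in r.probes}
    free = [p for p in clean.index if p not in taken]
    pick = np.random.default_rng(int(subseeds[3])).choice(
        len(free), size=min(cfg.n_dms, len(free)), replace=False
    )
    signs = np.random.default_rng(int(subseeds[3]) + 1).choice([-1.0, 1.0], size=len(pick))
    dms_effects = {
        free[i]: float(s * cfg.dms_delta_beta) for i, s in zip(pick, signs)
    }

    clock = gen_clock(clean, cfg.n_clock_probes, seed=int(subseeds[4]))

    expr_genes = [f"G{i:04d}" for i in range(1, cfg.n_genes_expr + 1)]
    # half the planted DEGs drawn from the genes present in the PPI graph so
    # the integration stage has genuine cross-source structure
    deg_rng = np.random.default_rng(int(subseeds[5]))
    n_graph_degs = cfg.n_planted_degs // 2
    graph_slice = expr_genes[:200]
    deg_pool = list(
        deg_rng.choice(len(graph_slice), size=n_graph_degs, replace=False)
    )
    rest_pool = [
        200 + i
        for i in deg_rng.choice(
            len(expr_genes) - 200, size=cfg.n_planted_degs - n_graph_degs,
            replace=False,
        )
    ]
    deg_signs = deg_rng.choice([-1.0, 1.0], size=cfg.n_planted_degs)
    planted_degs = {
        expr_genes[i]: float(s * cfg.deg_lfc)
        for i, s in zip(deg_pool + rest_pool, deg_signs)
    }

    manifest_genes = sorted({g for g in manifest["gene"] if g})
    graph_genes = sorted(set(manifest_genes) | set(graph_slice))
    mod_rng = np.random.default_rng(int(subseeds[6]))
    module = {
        manifest_genes[i]
        for i in mod_rng.choice(len(manifest_genes), size=cfg.module_size, replace=False)
    }
    # module genes carry real (predominantly hypo) methylation signal at
    # their probes so the module is recoverable from the data
    mod_sign_rng = np.random.default_rng(int(subseeds[6]) + 1)
    for g in sorted(module):
        sign = -1.0 if mod_sign_rng.random() < 0.8 else 1.0
        for p in clean.index[clean["gene"] == g]:
            if p not in taken:
                dms_effects[p] = float(sign * cfg.dms_delta_beta)

    truth = SyntheticTruth(
        dms_effects=dms_effects,
        dmr_regions=dmr_truth,
        module_genes=module,
        deg_genes=planted_degs,
        clock=clock,
        seed=seed,
    )

    beta, detp = gen_methylation(
        manifest, sheet, truth, noise_sd=cfg.noise_sd, seed=int(subseeds[7])
    )
    beta = apply_clock_truth(beta, clock, sheet)
    ppi = gen_ppi(
        graph_genes, cfg.ppi_edge_prob, module, cfg.module_density,
        seed=int(subseeds[8]),
    )
    # functionally related genes cluster in interaction networks: add a
    # denser edge tier among the genes carrying planted signal so the
    # integration stage sees realistic cross-source structure
    dmr_gene_truth = {
        str(manifest.loc[p, "gene"])
        for r in dmr_truth for p in r.probes
        if str(manifest.loc[p, "gene"])
    }
    signal_genes = sorted(
        (set(planted_degs) | module | dmr_gene_truth) & set(graph_genes)
    )
    path_rng = np.random.default_rng(int(subseeds[8]) + 1)
    extra = []
    for i in range(len(signal_genes)):
        for j in range(i + 1, len(signal_genes)):
            if path_rng.random() < cfg.pathway_edge_prob:
                extra.append(
                    (signal_genes[i], signal_genes[j], path_rng.uniform(0.4, 1.0))
                )
    if extra:
        ppi = (
            pd.concat(
                [ppi, pd.DataFrame(extra, columns=["gene_a", "gene_b", "confidence"])]
            )
            .sort_values("confidence", ascending=False)
            .drop_duplicates(["gene_a", "gene_b"])
            .sort_values(["gene_a", "gene_b"])
            .reset_index(drop=True)
        )
    counts = gen_expression(
        expr_genes, sheet, planted_degs, cfg.dispersion, seed=int(subseeds[9])
    )
    tf_names = [f"TF{i}" for i in range(1, cfg.n_tfs + 1)]
    tf_clusters, tf_targets = gen_tf_resources(
        manifest, dmr_truth, tf_names, set(planted_degs), seed=int(subseeds[10]),
    )

    # small gene-set collection over the expression universe, one set per
    # planted-DEG slice plus random sets, for the enrichment stage
    gs_rng = np.random.default_rng(int(subseeds[11]))
    gene_sets = {"planted_degs": set(planted_degs)}
    for k in range(5):
        size = int(gs_rng.integers(10, 50))
        members = gs_rng.choice(len(expr_genes), size=size, replace=False)
        gene_sets[f"random_set_{k + 1}"] = {expr_genes[i] for i in members}

    validate_truth(truth, manifest, ppi=ppi, counts=counts, beta=beta)
    return {
        "sheet": sheet,
        "manifest": manifest,
        "beta": beta,
        "detp": detp,
        "counts": counts,
        "ppi": ppi,
        "clock": clock,
        "tf_clusters": tf_clusters,
        "tf_targets": tf_targets,
        "gene_sets": gene_sets,
        "truth": truth,
    }


def write_bundle(bundle: dict, outdir) -> dict[str, str]:
    """Write a simulated bundle to TSV/BED/CSV/JSON files; returns paths."""
    from pathlib import Path

    from . import io as mio

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "sheet": out / "samples.tsv",
        "manifest": out / "manifest.tsv",
        "beta": out / "beta.tsv",
        "detp": out / "detp.tsv",
        "counts": out / "counts.tsv",
        "ppi": out / "ppi.tsv",
        "clock": out / "clock.csv",
        "tf_clusters": out / "tf_clusters.bed",
        "tf_targets": out / "tf_targets.tsv",
        "gene_sets": out / "gene_sets.gmt",
        "truth": out / "truth.json",
    }
    mio.write_sample_sheet(bundle["sheet"], paths["sheet"])
    mio.write_manifest(bundle["manifest"], paths["manifest"])
    mio.write_matrix(bundle["beta"], paths["beta"])
    mio.write_matrix(bundle["detp"], paths["detp"])
    mio.write_matrix(bundle["counts"], paths["counts"])
    mio.write_ppi(bundle["ppi"], paths["ppi"])
    bundle["clock"].to_csv(paths["clock"])
    mio.write_bed6(bundle["tf_clusters"], paths["tf_clusters"])
    bundle["tf_targets"].to_csv(paths["tf_targets"], sep="\t", index=False)
    mio.write_gmt(bundle["gene_sets"], paths["gene_sets"])
    mio.write_json(bundle["truth"].to_json_dict(), paths["truth"])
    return {k: str(v) for k, v in paths.items()}
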