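"""DMR-anchored transcription-factor regulatory networks.

DMRs (particularly those not mapped to genes) are annotated against a
TF binding-cluster track (BED, 0-based half-open); a TF is supported by a
DMR when their intervals overlap by at least ``min_overlap`` bp.  TFs
with DMR support are then joined to a TF->target interaction table
restricted to the differentially expressed genes, producing a typed
regulatory network whose edges carry the interaction mode (activation,
repression, unknown) and the target's expression direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import InvalidArgumentError, NamingMismatchError

MODES = ("activation", "repression", "unknown")


def _check_chrom_naming(dmr_chroms: set[str], bed_chroms: set[str]) -> None:
    if not dmr_chroms or not bed_chroms:
        return
    if dmr_chroms & bed_chroms:
        return
    dmr_pref = all(c.startswith("chr") for c in dmr_chroms)
    bed_pref = all(c.startswith("chr") for c in bed_chroms)
    if dmr_pref != bed_pref:
        raise NamingMismatchError(
            "chromosome naming differs between DMRs and TF clusters "
            "(e.g. 'chr1' vs '1'); rename one input to match the other"
        )


def annotate_dmrs_to_tfs(
    dmrs: pd.DataFrame,
    clusters: pd.DataFrame,
    min_overlap: int = 1,
    intergenic_only: bool = False,
    ann: pd.DataFrame | None = None,
) -> dict[str, list[str]]:
    """Map each TF to the DMR ids whose intervals overlap its clusters.

    Both inputs are 0-based half-open; overlap length is
    ``min(end) - max(start)`` and must reach ``min_overlap``.  With
    ``intergenic_only`` (requires the probe annotation), DMRs whose member
    probes map to any gene are excluded first — the stricter reading in
    which only gene-free DMRs feed the TF branch.
    """
    if min_overlap < 1:
        raise InvalidArgumentError("min_overlap must be >= 1")
    use = dmrs
    if intergenic_only:
        if ann is None:
            raise InvalidArgumentError("intergenic_only requires the probe annotation")
        keep = []
        for dmr_id, row in dmrs.iterrows():
            probes = str(row["probes"]).split(",") if row.get("probes") else []
            genes = {
                g
                for p in probes
                if p in ann.index
                for g in str(ann.loc[p, "gene"]).split(";")
                if g and g != "nan"
            }
            if not genes:
                keep.append(dmr_id)
        use = dmrs.loc[keep]

    _check_chrom_naming(
        set(map(str, use["chrom"])) if len(use) else set(),
        set(map(str, clusters["chrom"])) if len(clusters) else set(),
    )
    support: dict[str, list[str]] = {}
    by_chrom = dict(tuple(clusters.groupby("chrom", sort=False)))
    for dmr_id, row in use.iterrows():
        cl = by_chrom.get(str(row["chrom"]))
        if cl is None:
            continue
        ov = cl[
            (cl["end"].clip(upper=row["end"]) - cl["start"].clip(lower=row["start"]))
            >= min_overlap
        ]
        for tf in ov["name"]:
            lst = support.setdefault(str(tf), [])
            if dmr_id not in lst:
                lst.append(dmr_id)
    return support


@dataclass
class RegulatoryNetwork:
    """Typed TF->DEG edges with DMR provenance."""

    edges: pd.DataFrame  # tf, target, mode, supporting_dmrs, target_direction
    unmatched_tfs: list[str] = field(default_factory=list)

    def to_dot(self) -> str:
        """DOT graph; edge style encodes the interaction mode."""
        style = {"activation": "solid", "repression": "dashed", "unknown": "dotted"}
        arrow = {"activation": "normal", "repression": "tee", "unknown": "none"}
        lines = ["digraph regnet {"]
        for row in self.edges.itertuples(index=False):
            lines.append(
                f'  "{row.tf}" -> "{row.target}" '
                f'[style={style[row.mode]}, arrowhead={arrow[row.mode]}, '
                f'label="{row.target_direction}"];'
            )
        lines.append("}")
        return "\n".join(lines)


def normalize_mode(mode: str) -> str:
    """Map free-text interaction modes onto the three-value enum."""
    m = str(mode).strip().lower()
    if m in ("activation", "activate", "activator", "+"):
        return "activation"
    if m in ("repression", "repress", "repressor", "-"):
        return "repression"
    return "unknown"


def build_regulatory_network(
    tf_support: dict[str, list[str]],
    targets: pd.DataFrame,
    degs: pd.DataFrame,
) -> RegulatoryNetwork:
    """Join DMR-supported TFs to their differentially expressed targets.

    ``targets`` needs columns tf/target/mode; ``degs`` is a DegTable
    (index gene, columns direction and is_deg, or any table whose index
    is the DEG set with a ``direction`` column).  TFs with support but no
    DEG target appear in ``unmatched_tfs`` rather than as edges.
    """
    if "is_deg" in degs.columns:
        degs = degs[degs["is_deg"]]
    deg_dir = degs["direction"].to_dict()

    rows = []
    matched: set[str] = set()
    for row in targets.itertuples(index=False):
        tf = str(row.tf)
        if tf not in tf_support:
            continue
        target = str(row.target)
        if target not in deg_dir:
            continue
        matched.add(tf)
        rows.append(
            {
                "tf": tf,
                "target": target,
                "mode": normalize_mode(row.mode),
                "supporting_dmrs": ",".join(tf_support[tf]),
                "target_direction": deg_dir[target],
            }
        )
    edges = pd.DataFrame(
        rows, columns=["tf", "target", "mode", "supporting_dmrs", "target_direction"]
    ).drop_duplicates(["tf", "target", "mode"]).reset_index(drop=True)
    unmatched = sorted(set(tf_support) - matched)
    return RegulatoryNetwork(edges=edges, unmatched_tfs=unmatched)
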