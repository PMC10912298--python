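"""Clade partitioning, congruence scoring and ligand-label assignment.

A clade here is a maximal subtree whose subtending edge carries bootstrap
support at or above a threshold (default 90, since well-supported receptor
clades sit behind near-100 edges while the deep edges between them are
weak) and holds at least two leaves; uncovered leaves become flagged
singletons.  Compartmentalization of a categorical label (species, motif,
planted clade) over the partition is quantified as per-clade purity plus
the adjusted Rand index between the clade partition and the category
partition — an assertable statistic standing in for by-eye congruence
calls.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from sklearn.metrics import adjusted_rand_score

from .io_catalog import SeedTable
from .motifs import MotifReport, MotifDiversityTable
from .phylogeny import Node, PhyloTree

__all__ = [
    "Clade",
    "CladeAnnotation",
    "partition_clades",
    "compartmentalization",
    "assign_labels",
    "report",
    "COLOR_PALETTE",
]

#: Deterministic clade colors, assigned in clade-size order.
COLOR_PALETTE = [
    "yellow", "green", "magenta", "maroon", "lightred", "blue", "orange",
    "grey", "cyan", "olive", "purple", "teal", "brown", "pink", "navy",
    "gold",
]

DEFAULT_SUPPORT_MIN = 90.0
DEFAULT_SIZE_MIN = 2


@dataclass
class Clade:
    clade_id: int
    members: list[str]
    support: float | None = None
    unplaced: bool = False


@dataclass
class CladeAnnotation:
    clade_id: int
    members: list[str]
    modal_dryxxx: str = "NA"
    modal_cwxp: str = "NA"
    modal_npxxy: str = "NA"
    dryxxx_purity: float = 0.0
    cwxp_purity: float = 0.0
    npxxy_purity: float = 0.0
    seed_labels: list[str] = field(default_factory=list)
    assigned_label: str = ""
    color: str = ""
    flags: list[str] = field(default_factory=list)


def partition_clades(tree: PhyloTree, support_min: float = DEFAULT_SUPPORT_MIN,
                     size_min: int = DEFAULT_SIZE_MIN) -> list[Clade]:
    """Cut the tree into maximal well-supported clades.

    The tree is unrooted (its basal trifurcation is an artifact of the
    agglomeration order), so clades are defined on splits: every internal
    edge with support >= ``support_min`` nominates its smaller leaf side
    (at least ``size_min`` leaves) as a candidate clade, and candidates are
    accepted greedily by decreasing size subject to disjointness — so each
    accepted clade is maximal.  Leaves not covered become singleton clades
    flagged unplaced.  The result partitions the leaf set.
    """
    full = set(tree.taxa)
    n = len(full)
    ref = min(full)
    candidates: list[tuple[int, list[str], float]] = []

    def visit(node: Node) -> set[str]:
        if not node.children:
            return {node.name}  # type: ignore[arg-type]
        below: set[str] = set()
        for child, _ in node.children:
            cset = visit(child)
            if child.children and child.support is not None:
                if 2 * len(cset) < n or (2 * len(cset) == n and ref not in cset):
                    side = cset
                else:
                    side = full - cset
                if child.support >= support_min and len(side) >= size_min:
                    candidates.append((len(side), sorted(side), child.support))
            below |= cset
        return below

    visit(tree.root)
    clades: list[Clade] = []
    covered: set[str] = set()
    for size, members, sup in sorted(candidates, key=lambda c: (-c[0], c[1])):
        if not covered.intersection(members):
            clades.append(Clade(0, members, support=sup))
            covered.update(members)
    for leaf in sorted(full - covered):
        clades.append(Clade(0, [leaf], unplaced=True))
    clades.sort(key=lambda c: (-len(c.members), c.members[0]))
    for k, clade in enumerate(clades):
        clade.clade_id = k + 1
    return clades


class UndefinedIndexError(ValueError):
    pass


def compartmentalization(clades: list[Clade],
                         labels: Mapping[str, str]) -> dict:
    """Per-clade purity and adjusted Rand index against a category labelling.

    Members labelled "NA" (or absent from ``labels``) are excluded.  Purity
    is the maximum within-clade category frequency; the congruence index is
    the ARI between the clade partition and the category partition.  A
    single effective clade leaves the ARI undefined (flagged, not raised,
    unless every member is NA).
    """
    clade_of: list[int] = []
    cat_of: list[str] = []
    purities: dict[int, float] = {}
    for clade in clades:
        cats = [labels.get(m, "NA") for m in clade.members]
        cats = [c for c in cats if c != "NA"]
        if cats:
            counts = Counter(cats)
            purities[clade.clade_id] = max(counts.values()) / len(cats)
            for c in cats:
                clade_of.append(clade.clade_id)
                cat_of.append(c)
    if not clade_of:
        raise UndefinedIndexError("all category labels are NA")
    distinct_clades = len(set(clade_of))
    if distinct_clades < 2:
        return {
            "per_clade_purity": purities,
            "congruence_index": None,
            "flags": ["ari-undefined:single-clade"],
        }
    ari = float(adjusted_rand_score(clade_of, cat_of))
    return {"per_clade_purity": purities, "congruence_index": ari, "flags": []}


def _modal(values: list[str]) -> tuple[str, float]:
    vals = [v for v in values if v not in ("", "NA", "Truncated", None)]
    if not vals:
        return "NA", 0.0
    counts = Counter(vals)
    modal, n = counts.most_common(1)[0]
    # deterministic tie-break: lexicographically smallest modal value
    top = sorted(v for v, c in counts.items() if c == n)
    modal = top[0]
    return modal, counts[modal] / len(vals)


def assign_labels(clades: list[Clade], seeds: SeedTable,
                  motif_reports: Mapping[str, MotifReport]) -> list[CladeAnnotation]:
    """Attach modal motifs, seed-derived labels and colors to clades.

    A clade with exactly one distinct seed label inherits it; a seedless
    clade is labelled ``novel:<modal DRYxxx>``; conflicting seeds yield the
    label ``conflict`` plus a flag.  Colors come from a fixed palette in
    clade-size order (the order of ``partition_clades`` output).
    """
    annotations: list[CladeAnnotation] = []
    for k, clade in enumerate(clades):
        reports = [motif_reports.get(m) for m in clade.members]
        dryxxx, p_dry = _modal([r.dryxxx for r in reports if r])
        cwxp, p_cw = _modal([
            (r.cwxp if r.cwxp_discernible else r.cwxp_fallback) or "NA"
            for r in reports if r
        ])
        npxxy, p_np = _modal([r.npxxy for r in reports if r])
        seed_labels = sorted({seeds[m] for m in clade.members if m in seeds})
        flags = list((["unplaced"] if clade.unplaced else []))
        if len(seed_labels) == 1:
            label = seed_labels[0]
        elif not seed_labels:
            label = f"novel:{dryxxx}"
        else:
            label = "conflict"
            flags.append("conflicting-seeds:" + "+".join(seed_labels))
        annotations.append(
            CladeAnnotation(
                clade_id=clade.clade_id,
                members=list(clade.members),
                modal_dryxxx=dryxxx, modal_cwxp=cwxp, modal_npxxy=npxxy,
                dryxxx_purity=p_dry, cwxp_purity=p_cw, npxxy_purity=p_np,
                seed_labels=seed_labels,
                assigned_label=label,
                color=COLOR_PALETTE[k % len(COLOR_PALETTE)],
                flags=flags,
            )
        )
    return annotations


def report(annotations: list[CladeAnnotation],
           motifs: Mapping[str, MotifReport],
           diversity: MotifDiversityTable | None,
           stats: Mapping[str, float],
           out_dir: str | Path,
           header_comment: str | None = None) -> dict[str, Path]:
    """Write the clade table, diversity table and run summary.

    Deterministic given identical inputs: fixed column order, clades in
    clade_id order, members sorted.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "clades": out_dir / "clade_table.tsv",
        "diversity": out_dir / "dry_diversity.tsv",
        "summary": out_dir / "summary.json",
    }
    with open(paths["clades"], "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write(
            "clade_id\tlabel\tcolor\tn_members\tmodal_dryxxx\tdryxxx_purity"
            "\tmodal_cwxp\tcwxp_purity\tmodal_npxxy\tnpxxy_purity"
            "\tseed_labels\tflags\tmembers\n"
        )
        for ann in sorted(annotations, key=lambda a: a.clade_id):
            fh.write(
                f"{ann.clade_id}\t{ann.assigned_label}\t{ann.color}\t"
                f"{len(ann.members)}\t{ann.modal_dryxxx}\t{ann.dryxxx_purity:.3f}\t"
                f"{ann.modal_cwxp}\t{ann.cwxp_purity:.3f}\t"
                f"{ann.modal_npxxy}\t{ann.npxxy_purity:.3f}\t"
                f"{','.join(ann.seed_labels) or 'NA'}\t"
                f"{','.join(ann.flags) or 'ok'}\t"
                f"{','.join(ann.members)}\n"
            )
    with open(paths["diversity"], "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        if diversity is not None:
            fh.write("aa\tpos1\tpos2\tpos3\n")
            for aa, row in diversity.percent.iterrows():
                fh.write(f"{aa}\t{row[1]:.1f}\t{row[2]:.1f}\t{row[3]:.1f}\n")
        else:
            fh.write("aa\tpos1\tpos2\tpos3\n")
    summary = {"n_clades": len(annotations), **{k: stats[k] for k in sorted(stats)}}
    paths["summary"].write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return paths
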