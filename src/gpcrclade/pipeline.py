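"""End-to-end annotation pipeline and its run configuration.

Stage order mirrors the annotation workflow: catalogue in, 7TM topology,
motif loci and DRY-locus diversity, seeded similarity clustering to pull
out the GnRHR-like superfamily, 7TM-span and full-ORF neighbor-joining
phylogenies with bootstrap, clade partitioning, congruence scoring and
ligand-label assignment, reports out.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import annotation as ann
from . import clustering as clu
from . import codon_graph as cg
from . import motifs as mot
from . import phylogeny as phy
from . import topology as top
from .io_catalog import ReceptorRecord, SeedTable, write_catalogue

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "load_config"]


@dataclass
class RunConfig:
    """All pipeline knobs; every numeric parameter must be positive."""

    topology_mode: str = "predict"       # predict | annotate
    topology_file: str | None = None     # required for mode "annotate"
    cluster_threshold: float = 1e-50     # E-value edge threshold
    layout_rounds: int = 10000
    layout_dims: int = 3
    bootstrap_replicates: int = 1000
    support_min: float = 90.0
    size_min: int = 2
    seed: int = 0
    out_dir: str | None = None
    run_layout: bool = False             # layout is visualization only
    distance_model: str = "p"

    def validate(self) -> None:
        for name in ("cluster_threshold", "layout_rounds", "layout_dims",
                     "bootstrap_replicates", "support_min", "size_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"config parameter {name} must be positive")
        if self.topology_mode not in ("predict", "annotate"):
            raise ValueError(f"unknown topology mode {self.topology_mode!r}")
        if self.topology_mode == "annotate" and not self.topology_file:
            raise ValueError("topology mode 'annotate' needs topology_file")


def load_config(path: str | Path, **overrides) -> RunConfig:
    """Read a flat key=value config file; keyword overrides win."""
    fields = {f.name: f.type for f in dataclasses.fields(RunConfig)}
    kwargs = {}
    for raw in open(path):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"config line without '=': {line!r}")
        key, value = (s.strip() for s in line.split("=", 1))
        if key not in fields:
            raise ValueError(f"unknown config key {key!r}")
        kwargs[key] = _coerce(key, value)
    kwargs.update({k: v for k, v in overrides.items() if v is not None})
    cfg = RunConfig(**kwargs)
    cfg.validate()
    return cfg


def _coerce(key: str, value: str):
    if key in ("layout_rounds", "layout_dims", "bootstrap_replicates",
               "size_min", "seed"):
        return int(value)
    if key in ("cluster_threshold", "support_min"):
        return float(value)
    if key == "run_layout":
        return value.lower() in ("1", "true", "yes")
    return value


@dataclass
class PipelineResult:
    topologies: dict[str, top.TopologyMap] = field(default_factory=dict)
    motif_reports: dict[str, mot.MotifReport] = field(default_factory=dict)
    diversity: mot.MotifDiversityTable | None = None
    graph: clu.SimilarityGraph | None = None
    layout: clu.ClusterLayout | None = None
    extracted: set[str] = field(default_factory=set)
    alignment_7tm: phy.Alignment | None = None
    alignment_orf: phy.Alignment | None = None
    tree_7tm: phy.PhyloTree | None = None
    tree_orf: phy.PhyloTree | None = None
    tree_congruence: dict | None = None
    clades: list[ann.Clade] = field(default_factory=list)
    annotations: list[ann.CladeAnnotation] = field(default_factory=list)
    congruence: dict | None = None
    stats: dict = field(default_factory=dict)
    paths: dict[str, Path] = field(default_factory=dict)


def compute_topologies(records: list[ReceptorRecord],
                       config: RunConfig) -> dict[str, top.TopologyMap]:
    if config.topology_mode == "annotate":
        maps = top.read_topology_annotation(config.topology_file)
        return {m.record_id: m for m in maps}
    out = {}
    for rec in records:
        try:
            out[rec.record_id] = top.predict_topology(rec)
        except top.TopologyError as exc:
            logger.warning("topology: %s", exc)
    return out


def run_pipeline(records: list[ReceptorRecord], seeds: SeedTable,
                 config: RunConfig | None = None) -> PipelineResult:
    """Run every stage on an in-memory catalogue; write artifacts if
    ``config.out_dir`` is set."""
    config = config or RunConfig()
    config.validate()
    if seeds:
        seeds.check_ids(r.record_id for r in records)
    result = PipelineResult()
    header = f"seed={config.seed}"

    # --- topology and motifs over the whole catalogue
    result.topologies = compute_topologies(records, config)
    accepted = {rid: t for rid, t in result.topologies.items() if t.accepted}
    by_id = {r.record_id: r for r in records}
    for rid, topo in accepted.items():
        result.motif_reports[rid] = mot.extract_motifs(by_id[rid].protein_seq, topo)
    logger.info("topology: %d/%d records accepted as 7TM",
                len(accepted), len(records))

    # --- DRY-locus diversity and explainability over the catalogue
    dry3 = [r.dry3 for r in result.motif_reports.values()]
    if dry3:
        result.diversity = mot.build_diversity_table(dry3)
        pos_stats = mot.position_statistics(result.diversity)
        freqs = _dry_frequencies(dry3)
        result.stats.update(pos_stats)
        result.stats["explainable_fraction"] = cg.explainable_fraction(freqs)
        result.stats["n_diversity"] = result.diversity.n

    # --- seeded clustering
    result.graph = clu.pairwise_similarity(records, threshold=config.cluster_threshold)
    if seeds:
        result.extracted = clu.extract_seeded_clusters(result.graph, seeds)
    else:
        result.extracted = set(result.graph.nodes)
    if config.run_layout:
        result.layout = clu.layout_clans(result.graph, rounds=config.layout_rounds,
                                         dims=config.layout_dims, seed=config.seed)

    # --- phylogenies of the extracted, topology-accepted subset
    subset = sorted(rid for rid in result.extracted if rid in accepted)
    if len(subset) >= 3:
        seqs_7tm = [(rid, top.trim_to_7tm(by_id[rid], accepted[rid]))
                    for rid in subset]
        seqs_orf = [(rid, by_id[rid].protein_seq) for rid in subset]
        result.alignment_7tm = phy.align(seqs_7tm)
        result.alignment_orf = phy.align(seqs_orf)
        result.tree_7tm = phy.bootstrap(result.alignment_7tm,
                                        replicates=config.bootstrap_replicates,
                                        seed=config.seed,
                                        model=config.distance_model)
        result.tree_orf = phy.bootstrap(result.alignment_orf,
                                        replicates=config.bootstrap_replicates,
                                        seed=config.seed + 1,
                                        model=config.distance_model)
        result.tree_congruence = phy.compare_trees(result.tree_7tm, result.tree_orf)

        # --- clades, congruence, labels
        result.clades = ann.partition_clades(result.tree_7tm,
                                             support_min=config.support_min,
                                             size_min=config.size_min)
        result.annotations = ann.assign_labels(result.clades, seeds,
                                               result.motif_reports)
        dryxxx_labels = {
            rid: rep.dryxxx for rid, rep in result.motif_reports.items()
        }
        try:
            result.congruence = ann.compartmentalization(result.clades, dryxxx_labels)
        except ann.UndefinedIndexError:
            result.congruence = None
        if result.congruence:
            result.stats["motif_congruence_ari"] = result.congruence["congruence_index"]
        result.stats["n_clades"] = len(
            [c for c in result.clades if not c.unplaced]
        )
        result.stats["rf_7tm_vs_orf"] = result.tree_congruence["rf_distance"]

    # --- artifacts
    if config.out_dir:
        out_dir = Path(config.out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_catalogue(records, result.topologies, result.motif_reports,
                        out_dir / "catalogue.tsv", header_comment=header)
        result.graph.to_tsv(out_dir / "edges.tsv", header_comment=header)
        if result.layout is not None:
            result.layout.to_tsv(out_dir / "layout.tsv", header_comment=header)
        if result.tree_7tm is not None:
            result.tree_7tm.to_file(out_dir / "tree_7tm.nwk")
            result.tree_orf.to_file(out_dir / "tree_orf.nwk")
            result.alignment_7tm.to_fasta(out_dir / "aligned_7tm.fasta")
        report_paths = ann.report(result.annotations, result.motif_reports,
                                  result.diversity, result.stats, out_dir,
                                  header_comment=header)
        result.paths = {"catalogue": out_dir / "catalogue.tsv",
                        "edges": out_dir / "edges.tsv", **report_paths}
    return result


def _dry_frequencies(dry3_list: list[str]) -> dict[str, float]:
    """Percent frequency of each clean DRY-locus 3-mer."""
    clean = [m for m in dry3_list
             if len(m) == 3 and all(c in cg.AMINO_ACIDS for c in m)]
    if not clean:
        return {}
    out: dict[str, float] = {}
    for m in clean:
        out[m] = out.get(m, 0.0) + 1.0
    return {m: 100.0 * c / len(clean) for m, c in out.items()}
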