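"""All-vs-all similarity, CLANS-style force-directed layout, seeded extraction.

The similarity graph is built from exact Smith–Waterman local alignments
(BLOSUM62, gap open 11 / extend 1) with Karlin–Altschul E-values
``E = K * m * n * exp(-lambda * S)`` using the gapped BLOSUM62 constants
lambda = 0.267, K = 0.041.  At desk scale exact alignment makes a heuristic
search engine unnecessary, and for the E-value regimes of interest
(E << 1) the E-value and P-value are interchangeable.

The layout reproduces the CLANS scheme: attraction along each edge
proportional to -log10(E) times the displacement, a uniform inverse-square
repulsion between every node pair, and a linearly cooling step size.  The
layout is visualization only — cluster membership is defined by connected
components of the thresholded graph, which is the reproducible
formalization of "clustered with the seeds".
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging
import math
from pathlib import Path

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from Bio import Align
from Bio.Align import substitution_matrices

from .io_catalog import ReceptorRecord, SeedTable

__all__ = [
    "SimilarityGraph",
    "ClusterLayout",
    "pairwise_similarity",
    "layout_clans",
    "extract_seeded_clusters",
]

logger = logging.getLogger(__name__)

LAMBDA = 0.267   # gapped BLOSUM62 Karlin-Altschul lambda
KAPPA = 0.041    # gapped BLOSUM62 Karlin-Altschul K
EVALUE_FLOOR = 1e-180  # floor before taking logs, avoids infinite weights
DEFAULT_THRESHOLD = 1e-50


@dataclass
class SimilarityGraph:
    """Undirected E-value graph over receptor ids (no self-edges)."""

    nodes: list[str]
    edges: list[tuple[str, str, float, float]]  # (i, j, evalue, weight)
    threshold: float = DEFAULT_THRESHOLD

    def edge_set(self) -> set[frozenset[str]]:
        return {frozenset((i, j)) for i, j, _, _ in self.edges}

    def to_tsv(self, path: str | Path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            fh.write("id1\tid2\tevalue\tweight\n")
            for i, j, ev, w in sorted(self.edges):
                fh.write(f"{i}\t{j}\t{ev:.6g}\t{w:.6f}\n")


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def karlin_altschul_evalue(score: float, m: int, n: int) -> float:
    """E = K * m * n * exp(-lambda * S); underflows to 0.0 for huge scores."""
    log_e = math.log(KAPPA * m * n) - LAMBDA * score
    return math.exp(log_e) if log_e > -700 else 0.0


def pairwise_similarity(records: list[ReceptorRecord],
                        threshold: float = DEFAULT_THRESHOLD) -> SimilarityGraph:
    """All-vs-all Smith–Waterman similarity graph at an E-value threshold.

    Symmetric by construction (one alignment per unordered pair, with
    m = len(i), n = len(j) entering only as the product m*n).
    """
    if len(records) < 2:
        logger.warning("similarity graph over %d record(s): no edges possible",
                       len(records))
        return SimilarityGraph([r.record_id for r in records], [], threshold)
    aligner = _aligner()
    nodes = [r.record_id for r in records]
    seqs = [r.protein_seq for r in records]
    edges = []
    for a in range(len(records)):
        for b in range(a + 1, len(records)):
            score = aligner.score(seqs[a], seqs[b])
            ev = karlin_altschul_evalue(score, len(seqs[a]), len(seqs[b]))
            if ev <= threshold:
                weight = -math.log10(max(ev, EVALUE_FLOOR))
                edges.append((nodes[a], nodes[b], ev, weight))
    return SimilarityGraph(nodes, edges, threshold)


@dataclass
class ClusterLayout:
    """Node coordinates from the force-directed layout."""

    nodes: list[str]
    coordinates: np.ndarray  # (n_nodes, dims)
    rounds: int
    seed: int

    def to_tsv(self, path: str | Path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            dims = self.coordinates.shape[1]
            fh.write("id\t" + "\t".join("xyz"[:dims]) + "\n")
            for rid, row in zip(self.nodes, self.coordinates):
                fh.write(rid + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")

    def project_2d(self) -> np.ndarray:
        """Collapse to 2D along the first two principal axes."""
        centred = self.coordinates - self.coordinates.mean(axis=0)
        _, _, vt = np.linalg.svd(centred, full_matrices=False)
        return centred @ vt[:2].T


def layout_clans(graph: SimilarityGraph, rounds: int = 10000, dims: int = 3,
                 seed: int = 0, step: float = 0.05, attraction: float = 1.0,
                 repulsion: float = 0.05, eps: float = 1e-3) -> ClusterLayout:
    """Force-directed layout of the similarity graph.

    Nodes start uniformly in the unit cube (seeded RNG).  Each round every
    node moves by ``step_t * (sum attractive + sum repulsive)``: attraction
    along each edge proportional to its -log10(E) weight times the
    displacement, repulsion between every pair proportional to
    ``1 / (distance^2 + eps)`` directed apart.  The step decays linearly to
    zero over the configured rounds, so the result is deterministic given
    the seed.
    """
    rng = np.random.default_rng(seed)
    n = len(graph.nodes)
    coords = rng.uniform(0.0, 1.0, size=(n, dims))
    if n == 0:
        return ClusterLayout(graph.nodes, coords, rounds, seed)
    index = {rid: k for k, rid in enumerate(graph.nodes)}
    if graph.edges:
        ei = np.array([index[i] for i, _, _, _ in graph.edges])
        ej = np.array([index[j] for _, j, _, _ in graph.edges])
        ew = np.array([w for _, _, _, w in graph.edges])
        wmax = ew.max() or 1.0
    else:
        ei = ej = ew = None
    for t in range(rounds):
        step_t = step * (1.0 - t / rounds)
        force = np.zeros_like(coords)
        # repulsion: every pair, inverse-square, directed apart
        diff = coords[:, None, :] - coords[None, :, :]
        d2 = (diff ** 2).sum(axis=-1) + eps
        np.fill_diagonal(d2, np.inf)
        force += repulsion * (diff / d2[..., None]).sum(axis=1)
        # attraction: along edges, proportional to weight x displacement
        if ei is not None:
            disp = coords[ej] - coords[ei]
            pull = attraction * (ew / wmax)[:, None] * disp
            np.add.at(force, ei, pull)
            np.add.at(force, ej, -pull)
        coords = coords + step_t * force
    return ClusterLayout(graph.nodes, coords, rounds, seed)


def extract_seeded_clusters(graph: SimilarityGraph, seeds: SeedTable) -> set[str]:
    """Union of connected components containing at least one seed.

    Cluster membership is a property of the thresholded graph alone; the
    force-directed layout plays no part.
    """
    if not seeds:
        raise ValueError("seed table is empty")
    index = {rid: k for k, rid in enumerate(graph.nodes)}
    present = [rid for rid in seeds if rid in index]
    if not present:
        logger.warning("no seed id present in the similarity graph")
        return set()
    if graph.edges:
        ei = [index[i] for i, _, _, _ in graph.edges]
        ej = [index[j] for _, j, _, _ in graph.edges]
        mat = coo_matrix(
            (np.ones(len(ei)), (ei, ej)), shape=(len(graph.nodes),) * 2
        )
        _, labels = connected_components(mat, directed=False)
    else:
        labels = np.arange(len(graph.nodes))
    seed_comps = {labels[index[rid]] for rid in present}
    return {rid for rid, k in index.items() if labels[k] in seed_comps}
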