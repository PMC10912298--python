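"""Single-nucleotide explainability of motif variants under the genetic code.

Many DRY-locus variants differ from the canonical motif in ways a single
nucleotide substitution within one codon can produce (D->E, Y->F, R->K ...).
This module computes, for every amino-acid pair, the minimum nucleotide
Hamming distance over all codon pairs of the standard genetic code (stop
codons excluded), and classifies motif variants as single-nucleotide
explainable: every deviating position must be one nucleotide away from the
canonical residue.  The rule is applied per codon position — a variant
deviating at two positions is explainable when each deviation is a
single-nucleotide step, since the two events hit different codons.
"""

from __future__ import annotations

from functools import lru_cache
from typing import Mapping

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import unambiguous_dna_by_id

__all__ = [
    "CodonGraph",
    "min_nt_distance",
    "is_single_nt_explainable",
    "explainable_fraction",
    "codon_path",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


class AlphabetError(ValueError):
    pass


def _codons_by_aa() -> dict[str, list[str]]:
    table = unambiguous_dna_by_id[1].forward_table  # standard code, no stops
    by_aa: dict[str, list[str]] = {aa: [] for aa in AMINO_ACIDS}
    for codon, aa in table.items():
        by_aa[aa].append(codon)
    return by_aa


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


class CodonGraph:
    """Minimum nucleotide Hamming distance between amino-acid pairs.

    ``dist[a][b]`` is an integer in 0..3: 0 on the diagonal, >= 1 for
    distinct amino acids, symmetric by construction.
    """

    def __init__(self) -> None:
        self.codons = _codons_by_aa()
        n = len(AMINO_ACIDS)
        d = np.zeros((n, n), dtype=int)
        for i, a in enumerate(AMINO_ACIDS):
            for j, b in enumerate(AMINO_ACIDS):
                if i < j:
                    d[i, j] = d[j, i] = min(
                        _hamming(ca, cb)
                        for ca in self.codons[a]
                        for cb in self.codons[b]
                    )
        self._dist = d
        self._index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

    def distance(self, aa1: str, aa2: str) -> int:
        try:
            return int(self._dist[self._index[aa1], self._index[aa2]])
        except KeyError as exc:
            raise AlphabetError(f"non-standard amino acid {exc.args[0]!r}") from exc

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self._dist, index=list(AMINO_ACIDS),
                            columns=list(AMINO_ACIDS))

    def to_tsv(self, path) -> None:
        self.as_frame().to_csv(path, sep="\t")


@lru_cache(maxsize=1)
def _graph() -> CodonGraph:
    return CodonGraph()


def min_nt_distance(aa1: str, aa2: str) -> int:
    """Minimum Hamming distance between any codons of ``aa1`` and ``aa2``."""
    return _graph().distance(aa1, aa2)


def is_single_nt_explainable(motif: str, canonical: str = "DRY") -> bool:
    """True iff every deviating position is one nucleotide from canonical.

    The exact canonical motif (zero deviations) is trivially explainable.
    """
    if len(motif) != len(canonical):
        raise ValueError(
            f"motif {motif!r} and canonical {canonical!r} differ in length"
        )
    return all(
        min_nt_distance(m, c) == 1
        for m, c in zip(motif, canonical)
        if m != c
    )


def explainable_fraction(freqs: Mapping[str, float],
                         canonical: str = "DRY") -> float:
    """Total frequency of single-nucleotide-explainable motifs.

    ``freqs`` maps motif -> frequency (any non-negative scale, typically
    percent); the result is on the same scale.
    """
    total = 0.0
    for motif, pct in freqs.items():
        if pct < 0:
            raise ValueError(f"negative frequency for {motif!r}")
        if is_single_nt_explainable(motif, canonical):
            total += pct
    return total


def codon_path(motif: str, canonical: str = "DRY") -> list[tuple[str, str]] | None:
    """Explicit codon-level witness that ``motif`` is reachable from
    ``canonical`` by one single-nucleotide event per deviating codon.

    Returns per-position ``(canonical_codon, variant_codon)`` pairs at
    Hamming distance equal to ``min_nt_distance`` (0 for matching
    positions), or None if some deviation needs more than one nucleotide.
    """
    graph = _graph()
    path: list[tuple[str, str]] = []
    for m, c in zip(motif, canonical):
        if m == c:
            codon = graph.codons[c][0]
            path.append((codon, codon))
            continue
        best = min(
            ((ca, cb) for ca in graph.codons[c] for cb in graph.codons[m]),
            key=lambda pair: _hamming(*pair),
        )
        if _hamming(*best) != 1:
            return None
        path.append(best)
    return path
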