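"""Extraction of the conserved DRY / CWxP / NPxxY motif loci.

Class-A GPCRs carry three activation-related motifs at fixed topological
addresses: the DRY tripeptide at the TM3/ICL2 junction (extended here to a
six-residue DRYxxx window), CWxP within TM6, and NPxxY within TM7 near its
cytoplasmic end.  The "DRY locus" is the three-residue window at the
junction regardless of its actual residues — receptors with ERY, DRF, or
even DRHEAV-style junctions still have a DRY locus.

Extraction is anchored to the predicted topology and made robust to small
boundary error by scanning a few residues around the anchor and scoring
candidate windows against the canonical residue preferences (D/E, the
near-universal R, and an aromatic third position).

Positions are 1-based within the sequence that was segmented.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .topology import TopologyMap, TopologyError

__all__ = [
    "TRUNCATED",
    "MotifReport",
    "MotifDiversityTable",
    "extract_dry_locus",
    "extract_dryxxx",
    "extract_cwxp",
    "extract_npxxy",
    "extract_motifs",
    "build_diversity_table",
    "position_statistics",
    "sm1_statistics",
]

TRUNCATED = "Truncated"

AROMATIC = frozenset("WYFH")
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

DRY_SCAN = 3  # scan offsets -DRY_SCAN..+DRY_SCAN around the TM3-end anchor


@dataclass
class MotifReport:
    """Motif loci of one receptor. Fields may hold ``Truncated``."""

    record_id: str
    dry3: str = TRUNCATED
    dry3_start: int = 0
    dry3_low_confidence: bool = False
    dryxxx: str = TRUNCATED
    cwxp: str | None = None
    cwxp_start: int | None = None
    cwxp_discernible: bool = False
    cwxp_fallback: str | None = None
    npxxy: str = TRUNCATED
    npxxy_start: int | None = None
    npxxy_discernible: bool = False


def _window(seq: str, start: int, length: int) -> str:
    """1-based window of given length; Truncated if it leaves the sequence."""
    if start < 1 or start + length - 1 > len(seq):
        return TRUNCATED
    return seq[start - 1 : start + length - 1]


def _score_dry(win: str) -> int:
    score = 0
    if win[0] in "DE":
        score += 1
    if win[1] == "R":
        score += 2
    if win[2] in AROMATIC:
        score += 1
    return score


def extract_dry_locus(seq: str, topo: TopologyMap) -> tuple[str, int, bool]:
    """DRY locus: best-scoring 3-mer near the cytoplasmic end of TM3.

    The anchored candidate is the 3-residue window ending at the last
    residue of M3; offsets -3..+3 around it are scored (+1 for D/E first,
    +2 for R second, +1 for an aromatic third).  Ties prefer the smaller
    |offset|, then the more N-terminal window.  If every window scores 0
    the anchored window is returned flagged low-confidence.

    Returns ``(3-mer, start, low_confidence)``; the 3-mer is ``Truncated``
    when the window leaves the sequence.
    """
    if not topo.accepted:
        raise TopologyError(f"{topo.record_id}: topology not accepted")
    _, m3_end = topo.segment("M3")
    anchor = m3_end - 2  # window ending at the last residue of M3
    best: tuple[int, int, int] | None = None  # (-score, |off|, off)
    for off in range(-DRY_SCAN, DRY_SCAN + 1):
        win = _window(seq, anchor + off, 3)
        if win == TRUNCATED or "X" in win:
            continue
        key = (-_score_dry(win), abs(off), off)
        if best is None or key < best:
            best = key
    if best is None:
        return TRUNCATED, anchor, True
    if -best[0] == 0:
        win = _window(seq, anchor, 3)
        return (win, anchor, True)
    start = anchor + best[2]
    return _window(seq, start, 3), start, False


def extract_dryxxx(seq: str, dry_start: int) -> str:
    """Six residues from the DRY-locus start; Truncated if fewer remain."""
    return _window(seq, dry_start, 6)


def extract_cwxp(seq: str, topo: TopologyMap) -> tuple[str | None, int | None, bool, str | None]:
    """CWxP motif within TM6: a C..P pair three residues apart.

    Among matches the one whose C is nearest the TM6 midpoint wins (ties go
    to the more extracellular, i.e. C-terminal, match).  With no match the
    motif is not discernible and the fallback is the 6-mer centred on the
    TM6 midpoint — the value reported for receptors, like the GnRHR clade,
    that genuinely lack the motif.

    Returns ``(4-mer or None, start or None, discernible, fallback or None)``.
    """
    if not topo.accepted:
        raise TopologyError(f"{topo.record_id}: topology not accepted")
    m6_start, m6_end = topo.segment("M6")
    mid = (m6_start + m6_end) // 2
    best: tuple[int, int, int] | None = None  # (|i-mid|, -i, i)
    for i in range(m6_start, m6_end - 2):
        if i + 3 > m6_end:
            break
        if seq[i - 1] == "C" and seq[i + 2] == "P":
            key = (abs(i - mid), -i, i)
            if best is None or key < best:
                best = key
    if best is not None:
        start = best[2]
        return _window(seq, start, 4), start, True, None
    fallback = _window(seq, mid - 2, 6)
    return None, None, False, fallback


def extract_npxxy(seq: str, topo: TopologyMap) -> tuple[str, int | None, bool]:
    """NPxxY motif within TM7: [N|D] P x x [Y|F], nearest the cytoplasmic end.

    With no match the motif is not discernible and the reported 5-mer is the
    window ending two residues before TM7's cytoplasmic end.
    """
    if not topo.accepted:
        raise TopologyError(f"{topo.record_id}: topology not accepted")
    m7_start, m7_end = topo.segment("M7")
    best: int | None = None
    for i in range(m7_start, m7_end - 3):
        if i + 4 > m7_end:
            break
        if seq[i - 1] in "ND" and seq[i] == "P" and seq[i + 3] in "YF":
            best = i  # scanning N->C; the last hit is nearest the C side
    if best is not None:
        return _window(seq, best, 5), best, True
    start = m7_end - 6  # 5-mer ending 2 residues before the cytoplasmic end
    win = _window(seq, start, 5)
    return win, (start if win != TRUNCATED else None), False


def extract_motifs(seq: str, topo: TopologyMap) -> MotifReport:
    """All motif loci of one receptor (requires an accepted topology)."""
    dry3, dry_start, lowconf = extract_dry_locus(seq, topo)
    report = MotifReport(topo.record_id, dry3=dry3, dry3_start=dry_start,
                         dry3_low_confidence=lowconf)
    report.dryxxx = extract_dryxxx(seq, dry_start) if dry3 != TRUNCATED else TRUNCATED
    report.cwxp, report.cwxp_start, report.cwxp_discernible, report.cwxp_fallback = (
        extract_cwxp(seq, topo)
    )
    report.npxxy, report.npxxy_start, report.npxxy_discernible = extract_npxxy(seq, topo)
    return report


@dataclass
class MotifDiversityTable:
    """Per-position amino-acid percentages over the DRY locus.

    ``percent`` is a 20-row DataFrame (amino acids) with columns 1, 2, 3 on
    the 0-100 scale; ``n`` counts the records included; ``n_excluded``
    counts entries dropped for containing X or being truncated.
    """

    n: int
    percent: pd.DataFrame
    n_excluded: int = 0


class EmptyInputError(ValueError):
    pass


def build_diversity_table(dry3_list: Iterable[str]) -> MotifDiversityTable:
    """Tabulate DRY-locus diversity as per-position residue percentages.

    Entries containing X or marked Truncated are excluded from the
    percentages and counted separately.
    """
    kept, excluded = [], 0
    for m in dry3_list:
        if m == TRUNCATED or len(m) != 3 or any(c not in AMINO_ACIDS for c in m):
            excluded += 1
        else:
            kept.append(m)
    if not kept and excluded == 0:
        raise EmptyInputError("no DRY-locus entries supplied")
    if not kept:
        raise EmptyInputError("all DRY-locus entries were truncated or contained X")
    counts = pd.DataFrame(0, index=list(AMINO_ACIDS), columns=[1, 2, 3], dtype=float)
    for m in kept:
        for pos, aa in enumerate(m, start=1):
            counts.loc[aa, pos] += 1
    percent = counts / len(kept) * 100.0
    return MotifDiversityTable(n=len(kept), percent=percent, n_excluded=excluded)


def position_statistics(table: MotifDiversityTable) -> dict[str, float]:
    """Headline DRY-locus statistics: % R at position 2, % aromatic at 3."""
    return {
        "percent_R_pos2": float(table.percent.loc["R", 2]),
        "percent_aromatic_pos3": float(table.percent.loc[list(AROMATIC), 3].sum()),
    }


def sm1_statistics(catalogue: pd.DataFrame | str) -> dict[str, float]:
    """Catalogue-level DRY-locus statistics from an SM1-format table.

    Accepts a catalogue TSV path or DataFrame with a ``dry3`` column (the
    layout written by :func:`gpcrclade.io_catalog.write_catalogue`) and
    returns the record count, the percentage of records with the canonical
    DRY motif, and the position statistics.  This is the entry point for
    recomputing the headline numbers from a full multi-species catalogue.
    """
    from .io_catalog import read_catalogue

    if not isinstance(catalogue, pd.DataFrame):
        catalogue = read_catalogue(catalogue)
    dry3 = [m for m in catalogue["dry3"] if m not in ("", "NA")]
    table = build_diversity_table(dry3)
    stats = position_statistics(table)
    n_dry = sum(1 for m in dry3 if m == "DRY")
    return {
        "n": table.n,
        "percent_DRY": 100.0 * n_dry / table.n,
        **stats,
    }
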