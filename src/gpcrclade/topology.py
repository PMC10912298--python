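"""7TM topology: hydropathy-based prediction, annotation-file ingest, trimming.

Class-A GPCRs thread the membrane seven times with the N-terminus outside
and the C-terminus inside the cell.  The built-in predictor is a classical
Kyte–Doolittle sliding-window segmenter, not a neural network: it finds
hydrophobic cores (windowed mean hydropathy >= 1.5 over a 19-residue
window), merges near-adjacent cores, refines each run's boundaries by
extending while the raw per-residue hydropathy stays positive, and accepts
the map only when exactly seven helices remain.  Output of dedicated
transmembrane predictors (DeepTMHMM-style three-line files) can be ingested
instead via :func:`read_topology_annotation`.

All coordinates are 1-based and inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_catalog import ReceptorRecord

__all__ = [
    "KYTE_DOOLITTLE",
    "TopologyMap",
    "TopologyError",
    "predict_topology",
    "read_topology_annotation",
    "write_topology_annotation",
    "trim_to_7tm",
    "induced_topology",
]

#: Kyte–Doolittle hydropathy scale; X (unknown residue) scores 0.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
    "X": 0.0,
}

WINDOW = 19          # sliding-window width (residues)
TM_THRESHOLD = 1.5   # windowed mean >= this marks a TM-core candidate
MERGE_GAP = 3        # candidate runs separated by < this many residues merge
MIN_TM_LEN = 15      # runs shorter than this are discarded
MAX_TM_LEN = 35      # longer runs are trimmed about their hydropathy peak

#: Segment label order for an accepted class-A map (N-out convention).
CANONICAL_ORDER = (
    "O", "M1", "I", "M2", "O", "M3", "I", "M4",
    "O", "M5", "I", "M6", "O", "M7", "I",
)


class TopologyError(ValueError):
    pass


@dataclass
class TopologyMap:
    """Per-residue topology labels and derived segments for one receptor.

    ``labels`` is a string over {O, M, I} of protein length (M residues are
    numbered via ``segments``).  ``segments`` is an ordered list of
    ``(label, start, end)`` with 1-based inclusive coordinates tiling the
    sequence.  ``accepted`` is True iff exactly seven TM runs were found.
    """

    record_id: str
    labels: str
    segments: list[tuple[str, int, int]] = field(default_factory=list)
    accepted: bool = False
    flag: str = ""

    def segment(self, label: str) -> tuple[int, int]:
        for lab, s, e in self.segments:
            if lab == label:
                return s, e
        raise KeyError(f"{self.record_id}: no segment {label!r}")

    def tm_boundaries(self) -> list[tuple[int, int]]:
        return [(s, e) for lab, s, e in self.segments if lab.startswith("M")]

    def check(self, seq_len: int) -> None:
        if len(self.labels) != seq_len:
            raise TopologyError(
                f"{self.record_id}: labels length {len(self.labels)} != "
                f"sequence length {seq_len}"
            )
        pos = 0
        for lab, s, e in self.segments:
            if s != pos + 1 or e < s:
                raise TopologyError(f"{self.record_id}: segments do not tile")
            pos = e
        if pos != seq_len:
            raise TopologyError(f"{self.record_id}: segments do not cover sequence")
        if self.accepted:
            order = tuple(lab for lab, _, _ in self.segments)
            if tuple(l for l in order if l != "") != _expected_order(order):
                raise TopologyError(f"{self.record_id}: segment order not canonical")


def _expected_order(order: tuple[str, ...]) -> tuple[str, ...]:
    # Accepted maps follow CANONICAL_ORDER, except that an empty N-terminus
    # (M1 starting at residue 1) or empty C-terminus drops the flanking
    # O/I segment.
    expected = list(CANONICAL_ORDER)
    if order and order[0] == "M1":
        expected = expected[1:]
    if order and order[-1] == "M7":
        expected = expected[:-1]
    return tuple(expected)


def hydropathy_profile(seq: str, window: int = WINDOW) -> np.ndarray:
    """Windowed-mean Kyte–Doolittle profile, clipped windows at the ends."""
    vals = np.array([KYTE_DOOLITTLE.get(a, 0.0) for a in seq])
    half = window // 2
    csum = np.concatenate([[0.0], np.cumsum(vals)])
    n = len(seq)
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def _candidate_runs(mask: np.ndarray) -> list[list[int]]:
    runs: list[list[int]] = []
    start = None
    for i, m in enumerate(mask):
        if m and start is None:
            start = i
        elif not m and start is not None:
            runs.append([start, i - 1])
            start = None
    if start is not None:
        runs.append([start, len(mask) - 1])
    return runs


def predict_topology(record: ReceptorRecord) -> TopologyMap:
    """Segment a receptor into O / M1..M7 / I by hydropathy.

    Returns an accepted map iff exactly seven TM helices are found; sides
    are then assigned by alternation starting extracellular at the
    N-terminus (the class-A convention).
    """
    seq = record.protein_seq
    if len(seq) < 7 * MIN_TM_LEN:
        raise TopologyError(
            f"{record.record_id}: sequence length {len(seq)} < minimum "
            f"{7 * MIN_TM_LEN} for a 7TM receptor"
        )
    bad = set(seq) - set(KYTE_DOOLITTLE)
    if bad:
        raise TopologyError(
            f"{record.record_id}: non-amino-acid characters {sorted(bad)}"
        )
    profile = hydropathy_profile(seq)
    raw = np.array([KYTE_DOOLITTLE[a] for a in seq])
    runs = _candidate_runs(profile >= TM_THRESHOLD)

    # Merge candidate runs separated by short gaps.
    merged: list[list[int]] = []
    for run in runs:
        if merged and run[0] - merged[-1][1] - 1 < MERGE_GAP:
            merged[-1][1] = run[1]
        else:
            merged.append(run)

    # Boundary refinement: the windowed mean only clears the threshold where
    # most of the window sits in the helix, so cores undershoot the true
    # helix extent; extend outward while raw hydropathy stays positive.
    refined: list[list[int]] = []
    for k, (s, e) in enumerate(merged):
        left_limit = merged[k - 1][1] + 1 if k else 0
        right_limit = merged[k + 1][0] - 1 if k + 1 < len(merged) else len(seq) - 1
        while s > left_limit and raw[s - 1] > 0:
            s -= 1
        while e < right_limit and raw[e + 1] > 0:
            e += 1
        if refined and s <= refined[-1][1]:
            s = refined[-1][1] + 1
        refined.append([s, e])

    # Extension stops only at non-positive residues, so runs that now touch
    # are one helix whose core was split by a shallow notch in the windowed
    # profile: coalesce them before filtering on length.
    coalesced: list[list[int]] = []
    for s, e in refined:
        if coalesced and s <= coalesced[-1][1] + 1:
            coalesced[-1][1] = e
        else:
            coalesced.append([s, e])
    refined = coalesced

    # Length filters.
    kept: list[tuple[int, int]] = []
    for s, e in refined:
        length = e - s + 1
        if length < MIN_TM_LEN:
            continue
        if length > MAX_TM_LEN:
            peak = s + int(np.argmax(profile[s : e + 1]))
            half = MAX_TM_LEN // 2
            ns = max(s, peak - half)
            ne = min(e, ns + MAX_TM_LEN - 1)
            ns = max(s, ne - MAX_TM_LEN + 1)
            s, e = ns, ne
        kept.append((s, e))

    return _assemble(record.record_id, len(seq), kept)


def _assemble(record_id: str, n: int, tm_runs: list[tuple[int, int]]) -> TopologyMap:
    """Build a TopologyMap from 0-based inclusive TM runs."""
    accepted = len(tm_runs) == 7
    flag = "" if accepted else "non-7TM"
    labels = ["?"] * n
    segments: list[tuple[str, int, int]] = []
    pos = 0
    for k, (s, e) in enumerate(tm_runs):
        side = "O" if k % 2 == 0 else "I"  # loop preceding TM k+1
        if s > pos:
            segments.append((_side_label(side, k, accepted), pos + 1, s))
            for i in range(pos, s):
                labels[i] = side
        segments.append((f"M{k + 1}" if accepted else "M", s + 1, e + 1))
        for i in range(s, e + 1):
            labels[i] = "M"
        pos = e + 1
    if pos < n:
        side = "O" if len(tm_runs) % 2 == 0 else "I"
        segments.append((_side_label(side, len(tm_runs), accepted), pos + 1, n))
        for i in range(pos, n):
            labels[i] = side
    topo = TopologyMap(record_id, "".join(labels), segments, accepted, flag)
    topo.check(n)
    return topo


def _side_label(side: str, k: int, accepted: bool) -> str:
    return side


def read_topology_annotation(path: str | Path) -> list[TopologyMap]:
    """Read a DeepTMHMM-style three-line topology file.

    Each record is ``>id``, a sequence line, then a label line of equal
    length over {O, M, I} (lowercase and the B/S surface/signal labels are
    folded into O).  M runs are numbered in order of occurrence; a map is
    accepted iff it has exactly seven.
    """
    path = Path(path)
    lines = [ln.rstrip("\n") for ln in open(path) if ln.strip()]
    maps: list[TopologyMap] = []
    i = 0
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise TopologyError(f"{path}: expected header at line {i + 1}")
        rid = lines[i][1:].split()[0]
        if i + 2 >= len(lines):
            raise TopologyError(f"{path}: truncated record {rid!r}")
        seq, lab = lines[i + 1], lines[i + 2]
        if len(seq) != len(lab):
            raise TopologyError(
                f"{path}: {rid}: label line length {len(lab)} != "
                f"sequence length {len(seq)}"
            )
        norm = []
        for c in lab:
            c = c.upper()
            if c in ("B", "S", "O"):
                norm.append("O")
            elif c in ("M", "I"):
                norm.append(c)
            else:
                raise TopologyError(f"{path}: {rid}: unknown topology label {c!r}")
        runs = _candidate_runs(np.array([c == "M" for c in norm]))
        maps.append(_assemble(rid, len(seq), [(s, e) for s, e in runs]))
        i += 3
    return maps


def write_topology_annotation(records, topologies, path: str | Path) -> None:
    """Write DeepTMHMM-dialect three-line records (the reader's inverse)."""
    with open(path, "w") as fh:
        for rec in records:
            topo = topologies[rec.record_id]
            fh.write(f">{rec.record_id}\n{rec.protein_seq}\n{topo.labels}\n")


def trim_to_7tm(record: ReceptorRecord, topo: TopologyMap) -> str:
    """Return the 7TM span: first residue of M1 through last residue of M7.

    Interior loops (ECLs/ICLs) are retained; the N- and C-termini are
    removed. Requires an accepted topology.
    """
    if not topo.accepted:
        raise TopologyError(
            f"{record.record_id}: cannot trim an unaccepted topology "
            f"({topo.flag or 'not 7TM'})"
        )
    s1, _ = topo.segment("M1")
    _, e7 = topo.segment("M7")
    return record.protein_seq[s1 - 1 : e7]


def induced_topology(topo: TopologyMap) -> TopologyMap:
    """Topology of the trimmed 7TM span (coordinates shifted to start at M1)."""
    if not topo.accepted:
        raise TopologyError(f"{topo.record_id}: topology not accepted")
    s1, _ = topo.segment("M1")
    _, e7 = topo.segment("M7")
    offset = s1 - 1
    segments = [
        (lab, s - offset, e - offset)
        for lab, s, e in topo.segments
        if s >= s1 and e <= e7
    ]
    labels = topo.labels[s1 - 1 : e7]
    out = TopologyMap(topo.record_id, labels, segments, True, topo.flag)
    out.check(len(labels))
    return out
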