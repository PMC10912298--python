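"""Receptor catalogue I/O: FASTA, seed tables and the per-transcript catalogue TSV.

The catalogue follows the ``<SpeciesCode>_<name>`` identifier convention used
for decapod GPCR transcripts (e.g. ``Cm_GPCR_A26`` — *Carcinus maenas*).
Species are recovered from the prefix before the first underscore when it is
one of the known two-letter codes; anything else yields species ``"NA"``
rather than an error, since public accessions (``Ha_XP042226332``-style ids
aside) do not follow the convention.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio.Seq import Seq

__all__ = [
    "ReceptorRecord",
    "SeedTable",
    "KNOWN_SPECIES",
    "SEED_VOCABULARY",
    "FastaFormatError",
    "DuplicateIdError",
    "VocabularyError",
    "CatalogueError",
    "read_fasta",
    "write_fasta",
    "read_seed_table",
    "write_catalogue",
    "read_catalogue",
    "species_from_id",
]

#: Two-letter species codes of the decapods (plus outgroup taxa) this
#: catalogue convention covers.
KNOWN_SPECIES = frozenset(
    {
        "Cb", "Cm", "Cq", "Es", "Gl", "Ha", "Nn", "Pc", "Pm", "Po", "Sv",
        "Sp", "Pp", "Lv", "Mr", "Pj", "Dp", "Pt",
    }
)

#: Controlled vocabulary for seed (prior annotation) labels: receptors of the
#: GnRH-like neuropeptide superfamily plus an explicit outgroup marker.
SEED_VOCABULARY = frozenset(
    {"GnRHR", "CrzR", "RPCHR", "ACPR1", "ACPR2", "VR1", "VR2", "CCAPR", "Outgroup"}
)

_AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")
_NT_ALPHABET = frozenset("ACGTUN")


class FastaFormatError(ValueError):
    """Malformed FASTA input; the message names the offending line."""


class DuplicateIdError(ValueError):
    """Two or more records share an identifier."""


class VocabularyError(ValueError):
    """A seed label outside the controlled vocabulary."""


class CatalogueError(ValueError):
    """Inconsistent keyed collections passed to the catalogue writer."""


@dataclass
class ReceptorRecord:
    """One receptor transcript: protein sequence plus optional CDS.

    ``cds_has_stop`` flags whether the CDS retains a trailing stop codon
    (length ``3 * (len(protein) + 1)``) or not (exactly ``3 * len(protein)``).
    """

    record_id: str
    protein_seq: str
    species: str = "NA"
    cds_seq: str | None = None
    source: str = ""
    cds_has_stop: bool = False

    def __post_init__(self) -> None:
        self.protein_seq = self.protein_seq.upper()
        if self.cds_seq is not None:
            self.cds_seq = self.cds_seq.upper().replace("U", "T")
        if not self.species or self.species == "NA":
            self.species = species_from_id(self.record_id)

    def validate(self) -> None:
        """Check alphabet and, if a CDS is present, length and translation."""
        bad = set(self.protein_seq) - _AA_ALPHABET
        if bad:
            raise ValueError(
                f"{self.record_id}: non-amino-acid characters {sorted(bad)}"
            )
        if self.cds_seq is None:
            return
        n_aa = len(self.protein_seq)
        expected = 3 * (n_aa + 1) if self.cds_has_stop else 3 * n_aa
        if len(self.cds_seq) != expected:
            raise ValueError(
                f"{self.record_id}: CDS length {len(self.cds_seq)} != expected "
                f"{expected} (stop={'retained' if self.cds_has_stop else 'absent'})"
            )
        coding = self.cds_seq[: 3 * n_aa]
        translated = str(Seq(coding).translate())
        for i, (a, b) in enumerate(zip(translated, self.protein_seq)):
            if b != "X" and a != b:
                raise ValueError(
                    f"{self.record_id}: CDS translation mismatch at residue "
                    f"{i + 1}: {a} != {b}"
                )


class SeedTable(dict):
    """Mapping record_id -> ligand label, restricted to SEED_VOCABULARY."""

    def __setitem__(self, key: str, value: str) -> None:
        if value not in SEED_VOCABULARY:
            raise VocabularyError(
                f"unknown seed label {value!r} for {key!r}; "
                f"allowed: {sorted(SEED_VOCABULARY)}"
            )
        super().__setitem__(key, value)

    def check_ids(self, known_ids: Iterable[str]) -> None:
        known = set(known_ids)
        missing = [rid for rid in self if rid not in known]
        if missing:
            raise KeyError(f"seed ids not present in catalogue: {missing}")


def species_from_id(record_id: str) -> str:
    """Prefix before the first underscore, if it is a known species code."""
    prefix = record_id.split("_", 1)[0]
    return prefix if prefix in KNOWN_SPECIES else "NA"


def read_fasta(path: str | Path, kind: str = "protein") -> list[ReceptorRecord]:
    """Read a FASTA file into ReceptorRecords.

    The header token before the first whitespace becomes ``record_id``;
    the remainder is kept as ``source``. ``kind`` selects which sequence
    slot (protein or CDS) is filled and which alphabet is enforced.
    """
    if kind not in ("protein", "nucleotide"):
        raise ValueError(f"kind must be 'protein' or 'nucleotide', got {kind!r}")
    path = Path(path)
    records: list[ReceptorRecord] = []
    seen: dict[str, int] = {}
    current_id: str | None = None
    current_desc = ""
    chunks: list[str] = []

    def _flush() -> None:
        if current_id is None:
            return
        seq = "".join(chunks).upper()
        if kind == "protein":
            rec = ReceptorRecord(current_id, seq, source=current_desc)
        else:
            rec = ReceptorRecord(current_id, "", source=current_desc)
            rec.protein_seq = ""
            rec.cds_seq = seq.replace("U", "T")
        records.append(rec)

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                header = line[1:].strip()
                if not header:
                    raise FastaFormatError(f"{path}: empty header at line {lineno}")
                parts = header.split(None, 1)
                current_id = parts[0]
                current_desc = parts[1] if len(parts) > 1 else ""
                chunks = []
                seen[current_id] = seen.get(current_id, 0) + 1
            else:
                if current_id is None:
                    raise FastaFormatError(
                        f"{path}: sequence data before any header at line {lineno}"
                    )
                alpha = _AA_ALPHABET if kind == "protein" else _NT_ALPHABET
                bad = set(line.upper()) - alpha
                if bad:
                    raise FastaFormatError(
                        f"{path}: invalid {kind} characters {sorted(bad)} "
                        f"at line {lineno}"
                    )
                chunks.append(line)
    _flush()
    dups = sorted(rid for rid, n in seen.items() if n > 1)
    if dups:
        raise DuplicateIdError(f"{path}: duplicate record ids {dups}")
    return records


def write_fasta(records: Iterable[ReceptorRecord], path: str | Path,
                kind: str = "protein", width: int = 60) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            seq = rec.protein_seq if kind == "protein" else (rec.cds_seq or "")
            fh.write(f">{rec.record_id}" + (f" {rec.source}" if rec.source else "") + "\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_seed_table(path: str | Path) -> SeedTable:
    """Read a two-column TSV (record_id, label) into a SeedTable.

    An empty table is valid: the pipeline then runs unlabeled.
    """
    path = Path(path)
    table = SeedTable()
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        return table
    header = lines[0].split("\t")
    if header[:2] == ["record_id", "label"]:
        body = lines[1:]
    elif len(header) >= 2 and header[1] in SEED_VOCABULARY:
        body = lines  # headerless file
    else:
        raise FastaFormatError(
            f"{path}: expected columns 'record_id' and 'label', got {header}"
        )
    for ln in body:
        fields = ln.split("\t")
        if len(fields) < 2:
            raise FastaFormatError(f"{path}: row with fewer than 2 columns: {ln!r}")
        table[fields[0]] = fields[1]
    return table


_CATALOGUE_COLUMNS = [
    "record_id", "species", "protein_length", "cds_length",
    "tm_boundaries", "accepted", "flag",
    "dry3", "dry3_start", "dryxxx", "cwxp", "cwxp_start",
    "cwxp_discernible", "cwxp_fallback", "npxxy", "npxxy_start",
    "npxxy_discernible",
]


def write_catalogue(records, topologies: Mapping, motifs: Mapping,
                    path: str | Path, header_comment: str | None = None) -> None:
    """Write one TSV row per record: id, species, lengths, TM boundaries and
    motif loci. Deterministic: sorted by record_id, fixed column order.

    ``topologies`` / ``motifs`` map record_id -> TopologyMap / MotifReport.
    Records missing a topology get "NA" topology fields and flag "rejected".
    """
    by_id = {r.record_id: r for r in records}
    stray = (set(topologies) | set(motifs)) - set(by_id)
    if stray:
        raise CatalogueError(f"annotations for unknown record ids: {sorted(stray)}")
    path = Path(path)
    buf = io.StringIO()
    if header_comment:
        buf.write(f"# {header_comment}\n")
    buf.write("\t".join(_CATALOGUE_COLUMNS) + "\n")
    for rid in sorted(by_id):
        rec = by_id[rid]
        topo = topologies.get(rid)
        mot = motifs.get(rid)
        if topo is not None and topo.accepted:
            tm = ";".join(
                f"{lab}:{s}-{e}" for lab, s, e in topo.segments if lab.startswith("M")
            )
            accepted, flag = "yes", topo.flag or "ok"
        elif topo is not None:
            tm, accepted, flag = "NA", "no", topo.flag or "rejected"
        else:
            tm, accepted, flag = "NA", "NA", "rejected"
        if mot is not None:
            mrow = [
                mot.dry3, str(mot.dry3_start), mot.dryxxx,
                mot.cwxp or "NA", str(mot.cwxp_start or "NA"),
                "yes" if mot.cwxp_discernible else "no",
                mot.cwxp_fallback or "NA",
                mot.npxxy, str(mot.npxxy_start or "NA"),
                "yes" if mot.npxxy_discernible else "no",
            ]
        else:
            mrow = ["NA"] * 10
        row = [
            rid, rec.species, str(len(rec.protein_seq)),
            str(len(rec.cds_seq)) if rec.cds_seq else "NA",
            tm, accepted, flag, *mrow,
        ]
        buf.write("\t".join(row) + "\n")
    path.write_text(buf.getvalue())


def read_catalogue(path: str | Path):
    """Read a catalogue TSV (as written by write_catalogue) into a DataFrame."""
    import pandas as pd

    return pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
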