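"""Codon-level simulator of class-A receptor families with planted truth.

The generator emits receptor families whose statistical structure matches
what the analysis pipeline assumes about real decapod GPCR data: K clades,
each founded by an independent random ancestor with a clade-specific
DRYxxx / CWxP / NPxxY motif triplet (the default templates are the eight
GnRH-superfamily clades with their published modal triplets, e.g. the
GnRHR clade's DRHEAV junction with no discernible CWxP), a canonical 7TM
hydrophobic architecture (N-out, seven 23-residue helices, 12-residue
loops, C-in), codon-level evolution by single-nucleotide substitutions on
a star phylogeny within each clade, and unrelated 7TM decoys.

Motif placement respects hydropathy: the DRYxxx 6-mer opens ICL2 (the
TM3/ICL2 union), CWxP sits at the TM6 midpoint, and NPxxY lies inside TM7
ending nine residues before its cytoplasmic end, so every planted helix
remains detectable by a sliding-window segmenter.  Within-clade motif
codons are exempt from substitution by default, emulating the purifying
selection that keeps these triplets constant within real clades.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Seq import Seq

from .io_catalog import ReceptorRecord, SeedTable, write_fasta
from .topology import TopologyMap, predict_topology

__all__ = [
    "CladeTemplate",
    "TruthRow",
    "DEFAULT_TEMPLATES",
    "build_ancestor_cds",
    "evolve_family",
    "generate_dataset",
    "planted_topology",
]

HYDROPHILIC = "DEKRNQSTGP"   # loop / terminus alphabet
HYDROPHOBIC = "AILVFM"       # TM fill alphabet (all Kyte-Doolittle > 0)

_CODONS = {
    aa: sorted(
        "".join(c) for c in itertools.product("TCAG", repeat=3)
        if str(Seq("".join(c)).translate()) == aa
    )
    for aa in "ACDEFGHIKLMNPQRSTVWY"
}
_STOPS = {"TAA", "TAG", "TGA"}


class TemplateError(ValueError):
    pass


@dataclass
class CladeTemplate:
    """Architecture and motif triplet of one clade's founding receptor."""

    label: str
    dryxxx: str
    cwxp: str | None          # None for clades lacking a discernible CWxP
    npxxy: str
    cwxp_fallback: str | None = None  # 6-mer planted when cwxp is None
    tm_len: int = 23
    loop_len: int = 12
    n_term: int = 25
    c_term: int = 20

    def __post_init__(self) -> None:
        if len(self.dryxxx) != 6 or len(self.npxxy) != 5:
            raise TemplateError(f"{self.label}: bad motif lengths")
        if self.cwxp is not None and len(self.cwxp) != 4:
            raise TemplateError(f"{self.label}: CWxP must be a 4-mer")
        if self.cwxp is None and (self.cwxp_fallback is None
                                  or len(self.cwxp_fallback) != 6):
            raise TemplateError(
                f"{self.label}: a 6-mer fallback is required when CWxP is absent"
            )
        if self.dryxxx[:3] != "DRY" and self.loop_len < 6:
            raise TemplateError(f"{self.label}: ICL2 too short for DRYxxx")
        if self.tm_len < 17:
            raise TemplateError(f"{self.label}: TM too short to host motifs")


#: The eight clade templates with their published modal motif triplets.
DEFAULT_TEMPLATES = [
    CladeTemplate("GnRHR", "DRHEAV", None, "NPFIY", cwxp_fallback="TNTPYV"),
    CladeTemplate("CrzR", "DRFTAV", "CWTP", "NPIIY"),
    CladeTemplate("RPCHR", "DRYFAV", "CWTP", "NPIVY"),
    CladeTemplate("ACPR1", "DRYFAV", "CWTP", "NPIIY"),
    CladeTemplate("ACPR2", "DRYFAI", "CWTP", "NPLVY"),
    CladeTemplate("VR1", "DRARAV", "CWSP", "NPWIY"),
    CladeTemplate("VR2", "DRYQVI", "CSAP", "NPWIF"),
    CladeTemplate("CCAPR", "DRYDAI", "CWSP", "NPIIY"),
]

_SPECIES_CYCLE = ["Cm", "Po", "Pc", "Nn", "Ha", "Pm", "Gl", "Cq", "Es", "Cb", "Sv"]


@dataclass
class TruthRow:
    """Ground truth for one generated record."""

    record_id: str
    clade: str
    is_seed: bool
    is_decoy: bool
    tm_boundaries: list[tuple[int, int]]  # 1-based inclusive
    dryxxx: str
    cwxp: str        # the 4-mer, or the fallback 6-mer for CWxP-less clades
    npxxy: str
    seed_value: int


def _architecture(t: CladeTemplate) -> list[tuple[str, int]]:
    """Segment plan: (label, length) in N->C order."""
    plan: list[tuple[str, int]] = [("O", t.n_term)]
    loops = ["I", "O", "I", "O", "I", "O"]  # ICL1, ECL1, ICL2, ECL2, ICL3, ECL3
    for k in range(7):
        plan.append((f"M{k + 1}", t.tm_len))
        if k < 6:
            plan.append((loops[k], t.loop_len))
    plan.append(("I", t.c_term))
    return plan


def _motif_positions(t: CladeTemplate) -> dict[str, tuple[int, str]]:
    """0-based protein start positions of the planted motifs."""
    plan = _architecture(t)
    pos = 0
    seg: dict[str, tuple[int, int]] = {}
    loop_after: dict[str, tuple[int, int]] = {}
    prev_tm = None
    for lab, length in plan:
        if lab.startswith("M"):
            seg[lab] = (pos, pos + length - 1)
            prev_tm = lab
        elif prev_tm is not None and prev_tm not in loop_after:
            loop_after[prev_tm] = (pos, pos + length - 1)
        pos += length
    out: dict[str, tuple[int, str]] = {}
    icl2 = loop_after["M3"]
    out["dryxxx"] = (icl2[0], t.dryxxx)
    m6 = seg["M6"]
    mid = (m6[0] + m6[1] + 2) // 2  # 0-based midpoint, matches extractor
    if t.cwxp is not None:
        out["cwxp"] = (mid - 1, t.cwxp)  # C at the 1-based midpoint
    else:
        out["cwxp"] = (mid - 3, t.cwxp_fallback)  # 6-mer centred on midpoint
    m7 = seg["M7"]
    # ends 9 residues before the cytoplasmic end: deep enough that the
    # sliding-window mean stays above threshold through the motif's
    # hydrophilic residues, keeping the TM7 boundary hydropathy-detectable
    out["npxxy"] = (m7[1] - 13, t.npxxy)
    return out


def planted_topology(record_id: str, t: CladeTemplate) -> TopologyMap:
    """The TopologyMap the generator plants (independent of hydropathy)."""
    labels = []
    segments = []
    pos = 0
    for lab, length in _architecture(t):
        segments.append((lab, pos + 1, pos + length))
        labels.append(("M" if lab.startswith("M") else lab) * length)
        pos += length
    topo = TopologyMap(record_id, "".join(labels), segments, accepted=True)
    topo.check(pos)
    return topo


def _protein_plan(t: CladeTemplate, rng: np.random.Generator) -> str:
    chars: list[str] = []
    for lab, length in _architecture(t):
        alphabet = HYDROPHOBIC if lab.startswith("M") else HYDROPHILIC
        chars.extend(rng.choice(list(alphabet), size=length))
    for start, motif in _motif_positions(t).values():
        for k, aa in enumerate(motif):
            chars[start + k] = aa
    return "".join(chars)


def _encode(protein: str, rng: np.random.Generator) -> str:
    """CDS with codons drawn uniformly among synonyms (no stop retained)."""
    return "".join(
        _CODONS[aa][rng.integers(0, len(_CODONS[aa]))] for aa in protein
    )


def build_ancestor_cds(template: CladeTemplate, seed: int,
                       record_id: str | None = None) -> tuple[ReceptorRecord, TruthRow]:
    """Construct one clade-founding receptor at the codon level.

    Termini and loops are drawn from hydrophilic residues, TM blocks from
    hydrophobic ones, motifs overwritten at their planted loci, and codons
    chosen uniformly among synonyms — all from one seeded RNG, so the same
    seed reproduces the same CDS.  The translation is verified to contain
    exactly seven hydropathy-detectable TM helices.
    """
    rng = np.random.default_rng(seed)
    protein = _protein_plan(template, rng)
    cds = _encode(protein, rng)
    rid = record_id or f"Syn_{template.label}_anc"
    rec = ReceptorRecord(rid, protein, cds_seq=cds, source=f"synthetic {template.label}")
    rec.validate()
    topo = predict_topology(rec)
    if not topo.accepted:
        raise TemplateError(
            f"{template.label}: planted architecture not hydropathy-detectable"
        )
    truth = TruthRow(
        record_id=rid, clade=template.label, is_seed=False, is_decoy=False,
        tm_boundaries=[(s, e) for lab, s, e in planted_topology(rid, template).segments
                       if lab.startswith("M")],
        dryxxx=template.dryxxx,
        cwxp=template.cwxp or template.cwxp_fallback,  # type: ignore[arg-type]
        npxxy=template.npxxy,
        seed_value=seed,
    )
    return rec, truth


def _protected_nt(template: CladeTemplate) -> set[int]:
    prot: set[int] = set()
    for start, motif in _motif_positions(template).values():
        for aa_pos in range(start, start + len(motif)):
            prot.update(range(3 * aa_pos, 3 * aa_pos + 3))
    return prot


def evolve_family(ancestor: ReceptorRecord, n_members: int,
                  subs_per_site: float, seed: int,
                  protect_motifs: bool = True,
                  template: CladeTemplate | None = None,
                  id_prefix: str | None = None) -> tuple[list[ReceptorRecord], list[TruthRow]]:
    """Evolve a star-phylogeny family from a clade ancestor.

    Each member independently accumulates ``Poisson(rate * CDS length)``
    single-nucleotide substitutions (uniform position, uniform alternative
    base); events creating stop codons are redrawn.  With
    ``protect_motifs`` the planted motif codons are exempt, emulating
    purifying selection on the triplets.  Truth rows record the realized
    (post-mutation) motif triplets.
    """
    if not 0.0 <= subs_per_site <= 0.3:
        raise ValueError(f"substitution rate {subs_per_site} outside [0, 0.3]")
    if ancestor.cds_seq is None:
        raise ValueError("ancestor must carry a CDS")
    rng = np.random.default_rng(seed)
    length = len(ancestor.cds_seq)
    protected = _protected_nt(template) if (protect_motifs and template) else set()
    positions = np.array(sorted(set(range(length)) - protected))
    prefix = id_prefix or ancestor.record_id
    records: list[ReceptorRecord] = []
    truths: list[TruthRow] = []
    mpos = _motif_positions(template) if template else {}
    for m in range(n_members):
        cds = list(ancestor.cds_seq)
        n_sub = rng.poisson(subs_per_site * length)
        applied = 0
        while applied < n_sub:
            p = int(positions[rng.integers(0, len(positions))])
            old = cds[p]
            alt = "ACGT".replace(old, "")[rng.integers(0, 3)]
            codon_start = 3 * (p // 3)
            codon = cds[codon_start : codon_start + 3]
            codon[p - codon_start] = alt
            if "".join(codon) in _STOPS:
                continue  # redraw the event
            cds[p] = alt
            applied += 1
        cds_str = "".join(cds)
        protein = str(Seq(cds_str).translate())
        rid = f"{prefix}_{m + 1:02d}"
        rec = ReceptorRecord(rid, protein, cds_seq=cds_str,
                             source=f"synthetic member of {ancestor.record_id}")
        rec.validate()
        records.append(rec)
        realized = {
            key: "".join(protein[start + k] for k in range(len(motif)))
            for key, (start, motif) in mpos.items()
        }
        truths.append(
            TruthRow(
                record_id=rid,
                clade=template.label if template else "NA",
                is_seed=False, is_decoy=False,
                tm_boundaries=[
                    (s, e)
                    for lab, s, e in planted_topology(rid, template).segments
                    if lab.startswith("M")
                ] if template else [],
                dryxxx=realized.get("dryxxx", "NA"),
                cwxp=realized.get("cwxp", "NA"),
                npxxy=realized.get("npxxy", "NA"),
                seed_value=seed,
            )
        )
    return records, truths


def _identity(a: str, b: str) -> float:
    n = min(len(a), len(b))
    return sum(a[i] == b[i] for i in range(n)) / n


def _build_decoy(rng: np.random.Generator, rid: str,
                 template_proteins: list[str],
                 base: CladeTemplate) -> ReceptorRecord:
    """A 7TM decoy: same architecture, random residues at every locus,
    rejection-sampled to < 30% identity against every clade ancestor."""
    for _ in range(100):
        chars: list[str] = []
        for lab, length in _architecture(base):
            alphabet = HYDROPHOBIC if lab.startswith("M") else HYDROPHILIC
            chars.extend(rng.choice(list(alphabet), size=length))
        protein = "".join(chars)
        if all(_identity(protein, tp) < 0.30 for tp in template_proteins):
            cds = _encode(protein, rng)
            rec = ReceptorRecord(rid, protein, cds_seq=cds, source="synthetic decoy")
            rec.validate()
            return rec
    raise RuntimeError("decoy rejection sampling failed (identity ceiling)")


def generate_dataset(templates: list[CladeTemplate] | None = None,
                     members_per_clade: int = 8, n_decoys: int = 40,
                     rate: float = 0.03, seed: int = 0,
                     out_dir: str | Path | None = None,
                     protect_motifs: bool = True):
    """Generate the full study dataset: clades, decoys, truth, topology.

    Returns ``(records, truths, seeds)``; when ``out_dir`` is given, also
    writes protein FASTA, CDS FASTA, truth TSV, seed TSV and a
    DeepTMHMM-dialect topology file of the planted topologies.  The first
    member of each clade is designated the seed, carrying the clade's
    ligand label.  Deterministic: the same seed reproduces every file
    byte for byte.
    """
    templates = templates if templates is not None else DEFAULT_TEMPLATES
    master = np.random.default_rng(seed)
    records: list[ReceptorRecord] = []
    truths: list[TruthRow] = []
    seeds = SeedTable()
    topo_by_id: dict[str, TopologyMap] = {}
    for ti, template in enumerate(templates):
        anc_seed = int(master.integers(0, 2**31 - 1))
        species = _SPECIES_CYCLE[ti % len(_SPECIES_CYCLE)]
        anc, _ = build_ancestor_cds(template, anc_seed,
                                    record_id=f"{species}_{template.label}_anc")
        fam_seed = int(master.integers(0, 2**31 - 1))
        members, member_truths = evolve_family(
            anc, members_per_clade, rate, fam_seed,
            protect_motifs=protect_motifs, template=template,
            id_prefix=f"{species}_{template.label}",
        )
        member_truths[0].is_seed = True
        seeds[members[0].record_id] = template.label
        for rec, tr in zip(members, member_truths):
            records.append(rec)
            truths.append(tr)
            topo_by_id[rec.record_id] = planted_topology(rec.record_id, template)
    base = templates[0]
    # identity screen against the clade seeds (closest proxies for the
    # ancestors among the emitted records)
    template_proteins = [
        rec.protein_seq for rec, tr in zip(records, truths) if tr.is_seed
    ]
    for k in range(n_decoys):
        rid = f"{_SPECIES_CYCLE[k % len(_SPECIES_CYCLE)]}_GPCR_D{k + 1:02d}"
        decoy = _build_decoy(master, rid, template_proteins, base)
        records.append(decoy)
        truths.append(
            TruthRow(rid, "decoy", False, True,
                     [(s, e) for lab, s, e in planted_topology(rid, base).segments
                      if lab.startswith("M")],
                     "NA", "NA", "NA", seed)
        )
        topo_by_id[rid] = planted_topology(rid, base)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_fasta(records, out_dir / "protein.fasta", kind="protein")
        write_fasta(records, out_dir / "cds.fasta", kind="nucleotide")
        with open(out_dir / "truth.tsv", "w") as fh:
            fh.write("record_id\tclade\tis_seed\tis_decoy\ttm_boundaries"
                     "\tdryxxx\tcwxp\tnpxxy\tseed\n")
            for tr in truths:
                tm = ";".join(f"{s}-{e}" for s, e in tr.tm_boundaries)
                fh.write(
                    f"{tr.record_id}\t{tr.clade}\t{int(tr.is_seed)}\t"
                    f"{int(tr.is_decoy)}\t{tm}\t{tr.dryxxx}\t{tr.cwxp}\t"
                    f"{tr.npxxy}\t{tr.seed_value}\n"
                )
        with open(out_dir / "seeds.tsv", "w") as fh:
            fh.write("record_id\tlabel\n")
            for rid in sorted(seeds):
                fh.write(f"{rid}\t{seeds[rid]}\n")
        with open(out_dir / "topology.3line", "w") as fh:
            for rec in records:
                topo = topo_by_id[rec.record_id]
                fh.write(f">{rec.record_id}\n{rec.protein_seq}\n{topo.labels}\n")
    return records, truths, seeds
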