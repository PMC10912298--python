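"""Motif locus extraction and DRY-locus diversity."""

import random

import pytest

from gpcrclade.io_catalog import ReceptorRecord
from gpcrclade.motifs import (
    TRUNCATED, build_diversity_table, EmptyInputError, extract_cwxp,
    extract_dry_locus, extract_dryxxx, extract_motifs, extract_npxxy,
    position_statistics, sm1_statistics,
)
from gpcrclade.synthetic_data import DEFAULT_TEMPLATES, build_ancestor_cds
from gpcrclade.topology import TopologyMap, predict_topology


def make_topo(seq_len: int, m3_end=None, m6=None, m7=None) -> TopologyMap:
    """Minimal accepted TopologyMap with the segments a test cares about."""
    segments = []
    if m3_end is not None:
        segments.append(("M3", m3_end - 2, m3_end))
    if m6 is not None:
        segments.append(("M6", *m6))
    if m7 is not None:
        segments.append(("M7", *m7))
    topo = TopologyMap("T_x", "?" * seq_len, segments, accepted=True)
    return topo


@pytest.mark.parametrize("template", DEFAULT_TEMPLATES, ids=lambda t: t.label)
def test_planted_templates_recovered_exactly(template):
    """At substitution rate 0 every clade template's motif triplet is
    extracted verbatim, including the CWxP-less clade's fallback 6-mer."""
    rec, truth = build_ancestor_cds(template, seed=11)
    topo = predict_topology(rec)
    rep = extract_motifs(rec.protein_seq, topo)
    assert rep.dryxxx == template.dryxxx
    assert rep.dry3 == template.dryxxx[:3]
    assert rep.npxxy == template.npxxy
    assert rep.npxxy_discernible
    if template.cwxp is None:
        assert not rep.cwxp_discernible
        assert rep.cwxp_fallback == template.cwxp_fallback
    else:
        assert rep.cwxp_discernible
        assert rep.cwxp == template.cwxp


class TestDryLocus:
    def test_planted_drh_window_beats_anchor(self):
        # junction: helix tail LLL, then DRHEAV opening the loop
        seq = "L" * 30 + "DRHEAV" + "G" * 10
        topo = make_topo(len(seq), m3_end=30)
        dry3, start, lowconf = extract_dry_locus(seq, topo)
        assert (dry3, start, lowconf) == ("DRH", 31, False)
        assert extract_dryxxx(seq, start) == "DRHEAV"

    def test_unscorable_junction_returns_anchor_low_confidence(self):
        seq = "G" * 40
        topo = make_topo(len(seq), m3_end=30)
        dry3, start, lowconf = extract_dry_locus(seq, topo)
        assert start == 28  # the anchored window, ending at the M3 end
        assert dry3 == "GGG"
        assert lowconf

    def test_window_past_sequence_end_is_truncated(self):
        seq = "L" * 29
        topo = make_topo(len(seq), m3_end=30)
        dry3, _, _ = extract_dry_locus(seq, topo)
        assert dry3 == TRUNCATED

    def test_dryxxx_truncates_near_end(self):
        assert extract_dryxxx("LLDRY", 3) == TRUNCATED

    def test_dryxxx_prefix_is_dry3(self):
        seq = "L" * 30 + "ERYFAV" + "G" * 10
        topo = make_topo(len(seq), m3_end=30)
        dry3, start, _ = extract_dry_locus(seq, topo)
        assert extract_dryxxx(seq, start)[:3] == dry3 == "ERY"


class TestCwxp:
    def test_planted_cwtp_mid_helix(self):
        seq = "G" * 10 + "L" * 9 + "CWTP" + "L" * 10 + "G" * 10
        topo = make_topo(len(seq), m6=(11, 33))
        cwxp, start, discernible, fallback = extract_cwxp(seq, topo)
        assert (cwxp, discernible, fallback) == ("CWTP", True, None)
        assert seq[start - 1 : start + 3] == "CWTP"

    def test_no_match_reports_fallback_6mer(self):
        # TNTPYV centred on the M6 midpoint (position 22), no C..P anywhere
        seq = "G" * 10 + "L" * 9 + "TNTPYV" + "L" * 8 + "G" * 10
        topo = make_topo(len(seq), m6=(11, 33))
        cwxp, start, discernible, fallback = extract_cwxp(seq, topo)
        assert cwxp is None and start is None and not discernible
        assert fallback == "TNTPYV"

    def test_equidistant_matches_prefer_extracellular(self):
        # two C..P motifs, C at offsets equidistant from the M6 midpoint;
        # M6 runs cytoplasmic->extracellular, so the later one wins
        m6 = "LLLLL" + "CAAP" + "CVVP" + "LL"  # C at positions 11 and 15
        seq = "G" * 5 + m6 + "G" * 5
        topo = make_topo(len(seq), m6=(6, 20))  # midpoint 13: both C's 2 away
        cwxp, start, discernible, _ = extract_cwxp(seq, topo)
        assert discernible
        assert cwxp == "CVVP"


class TestNpxxy:
    def test_planted_npiiy_found(self):
        seq = "G" * 5 + "L" * 10 + "NPIIY" + "L" * 8 + "G" * 5
        topo = make_topo(len(seq), m7=(6, 28))
        npxxy, start, discernible = extract_npxxy(seq, topo)
        assert (npxxy, discernible) == ("NPIIY", True)
        assert seq[start - 1 : start + 4] == "NPIIY"

    def test_dplvy_variant_matches_pattern(self):
        seq = "G" * 5 + "L" * 10 + "DPLVY" + "L" * 8 + "G" * 5
        topo = make_topo(len(seq), m7=(6, 28))
        npxxy, _, discernible = extract_npxxy(seq, topo)
        assert (npxxy, discernible) == ("DPLVY", True)

    def test_cytoplasmic_most_match_wins(self):
        seq = "G" * 5 + "NPAAY" + "L" * 5 + "NPVVY" + "L" * 8 + "G" * 5
        topo = make_topo(len(seq), m7=(6, 28))
        npxxy, _, _ = extract_npxxy(seq, topo)
        assert npxxy == "NPVVY"

    def test_no_match_fallback_ends_two_before_helix_end(self):
        seq = "G" * 5 + "L" * 23 + "G" * 5
        topo = make_topo(len(seq), m7=(6, 28))
        npxxy, start, discernible = extract_npxxy(seq, topo)
        assert not discernible
        assert start + 4 == 28 - 2  # 5-mer ends 2 residues before M7 end
        assert npxxy == "LLLLL"


class TestDiversityTable:
    def test_direct_counting(self):
        table = build_diversity_table(["DRY", "DRY", "ERY", "DRF"])
        assert table.n == 4
        assert table.percent.loc["D", 1] == 75.0
        assert table.percent.loc["E", 1] == 25.0
        assert table.percent.loc["R", 2] == 100.0
        assert table.percent.loc["Y", 3] == 75.0
        assert table.percent.loc["F", 3] == 25.0

    def test_single_entry(self):
        table = build_diversity_table(["DRY"])
        assert table.percent.loc["D", 1] == 100.0
        assert table.percent.loc["R", 2] == 100.0
        assert table.percent.loc["Y", 3] == 100.0

    def test_positions_sum_to_100(self):
        rng = random.Random(0)
        motifs = [
            "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(3))
            for _ in range(137)
        ]
        table = build_diversity_table(motifs)
        for pos in (1, 2, 3):
            assert abs(table.percent[pos].sum() - 100.0) < 1e-9

    def test_order_invariance(self):
        motifs = ["DRY", "ERY", "DRF", "DKY", "DRC"] * 7
        shuffled = list(motifs)
        random.Random(3).shuffle(shuffled)
        t1 = build_diversity_table(motifs)
        t2 = build_diversity_table(shuffled)
        assert t1.percent.equals(t2.percent)

    def test_x_and_truncated_excluded_but_counted(self):
        table = build_diversity_table(["DRY", "DXY", TRUNCATED])
        assert table.n == 1
        assert table.n_excluded == 2

    def test_empty_input_raises(self):
        with pytest.raises(EmptyInputError):
            build_diversity_table([])


class TestPositionStatistics:
    def test_counting(self):
        table = build_diversity_table(["DRY", "DRF", "DKH"])
        stats = position_statistics(table)
        assert stats["percent_R_pos2"] == pytest.approx(66.67, abs=0.01)
        assert stats["percent_aromatic_pos3"] == pytest.approx(100.0)

    def test_no_aromatic(self):
        stats = position_statistics(build_diversity_table(["DRM"]))
        assert stats["percent_aromatic_pos3"] == 0.0


def test_sm1_statistics_from_catalogue_file(tmp_path):
    """The catalogue-level entry point recomputes n, %DRY, %R and %aromatic
    from an SM1-format table alone."""
    path = tmp_path / "sm1.tsv"
    rows = ["DRY"] * 6 + ["ERY", "DRF", "DKM", "GGG"]
    header = "record_id\tspecies\tdry3\n"
    body = "".join(f"r{i}\tCm\t{m}\n" for i, m in enumerate(rows))
    path.write_text(header + body)
    stats = sm1_statistics(path)
    assert stats["n"] == 10
    assert stats["percent_DRY"] == pytest.approx(60.0)
    assert stats["percent_R_pos2"] == pytest.approx(80.0)
    assert stats["percent_aromatic_pos3"] == pytest.approx(80.0)
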