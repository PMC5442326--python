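"""Sequence scanning: consensus matches against a brute-force oracle,
repeat counting, and the nearest-neighbour extinction coefficient."""
import itertools
import re

import pytest
from hypothesis import given, settings, strategies as st

from tetrahelix.seqscan import (
    MotifMatch,
    NucleotideSequence,
    SequenceAlphabetError,
    UnsupportedResidueError,
    classify_sequence,
    count_repeats,
    extinction_260,
    read_fasta,
    scan_agcga,
    scan_g4,
    write_bed,
    write_match_tsv,
)

VK34 = "GCGAGGGAGCGAGGG"
FOUR_VK34 = "A".join([VK34] * 4)  # four units joined by single adenines


# ---------------------------------------------------------------------------
# independent brute-force oracle
# ---------------------------------------------------------------------------

def oracle_occurrences(seq: str, word: str) -> list[int]:
    return [m.start() for m in re.finditer(f"(?={re.escape(word)})", seq)]


def oracle_all(seq: str, word: str, min_spacer: int, max_spacer: int):
    """Every chain of four occurrences with in-range spacers."""
    occs = oracle_occurrences(seq, word)
    out = []
    for chain in itertools.combinations(occs, 4):
        spacers = [chain[k + 1] - chain[k] - len(word) for k in range(3)]
        if all(min_spacer <= s <= max_spacer for s in spacers):
            out.append(chain)
    return out


def oracle_minimal(seq: str, word: str, min_spacer: int, max_spacer: int):
    """Leftmost start, then shortest end, then smallest repeat starts;
    matches must not overlap."""
    chains = oracle_all(seq, word, min_spacer, max_spacer)
    picked, cursor = [], 0
    while True:
        live = [c for c in chains if c[0] >= cursor]
        if not live:
            return picked
        best = min(live, key=lambda c: (c[0], c[-1], c))
        picked.append(best)
        cursor = best[-1] + len(word)


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

class TestScanExamples:
    def test_vk34_has_no_agcga_match(self):
        seq = NucleotideSequence("VK34", VK34)
        assert scan_agcga(seq) == []
        # single AGCGA occurrence at offset 7
        assert count_repeats(seq) == (1, [7])

    def test_four_vk34_matches_oracle(self):
        seq = NucleotideSequence("4VK34", FOUR_VK34)
        got = scan_agcga(seq, both_strands=False)
        expect = oracle_minimal(FOUR_VK34, "AGCGA", 1, 20)
        assert [m.repeat_starts for m in got] == [tuple(c) for c in expect]
        assert len(got) == 1  # a single consensus match in minimal mode

    def test_minimal_construction(self):
        s = "AGCGAT" * 3 + "AGCGA"
        seq = NucleotideSequence("m", s)
        (m,) = scan_agcga(seq, both_strands=False)
        assert m.spacer_lengths == (1, 1, 1)
        assert m.start == 0 and m.end == len(s)

    def test_g4_on_four_vk34(self):
        seq = NucleotideSequence("4VK34", FOUR_VK34)
        got = scan_g4(seq, both_strands=False)
        assert got[0].repeat_starts == (4, 12, 20, 28)
        assert got[0].spacer_lengths == (5, 5, 5)

    def test_g4_minimal_tract(self):
        (m,) = scan_g4(NucleotideSequence("g", "GGGTGGGTGGGTGGG"),
                       both_strands=False)
        assert m.spacer_lengths == (1, 1, 1)

    def test_vk34_is_not_g4(self):
        assert scan_g4(NucleotideSequence("VK34", VK34)) == []

    def test_match_interval_identity(self):
        seq = NucleotideSequence("m", "AGCGAT" * 3 + "AGCGA")
        (m,) = scan_agcga(seq, both_strands=False)
        assert m.end - m.start == 4 * 5 + sum(m.spacer_lengths)


class TestScanProperties:
    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=0, max_size=200),
           st.integers(0, 3), st.integers(0, 25))
    def test_equivalence_with_oracle(self, s, min_spacer, extra):
        max_spacer = min_spacer + extra
        seq = NucleotideSequence("r", s) if s else None
        if seq is None:
            return
        got = scan_agcga(seq, min_spacer, max_spacer, both_strands=False)
        expect = oracle_minimal(s, "AGCGA", min_spacer, max_spacer)
        assert [m.repeat_starts for m in got] == [tuple(c) for c in expect]

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGTG", min_size=30, max_size=150))
    def test_all_mode_equivalence(self, s):
        seq = NucleotideSequence("r", s)
        got = scan_agcga(seq, 1, 20, both_strands=False, report="all")
        expect = oracle_all(s, "AGCGA", 1, 20)
        assert sorted(m.repeat_starts for m in got) == sorted(
            tuple(c) for c in expect
        )

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=25, max_size=120))
    def test_strand_symmetry(self, s):
        """Matches on seq equal strand-flipped matches on its reverse
        complement after coordinate mapping."""
        seq = NucleotideSequence("r", s)
        rc = seq.reverse_complement()
        fwd = scan_agcga(seq, both_strands=True)
        rev = scan_agcga(rc, both_strands=True)
        flip = {"+": "-", "-": "+"}
        remapped = sorted(
            (len(s) - m.end, len(s) - m.start, flip[m.strand]) for m in rev
        )
        assert sorted((m.start, m.end, m.strand) for m in fwd) == remapped

    def test_spacer_monotonicity(self):
        """Enlarging the spacer window never removes an 'all'-mode match."""
        s = ("AGCGA" + "T" * 3) * 2 + ("AGCGA" + "T" * 9) + "AGCGA"
        seq = NucleotideSequence("m", s)
        small = scan_agcga(seq, 2, 10, both_strands=False, report="all")
        large = scan_agcga(seq, 1, 20, both_strands=False, report="all")
        assert set(m.repeat_starts for m in small) <= set(
            m.repeat_starts for m in large
        )

    def test_empty_sequence_rejected_symbols(self):
        with pytest.raises(SequenceAlphabetError) as err:
            NucleotideSequence("bad", "ACGTXACGT")
        assert err.value.position == 4

    def test_poly_t_scans_empty(self):
        summary = classify_sequence(NucleotideSequence("t", "T" * 80))
        assert summary["n_agcga_repeats"] == 0
        assert summary["agcga_matches"] == []
        assert summary["g4_matches"] == []
        assert not summary["dual_consensus"]


class TestClassify:
    def test_four_vk34_dual_consensus(self):
        assert classify_sequence(NucleotideSequence("4VK34", FOUR_VK34))[
            "dual_consensus"
        ]

    def test_agcga_only_not_dual(self):
        seq = NucleotideSequence("m", "AGCGAT" * 3 + "AGCGA")
        assert not classify_sequence(seq)["dual_consensus"]


class TestCountRepeats:
    @pytest.mark.parametrize(
        "s,word,overlap,expected",
        [
            (VK34, "AGCGA", True, [7]),
            ("AGCGAGCGA", "AGCGA", True, [0, 4]),
            ("AGCGAGCGA", "AGCGA", False, [0]),
            ("", "AGCGA", True, []),
        ],
    )
    def test_counts(self, s, word, overlap, expected):
        n, pos = count_repeats(NucleotideSequence("s", s), word,
                               allow_overlap=overlap)
        assert (n, pos) == (len(expected), expected)

    def test_empty_sequence_yields_empty_results(self):
        empty = NucleotideSequence("e", "")
        assert count_repeats(empty) == (0, [])
        assert scan_agcga(empty) == []

    def test_empty_word_rejected(self):
        with pytest.raises(ValueError):
            count_repeats(NucleotideSequence("s", "ACGT"), "")


class TestExtinction:
    def test_vk34_reference_value(self):
        # nearest-neighbour value for the 15-mer GCGAGGGAGCGAGGG
        assert extinction_260(NucleotideSequence("VK34", VK34)) == pytest.approx(
            155200, rel=0.01
        )

    def test_single_residue_is_mononucleotide(self):
        assert extinction_260(NucleotideSequence("a", "A")) == 15400

    def test_dinucleotide_hand_value(self):
        # two-mer: dimer coefficient alone, no interior mononucleotides
        assert extinction_260(NucleotideSequence("at", "AT")) == 22800

    def test_unsupported_residue(self):
        with pytest.raises(UnsupportedResidueError):
            extinction_260(NucleotideSequence("n", "ACGTN"))


class TestIO:
    def test_fasta_and_writers_roundtrip(self, tmp_path):
        fasta = tmp_path / "in.fa"
        fasta.write_text(">s1\nagcgat" * 1 + "\n>s2\n" +
                         "AGCGAT" * 3 + "AGCGA\n")
        seqs = read_fasta(fasta)
        assert [s.id for s in seqs] == ["s1", "s2"]
        assert seqs[0].residues == "AGCGAT"  # case-insensitive parse
        matches = scan_agcga(seqs[1], both_strands=False)
        bed = tmp_path / "out.bed"
        tsv = tmp_path / "out.tsv"
        write_bed(matches, bed)
        write_match_tsv(matches, tsv)
        line = bed.read_text().strip().split("\t")
        assert line == ["s2", "0", "23", "AGCGA_QUAD", "4", "+"]
        body = tsv.read_text().splitlines()[1].split("\t")
        assert body[5] == "0,6,12,18"
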