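"""Consensus-motif scanning for AGCGA-quadruplex and G-quadruplex forming
sequences.

The AGCGA-quadruplex consensus is four literal 5'-AGCGA-3' repeats separated
by three spacers of 1-20 arbitrary residues; the G-quadruplex folding
consensus is four 5'-GGG-3' tracts separated by spacers of 1-7 residues.
Matches are reported in 0-based half-open coordinates on the plus strand.
"""
from __future__ import annotations

import functools
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

ALPHABET = set("ACGTNI")
_COMPLEMENT = str.maketrans("ACGTNI", "TGCANC")

AGCGA_REPEAT = "AGCGA"
G4_REPEAT = "GGG"
N_REPEATS = 4


class SequenceAlphabetError(ValueError):
    """Raised when a sequence contains a symbol outside {A,C,G,T,N,I}."""

    def __init__(self, seq_id: str, position: int, symbol: str):
        self.seq_id, self.position, self.symbol = seq_id, position, symbol
        super().__init__(
            f"sequence {seq_id!r}: invalid symbol {symbol!r} at position {position}"
        )


@dataclass(frozen=True)
class NucleotideSequence:
    """A named DNA sequence over the alphabet {A,C,G,T,N,I}."""

    id: str
    residues: str

    def __post_init__(self):
        up = self.residues.upper()
        object.__setattr__(self, "residues", up)
        for i, ch in enumerate(up):
            if ch not in ALPHABET:
                raise SequenceAlphabetError(self.id, i, ch)

    def __len__(self) -> int:
        return len(self.residues)

    def reverse_complement(self) -> "NucleotideSequence":
        return NucleotideSequence(self.id, self.residues.translate(_COMPLEMENT)[::-1])


def read_fasta(path: str | Path) -> list[NucleotideSequence]:
    """Read a (wrapped or unwrapped, case-insensitive) multi-record FASTA."""
    return [
        NucleotideSequence(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    ]


@dataclass(frozen=True)
class MotifMatch:
    seq_id: str
    start: int
    end: int
    strand: str  # '+' or '-'
    motif_class: str  # 'AGCGA_QUAD' or 'G4'
    repeat_starts: tuple[int, ...]
    spacer_lengths: tuple[int, ...]

    @property
    def n_repeats(self) -> int:
        return len(self.repeat_starts)


def find_occurrences(seq: str, word: str, allow_overlap: bool = True) -> list[int]:
    """0-based start positions of literal ``word`` in ``seq``."""
    if not word:
        raise ValueError("word must be non-empty")
    out, i = [], 0
    while True:
        i = seq.find(word, i)
        if i < 0:
            return out
        out.append(i)
        i += 1 if allow_overlap else len(word)


def count_repeats(
    seq: NucleotideSequence, word: str = AGCGA_REPEAT, allow_overlap: bool = True
) -> tuple[int, list[int]]:
    """Count occurrences of a repeat word; overlaps counted when allowed."""
    pos = find_occurrences(seq.residues, word.upper(), allow_overlap)
    return len(pos), pos


# ---------------------------------------------------------------------------
# consensus scanning
# ---------------------------------------------------------------------------

def _chains(
    occs: list[int], word_len: int, min_spacer: int, max_spacer: int, n_repeats: int
) -> Iterator[tuple[int, ...]]:
    """Enumerate all chains of ``n_repeats`` occurrences with valid spacers.

    Chains are yielded in lexicographic order of their repeat starts, which
    makes downstream tie-breaking deterministic.
    """

    def extend(chain: tuple[int, ...], idx: int) -> Iterator[tuple[int, ...]]:
        if len(chain) == n_repeats:
            yield chain
            return
        prev_end = chain[-1] + word_len
        lo, hi = prev_end + min_spacer, prev_end + max_spacer
        for j in range(idx, len(occs)):
            if occs[j] > hi:
                break
            if occs[j] >= lo:
                yield from extend(chain + (occs[j],), j + 1)

    for i in range(len(occs)):
        yield from extend((occs[i],), i + 1)


def _match_from_chain(
    seq_id: str, chain: tuple[int, ...], word_len: int, strand: str, motif_class: str
) -> MotifMatch:
    spacers = tuple(
        chain[k + 1] - (chain[k] + word_len) for k in range(len(chain) - 1)
    )
    return MotifMatch(
        seq_id=seq_id,
        start=chain[0],
        end=chain[-1] + word_len,
        strand=strand,
        motif_class=motif_class,
        repeat_starts=chain,
        spacer_lengths=spacers,
    )


def _scan_strand(
    seq_id: str,
    residues: str,
    word: str,
    min_spacer: int,
    max_spacer: int,
    report: str,
    strand: str,
    motif_class: str,
) -> list[MotifMatch]:
    occs = find_occurrences(residues, word)
    if report == "all":
        chains = list(_chains(occs, len(word), min_spacer, max_spacer, N_REPEATS))
        return [_match_from_chain(seq_id, c, len(word), strand, motif_class) for c in chains]
    # minimal: leftmost start, then shortest end, then lexicographically
    # smallest repeat_starts; matches must not overlap.
    matches: list[MotifMatch] = []
    cursor = 0
    while True:
        live = [o for o in occs if o >= cursor]
        best: tuple[int, ...] | None = None
        for chain in _chains(live, len(word), min_spacer, max_spacer, N_REPEATS):
            key = (chain[0], chain[-1], chain)
            if best is None or key < (best[0], best[-1], best):
                best = chain
        if best is None:
            return matches
        matches.append(_match_from_chain(seq_id, best, len(word), strand, motif_class))
        cursor = best[-1] + len(word)


def _map_minus(match: MotifMatch, length: int, word_len: int) -> MotifMatch:
    """Map a match found on the reverse complement back to plus-strand coords."""
    starts = tuple(sorted(length - (s + word_len) for s in match.repeat_starts))
    spacers = tuple(starts[k + 1] - (starts[k] + word_len) for k in range(len(starts) - 1))
    return MotifMatch(
        seq_id=match.seq_id,
        start=length - match.end,
        end=length - match.start,
        strand="-",
        motif_class=match.motif_class,
        repeat_starts=starts,
        spacer_lengths=spacers,
    )


def _scan(
    seq: NucleotideSequence,
    word: str,
    motif_class: str,
    min_spacer: int,
    max_spacer: int,
    both_strands: bool,
    report: str,
) -> list[MotifMatch]:
    if min_spacer < 0:
        raise ValueError("min_spacer must be >= 0")
    if max_spacer < min_spacer:
        raise ValueError("max_spacer must be >= min_spacer")
    if report not in ("minimal", "all"):
        raise ValueError("report must be 'minimal' or 'all'")
    out = _scan_strand(
        seq.id, seq.residues, word, min_spacer, max_spacer, report, "+", motif_class
    )
    if both_strands:
        rc = seq.reverse_complement()
        minus = _scan_strand(
            seq.id, rc.residues, word, min_spacer, max_spacer, report, "-", motif_class
        )
        out += [_map_minus(m, len(seq), len(word)) for m in minus]
    return sorted(out, key=lambda m: (m.start, m.end, m.strand, m.repeat_starts))


def scan_agcga(
    seq: NucleotideSequence,
    min_spacer: int = 1,
    max_spacer: int = 20,
    both_strands: bool = True,
    report: str = "minimal",
) -> list[MotifMatch]:
    """Find AGCGA-quadruplex consensus matches (four AGCGA repeats)."""
    return _scan(seq, AGCGA_REPEAT, "AGCGA_QUAD", min_spacer, max_spacer, both_strands, report)


def scan_g4(
    seq: NucleotideSequence,
    min_spacer: int = 1,
    max_spacer: int = 7,
    both_strands: bool = True,
    report: str = "minimal",
) -> list[MotifMatch]:
    """Find G-quadruplex folding consensus matches (four GGG tracts)."""
    return _scan(seq, G4_REPEAT, "G4", min_spacer, max_spacer, both_strands, report)


def classify_sequence(
    seq: NucleotideSequence,
    agcga_kwargs: dict | None = None,
    g4_kwargs: dict | None = None,
) -> dict:
    """Summarize a sequence: repeat counts, both consensus scans, and whether
    it satisfies the AGCGA and G4 consensus simultaneously."""
    n_repeats, _ = count_repeats(seq, AGCGA_REPEAT)
    agcga = scan_agcga(seq, **(agcga_kwargs or {}))
    g4 = scan_g4(seq, **(g4_kwargs or {}))
    return {
        "seq_id": seq.id,
        "n_agcga_repeats": n_repeats,
        "agcga_matches": agcga,
        "g4_matches": g4,
        "dual_consensus": bool(agcga) and bool(g4),
    }


# ---------------------------------------------------------------------------
# extinction coefficient (nearest-neighbour method)
# ---------------------------------------------------------------------------

class UnsupportedResidueError(ValueError):
    pass


@functools.cache
def _extinction_table() -> tuple[dict[str, float], dict[str, float], str]:
    mono: dict[str, float] = {}
    di: dict[str, float] = {}
    citation = ""
    text = resources.files("tetrahelix.data").joinpath("extinction_nn.tsv").read_text()
    for line in text.splitlines():
        if line.startswith("# Source:"):
            citation = line[2:].strip()
        if not line or line.startswith("#") or line.startswith("kind\t"):
            continue
        kind, key, eps = line.split("\t")
        (mono if kind == "mono" else di)[key] = float(eps)
    return mono, di, citation


def extinction_260(seq: NucleotideSequence) -> float:
    """Molar extinction coefficient at 260 nm (M^-1 cm^-1), nearest-neighbour
    method: sum of dinucleotide coefficients minus interior mononucleotides."""
    mono, di, _ = _extinction_table()
    s = seq.residues
    if len(s) == 0:
        raise ValueError("cannot compute extinction coefficient of empty sequence")
    for i, ch in enumerate(s):
        if ch not in mono:
            raise UnsupportedResidueError(
                f"sequence {seq.id!r}: no extinction data for residue {ch!r} "
                f"at position {i} (unmodified A/C/G/T only)"
            )
    if len(s) == 1:
        return mono[s]
    total = sum(di[s[i : i + 2]] for i in range(len(s) - 1))
    total -= sum(mono[ch] for ch in s[1:-1])
    return total


def extinction_citation() -> str:
    """Provenance string of the shipped nearest-neighbour table."""
    return _extinction_table()[2]


# ---------------------------------------------------------------------------
# output writers
# ---------------------------------------------------------------------------

def write_bed(matches: Iterable[MotifMatch], path: str | Path) -> None:
    """BED6: chrom, start, end, name=motif_class, score=repeat count, strand."""
    with open(path, "w") as fh:
        for m in matches:
            fh.write(
                f"{m.seq_id}\t{m.start}\t{m.end}\t{m.motif_class}\t{m.n_repeats}\t{m.strand}\n"
            )


def write_match_tsv(matches: Iterable[MotifMatch], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("seq_id\tmotif_class\tstart\tend\tstrand\trepeat_starts\tspacer_lengths\n")
        for m in matches:
            fh.write(
                "\t".join(
                    [
                        m.seq_id,
                        m.motif_class,
                        str(m.start),
                        str(m.end),
                        m.strand,
                        ",".join(map(str, m.repeat_starts)),
                        ",".join(map(str, m.spacer_lengths)),
                    ]
                )
                + "\n"
            )
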