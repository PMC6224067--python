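"""Type-II restriction enzymes and double digests of linear DNA.

The AFLP protocol modeled by this package cuts genomic DNA with two
enzymes at once: EcoRI, a rare cutter recognizing ``GAATTC`` and cutting
``G|AATTC``, and MseI, a frequent cutter recognizing ``TTAA`` and cutting
``T|TAA``.  Both motifs are palindromic, so a single top-strand scan finds
every double-stranded site.

Coordinates are 0-based and half-open on the top strand throughout; a cut
position is the index of the first base to the right of the scissile bond.
Sequences are treated as linear (no circular topology).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

__all__ = [
    "Enzyme",
    "CutSite",
    "RawFragment",
    "ECORI",
    "MSEI",
    "TERMINUS",
    "reverse_complement",
    "find_sites",
    "count_sites",
    "double_digest",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_ALPHABET = frozenset("ACGTN")

#: End label for the natural (uncut) ends of a linear sequence.
TERMINUS = "TERMINUS"


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_sequence(sequence: str) -> str:
    """Uppercase *sequence* and validate its alphabet.

    Raises ``ValueError`` for an empty sequence or for any character
    outside ``{A, C, G, T, N}``, naming the first offending position.
    """
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    if not _ALPHABET.issuperset(seq):
        for i, ch in enumerate(seq):
            if ch not in _ALPHABET:
                raise ValueError(
                    f"invalid base {ch!r} at position {i}; expected A/C/G/T/N"
                )
    return seq


@dataclass(frozen=True)
class Enzyme:
    """A type-II restriction endonuclease.

    Parameters
    ----------
    name
        Short display name, e.g. ``"EcoRI"``.
    recognition
        Recognition motif on the top strand (uppercase A/C/G/T; the two
        default enzymes are palindromic).
    cut_offset
        Index within the motif where the top strand is cut.  EcoRI cuts
        G|AATTC (offset 1); MseI cuts T|TAA (offset 1).
    """

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        if len(self.recognition) < 4:
            raise ValueError("recognition motif must be at least 4 bp")
        if not set(self.recognition) <= set("ACGT"):
            raise ValueError("recognition motif must be uppercase A/C/G/T")
        if not 0 <= self.cut_offset < len(self.recognition):
            raise ValueError("cut_offset must lie within the motif")


ECORI = Enzyme("EcoRI", "GAATTC", 1)
MSEI = Enzyme("MseI", "TTAA", 1)

#: Enzymes resolvable by name on the command line.
BUILTIN_ENZYMES = {"EcoRI": ECORI, "MseI": MSEI}


@dataclass(frozen=True)
class CutSite:
    """A single top-strand cut produced by one enzyme."""

    seq_id: str
    cut_pos: int
    enzyme: str


@dataclass(frozen=True)
class RawFragment:
    """A cut-to-cut (or cut-to-terminus) interval of a digested sequence."""

    seq_id: str
    start: int
    end: int
    left_end: str
    right_end: str

    @property
    def length(self) -> int:
        return self.end - self.start


def _iter_motif_starts(seq: str, motif: str) -> Iterator[int]:
    # str.find with a start of i+1 reports overlapping occurrences too.
    i = seq.find(motif)
    while i != -1:
        yield i
        i = seq.find(motif, i + 1)


def find_sites(sequence: str, enzyme: Enzyme, seq_id: str = "seq") -> list[CutSite]:
    """All recognition-site cuts of *enzyme* in *sequence*, sorted by position.

    Overlapping motif occurrences are all reported.  Motif windows
    containing ``N`` never match (a reference gap must not fabricate a
    site).
    """
    seq = normalize_sequence(sequence)
    return [
        CutSite(seq_id, start + enzyme.cut_offset, enzyme.name)
        for start in _iter_motif_starts(seq, enzyme.recognition)
    ]


def count_sites(sequence: str, enzyme: Enzyme) -> int:
    """Number of recognition-site occurrences of *enzyme* in *sequence*."""
    return len(find_sites(sequence, enzyme))


def double_digest(
    sequence: str,
    enzyme_a: Enzyme = ECORI,
    enzyme_b: Enzyme = MSEI,
    seq_id: str = "seq",
) -> list[RawFragment]:
    """Fragment *sequence* at the union of the two enzymes' cut positions.

    Returns the ordered tiling of ``[0, len)``: consecutive fragments abut,
    internal boundaries carry the name of the cutting enzyme, and the two
    outermost ends are labeled ``TERMINUS``.  Should a user-supplied enzyme
    pair ever cut at the same position (impossible for EcoRI/MseI), the
    boundary is labeled with the lexicographically smaller enzyme name so
    results stay deterministic.
    """
    if enzyme_a.name == enzyme_b.name:
        raise ValueError("double_digest requires two distinct enzymes")
    seq = normalize_sequence(sequence)
    n = len(seq)

    cuts: dict[int, str] = {}
    for enz in (enzyme_a, enzyme_b):
        for site in find_sites(seq, enz, seq_id):
            pos = site.cut_pos
            if not 0 < pos < n:
                continue  # a cut at the very edge produces no new boundary
            prev = cuts.get(pos)
            cuts[pos] = enz.name if prev is None else min(prev, enz.name)

    boundaries = sorted(cuts)
    fragments: list[RawFragment] = []
    left = 0
    left_label = TERMINUS
    for pos in boundaries:
        fragments.append(RawFragment(seq_id, left, pos, left_label, cuts[pos]))
        left, left_label = pos, cuts[pos]
    fragments.append(RawFragment(seq_id, left, n, left_label, TERMINUS))
    return fragments


def digest_all(
    sequences: dict[str, str],
    enzyme_a: Enzyme = ECORI,
    enzyme_b: Enzyme = MSEI,
) -> list[RawFragment]:
    """Double-digest every record of a multi-FASTA dict, concatenating results."""
    out: list[RawFragment] = []
    for seq_id, seq in sequences.items():
        out.extend(double_digest(seq, enzyme_a, enzyme_b, seq_id=seq_id))
    return out


def fragment_sequence(fragment: RawFragment, sequences: str | dict[str, str]) -> str:
    """Top-strand slice of *fragment* from its source sequence."""
    seq = sequences if isinstance(sequences, str) else sequences[fragment.seq_id]
    return seq[fragment.start : fragment.end].upper()
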