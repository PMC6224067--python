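"""Recognition of AFLP fragments in sequencing reads.

A read is attributed to a predicted fragment when it shows the expected
terminal signatures — the EcoRI remnant plus selective bases
(``AATTC`` + AXX) at one end and, reading in from the other end, the MseI
remnant plus selective bases (``TAA`` + CXX) — and its implied insert
length matches the candidate's within a size tolerance.

Remnant and selective bases define marker identity, so no mismatches are
tolerated inside the signatures; elsewhere a small mismatch budget
(default 1) absorbs sequencing errors.  When two or more candidates
explain a read equally well it is left unassigned with an ambiguity flag
rather than guessed.  Groups of same-sized but non-identical sequences
for one primer combination — size homoplasy, the classic confounder of
fragment co-migration — are reported by :func:`detect_homoplasy`.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import edlib

from .amplify import DEFAULT_SIZE_TOL, PredictedFragment, PrimerCombo, bin_sizes
from .enzymes import normalize_sequence, reverse_complement

__all__ = [
    "Read",
    "EndSignatures",
    "ReadAssignment",
    "HomoplasyGroup",
    "recognize_ends",
    "assign_reads",
    "consensus_per_marker",
    "detect_homoplasy",
]

UNASSIGNED = "UNASSIGNED"

#: MseI-side overhang fill; a full-length amplicon core is the oriented
#: insert plus these two bases (see amplify.PredictedFragment.template).
_MSEI_FILL = 2

_IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C",
    frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y",
    frozenset("GC"): "S", frozenset("AT"): "W",
    frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("CGT"): "B", frozenset("AGT"): "D",
    frozenset("ACT"): "H", frozenset("ACG"): "V",
    frozenset("ACGT"): "N",
}


@dataclass(frozen=True)
class Read:
    """A sequencing read (quality values are carried but unused)."""

    read_id: str
    sequence: str
    quality: str | None = None

    def __post_init__(self) -> None:
        normalize_sequence(self.sequence)


@dataclass(frozen=True)
class EndSignatures:
    """Which terminal signatures of a primer combination a read shows.

    ``orientation`` is the strand that places the EcoRI remnant at the 5'
    end ('forward' = as given, 'reverse' = reverse complement), or None
    when neither signature is found.  Flags refer to that orientation.
    """

    orientation: str | None
    ecori_5p: bool
    msei_3p: bool

    @property
    def n_signatures(self) -> int:
        return int(self.ecori_5p) + int(self.msei_3p)


def _eco_sig(combo: PrimerCombo) -> str:
    return "AATTC" + combo.ecori_selective


def _mse_sig_3p(combo: PrimerCombo) -> str:
    # reverse complement of the MseI-side 5' reading TAA + CXX
    return reverse_complement("TAA" + combo.msei_selective)


def recognize_ends(read: Read | str, combo: PrimerCombo) -> EndSignatures:
    """Type the ends of a read against a primer combination's signatures.

    Both orientations are checked for a 5' EcoRI signature (AATTC + AXX)
    or a 5' MseI signature (TAA + CXX), and the complementary signature at
    the 3' end when the read is long enough.  No-match is a valid outcome.
    """
    seq = read.sequence if isinstance(read, Read) else read
    seq = normalize_sequence(seq)
    if len(seq) < 20:
        raise ValueError("reads shorter than 20 bp cannot be end-typed")
    eco = _eco_sig(combo)
    mse3 = _mse_sig_3p(combo)
    rc = reverse_complement(seq)

    for orientation, canon in (("forward", seq), ("reverse", rc)):
        eco_ok = canon.startswith(eco)
        mse_ok = canon.endswith(mse3) if len(canon) >= len(eco) + len(mse3) else False
        if eco_ok or mse_ok:
            return EndSignatures(orientation, eco_ok, mse_ok)
    return EndSignatures(None, False, False)


@dataclass(frozen=True)
class ReadAssignment:
    """Attribution of one read to a predicted marker (or UNASSIGNED)."""

    read_id: str
    marker_id: str
    orientation: str | None
    length_ok: bool
    ecori_end_ok: bool
    msei_end_ok: bool
    selective_ok: bool
    mismatches: int | None
    ambiguous: bool = False


def _canonical(seq: str, orientation: str) -> str:
    return seq if orientation == "forward" else reverse_complement(seq)


def assign_reads(
    reads: Sequence[Read],
    candidates: Sequence[PredictedFragment],
    size_tol: int = DEFAULT_SIZE_TOL,
    policy: str = "strict",
    mismatch_budget: int = 1,
) -> list[ReadAssignment]:
    """Assign reads to predicted fragments by signature + length + identity.

    Under the default ``strict`` policy a read must show both terminal
    signatures; its implied insert length (read length minus the 2-bp
    MseI-side fill) must match the candidate's within *size_tol*; and its
    edit distance to the candidate template, beyond the unavoidable length
    difference, must not exceed *mismatch_budget*.  Policy ``relaxed``
    additionally allows single-signature (3'-truncated) reads, without the
    length criterion.  Among candidates passing all criteria the unique
    best (fewest mismatches) wins; ties leave the read UNASSIGNED with an
    ambiguity flag.  No read is ever counted toward two markers.
    """
    if size_tol < 0:
        raise ValueError("size_tol must be >= 0")
    if policy not in ("strict", "relaxed"):
        raise ValueError("policy must be 'strict' or 'relaxed'")

    assignments = []
    for read in reads:
        seq = normalize_sequence(read.sequence)
        if len(seq) < 20:
            assignments.append(
                ReadAssignment(
                    read.read_id, UNASSIGNED, None, length_ok=False,
                    ecori_end_ok=False, msei_end_ok=False,
                    selective_ok=False, mismatches=None,
                )
            )
            continue
        best: list[tuple[int, PredictedFragment, EndSignatures, bool]] = []
        for cand in candidates:
            sig = recognize_ends(seq, cand.combo)
            if sig.orientation is None:
                continue
            canon = _canonical(seq, sig.orientation)
            both = sig.ecori_5p and sig.msei_3p
            if both:
                implied = len(canon) - _MSEI_FILL
                length_ok = abs(implied - cand.insert_length) <= size_tol
            else:
                length_ok = False
            if policy == "strict" and not (both and length_ok):
                continue
            if policy == "relaxed" and sig.n_signatures == 0:
                continue
            if policy == "relaxed" and both and not length_ok:
                continue
            template = cand.template
            if not both:
                # truncated read: compare against the template prefix
                template = template[: len(canon)]
            dist = edlib.align(canon, template, task="distance")["editDistance"]
            budget = mismatch_budget + abs(len(canon) - len(template))
            if dist <= budget:
                best.append((dist, cand, sig, length_ok))
        if not best:
            sig = recognize_ends(seq, candidates[0].combo) if candidates else EndSignatures(None, False, False)
            assignments.append(
                ReadAssignment(
                    read.read_id, UNASSIGNED, sig.orientation,
                    length_ok=False, ecori_end_ok=sig.ecori_5p,
                    msei_end_ok=sig.msei_3p, selective_ok=sig.n_signatures > 0,
                    mismatches=None,
                )
            )
            continue
        best.sort(key=lambda t: t[0])
        if len(best) > 1 and best[0][0] == best[1][0]:
            dist, cand, sig, length_ok = best[0]
            assignments.append(
                ReadAssignment(
                    read.read_id, UNASSIGNED, sig.orientation,
                    length_ok=length_ok, ecori_end_ok=sig.ecori_5p,
                    msei_end_ok=sig.msei_3p, selective_ok=True,
                    mismatches=dist, ambiguous=True,
                )
            )
            continue
        dist, cand, sig, length_ok = best[0]
        assignments.append(
            ReadAssignment(
                read.read_id, cand.marker_id, sig.orientation,
                length_ok=length_ok, ecori_end_ok=sig.ecori_5p,
                msei_end_ok=sig.msei_3p, selective_ok=True,
                mismatches=dist,
            )
        )
    return assignments


def marker_read_counts(assignments: Iterable[ReadAssignment]) -> Counter:
    """Reads per marker (UNASSIGNED counted under its own key)."""
    return Counter(a.marker_id for a in assignments)


def consensus_per_marker(
    assignments: Sequence[ReadAssignment],
    reads: Sequence[Read] | Mapping[str, Read],
) -> dict[str, str]:
    """Per-position majority-vote consensus of each marker's reads.

    Reads are first rotated into the canonical (EcoRI 5') orientation.
    The consensus length is the modal read length (smallest on ties) and
    the vote runs over reads of that length; position ties become IUPAC
    ambiguity codes.
    """
    by_id = (
        {r.read_id: r for r in reads} if not isinstance(reads, Mapping) else dict(reads)
    )
    grouped: dict[str, list[str]] = {}
    for a in assignments:
        if a.marker_id == UNASSIGNED:
            continue
        read = by_id[a.read_id]
        grouped.setdefault(a.marker_id, []).append(
            _canonical(normalize_sequence(read.sequence), a.orientation)
        )

    consensus: dict[str, str] = {}
    for marker, seqs in grouped.items():
        lengths = Counter(len(s) for s in seqs)
        top = max(lengths.values())
        modal = min(length for length, k in lengths.items() if k == top)
        modal_seqs = [s for s in seqs if len(s) == modal]
        out = []
        for col in zip(*modal_seqs):
            counts = Counter(col)
            best_n = max(counts.values())
            winners = frozenset(b for b, k in counts.items() if k == best_n)
            out.append(_IUPAC.get(winners, "N") if len(winners) > 1 else next(iter(winners)))
        consensus[marker] = "".join(out)
    return consensus


@dataclass(frozen=True)
class HomoplasyGroup:
    """Two or more distinct sequences co-migrating in one size bin."""

    combo: str
    sizes: tuple[float, ...]
    center: int
    sequences: dict[str, int]  # sequence -> count

    def __post_init__(self) -> None:
        if len(self.sequences) < 2:
            raise ValueError("a homoplasy group needs >= 2 distinct sequences")


HomoplasyEntry = tuple[str, float, str]  # (combo label, detected size, sequence)


def detect_homoplasy(
    entries: Iterable[HomoplasyEntry | PredictedFragment],
    tol: float = DEFAULT_SIZE_TOL,
) -> list[HomoplasyGroup]:
    """Find co-migrating non-identical sequences per (combo, size bin).

    Accepts (combo, size, sequence) triples — e.g. NGS consensus sequences
    with their electrophoresis sizes — or :class:`PredictedFragment`
    objects for a purely in-silico co-migration pre-warning.  A group is
    reported only when a bin holds at least two distinct sequences.
    """
    triples: list[HomoplasyEntry] = []
    for item in entries:
        if isinstance(item, PredictedFragment):
            triples.append((item.combo.label, item.detected_size, item.oriented_insert))
        else:
            combo, size, seq = item
            triples.append((str(combo), float(size), normalize_sequence(seq)))

    groups: list[HomoplasyGroup] = []
    by_combo: dict[str, list[tuple[float, str]]] = {}
    for combo, size, seq in triples:
        by_combo.setdefault(combo, []).append((size, seq))
    for combo in sorted(by_combo):
        items = by_combo[combo]
        for bin_ in bin_sizes([s for s, _ in items], tol):
            lo, hi = bin_[0], bin_[-1]
            seqs = Counter(seq for size, seq in items if lo <= size <= hi)
            if len(seqs) >= 2:
                groups.append(
                    HomoplasyGroup(
                        combo=combo,
                        sizes=tuple(bin_),
                        center=int(round((lo + hi) / 2)),
                        sequences=dict(seqs),
                    )
                )
    return groups
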