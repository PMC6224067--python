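"""Selective amplification of a double digest and virtual fingerprints.

After EcoRI/MseI digestion and adapter ligation, AFLP amplifies only those
fragments that carry one EcoRI end and one MseI end *and* whose first bases
beyond each remnant match the primers' 3' selective extensions (here named
AXX for the EcoRI primer and CXX for the MseI primer, as on the study's
8x8 primer grid).  This module predicts that amplified subset from a
digest, sizes each amplicon on the capillary-electrophoresis scale, and
assembles per-sample 0/1 fingerprint matrices.

Selective-base convention
-------------------------
The oriented insert is the cut-to-cut slice with the EcoRI cut at the 5'
end, so it begins with the remnant ``AATTC``.  The EcoRI primer's three
selective bases (AXX) are matched against insert positions 5-7, directly
after the remnant.  Reading the amplicon from the MseI side gives
``TAA`` + CXX, so the MseI selective triplet must equal the reverse
complement of the three insert bases preceding the terminal ``T``.  Both
conventions are unit-tested against published fragment reads
("AATTCAGG..." for E-AGG, "TAACAG..." for M-CAG).

A +1 preselective amplification step with fixed first bases A/C is
computationally a no-op here: any fragment passing the +3 selective match
necessarily passes +1, so it is not modeled separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .enzymes import ECORI, MSEI, RawFragment, digest_all, reverse_complement

__all__ = [
    "PrimerCombo",
    "PredictedFragment",
    "FingerprintMatrix",
    "DEFAULT_OFFSET",
    "DEFAULT_SIZE_TOL",
    "table1_combos",
    "combo_from_label",
    "orient_fragment",
    "select_fragments",
    "detected_size",
    "bin_sizes",
    "fingerprint",
    "virtual_profile",
]

ECORI_REMNANT = "AATTC"
MSEI_REMNANT = "TAA"

#: Default primer-tail contribution to the detected (electrophoresis) size:
#: 11 bp of EcoRI primer and 13 bp of MseI primer beyond the remnants.
DEFAULT_OFFSET = 24

#: Default size-bin half-width (bp); absorbs the 1-2 bp disagreement between
#: sizing software observed for the same physical fragment.
DEFAULT_SIZE_TOL = 2

#: Minimum cut-to-cut insert length that still carries both remnants and
#: both selective triplets (5 + 3 + 3 + 1).
MIN_INSERT = 12


@dataclass(frozen=True)
class PrimerCombo:
    """A selective primer pair: MseI side CXX, EcoRI side AXX.

    ``dye`` is the fluorescent label of the EcoRI primer (FAM/JOE/NED);
    it is metadata only and never affects fragment selection.
    """

    msei_selective: str
    ecori_selective: str
    dye: str | None = None

    def __post_init__(self) -> None:
        for name, sel, first in (
            ("msei_selective", self.msei_selective, "C"),
            ("ecori_selective", self.ecori_selective, "A"),
        ):
            if len(sel) != 3 or not set(sel) <= set("ACGT"):
                raise ValueError(f"{name} must be 3 bases over A/C/G/T, got {sel!r}")
            if sel[0] != first:
                raise ValueError(f"{name} must start with {first!r}, got {sel!r}")

    @property
    def label(self) -> str:
        """Marker-name prefix, MseI primer first: e.g. ``CAG_AGG``."""
        return f"{self.msei_selective}_{self.ecori_selective}"


def combo_from_label(label: str, dye: str | None = None) -> PrimerCombo:
    """Parse ``"CAG_AGG"`` (or ``"CAG,AGG"``) into a :class:`PrimerCombo`."""
    parts = label.replace(",", "_").split("_")
    if len(parts) != 2:
        raise ValueError(f"cannot parse primer combination {label!r}")
    return PrimerCombo(msei_selective=parts[0], ecori_selective=parts[1], dye=dye)


# The study's 8x8 selective-primer grid: 8 EcoRI AXX primers (with their
# dyes) crossed with 8 MseI CXX primers; 13 cells were unusable (low signal
# or too few fragments), leaving 51 combinations.
_MSEI_PRIMERS = ("CTG", "CTA", "CTT", "CAG", "CAC", "CAT", "CTC", "CAA")
_ECORI_GRID: tuple[tuple[str, str, frozenset[str]], ...] = (
    # (AXX, dye, unusable MseI primers)
    ("ACA", "FAM", frozenset()),
    ("ACT", "FAM", frozenset({"CTT"})),
    ("ACG", "JOE", frozenset({"CTT", "CAC", "CAT"})),
    ("AAG", "JOE", frozenset({"CTG", "CTA", "CAG"})),
    ("AGG", "JOE", frozenset({"CTT", "CAT"})),
    ("ACC", "NED", frozenset()),
    ("AGC", "NED", frozenset({"CTT", "CAG", "CAC", "CAT"})),
    ("AAC", "NED", frozenset()),
)


def table1_combos(include_unusable: bool = False) -> list[PrimerCombo]:
    """The bundled 8x8 primer grid; by default only the 51 usable combos."""
    combos = []
    for ecori, dye, unusable in _ECORI_GRID:
        for msei in _MSEI_PRIMERS:
            if include_unusable or msei not in unusable:
                combos.append(PrimerCombo(msei, ecori, dye))
    return combos


@dataclass(frozen=True)
class PredictedFragment:
    """An EcoRI-MseI fragment that passes (or may pass) selective amplification.

    ``oriented_insert`` is the cut-to-cut insert on the strand with the
    EcoRI cut at the 5' end; ``detected_size`` is its length plus the
    primer-tail sizing offset; ``marker_id`` is ``CXX_AXX_<size>``.
    """

    raw: RawFragment
    oriented_insert: str
    combo: PrimerCombo
    ecori_sel_observed: str
    msei_sel_observed: str
    detected_size: int
    marker_id: str

    @property
    def insert_length(self) -> int:
        return len(self.oriented_insert)

    @property
    def template(self) -> str:
        """The fully filled-in amplicon core: insert plus the MseI-side
        two-base overhang fill, so that its reverse complement begins
        ``TAA`` + CXX like a read entering from the MseI end."""
        return self.oriented_insert + "TA"


def detected_size(insert_length: int, offset: int = DEFAULT_OFFSET) -> int:
    """Capillary-electrophoresis size of an amplicon with the given
    cut-to-cut insert length (deterministic: insert + primer tails)."""
    if insert_length <= 0:
        raise ValueError("insert_length must be positive")
    return insert_length + offset


def orient_fragment(raw: RawFragment, genome: str | Mapping[str, str]) -> str:
    """Cut-to-cut insert of *raw* oriented with the EcoRI cut at the 5' end.

    For an EcoRI-left fragment this is the plain top-strand slice (which
    begins with the remnant AATTC).  For an MseI-left fragment the insert
    is read on the bottom strand; mapping the sticky-end fill-in into top
    coordinates, it is the reverse complement of
    ``genome[start+2 : end+4]`` — mirror-image fragments therefore yield
    byte-identical inserts and sizes.
    """
    seq = genome if isinstance(genome, str) else genome[raw.seq_id]
    ends = (raw.left_end, raw.right_end)
    if ends == (ECORI.name, MSEI.name):
        return seq[raw.start : raw.end].upper()
    if ends == (MSEI.name, ECORI.name):
        return reverse_complement(seq[raw.start + 2 : raw.end + 4].upper())
    raise ValueError(
        f"fragment must have one EcoRI and one MseI end, got {ends[0]}/{ends[1]}"
    )


@dataclass(frozen=True)
class _OrientedRecord:
    raw: RawFragment
    insert: str
    eco_sel: str
    mse_sel: str


def _oriented_records(
    fragments: Iterable[RawFragment],
    genome: str | Mapping[str, str],
    exclude_n: bool = True,
) -> list[_OrientedRecord]:
    """Orient every EcoRI+MseI fragment once and read off both observed
    selective triplets, independent of any particular primer combination."""
    records = []
    wanted = {(ECORI.name, MSEI.name), (MSEI.name, ECORI.name)}
    for frag in fragments:
        if (frag.left_end, frag.right_end) not in wanted:
            continue
        insert = orient_fragment(frag, genome)
        if len(insert) < MIN_INSERT:
            continue
        if exclude_n and "N" in insert:
            continue
        eco_sel = insert[5:8]
        mse_sel = reverse_complement(insert[-4:-1])
        records.append(_OrientedRecord(frag, insert, eco_sel, mse_sel))
    return records


def select_fragments(
    fragments: Iterable[RawFragment],
    genome: str | Mapping[str, str],
    combo: PrimerCombo,
    *,
    offset: int = DEFAULT_OFFSET,
    exclude_n: bool = True,
) -> list[PredictedFragment]:
    """Fragments of a double digest amplified by *combo*.

    Keeps fragments with exactly one EcoRI and one MseI end whose observed
    selective triplets equal the combo's AXX and CXX.  TERMINUS-ended and
    same-end fragments never amplify under the default AFLP policy
    (MseI-MseI amplification is suppressed, EcoRI-EcoRI is rare and
    unscored).  Returns fragments with detected sizes and marker ids; an
    empty result is valid.
    """
    out = []
    for rec in _oriented_records(fragments, genome, exclude_n=exclude_n):
        if rec.eco_sel == combo.ecori_selective and rec.mse_sel == combo.msei_selective:
            size = detected_size(len(rec.insert), offset)
            out.append(
                PredictedFragment(
                    raw=rec.raw,
                    oriented_insert=rec.insert,
                    combo=combo,
                    ecori_sel_observed=rec.eco_sel,
                    msei_sel_observed=rec.mse_sel,
                    detected_size=size,
                    marker_id=f"{combo.label}_{size}",
                )
            )
    return out


def bin_sizes(sizes: Iterable[int | float], tol: float) -> list[list[float]]:
    """Single-linkage binning of detected sizes.

    Sorted unique sizes are chained while consecutive gaps are <= *tol*;
    a chain is additionally split (left to right) whenever its width would
    exceed ``2 * tol``, so every bin spans at most the merge window of two
    co-migrating software calls.  Deterministic.
    """
    if tol < 0:
        raise ValueError("tol must be >= 0")
    uniq = sorted(set(sizes))
    bins: list[list[float]] = []
    for s in uniq:
        if bins and s - bins[-1][-1] <= tol and s - bins[-1][0] <= 2 * tol:
            bins[-1].append(s)
        else:
            bins.append([s])
    return bins


def _bin_center(bin_sizes_: Sequence[int | float]) -> int:
    mid = (bin_sizes_[0] + bin_sizes_[-1]) / 2
    return int(round(mid))


@dataclass
class FingerprintMatrix:
    """Samples x markers presence/absence calls (the 0/1 data of an AFLP
    fingerprint study), with an optional haplotype-dosage channel.

    ``calls`` is a pandas DataFrame indexed by sample id with one 0/1
    column per marker id; ``dosage`` counts how many of a sample's
    haplotypes carry the fragment (dominant scoring means
    ``call == 1  <=>  dosage >= 1``).
    """

    calls: pd.DataFrame
    dosage: pd.DataFrame | None = None
    groups: dict[str, str] | None = None
    profiles: dict[tuple[str, str], tuple[int, ...]] | None = None
    bins: dict[str, tuple[float, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = self.calls.to_numpy()
        if not ((vals == 0) | (vals == 1)).all():
            raise ValueError("calls must be binary 0/1")
        if self.dosage is not None:
            if (self.dosage.to_numpy() < vals).any():
                raise ValueError("dosage must be >= call for every cell")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.calls.index)

    @property
    def marker_ids(self) -> list[str]:
        return list(self.calls.columns)

    @property
    def n_profiles(self) -> int:
        """Number of (sample, primer combination) virtual profiles."""
        return len(self.profiles) if self.profiles is not None else 0

    def to_tsv(self, path) -> None:
        self.calls.to_csv(path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, path) -> "FingerprintMatrix":
        calls = pd.read_csv(path, sep="\t", index_col="sample_id")
        return cls(calls=calls.astype(int))


Haplotype = str | Mapping[str, str]


def _haplotype_records(hap: Haplotype) -> dict[str, str]:
    if isinstance(hap, str):
        return {"seq": hap}
    return dict(hap)


def virtual_profile(
    haplotypes: Sequence[Haplotype],
    combo: PrimerCombo,
    *,
    offset: int = DEFAULT_OFFSET,
) -> list[int]:
    """Sorted unique detected sizes for one sample and one primer
    combination — the in-silico analogue of an electropherogram."""
    sizes: set[int] = set()
    for hap in haplotypes:
        seqs = _haplotype_records(hap)
        frags = digest_all(seqs)
        for pf in select_fragments(frags, seqs, combo, offset=offset):
            sizes.add(pf.detected_size)
    return sorted(sizes)


def fingerprint(
    samples: Mapping[str, Sequence[Haplotype]],
    combos: Sequence[PrimerCombo],
    *,
    offset: int = DEFAULT_OFFSET,
    tol: float = DEFAULT_SIZE_TOL,
    groups: Mapping[str, str] | None = None,
) -> FingerprintMatrix:
    """Virtual AFLP fingerprints for a cohort.

    Each sample supplies one or two haplotype sequences (a string, or a
    dict of named regions).  For every (sample, combo) pair the haplotypes
    are digested and selectively amplified; detected sizes are harmonized
    across samples by per-combo single-linkage size bins of half-width
    *tol*, and each (combo, bin) becomes one marker ``CXX_AXX_<center>``.
    A marker is called 1 when at least one haplotype yields a fragment in
    the bin; dosage counts how many do.
    """
    sample_ids = list(samples)
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicate sample ids")
    if not combos:
        raise ValueError("at least one primer combination is required")

    by_label = {c.label: c for c in combos}
    if len(by_label) != len(combos):
        raise ValueError("duplicate primer combinations")

    # (combo label) -> list of (sample, haplotype index, detected size)
    hits: dict[str, list[tuple[str, int, int]]] = {c.label: [] for c in combos}
    profiles: dict[tuple[str, str], tuple[int, ...]] = {}

    for sample_id, haps in samples.items():
        if not 1 <= len(haps) <= 2:
            raise ValueError(
                f"sample {sample_id!r} must supply 1 or 2 haplotypes, got {len(haps)}"
            )
        per_combo_sizes: dict[str, set[int]] = {c.label: set() for c in combos}
        for h, hap in enumerate(haps):
            seqs = _haplotype_records(hap)
            records = _oriented_records(digest_all(seqs), seqs)
            for rec in records:
                label = f"{rec.mse_sel}_{rec.eco_sel}"
                if label in hits:
                    size = detected_size(len(rec.insert), offset)
                    hits[label].append((sample_id, h, size))
                    per_combo_sizes[label].add(size)
        for label, sizes in per_combo_sizes.items():
            profiles[(sample_id, label)] = tuple(sorted(sizes))

    call_cols: dict[str, pd.Series] = {}
    dose_cols: dict[str, pd.Series] = {}
    bins_out: dict[str, tuple[float, ...]] = {}
    for label in (c.label for c in combos):
        combo_hits = hits[label]
        if not combo_hits:
            continue
        for bin_ in bin_sizes([size for (_, _, size) in combo_hits], tol):
            lo, hi = bin_[0], bin_[-1]
            marker = f"{label}_{_bin_center(bin_)}"
            dose = pd.Series(0, index=sample_ids, dtype=int)
            # dosage = number of distinct haplotypes with a fragment in bin
            carriers: dict[str, set[int]] = {}
            for sample_id, h, size in combo_hits:
                if lo <= size <= hi:
                    carriers.setdefault(sample_id, set()).add(h)
            for sample_id, hs in carriers.items():
                dose[sample_id] = len(hs)
            call_cols[marker] = (dose > 0).astype(int)
            dose_cols[marker] = dose
            bins_out[marker] = tuple(bin_)

    calls = pd.DataFrame(call_cols, index=sample_ids, dtype=int)
    dosage = pd.DataFrame(dose_cols, index=sample_ids, dtype=int)
    return FingerprintMatrix(
        calls=calls,
        dosage=dosage,
        groups=dict(groups) if groups is not None else None,
        profiles=profiles,
        bins=bins_out,
    )
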