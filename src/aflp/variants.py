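"""SNP/indel effects on AFLP markers.

A marker can appear or disappear through a handful of mechanisms: (a) a
SNP inside the EcoRI or MseI recognition site introduces or destroys the
site; (b) a SNP in the primers' selective bases changes whether the
fragment amplifies; (c) an insertion/deletion inside the insert shifts the
detected size; (d) a SNP elsewhere in the insert creates a *new* internal
restriction site that splits the fragment; or (e) a combination of these.

This module applies variants to genomes (producing explicit haplotype
pairs), enumerates the complete single-substitution causal space of a
fragment — 6 EcoRI site + 4 MseI site + 3 + 3 selective positions, each
with 3 alternate bases, i.e. 48 substitutions per fragment — classifies a
variant's mechanism by re-fingerprinting, and annotates candidate variants
against a user-supplied VCF.

Enumeration covers substitutions only (indels at these positions form an
unbounded space and are handled through :func:`apply_variants`), and the
new-internal-site scan of mechanism (d) is a separate, explicitly invoked
check in :func:`classify_effect` rather than part of the 48-space.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .amplify import (
    DEFAULT_OFFSET,
    PredictedFragment,
    PrimerCombo,
    select_fragments,
)
from .enzymes import (
    ECORI,
    MSEI,
    double_digest,
    find_sites,
    normalize_sequence,
    reverse_complement,
)

__all__ = [
    "Variant",
    "KnownVariant",
    "VariantEffect",
    "apply_variants",
    "enumerate_site_substitutions",
    "classify_effect",
    "predict_candidates",
    "annotate_with_known",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class Variant:
    """A SNP or small indel in VCF-like representation.

    ``pos`` is the 0-based reference position of the first ``ref`` base;
    indels use the VCF anchor-base convention (e.g. ref ``AG`` / alt ``A``
    for a 1-bp deletion) and are assumed left-normalized.
    """

    seq_id: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        for allele in (self.ref, self.alt):
            if not set(allele) <= set(_BASES):
                raise ValueError(f"allele {allele!r} must be over A/C/G/T")
        if self.pos < 0:
            raise ValueError("pos must be >= 0")

    @property
    def kind(self) -> str:
        if len(self.ref) == len(self.alt) == 1:
            return "SNP"
        return "insertion" if len(self.alt) > len(self.ref) else "deletion"

    @property
    def size_delta(self) -> int:
        return len(self.alt) - len(self.ref)

    def inverse(self) -> "Variant":
        """The variant that undoes this one on the mutated sequence."""
        return Variant(self.seq_id, self.pos, self.alt, self.ref)


@dataclass(frozen=True)
class KnownVariant:
    """A candidate variant matched (or not) against a population VCF."""

    variant: Variant
    rsid: str | None = None
    maf: float | None = None

    def __post_init__(self) -> None:
        if self.maf is not None and not 0.0 <= self.maf <= 1.0:
            raise ValueError(f"MAF must be in [0, 1], got {self.maf}")


@dataclass(frozen=True)
class VariantEffect:
    """The fingerprint-level consequence of one variant for one primer
    combination.  ``mechanism`` is one of 'a'..'e' (see module docstring)
    or ``None`` for a variant with no effect on the combo's markers."""

    variant: Variant
    marker_id: str | None
    mechanism: str | None
    before_state: str
    after_state: str
    size_delta: int


def _resolve_seq(genome: str | Mapping[str, str], seq_id: str) -> str:
    if isinstance(genome, str):
        return genome
    try:
        return genome[seq_id]
    except KeyError:
        raise ValueError(f"unknown sequence id {seq_id!r}") from None


def _check_and_sort(seq: str, variants: Sequence[Variant]) -> list[Variant]:
    occupied: list[tuple[int, int]] = []
    for v in variants:
        end = v.pos + len(v.ref)
        if end > len(seq):
            raise ValueError(f"variant at {v.pos} extends beyond sequence end")
        observed = seq[v.pos : end]
        if observed != v.ref:
            raise ValueError(
                f"reference mismatch at position {v.pos}: expected {v.ref!r}, "
                f"observed {observed!r}"
            )
        occupied.append((v.pos, end))
    occupied.sort()
    for (s1, e1), (s2, e2) in zip(occupied, occupied[1:]):
        if s2 < e1:
            raise ValueError(f"overlapping variants at positions {s1} and {s2}")
    return sorted(variants, key=lambda v: v.pos, reverse=True)


def _apply_to_seq(seq: str, variants: Sequence[Variant]) -> str:
    """Apply non-overlapping variants to one sequence (validates refs)."""
    out = seq
    for v in _check_and_sort(seq, variants):
        out = out[: v.pos] + v.alt + out[v.pos + len(v.ref) :]
    return out


Zygosity = str | Sequence[str] | Mapping[Variant, str]


def _zygosity_of(v: Variant, i: int, zygosity: Zygosity | None) -> str:
    if zygosity is None:
        z = "hom"
    elif isinstance(zygosity, str):
        z = zygosity
    elif isinstance(zygosity, Mapping):
        z = zygosity.get(v, "hom")
    else:
        z = zygosity[i]
    if z not in ("hom", "het"):
        raise ValueError(f"zygosity must be 'hom' or 'het', got {z!r}")
    return z


def apply_variants(
    genome: str | Mapping[str, str],
    variants: Sequence[Variant],
    zygosity: Zygosity | None = None,
) -> tuple:
    """Apply variants to a genome and return a haplotype pair.

    Homozygous variants are applied to both haplotypes, heterozygous ones
    to haplotype 0 only (deterministic).  ``zygosity`` may be a single
    string, a per-variant sequence, or a mapping; the default is
    homozygous.  Coordinates are resolved once against the reference, so
    downstream indels shift consistently.

    Returns ``(hap0, hap1)`` as strings for a string genome, or as dicts
    keyed by sequence id for a multi-sequence genome.
    """
    hom = [v for i, v in enumerate(variants) if _zygosity_of(v, i, zygosity) == "hom"]
    het = [v for i, v in enumerate(variants) if _zygosity_of(v, i, zygosity) == "het"]

    if isinstance(genome, str):
        seq = normalize_sequence(genome)
        return (_apply_to_seq(seq, hom + het), _apply_to_seq(seq, hom))

    hap0: dict[str, str] = {}
    hap1: dict[str, str] = {}
    for seq_id, raw in genome.items():
        seq = normalize_sequence(raw)
        here_hom = [v for v in hom if v.seq_id == seq_id]
        here_het = [v for v in het if v.seq_id == seq_id]
        hap0[seq_id] = _apply_to_seq(seq, here_hom + here_het)
        hap1[seq_id] = _apply_to_seq(seq, here_hom)
    return (hap0, hap1)


def enumerate_site_substitutions(
    fragment: PredictedFragment,
    *,
    include_selective: bool = True,
) -> list[Variant]:
    """The complete single-substitution causal space of *fragment*.

    Substitutions at the 6 EcoRI recognition positions (the full GAATTC,
    including the leading G), the 4 MseI positions (TTAA) and, when
    ``include_selective`` is true, the 3 + 3 selective-base positions —
    3 alternate bases each, i.e. 48 variants (30 without selective bases).
    Every one of them, applied alone, abolishes the fragment's
    amplification for its combo.  Positions are genome coordinates.
    """
    raw = fragment.raw
    s, e = raw.start, raw.end
    entries: list[tuple[int, str]] = []
    if (raw.left_end, raw.right_end) == (ECORI.name, MSEI.name):
        entries += zip(range(s - 1, s + 5), "GAATTC")
        if include_selective:
            entries += zip(range(s + 5, s + 8), fragment.ecori_sel_observed)
            entries += zip(
                range(e - 4, e - 1), reverse_complement(fragment.msei_sel_observed)
            )
        entries += zip(range(e - 1, e + 3), "TTAA")
    elif (raw.left_end, raw.right_end) == (MSEI.name, ECORI.name):
        entries += zip(range(s - 1, s + 3), "TTAA")
        if include_selective:
            # top-strand bases after the TAA remnant read the CXX directly
            entries += zip(range(s + 3, s + 6), fragment.msei_sel_observed)
            entries += zip(
                range(e - 4, e - 1), reverse_complement(fragment.ecori_sel_observed)
            )
        entries += zip(range(e - 1, e + 5), "GAATTC")
    else:
        raise ValueError("fragment must have one EcoRI and one MseI end")

    variants = []
    for pos, ref in sorted(entries):
        for alt in _BASES:
            if alt != ref:
                variants.append(Variant(raw.seq_id, pos, ref, alt))
    return variants


def _site_starts(seq: str) -> dict[str, frozenset[int]]:
    return {
        enz.name: frozenset(
            site.cut_pos - enz.cut_offset for site in find_sites(seq, enz)
        )
        for enz in (ECORI, MSEI)
    }


def _selective_windows(fragments: Iterable[PredictedFragment]) -> list[range]:
    """Genome-coordinate windows of the selective bases of amplified
    fragments (both sides)."""
    windows = []
    for pf in fragments:
        s, e = pf.raw.start, pf.raw.end
        if (pf.raw.left_end, pf.raw.right_end) == (ECORI.name, MSEI.name):
            windows.append(range(s + 5, s + 8))
            windows.append(range(e - 4, e - 1))
        else:
            windows.append(range(s + 3, s + 6))
            windows.append(range(e - 4, e - 1))
    return windows


def classify_effect(
    reference: str | Mapping[str, str],
    variant: Variant,
    combo: PrimerCombo,
    *,
    offset: int = DEFAULT_OFFSET,
) -> VariantEffect:
    """Mechanism classification of one variant for one primer combination.

    Fingerprints the reference and the (homozygous) mutated sequence,
    diffs the combo's marker sizes, and labels the mechanism by locating
    the variant relative to restriction sites and selective bases.  A
    variant that leaves the combo's markers unchanged yields a no-effect
    record (mechanism ``None``), not an error.  Pure function of its
    arguments.
    """
    seq = normalize_sequence(_resolve_seq(reference, variant.seq_id))
    alt_seq = _apply_to_seq(seq, [variant])
    delta = variant.size_delta

    ref_sel = select_fragments(double_digest(seq), seq, combo, offset=offset)
    alt_sel = select_fragments(double_digest(alt_seq), alt_seq, combo, offset=offset)
    lost = Counter(pf.detected_size for pf in ref_sel) - Counter(
        pf.detected_size for pf in alt_sel
    )
    gained = Counter(pf.detected_size for pf in alt_sel) - Counter(
        pf.detected_size for pf in ref_sel
    )

    if not lost and not gained:
        return VariantEffect(variant, None, None, "unchanged", "unchanged", 0)

    mechanisms: set[str] = set()

    # --- restriction-site changes, in reference coordinates -------------
    ref_sites = _site_starts(seq)
    alt_sites = _site_starts(alt_seq)

    def back(p: int) -> int:
        return p if p <= variant.pos else p - delta

    for enz in (ECORI.name, MSEI.name):
        mapped_alt = frozenset(back(p) for p in alt_sites[enz])
        for p in mapped_alt - ref_sites[enz]:  # site gained
            interior = any(pf.raw.start <= p < pf.raw.end for pf in ref_sel)
            mechanisms.add("d" if interior else "a")
        if ref_sites[enz] - mapped_alt:  # site lost
            mechanisms.add("a")

    # --- selective-base changes -----------------------------------------
    var_span = range(variant.pos, variant.pos + max(len(variant.ref), 1))
    windows = _selective_windows(ref_sel)
    for pf in alt_sel:
        s, e = pf.raw.start, pf.raw.end
        shifted = [
            range(back(w.start), back(w.start) + 3)
            for w in _selective_windows([pf])
        ]
        windows.extend(shifted)
    if any(set(var_span) & set(w) for w in windows):
        mechanisms.add("b")

    # --- indel size shift -------------------------------------------------
    if delta != 0:
        mechanisms.add("c")

    mechanism = "e" if len(mechanisms) > 1 else (next(iter(mechanisms)) if mechanisms else "e")

    # --- affected marker and before/after states -------------------------
    if lost:
        before_size = min(lost)
        marker_id = f"{combo.label}_{before_size}"
        before = f"present at {before_size}"
        if delta != 0 and (before_size + delta) in gained:
            after = f"present at {before_size + delta}"
            size_delta = delta
        elif gained:
            after_size = min(gained)
            after = f"present at {after_size}"
            size_delta = after_size - before_size
        else:
            after = "absent"
            size_delta = delta if mechanism == "c" else 0
    else:
        after_size = min(gained)
        marker_id = f"{combo.label}_{after_size}"
        before = "absent"
        after = f"present at {after_size}"
        size_delta = delta if mechanism == "c" else 0

    return VariantEffect(variant, marker_id, mechanism, before, after, size_delta)


def predict_candidates(
    genome: str | Mapping[str, str],
    combo: PrimerCombo,
    target_size: int,
    window: int = 5,
    *,
    offset: int = DEFAULT_OFFSET,
) -> list[PredictedFragment]:
    """All of the combo's predicted fragments within ``target_size ± window``
    detected bp — the in-silico candidate reference set for recognizing a
    marker of known electrophoresis size in sequencing reads."""
    if window < 0:
        raise ValueError("window must be >= 0")
    seqs = {"seq": genome} if isinstance(genome, str) else dict(genome)
    out = []
    for seq_id, seq in seqs.items():
        frags = double_digest(seq, seq_id=seq_id)
        for pf in select_fragments(frags, seq, combo, offset=offset):
            if abs(pf.detected_size - target_size) <= window:
                out.append(pf)
    return out


def _first_malformed_line(path) -> int | None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 8 or not fields[1].isdigit():
                return lineno
    return None


def annotate_with_known(
    candidates: Sequence[Variant], vcf_source
) -> list[KnownVariant]:
    """Intersect candidate variants with a VCF by (seq_id, pos, ref, alt).

    Matched candidates carry the VCF's ID (rsid) and, when present, its
    INFO ``AF``/``MAF`` value; unmatched candidates are returned with empty
    annotation.  Exact allele match after left-normalization is required —
    positional-only coincidences are not annotated (avoids false rsid
    assignment).
    """
    from cyvcf2 import VCF

    known: dict[tuple[str, int, str, str], tuple[str | None, float | None]] = {}
    try:
        vcf = VCF(str(vcf_source))
        for rec in vcf:
            maf = rec.INFO.get("AF", rec.INFO.get("MAF"))
            if isinstance(maf, tuple):
                maf = maf[0]
            maf = float(maf) if maf is not None else None
            rsid = rec.ID if rec.ID not in (None, ".") else None
            for alt in rec.ALT:
                known[(rec.CHROM, rec.start, rec.REF, alt)] = (rsid, maf)
        vcf.close()
    except Exception as exc:  # htslib parse failure
        lineno = _first_malformed_line(vcf_source)
        where = f" at line {lineno}" if lineno is not None else ""
        raise ValueError(f"malformed VCF {vcf_source!s}{where}: {exc}") from exc

    out = []
    for cand in candidates:
        rsid, maf = known.get(
            (cand.seq_id, cand.pos, cand.ref, cand.alt), (None, None)
        )
        out.append(KnownVariant(cand, rsid, maf))
    return out
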