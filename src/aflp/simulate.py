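"""Synthetic genomes, cohorts and reads with known ground truth.

Every other module of this package is testable without external data
through these generators: i.i.d. genomes of controlled GC content,
planted EcoRI-MseI fragments that amplify for a chosen primer
combination at a chosen size, two-group cohorts in which each planted
marker segregates at a chosen per-group presence frequency via a single
causal substitution drawn from the fragment's 48-variant space, and
error-bearing sequencing reads of the planted amplicons.

All generators are pure functions of their parameters and seed.
Defaults echo the study design this toolkit emulates: a 65 + 30
two-group cohort and 41% GC (human-like base composition).  The
generated genomes are short i.i.d. sequences — no repeat families, no
linkage between markers, substitution-only read errors — so passing
tests demonstrate the pipeline's logic, not robustness to real human
genome structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .amplify import (
    DEFAULT_OFFSET,
    PredictedFragment,
    PrimerCombo,
    combo_from_label,
    select_fragments,
)
from .enzymes import double_digest, reverse_complement
from .ngs import Read
from .variants import Variant, enumerate_site_substitutions

__all__ = [
    "SimulationTruth",
    "simulate_genome",
    "plant_fragment",
    "simulate_cohort",
    "simulate_reads",
]

DEFAULT_GC = 0.41
DEFAULT_N1 = 65
DEFAULT_N2 = 30

_MOTIFS = ("GAATTC", "TTAA")


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_genome(length: int, gc: float = DEFAULT_GC, seed=0) -> str:
    """An i.i.d. random genome with P(G) = P(C) = gc/2.

    Reproducible for a fixed seed; ``gc`` of 0 or 1 gives AT-only or
    GC-only sequence.
    """
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be within [0, 1]")
    if length < 100:
        raise ValueError("length must be >= 100")
    rng = _rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    idx = rng.choice(4, size=length, p=p)
    return "".join(np.array(list("ACGT"))[idx])


@dataclass(frozen=True)
class PlantedFragment:
    """Ground truth for one planted EcoRI-MseI construct."""

    combo: PrimerCombo
    position: int
    insert_size: int
    detected_size: int
    insert_start: int
    insert_end: int
    insert: str
    marker_id: str


def _motif_free(seq: str) -> bool:
    return all(m not in seq for m in _MOTIFS)


def plant_fragment(
    genome: str,
    combo: PrimerCombo,
    insert_size: int,
    position: int,
    seed=0,
    *,
    offset: int = DEFAULT_OFFSET,
    max_attempts: int = 200,
) -> tuple[str, PlantedFragment]:
    """Write one amplifiable fragment construct into *genome*.

    The construct is ``G AATTC <AXX> <filler> <rc(CXX)> T TAA`` — an EcoRI
    site, the EcoRI selective bases, motif-free filler, the MseI selective
    context and an MseI site — so exactly one new fragment of the
    requested cut-to-cut insert size amplifies for *combo*.  Filler is
    drawn motif-free by rejection sampling; if the flanking genome keeps
    colliding with the construct after *max_attempts* retries an error is
    raised.
    """
    if insert_size < 12:
        raise ValueError("insert_size must be >= 12 (remnants + selective bases)")
    core_len = insert_size - 12
    rng = _rng(seed)
    head = "G" + "AATTC" + combo.ecori_selective
    tail = reverse_complement(combo.msei_selective) + "T" + "TAA"
    total = len(head) + core_len + len(tail)
    if position < 6 or position + total > len(genome) - 6:
        raise ValueError("position leaves no room for the construct")

    bases = np.array(list("ACGT"))
    for _ in range(max_attempts):
        filler = "".join(bases[rng.integers(0, 4, size=core_len)])
        construct = head + filler + tail
        # the construct must contain exactly its two intended motifs; its
        # fixed head (GAATTC...) and tail (...TTAA) can never combine with
        # flanking genome bases into a new motif, so junctions are safe
        if construct.count("GAATTC") != 1 or construct.count("TTAA") != 1:
            continue
        new_genome = genome[:position] + construct + genome[position + total :]
        insert_start = position + 1  # EcoRI cut: G|AATTC
        insert_end = insert_start + insert_size
        frags = double_digest(new_genome)
        planted = [
            pf
            for pf in select_fragments(frags, new_genome, combo, offset=offset)
            if pf.raw.start == insert_start and pf.raw.end == insert_end
        ]
        if len(planted) == 1:
            pf = planted[0]
            truth = PlantedFragment(
                combo=combo,
                position=position,
                insert_size=insert_size,
                detected_size=pf.detected_size,
                insert_start=insert_start,
                insert_end=insert_end,
                insert=pf.oriented_insert,
                marker_id=pf.marker_id,
            )
            return new_genome, truth
    raise RuntimeError(
        f"could not place a motif-free construct at {position} "
        f"after {max_attempts} attempts"
    )


@dataclass
class SimulationTruth:
    """Complete ground truth of a simulated cohort."""

    reference: str
    planted: list[PlantedFragment]
    causal_variants: dict[str, Variant]  # marker_id -> killing substitution
    genotypes: pd.DataFrame  # samples x markers: killed-haplotype count 0/1/2
    groups: dict[str, str]
    frequencies: dict[str, tuple[float, float]]  # marker -> (freq g1, freq g2)


MarkerSpec = tuple[PrimerCombo | str, float, float]


def simulate_cohort(
    n1: int = DEFAULT_N1,
    n2: int = DEFAULT_N2,
    markers: Sequence[MarkerSpec] = (),
    zygosity_model: str = "hw",
    seed=0,
    *,
    gc: float = DEFAULT_GC,
    spacing: int = 120,
    base_insert: int = 60,
    offset: int = DEFAULT_OFFSET,
) -> tuple[dict[str, tuple[str, str]], SimulationTruth]:
    """A two-group cohort of diploid samples with planted markers.

    A shared reference genome carries one planted fragment per marker
    spec ``(combo, freq_group1, freq_group2)``; insert sizes are assigned
    distinct values so markers never co-migrate.  For each marker one
    causal substitution is drawn from its 48-variant space; each sample
    carries it on 0, 1 or 2 haplotypes so that, under dominant scoring,
    the marker is present with its group's frequency.  Under the default
    Hardy-Weinberg model the killing-allele frequency is
    ``sqrt(1 - freq)`` and the killed-haplotype count is Binomial(2, .);
    model ``"fixed"`` kills both haplotypes with probability
    ``1 - freq`` (no heterozygotes).

    Returns ``(samples, truth)`` with ``samples`` mapping sample id to a
    haplotype pair.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("both groups need at least one sample")
    if zygosity_model not in ("hw", "fixed"):
        raise ValueError("zygosity_model must be 'hw' or 'fixed'")
    specs: list[tuple[PrimerCombo, float, float]] = []
    for combo, f1, f2 in markers:
        if isinstance(combo, str):
            combo = combo_from_label(combo)
        if not (0.0 <= f1 <= 1.0 and 0.0 <= f2 <= 1.0):
            raise ValueError("marker frequencies must be within [0, 1]")
        specs.append((combo, f1, f2))

    rng = _rng(seed)
    k = len(specs)
    insert_sizes = [base_insert + 7 * i for i in range(k)]
    genome_len = max(100, 60 + sum(s + 4 + spacing for s in insert_sizes) + 60)
    reference = simulate_genome(genome_len, gc=gc, seed=rng)

    planted: list[PlantedFragment] = []
    causal: dict[str, Variant] = {}
    pos = 30
    for (combo, _, _), ins in zip(specs, insert_sizes):
        reference, truth = plant_fragment(
            reference, combo, ins, pos, seed=rng, offset=offset
        )
        planted.append(truth)
        pos += ins + 4 + spacing

    # re-derive the planted PredictedFragments on the final reference (all
    # coordinates are stable: later plants never touch earlier constructs)
    frags = double_digest(reference)
    for (combo, _, _), truth in zip(specs, planted):
        pfs = [
            pf
            for pf in select_fragments(frags, reference, combo, offset=offset)
            if pf.raw.start == truth.insert_start
        ]
        if len(pfs) != 1:
            raise RuntimeError("planted fragment lost during cohort assembly")
        space = enumerate_site_substitutions(pfs[0])
        causal[truth.marker_id] = space[int(rng.integers(len(space)))]

    sample_ids = [f"g1_{i:03d}" for i in range(n1)] + [
        f"g2_{i:03d}" for i in range(n2)
    ]
    groups = {s: ("group1" if s.startswith("g1") else "group2") for s in sample_ids}

    marker_ids = [t.marker_id for t in planted]
    genotypes = pd.DataFrame(0, index=sample_ids, columns=marker_ids, dtype=int)
    samples: dict[str, tuple[str, str]] = {}
    for sid in sample_ids:
        to_kill: dict[Variant, int] = {}
        for (combo, f1, f2), truth in zip(specs, planted):
            f = f1 if groups[sid] == "group1" else f2
            if zygosity_model == "hw":
                a = math.sqrt(max(0.0, 1.0 - f))
                g = int(rng.binomial(2, a))
            else:
                g = 2 if rng.random() > f else 0
            genotypes.loc[sid, truth.marker_id] = g
            if g:
                to_kill[causal[truth.marker_id]] = g
        hap0 = list(reference)
        hap1 = list(reference)
        for variant, g in to_kill.items():
            hap0[variant.pos] = variant.alt
            if g == 2:
                hap1[variant.pos] = variant.alt
        samples[sid] = ("".join(hap0), "".join(hap1))

    truth = SimulationTruth(
        reference=reference,
        planted=planted,
        causal_variants=causal,
        genotypes=genotypes,
        groups=groups,
        frequencies={
            t.marker_id: (f1, f2) for (c, f1, f2), t in zip(specs, planted)
        },
    )
    return samples, truth


def simulate_reads(
    fragments: Sequence[PredictedFragment],
    depth: int,
    error_rate: float = 0.0,
    seed=0,
) -> tuple[list[Read], dict[str, str]]:
    """Full-length amplicon reads with i.i.d. substitution errors.

    Emits *depth* reads per fragment template in random orientation; each
    base is replaced by a uniformly drawn different base with probability
    *error_rate*.  Returns the reads and the true read -> marker mapping.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if not 0.0 <= error_rate < 0.1:
        raise ValueError("error_rate must be within [0, 0.1)")
    rng = _rng(seed)
    bases = "ACGT"
    reads: list[Read] = []
    truth: dict[str, str] = {}
    for pf in fragments:
        template = pf.template
        for d in range(depth):
            seq = list(template)
            if error_rate > 0:
                hits = np.nonzero(rng.random(len(seq)) < error_rate)[0]
                for i in hits:
                    choices = bases.replace(seq[i], "")
                    seq[i] = choices[int(rng.integers(3))]
            out = "".join(seq)
            if rng.random() < 0.5:
                out = reverse_complement(out)
            read_id = f"{pf.marker_id}_r{d:04d}"
            reads.append(Read(read_id, out))
            truth[read_id] = pf.marker_id
    return reads, truth
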