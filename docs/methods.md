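# Methods

## The virtual AFLP model

AFLP reduces a genome to the set of EcoRI–MseI restriction fragments that
survive selective PCR. This package models that reduction
deterministically, sequence-in → marker-set-out, with the wet-lab stages
abstracted as follows.

**Digestion.** Both enzymes cut wherever their motif occurs on the
(linear) top strand; both motifs are palindromic, so one scan covers both
strands. Coordinates are 0-based half-open; a cut position is the index
of the first base right of the scissile bond (EcoRI `G|AATTC` → motif
start + 1, MseI `T|TAA` → motif start + 1). Overlapping motif occurrences
all count; any motif window containing `N` never matches, because a
reference gap must not fabricate a site. Partial digestion, methylation
sensitivity and star activity are not modeled. Should a user-supplied
enzyme pair cut at one position, the boundary takes the lexicographically
smaller enzyme name (deterministic output).

**Orientation and the sticky-end fill.** Each EcoRI–MseI fragment is
represented by its *oriented insert*: the cut-to-cut sequence on the
strand with the EcoRI cut at the 5′ end, which therefore begins with the
remnant `AATTC`. Because both enzymes cut off-center, the two strands of
a physical fragment have staggered ends; for an MseI-left fragment the
oriented insert maps through the filled-in overhangs to
`revcomp(genome[start+2 : end+4])`. This makes mirror-image fragments
yield byte-identical inserts, so fingerprints are exactly strand-invariant
(the raw cut-to-cut boundaries alone are not: they mirror up to a 4-bp
EcoRI / 2-bp MseI shift).

**Selective amplification.** A primer combination (MseI C**XX**, EcoRI
A**XX**) amplifies a fragment when (i) it has exactly one EcoRI and one
MseI end — MseI–MseI amplification is suppressed by design and
EcoRI–EcoRI fragments are rare and unscored; fragments touching a
sequence terminus never amplify — and (ii) insert positions 5–7 equal the
EcoRI selective triplet while the reverse complement of the three bases
before the terminal `T` equals the MseI triplet (equivalently: the
amplicon read from the MseI side begins `TAA` + CXX). Published fragment
reads ("AATTCAGG…" for E-AGG, "TAACAG…" for M-CAG) pin this convention
down and it is unit-tested. A +1 preselective step with fixed first bases
A/C is implied by the primer names and is a computational no-op under +3
matching. Fragments containing `N` are excluded from amplification by
default.

**Sizing.** Detected (capillary-electrophoresis) size = cut-to-cut insert
length + a constant primer-tail offset, default **24 bp** (11 bp EcoRI
tail + 13 bp MseI tail). Published fragment tables show the two sizing
software packages disagreeing by 1–2 bp on the same molecule, so detected
sizes are harmonized across samples by single-linkage bins with
half-width **tol = 2 bp**, additionally split so no bin exceeds `2·tol`
in width (split left-to-right; deterministic). A marker is
`CXX_AXX_<bin center>`; peak-height/mobility modeling is out of scope.

**Scoring.** Dominant: a sample's call is 1 when at least one haplotype
yields a fragment in the bin. A dosage channel (0/1/2 haplotypes)
preserves the co-dominant information; `call == 1 ⟺ dosage ≥ 1` is an
enforced invariant.

## Variant effects

`apply_variants` builds explicit haplotype pairs (VCF-anchored alleles,
left-normalized, non-overlapping; heterozygous variants go to haplotype 0,
deterministically). `enumerate_site_substitutions` returns the complete
single-substitution causal space of a fragment: 6 EcoRI positions (the
full GAATTC, including the leading G) + 4 MseI positions + 3 + 3
selective bases, each with 3 alternate bases → **48 variants**, every one
of which abolishes the marker (30 when selective bases are excluded).
Indels at these positions form an unbounded space and are supported via
`apply_variants` but not enumerated. `classify_effect` re-fingerprints the
mutated genome and labels mechanisms **a** (site gain/loss at a fragment
boundary), **b** (selective-base change), **c** (indel size shift),
**d** (new internal site splitting an amplified fragment — reported by the
classifier although not part of the 48-space enumeration) and **e**
(combinations; an indel that also changes a site is classed e). VCF
annotation requires an exact (seq, pos, ref, alt) match; positional-only
coincidences are deliberately not annotated.

## Marker statistics

**Fisher's exact test** (via scipy's hypergeometric implementation,
verified in the tests against an exhaustive enumeration oracle in exact
rational arithmetic): `p_two` is the small-p two-tailed convention — the
sum of probabilities of all margin-fixed tables whose point probability
does not exceed the observed one — which matches the common online
calculators; the "doubling" convention differs and is not used. `p_one`
is the tail in the direction of the observed deviation, so
`p_one ≤ p_two`. The association scan builds one present/absent × group
table per marker and flags raw `p_two < α` (default 0.05), mirroring the
raw-threshold practice of small AFLP studies; Bonferroni and
Benjamini–Hochberg adjustments are available behind a flag and a warning
is emitted when >100 markers are tested uncorrected.

**Dissimilarities.** Dice (default, the usual choice for dominant AFLP
markers in diversity work), Jaccard and simple matching. A 0/0 ratio
(two all-absent profiles) is defined as distance 0, consistent with
"identical profiles are at distance 0". Note that Dice and Jaccard ignore
shared absences; when one group carries markers at low frequency, most of
the between-group signal sits in co-absences, and simple matching is the
appropriate metric for two-group separation (this is what the bundled
two-cluster analysis uses).

**Neighbor-joining.** Saitou–Nei agglomeration with the standard
Q-criterion; the post-join distance update is the *unweighted* variant:
the new node's distance to every other cluster is the average of
`d − branch` over the joined clusters' constituent taxa (taxon-count
weights), not the classical half-and-half rule. Both rules reconstruct
additive matrices exactly (tested to 1e-9 and cross-checked against an
independent NJ implementation); on noisy binary-marker distances the
taxon-count average uses every underlying sample and demonstrably places
outlier samples more stably, which is why it is the default here. Ties in
the Q-minimization break toward the lexicographically smallest active
pair; a negative branch length at a join is clamped to zero with the
deficit moved to the sister branch (pair path length preserved), raw
values kept in `Tree.raw_branch_lengths`. Newick output uses 6-decimal
fixed-format lengths and single-quotes labels containing spaces.

## Read recognition

A read is attributed to an in-silico predicted fragment when it shows the
EcoRI signature (`AATTC`+AXX) at the 5′ end of one strand and the MseI
signature (`TAA`+CXX) reading in from the other end, and its implied
insert length (read length − the 2-bp MseI-side fill) matches the
candidate within `size_tol` (default 2 bp). Signature bases define marker
identity and tolerate **zero** mismatches; elsewhere a budget of 1
mismatch (edit distance) absorbs sequencing errors. Consequence: with a
1% uniform substitution error, about `1 − 0.99¹⁴ ≈ 13%` of reads carry an
error inside the 14 signature positions and remain unassigned — the
design trades recall for precision (error-free reads are recovered 100%;
among assigned noisy reads ≥95% are correct). Ambiguous reads (two or
more equally good candidates) are left unassigned rather than guessed, so
no read ever counts toward two markers. Consensus is a per-position
majority vote over the assigned reads of modal length, ties becoming
IUPAC codes; base qualities are read but unused (documented extension
point). Size homoplasy — ≥2 distinct sequences sharing a (combo, size
bin) — is reported both from consensus sequences and purely in silico
from predicted fragments.

## Synthetic data

The generators define the study conditions under which everything above
is tested. Genomes are i.i.d. with GC default **0.41** (human-like);
default cohort sizes are **65 + 30** (patient/donor-style two-group
design). A planted fragment is the construct
`G AATTC AXX <motif-free filler> revcomp(CXX) T TAA` (minimum insert
12 bp), rejection-sampled so the construct contains exactly its two
intended motifs; its fixed head and tail cannot combine with flanking
bases into new motifs, so junctions are safe by construction, and each
plant is verified by re-digestion. Cohorts plant one causal substitution
per marker, drawn uniformly from the 48-space; a sample carries it on
0/1/2 haplotypes under Hardy–Weinberg with killing-allele frequency
`sqrt(1 − f)`, so the dominant-call presence probability is exactly the
requested group frequency `f` (a `fixed` model without heterozygotes is
also available). Markers get distinct insert sizes (7-bp spacing) so they
never co-migrate. Reads are full-length amplicon templates in random
orientation with i.i.d. substitution errors only (no homopolymer indels).
All generators are pure functions of (parameters, seed).

What passing tests do **not** show: robustness to repeat families and
size homoplasy at genome scale, linked markers, 454-style indel errors,
or partial digestion — real-genome features the i.i.d. generator does not
emulate.

## Problem sizes and numerical choices

The bundled analyses run at desk scale: double digests of kb-size
genomes, cohorts of 60–95 samples, 100-seed two-cluster simulations
(30+30 samples, 20 differential markers at presence 0.8 vs 0.2 — at
those frequencies a clean NJ bipartition is recovered in ≈98–99% of
seeds; occasional failures are samples whose binomial marker draw is
genuinely ambiguous), and the exhaustive Fisher verification over all
10 625 tables with total ≤ 20 (agreement with the exact-rational oracle
to <1e-12; the minimum spacing of distinct hypergeometric point
probabilities at these sizes makes floating-point tie-breaking a
non-issue). Full-genome digests of real chromosomes are supported by the
same code paths but are not part of the test suite.

## Known limitations

- Wet-lab effects (peak intensities, preferential amplification, partial
  digestion, dye overlap) are out of scope; the dosage channel is the
  only co-dominant information carried.
- The enumeration of causal variants covers substitutions only; the
  internal-site-gain mechanism (d) is detected by the classifier but not
  enumerated.
- Read matching is signature-and-length based, not a full aligner; large
  indels inside a read defeat it by design.
- Printed per-cohort P-value pairs in published marker tables are not
  reproducible from the single-2×2 construction implemented here and are
  not attempted.
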