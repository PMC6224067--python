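"""Variant application, causal-space enumeration and mechanism classification."""

import pytest

from aflp import (
    Variant,
    annotate_with_known,
    apply_variants,
    classify_effect,
    combo_from_label,
    double_digest,
    enumerate_site_substitutions,
    fingerprint,
    plant_fragment,
    predict_candidates,
    reverse_complement,
    select_fragments,
    simulate_genome,
    virtual_profile,
)


def planted_fragment(genome, truth, combo):
    pfs = select_fragments(double_digest(genome), genome, combo)
    return [p for p in pfs if p.raw.start == truth.insert_start][0]


class TestApplyVariants:
    def test_no_variants_identity(self, toy_genome):
        h0, h1 = apply_variants(toy_genome, [])
        assert h0 == h1 == toy_genome

    def test_ref_mismatch_names_position_and_base(self, toy_genome):
        with pytest.raises(ValueError, match="position 0.*expected 'C'.*observed 'A'"):
            apply_variants(toy_genome, [Variant("seq", 0, "C", "T")])

    def test_overlap_rejected(self, toy_genome):
        v1 = Variant("seq", 4, "AA", "A")
        v2 = Variant("seq", 5, "A", "G")
        with pytest.raises(ValueError, match="overlap"):
            apply_variants(toy_genome, [v1, v2])

    def test_out_of_bounds_rejected(self, toy_genome):
        with pytest.raises(ValueError, match="beyond"):
            apply_variants(toy_genome, [Variant("seq", 18, "CC", "C")])

    def test_homozygous_two_bp_deletion_shifts_size(self, planted, cag_agg):
        """A hom 2-nt deletion inside the fragment shifts its detected size
        by -2 on both haplotypes (the AA-deletion marker mechanism)."""
        genome, truth = planted
        pos = truth.insert_start + 20
        ref = genome[pos : pos + 3]
        v = Variant("seq", pos, ref, ref[0])
        h0, h1 = apply_variants(genome, [v], zygosity="hom")
        for hap in (h0, h1):
            assert truth.detected_size - 2 in virtual_profile([hap], cag_agg)
            assert truth.detected_size not in virtual_profile([hap], cag_agg)

    def test_heterozygous_site_kill_affects_one_haplotype(self, planted, cag_agg):
        genome, truth = planted
        # destroy the G of the fragment's EcoRI site on one haplotype
        g_pos = truth.insert_start - 1
        v = Variant("seq", g_pos, "G", "T")
        h0, h1 = apply_variants(genome, [v], zygosity="het")
        assert h1 == genome
        assert truth.detected_size not in virtual_profile([h0], cag_agg)
        # the two flanking fragments merge on the mutated haplotype
        assert len(double_digest(h0)) == len(double_digest(genome)) - 1

    def test_involution_restores_reference_fingerprint(self, planted, cag_agg):
        genome, truth = planted
        pf = planted_fragment(genome, truth, cag_agg)
        for v in enumerate_site_substitutions(pf)[::7]:
            mutated, _ = apply_variants(genome, [v])
            restored, _ = apply_variants(mutated, [v.inverse()])
            assert restored == genome

    def test_variant_kinds(self):
        assert Variant("s", 0, "A", "G").kind == "SNP"
        assert Variant("s", 0, "A", "AG").kind == "insertion"
        assert Variant("s", 0, "AG", "A").kind == "deletion"
        with pytest.raises(ValueError):
            Variant("s", 0, "A", "A")


class TestEnumerateSiteSubstitutions:
    def test_exactly_48(self, planted, cag_agg):
        genome, truth = planted
        pf = planted_fragment(genome, truth, cag_agg)
        subs = enumerate_site_substitutions(pf)
        assert len(subs) == 48
        assert len({(v.pos, v.alt) for v in subs}) == 48
        # 16 positions x 3 alternates
        assert len({v.pos for v in subs}) == 16

    def test_without_selective_bases_30(self, planted, cag_agg):
        genome, truth = planted
        pf = planted_fragment(genome, truth, cag_agg)
        assert len(enumerate_site_substitutions(pf, include_selective=False)) == 30

    def test_all_48_abolish_marker(self, planted, cag_agg):
        genome, truth = planted
        pf = planted_fragment(genome, truth, cag_agg)
        for v in enumerate_site_substitutions(pf):
            mutated, _ = apply_variants(genome, [v])
            assert truth.detected_size not in virtual_profile([mutated], cag_agg)

    def test_mirror_orientation_all_48_abolish(self, planted, cag_agg):
        """The genome-coordinate arithmetic also holds for MseI-left
        (reverse-oriented) fragments."""
        genome, truth = planted
        rc = reverse_complement(genome)
        pf = [
            p
            for p in select_fragments(double_digest(rc), rc, cag_agg)
            if p.oriented_insert == truth.insert
        ][0]
        assert pf.raw.left_end == "MseI"
        subs = enumerate_site_substitutions(pf)
        assert len(subs) == 48
        for v in subs:
            mutated, _ = apply_variants(rc, [v])
            assert truth.detected_size not in virtual_profile([mutated], cag_agg)


class TestClassifyEffect:
    def test_site_gain_mechanism_a(self, planted, cag_agg):
        """Restoring a destroyed EcoRI-site base is a site-introduction SNP:
        the marker is gained through mechanism (a)."""
        genome, truth = planted
        pf = planted_fragment(genome, truth, cag_agg)
        site_sub = [
            v for v in enumerate_site_substitutions(pf) if v.pos == truth.insert_start - 1
        ][0]
        mutated, _ = apply_variants(genome, [site_sub])
        eff = classify_effect(mutated, site_sub.inverse(), cag_agg)
        assert eff.mechanism == "a"
        assert eff.before_state == "absent"
        assert eff.after_state == f"present at {truth.detected_size}"
        assert eff.marker_id == truth.marker_id

    def test_selective_base_mechanism_b(self, planted, cag_agg):
        genome, truth = planted
        pf = planted_fragment(genome, truth, cag_agg)
        sel_sub = [
            v for v in enumerate_site_substitutions(pf) if v.pos == truth.insert_start + 5
        ][0]
        eff = classify_effect(genome, sel_sub, cag_agg)
        assert eff.mechanism == "b"
        assert eff.before_state == f"present at {truth.detected_size}"
        assert eff.after_state == "absent"

    def test_indel_size_shift_mechanism_c(self, planted, cag_agg):
        genome, truth = planted
        pos = truth.insert_start + 20
        ref = genome[pos : pos + 2]
        v = Variant("seq", pos, ref, ref[0])
        eff = classify_effect(genome, v, cag_agg)
        assert eff.mechanism == "c"
        assert eff.size_delta == -1
        assert eff.after_state == f"present at {truth.detected_size - 1}"

    def test_new_internal_site_mechanism_d(self, cag_agg):
        """A SNP creating a TTAA inside an amplified fragment replaces the
        marker with a shorter one (the internal MseI-site-gain case)."""
        # hand-built fragment whose filler carries CTG+TTAG: one SNP turns
        # TTAG into an internal MseI site whose upstream context (CTG =
        # revcomp CAG) lets the shorter 5' piece amplify for the same combo
        filler = "CCGCCGCC" + "CTG" + "TTAG" + "CCGCCGCCGCCGCCGCCGCCGCCGCC"
        construct = (
            "G" + "AATTC" + "AGG" + filler + reverse_complement("CAG") + "T" + "TAA"
        )
        genome = "CCGCCG" + construct + "CCGCCG"
        pfs = select_fragments(double_digest(genome), genome, cag_agg)
        assert len(pfs) == 1
        ttag = genome.find("TTAG")
        v = Variant("seq", ttag + 3, "G", "A")
        eff = classify_effect(genome, v, cag_agg)
        assert eff.mechanism == "d"
        assert eff.before_state.startswith("present")
        # the original marker is replaced by a shorter one
        assert eff.size_delta < 0
        assert eff.after_state.startswith("present at ")

    def test_no_effect_record(self, planted, cag_agg):
        genome, truth = planted
        pos = truth.insert_start - 200
        v = Variant("seq", pos, genome[pos], "ACGT".replace(genome[pos], "")[0])
        eff = classify_effect(genome, v, cag_agg)
        assert eff.mechanism is None
        assert eff.marker_id is None

    def test_pure_function(self, planted, cag_agg):
        genome, truth = planted
        pf = planted_fragment(genome, truth, cag_agg)
        v = enumerate_site_substitutions(pf)[10]
        assert classify_effect(genome, v, cag_agg) == classify_effect(
            genome, v, cag_agg
        )


@pytest.fixture(scope="module")
def three_sizes(cag_agg):
    genome = simulate_genome(3000, seed=9)
    target = 100  # detected size of a 76-bp insert with offset 24
    pos = 300
    for i, ins in enumerate((71, 76, 82)):  # detected 95, 100, 106
        genome, _ = plant_fragment(genome, cag_agg, ins, pos, seed=i)
        pos += ins + 300
    return genome, target


class TestPredictCandidates:

    def test_window_zero_exact(self, three_sizes, cag_agg):
        genome, target = three_sizes
        hits = predict_candidates(genome, cag_agg, target, window=0)
        assert [p.detected_size for p in hits] == [100]

    def test_window_five_excludes_plus_six(self, three_sizes, cag_agg):
        genome, target = three_sizes
        hits = predict_candidates(genome, cag_agg, target, window=5)
        assert sorted(p.detected_size for p in hits) == [95, 100]

    def test_monotone_in_window(self, three_sizes, cag_agg):
        genome, target = three_sizes
        prev: set = set()
        for w in (0, 2, 5, 8, 50):
            got = {p.raw.start for p in predict_candidates(genome, cag_agg, target, w)}
            assert prev <= got
            prev = got


VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##INFO=<ID=AF,Number=A,Type=Float,Description="Allele Frequency">\n'
    "##contig=<ID=seq>\n"
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
)


class TestAnnotateWithKnown:
    def test_empty_vcf_all_unannotated(self, tmp_path, planted, cag_agg):
        genome, truth = planted
        pf = planted_fragment(genome, truth, cag_agg)
        cands = enumerate_site_substitutions(pf)[:5]
        vcf = tmp_path / "empty.vcf"
        vcf.write_text(VCF_HEADER)
        out = annotate_with_known(cands, vcf)
        assert len(out) == 5
        assert all(k.rsid is None and k.maf is None for k in out)

    def test_single_match_carries_rsid_and_maf(self, tmp_path, planted, cag_agg):
        genome, truth = planted
        pf = planted_fragment(genome, truth, cag_agg)
        cands = enumerate_site_substitutions(pf)
        hit = cands[7]
        vcf = tmp_path / "one.vcf"
        vcf.write_text(
            VCF_HEADER
            + f"seq\t{hit.pos + 1}\trs12345\t{hit.ref}\t{hit.alt}\t.\t.\tAF=0.0424\n"
        )
        out = annotate_with_known(cands, vcf)
        annotated = [k for k in out if k.rsid is not None]
        assert len(annotated) == 1
        assert annotated[0].variant == hit
        assert annotated[0].rsid == "rs12345"
        assert annotated[0].maf == pytest.approx(0.0424)

    def test_positional_only_match_not_annotated(self, tmp_path, planted, cag_agg):
        genome, truth = planted
        pf = planted_fragment(genome, truth, cag_agg)
        hit = enumerate_site_substitutions(pf)[0]
        other_alt = "ACGT".replace(hit.ref, "").replace(hit.alt, "")[0]
        vcf = tmp_path / "pos.vcf"
        vcf.write_text(
            VCF_HEADER + f"seq\t{hit.pos + 1}\trs9\t{hit.ref}\t{other_alt}\t.\t.\t.\n"
        )
        out = annotate_with_known([hit], vcf)
        assert out[0].rsid is None

    def test_malformed_vcf_reports_line(self, tmp_path):
        vcf = tmp_path / "bad.vcf"
        vcf.write_text(VCF_HEADER + "seq\tnotanumber\t.\tA\tG\n")
        with pytest.raises(ValueError, match="line 5"):
            annotate_with_known([Variant("seq", 3, "A", "G")], vcf)

    def test_maf_range_enforced(self):
        from aflp import KnownVariant

        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            KnownVariant(Variant("s", 1, "A", "G"), "rs1", 1.5)
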