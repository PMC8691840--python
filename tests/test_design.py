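"""Donor/guide design arithmetic: oracles and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from knockin import design as dz
from knockin.seq import revcomp
from knockin.simulate import simulate_locus

DNA = st.text(alphabet="ACGT", min_size=0, max_size=80)


def brute_force_protospacers(window: str, insertion_point: int, radius: int):
    """Independent enumeration of every 20+3-mer with an NGG PAM."""
    w = window.upper()
    L = len(w)
    found = set()
    for s in range(L - 22):
        plus = w[s:s + 23]
        if plus[21:23] == "GG":
            cut = s + 17
            if abs(cut - insertion_point) <= radius:
                found.add((plus[:20], "+", cut))
        minus = revcomp(plus)
        if minus[21:23] == "GG":
            cut = L - (L - s - 23 + 17)  # mirror of plus-strand rule
            if abs(cut - insertion_point) <= radius:
                found.add((minus[:20], "-", cut))
    return found


class TestProtospacers:
    def test_matches_brute_force_on_random_windows(self):
        for seed in range(5):
            loc = simulate_locus(200, gc=0.5, seed=seed)
            tl = dz.TargetLocus("c", loc.seq, 0, 99, 99, dz.Terminus.C)
            got = {(g.spacer, g.strand, g.cut_site)
                   for g in dz.find_protospacers(tl, 50)}
            assert got == brute_force_protospacers(loc.seq, 99, 50)

    def test_known_pam_is_found(self):
        w = "A" * 30 + "T" * 20 + "CGG" + "A" * 30
        tl = dz.TargetLocus("c", w, 0, 50, 50, dz.Terminus.C)
        hits = dz.find_protospacers(tl, 10)
        assert any(g.pam == "CGG" and g.strand == "+" for g in hits)
        # the +-strand spacer ends 3 nt into the window before the PAM
        plus = [g for g in hits if g.pam == "CGG" and g.strand == "+"][0]
        assert plus.spacer == w[30:50]

    def test_at_only_window_has_no_guides(self):
        w = "AT" * 60
        tl = dz.TargetLocus("c", w, 0, 60, 60, dz.Terminus.C)
        assert dz.find_protospacers(tl, 60) == []

    def test_sorted_by_distance(self, toy_locus):
        locus, _ = toy_locus
        hits = dz.find_protospacers(locus, 100)
        dists = [abs(g.distance_to_insertion) for g in hits]
        assert dists == sorted(dists)


class TestCutSite:
    @pytest.mark.parametrize("start,expect", [(0, 17), (100, 117)])
    def test_plus_strand(self, start, expect):
        assert dz.cut_site_of(start, "+") == expect

    def test_minus_strand_by_revcomp_symmetry(self):
        # recompute every minus-strand cut on the reverse-complemented window
        loc = simulate_locus(300, gc=0.5, seed=3)
        tl = dz.TargetLocus("c", loc.seq, 0, 150, 150, dz.Terminus.C)
        minus = [g for g in dz.find_protospacers(tl, 150) if g.strand == "-"]
        rc = revcomp(loc.seq)
        tl_rc = dz.TargetLocus("c", rc, 0, 150, 150, dz.Terminus.C)
        plus_rc_cuts = {len(rc) - g.cut_site
                        for g in dz.find_protospacers(tl_rc, 200)
                        if g.strand == "+"}
        assert minus and all(g.cut_site in plus_rc_cuts for g in minus)


class TestHomologyArms:
    def test_reconstruction(self, toy_locus):
        locus, _ = toy_locus
        ip = locus.insertion_point
        left, right = dz.extract_homology_arms(locus, 35)
        assert left + right == locus.window_seq[ip - 35:ip + 35]
        assert len(left) == len(right) == 35

    def test_out_of_range_length_warns_but_returns(self, toy_locus):
        locus, _ = toy_locus
        with pytest.warns(UserWarning, match="outside recommended"):
            left, right = dz.extract_homology_arms(locus, 41)
        assert len(left) == 41

    def test_arm_beyond_window_is_boundary_error(self):
        loc = simulate_locus(90, gc=0.4, seed=2)
        tl = dz.TargetLocus("c", loc.seq, 0, 9, 9, dz.Terminus.C)
        with pytest.raises(dz.DesignError, match="beyond the locus window"):
            dz.extract_homology_arms(tl, 30)


class TestTagCassette:
    def test_720_orf_trims_to_714(self, tag_cassette):
        assert len(tag_cassette.block) == 714
        assert not tag_cassette.seq.startswith("ATG")
        assert tag_cassette.seq[-3:] not in ("TAA", "TAG", "TGA")

    def test_internal_stop_rejected(self):
        orf = "ATG" + "GCA" * 10 + "TGA" + "GCA" * 10 + "TAA"
        with pytest.raises(dz.DesignError, match="stop codon"):
            dz.build_tag_cassette(orf, "C")

    def test_linkers_keep_frame(self, tag_cassette):
        cas = dz.build_tag_cassette("ATG" + tag_cassette.seq + "TAA", "N",
                                    linker_5="GGTGGA", linker_3="")
        assert len(cas.block) == 720
        assert len(cas.block) % 3 == 0

    def test_off_frame_linker_rejected(self, tag_cassette):
        with pytest.raises(dz.DesignError, match="divisible by 3"):
            dz.build_tag_cassette("ATG" + tag_cassette.seq + "TAA", "N",
                                  linker_5="GGTG")


class TestDonorAssembly:
    def test_total_length_is_arms_plus_block(self, donor_780):
        assert len(donor_780.donor_seq) == 33 + 714 + 33 == 780

    def test_empty_cassette_is_identity_edit(self, toy_locus):
        locus, _ = toy_locus
        allele = dz.build_expected_allele(locus, "")
        assert allele == locus.window_seq

    def test_hdr_allele_length(self, toy_locus, tag_cassette):
        locus, _ = toy_locus
        allele = dz.build_expected_allele(locus, tag_cassette)
        assert len(allele) == len(locus.window_seq) + len(tag_cassette.block)

    def test_frame_conserved_across_junctions(self, toy_locus, tag_cassette):
        from knockin.seq import in_frame_stops
        locus, loc = toy_locus
        allele = dz.build_expected_allele(locus, tag_cassette)
        cds_hi = loc.orf_end + len(tag_cassette.block) - 3
        stops = [o for o in in_frame_stops(allele, locus.frame_anchor % 3)
                 if locus.frame_anchor <= o < cds_hi]
        assert stops == []


class TestPrimers:
    def test_donor_primers_biotinylated_and_tail_structure(self, donor_780):
        pp = dz.design_donor_primers(donor_780)
        assert pp.fwd_biotin and pp.rev_biotin
        assert pp.fwd_seq.startswith(donor_780.left_arm)
        assert revcomp(pp.rev_seq).endswith(donor_780.right_arm)

    def test_in_silico_pcr_reproduces_donor(self, donor_780):
        pp = dz.design_donor_primers(donor_780)
        product = dz.in_silico_pcr(donor_780.cassette.block,
                                   pp.fwd_seq, pp.rev_seq)
        assert product == donor_780.donor_seq

    def test_genotyping_primers_sit_outside_donor(self, toy_locus, donor_780):
        locus, _ = toy_locus
        gp = dz.design_genotyping_primers(locus, donor_780)
        assert gp.fwd_seq not in donor_780.donor_seq
        assert gp.rev_seq not in donor_780.donor_seq
        delta = gp.predicted_ki_amplicon_bp - gp.predicted_wt_amplicon_bp
        assert delta == len(donor_780.cassette.block)

    def test_genotyping_pcr_on_hdr_allele(self, toy_locus, donor_780):
        locus, _ = toy_locus
        gp = dz.design_genotyping_primers(locus, donor_780)
        allele = dz.build_expected_allele(locus, donor_780)
        product = dz.in_silico_pcr(allele, gp.fwd_seq, gp.rev_seq)
        assert len(product) == gp.predicted_ki_amplicon_bp

    def test_insufficient_flank_is_error(self, tag_cassette):
        loc = simulate_locus(200, gc=0.4, seed=9)
        tl = dz.TargetLocus("c", loc.seq, 0, 99, 99, dz.Terminus.C)
        arms = dz.extract_homology_arms(tl, 35)
        donor = dz.assemble_donor(tl, arms, tag_cassette)
        with pytest.raises(dz.DesignError, match="beyond both homology arms"):
            dz.design_genotyping_primers(tl, donor, flank_min=100)


class TestMolarity:
    def test_paper_regime(self):
        # ~10 ng/ul of a ~780-bp donor is ~20 nM
        assert dz.donor_molarity(10, 780) == pytest.approx(19.72, abs=0.01)

    def test_closed_form(self):
        assert dz.donor_molarity(0.650, 1000) == pytest.approx(1.0, rel=1e-9)

    @given(mass=st.floats(0.1, 1000), length=st.integers(50, 20000))
    @settings(max_examples=50, deadline=None)
    def test_matches_closed_form_and_halves_with_doubled_length(self, mass, length):
        m = dz.donor_molarity(mass, length)
        assert m == pytest.approx(mass * 1e6 / (650 * length), rel=1e-9)
        assert dz.donor_molarity(mass, 2 * length) == pytest.approx(m / 2, rel=1e-9)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(dz.DesignError):
            dz.donor_molarity(0, 780)
        with pytest.raises(dz.DesignError):
            dz.donor_molarity(10, -1)


class TestMixRecipe:
    def test_defaults_in_recommended_ranges(self):
        assert all(dz.MixRecipe().in_recommended_range().values())

    def test_out_of_range_flagged(self):
        checks = dz.MixRecipe(donor_ng_per_ul=50).in_recommended_range()
        assert not checks["donor_ng_per_ul"]
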