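"""Site calling, rate statistics, frameshifts and replacement substitutions."""

import numpy as np
import pytest

from minihet.align import map_clones
from minihet.heteroplasmy import (
    build_report,
    call_sites,
    detect_frameshifts,
    rate,
    replacement_substitutions,
    round_half_up,
    sites_per_clone,
    taq_error_expectation,
    unique_clone_count,
    unique_replacement_substitutions,
)
from minihet.seq_core import NucSequence


class TestRateArithmetic:
    @pytest.mark.parametrize(
        "sites, n, bp, expected",
        [
            (26, 26, 591, 0.0017),
            (8, 7, 591, 0.0019),
            (10, 12, 591, 0.0014),
            (17, 7, 1572, 0.0015),
            (0, 12, 591, 0.0),
        ],
    )
    def test_per_bp_per_clone_rate(self, sites, n, bp, expected):
        assert rate(sites, n, bp) == expected

    @pytest.mark.parametrize(
        "sites, n, expected", [(17, 7, 2.4), (0, 7, 0.0), (26, 26, 1.0)]
    )
    def test_sites_per_clone(self, sites, n, expected):
        assert sites_per_clone(sites, n) == expected

    @pytest.mark.parametrize(
        "erate, bp, expected", [(1.1e-4, 1000, 0.1), (0, 12345, 0.0), (1e-3, 500, 0.5)]
    )
    def test_polymerase_error_expectation(self, erate, bp, expected):
        assert taq_error_expectation(erate, bp) == expected

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            rate(5, 0, 100)
        with pytest.raises(ValueError):
            rate(5, 10, 0)

    def test_rate_is_linear_in_sites_and_inverse_linear_in_clones_and_bp(self):
        # asserted on the raw (unrounded) statistic over a grid
        for s in (3, 9, 27):
            for n in (5, 10):
                for bp in (300, 900):
                    raw = s / (n * bp)
                    assert rate(s, n, bp) == round_half_up(raw, 4)
                    assert rate(3 * s, n, bp) == round_half_up(3 * raw, 4)
                    assert rate(s, 2 * n, bp) == round_half_up(raw / 2, 4)


class TestSiteCalling:
    def test_planted_gene_and_trna_substitutions_recovered_exactly(
        self, gaurei_bundle, gaurei_matrix
    ):
        circle = gaurei_bundle.circle
        L = len(circle)
        gene = circle.gene.interval
        trna = circle.features_of_type("tRNA")[0].interval
        sites = call_sites(gaurei_matrix, circle)
        called = {s.ref_pos for s in sites if s.region in ("coding", "overlap", "tRNA")}
        planted = {
            p
            for subs in gaurei_bundle.truth.substitutions.values()
            for p, _r, _a in subs
            if gene.contains(p, L) or trna.contains(p, L)
        }
        assert called == planted

    def test_codon_positions_follow_gene_offset(self, gaurei_bundle, gaurei_matrix):
        circle = gaurei_bundle.circle
        for s in call_sites(gaurei_matrix, circle):
            if s.region in ("coding", "overlap"):
                assert s.codon_position == (s.ref_pos % 3) + 1  # gene at origin
            else:
                assert s.codon_position is None

    def test_ambiguity_codes_do_not_create_sites(self, gaurei_bundle):
        circle = gaurei_bundle.circle
        ref = circle.sequence.residues
        arc = gaurei_bundle.truth.arc
        base = "".join(ref[p] for p in arc.positions(len(circle)))
        with_n = "N" + base[1:]
        m = map_clones(circle, [NucSequence("c0", base), NucSequence("c1", with_n)])
        assert call_sites(m, circle) == []


class TestFrameshifts:
    def test_planted_single_bp_indels_flagged(self, gaurei_bundle, gaurei_matrix):
        calls = detect_frameshifts(gaurei_matrix, gaurei_bundle.circle)
        assert sorted(c.clone_id for c in calls) == sorted(
            gaurei_bundle.truth.frameshift_clones
        )
        for c in calls:
            assert abs(c.net_indel_len) % 3 != 0

    def test_in_frame_deletion_not_flagged_but_22bp_deletion_is(self, gaurei_bundle):
        circle = gaurei_bundle.circle
        ref = circle.sequence.residues
        arc = gaurei_bundle.truth.arc
        pos_list = list(arc.positions(len(circle)))
        base = "".join(ref[p] for p in pos_list)
        in_frame = base[:120] + base[123:]  # 3-bp deletion inside the gene
        big_shift = base[:100] + base[122:]  # 22-bp deletion (22 mod 3 = 1)
        m = map_clones(
            circle,
            [
                NucSequence("c0", base),
                NucSequence("c_inframe", in_frame),
                NucSequence("c_22del", big_shift),
            ],
        )
        calls = detect_frameshifts(m, circle)
        assert [c.clone_id for c in calls] == ["c_22del"]
        assert calls[0].net_indel_len == -22
        # a frameshift early in the gene truncates the protein severely
        assert calls[0].truncated_protein_len < 512


class TestReplacementSubstitutions:
    def test_reference_clone_has_no_differences(self, gaurei_bundle):
        circle = gaurei_bundle.circle
        ref = circle.sequence.residues
        arc = gaurei_bundle.truth.arc
        base = "".join(ref[p] for p in arc.positions(len(circle)))
        m = map_clones(circle, [NucSequence("c0", base), NucSequence("c1", base)])
        subs = replacement_substitutions(m, circle)
        assert subs == {"c0": [], "c1": []}

    def test_threonine_at_start_codon(self, gaurei_bundle):
        # ACG at codon 1 versus the reference ATG start codes for threonine
        circle = gaurei_bundle.circle
        L = len(circle)
        ref = circle.sequence.residues
        arc = gaurei_bundle.truth.arc
        pos_list = list(arc.positions(L))
        base = "".join(ref[p] for p in pos_list)
        k = pos_list.index(1)  # second base of the start codon
        assert base[k] == "T"
        mutated = base[:k] + "C" + base[k + 1 :]
        m = map_clones(circle, [NucSequence("c0", base), NucSequence("c1", mutated)])
        subs = replacement_substitutions(m, circle)
        assert subs["c1"] == [(1, "M", "T")]
        uniq = unique_replacement_substitutions(subs)
        assert uniq["c1"] == [(1, "M", "T")]


class TestUniqueClones:
    def test_one_identical_pair_among_26(self, gaurei_bundle):
        clones = list(gaurei_bundle.clones)
        clones[25] = NucSequence("dup_of_12", clones[11].residues)
        assert unique_clone_count(clones) == 25

    def test_all_distinct_and_all_identical(self, gaurei_bundle):
        assert unique_clone_count(gaurei_bundle.clones) == 26
        one = gaurei_bundle.clones[0]
        assert unique_clone_count([one] * 7) == 1


class TestReport:
    def test_surveyed_coding_bp_matches_design(self, gaurei_bundle, gaurei_matrix):
        rep = build_report(gaurei_matrix, gaurei_bundle.circle, gaurei_bundle.clones)
        assert rep.surveyed_bp["coding"] + rep.surveyed_bp["overlap"] == 591
        assert rep.surveyed_bp["noncoding"] == 316
        assert rep.n_clones == 26

    def test_rate_consistent_with_site_counts(self, gaurei_bundle, gaurei_matrix):
        rep = build_report(gaurei_matrix, gaurei_bundle.circle, gaurei_bundle.clones)
        coding_sites = rep.site_counts["coding"] + rep.site_counts["overlap"]
        assert rep.rate == rate(coding_sites, rep.n_clones, 591)
        assert sum(rep.codon_position_counts.values()) == coding_sites
        assert rep.unique_clone_count <= rep.n_clones

    def test_noncoding_length_range_brackets_reference(self, gaurei_bundle, gaurei_matrix):
        rep = build_report(gaurei_matrix, gaurei_bundle.circle, gaurei_bundle.clones)
        lo, hi = rep.noncoding_length_range
        assert lo <= 316 <= hi or hi - lo <= 40  # indels spread around 316
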