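"""Pairwise aligner vs a brute-force oracle; clone-to-reference mapping."""

import itertools

import numpy as np
import pytest

from minihet.align import (
    DEFAULT_PARAMS,
    AlignParams,
    global_align,
    map_clones,
    semiglobal_align,
)
from minihet.heteroplasmy import call_sites, indel_events
from minihet.seq_core import NucSequence


def brute_force_best_score(a: str, b: str, p: AlignParams) -> int:
    """Exhaustive enumeration over the whole alignment space.

    A gap run of length k costs ``gap_open + (k-1) * gap_extend``; the
    recursion tracks which state the alignment is in so affine costs are
    exact.  Independent of the DP implementation by construction.
    """
    best = [-(10**9)]

    def rec(i, j, score, last):
        if i == len(a) and j == len(b):
            if score > best[0]:
                best[0] = score
            return
        if i < len(a) and j < len(b):
            s = p.match if a[i] == b[j] else p.mismatch
            rec(i + 1, j + 1, score + s, "M")
        if i < len(a):
            rec(i + 1, j, score + (p.gap_extend if last == "X" else p.gap_open), "X")
        if j < len(b):
            rec(i, j + 1, score + (p.gap_extend if last == "Y" else p.gap_open), "Y")

    rec(0, 0, 0, None)
    return best[0]


def _rescore(aln, p: AlignParams) -> int:
    score = 0
    last = None
    for x, y in zip(aln.aligned_a, aln.aligned_b):
        if x == "-" or y == "-":
            state = "X" if y == "-" else "Y"
            score += p.gap_extend if state == last else p.gap_open
            last = state
        else:
            score += p.match if x == y else p.mismatch
            last = "M"
    return score


class TestGlobalAlign:
    def test_identity(self):
        aln = global_align("ACGT", "ACGT")
        assert aln.n_matches == 4
        assert "-" not in aln.aligned_a + aln.aligned_b

    def test_single_deletion_forced(self):
        aln = global_align("ACGT", "ACT")
        assert (aln.aligned_a.count("-"), aln.aligned_b.count("-")) == (0, 1)

    def test_empty_input_rejected(self):
        with pytest.raises(Exception):
            global_align("", "ACGT")

    def test_matches_bruteforce_oracle_on_all_pairs_of_seeded_8mers(self):
        rng = np.random.default_rng(17)
        seqs = ["".join(rng.choice(list("ACGT"), 8)) for _ in range(4)]
        for a, b in itertools.combinations_with_replacement(seqs, 2):
            aln = global_align(a, b)
            oracle = brute_force_best_score(a, b, DEFAULT_PARAMS)
            assert aln.score == oracle
            # the emitted alignment really achieves the optimal score
            assert _rescore(aln, DEFAULT_PARAMS) == aln.score
            assert aln.aligned_a.replace("-", "") == a
            assert aln.aligned_b.replace("-", "") == b

    @pytest.mark.parametrize("seed", range(6))
    def test_score_symmetric_under_argument_swap(self, seed):
        rng = np.random.default_rng(200 + seed)
        a = "".join(rng.choice(list("ACGT"), int(rng.integers(5, 25))))
        b = "".join(rng.choice(list("ACGT"), int(rng.integers(5, 25))))
        assert global_align(a, b).score == global_align(b, a).score


class TestSemiglobal:
    def test_locates_query_window_in_reference(self):
        ref = "AAAACCGGTAAAA"
        aln, start = semiglobal_align("CCGGT", ref)
        assert start == 4
        assert aln.aligned_b == "CCGGT"
        assert aln.score == 5 * DEFAULT_PARAMS.match


class TestMapClones:
    def test_identical_clones_give_uniform_columns(self, gaurei_bundle):
        circle = gaurei_bundle.circle
        ref = circle.sequence.residues
        arc = gaurei_bundle.truth.arc
        base = "".join(ref[p] for p in arc.positions(len(circle)))
        clones = [NucSequence(f"c{i}", base) for i in range(3)]
        m = map_clones(circle, clones)
        assert not m.insertions
        assert call_sites(m, circle) == []
        covered = m.covered_by_all()
        assert covered.sum() == len(base)

    def test_single_substitution_creates_one_two_allele_column(self, gaurei_bundle):
        circle = gaurei_bundle.circle
        L = len(circle)
        ref = circle.sequence.residues
        arc = gaurei_bundle.truth.arc
        pos_list = list(arc.positions(L))
        base = "".join(ref[p] for p in pos_list)
        mutated = list(base)
        k = 300
        mutated[k] = "G" if base[k] != "G" else "C"
        clones = [NucSequence("c0", base), NucSequence("c1", "".join(mutated))]
        m = map_clones(circle, clones)
        sites = call_sites(m, circle)
        assert [s.ref_pos for s in sites] == [pos_list[k]]
        assert sorted(s for s in sites[0].alleles.values()) == [1, 1]

    def test_planted_indels_recovered_as_equivalent_events(self, gaurei_bundle):
        circle = gaurei_bundle.circle
        L = len(circle)
        ref = circle.sequence.residues
        arc = gaurei_bundle.truth.arc
        pos_list = list(arc.positions(L))
        base = "".join(ref[p] for p in pos_list)
        del_clone = base[:300] + base[304:]
        ins_clone = base[:600] + "GATC" + base[600:]
        clones = [
            NucSequence("c0", base),
            NucSequence("c_del", del_clone),
            NucSequence("c_ins", ins_clone),
        ]
        m = map_clones(circle, clones)
        events = indel_events(m)
        by_clone = {e.clone_id: e for e in events}
        assert set(by_clone) == {"c_del", "c_ins"}
        d = by_clone["c_del"]
        assert (d.kind, d.length) == ("del", 4)
        # removing the reported reference segment reproduces the clone
        local = pos_list.index(d.ref_pos)
        assert base[:local] + base[local + 4 :] == del_clone
        i = by_clone["c_ins"]
        assert (i.kind, i.length) == ("ins", 4)

    def test_clone_order_permutation_leaves_site_calls_unchanged(
        self, gaurei_bundle, gaurei_matrix
    ):
        circle = gaurei_bundle.circle
        sites_fwd = call_sites(gaurei_matrix, circle)
        rng = np.random.default_rng(0)
        perm = list(rng.permutation(len(gaurei_bundle.clones)))
        shuffled = [gaurei_bundle.clones[i] for i in perm]
        m2 = map_clones(circle, shuffled)
        sites_rev = call_sites(m2, circle)
        assert [(s.ref_pos, s.region, s.alleles) for s in sites_fwd] == [
            (s.ref_pos, s.region, s.alleles) for s in sites_rev
        ]

    def test_unmappable_clone_excluded_with_warning(self, gaurei_bundle):
        circle = gaurei_bundle.circle
        ref = circle.sequence.residues
        arc = gaurei_bundle.truth.arc
        base = "".join(ref[p] for p in arc.positions(len(circle)))
        rng = np.random.default_rng(9)
        junk = "".join(rng.choice(list("ACGT"), 400))
        with pytest.warns(UserWarning, match="unmappable"):
            m = map_clones(circle, [NucSequence("ok", base), NucSequence("junk", junk)])
        assert m.clone_ids == ["ok"]
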