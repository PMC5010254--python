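"""Inverted-repeat detector vs a naive exhaustive implementation."""

import numpy as np
import pytest

from minihet.inverted_repeats import (
    DEFAULT_IR_PARAMS,
    IRScoringParams,
    find_inverted_repeats,
)
from minihet.seq_core import Interval, NucSequence, reverse_complement

_PAIR = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


def naive_best(s: str, p: IRScoringParams):
    """Straightforward nested-loop local DP over the valid triangle.

    Independent re-derivation of the recurrence with explicit Python
    loops; returns the maximal score and the first cell achieving it in
    (i, j) scan order.
    """
    n = len(s)
    H = [[0] * n for _ in range(n)]
    best, best_cell = 0, None
    for i in range(n):
        for j in range(n - 1 - i):
            sub = p.match if (s[i], s[n - 1 - j]) in _PAIR else p.mismatch
            diag = H[i - 1][j - 1] if i > 0 and j > 0 else 0
            up = H[i - 1][j] if i > 0 else 0
            left = H[i][j - 1] if j > 0 else 0
            val = max(0, diag + sub, up - p.gap_penalty, left - p.gap_penalty)
            H[i][j] = val
            if val > best:
                best, best_cell = val, (i, j)
    return best, best_cell


class TestToyExamples:
    def test_perfect_six_bp_arms(self):
        hits = find_inverted_repeats("GGGGCC" + "TTT" + "GGCCCC")
        assert len(hits) == 1
        h = hits[0]
        assert h.score == 18
        assert (h.arm1, h.arm2) == (Interval(0, 6), Interval(9, 15))
        assert (h.spacer_len, h.region_span) == (3, 15)

    def test_poly_a_has_no_self_complementarity(self):
        assert find_inverted_repeats("A" * 20) == []

    def test_too_short_sequence_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            assert find_inverted_repeats("ACGT") == []


class TestOracle:
    @pytest.mark.parametrize("seed", range(50))
    def test_matches_naive_dp_on_seeded_random_sequences(self, seed):
        rng = np.random.default_rng(1000 + seed)
        n = int(rng.integers(60, 81))
        s = "".join(rng.choice(list("ACGT"), n))
        naive_score, _cell = naive_best(s, DEFAULT_IR_PARAMS)
        hits = find_inverted_repeats(s, IRScoringParams(min_score=max(1, naive_score)))
        if naive_score == 0:
            assert hits == []
        else:
            assert hits, f"no hit found though naive best is {naive_score}"
            assert hits[0].score == naive_score

    @pytest.mark.parametrize("arm_len", range(3, 9))
    def test_planted_palindromic_arms_detected_iff_length_at_least_5(self, arm_len):
        rng = np.random.default_rng(arm_len)
        arm = "".join(rng.choice(list("GC"), arm_len))
        s = "A" * 15 + arm + "A" * 6 + reverse_complement(arm) + "A" * 15
        hits = find_inverted_repeats(s)
        if 3 * arm_len >= DEFAULT_IR_PARAMS.min_score:
            assert len(hits) == 1
            h = hits[0]
            assert h.score == 3 * arm_len
            assert h.arm1 == Interval(15, 15 + arm_len)
            assert h.arm2 == Interval(21 + arm_len, 21 + 2 * arm_len)
        else:
            assert hits == []


class TestInvariances:
    @pytest.mark.parametrize("seed", range(5))
    def test_output_mirrors_under_reverse_complement(self, seed):
        rng = np.random.default_rng(50 + seed)
        arm = "".join(rng.choice(list("GC"), 7))
        s = "A" * 10 + arm + "AAAA" + reverse_complement(arm) + "A" * 10
        n = len(s)
        fwd = find_inverted_repeats(s)
        rev = find_inverted_repeats(reverse_complement(s))
        assert [h.score for h in fwd] == [h.score for h in rev]
        for hf, hr in zip(fwd, rev):
            assert hr.arm1 == Interval(n - hf.arm2.end, n - hf.arm2.start)
            assert hr.arm2 == Interval(n - hf.arm1.end, n - hf.arm1.start)

    def test_no_hit_arms_overlap_and_all_meet_threshold(self, gaurei_bundle):
        hits = find_inverted_repeats(gaurei_bundle.circle.sequence)
        L = len(gaurei_bundle.circle)
        seen = set()
        for h in hits:
            assert h.score >= DEFAULT_IR_PARAMS.min_score
            arms = set(h.arm1.positions(L)) | set(h.arm2.positions(L))
            assert not (arms & seen)
            seen |= arms


class TestCircular:
    def test_planted_repeats_recovered_exactly_on_both_presets(
        self, gaurei_bundle, tminor_bundle
    ):
        for bundle, span in ((gaurei_bundle, 91), (tminor_bundle, 38)):
            hits = find_inverted_repeats(bundle.circle.sequence)
            top = hits[0]
            assert top.arm1 == bundle.truth.ir_arm1
            assert top.arm2 == bundle.truth.ir_arm2
            assert top.region_span == span
            assert top.score == 3 * top.arm1.span(len(bundle.circle))

    def test_origin_spanning_repeat_found_with_wrapped_coordinates(self):
        rng = np.random.default_rng(77)
        arm = "".join(rng.choice(list("GC"), 8))
        # arm1 ends 4 bp before the origin; arm2 wraps across it
        lead = "A" * 30
        s_linear = lead + arm + "AAAA" + reverse_complement(arm) + "A" * 30
        # rotate so the second arm straddles position 0
        rot = len(lead) + 8 + 4 + 4  # origin inside arm2
        s = s_linear[rot:] + s_linear[:rot]
        circ = NucSequence("c", s, "circular")
        hits = find_inverted_repeats(circ)
        assert hits
        top = hits[0]
        assert top.score == 24
        assert top.arm2.wraps
        assert top.arm1.span(len(s)) == 8 and top.arm2.span(len(s)) == 8
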