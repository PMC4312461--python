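"""Truth-vs-call matching rules and summary metrics."""

import itertools
import math

import numpy as np
import pytest

from paleovar.align_call import CalledVariant
from paleovar.evaluate import (
    CallEvent,
    TruthEvent,
    _max_window_matching,
    match_indels,
    match_snps,
    prepare_calls,
    prepare_truth,
)

REF_LEN = 100_000
MARGIN = 500


def tev(pos, copies=1, kind="deletion", alt="A"):
    return TruthEvent(pos, kind, alt, copies)


def cev(pos, copies=1, kind="deletion", alt="A"):
    return CallEvent(pos, kind, alt, copies)


class TestIndelMatching:
    def test_within_window_matches(self):
        res = match_indels([cev(1002)], [tev(1000)], REF_LEN)
        assert (res.correct, res.incorrect, res.missed) == (1, 0, 0)

    def test_beyond_window_no_match(self):
        res = match_indels([cev(1004)], [tev(1000)], REF_LEN)
        assert (res.correct, res.incorrect, res.missed) == (0, 1, 1)

    def test_two_flanking_calls_one_match(self):
        res = match_indels([cev(998), cev(1002)], [tev(1000)], REF_LEN)
        assert res.correct == 1 and res.incorrect == 1

    def test_event_level_scoring_ignores_genotype(self):
        # indel matching is position-only: a het call on a hom truth is one
        # correct event, not a half-credited allele pair
        res = match_indels([cev(1000, copies=1)], [tev(1000, copies=2)], REF_LEN)
        assert (res.correct, res.incorrect, res.missed) == (1, 0, 0)

    def test_edge_margin_excludes_both_sides(self):
        res = match_indels([cev(100)], [tev(REF_LEN - 100)], REF_LEN)
        assert (res.correct, res.incorrect, res.missed) == (0, 0, 0)

    def test_matcher_agrees_with_bruteforce_assignment(self):
        """Match counts equal the exhaustive optimal one-to-one assignment."""

        def brute_force(called, truth, window=3):
            best = 0
            k = min(len(called), len(truth))
            for size in range(k, -1, -1):
                for c_sub in itertools.combinations(range(len(called)), size):
                    for t_perm in itertools.permutations(range(len(truth)), size):
                        if all(
                            abs(called[i] - truth[j]) <= window
                            for i, j in zip(c_sub, t_perm)
                        ):
                            return size
            return best

        rng = np.random.default_rng(99)
        for _ in range(2000):
            n_c, n_t = int(rng.integers(0, 6)), int(rng.integers(0, 6))
            called = sorted(int(p) for p in rng.integers(0, 40, size=n_c))
            truth = sorted(int(p) for p in rng.integers(0, 40, size=n_t))
            pairs = _max_window_matching(called, truth, 3)
            assert len(pairs) == brute_force(called, truth)
            for i, j in pairs:
                assert abs(called[i] - truth[j]) <= 3


class TestSnpMatching:
    def test_exact_match(self):
        res = match_snps([cev(5000, kind="snp", alt="T")],
                         [tev(5000, kind="snp", alt="T")], REF_LEN)
        assert (res.correct, res.incorrect, res.missed) == (1, 0, 0)

    def test_wrong_allele_counts_both_ways(self):
        res = match_snps([cev(5000, kind="snp", alt="G")],
                         [tev(5000, kind="snp", alt="T")], REF_LEN)
        assert (res.correct, res.incorrect, res.missed) == (0, 1, 1)

    def test_indel_proximity_exclusion(self):
        res = match_snps(
            [cev(5000, kind="snp", alt="T")],
            [tev(5000, kind="snp", alt="T")],
            REF_LEN,
            indel_positions=[5004],
        )
        assert (res.correct, res.incorrect, res.missed) == (0, 0, 0)
        res = match_snps(
            [cev(5000, kind="snp", alt="T")],
            [tev(5000, kind="snp", alt="T")],
            REF_LEN,
            indel_positions=[5006],
        )
        assert res.correct == 1

    def test_het_truth_called_hom(self):
        # the matching copy is correct; the spurious second allele-call is not
        res = match_snps([cev(5000, kind="snp", alt="T", copies=2)],
                         [tev(5000, kind="snp", alt="T", copies=1)], REF_LEN)
        assert (res.correct, res.incorrect, res.missed) == (1, 1, 0)

    def test_translation_invariance(self):
        called = [cev(5000 + i * 37, kind="snp", alt="T") for i in range(50)]
        truth = [tev(5000 + i * 37, kind="snp", alt="T" if i % 3 else "G")
                 for i in range(60)]
        res1 = match_snps(called, truth, REF_LEN)
        shift = 1000
        called2 = [cev(c.pos + shift, kind="snp", alt=c.alt) for c in called]
        truth2 = [tev(t.pos + shift, kind="snp", alt=t.alt) for t in truth]
        res2 = match_snps(called2, truth2, REF_LEN)
        assert (res1.correct, res1.incorrect, res1.missed) == (
            res2.correct, res2.incorrect, res2.missed)


class TestMetrics:
    def test_accuracy_arithmetic(self):
        calls = [cev(1000 + 50 * i, kind="snp", alt="T") for i in range(10)]
        truth = [tev(1000 + 50 * i, kind="snp", alt="T") for i in range(9)]
        res = match_snps(calls, truth, REF_LEN)
        assert res.accuracy == pytest.approx(90.0)

    def test_homhet_ratio_of_ratios(self):
        # truth 100 hom + 50 het; 40 homs and 10 hets called correctly
        truth, calls = [], []
        for i in range(100):
            truth.append(tev(1000 + 20 * i, copies=2, kind="snp", alt="T"))
            if i < 40:
                calls.append(cev(1000 + 20 * i, copies=2, kind="snp", alt="T"))
        for i in range(50):
            truth.append(tev(4000 + 20 * i, copies=1, kind="snp", alt="T"))
            if i < 10:
                calls.append(cev(4000 + 20 * i, copies=1, kind="snp", alt="T"))
        res = match_snps(calls, truth, REF_LEN)
        assert res.homhet_ratio_of_ratios == pytest.approx(2.0)

    def test_perfect_calling_identity(self):
        truth = [tev(1000 + 20 * i, copies=1 + i % 2, kind="snp", alt="T")
                 for i in range(60)]
        calls = [cev(t.pos, copies=t.copies, kind="snp", alt="T") for t in truth]
        res = match_snps(calls, truth, REF_LEN)
        assert res.completeness == pytest.approx(100.0)
        assert res.homhet_ratio_of_ratios == pytest.approx(1.0)

    def test_zero_calls_gives_nan_accuracy(self):
        res = match_snps([], [tev(5000, kind="snp", alt="T")], REF_LEN)
        assert math.isnan(res.accuracy)
        assert res.completeness == 0.0

    def test_completeness_bounded_by_called(self):
        calls = [cev(1000 + 50 * i, kind="snp", alt="T") for i in range(5)]
        truth = [tev(1000 + 50 * i, kind="snp", alt="T") for i in range(20)]
        res = match_snps(calls, truth, REF_LEN)
        assert res.completeness <= res.accuracy
        assert res.completeness <= 100 and res.accuracy <= 100


class TestPrepare:
    def test_prepare_truth_left_aligns_and_merges(self, low_pair):
        snps, indels = prepare_truth(low_pair)
        assert all(e.copies in (1, 2) for e in snps + indels)
        # left-alignment is idempotent against the reference
        from paleovar.seq import left_align_indel

        for e in indels[:50]:
            pos, seq = left_align_indel(low_pair.reference, e.pos, e.alt, e.kind)
            assert (pos, seq) == (e.pos, e.alt)

    def test_prepare_calls_copies(self):
        calls = [
            CalledVariant(10, "snp", "A", "T", "hom", 50.0, 9),
            CalledVariant(20, "deletion", "AC", "", "het", 50.0, 9),
        ]
        snps, indels = prepare_calls(calls)
        assert snps[0].copies == 2 and indels[0].copies == 1
        assert indels[0].alt == "AC"
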