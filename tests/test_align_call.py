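"""Mapper and caller: index, unique-best mapping, pileup genotyping, filters."""

import math

import edlib
import numpy as np
import pytest

from paleovar.align_call import (
    CalledVariant,
    MappedRead,
    _fill_alignment_caches,
    _weighted_score,
    build_index,
    filter_calls,
    map_read,
    map_pool,
    pileup_and_call,
    write_sam,
)
from paleovar.read_sim import ErrorModel, ReadRecord, generate_raw_reads
from paleovar.seq import revcomp


def _read(seq: str) -> ReadRecord:
    qual = np.full(len(seq), 35, dtype=np.uint8)
    return ReadRecord("q", 1, 0, len(seq), "+", seq, qual)


def _planted_read(m: MappedRead | None):
    return None if m is None else (m.ref_start, m.strand)


@pytest.fixture(scope="module")
def reference():
    return "".join(np.random.default_rng(100).choice(list("ACGT"), size=10_000))


@pytest.fixture(scope="module")
def index(reference):
    return build_index(reference, 13)


class TestIndex:
    def test_kmer_positions(self):
        idx = build_index("ACGTACGT", 4)
        assert idx.lookup("ACGT") == [0, 4]
        assert idx.lookup("CGTA") == [1]

    def test_absent_kmer_empty(self):
        idx = build_index("ACGTACGT", 4)
        assert idx.lookup("TTTT") == []

    def test_every_kmer_retrievable(self, reference, index):
        for i in range(0, len(reference) - 13, 257):
            assert i in index.lookup(reference[i : i + 13])

    def test_small_k_rejected(self):
        with pytest.raises(ValueError):
            build_index("ACGTACGT", 3)


class TestMapRead:
    def test_exact_substring_maps_at_origin(self, reference, index):
        m = map_read(_read(reference[2000:2060]), index)
        assert m is not None
        assert (m.ref_start, m.strand) == (2000, "+")
        assert m.cigar == [("M", 60)]
        assert m.edit_distance == 0

    def test_reverse_strand(self, reference, index):
        m = map_read(_read(revcomp(reference[3000:3050])), index)
        assert m is not None
        assert (m.ref_start, m.strand) == (3000, "-")

    def test_duplicated_region_unmapped(self):
        core = "".join(np.random.default_rng(7).choice(list("ACGT"), size=400))
        pad = "".join(np.random.default_rng(8).choice(list("ACGT"), size=600))
        ref = core + pad + core
        idx = build_index(ref, 13)
        assert map_read(_read(core[50:100]), idx) is None

    def test_terminal_damage_within_budget(self, reference, index):
        # three C->T edits in the first nine bases of a 40 bp read are
        # within ceil(0.06*40)=3 edits
        start = next(
            s for s in range(1000, 9000)
            if reference[s : s + 9].count("C") >= 3 and len(set(reference[s:s+40])) == 4
        )
        seq = list(reference[start : start + 40])
        edited = 0
        for i in range(9):
            if seq[i] == "C" and edited < 3:
                seq[i] = "T"
                edited += 1
        m = map_read(_read("".join(seq)), index, max_mismatch_frac=0.06)
        assert m is not None and m.ref_start == start
        assert m.edit_distance == edited

    def test_over_budget_unmapped(self, reference, index):
        seq = list(reference[4000:4040])
        for i in (5, 12, 19, 26):
            seq[i] = "A" if seq[i] != "A" else "C"
        assert map_read(_read("".join(seq)), index, max_mismatch_frac=0.06) is None

    def test_mapped_fraction_monotone_in_edit_count(self, reference, index):
        rng = np.random.default_rng(55)
        fractions = []
        for n_edits in range(0, 5):
            mapped = 0
            for _ in range(150):
                s = int(rng.integers(0, len(reference) - 40))
                seq = list(reference[s : s + 40])
                for pos in rng.choice(40, size=n_edits, replace=False):
                    choices = [b for b in "ACGT" if b != seq[pos]]
                    seq[pos] = choices[int(rng.integers(3))]
                mapped += map_read(_read("".join(seq)), index) is not None
            fractions.append(mapped / 150)
        assert all(a >= b for a, b in zip(fractions, fractions[1:]))

    def test_agrees_with_exhaustive_alignment_oracle(self, reference, index):
        """Seeded mapper vs all-positions alignment on mapped status/locus."""
        rng = np.random.default_rng(77)
        budget = lambda n: math.ceil(0.05 * n)
        agree = total = 0
        for _ in range(10_000):
            n = int(rng.choice([40, 60, 80]))
            s = int(rng.integers(0, len(reference) - n))
            seq = list(reference[s : s + n])
            for pos in rng.choice(n, size=int(rng.integers(0, 4)), replace=False):
                choices = [b for b in "ACGT" if b != seq[pos]]
                seq[pos] = choices[int(rng.integers(3))]
            read = "".join(seq)
            if rng.random() < 0.5:
                read = revcomp(read)
            got = _planted_read(map_read(_read(read), index))

            # oracle: full-scan infix alignment on both strands
            best = None
            for strand, oriented in (("+", read), ("-", revcomp(read))):
                res = edlib.align(oriented, reference, mode="HW", task="locations")
                locs = {a for a, _ in res["locations"]}
                if best is None or res["editDistance"] < best[0]:
                    best = (res["editDistance"], strand, locs)
                elif res["editDistance"] == best[0]:
                    best = (best[0], None, best[2] | locs)
            dist, strand, locs = best
            if dist > budget(n) or strand is None or len(locs) > 1:
                expected = None
            else:
                expected = (min(locs), strand)
            if expected is None or got is None:
                agree += expected == got
            else:
                agree += got[1] == expected[1] and abs(got[0] - expected[0]) <= 1
            total += 1
        assert agree / total >= 0.999


def _pileup_column(ref, pos, bases, qual=35):
    """Build one-column MappedReads carrying the given bases at ``pos``."""
    out = []
    for b in bases:
        seq = ref[pos - 10 : pos] + b + ref[pos + 1 : pos + 11]
        read = ReadRecord(
            "p", 1, 0, len(seq), "+", seq, np.full(len(seq), qual, dtype=np.uint8)
        )
        m = MappedRead(read, pos - 10, "+", [("M", len(seq))], int(b != ref[pos]), 60, seq)
        _fill_alignment_caches(m, ref)
        out.append(m)
    return out


class TestPileupAndCall:
    ref = "".join(np.random.default_rng(3).choice(list("ACGT"), size=400))

    def test_hom_alt_column(self):
        pos = 200
        alt = "T" if self.ref[pos] != "T" else "A"
        calls = pileup_and_call(_pileup_column(self.ref, pos, alt * 10), self.ref)
        (c,) = [c for c in calls if c.ref_pos == pos]
        assert c.kind == "snp" and c.genotype == "hom" and c.alt_allele == alt
        assert c.call_quality > 20 and c.depth == 10

    def test_het_column(self):
        pos = 200
        ref_b = self.ref[pos]
        alt = "T" if ref_b != "T" else "A"
        calls = pileup_and_call(
            _pileup_column(self.ref, pos, ref_b * 5 + alt * 5), self.ref
        )
        (c,) = [c for c in calls if c.ref_pos == pos]
        assert c.genotype == "het" and c.alt_allele == alt

    def test_all_reference_no_record(self):
        pos = 200
        calls = pileup_and_call(
            _pileup_column(self.ref, pos, self.ref[pos] * 12), self.ref
        )
        assert calls == []

    def test_single_error_not_called_after_filter(self):
        pos = 200
        ref_b = self.ref[pos]
        alt = "T" if ref_b != "T" else "A"
        calls = pileup_and_call(
            _pileup_column(self.ref, pos, ref_b * 15 + alt), self.ref
        )
        calls = filter_calls(calls)
        assert [c for c in calls if c.ref_pos == pos] == []

    def test_het_snp_recovered_end_to_end(self, low_pair):
        """A 16x error-free pool recovers a known het SNP as het."""
        from paleovar.evaluate import prepare_truth

        snps, _ = prepare_truth(low_pair)
        target = next(
            t for t in snps
            if t.copies == 1 and 2000 < t.pos < 60_000
        )
        lo, hi = target.pos - 800, target.pos + 800
        sub_ref = low_pair.reference[lo:hi]
        idx = build_index(sub_ref, 13)
        reads = generate_raw_reads(
            [low_pair.chromosome1[lo:hi], low_pair.chromosome2[lo:hi]],
            raw_coverage=8, error_model=ErrorModel(rate=0.0),
            rng=np.random.default_rng(66),
        )
        mapped = map_pool(reads, idx)
        calls = filter_calls(pileup_and_call(mapped, sub_ref))
        hits = [
            c for c in calls
            if c.kind == "snp" and c.ref_pos == target.pos - lo
            and c.alt_allele == target.alt
        ]
        assert hits and hits[0].genotype == "het"


class TestFilterCalls:
    def _call(self, depth=10, qual=30.0):
        return CalledVariant(100, "snp", "A", "T", "het", qual, depth)

    def test_depth_window(self):
        assert filter_calls([self._call(depth=31)]) == []
        assert filter_calls([self._call(depth=30)]) != []
        assert filter_calls([self._call(depth=1)]) != []

    def test_quality_threshold(self):
        assert filter_calls([self._call(qual=19.9)]) == []
        assert filter_calls([self._call(qual=20.0)]) != []

    def test_empty_input(self):
        assert filter_calls([]) == []

    def test_inverted_window_rejected(self):
        with pytest.raises(ValueError):
            filter_calls([], min_depth=5, max_depth=4)


class TestWeightedScore:
    def test_gap_surcharge(self):
        assert _weighted_score("40=") == 0
        assert _weighted_score("20=2X18=") == 2
        assert _weighted_score("20=1D20=") == 2
        assert _weighted_score("20=3I17=") == 4


class TestSamOutput:
    def test_sam_parses_with_pysam(self, reference, index, tmp_path):
        pysam = pytest.importorskip("pysam")
        rng = np.random.default_rng(13)
        reads = []
        for i in range(50):
            s = int(rng.integers(0, len(reference) - 60))
            reads.append(_read(reference[s : s + 60]))
        mapped = map_pool(reads, index)
        path = tmp_path / "out.sam"
        write_sam(mapped, len(reference), path)
        with pysam.AlignmentFile(str(path)) as sam:
            rows = list(sam)
        assert len(rows) == len(mapped)
        assert all(not r.is_unmapped for r in rows)
        assert all(r.query_length == 60 for r in rows)
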