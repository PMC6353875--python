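"""Strand-aware 150-bp proximity overlap and its quadratic oracle."""

import numpy as np
import pytest

from cspfit.errors import InputError
from cspfit.overlap import (
    GenomicPeak,
    gap_between,
    overlap_peaks,
    read_bed,
    write_bed,
)
from cspfit.simulate import simulate_peaksets


def brute_force(a, b, max_gap, same_strand=True, strict=False):
    """O(n^2) reference: count every qualifying pair directly."""
    def ok(pa, pb):
        if pa.chrom != pb.chrom:
            return False
        if same_strand:
            if strict:
                if pa.strand != pb.strand:
                    return False
            elif "." not in (pa.strand, pb.strand) and pa.strand != pb.strand:
                return False
        return max(0, max(pa.start, pb.start) - min(pa.end, pb.end)) <= max_gap

    pairs = [(i, j) for i, pa in enumerate(a) for j, pb in enumerate(b) if ok(pa, pb)]
    return (
        len({i for i, _ in pairs}),
        len({j for _, j in pairs}),
        len(pairs),
    )


def random_peaks(rng, n, chroms=("chr1", "chr2"), span=5000):
    out = []
    for _ in range(n):
        s = int(rng.integers(0, span))
        w = int(rng.integers(1, 400))
        out.append(
            GenomicPeak(str(rng.choice(chroms)), s, s + w, str(rng.choice(["+", "-", "."])))
        )
    return tuple(out)


class TestReadBed:
    def test_bed6_parses_strand(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t200\t.\t0\t+\n")
        assert read_bed(p) == (GenomicPeak("chr1", 100, 200, "+"),)

    def test_bed3_defaults_to_unstranded(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t200\n")
        assert read_bed(p)[0].strand == "."

    def test_inverted_coordinates_error_with_line_number(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t200\nchr1\t200\t100\n")
        with pytest.raises(InputError, match=":2"):
            read_bed(p)

    def test_non_integer_coordinates_rejected(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\tx\t200\n")
        with pytest.raises(InputError, match="non-integer"):
            read_bed(p)

    def test_write_read_round_trip(self, tmp_path):
        peaks = (GenomicPeak("chr1", 0, 10, "+"), GenomicPeak("chr2", 5, 9, "."))
        write_bed(peaks, tmp_path / "rt.bed")
        assert read_bed(tmp_path / "rt.bed") == peaks


class TestGapRule:
    A = GenomicPeak("chr1", 100, 200, "+")

    def test_gap_of_100_qualifies_at_150(self):
        b = GenomicPeak("chr1", 300, 400, "+")
        assert gap_between(self.A, b) == 100
        assert overlap_peaks([self.A], [b]).pairs == 1

    def test_gap_of_151_does_not_qualify(self):
        b = GenomicPeak("chr1", 351, 400, "+")
        assert gap_between(self.A, b) == 151
        assert overlap_peaks([self.A], [b]).pairs == 0

    def test_gap_of_exactly_150_qualifies(self):
        b = GenomicPeak("chr1", 350, 400, "+")
        assert gap_between(self.A, b) == 150
        assert overlap_peaks([self.A], [b]).pairs == 1

    def test_touching_intervals_have_gap_zero(self):
        b = GenomicPeak("chr1", 200, 300, "+")
        assert gap_between(self.A, b) == 0
        assert overlap_peaks([self.A], [b], max_gap=0).pairs == 1

    def test_max_gap_zero_requires_contact(self):
        b = GenomicPeak("chr1", 201, 300, "+")
        assert overlap_peaks([self.A], [b], max_gap=0).pairs == 0

    def test_opposite_strands_do_not_qualify(self):
        b = GenomicPeak("chr1", 150, 250, "-")
        assert overlap_peaks([self.A], [b]).pairs == 0
        assert overlap_peaks([self.A], [b], same_strand=False).pairs == 1

    def test_unstranded_matches_anything_unless_strict(self):
        b = GenomicPeak("chr1", 150, 250, ".")
        assert overlap_peaks([self.A], [b]).pairs == 1
        assert overlap_peaks([self.A], [b], strict=True).pairs == 0

    def test_different_chromosomes_never_qualify(self):
        b = GenomicPeak("chr2", 100, 200, "+")
        assert gap_between(self.A, b) is None
        assert overlap_peaks([self.A], [b]).pairs == 0


def test_identical_sets_fully_self_overlap(rng):
    peaks = random_peaks(rng, 50)
    s = overlap_peaks(peaks, peaks)
    assert s.a_with_b == s.n_a and s.b_with_a == s.n_b


def test_sweep_matches_quadratic_oracle_on_random_sets(rng):
    for trial in range(60):
        a = random_peaks(rng, int(rng.integers(1, 120)))
        b = random_peaks(rng, int(rng.integers(1, 120)))
        max_gap = int(rng.choice([0, 1, 150, 151, 1000]))
        strict = bool(rng.integers(0, 2))
        s = overlap_peaks(a, b, max_gap=max_gap, strict=strict)
        assert (s.a_with_b, s.b_with_a, s.pairs) == brute_force(
            a, b, max_gap, strict=strict
        )


def test_pair_count_is_symmetric(rng):
    a = random_peaks(rng, 80)
    b = random_peaks(rng, 90)
    assert overlap_peaks(a, b).pairs == overlap_peaks(b, a).pairs


def test_summary_invariants(rng):
    a = random_peaks(rng, 60)
    b = random_peaks(rng, 60)
    s = overlap_peaks(a, b)
    assert s.a_with_b <= s.n_a and s.b_with_a <= s.n_b
    if s.pairs:
        assert s.pairs >= max(s.a_with_b, s.b_with_a)


class TestSimulatedPeaksets:
    def test_planted_pairs_all_qualify_under_the_gap_rule(self):
        a, b, truth = simulate_peaksets(40, 40, shared_fraction=1.0,
                                        jitter_bp=150, seed=3)
        s = overlap_peaks(a, b, max_gap=150)
        assert s.b_with_a == 40
        assert truth.planted.all()

    def test_zero_jitter_full_sharing_hits_every_planted_peak(self):
        a, b, truth = simulate_peaksets(30, 30, shared_fraction=1.0,
                                        jitter_bp=0, seed=4)
        s = overlap_peaks(a, b, max_gap=0)
        assert s.b_with_a == 30

    def test_sparse_background_produces_no_pairs(self):
        a, b, truth = simulate_peaksets(20, 20, shared_fraction=0.0,
                                        genome_size=50_000_000, seed=5)
        s = overlap_peaks(a, b, max_gap=150, same_strand=False)
        assert s.pairs == 0
        assert not truth.planted.any()
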