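"""Interval algebra and genomic text-format I/O."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from photoclose.intervals import (
    Fragment,
    GenomicInterval,
    filter_nfr,
    merge_peak_sets,
    nearest_tss,
    read_bed,
    read_fragments,
    read_narrowpeak,
    recenter_on_summit,
    write_bed,
    write_fragments,
    write_narrowpeak,
)


class TestTypes:
    def test_rejects_inverted_interval(self):
        with pytest.raises(ValueError, match="start < end"):
            GenomicInterval("chr1", 300, 100)

    def test_rejects_summit_outside(self):
        with pytest.raises(ValueError, match="summit"):
            GenomicInterval("chr1", 100, 300, summit=400)

    def test_rejects_nonpositive_insert(self):
        with pytest.raises(ValueError, match="insert_size"):
            Fragment("chr1", 100, 100)

    def test_anchor_falls_back_to_midpoint(self):
        iv = GenomicInterval("chr1", 100, 300)
        assert iv.anchor == 200
        assert GenomicInterval("chr1", 100, 300, summit=150).anchor == 150


class TestNarrowPeakIO:
    def test_summit_offset_maps_to_absolute(self, tmp_path):
        p = tmp_path / "a.narrowPeak"
        p.write_text("chr1\t100\t300\tpk1\t0\t.\t0\t-1\t-1\t50\n")
        (iv,) = read_narrowpeak(p)
        assert iv.summit == 150

    def test_offset_minus_one_is_no_summit(self, tmp_path):
        p = tmp_path / "a.narrowPeak"
        p.write_text("chr1\t100\t300\tpk1\t0\t.\t0\t-1\t-1\t-1\n")
        (iv,) = read_narrowpeak(p)
        assert iv.summit is None

    def test_end_before_start_raises_with_line(self, tmp_path):
        p = tmp_path / "a.narrowPeak"
        p.write_text("chr1\t300\t100\tpk1\t0\t.\t0\t-1\t-1\t-1\n")
        with pytest.raises(ValueError, match=":1:"):
            read_narrowpeak(p)

    def test_round_trip_is_identity(self, tmp_path):
        lines = (
            "chr1\t100\t300\tpk1\t5\t+\t0\t-1\t-1\t50\n"
            "chr2\t0\t200\tpk2\t0\t.\t0\t-1\t-1\t-1\n"
        )
        src = tmp_path / "in.narrowPeak"
        src.write_text(lines)
        dst = tmp_path / "out.narrowPeak"
        write_narrowpeak(dst, read_narrowpeak(src))
        assert dst.read_text() == lines

    def test_bed_round_trip(self, tmp_path):
        lines = "chr1\t10\t20\tx\t0\t+\nchr1\t30\t45\ty\t2\t-\n"
        src = tmp_path / "in.bed"
        src.write_text(lines)
        dst = tmp_path / "out.bed"
        write_bed(dst, read_bed(src))
        assert dst.read_text() == lines

    def test_fragment_round_trip(self, tmp_path):
        frags = [Fragment("chr1", 5, 80), Fragment("chr2", 0, 200)]
        p = tmp_path / "f.tsv"
        write_fragments(p, frags)
        assert read_fragments(p) == frags


class TestRecenter:
    def test_standard_window(self):
        pk = GenomicInterval("chr1", 900, 1200, name="p", summit=1000)
        (out,) = recenter_on_summit([pk], 200)
        assert (out.start, out.end) == (900, 1100)

    def test_boundary_shifts_not_truncates(self):
        pk = GenomicInterval("chr1", 0, 100, name="p", summit=50)
        (out,) = recenter_on_summit([pk], 200)
        assert (out.start, out.end) == (0, 200)
        assert len(out) == 200

    def test_right_boundary_shift_with_sizes(self):
        pk = GenomicInterval("chr1", 900, 1000, name="p", summit=990)
        (out,) = recenter_on_summit([pk], 200, chrom_sizes={"chr1": 1000})
        assert (out.start, out.end) == (800, 1000)

    def test_zero_width_rejected(self):
        pk = GenomicInterval("chr1", 900, 1200, name="p", summit=1000)
        with pytest.raises(ValueError):
            recenter_on_summit([pk], 0)

    def test_missing_summit_names_offenders(self):
        pk = GenomicInterval("chr1", 900, 1200, name="naked")
        with pytest.raises(ValueError, match="naked"):
            recenter_on_summit([pk], 200)


class TestMerge:
    def test_overlap_coalesces_and_counts_sources(self):
        a = [GenomicInterval("chr1", 100, 300)]
        b = [GenomicInterval("chr1", 250, 400)]
        ((iv, sources),) = merge_peak_sets([a, b], ["a", "b"])
        assert (iv.start, iv.end) == (100, 400)
        assert sources == {"a", "b"}

    def test_disjoint_stay_separate(self):
        a = [GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 200, 300)]
        merged = merge_peak_sets([a])
        assert [(iv.start, iv.end) for iv, _ in merged] == [(0, 100), (200, 300)]

    def test_idempotent_and_commutative(self, rng):
        def random_set(r):
            starts = r.integers(0, 5000, 30)
            return [
                GenomicInterval("chr1", int(s), int(s) + int(r.integers(50, 300)))
                for s in starts
            ]

        a, b = random_set(rng), random_set(rng)
        ab = [(iv.chrom, iv.start, iv.end) for iv, _ in merge_peak_sets([a, b])]
        ba = [(iv.chrom, iv.start, iv.end) for iv, _ in merge_peak_sets([b, a])]
        aa = [(iv.chrom, iv.start, iv.end) for iv, _ in merge_peak_sets([a, a])]
        aonly = [(iv.chrom, iv.start, iv.end) for iv, _ in merge_peak_sets([a])]
        assert ab == ba
        assert aa == aonly
        covered = sum(e - s for _, s, e in ab)
        assert covered <= sum(len(iv) for iv in a + b)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            merge_peak_sets([[]])


class TestNfrFilter:
    def test_threshold_is_inclusive(self):
        frags = [Fragment("chr1", 0, n) for n in (50, 100, 101)]
        kept = filter_nfr(frags, 100)
        assert [f.insert_size for f in kept] == [50, 100]

    def test_empty_and_infinite(self):
        assert filter_nfr([], 100) == []
        frags = [Fragment("chr1", 0, n) for n in (50, 500)]
        assert filter_nfr(frags, math.inf) == frags


class TestNearestTss:
    def test_forced_geometry_downstream(self):
        pk = GenomicInterval("chr1", 4900, 5100, name="p", summit=5000)
        tss = [
            GenomicInterval("chr1", 4000, 4001, "+", "geneA"),
            GenomicInterval("chr1", 7000, 7001, "+", "geneB"),
        ]
        assert nearest_tss([pk], tss)["p"] == ("geneA", 1000.0)

    def test_distance_zero_at_tss(self):
        pk = GenomicInterval("chr1", 4900, 5100, name="p", summit=5000)
        tss = [GenomicInterval("chr1", 5000, 5001, "+", "geneA")]
        assert nearest_tss([pk], tss)["p"] == ("geneA", 0.0)

    def test_minus_strand_sign_flips(self):
        pk = GenomicInterval("chr1", 4900, 5100, name="p", summit=5000)
        tss = [GenomicInterval("chr1", 6000, 6001, "-", "geneA")]
        # peak is downstream of a minus-strand TSS at 6000
        assert nearest_tss([pk], tss)["p"] == ("geneA", 1000.0)

    def test_chromosome_without_tss(self):
        pk = GenomicInterval("chr9", 100, 300, name="p", summit=200)
        tss = [GenomicInterval("chr1", 0, 1, "+", "g")]
        gene, dist = nearest_tss([pk], tss)["p"]
        assert gene is None and math.isinf(dist)

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(5):
            peaks = [
                GenomicInterval(
                    f"chr{int(rng.integers(1, 3))}", int(s), int(s) + 200,
                    name=f"p{i}", summit=int(s) + 100,
                )
                for i, s in enumerate(rng.integers(0, 100_000, 100))
            ]
            tss = [
                GenomicInterval(
                    f"chr{int(rng.integers(1, 3))}", int(s), int(s) + 1,
                    "+" if rng.random() < 0.5 else "-", f"g{i}",
                )
                for i, s in enumerate(rng.integers(0, 100_000, 20))
            ]
            got = nearest_tss(peaks, tss)
            for p in peaks:
                cands = [t for t in tss if t.chrom == p.chrom]
                if not cands:
                    assert got[p.name][0] is None
                    continue
                best = min(cands, key=lambda t: (abs(p.anchor - t.start), t.name))
                raw = p.anchor - best.start
                expect = float(raw if best.strand == "+" else -raw)
                assert got[p.name] == (best.name, expect)


@settings(deadline=None, max_examples=30)
@given(
    st.lists(
        st.tuples(st.integers(0, 10_000), st.integers(1, 400)), min_size=1, max_size=40
    )
)
def test_merge_output_is_sorted_and_disjoint(spans):
    peaks = [GenomicInterval("chr1", s, s + w) for s, w in spans]
    merged = merge_peak_sets([peaks])
    prev_end = -1
    for iv, _ in merged:
        assert iv.start > prev_end  # strictly disjoint after coalescing
        prev_end = iv.end
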