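"""Atlas construction, signal quantification, partitioning, specificity."""

import numpy as np
import pandas as pd
import pytest

from photoclose.atlas import (
    AtlasElement,
    annotate_repeat_fraction,
    classify_specificity,
    overlap_fraction,
    partition_promoter_enhancer,
    quantify_signal,
    repeat_filter,
)
from photoclose.intervals import Fragment, GenomicInterval


def element(start, end, summit=None, name="e", tss_distance=np.nan, repeat=0.0):
    return AtlasElement(
        interval=GenomicInterval("chr1", start, end, name=name, summit=summit),
        tss_distance=tss_distance,
        repeat_fraction=repeat,
    )


class TestQuantifySignal:
    def test_single_fragment_at_summit(self):
        el = element(900, 1100, summit=1000)
        frag = Fragment("chr1", 980, 1020)  # midpoint exactly 1000
        sm = quantify_signal([el], [frag], window=3000, bin_width=5)
        assert sm.matrix.sum() == 1
        # bin 300 is the first bin right of center
        assert sm.matrix[0, 300] == 1

    def test_no_fragments_zero_matrix(self):
        sm = quantify_signal([element(900, 1100, 1000)], [], 3000, 5)
        assert sm.matrix.sum() == 0

    def test_matches_naive_rescan(self, rng):
        els = [
            element(int(s), int(s) + 200, int(s) + 100, name=f"e{i}")
            for i, s in enumerate(rng.integers(2000, 50_000, 20))
        ]
        frags = [
            Fragment("chr1", int(s), int(s) + int(rng.integers(30, 120)))
            for s in rng.integers(0, 60_000, 2000)
        ]
        sm = quantify_signal(els, frags, window=1000, bin_width=10)
        for i, el in enumerate(els):
            lo = el.interval.summit - 500
            expect = np.zeros(100)
            for f in frags:
                mid = (f.start + f.end) // 2
                if lo <= mid < lo + 1000:
                    expect[(mid - lo) // 10] += 1
            assert np.array_equal(sm.matrix[i], expect)

    def test_window_bin_mismatch_rejected(self):
        with pytest.raises(ValueError):
            quantify_signal([element(0, 200, 100)], [], 1000, 7)

    def test_missing_summit_rejected(self):
        with pytest.raises(ValueError, match="summit"):
            quantify_signal([element(0, 200)], [], 1000, 5)


class TestPartition:
    @pytest.mark.parametrize(
        "dist,expected",
        [
            (-500.0, "promoter"),   # 500 bp upstream
            (2000.0, "enhancer"),   # far downstream
            (0.0, "promoter"),      # at the TSS
            (-1000.0, "enhancer"),  # boundary: strict inequality
            (100.0, "enhancer"),    # boundary: strict inequality
            (99.0, "promoter"),
            (-999.0, "promoter"),
        ],
    )
    def test_boundaries(self, dist, expected):
        (el,) = partition_promoter_enhancer([element(0, 200, tss_distance=dist)])
        assert el.region_class == expected

    def test_partition_exhaustive_exclusive(self, rng):
        els = [
            element(0, 200, tss_distance=float(d))
            for d in rng.integers(-5000, 5000, 200)
        ]
        partition_promoter_enhancer(els)
        assert all(e.region_class in ("promoter", "enhancer") for e in els)


class TestRepeatFilter:
    def test_above_threshold_dropped(self):
        els = [element(0, 200, name="drop", repeat=0.75),
               element(0, 200, name="keep", repeat=0.70)]
        kept = repeat_filter(els)
        assert [e.name for e in kept] == ["drop", "keep"][1:]

    def test_annotation_from_bed(self):
        el = element(100, 300, name="x")
        repeats = [GenomicInterval("chr1", 0, 250), GenomicInterval("chr1", 240, 260)]
        annotate_repeat_fraction([el], repeats)
        assert el.repeat_fraction == pytest.approx(160 / 200)

    def test_no_repeats_identity(self):
        els = [element(0, 200), element(300, 500)]
        assert repeat_filter(els) == els


class TestOverlapFraction:
    def test_identical_sets(self):
        a = [GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 200, 300)]
        assert overlap_fraction(a, a) == 1.0

    def test_asymmetric_subset(self):
        a = [GenomicInterval("chr1", i * 1000, i * 1000 + 100) for i in range(10)]
        extras = [
            GenomicInterval("chr2", i * 1000, i * 1000 + 100) for i in range(10)
        ]
        b = a + extras
        assert overlap_fraction(a, b) == 1.0
        assert overlap_fraction(b, a) == 0.5

    def test_empty_a_rejected(self):
        with pytest.raises(ValueError):
            overlap_fraction([], [GenomicInterval("chr1", 0, 10)])

    def test_matches_brute_force(self, rng):
        def random_set(n):
            return [
                GenomicInterval(
                    f"chr{int(rng.integers(1, 3))}", int(s),
                    int(s) + int(rng.integers(50, 400)),
                )
                for s in rng.integers(0, 20_000, n)
            ]

        a, b = random_set(50), random_set(30)
        got = overlap_fraction(a, b)
        expect = np.mean([any(x.overlaps(y) for y in b) for x in a])
        assert got == pytest.approx(expect)


class TestClassifySpecificity:
    @staticmethod
    def fake_diff(rows):
        return pd.DataFrame(
            rows, columns=["log2_fold_change", "q_value", "call"]
        ).rename_axis("name")

    def test_three_way_plus_non_pr(self):
        els = [element(0, 200, name="rod"), element(1000, 1200, name="liverish"),
               element(2000, 2200, name="shared")]
        for e in els:
            e.region_class = "enhancer"
        diff = pd.DataFrame(
            {
                "log2_fold_change": [2.0, 0.1, 0.0],
                "q_value": [0.01, 0.9, 0.8],
                "call": ["A_up", "ns", "ns"],
            },
            index=["rod", "liverish", "shared"],
        )
        non_pr = {"liver": [GenomicInterval("chr1", 1100, 1300)]}
        els, cascade = classify_specificity(els, diff, non_pr)
        by_name = {e.name: e.specificity for e in els}
        assert by_name == {
            "rod": "rod_specific", "liverish": "non_PR", "shared": "shared_PR"
        }

    def test_missing_element_rejected(self):
        els = [element(0, 200, name="x")]
        diff = pd.DataFrame(
            {"log2_fold_change": [], "q_value": [], "call": []}
        )
        with pytest.raises(ValueError, match="absent"):
            classify_specificity(els, diff, {})

    def test_cascade_counts_monotone(self, rng):
        els = []
        for i in range(50):
            e = element(i * 1000, i * 1000 + 200, name=f"e{i}",
                        repeat=float(rng.random()))
            e.region_class = "promoter" if rng.random() < 0.3 else "enhancer"
            els.append(e)
        diff = pd.DataFrame(
            {
                "log2_fold_change": rng.normal(0, 1, 50),
                "q_value": rng.random(50),
                "call": rng.choice(["A_up", "B_up", "ns"], 50),
            },
            index=[f"e{i}" for i in range(50)],
        )
        _, cascade = classify_specificity(els, diff, {})
        totals = [sum(v.values()) for v in cascade.stage_counts.values()]
        assert totals == sorted(totals, reverse=True)

    def test_recovers_planted_classes_on_synthetic_data(self, bundle):
        """Balanced accuracy >= 0.9 against planted truth at study defaults."""
        from photoclose.differential import CountMatrix, nb_diff_test
        from photoclose.intervals import merge_peak_sets, recenter_on_summit
        from photoclose.atlas import build_atlas
        from photoclose.simulate import counts_from_fragments

        calls = {
            g: recenter_on_summit(bundle.peak_calls[g], 200, bundle.chrom_sizes)
            for g in ("rod", "green_cone", "blue_cone")
        }
        merged = merge_peak_sets(list(calls.values()), list(calls))
        elements = build_atlas(merged, bundle.tss, bundle.repeats)
        partition_promoter_enhancer(elements)
        counts = counts_from_fragments([e.interval for e in elements], bundle.fragments)
        collapsed = {
            s: ("rod" if g == "rod" else "cone")
            for s, g in bundle.atac_counts.groups.items()
        }
        diff = nb_diff_test(CountMatrix(counts, collapsed), "rod", "cone")
        elements, _ = classify_specificity(
            elements, diff,
            {"non_photoreceptor": bundle.peak_calls["non_photoreceptor"]},
        )
        truth_by_span = {
            (p.chrom, p.start, p.end): bundle.truth.peak_class_labels[p.name]
            for p in bundle.peaks
        }
        recalls = []
        pred = {}
        for e in elements:
            key = (e.interval.chrom, e.interval.start, e.interval.end)
            if key in truth_by_span:
                pred.setdefault(truth_by_span[key], []).append(e.specificity)
        for cls, preds in pred.items():
            recalls.append(np.mean([p == cls for p in preds]))
        assert len(pred) == 4
        assert np.mean(recalls) >= 0.9
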