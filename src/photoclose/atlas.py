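"""Cross-sample peak atlas: signal quantification, promoter/enhancer
partitioning, repeat filtering and specificity classification.

Atlas elements are fixed-width summit-centered intervals merged across
sample groups. Specificity follows the three-way differential scheme
(rod-specific / cone-specific / shared) with a non-photoreceptor flag for
elements overlapping peaks from other cell types, and the published filter
cascade: remove promoters, remove non-photoreceptor elements, remove
repeat-dominated elements (>70 % repeat overlap).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .differential import CountMatrix, nb_diff_test
from .intervals import Fragment, GenomicInterval, filter_nfr, nearest_tss

SPECIFICITY_LEVELS = (
    "shared_PR",
    "rod_specific",
    "cone_specific",
    "non_PR",
    "unassigned",
)


@dataclass
class AtlasElement:
    interval: GenomicInterval
    source_flags: set[str] = field(default_factory=set)
    region_class: str | None = None  # promoter / enhancer
    specificity: str = "unassigned"
    nearest_gene: str | None = None
    tss_distance: float = float("nan")
    repeat_fraction: float = 0.0

    @property
    def name(self) -> str:
        return self.interval.name


@dataclass
class SignalMatrix:
    """Elements x bins fragment-midpoint counts around an anchor."""

    element_names: list[str]
    matrix: np.ndarray
    bin_width: int
    window: int
    anchor: str = "summit"

    def to_frame(self) -> pd.DataFrame:
        centers = (np.arange(self.matrix.shape[1]) + 0.5) * self.bin_width - self.window / 2
        return pd.DataFrame(self.matrix, index=self.element_names, columns=centers)


def quantify_signal(
    elements: Sequence[AtlasElement | GenomicInterval],
    fragments: Sequence[Fragment],
    window: int = 3000,
    bin_width: int = 5,
    anchor: str = "summit",
    per_million: bool = False,
    count_mode: str = "midpoint",
    nfr_max_insert: int | None = None,
) -> SignalMatrix:
    """Per-bin fragment counts in a window centered on each element's anchor.

    Entry (i, j) counts fragment midpoints (or 5' cut sites with
    ``count_mode='cutsite'``) falling in bin j of element i; bins tile
    ``[anchor - window/2, anchor + window/2)``.
    """
    if window % bin_width:
        raise ValueError("window must be divisible by bin_width")
    ivs = [e.interval if isinstance(e, AtlasElement) else e for e in elements]
    missing = [iv.name for iv in ivs if anchor == "summit" and iv.summit is None]
    if missing:
        raise ValueError(f"elements without summit anchor: {missing}")
    if nfr_max_insert is not None:
        fragments = filter_nfr(fragments, nfr_max_insert)
    n_bins = window // bin_width
    half = window // 2
    mat = np.zeros((len(ivs), n_bins), dtype=float)
    # bucket fragment positions by chromosome once
    pos_by_chrom: dict[str, list[int]] = {}
    for f in fragments:
        pos = f.midpoint if count_mode == "midpoint" else f.start
        pos_by_chrom.setdefault(f.chrom, []).append(pos)
    sorted_pos = {c: np.sort(np.asarray(v)) for c, v in pos_by_chrom.items()}
    for i, iv in enumerate(ivs):
        positions = sorted_pos.get(iv.chrom)
        if positions is None:
            continue
        a = iv.anchor
        lo, hi = a - half, a + half
        s, e = np.searchsorted(positions, [lo, hi])
        if e > s:
            bins = (positions[s:e] - lo) // bin_width
            mat[i] += np.bincount(bins.astype(int), minlength=n_bins)
    if per_million:
        total = sum(len(v) for v in pos_by_chrom.values())
        if total > 0:
            mat *= 1e6 / total
    return SignalMatrix([iv.name for iv in ivs], mat, bin_width, window, anchor)


def build_atlas(
    merged: Sequence[tuple[GenomicInterval, set[str]]],
    tss_table: Sequence[GenomicInterval],
    repeats: Sequence[GenomicInterval] | None = None,
) -> list[AtlasElement]:
    """Assemble atlas elements with nearest-gene and repeat annotations."""
    ivs = [m[0] for m in merged]
    assignment = nearest_tss(ivs, tss_table)
    elements = []
    for iv, sources in merged:
        gene, dist = assignment[iv.name]
        elements.append(
            AtlasElement(
                interval=iv,
                source_flags=set(sources),
                nearest_gene=gene,
                tss_distance=dist,
                repeat_fraction=0.0,
            )
        )
    if repeats is not None:
        annotate_repeat_fraction(elements, repeats)
    return elements


def annotate_repeat_fraction(
    elements: Sequence[AtlasElement], repeats: Sequence[GenomicInterval]
) -> None:
    """Set each element's fraction of bases covered by repeat intervals."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for r in repeats:
        by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
    for v in by_chrom.values():
        v.sort()
    for el in elements:
        iv = el.interval
        covered = 0
        last_end = iv.start
        for s, e in by_chrom.get(iv.chrom, []):
            if e <= iv.start or s >= iv.end:
                continue
            s, e = max(s, last_end, iv.start), min(e, iv.end)
            if e > s:
                covered += e - s
                last_end = e
        el.repeat_fraction = covered / len(iv)


def partition_promoter_enhancer(
    elements: Sequence[AtlasElement],
    upstream: int = 1000,
    downstream: int = 100,
) -> list[AtlasElement]:
    """Label each element promoter or enhancer by its signed TSS distance.

    Promoter iff -upstream < d < +downstream (strict, strand-aware,
    summit-anchored); everything else, including unassigned distances, is
    an enhancer. Exhaustive and exclusive.
    """
    for el in elements:
        d = el.tss_distance
        el.region_class = (
            "promoter" if (np.isfinite(d) and -upstream < d < downstream) else "enhancer"
        )
    return list(elements)


def repeat_filter(
    elements: Sequence[AtlasElement], max_fraction: float = 0.70
) -> list[AtlasElement]:
    """Drop elements with repeat overlap strictly above ``max_fraction``."""
    return [e for e in elements if e.repeat_fraction <= max_fraction]


def overlap_fraction(
    set_a: Sequence[GenomicInterval], set_b: Sequence[GenomicInterval]
) -> float:
    """Fraction of a-elements overlapping (>=1 bp) at least one b-element."""
    if not set_a:
        raise ValueError("overlap_fraction undefined for empty set_a")
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {b.chrom for b in set_b}:
        bs = sorted((b for b in set_b if b.chrom == chrom), key=lambda b: b.start)
        starts = np.array([b.start for b in bs])
        # running max of ends lets a single bisect answer "any overlap?"
        ends = np.maximum.accumulate(np.array([b.end for b in bs]))
        by_chrom[chrom] = (starts, ends)
    n_hit = 0
    for a in set_a:
        entry = by_chrom.get(a.chrom)
        if entry is None:
            continue
        starts, ends = entry
        i = int(np.searchsorted(starts, a.end, side="left")) - 1
        if i >= 0 and ends[i] > a.start:
            n_hit += 1
    return n_hit / len(set_a)


@dataclass
class FilterCascade:
    """Survivor counts through the published specificity filter cascade."""

    stage_counts: dict[str, dict[str, int]]  # stage -> class -> count

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stage_counts).T


def classify_specificity(
    elements: Sequence[AtlasElement],
    diff_results: pd.DataFrame,
    non_pr_peak_sets: Mapping[str, Sequence[GenomicInterval]] | None = None,
) -> tuple[list[AtlasElement], FilterCascade]:
    """Assign specificity labels and run the filter cascade.

    ``diff_results`` is the rod-vs-cone accessibility table (A = rod) from
    :func:`photoclose.differential.nb_diff_test`, indexed by element name.
    Elements significantly more open in rods are rod_specific, in cones
    cone_specific, otherwise shared_PR; any element overlapping a
    non-photoreceptor peak set is flagged non_PR (taking precedence). The
    cascade then removes promoters, non-PR elements and repeat-dominated
    elements in that order, reporting per-stage survivor counts.
    """
    non_pr_flat: list[GenomicInterval] = []
    for peaks in (non_pr_peak_sets or {}).values():
        non_pr_flat.extend(peaks)
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {p.chrom for p in non_pr_flat}:
        ps = sorted(
            (p for p in non_pr_flat if p.chrom == chrom), key=lambda p: p.start
        )
        by_chrom[chrom] = (
            np.array([p.start for p in ps]),
            np.maximum.accumulate(np.array([p.end for p in ps])),
        )

    def hits_non_pr(iv: GenomicInterval) -> bool:
        entry = by_chrom.get(iv.chrom)
        if entry is None:
            return False
        starts, ends = entry
        i = int(np.searchsorted(starts, iv.end, side="left")) - 1
        return i >= 0 and ends[i] > iv.start

    missing = [e.name for e in elements if e.name not in diff_results.index]
    if missing:
        raise ValueError(f"elements absent from diff_results: {missing[:5]}")
    for el in elements:
        row = diff_results.loc[el.name]
        if hits_non_pr(el.interval):
            el.specificity = "non_PR"
        elif row["call"] == "A_up":
            el.specificity = "rod_specific"
        elif row["call"] == "B_up":
            el.specificity = "cone_specific"
        else:
            el.specificity = "shared_PR"

    def tally(els):
        out = {c: 0 for c in ("shared_PR", "rod_specific", "cone_specific", "non_PR")}
        for e in els:
            out[e.specificity] += 1
        return out

    stage: list[AtlasElement] = list(elements)
    cascade = {"all": tally(stage)}
    stage = [e for e in stage if e.region_class != "promoter"]
    cascade["minus_promoters"] = tally(stage)
    stage = [e for e in stage if e.specificity != "non_PR"]
    cascade["minus_non_PR"] = tally(stage)
    stage = repeat_filter(stage)
    cascade["minus_repeats"] = tally(stage)
    return list(elements), FilterCascade(cascade)


def atlas_to_frame(elements: Sequence[AtlasElement]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "name": e.name,
                "chrom": e.interval.chrom,
                "start": e.interval.start,
                "end": e.interval.end,
                "summit": e.interval.summit,
                "sources": ",".join(sorted(e.source_flags)),
                "region_class": e.region_class,
                "specificity": e.specificity,
                "nearest_gene": e.nearest_gene,
                "tss_distance": e.tss_distance,
                "repeat_fraction": e.repeat_fraction,
            }
            for e in elements
        ]
    ).set_index("name")
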