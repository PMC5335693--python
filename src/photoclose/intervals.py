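"""Strand-aware genomic interval algebra and text-format I/O.

All coordinates are 0-based half-open, BED-style. Readers and writers are
bit-faithful on canonical records: read followed by write reproduces the
input line for BED6 and 10-column narrowPeak.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

STRANDS = ("+", "-", ".")


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """A half-open genomic interval with optional summit.

    ``summit`` is an absolute base-pair position (not an offset) and, when
    present, must lie inside ``[start, end)``.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = "."
    summit: int | None = None
    score: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.summit is not None and not (self.start <= self.summit < self.end):
            raise ValueError(
                f"summit {self.summit} outside [{self.start}, {self.end}) "
                f"for {self.name}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    @property
    def anchor(self) -> int:
        """Summit when present, interval midpoint otherwise."""
        return self.summit if self.summit is not None else self.midpoint

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True, slots=True)
class Fragment:
    """A sequenced fragment (paired-end insert) on a chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"fragment {self.chrom}:{self.start}-{self.end} has insert_size <= 0"
            )

    @property
    def insert_size(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _fmt_score(score: float) -> str:
    return str(int(score)) if float(score).is_integer() else repr(float(score))


def read_bed(path) -> list[GenomicInterval]:
    """Read BED3/BED6 into intervals. Extra columns are ignored."""
    out = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end <= start")
            name = f[3] if len(f) > 3 else "."
            score = float(f[4]) if len(f) > 4 else 0.0
            strand = f[5] if len(f) > 5 else "."
            out.append(GenomicInterval(f[0], start, end, strand, name, None, score))
    return out


def write_bed(path, intervals: Iterable[GenomicInterval], columns: int = 6) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if columns >= 6:
                fields += [iv.name, _fmt_score(iv.score), iv.strand]
            fh.write("\t".join(fields) + "\n")


def read_narrowpeak(path) -> list[GenomicInterval]:
    """Read 10-column narrowPeak; column 10 is the summit offset (-1 = absent)."""
    out = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 10:
                raise ValueError(
                    f"{path}:{lineno}: narrowPeak requires 10 columns, got {len(f)}"
                )
            start, end = int(f[1]), int(f[2])
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end <= start")
            offset = int(f[9])
            if offset == -1:
                summit = None
            else:
                summit = start + offset
                if not (start <= summit < end):
                    raise ValueError(
                        f"{path}:{lineno}: summit offset {offset} outside interval"
                    )
            out.append(
                GenomicInterval(f[0], start, end, f[5], f[3], summit, float(f[4]))
            )
    return out


def write_narrowpeak(path, intervals: Iterable[GenomicInterval]) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            offset = -1 if iv.summit is None else iv.summit - iv.start
            fh.write(
                "\t".join(
                    [
                        iv.chrom,
                        str(iv.start),
                        str(iv.end),
                        iv.name,
                        _fmt_score(iv.score),
                        iv.strand,
                        "0",
                        "-1",
                        "-1",
                        str(offset),
                    ]
                )
                + "\n"
            )


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered {name: sequence} dict."""
    seqs: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0]
                if name in seqs:
                    raise ValueError(f"duplicate FASTA record {name!r}")
                seqs[name] = []
            else:
                if name is None:
                    raise ValueError("FASTA sequence before first header")
                seqs[name].append(line.upper())
    return {k: "".join(v) for k, v in seqs.items()}


def write_fasta(path, seqs: dict[str, str], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fragments(path) -> list[Fragment]:
    """Read a 3-column fragment table (chrom, start, end)."""
    out = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns")
            out.append(Fragment(f[0], int(f[1]), int(f[2])))
    return out


def write_fragments(path, fragments: Iterable[Fragment]) -> None:
    with open(path, "w") as fh:
        for fr in fragments:
            fh.write(f"{fr.chrom}\t{fr.start}\t{fr.end}\n")


def read_chrom_sizes(path) -> dict[str, int]:
    sizes = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            f = line.split("\t")
            sizes[f[0]] = int(f[1])
    return sizes


def write_chrom_sizes(path, sizes: dict[str, int]) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")


def write_bedgraph(path, records: Iterable[tuple[str, int, int, float]]) -> None:
    """Write a 4-column bedGraph (no track line)."""
    with open(path, "w") as fh:
        for chrom, start, end, value in records:
            fh.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")


# ---------------------------------------------------------------------------
# Interval operations
# ---------------------------------------------------------------------------


def recenter_on_summit(
    peaks: Sequence[GenomicInterval],
    width: int = 200,
    chrom_sizes: dict[str, int] | None = None,
) -> list[GenomicInterval]:
    """Standardise peaks to fixed-width elements centered on their summits.

    Each output is ``[summit - width/2, summit + width/2)``. At chromosome
    boundaries the element is shifted, not truncated, so every element keeps
    the same width (required for binned signal matrices).
    """
    if width <= 0 or width % 2:
        raise ValueError("width must be a positive even integer")
    missing = [p.name for p in peaks if p.summit is None]
    if missing:
        raise ValueError(f"peaks without summit: {missing}")
    half = width // 2
    out = []
    for p in peaks:
        start = p.summit - half
        end = p.summit + half
        if start < 0:
            start, end = 0, width
        if chrom_sizes is not None:
            size = chrom_sizes.get(p.chrom)
            if size is not None and end > size:
                if size < width:
                    raise ValueError(
                        f"chromosome {p.chrom} shorter than element width {width}"
                    )
                start, end = size - width, size
        summit = min(max(p.summit, start), end - 1)
        out.append(replace(p, start=start, end=end, summit=summit))
    return out


def merge_peak_sets(
    sets: Sequence[Sequence[GenomicInterval]],
    source_names: Sequence[str] | None = None,
) -> list[tuple[GenomicInterval, set[str]]]:
    """Merge peak sets into a master atlas, coalescing >=1 bp overlaps.

    Returns ``(interval, contributing_sources)`` pairs sorted by
    (chrom, start). Commutative and idempotent.
    """
    if not sets or all(len(s) == 0 for s in sets):
        raise ValueError("merge_peak_sets requires at least one non-empty set")
    if source_names is None:
        source_names = [f"set{i}" for i in range(len(sets))]
    tagged = [
        (p.chrom, p.start, p.end, source_names[i])
        for i, peaks in enumerate(sets)
        for p in peaks
    ]
    tagged.sort()
    out: list[tuple[GenomicInterval, set[str]]] = []
    cur_chrom, cur_start, cur_end, cur_src = None, 0, 0, set()
    idx = 0

    def flush():
        nonlocal idx
        if cur_chrom is not None:
            iv = GenomicInterval(
                cur_chrom, cur_start, cur_end, ".", f"atlas_{idx:06d}"
            )
            out.append((iv, set(cur_src)))
            idx += 1

    for chrom, start, end, src in tagged:
        if chrom != cur_chrom or start >= cur_end:
            flush()
            cur_chrom, cur_start, cur_end, cur_src = chrom, start, end, {src}
        else:
            cur_end = max(cur_end, end)
            cur_src.add(src)
    flush()
    return out


def filter_nfr(
    fragments: Sequence[Fragment], max_insert: int | float = 100
) -> list[Fragment]:
    """Keep nucleosome-free fragments: insert size <= ``max_insert``.

    Fragments with insert size strictly greater than the threshold are
    removed (an insert of exactly 100 bp is retained at the default).
    """
    return [f for f in fragments if f.insert_size <= max_insert]


def nearest_tss(
    peaks: Sequence[GenomicInterval],
    tss_table: Sequence[GenomicInterval],
    warn_unstranded: bool = True,
) -> dict[str, tuple[str | None, float]]:
    """Assign each peak to its nearest TSS, summit-to-TSS distance.

    The distance sign is strand-aware on the *gene's* strand: negative means
    the peak lies upstream of the TSS. Ties break by smaller absolute
    distance then lexicographic gene id. Peaks on chromosomes without any
    TSS map to ``(None, inf)``.
    """
    by_chrom: dict[str, list[tuple[int, str, str]]] = {}
    for t in tss_table:
        strand = t.strand
        if strand == ".":
            strand = "+"
        by_chrom.setdefault(t.chrom, []).append((t.start, t.name, strand))
    for v in by_chrom.values():
        v.sort()

    result: dict[str, tuple[str | None, float]] = {}
    for p in peaks:
        entries = by_chrom.get(p.chrom)
        if not entries:
            result[p.name] = (None, math.inf)
            continue
        anchor = p.anchor
        positions = [e[0] for e in entries]
        i = int(np.searchsorted(positions, anchor))
        dists = [
            abs(anchor - positions[j]) for j in (i - 1, i) if 0 <= j < len(entries)
        ]
        best_d = min(dists)
        # all TSSs at exactly best_d, so gene-id ties resolve deterministically
        lo = int(np.searchsorted(positions, anchor - best_d, side="left"))
        hi = int(np.searchsorted(positions, anchor + best_d, side="right"))
        best = min(
            (e for e in entries[lo:hi] if abs(anchor - e[0]) == best_d),
            key=lambda e: e[1],
        )
        tss_pos, gene, strand = best
        raw = anchor - tss_pos
        signed = raw if strand == "+" else -raw
        result[p.name] = (gene, float(signed))
    return result
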