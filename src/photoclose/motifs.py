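"""PWM scanning and motif-grammar statistics.

Implements the motif layer of the comparative photoreceptor analysis:
log-odds scanning of position-weight matrices (natural-log units, matching
the HOMER convention in which a "relaxed threshold of 5" is meaningful),
known-motif enrichment against composition-matched genomic background,
redundancy collapse of a motif library by aligned Pearson correlation,
pairwise co-occurrence enrichment over a fixed peak universe, central
density profiles around peak summits, and strand-resolved spacing profiles
between motif pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats

from .seqs import BASES, encode, mono_di_frequencies, revcomp

EPSILON = 0.001  # probability smoothing applied before log-odds


@dataclass
class Pwm:
    """A position probability matrix with log-odds scoring metadata."""

    name: str
    matrix: np.ndarray  # width x 4, rows sum to 1
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    log_odds_threshold: float = 0.0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4 or self.width < 1:
            raise ValueError(f"PWM {self.name}: matrix must be width x 4")
        sums = self.matrix.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-4):
            raise ValueError(f"PWM {self.name}: rows must sum to 1 (got {sums})")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))

    def smoothed(self) -> np.ndarray:
        """Probabilities after epsilon smoothing and renormalisation."""
        m = self.matrix + EPSILON
        return m / m.sum(axis=1, keepdims=True)

    def log_odds(self) -> np.ndarray:
        """width x 5 natural-log odds; column 5 (N) contributes zero."""
        lo = np.log(self.smoothed() / self.background[None, :])
        return np.concatenate([lo, np.zeros((self.width, 1))], axis=1)

    def reverse_complement(self) -> "Pwm":
        return Pwm(
            self.name,
            self.matrix[::-1, ::-1].copy(),
            self.background[::-1].copy(),
            self.log_odds_threshold,
        )

    def information_content(self) -> np.ndarray:
        """Per-column information content in bits: 2 + sum p log2 p.

        Computed on the raw probabilities (0 log 0 = 0), not the smoothed
        ones, so boundary cases like (0.5, 0.5, 0, 0) score exactly 1 bit.
        """
        m = self.matrix
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(m > 0, m * np.log2(np.where(m > 0, m, 1.0)), 0.0)
        return 2.0 + plogp.sum(axis=1)

    def max_score(self) -> float:
        return float(self.log_odds()[:, :4].max(axis=1).sum())


@dataclass(frozen=True)
class MotifHit:
    seq_id: str
    offset: int  # forward-strand coordinate of the match start
    strand: str
    score: float


def consensus_pwm(name: str, consensus: str, p: float = 0.997) -> Pwm:
    """Build a near-deterministic PWM from a consensus string.

    IUPAC codes N (uniform), W (A/T), S (C/G), R (A/G), Y (C/T) are spread
    evenly over their bases.
    """
    groups = {"N": "ACGT", "W": "AT", "S": "CG", "R": "AG", "Y": "CT"}
    rows = []
    for ch in consensus.upper():
        row = np.full(4, (1 - p) / 3)
        if ch in BASES:
            row[BASES.index(ch)] = p
        elif ch in groups:
            row = np.full(4, 0.01)
            for b in groups[ch]:
                row[BASES.index(b)] = (1 - 0.02 * (4 - len(groups[ch])) / 2) / len(
                    groups[ch]
                )
            row /= row.sum()
        else:
            raise ValueError(f"unsupported consensus symbol {ch!r}")
        rows.append(row / row.sum())
    return Pwm(name, np.array(rows))


# ---------------------------------------------------------------------------
# HOMER-style motif text I/O
# ---------------------------------------------------------------------------


def read_motifs(path) -> list[Pwm]:
    """Read HOMER-style motif text: '>name<TAB>consensus<TAB>threshold' headers
    followed by one line of four tab-separated base probabilities per position.
    """
    motifs: list[Pwm] = []
    name, thr, rows = None, 0.0, []

    def flush():
        if name is not None:
            if not rows:
                raise ValueError(f"motif {name!r} has no probability rows")
            motifs.append(Pwm(name, np.array(rows), log_odds_threshold=thr))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                flush()
                fields = line[1:].split("\t")
                name = fields[0]
                thr = float(fields[2]) if len(fields) > 2 else 0.0
                rows = []
            else:
                vals = [float(x) for x in line.split("\t")]
                if len(vals) != 4:
                    raise ValueError(f"{path}:{lineno}: expected 4 probabilities")
                rows.append(vals)
    flush()
    return motifs


def write_motifs(path, motifs: Iterable[Pwm]) -> None:
    with open(path, "w") as fh:
        for m in motifs:
            fh.write(f">{m.name}\t{m.consensus}\t{m.log_odds_threshold:g}\n")
            for row in m.matrix:
                fh.write("\t".join(f"{x:.6f}" for x in row) + "\n")


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------


def _scan_one(codes: np.ndarray, lodds: np.ndarray) -> np.ndarray:
    """Scores at every start position of one strand (vectorised)."""
    w = lodds.shape[0]
    if len(codes) < w:
        return np.empty(0)
    windows = sliding_window_view(codes, w)
    return lodds[np.arange(w)[None, :], windows].sum(axis=1)


def scan(
    sequences: Mapping[str, str], pwm: Pwm, threshold: float | None = None
) -> list[MotifHit]:
    """Scan both strands; report every position scoring >= threshold.

    Reverse-strand hits report the forward-strand coordinate of the match
    start. ``N`` positions contribute zero to the score.
    """
    if threshold is None:
        threshold = pwm.log_odds_threshold
    lodds_fwd = pwm.log_odds()
    lodds_rev = pwm.reverse_complement().log_odds()
    hits: list[MotifHit] = []
    for seq_id, seq in sequences.items():
        codes = encode(seq)
        for strand, lodds in (("+", lodds_fwd), ("-", lodds_rev)):
            scores = _scan_one(codes, lodds)
            for off in np.flatnonzero(scores >= threshold):
                hits.append(MotifHit(seq_id, int(off), strand, float(scores[off])))
    return hits


def hit_presence(
    sequences: Mapping[str, str],
    motifs: Sequence[Pwm],
    threshold: float | None = None,
) -> pd.DataFrame:
    """Boolean peaks x motifs presence matrix (>=1 hit anywhere)."""
    ids = list(sequences)
    data = {}
    for m in motifs:
        hits = scan(sequences, m, threshold)
        present = {h.seq_id for h in hits}
        data[m.name] = [i in present for i in ids]
    return pd.DataFrame(data, index=ids)


# ---------------------------------------------------------------------------
# Background construction
# ---------------------------------------------------------------------------


def sample_matched_background(
    genome: Mapping[str, str],
    targets: Sequence[str],
    n: int = 50000,
    length: int = 200,
    rng: np.random.Generator | None = None,
    l1_tolerance: float = 0.05,
    max_masked_fraction: float = 0.70,
    pool_factor: int = 5,
    max_iter: int = 20000,
) -> tuple[list[str], dict]:
    """Draw random genomic windows matched to the targets' composition.

    Windows are drawn uniformly from the genome, windows with more than
    ``max_masked_fraction`` masked (N) bases are rejected, and the
    remaining pool is greedily subsampled so the pooled mono- and
    di-nucleotide frequency vector approaches the target set's within
    ``l1_tolerance`` (L1). Returns the sequences and a metadata dict with
    the achieved L1 distance.
    """
    rng = np.random.default_rng() if rng is None else rng
    chroms = [c for c in genome if len(genome[c]) >= length]
    if not chroms:
        raise ValueError("genome has no chromosome longer than the window length")
    lengths = np.array([len(genome[c]) - length + 1 for c in chroms], dtype=float)
    total_positions = int(lengths.sum())
    if n * length > sum(len(genome[c]) for c in chroms):
        raise ValueError(
            f"genome too short for {n} background windows of {length} bp"
        )
    probs = lengths / lengths.sum()

    pool: list[str] = []
    feats: list[np.ndarray] = []
    attempts = 0
    while len(pool) < pool_factor * n and attempts < 50 * pool_factor * n:
        attempts += 1
        ci = rng.choice(len(chroms), p=probs)
        start = int(rng.integers(0, lengths[ci]))
        seq = genome[chroms[ci]][start : start + length]
        if seq.count("N") / length > max_masked_fraction:
            continue
        pool.append(seq)
        feats.append(mono_di_frequencies([seq]))
    if len(pool) < n:
        raise ValueError(
            f"could not draw {n} unmasked windows ({len(pool)} available)"
        )
    feats_arr = np.stack(feats)
    target_vec = mono_di_frequencies(list(targets))

    selected = np.zeros(len(pool), dtype=bool)
    selected[:n] = True
    current = feats_arr[selected].mean(axis=0)

    def l1(v):
        return float(np.abs(v - target_vec).sum())

    best = l1(current)
    it = 0
    while best > l1_tolerance and it < max_iter:
        it += 1
        out_i = int(rng.choice(np.flatnonzero(selected)))
        in_i = int(rng.choice(np.flatnonzero(~selected)))
        cand = current + (feats_arr[in_i] - feats_arr[out_i]) / n
        if l1(cand) < best:
            selected[out_i] = False
            selected[in_i] = True
            current = cand
            best = l1(cand)
    meta = {"achieved_l1": best, "tolerance": l1_tolerance, "iterations": it}
    if best > l1_tolerance:
        import warnings

        warnings.warn(
            f"background matching reached L1={best:.4f} > tolerance "
            f"{l1_tolerance} after {it} swaps; reporting best achieved"
        )
    return [pool[i] for i in np.flatnonzero(selected)], meta


# ---------------------------------------------------------------------------
# Enrichment, density, spacing
# ---------------------------------------------------------------------------


def motif_enrichment(
    target_seqs: Mapping[str, str],
    background_seqs: Mapping[str, str],
    motifs: Sequence[Pwm],
    threshold: float | None = None,
) -> pd.DataFrame:
    """Known-motif enrichment: fraction of target vs background sequences
    containing >=1 hit, with a hypergeometric p-value per motif.

    Returns a DataFrame sorted by p-value with columns ``motif``,
    ``n_target``, ``n_background``, ``ratio`` and ``log10_p``.
    """
    n_t, n_b = len(target_seqs), len(background_seqs)
    if n_t == 0 or n_b == 0:
        raise ValueError("target and background sets must be non-empty")
    rows = []
    for m in motifs:
        thr = m.log_odds_threshold if threshold is None else threshold
        t = len({h.seq_id for h in scan(target_seqs, m, thr)})
        b = len({h.seq_id for h in scan(background_seqs, m, thr)})
        ft, fb = t / n_t, b / n_b
        ratio = ft / fb if fb > 0 else np.inf if ft > 0 else 1.0
        # P(X >= t) for X ~ Hypergeom(N=n_t+n_b, K=t+b, n=n_t)
        p = float(stats.hypergeom.sf(t - 1, n_t + n_b, t + b, n_t))
        rows.append((m.name, t, b, ratio, np.log10(max(p, 1e-300))))
    df = pd.DataFrame(
        rows, columns=["motif", "n_target", "n_background", "ratio", "log10_p"]
    )
    return df.sort_values("log10_p").reset_index(drop=True)


def central_density_profile(
    sequences: Mapping[str, str],
    pwm: Pwm,
    threshold: float | None = None,
    bin_width: int = 5,
) -> pd.DataFrame:
    """Motif density versus distance from the sequence center.

    Sequences must share one width (summit-centered windows). A hit is
    binned by its motif midpoint; density is hits per peak per bin.
    """
    widths = {len(s) for s in sequences.values()}
    if len(widths) != 1:
        raise ValueError(f"sequences must be equal width, got widths {widths}")
    (width,) = widths
    n_bins = width // bin_width
    counts = np.zeros(n_bins)
    for h in scan(sequences, pwm, threshold):
        mid = h.offset + pwm.width // 2
        b = min(mid // bin_width, n_bins - 1)
        counts[b] += 1
    n_peaks = len(sequences)
    centers = (np.arange(n_bins) + 0.5) * bin_width - width / 2
    return pd.DataFrame(
        {"position": centers, "density": counts / max(n_peaks, 1)}
    )


def pwm_similarity(a: Pwm, b: Pwm, min_overlap: int = 4) -> float:
    """Max Pearson correlation of aligned probability columns over all
    ungapped offsets and both orientations of ``b``.

    Alignments with fewer than ``min_overlap`` overlapping columns are not
    considered (short motifs fall back to full-overlap alignments).
    """
    best = -1.0
    ma = a.matrix
    for mb in (b.matrix, b.reverse_complement().matrix):
        wa, wb = ma.shape[0], mb.shape[0]
        ov_min = min(min_overlap, wa, wb)
        for shift in range(-(wb - ov_min), wa - ov_min + 1):
            lo_a, hi_a = max(0, shift), min(wa, shift + wb)
            if hi_a - lo_a < ov_min:
                continue
            xa = ma[lo_a:hi_a].ravel()
            xb = mb[lo_a - shift : hi_a - shift].ravel()
            if xa.std() == 0 or xb.std() == 0:
                continue
            r = float(np.corrcoef(xa, xb)[0, 1])
            best = max(best, r)
    return best


def collapse_redundant(
    motifs: Sequence[Pwm],
    scores: Mapping[str, float] | None = None,
    pcc_threshold: float = 0.6,
) -> tuple[list[Pwm], dict[str, str]]:
    """Collapse a motif library to a non-redundant set.

    Greedy highest-score-first clustering: the best-scoring unassigned
    motif seeds a cluster and absorbs every unassigned motif whose aligned
    Pearson correlation (either orientation) exceeds ``pcc_threshold``.
    Returns the seed motifs and a member -> seed name mapping.
    """
    if not motifs:
        raise ValueError("empty motif library")
    if scores is None:
        scores = {m.name: 0.0 for m in motifs}
    order = sorted(motifs, key=lambda m: (-scores.get(m.name, 0.0), m.name))
    seeds: list[Pwm] = []
    mapping: dict[str, str] = {}
    for m in order:
        if m.name in mapping:
            continue
        seeds.append(m)
        mapping[m.name] = m.name
        for other in order:
            if other.name in mapping:
                continue
            if pwm_similarity(m, other) > pcc_threshold:
                mapping[other.name] = m.name
    return seeds, mapping


@dataclass
class CooccurrenceMatrix:
    motif_names: list[str]
    n_peaks: int
    per_motif: np.ndarray  # n_i
    observed: np.ndarray  # O_ij
    expected: np.ndarray  # E_ij = n_i n_j / N
    enrichment: np.ndarray  # log2(O/E); -inf where O == 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.enrichment, index=self.motif_names, columns=self.motif_names
        )


def cooccurrence(presence: pd.DataFrame) -> CooccurrenceMatrix:
    """Pairwise co-occurrence enrichment from a boolean peaks x motifs matrix.

    ``n_i`` counts peaks with >=1 hit of motif i; ``O_ij`` peaks with both;
    ``E_ij = n_i * n_j / N``; enrichment ``log2(O/E)``.
    """
    n_peaks = presence.shape[0]
    if n_peaks == 0:
        raise ValueError("empty peak universe")
    mat = presence.to_numpy(dtype=bool)
    n_i = mat.sum(axis=0).astype(float)
    observed = (mat.T.astype(float) @ mat.astype(float)).astype(float)
    expected = np.outer(n_i, n_i) / n_peaks
    with np.errstate(divide="ignore", invalid="ignore"):
        enrich = np.log2(observed / expected)
    enrich[np.isnan(enrich)] = 0.0
    np.fill_diagonal(enrich, 0.0)
    return CooccurrenceMatrix(
        list(presence.columns), n_peaks, n_i, observed, expected, enrich
    )


def spacing_profile(
    sequences: Mapping[str, str],
    primary: Pwm,
    secondary: Pwm,
    threshold: float = 5.0,
    primary_threshold: float | None = None,
) -> pd.DataFrame:
    """Strand-resolved density of secondary hits around the best primary hit.

    Each sequence is re-anchored on its highest-scoring primary hit (ties:
    leftmost) and oriented by the primary strand. Secondary hits overlapping
    the primary match are masked out. Returns a tidy frame with columns
    ``offset`` (signed, 1 bp), ``relative_strand`` (same/opposite) and
    ``count``.
    """
    if primary_threshold is None:
        primary_threshold = threshold
    prim_hits: dict[str, MotifHit] = {}
    for h in scan(sequences, primary, primary_threshold):
        cur = prim_hits.get(h.seq_id)
        if cur is None or (h.score, -h.offset) > (cur.score, -cur.offset):
            prim_hits[h.seq_id] = h
    if not prim_hits:
        import warnings

        warnings.warn("no primary hits; spacing profile is empty")
        return pd.DataFrame(columns=["offset", "relative_strand", "count"])

    tallies: dict[tuple[int, str], int] = {}
    sec_hits = scan(sequences, secondary, threshold)
    for h in sec_hits:
        p = prim_hits.get(h.seq_id)
        if p is None:
            continue
        # mask secondary hits overlapping the primary occurrence
        if h.offset < p.offset + primary.width and p.offset < h.offset + secondary.width:
            continue
        delta = h.offset - p.offset
        same = h.strand == p.strand
        if p.strand == "-":
            delta = -delta
        key = (delta, "same" if same else "opposite")
        tallies[key] = tallies.get(key, 0) + 1
    rows = [
        {"offset": k[0], "relative_strand": k[1], "count": v}
        for k, v in sorted(tallies.items())
    ]
    return pd.DataFrame(rows, columns=["offset", "relative_strand", "count"])


def trim_low_info(pwm: Pwm, min_bits: float = 1.0) -> Pwm:
    """Trim flanking columns with information content below ``min_bits``."""
    ic = pwm.information_content()
    keep = np.flatnonzero(ic >= min_bits)
    if keep.size == 0:
        raise ValueError(f"all columns of {pwm.name} below {min_bits} bits")
    lo, hi = keep[0], keep[-1] + 1
    return Pwm(
        pwm.name,
        pwm.matrix[lo:hi].copy(),
        pwm.background.copy(),
        pwm.log_odds_threshold,
    )
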