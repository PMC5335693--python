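"""Synthetic photoreceptor chromatin datasets with planted ground truth.

The generator emulates the statistical structure of a purified rod / green
cone / blue cone (Nrl-null) ATAC-seq study: a peak universe of shared,
rod-specific, cone-specific and non-photoreceptor elements; large
rod-closed domains depleted of rod signal in which cone-specific peaks
preferentially reside (and which are depleted of genes, so cone-specific
peaks sit farther from TSSs); negative-binomial fragment counts;
paired-end-style fragments with a short/nucleosomal insert mixture; an
order-1 Markov genome with planted motif content; gene expression
directionally coupled to nearby peak accessibility; and an 84-bp reporter
(CRE-seq) library carrying homeodomain dimer k-mers with a planted
repressive effect.

Every quantity is drawn from a single seeded generator, so identical
(config, seed) pairs produce byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .differential import CountMatrix
from .intervals import (
    Fragment,
    GenomicInterval,
    filter_nfr,
    nearest_tss,
    write_bed,
    write_chrom_sizes,
    write_fasta,
    write_fragments,
    write_narrowpeak,
)
from .kmers import CreConstruct, DimerKmerScheme, present_classes, mutate_crx_sites
from .motifs import Pwm, consensus_pwm, write_motifs
from .seqs import BASES, revcomp

PEAK_CLASSES = ("shared_PR", "rod_specific", "cone_specific", "non_PR")
GROUPS = ("rod", "green_cone", "blue_cone")
PEAK_WIDTH = 200

# consensus sequences for the planted motif library; near-deterministic PWMs
DEFAULT_MOTIF_CONSENSI = {
    "CRX_K50": "CTAATCC",
    "Q50_HD": "TAATTA",
    "MAF": "TGCTGACTCAGCA",
    "NR": "AGGTCA",
    "bHLH": "CATATG",
    "MADS": "CCWWWWWWWWGG",
    "CTCF": "CCACCAGGGGGCGC",
}

# per-class planting probability for each motif
DEFAULT_MOTIF_RATES: dict[str, dict[str, float]] = {
    "CRX_K50": {"shared_PR": 0.6, "rod_specific": 0.5, "cone_specific": 0.5},
    "CTCF": {"shared_PR": 0.4, "non_PR": 0.5},
    "MAF": {"rod_specific": 0.8, "shared_PR": 0.1},
    "NR": {"rod_specific": 0.6, "shared_PR": 0.1},
    "Q50_HD": {"cone_specific": 0.8, "shared_PR": 0.1},
    "bHLH": {"cone_specific": 0.6, "shared_PR": 0.1},
    "MADS": {"shared_PR": 0.2},
}


@dataclass
class SimConfig:
    """Parameters of the synthetic study; defaults are the study conditions.

    Peak-class counts keep the published rod:cone specific-peak imbalance
    (~1:5-9) at desk scale; rod-closed domains are 0.5-1 Mb on a 10 Mb
    genome, preserving the windows-per-domain ratio of the Mb-scale domains
    seen in real rods.
    """

    genome_length: int = 10_000_000
    n_chromosomes: int = 2
    seed: int = 0
    n_replicates_per_group: int = 2
    peak_counts: dict[str, int] = field(
        default_factory=lambda: {
            "shared_PR": 1100,
            "rod_specific": 40,
            "cone_specific": 240,
            "non_PR": 220,
        }
    )
    closed_domain_spans: list[tuple[int, int]] = field(
        default_factory=lambda: [(1_000_000, 1), (500_000, 2)]
    )
    nb_mean_open: float = 100.0
    nb_mean_closed: float | None = None  # derived: nb_mean_open * 2**-lfc_planted
    nb_dispersion: float = 0.05
    peak_strength_sigma: float = 0.8  # lognormal spread of per-peak baseline
    group_effect_sigma: float = 0.1  # diffuse per-(group, peak) subtype effect
    lfc_planted: float = 2.0
    n_genes: int = 800
    domain_gene_density: float = 0.4  # gene density in domains vs open regions
    expr_coupling: float = 0.8
    expr_lfc: float = 2.0
    motif_plant_rates: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_MOTIF_RATES.items()}
    )
    cre_n_constructs: int = 400
    cre_repression_effect: float = 1.0
    cre_noise_sd: float = 1.0
    background_frag_per_bp: float = 1e-2  # ~500 fragments per 50 kb window
    domain_closure_factor: float = 0.1  # rod background rate inside domains
    cone_in_domain_fraction: float = 0.8
    repeat_fraction_of_genome: float = 0.05
    gc_content: float = 0.42
    dinucleotide_bias: float = 0.1  # CpG-depletion-like order-1 structure

    def __post_init__(self) -> None:
        if self.nb_mean_closed is None:
            self.nb_mean_closed = self.nb_mean_open * 2.0 ** (-self.lfc_planted)
        counts_ok = all(v >= 0 for v in self.peak_counts.values())
        if not counts_ok or self.n_genes < 0 or self.cre_n_constructs < 0:
            raise ValueError("all counts must be >= 0")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        for probs in (self.expr_coupling, self.cone_in_domain_fraction):
            if not 0 <= probs <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        unknown = set(self.peak_counts) - set(PEAK_CLASSES)
        if unknown:
            raise ValueError(f"unknown peak classes: {sorted(unknown)}")


@dataclass
class SimTruth:
    """Planted ground truth for every emitted peak, gene and construct."""

    peak_class_labels: dict[str, str]
    domain_intervals: list[GenomicInterval]
    gene_direction_labels: dict[str, str]  # rod_up / cone_up / null
    planted_motif_occurrences: dict[str, list[tuple[str, int, str]]]
    cre_kmer_labels: dict[str, list[str]]


@dataclass
class SimBundle:
    config: SimConfig
    chrom_sizes: dict[str, int]
    genome: dict[str, str]
    tss: list[GenomicInterval]
    repeats: list[GenomicInterval]
    peaks: list[GenomicInterval]  # master universe, all classes
    peak_calls: dict[str, list[GenomicInterval]]  # per sample group + non_PR set
    fragments: dict[str, list[Fragment]]  # per sample
    atac_counts: CountMatrix
    rna_counts: CountMatrix
    motif_library: list[Pwm]
    cre_constructs: list[CreConstruct]
    truth: SimTruth

    def write(self, outdir) -> None:
        """Write every artifact as plain text under ``outdir``."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(out / "genome.fa", self.genome)
        write_chrom_sizes(out / "chrom.sizes", self.chrom_sizes)
        write_bed(out / "tss.bed", self.tss)
        write_bed(out / "repeats.bed", self.repeats, columns=3)
        write_narrowpeak(out / "peaks_master.narrowPeak", self.peaks)
        for name, calls in self.peak_calls.items():
            write_narrowpeak(out / f"peaks_{name}.narrowPeak", calls)
        for sample, frags in self.fragments.items():
            write_fragments(out / f"fragments_{sample}.tsv", frags)
        self.atac_counts.counts.to_csv(out / "atac_counts.tsv", sep="\t")
        self.rna_counts.counts.to_csv(out / "rna_counts.tsv", sep="\t")
        write_motifs(out / "motifs.txt", self.motif_library)
        from .kmers import write_cre_table

        write_cre_table(out / "cre_constructs.tsv", self.cre_constructs)
        truth = {
            "peak_class_labels": self.truth.peak_class_labels,
            "domain_intervals": [
                [d.chrom, d.start, d.end] for d in self.truth.domain_intervals
            ],
            "gene_direction_labels": self.truth.gene_direction_labels,
            "planted_motif_occurrences": self.truth.planted_motif_occurrences,
            "cre_kmer_labels": {
                k: sorted(v) for k, v in self.truth.cre_kmer_labels.items()
            },
        }
        (out / "truth.json").write_text(json.dumps(truth, sort_keys=True, indent=1))


# ---------------------------------------------------------------------------
# Genome sequence: order-1 Markov chain
# ---------------------------------------------------------------------------


def _raw_transition_matrix(gc: float, bias: float) -> np.ndarray:
    at = (1 - gc) / 2
    base = np.array([at, gc / 2, gc / 2, at])
    trans = np.tile(base, (4, 1))
    # deplete G after C, enrich T after C (CpG -> TpG drift)
    trans[1, 2] *= 1 - bias * 4
    trans[1, 3] += base[2] * bias * 4
    trans /= trans.sum(axis=1, keepdims=True)
    return trans


def _transition_matrix(gc: float, bias: float) -> np.ndarray:
    """Order-1 transition probabilities with CpG-like depletion.

    The CpG adjustment perturbs the stationary composition, so the base
    row is calibrated by fixed-point iteration until the chain's
    stationary GC matches the requested value.
    """
    g = gc
    trans = _raw_transition_matrix(g, bias)
    for _ in range(40):
        pi = np.full(4, 0.25)
        for _ in range(60):
            pi = pi @ trans
        current = pi[1] + pi[2]
        g = float(np.clip(g + (gc - current), 0.02, 0.98))
        trans = _raw_transition_matrix(g, bias)
    return trans


def _markov_codes_python(u: np.ndarray, cum: np.ndarray, first: int) -> np.ndarray:
    out = np.empty(len(u), dtype=np.int8)
    state = first
    for i in range(len(u)):
        row = cum[state]
        x = u[i]
        state = 0 if x < row[0] else 1 if x < row[1] else 2 if x < row[2] else 3
        out[i] = state
    return out


try:  # numba gives a ~100x faster per-base loop when available
    from numba import njit

    _markov_codes_fast = njit(cache=False)(_markov_codes_python)
except Exception:  # pragma: no cover
    _markov_codes_fast = None


def markov_sequence(
    length: int, rng: np.random.Generator, gc: float = 0.42, bias: float = 0.1
) -> str:
    """Sample an order-1 Markov DNA sequence of the given length."""
    trans = _transition_matrix(gc, bias)
    cum = np.cumsum(trans, axis=1)
    first = int(rng.integers(0, 4))
    u = rng.random(length - 1)
    fn = _markov_codes_fast or _markov_codes_python
    codes = fn(u, cum, first)
    lookup = np.frombuffer("ACGT".encode(), dtype=np.uint8)
    arr = np.empty(length, dtype=np.uint8)
    arr[0] = lookup[first]
    arr[1:] = lookup[codes]
    return arr.tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# Planting
# ---------------------------------------------------------------------------


def plant_motif(sequence: str, pwm_or_kmer, offset: int, strand: str = "+") -> str:
    """Write a motif into a sequence at ``offset`` on the given strand.

    For a PWM the per-column consensus is written; for a k-mer string the
    literal. Strand '-' writes the reverse complement. Only the interval
    ``[offset, offset + width)`` changes.
    """
    word = pwm_or_kmer.consensus if isinstance(pwm_or_kmer, Pwm) else str(pwm_or_kmer)
    if offset < 0 or offset + len(word) > len(sequence):
        raise ValueError(
            f"motif of width {len(word)} at offset {offset} exceeds sequence "
            f"length {len(sequence)}"
        )
    if strand == "-":
        word = revcomp(word)
    return sequence[:offset] + word + sequence[offset + len(word) :]


def _place_nonoverlapping(
    rng: np.random.Generator,
    n: int,
    regions: list[tuple[str, int, int]],
    width: int,
    occupied: dict[str, list[tuple[int, int]]],
    min_gap: int = 100,
    max_tries_per_item: int = 200,
    what: str = "peaks",
) -> list[tuple[str, int]]:
    """Place ``n`` width-bp items uniformly inside ``regions`` without overlap."""
    if n == 0:
        return []
    weights = np.array([r[2] - r[1] for r in regions], dtype=float)
    if weights.sum() < n * (width + min_gap) * 2:
        raise ValueError(
            f"genome too short to host {n} {what} of {width} bp: only "
            f"{int(weights.sum())} bp of eligible sequence"
        )
    placed: list[tuple[str, int]] = []
    for _ in range(n):
        for attempt in range(max_tries_per_item):
            ri = int(rng.choice(len(regions), p=weights / weights.sum()))
            chrom, lo, hi = regions[ri]
            if hi - lo < width:
                continue
            start = int(rng.integers(lo, hi - width + 1))
            clashes = any(
                start < e + min_gap and s - min_gap < start + width
                for s, e in occupied.get(chrom, [])
            )
            if not clashes:
                occupied.setdefault(chrom, []).append((start, start + width))
                placed.append((chrom, start))
                break
        else:
            raise ValueError(
                f"could not place {n} {what}: placement saturated after "
                f"{len(placed)} items (binding constraint: eligible span "
                f"{int(weights.sum())} bp, width {width} bp, gap {min_gap} bp)"
            )
    return placed


def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float, size=None):
    """NB draw parameterised by mean and dispersion (Var = mu + a mu^2)."""
    if mean <= 0:
        return np.zeros(size or 1, dtype=int) if size else 0
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)


# ---------------------------------------------------------------------------
# Main generator
# ---------------------------------------------------------------------------


def simulate_dataset(config: SimConfig) -> SimBundle:
    """Generate the full synthetic study bundle (see module docstring)."""
    rng = np.random.default_rng(config.seed)

    # --- chromosomes -------------------------------------------------------
    chrom_len = config.genome_length // config.n_chromosomes
    chrom_sizes = {f"chr{i + 1}": chrom_len for i in range(config.n_chromosomes)}

    # --- rod-closed domains ------------------------------------------------
    domains: list[GenomicInterval] = []
    occupied_domains: dict[str, list[tuple[int, int]]] = {}
    for span, count in config.closed_domain_spans:
        if span > chrom_len:
            raise ValueError(
                f"closed domain of {span} bp exceeds chromosome length "
                f"{chrom_len} bp (binding constraint: genome_length / "
                f"n_chromosomes)"
            )
        for _ in range(count):
            for attempt in range(200):
                chrom = f"chr{int(rng.integers(0, config.n_chromosomes)) + 1}"
                start = int(rng.integers(0, chrom_len - span + 1))
                if not any(
                    start < e and s < start + span
                    for s, e in occupied_domains.get(chrom, [])
                ):
                    occupied_domains.setdefault(chrom, []).append(
                        (start, start + span)
                    )
                    domains.append(
                        GenomicInterval(chrom, start, start + span, name="domain")
                    )
                    break
            else:
                raise ValueError(
                    f"could not place closed domain of {span} bp: genome too "
                    "crowded (binding constraint: closed_domain_spans vs "
                    "genome_length)"
                )

    domain_regions = [(d.chrom, d.start, d.end) for d in domains]
    open_regions: list[tuple[str, int, int]] = []
    for chrom, size in chrom_sizes.items():
        edges = sorted(
            [(d.start, d.end) for d in domains if d.chrom == chrom]
        )
        prev = 0
        for s, e in edges:
            if s > prev:
                open_regions.append((chrom, prev, s))
            prev = e
        if prev < size:
            open_regions.append((chrom, prev, size))

    # --- peaks --------------------------------------------------------------
    occupied: dict[str, list[tuple[int, int]]] = {}
    peak_specs: list[tuple[str, str, int]] = []  # (class, chrom, start)
    n_cone = config.peak_counts.get("cone_specific", 0)
    n_cone_in = int(round(n_cone * config.cone_in_domain_fraction)) if domains else 0
    for cls, n in config.peak_counts.items():
        if cls == "cone_specific":
            inside = _place_nonoverlapping(
                rng, n_cone_in, domain_regions, PEAK_WIDTH, occupied,
                what="cone-specific peaks (in-domain)",
            ) if n_cone_in else []
            outside = _place_nonoverlapping(
                rng, n - n_cone_in, open_regions, PEAK_WIDTH, occupied,
                what="cone-specific peaks",
            )
            for chrom, start in inside + outside:
                peak_specs.append((cls, chrom, start))
        else:
            for chrom, start in _place_nonoverlapping(
                rng, n, open_regions, PEAK_WIDTH, occupied, what=f"{cls} peaks"
            ):
                peak_specs.append((cls, chrom, start))

    order = sorted(range(len(peak_specs)), key=lambda i: (peak_specs[i][1], peak_specs[i][2]))
    peaks: list[GenomicInterval] = []
    peak_class_labels: dict[str, str] = {}
    for rank, i in enumerate(order):
        cls, chrom, start = peak_specs[i]
        name = f"peak_{rank:05d}"
        peaks.append(
            GenomicInterval(
                chrom, start, start + PEAK_WIDTH, ".", name,
                summit=start + PEAK_WIDTH // 2,
            )
        )
        peak_class_labels[name] = cls

    # --- genes (TSSs), depleted but not absent inside closed domains -------
    open_bp = sum(hi - lo for _, lo, hi in open_regions)
    domain_bp = sum(hi - lo for _, lo, hi in domain_regions)
    w_domain = config.domain_gene_density * domain_bp
    n_domain_genes = (
        int(round(config.n_genes * w_domain / (open_bp + w_domain)))
        if domain_bp
        else 0
    )
    tss: list[GenomicInterval] = []
    gene_occupied: dict[str, list[tuple[int, int]]] = {}
    placements = _place_nonoverlapping(
        rng, config.n_genes - n_domain_genes, open_regions, 1, gene_occupied,
        min_gap=500, what="genes",
    )
    if n_domain_genes:
        placements += _place_nonoverlapping(
            rng, n_domain_genes, domain_regions, 1, gene_occupied,
            min_gap=500, what="genes (in-domain)",
        )
    for chrom, start in placements:
        gid = f"gene_{len(tss):05d}"
        strand = "+" if rng.random() < 0.5 else "-"
        tss.append(GenomicInterval(chrom, start, start + 1, strand, gid))
    tss.sort(key=lambda t: (t.chrom, t.start, t.name))
    tss = [
        GenomicInterval(t.chrom, t.start, t.end, t.strand, f"gene_{i:05d}")
        for i, t in enumerate(tss)
    ]

    # --- repeats ------------------------------------------------------------
    repeats: list[GenomicInterval] = []
    target_bp = config.repeat_fraction_of_genome * config.genome_length
    acc = 0
    while acc < target_bp:
        chrom = f"chr{int(rng.integers(0, config.n_chromosomes)) + 1}"
        length = int(rng.integers(200, 2000))
        start = int(rng.integers(0, chrom_len - length))
        repeats.append(GenomicInterval(chrom, start, start + length, name="repeat"))
        acc += length
    repeats.sort(key=lambda r: (r.chrom, r.start))

    # --- genome sequence and motif planting --------------------------------
    garr = {
        chrom: bytearray(
            markov_sequence(
                size, rng, config.gc_content, config.dinucleotide_bias
            ).encode()
        )
        for chrom, size in chrom_sizes.items()
    }
    motif_library = [
        consensus_pwm(name, cons) for name, cons in DEFAULT_MOTIF_CONSENSI.items()
    ]
    pwm_by_name = {m.name: m for m in motif_library}
    planted: dict[str, list[tuple[str, int, str]]] = {}
    for p in peaks:
        cls = peak_class_labels[p.name]
        seq = garr[p.chrom][p.start : p.end].decode()
        used: list[tuple[int, int]] = []
        occs: list[tuple[str, int, str]] = []
        for motif_name, rates in config.motif_plant_rates.items():
            rate = rates.get(cls, 0.0)
            if rate <= 0 or rng.random() >= rate:
                continue
            pwm = pwm_by_name[motif_name]
            w = pwm.width
            for attempt in range(20):
                center = PEAK_WIDTH // 2 + rng.normal(0, 30)
                off = int(np.clip(round(center - w / 2), 0, PEAK_WIDTH - w))
                if not any(off < e and s < off + w for s, e in used):
                    strand = "+" if rng.random() < 0.5 else "-"
                    seq = plant_motif(seq, pwm, off, strand)
                    used.append((off, off + w))
                    occs.append((motif_name, off, strand))
                    break
        if occs:
            planted[p.name] = occs
            garr[p.chrom][p.start : p.end] = seq.encode()
    genome = {chrom: arr.decode() for chrom, arr in garr.items()}

    # --- fragments and ATAC counts ------------------------------------------
    samples = [
        f"{g}_{r + 1}" for g in GROUPS for r in range(config.n_replicates_per_group)
    ]
    closed_mean = config.nb_mean_closed
    # per-peak baseline strength, shared across samples so replicates agree
    # on the peak ranking (fold changes are unaffected: strength cancels)
    strength = {
        p.name: float(s)
        for p, s in zip(
            peaks,
            np.exp(rng.normal(0, config.peak_strength_sigma, len(peaks))),
        )
    }
    # small diffuse subtype effect, shared by replicates of a group, so
    # biological replicates rank closer to each other than to other groups
    group_factor = {
        g: np.exp(rng.normal(0, config.group_effect_sigma, len(peaks)))
        for g in GROUPS
    }
    peak_index = {p.name: i for i, p in enumerate(peaks)}

    def peak_mean(cls: str, group: str) -> float:
        if cls == "shared_PR" or cls == "non_PR":
            return config.nb_mean_open
        if cls == "rod_specific":
            return config.nb_mean_open if group == "rod" else closed_mean
        if cls == "cone_specific":
            return closed_mean if group == "rod" else config.nb_mean_open
        raise ValueError(cls)

    fragments: dict[str, list[Fragment]] = {}
    for sample in samples:
        group = sample.rsplit("_", 1)[0]
        frags: list[Fragment] = []
        for p in peaks:
            mean = (
                strength[p.name]
                * group_factor[group][peak_index[p.name]]
                * peak_mean(peak_class_labels[p.name], group)
            )
            k = int(_nb_draw(rng, mean, config.nb_dispersion))
            if k:
                mids = np.clip(
                    np.round(p.summit + rng.normal(0, 30, k)), p.start, p.end - 1
                ).astype(int)
                inserts = rng.integers(40, 101, k)
                starts = np.maximum(mids - inserts // 2, 0)
                frags.extend(
                    Fragment(p.chrom, int(s), int(s + i))
                    for s, i in zip(starts, inserts)
                )
            k2 = int(rng.poisson(0.3 * k))
            if k2:  # nucleosomal inserts, removed by the NFR filter
                mids = np.clip(
                    np.round(p.summit + rng.normal(0, 60, k2)), p.start, p.end - 1
                ).astype(int)
                inserts = np.maximum(
                    np.round(rng.normal(200, 20, k2)).astype(int), 150
                )
                starts = np.maximum(mids - inserts // 2, 0)
                frags.extend(
                    Fragment(p.chrom, int(s), int(s + i))
                    for s, i in zip(starts, inserts)
                )
        # genomic background, depleted in closed domains for rods
        segs = [(c, lo, hi, False) for c, lo, hi in open_regions] + [
            (c, lo, hi, True) for c, lo, hi in domain_regions
        ]
        for chrom, lo, hi, is_domain in segs:
            rate = config.background_frag_per_bp
            if is_domain and group == "rod":
                rate *= config.domain_closure_factor
            nbg = int(rng.poisson(rate * (hi - lo)))
            if not nbg:
                continue
            mids = rng.integers(lo, hi, nbg)
            inserts = rng.integers(40, 101, nbg)
            starts = np.maximum(mids - inserts // 2, 0)
            ends = np.minimum(starts + inserts, chrom_sizes[chrom])
            frags.extend(
                Fragment(chrom, int(s), int(e))
                for s, e in zip(starts, ends)
                if e > s
            )
        fragments[sample] = frags

    atac_counts = counts_from_fragments(peaks, fragments)
    atac_groups = {s: s.rsplit("_", 1)[0] for s in samples}
    atac_cm = CountMatrix(atac_counts, atac_groups)

    # --- gene expression coupled to differential peaks -----------------------
    assignment = nearest_tss(peaks, tss)
    gene_direction: dict[str, str] = {t.name: "null" for t in tss}
    for p in peaks:
        cls = peak_class_labels[p.name]
        if cls not in ("rod_specific", "cone_specific"):
            continue
        gene, _dist = assignment[p.name]
        if gene is None or gene_direction[gene] != "null":
            continue
        concordant = "rod_up" if cls == "rod_specific" else "cone_up"
        discordant = "cone_up" if cls == "rod_specific" else "rod_up"
        gene_direction[gene] = (
            concordant if rng.random() < config.expr_coupling else discordant
        )

    rna_samples = [
        f"{g}_{r + 1}"
        for g in ("rod", "blue_cone")
        for r in range(config.n_replicates_per_group)
    ]
    base = rng.lognormal(np.log(200), 1.0, len(tss))
    rna = {}
    for sample in rna_samples:
        group = sample.rsplit("_", 1)[0]
        means = base.copy()
        for gi, t in enumerate(tss):
            d = gene_direction[t.name]
            if d == "rod_up":
                means[gi] *= 2 ** (config.expr_lfc / 2 * (1 if group == "rod" else -1))
            elif d == "cone_up":
                means[gi] *= 2 ** (config.expr_lfc / 2 * (-1 if group == "rod" else 1))
        rna[sample] = np.array(
            [int(_nb_draw(rng, m, config.nb_dispersion)) for m in means]
        )
    rna_counts = pd.DataFrame(rna, index=[t.name for t in tss])
    rna_cm = CountMatrix(rna_counts, {s: s.rsplit("_", 1)[0] for s in rna_samples})

    # --- per-group peak calls ------------------------------------------------
    by_class = {
        cls: [p for p in peaks if peak_class_labels[p.name] == cls]
        for cls in PEAK_CLASSES
    }
    peak_calls = {
        "rod": sorted(
            by_class["shared_PR"] + by_class["rod_specific"] + by_class["non_PR"],
            key=lambda p: (p.chrom, p.start),
        ),
        "green_cone": sorted(
            by_class["shared_PR"] + by_class["cone_specific"] + by_class["non_PR"],
            key=lambda p: (p.chrom, p.start),
        ),
        "blue_cone": sorted(
            by_class["shared_PR"] + by_class["cone_specific"] + by_class["non_PR"],
            key=lambda p: (p.chrom, p.start),
        ),
        "non_photoreceptor": sorted(
            by_class["non_PR"], key=lambda p: (p.chrom, p.start)
        ),
    }

    # --- CRE-seq library ------------------------------------------------------
    scheme = DimerKmerScheme()
    constructs: list[CreConstruct] = []
    cre_labels: dict[str, list[str]] = {}
    n = config.cre_n_constructs
    for i in range(n):
        seq = "".join(BASES[j] for j in rng.integers(0, 4, 84))
        crx_off = int(rng.integers(0, 84 - 7))
        seq = plant_motif(seq, "CTAATCC", crx_off, "+")
        if i < n // 2:  # plant the homotypic TAAT dimer away from the CRX site
            for attempt in range(50):
                off = int(rng.integers(0, 84 - 11))
                if off + 11 <= crx_off or off >= crx_off + 7:
                    spacer = "".join(BASES[j] for j in rng.integers(0, 4, 3))
                    seq = plant_motif(seq, "TAAT" + spacer + "ATTA", off, "+")
                    break
        native_classes = present_classes(seq, scheme)
        expr = float(rng.normal(0, config.cre_noise_sd))
        if "homotypic_TAAT" in native_classes:
            expr -= config.cre_repression_effect
        cid = f"cre_{i:04d}_native"
        constructs.append(CreConstruct(cid, seq, "native", expr))
        cre_labels[cid] = sorted(native_classes)

        mut_seq = mutate_crx_sites(seq)
        mid = f"cre_{i:04d}_mut"
        mut_expr = float(rng.normal(0, config.cre_noise_sd))
        constructs.append(CreConstruct(mid, mut_seq, "crx_mutant", mut_expr))
        cre_labels[mid] = sorted(present_classes(mut_seq, scheme))

        if i % 4 == 0:
            scr = "".join(
                np.array(list(seq))[rng.permutation(84)]
            )
            sid = f"cre_{i:04d}_scr"
            constructs.append(
                CreConstruct(sid, scr, "scrambled", float(rng.normal(0, config.cre_noise_sd)))
            )
            cre_labels[sid] = sorted(present_classes(scr, scheme))

    truth = SimTruth(
        peak_class_labels=peak_class_labels,
        domain_intervals=domains,
        gene_direction_labels=gene_direction,
        planted_motif_occurrences=planted,
        cre_kmer_labels=cre_labels,
    )
    return SimBundle(
        config=config,
        chrom_sizes=chrom_sizes,
        genome=genome,
        tss=tss,
        repeats=repeats,
        peaks=peaks,
        peak_calls=peak_calls,
        fragments=fragments,
        atac_counts=atac_cm,
        rna_counts=rna_cm,
        motif_library=motif_library,
        cre_constructs=constructs,
        truth=truth,
    )


def counts_from_fragments(
    peaks: Sequence[GenomicInterval],
    fragments: dict[str, list[Fragment]],
    max_insert: int = 100,
) -> pd.DataFrame:
    """Count NFR fragment midpoints per peak per sample (peaks x samples)."""
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    names = [p.name for p in peaks]
    name_index = {n: i for i, n in enumerate(names)}
    for chrom in {p.chrom for p in peaks}:
        ps = sorted((p for p in peaks if p.chrom == chrom), key=lambda p: p.start)
        by_chrom[chrom] = (
            np.array([p.start for p in ps]),
            np.array([p.end for p in ps]),
            np.array([name_index[p.name] for p in ps]),
        )
    data = {}
    for sample, frags in fragments.items():
        counts = np.zeros(len(names), dtype=int)
        kept = filter_nfr(frags, max_insert)
        mids_by_chrom: dict[str, list[int]] = {}
        for f in kept:
            mids_by_chrom.setdefault(f.chrom, []).append(f.midpoint)
        for chrom, mids in mids_by_chrom.items():
            entry = by_chrom.get(chrom)
            if entry is None:
                continue
            starts, ends, idx = entry
            m = np.asarray(mids)
            i = np.searchsorted(starts, m, side="right") - 1
            ok = (i >= 0) & (m < ends[np.maximum(i, 0)])
            hit = np.bincount(i[ok], minlength=len(starts))
            counts[idx] += hit
        data[sample] = counts
    return pd.DataFrame(data, index=names)


# ---------------------------------------------------------------------------
# Count-only generators for calibration studies
# ---------------------------------------------------------------------------


def simulate_null_counts(
    n_features: int,
    n_per_group: int = 2,
    mean: float = 100.0,
    dispersion: float = 0.05,
    seed: int = 0,
) -> CountMatrix:
    """NB counts with no planted effect: both groups share one mean."""
    rng = np.random.default_rng(seed)
    samples = [f"a_{i}" for i in range(n_per_group)] + [
        f"b_{i}" for i in range(n_per_group)
    ]
    counts = pd.DataFrame(
        {
            s: _nb_draw(rng, mean, dispersion, size=n_features)
            for s in samples
        },
        index=[f"f_{i}" for i in range(n_features)],
    )
    groups = {s: s.split("_")[0] for s in samples}
    return CountMatrix(counts, groups)


def simulate_planted_counts(
    n_features: int,
    n_planted: int,
    lfc: float = 3.0,
    n_per_group: int = 2,
    mean: float = 100.0,
    dispersion: float = 0.05,
    seed: int = 0,
) -> tuple[CountMatrix, np.ndarray]:
    """NB counts with the first ``n_planted`` features shifted by ``lfc``
    (group a up). Returns the matrix and the boolean planted mask."""
    rng = np.random.default_rng(seed)
    mask = np.zeros(n_features, dtype=bool)
    mask[:n_planted] = True
    mean_a = np.where(mask, mean * 2**lfc, mean)
    mean_b = np.full(n_features, mean)
    data = {}
    for i in range(n_per_group):
        data[f"a_{i}"] = np.array(
            [int(_nb_draw(rng, m, dispersion)) for m in mean_a]
        )
    for i in range(n_per_group):
        data[f"b_{i}"] = np.array(
            [int(_nb_draw(rng, m, dispersion)) for m in mean_b]
        )
    counts = pd.DataFrame(data, index=[f"f_{i}" for i in range(n_features)])
    groups = {s: s.split("_")[0] for s in counts.columns}
    return CountMatrix(counts, groups), mask
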