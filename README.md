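# photoclose

Comparative open-chromatin analysis of rod and cone photoreceptors, built
as a tested, reusable pipeline and exercised end to end on synthetic data
with planted ground truth.

Mouse rods are unusual: their nuclei are inverted (heterochromatin at the
center) and their chromatin landscape is globally more closed than that
of cones and dozens of other cell types, with megabase-scale runs of
regulatory elements selectively shut down. This package implements the
statistical machinery such a study needs, for analysts who have peak
calls, fragment tables and count matrices and want the comparative
layer on top:

- **Peak atlas** — merge per-cell-type peak calls into a master list of
  200 bp summit-centered elements, assign nearest TSSs, partition
  promoters (−1 kb < d < +100 bp, strand-aware) from enhancers, classify
  rod/cone specificity, and run the filter cascade (promoters out,
  non-photoreceptor elements out, >70 % repeat overlap out).
- **Differential accessibility/expression** — median-of-ratios size
  factors (s_j = median_i K_ij / (∏_j K_ij)^{1/n}) and a simplified
  negative-binomial test: LFC = log2(μ̂_A/μ̂_B) with pseudocount 0.5,
  method-of-moments dispersion shrunk to a mean-dispersion trend,
  delta-method SE, BH-adjusted q-values, calls at |LFC| > 1 with
  FDR 0.1 (accessibility) or 0.05 (expression).
- **Global closure statistic** — normalised fragment coverage in fixed
  50 kb windows, its ECDF F(x) = #(windows ≤ x)/n, and a lower-tail
  area-between-ECDFs summary whose positive sign means "more closed".
- **Motif grammar** — natural-log-odds PWM scanning, composition-matched
  genomic background, known-motif enrichment, redundancy collapse by
  aligned Pearson correlation (PCC > 0.6), pairwise co-occurrence
  enrichment log2(O_ij/E_ij) with E_ij = n_i·n_j/N, and strand-resolved
  spacing profiles.
- **Homeodomain dimer k-mers** — exact-match scanning for TAAT/TAAG
  cores and inverted dimer configurations (TAAT[N]₃ATTA, TAAG[N]₃CTTA,
  TAAT[N]₃CTTA), CRX-site point mutation (CTAATCC→CTACTCC), and
  Wilcoxon stratification of reporter (CRE-seq) expression.
- **Integration** — peak–gene concordance quadrants among
  doubly-significant pairs, the sign-agreement fraction, and Spearman/
  UPGMA sample relatedness.
- **Synthetic data** — a fully parameterised generator that plants all
  of the above structure (closed domains, peak classes, NB counts,
  motifs, coupled expression, repressive dimers) with a machine-readable
  truth record, so every stage is testable offline.

## Worked example

The numbered scripts under `analysis/` run the study on synthetic data
(seed 1) and write their tables under `results/`. For example:

```bash
python analysis/04_global_closure.py
```

prints, among all sample pairs, the rod row of the closure analysis:

```
 sample    reference  area_x1e4  dominance
  rod_1        rod_2      0.064      0.658
  rod_1 green_cone_1      4.126      0.332
  rod_1 green_cone_2      4.119      0.332
  rod_1  blue_cone_1      3.946      0.312
  rod_1  blue_cone_2      3.841      0.314
rod_1 lower-tail area is positive against every non-rod sample: True
```

The positive lower-tail area against every cone sample (and ~0 against
the other rod replicate) is the package's scalar rendering of the
left-shifted rod ECDF: rods have more low-coverage 50 kb windows — a
globally more closed landscape. Likewise `analysis/06_reporter_kmers.py`
prints

```
homotypic TAAT dimer, native: median shift -1.19, p = 5.6e-25;
CRX-mutant controls: p = 0.071
```

— the planted repressive effect of the TAAT[N]₃ATTA configuration is
detected in native constructs and vanishes when CRX sites are mutated,
while no other k-mer class reaches significance.

A YAML-configured run of the whole pipeline:

```bash
photoclose run --config run.yaml        # stages: atlas → differential →
                                        # closure → motifs → creseq → integration
photoclose simulate --seed 1 --out scratch/simdata
```

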