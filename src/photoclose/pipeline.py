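"""End-to-end pipeline driver: simulate (or load) inputs, then run the
atlas, differential, closure, motif, reporter and integration stages in
dependency order, writing plain-text tables under a run directory.

Every run writes a manifest carrying the configuration hash and package
version, and logs per-stage element counts (the filter-cascade ledger).
Identical configuration and seed give byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atlas import (
    atlas_to_frame,
    build_atlas,
    classify_specificity,
    partition_promoter_enhancer,
)
from .closure import closure_shift, ecdf, window_coverage
from .differential import CountMatrix, nb_diff_test
from .integrate import (
    directional_correlation,
    link_peaks_to_expression,
    sample_relatedness,
)
from .intervals import filter_nfr, merge_peak_sets, recenter_on_summit
from .kmers import DimerKmerScheme, classify_constructs, stratify_expression
from .motifs import hit_presence, cooccurrence, motif_enrichment, sample_matched_background
from .simulate import SimConfig, SimBundle, counts_from_fragments, simulate_dataset

logger = logging.getLogger(__name__)

ALL_STAGES = ("atlas", "differential", "closure", "motifs", "creseq", "integration")


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("pipeline config must be a mapping")
    return cfg


def config_hash(cfg: dict) -> str:
    """Hash of the scientific configuration (output location excluded)."""
    payload = {k: v for k, v in cfg.items() if k != "outdir"}
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def peak_sequences(bundle: SimBundle, names, elements=None) -> dict[str, str]:
    """200 bp element sequences from the bundle genome, by element name."""
    lookup = {p.name: p for p in bundle.peaks}
    if elements is not None:
        lookup.update({e.name: e.interval for e in elements})
    out = {}
    for n in names:
        iv = lookup[n]
        out[n] = bundle.genome[iv.chrom][iv.start : iv.end]
    return out


def run_pipeline(config: dict | str | Path, outdir: str | Path | None = None) -> dict:
    """Run the configured stages; returns a dict of in-memory results."""
    if not isinstance(config, dict):
        config = load_config(config)
    cfg = dict(config)
    stages = cfg.get("stages", list(ALL_STAGES))
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages requested: {sorted(unknown)}")
    outdir = Path(outdir or cfg.get("outdir", "photoclose_run"))
    outdir.mkdir(parents=True, exist_ok=True)

    sim_kwargs = dict(cfg.get("simulate", {}))
    if "seed" in cfg:
        sim_kwargs.setdefault("seed", cfg["seed"])
    sim_config = SimConfig(**sim_kwargs)
    bundle = simulate_dataset(sim_config)
    results: dict = {"bundle": bundle}

    if any(s in stages for s in ("motifs",)) and not bundle.genome:
        raise ValueError("stage 'motifs' requires a genome FASTA")

    # --- atlas -------------------------------------------------------------
    elements = None
    if "atlas" in stages:
        calls = {g: bundle.peak_calls[g] for g in ("rod", "green_cone", "blue_cone")}
        if cfg.get("recenter_sources", True):
            calls = {
                g: recenter_on_summit(v, 200, bundle.chrom_sizes)
                for g, v in calls.items()
            }
        merged = merge_peak_sets(list(calls.values()), list(calls))
        elements = build_atlas(merged, bundle.tss, bundle.repeats)
        partition_promoter_enhancer(elements)
        logger.info("atlas: %d elements", len(elements))
        results["elements"] = elements

    # --- differential ------------------------------------------------------
    if "differential" in stages:
        if elements is None:
            raise ValueError("stage 'differential' requires stage 'atlas'")
        ivs = [e.interval for e in elements]
        counts = counts_from_fragments(ivs, bundle.fragments)
        collapsed = {
            s: ("rod" if g == "rod" else "cone")
            for s, g in bundle.atac_counts.groups.items()
        }
        cm = CountMatrix(counts, collapsed)
        atac_diff = nb_diff_test(
            cm, "rod", "cone",
            lfc_threshold=cfg.get("atac_lfc", 1.0), fdr=cfg.get("atac_fdr", 0.1),
        )
        rna_diff = nb_diff_test(
            bundle.rna_counts, "rod", "blue_cone",
            lfc_threshold=cfg.get("rna_lfc", 1.0), fdr=cfg.get("rna_fdr", 0.05),
        )
        _, cascade = classify_specificity(
            elements, atac_diff,
            {"non_photoreceptor": bundle.peak_calls["non_photoreceptor"]},
        )
        for stage_name, tally in cascade.stage_counts.items():
            logger.info("cascade %s: %s", stage_name, tally)
        atlas_to_frame(elements).to_csv(outdir / "atlas.tsv", sep="\t")
        atac_diff.to_csv(outdir / "atac_differential.tsv", sep="\t")
        rna_diff.to_csv(outdir / "rna_differential.tsv", sep="\t")
        cascade.to_frame().to_csv(outdir / "filter_cascade.tsv", sep="\t")
        results.update(
            atac_diff=atac_diff, rna_diff=rna_diff, cascade=cascade, atac_cm=cm
        )

    # --- closure -----------------------------------------------------------
    if "closure" in stages:
        window = int(cfg.get("closure_window", 50000))
        ecdfs = {}
        for sample, frags in bundle.fragments.items():
            cov = window_coverage(
                filter_nfr(frags), bundle.chrom_sizes, window, sample
            )
            ecdfs[sample] = ecdf(cov.windows["normalized"].to_numpy())
        rod_sample = next(s for s in ecdfs if s.startswith("rod"))
        shifts = closure_shift(
            ecdfs[rod_sample], {k: v for k, v in ecdfs.items() if k != rod_sample}
        )
        pd.DataFrame(
            [
                {"sample": rod_sample, "reference": s.reference_id,
                 "area": s.area, "dominance": s.dominance}
                for s in shifts
            ]
        ).to_csv(outdir / "closure_shift.tsv", sep="\t", index=False)
        results.update(ecdfs=ecdfs, shifts=shifts)

    # --- motifs ------------------------------------------------------------
    if "motifs" in stages:
        if "differential" not in stages:
            raise ValueError("stage 'motifs' requires stage 'differential'")
        rng = np.random.default_rng(sim_config.seed + 1)
        by_spec: dict[str, list] = {}
        for e in elements:
            by_spec.setdefault(e.specificity, []).append(e)
        enrich_tables = {}
        for spec in ("rod_specific", "cone_specific"):
            els = by_spec.get(spec, [])
            if not els:
                continue
            targets = peak_sequences(bundle, [], els)
            targets = {
                e.name: bundle.genome[e.interval.chrom][
                    e.interval.start : e.interval.end
                ]
                for e in els
            }
            bg, _meta = sample_matched_background(
                bundle.genome, list(targets.values()),
                n=min(2000, 10 * len(targets)), length=200, rng=rng,
            )
            bg_map = {f"bg_{i}": s for i, s in enumerate(bg)}
            table = motif_enrichment(
                targets, bg_map, bundle.motif_library,
                threshold=cfg.get("motif_threshold", 5.0),
            )
            table.to_csv(outdir / f"motif_enrichment_{spec}.tsv", sep="\t", index=False)
            enrich_tables[spec] = table
        shared = by_spec.get("shared_PR", [])
        presence = hit_presence(
            {
                e.name: bundle.genome[e.interval.chrom][
                    e.interval.start : e.interval.end
                ]
                for e in shared
            },
            bundle.motif_library,
            threshold=cfg.get("motif_threshold", 5.0),
        )
        cooc = cooccurrence(presence)
        cooc.to_frame().to_csv(outdir / "motif_cooccurrence.tsv", sep="\t")
        results.update(enrichment=enrich_tables, cooccurrence=cooc)

    # --- creseq ------------------------------------------------------------
    if "creseq" in stages:
        scheme = DimerKmerScheme()
        table = classify_constructs(bundle.cre_constructs, scheme)
        table.to_csv(outdir / "cre_classes.tsv", sep="\t", index=False)
        strat_rows = []
        for cls in scheme.class_names:
            for variant in ("native", "crx_mutant"):
                try:
                    r = stratify_expression(
                        bundle.cre_constructs, cls, variant, scheme
                    )
                except ValueError:
                    continue
                strat_rows.append(
                    {
                        "class": cls, "variant": variant,
                        "n_with": r.n_with, "n_without": r.n_without,
                        "median_difference": r.median_difference,
                        "p_value": r.p_value,
                    }
                )
        strat = pd.DataFrame(strat_rows)
        strat.to_csv(outdir / "cre_stratification.tsv", sep="\t", index=False)
        results["cre_stratification"] = strat

    # --- integration -------------------------------------------------------
    if "integration" in stages:
        if "differential" not in stages:
            raise ValueError("stage 'integration' requires stage 'differential'")
        links = link_peaks_to_expression(
            elements, results["atac_diff"], results["rna_diff"],
            fdr_atac=cfg.get("link_fdr_atac", 0.1),
            fdr_rna=cfg.get("link_fdr_rna", 0.1),
        )
        summary = directional_correlation(links)
        links.to_csv(outdir / "peak_gene_links.tsv", sep="\t")
        rel = sample_relatedness(results["atac_cm"].counts)
        rel.rho.to_csv(outdir / "sample_relatedness.tsv", sep="\t")
        with open(outdir / "directional_summary.json", "w") as fh:
            json.dump(
                {
                    "counts": summary.counts,
                    "sign_agreement": summary.sign_agreement,
                    "ci": [summary.ci_low, summary.ci_high],
                },
                fh, indent=1, sort_keys=True,
            )
        results.update(links=links, directional=summary, relatedness=rel)

    manifest = {
        "version": __version__,
        "config_hash": config_hash(cfg),
        "stages": list(stages),
        "seed": sim_config.seed,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return results
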