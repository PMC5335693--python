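"""Integration of chromatin accessibility with gene expression, and
sample-relatedness summaries.

Peaks are linked to their nearest gene and classified into concordance
quadrants when both the accessibility and the expression change are
significant: concordant_rod (more open and higher expressed in rods),
concordant_cone, or discordant. Sample relatedness is the pairwise
Spearman correlation over shared-atlas counts, clustered by average
linkage on 1 - rho.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.proportion import proportion_confint

from .atlas import AtlasElement

logger = logging.getLogger(__name__)

CONCORDANCE_CLASSES = ("concordant_rod", "concordant_cone", "discordant", "ns")


def link_peaks_to_expression(
    elements: list[AtlasElement],
    atac_diff: pd.DataFrame,
    rna_diff: pd.DataFrame,
    fdr_atac: float = 0.1,
    fdr_rna: float = 0.1,
) -> pd.DataFrame:
    """Build the peak-gene concordance table.

    Both differential tables must use rods as group A (positive LFC = more
    open / higher expressed in rods). A peak whose nearest gene is missing
    from ``rna_diff`` is classed ns and logged.
    """
    rows = []
    for el in elements:
        a = atac_diff.loc[el.name]
        gene = el.nearest_gene
        if gene is None or gene not in rna_diff.index:
            if gene is not None:
                logger.warning("gene %s absent from rna_diff; peak %s -> ns", gene, el.name)
            rows.append(
                {
                    "peak": el.name,
                    "gene": gene,
                    "tss_distance": el.tss_distance,
                    "atac_lfc": a["log2_fold_change"],
                    "atac_q": a["q_value"],
                    "rna_lfc": np.nan,
                    "rna_q": np.nan,
                    "concordance": "ns",
                }
            )
            continue
        r = rna_diff.loc[gene]
        if a["q_value"] < fdr_atac and r["q_value"] < fdr_rna:
            same_sign = np.sign(a["log2_fold_change"]) == np.sign(r["log2_fold_change"])
            if same_sign:
                cls = (
                    "concordant_rod"
                    if a["log2_fold_change"] > 0
                    else "concordant_cone"
                )
            else:
                cls = "discordant"
        else:
            cls = "ns"
        rows.append(
            {
                "peak": el.name,
                "gene": gene,
                "tss_distance": el.tss_distance,
                "atac_lfc": a["log2_fold_change"],
                "atac_q": a["q_value"],
                "rna_lfc": r["log2_fold_change"],
                "rna_q": r["q_value"],
                "concordance": cls,
            }
        )
    return pd.DataFrame(rows).set_index("peak")


@dataclass
class DirectionalSummary:
    counts: dict[str, int]
    sign_agreement: float | None  # None when no doubly-significant links
    ci_low: float | None
    ci_high: float | None


def directional_correlation(links: pd.DataFrame) -> DirectionalSummary:
    """Counts per concordance class and the sign-agreement fraction
    (concordant / (concordant + discordant)) with a binomial interval."""
    counts = {c: int((links["concordance"] == c).sum()) for c in CONCORDANCE_CLASSES}
    concordant = counts["concordant_rod"] + counts["concordant_cone"]
    total = concordant + counts["discordant"]
    if total == 0:
        return DirectionalSummary(counts, None, None, None)
    lo, hi = proportion_confint(concordant, total, method="wilson")
    return DirectionalSummary(counts, concordant / total, float(lo), float(hi))


@dataclass
class RelatednessMatrix:
    sample_ids: list[str]
    rho: pd.DataFrame
    linkage: np.ndarray  # scipy linkage matrix, average on 1 - rho

    def mutual_nearest_neighbors(self) -> dict[str, str]:
        """Nearest other sample by rho for each sample."""
        out = {}
        for s in self.sample_ids:
            others = self.rho[s].drop(s)
            out[s] = others.idxmax()
        return out


def sample_relatedness(counts: pd.DataFrame) -> RelatednessMatrix:
    """Pairwise Spearman rho over per-feature counts; UPGMA tree on 1 - rho."""
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    constant = [c for c in counts.columns if counts[c].nunique() <= 1]
    if constant:
        raise ValueError(f"constant samples (Spearman undefined): {constant}")
    rho_arr, _ = stats.spearmanr(counts.to_numpy())
    rho_arr = np.atleast_2d(rho_arr)
    rho = pd.DataFrame(rho_arr, index=counts.columns, columns=counts.columns)
    dist = 1.0 - rho.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)
    link = hierarchy.average(squareform(dist, checks=False))
    return RelatednessMatrix(list(counts.columns), rho, link)
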