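"""Median-of-ratios normalisation and a simplified negative-binomial
differential test with Benjamini-Hochberg FDR control.

The same engine serves accessibility (peak counts, default |log2 FC| > 1
at FDR 0.1) and expression (gene counts, default FDR 0.05). It is a
deliberately simplified thresholded NB test: per-feature method-of-moments
dispersion shrunk toward a parametric mean-dispersion trend, a delta-method
standard error on the log2 fold change, and a two-sided normal p-value for
the composite hypothesis |LFC| <= threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

PSEUDOCOUNT = 0.5  # added to normalized group means before the log-ratio
MIN_DISPERSION = 1e-8


@dataclass
class CountMatrix:
    """Features x samples non-negative integer counts with group labels."""

    counts: pd.DataFrame  # index: feature ids, columns: sample ids
    groups: dict[str, str]  # sample id -> group label
    size_factors: pd.Series | None = None

    def __post_init__(self) -> None:
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")
        missing = [s for s in self.counts.columns if s not in self.groups]
        if missing:
            raise ValueError(f"samples without group label: {missing}")

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.counts.columns if self.groups[s] == group]


def size_factors_median_of_ratios(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios (DESeq-style) size factors.

    s_j = median over reference features i of K_ij / geomean_i, where the
    reference features are those with strictly positive counts in every
    sample.
    """
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    arr = counts.to_numpy(dtype=float)
    positive = (arr > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no feature has all-positive counts; the median-of-ratios "
            "reference is empty (consider a pseudocount mode)"
        )
    ref = arr[positive]
    log_geomean = np.log(ref).mean(axis=1)
    ratios = np.log(ref) - log_geomean[:, None]
    sf = np.exp(np.median(ratios, axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _dispersion_trend(mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Fit alpha(mu) = a0 + a1/mu on features with usable estimates."""
    ok = (alpha > MIN_DISPERSION) & (mu > 0)
    if ok.sum() < 3:
        fill = float(np.median(alpha[alpha > 0])) if (alpha > 0).any() else 0.01
        return np.full_like(mu, max(fill, MIN_DISPERSION))
    X = np.column_stack([np.ones(ok.sum()), 1.0 / mu[ok]])
    coef, *_ = np.linalg.lstsq(X, alpha[ok], rcond=None)
    trend = coef[0] + coef[1] / np.maximum(mu, 1e-8)
    return np.maximum(trend, MIN_DISPERSION)


def nb_diff_test(
    cm: CountMatrix,
    group_a: str,
    group_b: str,
    lfc_threshold: float = 1.0,
    fdr: float = 0.1,
    shrink_weight: float = 0.5,
    lfc_test: str = "point",
) -> pd.DataFrame:
    """NB differential test between two sample groups, with an LFC cutoff.

    Per feature: normalized group means (pseudocount 0.5), LFC =
    log2(mean_A / mean_B), pooled method-of-moments dispersion shrunk
    toward the fitted mean-dispersion trend, delta-method SE, a two-sided
    normal p-value, BH q, and a call in {A_up, B_up, ns} requiring both
    q < fdr and |LFC| > lfc_threshold.

    ``lfc_test`` selects the null hypothesis behind the p-value:
    ``"point"`` (default) tests LFC = 0 (z = |LFC|/SE) and applies the
    fold-change cutoff only to the call; ``"threshold"`` tests the
    composite null |LFC| <= lfc_threshold (z = (|LFC| - threshold)/SE
    clipped at zero), which is markedly more conservative near the
    threshold.

    Returns a DataFrame indexed by feature with columns ``log2_fold_change``,
    ``standard_error``, ``p_value``, ``q_value``, ``call``.
    """
    if lfc_test not in ("point", "threshold"):
        raise ValueError(f"unknown lfc_test {lfc_test!r}")
    sa, sb = cm.samples_in(group_a), cm.samples_in(group_b)
    if not sa or not sb:
        raise ValueError(f"missing samples for groups {group_a!r}/{group_b!r}")
    if len(sa) < 2 or len(sb) < 2:
        warnings.warn(
            "fewer than 2 replicates in a group; dispersion is pooled across "
            "all samples and the test is anti-conservative"
        )
    counts = cm.counts[sa + sb]
    sf = (
        cm.size_factors[sa + sb]
        if cm.size_factors is not None
        else size_factors_median_of_ratios(counts)
    )
    norm = counts.to_numpy(dtype=float) / sf.to_numpy()[None, :]
    na, nb = len(sa), len(sb)
    xa, xb = norm[:, :na], norm[:, na:]
    mu_a, mu_b = xa.mean(axis=1), xb.mean(axis=1)
    lfc = np.log2((mu_a + PSEUDOCOUNT) / (mu_b + PSEUDOCOUNT))

    # pooled method-of-moments dispersion: Var = mu + alpha mu^2 per group
    mu_all = norm.mean(axis=1)
    num = np.zeros(len(counts))
    den = np.zeros(len(counts))
    for x, mu in ((xa, mu_a), (xb, mu_b)):
        if x.shape[1] >= 2:
            v = x.var(axis=1, ddof=1)
            num += v - mu
            den += mu**2
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_raw = np.where(den > 0, num / np.maximum(den, 1e-12), 0.0)
    if (den == 0).all():  # 1-vs-1: pool variance across every sample
        v = norm.var(axis=1, ddof=1)
        alpha_raw = (v - mu_all) / np.maximum(mu_all**2, 1e-12)
    alpha_raw = np.maximum(alpha_raw, MIN_DISPERSION)
    trend = _dispersion_trend(mu_all, alpha_raw)
    alpha = np.maximum(
        (1 - shrink_weight) * alpha_raw + shrink_weight * trend, MIN_DISPERSION
    )

    # delta method on log2(mu_a/mu_b): Var(mean of n NB draws) = (mu + a mu^2)/n
    ma, mb = mu_a + PSEUDOCOUNT, mu_b + PSEUDOCOUNT
    var_a = (mu_a + alpha * mu_a**2) / na
    var_b = (mu_b + alpha * mu_b**2) / nb
    se = np.sqrt(var_a / ma**2 + var_b / mb**2) / np.log(2)
    se = np.maximum(se, 1e-12)

    if lfc_test == "threshold":
        z = np.maximum(np.abs(lfc) - lfc_threshold, 0.0) / se
    else:
        z = np.abs(lfc) / se
    p = 2.0 * stats.norm.sf(z)
    p = np.minimum(p, 1.0)
    both_zero = (counts.to_numpy().sum(axis=1) == 0)
    lfc[both_zero] = 0.0
    p[both_zero] = 1.0
    q = bh_adjust(p)
    call = np.where(
        (q < fdr) & (np.abs(lfc) > lfc_threshold),
        np.where(lfc > 0, "A_up", "B_up"),
        "ns",
    )
    return pd.DataFrame(
        {
            "log2_fold_change": lfc,
            "standard_error": se,
            "p_value": p,
            "q_value": q,
            "call": call,
        },
        index=counts.index,
    )
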