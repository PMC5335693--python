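"""Homeodomain dimer k-mer grammar and reporter-library stratification.

K50 homeodomain factors such as CRX bind a TAAT core (with a tolerated
TAAG variant at position 4). In photoreceptor open chromatin these cores
occur in an inverted paired configuration on opposite strands separated by
exactly three nucleotides. This module scans sequences for the monomer and
dimer k-mer classes, applies the CRX-site point mutation used for control
constructs, and stratifies reporter (CRE-seq) expression by k-mer presence
with a rank-based test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .seqs import revcomp

VARIANT_CLASSES = ("native", "crx_mutant", "scrambled")


@dataclass(frozen=True)
class DimerKmerScheme:
    """Monomer cores and inverted dimer configurations with a fixed spacer.

    Dimer classes (spacer of ``spacer`` unconstrained nucleotides):

    - ``homotypic_TAAT``: TAAT [N]x ATTA (self-reverse-complementary)
    - ``homotypic_TAAG``: TAAG [N]x CTTA (self-reverse-complementary)
    - ``heterotypic``:    TAAT [N]x CTTA, or its reverse complement
      TAAG [N]x ATTA

    Monomer classes are 4-mer exact matches counting either strand's
    literal (TAAT/ATTA, TAAG/CTTA). All classes are closed under reverse
    complement of the scanned sequence.
    """

    spacer: int = 3
    monomers: dict = field(
        default_factory=lambda: {
            "monomer_TAAT": ("TAAT", "ATTA"),
            "monomer_TAAG": ("TAAG", "CTTA"),
        }
    )

    def dimer_patterns(self) -> dict[str, tuple[tuple[str, str], ...]]:
        """Forward-strand (left, right) half-site literals per dimer class."""
        return {
            "homotypic_TAAT": (("TAAT", "ATTA"),),
            "homotypic_TAAG": (("TAAG", "CTTA"),),
            "heterotypic": (("TAAT", "CTTA"), ("TAAG", "ATTA")),
        }

    @property
    def class_names(self) -> list[str]:
        return list(self.monomers) + list(self.dimer_patterns())


def _find_all(seq: str, pattern: str) -> list[int]:
    out, i = [], seq.find(pattern)
    while i != -1:
        out.append(i)
        i = seq.find(pattern, i + 1)
    return out


def scan_kmers(
    sequence: str, scheme: DimerKmerScheme | None = None
) -> dict[str, list[int]]:
    """Exact-match scan for every k-mer class of the scheme.

    Returns {class name: sorted forward-strand match offsets}; a class is
    present iff its offset list is non-empty. Dimer matches span
    ``4 + spacer + 4`` bp with the spacer unconstrained. Only A/C/G/T are
    accepted (exact matching has no ambiguity semantics).
    """
    if set(sequence.upper()) - set("ACGT"):
        bad = sorted(set(sequence.upper()) - set("ACGT"))
        raise ValueError(f"ambiguity codes not supported in exact scan: {bad}")
    scheme = scheme or DimerKmerScheme()
    seq = sequence.upper()
    result: dict[str, list[int]] = {}
    for name, (fwd, rc) in scheme.monomers.items():
        offs = set(_find_all(seq, fwd)) | set(_find_all(seq, rc))
        result[name] = sorted(offs)
    gap = scheme.spacer
    for name, pairs in scheme.dimer_patterns().items():
        offs: set[int] = set()
        for left, right in pairs:
            for i in _find_all(seq, left):
                j = i + 4 + gap
                if seq[j : j + 4] == right:
                    offs.add(i)
        result[name] = sorted(offs)
    return result


def present_classes(
    sequence: str, scheme: DimerKmerScheme | None = None
) -> set[str]:
    return {k for k, v in scan_kmers(sequence, scheme).items() if v}


CRX_SITE = "CTAATCC"
CRX_MUTANT = "CTACTCC"
CRX_SITE_RC = revcomp(CRX_SITE)  # GGATTAG
CRX_MUTANT_RC = revcomp(CRX_MUTANT)  # GGAGTAG


def mutate_crx_sites(sequence: str) -> str:
    """Eliminate CRX binding sites by point mutation (CTAATCC -> CTACTCC).

    Both strands are handled: forward-strand CTAATCC becomes CTACTCC and
    reverse-strand occurrences (GGATTAG on the forward strand) become
    GGAGTAG. Replacement is left-to-right and non-overlapping; the
    operation is idempotent.
    """
    seq = sequence
    out = []
    i = 0
    n = len(seq)
    while i < n:
        if seq.startswith(CRX_SITE, i):
            out.append(CRX_MUTANT)
            i += len(CRX_SITE)
        elif seq.startswith(CRX_SITE_RC, i):
            out.append(CRX_MUTANT_RC)
            i += len(CRX_SITE_RC)
        else:
            out.append(seq[i])
            i += 1
    return "".join(out)


# ---------------------------------------------------------------------------
# CRE-seq constructs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CreConstruct:
    construct_id: str
    sequence: str
    variant_class: str  # native / crx_mutant / scrambled
    expression: float

    def __post_init__(self) -> None:
        if self.variant_class not in VARIANT_CLASSES:
            raise ValueError(f"unknown variant_class {self.variant_class!r}")


def read_cre_table(path) -> list[CreConstruct]:
    df = pd.read_csv(path, sep="\t")
    return [
        CreConstruct(
            str(r.construct_id), str(r.sequence), str(r.variant_class), float(r.expression)
        )
        for r in df.itertuples()
    ]


def write_cre_table(path, constructs: Iterable[CreConstruct]) -> None:
    pd.DataFrame(
        [
            {
                "construct_id": c.construct_id,
                "variant_class": c.variant_class,
                "sequence": c.sequence,
                "expression": c.expression,
            }
            for c in constructs
        ]
    ).to_csv(path, sep="\t", index=False)


def classify_constructs(
    constructs: Sequence[CreConstruct], scheme: DimerKmerScheme | None = None
) -> pd.DataFrame:
    """Presence/absence table of every k-mer class per construct."""
    scheme = scheme or DimerKmerScheme()
    rows = []
    for c in constructs:
        present = present_classes(c.sequence, scheme)
        row = {
            "construct_id": c.construct_id,
            "variant_class": c.variant_class,
            "expression": c.expression,
        }
        for name in scheme.class_names:
            row[name] = name in present
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class StratifiedResult:
    class_label: str
    variant_class: str
    n_with: int
    n_without: int
    median_with: float
    median_without: float
    median_difference: float  # with - without
    p_value: float


def stratify_expression(
    constructs: Sequence[CreConstruct],
    class_label: str,
    variant_class: str = "native",
    scheme: DimerKmerScheme | None = None,
    method: str = "normal",
    n_permutations: int = 10000,
    rng: np.random.Generator | None = None,
) -> StratifiedResult:
    """Compare expression of constructs with vs without a k-mer class.

    Within the requested ``variant_class``, constructs are split by
    presence of ``class_label`` and compared with a two-sided Wilcoxon
    rank-sum test (normal approximation with tie correction). With
    ``method='permutation'`` the p-value is a Monte-Carlo permutation
    p-value of the rank-sum statistic (recommended for n <= 20).
    """
    scheme = scheme or DimerKmerScheme()
    subset = [c for c in constructs if c.variant_class == variant_class]
    has, lacks = [], []
    for c in subset:
        (has if class_label in present_classes(c.sequence, scheme) else lacks).append(
            c.expression
        )
    if len(has) < 2 or len(lacks) < 2:
        raise ValueError(
            f"stratum too small for {class_label}/{variant_class}: "
            f"{len(has)} with, {len(lacks)} without"
        )
    x, y = np.asarray(has), np.asarray(lacks)
    if np.ptp(np.concatenate([x, y])) == 0:
        # degenerate: every construct has identical expression
        return StratifiedResult(
            class_label, variant_class, len(has), len(lacks),
            float(x[0]), float(y[0]), 0.0, 1.0,
        )
    if method == "normal":
        p = float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
    elif method == "permutation":
        rng = np.random.default_rng() if rng is None else rng
        pooled = np.concatenate([x, y])
        ranks = stats.rankdata(pooled)
        obs = ranks[: len(x)].sum()
        null = np.empty(n_permutations)
        for i in range(n_permutations):
            null[i] = rng.permutation(ranks)[: len(x)].sum()
        p = float(
            (np.sum(np.abs(null - ranks.mean() * len(x)) >= abs(obs - ranks.mean() * len(x))) + 1)
            / (n_permutations + 1)
        )
    else:
        raise ValueError(f"unknown method {method!r}")
    return StratifiedResult(
        class_label=class_label,
        variant_class=variant_class,
        n_with=len(has),
        n_without=len(lacks),
        median_with=float(np.median(x)),
        median_without=float(np.median(y)),
        median_difference=float(np.median(x) - np.median(y)),
        p_value=p,
    )
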