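"""Ratio-of-ratios enrichment scores with Fisher exact tests and BH adjustment.

The enrichment score compares a foreground DHS set against a background set
(the static sex-independent DHS in the source analyses) for a binary feature.
Two variants exist:

* ``odds`` - ES = (a_in / a_out) / (b_in / b_out): the ratio of in/not-in
  ratios, equal to the sample odds ratio of the 2x2 table.  Used for the
  enhancer/promoter/insulator, gene-mapping, gene-class and chromatin-state
  batches.
* ``percentage`` - ES = (a_in / (a_in + a_out)) / (b_in / (b_in + b_out)):
  the ratio of feature percentages, used for feature-overlap batches such as
  TF-binding-site enrichment.

Significance is a two-sided Fisher exact test with Benjamini-Hochberg
adjustment across the batch; adjusted p < 1e-3 is called significant, and
ES < 1 is reported as depletion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Set

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ContingencyTable",
    "EnrichmentResult",
    "enrichment_score",
    "fisher_two_sided",
    "bh_adjust",
    "enrich_batch",
]

SIGNIFICANCE_PADJ = 1e-3


@dataclass(frozen=True)
class ContingencyTable:
    """Foreground/background counts with and without a feature."""

    a_in: int
    a_out: int
    b_in: int
    b_out: int

    def __post_init__(self) -> None:
        if min(self.a_in, self.a_out, self.b_in, self.b_out) < 0:
            raise ValueError("all counts must be >= 0")
        if self.a_in + self.a_out == 0 or self.b_in + self.b_out == 0:
            raise ValueError("both sets must be non-empty")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a_in, self.a_out], [self.b_in, self.b_out]])


def enrichment_score(t: ContingencyTable, variant: str = "odds") -> float:
    """ES = (ratio A)/(ratio B); no pseudocount — zero denominators raise."""
    if variant == "odds":
        if t.a_out == 0 or t.b_in == 0 or t.b_out == 0:
            raise ValueError(
                "odds-style ES undefined with zero denominator "
                f"(a_out={t.a_out}, b_in={t.b_in}, b_out={t.b_out})"
            )
        return (t.a_in / t.a_out) / (t.b_in / t.b_out)
    if variant == "percentage":
        if t.b_in == 0:
            raise ValueError("percentage-style ES undefined with b_in = 0")
        return (t.a_in / (t.a_in + t.a_out)) / (t.b_in / (t.b_in + t.b_out))
    raise ValueError(f"unknown ES variant {variant!r}")


def fisher_two_sided(t: ContingencyTable) -> float:
    """Two-sided Fisher exact p: total probability of tables (fixed margins)
    no more likely than the observed one."""
    return float(stats.fisher_exact(t.as_array(), alternative="two-sided")[1])


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    pvalues = np.asarray(pvalues, dtype=float)
    if pvalues.size == 0:
        return pvalues.copy()
    if np.any((pvalues < 0) | (pvalues > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(pvalues, method="fdr_bh")[1]


@dataclass
class EnrichmentResult:
    foreground: str
    feature: str
    table: ContingencyTable
    es: float
    pvalue: float
    padj: float

    @property
    def direction(self) -> str:
        return "enrichment" if self.es > 1 else "depletion"

    @property
    def significant(self) -> bool:
        return self.padj < SIGNIFICANCE_PADJ


def enrich_batch(
    foreground_sets: Mapping[str, Set],
    feature_sets: Mapping[str, Set],
    background: Set,
    variant: str = "odds",
) -> pd.DataFrame:
    """One enrichment per (foreground, feature) pair against a shared background.

    Sets are collections of DHS identifiers; a feature set holds the ids
    carrying the feature.  Foregrounds must be disjoint from the background.
    BH adjustment spans the whole batch.
    """
    background = set(background)
    for name, fg in foreground_sets.items():
        if set(fg) & background:
            raise ValueError(
                f"foreground {name!r} overlaps the background set "
                f"({len(set(fg) & background)} shared ids)"
            )
    results: List[EnrichmentResult] = []
    pvalues: List[float] = []
    for fg_name, fg in foreground_sets.items():
        fg = set(fg)
        for feat_name, feat in feature_sets.items():
            feat = set(feat)
            t = ContingencyTable(
                a_in=len(fg & feat),
                a_out=len(fg - feat),
                b_in=len(background & feat),
                b_out=len(background - feat),
            )
            es = enrichment_score(t, variant=variant)
            p = fisher_two_sided(t)
            results.append(EnrichmentResult(fg_name, feat_name, t, es, p, padj=np.nan))
            pvalues.append(p)
    padj = bh_adjust(pvalues)
    for r, q in zip(results, padj):
        r.padj = float(q)
    return pd.DataFrame(
        {
            "foreground": [r.foreground for r in results],
            "feature": [r.feature for r in results],
            "a_in": [r.table.a_in for r in results],
            "a_out": [r.table.a_out for r in results],
            "b_in": [r.table.b_in for r in results],
            "b_out": [r.table.b_out for r in results],
            "es": [r.es for r in results],
            "pvalue": [r.pvalue for r in results],
            "padj": [r.padj for r in results],
            "direction": [r.direction for r in results],
            "significant": [r.significant for r in results],
        }
    )
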