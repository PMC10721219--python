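"""Sex-biased gene calling and hypophysectomy response classes.

Sex-biased genes are called from expression fold-changes and adjusted
p-values with biotype-specific thresholds (RefSeq: |FC| > 1.5; multi-exonic
lncRNA: |FC| > 2; both with padj < 0.05 and FPKM > 0.25 in the higher sex).
Stringently sex-independent genes require FPKM > 1 in both sexes,
|FC| < 1.2 and padj > 0.1.  All inequalities are strict; boundary values
fail.

Class I sex-biased genes are downregulated by hypophysectomy in their
dominant sex (hypox FC < 1/2 with padj < 0.05); class II genes are
upregulated by hypophysectomy in the opposite sex (hypox FC > 2 with
padj < 0.05).  A gene meeting both definitions resolves to class I with a
warning.  Subclasses A/B/C are defined by an external rule table and default
to unassigned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Tuple

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SexBiasThresholds",
    "call_sex_bias",
    "call_hypox_class",
    "classify_genes",
    "tabulate_classes",
]

REQUIRED_FIELDS = (
    "gene_id", "biotype", "fpkm_m", "fpkm_f", "fc_mf", "padj_mf",
    "hypox_fc_m", "hypox_padj_m", "hypox_fc_f", "hypox_padj_f",
)


@dataclass
class SexBiasThresholds:
    fc_by_biotype: Dict[str, float] = field(
        default_factory=lambda: {"refseq": 1.5, "lncRNA": 2.0}
    )
    padj_max: float = 0.05
    fpkm_min: float = 0.25
    indep_fpkm_min: float = 1.0
    indep_fc_max: float = 1.2
    indep_padj_min: float = 0.1
    hypox_fc: float = 2.0
    hypox_padj_max: float = 0.05


def _check_row(row: Mapping) -> None:
    missing = [f for f in REQUIRED_FIELDS if f not in row or pd.isna(row[f])]
    if missing:
        raise ValueError(f"gene row missing fields: {missing}")


def call_sex_bias(row: Mapping, thresholds: SexBiasThresholds = SexBiasThresholds()
                  ) -> str:
    """male / female / independent_stringent / other for one expression row.

    ``fc_mf`` is the male/female expression ratio; female bias corresponds to
    fc_mf < 1/threshold.
    """
    _check_row(row)
    thr = thresholds.fc_by_biotype.get(row["biotype"])
    if thr is None:
        raise ValueError(f"unknown biotype {row['biotype']!r}")
    fc, padj = row["fc_mf"], row["padj_mf"]
    if fc > thr and padj < thresholds.padj_max and row["fpkm_m"] > thresholds.fpkm_min:
        return "male"
    if fc < 1.0 / thr and padj < thresholds.padj_max and \
            row["fpkm_f"] > thresholds.fpkm_min:
        return "female"
    if (row["fpkm_m"] > thresholds.indep_fpkm_min
            and row["fpkm_f"] > thresholds.indep_fpkm_min
            and 1.0 / thresholds.indep_fc_max < fc < thresholds.indep_fc_max
            and padj > thresholds.indep_padj_min):
        return "independent_stringent"
    return "other"


def call_hypox_class(
    row: Mapping, sex_bias: str,
    thresholds: SexBiasThresholds = SexBiasThresholds(),
) -> Tuple[str, Optional[str]]:
    """(hypox class, responding sex) for a sex-biased gene.

    Class I: dominant-sex hypox FC < 1/hypox_fc with padj < 0.05.
    Class II: opposite-sex hypox FC > hypox_fc with padj < 0.05.
    Dual qualifiers resolve to class I (logged).
    """
    if sex_bias not in ("male", "female"):
        raise ValueError("hypox class is defined only for sex-biased genes")
    _check_row(row)
    dominant = "m" if sex_bias == "male" else "f"
    opposite = "f" if sex_bias == "male" else "m"
    is_i = (row[f"hypox_fc_{dominant}"] < 1.0 / thresholds.hypox_fc
            and row[f"hypox_padj_{dominant}"] < thresholds.hypox_padj_max)
    is_ii = (row[f"hypox_fc_{opposite}"] > thresholds.hypox_fc
             and row[f"hypox_padj_{opposite}"] < thresholds.hypox_padj_max)
    if is_i and is_ii:
        logger.warning(
            "gene %s meets both class I and class II criteria; assigned class I",
            row.get("gene_id", "?"),
        )
    if is_i:
        return "I", dominant
    if is_ii:
        return "II", opposite
    return "none", None


def classify_genes(
    table: pd.DataFrame, thresholds: SexBiasThresholds = SexBiasThresholds()
) -> pd.DataFrame:
    """Apply sex-bias and hypox-class calling to a whole expression table."""
    records = []
    for _, row in table.iterrows():
        bias = call_sex_bias(row, thresholds)
        if bias in ("male", "female"):
            hypox, responder = call_hypox_class(row, bias, thresholds)
        else:
            hypox, responder = "none", None
        records.append(
            {
                "gene_id": row["gene_id"],
                "sex_bias": bias,
                "hypox_class": hypox,
                "responding_sex": responder,
                "subclass": "unassigned",
            }
        )
    return pd.DataFrame(records)


def tabulate_classes(labels: pd.DataFrame) -> pd.DataFrame:
    """Counts and responder percentages per sex x hypox class.

    Percentages are of each sex's sex-biased genes; counts over classes I and
    II sum to the number of sex-biased genes with a class.
    """
    rows = []
    for sex in ("male", "female"):
        sex_genes = labels[labels["sex_bias"] == sex]
        n_sex = len(sex_genes)
        for cls in ("I", "II"):
            k = int((sex_genes["hypox_class"] == cls).sum())
            rows.append(
                {
                    "sex_bias": sex,
                    "hypox_class": cls,
                    "count": k,
                    "percent_of_sex_biased": 100.0 * k / n_sex if n_sex else float("nan"),
                }
            )
    return pd.DataFrame(rows)
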