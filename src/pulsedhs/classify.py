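"""Cross-classification of reference DHS by pulse response and sex bias.

A reference DHS is *dynamic* when it overlaps a region that opens in
STAT5-high vs. STAT5-low livers; DHS overlapping only closing regions, and
DHS with no differential overlap at all, are *static* with respect to
GH/STAT5 pulses.  Combined with the sex-bias annotation this yields the six
classes (dynamic/static x male/female/independent) the downstream enrichment
analyses are built on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, overlaps_any

logger = logging.getLogger(__name__)

__all__ = [
    "RESPONSE_LABELS",
    "SEX_BIAS_LABELS",
    "ClassSummary",
    "label_response",
    "cross_classify",
    "summarize",
    "percentage",
    "proportion_ratio",
    "label_hypox_responses",
]

RESPONSE_LABELS = ("dynamic_opened", "dynamic_closed", "static")
SEX_BIAS_LABELS = ("male", "female", "independent")
HYPOX_LABELS = ("open", "close", "static", "none")


def label_response(
    reference_dhs: Sequence[GenomicInterval],
    up_in_high: Sequence[GenomicInterval],
    up_in_low: Sequence[GenomicInterval],
) -> List[str]:
    """Label each reference DHS dynamic_opened / dynamic_closed / static.

    Overlap threshold is >= 1 bp.  A DHS overlapping regions of both
    directions resolves to dynamic_opened with a logged warning.
    """
    hits_high = overlaps_any(reference_dhs, up_in_high)
    hits_low = overlaps_any(reference_dhs, up_in_low)
    n_conflicts = int(np.sum(hits_high & hits_low))
    if n_conflicts:
        logger.warning(
            "label_response: %d DHS overlap both opening and closing regions; "
            "resolved as dynamic_opened", n_conflicts,
        )
    return [
        "dynamic_opened" if h else ("dynamic_closed" if l else "static")
        for h, l in zip(hits_high, hits_low)
    ]


def cross_classify(
    sex_bias: Sequence[str], response: Sequence[str]
) -> Dict[str, int]:
    """Partition DHS into the six dynamic/static x sex-bias classes.

    Only pulse-opened DHS count as dynamic; pulse-closed DHS are designated
    static alongside non-differential DHS, matching the reference-catalog
    convention for the rare closing sites.
    """
    if len(sex_bias) != len(response):
        raise ValueError("sex_bias and response must have equal length")
    counts = {
        f"{dyn}_{sex}": 0
        for dyn in ("dynamic", "static")
        for sex in SEX_BIAS_LABELS
    }
    for i, (bias, resp) in enumerate(zip(sex_bias, response)):
        if bias not in SEX_BIAS_LABELS or resp not in RESPONSE_LABELS:
            raise ValueError(f"DHS at index {i} has missing/unknown labels "
                             f"({bias!r}, {resp!r})")
        axis = "dynamic" if resp == "dynamic_opened" else "static"
        counts[f"{axis}_{bias}"] += 1
    return counts


def percentage(k: int, n: int) -> Tuple[float, int]:
    """(unrounded percentage, integer presentation value) of k out of n."""
    if n == 0:
        raise ValueError("percentage undefined for n = 0")
    pct = 100.0 * k / n
    return pct, int(round(pct))


def proportion_ratio(k1: int, n1: int, k2: int, n2: int) -> Tuple[float, float]:
    """(unrounded, 1-decimal presentation) ratio of two proportions."""
    if n1 == 0 or n2 == 0 or k2 == 0:
        raise ValueError("proportion_ratio undefined for zero denominators")
    ratio = (k1 / n1) / (k2 / n2)
    return ratio, round(ratio, 1)


@dataclass
class ClassSummary:
    """Counts with derived (unrounded) percentages; rounding only at presentation."""

    counts: Dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def pct(self, key: str, of: Optional[Sequence[str]] = None) -> float:
        n = self.total if of is None else sum(self.counts[k] for k in of)
        return percentage(self.counts[key], n)[0]

    def to_frame(self) -> pd.DataFrame:
        total = self.total
        return pd.DataFrame(
            {
                "class": list(self.counts),
                "count": list(self.counts.values()),
                "percent": [100.0 * v / total if total else np.nan
                            for v in self.counts.values()],
            }
        )


def summarize(counts: Mapping[str, int]) -> ClassSummary:
    """Wrap class counts with percentage/ratio accessors."""
    if any(v < 0 for v in counts.values()):
        raise ValueError("counts must be >= 0")
    if sum(counts.values()) == 0:
        raise ValueError("summarize undefined for all-zero counts")
    return ClassSummary(dict(counts))


def label_hypox_responses(
    reference_dhs: Sequence[GenomicInterval],
    comparisons: Mapping[str, Mapping[str, Sequence[GenomicInterval]]],
    valid_comparisons: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Label each reference DHS open/close/static/none per comparison.

    ``comparisons`` maps a comparison id (e.g. ``hypox_vs_intact_male``,
    ``gh30_vs_hypox``) to a dict with keys ``open`` and ``close`` (differential
    region lists) and ``peak_union``.  A DHS not overlapping the comparison's
    peak union is labeled ``none``; overlap with an opening region beats
    overlap with a closing region (with a logged warning), mirroring the
    dynamic-label conflict rule.
    """
    if valid_comparisons is not None:
        unknown = set(comparisons) - set(valid_comparisons)
        if unknown:
            raise ValueError(f"unknown comparison ids: {sorted(unknown)}")
    out = {}
    for comp_id, sets in comparisons.items():
        missing = {"open", "close", "peak_union"} - set(sets)
        if missing:
            raise ValueError(f"comparison {comp_id} missing keys {sorted(missing)}")
        hits_open = overlaps_any(reference_dhs, sets["open"])
        hits_close = overlaps_any(reference_dhs, sets["close"])
        in_union = overlaps_any(reference_dhs, sets["peak_union"])
        n_conflicts = int(np.sum(hits_open & hits_close))
        if n_conflicts:
            logger.warning(
                "label_hypox_responses[%s]: %d DHS overlap both directions; "
                "labeled open", comp_id, n_conflicts,
            )
        out[comp_id] = [
            "open" if o else ("close" if c else ("static" if u else "none"))
            for o, c, u in zip(hits_open, hits_close, in_union)
        ]
    frame = pd.DataFrame(out)
    frame.insert(0, "dhs_index", np.arange(len(reference_dhs)))
    return frame
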