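"""Windowed differential chromatin-accessibility testing and sample QC.

The genome is tiled with half-overlapping windows (default 200 bp, step 100);
per-window cut counts are compared between two sample groups with a pooled
G-test (likelihood ratio against library-size-proportional expectation),
normalized as counts per million, with BH adjustment over all tested windows.
Significant windows (|FC| > fc_min and FDR < fdr_max) are merged per direction
and kept only when they overlap a peak-union site.

Sample QC projects per-sample normalized read densities over the top
differential regions onto PC1 and flags samples falling on the wrong side of
the midpoint between the two group medians.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .intervals import CutSiteTrack, Genome, GenomicInterval, merge_intervals, overlaps_any

__all__ = [
    "WindowCounts",
    "QCConfig",
    "window_counts",
    "test_windows",
    "call_differential_regions",
    "detect_outliers",
    "flag_by_midpoint",
]

PSEUDOCOUNT = 0.5


@dataclass
class WindowCounts:
    """Per-window, per-sample raw cut counts over a genome tiling."""

    chroms: np.ndarray  # per-window chromosome name
    starts: np.ndarray
    ends: np.ndarray
    counts: np.ndarray  # shape (n_windows, n_samples)
    sample_ids: List[str]
    library_sizes: np.ndarray  # per-sample total cut counts

    def __post_init__(self) -> None:
        assert self.counts.shape == (len(self.starts), len(self.sample_ids))


@dataclass
class QCConfig:
    """Outlier-detection settings: top-N regions ranked by decreasing opening FC."""

    top_n: Tuple[int, ...] = (200, 600)


def window_counts(
    tracks: Mapping[str, CutSiteTrack],
    genome: Genome,
    window_bp: int = 200,
    step: Optional[int] = None,
) -> WindowCounts:
    """Tile the genome and count cut sites per window per sample.

    Windows are half-open; a cut at a boundary position belongs to the window
    whose span contains it.  No read extension is applied: cut sites are
    counted exactly where they fall.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    step = step if step is not None else window_bp // 2
    if step <= 0:
        raise ValueError("step must be positive")
    sample_ids = list(tracks)
    lib_sizes = np.array([tracks[s].total_cuts for s in sample_ids], dtype=np.int64)
    if lib_sizes.sum() == 0:
        import warnings

        warnings.warn("window_counts: all tracks are empty", stacklevel=2)
    all_chroms: List[np.ndarray] = []
    all_starts: List[np.ndarray] = []
    all_counts: List[np.ndarray] = []
    for chrom, chrom_len in genome.items():
        starts = np.arange(0, max(chrom_len - window_bp, 0) + 1, step, dtype=np.int64)
        if starts.size == 0:
            continue
        per_sample = np.zeros((starts.size, len(sample_ids)), dtype=np.int64)
        for j, sid in enumerate(sample_ids):
            pos, cnt = tracks[sid].positions(chrom)
            if pos.size == 0:
                continue
            csum = np.concatenate([[0], np.cumsum(cnt)])
            lo = np.searchsorted(pos, starts)
            hi = np.searchsorted(pos, starts + window_bp)
            per_sample[:, j] = csum[hi] - csum[lo]
        all_chroms.append(np.full(starts.size, chrom, dtype=object))
        all_starts.append(starts)
        all_counts.append(per_sample)
    starts = np.concatenate(all_starts) if all_starts else np.empty(0, np.int64)
    return WindowCounts(
        chroms=np.concatenate(all_chroms) if all_chroms else np.empty(0, object),
        starts=starts,
        ends=starts + window_bp,
        counts=np.vstack(all_counts) if all_counts else np.empty((0, len(sample_ids))),
        sample_ids=sample_ids,
        library_sizes=lib_sizes,
    )


def _g_statistic(pooled_a: np.ndarray, pooled_b: np.ndarray,
                 lib_a: float, lib_b: float) -> np.ndarray:
    """Likelihood-ratio G for pooled counts vs. library-proportional expectation."""
    total = pooled_a + pooled_b
    frac_a = lib_a / (lib_a + lib_b)
    e_a = total * frac_a
    e_b = total * (1.0 - frac_a)
    with np.errstate(divide="ignore", invalid="ignore"):
        term_a = np.where(pooled_a > 0, pooled_a * np.log(pooled_a / e_a), 0.0)
        term_b = np.where(pooled_b > 0, pooled_b * np.log(pooled_b / e_b), 0.0)
    return 2.0 * (term_a + term_b)


def test_windows(
    wc: WindowCounts, group_labels: Mapping[str, str] | Sequence[str]
) -> pd.DataFrame:
    """Per-window differential test between the two groups in ``group_labels``.

    Returns a DataFrame (one row per tested window) with CPM-normalized group
    means, log2 fold-change with pseudocount 0.5, G-test p-value (chi-square,
    1 df) and BH-adjusted p-value.  Windows where both group sums are zero are
    excluded from testing.
    """
    if isinstance(group_labels, Mapping):
        labels = [group_labels[s] for s in wc.sample_ids]
    else:
        labels = list(group_labels)
    uniq = sorted(set(labels))
    if len(uniq) != 2:
        raise ValueError(f"exactly two groups required, got {uniq}")
    group_a, group_b = uniq
    mask_a = np.array([lab == group_a for lab in labels])
    mask_b = ~mask_a

    lib = wc.library_sizes.astype(float)
    pooled_a = wc.counts[:, mask_a].sum(axis=1)
    pooled_b = wc.counts[:, mask_b].sum(axis=1)
    tested = (pooled_a + pooled_b) > 0

    cpm = wc.counts / np.maximum(lib, 1.0)[None, :] * 1e6
    mean_a = cpm[:, mask_a].mean(axis=1)
    mean_b = cpm[:, mask_b].mean(axis=1)
    log2fc = np.log2((mean_a + PSEUDOCOUNT) / (mean_b + PSEUDOCOUNT))

    g = _g_statistic(pooled_a[tested], pooled_b[tested],
                     lib[mask_a].sum(), lib[mask_b].sum())
    pvalues = stats.chi2.sf(g, df=1)
    # exact-null windows (G == 0) have p exactly 1
    pvalues = np.where(g <= 0, 1.0, pvalues)
    padj = multipletests(pvalues, method="fdr_bh")[1]

    out = pd.DataFrame(
        {
            "chrom": wc.chroms[tested],
            "start": wc.starts[tested],
            "end": wc.ends[tested],
            "mean_cpm_a": mean_a[tested],
            "mean_cpm_b": mean_b[tested],
            "log2fc": log2fc[tested],
            "g_stat": g,
            "pvalue": pvalues,
            "padj": padj,
        }
    )
    out.attrs["group_a"] = group_a
    out.attrs["group_b"] = group_b
    return out.reset_index(drop=True)


def _merge_window_rows(rows: pd.DataFrame) -> List[Tuple[str, int, int, float, float]]:
    """Merge overlapping/book-ended significant windows of one direction."""
    regions = []
    for chrom, sub in rows.groupby("chrom", sort=True):
        sub = sub.sort_values("start")
        cur_start = cur_end = None
        best_padj = np.inf
        best_fc = 0.0
        for row in sub.itertuples():
            if cur_start is None:
                cur_start, cur_end = row.start, row.end
                best_padj, best_fc = row.padj, row.log2fc
            elif row.start <= cur_end:
                cur_end = max(cur_end, row.end)
                best_padj = min(best_padj, row.padj)
                if abs(row.log2fc) > abs(best_fc):
                    best_fc = row.log2fc
            else:
                regions.append((chrom, int(cur_start), int(cur_end), best_padj, best_fc))
                cur_start, cur_end = row.start, row.end
                best_padj, best_fc = row.padj, row.log2fc
        if cur_start is not None:
            regions.append((chrom, int(cur_start), int(cur_end), best_padj, best_fc))
    return regions


def call_differential_regions(
    window_stats: pd.DataFrame,
    peak_union: Sequence[GenomicInterval],
    fc_min: float = 2.0,
    fdr_max: float = 0.05,
) -> pd.DataFrame:
    """Merge significant windows per direction and filter by peak-union overlap.

    A window is significant when |fold-change| > ``fc_min`` and padj <
    ``fdr_max``.  Merged regions of opposite direction are never combined.
    Regions with no >= 1 bp overlap with the peak union are dropped.
    """
    log2_min = np.log2(fc_min)
    sig = window_stats[
        (window_stats["padj"] < fdr_max) & (window_stats["log2fc"].abs() > log2_min)
    ]
    records = []
    for direction, rows in (
        ("up_in_A", sig[sig["log2fc"] > 0]),
        ("up_in_B", sig[sig["log2fc"] < 0]),
    ):
        for chrom, start, end, padj, log2fc in _merge_window_rows(rows):
            records.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "direction": direction,
                    "padj": padj,
                    "log2fc": log2fc,
                    "fold_change": float(2.0 ** abs(log2fc)),
                }
            )
    regions = pd.DataFrame(
        records, columns=["chrom", "start", "end", "direction", "padj",
                          "log2fc", "fold_change"]
    )
    if len(regions) and peak_union is not None:
        ivs = [GenomicInterval(r.chrom, r.start, r.end) for r in regions.itertuples()]
        keep = overlaps_any(ivs, peak_union)
        regions = regions[keep]
    return regions.sort_values(["chrom", "start"]).reset_index(drop=True)


def region_intervals(regions: pd.DataFrame, direction: Optional[str] = None
                     ) -> List[GenomicInterval]:
    """Convert a differential-region table (optionally one direction) to intervals."""
    sub = regions if direction is None else regions[regions["direction"] == direction]
    return [GenomicInterval(r.chrom, int(r.start), int(r.end))
            for r in sub.itertuples()]


def _rank_regions(regions: pd.DataFrame) -> pd.DataFrame:
    """Opening regions ordered by decreasing fold-change; ties by padj, coordinate."""
    up = regions[regions["direction"] == "up_in_A"]
    return up.sort_values(
        ["fold_change", "padj", "chrom", "start"],
        ascending=[False, True, True, True],
    )


def flag_by_midpoint(values: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Flag samples lying past the midpoint of the two group medians.

    A sample is flagged when its 1-D coordinate (e.g. PC1) falls on the far
    side of the midpoint between the two group medians relative to its own
    group's median — the empirical-cutoff rule used to spot mislabeled
    cohort members.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    uniq = sorted(set(labels.tolist()))
    if len(uniq) != 2:
        raise ValueError("exactly two groups required")
    med = {grp: np.median(values[labels == grp]) for grp in uniq}
    midpoint = (med[uniq[0]] + med[uniq[1]]) / 2.0
    flags = np.zeros(len(values), dtype=bool)
    for i, (v, lab) in enumerate(zip(values, labels)):
        own_side = np.sign(med[lab] - midpoint)
        flags[i] = v != midpoint and np.sign(v - midpoint) == -own_side
    return flags


def detect_outliers(
    regions: pd.DataFrame,
    tracks: Mapping[str, CutSiteTrack],
    group_labels: Mapping[str, str],
    qc: QCConfig = QCConfig(),
) -> pd.DataFrame:
    """Flag samples whose PC1 coordinate contradicts their group label.

    For each top-N cut (default 200 and 600) of the opening differential
    regions ranked by decreasing fold-change, computes per-sample reads per kb
    per million over those regions, standardizes, takes PC1, and flags a
    sample lying on the far side of the midpoint between the two group PC1
    medians relative to its own group's median.  A sample flagged at either
    top-N is flagged overall.
    """
    sample_ids = list(tracks)
    labels = np.array([group_labels[s] for s in sample_ids])
    uniq = sorted(set(labels))
    if len(uniq) != 2:
        raise ValueError("exactly two groups required")
    for grp in uniq:
        if (labels == grp).sum() < 3:
            raise ValueError(f"need >= 3 samples per group, got {(labels == grp).sum()} in {grp}")
    ranked = _rank_regions(regions)
    lib = np.array([tracks[s].total_cuts for s in sample_ids], dtype=float)
    result = pd.DataFrame({"sample_id": sample_ids, "group": labels})
    any_flag = np.zeros(len(sample_ids), dtype=bool)
    for top_n in qc.top_n:
        top = ranked.head(top_n)
        if len(top) < 2:
            raise ValueError("too few differential regions for outlier QC")
        rpkm = np.zeros((len(sample_ids), len(top)))
        kb = (top["end"] - top["start"]).to_numpy(float) / 1000.0
        for i, sid in enumerate(sample_ids):
            counts = np.array(
                [tracks[sid].count_in(r.chrom, r.start, r.end) for r in top.itertuples()],
                dtype=float,
            )
            rpkm[i] = counts / kb / (lib[i] / 1e6)
        mat = rpkm - rpkm.mean(axis=0)
        sd = rpkm.std(axis=0)
        mat = mat / np.where(sd > 0, sd, 1.0)
        if np.allclose(mat, 0):
            raise ValueError("degenerate PC1: zero variance across samples")
        # PC1 via SVD of the standardized sample x region matrix
        u, s, _ = np.linalg.svd(mat, full_matrices=False)
        pc1 = u[:, 0] * s[0]
        flags = flag_by_midpoint(pc1, labels)
        result[f"pc1_top{top_n}"] = pc1
        result[f"flagged_top{top_n}"] = flags
        any_flag |= flags
    result["flagged"] = any_flag
    return result
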