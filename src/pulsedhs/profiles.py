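"""Normalized DNase-I cut-site aggregate profiles and RiPPM normalization.

An aggregate profile sums cut sites at each of the 2000 positions of 2-kb
windows centered on DHS midpoints, normalizes by the library's cut sites in
the reference DHS set (per million) and by the number of windows, smooths
with LOWESS, and subtracts the smoothed baseline estimated from the first
200 positions.  Doubling sequencing depth uniformly leaves the profile
unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

from .intervals import CutSiteTrack, Genome, GenomicInterval, merge_intervals

__all__ = [
    "WINDOW_BP",
    "AggregateProfile",
    "center_windows",
    "aggregate",
    "rippm_factor",
    "rippm_normalize",
]

WINDOW_BP = 2000
HALF_WINDOW = WINDOW_BP // 2
BASELINE_BP = 200


@dataclass
class AggregateProfile:
    """Smoothed, baseline-offset profile over a 2-kb DHS-centered window."""

    values: np.ndarray  # length 2000, smoothed and offset
    raw: np.ndarray  # pre-smoothing normalized values, length 2000
    n_regions: int
    reference_read_count: int

    def __post_init__(self) -> None:
        if len(self.values) != WINDOW_BP:
            raise ValueError(f"profile must have length {WINDOW_BP}")

    @property
    def peak_value(self) -> float:
        return float(np.max(self.values))

    @property
    def offsets(self) -> np.ndarray:
        """Position offsets relative to the DHS midpoint (-1000..999)."""
        return np.arange(-HALF_WINDOW, HALF_WINDOW)


def center_windows(
    dhs_set: Sequence[GenomicInterval], genome: Optional[Genome] = None
) -> List[GenomicInterval]:
    """2-kb windows centered at floor DHS midpoints; off-chromosome windows dropped."""
    windows: List[GenomicInterval] = []
    dropped = 0
    for dhs in dhs_set:
        mid = dhs.midpoint
        start, end = mid - HALF_WINDOW, mid + HALF_WINDOW
        if start < 0 or (genome is not None and
                         (dhs.chrom not in genome or end > genome[dhs.chrom])):
            dropped += 1
            continue
        windows.append(GenomicInterval(dhs.chrom, start, end))
    if dropped:
        warnings.warn(
            f"center_windows: dropped {dropped} windows extending past chromosome ends",
            stacklevel=2,
        )
    return windows


def aggregate(
    track: CutSiteTrack,
    windows: Sequence[GenomicInterval],
    reference_dhs: Sequence[GenomicInterval],
    lowess_frac: float = 0.02,
    smooth: bool = True,
) -> AggregateProfile:
    """Build the normalized cut-site aggregate profile for one track.

    For position t in 0..1999, S(t) sums cut counts at offset t over all
    windows; V(t) = S(t) / (R / 1e6) / N where R is the track's cut sites
    inside ``reference_dhs`` and N the number of windows.  V is smoothed by
    LOWESS (span ``lowess_frac``, 0 robustness iterations) and the mean of
    the smoothed values over the first 200 positions is subtracted.
    """
    if not windows:
        raise ValueError("aggregate requires at least one window")
    ref_count = track.count_in_intervals(list(reference_dhs))
    if ref_count == 0:
        raise ValueError("no cut sites fall within the reference DHS set (R = 0)")
    s = np.zeros(WINDOW_BP, dtype=np.int64)
    for w in windows:
        s += track.profile(w.chrom, w.start, w.end)
    raw = s / (ref_count / 1e6) / len(windows)
    if smooth:
        t = np.arange(WINDOW_BP, dtype=float)
        smoothed = lowess(raw, t, frac=lowess_frac, it=0, return_sorted=False)
    else:
        smoothed = raw.copy()
    values = smoothed - smoothed[:BASELINE_BP].mean()
    return AggregateProfile(
        values=values, raw=raw, n_regions=len(windows), reference_read_count=ref_count
    )


def rippm_factor(
    track: CutSiteTrack, peak_union: Sequence[GenomicInterval]
) -> float:
    """Reads-in-peaks-per-million scaling factor: cuts inside the union / 1e6."""
    if not peak_union:
        raise ValueError("peak_union must be non-empty")
    in_peaks = track.count_in_intervals(list(peak_union))
    if in_peaks == 0:
        raise ValueError("no reads fall within the peak union")
    return in_peaks / 1e6


def rippm_normalize(count, factor: float):
    """Divide a raw read count (scalar or array) by the RiPPM factor."""
    if factor <= 0:
        raise ValueError("RiPPM factor must be positive")
    return np.asarray(count, dtype=float) / factor if np.ndim(count) else count / factor
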