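"""Genomic interval arithmetic, BED I/O, cut-site tracks, and a minimal peak caller.

Coordinates are 0-based half-open throughout (BED convention): an interval
``[start, end)`` covers ``end - start`` base pairs.  A DNase-I cut site is the
5'-end of a sequenced fragment: position ``start`` for a plus-strand read and
``end - 1`` for a minus-strand read.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicInterval",
    "Genome",
    "ReadRecord",
    "CutSiteTrack",
    "BedParseError",
    "read_bed",
    "write_bed",
    "reads_from_bed",
    "read_chrom_sizes",
    "merge_intervals",
    "overlap_bp",
    "overlaps_any",
    "extract_cut_sites",
    "filter_peaks",
    "call_peaks",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic region."""

    chrom: str
    start: int
    end: int
    name: Optional[str] = None
    score: Optional[float] = None
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be nonempty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"start must be < end, got [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be one of +, -, . (got {self.strand!r})")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class ReadRecord:
    """A single aligned sequence read (stranded)."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"read start must be < end ({self.start} >= {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"read strand must be + or -, got {self.strand!r}")

    @property
    def cut_site(self) -> int:
        """5'-end of the read: start on +, end - 1 on -."""
        return self.start if self.strand == "+" else self.end - 1


class Genome:
    """Ordered map of chromosome name -> length in bp."""

    def __init__(self, sizes: Mapping[str, int]):
        self._sizes: Dict[str, int] = {}
        for name, length in sizes.items():
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length {length}")
            if name in self._sizes:
                raise ValueError(f"duplicate chromosome name {name}")
            self._sizes[name] = int(length)

    def __getitem__(self, chrom: str) -> int:
        return self._sizes[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._sizes

    def __iter__(self):
        return iter(self._sizes)

    def items(self):
        return self._sizes.items()

    def __len__(self) -> int:
        return len(self._sizes)

    def __eq__(self, other) -> bool:
        return isinstance(other, Genome) and self._sizes == other._sizes


class BedParseError(ValueError):
    """Raised for malformed BED lines; the message names the offending line."""


def read_bed(path) -> List[GenomicInterval]:
    """Read BED3-BED6 into a list of intervals (0-based half-open preserved)."""
    intervals: List[GenomicInterval] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}: line {lineno}: fewer than 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise BedParseError(
                    f"{path}: line {lineno}: non-integer coordinates "
                    f"({fields[1]!r}, {fields[2]!r})"
                ) from None
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score: Optional[float] = None
            if len(fields) > 4 and fields[4] != ".":
                try:
                    score = float(fields[4])
                except ValueError:
                    raise BedParseError(
                        f"{path}: line {lineno}: non-numeric score {fields[4]!r}"
                    ) from None
            strand = fields[5] if len(fields) > 5 else "."
            try:
                intervals.append(
                    GenomicInterval(chrom, start, end, name=name, score=score, strand=strand)
                )
            except ValueError as exc:
                raise BedParseError(f"{path}: line {lineno}: {exc}") from None
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path) -> None:
    """Write intervals as BED; emits 6 columns when any name/score/strand is set."""
    intervals = list(intervals)
    extended = any(
        iv.name is not None or iv.score is not None or iv.strand != "."
        for iv in intervals
    )
    with open(path, "w") as handle:
        for iv in intervals:
            if extended:
                score = "." if iv.score is None else format(iv.score, "g")
                handle.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t{score}\t{iv.strand}\n"
                )
            else:
                handle.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def reads_from_bed(path) -> List[ReadRecord]:
    """Read stranded sequence reads from a BED6 file."""
    reads = []
    for lineno, iv in enumerate(read_bed(path), start=1):
        if iv.strand not in ("+", "-"):
            raise BedParseError(
                f"{path}: record {lineno}: reads require an explicit +/- strand"
            )
        reads.append(ReadRecord(iv.chrom, iv.start, iv.end, iv.strand))
    return reads


def read_chrom_sizes(path) -> Genome:
    """Read a two-column chrom-sizes file (name, length)."""
    sizes: Dict[str, int] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) < 2:
                raise BedParseError(f"{path}: line {lineno}: expected 2 columns")
            sizes[fields[0]] = int(fields[1])
    return Genome(sizes)


def merge_intervals(intervals: Sequence[GenomicInterval]) -> List[GenomicInterval]:
    """Union-merge: combines overlapping and book-ended (end == next start) intervals.

    Output is sorted by (chrom, start) and covers exactly the union of input bases.
    Idempotent.  Names/scores/strands are dropped (a merged region has no single
    provenance).
    """
    by_chrom: Dict[str, List[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    merged: List[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda iv: (iv.start, iv.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:  # overlap or book-ended
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_start, cur_end))
    return merged


def overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of base pairs shared by two intervals (0 across chromosomes)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


class _MergedIndex:
    """Sorted, merged interval index per chromosome for fast any-overlap queries."""

    def __init__(self, subjects: Sequence[GenomicInterval]):
        self._starts: Dict[str, np.ndarray] = {}
        self._ends: Dict[str, np.ndarray] = {}
        for iv in merge_intervals(subjects):
            self._starts.setdefault(iv.chrom, []).append(iv.start)  # type: ignore[union-attr]
            self._ends.setdefault(iv.chrom, []).append(iv.end)  # type: ignore[union-attr]
        for chrom in self._starts:
            self._starts[chrom] = np.asarray(self._starts[chrom])
            self._ends[chrom] = np.asarray(self._ends[chrom])

    def overlaps(self, iv: GenomicInterval) -> bool:
        starts = self._starts.get(iv.chrom)
        if starts is None:
            return False
        idx = int(np.searchsorted(starts, iv.end, side="left"))
        return idx > 0 and self._ends[iv.chrom][idx - 1] > iv.start


def overlaps_any(
    queries: Sequence[GenomicInterval], subjects: Sequence[GenomicInterval]
) -> np.ndarray:
    """Boolean vector: does each query share >= 1 bp with any subject interval?"""
    if not subjects:
        return np.zeros(len(queries), dtype=bool)
    index = _MergedIndex(subjects)
    return np.array([index.overlaps(q) for q in queries], dtype=bool)


class CutSiteTrack:
    """Sparse per-chromosome DNase-I cut-site counts plus the library total.

    Positions are stored sorted with parallel integer counts; this keeps a
    10-Mb genome with ~1e5-1e6 cuts per sample small and makes window counting
    a pair of binary searches.
    """

    def __init__(
        self,
        counts: Mapping[str, Tuple[np.ndarray, np.ndarray]],
        total_mapped_reads: int,
        skipped_reads: int = 0,
    ):
        self._counts: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
        total = 0
        for chrom, (pos, cnt) in counts.items():
            pos = np.asarray(pos, dtype=np.int64)
            cnt = np.asarray(cnt, dtype=np.int64)
            if pos.size and np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions for {chrom} must be strictly increasing")
            if np.any(cnt < 0):
                raise ValueError("cut counts must be >= 0")
            self._counts[chrom] = (pos, cnt)
            total += int(cnt.sum())
        if total > total_mapped_reads:
            raise ValueError(
                f"sum of cut counts ({total}) exceeds total_mapped_reads "
                f"({total_mapped_reads})"
            )
        self.total_mapped_reads = int(total_mapped_reads)
        self.skipped_reads = int(skipped_reads)
        self._total_cuts = total

    @classmethod
    def from_positions(
        cls, positions_by_chrom: Mapping[str, Sequence[int]], total_mapped_reads=None,
        skipped_reads: int = 0,
    ) -> "CutSiteTrack":
        counts = {}
        n = 0
        for chrom, positions in positions_by_chrom.items():
            pos, cnt = np.unique(np.asarray(positions, dtype=np.int64), return_counts=True)
            counts[chrom] = (pos, cnt)
            n += int(cnt.sum())
        if total_mapped_reads is None:
            total_mapped_reads = n + skipped_reads
        return cls(counts, total_mapped_reads, skipped_reads=skipped_reads)

    @property
    def chroms(self) -> List[str]:
        return list(self._counts)

    @property
    def total_cuts(self) -> int:
        return self._total_cuts

    def positions(self, chrom: str) -> Tuple[np.ndarray, np.ndarray]:
        return self._counts.get(chrom, (np.empty(0, np.int64), np.empty(0, np.int64)))

    def count_in(self, chrom: str, start: int, end: int) -> int:
        """Total cut sites with start <= position < end."""
        pos, cnt = self.positions(chrom)
        lo, hi = np.searchsorted(pos, [start, end])
        return int(cnt[lo:hi].sum())

    def count_in_intervals(self, intervals: Sequence[GenomicInterval]) -> int:
        """Cut sites falling inside the union of the given intervals."""
        return sum(
            self.count_in(iv.chrom, iv.start, iv.end)
            for iv in merge_intervals(intervals)
        ) if intervals else 0

    def profile(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Dense per-bp cut counts over [start, end)."""
        pos, cnt = self.positions(chrom)
        lo, hi = np.searchsorted(pos, [start, end])
        out = np.zeros(end - start, dtype=np.int64)
        out[pos[lo:hi] - start] = cnt[lo:hi]
        return out

    @staticmethod
    def pool(tracks: Sequence["CutSiteTrack"]) -> "CutSiteTrack":
        """Sum several tracks (the aggregate-plot analog of concatenating libraries)."""
        merged: Dict[str, List[np.ndarray]] = {}
        total = 0
        skipped = 0
        for track in tracks:
            total += track.total_mapped_reads
            skipped += track.skipped_reads
            for chrom in track.chroms:
                pos, cnt = track.positions(chrom)
                merged.setdefault(chrom, []).append(np.repeat(pos, cnt))
        counts = {}
        for chrom, parts in merged.items():
            pos, cnt = np.unique(np.concatenate(parts), return_counts=True)
            counts[chrom] = (pos, cnt)
        return CutSiteTrack(counts, total, skipped_reads=skipped)


def extract_cut_sites(
    reads: Sequence[ReadRecord], genome: Optional[Genome] = None
) -> CutSiteTrack:
    """Locate the DNase-I cut site of each read (its 5'-end) and tally per position.

    With a genome supplied, reads whose cut site falls off the chromosome end
    are skipped with a logged warning; the skip count is recorded on the track
    so that ``sum(counts) + skipped == len(reads)``.
    """
    positions: Dict[str, List[int]] = {}
    skipped = 0
    for read in reads:
        site = read.cut_site
        if genome is not None:
            if read.chrom not in genome or not (0 <= site < genome[read.chrom]):
                skipped += 1
                continue
        positions.setdefault(read.chrom, []).append(site)
    if skipped:
        logger.warning("extract_cut_sites: skipped %d reads off chromosome ends", skipped)
    return CutSiteTrack.from_positions(
        positions, total_mapped_reads=len(reads), skipped_reads=skipped
    )


def filter_peaks(
    peaks: Sequence[GenomicInterval],
    blacklist: Sequence[GenomicInterval],
    reads: Sequence[ReadRecord],
) -> List[GenomicInterval]:
    """Drop blacklist-overlapping peaks and 'straight peaks'.

    A straight peak's read support is >= 5 copies of one identical read
    signature (chrom, start, end, strand) with no other distinct read
    overlapping the peak.
    """
    kept: List[GenomicInterval] = []
    in_blacklist = overlaps_any(peaks, blacklist)
    reads_by_chrom: Dict[str, List[ReadRecord]] = {}
    for read in reads:
        reads_by_chrom.setdefault(read.chrom, []).append(read)
    n_blacklisted = 0
    n_straight = 0
    for peak, blacklisted in zip(peaks, in_blacklist):
        if blacklisted:
            n_blacklisted += 1
            continue
        signatures = Counter(
            (r.chrom, r.start, r.end, r.strand)
            for r in reads_by_chrom.get(peak.chrom, ())
            if r.start < peak.end and r.end > peak.start
        )
        if len(signatures) == 1 and next(iter(signatures.values())) >= 5:
            n_straight += 1
            continue
        kept.append(peak)
    if n_blacklisted or n_straight:
        logger.info(
            "filter_peaks: removed %d blacklisted and %d straight peaks of %d",
            n_blacklisted, n_straight, len(peaks),
        )
    return kept


def call_peaks(
    track: CutSiteTrack,
    genome: Genome,
    window_bp: int = 150,
    local_bg_bp: int = 5000,
    p_threshold: float = 1e-5,
) -> List[GenomicInterval]:
    """Minimal Poisson local-background peak caller over cut-site counts.

    Slides half-overlapping windows of ``window_bp``; a window is significant
    when its count exceeds the Poisson upper tail (p < ``p_threshold``) of
    lambda = max(genome-wide mean, local mean over ``local_bg_bp``) scaled to
    the window size.  Significant windows are union-merged into peaks.
    Deterministic given inputs.
    """
    if window_bp >= local_bg_bp:
        raise ValueError("window_bp must be < local_bg_bp")
    if track.total_cuts == 0:
        return []
    genome_bp = sum(length for _, length in genome.items())
    global_rate = track.total_cuts / genome_bp  # cuts per bp
    step = max(1, window_bp // 2)
    significant: List[GenomicInterval] = []
    for chrom, chrom_len in genome.items():
        pos, cnt = track.positions(chrom)
        if pos.size == 0:
            continue
        # only windows near observed cuts can be significant
        candidate_starts = np.unique(
            np.concatenate([(pos // step - k) * step for k in range(window_bp // step + 1)])
        )
        candidate_starts = candidate_starts[
            (candidate_starts >= 0) & (candidate_starts + window_bp <= chrom_len)
        ]
        if candidate_starts.size == 0:
            continue
        lo = np.searchsorted(pos, candidate_starts)
        hi = np.searchsorted(pos, candidate_starts + window_bp)
        csum = np.concatenate([[0], np.cumsum(cnt)])
        win_counts = csum[hi] - csum[lo]
        half_bg = local_bg_bp // 2
        centers = candidate_starts + window_bp // 2
        bg_lo = np.clip(centers - half_bg, 0, chrom_len)
        bg_hi = np.clip(centers + half_bg, 0, chrom_len)
        bg_counts = (
            csum[np.searchsorted(pos, bg_hi)] - csum[np.searchsorted(pos, bg_lo)]
        )
        local_rate = bg_counts / np.maximum(bg_hi - bg_lo, 1)
        lam = np.maximum(global_rate, local_rate) * window_bp
        pvals = stats.poisson.sf(win_counts - 1, lam)
        for start in candidate_starts[pvals < p_threshold]:
            significant.append(GenomicInterval(chrom, int(start), int(start) + window_bp))
    return merge_intervals(significant)
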