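"""DHS annotation: target genes, chromatin states, motif scanning, TF binding.

Target-gene assignment is TAD-constrained nearest TSS (distance measured to
the DHS midpoint).  Chromatin-state assignment takes the state with the most
overlapping base pairs, breaking exact ties toward the segment with the
smaller genomic coordinates.  Motif scanning scores a position weight matrix
at every offset on both strands and thresholds on an exact null score
distribution computed by dynamic programming under the 0-order background,
at a configurable p-value (default 5e-4).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, overlap_bp, overlaps_any

__all__ = [
    "PWM",
    "MotifHit",
    "assign_target_gene",
    "assign_chrom_state",
    "scan_motif",
    "label_bound",
    "read_motif_file",
]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def assign_target_gene(
    dhs: GenomicInterval,
    genes: pd.DataFrame,
    tads: Sequence[GenomicInterval],
) -> Optional[str]:
    """The gene whose TSS is nearest the DHS midpoint within the same TAD.

    ``genes`` carries columns gene_id, tss, tad_id.  The DHS belongs to the
    TAD containing its midpoint; returns None when the DHS is in no TAD or
    the TAD holds no gene.  Exact distance ties break toward the smaller TSS
    coordinate.
    """
    mid = dhs.midpoint
    tad_id = None
    for tad in tads:
        if tad.chrom == dhs.chrom and tad.start <= mid < tad.end:
            tad_id = tad.name
            break
    if tad_id is None:
        return None
    candidates = genes[genes["tad_id"] == tad_id]
    if candidates.empty:
        return None
    dist = (candidates["tss"] - mid).abs()
    best = candidates.assign(_dist=dist).sort_values(["_dist", "tss"]).iloc[0]
    return str(best["gene_id"])


def assign_chrom_state(
    dhs: GenomicInterval, segments: Sequence[GenomicInterval]
) -> str:
    """State (segment name) with the largest bp overlap; ties -> smaller start.

    Overlap is summed across segments sharing a state; an exact tie between
    states resolves to the state whose overlapping segment starts first.
    The DHS must be fully covered by the segmentation.
    """
    overlap_by_state: Dict[str, int] = {}
    min_start_by_state: Dict[str, int] = {}
    covered = 0
    for seg in segments:
        bp = overlap_bp(dhs, seg)
        if bp == 0:
            continue
        state = seg.name or "?"
        covered += bp
        overlap_by_state[state] = overlap_by_state.get(state, 0) + bp
        min_start_by_state[state] = min(
            min_start_by_state.get(state, seg.start), seg.start
        )
    if covered < len(dhs):
        raise ValueError(
            f"DHS {dhs.chrom}:{dhs.start}-{dhs.end} not fully covered by segmentation"
        )
    return min(
        overlap_by_state,
        key=lambda s: (-overlap_by_state[s], min_start_by_state[s]),
    )


@dataclass
class PWM:
    """Position weight matrix: per-position base probabilities over A, C, G, T."""

    motif_id: str
    matrix: np.ndarray  # shape (length, 4), rows sum to 1
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("matrix must have shape (length, 4)")
        if self.matrix.shape[0] < 4:
            raise ValueError("motif length must be >= 4")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each PWM position must sum to 1")
        if not np.isclose(self.background.sum(), 1.0):
            raise ValueError("background must sum to 1")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @classmethod
    def from_counts(cls, motif_id: str, counts, pseudocount: float = 0.0,
                    background=None) -> "PWM":
        counts = np.asarray(counts, dtype=float) + pseudocount
        matrix = counts / counts.sum(axis=1, keepdims=True)
        kwargs = {} if background is None else {"background": np.asarray(background)}
        return cls(motif_id, matrix, **kwargs)

    def log_odds(self, min_prob: float = 1e-4) -> np.ndarray:
        """Per-position log2 likelihood ratios vs. the background."""
        p = np.maximum(self.matrix, min_prob)
        return np.log2(p / self.background[None, :])

    def reverse_complement(self) -> "PWM":
        return PWM(self.motif_id, self.matrix[::-1, ::-1],
                   background=self.background[::-1])


def read_motif_file(path, fmt: str = "transfac") -> List[PWM]:
    """Read PWMs from a TRANSFAC or MEME (minimal) motif file via Bio.motifs."""
    from Bio import motifs as bio_motifs

    fmt_map = {"transfac": "transfac", "meme": "minimal"}
    with open(path) as handle:
        parsed = bio_motifs.parse(handle, fmt_map[fmt])
    out = []
    for m in parsed:
        counts = np.array([[m.counts[b][i] for b in _BASES]
                           for i in range(m.length)], dtype=float)
        name = m.name or getattr(m, "id", None) or "motif"
        out.append(PWM.from_counts(name, counts, pseudocount=0.25))
    return out


@dataclass(frozen=True)
class MotifHit:
    position: int  # 0-based offset of the match start on the forward strand
    strand: str
    score: float  # log2 likelihood ratio


_SCALE = 1000  # score discretization: 1/1000 log2 units


def _score_threshold(pwm: PWM, p_threshold: float, scale: int = _SCALE) -> float:
    """Smallest score whose upper-tail null probability is <= p_threshold.

    The null distribution of integerized scores under the 0-order background
    is computed exactly by dynamic programming (convolution over positions).
    Scores are discretized to 1/``scale`` log2 units after shifting each
    position to a non-negative range, matching the usual exact-p-value
    scanning construction.
    """
    lod = pwm.log_odds()
    offsets = lod.min(axis=1)
    int_scores = np.rint((lod - offsets[:, None]) * scale).astype(np.int64)
    max_total = int(int_scores.max(axis=1).sum())
    dist = np.zeros(max_total + 1)
    dist[0] = 1.0
    pos_max = 0
    for i in range(len(pwm)):
        new = np.zeros(max_total + 1)
        for b in range(4):
            s = int(int_scores[i, b])
            new[s:pos_max + s + 1] += pwm.background[b] * dist[:pos_max + 1]
        dist = new
        pos_max += int(int_scores[i].max())
    tail = np.cumsum(dist[::-1])[::-1]  # P(int score >= s)
    meets = np.nonzero(tail <= p_threshold)[0]
    if meets.size == 0:
        # short motifs: even the best attainable score has null p above the
        # threshold; a perfect match is still reported (threshold = max score)
        return max_total / scale + offsets.sum()
    return meets[0] / scale + offsets.sum()


def _forward_scores(seq_idx: np.ndarray, valid: np.ndarray, lod: np.ndarray
                    ) -> Tuple[np.ndarray, np.ndarray]:
    """Sliding log-odds scores and validity (no-N) mask over all offsets."""
    L = lod.shape[0]
    n_offsets = len(seq_idx) - L + 1
    if n_offsets <= 0:
        return np.empty(0), np.empty(0, dtype=bool)
    scores = np.zeros(n_offsets)
    ok = np.ones(n_offsets, dtype=bool)
    for i in range(L):
        window = seq_idx[i:i + n_offsets]
        scores += lod[i][np.clip(window, 0, 3)]
        ok &= valid[i:i + n_offsets]
    return scores, ok


def scan_motif(
    sequence: str, pwm: PWM, p_threshold: float = 0.0005
) -> List[MotifHit]:
    """All motif matches on both strands at exact null p <= ``p_threshold``.

    Offsets containing N are skipped (no hit).  Sequences shorter than the
    motif yield zero hits.  A minus-strand hit at position i means the
    reverse complement of sequence[i:i+L] matches the motif; its reported
    position is the forward-strand start i.
    """
    sequence = sequence.upper()
    seq_idx = np.array([_BASE_INDEX.get(c, -1) for c in sequence], dtype=np.int64)
    valid = seq_idx >= 0
    if len(sequence) < len(pwm):
        return []
    threshold = _score_threshold(pwm, p_threshold)
    # tolerance absorbs the per-position rounding of the score grid
    tol = 0.5 * len(pwm) / _SCALE + 1e-9
    hits: List[MotifHit] = []
    for strand, mat in (("+", pwm), ("-", pwm.reverse_complement())):
        lod = mat.log_odds()
        scores, ok = _forward_scores(seq_idx, valid, lod)
        for pos in np.nonzero(ok & (scores >= threshold - tol))[0]:
            hits.append(MotifHit(int(pos), strand, float(scores[pos])))
    return sorted(hits, key=lambda h: (h.position, h.strand))


def label_bound(
    dhs_set: Sequence[GenomicInterval], tf_peaks: Sequence[GenomicInterval]
) -> np.ndarray:
    """Per-DHS boolean: bound iff >= 1 bp overlap with any TF peak."""
    return overlaps_any(dhs_set, tf_peaks)
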