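"""Synthetic DNase-seq cut-site data with pulsatile/static DHS structure.

The generator emulates the study design the analysis assumes: cohorts of
STAT5-high (n = 8) and STAT5-low (n = 10) male livers plus female livers
(n = 6), with five DHS classes:

* ``dynamic_male`` - opens with each GH/STAT5 pulse; STAT5-high male
  accessibility is ``fold_dynamic_high_low`` (default 3.8) times the
  STAT5-low male level, which equals the female level.
* ``static_male`` - constitutively open in male liver at a level 2.6-fold
  below the dynamic-class peak, independent of STAT5 activity; female
  accessibility is ``fold_static_mf``-fold (default 2.6) lower than male.
* ``static_female`` - female accessibility is ``fold_static_fm``-fold
  (default 2.8) higher than male, in both STAT5 groups.
* ``dynamic_indep`` - sex-independent but pulse-responsive (off by default).
* ``background`` - static sex-independent; equal mean accessibility in every
  group.

Counts are negative-binomial (gamma-Poisson; dispersion 0 recovers Poisson),
cut positions spread around each DHS midpoint with a truncated Gaussian, and
a uniform low-rate background of cuts covers the rest of the genome.  STAT5
motif counts and binding flags are planted per class at the configured
frequencies.  Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .intervals import CutSiteTrack, Genome, GenomicInterval

__all__ = [
    "DHS_CLASSES",
    "SimConfig",
    "SimTruth",
    "simulate_annotations",
    "simulate_cut_tracks",
    "simulate_expression",
]

DHS_CLASSES = (
    "dynamic_male",
    "static_male",
    "static_female",
    "dynamic_indep",
    "background",
)

GENE_CLASSES = (
    "male_I",
    "male_II",
    "female_I",
    "female_II",
    "sex_independent",
)

#: Relative accessibility (arbitrary units) per class and group.  The
#: dynamic-class STAT5-high peak is 3.8x its trough; the static male level sits
#: fold_dynamic/2.6 below that peak per the configured static/dynamic contrast.
_CHROM_STATES = [f"E{i}" for i in range(1, 15)]


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort; defaults are the study conditions."""

    seed: int = 0
    chrom: str = "chr1"
    chrom_length: int = 10_000_000
    n_dhs: Dict[str, int] = field(
        default_factory=lambda: {
            "dynamic_male": 200,
            "static_male": 400,
            "static_female": 200,
            "dynamic_indep": 0,
            "background": 2000,
        }
    )
    dhs_width: int = 400
    fold_dynamic_high_low: float = 3.8
    fold_static_peak_ratio: float = 2.6  # dynamic peak vs. static male level
    fold_static_mf: float = 2.6
    fold_static_fm: float = 2.8
    fold_peak_vs_background: float = 2.64  # dynamic peak vs. static sex-indep level
    motif_freq: Dict[str, float] = field(
        default_factory=lambda: {
            "dynamic_male": 0.81,
            "static_male": 0.38,
            "static_female": 0.25,
            "dynamic_indep": 0.25,
            "background": 0.25,
        }
    )
    bound_freq: Dict[str, float] = field(
        default_factory=lambda: {
            "dynamic_male": 0.85,
            "static_male": 0.32,
            "static_female": 0.10,
            "dynamic_indep": 0.50,
            "background": 0.19,
        }
    )
    n_high: int = 8
    n_low: int = 10
    n_female: int = 6
    depth: float = 2e5  # mean cut sites per sample
    dispersion: float = 0.1  # NB overdispersion; 0 -> Poisson
    peak_shape_sd: float = 120.0  # bp spread of cuts around the DHS midpoint
    background_cut_fraction: float = 0.3  # share of depth scattered uniformly
    n_genes: int = 300
    tad_size: int = 500_000
    expression_noise: float = 0.0

    def __post_init__(self) -> None:
        for key in ("fold_dynamic_high_low", "fold_static_mf", "fold_static_fm"):
            if getattr(self, key) < 1:
                raise ValueError(f"{key} must be >= 1")
        for cls, p in {**self.motif_freq, **self.bound_freq}.items():
            if not 0 <= p <= 1:
                raise ValueError(f"probability for {cls} out of [0, 1]: {p}")
        for group, n in (("n_high", self.n_high), ("n_low", self.n_low),
                         ("n_female", self.n_female)):
            if n < 2:
                raise ValueError(f"{group} must be >= 2 for group testing")
        unknown = set(self.n_dhs) - set(DHS_CLASSES)
        if unknown:
            raise ValueError(f"unknown DHS classes: {sorted(unknown)}")

    @property
    def genome(self) -> Genome:
        return Genome({self.chrom: self.chrom_length})

    def class_intensity(self, dhs_class: str, group: str) -> float:
        """Mean accessibility (arbitrary units) for a DHS class in a sample group."""
        fold = self.fold_dynamic_high_low
        static_male_level = fold / self.fold_static_peak_ratio
        bg_level = fold / self.fold_peak_vs_background
        female_level = 0.98 * bg_level  # static female-biased sites sit near background
        table = {
            "dynamic_male": {"high": fold, "low": 1.0, "female": 1.0},
            "static_male": {
                "high": static_male_level,
                "low": static_male_level,
                "female": static_male_level / self.fold_static_mf,
            },
            "static_female": {
                "high": female_level / self.fold_static_fm,
                "low": female_level / self.fold_static_fm,
                "female": female_level,
            },
            "dynamic_indep": {"high": fold, "low": 1.0, "female": fold},
            "background": {"high": bg_level, "low": bg_level, "female": bg_level},
        }
        return table[dhs_class][group]


@dataclass
class SimTruth:
    """Ground-truth labels emitted alongside the synthetic data."""

    dhs: pd.DataFrame  # interval coords, class, stat5_bound, motif_count, tad_id
    genes: pd.DataFrame  # gene_id, tss, strand, biotype, tad_id, sex_bias, hypox_class
    config: SimConfig


def _place_dhs(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Place non-overlapping DHS uniformly; deterministic given the generator."""
    classes = [cls for cls in DHS_CLASSES for _ in range(config.n_dhs.get(cls, 0))]
    n_total = len(classes)
    margin = 2000  # keep aggregate windows on-chromosome
    gap = 200
    usable = config.chrom_length - 2 * margin
    slot = config.dhs_width + gap
    if n_total * slot > usable:
        raise ValueError(
            f"genome too small to place {n_total} non-overlapping DHS of width "
            f"{config.dhs_width}"
        )
    # sample distinct slot indices, then jitter within the slot's free play
    slots = np.sort(rng.choice(usable // slot, size=n_total, replace=False))
    starts = margin + slots * slot + rng.integers(0, gap, size=n_total)
    order = rng.permutation(n_total)  # decouple class from genomic position
    records = []
    for i, (start, cls_idx) in enumerate(zip(starts, order)):
        records.append(
            {
                "dhs_id": f"dhs_{i:05d}",
                "chrom": config.chrom,
                "start": int(start),
                "end": int(start) + config.dhs_width,
                "dhs_class": classes[cls_idx],
            }
        )
    return pd.DataFrame(records)


def _state_for_class(dhs_class: str, sex: str, rng: np.random.Generator) -> str:
    """Class- and sex-dependent chromatin state at a DHS.

    Mirrors the motif of the biology: open enhancers sit in E6; dynamic
    male-biased DHS fall into enhancer-marked-but-closed states (E9/E10) in
    female liver; static female-biased DHS fall into inactive states (E1/E2)
    in male liver.
    """
    def pick(states, probs):
        return states[rng.choice(len(states), p=probs)]

    if dhs_class == "dynamic_male" and sex == "F":
        return pick(["E9", "E10", "E2"], [0.5, 0.3, 0.2])
    if dhs_class == "static_male" and sex == "F":
        return pick(["E2", "E1", "E10"], [0.5, 0.3, 0.2])
    if dhs_class == "static_female" and sex == "M":
        return pick(["E1", "E2", "E12"], [0.4, 0.4, 0.2])
    return pick(["E6", "E5", "E9"], [0.6, 0.25, 0.15])


def simulate_annotations(
    config: SimConfig,
) -> Tuple[
    List[GenomicInterval],  # DHS catalog
    pd.DataFrame,  # genes with TSS
    List[GenomicInterval],  # TADs
    Dict[str, List[GenomicInterval]],  # per-sex chromatin-state segmentation
    Dict[str, List[GenomicInterval]],  # TF-binding peak sets
    SimTruth,
]:
    """Generate the static annotation inputs of the pipeline plus ground truth."""
    rng = np.random.default_rng(config.seed)
    dhs = _place_dhs(config, rng)

    # TADs tile the genome
    tads: List[GenomicInterval] = []
    boundaries = list(range(0, config.chrom_length, config.tad_size))
    for i, start in enumerate(boundaries):
        end = min(start + config.tad_size, config.chrom_length)
        tads.append(GenomicInterval(config.chrom, start, end, name=f"tad_{i:03d}"))
    mid = (dhs["start"] + dhs["end"]) // 2
    dhs["tad_id"] = [f"tad_{int(m // config.tad_size):03d}" for m in mid]

    # planted motif counts and STAT5 binding
    motif_p = dhs["dhs_class"].map(config.motif_freq).to_numpy(float)
    has_motif = rng.random(len(dhs)) < motif_p
    extra = rng.poisson(
        np.where(dhs["dhs_class"] == "dynamic_male", 0.9, 0.3), size=len(dhs)
    )
    dhs["motif_count"] = np.where(has_motif, 1 + extra, 0)
    bound_p = dhs["dhs_class"].map(config.bound_freq).to_numpy(float)
    dhs["stat5_bound"] = rng.random(len(dhs)) < bound_p

    # chromatin-state segmentation per sex: DHS-covering segments get class-
    # dependent states; gaps are tiled with background-weighted random states
    states: Dict[str, List[GenomicInterval]] = {}
    for sex in ("M", "F"):
        segs: List[GenomicInterval] = []
        cursor = 0
        for row in dhs.sort_values("start").itertuples():
            seg_start = max(cursor, row.start - 100)
            while cursor < seg_start:
                length = min(int(rng.integers(2000, 50_000)), seg_start - cursor)
                state = _CHROM_STATES[rng.choice(14)]
                segs.append(GenomicInterval(config.chrom, cursor, cursor + length,
                                            name=state))
                cursor += length
            seg_end = row.end + 100
            segs.append(
                GenomicInterval(config.chrom, cursor, seg_end,
                                name=_state_for_class(row.dhs_class, sex, rng))
            )
            cursor = seg_end
        while cursor < config.chrom_length:
            length = min(int(rng.integers(2000, 50_000)), config.chrom_length - cursor)
            segs.append(GenomicInterval(config.chrom, cursor, cursor + length,
                                        name=_CHROM_STATES[rng.choice(14)]))
            cursor += length
        states[sex] = segs

    # STAT5 ChIP peaks at bound DHS (a sub-interval) plus decoys elsewhere
    stat5_peaks: List[GenomicInterval] = []
    for row in dhs[dhs["stat5_bound"]].itertuples():
        center = (row.start + row.end) // 2 + int(rng.integers(-50, 51))
        stat5_peaks.append(GenomicInterval(config.chrom, center - 75, center + 75))
    tf_peaks = {"STAT5": sorted(stat5_peaks, key=lambda iv: iv.start)}

    genes = _simulate_genes(config, tads, rng)

    catalog = [
        GenomicInterval(r.chrom, r.start, r.end, name=r.dhs_id)
        for r in dhs.itertuples()
    ]
    truth = SimTruth(dhs=dhs, genes=genes, config=config)
    return catalog, genes[["gene_id", "tss", "strand", "biotype", "tad_id"]].copy(), \
        tads, states, tf_peaks, truth


def _simulate_genes(
    config: SimConfig, tads: Sequence[GenomicInterval], rng: np.random.Generator
) -> pd.DataFrame:
    class_probs = {
        "male_I": 0.15,
        "male_II": 0.05,
        "female_I": 0.15,
        "female_II": 0.05,
        "sex_independent": 0.60,
    }
    labels = rng.choice(
        list(class_probs), size=config.n_genes, p=list(class_probs.values())
    )
    tss = np.sort(rng.choice(config.chrom_length, size=config.n_genes, replace=False))
    records = []
    for i, (pos, label) in enumerate(zip(tss, labels)):
        tad_idx = int(pos // config.tad_size)
        records.append(
            {
                "gene_id": f"gene_{i:04d}",
                "tss": int(pos),
                "strand": "+" if rng.random() < 0.5 else "-",
                "biotype": "refseq" if rng.random() < 0.85 else "lncRNA",
                "tad_id": f"tad_{tad_idx:03d}",
                "sex_bias_true": label.split("_")[0]
                if label != "sex_independent" else "independent",
                "hypox_class_true": label.split("_")[1]
                if label != "sex_independent" else "none",
            }
        )
    return pd.DataFrame(records)


def _nb_counts(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """Negative-binomial counts via gamma-Poisson mixing; dispersion 0 -> Poisson."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion)
    return rng.poisson(lam)


def simulate_cut_tracks(
    config: SimConfig, truth: SimTruth
) -> Tuple[Dict[str, CutSiteTrack], pd.DataFrame]:
    """Draw per-sample cut-site tracks plus the sample sheet.

    Per-DHS per-sample counts are negative-binomial with mean equal to the
    depth-scaled class intensity for the sample's group; cut positions are
    Gaussian around the DHS midpoint truncated to the DHS +/- 500 bp, and a
    uniform background of cuts covers the chromosome.
    """
    rng = np.random.default_rng(config.seed + 1)
    dhs = truth.dhs
    groups = (
        [("high", "M", "high", "intact")] * config.n_high
        + [("low", "M", "low", "intact")] * config.n_low
        + [("female", "F", "NA", "intact")] * config.n_female
    )
    intensity = {
        group: dhs["dhs_class"].map(
            lambda cls, g=group: config.class_intensity(cls, g)
        ).to_numpy(float)
        for group in ("high", "low", "female")
    }
    # scale intensity units so an average library lands near `depth`
    dhs_budget = config.depth * (1 - config.background_cut_fraction)
    mean_units = np.mean([intensity[g].sum() for g in ("high", "low", "female")])
    unit = dhs_budget / mean_units

    mid = ((dhs["start"] + dhs["end"]) // 2).to_numpy()
    lo_bound = (dhs["start"] - 500).to_numpy()
    hi_bound = (dhs["end"] + 500).to_numpy()

    tracks: Dict[str, CutSiteTrack] = {}
    meta_rows = []
    counters = {"high": 0, "low": 0, "female": 0}
    for group, sex, stat5, treatment in groups:
        counters[group] += 1
        sample_id = f"{group}_{counters[group]:02d}"
        counts = _nb_counts(rng, intensity[group] * unit, config.dispersion)
        positions = []
        for i, c in enumerate(counts):
            if c == 0:
                continue
            offsets = rng.normal(0.0, config.peak_shape_sd, size=c)
            pos = np.clip(
                mid[i] + np.rint(offsets).astype(np.int64), lo_bound[i], hi_bound[i] - 1
            )
            positions.append(pos)
        n_bg = rng.poisson(config.depth * config.background_cut_fraction)
        positions.append(rng.integers(0, config.chrom_length, size=n_bg))
        all_pos = np.clip(np.concatenate(positions), 0, config.chrom_length - 1)
        tracks[sample_id] = CutSiteTrack.from_positions({config.chrom: all_pos})
        meta_rows.append(
            {
                "sample_id": sample_id,
                "sex": sex,
                "stat5_activity": stat5,
                "treatment": treatment,
                "group": group,
            }
        )
    return tracks, pd.DataFrame(meta_rows)


def simulate_expression(config: SimConfig, truth: SimTruth) -> pd.DataFrame:
    """Emit a gene expression table (FPKM, fold-changes, adjusted p-values)
    consistent with each gene's true sex-bias and hypophysectomy class.

    With ``expression_noise = 0`` the table is classified back into its truth
    labels exactly by the gene-class calling rules.
    """
    rng = np.random.default_rng(config.seed + 2)
    genes = truth.genes
    rows = []
    noise = config.expression_noise
    for g in genes.itertuples():
        bias = g.sex_bias_true
        hypox = g.hypox_class_true
        jitter = lambda x: x * float(np.exp(rng.normal(0.0, noise))) if noise > 0 else x
        base = float(rng.uniform(1.0, 50.0))
        # defaults: clearly non-responsive
        row = {
            "gene_id": g.gene_id,
            "biotype": g.biotype,
            "fpkm_m": base,
            "fpkm_f": base,
            "fc_mf": 1.0,
            "padj_mf": 0.9,
            "hypox_fc_m": 1.0,
            "hypox_padj_m": 0.9,
            "hypox_fc_f": 1.0,
            "hypox_padj_f": 0.9,
        }
        if bias == "independent":
            row["fc_mf"] = jitter(float(rng.uniform(0.9, 1.1)))
            rows.append(row)
            continue
        fc_threshold = 1.5 if g.biotype == "refseq" else 2.0
        fold = jitter(float(rng.uniform(fc_threshold * 1.5, 10.0)))
        if bias == "male":
            row.update(fc_mf=fold, padj_mf=0.001, fpkm_m=base * fold, fpkm_f=base)
            dominant, opposite = "m", "f"
        else:
            row.update(fc_mf=1.0 / fold, padj_mf=0.001, fpkm_f=base * fold, fpkm_m=base)
            dominant, opposite = "f", "m"
        if hypox == "I":
            row[f"hypox_fc_{dominant}"] = jitter(float(rng.uniform(0.05, 0.4)))
            row[f"hypox_padj_{dominant}"] = 0.001
        elif hypox == "II":
            row[f"hypox_fc_{opposite}"] = jitter(float(rng.uniform(2.5, 8.0)))
            row[f"hypox_padj_{opposite}"] = 0.001
        rows.append(row)
    return pd.DataFrame(rows)
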