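"""End-to-end orchestration: simulate -> differential+QC -> classify ->
profiles -> annotate -> geneclass -> enrich, with a hashed artifact manifest.

Each stage writes plain-text artifacts (BED/TSV/JSON) into the output
directory and registers them in a manifest of SHA-256 content hashes;
re-running with the same config and seed reproduces identical hashes.  A
stage finding its inputs neither in memory nor on disk raises
``PipelineError`` naming the stage to run first.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import annotate as annotate_mod
from . import classify as classify_mod
from . import differential as diff_mod
from . import enrich as enrich_mod
from . import gene_classes as gc_mod
from . import profiles as prof_mod
from .intervals import (
    CutSiteTrack,
    Genome,
    GenomicInterval,
    call_peaks,
    merge_intervals,
    read_bed,
    write_bed,
)
from .simulate import (
    SimConfig,
    SimTruth,
    simulate_annotations,
    simulate_cut_tracks,
    simulate_expression,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "STAGES", "run"]

STAGES = ("simulate", "diff", "classify", "profile", "annotate", "geneclass", "enrich")

#: sex-bias designation applied to the reference catalog, keyed by truth class
SEX_BIAS_OF_CLASS = {
    "dynamic_male": "male",
    "static_male": "male",
    "static_female": "female",
    "dynamic_indep": "independent",
    "background": "independent",
}


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    outdir: str = "pulsedhs_out"
    seed: int = 0
    sim: SimConfig = None  # type: ignore[assignment]
    window_bp: int = 200
    step: Optional[int] = None
    fc_min: float = 2.0
    fdr_max: float = 0.05
    top_n: Sequence[int] = (200, 600)
    lowess_frac: float = 0.02
    motif_p_threshold: float = 0.0005
    es_variant_overlap: str = "percentage"
    es_variant_state: str = "odds"

    def __post_init__(self) -> None:
        if self.sim is None:
            self.sim = SimConfig(seed=self.seed)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        sim_data = data.pop("sim", None)
        cfg = cls(**data)
        if sim_data:
            base = dataclasses.asdict(cfg.sim)
            base.update(sim_data)
            cfg.sim = SimConfig(**base)
        return cfg


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


class _Context:
    """In-memory stage outputs plus artifact registry."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.data: Dict[str, object] = {}
        self.artifacts: List[Path] = []

    def path(self, *parts: str) -> Path:
        p = self.outdir.joinpath(*parts)
        p.parent.mkdir(parents=True, exist_ok=True)
        return p

    def register(self, path: Path) -> None:
        self.artifacts.append(path)

    def write_tsv(self, frame: pd.DataFrame, *parts: str) -> Path:
        p = self.path(*parts)
        frame.to_csv(p, sep="\t", index=False)
        self.register(p)
        return p

    def write_bed(self, intervals, *parts: str) -> Path:
        p = self.path(*parts)
        write_bed(intervals, p)
        self.register(p)
        return p

    def write_json(self, obj, *parts: str) -> Path:
        p = self.path(*parts)
        with open(p, "w") as handle:
            json.dump(obj, handle, indent=2, sort_keys=True)
            handle.write("\n")
        self.register(p)
        return p


def _require(ctx: _Context, key: str, stage_needed: str, loader=None):
    if key in ctx.data:
        return ctx.data[key]
    if loader is not None:
        try:
            value = loader(ctx)
        except FileNotFoundError:
            value = None
        if value is not None:
            ctx.data[key] = value
            return value
    raise PipelineError(
        f"missing dependency {key!r}: run stage {stage_needed!r} first"
    )


# ---------------------------------------------------------------- loaders

def _load_tracks(ctx: _Context):
    cuts_dir = ctx.outdir / "cuts"
    if not cuts_dir.is_dir():
        return None
    tracks = {}
    for bed in sorted(cuts_dir.glob("*.bed")):
        positions: Dict[str, List[int]] = {}
        counts_list: Dict[str, List[int]] = {}
        for iv in read_bed(bed):
            positions.setdefault(iv.chrom, []).append(iv.start)
            counts_list.setdefault(iv.chrom, []).append(int(iv.score or 1))
        expanded = {
            chrom: np.repeat(positions[chrom], counts_list[chrom])
            for chrom in positions
        }
        tracks[bed.stem] = CutSiteTrack.from_positions(expanded)
    return tracks or None


def _load_tsv(name):
    def loader(ctx: _Context):
        p = ctx.outdir / name
        if not p.is_file():
            return None
        return pd.read_csv(p, sep="\t")
    return loader


def _load_bed(name):
    def loader(ctx: _Context):
        p = ctx.outdir / name
        if not p.is_file():
            return None
        return read_bed(p)
    return loader


def _load_meta(ctx: _Context):
    frame = _load_tsv("samples.tsv")(ctx)
    return frame


# ---------------------------------------------------------------- stages

def _stage_simulate(ctx: _Context) -> None:
    sim = ctx.config.sim
    catalog, genes, tads, states, tf_peaks, truth = simulate_annotations(sim)
    tracks, meta = simulate_cut_tracks(sim, truth)
    expression = simulate_expression(sim, truth)

    ctx.data.update(
        catalog=catalog, genes=genes, tads=tads, states=states,
        tf_peaks=tf_peaks, truth=truth, tracks=tracks, meta=meta,
        expression=expression,
    )
    ctx.write_bed(catalog, "catalog.bed")
    ctx.write_bed(tads, "tads.bed")
    for sex, segs in states.items():
        ctx.write_bed(segs, f"states_{sex}.bed")
    for tf, peaks in tf_peaks.items():
        ctx.write_bed(peaks, f"tf_{tf}.bed")
    ctx.write_tsv(genes, "genes.tsv")
    ctx.write_tsv(meta, "samples.tsv")
    ctx.write_tsv(expression, "expression.tsv")
    ctx.write_tsv(truth.dhs, "truth_dhs.tsv")
    ctx.write_tsv(truth.genes, "truth_genes.tsv")
    for sample_id, track in tracks.items():
        rows = []
        for chrom in track.chroms:
            pos, cnt = track.positions(chrom)
            rows.append(pd.DataFrame(
                {"chrom": chrom, "start": pos, "end": pos + 1,
                 "name": ".", "score": cnt, "strand": "."}
            ))
        frame = pd.concat(rows) if rows else pd.DataFrame(
            columns=["chrom", "start", "end", "name", "score", "strand"])
        p = ctx.path("cuts", f"{sample_id}.bed")
        frame.to_csv(p, sep="\t", index=False, header=False)
        ctx.register(p)


def _stage_diff(ctx: _Context) -> None:
    cfg = ctx.config
    tracks = _require(ctx, "tracks", "simulate", _load_tracks)
    meta = _require(ctx, "meta", "simulate", _load_meta)
    genome = cfg.sim.genome

    male = meta[meta["group"].isin(["high", "low"])]
    male_tracks = {s: tracks[s] for s in male["sample_id"]}
    labels = dict(zip(male["sample_id"], male["group"]))

    # per-sample peak calls merged into the peak-union catalog
    peaks_per_sample = [
        call_peaks(track, genome) for track in male_tracks.values()
    ]
    peak_union = merge_intervals([iv for peaks in peaks_per_sample for iv in peaks])

    def run_test(selected: Mapping[str, CutSiteTrack]) -> pd.DataFrame:
        wc = diff_mod.window_counts(selected, genome, window_bp=cfg.window_bp,
                                    step=cfg.step)
        sel_labels = {s: labels[s] for s in selected}
        return diff_mod.test_windows(wc, sel_labels)

    stats = run_test(male_tracks)
    regions = diff_mod.call_differential_regions(
        stats, peak_union, fc_min=cfg.fc_min, fdr_max=cfg.fdr_max
    )
    qc = diff_mod.detect_outliers(
        regions, male_tracks, labels, diff_mod.QCConfig(top_n=tuple(
            min(n, max(len(regions), 2)) for n in cfg.top_n))
    )
    flagged = set(qc.loc[qc["flagged"], "sample_id"])
    if flagged:
        logger.info("diff: excluding %d flagged outlier samples: %s",
                    len(flagged), sorted(flagged))
        kept = {s: t for s, t in male_tracks.items() if s not in flagged}
        stats = run_test(kept)
        regions = diff_mod.call_differential_regions(
            stats, peak_union, fc_min=cfg.fc_min, fdr_max=cfg.fdr_max
        )
    ctx.data.update(window_stats=stats, regions=regions, qc=qc,
                    peak_union=peak_union)
    ctx.write_tsv(stats, "window_stats.tsv")
    ctx.write_tsv(regions, "regions.tsv")
    ctx.write_tsv(qc, "qc.tsv")
    ctx.write_bed(peak_union, "peak_union.bed")


def _region_list(regions: pd.DataFrame, direction: str) -> List[GenomicInterval]:
    return diff_mod.region_intervals(regions, direction)


def _stage_classify(ctx: _Context) -> None:
    catalog = _require(ctx, "catalog", "simulate", _load_bed("catalog.bed"))
    regions = _require(ctx, "regions", "diff", _load_tsv("regions.tsv"))
    truth_dhs = _require(ctx, "truth_df", "simulate", _load_tsv("truth_dhs.tsv"))

    response = classify_mod.label_response(
        catalog,
        _region_list(regions, "up_in_A"),
        _region_list(regions, "up_in_B"),
    )
    sex_bias = truth_dhs["dhs_class"].map(SEX_BIAS_OF_CLASS).tolist()
    counts = classify_mod.cross_classify(sex_bias, response)
    annotations = pd.DataFrame(
        {
            "dhs_id": [iv.name for iv in catalog],
            "chrom": [iv.chrom for iv in catalog],
            "start": [iv.start for iv in catalog],
            "end": [iv.end for iv in catalog],
            "sex_bias": sex_bias,
            "response": response,
        }
    )
    ctx.data.update(dhs_annotations=annotations, class_counts=counts)
    ctx.write_tsv(annotations, "dhs_annotations.tsv")
    ctx.write_json(counts, "class_counts.json")


def _class_key(row) -> str:
    axis = "dynamic" if row.response == "dynamic_opened" else "static"
    return f"{axis}_{row.sex_bias}"


def _stage_profile(ctx: _Context) -> None:
    cfg = ctx.config
    tracks = _require(ctx, "tracks", "simulate", _load_tracks)
    meta = _require(ctx, "meta", "simulate", _load_meta)
    annotations = _require(ctx, "dhs_annotations", "classify",
                           _load_tsv("dhs_annotations.tsv"))
    catalog = _require(ctx, "catalog", "simulate", _load_bed("catalog.bed"))
    genome = cfg.sim.genome

    pooled = {
        group: CutSiteTrack.pool([tracks[s] for s in sub["sample_id"]])
        for group, sub in meta.groupby("group")
    }
    reference = list(catalog)
    rows = []
    peaks: Dict[str, Dict[str, float]] = {}
    for class_key in sorted({_class_key(r) for r in annotations.itertuples()}):
        members = [
            iv for iv, r in zip(catalog, annotations.itertuples())
            if _class_key(r) == class_key
        ]
        windows = prof_mod.center_windows(members, genome)
        if not windows:
            continue
        peaks[class_key] = {}
        for group, track in pooled.items():
            profile = prof_mod.aggregate(
                track, windows, reference, lowess_frac=cfg.lowess_frac
            )
            peaks[class_key][group] = profile.peak_value
            rows.append(pd.DataFrame(
                {"dhs_set": class_key, "group": group,
                 "offset": profile.offsets, "value": profile.values}
            ))
    profiles_frame = pd.concat(rows, ignore_index=True)
    ctx.data.update(profiles=profiles_frame, profile_peaks=peaks)
    ctx.write_tsv(profiles_frame, "profiles.tsv")
    ctx.write_json(peaks, "profile_peaks.json")


def _stage_annotate(ctx: _Context) -> None:
    catalog = _require(ctx, "catalog", "simulate", _load_bed("catalog.bed"))
    genes = _require(ctx, "genes", "simulate", _load_tsv("genes.tsv"))
    tads = _require(ctx, "tads", "simulate", _load_bed("tads.bed"))
    truth_dhs = _require(ctx, "truth_df", "simulate", _load_tsv("truth_dhs.tsv"))
    annotations = _require(ctx, "dhs_annotations", "classify",
                           _load_tsv("dhs_annotations.tsv"))
    states = ctx.data.get("states") or {
        "M": read_bed(ctx.outdir / "states_M.bed"),
        "F": read_bed(ctx.outdir / "states_F.bed"),
    }
    tf_peaks = ctx.data.get("tf_peaks") or {
        "STAT5": read_bed(ctx.outdir / "tf_STAT5.bed")
    }
    bound = annotate_mod.label_bound(catalog, tf_peaks["STAT5"])
    target = [annotate_mod.assign_target_gene(iv, genes, tads) for iv in catalog]
    state_m = [annotate_mod.assign_chrom_state(iv, states["M"]) for iv in catalog]
    state_f = [annotate_mod.assign_chrom_state(iv, states["F"]) for iv in catalog]
    master = annotations.copy()
    master["stat5_bound"] = bound
    master["motif_count"] = truth_dhs["motif_count"].to_numpy()
    master["state_m"] = state_m
    master["state_f"] = state_f
    master["target_gene"] = target
    ctx.data["master"] = master
    ctx.write_tsv(master, "master_annotations.tsv")


def _stage_geneclass(ctx: _Context) -> None:
    expression = _require(ctx, "expression", "simulate", _load_tsv("expression.tsv"))
    labels = gc_mod.classify_genes(expression)
    tab = gc_mod.tabulate_classes(labels)
    ctx.data.update(gene_labels=labels, gene_class_table=tab)
    ctx.write_tsv(labels, "gene_classes.tsv")
    ctx.write_tsv(tab, "gene_class_summary.tsv")


def _stage_enrich(ctx: _Context) -> None:
    cfg = ctx.config
    master = _require(ctx, "master", "annotate", _load_tsv("master_annotations.tsv"))
    key = master.apply(
        lambda r: ("dynamic" if r["response"] == "dynamic_opened" else "static")
        + "_" + r["sex_bias"], axis=1,
    )
    ids = master["dhs_id"]
    foregrounds = {
        name: set(ids[key == name])
        for name in ("dynamic_male", "static_male", "static_female")
        if (key == name).any()
    }
    background = set(ids[key == "static_independent"])
    bound_mask = master["stat5_bound"].astype(str).str.lower().isin(["true", "1"])
    features_overlap = {
        "stat5_bound": set(ids[bound_mask]),
        "stat5_motif": set(ids[master["motif_count"] > 0]),
    }
    # only states represented in the background have a defined ratio-of-ratios
    features_state = {
        f"state_{s}": members
        for s in sorted(master["state_m"].unique())
        if (members := set(ids[master["state_m"] == s])) & background
    }
    overlap_res = enrich_mod.enrich_batch(
        foregrounds, features_overlap, background, variant=cfg.es_variant_overlap
    )
    state_res = enrich_mod.enrich_batch(
        foregrounds, features_state, background, variant=cfg.es_variant_state
    )
    results = pd.concat(
        [overlap_res.assign(batch="tf_overlap"), state_res.assign(batch="chrom_state")],
        ignore_index=True,
    )
    ctx.data["enrichment"] = results
    ctx.write_tsv(results, "enrichment.tsv")


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "diff": _stage_diff,
    "classify": _stage_classify,
    "profile": _stage_profile,
    "annotate": _stage_annotate,
    "geneclass": _stage_geneclass,
    "enrich": _stage_enrich,
}


def run(
    config: PipelineConfig, stages: Optional[Sequence[str]] = None
) -> Dict[str, str]:
    """Execute the requested stages in dependency order; return the manifest.

    ``stages`` defaults to all stages.  The manifest (relative path ->
    SHA-256) is also written to ``manifest.json`` in the output directory.
    """
    stages = list(STAGES) if stages is None else list(stages)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise PipelineError(f"unknown stages: {sorted(unknown)}")
    ctx = _Context(config)
    for stage in STAGES:
        if stage in stages:
            logger.info("running stage %s", stage)
            _STAGE_FUNCS[stage](ctx)
    manifest = {
        str(p.relative_to(ctx.outdir)): _sha256(p) for p in ctx.artifacts
    }
    with open(ctx.outdir / "manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
        handle.write("\n")
    return manifest
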