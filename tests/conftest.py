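import numpy as np
import pandas as pd
import pytest

from pulsedhs import differential as dm
from pulsedhs.classify import label_response
from pulsedhs.intervals import CutSiteTrack, call_peaks, merge_intervals
from pulsedhs.simulate import (
    SimConfig,
    simulate_annotations,
    simulate_cut_tracks,
    simulate_expression,
)


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A fast, reduced cohort for smoke/unit tests."""
    return SimConfig(
        seed=11,
        chrom_length=2_000_000,
        n_dhs={
            "dynamic_male": 40,
            "static_male": 60,
            "static_female": 40,
            "dynamic_indep": 10,
            "background": 300,
        },
        depth=5e4,
        n_genes=80,
        tad_size=200_000,
    )


@pytest.fixture(scope="session")
def small_sim(small_config):
    catalog, genes, tads, states, tf_peaks, truth = simulate_annotations(small_config)
    tracks, meta = simulate_cut_tracks(small_config, truth)
    expression = simulate_expression(small_config, truth)
    return {
        "config": small_config,
        "catalog": catalog,
        "genes": genes,
        "tads": tads,
        "states": states,
        "tf_peaks": tf_peaks,
        "truth": truth,
        "tracks": tracks,
        "meta": meta,
        "expression": expression,
    }


@pytest.fixture(scope="session")
def default_sim():
    """The default study-scale simulation plus the differential stage outputs.

    Shared session-wide because the full cohort (2800 DHS, 24 samples,
    ~2e5 cuts each) takes tens of seconds to generate and test.
    """
    config = SimConfig(seed=20_260_919)
    catalog, genes, tads, states, tf_peaks, truth = simulate_annotations(config)
    tracks, meta = simulate_cut_tracks(config, truth)

    male = meta[meta["group"].isin(["high", "low"])]
    male_tracks = {s: tracks[s] for s in male["sample_id"]}
    labels = dict(zip(male["sample_id"], male["group"]))
    peaks = [call_peaks(track, config.genome) for track in male_tracks.values()]
    peak_union = merge_intervals([iv for p in peaks for iv in p])
    wc = dm.window_counts(male_tracks, config.genome)
    stats = dm.test_windows(wc, labels)
    regions = dm.call_differential_regions(stats, peak_union)
    response = label_response(
        catalog,
        dm.region_intervals(regions, "up_in_A"),
        dm.region_intervals(regions, "up_in_B"),
    )
    return {
        "config": config,
        "catalog": catalog,
        "genes": genes,
        "tads": tads,
        "states": states,
        "tf_peaks": tf_peaks,
        "truth": truth,
        "tracks": tracks,
        "meta": meta,
        "peak_union": peak_union,
        "window_stats": stats,
        "regions": regions,
        "response": response,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
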