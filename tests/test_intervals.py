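import numpy as np
import pytest

from pulsedhs.intervals import (
    BedParseError,
    CutSiteTrack,
    Genome,
    GenomicInterval,
    ReadRecord,
    call_peaks,
    extract_cut_sites,
    filter_peaks,
    merge_intervals,
    overlap_bp,
    overlaps_any,
    read_bed,
    write_bed,
)


def brute_force_union(intervals):
    """Per-base occupancy oracle for merge."""
    by_chrom = {}
    for iv in intervals:
        occ = by_chrom.setdefault(iv.chrom, set())
        occ.update(range(iv.start, iv.end))
    out = []
    for chrom in sorted(by_chrom):
        positions = sorted(by_chrom[chrom])
        start = prev = positions[0]
        for p in positions[1:]:
            if p != prev + 1:
                out.append(GenomicInterval(chrom, start, prev + 1))
                start = p
            prev = p
        out.append(GenomicInterval(chrom, start, prev + 1))
    return out


class TestGenomicInterval:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"chrom": "chr1", "start": 200, "end": 100},
            {"chrom": "chr1", "start": 100, "end": 100},
            {"chrom": "chr1", "start": -1, "end": 100},
            {"chrom": "", "start": 0, "end": 100},
            {"chrom": "chr1", "start": 0, "end": 100, "strand": "x"},
        ],
    )
    def test_invariant_violations_raise(self, kwargs):
        with pytest.raises(ValueError):
            GenomicInterval(**kwargs)

    def test_length_and_midpoint(self):
        iv = GenomicInterval("chr1", 100, 301)
        assert len(iv) == 201
        assert iv.midpoint == 200


class TestBedIO:
    def test_parse_simple_line(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t200\n")
        assert read_bed(p) == [GenomicInterval("chr1", 100, 200)]

    def test_round_trip_identity(self, tmp_path):
        intervals = [
            GenomicInterval("chr1", 100, 200, name="a", score=3.5, strand="+"),
            GenomicInterval("chr2", 0, 50, name="b", score=-1.0, strand="-"),
            GenomicInterval("chr2", 70, 90),
        ]
        p = tmp_path / "rt.bed"
        write_bed(intervals, p)
        again = read_bed(p)
        assert again == intervals
        write_bed(again, tmp_path / "rt2.bed")
        assert (tmp_path / "rt.bed").read_text() == (tmp_path / "rt2.bed").read_text()

    @pytest.mark.parametrize(
        "content",
        ["chr1\t200\t100\n", "chr1\tabc\t100\n", "chr1\t100\n"],
    )
    def test_malformed_line_names_line_number(self, tmp_path, content):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t1\t2\n" + content)
        with pytest.raises(BedParseError, match="line 2"):
            read_bed(p)


class TestMerge:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ([("chr1", 100, 200), ("chr1", 150, 250)], [("chr1", 100, 250)]),
            ([("chr1", 100, 200), ("chr1", 200, 300)], [("chr1", 100, 300)]),
            ([("chr1", 100, 200), ("chr2", 100, 200)],
             [("chr1", 100, 200), ("chr2", 100, 200)]),
            ([], []),
        ],
    )
    def test_examples(self, raw, expected):
        got = merge_intervals([GenomicInterval(*r) for r in raw])
        assert [(iv.chrom, iv.start, iv.end) for iv in got] == expected

    def test_matches_per_base_oracle_and_idempotent(self, rng):
        starts = rng.integers(0, 5000, size=1000)
        lengths = rng.integers(1, 120, size=1000)
        chroms = rng.choice(["chr1", "chr2"], size=1000)
        ivs = [
            GenomicInterval(c, int(s), int(s + l))
            for c, s, l in zip(chroms, starts, lengths)
        ]
        merged = merge_intervals(ivs)
        assert merged == brute_force_union(ivs)
        assert merge_intervals(merged) == merged
        # sorted, non-overlapping, non-bookended
        for a, b in zip(merged, merged[1:]):
            if a.chrom == b.chrom:
                assert a.end < b.start


class TestOverlap:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            (("chr1", 100, 300), ("chr1", 250, 500), 50),
            (("chr1", 100, 200), ("chr2", 100, 200), 0),
            (("chr1", 100, 200), ("chr1", 100, 200), 100),
            (("chr1", 100, 200), ("chr1", 200, 300), 0),
        ],
    )
    def test_examples(self, a, b, expected):
        assert overlap_bp(GenomicInterval(*a), GenomicInterval(*b)) == expected

    def test_symmetric_and_bounded(self, rng):
        for _ in range(200):
            s1, s2 = rng.integers(0, 1000, size=2)
            a = GenomicInterval("chr1", int(s1), int(s1) + int(rng.integers(1, 100)))
            b = GenomicInterval("chr1", int(s2), int(s2) + int(rng.integers(1, 100)))
            assert overlap_bp(a, b) == overlap_bp(b, a)
            assert 0 <= overlap_bp(a, b) <= min(len(a), len(b))

    def test_overlaps_any_agrees_with_pairwise(self, rng):
        subjects = [
            GenomicInterval("chr1", int(s), int(s) + int(l))
            for s, l in zip(rng.integers(0, 10000, 300), rng.integers(1, 200, 300))
        ]
        queries = [
            GenomicInterval("chr1", int(s), int(s) + int(l))
            for s, l in zip(rng.integers(0, 10000, 300), rng.integers(1, 200, 300))
        ]
        got = overlaps_any(queries, subjects)
        expected = [
            any(overlap_bp(q, s) > 0 for s in subjects) for q in queries
        ]
        assert got.tolist() == expected


class TestExtractCutSites:
    def test_five_prime_rule(self):
        track = extract_cut_sites([ReadRecord("chr1", 100, 150, "+")])
        assert track.count_in("chr1", 100, 101) == 1
        track = extract_cut_sites([ReadRecord("chr1", 100, 150, "-")])
        assert track.count_in("chr1", 149, 150) == 1
        assert track.count_in("chr1", 100, 101) == 0

    def test_additivity_and_total(self):
        reads = [ReadRecord("chr1", 100, 150, "+")] * 3
        track = extract_cut_sites(reads)
        assert track.count_in("chr1", 100, 101) == 3
        assert track.total_mapped_reads == 3

    def test_off_end_reads_skipped_and_conserved(self):
        genome = Genome({"chr1": 120})
        reads = [
            ReadRecord("chr1", 100, 150, "-"),  # cut at 149, off end
            ReadRecord("chr1", 10, 60, "+"),
            ReadRecord("chrX", 0, 50, "+"),  # unknown chromosome
        ]
        track = extract_cut_sites(reads, genome)
        assert track.skipped_reads == 2
        assert track.total_cuts + track.skipped_reads == len(reads)


class TestFilterPeaks:
    def _reads(self, n, start=100, distinct=0):
        reads = [ReadRecord("chr1", start, start + 50, "+")] * n
        reads += [ReadRecord("chr1", start + 5, start + 55, "+")] * distinct
        return reads

    def test_blacklist_removal(self):
        peaks = [GenomicInterval("chr1", 100, 200), GenomicInterval("chr1", 500, 600)]
        blacklist = [GenomicInterval("chr1", 150, 160)]
        kept = filter_peaks(peaks, blacklist, [])
        assert kept == [GenomicInterval("chr1", 500, 600)]

    def test_straight_peak_rule(self):
        peak = [GenomicInterval("chr1", 90, 180)]
        # 5 identical reads only -> straight peak, removed
        assert filter_peaks(peak, [], self._reads(5)) == []
        # 4 identical reads -> kept
        assert filter_peaks(peak, [], self._reads(4)) == peak
        # 5 identical + 1 distinct overlapping read -> kept
        assert filter_peaks(peak, [], self._reads(5, distinct=1)) == peak

    def test_output_subset_of_input(self, rng):
        peaks = [
            GenomicInterval("chr1", int(s), int(s) + 100)
            for s in rng.integers(0, 100000, 50)
        ]
        blacklist = [GenomicInterval("chr1", 0, 20000)]
        kept = filter_peaks(peaks, blacklist, [])
        assert set(kept) <= set(peaks)


class TestCallPeaks:
    def _uniform_track(self, rng, chrom_len=200_000, rate=0.002):
        n = rng.poisson(chrom_len * rate)
        return CutSiteTrack.from_positions(
            {"chr1": rng.integers(0, chrom_len, size=n)}
        )

    def test_zero_track_gives_no_peaks(self):
        track = CutSiteTrack.from_positions({})
        assert call_peaks(track, Genome({"chr1": 10_000})) == []

    def test_single_spike_found(self, rng):
        genome = Genome({"chr1": 200_000})
        base = self._uniform_track(rng)
        spike = rng.normal(100_000, 30, size=2000).astype(int)
        pos, _ = base.positions("chr1")
        track = CutSiteTrack.from_positions({"chr1": np.concatenate([pos, spike])})
        peaks = call_peaks(track, genome)
        assert len(peaks) == 1
        assert peaks[0].start < 100_000 < peaks[0].end

    def test_two_separated_spikes_give_two_peaks(self, rng):
        genome = Genome({"chr1": 200_000})
        spikes = np.concatenate(
            [
                rng.normal(50_000, 30, size=2000).astype(int),
                rng.normal(150_000, 30, size=2000).astype(int),
            ]
        )
        base = self._uniform_track(rng)
        pos, _ = base.positions("chr1")
        track = CutSiteTrack.from_positions({"chr1": np.concatenate([pos, spikes])})
        peaks = call_peaks(track, genome)
        assert len(peaks) == 2

    def test_window_must_be_smaller_than_background(self):
        track = CutSiteTrack.from_positions({"chr1": [5]})
        with pytest.raises(ValueError):
            call_peaks(track, Genome({"chr1": 100}), window_bp=500, local_bg_bp=100)


class TestCutSiteTrack:
    def test_counts_cannot_exceed_total(self):
        with pytest.raises(ValueError):
            CutSiteTrack(
                {"chr1": (np.array([1, 2]), np.array([3, 4]))}, total_mapped_reads=5
            )

    def test_pool_sums_counts(self):
        a = CutSiteTrack.from_positions({"chr1": [10, 10, 20]})
        b = CutSiteTrack.from_positions({"chr1": [10, 30], "chr2": [5]})
        pooled = CutSiteTrack.pool([a, b])
        assert pooled.count_in("chr1", 10, 11) == 3
        assert pooled.total_cuts == a.total_cuts + b.total_cuts


class TestReadsFromBed:
    def test_bed6_reads_round_trip(self, tmp_path):
        from pulsedhs.intervals import reads_from_bed

        p = tmp_path / "reads.bed"
        p.write_text("chr1\t100\t150\tr1\t0\t+\nchr1\t200\t260\tr2\t0\t-\n")
        reads = reads_from_bed(p)
        assert [r.cut_site for r in reads] == [100, 259]

    def test_strandless_read_rejected(self, tmp_path):
        from pulsedhs.intervals import reads_from_bed

        p = tmp_path / "reads.bed"
        p.write_text("chr1\t100\t150\n")
        with pytest.raises(BedParseError, match="strand"):
            reads_from_bed(p)
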