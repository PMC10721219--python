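import numpy as np
import pandas as pd
import pytest

from pulsedhs.annotate import (
    PWM,
    assign_chrom_state,
    assign_target_gene,
    label_bound,
    read_motif_file,
    scan_motif,
)
from pulsedhs.intervals import GenomicInterval, overlap_bp

RC = str.maketrans("ACGT", "TGCA")


def consensus_pwm(seq, eps=1e-12):
    """Near-degenerate PWM matching only the given consensus."""
    base_idx = {b: i for i, b in enumerate("ACGT")}
    mat = np.full((len(seq), 4), eps / 3)
    for i, b in enumerate(seq):
        mat[i] = eps / 3
        mat[i, base_idx[b]] = 1 - eps
    return PWM("consensus", mat)


class TestTargetGene:
    def _setup(self):
        tads = [GenomicInterval("chr1", 0, 10_000, name="t0"),
                GenomicInterval("chr1", 10_000, 20_000, name="t1")]
        genes = pd.DataFrame(
            {
                "gene_id": ["A", "B", "C"],
                "tss": [2000, 9000, 10_500],
                "tad_id": ["t0", "t0", "t1"],
            }
        )
        return genes, tads

    def test_nearest_tss_in_tad(self):
        genes, tads = self._setup()
        dhs = GenomicInterval("chr1", 4900, 5100)  # mid 5000
        assert assign_target_gene(dhs, genes, tads) == "A"  # 3000 < 4000

    def test_nearer_tss_in_other_tad_ignored(self):
        genes, tads = self._setup()
        dhs = GenomicInterval("chr1", 9800, 10_000)  # mid 9900, in t0
        # C at 10_500 is 600 bp away but in t1; B at 9000 (900 bp) wins
        assert assign_target_gene(dhs, genes, tads) == "B"

    def test_empty_tad_and_no_tad(self):
        genes, tads = self._setup()
        genes_t0_only = genes[genes["tad_id"] == "t0"]
        assert assign_target_gene(
            GenomicInterval("chr1", 15_000, 15_200), genes_t0_only, tads
        ) is None
        assert assign_target_gene(
            GenomicInterval("chr1", 25_000, 25_200), genes, tads
        ) is None

    def test_tie_breaks_to_smaller_tss(self):
        tads = [GenomicInterval("chr1", 0, 10_000, name="t0")]
        genes = pd.DataFrame(
            {"gene_id": ["L", "R"], "tss": [4000, 6000], "tad_id": ["t0", "t0"]}
        )
        dhs = GenomicInterval("chr1", 4900, 5100)  # mid 5000, both 1000 bp away
        assert assign_target_gene(dhs, genes, tads) == "L"

    def test_matches_brute_force_oracle(self, rng):
        tad_size = 5000
        tads = [GenomicInterval("chr1", i * tad_size, (i + 1) * tad_size,
                                name=f"t{i}") for i in range(20)]
        tss = np.sort(rng.choice(100_000, size=60, replace=False))
        genes = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(60)],
                "tss": tss,
                "tad_id": [f"t{p // tad_size}" for p in tss],
            }
        )
        for _ in range(200):
            start = int(rng.integers(0, 99_000))
            dhs = GenomicInterval("chr1", start, start + int(rng.integers(50, 400)))
            mid = dhs.midpoint
            same_tad = genes[genes["tad_id"] == f"t{mid // tad_size}"]
            if same_tad.empty:
                expected = None
            else:
                d = (same_tad["tss"] - mid).abs()
                best = same_tad.loc[d == d.min()].sort_values("tss").iloc[0]
                expected = best["gene_id"]
            assert assign_target_gene(dhs, genes, tads) == expected


class TestChromState:
    def test_largest_overlap_wins(self):
        segs = [GenomicInterval("chr1", 0, 250, name="E6"),
                GenomicInterval("chr1", 250, 500, name="E5")]
        assert assign_chrom_state(GenomicInterval("chr1", 100, 300), segs) == "E6"

    def test_tie_breaks_to_smaller_coordinate(self):
        segs = [GenomicInterval("chr1", 0, 200, name="E3"),
                GenomicInterval("chr1", 200, 400, name="E9")]
        assert assign_chrom_state(GenomicInterval("chr1", 100, 300), segs) == "E3"

    def test_uncovered_dhs_raises(self):
        segs = [GenomicInterval("chr1", 0, 150, name="E1")]
        with pytest.raises(ValueError, match="not fully covered"):
            assign_chrom_state(GenomicInterval("chr1", 100, 300), segs)

    def test_matches_per_base_oracle(self, rng):
        for _ in range(50):
            # random segmentation tiling [0, 3000) with 14 states
            cuts = np.sort(rng.choice(np.arange(1, 3000), size=8, replace=False))
            bounds = [0, *cuts.tolist(), 3000]
            states = rng.choice([f"E{i}" for i in range(1, 15)], size=len(bounds) - 1)
            segs = [GenomicInterval("chr1", a, b, name=s)
                    for a, b, s in zip(bounds, bounds[1:], states)]
            start = int(rng.integers(0, 2500))
            dhs = GenomicInterval("chr1", start, start + int(rng.integers(50, 500)))
            # per-base oracle with the smaller-coordinate tie rule
            per_state = {}
            first_start = {}
            for seg in segs:
                bp = overlap_bp(dhs, seg)
                if bp:
                    per_state[seg.name] = per_state.get(seg.name, 0) + bp
                    first_start.setdefault(seg.name, seg.start)
            expected = min(per_state, key=lambda s: (-per_state[s], first_start[s]))
            assert assign_chrom_state(dhs, segs) == expected


class TestScanMotif:
    def test_consensus_single_forward_hit(self):
        pwm = consensus_pwm("ACGT")
        hits = scan_motif("AAACGTAA", pwm, p_threshold=0.0005)
        forward = [h for h in hits if h.strand == "+"]
        assert [h.position for h in forward] == [2]

    def test_reverse_complement_site_found_on_minus(self):
        pwm = consensus_pwm("ACGGT")
        site_rc = "ACGGT".translate(RC)[::-1]  # ACCGT
        seq = "TTTT" + site_rc + "TTTT"
        hits = scan_motif(seq, pwm, p_threshold=0.0005)
        assert any(h.strand == "-" and h.position == 4 for h in hits)

    def test_hit_count_invariant_under_reverse_complement(self, rng):
        pwm = PWM.from_counts(
            "m", rng.integers(1, 20, size=(6, 4)).astype(float)
        )
        seq = "".join(rng.choice(list("ACGT"), size=300))
        rc = seq.translate(RC)[::-1]
        assert len(scan_motif(seq, pwm)) == len(scan_motif(rc, pwm))

    def test_short_sequence_and_n_handling(self):
        pwm = consensus_pwm("ACGT")
        assert scan_motif("ACG", pwm) == []
        assert scan_motif("AANCGTAA", pwm) == []  # N inside every candidate site

    def test_null_hit_rate_matches_threshold(self, rng):
        """On i.i.d. uniform sequence the hit rate per scored position is close
        to the exact-null threshold probability."""
        pwm = PWM.from_counts("m", rng.integers(1, 30, size=(8, 4)).astype(float))
        p_thr = 0.005
        n_hits = 0
        n_positions = 0
        for _ in range(60):
            seq = "".join(rng.choice(list("ACGT"), size=2000))
            hits = scan_motif(seq, pwm, p_threshold=p_thr)
            n_hits += len(hits)
            n_positions += 2 * (len(seq) - len(pwm) + 1)
        rate = n_hits / n_positions
        # the DP threshold guarantees rate <= p_thr up to discretization;
        # demand the right order of magnitude
        assert rate <= p_thr * 1.2
        assert rate >= p_thr / 4

    def test_invalid_pwm_rejected(self):
        with pytest.raises(ValueError):
            PWM("bad", np.full((3, 4), 0.25))  # too short
        with pytest.raises(ValueError):
            PWM("bad", np.full((6, 4), 0.3))  # rows don't sum to 1


class TestMotifIO:
    def test_transfac_round_trip(self, tmp_path):
        content = (
            "ID  STAT5_TEST\nBF  none\n"
            "P0      A      C      G      T\n"
            "01      0      0      0     12      T\n"
            "02      0      0      0     12      T\n"
            "03      0     12      0      0      C\n"
            "04      3      3      3      3      N\n"
            "05     12      0      0      0      A\n"
            "06     12      0      0      0      A\n"
            "XX\n//\n"
        )
        p = tmp_path / "motif.transfac"
        p.write_text(content)
        pwms = read_motif_file(p, fmt="transfac")
        assert len(pwms) == 1
        assert len(pwms[0]) == 6
        # consensus TTC.AA: position 0 dominated by T
        assert pwms[0].matrix[0].argmax() == 3


class TestLabelBound:
    def test_one_bp_overlap_bounds(self):
        dhs = [GenomicInterval("chr1", 100, 200), GenomicInterval("chr1", 300, 400)]
        peaks = [GenomicInterval("chr1", 199, 250), GenomicInterval("chr1", 400, 500)]
        got = label_bound(dhs, peaks)
        assert got.tolist() == [True, False]  # book-ended peak does not bind

    def test_matches_brute_force_on_random_sets(self, rng):
        dhs = [GenomicInterval("chr1", int(s), int(s) + 200)
               for s in rng.integers(0, 500_000, 1000)]
        peaks = [GenomicInterval("chr1", int(s), int(s) + 150)
                 for s in rng.integers(0, 500_000, 300)]
        got = label_bound(dhs, peaks)
        expected = [any(overlap_bp(d, p) > 0 for p in peaks) for d in dhs]
        assert got.tolist() == expected
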