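"""ROH detection, F_ROH decomposition, and segment-length-to-generations."""

import numpy as np
import pytest

from snppop.dataset import MISSING, make_dataset
from snppop.roh import (
    AUTOSOMAL_GENOME_KB,
    ROHConfig,
    detect_roh,
    froh,
    generations_from_length,
    length_class,
)
from snppop.simulate import SimulationConfig, implant_roh, simulate_wright_fisher

SMALL_CFG = ROHConfig(
    window_snps=20,
    window_threshold=0.05,
    min_length_kb=1000.0,
    min_snps=20,
    max_density_kb_per_snp=150.0,
    max_missing_in_window=2,
)


def het_background(n_variants=400, spacing_bp=25_000, n_samples=1):
    calls = np.ones((n_samples, n_variants), dtype=np.int8)
    pos = (np.arange(n_variants) + 1) * spacing_bp
    return make_dataset(calls, pos=pos)


class TestDetect:
    def test_fully_heterozygous_sample_has_no_segments(self):
        assert detect_roh(het_background()) == []

    def test_implanted_run_recovered_with_exact_bounds(self):
        data = het_background()
        pos = data.variants["pos"].to_numpy()
        start, end = pos[100], pos[179]  # 80 SNPs, 1975 kb
        implanted, _ = implant_roh(data, [("S1", "1", start, end - start)], seed=1)
        segs = detect_roh(implanted)
        assert len(segs) == 1
        spacing = 25_000
        assert abs(segs[0].start_bp - start) <= spacing
        assert abs(segs[0].end_bp - end) <= spacing
        assert segs[0].n_snps == 80

    def test_sub_minimum_implant_rejected(self):
        # 800 kb homozygous run: below the 1000 kb minimum
        data = het_background()
        pos = data.variants["pos"].to_numpy()
        start = pos[100]
        implanted, _ = implant_roh(data, [("S1", "1", start, 800_000)], seed=1)
        assert detect_roh(implanted) == []

    def test_heterozygote_splits_run(self):
        data = het_background()
        pos = data.variants["pos"].to_numpy()
        implanted, _ = implant_roh(data, [("S1", "1", pos[50], pos[250] - pos[50])], seed=1)
        implanted.calls[0, 150] = 1  # het inside the run
        segs = detect_roh(implanted)
        assert len(segs) == 2
        assert all(s.length_kb >= 1000 for s in segs)

    def test_large_gap_splits_run(self):
        n = 200
        calls = np.zeros((1, n), dtype=np.int8)
        pos = np.concatenate([(np.arange(100) + 1) * 30_000, 5_000_000 + (np.arange(100) + 1) * 30_000])
        d = make_dataset(calls, pos=pos)
        cfg = ROHConfig(max_gap_kb=1000.0)
        segs = detect_roh(d, cfg)
        assert len(segs) == 2

    def test_segment_invariants_hold(self):
        cfg = SimulationConfig(
            n_populations=1,
            n_samples_per_pop=8,
            n_chromosomes=4,
            chromosome_length_bp=3_000_000,
            n_variants_per_chrom=150,
            ne_history=[(0, 20), (60, 20)],
            seed=9,
        )
        data, _ = simulate_wright_fisher(cfg)
        rcfg = ROHConfig()
        for seg in detect_roh(data, rcfg):
            assert seg.end_bp > seg.start_bp
            assert seg.n_snps >= rcfg.min_snps
            assert seg.length_kb >= rcfg.min_length_kb
            assert seg.length_kb / seg.n_snps <= rcfg.max_density_kb_per_snp

    def test_matches_exhaustive_reference_scan(self):
        # oracle: every maximal non-het run (gap-split) tested directly
        # against the length/count/density filters, plus window support
        rng = np.random.default_rng(12)
        n_var = 480
        calls = rng.choice([0, 1, 2, MISSING], size=(3, n_var), p=[0.42, 0.12, 0.42, 0.04]).astype(
            np.int8
        )
        pos = np.sort(rng.choice(np.arange(1, 12_000_000, 999), size=n_var, replace=False))
        data = make_dataset(calls, pos=pos)
        # window_threshold = 1/window_snps makes "some clean window overlaps
        # the run" exactly equivalent to the per-variant hit-fraction rule
        cfg = ROHConfig(
            window_snps=25,
            window_threshold=1 / 25,
            min_snps=10,
            min_length_kb=500,
            max_missing_in_window=2,
        )
        got = {
            (s.sample_id, s.start_bp, s.end_bp, s.n_snps) for s in detect_roh(data, cfg)
        }
        expected = set()
        for i in range(3):
            g = calls[i]
            runs = []
            start = None
            for j in range(n_var):
                good = g[j] != 1
                if good:
                    if start is None:
                        start = j
                    elif pos[j] - pos[j - 1] > cfg.max_gap_kb * 1000:
                        runs.append((start, j - 1))
                        start = j
                elif start is not None:
                    runs.append((start, j - 1))
                    start = None
            if start is not None:
                runs.append((start, n_var - 1))
            for a, b in runs:
                n_snps = b - a + 1
                length_kb = (pos[b] - pos[a]) / 1000
                if n_snps < cfg.min_snps or length_kb < cfg.min_length_kb:
                    continue
                if length_kb / n_snps > cfg.max_density_kb_per_snp:
                    continue
                # window support: some window within the run is clean enough
                w = min(cfg.window_snps, n_var)
                supported = False
                for s0 in range(n_var - w + 1):
                    win = g[s0 : s0 + w]
                    if (win == 1).sum() <= cfg.max_het_in_window and (
                        win == MISSING
                    ).sum() <= cfg.max_missing_in_window:
                        if s0 + w - 1 >= a and s0 <= b:  # overlaps run
                            supported = True
                            break
                if supported:
                    expected.add((data.samples["sample_id"][i], int(pos[a]), int(pos[b]), n_snps))
        assert got == expected

    def test_raising_min_length_never_adds_segments(self):
        data = het_background()
        pos = data.variants["pos"].to_numpy()
        implanted, _ = implant_roh(
            data, [("S1", "1", pos[50], 1_500_000), ("S1", "1", pos[250], 3_000_000)], seed=2
        )
        counts = []
        for min_len in (500, 1000, 2000, 4000):
            cfg = ROHConfig(min_length_kb=min_len)
            counts.append(len(detect_roh(implanted, cfg)))
        assert counts == sorted(counts, reverse=True)


class TestFroh:
    def test_no_segments_gives_zero(self):
        s = froh([], ["S1"])[0]
        assert s.froh_total == 0.0

    def test_genome_fraction_arithmetic(self):
        from snppop.roh import ROHSegment

        seg = ROHSegment("S1", "1", 0, 22_657_700, 100)
        s = froh([seg], ["S1"])[0]
        assert s.froh_total == pytest.approx(0.01)

    def test_class_decomposition_sums_to_total(self):
        from snppop.roh import ROHSegment

        segs = [
            ROHSegment("S1", "1", 0, 2_000_000, 50),
            ROHSegment("S1", "2", 0, 5_000_000, 80),
            ROHSegment("S1", "3", 0, 13_000_000, 200),
        ]
        s = froh(segs, ["S1"])[0]
        assert sum(s.froh_by_class.values()) == pytest.approx(s.froh_total)
        assert s.froh_by_class["1-4Mb"] > 0
        assert s.froh_by_class["4-8Mb"] > 0
        assert s.froh_by_class[">12Mb"] > 0

    def test_class_bounds_lower_inclusive(self):
        assert length_class(4000.0) == "4-8Mb"
        assert length_class(12_000.0) == ">12Mb"
        assert length_class(999.0) is None

    def test_implant_recovery_ten_percent(self):
        # ~10% of a small synthetic genome implanted as autozygous
        n_var, spacing = 2000, 15_000  # 10 chromosomes x 3 Mb
        calls = np.ones((2, n_var), dtype=np.int8)
        chrom = [str(c + 1) for c in range(10) for _ in range(200)]
        pos = np.tile((np.arange(200) + 1) * spacing, 10)
        data = make_dataset(calls, chrom=chrom, pos=pos)
        genome_kb = 10 * 199 * spacing / 1000
        implants = [
            ("S1", "1", 15_000, 1_500_000),
            ("S1", "4", 300_000, 1_500_000),
            ("S2", "2", 15_000, 1_500_000),
            ("S2", "7", 600_000, 1_500_000),
        ]
        implanted, _ = implant_roh(data, implants, seed=3)
        cfg = ROHConfig(window_snps=40)
        summaries = froh(detect_roh(implanted, cfg), ["S1", "S2"], genome_length_kb=genome_kb)
        target = 2 * 1_500_000 / 1000 / genome_kb
        for s in summaries:
            assert s.froh_total == pytest.approx(target, abs=0.015)


class TestGenerations:
    @pytest.mark.parametrize(
        "length_mb, expected", [(12, 100 / 24), (50, 1.0), (1, 50.0)]
    )
    def test_known_values(self, length_mb, expected):
        assert generations_from_length(length_mb) == pytest.approx(expected)

    def test_twelve_mb_prints_as_4_17(self):
        assert round(generations_from_length(12), 2) == 4.17

    def test_nonpositive_length_raises(self):
        with pytest.raises(ValueError):
            generations_from_length(0)
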