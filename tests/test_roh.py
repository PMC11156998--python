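import numpy as np
import pandas as pd
import pytest

from popsig import PopulationMap, ROHParams, categorize_roh, detect_roh, froh, summarize_counts
from conftest import make_matrix
from oracles import roh_oracle

SMALL = ROHParams(
    scan_window_snps=10, min_snps=10, min_length_bp=10_000,
    max_bp_per_snp=10_000, max_gap_bp=100_000,
)


def segments_as_tuples(df):
    return [tuple(r) for r in df[["start", "end", "length", "n_snps"]].itertuples(index=False)]


class TestDetectRoh:
    def test_all_het_sample_has_no_segments(self):
        g = make_matrix([np.ones(200, dtype=int)])
        assert len(detect_roh(g, "s0", SMALL)) == 0

    def test_fully_homozygous_chromosome_is_one_segment(self):
        pos = np.arange(200) * 2000 + 1
        g = make_matrix([np.zeros(200, dtype=int)], pos=pos)
        seg = detect_roh(g, "s0", SMALL)
        assert len(seg) == 1
        row = seg.iloc[0]
        assert (row["start"], row["end"], row["n_snps"]) == (pos[0], pos[-1], 200)
        assert segments_as_tuples(seg) == roh_oracle(pos, [0] * 200, SMALL)

    def test_het_splits_run_when_window_het_zero(self):
        params = ROHParams(
            scan_window_snps=10, min_snps=10, min_length_bp=10_000,
            max_bp_per_snp=10_000, max_gap_bp=100_000, max_het_per_window=0,
        )
        calls = np.zeros(200, dtype=int)
        calls[100] = 1
        pos = np.arange(200) * 2000 + 1
        g = make_matrix([calls], pos=pos)
        seg = detect_roh(g, "s0", params)
        assert len(seg) == 2
        assert segments_as_tuples(seg) == roh_oracle(pos, calls.tolist(), params)

    def test_gap_splits_run(self):
        pos = np.concatenate([np.arange(100) * 2000 + 1,
                              np.arange(100) * 2000 + 1_000_000])
        g = make_matrix([np.zeros(200, dtype=int)], pos=pos)
        seg = detect_roh(g, "s0", SMALL)
        assert len(seg) == 2

    def test_short_chromosome_yields_no_calls(self):
        g = make_matrix([[0, 0, 0]])
        assert len(detect_roh(g, "s0", SMALL)) == 0

    def test_min_length_monotonicity(self):
        rng = np.random.default_rng(3)
        calls = rng.choice([0, 1, 2], size=300, p=[0.48, 0.04, 0.48])
        pos = np.sort(rng.choice(600_000, 300, replace=False)) + 1
        g = make_matrix([calls], pos=pos)
        counts = []
        for min_len in (5_000, 20_000, 80_000):
            p = ROHParams(scan_window_snps=10, min_snps=5, min_length_bp=min_len,
                          max_bp_per_snp=50_000, max_gap_bp=1_000_000)
            counts.append(len(detect_roh(g, "s0", p)))
        assert counts == sorted(counts, reverse=True)

    def test_lower_window_het_never_lengthens_roh(self):
        rng = np.random.default_rng(4)
        calls = rng.choice([0, 1, 2], size=400, p=[0.45, 0.1, 0.45])
        pos = np.arange(400) * 1500 + 1
        g = make_matrix([calls], pos=pos)
        totals = []
        for het in (2, 1, 0):
            p = ROHParams(scan_window_snps=10, min_snps=5, min_length_bp=5_000,
                          max_bp_per_snp=50_000, max_gap_bp=1_000_000,
                          max_het_per_window=het)
            seg = detect_roh(g, "s0", p)
            totals.append(seg["length"].sum() if len(seg) else 0)
        assert totals == sorted(totals, reverse=True)


class TestOracleEquivalence:
    def test_random_genomes_match_brute_force(self):
        """Vectorized detection equals the exhaustive reference on random
        genotype vectors with varied thresholds."""
        rng = np.random.default_rng(99)
        for rep in range(60):
            n = 500
            p_het = rng.choice([0.02, 0.1, 0.3])
            p_mis = rng.choice([0.0, 0.02, 0.1])
            # blocky genotypes: homozygous backbone with het/missing noise
            calls = rng.choice(
                [0, 2, 1, -1], size=n,
                p=[(1 - p_het - p_mis) / 2, (1 - p_het - p_mis) / 2, p_het, p_mis],
            )
            pos = np.sort(rng.choice(2_000_000, size=n, replace=False)) + 1
            params = ROHParams(
                scan_window_snps=int(rng.choice([5, 10, 25, 50])),
                max_het_per_window=int(rng.choice([0, 1, 2])),
                max_missing_per_window=int(rng.choice([1, 2])),
                window_hit_threshold=float(rng.choice([0.05, 0.2, 1.0])),
                min_snps=int(rng.choice([5, 20])),
                min_length_bp=int(rng.choice([5_000, 50_000])),
                max_bp_per_snp=int(rng.choice([20_000, 100_000])),
                max_gap_bp=int(rng.choice([50_000, 1_000_000])),
            )
            g = make_matrix([calls], pos=pos)
            got = segments_as_tuples(detect_roh(g, "s0", params))
            want = roh_oracle(pos, calls.tolist(), params)
            assert got == want, f"rep {rep}: {params}"


class TestFroh:
    def test_no_segments_is_zero(self):
        assert froh(pd.DataFrame(columns=["length"])) == 0.0

    def test_paper_scale_arithmetic(self):
        seg = pd.DataFrame({"length": [240_000_000]})
        assert froh(seg, 2.4e9) == pytest.approx(0.1)

    def test_toy_sum(self):
        seg = pd.DataFrame({"length": [100_000, 150_000]})
        assert froh(seg, 1_000_000) == pytest.approx(0.25)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            froh(pd.DataFrame({"length": [100]}), 0)
        with pytest.raises(ValueError):
            froh(pd.DataFrame({"length": [-5]}), 1e6)

    def test_fully_homozygous_genome_identity(self):
        """F_ROH of an all-homozygous genome equals covered span / L_auto."""
        pos = np.arange(300) * 1000 + 1
        g = make_matrix([np.full(300, 2, dtype=int)], pos=pos)
        params = ROHParams(scan_window_snps=10, min_snps=10, min_length_bp=10_000,
                           max_bp_per_snp=10_000, max_gap_bp=1_000_000)
        seg = detect_roh(g, "s0", params)
        covered = pos[-1] - pos[0] + 1
        assert froh(seg, 10 * covered) == pytest.approx(0.1)


class TestCategorize:
    def make_segments(self, lengths, sample="a"):
        return pd.DataFrame(
            {"sample": sample, "chrom": "1", "start": 1,
             "end": np.asarray(lengths), "length": lengths,
             "n_snps": 50}
        )

    def test_one_per_category(self):
        seg = self.make_segments([120_000, 200_000, 300_000, 500_000])
        counts = categorize_roh(seg)
        assert counts.loc["all"].tolist() == [4, 1, 1, 1, 1]

    def test_boundary_150kb_goes_to_lower_class(self):
        counts = categorize_roh(self.make_segments([150_000]))
        assert counts.loc["all", "roh_100_150kb"] == 1
        counts = categorize_roh(self.make_segments([150_001]))
        assert counts.loc["all", "roh_150_250kb"] == 1

    def test_sub100kb_segment_violates_contract(self):
        with pytest.raises(ValueError):
            categorize_roh(self.make_segments([90_000]))

    def test_published_row_reconstruction(self):
        """Category counts of 2929/1448/418/169 total 4964 (the Arab row of
        the reference goat ROH table)."""
        from popsig.datasets import goat_roh_counts

        tab = goat_roh_counts()
        row = tab.loc["Arab"]
        assert row["total"] == 4964 == row.iloc[1:].sum()

    def test_summarize_counts_adds_overall_and_shares(self):
        counts = pd.DataFrame(
            {"total": [4, 2], "roh_100_150kb": [2, 1], "roh_150_250kb": [1, 1],
             "roh_250_400kb": [1, 0], "roh_gt400kb": [0, 0]},
            index=["p1", "p2"],
        )
        s = summarize_counts(counts)
        assert s.loc["overall", "total"] == 6
        assert s.loc["overall", "roh_100_150kb_pct"] == pytest.approx(50.0)
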