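import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from popsig import PopulationMap, add_z, call_outliers, fst_windows, hp_windows, n_tail, site_fst, zscore
from popsig.selection import select_tail
from conftest import make_matrix
from oracles import merge_intervals_oracle


class TestSiteFst:
    @pytest.mark.parametrize(
        "p1, p2, expected",
        [
            (0.5, 0.5, 0.0),   # no differentiation
            (1.0, 0.0, 1.0),   # fixed difference
            (0.8, 0.2, 0.36),  # 1 - (0.16+0.16)/(2*0.25)
        ],
    )
    def test_closed_form_values(self, p1, p2, expected):
        assert site_fst([p1], [p2])[0] == pytest.approx(expected)

    def test_fixed_pooled_frequency_is_undefined(self):
        assert np.isnan(site_fst([0.0], [0.0])[0])
        assert np.isnan(site_fst([1.0], [1.0])[0])

    def test_bounded_on_dense_frequency_grid(self):
        grid = np.linspace(0, 1, 101)
        p1, p2 = np.meshgrid(grid, grid)
        vals = site_fst(p1.ravel(), p2.ravel())
        finite = vals[np.isfinite(vals)]
        assert finite.min() >= -1e-12
        assert finite.max() <= 1 + 1e-12


def two_pop_matrix(calls_a, calls_b, pos):
    calls = np.vstack([calls_a, calls_b])
    n_a = len(calls_a)
    samples = [f"a{i}" for i in range(n_a)] + [f"b{i}" for i in range(len(calls_b))]
    g = make_matrix(calls, pos=pos, samples=samples)
    pops = PopulationMap(
        {s: ("A" if s.startswith("a") else "B") for s in samples}
    )
    return g, pops


class TestFstWindows:
    def test_same_population_rejected(self):
        g, pops = two_pop_matrix([[0, 1]], [[1, 2]], [100, 200])
        with pytest.raises(ValueError):
            fst_windows(g, pops, "A", "A")

    def test_window_mean_of_site_values(self):
        # pop A fixed ref, pop B fixed alt at 2 sites; one undifferentiated site
        a = [[0, 0, 1], [0, 0, 1]]
        b = [[2, 2, 1], [2, 2, 1]]
        g, pops = two_pop_matrix(a, b, [100, 200, 300])
        w = fst_windows(g, pops, "A", "B", window=1000, step=1000, min_snps=1)
        assert len(w) == 1
        assert w["fst"].iloc[0] == pytest.approx((1 + 1 + 0) / 3)

    def test_min_snps_drops_sparse_windows(self):
        a = [[0] * 5]
        b = [[2] * 5]
        pos = [100, 200, 300, 400, 100_000_100]
        g, pops = two_pop_matrix(a, b, pos)
        w = fst_windows(g, pops, "A", "B", window=1000, step=1000, min_snps=2)
        assert len(w) == 1  # lone distant SNP's window dropped

    def test_dialects_agree_on_sign_of_strong_differentiation(self):
        rng = np.random.default_rng(0)
        a = rng.choice([0, 1], size=(6, 100), p=[0.9, 0.1])
        b = rng.choice([1, 2], size=(6, 100), p=[0.1, 0.9])
        pos = np.arange(100) * 10 + 1
        g, pops = two_pop_matrix(a, b, pos)
        for dialect in ("mean", "wc", "hudson"):
            w = fst_windows(g, pops, "A", "B", window=1000, step=1000,
                            min_snps=1, dialect=dialect)
            assert w["fst"].iloc[0] > 0.5


class TestHpWindows:
    def make_counts_matrix(self, maj, minr):
        """Matrix of 10 diploids whose alt counts realize per-SNP
        major/minor allele counts (total 20 alleles per site)."""
        calls = []
        for M, m in zip(maj, minr):
            assert M + m == 20
            # m alt alleles among 20: m//2 hom-alt + (m%2) het
            col = [2] * (m // 2) + [1] * (m % 2)
            col += [0] * (10 - len(col))
            calls.append(col)
        return np.array(calls).T

    def test_hand_arithmetic(self):
        # per-SNP maj {18,15,12}, min {2,5,8} -> Hp = 2*45*15/60^2 = 0.375
        calls = self.make_counts_matrix([18, 15, 12], [2, 5, 8])
        g = make_matrix(calls, pos=[100, 200, 300])
        pops = PopulationMap({s: "p" for s in g.samples})
        w = hp_windows(g, pops, "p", window=1000, step=1000)
        assert w["hp"].iloc[0] == pytest.approx(0.375)

    def test_fixation_gives_zero(self):
        calls = self.make_counts_matrix([20, 20], [0, 0])
        g = make_matrix(calls, pos=[100, 200])
        pops = PopulationMap({s: "p" for s in g.samples})
        assert hp_windows(g, pops, "p", 1000, 1000)["hp"].iloc[0] == 0.0

    def test_balanced_counts_give_half(self):
        calls = self.make_counts_matrix([10, 10], [10, 10])
        g = make_matrix(calls, pos=[100, 200])
        pops = PopulationMap({s: "p" for s in g.samples})
        assert hp_windows(g, pops, "p", 1000, 1000)["hp"].iloc[0] == pytest.approx(0.5)

    @settings(deadline=None, max_examples=60)
    @given(st.lists(st.integers(0, 20), min_size=1, max_size=8))
    def test_bounds_and_maximum_condition(self, alt_counts):
        maj = [max(a, 20 - a) for a in alt_counts]
        minr = [min(a, 20 - a) for a in alt_counts]
        calls = self.make_counts_matrix(maj, minr)
        g = make_matrix(calls, pos=(np.arange(len(maj)) + 1) * 10)
        pops = PopulationMap({s: "p" for s in g.samples})
        hp = hp_windows(g, pops, "p", 10_000, 10_000)["hp"].iloc[0]
        assert 0.0 <= hp <= 0.5
        # Hp = 0.5 iff the summed major and minor counts are equal
        assert (hp == pytest.approx(0.5)) == (sum(maj) == sum(minr))


class TestZscore:
    def test_hand_values(self):
        np.testing.assert_allclose(zscore([0, 1, 2]), [-1, 0, 1])

    def test_constant_scan_is_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            zscore([3.0, 3.0, 3.0])

    def test_centering_and_unit_sd(self):
        rng = np.random.default_rng(1)
        z = zscore(rng.gamma(2, size=1000))
        assert abs(z.mean()) < 1e-12
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-9)


class TestOutlierCalling:
    def make_scan(self, z_values, step=25_000, window=100_000):
        n = len(z_values)
        starts = np.arange(n) * step + 1
        return pd.DataFrame(
            {"chrom": "1", "start": starts, "end": starts + window,
             "z": z_values}
        )

    def test_tail_count_rule(self):
        assert n_tail(98_660, 0.01) == 987
        assert n_tail(98_573, 0.01) == 986
        assert n_tail(100, 0.01) == 1

    def test_disjoint_tails_give_no_regions(self):
        z = np.linspace(-3, 3, 200)
        fst = self.make_scan(z)           # top tail at the right end
        hp = self.make_scan(z)            # bottom tail at the left end
        regions = call_outliers(fst, hp, tail=0.01)
        assert len(regions) == 0

    def test_consecutive_outliers_merge_to_one_region(self):
        z = np.zeros(300)
        z[100:103] = 8.0                  # three consecutive windows
        fst = self.make_scan(z)
        hp = self.make_scan(-z)
        regions = call_outliers(fst, hp, tail=0.01)
        members = [("1", int(100 + i) * 25_000 + 1, int(100 + i) * 25_000 + 100_001)
                   for i in range(3)]
        expected = merge_intervals_oracle(members)
        assert len(regions) == len(expected) == 1
        assert (regions["start"].iloc[0], regions["end"].iloc[0]) == expected[0][1:]
        assert regions["n_windows"].iloc[0] == 3
        assert regions["peak_zfst"].iloc[0] == pytest.approx(8.0)

    def test_grid_mismatch_raises_when_strict(self):
        fst = self.make_scan(np.arange(10.0))
        hp = self.make_scan(np.arange(12.0))
        with pytest.raises(ValueError, match="grid"):
            call_outliers(fst, hp)
        # non-strict mode intersects the shared windows
        call_outliers(fst, hp, strict_grid=False)

    def test_tie_break_is_deterministic(self):
        z = np.zeros(100)
        z[[5, 50, 95]] = 2.0              # three tied extreme windows, k=1
        fst = self.make_scan(z)
        picked = select_tail(fst, "z", 0.01, "upper")
        assert len(picked) == 1
        assert picked["start"].iloc[0] == 5 * 25_000 + 1  # lowest coordinate wins
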