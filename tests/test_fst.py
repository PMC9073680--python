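"""Hudson F_ST components, windows, outlier merging and genotype PCA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from hornscan import fst as fstmod
from hornscan.fst import (
    WindowStat,
    genome_wide_fst,
    genotype_pca,
    merge_outliers,
    site_fst,
    windowed_fst,
)


class TestSiteFst:
    def test_equal_fixed_alleles_give_zero_components(self):
        num, den = site_fst(0.0, 10, 0.0, 10)
        assert num == 0.0 and den == 0.0

    def test_fixed_difference_is_one(self):
        num, den = site_fst(1.0, 100, 0.0, 100)
        assert num / den == pytest.approx(1.0)

    def test_hand_evaluated_components(self):
        # p1=0.5, n1=16, p2=0, n2=24: num = 0.25 - 0.25/15, den = 0.5
        num, den = site_fst(0.5, 16, 0.0, 24)
        assert num == pytest.approx(0.25 - 0.25 / 15)
        assert den == pytest.approx(0.5)

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            site_fst(0.5, 1, 0.5, 10)

    def test_identical_frequencies_nonpositive_in_expectation(self, rng):
        # E[num] <= 0 when the true frequencies coincide
        p = 0.3
        n1 = n2 = 20
        nums = []
        for _ in range(2000):
            p1 = rng.binomial(n1, p) / n1
            p2 = rng.binomial(n2, p) / n2
            num, _ = site_fst(p1, n1, p2, n2)
            nums.append(num)
        assert np.mean(nums) == pytest.approx(0.0, abs=5e-3)


def _sites(scaffold, data):
    return pd.DataFrame(
        [(scaffold, pos, num, den) for pos, num, den in data],
        columns=["scaffold", "pos", "num", "den"],
    )


class TestWindowedFst:
    def test_single_window_ratio_of_sums(self):
        """Components {(0.2,0.5),(0.1,0.5),(0.0,0.2)} -> 0.3/1.2 = 0.25."""
        sites = _sites("s", [(100, 0.2, 0.5), (200, 0.1, 0.5), (300, 0.0, 0.2)])
        wins = windowed_fst(sites, {"s": 1000}, window=1000, step=1000, min_snps=1)
        assert len(wins) == 1
        assert wins[0].fst == pytest.approx(0.25)

    def test_window_tiling_and_partial_flag(self):
        sites = _sites("s", [(1, 0.1, 0.2)])
        wins = windowed_fst(sites, {"s": 25_000}, window=10_000, step=5_000,
                            min_snps=1)
        starts = [w.start for w in wins]
        assert starts == [0, 5_000, 10_000, 15_000, 20_000]
        assert [w.partial for w in wins] == [False, False, False, False, True]
        # every position is covered by window/step = 2 windows except edges
        covered = np.zeros(25_000)
        for w in wins:
            covered[w.start : w.end] += 1
        assert covered[10_000:20_000].min() == 2

    def test_sparse_window_reports_missing(self):
        sites = _sites("s", [(100, 0.2, 0.5)])
        wins = windowed_fst(sites, {"s": 1000}, window=1000, step=1000)
        assert np.isnan(wins[0].fst)

    def test_unsorted_input_rejected(self):
        sites = _sites("s", [(300, 0.1, 0.2), (100, 0.1, 0.2)])
        with pytest.raises(ValueError, match="sorted"):
            windowed_fst(sites, {"s": 1000})

    @given(st.data())
    def test_ratio_of_sums_split_invariance(self, data):
        """Summing components over arbitrary sublists and re-aggregating
        yields the identical window value."""
        n = data.draw(st.integers(2, 40))
        rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
        num = rng.normal(0.1, 0.2, n)
        den = rng.uniform(0.1, 1.0, n)
        cuts = sorted(
            data.draw(st.lists(st.integers(1, n - 1), max_size=5, unique=True))
        )
        parts = np.split(np.arange(n), cuts)
        whole = num.sum() / den.sum()
        resummed = sum(num[p].sum() for p in parts) / sum(
            den[p].sum() for p in parts
        )
        assert resummed == pytest.approx(whole, rel=1e-12)


class TestMergeOutliers:
    def test_no_window_above_threshold(self):
        wins = [WindowStat("s", 0, 10_000, 10, 0.3)]
        assert merge_outliers(wins, 0.5) == []

    def test_two_overlapping_windows_merge(self):
        wins = [
            WindowStat("s", 0, 10_000, 10, 0.6),
            WindowStat("s", 5_000, 15_000, 10, 0.7),
        ]
        regions = merge_outliers(wins, 0.5)
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end) == (0, 15_000)
        assert regions[0].peak_fst == pytest.approx(0.7)

    def test_gap_bridging_is_opt_in(self):
        wins = [
            WindowStat("s", 0, 10_000, 10, 0.6),
            WindowStat("s", 20_000, 30_000, 10, 0.7),
        ]
        assert len(merge_outliers(wins, 0.5)) == 2
        assert len(merge_outliers(wins, 0.5, max_gap=10_000)) == 1

    def test_regions_do_not_overlap(self, dataset, decisions):
        table = dataset.table
        lengths = {n: int(r["length"]) for n, r in table.scaffolds.iterrows()}
        sites = fstmod.pair_site_components(table, "NC", "AZ", decisions)
        wins = windowed_fst(sites, lengths, comparison="NC-AZ")
        regions = merge_outliers(wins, 0.5)
        by_scaffold: dict[str, list] = {}
        for r in regions:
            by_scaffold.setdefault(r.scaffold, []).append(r)
        for rs in by_scaffold.values():
            rs.sort(key=lambda r: r.start)
            for a, b in zip(rs, rs[1:]):
                assert a.end <= b.start


class TestGenomeWide:
    def test_single_site_genome_equals_site_ratio(self):
        sites = _sites("s", [(10, 0.3, 0.6)])
        assert genome_wide_fst(sites) == pytest.approx(0.5)

    def test_scaffold_exclusion(self):
        sites = pd.concat(
            [_sites("a", [(10, 1.0, 1.0)]), _sites("z", [(10, 0.0, 1.0)])]
        )
        assert genome_wide_fst(sites, exclude_scaffolds={"z"}) == pytest.approx(1.0)

    def test_empty_after_exclusion_rejected(self):
        sites = _sites("z", [(10, 0.1, 0.5)])
        with pytest.raises(ValueError):
            genome_wide_fst(sites, exclude_scaffolds={"z"})

    def test_split_half_resampling_centers_on_zero(self, dataset, decisions, rng):
        """F_ST of a population against itself (random half splits)."""
        table = dataset.table
        nc = [s for s in table.samples if table.meta.loc[s, "population"] == "NC"]
        values = []
        for _ in range(10):
            half = set(rng.choice(nc, size=6, replace=False))
            meta = table.meta.copy()
            meta.loc[list(half), "population"] = "NC_a"
            meta.loc[[s for s in nc if s not in half], "population"] = "NC_b"
            relabelled = type(table)(
                table.sites, table.gt, table.samples, meta, table.scaffolds
            )
            comp = fstmod.pair_site_components(relabelled, "NC_a", "NC_b", decisions)
            values.append(comp["num"].sum() / comp["den"].sum())
        assert np.mean(values) == pytest.approx(0.0, abs=0.02)


class TestGenotypePca:
    def test_duplicate_samples_identical_coordinates(self, rng):
        base = rng.integers(0, 3, size=(4, 50)).astype(float)
        X = np.vstack([base, base[0]])
        coords, _, _ = genotype_pca(X, 2)
        assert np.allclose(coords[0], coords[-1])

    def test_matches_covariance_eigendecomposition(self, rng):
        """Coordinates agree (up to sign fixed by the loading convention)
        with a brute-force eigensolver of the sample covariance."""
        X = rng.normal(size=(3, 8))
        coords, explained, _ = genotype_pca(X, 2)
        Xc = X - X.mean(axis=0)
        evals, evecs = np.linalg.eigh(Xc.T @ Xc / (X.shape[0] - 1))
        order = np.argsort(evals)[::-1]
        for c in range(2):
            brute = Xc @ evecs[:, order[c]]
            assert explained[c] == pytest.approx(evals[order[c]])
            assert min(
                np.abs(coords[:, c] - brute).max(),
                np.abs(coords[:, c] + brute).max(),
            ) < 1e-9

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            genotype_pca(np.ones((3, 5)), 2)

    def test_sign_convention_deterministic(self, rng):
        X = rng.normal(size=(6, 12))
        c1, _, l1 = genotype_pca(X, 3)
        c2, _, l2 = genotype_pca(X.copy(), 3)
        assert np.allclose(c1, c2) and np.allclose(l1, l2)
        for c in range(3):
            assert l1[c, np.argmax(np.abs(l1[c]))] > 0
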