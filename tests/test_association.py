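"""Pair-table join, binning, thresholds, categories, enhancer comparison."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr, rankdata

from osn_identity.association import (
    AssociationError,
    CloseThresholds,
    binned_distribution,
    build_pair_table,
    category_tests,
    classify_pairs,
    close_thresholds,
    enhancer_comparison,
    first_bins_spearman,
    proportion_close_by_bin,
)


def _toy_sources(n=6, rng=None):
    rng = rng or np.random.default_rng(0)
    pops = [f"OR{i}" for i in range(n)]
    cmat = pd.DataFrame(0.0, index=pops, columns=pops)
    for a, b in itertools.combinations(range(n), 2):
        d = float(rng.uniform(1, 10))
        cmat.iloc[a, b] = cmat.iloc[b, a] = d
    aa = cmat * 10 + 1
    rows = []
    for a, b in itertools.combinations(pops, 2):
        same = (int(a[2:]) < 3) == (int(b[2:]) < 3)
        rows.append(
            {
                "gene_a": a,
                "gene_b": b,
                "same_cluster": same,
                "same_chromosome": same,
                "distance": float(rng.integers(1, 100)) if same else np.nan,
            }
        )
    clusters = {p: 0 if int(p[2:]) < 3 else 1 for p in pops}
    classes = {p: "I" for p in pops}
    return cmat, pd.DataFrame(rows), aa, clusters, classes


class TestBuildPairTable:
    def test_complete_sources_give_all_pairs(self):
        cmat, gp, aa, clusters, classes = _toy_sources(3)
        table = build_pair_table(cmat, gp, aa, clusters, classes)
        assert len(table) == 3

    def test_population_missing_from_aa_dropped(self):
        cmat, gp, aa, clusters, classes = _toy_sources(4)
        aa = aa.drop(index="OR3", columns="OR3")
        table = build_pair_table(cmat, gp, aa, clusters, classes)
        assert len(table) == 3  # pairs among OR0..OR2 only
        assert not table["pop_a"].str.contains("OR3").any()

    def test_matches_nested_loop_oracle(self):
        cmat, gp, aa, clusters, classes = _toy_sources(10)
        table = build_pair_table(cmat, gp, aa, clusters, classes)
        gmap = {frozenset((r.gene_a, r.gene_b)): r for r in gp.itertuples()}
        assert len(table) == 45
        for row in table.itertuples():
            assert row.transcriptomic_distance == cmat.loc[row.pop_a, row.pop_b]
            assert row.aa_difference == aa.loc[row.pop_a, row.pop_b]
            g = gmap[frozenset((row.pop_a, row.pop_b))]
            assert row.same_cluster == g.same_cluster
            if g.same_cluster:
                assert row.genomic_distance == g.distance
            else:
                assert np.isnan(row.genomic_distance)

    def test_empty_intersection_rejected(self):
        cmat, gp, aa, clusters, classes = _toy_sources(3)
        with pytest.raises(AssociationError):
            build_pair_table(cmat, gp, aa.rename(index=str.lower, columns=str.lower), clusters, classes)


class TestBinning:
    def _table(self, values):
        return pd.DataFrame(
            {
                "pop_a": [f"a{i}" for i in range(len(values))],
                "pop_b": [f"b{i}" for i in range(len(values))],
                "transcriptomic_distance": np.arange(len(values), dtype=float),
                "genomic_distance": values,
                "aa_difference": values,
                "same_cluster": True,
                "same_class": True,
                "same_chromosome": True,
            }
        )

    def test_equal_width_halves_split_at_midrange(self):
        table = self._table(np.array([0.0, 1.0, 9.0, 10.0]))
        bins = binned_distribution(table, "aa", 2, mode="equal_width")
        assert len(bins[0]) == 2 and len(bins[1]) == 2

    def test_equal_frequency_bin_sizes_differ_by_at_most_one(self, rng):
        table = self._table(rng.normal(size=23))
        bins = binned_distribution(table, "aa", 4, mode="equal_frequency")
        sizes = [len(b) for b in bins]
        assert sum(sizes) == 23
        assert max(sizes) - min(sizes) <= 1

    def test_membership_matches_direct_binning_oracle(self, rng):
        vals = rng.uniform(0, 100, 40)
        table = self._table(vals)
        n_bins = 5
        bins = binned_distribution(table, "genomic", n_bins, mode="equal_width")
        edges = np.linspace(vals.min(), vals.max(), n_bins + 1)
        for b, frame in enumerate(bins):
            for v in frame["genomic_distance"]:
                lo, hi = edges[b], edges[b + 1]
                assert (lo <= v < hi) or (b == n_bins - 1 and v == hi)

    def test_too_few_bins_rejected(self):
        with pytest.raises(AssociationError):
            binned_distribution(self._table(np.arange(5.0)), "aa", 1)


class TestFirstBinsSpearman:
    def _table(self, x, y):
        n = len(x)
        return pd.DataFrame(
            {
                "pop_a": [f"a{i}" for i in range(n)],
                "pop_b": [f"b{i}" for i in range(n)],
                "transcriptomic_distance": y,
                "genomic_distance": x,
                "aa_difference": x,
                "same_cluster": True,
                "same_class": True,
                "same_chromosome": True,
            }
        )

    def test_perfect_monotone_increasing_rho_one(self):
        x = np.linspace(0, 1, 20)
        rho, _, n = first_bins_spearman(self._table(x, x**2), "aa", n_bins=4, n_first_bins=4)
        assert rho == pytest.approx(1.0)
        assert n == 20

    def test_perfect_monotone_decreasing_rho_minus_one(self):
        x = np.linspace(0, 1, 20)
        rho, _, _ = first_bins_spearman(self._table(x, -x), "aa", n_bins=4, n_first_bins=4)
        assert rho == pytest.approx(-1.0)

    def test_matches_rank_pearson_oracle(self, rng):
        x = rng.uniform(0, 1, 30)
        y = rng.uniform(0, 1, 30)
        rho, p, n = first_bins_spearman(self._table(x, y), "aa", n_bins=5, n_first_bins=5)
        expected = pearsonr(rankdata(x), rankdata(y)).statistic
        assert rho == pytest.approx(expected, abs=1e-12)
        assert n == 30

    def test_restricted_to_first_bins_only(self, rng):
        x = np.concatenate([np.linspace(0, 1, 15), [100.0]])
        y = rng.uniform(size=16)
        _, _, n = first_bins_spearman(self._table(x, y), "aa", n_bins=4, n_first_bins=3)
        assert n == 15


class TestThresholdsAndCategories:
    def test_constant_distances_percentiles_collapse(self):
        t = close_thresholds([10] * 7, [10] * 7)
        assert t.genomic_close == 10
        assert t.aa_close == 10

    def test_linear_interpolation_hand_value(self):
        t = close_thresholds(np.arange(1, 101), np.arange(1, 101))
        # numpy linear interpolation: 95th of 1..100 -> 95.05, 5th -> 5.95
        assert t.genomic_close == pytest.approx(95.05)
        assert t.aa_close == pytest.approx(5.95)

    def _table(self):
        return pd.DataFrame(
            {
                "pop_a": list("abcd"),
                "pop_b": list("efgh"),
                "transcriptomic_distance": [1.0, 2.0, 3.0, 4.0],
                "genomic_distance": [5.0, np.nan, 50.0, np.nan],
                "aa_difference": [1.0, 1.0, 10.0, 10.0],
                "same_cluster": [True, False, True, False],
                "same_class": True,
                "same_chromosome": [True, False, True, False],
            }
        )

    def test_four_way_labels_follow_predicates(self):
        t = CloseThresholds(genomic_close=10.0, aa_close=2.0)
        out = classify_pairs(self._table(), t)
        assert list(out["category"]) == [
            "near_similar",
            "far_similar",
            None,  # same cluster but beyond the close threshold
            "far_dissimilar",
        ]

    def test_random_table_matches_predicate_oracle(self, rng):
        n = 60
        table = pd.DataFrame(
            {
                "pop_a": [f"a{i}" for i in range(n)],
                "pop_b": [f"b{i}" for i in range(n)],
                "transcriptomic_distance": rng.uniform(size=n),
                "genomic_distance": rng.uniform(0, 100, n),
                "aa_difference": rng.uniform(0, 100, n),
                "same_cluster": rng.random(n) < 0.5,
                "same_class": True,
                "same_chromosome": True,
            }
        )
        table.loc[~table.same_cluster, "genomic_distance"] = np.nan
        t = CloseThresholds(genomic_close=50.0, aa_close=50.0)
        out = classify_pairs(table, t)
        for row in out.itertuples():
            sim = row.aa_difference <= 50
            if row.same_cluster and row.genomic_distance <= 50:
                expected = "near_similar" if sim else "near_dissimilar"
            elif not row.same_cluster:
                expected = "far_similar" if sim else "far_dissimilar"
            else:
                expected = None
            assert row.category == expected

    def test_classification_partitions_retained_pairs(self, rng):
        n = 80
        table = pd.DataFrame(
            {
                "transcriptomic_distance": rng.uniform(size=n),
                "genomic_distance": rng.uniform(0, 100, n),
                "aa_difference": rng.uniform(0, 100, n),
                "same_cluster": rng.random(n) < 0.6,
                "same_class": True,
                "same_chromosome": True,
            }
        )
        table.loc[~table.same_cluster, "genomic_distance"] = np.nan
        out = classify_pairs(table, CloseThresholds(40.0, 60.0))
        retained = out["category"].notna().sum()
        assert out["category"].value_counts().sum() == retained


class TestCategoryTests:
    def test_bonferroni_factor_equals_number_of_comparisons(self, rng):
        frames = []
        for cat in ("near_similar", "far_similar", "near_dissimilar", "far_dissimilar"):
            frames.append(
                pd.DataFrame(
                    {"transcriptomic_distance": rng.uniform(size=10), "category": cat}
                )
            )
        res = category_tests(pd.concat(frames))
        assert len(res) == 6
        assert np.allclose(
            res["pvalue_bonferroni"], np.minimum(res["pvalue"] * 6, 1.0)
        )

    def test_null_pvalues_roughly_uniform(self):
        """Two categories drawn from one distribution: p ~ Uniform(0,1)."""
        ps = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            table = pd.DataFrame(
                {
                    "transcriptomic_distance": rng.normal(size=40),
                    "category": ["near_similar"] * 20 + ["far_similar"] * 20,
                }
            )
            ps.append(category_tests(table)["pvalue"].iloc[0])
        assert 0.01 < np.mean(np.asarray(ps) < 0.05) < 0.11
        assert abs(np.mean(ps) - 0.5) < 0.07

    def test_single_category_rejected(self):
        with pytest.raises(AssociationError):
            category_tests(
                pd.DataFrame({"transcriptomic_distance": [1.0, 2.0], "category": "near_similar"})
            )


class TestProportionCloseByBin:
    def _table(self, n, rng):
        return pd.DataFrame(
            {
                "transcriptomic_distance": rng.uniform(0, 10, n),
                "genomic_distance": rng.uniform(0, 100, n),
                "aa_difference": rng.uniform(0, 100, n),
                "same_cluster": True,
                "same_class": True,
                "same_chromosome": True,
            }
        )

    def test_all_close_every_bin_one(self, rng):
        table = self._table(30, rng)
        t = CloseThresholds(genomic_close=1000.0, aa_close=1000.0)
        out = proportion_close_by_bin(table, t, 4)
        filled = out.dropna()
        assert (filled["prop_genomic_close"] == 1.0).all()
        assert (filled["prop_aa_close"] == 1.0).all()

    def test_none_close_every_bin_zero(self, rng):
        table = self._table(30, rng)
        t = CloseThresholds(genomic_close=1e-9, aa_close=1e-9)
        out = proportion_close_by_bin(table, t, 4).dropna()
        assert (out["prop_genomic_close"] == 0.0).all()

    def test_matches_direct_counting_oracle(self, rng):
        table = self._table(50, rng)
        t = CloseThresholds(genomic_close=50.0, aa_close=30.0)
        out = proportion_close_by_bin(table, t, 5)
        edges = np.linspace(
            table.transcriptomic_distance.min(), table.transcriptomic_distance.max(), 6
        )
        for row in out.itertuples():
            if row.n_pairs == 0:
                continue
            lo, hi = edges[row.bin], edges[row.bin + 1]
            mask = (table.transcriptomic_distance >= lo) & (
                (table.transcriptomic_distance < hi)
                | ((row.bin == 4) & (table.transcriptomic_distance <= hi))
            )
            assert row.n_pairs == mask.sum()
            assert row.prop_genomic_close == pytest.approx(
                (table.genomic_distance[mask] <= 50).mean()
            )


class TestEnhancerComparison:
    def _cmat(self, n, rng):
        pops = [f"OR{i}" for i in range(n)]
        m = rng.uniform(1, 10, (n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        return pd.DataFrame(m, index=pops, columns=pops), pops

    def test_enhancer_covering_whole_cluster_rejected(self, rng):
        cmat, pops = self._cmat(4, rng)
        with pytest.raises(AssociationError):
            enhancer_comparison(cmat, pops, pops)

    def test_tight_enhancer_set_has_smaller_median(self, rng):
        cmat, pops = self._cmat(8, rng)
        enh = pops[:4]
        for a, b in itertools.combinations(enh, 2):
            cmat.loc[a, b] = cmat.loc[b, a] = 0.01
        res = enhancer_comparison(cmat, pops, enh)
        assert res["median_within"] < res["median_other"]
        assert res["pvalue"] < 0.05

    def test_null_labels_give_uniform_pvalues(self):
        ps = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            cmat, pops = self._cmat(10, rng)
            enh = list(rng.choice(pops, 4, replace=False))
            ps.append(enhancer_comparison(cmat, pops, enh)["pvalue"])
        assert 0.0 <= np.mean(np.asarray(ps) < 0.05) < 0.12
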