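"""Disparity statistics and exact 1-D k-means clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from burdenval.config import SyntheticConfig
from burdenval.disparity import (classify_clusters, disparity_index,
                                 gender_disparity, location_quotient,
                                 round_half_away)
from burdenval.errors import ClusteringError, UndefinedStatisticError
from burdenval.synthetic import generate_burden, generate_economy
from burdenval.valuation import monetize

from conftest import brute_force_kmeans_1d


class TestGenderDisparity:
    @pytest.mark.parametrize("male,female,expected", [
        (0.061, 0.016, 281.25),   # the most male-skewed province
        (0.157, 0.059, 166.10),   # a high-disparity province
        (0.5, 0.5, 0.0),
    ])
    def test_published_scale_examples(self, male, female, expected):
        assert round_half_away(gender_disparity(male, female), 2) == expected

    def test_zero_female_loss_is_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            gender_disparity(1.0, 0.0)


class TestLocationQuotient:
    def test_definition_cases(self):
        assert location_quotient(5.0, 50.0, 1e6, 1e7) == pytest.approx(1.0)
        assert location_quotient(0.10, 1.0, 0.05e7, 1e7) == pytest.approx(2.0)
        # single-province nation
        assert location_quotient(3.3, 3.3, 42.0, 42.0) == 1.0

    def test_population_share_above_one_raises(self):
        from burdenval.errors import DataError
        with pytest.raises(DataError):
            location_quotient(1.0, 2.0, 20.0, 10.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_population_weighted_mean_is_one_on_full_partition(self, seed):
        cfg = SyntheticConfig(n_provinces=12, seed=seed)
        cells = generate_burden(cfg)
        econ = generate_economy(cfg).set_index("province")
        both = cells[(cells["sex"] == "both") & (cells["measure"] == "DALY")]
        vlw = both.groupby("province")["count"].sum()
        lq = pd.Series({
            p: location_quotient(vlw[p], vlw.sum(),
                                 econ.loc[p, "population"],
                                 econ["population"].sum())
            for p in vlw.index})
        pop_share = econ["population"] / econ["population"].sum()
        assert float((pop_share * lq).sum()) == pytest.approx(1.0, rel=1e-12)


class TestDisparityIndex:
    def test_definition_cases(self):
        assert disparity_index(1.2, 1.2) == 1.0
        assert disparity_index(3.6, 1.2) == pytest.approx(3.0)
        assert disparity_index(0.0, 1.2) == 0.0

    def test_zero_national_ratio_is_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            disparity_index(1.0, 0.0)


def test_benchmark_invariance_of_gender_disparity(benchmarks, le):
    """At full precision the statistic is identical across VSL benchmarks."""
    cells = generate_burden(SyntheticConfig(n_provinces=8, seed=11))
    results = []
    for b in benchmarks.values():
        loss = monetize(cells, b, le)
        wide = loss.pivot_table(index=["province", "measure"], columns="sex",
                                values="vlw_billion_usd")
        results.append(100 * (wide["male"] - wide["female"]) / wide["female"])
    np.testing.assert_allclose(results[0], results[1], rtol=1e-9)
    np.testing.assert_allclose(results[0], results[2], rtol=1e-9)


class TestClassifyClusters:
    def test_well_separated_pairs(self):
        values = pd.Series([1, 2, 101, 102, 201, 202, 301, 302],
                           index=list("abcdefgh"), dtype=float)
        labels = classify_clusters(values, k=4)
        assert labels["a"] == labels["b"] == "very low"
        assert labels["g"] == labels["h"] == "very high"
        assert len(set(labels)) == 4

    def test_deterministic_regardless_of_seed(self):
        values = np.random.default_rng(3).normal(size=20)
        a = classify_clusters(values, k=4, seed=1)
        b = classify_clusters(values, k=4, seed=99)
        assert list(a) == list(b)

    def test_fewer_distinct_values_than_k_raises(self):
        with pytest.raises(ClusteringError):
            classify_clusters([1.0, 1.0, 1.0, 2.0, 2.0], k=4)

    @pytest.mark.parametrize("k", [2, 3, 4])
    @pytest.mark.parametrize("n", [5, 8, 12])
    def test_matches_brute_force_oracle(self, n, k):
        rng = np.random.default_rng(n * 100 + k)
        for _ in range(10):
            values = rng.uniform(0, 10, size=n)
            got = classify_clusters(values, k=k,
                                    labels=[str(i) for i in range(k)])
            got_ids = got.astype(int).to_numpy()
            want_ids, want_cost = brute_force_kmeans_1d(values, k)
            cost = sum(
                float(np.sum((values[got_ids == c]
                              - values[got_ids == c].mean()) ** 2))
                for c in range(k))
            assert cost == pytest.approx(want_cost, abs=1e-9)
            assert (got_ids == want_ids).all()

    @settings(derandomize=True, max_examples=40)
    @given(st.lists(st.floats(-1e3, 1e3), min_size=4, max_size=12,
                    unique=True))
    def test_property_matches_oracle_cost(self, values):
        got = classify_clusters(values, k=4,
                                labels=[str(i) for i in range(4)])
        ids = got.astype(int).to_numpy()
        arr = np.asarray(values)
        cost = sum(float(np.sum((arr[ids == c] - arr[ids == c].mean()) ** 2))
                   for c in range(4))
        _, want = brute_force_kmeans_1d(values, 4)
        assert cost == pytest.approx(want, abs=1e-6)

    def test_labels_ordered_by_centroid(self):
        values = [10.0, -5.0, 100.0, 0.5, 55.0, 60.0, -4.0, 11.0]
        labels = classify_clusters(values, k=4)
        means = {}
        for v, lab in zip(values, labels):
            means.setdefault(lab, []).append(v)
        ordered = sorted(means, key=lambda lab: np.mean(means[lab]))
        assert ordered == ["very low", "low", "high", "very high"]
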