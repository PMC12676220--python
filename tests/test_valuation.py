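"""Benefit transfer, VSLY, monetization and ratio contracts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from burdenval.config import SyntheticConfig, VSLBenchmark
from burdenval.errors import (DataError, JoinError, UndefinedStatisticError,
                              VocabularyError)
from burdenval.synthetic import generate_burden
from burdenval.valuation import (combined_sex_vlw, daly_yll_gap,
                                 daly_yll_gap_table, monetize,
                                 national_totals, transfer_vsl, vlw_to_gdp,
                                 vsly)


def cells_df(rows):
    """rows: (province, sex, age, measure, count)"""
    return pd.DataFrame(
        [{"province": p, "sex": s, "age_group": a, "measure": m,
          "rate": np.nan, "population": np.nan, "count": c}
         for p, s, a, m, c in rows])


class TestTransferVSL:
    def test_zero_elasticity_is_identity(self):
        assert transfer_vsl(5e6, 1000, 50_000, 0.0) == 5e6

    def test_equal_incomes_is_identity(self):
        assert transfer_vsl(5e6, 4300, 4300, 1.0) == 5e6

    def test_income_adjusted_transfer(self):
        # a 10M reference at a 0.12 income ratio with unit elasticity
        assert transfer_vsl(10_000_000, 1200, 10_000, 1.0) == \
            pytest.approx(1_200_000)

    @pytest.mark.parametrize("kwargs", [
        dict(vsl_reference=-1, gdp_target_pc=1, gdp_reference_pc=1),
        dict(vsl_reference=1, gdp_target_pc=0, gdp_reference_pc=1),
        dict(vsl_reference=1, gdp_target_pc=1, gdp_reference_pc=1,
             elasticity=-0.5),
    ])
    def test_domain_errors(self, kwargs):
        with pytest.raises(ValueError):
            transfer_vsl(**kwargs)

    @settings(derandomize=True, max_examples=50)
    @given(ratio=st.floats(0.01, 100), c=st.floats(0.1, 10))
    def test_unit_elasticity_is_homogeneous_in_income_ratio(self, ratio, c):
        base = transfer_vsl(1e6, ratio, 1.0, 1.0)
        scaled = transfer_vsl(1e6, c * ratio, 1.0, 1.0)
        assert scaled == pytest.approx(c * base, rel=1e-12)


class TestVSLY:
    def test_sex_specific_quotients(self, benchmarks, le):
        assert vsly(benchmarks["wage"], "both", le) == \
            pytest.approx(12_925.17, abs=0.01)
        assert vsly(benchmarks["wage"], "male", le) == \
            pytest.approx(15_658.48, abs=0.01)

    def test_unit_life_expectancy_returns_vsl(self, benchmarks, le):
        one = le.model_copy(update={"male": 1.0})
        assert vsly(benchmarks["wage"], "male", one) == \
            benchmarks["wage"].vsl_usd

    def test_unknown_sex_raises(self, benchmarks, le):
        with pytest.raises(VocabularyError):
            vsly(benchmarks["wage"], "other", le)


class TestMonetize:
    def test_hand_computed_single_cell(self, benchmarks, le):
        cells = cells_df([("P", "male", "<1", "DALY", 100_000.0)])
        loss = monetize(cells, benchmarks["wage"], le)
        assert loss["vlw_billion_usd"].iloc[0] == \
            pytest.approx(1.5658, abs=5e-5)

    def test_zero_burden_gives_zero_loss(self, benchmarks, le):
        cells = cells_df([("P", s, a, "DALY", 0.0)
                          for s in ("male", "female")
                          for a in ("<1", "1-4")])
        loss = monetize(cells, benchmarks["wage"], le)
        assert (loss["vlw_billion_usd"] == 0).all()

    def test_additive_over_age_bins_and_provinces(self, benchmarks, le):
        split = cells_df([("P1", "male", "<1", "DALY", 300.0),
                          ("P1", "male", "1-4", "DALY", 700.0),
                          ("P2", "male", "<1", "DALY", 500.0)])
        merged = cells_df([("P1", "male", "all", "DALY", 1000.0),
                           ("P2", "male", "all", "DALY", 500.0)])
        a = monetize(split, benchmarks["wage"], le)
        b = monetize(merged, benchmarks["wage"], le)
        pd.testing.assert_frame_equal(a, b)
        nat = national_totals(a)
        assert nat["vlw_billion_usd"].iloc[0] == \
            pytest.approx(a["vlw_billion_usd"].sum())

    def test_linear_in_vsl(self, benchmarks, le):
        cells = generate_burden(SyntheticConfig(n_provinces=4, seed=5))
        wage = monetize(cells, benchmarks["wage"], le)
        usdot = monetize(cells, benchmarks["usdot"], le)
        np.testing.assert_allclose(
            usdot["vlw_billion_usd"],
            wage["vlw_billion_usd"] * 1.77 / 0.95, rtol=1e-12)

    def test_missing_counts_and_population_raise(self, benchmarks, le):
        cells = cells_df([("P", "male", "<1", "DALY", np.nan)])
        with pytest.raises(DataError):
            monetize(cells, benchmarks["wage"], le)

    def test_counts_derived_from_rate_and_population(self, benchmarks, le):
        cells = cells_df([("P", "male", "<1", "DALY", np.nan)])
        cells.loc[0, ["rate", "population"]] = [100.0, 1e6]
        loss = monetize(cells, benchmarks["wage"], le)
        expected = 1000.0 * vsly(benchmarks["wage"], "male", le) / 1e9
        assert loss["vlw_billion_usd"].iloc[0] == pytest.approx(expected)

    def test_combined_sex_accounting_identity(self, benchmarks, le):
        """VLW_both*LE_both == VLW_m*LE_m + VLW_f*LE_f for shared counts."""
        cells = generate_burden(SyntheticConfig(n_provinces=5, seed=9))
        loss = monetize(cells, benchmarks["oecd"], le)
        wide = loss.pivot_table(index=["province", "measure"], columns="sex",
                                values="vlw_billion_usd")
        np.testing.assert_allclose(
            wide["both"] * le.both,
            wide["male"] * le.male + wide["female"] * le.female, rtol=1e-12)


def test_combined_sex_vlw_recovers_published_national(benchmarks, le):
    got = combined_sex_vlw(6.931, 3.309, benchmarks["wage"], le)
    assert got == pytest.approx(9.030, abs=0.01)


class TestRatiosAndGap:
    def test_vlw_to_gdp_hand_values(self, benchmarks):
        losses = pd.DataFrame({
            "province": ["A", "B"], "sex": "both", "measure": "DALY",
            "benchmark": "wage", "vlw_billion_usd": [1.0, 0.0]})
        econ = pd.DataFrame({"province": ["A", "B"],
                             "gdp_usd": [100e9, 50e9]})
        ratios = vlw_to_gdp(losses, econ)
        assert ratios["ratio_percent"].tolist() == pytest.approx([1.0, 0.0])

    def test_unmatched_province_raises_join_error(self):
        losses = pd.DataFrame({
            "province": ["A", "Z"], "sex": "both", "measure": "DALY",
            "benchmark": "wage", "vlw_billion_usd": [1.0, 1.0]})
        econ = pd.DataFrame({"province": ["A"], "gdp_usd": [1e9]})
        with pytest.raises(JoinError, match="Z"):
            vlw_to_gdp(losses, econ)

    def test_gap_examples(self):
        assert daly_yll_gap(1.0, 1.0) == 0.0
        # the two provinces with the largest and a mid-size published gap
        assert round(daly_yll_gap(0.042, 0.037)) == 12
        assert daly_yll_gap(0.096, 0.090) == pytest.approx(6.25)

    def test_gap_zero_daly_raises(self):
        with pytest.raises(UndefinedStatisticError):
            daly_yll_gap(0.0, 0.0)

    def test_gap_table_matches_scalar(self, benchmarks, le):
        cells = generate_burden(SyntheticConfig(n_provinces=3, seed=2))
        loss = monetize(cells, benchmarks["wage"], le)
        gaps = daly_yll_gap_table(loss)
        wide = loss.pivot_table(index=["province", "sex"], columns="measure",
                                values="vlw_billion_usd")
        for _, row in gaps.iterrows():
            d, y = wide.loc[(row["province"], row["sex"])]
            assert row["gap_percent"] == pytest.approx(daly_yll_gap(d, y))
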