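"""Monetization of disease burden into value of lost welfare (VLW).

The chain is: a value of a statistical life (VSL) benchmark, optionally
income-transferred from a reference economy, is divided by sex-specific
life expectancy to give a value per statistical life year (VSLY); burden
counts (DALYs or YLLs) are multiplied by the VSLY and summed over age
groups to give a welfare loss per (province, sex, measure, benchmark) in
billion USD; losses are normalized by provincial GDP to a percent ratio.

Combined-sex losses are always computed from combined-sex counts with the
combined life expectancy — never as the sum of the male and female losses,
which use different divisors.  The accounting identity

    VLW_both * LE_both == VLW_male * LE_male + VLW_female * LE_female

follows from the shared counts and is what national tables obey.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import LifeExpectancyTable, VSLBenchmark
from .errors import DataError, JoinError, UndefinedStatisticError

#: canonical column order of a welfare-loss table
LOSS_COLUMNS = ["province", "sex", "measure", "benchmark",
                "vlw_billion_usd"]

RATIO_COLUMNS = ["province", "sex", "measure", "benchmark", "ratio_percent"]


def transfer_vsl(vsl_reference: float, gdp_target_pc: float,
                 gdp_reference_pc: float, elasticity: float = 1.0) -> float:
    """Benefit-transfer a reference VSL to a target economy.

    Returns ``vsl_reference * (gdp_target_pc / gdp_reference_pc)**elasticity``
    — the standard income-adjustment with elasticity 1.0 the conventional
    choice for transfers to lower-middle-income settings.
    """
    if vsl_reference <= 0 or gdp_target_pc <= 0 or gdp_reference_pc <= 0:
        raise ValueError("VSL and GDP-per-capita inputs must be positive")
    if elasticity < 0:
        raise ValueError("elasticity must be non-negative")
    return vsl_reference * (gdp_target_pc / gdp_reference_pc) ** elasticity


def vsly(benchmark: VSLBenchmark, sex: str,
         le: LifeExpectancyTable) -> float:
    """Value per statistical life year: VSL / life expectancy, in USD."""
    return benchmark.vsl_usd / le.for_sex(sex)


def monetize(cells: pd.DataFrame, benchmark: VSLBenchmark,
             le: LifeExpectancyTable) -> pd.DataFrame:
    """Monetize burden cells into welfare losses, in billion USD.

    For each (province, sex, measure), the loss is the age-summed burden
    count times the sex-specific VSLY.  Counts are derived from rate and
    population when absent.
    """
    cells = cells.copy()
    count = cells["count"].astype(float)
    if count.isna().any():
        derivable = cells["rate"].notna() & cells["population"].notna()
        fill = cells["rate"] / 1e5 * cells["population"]
        count = count.where(count.notna(), fill.where(derivable))
        if count.isna().any():
            bad = cells.loc[count.isna(), "province"].unique().tolist()
            raise DataError(
                "cells carry neither counts nor (rate, population) to derive "
                f"them; provinces: {sorted(bad)[:5]}")
    cells["count"] = count

    per_sex = {sex: vsly(benchmark, sex, le)
               for sex in cells["sex"].unique()}
    cells["_usd"] = cells["count"] * cells["sex"].map(per_sex)
    out = (cells.groupby(["province", "sex", "measure"], as_index=False,
                         sort=True)["_usd"].sum())
    out["benchmark"] = benchmark.name
    out["vlw_billion_usd"] = out.pop("_usd") / 1e9
    return out[LOSS_COLUMNS]


def national_totals(losses: pd.DataFrame,
                    label: str = "National") -> pd.DataFrame:
    """Sum provincial losses into a national row per (sex, measure, benchmark).

    Valid because welfare losses are additive over any partition of the
    nation at fixed sex (the VSLY multiplier is constant within a sex).
    """
    tot = (losses.groupby(["sex", "measure", "benchmark"], as_index=False,
                          sort=True)["vlw_billion_usd"].sum())
    tot.insert(0, "province", label)
    return tot[LOSS_COLUMNS]


def combined_sex_vlw(vlw_male: float, vlw_female: float,
                     benchmark: VSLBenchmark, le: LifeExpectancyTable,
                     measure: str = "DALY",
                     province: str = "combined") -> float:
    """Recover the combined-sex welfare loss from sex-specific losses.

    Inverts each sex's loss (billion USD) to its burden count via the
    sex-specific VSLY, sums the counts, and re-monetizes with the
    combined-sex VSLY — the accounting identity linking the Both column of
    a published table to its Males/Females columns.
    """
    cells = pd.DataFrame({
        "province": [province],
        "sex": ["both"],
        "age_group": ["all"],
        "measure": [measure],
        "rate": [np.nan],
        "population": [np.nan],
        "count": [vlw_male * 1e9 / vsly(benchmark, "male", le)
                  + vlw_female * 1e9 / vsly(benchmark, "female", le)],
    })
    loss = monetize(cells, benchmark, le)
    return float(loss["vlw_billion_usd"].iloc[0])


def vlw_to_gdp(losses: pd.DataFrame, econ: pd.DataFrame) -> pd.DataFrame:
    """Welfare loss as a percent of provincial GDP.

    ``ratio_percent = 100 * VLW / GDP`` with both sides in USD.  Raises
    :class:`JoinError` when loss provinces are missing from the economy
    table.
    """
    merged = losses.merge(econ[["province", "gdp_usd"]], on="province",
                          how="left")
    unmatched = merged.loc[merged["gdp_usd"].isna(), "province"].unique()
    if len(unmatched):
        raise JoinError(
            f"provinces absent from economy table: {sorted(unmatched)}")
    if (merged["gdp_usd"] <= 0).any():
        raise DataError("economy table carries non-positive GDP")
    merged["ratio_percent"] = (100.0 * merged["vlw_billion_usd"] * 1e9
                               / merged["gdp_usd"])
    return merged[RATIO_COLUMNS]


def daly_yll_gap(vlw_daly: float, vlw_yll: float) -> float:
    """Percent by which the DALY-based loss exceeds the YLL-based loss.

    ``100 * (VLW_DALY - VLW_YLL) / VLW_DALY``; the DALY denominator makes
    the gap the morbidity (YLD) share of the monetized burden.
    """
    if vlw_daly == 0:
        raise UndefinedStatisticError(
            "DALY-based welfare loss is zero; gap undefined")
    return 100.0 * (vlw_daly - vlw_yll) / vlw_daly


def daly_yll_gap_table(losses: pd.DataFrame) -> pd.DataFrame:
    """Per-(province, sex, benchmark) DALY-YLL gap from a long loss table."""
    wide = losses.pivot_table(index=["province", "sex", "benchmark"],
                              columns="measure", values="vlw_billion_usd",
                              aggfunc="first")
    missing = [m for m in ("DALY", "YLL") if m not in wide.columns]
    if missing:
        raise DataError(f"loss table lacks measure(s) {missing} for gap")
    if (wide["DALY"] == 0).any():
        raise UndefinedStatisticError(
            "zero DALY-based welfare loss; gap undefined")
    out = wide.reset_index()
    out["gap_percent"] = 100.0 * (out["DALY"] - out["YLL"]) / out["DALY"]
    return out[["province", "sex", "benchmark", "gap_percent"]]
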