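"""Readers and writers for burden and economy tables.

The burden reader targets the GBD results-tool export shape: a
comma-delimited table with ``measure, location, sex, age, cause, metric,
year, value`` columns.  Sex and measure labels are normalized onto the
package's controlled vocabularies, and rates are materialized into
absolute counts whenever a population table can be joined.  The economy
reader handles local-currency-to-USD conversion.  All writers emit plain
CSV that round-trips at full float precision.
"""

from __future__ import annotations

import os
from typing import Mapping, Optional

import pandas as pd

from .config import MEASURES, SEXES, CurrencyConfig
from .errors import DataError, SchemaError, VocabularyError

GBD_COLUMNS = ["measure", "location", "sex", "age", "cause", "metric",
               "year", "value"]

#: canonical column order of a materialized burden-cell table
CELL_COLUMNS = ["province", "sex", "age_group", "measure", "rate",
                "population", "count"]

ECONOMY_COLUMNS = ["province", "gdp_local", "gdp_usd",
                   "gdp_per_capita_usd", "population"]

_SEX_ALIASES = {
    "male": "male", "males": "male",
    "female": "female", "females": "female",
    "both": "both", "both sexes": "both", "all": "both",
}

_MEASURE_ALIASES = {
    "daly": "DALY",
    "dalys": "DALY",
    "dalys (disability-adjusted life years)": "DALY",
    "yll": "YLL",
    "ylls": "YLL",
    "ylls (years of life lost)": "YLL",
}


def _normalize_labels(series: pd.Series, aliases: Mapping[str, str],
                      kind: str) -> pd.Series:
    normalized = series.astype(str).str.strip().str.lower().map(aliases)
    if normalized.isna().any():
        bad = series[normalized.isna()]
        row, label = bad.index[0], bad.iloc[0]
        raise VocabularyError(
            f"unknown {kind} label {label!r} at row {row}")
    return normalized


def read_burden_table(path: str, cause_filter: str, metric: str,
                      population: Optional[pd.DataFrame] = None,
                      column_map: Optional[Mapping[str, str]] = None,
                      ) -> pd.DataFrame:
    """Read a GBD-export-style burden table into burden cells.

    Parameters
    ----------
    path
        CSV file with the standard export columns (a ``column_map`` of
        ``{file_column: standard_column}`` accommodates renamed variants).
    cause_filter
        Case-insensitive substring selecting the cause of interest
        (e.g. ``"congenital heart"``).
    metric
        ``"Rate"`` (events per 100,000) or ``"Number"`` (absolute counts).
    population
        Optional table with ``province, sex, population`` columns used to
        materialize counts from rates (or rates from counts).

    Returns
    -------
    DataFrame with :data:`CELL_COLUMNS`; ``count`` (respectively ``rate``)
    is NaN when no population is joinable.
    """
    if metric not in ("Rate", "Number"):
        raise ValueError(f"metric must be 'Rate' or 'Number', got {metric!r}")
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in GBD_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")

    keep = df["cause"].astype(str).str.lower().str.contains(
        cause_filter.lower(), regex=False)
    keep &= df["metric"].astype(str).str.strip() == metric
    df = df.loc[keep].reset_index(drop=True)

    cells = pd.DataFrame({
        "province": df["location"].astype(str),
        "age_group": df["age"].astype(str),
    })
    if len(df):
        cells["sex"] = _normalize_labels(df["sex"], _SEX_ALIASES, "sex")
        cells["measure"] = _normalize_labels(df["measure"], _MEASURE_ALIASES,
                                             "measure")
    else:
        cells["sex"] = pd.Series(dtype=str)
        cells["measure"] = pd.Series(dtype=str)

    value = df["value"].astype(float)
    if population is not None:
        pop = population[["province", "sex", "population"]]
        cells = cells.merge(pop, on=["province", "sex"], how="left")
    else:
        cells["population"] = float("nan")

    if metric == "Rate":
        cells["rate"] = value
        cells["count"] = cells["rate"] / 1e5 * cells["population"]
    else:
        cells["count"] = value
        cells["rate"] = cells["count"] / cells["population"] * 1e5
    return cells[CELL_COLUMNS]


def read_population_table(path: str) -> pd.DataFrame:
    """Read a ``province, sex, population`` table."""
    df = pd.read_csv(path)
    missing = [c for c in ("province", "sex", "population")
               if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    df["sex"] = _normalize_labels(df["sex"], _SEX_ALIASES, "sex")
    return df[["province", "sex", "population"]]


def read_economy_table(path: str, currency: CurrencyConfig,
                       in_usd: bool = False) -> pd.DataFrame:
    """Read a provincial economy table and express GDP in USD.

    Accepts a ``gdp_usd`` column (used directly), a ``gdp_local`` column
    (converted with ``currency.exchange_rate``), or an ambiguous ``gdp``
    column interpreted per the ``in_usd`` flag.  ``gdp_per_capita_usd`` is
    recomputed when absent.
    """
    df = pd.read_csv(path)
    missing = [c for c in ("province", "population") if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")

    if "gdp_usd" in df.columns:
        gdp_usd = df["gdp_usd"].astype(float)
        gdp_local = df.get("gdp_local", gdp_usd * currency.exchange_rate)
    elif "gdp_local" in df.columns:
        gdp_local = df["gdp_local"].astype(float)
        gdp_usd = gdp_local / currency.exchange_rate
    elif "gdp" in df.columns:
        raw = df["gdp"].astype(float)
        if in_usd:
            gdp_usd, gdp_local = raw, raw * currency.exchange_rate
        else:
            gdp_local, gdp_usd = raw, raw / currency.exchange_rate
    else:
        raise SchemaError(
            "missing required columns: need one of gdp_usd, gdp_local, gdp")

    out = pd.DataFrame({
        "province": df["province"].astype(str),
        "gdp_local": pd.Series(gdp_local, dtype=float),
        "gdp_usd": pd.Series(gdp_usd, dtype=float),
        "population": df["population"].astype(float),
    })
    if "gdp_per_capita_usd" in df.columns:
        out["gdp_per_capita_usd"] = df["gdp_per_capita_usd"].astype(float)
    else:
        out["gdp_per_capita_usd"] = out["gdp_usd"] / out["population"]

    bad = out[(out["gdp_usd"] <= 0) | (out["population"] <= 0)]
    if len(bad):
        raise DataError(
            "non-positive GDP or population for province(s): "
            f"{sorted(bad['province'].tolist())}")
    return out[ECONOMY_COLUMNS]


def write_results(records: pd.DataFrame, path: str) -> None:
    """Write a tidy result table as CSV; full precision, stable columns.

    Raises :class:`DataError` on an empty collection rather than emitting
    an empty file.
    """
    if records is None or len(records) == 0:
        raise DataError(f"refusing to write empty result table to {path}")
    records.to_csv(path, index=False)


def read_results(path: str) -> pd.DataFrame:
    return pd.read_csv(path)


def write_gbd_export(cells: pd.DataFrame, path: str,
                     cause: str = "Congenital heart anomalies",
                     year: int = 2021) -> None:
    """Write burden cells in the GBD results-export dialect.

    Emits one ``Rate`` and one ``Number`` row per cell, so the file can be
    read back under either metric.
    """
    if len(cells) == 0:
        raise DataError(f"refusing to write empty burden table to {path}")
    sex_out = {"male": "Male", "female": "Female", "both": "Both sexes"}
    rows = []
    for metric, col in (("Rate", "rate"), ("Number", "count")):
        rows.append(pd.DataFrame({
            "measure": cells["measure"],
            "location": cells["province"],
            "sex": cells["sex"].map(sex_out),
            "age": cells["age_group"],
            "cause": cause,
            "metric": metric,
            "year": year,
            "value": cells[col].astype(float),
        }))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def write_population_table(cells: pd.DataFrame, path: str) -> None:
    """Write the per-(province, sex) populations carried by burden cells."""
    pop = (cells[["province", "sex", "population"]]
           .drop_duplicates()
           .sort_values(["province", "sex"])
           .reset_index(drop=True))
    pop.to_csv(path, index=False)


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
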