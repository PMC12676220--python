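"""Synthetic province-level burden and economy tables.

Generates data with the statistical structure the valuation pipeline
assumes, so every downstream stage is testable without external
downloads: province-like units on an east-west axis with a GDP-per-capita
gradient; infancy-dominated age structure; male burden rates exceeding
female rates by a configurable factor; YLL rates an exact
``(1 - yld_share)`` multiple of DALY rates; burden rates (anti)correlated
with provincial income; and multiplicative lognormal measurement noise on
rates only (populations are noise-free).

Accounting identities hold by construction: combined-sex counts are the
sum of the male and female counts, and GDP equals GDP per capita times
population exactly.  Identical config and seed give byte-identical
tables.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import IDR_PER_USD_2021, SyntheticConfig
from .io import CELL_COLUMNS, ECONOMY_COLUMNS


def province_labels(n: int) -> list[str]:
    """West-to-east ordered synthetic province labels."""
    return [f"Province-{i + 1:02d}" for i in range(n)]


def _province_frame(config: SyntheticConfig) -> pd.DataFrame:
    """Shared per-province draws: position, population, GDP pc, burden level.

    Both generators derive from this frame (same seed stream), so burden
    and economy tables are mutually consistent.  Provinces sit at
    positions ``s`` in [-1, 1]; GDP per capita rises with ``s`` as
    ``exp(gdp_gradient * s)`` and the province burden multiplier follows
    ``exp(spread * (rho * s + sqrt(1 - rho^2) * z))`` so that
    ``burden_gdp_correlation`` of +-1 gives exact (anti)alignment of
    ranks and intermediate values mix in province-level heterogeneity.
    """
    n = config.n_provinces
    rng = np.random.default_rng([config.seed, 0])
    s = np.linspace(-1.0, 1.0, n) if n > 1 else np.zeros(1)
    lo, hi = config.population_range
    population = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    z = rng.standard_normal(n)
    rho = config.burden_gdp_correlation
    gdp_pc = config.gdp_pc_base * np.exp(config.gdp_gradient * s)
    burden_level = np.exp(config.burden_spread
                          * (rho * s + np.sqrt(1.0 - rho ** 2) * z))
    return pd.DataFrame({
        "province": province_labels(n),
        "position": s,
        "population": population,
        "gdp_per_capita_usd": gdp_pc,
        "burden_level": burden_level,
    })


def generate_burden(config: SyntheticConfig) -> pd.DataFrame:
    """Generate burden cells for both measures, both sexes plus combined.

    Female DALY rates are ``base_daly_rate * age_weight * burden_level``
    perturbed by mean-one lognormal noise with CV ``noise_cv``; male rates
    carry the ``(1 + male_excess)`` factor before their own noise draw.
    YLL rates share the DALY noise so YLL <= DALY holds cell-wise.  The
    two sexes split each province's population equally; combined-sex rows
    are derived from summed counts.
    """
    prov = _province_frame(config)
    ages = np.asarray(config.age_groups)
    w = np.asarray(config.age_weights, dtype=float)
    w = w / w.sum()

    rng = np.random.default_rng([config.seed, 1])
    n, a = len(prov), len(ages)
    if config.noise_cv > 0:
        sigma = np.sqrt(np.log1p(config.noise_cv ** 2))
        noise = rng.lognormal(-sigma ** 2 / 2, sigma, size=(n, 2, a))
    else:
        noise = np.ones((n, 2, a))

    frames = []
    for ip, row in prov.iterrows():
        pop_sex = row["population"] / 2.0
        base = config.base_daly_rate * row["burden_level"] * w
        daly_f = base * noise[ip, 0]
        daly_m = base * (1.0 + config.male_excess) * noise[ip, 1]
        for measure, scale in (("DALY", 1.0), ("YLL", 1.0 - config.yld_share)):
            rate_f, rate_m = daly_f * scale, daly_m * scale
            count_f = rate_f / 1e5 * pop_sex
            count_m = rate_m / 1e5 * pop_sex
            count_b = count_m + count_f
            rate_b = count_b / row["population"] * 1e5
            for sex, rate, popn, count in (
                    ("male", rate_m, pop_sex, count_m),
                    ("female", rate_f, pop_sex, count_f),
                    ("both", rate_b, row["population"], count_b)):
                frames.append(pd.DataFrame({
                    "province": row["province"],
                    "sex": sex,
                    "age_group": ages,
                    "measure": measure,
                    "rate": rate,
                    "population": popn,
                    "count": count,
                }))
    cells = pd.concat(frames, ignore_index=True)
    return (cells.sort_values(["province", "measure", "sex", "age_group"],
                              kind="stable")
            .reset_index(drop=True)[CELL_COLUMNS])


def generate_economy(config: SyntheticConfig,
                     exchange_rate: float = IDR_PER_USD_2021) -> pd.DataFrame:
    """Generate one economic record per province.

    GDP equals GDP per capita times population exactly; the local-currency
    column is the USD value scaled by ``exchange_rate``.
    """
    prov = _province_frame(config)
    econ = pd.DataFrame({
        "province": prov["province"],
        "gdp_usd": prov["gdp_per_capita_usd"] * prov["population"],
        "gdp_per_capita_usd": prov["gdp_per_capita_usd"],
        "population": prov["population"],
    })
    econ["gdp_local"] = econ["gdp_usd"] * exchange_rate
    return econ[ECONOMY_COLUMNS]
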