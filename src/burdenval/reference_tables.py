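"""Published provincial welfare-loss estimates bundled for reproduction.

The 2021 Indonesian congenital-heart-disease VLW tables (billion USD,
three VSL benchmarks x three sex strata, DALY- and YLL-based), as
printed to three decimals.  These are used by the reproduction checks:
rounded-input gender disparities, the combined-sex accounting identity
and the cross-benchmark scaling all take the printed values as inputs.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

NATIONAL_LABEL = "Indonesia"

_FILES = {"DALY": "indonesia_chd_vlw_daly_2021.csv",
          "YLL": "indonesia_chd_vlw_yll_2021.csv"}


def load_published_vlw(measure: str | None = None) -> pd.DataFrame:
    """Load the published VLW tables as a tidy loss table.

    Returns the standard long layout (``province, sex, measure,
    benchmark, vlw_billion_usd``); ``measure`` restricts to ``"DALY"`` or
    ``"YLL"``.  The national aggregate carries the province label
    :data:`NATIONAL_LABEL`.
    """
    measures = [measure] if measure else list(_FILES)
    frames = []
    for m in measures:
        if m not in _FILES:
            raise ValueError(f"measure must be one of {list(_FILES)}")
        ref = resources.files("burdenval.data") / _FILES[m]
        with resources.as_file(ref) as path:
            wide = pd.read_csv(path)
        long = wide.melt(id_vars="province", var_name="key",
                         value_name="vlw_billion_usd")
        long[["benchmark", "sex"]] = long["key"].str.split("_", expand=True)
        long["measure"] = m
        frames.append(long.drop(columns="key"))
    out = pd.concat(frames, ignore_index=True)
    return out[["province", "sex", "measure", "benchmark",
                "vlw_billion_usd"]]


def published_provinces() -> list[str]:
    """The 34 provincial labels (national row excluded), sorted."""
    df = load_published_vlw("DALY")
    provinces = sorted(set(df["province"]) - {NATIONAL_LABEL})
    return provinces
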