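"""Gender and geographic disparity statistics with cluster labeling.

Three statistics over welfare losses:

* gender relative difference — percent excess of the male loss over the
  female loss;
* location quotient (LQ) — a province's share of the national loss
  divided by its share of the national population (LQ > 1 flags a
  disproportionate burden);
* disparity index — the provincial loss-to-GDP ratio divided by a
  national reference ratio.

Provinces are then grouped by a one-dimensional k-means.  Because optimal
1-D k-means partitions are contiguous in sorted order, the clustering is
solved exactly by dynamic programming over contiguous partitions rather
than by Lloyd iterations, so the result is deterministic and globally
optimal in within-cluster sum of squares.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ClusteringError, DataError, UndefinedStatisticError

#: default ordered label sets, lowest cluster first
GEO_LABELS = ("very low", "low", "high", "very high")
GENDER_LABELS = ("low", "moderate", "high", "very high")

STATISTICS = ("gender_rel_diff_percent", "location_quotient",
              "disparity_index")


def round_half_away(x: float, ndigits: int) -> float:
    """Round half away from zero (presentation rounding of the tables)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def gender_disparity(vlw_male: float, vlw_female: float) -> float:
    """Male-female relative difference, percent of the female loss."""
    if vlw_female <= 0:
        raise UndefinedStatisticError(
            "female welfare loss must be positive for gender disparity")
    return 100.0 * (vlw_male - vlw_female) / vlw_female


def gender_disparity_table(losses: pd.DataFrame,
                           rounded_inputs: bool = False) -> pd.DataFrame:
    """Gender disparity per (province, measure, benchmark).

    ``rounded_inputs=True`` first rounds the losses to 3 decimals (billion
    USD), reproducing statistics computed from published table values
    rather than from full-precision internals.
    """
    df = losses.copy()
    if rounded_inputs:
        df["vlw_billion_usd"] = df["vlw_billion_usd"].map(
            lambda v: round_half_away(v, 3))
    wide = df.pivot_table(index=["province", "measure", "benchmark"],
                          columns="sex", values="vlw_billion_usd",
                          aggfunc="first")
    missing = [s for s in ("male", "female") if s not in wide.columns]
    if missing:
        raise DataError(f"loss table lacks sex(es) {missing}")
    if (wide["female"] <= 0).any():
        bad = wide.index[wide["female"] <= 0].get_level_values(0).unique()
        raise UndefinedStatisticError(
            f"non-positive female loss for {sorted(bad)}")
    out = wide.reset_index()
    out["value"] = 100.0 * (out["male"] - out["female"]) / out["female"]
    out["statistic"] = "gender_rel_diff_percent"
    return out[["province", "measure", "benchmark", "statistic", "value"]]


def location_quotient(vlw_province: float, vlw_national: float,
                      pop_province: float, pop_national: float) -> float:
    """Share of national loss over share of national population."""
    if vlw_national <= 0 or pop_national <= 0:
        raise UndefinedStatisticError("national loss and population must be "
                                      "positive for a location quotient")
    if pop_province > pop_national:
        raise DataError("province population exceeds national population")
    return (vlw_province / vlw_national) / (pop_province / pop_national)


def location_quotient_table(losses: pd.DataFrame,
                            populations: pd.DataFrame) -> pd.DataFrame:
    """LQ per (province, measure, benchmark) from combined-sex losses.

    ``populations`` carries ``province, population``; the national totals
    are the sums over the provinces present, which must partition the
    nation.
    """
    both = losses[losses["sex"] == "both"]
    if len(both) == 0:
        raise DataError("loss table lacks combined-sex rows for LQ")
    pop = populations[["province", "population"]].drop_duplicates("province")
    merged = both.merge(pop, on="province", how="left")
    if merged["population"].isna().any():
        bad = merged.loc[merged["population"].isna(), "province"].unique()
        raise DataError(f"no population for province(s) {sorted(bad)}")
    nat = merged.groupby(["measure", "benchmark"])["vlw_billion_usd"] \
                .transform("sum")
    pop_nat = merged.groupby(["measure", "benchmark"])["population"] \
                    .transform("sum")
    merged["value"] = ((merged["vlw_billion_usd"] / nat)
                       / (merged["population"] / pop_nat))
    merged["statistic"] = "location_quotient"
    return merged[["province", "measure", "benchmark", "statistic", "value"]]


def disparity_index(ratio_province: float, ratio_national: float) -> float:
    """Provincial loss-to-GDP ratio relative to the national reference."""
    if ratio_national <= 0:
        raise UndefinedStatisticError(
            "national loss-to-GDP ratio must be positive")
    return ratio_province / ratio_national


def disparity_index_table(ratios: pd.DataFrame,
                          national_label: Optional[str] = None,
                          reference: str = "aggregate") -> pd.DataFrame:
    """Disparity index per (province, measure, benchmark).

    The national reference ratio is either the row labelled
    ``national_label`` (the aggregate national ratio, the default reading
    of "national average") or, with ``reference="province_mean"``, the
    unweighted mean of the provincial ratios.
    """
    both = ratios[ratios["sex"] == "both"].copy()
    is_nat = (both["province"] == national_label) if national_label else \
        pd.Series(False, index=both.index)
    prov = both[~is_nat]
    if reference == "aggregate":
        if national_label is None or not is_nat.any():
            raise DataError("aggregate reference needs a national row; pass "
                            "national_label")
        ref = both[is_nat].set_index(["measure", "benchmark"])["ratio_percent"]
    elif reference == "province_mean":
        ref = prov.groupby(["measure", "benchmark"])["ratio_percent"].mean()
    else:
        raise ValueError(f"unknown reference mode {reference!r}")
    out = prov.copy()
    key = list(zip(out["measure"], out["benchmark"]))
    out["_ref"] = [ref.loc[k] for k in key]
    if (out["_ref"] <= 0).any():
        raise UndefinedStatisticError("national reference ratio is zero")
    out["value"] = out["ratio_percent"] / out["_ref"]
    out["statistic"] = "disparity_index"
    return out[["province", "measure", "benchmark", "statistic", "value"]]


def _contiguous_kmeans(sorted_values: np.ndarray, k: int) -> np.ndarray:
    """Exact 1-D k-means on sorted values via dynamic programming.

    Returns cluster ids 0..k-1 in ascending value order.  O(k n^2) with
    prefix-sum within-cluster costs; ties broken toward the earliest
    feasible boundary.
    """
    n = len(sorted_values)
    s1 = np.concatenate([[0.0], np.cumsum(sorted_values)])
    s2 = np.concatenate([[0.0], np.cumsum(sorted_values ** 2)])

    def cost(i: int, j: int) -> float:
        # within-cluster SSE of sorted_values[i:j+1]
        m = j - i + 1
        tot = s1[j + 1] - s1[i]
        return max((s2[j + 1] - s2[i]) - tot * tot / m, 0.0)

    dp = np.full((k + 1, n + 1), np.inf)
    split = np.zeros((k + 1, n + 1), dtype=int)
    dp[0, 0] = 0.0
    for m in range(1, k + 1):
        for j in range(m, n + 1):
            best, arg = np.inf, m - 1
            for i in range(m - 1, j):
                c = dp[m - 1, i] + cost(i, j - 1)
                if np.isinf(best) or c < best - 1e-12 * (1.0 + best):
                    best, arg = c, i
            dp[m, j], split[m, j] = best, arg

    labels = np.empty(n, dtype=int)
    j = n
    for m in range(k, 0, -1):
        i = split[m, j]
        labels[i:j] = m - 1
        j = i
    return labels


def classify_clusters(values: Sequence[float] | pd.Series, k: int = 4,
                      seed: int = 0,
                      labels: Optional[Sequence[str]] = None):
    """Group 1-D disparity values into k clusters, labelled low to high.

    Solves the 1-D k-means problem exactly (optimal partitions are
    contiguous in sorted order), so identical input always yields
    identical labels; ``seed`` is accepted for interface stability but the
    algorithm is deterministic.  Returns a :class:`pandas.Series` of
    labels aligned with the input (index preserved for Series input).
    Raises :class:`ClusteringError` when there are fewer than ``k``
    distinct values.
    """
    if isinstance(values, pd.Series):
        index, arr = values.index, values.to_numpy(dtype=float)
    else:
        arr = np.asarray(list(values), dtype=float)
        index = pd.RangeIndex(len(arr))
    if len(np.unique(arr)) < k:
        raise ClusteringError(
            f"need at least {k} distinct values, got {len(np.unique(arr))}")
    if labels is None:
        labels = GEO_LABELS if k == 4 else [str(i) for i in range(k)]
    if len(labels) != k:
        raise ValueError(f"need {k} labels, got {len(labels)}")

    order = np.argsort(arr, kind="stable")
    sorted_ids = _contiguous_kmeans(arr[order], k)
    ids = np.empty(len(arr), dtype=int)
    ids[order] = sorted_ids
    return pd.Series([labels[i] for i in ids], index=index, name="cluster")
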