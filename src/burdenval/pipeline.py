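"""End-to-end orchestration: burden tables -> losses -> disparities.

A :class:`PipelineConfig` names either input files (GBD-style burden
export, population table, economy table) or a synthetic-data
configuration; :func:`run_pipeline` then monetizes the burden under each
configured VSL benchmark, normalizes by GDP, computes the gender and
geographic disparity statistics with k-means cluster labels, and
optionally writes the result tables plus a run manifest.

Disparity statistics are computed once per measure from the first
configured benchmark at full precision: the gender relative difference,
the location quotient and the disparity index are all invariant to a
rescaling of the VSL, so the choice of benchmark does not affect them.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd
from pydantic import BaseModel, Field, ValidationError

from . import __version__
from .config import (CurrencyConfig, LifeExpectancyTable, SyntheticConfig,
                     VSLBenchmark, default_benchmarks)
from .disparity import (GENDER_LABELS, GEO_LABELS, classify_clusters,
                        disparity_index_table, gender_disparity_table,
                        location_quotient_table, round_half_away)
from .errors import BurdenvalError
from . import io as bio
from .synthetic import generate_burden, generate_economy
from .valuation import (daly_yll_gap_table, monetize, national_totals,
                        vlw_to_gdp)


class PipelineConfig(BaseModel):
    """Everything one run needs; exactly one data source must be active."""

    synthetic: Optional[SyntheticConfig] = None
    burden_path: Optional[str] = None
    population_path: Optional[str] = None
    economy_path: Optional[str] = None
    cause_filter: str = "congenital heart"
    metric: str = "Rate"
    economy_in_usd: bool = True
    currency: CurrencyConfig = Field(default_factory=CurrencyConfig)
    benchmarks: list[VSLBenchmark] = Field(default_factory=default_benchmarks)
    run_benchmarks: Optional[list[str]] = None
    life_expectancy: LifeExpectancyTable = Field(
        default_factory=LifeExpectancyTable)
    measures: list[str] = Field(default_factory=lambda: ["DALY", "YLL"])
    sexes: list[str] = Field(default_factory=lambda: ["male", "female", "both"])
    cluster_k: int = 4
    gender_labels: list[str] = Field(default_factory=lambda: list(GENDER_LABELS))
    geo_labels: list[str] = Field(default_factory=lambda: list(GEO_LABELS))
    rounded_inputs: bool = False
    disparity_reference: str = "aggregate"
    national_label: str = "National"
    out_dir: Optional[str] = None
    presentation_rounding: bool = True
    quiet: bool = True


@dataclass
class ResultBundle:
    """The tables one pipeline run produces, plus its manifest."""

    losses: pd.DataFrame
    ratios: pd.DataFrame
    gaps: Optional[pd.DataFrame]
    disparities: pd.DataFrame
    manifest: dict = field(default_factory=dict)


def validate_config(config) -> list[str]:
    """Return a list of problems (empty iff the pipeline can run).

    Accepts a :class:`PipelineConfig` or a raw mapping; problems name the
    offending key rather than raising.
    """
    if not isinstance(config, PipelineConfig):
        try:
            config = PipelineConfig.model_validate(config)
        except ValidationError as err:
            return [
                ".".join(str(p) for p in e["loc"]) + ": " + e["msg"]
                for e in err.errors()
            ]
    problems: list[str] = []
    has_files = config.burden_path is not None
    if config.synthetic is not None and has_files:
        problems.append("synthetic/burden_path: exactly one data source may "
                        "be active, got both")
    if config.synthetic is None and not has_files:
        problems.append("synthetic/burden_path: no data source configured")
    if has_files and config.economy_path is None:
        problems.append("economy_path: required with burden_path")
    defined = {b.name for b in config.benchmarks}
    for name in config.run_benchmarks or []:
        if name not in defined:
            problems.append(f"run_benchmarks: benchmark {name!r} is not "
                            "defined")
    for m in config.measures:
        if m not in ("DALY", "YLL"):
            problems.append(f"measures: unknown measure {m!r}")
    for s in config.sexes:
        if s not in ("male", "female", "both"):
            problems.append(f"sexes: unknown sex {s!r}")
    if config.cluster_k < 1:
        problems.append("cluster_k: must be >= 1")
    if len(config.gender_labels) != config.cluster_k:
        problems.append("gender_labels: need exactly cluster_k labels")
    if len(config.geo_labels) != config.cluster_k:
        problems.append("geo_labels: need exactly cluster_k labels")
    return problems


def _log(quiet: bool, stage: str, rows_in: int, rows_out: int,
         t0: float) -> None:
    if not quiet:
        print(f"[{stage}] rows_in={rows_in} rows_out={rows_out} "
              f"wall={time.perf_counter() - t0:.3f}s", file=sys.stderr)


def _stage(name: str):
    """Decorator tagging stage failures with the stage name."""
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except BurdenvalError as e:
                raise type(e)(f"stage {name!r}: {e}") from e
        return inner
    return wrap


@_stage("acquire")
def _acquire(config: PipelineConfig):
    if config.synthetic is not None:
        cells = generate_burden(config.synthetic)
        econ = generate_economy(config.synthetic,
                                exchange_rate=config.currency.exchange_rate)
    else:
        population = (bio.read_population_table(config.population_path)
                      if config.population_path else None)
        cells = bio.read_burden_table(config.burden_path, config.cause_filter,
                                      config.metric, population=population)
        econ = bio.read_economy_table(config.economy_path, config.currency,
                                      in_usd=config.economy_in_usd)
    cells = cells[cells["measure"].isin(config.measures)
                  & cells["sex"].isin(config.sexes)].reset_index(drop=True)
    return cells, econ


@_stage("disparity")
def _disparities(config: PipelineConfig, losses: pd.DataFrame,
                 ratios: pd.DataFrame, econ: pd.DataFrame) -> pd.DataFrame:
    first = losses["benchmark"].iloc[0]
    prov_losses = losses[(losses["benchmark"] == first)
                         & (losses["province"] != config.national_label)]
    prov_ratios = ratios[ratios["benchmark"] == first]
    parts = []
    if {"male", "female"} <= set(config.sexes):
        parts.append(("gender", config.gender_labels,
                      gender_disparity_table(
                          prov_losses, rounded_inputs=config.rounded_inputs)))
    if "both" in config.sexes:
        parts.append(("geo", config.geo_labels,
                      location_quotient_table(
                          prov_losses, econ[["province", "population"]])))
        parts.append(("geo", config.geo_labels,
                      disparity_index_table(
                          prov_ratios, national_label=config.national_label,
                          reference=config.disparity_reference)))
    out = []
    for _, labels, table in parts:
        for measure, grp in table.groupby("measure"):
            grp = grp.copy()
            grp["cluster_label"] = classify_clusters(
                grp.set_index("province")["value"], k=config.cluster_k,
                labels=labels).values
            out.append(grp)
    if not out:
        return pd.DataFrame(columns=["province", "measure", "benchmark",
                                     "statistic", "value", "cluster_label"])
    return (pd.concat(out, ignore_index=True)
            .sort_values(["statistic", "measure", "province"], kind="stable")
            .reset_index(drop=True))


def _presentation_tables(config: PipelineConfig,
                         losses: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Wide per-measure tables mirroring the published layout."""
    tables = {}
    for measure, grp in losses.groupby("measure"):
        wide = grp.pivot_table(index="province", columns=["benchmark", "sex"],
                               values="vlw_billion_usd", aggfunc="first")
        wide.columns = [f"{b}_{s}" for b, s in wide.columns]
        if config.presentation_rounding:
            wide = wide.map(lambda v: round_half_away(v, 3))
        tables[f"vlw_wide_{measure.lower()}"] = wide.reset_index()
    return tables


def run_pipeline(config: PipelineConfig) -> ResultBundle:
    """Run the full analysis and return (and optionally write) the bundle."""
    problems = validate_config(config)
    if problems:
        raise BurdenvalError("invalid configuration: " + "; ".join(problems))

    t0 = time.perf_counter()
    cells, econ = _acquire(config)
    _log(config.quiet, "acquire", 0, len(cells), t0)

    benchmarks = config.benchmarks
    if config.run_benchmarks:
        benchmarks = [b for b in benchmarks
                      if b.name in config.run_benchmarks]

    t0 = time.perf_counter()
    losses = pd.concat(
        [monetize(cells, b, config.life_expectancy) for b in benchmarks],
        ignore_index=True)
    losses = pd.concat(
        [losses, national_totals(losses, label=config.national_label)],
        ignore_index=True)
    _log(config.quiet, "monetize", len(cells), len(losses), t0)

    t0 = time.perf_counter()
    nat_econ = pd.DataFrame({
        "province": [config.national_label],
        "gdp_local": [econ["gdp_local"].sum()],
        "gdp_usd": [econ["gdp_usd"].sum()],
        "gdp_per_capita_usd": [econ["gdp_usd"].sum()
                               / econ["population"].sum()],
        "population": [econ["population"].sum()],
    })
    econ_full = pd.concat([econ, nat_econ], ignore_index=True)
    ratios = vlw_to_gdp(losses, econ_full)
    _log(config.quiet, "ratios", len(losses), len(ratios), t0)

    gaps = None
    if {"DALY", "YLL"} <= set(config.measures):
        gaps = daly_yll_gap_table(losses)

    t0 = time.perf_counter()
    disparities = _disparities(config, losses, ratios, econ)
    _log(config.quiet, "disparity", len(losses), len(disparities), t0)

    payload = config.model_dump_json(exclude={"out_dir", "quiet"})
    manifest = {
        "version": __version__,
        "config_sha256": hashlib.sha256(payload.encode()).hexdigest(),
        "seed": config.synthetic.seed if config.synthetic else None,
        "rows": {"losses": len(losses), "ratios": len(ratios),
                 "disparities": len(disparities)},
        "config": json.loads(payload),
    }
    bundle = ResultBundle(losses=losses, ratios=ratios, gaps=gaps,
                          disparities=disparities, manifest=manifest)
    if config.out_dir:
        _write_bundle(config, bundle)
    return bundle


@_stage("write")
def _write_bundle(config: PipelineConfig, bundle: ResultBundle) -> None:
    import os

    out = bio.ensure_dir(config.out_dir)
    written: list[str] = []
    try:
        tables = {"vlw": bundle.losses, "vlw_to_gdp": bundle.ratios,
                  "disparity": bundle.disparities}
        if bundle.gaps is not None:
            tables["daly_yll_gap"] = bundle.gaps
        tables.update(_presentation_tables(config, bundle.losses))
        for name, table in tables.items():
            path = os.path.join(out, f"{name}.csv")
            bio.write_results(table, path)
            written.append(path)
        path = os.path.join(out, "manifest.txt")
        with open(path, "w") as fh:
            json.dump(bundle.manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        written.append(path)
    except Exception:
        for path in written:
            if os.path.exists(path):
                os.unlink(path)
        raise
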