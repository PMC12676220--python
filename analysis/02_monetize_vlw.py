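"""Monetize the synthetic burden into welfare losses and GDP ratios.

Runs the full valuation under all three VSL benchmarks, writes the loss
and ratio tables under results/valuation/, and reports the national
totals plus the DALY-YLL gap distribution.
"""

import os

from burdenval.pipeline import PipelineConfig, run_pipeline

OUT = os.path.join(os.path.dirname(__file__), "..", "results", "valuation")


def main() -> None:
    config = PipelineConfig(synthetic={"seed": 2021}, out_dir=OUT,
                            quiet=True)
    bundle = run_pipeline(config)

    nat = bundle.losses.query("province == 'National' and sex == 'both'")
    print(f"tables -> {OUT}")
    print("national welfare loss, billion USD (combined sexes):")
    for _, row in nat.sort_values(["measure", "benchmark"]).iterrows():
        print(f"  {row['measure']:4s} {row['benchmark']:5s} "
              f"{row['vlw_billion_usd']:7.3f}")

    nat_ratio = bundle.ratios.query(
        "province == 'National' and sex == 'both' and benchmark == 'wage'")
    for _, row in nat_ratio.iterrows():
        print(f"national wage {row['measure']} VLW-to-GDP: "
              f"{row['ratio_percent']:.2f}%")

    gaps = bundle.gaps.query("sex == 'both' and benchmark == 'wage' and "
                             "province != 'National'")["gap_percent"]
    print(f"provincial DALY-YLL gap: median {gaps.median():.1f}%, "
          f"max {gaps.max():.1f}%")


if __name__ == "__main__":
    main()
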