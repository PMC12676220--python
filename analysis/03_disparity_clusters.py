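"""Gender and geographic disparity statistics with cluster labels.

Reuses the pipeline bundle from the same seed as 02 and reports the
extremes of each statistic and the cluster occupancy, mirroring the kind
of summary a provincial equity analysis prints.
"""

import os

from burdenval.pipeline import PipelineConfig, run_pipeline

OUT = os.path.join(os.path.dirname(__file__), "..", "results", "disparity")


def main() -> None:
    bundle = run_pipeline(PipelineConfig(synthetic={"seed": 2021},
                                         out_dir=OUT, quiet=True))
    disp = bundle.disparities

    for stat in ("gender_rel_diff_percent", "location_quotient",
                 "disparity_index"):
        daly = disp[(disp["statistic"] == stat) & (disp["measure"] == "DALY")]
        top = daly.nlargest(3, "value")
        unit = "%" if stat.endswith("percent") else ""
        print(f"{stat} (DALY), top provinces:")
        for _, row in top.iterrows():
            print(f"  {row['province']:12s} {row['value']:8.2f}{unit} "
                  f"[{row['cluster_label']}]")
        occupancy = daly["cluster_label"].value_counts().to_dict()
        print(f"  cluster occupancy: {occupancy}")


if __name__ == "__main__":
    main()
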