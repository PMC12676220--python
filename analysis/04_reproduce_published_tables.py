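"""Reproduction checks against the bundled published VLW tables.

From the printed 2021 Indonesian provincial tables (billion USD, three
decimals) this recomputes: the rounded-input gender disparities, the
combined-sex national accounting identity, the cross-benchmark scaling,
and the DALY-YLL gaps; writes the derived tables under
results/published/ and prints the headline comparisons.
"""

import os

from burdenval import io as bio
from burdenval.config import LifeExpectancyTable, default_benchmarks
from burdenval.disparity import gender_disparity_table, round_half_away
from burdenval.reference_tables import NATIONAL_LABEL, load_published_vlw
from burdenval.valuation import combined_sex_vlw, daly_yll_gap_table

OUT = os.path.join(os.path.dirname(__file__), "..", "results", "published")


def main() -> None:
    published = load_published_vlw()
    wage = published[published["benchmark"] == "wage"]
    provincial = wage[wage["province"] != NATIONAL_LABEL]
    le = LifeExpectancyTable()
    benchmarks = {b.name: b for b in default_benchmarks()}

    bio.ensure_dir(OUT)

    gender = gender_disparity_table(provincial, rounded_inputs=True)
    gender["value"] = gender["value"].map(lambda v: round_half_away(v, 2))
    bio.write_results(gender, os.path.join(OUT, "gender_disparity.csv"))
    print("gender disparity from printed wage values (percent):")
    for prov, measure in (("Riau Islands", "DALY"), ("Riau Islands", "YLL"),
                          ("Aceh", "DALY"), ("West Kalimantan", "DALY"),
                          ("Maluku", "DALY")):
        row = gender.query("province == @prov and measure == @measure")
        print(f"  {prov:16s} {measure:4s} {row['value'].iloc[0]:7.2f}")

    print("combined-sex identity, national wage values (billion USD):")
    nat = wage[wage["province"] == NATIONAL_LABEL]
    for measure in ("DALY", "YLL"):
        bysex = nat[nat["measure"] == measure].set_index("sex")[
            "vlw_billion_usd"]
        implied = combined_sex_vlw(bysex["male"], bysex["female"],
                                   benchmarks["wage"], le, measure=measure)
        print(f"  {measure:4s} implied {implied:.3f} vs printed "
              f"{bysex['both']:.3f}")

    gaps = daly_yll_gap_table(wage)
    bio.write_results(gaps, os.path.join(OUT, "daly_yll_gap.csv"))
    both = gaps[gaps["sex"] == "both"].set_index("province")["gap_percent"]
    print(f"DALY-YLL gap: Yogyakarta {both['Yogyakarta']:.1f}%, "
          f"Bali {both['Bali']:.2f}%, national {both[NATIONAL_LABEL]:.1f}%")

    scale = benchmarks["usdot"].vsl_usd / benchmarks["wage"].vsl_usd
    wj = wage.query("province == 'West Java' and measure == 'DALY' "
                    "and sex == 'both'")["vlw_billion_usd"].iloc[0]
    print(f"benchmark scaling: West Java wage {wj:.3f} x {scale:.4f} = "
          f"{round_half_away(wj * scale, 3):.3f} (printed USDOT 2.979)")


if __name__ == "__main__":
    main()
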