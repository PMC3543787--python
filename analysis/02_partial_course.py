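"""Partial steroid course: half the absolute risk reduction for every outcome.

Many late-preterm patients deliver before completing the 48-hour regimen.
Modelling an interrupted course as retaining 50% of each absolute risk
reduction (delivery costs unchanged) roughly doubles the ICER: ~$127-130K/QALY,
above the $100K/QALY threshold at every week — a partial course is not
cost-effective.  Writes results/02_partial_course.csv.
"""

from pathlib import Path

import pandas as pd

from acs_cea import builtin_parameter_set, compare, to_partial_course

OUT = Path(__file__).resolve().parents[1] / "results" / "02_partial_course.csv"


def main() -> None:
    rows = []
    for ga in (34, 35, 36):
        full = compare(builtin_parameter_set(ga))
        part = compare(to_partial_course(builtin_parameter_set(ga)))
        rows.append(
            {
                "ga_week": ga,
                "incremental_cost": part.incremental_cost,
                "incremental_effect": part.incremental_effect,
                "icer": part.icer,
                "icer_ratio_vs_full": part.icer / full.icer,
                "classification": part.classification,
            }
        )
        print(
            f"{ga} wk partial course: ICER ${part.icer:,.2f}/QALY "
            f"({part.icer / full.icer:.2f}x the full-course ICER) "
            f"-> {part.classification}"
        )
    OUT.parent.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(OUT, index=False, float_format="%.6f")
    print(f"written: {OUT}")


if __name__ == "__main__":
    main()
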