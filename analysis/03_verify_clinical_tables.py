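"""Recompute the published univariable odds ratios from the reference counts.

The package ships the categorical counts of a published 217-patient training
cohort (STAS-positive vs negative).  This script recomputes each variable's
univariable Wald OR and 95% CI from those counts with
stas_habitat.evaluation_stats.odds_ratio_wald and compares them, after
2-decimal rounding, with the values the study printed.  Two printed rows
(SCCA and spiculation) are arithmetically inconsistent with their own counts
and are reported but not compared.  Also checks the cohort arithmetic: the
37.79% training prevalence and the 7:3 split of 310 into 217/93.
"""

from pathlib import Path

import pandas as pd

from stas_habitat import reference_cohort as ref
from stas_habitat.pipeline import split_cohort

ROOT = Path(__file__).resolve().parents[1]


def half_up(x: float, nd: int = 2) -> float:
    import decimal

    return float(
        decimal.Decimal(repr(x)).quantize(
            decimal.Decimal("0." + "0" * nd), rounding=decimal.ROUND_HALF_UP
        )
    )


def main() -> None:
    rows = []
    computed = ref.univariable_or_table()
    for var, (or_p, lo_p, hi_p) in ref.PRINTED_UNIVARIABLE_OR.items():
        c = computed[var]
        rows.append(
            {
                "variable": var,
                "or": half_up(c["or"]),
                "ci_low": half_up(c["ci_low"]),
                "ci_high": half_up(c["ci_high"]),
                "published_or": or_p,
                "published_ci": f"{lo_p}-{hi_p}",
                "match": half_up(c["or"]) == or_p
                and half_up(c["ci_low"]) == lo_p
                and half_up(c["ci_high"]) == hi_p,
            }
        )
    table = pd.DataFrame(rows).set_index("variable")
    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    table.to_csv(out / "univariable_or.csv")
    print(table)
    print(f"\nall rows match after 2-dp rounding: {bool(table['match'].all())}")
    for var, reason in ref.INCONSISTENT_PRINTED_ROWS.items():
        print(f"not compared — {var}: {reason}")

    prev = ref.TRAINING_STAS_POSITIVE / ref.TRAINING_N
    print(f"\ntraining prevalence: {ref.TRAINING_STAS_POSITIVE}/{ref.TRAINING_N} "
          f"= {prev:.2%}")
    labels = pd.Series([1] * 117 + [0] * 193, index=range(ref.CENTER1_N))
    split = split_cohort(labels, (0.7, 0.3), seed=0)
    print(f"7:3 split of {ref.CENTER1_N}: "
          f"{(split == 'train').sum()}/{(split == 'validation').sum()}")
    print(f"OR table -> {out / 'univariable_or.csv'}")


if __name__ == "__main__":
    main()
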