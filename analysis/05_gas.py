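#!/usr/bin/env python
"""Gas production: per-sample totals, dose-response trend, and Dunnett
many-to-one contrasts against each pure community.

Reads results/study/, writes results/gas/.
"""

import json
from pathlib import Path

from commvade.gas_analysis import dose_trend, many_to_one, summarize_gas
from commvade.tables_io import read_gas, read_metadata

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    gas = read_gas(ROOT / "study" / "gas.csv")
    metadata = read_metadata(ROOT / "study" / "metadata.tsv")
    out = ROOT / "gas"
    out.mkdir(parents=True, exist_ok=True)

    summary = summarize_gas(gas, metadata)
    summary.per_sample.to_csv(out / "totals.tsv", sep="\t", index=False)
    print("mean cumulative gas at final week (mL):")
    print(summary.per_sample.groupby("treatment")["total_gas"].mean().round(0))

    trend = dose_trend(summary)
    print(
        f"\ntrend on log10(dose): slope = {trend.slope:.0f} mL per decade, "
        f"F{trend.df_num},{trend.df_den} = {trend.F:.2f}, P = {trend.p:.3g}, "
        f"R2 = {trend.r2:.2f}"
    )

    report = {"trend": trend.__dict__}
    for control in ("HP", "LP"):
        table = many_to_one(summary, control, seed=0)
        table.to_csv(out / f"dunnett_vs_{control}.tsv", sep="\t", index=False)
        verdicts = dict(zip(table["treatment"], table["significant"].astype(bool)))
        report[f"vs_{control}"] = verdicts
        diff = [t for t, sig in verdicts.items() if sig and t.startswith("D")]
        same = [t for t, sig in verdicts.items() if not sig and t.startswith("D")]
        print(f"Dunnett vs {control}: differs {diff}; indistinguishable {same}")
    (out / "gas_tests.json").write_text(json.dumps(report, indent=1, default=str))


if __name__ == "__main__":
    main()
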