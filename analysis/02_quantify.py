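#!/usr/bin/env python
"""Quantify the default study: normalization, ratios, intensity-ranked
z-scores and tiered significance calls at all three levels.

Reads results/data/default (run 01_simulate.py first) and writes the
per-level quantification tables under results/quant/.
"""

from pathlib import Path

import pandas as pd

from phosflow import io as pio
from phosflow.quantify import run_quantification

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    data = ROOT / "results" / "data" / "default"
    out = ROOT / "results" / "quant"
    out.mkdir(parents=True, exist_ok=True)

    psms = pio.read_psm_table(data / "psms.tsv")
    design = pio.read_design(data / "design.tsv")
    result = run_quantification(psms, design)

    result["scale_factors"].to_csv(out / "scale_factors.tsv", sep="\t", index=False)
    print("channel scale factors:")
    print(result["scale_factors"].to_string(index=False))

    for level, table in result["levels"].items():
        table.to_csv(out / f"quant_{level}.tsv", sep="\t", index=False)
        case = table[table["sample_label"] == "IFN"]
        print(
            f"{level}: {len(case)} detected, {int(case['significant'].sum())} significant, "
            f"{int(case['regulated'].sum())} regulated "
            f"({int((case['regulated'] & (case['signed_fc'] > 0)).sum())} up / "
            f"{int((case['regulated'] & (case['signed_fc'] < 0)).sum())} down)"
        )
    print(f"tables -> {out}")


if __name__ == "__main__":
    main()
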