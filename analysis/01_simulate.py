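#!/usr/bin/env python
"""Generate the two synthetic studies used throughout the analysis.

Writes the default planted-effect study (4-plex, duplicate labelling
experiments, ~124 regulated phosphosites, planted P at +1 motif, 8
kinases with planted activity shifts) and a no-effect calibration study
(one PSM per site) under results/data/.
"""

import argparse
from pathlib import Path

import phosflow as pf

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=11)
    args = parser.parse_args()

    out = ROOT / "results" / "data"
    dataset = pf.generate_dataset(seed=args.seed)
    pf.write_dataset(dataset, out / "default")
    phospho = int((dataset.psms["population"] != "nonphospho").sum())
    print(f"default study: {len(dataset.psms)} PSMs ({phospho} phospho), "
          f"{len(dataset.truth.regulated_sites)} planted regulated sites, "
          f"{len(dataset.truth.kinase_truth)} active kinases -> {out / 'default'}")

    null_ds = pf.generate_dataset(pf.null_config(), seed=args.seed + 1)
    pf.write_dataset(null_ds, out / "null")
    print(f"null study: {len(null_ds.psms)} PSMs, no planted effects -> {out / 'null'}")


if __name__ == "__main__":
    main()
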