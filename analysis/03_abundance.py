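#!/usr/bin/env python
"""Relative protein abundance by NSAF from the non-phospho PSM counts of
the default study. Writes results/abundance/nsaf.tsv."""

from pathlib import Path

from phosflow import io as pio
from phosflow.abundance import nsaf_from_psms

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    data = ROOT / "results" / "data" / "default"
    out = ROOT / "results" / "abundance"
    out.mkdir(parents=True, exist_ok=True)

    psms = pio.read_psm_table(data / "psms.tsv")
    proteome = pio.read_fasta(data / "proteome.fasta")
    nsaf = nsaf_from_psms(psms, proteome)
    nsaf.sort_values("nsaf", ascending=False).to_csv(out / "nsaf.tsv", sep="\t", index=False)

    top = nsaf.nlargest(5, "nsaf")
    print(f"{len(nsaf)} detected proteins; NSAF sums to {nsaf['nsaf'].sum():.12f}")
    print("most abundant proteins:")
    print(top.to_string(index=False))
    print(f"table -> {out / 'nsaf.tsv'}")


if __name__ == "__main__":
    main()
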