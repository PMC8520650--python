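#!/usr/bin/env python
"""Kinase inference on the default study's upregulated phosphosites:
motif-x-style enrichment, kinase-family substrate percentages and
regulatory-site activity scores. Writes results/kinase/."""

from pathlib import Path

import pandas as pd

from phosflow import io as pio
from phosflow.kinase import (
    activity_scores,
    extract_windows,
    family_percentages,
    match_motif_families,
    motif_search,
    motifs_to_frame,
    peptide_key,
    proteome_windows,
)

ROOT = Path(__file__).resolve().parents[1]
MIN_OCCURRENCES = 10  # desk-scale support floor


def main() -> None:
    data = ROOT / "results" / "data" / "default"
    quant = ROOT / "results" / "quant"
    out = ROOT / "results" / "kinase"
    out.mkdir(parents=True, exist_ok=True)

    proteome = pio.read_fasta(data / "proteome.fasta")
    sites = pd.read_csv(quant / "quant_phosphosite.tsv", sep="\t")
    peptides = pd.read_csv(quant / "quant_phosphopeptide.tsv", sep="\t")
    annotations = pio.read_annotations(data / "annotations.tsv")
    links = pd.read_csv(data / "links.tsv", sep="\t")
    family_patterns = pd.read_csv(data / "family_patterns.tsv", sep="\t")

    case = sites[sites["sample_label"] == "IFN"]
    up = case[case["regulated"] & (case["signed_fc"] > 0)]
    windows = extract_windows(up[["protein", "residue", "position"]], proteome)
    motifs = motif_search(
        windows["window"].tolist(), proteome_windows(proteome),
        min_occurrences=MIN_OCCURRENCES,
    )
    motif_table = motifs_to_frame(motifs)
    motif_table.to_csv(out / "motifs.tsv", sep="\t", index=False)
    print(f"motif enrichment over {len(windows)} upregulated-site windows:")
    print(motif_table.to_string(index=False))
    print("family matches of enriched motifs:")
    print(match_motif_families(motifs, family_patterns).to_string(index=False))

    case_p = peptides[peptides["sample_label"] == "IFN"]
    up_keys = [
        peptide_key(p, s)
        for p, s, r, fc in zip(case_p["peptide"], case_p["site_positions"],
                               case_p["regulated"], case_p["signed_fc"])
        if r and fc > 0
    ]
    det_keys = [
        peptide_key(p, s) for p, s in zip(case_p["peptide"], case_p["site_positions"])
    ]
    fams = family_percentages(up_keys, det_keys, links)
    fams.to_csv(out / "family_percentages.tsv", sep="\t", index=False)
    print("\nkinase-family substrate percentages:")
    print(fams.to_string(index=False))

    scores, coverage = activity_scores(sites, annotations, sample_label="IFN")
    scores.to_csv(out / "activity_scores.tsv", sep="\t", index=False)
    print("\nkinase activity scores (threshold 0.53):")
    print(scores.to_string(index=False))
    print(f"coverage: {coverage}")
    print(f"tables -> {out}")


if __name__ == "__main__":
    main()
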