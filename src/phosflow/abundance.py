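"""Relative protein abundance by normalized spectral abundance factor.

NSAF estimates the relative abundance of a protein from its spectral
count (number of PSMs) corrected for protein length: the spectral
abundance factor SAF_i = count_i / length_i is normalized so that the
NSAF values of all detected proteins sum to one.
"""

from __future__ import annotations

from typing import Mapping

import pandas as pd


def compute_nsaf(
    spectral_counts: Mapping[str, int] | pd.Series,
    lengths: Mapping[str, int] | pd.Series,
) -> pd.DataFrame:
    """NSAF table for the detected proteins.

    spectral_counts maps protein accession to PSM count (>= 1 for detected
    proteins); lengths maps accession to residue count. A detected protein
    without a length (e.g. absent from the FASTA) is a hard error.
    """
    counts = pd.Series(dict(spectral_counts), dtype=float)
    lens = pd.Series(dict(lengths), dtype=float)
    if counts.empty:
        raise ValueError("no detected proteins")
    missing = counts.index.difference(lens.index)
    if len(missing):
        raise ValueError(f"no length for detected protein(s): {sorted(missing)[:5]}")
    if (counts < 1).any():
        raise ValueError("spectral counts of detected proteins must be >= 1")
    if (lens.loc[counts.index] <= 0).any():
        raise ValueError("protein lengths must be positive")
    saf = counts / lens.loc[counts.index]
    nsaf = saf / saf.sum()
    return pd.DataFrame(
        {
            "protein": counts.index,
            "spectral_count": counts.astype(int).to_numpy(),
            "length": lens.loc[counts.index].astype(int).to_numpy(),
            "saf": saf.to_numpy(),
            "nsaf": nsaf.to_numpy(),
        }
    ).reset_index(drop=True)


def nsaf_from_psms(
    psms: pd.DataFrame,
    proteome: Mapping[str, str],
    include_phospho: bool = False,
) -> pd.DataFrame:
    """NSAF from a PSM table; by default only the non-phospho population
    feeds the spectral counts (the proteome tier of the study design)."""
    sub = psms if include_phospho else psms[psms["population"] == "nonphospho"]
    counts = sub.groupby("protein")["psm_id"].nunique()
    lengths = {acc: len(seq) for acc, seq in proteome.items()}
    return compute_nsaf(counts, lengths)
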