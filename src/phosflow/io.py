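"""Readers, writers and validators for the pipeline's on-disk formats.

All tabular formats are header-ed TSV; sequences travel as FASTA. The PSM
table carries one row per peptide-spectrum match with the fixed columns
``psm_id, experiment_id, peptide, protein, site_positions, population``
followed by one reporter-intensity column per isobaric channel. Phosphosites
are addressed as ``<residue><1-based position>`` on the protein (e.g.
``S727``); multiple localized sites on one PSM are semicolon-joined in
ascending position order.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
PHOSPHO_RESIDUES = "STY"
POPULATIONS = ("nonphospho", "mono", "multi")
PSM_FIXED_COLUMNS = [
    "psm_id",
    "experiment_id",
    "peptide",
    "protein",
    "site_positions",
    "population",
]
DESIGN_COLUMNS = ["experiment_id", "channel", "sample_label", "is_denominator"]
ANNOTATION_COLUMNS = ["kinase_accession", "site", "effect"]
EFFECT_INDUCED = "activity, induced"
EFFECT_INHIBITED = "activity, inhibited"

_SITE_RE = re.compile(r"^([STY])(\d+)$")


def format_site(residue: str, position: int) -> str:
    return f"{residue}{position}"


def parse_site(token: str) -> tuple[str, int]:
    """Parse a ``S727``-style site token into (residue, 1-based position)."""
    m = _SITE_RE.match(token.strip())
    if not m:
        raise ValueError(f"malformed phosphosite token {token!r}; expected e.g. 'S727'")
    return m.group(1), int(m.group(2))


def parse_site_positions(field: str | float | None) -> list[tuple[str, int]]:
    """Parse a semicolon-joined site list; empty/NaN means no sites."""
    if field is None or (isinstance(field, float) and pd.isna(field)):
        return []
    field = str(field).strip()
    if not field:
        return []
    return [parse_site(tok) for tok in field.split(";")]


def format_site_positions(sites: Iterable[tuple[str, int]]) -> str:
    return ";".join(format_site(r, p) for r, p in sorted(sites, key=lambda s: s[1]))


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    proteome = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        proteome[rec.id] = str(rec.seq).upper()
    if not proteome:
        raise ValueError(f"no sequences found in {path}")
    return proteome


def write_fasta(proteome: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=acc, description="") for acc, seq in proteome.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Design table


def validate_design(design: pd.DataFrame) -> None:
    missing = set(DESIGN_COLUMNS) - set(design.columns)
    if missing:
        raise ValueError(f"design table missing columns: {sorted(missing)}")
    for exp, grp in design.groupby("experiment_id"):
        n_den = int(grp["is_denominator"].astype(bool).sum())
        if n_den != 1:
            raise ValueError(
                f"experiment {exp!r} must have exactly one denominator channel, found {n_den}"
            )
        if grp["channel"].duplicated().any():
            raise ValueError(f"experiment {exp!r} has duplicate channel labels")


def read_design(path: str | Path) -> pd.DataFrame:
    design = pd.read_csv(path, sep="\t", dtype={"channel": str, "experiment_id": str})
    design["is_denominator"] = design["is_denominator"].astype(int)
    validate_design(design)
    return design


def write_design(design: pd.DataFrame, path: str | Path) -> None:
    out = design.copy()
    out["is_denominator"] = out["is_denominator"].astype(int)
    out.to_csv(path, sep="\t", index=False)


def design_channels(design: pd.DataFrame, experiment: str) -> list[str]:
    return design.loc[design["experiment_id"] == experiment, "channel"].tolist()


def denominator_channel(design: pd.DataFrame, experiment: str) -> str:
    grp = design[design["experiment_id"] == experiment]
    den = grp.loc[grp["is_denominator"].astype(bool), "channel"]
    if len(den) != 1:
        raise ValueError(f"experiment {experiment!r} lacks a unique denominator channel")
    return den.iloc[0]


def sample_label(design: pd.DataFrame, experiment: str, channel: str) -> str:
    grp = design[
        (design["experiment_id"] == experiment) & (design["channel"] == channel)
    ]
    if grp.empty:
        raise KeyError(f"channel {channel!r} not in design of experiment {experiment!r}")
    return grp["sample_label"].iloc[0]


# ---------------------------------------------------------------------------
# PSM table


def intensity_columns(psms: pd.DataFrame, design: pd.DataFrame | None = None) -> list[str]:
    """Reporter-intensity columns of a PSM table (everything past the fixed block)."""
    extra = [c for c in psms.columns if c not in PSM_FIXED_COLUMNS]
    if design is not None:
        channels = set(design["channel"])
        extra = [c for c in extra if c in channels]
        missing = channels - set(extra)
        if missing:
            raise ValueError(f"PSM table lacks intensity columns for channels {sorted(missing)}")
    return extra


def read_psm_table(path: str | Path) -> pd.DataFrame:
    psms = pd.read_csv(
        path,
        sep="\t",
        dtype={"psm_id": str, "experiment_id": str, "protein": str, "peptide": str},
    )
    psms["site_positions"] = psms["site_positions"].fillna("").astype(str)
    return psms


def write_psm_table(psms: pd.DataFrame, path: str | Path) -> None:
    psms.to_csv(path, sep="\t", index=False)


def validate_psms(
    psms: pd.DataFrame,
    design: pd.DataFrame | None = None,
    proteome: Mapping[str, str] | None = None,
) -> None:
    """Check PSM-record invariants; raise ValueError on the first violation."""
    missing = set(PSM_FIXED_COLUMNS) - set(psms.columns)
    if missing:
        raise ValueError(f"PSM table missing columns: {sorted(missing)}")
    bad_pop = set(psms["population"]) - set(POPULATIONS)
    if bad_pop:
        raise ValueError(f"unknown PSM populations: {sorted(bad_pop)}")
    icols = intensity_columns(psms, design)
    if not icols:
        raise ValueError("PSM table has no intensity columns")
    if (psms[icols].to_numpy() <= 0).all(axis=1).any():
        raise ValueError("PSM with no positive reporter intensity")
    for row in psms.itertuples(index=False):
        sites = parse_site_positions(row.site_positions)
        n = len(sites)
        pop = row.population
        if (pop == "nonphospho") != (n == 0) or (pop == "mono") != (n == 1) or (
            pop == "multi"
        ) != (n >= 2):
            raise ValueError(
                f"PSM {row.psm_id}: population {pop!r} inconsistent with {n} localized site(s)"
            )
        if proteome is not None and n:
            seq = proteome.get(row.protein)
            if seq is None:
                raise ValueError(f"PSM {row.psm_id}: protein {row.protein!r} not in proteome")
            for res, pos in sites:
                if pos < 1 or pos > len(seq):
                    raise ValueError(
                        f"PSM {row.psm_id}: site {res}{pos} outside protein {row.protein}"
                    )
                if seq[pos - 1] != res:
                    raise ValueError(
                        f"PSM {row.psm_id}: site {res}{pos} does not match proteome residue "
                        f"{seq[pos - 1]!r} on {row.protein}"
                    )


# ---------------------------------------------------------------------------
# Kinase regulatory-site annotations


def read_annotations(path: str | Path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", dtype=str)
    validate_annotations(ann)
    return ann


def write_annotations(ann: pd.DataFrame, path: str | Path) -> None:
    ann.to_csv(path, sep="\t", index=False)


def validate_annotations(ann: pd.DataFrame) -> None:
    missing = set(ANNOTATION_COLUMNS) - set(ann.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    bad = set(ann["effect"]) - {EFFECT_INDUCED, EFFECT_INHIBITED}
    if bad:
        raise ValueError(
            f"annotation effects must be {EFFECT_INDUCED!r} or {EFFECT_INHIBITED!r}; got {sorted(bad)}"
        )
    for tok in ann["site"]:
        parse_site(tok)


def annotation_sites(ann: pd.DataFrame) -> pd.DataFrame:
    """Annotation table with the site token split into residue/position columns."""
    parsed = [parse_site(tok) for tok in ann["site"]]
    out = ann.copy()
    out["residue"] = [r for r, _ in parsed]
    out["position"] = [p for _, p in parsed]
    out["direction"] = [1 if e == EFFECT_INDUCED else -1 for e in out["effect"]]
    return out
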