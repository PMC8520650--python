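"""End-to-end orchestration, configuration and summary reporting.

`analyze` runs the full chain in memory (quantification at all three
levels, NSAF, motif enrichment, family percentages, kinase activity
scores, and a descriptive principal-component summary of per-sample
fold-change vectors); `run_pipeline` wraps it with file I/O, a run log
and TSV/JSON outputs. Stage errors propagate annotated with the stage
name.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .abundance import nsaf_from_psms
from .kinase import (
    DEFAULT_ACTIVITY_THRESHOLD,
    DEFAULT_MIN_OCCURRENCES,
    DEFAULT_P_THRESHOLD,
    activity_scores,
    extract_windows,
    family_percentages,
    match_motif_families,
    motif_search,
    motifs_to_frame,
    peptide_key,
    proteome_windows,
)
from .quantify import (
    DEFAULT_FC_THRESHOLD,
    DEFAULT_MIN_PSMS_PROTEIN,
    DEFAULT_Z_PHOSPHO,
    DEFAULT_Z_PROTEIN,
    run_quantification,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and parameters of one pipeline run."""

    psms: str
    design: str
    fasta: str
    out_dir: str
    annotations: str | None = None
    links: str | None = None
    family_patterns: str | None = None
    case_label: str | None = None
    bin_size: int = 300
    robust: bool = True
    per_population: bool = False
    z_phospho: float = DEFAULT_Z_PHOSPHO
    z_protein: float = DEFAULT_Z_PROTEIN
    fc_threshold: float = DEFAULT_FC_THRESHOLD
    min_psms_protein: int = DEFAULT_MIN_PSMS_PROTEIN
    motif_p_threshold: float = DEFAULT_P_THRESHOLD
    motif_min_occurrences: int = DEFAULT_MIN_OCCURRENCES
    motif_background: str = "proteome"  # or "detected"
    activity_threshold: float = DEFAULT_ACTIVITY_THRESHOLD

    def validate(self) -> None:
        for name in ("psms", "design", "fasta", "annotations", "links", "family_patterns"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{name} path does not exist: {path}")
        for name in ("z_phospho", "z_protein", "fc_threshold", "motif_p_threshold",
                     "activity_threshold"):
            if not getattr(self, name) > 0:
                raise ValueError(f"threshold {name} must be positive")
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _infer_case_label(design: pd.DataFrame) -> str:
    """The contrast of interest: the sample label not shared with any
    denominator channel. Ambiguity requires an explicit choice."""
    den_labels = set(
        design.loc[design["is_denominator"].astype(bool), "sample_label"]
    )
    case = sorted(set(design["sample_label"]) - den_labels)
    if len(case) != 1:
        raise ValueError(
            f"cannot infer the case contrast from labels {case}; set case_label explicitly"
        )
    return case[0]


def pca_of_fold_changes(ratios: pd.DataFrame) -> dict:
    """Descriptive PCA of per-sample (experiment x channel) phosphosite
    median log2 fold-change vectors, on sites observed in every sample."""
    phospho = ratios[ratios["population"].isin(["mono", "multi"])]
    if phospho.empty:
        return {"samples": [], "coordinates": [], "explained_variance_ratio": []}
    table = (
        phospho.groupby(["protein", "site_positions", "experiment_id", "channel"])  # per sample
        ["log2_ratio"]
        .median()
        .unstack(["experiment_id", "channel"])
        .dropna(axis=0)
    )
    if table.shape[0] < 3 or table.shape[1] < 2:
        return {"samples": [], "coordinates": [], "explained_variance_ratio": []}
    labels = {}
    for exp, ch in table.columns:
        sub = phospho[(phospho["experiment_id"] == exp) & (phospho["channel"] == ch)]
        labels[(exp, ch)] = sub["sample_label"].iloc[0] if len(sub) else ""
    samples = [f"{exp}:{ch}:{labels[(exp, ch)]}" for exp, ch in table.columns]
    x = table.to_numpy().T  # samples x sites
    xc = x - x.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(xc, full_matrices=False)
    coords = u * s
    var = s**2
    evr = (var / var.sum()).tolist() if var.sum() > 0 else [0.0] * len(s)
    k = min(2, coords.shape[1])
    return {
        "samples": samples,
        "coordinates": [list(map(float, row[:k])) for row in coords],
        "explained_variance_ratio": [float(v) for v in evr[:k]],
    }


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            result = fn(*args, **kwargs)
        except Exception as exc:  # annotate with the stage name and re-raise
            raise type(exc)(f"[stage {name}] {exc}") from exc
        logger.info("stage %s finished in %.2f s", name, time.perf_counter() - t0)
        return result

    return wrap


def analyze(
    psms: pd.DataFrame,
    design: pd.DataFrame,
    proteome: Mapping[str, str],
    annotations: pd.DataFrame | None = None,
    links: pd.DataFrame | None = None,
    family_patterns: pd.DataFrame | None = None,
    case_label: str | None = None,
    bin_size: int = 300,
    robust: bool = True,
    per_population: bool = False,
    z_phospho: float = DEFAULT_Z_PHOSPHO,
    z_protein: float = DEFAULT_Z_PROTEIN,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    min_psms_protein: int = DEFAULT_MIN_PSMS_PROTEIN,
    motif_p_threshold: float = DEFAULT_P_THRESHOLD,
    motif_min_occurrences: int = DEFAULT_MIN_OCCURRENCES,
    motif_background: str = "proteome",
    activity_threshold: float = DEFAULT_ACTIVITY_THRESHOLD,
) -> dict:
    """Run the full analysis in memory and return a result bundle."""
    pio.validate_psms(psms, design, proteome)
    if case_label is None:
        case_label = _infer_case_label(design)

    quant = _stage("quantify")(
        run_quantification,
        psms,
        design,
        bin_size=bin_size,
        robust=robust,
        per_population=per_population,
        z_phospho=z_phospho,
        z_protein=z_protein,
        fc_threshold=fc_threshold,
        min_psms_protein=min_psms_protein,
    )
    levels = quant["levels"]

    nsaf = _stage("nsaf")(nsaf_from_psms, psms, proteome)

    sites = levels["phosphosite"]
    case_sites = sites[sites["sample_label"] == case_label]
    up_sites = case_sites[case_sites["regulated"] & (case_sites["signed_fc"] > 0)]
    site_windows = _stage("windows")(
        extract_windows, up_sites[["protein", "residue", "position"]], proteome
    )
    if motif_background == "proteome":
        background = _stage("background")(proteome_windows, proteome)
    elif motif_background == "detected":
        background = _stage("background")(
            extract_windows, case_sites[["protein", "residue", "position"]], proteome
        )["window"].tolist()
    else:
        raise ValueError("motif_background must be 'proteome' or 'detected'")
    motifs = _stage("motifs")(
        motif_search,
        site_windows["window"].tolist(),
        background,
        p_threshold=motif_p_threshold,
        min_occurrences=motif_min_occurrences,
    )

    peptides = levels["phosphopeptide"]
    case_peps = peptides[peptides["sample_label"] == case_label]
    detected_keys = [
        peptide_key(p, s) for p, s in zip(case_peps["peptide"], case_peps["site_positions"])
    ]
    up_mask = case_peps["regulated"] & (case_peps["signed_fc"] > 0)
    up_keys = [
        peptide_key(p, s)
        for p, s in zip(case_peps.loc[up_mask, "peptide"], case_peps.loc[up_mask, "site_positions"])
    ]
    families = (
        _stage("families")(family_percentages, up_keys, detected_keys, links)
        if links is not None and len(links)
        else None
    )

    activity, coverage = (
        _stage("activity")(
            activity_scores,
            sites,
            annotations,
            threshold=activity_threshold,
            sample_label=case_label,
        )
        if annotations is not None and len(annotations)
        else (None, {})
    )

    pca = _stage("pca")(pca_of_fold_changes, quant["ratios"])

    counts = {}
    for level, table in levels.items():
        case = table[table["sample_label"] == case_label]
        counts[level] = {
            "detected": int(len(case)),
            "significant": int(case["significant"].sum()),
            "regulated": int(case["regulated"].sum()),
            "regulated_up": int((case["regulated"] & (case["signed_fc"] > 0)).sum()),
            "regulated_down": int((case["regulated"] & (case["signed_fc"] < 0)).sum()),
        }

    return {
        "case_label": case_label,
        "quant": quant,
        "levels": levels,
        "nsaf": nsaf,
        "motifs": motifs,
        "motif_table": motifs_to_frame(motifs),
        "motif_families": (
            match_motif_families(motifs, family_patterns)
            if family_patterns is not None and len(family_patterns)
            else None
        ),
        "families": families,
        "activity": activity,
        "activity_coverage": coverage,
        "pca": pca,
        "counts": counts,
        "thresholds": {
            "z_phospho": z_phospho,
            "z_protein": z_protein,
            "fc_threshold": fc_threshold,
            "min_psms_protein": min_psms_protein,
            "motif_p_threshold": motif_p_threshold,
            "motif_min_occurrences": motif_min_occurrences,
            "activity_threshold": activity_threshold,
            "bin_size": bin_size,
            "robust": robust,
        },
    }


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """File-level orchestration: read inputs, run `analyze`, write per-level
    quant TSVs, NSAF, motif/activity/family tables and report.json under
    config.out_dir. Deterministic given inputs."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("phosflow")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        psms = pio.read_psm_table(config.psms)
        design = pio.read_design(config.design)
        proteome = pio.read_fasta(config.fasta)
        annotations = pio.read_annotations(config.annotations) if config.annotations else None
        links = pd.read_csv(config.links, sep="\t") if config.links else None
        family_patterns = (
            pd.read_csv(config.family_patterns, sep="\t") if config.family_patterns else None
        )
        result = analyze(
            psms,
            design,
            proteome,
            annotations=annotations,
            links=links,
            family_patterns=family_patterns,
            case_label=config.case_label,
            bin_size=config.bin_size,
            robust=config.robust,
            per_population=config.per_population,
            z_phospho=config.z_phospho,
            z_protein=config.z_protein,
            fc_threshold=config.fc_threshold,
            min_psms_protein=config.min_psms_protein,
            motif_p_threshold=config.motif_p_threshold,
            motif_min_occurrences=config.motif_min_occurrences,
            motif_background=config.motif_background,
            activity_threshold=config.activity_threshold,
        )

        for level, table in result["levels"].items():
            table.to_csv(out_dir / f"quant_{level}.tsv", sep="\t", index=False)
        result["quant"]["scale_factors"].to_csv(
            out_dir / "scale_factors.tsv", sep="\t", index=False
        )
        result["nsaf"].to_csv(out_dir / "nsaf.tsv", sep="\t", index=False)
        result["motif_table"].to_csv(out_dir / "motifs.tsv", sep="\t", index=False)
        if result["families"] is not None:
            result["families"].to_csv(out_dir / "family_percentages.tsv", sep="\t", index=False)
        if result["activity"] is not None:
            result["activity"].to_csv(out_dir / "activity_scores.tsv", sep="\t", index=False)

        report = {
            "config": asdict(config),
            "case_label": result["case_label"],
            "counts": result["counts"],
            "thresholds": result["thresholds"],
            "scale_factors": result["quant"]["scale_factors"].to_dict(orient="records"),
            "stage_log": result["quant"]["log"],
            "nsaf_total": float(result["nsaf"]["nsaf"].sum()),
            "motifs": result["motif_table"].to_dict(orient="records"),
            "activity": (
                result["activity"].to_dict(orient="records")
                if result["activity"] is not None
                else []
            ),
            "activity_coverage": result["activity_coverage"],
            "families": (
                result["families"].to_dict(orient="records")
                if result["families"] is not None
                else []
            ),
            "pca": result["pca"],
        }
        with open(out_dir / "report.json", "w") as fh:
            json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
        result["report"] = report
        return result
    finally:
        root.removeHandler(handler)
        handler.close()
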