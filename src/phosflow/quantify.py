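"""Reporter quantification: normalization, ratios, intensity-ranked
z-scores, multi-level aggregation and tiered significance calls.

The chain mirrors standard isobaric-label practice: per-experiment
sum-of-intensities channel normalization over all (phospho and
non-phospho) PSMs; log2 ratios of every channel against the experiment's
denominator channel; standardization of the ratios within consecutive
rank bins of total reporter intensity so that the intensity-dependence
of ratio variance is removed; PSM-count-weighted combination of
per-experiment medians at the phosphosite, phosphopeptide and protein
level; and threshold-based significance (|z| >= 1 for phospho levels,
|z| >= 1.96 plus a five-PSM floor for proteins) and regulation
(|fold change| >= 1.5) calls.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import io as pio
from .io import parse_site_positions

logger = logging.getLogger(__name__)

MAD_TO_SD = 1.4826  # consistency factor: MAD of a normal sample -> sd

LEVELS = ("phosphosite", "phosphopeptide", "protein")
DEFAULT_Z_PHOSPHO = 1.0
DEFAULT_Z_PROTEIN = 1.96
DEFAULT_FC_THRESHOLD = 1.5
DEFAULT_MIN_PSMS_PROTEIN = 5


# ---------------------------------------------------------------------------
# Channel normalization


def normalize_channels(
    psms: pd.DataFrame, design: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sum-of-intensities channel normalization, per experiment.

    The scale factor of a channel is the grand mean of the per-channel
    intensity sums divided by that channel's sum, computed jointly over
    phospho and non-phospho PSMs; after scaling all per-channel sums within
    an experiment are equal.

    Returns the scaled PSM table and a factor table
    (experiment_id, channel, raw_sum, factor).
    """
    pio.validate_design(design)
    scaled = psms.copy()
    rows = []
    for exp in dict.fromkeys(design["experiment_id"]):
        channels = pio.design_channels(design, exp)
        mask = scaled["experiment_id"] == exp
        if not mask.any():
            raise ValueError(f"no PSMs for experiment {exp!r}")
        sums = scaled.loc[mask, channels].sum(axis=0)
        zero = sums[sums <= 0]
        if len(zero):
            raise ValueError(
                f"channel(s) {list(zero.index)} of experiment {exp!r} have zero total intensity"
            )
        grand_mean = sums.mean()
        factors = grand_mean / sums
        scaled.loc[mask, channels] = scaled.loc[mask, channels].to_numpy() * factors.to_numpy()
        for ch in channels:
            rows.append(
                {
                    "experiment_id": exp,
                    "channel": ch,
                    "raw_sum": float(sums[ch]),
                    "factor": float(factors[ch]),
                }
            )
        logger.info(
            "normalized experiment %s: factors %s",
            exp,
            {ch: round(float(factors[ch]), 4) for ch in channels},
        )
    return scaled, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Ratios


def compute_ratios(psms: pd.DataFrame, design: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Per-PSM log2 ratios of each non-denominator channel against the
    experiment's denominator channel, on (already normalized) intensities.

    PSMs with non-positive denominator intensity are dropped; individual
    channel records with non-positive intensity are likewise dropped. Both
    counts are reported in the returned log dict. ``total_intensity`` is the
    sum of the PSM's channel intensities within its experiment's design.
    """
    pio.validate_design(design)
    frames = []
    dropped_denominator = 0
    dropped_channel = 0
    for exp in dict.fromkeys(design["experiment_id"]):
        channels = pio.design_channels(design, exp)
        den = pio.denominator_channel(design, exp)
        labels = {ch: pio.sample_label(design, exp, ch) for ch in channels}
        sub = psms[psms["experiment_id"] == exp]
        if sub.empty:
            continue
        den_ok = sub[den].to_numpy() > 0
        dropped_denominator += int((~den_ok).sum())
        sub = sub.loc[den_ok]
        total = sub[channels].sum(axis=1)
        for ch in channels:
            if ch == den:
                continue
            ok = sub[ch].to_numpy() > 0
            dropped_channel += int((~ok).sum())
            part = sub.loc[ok]
            frames.append(
                pd.DataFrame(
                    {
                        "psm_id": part["psm_id"].to_numpy(),
                        "experiment_id": exp,
                        "channel": ch,
                        "sample_label": labels[ch],
                        "population": part["population"].to_numpy(),
                        "peptide": part["peptide"].to_numpy(),
                        "protein": part["protein"].to_numpy(),
                        "site_positions": part["site_positions"].to_numpy(),
                        "log2_ratio": np.log2(
                            part[ch].to_numpy() / part[den].to_numpy()
                        ),
                        "total_intensity": total.loc[part.index].to_numpy(),
                    }
                )
            )
    ratios = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(
            columns=[
                "psm_id", "experiment_id", "channel", "sample_label", "population",
                "peptide", "protein", "site_positions", "log2_ratio", "total_intensity",
            ]
        )
    )
    log = {"dropped_zero_denominator": dropped_denominator, "dropped_zero_channel": dropped_channel}
    if dropped_denominator or dropped_channel:
        logger.info("ratio stage drops: %s", log)
    return ratios, log


# ---------------------------------------------------------------------------
# Intensity-ranked z-scores


def _bin_edges(n: int, bin_size: int) -> list[tuple[int, int]]:
    """Consecutive bins of ``bin_size``; a final remainder shorter than
    bin_size/2 is absorbed into the previous bin."""
    if n <= bin_size:
        return [(0, n)]
    edges = list(range(0, n, bin_size))
    bins = [(s, min(s + bin_size, n)) for s in edges]
    last_len = bins[-1][1] - bins[-1][0]
    if len(bins) > 1 and last_len < bin_size / 2:
        bins[-2] = (bins[-2][0], bins[-1][1])
        bins.pop()
    return bins


def assign_zscores(
    ratios: pd.DataFrame,
    bin_size: int = 300,
    robust: bool = True,
    per_population: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Standardize log2 ratios within total-intensity rank bins.

    Within each experiment x channel (optionally also per peptide
    population), records sorted by total intensity descending are cut into
    consecutive bins of ``bin_size`` and each ratio is centered and scaled by
    the bin's median and 1.4826*MAD (``robust=True``) or mean and sd. Groups
    with fewer than ``2 * bin_size`` records fall back to a single bin.
    Zero-spread bins yield z = 0 with a warning.
    """
    out = ratios.copy()
    z = np.full(len(out), np.nan)
    group_cols = ["experiment_id", "channel"] + (["population"] if per_population else [])
    log = {"fallback_single_bin_groups": 0, "zero_spread_bins": 0, "n_groups": 0}
    for _, grp in out.groupby(group_cols, sort=True):
        log["n_groups"] += 1
        order = grp.sort_values(
            ["total_intensity", "psm_id"], ascending=[False, True], kind="mergesort"
        ).index.to_numpy()
        n = len(order)
        if n < 2 * bin_size:
            bins = [(0, n)]
            log["fallback_single_bin_groups"] += 1
        else:
            bins = _bin_edges(n, bin_size)
        for start, stop in bins:
            idx = order[start:stop]
            vals = out.loc[idx, "log2_ratio"].to_numpy()
            if robust:
                center = np.median(vals)
                scale = MAD_TO_SD * np.median(np.abs(vals - center))
            else:
                center = vals.mean()
                scale = vals.std(ddof=1) if len(vals) > 1 else 0.0
            if not np.isfinite(scale) or scale == 0.0:
                z[out.index.get_indexer(idx)] = 0.0
                log["zero_spread_bins"] += 1
                logger.warning(
                    "zero-spread bin (%d records); z set to 0", stop - start
                )
            else:
                z[out.index.get_indexer(idx)] = (vals - center) / scale
    out["z"] = z
    return out, log


# ---------------------------------------------------------------------------
# Aggregation


def signed_fold_change(log2fc: np.ndarray | float) -> np.ndarray | float:
    """Linear-scale fold change with reciprocal down-regulation negated:
    2**L for L >= 0, -2**(-L) otherwise (so -1.5 means a 1.5-fold drop)."""
    arr = np.asarray(log2fc, dtype=float)
    out = np.where(arr >= 0, 2.0**arr, -(2.0 ** (-arr)))
    return float(out) if np.isscalar(log2fc) or arr.ndim == 0 else out


def _explode_sites(ratios: pd.DataFrame) -> pd.DataFrame:
    phospho = ratios[ratios["population"].isin(["mono", "multi"])].copy()
    parsed = phospho["site_positions"].map(parse_site_positions)
    phospho = phospho.loc[phospho.index.repeat(parsed.map(len))]
    flat = [s for sites in parsed for s in sites]
    phospho["residue"] = [r for r, _ in flat]
    phospho["position"] = [p for _, p in flat]
    return phospho.reset_index(drop=True)


def aggregate(ratios: pd.DataFrame, level: str) -> pd.DataFrame:
    """Combine PSM-level z and log2 ratios into per-key statistics.

    Per experiment the key statistic is the median over that key's records;
    experiments are then combined by a weighted average with weights equal
    to per-experiment PSM counts. Multi-phospho PSMs contribute their
    whole-peptide ratio to each constituent phosphosite; the protein level
    uses only non-phospho PSMs; phosphopeptides key on (peptide, site set).
    """
    if level not in LEVELS:
        raise ValueError(f"level must be one of {LEVELS}, got {level!r}")
    if level == "phosphosite":
        df = _explode_sites(ratios)
        keys = ["protein", "residue", "position"]
    elif level == "phosphopeptide":
        df = ratios[ratios["population"].isin(["mono", "multi"])].copy()
        keys = ["peptide", "site_positions"]
    else:
        df = ratios[ratios["population"] == "nonphospho"].copy()
        keys = ["protein"]
    if df.empty:
        return pd.DataFrame(
            columns=keys + ["sample_label", "combined_z", "combined_log2fc", "signed_fc",
                            "total_psms", "n_experiments", "single_experiment"]
        )
    n_total_experiments = df["experiment_id"].nunique()
    per_exp = (
        df.groupby(keys + ["sample_label", "experiment_id"], sort=True)
        .agg(
            median_z=("z", "median"),
            median_log2fc=("log2_ratio", "median"),
            n_psms=("psm_id", "nunique"),
        )
        .reset_index()
    )
    per_exp["wz"] = per_exp["median_z"] * per_exp["n_psms"]
    per_exp["wl"] = per_exp["median_log2fc"] * per_exp["n_psms"]
    combined = (
        per_exp.groupby(keys + ["sample_label"], sort=True)
        .agg(
            wz=("wz", "sum"),
            wl=("wl", "sum"),
            total_psms=("n_psms", "sum"),
            n_experiments=("experiment_id", "nunique"),
        )
        .reset_index()
    )
    combined["combined_z"] = combined["wz"] / combined["total_psms"]
    combined["combined_log2fc"] = combined["wl"] / combined["total_psms"]
    combined["signed_fc"] = signed_fold_change(combined["combined_log2fc"].to_numpy())
    combined["single_experiment"] = combined["n_experiments"] < n_total_experiments
    combined = combined.drop(columns=["wz", "wl"])

    wide = per_exp.pivot_table(
        index=keys + ["sample_label"],
        columns="experiment_id",
        values=["median_z", "median_log2fc", "n_psms"],
        aggfunc="first",
    )
    wide.columns = [f"{stat}_{exp}" for stat, exp in wide.columns]
    combined = combined.merge(wide.reset_index(), on=keys + ["sample_label"], how="left")
    return combined


# ---------------------------------------------------------------------------
# Significance / regulation calls


def call_significance(
    quant: pd.DataFrame,
    level: str,
    z_threshold: float | None = None,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    min_psms: int = DEFAULT_MIN_PSMS_PROTEIN,
) -> pd.DataFrame:
    """Tiered calls: phospho levels are significant at |z| >= 1 (68.3%
    central coverage), proteins at |z| >= 1.96 (95%) with at least
    ``min_psms`` PSMs; regulation additionally requires
    |signed fold change| >= 1.5. Comparisons are inclusive."""
    if level not in LEVELS:
        raise ValueError(f"level must be one of {LEVELS}, got {level!r}")
    if z_threshold is None:
        z_threshold = DEFAULT_Z_PROTEIN if level == "protein" else DEFAULT_Z_PHOSPHO
    out = quant.copy()
    significant = out["combined_z"].abs() >= z_threshold
    if level == "protein":
        significant &= out["total_psms"] >= min_psms
    out["significant"] = significant
    out["regulated"] = significant & (out["signed_fc"].abs() >= fc_threshold)
    return out


# ---------------------------------------------------------------------------
# Convenience chain


def run_quantification(
    psms: pd.DataFrame,
    design: pd.DataFrame,
    bin_size: int = 300,
    robust: bool = True,
    per_population: bool = False,
    z_phospho: float = DEFAULT_Z_PHOSPHO,
    z_protein: float = DEFAULT_Z_PROTEIN,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    min_psms_protein: int = DEFAULT_MIN_PSMS_PROTEIN,
) -> dict:
    """Full chain: normalize -> ratios -> z -> aggregate -> call, at all
    three levels. Returns a dict with the scaled PSMs, scale factors, ratio
    records and one called table per level, plus stage diagnostics."""
    scaled, factors = normalize_channels(psms, design)
    ratios, ratio_log = compute_ratios(scaled, design)
    ratios, z_log = assign_zscores(
        ratios, bin_size=bin_size, robust=robust, per_population=per_population
    )
    levels: dict[str, pd.DataFrame] = {}
    for level in LEVELS:
        quant = aggregate(ratios, level)
        zt = z_protein if level == "protein" else z_phospho
        levels[level] = call_significance(
            quant, level, z_threshold=zt, fc_threshold=fc_threshold, min_psms=min_psms_protein
        )
    return {
        "scaled_psms": scaled,
        "scale_factors": factors,
        "ratios": ratios,
        "levels": levels,
        "log": {"ratio": ratio_log, "zscore": z_log},
    }
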