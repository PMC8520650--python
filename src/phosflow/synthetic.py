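"""Seeded synthetic fixtures with known ground truth.

Emulates the data shape of a 4-plex isobaric-label (iTRAQ/TMT) phospho-
proteomics study run as duplicate labelling experiments: a background
proteome, a PSM-level reporter-intensity table covering non-, mono- and
multi-phosphorylated peptide populations, an experimental design mapping
channels to samples with one denominator (reference) channel per
experiment, and a PhosphoSitePlus-like kinase regulatory-site annotation
table. Every generated effect (site-level fold changes, sequence motifs
around regulated sites, kinase activity shifts, per-channel loading
biases) is recorded in a :class:`GroundTruth` so that each downstream
stage is testable by parameter recovery.

The intensity model is log-normal in the PSM's total reporter signal;
the log2-ratio noise standard deviation decreases linearly in log total
intensity between a high-noise floor at the 1st population percentile
and a low-noise floor at the 99th. This reproduces the intensity-
dependent variance that the rank-binned z-scoring in
:mod:`phosflow.quantify` exists to remove.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .io import (
    EFFECT_INDUCED,
    EFFECT_INHIBITED,
    PHOSPHO_RESIDUES,
    PSM_FIXED_COLUMNS,
    STANDARD_AA,
    format_site,
    format_site_positions,
)

# Average residue composition of a vertebrate proteome (UniProt-style
# frequencies, renormalized); used as the default background composition.
_RAW_AA_FREQUENCIES = {
    "A": 0.0825, "R": 0.0553, "N": 0.0406, "D": 0.0545, "C": 0.0137,
    "Q": 0.0393, "E": 0.0675, "G": 0.0707, "H": 0.0227, "I": 0.0596,
    "L": 0.0966, "K": 0.0584, "M": 0.0242, "F": 0.0386, "P": 0.0470,
    "S": 0.0656, "T": 0.0534, "W": 0.0108, "Y": 0.0292, "V": 0.0687,
}
NATURAL_AA_FREQUENCIES: dict[str, float] = {
    a: f / sum(_RAW_AA_FREQUENCIES.values()) for a, f in _RAW_AA_FREQUENCIES.items()
}

DEFAULT_FAMILY_PATTERNS: list[tuple[str, str]] = [
    ("MAPK/CDK", "sP"),
    ("CK", "s.E"),
    ("CaMK", "R..s"),
    ("AKT", "R.R..s"),
]

MAX_SEED = 2**31 - 1


@dataclass
class NoiseParams:
    """Intensity and ratio-noise model of the PSM generator.

    log_intensity_mean/sd parameterize the log-normal total reporter
    intensity (natural-log scale). ratio_sd_high and ratio_sd_low are the
    log2-ratio noise standard deviations at the 1st and 99th percentile
    of log total intensity; the sd interpolates linearly in between. The
    noise is realized as independent per-channel log2 perturbations of
    sd/sqrt(2) on every channel including the denominator, so a channel-
    vs-denominator ratio has exactly the stated sd.
    """

    log_intensity_mean: float = 14.5
    log_intensity_sd: float = 1.2
    ratio_sd_high: float = 0.5
    ratio_sd_low: float = 0.12
    min_psms_per_site: int = 2
    extra_psms_poisson: float = 2.0


@dataclass
class GroundTruth:
    """Planted effects of a synthetic dataset.

    regulated_sites: (protein, residue, position, planted log2 fold change)
    planted_motifs:  (pattern spec like 'P@+1', fraction of upregulated sites carrying it)
    kinase_truth:    (kinase accession, intended activity direction +1/-1)
    channel_loadings: (experiment, channel) -> multiplicative bias factor
    unregulated_sites / coregulated_sites: bookkeeping for recovery metrics —
    the detected null-site universe, and secondary sites that ride on
    multiply phosphorylated peptides of regulated primaries (their emitted
    ratios follow the primary's fold change).
    """

    regulated_sites: list[tuple[str, str, int, float]] = field(default_factory=list)
    planted_motifs: list[tuple[str, float]] = field(default_factory=list)
    kinase_truth: list[tuple[str, int]] = field(default_factory=list)
    channel_loadings: dict[tuple[str, str], float] = field(default_factory=dict)
    unregulated_sites: list[tuple[str, str, int]] = field(default_factory=list)
    coregulated_sites: list[tuple[str, str, int, float]] = field(default_factory=list)

    def validate(self, proteome: Mapping[str, str]) -> None:
        for prot, res, pos, l2fc in self.regulated_sites:
            seq = proteome.get(prot)
            if seq is None or pos < 1 or pos > len(seq) or seq[pos - 1] != res:
                raise ValueError(f"regulated site {res}{pos} absent from {prot}")
            if res not in PHOSPHO_RESIDUES:
                raise ValueError(f"regulated residue {res!r} is not S/T/Y")
            if not math.isfinite(l2fc) or l2fc == 0.0:
                raise ValueError(f"planted log2 fold change must be finite and nonzero, got {l2fc}")
        for bias in self.channel_loadings.values():
            if not bias > 0:
                raise ValueError("channel bias factors must be strictly positive")


@dataclass
class SimulationConfig:
    """Study conditions of the default synthetic dataset.

    Desk-scale proxy for a 4-plex duplicate-experiment design: 1,000
    background proteins, 2 experiments x 4 channels (two reference-genotype
    channels, the first of which is the ratio denominator, and two case
    channels), ~2,500 detected phosphosites at ~4 PSMs per site per
    experiment (~20,000 phospho-PSMs) plus a proteome tier of ~900
    detected proteins at ~20,000 non-phospho PSMs. The regulated fraction
    (~5% of sites, as in real deep phosphoproteomes) and the proteome-
    dominated intensity pool keep the linear intensity sums the channel
    normalization relies on from being distorted by the planted
    asymmetry of 2^L between up- and down-regulation.
    """

    n_proteins: int = 1000
    length_range: tuple[int, int] = (100, 500)
    aa_frequencies: dict[str, float] | None = None
    n_experiments: int = 2
    channels: tuple[str, ...] = ("114", "115", "116", "117")
    denominator: str = "114"
    channel_labels: dict[str, str] = field(
        default_factory=lambda: {"114": "WT", "115": "WT", "116": "IFN", "117": "IFN"}
    )
    n_sites: int = 2500
    min_site_spacing: int = 8
    n_regulated: int = 100
    regulated_magnitudes: tuple[float, ...] = (math.log2(1.5), 1.0, 2.0)
    n_kinases: int = 30
    sites_per_kinase: int = 4
    n_active_kinases: int = 8
    active_site_count: int = 3
    active_magnitude: float = 1.2
    motif_fraction: float = 0.6
    motif_offset: int = 1
    motif_residue: str = "P"
    multi_fraction: float = 0.15
    n_detected_proteins: int = 900
    nonphospho_min: int = 1
    nonphospho_poisson: float = 10.0
    channel_bias_sigma: float = 0.15
    noise: NoiseParams = field(default_factory=NoiseParams)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if "noise" in data and isinstance(data["noise"], dict):
            data["noise"] = NoiseParams(**data["noise"])
        for key in ("length_range", "channels", "regulated_magnitudes"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)


def null_config(n_sites: int = 5000) -> SimulationConfig:
    """No-effect calibration conditions: one experiment, one PSM per site,
    one sample label per channel, so each phosphosite maps to exactly one
    ratio record and the site-level call rate measures per-record z
    calibration."""
    return SimulationConfig(
        n_experiments=1,
        channel_labels={"114": "ref", "115": "s1", "116": "s2", "117": "s3"},
        n_sites=n_sites,
        n_regulated=0,
        n_active_kinases=0,
        motif_fraction=0.0,
        noise=NoiseParams(min_psms_per_site=1, extra_psms_poisson=0.0),
    )


@dataclass
class Dataset:
    """In-memory bundle of one synthetic study."""

    proteome: dict[str, str]
    psms: pd.DataFrame
    design: pd.DataFrame
    annotations: pd.DataFrame
    links: pd.DataFrame
    family_patterns: pd.DataFrame
    truth: GroundTruth
    config: SimulationConfig


# ---------------------------------------------------------------------------
# Proteome


def _validate_frequencies(freqs: Mapping[str, float]) -> tuple[list[str], np.ndarray]:
    bad = set(freqs) - set(STANDARD_AA)
    if bad:
        raise ValueError(f"composition contains non-standard residues: {sorted(bad)}")
    aas = sorted(freqs)
    p = np.array([freqs[a] for a in aas], dtype=float)
    if (p < 0).any():
        raise ValueError("composition frequencies must be non-negative")
    total = p.sum()
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"composition must sum to 1 (got {total:.8f})")
    return aas, p / total


def generate_proteome(
    n_proteins: int,
    length_range: tuple[int, int],
    aa_frequencies: Mapping[str, float] | None = None,
    seed: int = 0,
) -> dict[str, str]:
    """Draw a random proteome of i.i.d. residues; deterministic given seed."""
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    lo, hi = length_range
    if lo < 15:
        raise ValueError("minimum protein length must be >= 15")
    aas, p = _validate_frequencies(aa_frequencies or NATURAL_AA_FREQUENCIES)
    rng = np.random.default_rng(seed)
    proteome: dict[str, str] = {}
    aa_arr = np.array(aas)
    for i in range(n_proteins):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(aa_arr, size=length, p=p))
        proteome[f"PROT{i + 1:05d}"] = seq
    return proteome


# ---------------------------------------------------------------------------
# Design


def make_design(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    for e in range(1, config.n_experiments + 1):
        exp = f"EXP{e}"
        for ch in config.channels:
            rows.append(
                {
                    "experiment_id": exp,
                    "channel": ch,
                    "sample_label": config.channel_labels[ch],
                    "is_denominator": int(ch == config.denominator),
                }
            )
    design = pd.DataFrame(rows)
    pio.validate_design(design)
    return design


# ---------------------------------------------------------------------------
# PSM emission


@dataclass
class _SiteSpec:
    protein: str
    residue: str
    position: int
    log2fc: float
    peptide: str
    pep_start: int  # 0-based start of peptide in protein
    secondary_candidates: list[tuple[str, int]]


def _site_peptide(seq: str, pos: int, rng: np.random.Generator) -> tuple[str, int]:
    left = int(rng.integers(4, 10))
    right = int(rng.integers(4, 10))
    start = max(0, pos - 1 - left)
    end = min(len(seq), pos + right)
    return seq[start:end], start


def _emit_psms(
    proteome: Mapping[str, str],
    design: pd.DataFrame,
    site_specs: Sequence[_SiteSpec],
    nonphospho_proteins: Sequence[str],
    noise: NoiseParams,
    channel_loadings: Mapping[tuple[str, str], float],
    multi_fraction: float,
    rng: np.random.Generator,
    nonphospho_min: int = 1,
    nonphospho_poisson: float = 3.2,
) -> tuple[pd.DataFrame, list[tuple[str, str, int, float]]]:
    """Core PSM generator. Returns the PSM table and the list of secondary
    (co-regulated) sites that received non-null ratios via shared peptides."""
    experiments = list(dict.fromkeys(design["experiment_id"]))
    channels_by_exp = {e: pio.design_channels(design, e) for e in experiments}
    den_by_exp = {e: pio.denominator_channel(design, e) for e in experiments}
    labels_by_exp = {
        e: {ch: pio.sample_label(design, e, ch) for ch in channels_by_exp[e]}
        for e in experiments
    }
    den_label = {e: labels_by_exp[e][den_by_exp[e]] for e in experiments}

    # Draw PSM counts first so the intensity population can be generated in
    # one deterministic block.
    phospho_counts: list[tuple[int, str, int]] = []  # (site index, experiment, count)
    for e in experiments:
        for i in range(len(site_specs)):
            n = noise.min_psms_per_site + (
                int(rng.poisson(noise.extra_psms_poisson))
                if noise.extra_psms_poisson > 0
                else 0
            )
            phospho_counts.append((i, e, n))
    nonphospho_counts: list[tuple[str, str, int]] = []
    for e in experiments:
        for acc in nonphospho_proteins:
            extra = int(rng.poisson(nonphospho_poisson)) if nonphospho_poisson > 0 else 0
            nonphospho_counts.append((acc, e, nonphospho_min + extra))

    n_phospho = sum(n for _, _, n in phospho_counts)
    n_nonphospho = sum(n for _, _, n in nonphospho_counts)
    m_total = n_phospho + n_nonphospho
    totals = rng.lognormal(noise.log_intensity_mean, noise.log_intensity_sd, m_total)
    log_t = np.log(totals)
    if noise.ratio_sd_high == noise.ratio_sd_low:
        sd_ratio = np.full(m_total, float(noise.ratio_sd_high))
    else:
        p1, p99 = np.percentile(log_t, [1, 99])
        if p99 > p1:
            frac = np.clip((log_t - p1) / (p99 - p1), 0.0, 1.0)
            sd_ratio = noise.ratio_sd_high + (noise.ratio_sd_low - noise.ratio_sd_high) * frac
        else:
            sd_ratio = np.full(m_total, (noise.ratio_sd_high + noise.ratio_sd_low) / 2.0)

    rows: list[dict] = []
    coregulated: dict[tuple[str, str, int], float] = {}
    m = 0
    psm_idx = 0

    def build_row(
        exp: str,
        peptide: str,
        protein: str,
        sites: list[tuple[str, int]],
        population: str,
        log2fc: float,
        m_index: int,
    ) -> dict:
        nonlocal psm_idx
        psm_idx += 1
        channels = channels_by_exp[exp]
        den = den_by_exp[exp]
        base = totals[m_index] / len(channels)
        # per-channel log2 noise of sd/sqrt(2) on every channel (reference
        # included) makes the channel-vs-denominator ratio noise have the
        # stated sd with mean 0 while keeping expected intensities equal
        # across channels
        eps = rng.normal(0.0, sd_ratio[m_index] / math.sqrt(2.0), size=len(channels))
        row = {
            "psm_id": f"PSM{psm_idx:07d}",
            "experiment_id": exp,
            "peptide": peptide,
            "protein": protein,
            "site_positions": format_site_positions(sites),
            "population": population,
        }
        for ch, e_ch in zip(channels, eps):
            label = labels_by_exp[exp][ch]
            shift = log2fc if (log2fc != 0.0 and label != den_label[exp]) else 0.0
            intensity = base * 2.0 ** (shift + float(e_ch))
            intensity *= channel_loadings.get((exp, ch), 1.0)
            row[ch] = intensity
        return row

    for i, exp, count in phospho_counts:
        spec = site_specs[i]
        for _ in range(count):
            sites = [(spec.residue, spec.position)]
            population = "mono"
            if spec.secondary_candidates and rng.random() < multi_fraction:
                j = int(rng.integers(len(spec.secondary_candidates)))
                sec = spec.secondary_candidates[j]
                sites.append(sec)
                population = "multi"
                if spec.log2fc != 0.0:
                    coregulated.setdefault(
                        (spec.protein, sec[0], sec[1]), spec.log2fc
                    )
            rows.append(
                build_row(exp, spec.peptide, spec.protein, sites, population, spec.log2fc, m)
            )
            m += 1
    for acc, exp, count in nonphospho_counts:
        seq = proteome[acc]
        for j in range(count):
            start = (j * 13) % max(1, len(seq) - 12)
            peptide = seq[start : start + 12]
            rows.append(build_row(exp, peptide, acc, [], "nonphospho", 0.0, m))
            m += 1

    psms = pd.DataFrame(rows)
    coreg = [(p, r, q, l) for (p, r, q), l in sorted(coregulated.items())]
    return psms, coreg


def generate_psm_table(
    proteome: Mapping[str, str],
    design: pd.DataFrame,
    truth: GroundTruth,
    noise: NoiseParams,
    seed: int = 0,
    extra_sites: Sequence[tuple[str, str, int]] = (),
    nonphospho_proteins: Sequence[str] = (),
    multi_fraction: float = 0.0,
    nonphospho_min: int = 1,
    nonphospho_poisson: float = 3.2,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Emit a PSM table for the sites in ``truth`` (plus optional unregulated
    ``extra_sites``), honoring planted fold changes and channel loadings.

    Unregulated sites have expected log2 ratio 0 against the denominator;
    regulated sites carry their planted value in every channel whose sample
    label differs from the denominator channel's label.
    """
    pio.validate_design(design)
    rng = np.random.default_rng(seed)
    site_rows: list[tuple[str, str, int, float]] = list(truth.regulated_sites) + [
        (p, r, q, 0.0) for p, r, q in extra_sites
    ]
    specs: list[_SiteSpec] = []
    for prot, res, pos, l2fc in site_rows:
        seq = proteome.get(prot)
        if seq is None:
            raise ValueError(f"site protein {prot!r} absent from proteome")
        if pos < 1 or pos > len(seq):
            raise ValueError(f"site index {pos} beyond protein {prot} (length {len(seq)})")
        if seq[pos - 1] != res:
            raise ValueError(f"site {res}{pos} does not match proteome residue on {prot}")
        peptide, start = _site_peptide(seq, pos, rng)
        cands = [
            (seq[q - 1], q)
            for q in range(start + 1, start + len(peptide) + 1)
            if seq[q - 1] in PHOSPHO_RESIDUES and q != pos
        ]
        specs.append(_SiteSpec(prot, res, pos, l2fc, peptide, start, cands))
    psms, coreg = _emit_psms(
        proteome,
        design,
        specs,
        nonphospho_proteins,
        noise,
        truth.channel_loadings,
        multi_fraction,
        rng,
        nonphospho_min=nonphospho_min,
        nonphospho_poisson=nonphospho_poisson,
    )
    truth.coregulated_sites = coreg
    return psms, truth


# ---------------------------------------------------------------------------
# Kinase regulatory-site annotations


def generate_kinase_annotations(
    proteome: Mapping[str, str],
    n_kinases: int,
    sites_per_kinase: int,
    effect_mix: float,
    seed: int = 0,
    exclude: Sequence[str] = (),
) -> pd.DataFrame:
    """Annotate random S/T/Y sites on randomly chosen proteome accessions
    with 'activity, induced' (probability ``effect_mix``) or
    'activity, inhibited' regulatory effects."""
    if not 0.0 <= effect_mix <= 1.0:
        raise ValueError(f"effect_mix must be in [0, 1], got {effect_mix}")
    rng = np.random.default_rng(seed)
    candidates = [
        acc
        for acc in proteome
        if acc not in set(exclude)
        and sum(c in PHOSPHO_RESIDUES for c in proteome[acc]) >= sites_per_kinase
    ]
    if len(candidates) < n_kinases:
        raise ValueError("not enough proteins with sufficient S/T/Y sites for annotation")
    order = rng.permutation(len(candidates))
    rows = []
    for idx in order[:n_kinases]:
        acc = candidates[idx]
        seq = proteome[acc]
        sty = [i + 1 for i, c in enumerate(seq) if c in PHOSPHO_RESIDUES]
        picks = rng.choice(len(sty), size=sites_per_kinase, replace=False)
        for k in sorted(picks):
            pos = sty[k]
            effect = EFFECT_INDUCED if rng.random() < effect_mix else EFFECT_INHIBITED
            rows.append(
                {
                    "kinase_accession": acc,
                    "site": format_site(seq[pos - 1], pos),
                    "effect": effect,
                }
            )
    ann = pd.DataFrame(rows, columns=pio.ANNOTATION_COLUMNS)
    pio.validate_annotations(ann)
    return ann


# ---------------------------------------------------------------------------
# Full dataset orchestration


def _select_spaced_sites(
    seq: str,
    sty_positions: Sequence[int],
    taken: set[int],
    n_wanted: int,
    spacing: int,
    rng: np.random.Generator,
) -> list[int]:
    """Pick up to n_wanted S/T/Y positions at pairwise distance >= spacing
    from each other and from already-taken positions."""
    chosen: list[int] = []
    candidates = list(sty_positions)
    rng.shuffle(candidates)
    for pos in candidates:
        if all(abs(pos - t) >= spacing for t in taken) and all(
            abs(pos - c) >= spacing for c in chosen
        ):
            chosen.append(pos)
            if len(chosen) == n_wanted:
                break
    return chosen


def generate_dataset(config: SimulationConfig | None = None, seed: int = 0) -> Dataset:
    """Generate a complete synthetic study: proteome, design, PSM table,
    kinase annotations, phosphopeptide-to-family link table and ground truth.

    Fully deterministic given ``seed``; identical seeds yield byte-identical
    fixture files through :func:`write_dataset`.
    """
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(seed)

    def sub_seed() -> int:
        return int(rng.integers(0, MAX_SEED))

    proteome = generate_proteome(
        cfg.n_proteins, cfg.length_range, cfg.aa_frequencies, seed=sub_seed()
    )
    accs = list(proteome)
    seqs = {acc: list(proteome[acc]) for acc in accs}
    sty_index = {
        acc: [i + 1 for i, c in enumerate(proteome[acc]) if c in PHOSPHO_RESIDUES]
        for acc in accs
    }
    taken: dict[str, set[int]] = {acc: set() for acc in accs}

    # --- active kinases and their regulated annotated sites
    kinase_truth: list[tuple[str, int]] = []
    kinase_site_rows: list[tuple[str, str, int, float]] = []
    planted_ann_rows: list[dict] = []
    shuffled = list(accs)
    rng.shuffle(shuffled)
    k_iter = iter(shuffled)
    for j in range(cfg.n_active_kinases):
        direction = 1 if j < (cfg.n_active_kinases + 1) // 2 else -1
        effect_sign = 1 if j % 2 == 0 else -1
        effect = EFFECT_INDUCED if effect_sign > 0 else EFFECT_INHIBITED
        while True:
            acc = next(k_iter)
            picks = _select_spaced_sites(
                proteome[acc],
                sty_index[acc],
                taken[acc],
                cfg.active_site_count,
                cfg.min_site_spacing,
                rng,
            )
            if len(picks) == cfg.active_site_count:
                break
        kinase_truth.append((acc, direction))
        for pos in sorted(picks):
            taken[acc].add(pos)
            res = proteome[acc][pos - 1]
            l2fc = direction * effect_sign * cfg.active_magnitude
            kinase_site_rows.append((acc, res, pos, l2fc))
            planted_ann_rows.append(
                {"kinase_accession": acc, "site": format_site(res, pos), "effect": effect}
            )
    active_accs = {acc for acc, _ in kinase_truth}

    # --- generic detected-site universe
    lengths = np.array([len(proteome[a]) for a in accs], dtype=float)
    weights = lengths / lengths.sum()
    generic_sites: list[tuple[str, str, int]] = []
    attempts = 0
    while len(generic_sites) < cfg.n_sites and attempts < 80 * cfg.n_sites:
        attempts += 1
        acc = accs[int(rng.choice(len(accs), p=weights))]
        cand = [
            p
            for p in sty_index[acc]
            if all(abs(p - t) >= cfg.min_site_spacing for t in taken[acc])
        ]
        if not cand:
            continue
        pos = int(cand[int(rng.integers(len(cand)))])
        taken[acc].add(pos)
        generic_sites.append((acc, proteome[acc][pos - 1], pos))
    if len(generic_sites) < cfg.n_sites:
        raise RuntimeError("could not place the requested number of phosphosites")

    # --- regulated assignment among generic sites
    reg_idx = rng.choice(len(generic_sites), size=cfg.n_regulated, replace=False)
    reg_idx = sorted(int(i) for i in reg_idx)
    regulated: list[tuple[str, str, int, float]] = []
    mags = cfg.regulated_magnitudes
    for rank, i in enumerate(reg_idx):
        acc, res, pos = generic_sites[i]
        l2fc = mags[rank % len(mags)] * (1.0 if rank % 2 == 0 else -1.0)
        regulated.append((acc, res, pos, l2fc))
    reg_keys = {(a, r, p) for a, r, p, _ in regulated}
    unregulated = [s for s in generic_sites if s not in reg_keys]
    all_regulated = regulated + kinase_site_rows

    # --- motif planting on upregulated sites (mutate residue at +offset)
    n_up, n_planted = 0, 0
    site_position_sets = taken  # selected positions per protein
    for acc, res, pos, l2fc in all_regulated:
        if l2fc <= 0:
            continue
        n_up += 1
        target = pos + cfg.motif_offset  # 1-based position receiving the fixed residue
        if target < 1 or target > len(seqs[acc]):
            continue
        if target in site_position_sets[acc]:
            continue
        if rng.random() < cfg.motif_fraction:
            seqs[acc][target - 1] = cfg.motif_residue
            n_planted += 1
    proteome = {acc: "".join(chars) for acc, chars in seqs.items()}

    # --- design and channel loadings
    design = make_design(cfg)
    loadings = {
        (row.experiment_id, row.channel): float(np.exp(rng.normal(0.0, cfg.channel_bias_sigma)))
        if cfg.channel_bias_sigma > 0
        else 1.0
        for row in design.itertuples(index=False)
    }

    # --- PSM table
    nonphospho_proteins = sorted(
        accs[int(i)] for i in rng.choice(len(accs), size=cfg.n_detected_proteins, replace=False)
    )
    truth = GroundTruth(
        regulated_sites=all_regulated,
        planted_motifs=[
            (f"{cfg.motif_residue}@{cfg.motif_offset:+d}", cfg.motif_fraction)
        ]
        if cfg.motif_fraction > 0
        else [],
        kinase_truth=kinase_truth,
        channel_loadings=loadings,
        unregulated_sites=unregulated,
    )
    truth.validate(proteome)
    psms, truth = generate_psm_table(
        proteome,
        design,
        truth,
        cfg.noise,
        seed=sub_seed(),
        extra_sites=unregulated,
        nonphospho_proteins=nonphospho_proteins,
        multi_fraction=cfg.multi_fraction,
        nonphospho_min=cfg.nonphospho_min,
        nonphospho_poisson=cfg.nonphospho_poisson,
    )

    # --- annotations: planted regulatory sites + background kinases
    background_n = max(0, cfg.n_kinases - cfg.n_active_kinases)
    n_detected_bg = background_n // 2
    detected_by_prot: dict[str, list[tuple[str, int]]] = {}
    for acc, res, pos in unregulated:
        detected_by_prot.setdefault(acc, []).append((res, pos))
    bg_detected_rows: list[dict] = []
    used_bg: set[str] = set(active_accs)
    for acc in sorted(detected_by_prot):
        if len(bg_detected_rows) // max(1, cfg.sites_per_kinase) >= n_detected_bg:
            break
        if acc in used_bg or len(detected_by_prot[acc]) < 2:
            continue
        used_bg.add(acc)
        for res, pos in sorted(detected_by_prot[acc], key=lambda s: s[1])[
            : cfg.sites_per_kinase
        ]:
            effect = EFFECT_INDUCED if rng.random() < 0.5 else EFFECT_INHIBITED
            bg_detected_rows.append(
                {"kinase_accession": acc, "site": format_site(res, pos), "effect": effect}
            )
    n_random_bg = background_n - len({r["kinase_accession"] for r in bg_detected_rows})
    random_bg = (
        generate_kinase_annotations(
            proteome,
            n_random_bg,
            cfg.sites_per_kinase,
            effect_mix=0.5,
            seed=sub_seed(),
            exclude=sorted(used_bg),
        )
        if n_random_bg > 0
        else pd.DataFrame(columns=pio.ANNOTATION_COLUMNS)
    )
    annotations = pd.concat(
        [pd.DataFrame(planted_ann_rows), pd.DataFrame(bg_detected_rows), random_bg],
        ignore_index=True,
    )
    if len(annotations):
        pio.validate_annotations(annotations)

    # --- phosphopeptide-to-kinase-family link table
    family_patterns = pd.DataFrame(DEFAULT_FAMILY_PATTERNS, columns=["family", "pattern"])
    from .kinase import link_peptides_to_families  # local import: avoids cycle at module load

    links = link_peptides_to_families(psms, proteome, family_patterns)

    return Dataset(
        proteome=proteome,
        psms=psms,
        design=design,
        annotations=annotations,
        links=links,
        family_patterns=family_patterns,
        truth=truth,
        config=cfg,
    )


# ---------------------------------------------------------------------------
# Serialization


def truth_frames(truth: GroundTruth) -> dict[str, pd.DataFrame]:
    return {
        "truth_sites": pd.DataFrame(
            truth.regulated_sites, columns=["protein", "residue", "position", "log2fc"]
        ),
        "truth_null_sites": pd.DataFrame(
            truth.unregulated_sites, columns=["protein", "residue", "position"]
        ),
        "truth_coregulated": pd.DataFrame(
            truth.coregulated_sites, columns=["protein", "residue", "position", "log2fc"]
        ),
        "truth_kinases": pd.DataFrame(
            truth.kinase_truth, columns=["kinase_accession", "direction"]
        ),
        "truth_loadings": pd.DataFrame(
            [(e, c, b) for (e, c), b in sorted(truth.channel_loadings.items())],
            columns=["experiment_id", "channel", "bias"],
        ),
        "truth_motifs": pd.DataFrame(
            truth.planted_motifs, columns=["pattern", "fraction"]
        ),
    }


def write_dataset(dataset: Dataset, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "proteome": outdir / "proteome.fasta",
        "psms": outdir / "psms.tsv",
        "design": outdir / "design.tsv",
        "annotations": outdir / "annotations.tsv",
        "links": outdir / "links.tsv",
        "family_patterns": outdir / "family_patterns.tsv",
    }
    pio.write_fasta(dataset.proteome, paths["proteome"])
    pio.write_psm_table(dataset.psms, paths["psms"])
    pio.write_design(dataset.design, paths["design"])
    pio.write_annotations(dataset.annotations, paths["annotations"])
    dataset.links.to_csv(paths["links"], sep="\t", index=False)
    dataset.family_patterns.to_csv(paths["family_patterns"], sep="\t", index=False)
    for name, frame in truth_frames(dataset.truth).items():
        p = outdir / f"{name}.tsv"
        frame.to_csv(p, sep="\t", index=False)
        paths[name] = p
    return paths
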