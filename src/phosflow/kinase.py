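"""Kinase inference from regulated phosphosites.

Three complementary approaches:

1. Substrate-centric motif enrichment: a motif-x-style greedy search
   over 15-residue sequence windows of upregulated sites, fixing one
   (offset, residue) pair per step by a one-sided binomial test against
   a background window set (all S/T/Y windows of the proteome by
   default).
2. Kinase-family substrate percentages: the fraction of a family's
   linked phosphopeptides that are upregulated, from a user-supplied
   phosphopeptide-to-family link table.
3. A regulatory-site activity score: the PSM-weighted, direction-signed
   average of the log2 fold changes of significant annotated
   phosphosites on a kinase, with 'activity, induced' counting +1 and
   'activity, inhibited' counting -1; |score| >= 0.53 calls the kinase
   increased or decreased.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom

from . import io as pio
from .io import PHOSPHO_RESIDUES, STANDARD_AA, parse_site_positions

logger = logging.getLogger(__name__)

WINDOW_FLANK = 7  # offsets -7..+7 around the central residue
WINDOW_LENGTH = 2 * WINDOW_FLANK + 1
PAD = "_"

DEFAULT_P_THRESHOLD = 1e-6
DEFAULT_MIN_OCCURRENCES = 20
DEFAULT_ACTIVITY_THRESHOLD = 0.53


# ---------------------------------------------------------------------------
# Sequence windows


def extract_window(seq: str, residue: str, position: int) -> str:
    """15-residue window centered on the site, center lowercased, terminal
    overhangs padded with '_'. Residue must match the sequence."""
    if position < 1 or position > len(seq):
        raise ValueError(f"site position {position} outside sequence of length {len(seq)}")
    if seq[position - 1] != residue:
        raise ValueError(
            f"site residue {residue!r} does not match sequence residue "
            f"{seq[position - 1]!r} at position {position}"
        )
    left = seq[max(0, position - 1 - WINDOW_FLANK) : position - 1]
    right = seq[position : position + WINDOW_FLANK]
    return (
        PAD * (WINDOW_FLANK - len(left))
        + left
        + residue.lower()
        + right
        + PAD * (WINDOW_FLANK - len(right))
    )


def extract_windows(sites: pd.DataFrame, proteome: Mapping[str, str]) -> pd.DataFrame:
    """Windows for a (protein, residue, position) site table."""
    windows = []
    for row in sites.itertuples(index=False):
        seq = proteome.get(row.protein)
        if seq is None:
            raise ValueError(f"protein {row.protein!r} not in proteome")
        windows.append(extract_window(seq, row.residue, int(row.position)))
    out = sites.copy()
    out["window"] = windows
    return out


def proteome_windows(
    proteome: Mapping[str, str], centers: str = PHOSPHO_RESIDUES
) -> list[str]:
    """Windows of every S/T/Y (or chosen subset) in the proteome — the
    default motif-search background."""
    windows = []
    for seq in proteome.values():
        for i, c in enumerate(seq):
            if c in centers:
                windows.append(extract_window(seq, c, i + 1))
    return windows


# ---------------------------------------------------------------------------
# Pattern matching


def parse_pattern(pattern: str) -> tuple[str, list[tuple[int, str]]]:
    """Split a motif pattern like 'sP', 's.E', 'R..s' or 'sP...K' into its
    center anchor (lowercase s/t/y, or 'x' for any center) and fixed
    (offset, residue) pairs; '.' is a wildcard."""
    anchors = [i for i, c in enumerate(pattern) if c in "styx"]
    if len(anchors) != 1:
        raise ValueError(
            f"pattern {pattern!r} must contain exactly one lowercase s/t/y center anchor"
        )
    ci = anchors[0]
    fixed = []
    for i, c in enumerate(pattern):
        if i == ci or c == ".":
            continue
        if c not in STANDARD_AA or not c.isupper():
            raise ValueError(f"pattern {pattern!r} has invalid fixed residue {c!r}")
        offset = i - ci
        if not -WINDOW_FLANK <= offset <= WINDOW_FLANK:
            raise ValueError(f"pattern {pattern!r} exceeds the 15-residue window")
        fixed.append((offset, c))
    return pattern[ci], fixed


def match_pattern(window: str, pattern: str) -> bool:
    """True iff every fixed residue of the pattern matches the window at its
    offset relative to the center (window position 7)."""
    if len(window) != WINDOW_LENGTH:
        raise ValueError(f"window must be {WINDOW_LENGTH} characters, got {len(window)}")
    center, fixed = parse_pattern(pattern)
    wc = window[WINDOW_FLANK]
    if center == "x":
        if wc not in "sty":
            return False
    elif wc != center:
        return False
    for offset, res in fixed:
        if window[WINDOW_FLANK + offset] != res:
            return False
    return True


def build_pattern(center: str, fixed: Sequence[tuple[int, str]]) -> str:
    """Assemble the compact pattern string from a center and fixed pairs."""
    if not fixed:
        return center
    offsets = [o for o, _ in fixed]
    lo, hi = min(0, min(offsets)), max(0, max(offsets))
    by_offset = dict(fixed)
    chars = []
    for o in range(lo, hi + 1):
        if o == 0:
            chars.append(center)
        else:
            chars.append(by_offset.get(o, "."))
    return "".join(chars)


# ---------------------------------------------------------------------------
# Motif-x style enrichment


@dataclass
class MotifResult:
    pattern: str
    center: str
    fixed: tuple[tuple[int, str], ...]
    steps: list[dict] = field(default_factory=list)
    fg_matches: int = 0
    fg_size: int = 0
    bg_matches: int = 0
    bg_size: int = 0
    fold_enrichment: float = float("nan")

    @property
    def p_values(self) -> list[float]:
        return [s["p"] for s in self.steps]


def binomial_tail(k: int, n: int, q: float) -> float:
    """One-sided binomial upper tail P(X >= k), X ~ Binomial(n, q)."""
    if k <= 0:
        return 1.0
    return float(binom.sf(k - 1, n, q))


def _window_matrix(windows: Sequence[str]) -> np.ndarray:
    return np.array([list(w) for w in windows], dtype="U1").reshape(len(windows), WINDOW_LENGTH)


def _grow_motif(
    fg: np.ndarray,
    bg: np.ndarray,
    p_threshold: float,
    min_occurrences: int,
    allow_center: bool,
) -> MotifResult | None:
    fixed: list[tuple[int, str]] = []
    steps: list[dict] = []
    cur_fg, cur_bg = fg, bg
    fixed_offsets: set[int] = set()
    while True:
        n_fg, n_bg = len(cur_fg), len(cur_bg)
        if n_fg == 0 or n_bg == 0:
            break
        best = None
        cols = [
            o
            for o in range(-WINDOW_FLANK, WINDOW_FLANK + 1)
            if o not in fixed_offsets and (o != 0 or allow_center)
        ]
        for offset in cols:
            col = WINDOW_FLANK + offset
            residues, counts = np.unique(cur_fg[:, col], return_counts=True)
            for res, k in zip(residues, counts):
                if res == PAD or int(k) < min_occurrences:
                    continue
                if offset != 0 and not (res.isupper() and res in STANDARD_AA):
                    continue
                q = float((cur_bg[:, col] == res).sum()) / n_bg
                p = binomial_tail(int(k), n_fg, q)
                if p > p_threshold:
                    continue
                key = (p, abs(offset), str(res))
                if best is None or key < best[0]:
                    best = (key, offset, str(res), int(k), q, p)
        if best is None:
            break
        _, offset, res, k, q, p = best
        fixed.append((offset, res))
        fixed_offsets.add(offset)
        steps.append(
            {"offset": offset, "residue": res, "k": k, "n_fg": n_fg, "q": q, "p": p}
        )
        col = WINDOW_FLANK + offset
        cur_fg = cur_fg[cur_fg[:, col] == res]
        cur_bg = cur_bg[cur_bg[:, col] == res]
    if not fixed:
        return None
    center_fixed = [r for o, r in fixed if o == 0]
    center = center_fixed[0] if center_fixed else None
    return MotifResult(
        pattern="",
        center=center or "",
        fixed=tuple((o, r) for o, r in fixed if o != 0),
        steps=steps,
    )


def _matches_fixed(mat: np.ndarray, fixed: Iterable[tuple[int, str]], center: str | None) -> np.ndarray:
    mask = np.ones(len(mat), dtype=bool)
    if center:
        mask &= mat[:, WINDOW_FLANK] == center
    for offset, res in fixed:
        mask &= mat[:, WINDOW_FLANK + offset] == res
    return mask


def motif_enrichment(
    foreground: Sequence[str],
    background: Sequence[str],
    p_threshold: float = DEFAULT_P_THRESHOLD,
    min_occurrences: int = DEFAULT_MIN_OCCURRENCES,
    center: str = "any",
    max_motifs: int = 50,
) -> list[MotifResult]:
    """Iterative greedy motif extraction.

    Each round grows one motif by repeatedly fixing the (offset, residue)
    pair with the smallest one-sided binomial tail p-value (ties broken by
    smaller p, then smaller |offset|, then alphabetical residue), requiring
    p <= p_threshold and at least ``min_occurrences`` foreground carriers,
    and restricting both window sets to the carriers. Fold enrichment is
    computed on the round's starting foreground/background; matched
    foreground windows are removed before the next round. Deterministic
    given inputs.
    """
    if center not in ("any", "s", "t", "y"):
        raise ValueError("center must be 'any' or one of 's','t','y'")
    fg_list = list(foreground)
    bg_list = list(background)
    if center != "any":
        fg_list = [w for w in fg_list if w[WINDOW_FLANK] == center]
        bg_list = [w for w in bg_list if w[WINDOW_FLANK] == center]
    if not fg_list:
        logger.info("motif search: empty foreground (center=%s)", center)
        return []
    if not bg_list:
        raise ValueError("motif search requires a non-empty background")
    fg = _window_matrix(fg_list)
    bg = _window_matrix(bg_list)
    results: list[MotifResult] = []
    while len(results) < max_motifs and len(fg):
        motif = _grow_motif(fg, bg, p_threshold, min_occurrences, allow_center=(center == "any"))
        if motif is None:
            break
        eff_center = motif.center or (center if center != "any" else None)
        fg_mask = _matches_fixed(fg, motif.fixed, eff_center)
        bg_mask = _matches_fixed(bg, motif.fixed, eff_center)
        motif.fg_matches = int(fg_mask.sum())
        motif.fg_size = len(fg)
        motif.bg_matches = int(bg_mask.sum())
        motif.bg_size = len(bg)
        fg_frac = motif.fg_matches / motif.fg_size
        bg_frac = motif.bg_matches / motif.bg_size if motif.bg_size else np.nan
        motif.fold_enrichment = float(fg_frac / bg_frac) if bg_frac else float("inf")
        motif.pattern = build_pattern(eff_center or "x", motif.fixed)
        results.append(motif)
        fg = fg[~fg_mask]
    return results


def motif_search(
    foreground: Sequence[str],
    background: Sequence[str],
    p_threshold: float = DEFAULT_P_THRESHOLD,
    min_occurrences: int = DEFAULT_MIN_OCCURRENCES,
    centers: Sequence[str] = ("s", "t", "y"),
) -> list[MotifResult]:
    """Run the enrichment separately per center residue and pool the
    results, sorted by first-step p-value."""
    results: list[MotifResult] = []
    for c in centers:
        results.extend(
            motif_enrichment(
                foreground,
                background,
                p_threshold=p_threshold,
                min_occurrences=min_occurrences,
                center=c,
            )
        )
    return sorted(results, key=lambda m: (m.steps[0]["p"], m.pattern))


def motifs_to_frame(motifs: Sequence[MotifResult]) -> pd.DataFrame:
    rows = []
    for m in motifs:
        rows.append(
            {
                "pattern": m.pattern,
                "fold_enrichment": m.fold_enrichment,
                "fg_matches": m.fg_matches,
                "fg_size": m.fg_size,
                "bg_matches": m.bg_matches,
                "bg_size": m.bg_size,
                "p_chain": ";".join(f"{p:.3e}" for p in m.p_values),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "pattern", "fold_enrichment", "fg_matches", "fg_size",
            "bg_matches", "bg_size", "p_chain",
        ],
    )


# ---------------------------------------------------------------------------
# Kinase-family substrate percentages


def peptide_key(peptide: str, site_positions: str) -> str:
    return f"{peptide}|{site_positions}"


def link_peptides_to_families(
    psms: pd.DataFrame,
    proteome: Mapping[str, str],
    family_patterns: pd.DataFrame,
    any_center: bool = True,
) -> pd.DataFrame:
    """Phosphopeptide-to-family link table built by matching each detected
    phosphopeptide's site windows against family consensus patterns."""
    phospho = psms[psms["population"].isin(["mono", "multi"])]
    uniq = phospho[["peptide", "site_positions", "protein"]].drop_duplicates()
    rows = []
    patterns = []
    for row in family_patterns.itertuples(index=False):
        pat = row.pattern
        if any_center:
            i = _anchor_index(pat)
            pat = pat[:i] + "x" + pat[i + 1 :]
        patterns.append((row.family, pat))
    for rec in uniq.itertuples(index=False):
        seq = proteome.get(rec.protein)
        if seq is None:
            continue
        key = peptide_key(rec.peptide, rec.site_positions)
        windows = [
            extract_window(seq, res, pos)
            for res, pos in parse_site_positions(rec.site_positions)
        ]
        for family, pattern in patterns:
            if any(match_pattern(w, pattern) for w in windows):
                rows.append({"peptide_key": key, "family": family})
    return pd.DataFrame(rows, columns=["peptide_key", "family"]).drop_duplicates()


def _anchor_index(pattern: str) -> int:
    anchors = [i for i, c in enumerate(pattern) if c in "styx"]
    if len(anchors) != 1:
        raise ValueError(f"pattern {pattern!r} lacks a unique center anchor")
    return anchors[0]


def family_percentages(
    upregulated: Iterable[str],
    detected: Iterable[str],
    links: pd.DataFrame,
) -> pd.DataFrame:
    """Per kinase family: 100 x (upregulated linked phosphopeptides) /
    (all detected linked phosphopeptides), plus an '(unmatched)' row giving
    the fraction of upregulated peptides with no family link."""
    up = set(upregulated)
    det = set(detected) | up
    rows = []
    linked_keys: set[str] = set()
    if len(links):
        for family, grp in links.groupby("family", sort=True):
            keys = set(grp["peptide_key"])
            linked_keys |= keys
            denom = len(det & keys)
            num = len(up & keys)
            rows.append(
                {
                    "family": family,
                    "n_upregulated": num,
                    "n_detected": denom,
                    "percentage": 100.0 * num / denom if denom else float("nan"),
                }
            )
    n_unmatched = len(up - linked_keys)
    rows.append(
        {
            "family": "(unmatched)",
            "n_upregulated": n_unmatched,
            "n_detected": len(up),
            "percentage": 100.0 * n_unmatched / len(up) if up else float("nan"),
        }
    )
    return pd.DataFrame(rows, columns=["family", "n_upregulated", "n_detected", "percentage"])


def match_motif_families(
    motifs: Sequence[MotifResult], family_patterns: pd.DataFrame
) -> pd.DataFrame:
    """Label enriched motifs with the kinase families whose consensus
    pattern they contain (fixed positions of the consensus are a subset of
    the motif's fixed positions; centers compatible)."""
    rows = []
    for m in motifs:
        families = []
        for row in family_patterns.itertuples(index=False):
            center, fixed = parse_pattern(row.pattern)
            if center in "sty" and m.center and m.center != center:
                continue
            if set(fixed) <= set(m.fixed):
                families.append(row.family)
        rows.append({"pattern": m.pattern, "families": ";".join(families)})
    return pd.DataFrame(rows, columns=["pattern", "families"])


# ---------------------------------------------------------------------------
# Kinase activity score


def activity_scores(
    site_quant: pd.DataFrame,
    annotations: pd.DataFrame,
    threshold: float = DEFAULT_ACTIVITY_THRESHOLD,
    sample_label: str | None = None,
) -> tuple[pd.DataFrame, dict]:
    """PSM-weighted, direction-signed kinase activity scores.

    score(k) = sum_s(L_s * n_s * d_s) / sum_s(n_s) over the kinase's
    annotated phosphosites s that pass the phospho significance call, with
    L_s the combined log2 fold change, n_s the site's total PSM count and
    d_s = +1 for 'activity, induced' / -1 for 'activity, inhibited'.
    Kinases with no significant annotated site are omitted and reported in
    the coverage summary.
    """
    pio.validate_annotations(annotations)
    ann = pio.annotation_sites(annotations)
    sq = site_quant
    if sample_label is not None:
        sq = sq[sq["sample_label"] == sample_label]
    detected = sq.merge(
        ann,
        left_on=["protein", "residue", "position"],
        right_on=["kinase_accession", "residue", "position"],
        how="inner",
    )
    sig = detected[detected["significant"]]
    rows = []
    for kin, grp in sig.groupby("kinase_accession", sort=True):
        n = grp["total_psms"].to_numpy(dtype=float)
        contrib = grp["combined_log2fc"].to_numpy() * n * grp["direction"].to_numpy()
        score = float(contrib.sum() / n.sum())
        call = (
            "increased"
            if score >= threshold
            else "decreased"
            if score <= -threshold
            else "unchanged"
        )
        rows.append(
            {
                "kinase": kin,
                "score": score,
                "n_sites": int(len(grp)),
                "total_psms": int(n.sum()),
                "call": call,
            }
        )
    scores = pd.DataFrame(rows, columns=["kinase", "score", "n_sites", "total_psms", "call"])
    coverage = {
        "n_kinases_annotated": int(annotations["kinase_accession"].nunique()),
        "n_kinases_with_detected_site": int(detected["kinase_accession"].nunique()),
        "n_kinases_scored": int(len(scores)),
        "n_annotated_sites_not_detected": int(len(ann) - len(detected)),
    }
    return scores, coverage
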