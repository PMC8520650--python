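# Methods

`phosflow` implements a quantification and kinase-inference chain for
isobaric-label (iTRAQ/TMT) phosphoproteomics of the kind used to compare a
perturbed condition against a reference across duplicate labelling
experiments — e.g. interferon-driven phosphorylation changes in brain tissue
or glial cells. Because such studies hinge on PSM-level reporter statistics
that public summary tables do not preserve, the package ships a seeded
synthetic-data generator whose planted effects make every downstream stage
testable by parameter recovery.

## Quantification model

**Channel normalization.** Within each labelling experiment, reporter
intensities are scaled per channel by the *sum of all intensities* rule:
the factor for channel *c* is the grand mean of per-channel intensity sums
divided by channel *c*'s sum, computed jointly over phosphorylated and
non-phosphorylated PSMs. After scaling, all per-channel sums within an
experiment are equal (conservation is checked to 1e-9 relative tolerance).
A channel with zero total intensity is a hard error. One structural
property of this rule is worth knowing: regulation that is symmetric in
log2 space is asymmetric in linear space (2^2 = 4 vs 2^-2 = 0.25), so a
large regulated fraction inflates the case channels' sums and the
normalization then imposes a small global negative shift on all case
ratios. At realistic regulated fractions (a few percent of sites, with the
proteome tier dominating the pooled sums) the shift is ≈ −0.015 log2 units;
the recovery bias reported by the acceptance script includes it.

**Ratios.** For every PSM the log2 ratio of each channel against the
experiment's denominator (reference) channel is taken on normalized
intensities. The denominator channel's own ratio is identically zero and is
not emitted. PSMs with non-positive denominator intensity are dropped and
counted in the run log; `total_intensity` is the PSM's summed reporter
signal, the covariate for the variance model below.

**Intensity-ranked z-scores.** Reporter-ratio variance shrinks as total
reporter intensity grows. To make one significance threshold meaningful
across the intensity range, ratios are standardized within consecutive rank
bins: records of each experiment × channel are sorted by total intensity
descending and cut into bins of 300 PSMs (a trailing remainder shorter than
150 is absorbed into the previous bin; groups with fewer than 600 records
fall back to a single bin). Within a bin, z = (ratio − center)/scale with
center/scale either robust (median and 1.4826·MAD, the default — robust
estimators resist contamination of bin statistics by genuinely regulated
sites) or moment-based (mean and sd, retained because it admits an exact
oracle: with a single global bin it must equal whole-population
standardization to machine precision, which the tests assert). A
zero-spread bin yields z = 0 with a warning. An optional `per_population`
flag additionally stratifies the binning by peptide population
(non/mono/multi-phosphorylated); the default pools them, since the
reference description of the procedure is ambiguous on this point and the
generator gives all populations the same noise law.

**Aggregation.** Statistics are combined per phosphosite (protein,
residue, 1-based position), per phosphopeptide (peptide sequence + site
set), and per protein (non-phospho PSMs only). A multiply phosphorylated
PSM contributes its whole-peptide ratio to each of its localized sites —
apportionment between co-occurring sites is not identifiable from reporter
data. Within each experiment the key statistic is the median over the
key's records; experiments are combined by a weighted average with weights
equal to per-experiment PSM counts (PSM count is the only per-experiment
abundance measure available). Keys observed in a single experiment carry
that experiment's median and are flagged. The linear-scale *signed fold
change* is 2^L for combined log2FC L ≥ 0 and −2^(−L) otherwise, so that a
1.5-fold decrease reads −1.5.

**Tiered significance.** Phosphosites and phosphopeptides are significant
at |z| ≥ 1 (the 68.3% central band of a standard normal); proteins at
|z| ≥ 1.96 (95%) with at least 5 PSMs. Regulation additionally requires
|signed fold change| ≥ 1.5. All comparisons are inclusive and all
thresholds configurable. No multiple-testing correction is applied at this
stage — the calls are threshold-based by design, and the null calibration
of the z-scores (below) is what gives the thresholds their meaning.

## Protein abundance

Relative abundance is the normalized spectral abundance factor: NSAF_i =
(count_i / length_i) / Σ_j (count_j / length_j) over detected proteins,
with spectral counts taken from the non-phosphorylated population by
default (configurable). NSAF is scale-invariant in the counts and sums to
one by construction.

## Kinase inference

**Motif enrichment (substrate-centric).** Sequence windows of 15 residues
(offsets −7..+7, center lowercased, `_`-padded at protein termini) are
extracted for upregulated phosphosites and compared against a background —
all S/T/Y windows of the supplied proteome by default, or the detected
sites. The search is motif-x-like and greedy: at each step, for every
unfixed (offset, residue) pair, the one-sided binomial tail
P(X ≥ k | n_fg, q) is computed with k the foreground carriers and q the
current-background frequency; the smallest p (ties: smaller |offset|, then
alphabetical residue) is fixed if p ≤ 1e-6 and k ≥ the support floor, and
both window sets are restricted to carriers. When no pair qualifies the
motif is emitted with fold enrichment computed on the round's *starting*
foreground/background; its foreground matches are removed and the search
restarts. Runs are per center residue (s/t/y) by default. The support
floor defaults to 20 (the conventional motif-x setting for
thousands-strong foregrounds); desk-scale runs in this repository use 10,
proportional to their ~50-window foregrounds. Step p-values are checked
against an exact combinatorial sum in the tests.

**Family percentages.** Given a phosphopeptide→kinase-family link table
(here built by matching site windows against family consensus patterns —
proline-directed sP for MAPK/CDK, acidophilic s.E for CK, basophilic R..s
for CaMK, R.R..s for AKT; in a real study this table would come from a
kinase-substrate prediction resource), each family's percentage is
100 × (upregulated linked peptides) / (all detected linked peptides), plus
an `(unmatched)` row for upregulated peptides with no link.

**Activity scores (kinase-centric).** For each kinase with regulatory-site
annotations ("activity, induced" / "activity, inhibited"), the score is

    score(k) = Σ_s L_s · n_s · d_s / Σ_s n_s

over the kinase's annotated phosphosites that pass the phospho
significance call, with L_s the combined log2 fold change, n_s the site's
total PSM count and d_s = ±1 by annotated effect. The score is a
PSM-weighted, direction-signed average — bounded by the largest |L_s| and
invariant to uniform rescaling of PSM counts. Kinases whose annotated
sites are all non-significant (or undetected) are omitted and tallied in a
coverage summary, mirroring the sparse annotation coverage typical of
these analyses. The call threshold defaults to 0.53, the value the source
analysis states for a 1.5-fold activity change; note that log2(1.5) =
0.585, so the stated constant and its stated interpretation disagree
slightly — we keep 0.53 as the default and leave both the constant and the
interpretation configurable rather than silently "correcting" either.
"Significant" feeding the score means the phosphosite tier (|z| ≥ 1), and
n_s is the site's PSM count summed over experiments; both are choices the
reference description leaves open.

## Synthetic data generator

The generator emulates the observable structure of a 4-plex
duplicate-experiment study; it defines the study conditions under which
the pipeline is validated.

* **Proteome**: 1,000 i.i.d.-residue proteins of 100–500 residues drawn
  from a vertebrate-average composition (configurable; degenerate
  compositions are allowed for tests).
* **Design**: 2 experiments × 4 channels; two reference channels labelled
  WT (the first is the ratio denominator) and two case channels labelled
  IFN. Planted fold changes act on every channel whose sample label
  differs from the denominator's.
* **Sites**: 2,500 detected phosphosites at existing S/T/Y positions,
  pairwise ≥ 8 residues apart within a protein (so motif planting cannot
  collide with another selected site). 100 sites are regulated with
  log2FC magnitudes cycling through {log2 1.5, 1, 2} and alternating
  sign; 8 kinases carry 3 annotated regulated sites each at |log2FC| =
  1.2 (half annotated as induced, half as inhibited with the site sign
  flipped, so both effect labels are exercised). The regulated fraction
  (~5%) matches deep phosphoproteomes; see the normalization note above
  for why this matters.
* **Motif planting**: 60% of upregulated sites receive a proline at
  offset +1 by mutating the emitted proteome, making motif recovery a
  quantitative test.
* **Intensities**: total reporter signal is log-normal (ln-scale mean
  14.5, sd 1.2). Ratio noise sd interpolates linearly in log total
  intensity from 0.5 at the 1st percentile to 0.12 at the 99th —
  the intensity-dependent variance the rank-binned z-scoring exists to
  remove. Noise is realized as independent per-channel log2 perturbations
  of sd/√2 on *every* channel including the denominator, so
  channel-vs-denominator ratios have exactly the stated sd and mean 0 and
  no channel is structurally noise-free. Per-channel multiplicative
  loading biases (log-normal, σ = 0.15) are applied last and are
  recoverable by the normalization.
* **PSM depth**: 2 + Poisson(2) PSMs per site per experiment (~20k
  phospho-PSMs); 15% of phospho-PSMs carry a second localized site chosen
  from the same peptide (excluding other selected sites). Such secondary
  sites inherit the peptide's ratio; when the primary is regulated they
  are recorded in the ground truth as *co-regulated* and excluded from
  the null universe of the recovery metrics. A proteome tier of 900
  detected proteins at 1 + Poisson(10) non-phospho PSMs per experiment
  (~20k PSMs) anchors the normalization sums and feeds NSAF and the
  protein-level calls.
* **No-effect variant** (`null_config()`): one experiment, 5,000 sites at
  exactly one PSM each, one sample label per channel and no planted
  effects, so each phosphosite maps to exactly one ratio record and the
  site-level significant fraction measures per-record z calibration
  directly (expected 2·(1−Φ(1)) ≈ 0.317).

Everything is deterministic given the seed, down to byte-identical fixture
files.

### What the generator does not emulate

Raw spectra, chromatography, identification error and FDR, label isotope
impurity, missing channels, peptide-level interference between co-eluting
species, shared peptides between proteins, and any biological correlation
structure between sites on the same protein or pathway. Passing recovery
tests therefore demonstrate that the chain is correct and well calibrated
under its own statistical assumptions — Gaussian intensity-dependent ratio
noise and independent sites — not that it is robust to the full error
structure of real reporter data.

## Evaluation conventions

Recovery metrics live in `phosflow.evaluate` and are used by the tests,
the acceptance script and `analysis/05_report.py` alike:

* *Bias/RMSE*: mean and root-mean-square error of combined log2FC over
  planted sites.
* *Sensitivity*: fraction of planted sites with |log2FC| strictly above
  log2 1.5 that are called regulated with the planted sign. Sites planted
  exactly at the 1.5-fold boundary are excluded — an unbiased estimator
  lands on either side of the threshold with probability ~½, so their
  recovery (reported separately as `boundary_recovery`, expected ≈ 0.5)
  measures the threshold's sharpness, not the pipeline's power.
* *Specificity*: fraction of the detected null universe not called
  regulated, excluding co-regulated secondary sites.
* *Kinase direction sensitivity/specificity*: planted-direction calls over
  active kinases; over all annotated null kinases a kinase is a true
  negative when unscored or scored "unchanged".

## Numerical and degenerate-input choices

Zero-spread z bins yield z = 0 (warned); zero-denominator PSMs are dropped,
not imputed; a detected protein absent from the FASTA is a hard error, as
is a site whose residue disagrees with the proteome. Motif ties break
deterministically (p, |offset|, residue); sorting before binning breaks
intensity ties by PSM id so runs are reproducible. Threshold comparisons
are inclusive throughout. The background frequency q in the motif search
counts `_` padding as a non-match against the full window count, which is
slightly conservative for sites within 7 residues of a protein terminus.

## Problem sizes

The default study (~40k PSMs, ~2,500 sites) and the no-effect study
(~15k PSMs) are sized so that the full suite and the acceptance script
each complete in well under a minute of compute while keeping Monte-Carlo
noise on the headline metrics (null significant fraction, recovery bias)
several times smaller than their acceptance bands.
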