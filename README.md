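# phosflow

Quantification and kinase inference for isobaric-label (iTRAQ/TMT)
phosphoproteomics, written for studies that compare a perturbed condition
against a reference across duplicate labelling experiments — for example,
interferon-driven phosphorylation changes in brain tissue and glial cells.
Because the method operates on PSM-level reporter statistics that published
summary tables do not preserve, the package includes a seeded synthetic-data
generator with known ground truth, so every stage is validated by parameter
recovery rather than by re-processing deposited raw data.

## What it computes

Starting from a PSM table (one row per peptide-spectrum match with
per-channel reporter intensities), an experimental design (channel → sample,
one denominator channel per experiment) and a proteome FASTA:

1. **Channel normalization** — sum-of-intensities scaling per experiment:
   factor(c) = mean over channels of per-channel sums / sum(c), over phospho
   and non-phospho PSMs jointly.
2. **Ratios** — per PSM, log2(I_c / I_denominator) on normalized
   intensities.
3. **Intensity-ranked z-scores** — ratios standardized within consecutive
   rank bins of total reporter intensity (default 300 PSMs/bin, robust
   median/1.4826·MAD), removing the intensity dependence of ratio variance:
   z = (log2 ratio − center)/scale per bin.
4. **Aggregation** — per phosphosite, phosphopeptide and protein
   (non-phospho PSMs only): per-experiment medians combined by a
   PSM-count-weighted average; signed fold change = 2^L (L ≥ 0) or −2^(−L).
5. **Tiered calls** — significant at |z| ≥ 1 for phospho levels (68.3%
   central coverage), |z| ≥ 1.96 and ≥ 5 PSMs for proteins (95%); regulated
   additionally requires |signed FC| ≥ 1.5.
6. **NSAF** — relative protein abundance, (count/length) normalized to sum
   to one over detected proteins.
7. **Kinase inference** — (i) motif-x-style greedy binomial enrichment of
   15-residue windows of upregulated sites against a proteome background;
   (ii) kinase-family substrate percentages from a phosphopeptide→family
   link table; (iii) a regulatory-site activity score per kinase,
   score = Σ L_s·n_s·d_s / Σ n_s over significant annotated sites
   (d = +1 induced / −1 inhibited), called at |score| ≥ 0.53.

See `docs/methods.md` for the model, parameter defaults and the generator's
assumptions.

## Worked example

Generate a synthetic study and run the kinase-inference layer
(`analysis/01_simulate.py` … `05_report.py` run the same steps as a
narrative; everything below is importable from the package):

```
python analysis/01_simulate.py --seed 11
python analysis/02_quantify.py
python analysis/04_kinase_inference.py
```

The quantification step prints the per-level calls for the case (IFN)
contrast:

```
phosphosite: 4384 detected, 576 significant, 232 regulated (114 up / 118 down)
phosphopeptide: 4404 detected, 602 significant, 233 regulated (113 up / 120 down)
protein: 900 detected, 0 significant, 0 regulated (0 up / 0 down)
```

— the study plants 124 regulated phosphosites (plus sites co-regulated via
multiply phosphorylated peptides) and no protein-level changes, and the
calls mirror that. The kinase step then reports:

```
pattern  fold_enrichment  fg_matches  fg_size  bg_matches  bg_size   p_chain
     tP         6.587005          18       56         775    15882 8.692e-11
     sP         6.552546          12       39         923    19656 1.365e-07

   kinase     score  n_sites  total_psms      call
PROT00016 -1.127557        3          24 decreased
PROT00330  1.121757        3          25 increased
...
coverage: {'n_kinases_annotated': 30, 'n_kinases_with_detected_site': 26,
           'n_kinases_scored': 8, 'n_annotated_sites_not_detected': 25}
```

The proline planted at +1 in 60% of upregulated sites returns as the top
motifs (`tP`, `sP` — both matching the proline-directed MAPK/CDK consensus)
at ~6.6-fold enrichment, and all 8 kinases planted with activity shifts are
called in the correct direction while the 22 annotated null kinases are
not. `analysis/05_report.py` closes the loop with recovery metrics: planted
log2 fold changes recovered with |bias| ≈ 0.02, sensitivity 1.0 on
supra-threshold sites, specificity 1.0 on null sites, and a null-study
significant fraction of 0.317 — exactly the 2·(1−Φ(1)) band the |z| ≥ 1
threshold implies.

A `phosflow` console script exposes the same stages
(`simulate`, `quantify`, `nsaf`, `kinase`, `report`, `all`); tabular I/O is
TSV, sequences FASTA, configuration YAML.

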