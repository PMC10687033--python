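# clonotrace

Single-cell TCR repertoire analysis for paired tumour / peripheral-blood
cohorts: clonal diversity statistics, tumour–blood clonotype sharing and
longitudinal tracking, pseudotime response contrasts, and a gene-signature
survival biomarker. The package grew out of the analysis pattern used to
study checkpoint-inhibitor response in advanced hepatocellular carcinoma
(atezolizumab + bevacizumab), where clonally expanded cytotoxic CD8 T_EMRA
cells shared between tumour and blood mark responding patients — but every
stage works on any cohort with 10x-style V(D)J contig tables, a per-cell
metadata table and (optionally) bulk expression with survival follow-up.

It is written for computational immunologists who have annotated T cells
(phenotype labels, compartment, timepoint, response) and want the repertoire
arithmetic done correctly and reproducibly.

## What it computes

**Clonotypes.** Cells with a productive TCR are grouped by identical CDR3
nucleotide sequence(s) — by default the sorted set of a cell's productive
CDR3nt strings (`paired`), optionally single-linkage over shared chains
(`any_chain`). NK, γδ T and MAIT cells are excluded; clonotypes observed in
two or more patients are removed as likely invariant/artefactual.

**Repertoire statistics**, per sample and per phenotype, for clone sizes
n_1..n_S over N cells with frequencies p_i = n_i/N:

- evenness `J = −Σ p_i ln p_i / ln S` (Pielou; 0 when S = 1 by convention),
  clonality `1 − J`;
- richness `S / N`;
- Gini index of the clone-size vector, uncorrected estimator (comparable to
  R's `ineq::Gini` default);
- dominant clonotypes: ≥ 5 cells and/or ≥ 1 % of the sample repertoire.

**Sharing and tracking.** Per patient, the exact key intersection between
the tumour repertoire and pre-treatment blood, normalised four ways (by
tumour TCRs, blood TCRs, blood cells, and per tumour phenotype); tracking of
a tumour phenotype's clonotypes through week 0/3/6 blood; and the shared-TCR
weight `|A ∩ B| / |A|` between phenotypes along a trajectory.

**Pseudotime contrasts.** Two-sample Kolmogorov–Smirnov tests of responder
vs non-responder cell (or shared-cell) distributions along supplied
pseudotime, plus binned density / richness / Gini profiles. Pseudotime is an
input column; trajectories are never inferred here.

**Biomarker & survival.** Built-in 36-gene CD8 T_EMRA and 16-gene Macro
CXCL10 signatures (and their 52-gene union), scored per bulk sample with a
rank-based single-sample enrichment statistic (ssGSEA, exponent 0.25);
cohort dichotomisation by median or by maximally selected rank statistics
(the cut-point maximising the standardized log-rank statistic
`|O − E|/√V`); Kaplan–Meier curves, median survival and the log-rank test.

**Synthetic cohorts.** A seeded generator produces the full data shape —
power-law clone sizes, response-dependent sharing, phenotype-specific
expansion, clonotype persistence, three-lineage pseudotime, and bulk
expression + exponential survival with a planted biomarker-high stratum —
with exact ground truth, so every downstream stage is testable without
access-controlled patient data.

## Worked example

```sh
clonotrace simulate --seed 7 --out cohort
clonotrace ingest --contigs cohort --meta cohort/cell_meta.tsv --identity paired --out cells.tsv
clonotrace sharing --cells cells.tsv --out sharing.tsv
clonotrace trajectory --cells cells.tsv --lineage TEMRA --bins 10 --out profile.tsv
clonotrace biomarker --expr cohort/bulk_expr.tsv --surv cohort/survival.csv \
    --signature combined --cut maxstat --endpoint os --out bio
```

prints, among other things:

```
100000 cells written (0 without a productive TCR, 0 restrictive-TCR, ...)
20 patients -> sharing.tsv
TEMRA: KS D=0.3954 p=8.9e-102 (n=2488 resp, 1066 nonresp)
combined [maxstat split, os]: chi2=130.91 p=2.59e-30; medians={'high': 16.44454555, 'low': 2.351945286}
```

Reading: the simulated responders' cells sit significantly later on the
TEMRA pseudotime lineage than non-responders' (KS D = 0.40), and splitting
the 311 bulk samples at the maxstat cut-point of the combined signature
score separates overall survival sharply (median 16.4 vs 2.4 months,
log-rank p ≈ 3e-30) — recovering the structure the generator planted.
`sharing.tsv` holds one row per patient with the shared clonotype count and
the tumour-/blood-side shared proportions.

The same operations are available as library functions
(`clonotrace.baseline_sharing`, `clonotrace.ssgsea_scores`, ...) on pandas
DataFrames; see the docstrings and `docs/methods.md`.

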