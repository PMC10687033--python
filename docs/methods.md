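# Methods

This note documents the statistical definitions, the synthetic-data model,
the numerical conventions, and the open design choices made in clonotrace.

## Clonotype identity and filtering

A clonotype is the set of cells carrying identical CDR3 nucleotide
sequence(s). Two readings exist and both are implemented:

- **paired** (default): the clonotype key is the lexicographically sorted,
  `_`-joined set of a cell's productive CDR3nt strings, so two cells match
  only when their full productive chain sets are identical. This is the
  stricter, CellRanger-style convention.
- **any_chain**: single-linkage — cells merge whenever they share any one
  productive CDR3nt. The component key is its lexicographically smallest
  CDR3, which makes keys deterministic but no longer a literal chain list.

Cells with no productive contig are excluded. Cells annotated NK, γδ T or
MAIT are excluded ("restrictive TCR" phenotypes: their receptors are
invariant or non-αβ, so CDR3-based clonotype logic does not apply); the
filter is a word-boundary regex over the phenotype label, deliberately
conservative so that labels like "CD8 NKG7hi" survive. Cells with a
productive TCR but no phenotype annotation are dropped at ingest with a
logged count. Clonotype keys observed in ≥ 2 patients are removed outright —
cross-patient CDR3 identity at nucleotide level is far more likely an
invariant sequence or artefact than a shared tumour-relevant clone.

Cell QC presets: biopsy 200–6000 genes, ≥ 400 UMIs, ≤ 50 % mitochondrial
reads; pbmc identical but ≤ 15 % mitochondrial. The high biopsy
mitochondrial ceiling reflects that tightening it mostly removes tumour and
dying cells rather than lymphocytes; all four thresholds are overridable.

## Repertoire statistics

For one stratum with clone sizes n_1..n_S, N = Σ n_i, p_i = n_i/N:

- **Evenness** J = H / ln S with H = −Σ p_i ln p_i (natural log). S = 1 is
  the 0/0 corner; we define J = 0 there, the limit of a two-clone table as
  one frequency → 1, so a monoclonal sample has clonality 1.
  **Clonality** = 1 − J by construction, exactly.
- **Richness** = S/N, unique clonotypes per TCR-bearing cell. An alternative
  reading ("cells with a unique TCR" = cells whose clonotype is a
  singleton) is available via `richness(..., denominator="singleton_cells")`;
  it can exceed 1 and errors when no singleton exists, which is why it is
  not the default.
- **Gini** uses the uncorrected estimator
  G = Σ_ij |n_i − n_j| / (2 S² n̄), computed by the sorted-vector identity;
  this matches R `ineq::Gini`'s default so values are comparable across
  toolchains. The small-sample S/(S−1) correction is available behind
  `corrected=True`. Tiny negative rounding residues are clipped to 0.
- **Dominant clonotypes**: n_i ≥ 5 cells (`min_cells`), n_i/N ≥ 1 %
  (`min_fraction`), or the union (`either`, the default since the two
  published rules are used jointly). The cell threshold is ≥ 5, not > 5;
  both appear in the literature and the threshold is configurable.

All statistics are computed per sample and per sample × phenotype.

## Sharing and tracking

Shared clonotypes are the exact key intersection of a patient's tumour
repertoire with one blood sample. The "tumour-specific shared" set is always
anchored at pre-treatment blood (week 0); week 3/6 intersections are
reported separately and never feed the baseline set, so treatment-induced
blood clones cannot masquerade as baseline sharing. Multiple biopsies of one
patient are merged into one repertoire by default (flag to forbid).
Proportions are reported on four denominators: unique tumour TCRs, unique
blood TCRs, blood cells with a productive TCR (after the restrictive-TCR
exclusion — not all PBMCs), and per tumour phenotype. Cohort-level
per-phenotype shared fractions are emitted under both reductions — cells
pooled across patients and the mean of per-patient fractions — because the
two differ whenever patients contribute unequal cell numbers and the right
choice depends on the question.

Tracking collects the unique clonotype keys of one tumour phenotype and, at
each blood timepoint with a sample, reports matching cells over the
timepoint's denominator cells; timepoints without a sample are absent from
the result, never zero.

The shared-TCR weight between phenotypes A (earlier on a trajectory) and B
is |keys(A) ∩ keys(B)| / S_A — asymmetric by design.

## Pseudotime contrasts

Pseudotime is consumed, never inferred: any trajectory tool's output can be
supplied, and the downstream comparisons are what carry the conclusions.
The responder vs non-responder contrast is the two-sample Kolmogorov–Smirnov
test: D is the exact sup of |ECDF₁ − ECDF₂| over the pooled support (ECDFs
right-continuous, so ties are handled by evaluating after each distinct
value), and the p-value is the asymptotic Kolmogorov distribution at
√(n₁n₂/(n₁+n₂))·D. D is invariant under any strictly monotone transform of
pseudotime, so the contrast does not depend on the trajectory tool's time
scale.

Binned profiles split the pseudotime range into equal-width bins and compute
density (bin count / total), richness or Gini on each bin's clone-size
table; bins with < 5 cells (configurable) are reported absent rather than
zero, since a 3-cell Gini is noise. A Gaussian-kernel smoother (Silverman
bandwidth) is provided for plotting only; statistics always use raw values.

## Signature scoring and survival

The built-in signatures (36-gene CD8 T_EMRA, 16-gene Macro CXCL10, 52-gene
disjoint union) are transcribed verbatim from their source marker tables,
including the symbols "KRLK1" (almost certainly KLRK1) and "WARS" (now
WARS1) as printed; `fix_symbols=True` rewrites them through an alias table.
Fidelity to the printed lists comes first because the scores are rank-based
and silently "fixing" symbols changes which rows match a matrix.

The per-sample enrichment score follows the GSVA-style ssGSEA recipe: genes
ranked per sample (average ranks for ties), a walk from highest to lowest
expression accumulating the rank^0.25-weighted ECDF of in-set genes minus
the unweighted ECDF of out-of-set genes, score = the sum of the running
difference; with `normalize=True` (default) scores are divided by their
range across samples. Exponent 0.25 and range-normalization are that
implementation's documented defaults; both raw and normalized scores are
obtainable since the normalization flag used in any given published analysis
is rarely stated. Scores are invariant under strictly monotone per-sample
transforms of expression. Symbols are matched case-insensitively after
trimming; unmatched symbols are logged, never imputed.

Dichotomisation: median split sends ties at the median to "low" (keeps
"high" strictly above the median; deterministic and conservative for the
high group). The maxstat cut-point scans the observed scores whose split
keeps both groups within [10 %, 90 %] of the cohort and maximises the
standardized log-rank statistic |O − E|/√V; ties on the statistic resolve to
the smallest cut-point. No selection-adjusted p-value is attached to the
chosen cut-point — the improved-Bonferroni approximation is out of scope —
so downstream reports show the ordinary log-rank p of the induced split,
which is what the corresponding figures display; it is optimistic under
selection and should be read as descriptive.

Kaplan–Meier curves and medians (smallest t with S(t) ≤ 0.5; absent if
unreached) come from lifelines; the log-rank (O, E, V) machinery is
implemented in-package because the maxstat scan needs the standardized
statistic at every candidate, and is cross-checked against lifelines and a
brute-force risk-table oracle in the tests. With no censoring the KM
estimate equals the empirical survivor function exactly.

## The synthetic cohort generator

The generator emulates the *structure* of a paired-compartment
immunotherapy cohort, not its transcriptomes. Defaults describe the emulated
study: 20 patients, 60 % responders; ~500 TCR-bearing tumour cells and
~1500 blood cells per sample; clone sizes from a discrete power law
P(k) ∝ k^(−α), α = 2.5, truncated at the sample size (one interpretable
skew knob; smaller α → heavier tail → higher Gini); tumour clonotypes
seeded into week-0 blood with probability 2 % (responders) vs 0.5 %
(non-responders); blood clonotypes persisting to the next timepoint with
probability 0.8; a TEMRA-skewed phenotype mix in responders, with planted
shared clones preferentially TEMRA and blood cells mirroring the tumour
phenotype with probability 0.8; bulk: 311 samples (253 treated / 58
control labels), 2000 genes — the 52 signature genes plus filler — with
log-normal expression, the signature genes shifted by +1 log unit in a
planted 50 % "biomarker-high" stratum whose exponential survival scales
give median overall survival ≈ 12 vs ≈ 2 months (scales 17.3 / 2.9;
PFS at 0.6× those scales), 20 % uniform censoring. The 2000-gene universe
is a deliberately reduced stand-in for a genome-wide matrix; rank-based
scoring behaves the same once the out-of-set pool is large.

Clonotype CDR3 pairs embed a base-4 global counter, so keys are unique by
construction and sharing/persistence ground truth is exact set membership —
recovery tests are exact, not probabilistic. Pseudotime: naive cells draw
uniformly on [0, 0.25], effector-memory on [0.2, 0.5] (assigned a random
lineage), terminal phenotypes on [0.4, 1.0] of their own lineage; responder
TEMRA-lineage cells are warped toward the lineage end by u → √u. Blood
samples are capped at their configured size; when persistence would
overflow a sample, background (fill) clones are trimmed before planted
shared clones.

Everything is driven by one integer-seeded PCG64 generator; `write_cohort`
output is byte-identical across runs (sorted orderings, fixed float
formats). What the generator does **not** emulate: realistic V(D)J sequence
statistics, transcriptome counts/dropout, clone-size correlation between
compartments, non-exponential survival, covariate structure. Passing
recovery tests therefore demonstrates the pipeline's correctness on data
with the planted structure, not performance on real repertoires.

## Problem sizes used by the tests

The recovery suites run 20 seeded cohorts of 40 patients (1000 tumour /
2000-per-timepoint blood cells, sharing 2 % vs 0.5 %) for sharing, and 20
seeded bulk cohorts at the default 311 × 2000 size for the biomarker; these
sizes give binomial noise small enough for the sign and agreement checks
while keeping the whole suite in a few minutes. Oracle-equivalence checks
use ≥ 100 random small instances per statistic at 1e-10.

## Known limitations

- Exact-match sharing only; no similarity-based (GLIPH-style) clustering.
- No rarefaction/extrapolation diversity estimators or bootstrap CIs.
- The maxstat p-value is unadjusted for cut-point selection (see above).
- `any_chain` identity keys are component representatives, not chain lists.
- The KS p-value is asymptotic; for very small samples it is approximate
  (D itself is always exact).
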