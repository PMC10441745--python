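# Methods

## Problem and model

`exocerna` implements a competing-endogenous-RNA (ceRNA) biomarker analysis
for a two-arm case/control transcriptomic study: plasma-exosome lncRNA,
miRNA and mRNA abundances measured in first-episode schizophrenia patients
and matched healthy controls. The sponge hypothesis states that a lncRNA
sequestering a miRNA de-represses that miRNA's mRNA targets, so a genuine
lncRNA–miRNA–mRNA axis shows the miRNA regulated in the *opposite*
direction to its lncRNA and mRNA partners. The pipeline runs, in order:
differential expression, directional ceRNA network construction, partial
correlation with clinical severity, over-representation analysis, PPI hub
ranking, and single- versus combined-marker ROC diagnostics.

## Differential expression

Each feature is tested with a two-sample Student's t-test (pooled variance,
df = n1 + n2 − 2, Welch available by flag) on log2(value + pseudocount);
the fold change is the ratio of pseudocount-shifted group means. A feature
is differentially expressed when |log2FC| ≥ 1 (fold change ≥ 2 in either
direction, boundary inclusive) **and** p ≤ 0.05 (inclusive). The gate uses
raw p-values; a Benjamini–Hochberg column is emitted for transparency but
deliberately not used for filtering, matching the raw-p protocol of
small-n exploratory exosome studies. Defaults: pseudocount 1.0, testing on
the log2 scale (both exposed in config, since sequencing normalization
conventions vary and the simulator emits already-normalized abundances).

## ceRNA network construction

Per polarity (up-regulated miRNAs vs down-regulated partners, and the
mirror image) the construction runs two branches:

1. lncRNA branch: predicted lncRNA targets of the DE miRNA set ∩
   oppositely regulated DE lncRNAs; reverse-identify the miRNAs with ≥ 1
   target in that overlap (set A).
2. mRNA branch: the same against DE mRNAs (set B).

Final miRNAs = A ∩ B; lncRNA/mRNA nodes are kept only while linked to a
surviving miRNA, so the result is tripartite with no isolated nodes, all
edges present in the input target tables, and one regulation direction per
node class. Triplet axes are all lncRNA–miRNA–mRNA length-2 paths. The
construction is verified against a brute-force enumerator of all candidate
triples on random instances. Input pairs are de-duplicated with a warning;
ids are case-sensitive.

## Clinical statistics

Demographics: pooled t-tests for age and education (also from summary
statistics), Pearson chi-square for sex (continuity correction off by
default; a zero statistic gives p = 1 either way). Severity association:
Pearson partial correlation — the correlation of the least-squares
residuals of x and y on an intercept plus covariates (age, sex 0/1,
education) — with p from t = r√(df/(1−r²)), df = n − 2 − k. Computed on
log2(value + 1) over case samples only, since controls carry no PANSS
scores; one result per network feature × four PANSS scores (positive,
negative, general, total), raw p flagged at 0.05 with a BH column for
transparency. Cross-checked in tests against the recursive
partial-correlation formula, the precision-matrix identity and
`pingouin.partial_corr`.

## Enrichment and PPI hubs

Over-representation uses the hypergeometric upper tail P[X ≥ overlap] with
the expressed mRNAs as the background universe (an expression-backed
background is the defensible choice when the assay, not the genome,
defines what could have been detected). Significance is raw p < 0.05
(strict). The PPI step keeps edges with confidence score strictly > 0.4
(the STRING medium-confidence convention) between network mRNAs and ranks
connected genes by degree, ties broken lexicographically — the cytoHubba
"Degree" analogue. Other centralities are out of scope.

## ROC diagnostics

AUC is the Mann–Whitney pair-winning probability with ties credited ½
(computed via midranks), oriented case-positive with no flipping of
AUC < 0.5. Curves sweep the distinct score values and their trapezoidal
area equals the pair-counting AUC exactly. A triplet is combined by an
in-sample logistic regression on standardized log2 features, the linear
predictor serving as the composite score; this is the standard multi-marker
ROC practice and deterministic given the inputs. Perfect separation falls
back to a ridge-stabilized fit (L2, C = 1) with a logged notice.
In-sample AUC is reported by default — the protocol apparent in web-tool
multi-marker ROC reports — with leave-one-out scoring available via
`loo=True` as the honest out-of-sample alternative (in-sample combined
AUCs are optimistically biased at n = 10 + 10).

## Synthetic data

The generator emulates the study design end to end: 10 cases and 10
controls, log-normal expression (Gaussian on the log2 scale,
exponentiated — the simplest model consistent with t-testing on logs),
five planted ceRNA triplets shifted ±2 log2 units with log2-scale noise
SD 0.5 by default, guaranteed planted target edges plus Bernoulli
background edges, annotation sets with one term concentrated on the
planted mRNAs, and a high-confidence PPI clique over the planted mRNAs on
top of background edges.

Clinical scores: age ≈ N(34, 12²), education ≈ N(10.4, 3.4²) (clipped to
plausible ranges), sexes balanced within arms. PANSS subscores are
truncated normals driven by a shared latent severity factor with loadings
summing to 18 and means summing to 75.6, so totals centre near 75.6 with
SD ≈ 18.6; the total is always the exact sum of the three subscores, and
controls carry missing PANSS. Planted features couple to the *realized*
standardized PANSS total (case noise = σ·(r·z + √(1−r²)·ε)), so the
feature–severity correlation hits `clinical_link_r` without attenuation
from subscore noise; up-regulated partners couple positively, the miRNA
negatively.

What the simulator does **not** model: count noise / library-size effects
(abundances are already normalized), medication or longitudinal effects,
correlated co-expression beyond the planted axes, realistic target-network
topology (background edges are independent Bernoulli), or annotation-term
overlap structure. Passing tests therefore demonstrate the statistical
machinery is correct and well calibrated under the stated model — not that
the pipeline's biological conclusions transfer to any particular real
dataset.

## Study conditions used by the verification suite

- Structure recovery: 5 planted triplets, |log2FC| = 2, σ = 0.5,
  n = 10/10 — an effect size at which per-feature t-test power is ≈ 1, so
  all five axes should survive DE and construction in ≥ 99/100 seeds.
- Marker-ordering check: a single planted triplet at |log2FC| = 0.5,
  σ = 0.5 — chosen so single-marker AUCs fall in the 0.6–0.85 range the
  field typically reports for individual exosomal markers, leaving the
  combined axis room to improve; the combined score must beat the best
  single marker in ≥ 80% of 200 seeds.
- Null calibration: no planted effect, 2000 features; the p ≤ 0.05 gate
  criterion must fire within the binomial 99% band around 5%.
- Oracle equivalence on small instances: brute-force triple enumeration
  (≤ 30 features/class), exhaustive AUC pair counting (n ≤ 12),
  combinatorial hypergeometric enumeration (universe ≤ 15), recursive
  partial correlation (tolerance 1e-8).

Simulation sizes in the default test and acceptance runs (hundreds of
features, tens of samples) are the package's own choice of scale: large
enough for calibration statements, small enough that the whole suite runs
in well under a minute.

## Numerical notes and limitations

- Determinism: one `numpy` Generator per simulation seeded from
  `SimulationConfig.seed`; identical config ⇒ byte-identical output files.
- Zero-variance t-test inputs with equal means return (t = 0, p = 1);
  unequal means raise a degenerate-input error.
- Collinear covariates raise an error naming the offending column;
  constant x or y raises an undefined-correlation error.
- Stage re-runs from serialized TSVs reproduce results to the 6-significant-
  digit serialization precision, not byte-for-byte.
- With 10 cases, partial correlations against 4 scores across dozens of
  network features will produce chance findings; the BH column is provided
  precisely because the raw-p protocol does not control for this.
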