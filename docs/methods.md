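# Methods

## Model and assumptions

`diffconnect` treats directed differentiation as a signature-matching
problem. The transition of interest is summarized as a ranked gene list:
genes ordered by a signed two-class metric contrasting the cell state of
origin (stem cells, the first CLS class) against the target tissue (the
second class), first-minus-second. A compound instance is summarized as a
pair of gene sets — its x most up- and most downregulated genes under
treatment relative to vehicle. The working hypothesis is purely
transcriptional: a compound whose signature is *correlated* with the
contrast (up genes high, down genes low) is a candidate for pushing cells
along that transition; an anticorrelated one for opposing it. Nothing in
the score models dose, kinetics, cell-line context or off-target toxicity;
the ranked shortlist is a hypothesis generator, not a potency predictor.

## Connectivity score

The enrichment score of a query set in a ranked list of N genes is the
signed extreme of a weighted Kolmogorov–Smirnov running sum: a hit at
position i adds |m_i|^p / N_R (N_R = Σ over hits of |m|^p), a miss
subtracts 1/(N − N_hits). With the default weight exponent p = 1, hits
near the extremes of the metric count more; p = 0 recovers the classic
unweighted KS statistic of early connectivity mapping. Per instance,

    combined = (score_up − score_down) / 2,

computed unconditionally. Some connectivity-mapping implementations zero
the combined score when the two set scores share a sign; here the formula
is applied as printed and sign agreement is reported as a `same_sign` flag
instead, preserving information. Ranking granularity is the treatment
instance; optional per-compound collapse keeps each compound's extreme
|combined| instance.

Numerical choices:

- The running sum is assembled from two separately normalized cumulative
  masses (hit mass / its own total, miss count / miss total), so a query
  occupying exactly the top-k or bottom-k positions reaches ±1 *exactly*
  in floating point, not merely to rounding.
- The ES peak is the earliest position whose |deviation| is within 1e-12
  of the maximum. The slack makes the documented earliest-position
  tie-break robust when float rounding splits an exact tie between a
  positive and a negative peak of equal magnitude.
- If every hit carries a metric of exactly 0 under p = 1 (total hit
  weight 0), the walk falls back to equal hit weights rather than
  dividing by zero.
- Query genes absent from the ranked list (routine across platforms) are
  dropped and counted; only an empty overlap raises, as does a query
  covering the whole list (no miss mass).
- Ranking ties break by source id ascending; differential-metric ties
  break by gene symbol ascending. All outputs are bit-reproducible.

The empirical-null helper scores uniformly random gene sets. For a signed,
sign-symmetric metric profile (what a two-class differential contrast
produces) the null is symmetric about 0 by the mirror argument: reversing
a random set maps its walk to the negated walk. On an all-positive metric
list the weighted null is *not* centered — worth knowing if the helper is
pointed at a single-condition ranking.

## Differential ranking

Signal-to-noise is (µ_A − µ_B)/(s_A + s_B) with each class standard
deviation floored at 0.2·|class mean| (0.2 when the mean is 0) — the GSEA
floor, which keeps near-constant genes from dominating — and requires at
least 3 samples per class. The log2-ratio metric is log2(µ_A/µ_B) on
raw-scale data or the difference of means under the `pre_logged` flag
(public expression matrices ship both ways; the flag is explicit because
the two conventions silently differ by an exponent). Probe collapsing
defaults to per-sample max across a gene's probes, matching mainstream
GSEA usage; mean is available. The signature size default x = 50 follows
standard connectivity-mapping practice; useful values in the literature
vary by a factor of a few, and x is a first-class parameter everywhere.

## Target prediction

The training filter keeps compound–target pairs with affinity strictly
below 10 µM *and* assay confidence 9 or 10; affinities are canonicalized
to nM at read time so the threshold is applied in one unit. A pair is
active if any assay passes (existence criterion); pairs are deduplicated
and all counts run over unique compounds.

The classifier is a multi-target Laplacian-modified Naïve Bayes:

    score(F, t) = Σ_{f ∈ F} log[(A_tf + 1) / (T_f · P(t) + 1)]

with P(t) = n_actives/n_total. This estimator form is the standard
Laplacian-corrected relative likelihood used across the ligand-based
target-prediction literature; the smoothing pulls each ratio toward 1, so
a feature absent from training contributes exactly 0 and scores decompose
additively over features. Scores are uncalibrated log-likelihood sums:
comparable across targets for one compound, not across compounds.

Fingerprints are unfolded Morgan radius-2 sparse identifiers
(ECFP4-equivalent) by default; folding to a fixed width is available but
introduces collision artifacts in count-based training, hence not the
default. Standardization applies aromatic perception, explicit-hydrogen
removal, charge neutralization and largest-fragment selection, and is
idempotent; coordinate-cleanup steps are irrelevant to 2D features and are
omitted. `top_k` defaults to 5 predicted targets per compound.

## Disease annotation and integration

Predicted protein targets map to gene symbols via a two-column table; each
prediction then carries the inference score of its gene for the requested
disease id (0 when unlinked, flagged when unmapped). Disease scoping is a
parameter, never hardcoded. The integrated report contains one record per
scored instance — structureless compounds keep a connectivity-only record
— and the evidence layers are passed through bit-identical; the report
deliberately provides no combined meta-score, because any weighting of
connectivity vs predicted mechanism vs disease relevance is a judgment the
user should make in view of their assay.

## Synthetic data: what it emulates, what it does not

The generators produce every pipeline input with known ground truth. The
expression model is a log-normal baseline (per-gene log2 means N(7, 1.5),
Gaussian log-scale noise of 0.25 sd, 5 samples per class) with 100 of 1000
genes shifted by ±2 log2 units in the second class — a clean, realistic
effect size for a stem-cell vs tissue contrast. A 20% fraction of genes
gets a second, systematically dimmer probe to exercise max-collapse.
The compound cohort (default 100 instances) plants one mimic (up set from
the contrast's top decile, down set from the bottom decile), one reverser
(the converse) and uniform background. The bioactivity set (200 compounds,
20 targets) gives each target 3 private fingerprint features; actives carry
them plus Bernoulli(0.3) shared noise features, and 20% of triples are
constructed to fail the training filter so rejection paths are covered.

These fixtures validate the *machinery*: that planted signal is recovered,
extremes behave, counts add up. They do not emulate probe-effect
structure, correlated gene modules, batch effects, chemical-space
clustering or assay noise heterogeneity — so green tests here demonstrate
correctness of the implementation, not expected performance on real
microarray or ChEMBL-scale data. Synthetic fingerprints are abstract
integer sets precisely so the Naïve Bayes tests are independent of any
chemistry toolkit; a small curated list of real drug SMILES covers the
standardization/fingerprint path.

Problem sizes throughout (1000-gene universe, 100-instance cohorts, 20
seeds for recovery rates, 1000-permutation nulls) are the package's chosen
desk-scale defaults: large enough for stable recovery statistics, small
enough to run interactively.

## Known limitations

- GCT v1.2 only; v1.3 extras are rejected by design.
- No NES-style normalization or FDR machinery; the null helper is the
  only permutation tool.
- The Naïve Bayes is uncalibrated and trained per-target independently;
  no multi-label dependence, no probability outputs.
- `compound_ranked_profile` assumes a shared gene universe between
  treatment and vehicle; it aligns by id, not by fuzzy matching.
- The CLS reader accepts index- and name-coded assignment lines but only
  categorical (two-class downstream) phenotypes, not continuous ones.
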