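# diffconnect

Connectivity-map compound selection for directed stem-cell differentiation.

Inducing stem cells to differentiate into a target tissue (for example,
cardiomyocytes for myocardial repair) is usually driven by transcription
factors or by small molecules found ad hoc. `diffconnect` implements a
systematic, data-driven alternative: if a compound's treatment-induced gene
expression signature is strongly *correlated* with the expression change
from stem cells to the target tissue, that compound is a candidate for
pushing differentiation in that direction. The package ranks a compound
library by that transcriptional connectivity and annotates each candidate
with in-silico-predicted protein targets and disease-relevance scores, so
the shortlist comes with a mechanistic hypothesis attached.

It is a library first (import `diffconnect`), with narrative scripts in
`examples/` and a thin `diffconnect` CLI for file-based runs.

## The method

**Connectivity scoring.** The tissue contrast (e.g. embryonic stem cells vs
adult ventricular heart) is a gene list ranked by a two-class differential
metric (signal-to-noise with the GSEA variance floor, or log2 ratio of class
means), built from GCT/CLS/CHIP inputs with max-probe collapsing of probes
to gene symbols. Each compound instance contributes a *signature*: the top
and bottom x = 50 genes of its treatment-vs-vehicle log2-ratio profile
(read from GMT as `<instance>_UP` / `<instance>_DN` pairs). Each set is
scored against the ranked list with a weighted Kolmogorov–Smirnov
enrichment statistic: walking down the list, a hit at position *i* adds
|m_i|^p / N_R (N_R = Σ_hits |m|^p, default p = 1; p = 0 gives the classic
unweighted KS), a miss subtracts 1/(N − N_hits); the enrichment score ES is
the signed running-sum value of maximal absolute deviation, so ES ∈ [−1, 1].
The two set scores combine as

    combined = (score_up − score_down) / 2

and the cohort is rank-ordered by the combined score (rank_positive 1 =
strongest mimic, rank_negative 1 = strongest reverser). Leading-edge genes
— the query genes at or before the ES peak — expose which genes drive each
instance's connectivity.

**Target prediction.** Bioactivity triples are filtered to high-quality
actives (affinity < 10 µM, assay confidence 9 or 10), structures are
standardized (aromatize, remove explicit H, neutralize, largest fragment)
and featurized as unfolded ECFP4-equivalent Morgan radius-2 fingerprints.
A multi-target Laplacian-modified Naïve Bayes scores a query fingerprint F
against each target t:

    score(F, t) = Σ_{f ∈ F} log[(A_tf + 1) / (T_f · P(t) + 1)]

with A_tf the per-feature active count, T_f the global feature count and
P(t) = n_actives / n_total. Predictions can be annotated with direct
experimental support (minimum measured affinity) and with CTD-style
disease–gene inference scores via a protein→gene map.

**Integration.** One record per scored instance joins connectivity rank,
predicted targets with their disease-relevance scores, and the approved-drug
flag — side by side, with no invented meta-score.

## Worked example

`python examples/rank_compounds.py` builds a synthetic stem-cell vs tissue
contrast (1000 genes, 100 planted differential genes) and a 100-instance
cohort with one planted mimic and one planted reverser, then ranks it:

```
top 5 by positive connectivity (transcriptional mimics):
source_id  score_up  score_down  combined  rank_positive  rank_negative
INST00084  0.949474   -0.947368  0.948421              1            100
INST00032  0.425317   -0.739367  0.582342              2             99
INST00064  0.549330   -0.564968  0.557149              3             98
...
truth: top instance is a planted 'mimic', bottom is a planted 'reverser'
```

The planted mimic's up set sits in the top decile of the contrast and its
down set in the bottom decile, so its up score approaches +1, its down
score −1, and its combined score ≈ 0.95 — rank 1 of 100. Background
instances score near 0 (zero connectivity). `examples/predict_targets.py`
and `examples/integrated_report.py` walk the other two layers; the same
steps run from the shell via `diffconnect simulate | rank | predict-targets
| annotate | report`.

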