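"""Train Naive Bayes target models and predict targets for held-out actives.

Generates a synthetic bioactivity set (200 compounds, 20 targets, each
target defined by 3 private fingerprint features plus shared noise),
applies the training filter (affinity < 10 uM, confidence 9 or 10),
trains the Laplacian-modified Naive Bayes, and scores a few held-out
compounds.  Real chemistry works the same way: see the standardize /
fingerprint step at the bottom.
"""

from diffconnect import (
    EXAMPLE_DRUG_SMILES,
    FixtureSpec,
    filter_bioactivities,
    fingerprint,
    gen_bioactivity_set,
    score_targets,
    standardize,
    train,
)

spec = FixtureSpec(seed=7)
bio = gen_bioactivity_set(spec)
kept, tally = filter_bioactivities(bio.triples)
print(f"training filter kept {len(kept)}/{len(bio.triples)} triples "
      f"(rejected: {dict(tally)})")

held_out = {t.compound_id for i, t in enumerate(bio.triples)
            if (i // spec.n_targets) % 10 == 0}
training = [t for t in kept if t.compound_id not in held_out]
models = train(training, bio.fingerprints)
print(f"trained {len(models)} target models on {models.n_total} unique compounds")

correct = 0
for compound_id in sorted(held_out)[:5]:
    top = score_targets(bio.fingerprints[compound_id], models, top_k=3)
    flags = " ".join(f"{p.target_id}({p.score:.2f})" for p in top)
    truth = bio.truth[compound_id]
    hit = "OK" if top[0].target_id == truth else "MISS"
    correct += top[0].target_id == truth
    print(f"  {compound_id}: true target {truth}; predicted {flags} [{hit}]")
print("scores are sums of per-feature log likelihood ratios; higher = more "
      "likely to bind that target.")

# the same featurization on a real drug structure
smiles = EXAMPLE_DRUG_SMILES["famotidine"]
fp = fingerprint(standardize(smiles))
print(f"\nfamotidine: standardized SMILES {standardize(smiles)}")
print(f"ECFP4-equivalent fingerprint: {len(fp)} circular substructure features")
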