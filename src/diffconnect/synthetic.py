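"""Deterministic synthetic-data generators with known ground truth.

Every external input of the pipeline can be emulated here so the whole
method is testable without downloads: a two-class expression matrix with
planted differential genes (the stem-cell vs target-tissue contrast), a
cohort of compound treatment instances with planted transcriptional
mimics and reversers, and a bioactivity training set whose targets are
defined by private fingerprint features.

The expression model is a log-normal baseline — per-gene log2 means drawn
from N(7, 1.5), additive Gaussian noise on the log2 scale — with the
second phenotype class shifting the planted genes by +-``effect_size``
log2 units (half up, half down).  Synthetic fingerprints are abstract
integer feature sets, which decouples the Naive Bayes machinery from any
chemistry toolkit; a small curated list of real drug SMILES is provided
separately for standardization/fingerprint tests.

All generators are pure functions of a :class:`FixtureSpec`: the same
seed yields byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np

from .errors import ValidationError
from .io import (
    BioactivityTriple,
    CompoundRecord,
    DiseaseGeneLink,
    ExpressionProfile,
    PhenotypeAssignment,
    ProbeMap,
    write_bioactivities,
    write_chip,
    write_cls,
    write_compounds,
    write_disease_links,
    write_gct,
    write_gene_protein_map,
    write_gmt,
)
from .signatures import GeneSignature, RankedGeneList
from .targets import Fingerprint

__all__ = [
    "FixtureSpec",
    "TwoClassFixture",
    "InstanceFixture",
    "BioactivityFixture",
    "EXAMPLE_DRUG_SMILES",
    "gen_two_class_expression",
    "gen_compound_instances",
    "gen_bioactivity_set",
    "write_fixture_dir",
]

# Real drug structures for standardization/fingerprint tests, including the
# four compounds validated for cardiomyocyte differentiation and famotidine's
# comparator drugs.  SMILES are from public structure databases.
EXAMPLE_DRUG_SMILES: dict[str, str] = {
    "famotidine": "NC(=N)Nc1nc(CSCCC(=N)NS(N)(=O)=O)cs1",
    "prilocaine": "CCCNC(C)C(=O)Nc1ccccc1C",
    "bethanechol": "C[N+](C)(C)CC(C)OC(N)=O",
    "phenylbutyrate_sodium": "O=C([O-])CCCc1ccccc1.[Na+]",
    "troglitazone": "Cc1c(C)c2c(c(C)c1O)CCC(C)(COc1ccc(CC3SC(=O)NC3=O)cc1)O2",
    "resveratrol": "Oc1ccc(/C=C/c2cc(O)cc(O)c2)cc1",
    "estradiol": "C[C@]12CC[C@H]3[C@@H](CCc4cc(O)ccc43)[C@@H]1CC[C@@H]2O",
    "cimetidine": "C/C1=C(\\CSCCNC(=N/C#N)NC)N=CN1",
    "aspirin": "CC(=O)Oc1ccccc1C(=O)O",
    "caffeine": "Cn1c(=O)c2c(ncn2C)n(C)c1=O",
}


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic study conditions.

    Defaults mirror a desk-scale version of the real setting: a
    1000-gene universe, 5 microarray samples per phenotype class, 100
    differential genes shifted by 2 log2 units, a 100-instance compound
    cohort with one planted mimic and one planted reverser, and a
    bioactivity set of 200 compounds over 20 targets with 3 private
    features each.
    """

    seed: int = 0
    # expression fixture
    n_genes: int = 1000
    n_samples_per_class: int = 5
    n_de_genes: int = 100
    effect_size: float = 2.0
    noise_sd: float = 0.25
    multi_probe_fraction: float = 0.2
    unmapped_probe_fraction: float = 0.0
    class_labels: tuple[str, str] = ("STEM", "TISSUE")
    # compound-instance fixture
    n_instances: int = 100
    n_planted_mimics: int = 1
    n_planted_reversers: int = 1
    signature_size: int = 50
    # bioactivity fixture
    n_compounds: int = 200
    n_targets: int = 20
    features_per_target: int = 3
    n_noise_features: int = 30
    noise_feature_prob: float = 0.3
    filter_violation_fraction: float = 0.2

    def __post_init__(self) -> None:
        positive = {
            "n_genes": self.n_genes,
            "n_samples_per_class": self.n_samples_per_class,
            "n_de_genes": self.n_de_genes,
            "n_instances": self.n_instances,
            "signature_size": self.signature_size,
            "n_compounds": self.n_compounds,
            "n_targets": self.n_targets,
            "features_per_target": self.features_per_target,
        }
        for name, value in positive.items():
            if value < 1:
                raise ValidationError(f"{name} must be positive, got {value}")
        if self.n_de_genes > self.n_genes:
            raise ValidationError("n_de_genes cannot exceed n_genes")
        if self.n_planted_mimics + self.n_planted_reversers > self.n_instances:
            raise ValidationError("planted instances cannot exceed n_instances")
        for name in ("multi_probe_fraction", "unmapped_probe_fraction",
                     "noise_feature_prob", "filter_violation_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")


class TwoClassFixture(NamedTuple):
    profile: ExpressionProfile  # probe-level, linear-scale values
    phenotype: PhenotypeAssignment
    probe_map: ProbeMap
    de_genes_up: list[str]  # up in class A relative to class B
    de_genes_down: list[str]


class InstanceFixture(NamedTuple):
    signatures: list[GeneSignature]
    truth: dict[str, str]  # source_id -> mimic | reverser | background
    compounds: list[CompoundRecord]


class BioactivityFixture(NamedTuple):
    triples: list[BioactivityTriple]
    fingerprints: dict[str, Fingerprint]
    truth: dict[str, str]  # compound_id -> its mechanistic target
    n_violations: int  # triples constructed to fail the training filter


def gen_two_class_expression(spec: FixtureSpec) -> TwoClassFixture:
    """Two-class probe-level expression matrix with planted differential genes.

    Class B shifts ``n_de_genes`` genes by ``effect_size`` log2 units,
    half upward and half downward; in the first-minus-second-class
    contrast those appear as ``de_genes_down`` and ``de_genes_up``
    respectively.  A fraction of genes gets a second (noisier) probe and,
    optionally, some probes are left out of the CHIP map.
    """
    rng = np.random.default_rng(spec.seed)
    genes = [f"GENE{i + 1:05d}" for i in range(spec.n_genes)]
    base = rng.normal(7.0, 1.5, size=spec.n_genes)
    de_idx = rng.choice(spec.n_genes, size=spec.n_de_genes, replace=False)
    half = spec.n_de_genes // 2
    up_in_b, down_in_b = de_idx[:half], de_idx[half:]
    shift_b = np.zeros(spec.n_genes)
    shift_b[up_in_b] = spec.effect_size
    shift_b[down_in_b] = -spec.effect_size

    n = spec.n_samples_per_class
    log2_a = base[:, None] + rng.normal(0.0, spec.noise_sd, size=(spec.n_genes, n))
    log2_b = (base + shift_b)[:, None] + rng.normal(0.0, spec.noise_sd, size=(spec.n_genes, n))
    gene_log2 = np.hstack([log2_a, log2_b])

    probe_ids: list[str] = []
    mapping: dict[str, str] = {}
    rows: list[np.ndarray] = []
    n_multi = int(round(spec.multi_probe_fraction * spec.n_genes))
    multi = set(rng.choice(spec.n_genes, size=n_multi, replace=False).tolist())
    for i, gene in enumerate(genes):
        probe = f"P{i + 1:05d}_at"
        probe_ids.append(probe)
        mapping[probe] = gene
        rows.append(gene_log2[i])
        if i in multi:
            probe2 = f"P{i + 1:05d}_x_at"
            probe_ids.append(probe2)
            mapping[probe2] = gene
            # secondary probes read systematically dimmer
            atten = abs(rng.normal(0.5, 0.2))
            rows.append(gene_log2[i] - atten + rng.normal(0.0, 0.1, size=2 * n))
    n_unmapped = int(round(spec.unmapped_probe_fraction * len(probe_ids)))
    for j in range(n_unmapped):
        probe_ids.append(f"AFFX-CTRL{j + 1:03d}_at")
        rows.append(rng.normal(7.0, 1.5) + rng.normal(0.0, spec.noise_sd, size=2 * n))

    values = np.round(2.0 ** np.vstack(rows), 4)  # linear expression units
    samples = [f"{spec.class_labels[0]}_{k + 1}" for k in range(n)] + [
        f"{spec.class_labels[1]}_{k + 1}" for k in range(n)
    ]
    profile = ExpressionProfile(probe_ids, samples, values)
    phenotype = PhenotypeAssignment(list(spec.class_labels), [0] * n + [1] * n)
    probe_map = ProbeMap(mapping)
    return TwoClassFixture(
        profile=profile,
        phenotype=phenotype,
        probe_map=probe_map,
        de_genes_up=[genes[i] for i in sorted(down_in_b)],
        de_genes_down=[genes[i] for i in sorted(up_in_b)],
    )


def gen_compound_instances(
    spec: FixtureSpec, tissue_ranked: RankedGeneList
) -> InstanceFixture:
    """Compound-instance signatures with planted mimics and reversers.

    Mimics draw their up set from the top decile of the tissue list and
    their down set from the bottom decile; reversers do the converse;
    background instances draw both sets uniformly.
    """
    n_genes = len(tissue_ranked)
    x = spec.signature_size
    if n_genes < 10 * x:
        raise ValidationError(
            f"tissue list has {n_genes} genes; instance generation needs >= {10 * x}"
        )
    rng = np.random.default_rng(spec.seed + 1)
    decile = n_genes // 10
    symbols = np.asarray(tissue_ranked.gene_symbols, dtype=object)
    top, bottom = symbols[:decile], symbols[-decile:]

    labels = (
        ["mimic"] * spec.n_planted_mimics
        + ["reverser"] * spec.n_planted_reversers
        + ["background"] * (spec.n_instances - spec.n_planted_mimics - spec.n_planted_reversers)
    )
    rng.shuffle(labels)
    drug_names = list(EXAMPLE_DRUG_SMILES)
    signatures, compounds, truth = [], [], {}
    for i, label in enumerate(labels):
        source_id = f"INST{i + 1:05d}"
        if label == "mimic":
            up = rng.choice(top, size=x, replace=False)
            down = rng.choice(bottom, size=x, replace=False)
        elif label == "reverser":
            up = rng.choice(bottom, size=x, replace=False)
            down = rng.choice(top, size=x, replace=False)
        else:
            both = rng.choice(symbols, size=2 * x, replace=False)
            up, down = both[:x], both[x:]
        signatures.append(
            GeneSignature(tuple(up), tuple(down), x=x, source_id=source_id)
        )
        truth[source_id] = label
        name = drug_names[i % len(drug_names)]
        compounds.append(
            CompoundRecord(
                compound_id=f"CPD{i + 1:05d}",
                instance_id=source_id,
                structure=EXAMPLE_DRUG_SMILES[name],
                cell_line="MCF7",
                therapeutic_flag=bool(rng.integers(0, 2)),
            )
        )
    return InstanceFixture(signatures, truth, compounds)


# feature-id layout for synthetic fingerprints
_NOISE_FEATURE_BASE = 1_000_000
_PRIVATE_FEATURE_BASE = 2_000_000


def gen_bioactivity_set(spec: FixtureSpec) -> BioactivityFixture:
    """Bioactivity triples whose targets own private fingerprint features.

    Each target t owns ``features_per_target`` private feature ids; an
    active of t carries all of them plus Bernoulli-sampled shared noise
    features.  A ``filter_violation_fraction`` of the triples is made to
    fail the training filter (affinity >= 10 uM or confidence < 9) so the
    rejection paths are exercised; the truth map still records every
    compound's mechanistic target.
    """
    rng = np.random.default_rng(spec.seed + 2)
    targets = [f"T{t + 1:04d}" for t in range(spec.n_targets)]
    private = {
        t: frozenset(
            _PRIVATE_FEATURE_BASE + ti * spec.features_per_target + j
            for j in range(spec.features_per_target)
        )
        for ti, t in enumerate(targets)
    }
    noise_pool = np.arange(_NOISE_FEATURE_BASE, _NOISE_FEATURE_BASE + spec.n_noise_features)

    n_viol = int(round(spec.filter_violation_fraction * spec.n_compounds))
    violate = np.zeros(spec.n_compounds, dtype=bool)
    violate[rng.choice(spec.n_compounds, size=n_viol, replace=False)] = True

    triples, fingerprints, truth = [], {}, {}
    for i in range(spec.n_compounds):
        compound_id = f"NB{i + 1:05d}"
        target = targets[i % spec.n_targets]
        truth[compound_id] = target
        noise = noise_pool[rng.random(spec.n_noise_features) < spec.noise_feature_prob]
        fingerprints[compound_id] = Fingerprint(
            frozenset(private[target]) | frozenset(int(f) for f in noise)
        )
        if violate[i]:
            if rng.random() < 0.5:  # weak binder, good assay
                affinity = float(10.0 ** rng.uniform(4.0, 5.0))  # 10 uM - 100 uM
                confidence = int(rng.choice([9, 10]))
            else:  # potent but low-confidence assay
                affinity = float(10.0 ** rng.uniform(0.0, 3.9))
                confidence = int(rng.integers(1, 9))
        else:
            affinity = float(10.0 ** rng.uniform(0.0, 3.9))  # 1 nM - ~8 uM
            confidence = int(rng.choice([9, 10]))
        triples.append(
            BioactivityTriple(
                compound_id=compound_id,
                structure="C",  # fingerprints are supplied separately
                target_id=target,
                affinity_nM=round(affinity, 3),
                confidence_level=confidence,
            )
        )
    return BioactivityFixture(triples, fingerprints, truth, n_viol)


def write_fixture_dir(spec: FixtureSpec, outdir: str | Path) -> dict[str, str]:
    """Generate one coherent fixture set and write every pipeline input file.

    Returns a name -> path mapping of the written files.  The disease-link
    table links each synthetic target's gene to a synthetic cardiovascular
    disease id (plus a second disease for scoping tests).
    """
    from .signatures import collapse_probes, differential_ranking

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    expr = gen_two_class_expression(spec)
    collapsed, _ = collapse_probes(expr.profile, expr.probe_map)
    ranked = differential_ranking(
        collapsed, expr.phenotype, metric="log2_ratio_of_classes"
    )
    inst = gen_compound_instances(spec, ranked)
    bio = gen_bioactivity_set(spec)

    rng = np.random.default_rng(spec.seed + 3)
    gene_protein = {t: f"G_{t}" for t in sorted({tr.target_id for tr in bio.triples})}
    links = []
    for target, gene in gene_protein.items():
        links.append(
            DiseaseGeneLink(gene, "MESH:D002318", round(float(rng.uniform(1, 100)), 2))
        )
        links.append(
            DiseaseGeneLink(gene, "MESH:D009369", round(float(rng.uniform(1, 100)), 2))
        )

    paths = {
        "gct": outdir / "expression.gct",
        "cls": outdir / "phenotype.cls",
        "chip": outdir / "probes.chip",
        "gmt": outdir / "signatures.gmt",
        "compounds": outdir / "compounds.tsv",
        "bioactivities": outdir / "bioactivities.tsv",
        "disease_links": outdir / "disease_links.tsv",
        "gene_protein_map": outdir / "gene_protein_map.tsv",
        "truth": outdir / "truth.json",
    }
    write_gct(expr.profile, paths["gct"])
    write_cls(expr.phenotype, paths["cls"])
    write_chip(expr.probe_map, paths["chip"])
    write_gmt(inst.signatures, paths["gmt"])
    write_compounds(inst.compounds, paths["compounds"])
    write_bioactivities(bio.triples, paths["bioactivities"])
    write_disease_links(links, paths["disease_links"])
    write_gene_protein_map(gene_protein, paths["gene_protein_map"])
    paths["truth"].write_text(
        json.dumps(
            {
                "spec": asdict(spec),
                "de_genes_up": expr.de_genes_up,
                "de_genes_down": expr.de_genes_down,
                "instance_labels": inst.truth,
                "compound_targets": bio.truth,
                "n_filter_violations": bio.n_violations,
            },
            indent=1,
        ),
        encoding="utf-8",
    )
    return {k: str(v) for k, v in paths.items()}
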