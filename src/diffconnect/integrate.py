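"""Fuse the three evidence layers into one ranked selection report.

Each scored treatment instance gets a record joining (1) its connectivity
scores and ranks against the tissue contrast, (2) the predicted protein
targets of its compound with any direct experimental support, and (3) the
disease-relevance (inference) score of each predicted target's gene for a
chosen disease, plus the approved-drug flag.  The layers are reported
side by side — no meta-score is invented — so a user can shortlist
compounds that rank high on connectivity and whose predicted targets are
plausibly relevant to the disease or transition of interest.

Instances without a usable structure keep their connectivity record with
an empty prediction list; they are never silently dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .connectivity import ConnectivityResult
from .errors import JoinError, ValidationError
from .io import CompoundRecord, DiseaseGeneLink
from .targets import TargetPrediction

__all__ = [
    "IntegratedRecord",
    "annotate_disease_relevance",
    "build_report",
    "report_table",
    "write_report_tsv",
]


@dataclass
class IntegratedRecord:
    compound_id: str
    instance_id: str
    combined_score: float
    rank_positive: int
    rank_negative: int
    therapeutic_flag: bool
    predicted_targets: list[TargetPrediction] = field(default_factory=list)
    leading_edge_up: tuple[str, ...] = ()
    leading_edge_down: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        scores = [p.score for p in self.predicted_targets]
        if scores != sorted(scores, reverse=True):
            raise ValidationError("predicted targets must be sorted by score descending")


def annotate_disease_relevance(
    predictions: Iterable[TargetPrediction],
    links: Iterable[DiseaseGeneLink],
    gene_protein_map: Mapping[str, str],
    disease_id: str,
) -> list[TargetPrediction]:
    """Attach the disease inference score of each prediction's gene.

    ``gene_protein_map`` maps protein target ids to gene symbols.  A
    target without a gene mapping is flagged ``unmapped`` with score 0; a
    mapped gene without a link to ``disease_id`` scores 0 unflagged.
    """
    by_gene = {
        link.gene_symbol: link.inference_score
        for link in links
        if link.disease_id == disease_id
    }
    if not by_gene:
        warnings.warn(
            f"no disease-gene links found for disease {disease_id!r}; "
            "all inference scores are 0"
        )
    out = []
    for p in predictions:
        gene = gene_protein_map.get(p.target_id)
        if gene is None:
            p.unmapped = True
            p.gene_symbol = None
            p.disease_inference_score = 0.0
        else:
            p.unmapped = False
            p.gene_symbol = gene
            p.disease_inference_score = by_gene.get(gene, 0.0)
        out.append(p)
    return out


def build_report(
    connectivity_results: Sequence[ConnectivityResult],
    predictions_by_compound: Mapping[str, Sequence[TargetPrediction]],
    compounds: Sequence[CompoundRecord],
    sort_by: str = "rank_positive",
) -> list[IntegratedRecord]:
    """One integrated record per scored instance.

    Connectivity scores are carried through untouched; compounds without
    predictions (e.g. structureless records) get empty prediction lists.
    Results must already carry ranks (see ``rank_instances``).
    """
    if not connectivity_results:
        raise ValidationError("connectivity table is empty")
    if sort_by not in ("rank_positive", "rank_negative"):
        raise ValueError(f"sort_by must be rank_positive or rank_negative, got {sort_by!r}")
    by_instance: dict[str, CompoundRecord] = {}
    for rec in compounds:
        if rec.instance_id in by_instance:
            raise JoinError(f"duplicate instance id {rec.instance_id!r} in compound table")
        by_instance[rec.instance_id] = rec
    records = []
    for r in connectivity_results:
        if r.rank_positive is None or r.rank_negative is None:
            raise ValidationError(
                f"instance {r.source_id!r} has no ranks; run rank_instances first"
            )
        compound = by_instance.get(r.source_id)
        compound_id = compound.compound_id if compound else r.source_id
        preds = list(predictions_by_compound.get(compound_id, []))
        preds.sort(key=lambda p: (-p.score, p.target_id))
        records.append(
            IntegratedRecord(
                compound_id=compound_id,
                instance_id=r.source_id,
                combined_score=r.combined,
                rank_positive=r.rank_positive,
                rank_negative=r.rank_negative,
                therapeutic_flag=compound.therapeutic_flag if compound else False,
                predicted_targets=preds,
                leading_edge_up=r.leading_edge_up,
                leading_edge_down=r.leading_edge_down,
            )
        )
    records.sort(key=lambda rec: getattr(rec, sort_by))
    return records


def _targets_cell(preds: Sequence[TargetPrediction]) -> str:
    parts = []
    for p in preds:
        support = "" if p.experimental_support_nM is None else f"{p.experimental_support_nM:g}"
        disease = "" if p.disease_inference_score is None else f"{p.disease_inference_score:g}"
        parts.append(f"{p.target_id}:{p.score:.4f}:{support}:{disease}")
    return ";".join(parts)


def report_table(records: Sequence[IntegratedRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "compound_id": [r.compound_id for r in records],
            "instance_id": [r.instance_id for r in records],
            "combined_score": [r.combined_score for r in records],
            "rank_positive": [r.rank_positive for r in records],
            "rank_negative": [r.rank_negative for r in records],
            "therapeutic_flag": [r.therapeutic_flag for r in records],
            "predicted_targets": [_targets_cell(r.predicted_targets) for r in records],
            "leading_edge_up": [";".join(r.leading_edge_up) for r in records],
            "leading_edge_down": [";".join(r.leading_edge_down) for r in records],
        }
    )


def write_report_tsv(records: Sequence[IntegratedRecord], path: str | Path) -> None:
    report_table(records).to_csv(path, sep="\t", index=False)
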