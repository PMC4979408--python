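"""From expression matrices to ranked gene lists and query signatures.

The ranked list is the substrate of the connectivity walk: genes sorted by
a signed two-class metric, most upregulated first.  Two metrics are
provided — the GSEA signal-to-noise ratio (with its variance floor) and
the log2 ratio of class means — plus the treatment-vs-vehicle log2 ratio
used for per-compound instance profiles.  A query signature is the pair of
the top ``x`` and bottom ``x`` genes of such a list (``x`` = 50 by
default).

Orientation: metrics are always first-class-minus-second-class in the
order the CLS file declares them, so a "stem cells vs heart" contrast
ranks stem-cell-high genes first when stem cells are the first CLS class.
Ties are broken by gene symbol (ascending) for bitwise reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, NamedTuple

import numpy as np

from .errors import ClassCountError, SignatureSizeError, ValidationError
from .io import ExpressionProfile, PhenotypeAssignment, ProbeMap

__all__ = [
    "RankedGeneList",
    "GeneSignature",
    "CollapseResult",
    "CompoundProfileResult",
    "collapse_probes",
    "differential_ranking",
    "compound_ranked_profile",
    "extract_signature",
    "write_rnk",
    "read_rnk",
]


@dataclass
class RankedGeneList:
    """Gene symbols ordered by a signed ranking metric, best-upregulated first.

    ``metric_values`` must be non-increasing and aligned with
    ``gene_symbols``; symbols must be unique.
    """

    gene_symbols: list[str]
    metric_values: np.ndarray
    metric_name: str = "metric"

    def __post_init__(self) -> None:
        self.gene_symbols = list(self.gene_symbols)
        self.metric_values = np.asarray(self.metric_values, dtype=float)
        if len(self.gene_symbols) != len(self.metric_values):
            raise ValidationError("symbols and metric values differ in length")
        if len(set(self.gene_symbols)) != len(self.gene_symbols):
            raise ValidationError("duplicate gene symbols in ranked list")
        if np.any(np.diff(self.metric_values) > 0):
            raise ValidationError("metric values must be non-increasing")

    def __len__(self) -> int:
        return len(self.gene_symbols)

    def position_of(self, symbol: str) -> int:
        """1-based rank of a symbol."""
        return self.gene_symbols.index(symbol) + 1


@dataclass(frozen=True)
class GeneSignature:
    """Paired up/down gene sets of one compound instance (or contrast).

    ``up_genes`` and ``down_genes`` are stored in rank order and must be
    disjoint; ``x`` is the signature-size parameter they were cut at.
    """

    up_genes: tuple[str, ...]
    down_genes: tuple[str, ...]
    x: int
    source_id: str = ""

    def __post_init__(self) -> None:
        if set(self.up_genes) & set(self.down_genes):
            raise ValidationError(
                f"up and down sets of {self.source_id or 'signature'} overlap"
            )
        if len(set(self.up_genes)) != len(self.up_genes):
            raise ValidationError("duplicate genes in up set")
        if len(set(self.down_genes)) != len(self.down_genes):
            raise ValidationError("duplicate genes in down set")
        if self.x < 1:
            raise ValidationError("signature size x must be positive")

    def swapped(self) -> "GeneSignature":
        """The same signature with up and down sets exchanged."""
        return GeneSignature(self.down_genes, self.up_genes, self.x, self.source_id)


class CollapseResult(NamedTuple):
    profile: ExpressionProfile
    n_dropped: int  # probes without a symbol mapping


class CompoundProfileResult(NamedTuple):
    ranked: RankedGeneList
    n_excluded: int  # genes dropped for non-positive means (raw-scale input)


def _ordered(symbols: np.ndarray, metrics: np.ndarray, name: str) -> RankedGeneList:
    # stable order: metric descending, then symbol ascending
    order = np.lexsort((symbols, -metrics))
    return RankedGeneList(
        gene_symbols=list(symbols[order]), metric_values=metrics[order], metric_name=name
    )


def collapse_probes(
    profile: ExpressionProfile,
    probe_map: ProbeMap,
    mode: Literal["max", "mean"] = "max",
) -> CollapseResult:
    """Collapse a probe-level matrix to one row per gene symbol.

    ``mode="max"`` takes, per sample, the maximum across a gene's probes
    (the GSEA ``max_probe`` behaviour); ``mode="mean"`` averages them.
    Probes without a mapping are dropped and counted.
    """
    if mode not in ("max", "mean"):
        raise ValueError(f"unknown collapse mode {mode!r}")
    groups: dict[str, list[int]] = {}
    n_dropped = 0
    for i, probe in enumerate(profile.probe_ids):
        symbol = probe_map.get(probe)
        if symbol is None:
            n_dropped += 1
            continue
        groups.setdefault(symbol, []).append(i)
    if not groups:
        raise ValidationError("no probe maps to a gene symbol; nothing to collapse")
    symbols = sorted(groups)
    values = np.empty((len(symbols), profile.n_samples))
    for row, symbol in enumerate(symbols):
        block = profile.values[groups[symbol]]
        values[row] = block.max(axis=0) if mode == "max" else block.mean(axis=0)
    collapsed = ExpressionProfile(symbols, list(profile.sample_ids), values)
    return CollapseResult(collapsed, n_dropped)


def differential_ranking(
    profile: ExpressionProfile,
    phen: PhenotypeAssignment,
    metric: Literal["signal2noise", "log2_ratio_of_classes"] = "signal2noise",
    pre_logged: bool = False,
) -> RankedGeneList:
    """Rank genes by a two-class differential metric, class A minus class B.

    Class A is the first class the CLS file declares.  ``signal2noise`` is
    (mu_A - mu_B) / (s_A + s_B) with each class standard deviation floored
    at 0.2 x |class mean| (0.2 when the mean is zero) and requires >= 3
    samples per class.  ``log2_ratio_of_classes`` is log2(mu_A / mu_B) on
    raw-scale data, or the difference of means when ``pre_logged`` is set.
    """
    if phen.n_classes != 2:
        raise ClassCountError(
            f"differential ranking requires exactly 2 classes, got {phen.n_classes}"
        )
    if phen.n_samples != profile.n_samples:
        raise ValidationError(
            f"phenotype covers {phen.n_samples} samples, matrix has {profile.n_samples}"
        )
    a_idx = phen.samples_in_class(0)
    b_idx = phen.samples_in_class(1)
    min_per_class = 3 if metric == "signal2noise" else 1
    if len(a_idx) < min_per_class or len(b_idx) < min_per_class:
        raise ValidationError(
            f"metric {metric!r} needs >= {min_per_class} samples per class "
            f"(got {len(a_idx)} and {len(b_idx)})"
        )
    a = profile.values[:, a_idx]
    b = profile.values[:, b_idx]
    mu_a, mu_b = a.mean(axis=1), b.mean(axis=1)
    if metric == "signal2noise":
        s_a = _floored_std(a, mu_a)
        s_b = _floored_std(b, mu_b)
        values = (mu_a - mu_b) / (s_a + s_b)
    elif metric == "log2_ratio_of_classes":
        if pre_logged:
            values = mu_a - mu_b
        else:
            if np.any(mu_a <= 0) or np.any(mu_b <= 0):
                raise ValidationError(
                    "log2 ratio needs positive class means; "
                    "use pre_logged=True for log-scale matrices"
                )
            values = np.log2(mu_a / mu_b)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return _ordered(np.asarray(profile.probe_ids, dtype=object), values, metric)


def _floored_std(block: np.ndarray, means: np.ndarray) -> np.ndarray:
    """Sample standard deviation with the GSEA variance floor."""
    s = block.std(axis=1, ddof=1)
    floor = np.where(means == 0, 0.2, 0.2 * np.abs(means))
    return np.maximum(s, floor)


def compound_ranked_profile(
    treatment: ExpressionProfile,
    vehicle: ExpressionProfile,
    pre_logged: bool = False,
) -> CompoundProfileResult:
    """Rank genes of one compound instance by log2(treatment / vehicle).

    Both profiles must cover the same gene universe (row ids).  On
    raw-scale data, genes whose treatment or vehicle mean is non-positive
    are excluded and counted; on pre-logged data the metric is the
    difference of means and nothing is excluded.
    """
    if set(treatment.probe_ids) != set(vehicle.probe_ids):
        raise ValidationError("treatment and vehicle cover different gene universes")
    order = [vehicle.probe_ids.index(g) for g in treatment.probe_ids]
    mu_t = treatment.values.mean(axis=1)
    mu_v = vehicle.values.mean(axis=1)[order]
    symbols = np.asarray(treatment.probe_ids, dtype=object)
    if pre_logged:
        metric = mu_t - mu_v
        n_excluded = 0
    else:
        keep = (mu_t > 0) & (mu_v > 0)
        n_excluded = int((~keep).sum())
        symbols = symbols[keep]
        metric = np.log2(mu_t[keep] / mu_v[keep])
        if symbols.size == 0:
            raise ValidationError("no gene has positive treatment and vehicle means")
    ranked = _ordered(symbols, metric, "log2_ratio_treatment_vs_vehicle")
    return CompoundProfileResult(ranked, n_excluded)


def extract_signature(
    ranked: RankedGeneList, x: int = 50, source_id: str = ""
) -> GeneSignature:
    """Cut the top ``x`` and bottom ``x`` genes of a ranked list.

    The default x = 50 follows common connectivity-mapping practice.  The
    list must hold at least 2x genes so the two sets cannot overlap.
    """
    if x < 1:
        raise SignatureSizeError("signature size x must be >= 1")
    if len(ranked) < 2 * x:
        raise SignatureSizeError(
            f"ranked list has {len(ranked)} genes; signature size {x} "
            f"requires at least {2 * x}"
        )
    return GeneSignature(
        up_genes=tuple(ranked.gene_symbols[:x]),
        down_genes=tuple(ranked.gene_symbols[-x:]),
        x=x,
        source_id=source_id,
    )


def write_rnk(ranked: RankedGeneList, path: str | Path) -> None:
    """Export as a two-column RNK-style TSV (symbol, metric)."""
    lines = [f"{g}\t{repr(float(v))}" for g, v in zip(ranked.gene_symbols, ranked.metric_values)]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_rnk(path: str | Path, metric_name: str = "metric") -> RankedGeneList:
    symbols, values = [], []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        g, v = line.split("\t")
        symbols.append(g)
        values.append(float(v))
    return RankedGeneList(symbols, np.asarray(values), metric_name)
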