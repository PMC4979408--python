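"""Weighted Kolmogorov-Smirnov connectivity scoring.

The enrichment score (ES) walks down a ranked gene list and accumulates a
running sum: hitting a query gene adds a weight proportional to
|metric|^p (p = 1 by default, p = 0 recovers the classic unweighted KS
statistic used by the original Connectivity Map), missing one subtracts
1/(N - N_hits).  The ES is the signed running-sum value at the point of
maximal absolute deviation from zero, so it lies in [-1, 1]: +1 when the
query sits entirely at the top of the list, -1 entirely at the bottom, and
near 0 for an uncorrelated query.

A compound instance contributes an up set and a down set; their two scores
are combined as

    combined = (score_up - score_down) / 2

so a compound whose up genes sit high in the tissue contrast and whose
down genes sit low (a transcriptional mimic of the transition) scores near
+1, and a reverser scores near -1.  The combined score is computed by this
formula unconditionally; score pairs that share a sign are flagged
(``same_sign``) rather than zeroed, unlike the original CMap convention.

Query genes absent from the ranked list are dropped and counted
(cross-platform symbol gaps are routine); only an empty overlap is an
error.  Ties between equal-|deviation| peaks resolve to the earliest
position, and instance ranking breaks score ties by source id, so all
outputs are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateQueryError, EmptyOverlapError, ValidationError
from .signatures import GeneSignature, RankedGeneList

__all__ = [
    "EnrichmentResult",
    "ConnectivityResult",
    "enrichment_score",
    "leading_edge",
    "connectivity",
    "rank_instances",
    "results_table",
    "write_scores_tsv",
    "null_distribution",
]


@dataclass(frozen=True)
class EnrichmentResult:
    """Outcome of one running-sum walk."""

    es: float  # signed extreme of the running sum, in [-1, 1]
    peak_position: int  # 1-based position of the extreme deviation
    hits_found: int  # query genes present in the ranked list
    hits_missing: int  # query genes absent from it

    def __post_init__(self) -> None:
        if not -1.0 <= self.es <= 1.0:
            raise ValidationError(f"enrichment score {self.es} outside [-1, 1]")


@dataclass(frozen=True)
class ConnectivityResult:
    """Up/down/combined connectivity of one instance against a tissue list."""

    source_id: str
    score_up: float
    score_down: float
    combined: float
    leading_edge_up: tuple[str, ...]
    leading_edge_down: tuple[str, ...]
    n_hits_up: int
    n_hits_down: int
    n_missing_up: int = 0
    n_missing_down: int = 0
    same_sign: bool = False  # score_up and score_down agree in sign
    rank_positive: int | None = None
    rank_negative: int | None = None


def _walk(ranked: RankedGeneList, query: Iterable[str], p: int) -> tuple[np.ndarray, int, int]:
    """Running sum of the weighted KS walk; returns (running, n_hits, n_missing)."""
    if p not in (0, 1):
        raise ValueError(f"weight exponent p must be 0 or 1, got {p}")
    query_set = set(query)
    n = len(ranked)
    if n == 0:
        raise ValidationError("empty ranked list")
    hit = np.fromiter((g in query_set for g in ranked.gene_symbols), dtype=bool, count=n)
    n_hits = int(hit.sum())
    n_missing = len(query_set) - n_hits
    if n_hits == 0:
        raise EmptyOverlapError("query shares no genes with the ranked list")
    if n_hits == n:
        raise DegenerateQueryError("query covers the entire ranked list; no misses")
    weights = np.where(hit, np.abs(ranked.metric_values) ** p if p else 1.0, 0.0)
    hit_cum = np.cumsum(weights)
    if hit_cum[-1] == 0:
        # all hit metrics are exactly zero: fall back to equal weights
        hit_cum = np.cumsum(hit.astype(float))
    # hit and miss cumulative masses are normalized separately (each by its
    # own cumulative total) so a query at either extreme reaches exactly +-1
    hit_mass = hit_cum / hit_cum[-1]
    miss_mass = np.cumsum(~hit).astype(float) / (n - n_hits)
    return hit_mass - miss_mass, n_hits, n_missing


def enrichment_score(
    ranked: RankedGeneList, query: Iterable[str], p: int = 1
) -> EnrichmentResult:
    """Weighted KS enrichment of a gene set in a ranked list.

    Parameters
    ----------
    ranked
        Ranked gene list (most upregulated first) with signed metrics.
    query
        Gene symbols to test; genes absent from ``ranked`` are dropped and
        reported in ``hits_missing``.
    p
        Weight exponent: 1 weighs each hit by |metric| (default),
        0 gives the classic unweighted KS statistic.
    """
    running, n_hits, n_missing = _walk(ranked, query, p)
    # earliest maximal |deviation|; the 1e-12 slack keeps the tie-break at
    # the earliest position even when float rounding splits an exact tie
    deviation = np.abs(running)
    peak = int(np.argmax(deviation >= deviation.max() - 1e-12))
    return EnrichmentResult(
        es=float(running[peak]),
        peak_position=peak + 1,
        hits_found=n_hits,
        hits_missing=n_missing,
    )


def leading_edge(ranked: RankedGeneList, query: Iterable[str], p: int = 1) -> list[str]:
    """Query genes driving the enrichment signal.

    For a non-negative ES these are the query genes at or before the
    running-sum peak; for a negative ES, those at or after it.  Returned
    in ranked-list order.
    """
    query_set = set(query)
    result = enrichment_score(ranked, query_set, p)
    peak = result.peak_position - 1
    if result.es >= 0:
        return [g for g in ranked.gene_symbols[: peak + 1] if g in query_set]
    return [g for g in ranked.gene_symbols[peak:] if g in query_set]


def connectivity(
    tissue_ranked: RankedGeneList, sig: GeneSignature, p: int = 1
) -> ConnectivityResult:
    """Score one instance signature against the tissue ranked list."""
    try:
        up = enrichment_score(tissue_ranked, sig.up_genes, p)
    except (EmptyOverlapError, DegenerateQueryError) as exc:
        raise type(exc)(f"up set of {sig.source_id or 'signature'}: {exc}") from exc
    try:
        down = enrichment_score(tissue_ranked, sig.down_genes, p)
    except (EmptyOverlapError, DegenerateQueryError) as exc:
        raise type(exc)(f"down set of {sig.source_id or 'signature'}: {exc}") from exc
    combined = (up.es - down.es) / 2.0
    return ConnectivityResult(
        source_id=sig.source_id,
        score_up=up.es,
        score_down=down.es,
        combined=combined,
        leading_edge_up=tuple(leading_edge(tissue_ranked, sig.up_genes, p)),
        leading_edge_down=tuple(leading_edge(tissue_ranked, sig.down_genes, p)),
        n_hits_up=up.hits_found,
        n_hits_down=down.hits_found,
        n_missing_up=up.hits_missing,
        n_missing_down=down.hits_missing,
        same_sign=(up.es > 0) == (down.es > 0) and up.es != 0 and down.es != 0,
    )


def rank_instances(
    results: Sequence[ConnectivityResult], per_compound: dict[str, str] | None = None
) -> list[ConnectivityResult]:
    """Assign positive and negative ranks by combined score.

    ``rank_positive`` = 1 for the largest combined score, ``rank_negative``
    = 1 for the smallest; ties are ordered by source id.  Returns new
    result objects sorted by ``rank_positive``.  When ``per_compound``
    (instance id -> compound id) is given, instances are first collapsed
    to the per-compound extreme combined score and only those
    representatives are ranked.
    """
    if not results:
        raise ValidationError("no connectivity results to rank")
    pool = list(results)
    if per_compound is not None:
        best: dict[str, ConnectivityResult] = {}
        for r in pool:
            c = per_compound.get(r.source_id, r.source_id)
            if c not in best or abs(r.combined) > abs(best[c].combined):
                best[c] = r
        pool = list(best.values())
    pos = sorted(pool, key=lambda r: (-r.combined, r.source_id))
    neg = sorted(pool, key=lambda r: (r.combined, r.source_id))
    neg_rank = {r.source_id: i + 1 for i, r in enumerate(neg)}
    return [
        replace(r, rank_positive=i + 1, rank_negative=neg_rank[r.source_id])
        for i, r in enumerate(pos)
    ]


def results_table(results: Sequence[ConnectivityResult]) -> pd.DataFrame:
    """Tabulate connectivity results (one row per instance)."""
    return pd.DataFrame(
        {
            "source_id": [r.source_id for r in results],
            "score_up": [r.score_up for r in results],
            "score_down": [r.score_down for r in results],
            "combined": [r.combined for r in results],
            "rank_positive": [r.rank_positive for r in results],
            "rank_negative": [r.rank_negative for r in results],
            "n_hits_up": [r.n_hits_up for r in results],
            "n_hits_down": [r.n_hits_down for r in results],
            "same_sign": [r.same_sign for r in results],
            "leading_edge_up": [";".join(r.leading_edge_up) for r in results],
            "leading_edge_down": [";".join(r.leading_edge_down) for r in results],
        }
    )


def write_scores_tsv(results: Sequence[ConnectivityResult], path: str | Path) -> None:
    results_table(results).to_csv(path, sep="\t", index=False)


def read_scores_tsv(path: str | Path) -> list[ConnectivityResult]:
    """Read back a scores TSV written by :func:`write_scores_tsv`."""
    df = pd.read_csv(path, sep="\t", dtype={"source_id": str}, keep_default_na=False)
    results = []
    for row in df.itertuples(index=False):
        results.append(
            ConnectivityResult(
                source_id=row.source_id,
                score_up=float(row.score_up),
                score_down=float(row.score_down),
                combined=float(row.combined),
                leading_edge_up=tuple(str(row.leading_edge_up).split(";")) if row.leading_edge_up else (),
                leading_edge_down=tuple(str(row.leading_edge_down).split(";")) if row.leading_edge_down else (),
                n_hits_up=int(row.n_hits_up),
                n_hits_down=int(row.n_hits_down),
                same_sign=str(row.same_sign) in ("True", "true", "1"),
                rank_positive=int(row.rank_positive) if str(row.rank_positive) not in ("", "None") else None,
                rank_negative=int(row.rank_negative) if str(row.rank_negative) not in ("", "None") else None,
            )
        )
    return results


def null_distribution(
    ranked: RankedGeneList, set_size: int, n_perm: int, seed: int, p: int = 1
) -> np.ndarray:
    """Enrichment scores of uniformly random gene sets (empirical null).

    Draws ``n_perm`` sets of ``set_size`` genes without replacement from
    the ranked list and scores each; reproducible for a fixed seed.
    """
    n = len(ranked)
    if set_size >= n:
        raise ValidationError(f"set_size {set_size} must be smaller than the list ({n})")
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    symbols = np.asarray(ranked.gene_symbols, dtype=object)
    scores = np.empty(n_perm)
    for i in range(n_perm):
        picked = rng.choice(symbols, size=set_size, replace=False)
        scores[i] = enrichment_score(ranked, picked, p).es
    return scores
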