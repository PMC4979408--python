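"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from diffconnect import RankedGeneList

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def es_running_sum_oracle(symbols, metrics, query, p=1):
    """Brute-force weighted-KS enrichment: recompute the prefix sum from
    scratch at every position.  Independent of the streaming implementation.

    Returns (es, peak_position_1based).
    """
    query = set(query)
    n = len(symbols)
    hits = [i for i, g in enumerate(symbols) if g in query]
    n_hits = len(hits)
    assert 0 < n_hits < n
    nr = 0.0
    for i in hits:
        nr += abs(metrics[i]) ** p if p else 1.0
    prefix = []
    for k in range(1, n + 1):
        s = 0.0
        for i in range(k):
            if symbols[i] in query:
                s += (abs(metrics[i]) ** p if p else 1.0) / nr
            else:
                s -= 1.0 / (n - n_hits)
        prefix.append(s)
    # earliest position within float noise of the maximal |deviation|
    best_abs = max(abs(s) for s in prefix)
    for k, s in enumerate(prefix, start=1):
        if abs(s) >= best_abs - 1e-12:
            return s, k
    raise AssertionError("unreachable")


@pytest.fixture
def es_oracle():
    return es_running_sum_oracle


def make_ranked(n: int, seed: int = 0, signed: bool = True) -> RankedGeneList:
    """A ranked list with a realistic signed (sign-symmetric) metric profile."""
    rng = np.random.default_rng(seed)
    z = np.sort(rng.normal(size=n))[::-1]
    metrics = (z - z[::-1]) / 2.0 if signed else np.abs(z) + 0.01
    return RankedGeneList([f"G{i:05d}" for i in range(n)], metrics)


@pytest.fixture
def ranked_factory():
    return make_ranked


@pytest.fixture
def ranked1000():
    return make_ranked(1000, seed=42)
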