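"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cheimp import SCHEMA_COLUMNS


def brute_force_weighted_quantile(values, weights, q):
    """Sequential sort-and-accumulate weighted ECDF inverse.

    Independent of the pipeline implementation: plain Python running
    sums over the sorted pairs, returning the first value whose
    cumulative weight reaches ``q`` of the total.
    """
    pairs = sorted(zip(values, weights), key=lambda p: p[0])
    total = 0.0
    for _, w in pairs:
        total += w
    target = q * total
    acc = 0.0
    for v, w in pairs:
        acc += w
        if acc >= target:
            return v
    return pairs[-1][0]


def make_frame(rows):
    """Build a survey frame from (id, A, K, f_who, f_wb, x, oop, w) tuples."""
    return pd.DataFrame(rows, columns=list(SCHEMA_COLUMNS))


@pytest.fixture
def toy_three_households():
    """Three single-adult households with food shares 0.2 / 0.5 / 0.8.

    Under the inclusive 45th-55th percentile band only the middle
    household is selected, giving a poverty line of exactly 50.
    """
    return make_frame(
        [
            ("h1", 1, 0, 20.0, 20.0, 100.0, 0.0, 1.0),
            ("h2", 1, 0, 50.0, 50.0, 100.0, 0.0, 1.0),
            ("h3", 1, 0, 80.0, 80.0, 100.0, 0.0, 1.0),
        ]
    )


@pytest.fixture
def random_frame_factory():
    """Factory for small random-but-valid survey frames."""

    def _make(n=200, seed=0, oop_zero_prob=0.4):
        rng = np.random.default_rng(seed)
        adults = 1 + rng.poisson(1.5, n)
        kids = rng.poisson(1.2, n)
        total = np.exp(rng.normal(7.5, 0.8, n))
        wf = np.clip(rng.beta(3, 5, n), 0.02, 0.95)
        food_wb = wf * total
        food_who = food_wb * rng.uniform(0.7, 1.0, n)
        oop = np.where(
            rng.random(n) < oop_zero_prob,
            0.0,
            rng.uniform(0, 0.9, n) * (total - food_wb),
        )
        weight = np.exp(rng.normal(0, 0.4, n))
        return make_frame(
            list(
                zip(
                    [f"r{i}" for i in range(n)],
                    adults,
                    kids,
                    food_who,
                    food_wb,
                    total,
                    oop,
                    weight,
                )
            )
        )

    return _make
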