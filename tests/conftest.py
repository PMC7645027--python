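"""Shared fixtures and independent oracles for the test suite.

The oracles deliberately re-derive the quantities with literal per-cell
loops and pairwise enumeration, independent of the vectorized paths they
check.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest

import scxtalk as sx
from scxtalk.synthetic import PlantedPair


# ---------------------------------------------------------------- oracles


def oracle_top_set(values: np.ndarray, t: float) -> set[int]:
    """Top-t gene indices: descending value, ascending index tie-break."""
    N = len(values)
    k = int(np.floor(t * N))
    order = sorted(range(N), key=lambda i: (-values[i], i))
    return set(order[:k])


def oracle_score(
    X: np.ndarray,
    cols_a: list[int],
    cols_b: list[int],
    partner_a: list[int],
    partner_b: list[int],
    t: float,
    mode: str,
) -> tuple[float, float]:
    """Literal per-cell double loop over the score definition."""
    term_a = 0.0
    for c in cols_a:
        top = oracle_top_set(X[:, c], t)
        il = all(g in top for g in partner_a)
        ir = all(g in top for g in partner_b)
        term_a += (il and not ir) if mode == "paracrine" else il
    term_b = 0.0
    for c in cols_b:
        top = oracle_top_set(X[:, c], t)
        il = all(g in top for g in partner_a)
        ir = all(g in top for g in partner_b)
        term_b += (ir and not il) if mode == "paracrine" else ir
    return term_a / len(cols_a), term_b / len(cols_b)


def oracle_nes(values: np.ndarray, in_mask: np.ndarray) -> float:
    """Brute-force pairwise probability P(in-set gene > out-set gene)."""
    inside = values[in_mask]
    outside = values[~in_mask]
    wins = 0.0
    for x in inside:
        for y in outside:
            if x > y:
                wins += 1.0
            elif x == y:
                wins += 0.5
    return wins / (len(inside) * len(outside))


def oracle_binom_upper_tail(k: int, n: int, p: float) -> float:
    """Exhaustive enumeration of all 2^n Bernoulli outcomes (n <= 12)."""
    from itertools import product

    total = 0.0
    for outcome in product((0, 1), repeat=n):
        if sum(outcome) >= k:
            prob = 1.0
            for b in outcome:
                prob *= p if b else 1 - p
            total += prob
    return total


# --------------------------------------------------------------- fixtures


@pytest.fixture(scope="session")
def bundled_table():
    return sx.bundled_interaction_table()


@pytest.fixture(scope="session")
def bundled_sigs():
    return sx.bundled_signatures()


@pytest.fixture(scope="session")
def default_cfg():
    return sx.default_config(seed=101)


@pytest.fixture(scope="session")
def planted_dataset(default_cfg):
    """Default-scale dataset with one planted paracrine pair (f 0.8 / 0.4)."""
    pair = sx.InteractionPair(("VCAN",), ("TLR2",))
    cfg = dataclasses.replace(
        default_cfg,
        planted_pairs=(PlantedPair(pair, "tumor", "myeloid", 0.8, 0.4),),
    )
    matrix, assignment, truth = sx.generate_dataset(cfg)
    return matrix, assignment, truth, pair


@pytest.fixture()
def tiny_matrix():
    """5 genes x 4 cells with a strict descending profile in each cell."""
    genes = np.array(["g1", "g2", "g3", "g4", "g5"], dtype=object)
    cells = np.array(["c1", "c2", "c3", "c4"], dtype=object)
    X = np.tile(np.array([5.0, 4.0, 3.0, 2.0, 1.0])[:, None], (1, 4))
    return sx.ExpressionMatrix(genes, cells, X)


def random_instance(rng: np.random.Generator):
    """A random small matrix plus a random pair and cluster split."""
    N = int(rng.integers(10, 51))
    C = int(rng.integers(4, 21))
    X = rng.random((N, C)) * 10
    if rng.random() < 0.3:  # inject ties / dropout-style zeros
        X[rng.random((N, C)) < 0.3] = 0.0
    split = int(rng.integers(1, C))
    cols_a = list(range(split))
    cols_b = list(range(split, C))
    size_a = int(rng.integers(1, 3))
    size_b = int(rng.integers(1, 3))
    idx = rng.choice(N, size=size_a + size_b, replace=False)
    return X, cols_a, cols_b, list(idx[:size_a]), list(idx[size_a:])
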