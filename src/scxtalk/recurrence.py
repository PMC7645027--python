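"""Cross-patient recurrence of active ligand-receptor pairs.

The number of patients in which a pair passes the per-patient significance
filter is tested against a binomial null.  The null per-patient activation
probability is estimated empirically: a pooled synthetic patient is built
by sampling 500 malignant and 500 non-malignant cells, the interaction
table is row-shuffled many times (pairing each ligand with a random
receptor from the table, which preserves the expression distribution of
the genes involved), and the full score + bootstrap + filter pipeline is
run on each shuffled table.  The mean fraction of active pairs is the
binomial ``p``; observing a pair in k of n patients is then scored by the
exact upper tail P(X >= k), X ~ Binomial(n, p).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .matrixio import ClusterAssignment, ExpressionMatrix
from .resources import InteractionPair, InteractionTable, restrict_pairs
from .scoring import (
    bootstrap_null_scores,
    filter_significant,
    pooled_empirical_pvalues,
    score_table,
    top_set_size,
)

logger = logging.getLogger(__name__)

__all__ = [
    "NullRateEstimate",
    "shuffle_table",
    "estimate_null_rate",
    "recurrence_pvalue",
    "aggregate_patients",
]


@dataclass
class NullRateEstimate:
    """Estimated probability that a random pair is called active in one patient."""

    p_null: float
    compartment: str | None = None
    n_cells_per_side: int = 500
    n_tables: int = 100
    seed: int | None = None
    active_counts: list[int] | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.p_null <= 1:
            raise ValueError("p_null must be in [0, 1]")
        if self.n_tables < 1:
            raise ValueError("n_tables must be >= 1")


def shuffle_table(table: InteractionTable, seed=None) -> InteractionTable:
    """Row-shuffle: permute the receptor column against the ligand column.

    The multisets of ligand and of receptor partner tokens are unchanged;
    only the pairing is randomized (derangement not enforced).
    """
    if len(table) < 2:
        raise ValueError("need at least 2 pairs to shuffle")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm = rng.permutation(len(table))
    pairs = [
        InteractionPair(
            partner_a=table.pairs[i].partner_a,
            partner_b=table.pairs[int(perm[i])].partner_b,
            family=table.pairs[i].family,
            source="shuffled",
        )
        for i in range(len(table))
    ]
    return InteractionTable(pairs, allow_duplicates=True)


def _sample_side(cells: Sequence, n: int, rng: np.random.Generator) -> list:
    cells = list(cells)
    if len(cells) >= n:
        return list(rng.choice(cells, size=n, replace=False))
    warnings.warn(
        f"only {len(cells)} cells available for a side of {n}; sampling with replacement"
    )
    return list(rng.choice(cells, size=n, replace=True))


def estimate_null_rate(
    matrix: ExpressionMatrix,
    malignant_cells: Sequence,
    nonmalignant_cells: Sequence,
    table: InteractionTable,
    t: float = 0.20,
    mode: str = "paracrine",
    n_iter: int = 1000,
    p_max: float = 0.05,
    s_min: float = 0.50,
    n_tables: int = 100,
    n_cells_per_side: int = 500,
    seed: int | None = None,
    compartment: str | None = None,
    share_null: bool = True,
) -> NullRateEstimate:
    """Estimate the per-patient null activation rate on a pooled synthetic
    patient by rescoring row-shuffled interaction tables.

    ``share_null=True`` (default) draws the pooled bootstrap null
    distribution once for the synthetic patient and reuses it for every
    shuffled table — the null redraws top sets uniformly at random, so it
    does not depend on which genes a shuffled table names.
    """
    if len(malignant_cells) == 0 or len(nonmalignant_cells) == 0:
        raise ValueError("both compartments must be non-empty")
    rng = np.random.default_rng(seed)
    side_a = _sample_side(malignant_cells, n_cells_per_side, rng)
    side_b = _sample_side(nonmalignant_cells, n_cells_per_side, rng)
    # barcodes may repeat when sampling with replacement; relabel uniquely
    cell_pos_src = {c: i for i, c in enumerate(matrix.cells)}
    cols = [cell_pos_src[c] for c in side_a + side_b]
    pooled = ExpressionMatrix(
        matrix.genes.copy(),
        np.array([f"synth{i}|{c}" for i, c in enumerate(side_a + side_b)], dtype=object),
        matrix.values[:, cols],
    )
    labels = pd.Series(
        ["malignant"] * len(side_a) + ["microenvironment"] * len(side_b),
        index=pooled.cells,
    )
    clusters = ClusterAssignment(labels, "malignant", "microenvironment")

    restricted, _ = restrict_pairs(table, pooled.genes)
    if len(restricted) < 2:
        raise ValueError("fewer than 2 scoreable pairs on the pooled patient")
    cell_pos = {c: i for i, c in enumerate(pooled.cells)}
    cols_a = np.array([cell_pos[c] for c in clusters.member_cells("malignant")])
    cols_b = np.array([cell_pos[c] for c in clusters.member_cells("microenvironment")])
    k = top_set_size(pooled.n_genes, t)

    shared_null = None
    if share_null:
        shared_null = bootstrap_null_scores(
            pooled.n_genes, pooled.n_cells, k, restricted, pooled.gene_index(),
            cols_a, cols_b, mode, n_iter, rng,
        )

    active_counts: list[int] = []
    for _ in range(n_tables):
        shuffled = shuffle_table(restricted, rng)
        results = score_table(pooled, clusters, shuffled, t=t, mode=mode)
        null = shared_null
        if null is None:
            null = bootstrap_null_scores(
                pooled.n_genes, pooled.n_cells, k, shuffled, pooled.gene_index(),
                cols_a, cols_b, mode, n_iter, rng,
            )
        results = results.copy()
        results["p_value"] = pooled_empirical_pvalues(results["score"].to_numpy(), null)
        active = filter_significant(results, p_max=p_max, s_min=s_min)
        active_counts.append(len(active))

    p_null = float(np.mean(active_counts) / len(restricted))
    logger.info(
        "null activation rate %.4g over %d shuffled tables of %d pairs",
        p_null, n_tables, len(restricted),
    )
    return NullRateEstimate(
        p_null=p_null, compartment=compartment, n_cells_per_side=n_cells_per_side,
        n_tables=n_tables, seed=seed, active_counts=active_counts,
    )


def recurrence_pvalue(k: int, n: int, p_null: float) -> float:
    """Exact binomial upper tail P(X >= k) with X ~ Binomial(n, p_null)."""
    if not 0 <= k <= n:
        raise ValueError("k must satisfy 0 <= k <= n")
    if not 0 < p_null < 1:
        raise ValueError("p_null must lie strictly between 0 and 1")
    if k == 0:
        return 1.0
    return float(scipy.stats.binomtest(k, n, p_null, alternative="greater").pvalue)


def aggregate_patients(
    per_patient: Mapping[str, pd.DataFrame],
    p_null: float,
    min_patients: int = 4,
    n_patients: int | None = None,
) -> pd.DataFrame:
    """Cross-patient recurrence table from per-patient filtered results.

    ``per_patient`` maps patient id to that patient's filtered score table
    (rows = active pairs).  ``n_patients`` defaults to the number of result
    sets supplied; pass the size of the tested cohort when some patients
    produced empty tables that are not in the mapping.

    Returns pairs present in at least ``min_patients`` patients with their
    patient count k, cohort size n and exact binomial upper-tail p-value,
    sorted by k descending then p ascending.
    """
    if len(per_patient) == 0:
        raise ValueError("at least one patient result set is required")
    n = n_patients if n_patients is not None else len(per_patient)
    if n < len(per_patient):
        raise ValueError("n_patients smaller than the number of result sets")
    counts: dict[str, int] = {}
    for patient, df in per_patient.items():
        if "pair_id" not in df.columns:
            raise ValueError(f"patient {patient!r}: results lack a pair_id column")
        for pid in set(df["pair_id"]):
            counts[pid] = counts.get(pid, 0) + 1
    rows = [
        {"pair_id": pid, "k": k, "n": n, "p_value": recurrence_pvalue(k, n, p_null)}
        for pid, k in counts.items()
        if k >= min_patients
    ]
    out = pd.DataFrame(rows, columns=["pair_id", "k", "n", "p_value"])
    return out.sort_values(
        ["k", "p_value", "pair_id"], ascending=[False, True, True]
    ).reset_index(drop=True)
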