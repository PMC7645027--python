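"""Rank-based cross-talk scoring of ligand-receptor pairs between two
clusters of single cells.

For every cell the genes in the top fraction ``t`` of its ranked expression
profile (default 20%) form the top set G^T.  A pair (L, R) between clusters
A and B scores

    s(L, R) = 1/2 [ mean_{cells in A} I(L in G^T) * I(R not in G^T)
                  + mean_{cells in B} I(R in G^T) * I(L not in G^T) ]

in paracrine mode; autocrine mode drops the "not in the other top set"
factors.  A complex partner counts as present only when every subunit is in
the top set.  Significance comes from a bootstrap null that redraws each
cell's top set uniformly at random (equivalently, permutes the gene labels
of each cell's profile) and rescores the whole table, pooling null scores
across pairs.
"""

from __future__ import annotations

import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .matrixio import ClusterAssignment, ExpressionMatrix
from .resources import InteractionPair, InteractionTable, restrict_pairs

logger = logging.getLogger(__name__)

__all__ = [
    "top_set_size",
    "top_gene_mask",
    "top_gene_set",
    "partner_in_top",
    "score_pair",
    "score_table",
    "bootstrap_pvalues",
    "filter_significant",
    "CrosstalkScorer",
]

MODES = ("paracrine", "autocrine")


def top_set_size(n_genes: int, t: float) -> int:
    if not 0 < t <= 1:
        raise ValueError("top fraction t must be in (0, 1]")
    k = int(np.floor(t * n_genes))
    if k == 0:
        raise ValueError(f"floor(t * n_genes) = 0 for t={t}, n_genes={n_genes}")
    return k


def top_gene_mask(X: np.ndarray, t: float, warn_ties: bool = False) -> np.ndarray:
    """Boolean genes x cells mask of each cell's top-t genes.

    The top set has exactly ``floor(t * n_genes)`` members per cell; ties at
    the boundary are broken deterministically by gene index order (stable
    sort on descending expression).
    """
    X = np.asarray(X, dtype=float)
    N, C = X.shape
    k = top_set_size(N, t)
    order = np.argsort(-X, axis=0, kind="stable")
    mask = np.zeros((N, C), dtype=bool)
    cols = np.arange(C)
    mask[order[:k, :], cols[None, :]] = True
    if warn_ties and k < N:
        boundary = X[order[k - 1, :], cols] == X[order[k, :], cols]
        if boundary.any():
            logger.warning(
                "top-set boundary tie in %d cell(s); broken by gene index order",
                int(boundary.sum()),
            )
    return mask


def top_gene_set(profile, t: float, genes=None) -> set[str]:
    """The top-t gene set of a single expression profile."""
    if isinstance(profile, pd.Series):
        genes = profile.index.to_numpy()
        values = profile.to_numpy(dtype=float)
    else:
        values = np.asarray(profile, dtype=float)
        if genes is None:
            raise ValueError("gene symbols required for a bare vector")
        genes = np.asarray(genes)
    mask = top_gene_mask(values[:, None], t, warn_ties=True)[:, 0]
    return set(genes[mask])


def partner_in_top(partner: Sequence[str], topset: set[str]) -> int:
    """1 iff every member gene of the partner is in the top set."""
    if not partner:
        raise ValueError("partner must be non-empty")
    return int(all(g in topset for g in partner))


def _partner_indicator(
    partner: Sequence[str], mask: np.ndarray, gene_pos: dict[str, int]
) -> np.ndarray:
    """Per-cell indicator that all subunits of a partner are in the top set."""
    idx = [gene_pos[g] for g in partner]
    return mask[idx, :].all(axis=0)


def _pair_components(
    pair: InteractionPair,
    mask: np.ndarray,
    gene_pos: dict[str, int],
    cols_a: np.ndarray,
    cols_b: np.ndarray,
    mode: str,
) -> tuple[float, float]:
    il = _partner_indicator(pair.partner_a, mask, gene_pos)
    ir = _partner_indicator(pair.partner_b, mask, gene_pos)
    if mode == "paracrine":
        score_a = float(np.mean(il[cols_a] & ~ir[cols_a]))
        score_b = float(np.mean(ir[cols_b] & ~il[cols_b]))
    elif mode == "autocrine":
        score_a = float(np.mean(il[cols_a]))
        score_b = float(np.mean(ir[cols_b]))
    else:
        raise ValueError(f"mode must be one of {MODES}")
    return score_a, score_b


def score_pair(
    pair: InteractionPair,
    matrix: ExpressionMatrix,
    cells_a: Sequence,
    cells_b: Sequence,
    t: float = 0.20,
    mode: str = "paracrine",
) -> dict:
    """Score a single pair between two groups of cells.

    Returns a dict with per-cluster components ``score_a``/``score_b`` and
    the total ``score`` (their mean), all in [0, 1].
    """
    if len(cells_a) == 0 or len(cells_b) == 0:
        raise ValueError("both clusters must be non-empty")
    gene_pos = matrix.gene_index()
    missing = sorted(pair.genes - set(gene_pos))
    if missing:
        raise ValueError(f"pair {pair.pair_id}: gene(s) absent from matrix: {missing}")
    mask = top_gene_mask(matrix.to_dense(), t)
    cell_pos = {c: i for i, c in enumerate(matrix.cells)}
    cols_a = np.array([cell_pos[c] for c in cells_a])
    cols_b = np.array([cell_pos[c] for c in cells_b])
    score_a, score_b = _pair_components(pair, mask, gene_pos, cols_a, cols_b, mode)
    return {
        "pair_id": pair.pair_id,
        "mode": mode,
        "score_a": score_a,
        "score_b": score_b,
        "score": (score_a + score_b) / 2.0,
        "n_cells_a": len(cells_a),
        "n_cells_b": len(cells_b),
    }


def _score_all(
    table: InteractionTable,
    mask: np.ndarray,
    gene_pos: dict[str, int],
    cols_a: np.ndarray,
    cols_b: np.ndarray,
    mode: str,
) -> tuple[np.ndarray, np.ndarray]:
    """(score_a, score_b) arrays over the table's pairs, given a top mask."""
    indicators: dict[tuple[str, ...], np.ndarray] = {}

    def ind(partner: tuple[str, ...]) -> np.ndarray:
        if partner not in indicators:
            indicators[partner] = _partner_indicator(partner, mask, gene_pos)
        return indicators[partner]

    sa = np.empty(len(table))
    sb = np.empty(len(table))
    for j, pair in enumerate(table):
        il, ir = ind(pair.partner_a), ind(pair.partner_b)
        if mode == "paracrine":
            sa[j] = np.mean(il[cols_a] & ~ir[cols_a])
            sb[j] = np.mean(ir[cols_b] & ~il[cols_b])
        else:
            sa[j] = np.mean(il[cols_a])
            sb[j] = np.mean(ir[cols_b])
    return sa, sb


def _resolve_clusters(
    matrix: ExpressionMatrix, clusters: ClusterAssignment
) -> tuple[np.ndarray, np.ndarray]:
    clusters.validate_against(matrix)
    cells_a, cells_b = clusters.split()
    cell_pos = {c: i for i, c in enumerate(matrix.cells)}
    return (
        np.array([cell_pos[c] for c in cells_a]),
        np.array([cell_pos[c] for c in cells_b]),
    )


def score_table(
    matrix: ExpressionMatrix,
    clusters: ClusterAssignment,
    table: InteractionTable,
    t: float = 0.20,
    mode: str = "paracrine",
) -> pd.DataFrame:
    """Score every scoreable pair of the table between the two clusters.

    Pairs with member genes absent from the matrix are dropped (reported in
    the log).  Results are sorted by descending score with pair_id
    tie-break.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    restricted, dropped = restrict_pairs(table, matrix.genes)
    if len(restricted) == 0:
        raise ValueError("no scoreable pairs: every pair has genes outside the matrix")
    if len(dropped):
        logger.info("%d pair(s) unscoreable in this matrix", len(dropped))
    cols_a, cols_b = _resolve_clusters(matrix, clusters)
    mask = top_gene_mask(matrix.to_dense(), t, warn_ties=True)
    sa, sb = _score_all(restricted, mask, matrix.gene_index(), cols_a, cols_b, mode)
    out = pd.DataFrame(
        {
            "pair_id": restricted.pair_ids,
            "mode": mode,
            "score_a": sa,
            "score_b": sb,
            "score": (sa + sb) / 2.0,
            "n_cells_a": len(cols_a),
            "n_cells_b": len(cols_b),
        }
    )
    return out.sort_values(["score", "pair_id"], ascending=[False, True]).reset_index(drop=True)


def _random_top_mask(n_genes: int, n_cells: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random k-subset top mask per cell (gene-label permutation null)."""
    u = rng.random((n_genes, n_cells))
    idx = np.argpartition(u, k - 1, axis=0)[:k, :]
    mask = np.zeros((n_genes, n_cells), dtype=bool)
    mask[idx, np.arange(n_cells)[None, :]] = True
    return mask


def bootstrap_null_scores(
    n_genes: int,
    n_cells: int,
    k: int,
    table: InteractionTable,
    gene_pos: dict[str, int],
    cols_a: np.ndarray,
    cols_b: np.ndarray,
    mode: str,
    n_iter: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """(n_iter, n_pairs) null scores from random per-cell top sets."""
    out = np.empty((n_iter, len(table)))
    for i in range(n_iter):
        mask = _random_top_mask(n_genes, n_cells, k, rng)
        sa, sb = _score_all(table, mask, gene_pos, cols_a, cols_b, mode)
        out[i] = (sa + sb) / 2.0
    return out


def pooled_empirical_pvalues(observed: np.ndarray, null_scores: np.ndarray) -> np.ndarray:
    """Empirical upper-tail p-values against a null pooled across pairs.

    Null scores from all pairs are pooled into one distribution per
    (dataset, clusters, mode, t); the exceedance count is averaged per
    iteration so that p = (1 + mean per-iteration count >= observed)
    / (1 + n_iter), which keeps p within [1/(n_iter+1), 1].
    """
    n_iter, n_pairs = null_scores.shape
    pooled = np.sort(null_scores.ravel())
    # count of pooled nulls >= each observed score
    ge = pooled.size - np.searchsorted(pooled, observed, side="left")
    return (1.0 + ge / n_pairs) / (1.0 + n_iter)


def bootstrap_pvalues(
    matrix: ExpressionMatrix,
    clusters: ClusterAssignment,
    table: InteractionTable,
    t: float = 0.20,
    mode: str = "paracrine",
    n_iter: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Score the table and attach pooled bootstrap p-values.

    The null redraws every cell's top set as a uniform random
    floor(t * n_genes)-subset of the gene universe and rescores all pairs;
    p-values are empirical with a +1 correction (never exactly zero).
    """
    if n_iter < 100:
        warnings.warn(f"n_iter={n_iter} < 100: p-value resolution is coarse")
    results = score_table(matrix, clusters, table, t=t, mode=mode)
    restricted, _ = restrict_pairs(table, matrix.genes)
    cols_a, cols_b = _resolve_clusters(matrix, clusters)
    rng = np.random.default_rng(seed)
    k = top_set_size(matrix.n_genes, t)
    null = bootstrap_null_scores(
        matrix.n_genes, matrix.n_cells, k, restricted, matrix.gene_index(),
        cols_a, cols_b, mode, n_iter, rng,
    )
    results = results.copy()
    results["p_value"] = pooled_empirical_pvalues(results["score"].to_numpy(), null)
    return results


def filter_significant(
    results: pd.DataFrame, p_max: float = 0.05, s_min: float = 0.50
) -> pd.DataFrame:
    """Keep pairs with p < p_max, total score > s_min and a strictly
    positive contribution from each cluster."""
    if "p_value" not in results.columns:
        raise ValueError("p-values not computed; run the bootstrap first")
    keep = (
        (results["p_value"] < p_max)
        & (results["score"] > s_min)
        & (results["score_a"] > 0)
        & (results["score_b"] > 0)
    )
    return results.loc[keep].reset_index(drop=True)


class CrosstalkScorer(BaseEstimator):
    """Scikit-learn style estimator for cluster-pair cross-talk scoring.

    ``fit(X, y)`` takes a cells x genes DataFrame (gene symbols as columns)
    and per-cell cluster labels ``y``; it computes the score of every
    scoreable pair between ``cluster_a`` and ``cluster_b`` and, when
    ``n_iter > 0``, pooled bootstrap p-values.

    Parameters
    ----------
    interactions : InteractionTable of candidate pairs.
    cluster_a, cluster_b : the two cluster labels to compare.  When None,
        ``y`` must contain exactly two distinct labels, assigned in sorted
        order.
    mode : "paracrine" (default) or "autocrine".
    top_fraction : fraction t of each cell's ranked profile forming the top
        set (default 0.20).
    n_iter : bootstrap iterations (0 disables significance testing).
    p_max, s_min : thresholds used by :attr:`significant_`.
    random_state : seed for the bootstrap.

    Attributes
    ----------
    results_ : DataFrame of per-pair scores (and p-values if bootstrapped).
    significant_ : results passing the significance and both-cluster filter.
    dropped_pairs_ : report of pairs unscoreable in the fitted universe.
    """

    def __init__(
        self,
        interactions: InteractionTable | None = None,
        cluster_a: str | None = None,
        cluster_b: str | None = None,
        mode: str = "paracrine",
        top_fraction: float = 0.20,
        n_iter: int = 1000,
        p_max: float = 0.05,
        s_min: float = 0.50,
        random_state: int | None = None,
    ):
        self.interactions = interactions
        self.cluster_a = cluster_a
        self.cluster_b = cluster_b
        self.mode = mode
        self.top_fraction = top_fraction
        self.n_iter = n_iter
        self.p_max = p_max
        self.s_min = s_min
        self.random_state = random_state

    def _as_matrix(self, X) -> ExpressionMatrix:
        if isinstance(X, ExpressionMatrix):
            return X
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a cells x genes DataFrame or an ExpressionMatrix")
        return ExpressionMatrix(
            X.columns.to_numpy(dtype=object), X.index.to_numpy(dtype=object),
            X.to_numpy(dtype=float).T,
        )

    def fit(self, X, y):
        if self.interactions is None or len(self.interactions) == 0:
            raise ValueError("an interaction table is required")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        matrix = self._as_matrix(X)
        y = pd.Series(np.asarray(y, dtype=object), index=matrix.cells)
        a, b = self.cluster_a, self.cluster_b
        if a is None or b is None:
            found = sorted(y.unique())
            if len(found) != 2:
                raise ValueError(
                    "cluster_a/cluster_b unset and y does not contain exactly two labels"
                )
            a, b = found
        clusters = ClusterAssignment(y, cluster_a=a, cluster_b=b)
        restricted, self.dropped_pairs_ = restrict_pairs(self.interactions, matrix.genes)
        if self.n_iter > 0:
            self.results_ = bootstrap_pvalues(
                matrix, clusters, restricted, t=self.top_fraction, mode=self.mode,
                n_iter=self.n_iter, seed=self.random_state,
            )
            self.significant_ = filter_significant(self.results_, self.p_max, self.s_min)
        else:
            self.results_ = score_table(
                matrix, clusters, restricted, t=self.top_fraction, mode=self.mode
            )
        self.n_features_in_ = matrix.n_genes
        self.feature_names_in_ = matrix.genes
        self.clusters_ = (a, b)
        return self

    def transform(self, X=None) -> pd.DataFrame:
        """Return the fitted per-pair score table."""
        check_is_fitted(self, "results_")
        return self.results_
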