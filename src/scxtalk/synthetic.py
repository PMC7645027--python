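"""Synthetic single-cell datasets with planted cell-type signatures and
planted ligand-receptor activations.

The generator emulates the data the scoring and classification machinery
assumes: log-normal baseline expression, cluster-specific up-shifts of
signature genes, Bernoulli drop-out, and ligand-receptor plantings that
manipulate per-cell ranks directly.  Because the pair score is purely
rank-based, planting a partner above (or below) the top-t rank threshold in
a controlled fraction of a cluster's cells makes the expected score
closed-form: (f_ligand + f_receptor) / 2, and exact for the realized
per-cell draws.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .matrixio import ClusterAssignment, ExpressionMatrix
from .resources import GeneSignature, InteractionPair
from .scoring import top_set_size

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterSpec",
    "PlantedPair",
    "SyntheticConfig",
    "SyntheticTruth",
    "generate_dataset",
    "null_cohort",
    "default_config",
]


@dataclass(frozen=True)
class ClusterSpec:
    label: str
    n_cells: int = 200
    signature: GeneSignature | None = None
    malignant: bool = False

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("cluster must have at least one cell")


@dataclass(frozen=True)
class PlantedPair:
    """A ligand-receptor activation planted between two clusters.

    ``f_ligand`` is the fraction of ligand-cluster cells in which every
    ligand subunit is forced into the cell's top set (Bernoulli per cell);
    ``f_receptor`` analogously on the receptor cluster.  In paracrine mode
    the opposite partner is forced out of the top set across the whole
    cluster, so the planted paracrine and autocrine scores coincide.
    """

    pair: InteractionPair
    cluster_ligand: str
    cluster_receptor: str
    f_ligand: float = 1.0
    f_receptor: float = 1.0
    mode: str = "paracrine"
    exact_counts: bool = False  # plant exactly round(f*n) cells instead of Bernoulli(f)

    def __post_init__(self) -> None:
        if not (0 <= self.f_ligand <= 1 and 0 <= self.f_receptor <= 1):
            raise ValueError("planting fractions must be in [0, 1]")
        if self.mode not in ("paracrine", "autocrine"):
            raise ValueError("mode must be paracrine or autocrine")

    @property
    def expected_score(self) -> float:
        return (self.f_ligand + self.f_receptor) / 2.0


@dataclass(frozen=True)
class SyntheticConfig:
    n_genes: int = 1000
    clusters: tuple[ClusterSpec, ...] = ()
    signature_effect: float = 2.0
    planted_pairs: tuple[PlantedPair, ...] = ()
    dropout_rate: float = 0.3
    baseline_loc: float = 1.0
    baseline_scale: float = 0.5
    top_fraction: float = 0.20
    seed: int = 0
    extra_genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.clusters:
            raise ValueError("at least one cluster is required")
        labels = [c.label for c in self.clusters]
        if len(set(labels)) != len(labels):
            raise ValueError("cluster labels must be unique")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        known = set(labels)
        for pp in self.planted_pairs:
            if pp.cluster_ligand not in known or pp.cluster_receptor not in known:
                raise ValueError(f"planted pair {pp.pair.pair_id} names an unknown cluster")


@dataclass
class SyntheticTruth:
    """Ground truth of a generated dataset."""

    cluster_of: pd.Series  # cell_id -> cluster label
    signature_of_cluster: dict[str, str | None]
    expected_scores: pd.DataFrame  # per planted pair: expected + realized fractions
    seed: int


def _gene_universe(config: SyntheticConfig) -> np.ndarray:
    named: list[str] = []
    seen: set[str] = set()

    def add(g: str) -> None:
        if g not in seen:
            named.append(g)
            seen.add(g)

    for cl in config.clusters:
        if cl.signature is not None:
            for g in sorted(cl.signature.genes):
                add(g)
    for pp in config.planted_pairs:
        for g in pp.pair.partner_a + pp.pair.partner_b:
            add(g)
    for g in config.extra_genes:
        add(g)
    if len(named) > config.n_genes:
        raise ValueError(
            f"n_genes={config.n_genes} too small for {len(named)} named genes"
        )
    fillers = [f"G{i:05d}" for i in range(config.n_genes - len(named))]
    return np.array(named + fillers, dtype=object)


def generate_dataset(
    config: SyntheticConfig,
) -> tuple[ExpressionMatrix, ClusterAssignment, SyntheticTruth]:
    """Generate one dataset; fully reproducible under ``config.seed``.

    Raises if a planting is infeasible, i.e. a cell would need more forced
    top genes than floor(top_fraction * n_genes) admits.
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_universe(config)
    gene_pos = {g: i for i, g in enumerate(genes)}
    N = config.n_genes
    k = top_set_size(N, config.top_fraction)

    cells: list[str] = []
    labels: list[str] = []
    for cl in config.clusters:
        cells += [f"{cl.label}.{i:04d}" for i in range(cl.n_cells)]
        labels += [cl.label] * cl.n_cells
    C = len(cells)
    cols_of = {
        cl.label: np.flatnonzero(np.array(labels, dtype=object) == cl.label)
        for cl in config.clusters
    }

    X = rng.lognormal(config.baseline_loc, config.baseline_scale, size=(N, C))
    protected = np.zeros((N, C), dtype=bool)

    for cl in config.clusters:
        if cl.signature is None or config.signature_effect == 0:
            continue
        rows = [gene_pos[g] for g in sorted(cl.signature.genes)]
        X[np.ix_(rows, cols_of[cl.label])] += config.signature_effect
        protected[np.ix_(rows, cols_of[cl.label])] = True

    # rank plantings: forced-high entries go above every baseline value,
    # forced-low entries to zero (the bottom of the profile)
    high_base = float(X.max()) + 1.0
    forced_high = np.zeros((N, C), dtype=bool)
    truth_rows = []
    for pp in config.planted_pairs:
        rec = {"pair_id": pp.pair.pair_id, "mode": pp.mode,
               "cluster_ligand": pp.cluster_ligand,
               "cluster_receptor": pp.cluster_receptor,
               "f_ligand": pp.f_ligand, "f_receptor": pp.f_receptor,
               "expected_score": pp.expected_score}
        for side, partner, other, frac in (
            ("ligand", pp.pair.partner_a, pp.pair.partner_b, pp.f_ligand),
            ("receptor", pp.pair.partner_b, pp.pair.partner_a, pp.f_receptor),
        ):
            cluster = pp.cluster_ligand if side == "ligand" else pp.cluster_receptor
            cols = cols_of[cluster]
            rows = [gene_pos[g] for g in partner]
            if pp.exact_counts:
                on = np.zeros(len(cols), dtype=bool)
                on[rng.permutation(len(cols))[: int(round(frac * len(cols)))]] = True
            else:
                on = rng.random(len(cols)) < frac
            for j, g in enumerate(rows):
                X[g, cols[on]] = high_base + 0.01 * j
                X[g, cols[~on]] = 0.0
                forced_high[g, cols[on]] = True
                protected[g, cols] = True
            if pp.mode == "paracrine":
                other_rows = [gene_pos[g] for g in other]
                for g in other_rows:
                    X[g, cols] = 0.0
                    protected[g, cols] = True
            rec[f"realized_f_{side}"] = float(on.mean())
        rec["realized_score"] = (rec["realized_f_ligand"] + rec["realized_f_receptor"]) / 2.0
        truth_rows.append(rec)

    if forced_high.sum(axis=0).max(initial=0) > k:
        raise ValueError(
            "planting infeasible: a cell has more forced top genes than the "
            f"top set admits (k={k})"
        )

    if config.dropout_rate > 0:
        drop = rng.random((N, C)) < config.dropout_rate
        X[drop & ~protected] = 0.0

    # the rank machinery needs at least k strictly positive values per cell,
    # otherwise zero-valued forced-out genes could re-enter the top set
    min_positive = int((X > 0).sum(axis=0).min())
    if min_positive < k:
        raise ValueError(
            f"a cell has only {min_positive} positive values (< top set size {k}); "
            "lower dropout_rate or top_fraction"
        )

    meta = pd.DataFrame(
        {
            "cluster": labels,
            "malignant": [
                next(c.malignant for c in config.clusters if c.label == lab)
                for lab in labels
            ],
        },
        index=pd.Index(cells, name="cell_id"),
    )
    matrix = ExpressionMatrix(genes, np.array(cells, dtype=object), X, meta)
    first_two = [c.label for c in config.clusters[:2]]
    assignment = ClusterAssignment(
        pd.Series(labels, index=cells),
        cluster_a=first_two[0],
        cluster_b=first_two[-1] if len(first_two) > 1 else None,
    )
    truth = SyntheticTruth(
        cluster_of=pd.Series(labels, index=cells),
        signature_of_cluster={c.label: (c.signature.name if c.signature else None)
                              for c in config.clusters},
        expected_scores=pd.DataFrame(truth_rows),
        seed=config.seed,
    )
    return matrix, assignment, truth


def null_cohort(
    n_patients: int, config: SyntheticConfig, seed: int | None = None
) -> list[tuple[ExpressionMatrix, ClusterAssignment, SyntheticTruth]]:
    """Independent structureless datasets (no signatures, no plantings) for
    calibration experiments."""
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    base = replace(
        config,
        planted_pairs=(),
        clusters=tuple(
            dataclasses.replace(c, signature=None) for c in config.clusters
        ),
    )
    child_seeds = np.random.SeedSequence(seed).generate_state(n_patients) % (2**31)
    return [generate_dataset(replace(base, seed=int(s))) for s in child_seeds]


def default_config(seed: int = 0) -> SyntheticConfig:
    """The stock study design: 1,000 genes, 3 clusters x 200 cells."""
    from .resources import bundled_signatures

    sigs = {s.name: s for s in bundled_signatures()}
    clusters = (
        ClusterSpec("tumor", 200, sigs["GSC_core"], malignant=True),
        ClusterSpec("myeloid", 200, sigs["Macrophage_core"]),
        ClusterSpec("oligodendrocyte", 200, sigs["Oligodendrocyte_core"]),
    )
    # the bundled signature vocabulary and ligand-receptor genes live in the
    # universe so every signature is usable and every pair scoreable
    from .resources import bundled_interaction_table

    vocab = set().union(*(s.genes for s in sigs.values()))
    vocab |= bundled_interaction_table().genes
    return SyntheticConfig(n_genes=1000, clusters=clusters, seed=seed,
                           extra_genes=tuple(sorted(vocab)))
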