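"""Rank-product gene elimination, key-gene extraction, and multi-run consensus.

A gene whose row of the feature selection matrix F varies strongly across
category columns discriminates between categories; a flat row does not.
Per column, genes are ranked descending by weight (rank 1 = largest, ties
get the average rank), and the per-gene rank product is the geometric mean
of its column ranks.  A discriminative gene earns a rank near 1 in at least
one column and therefore a small rank product; flat rows collect mid-range
ranks everywhere and sort last.  Each elimination round removes the genes
with the largest rank products, rebuilds the sample graph on the reduced
matrix, and refits.

Because F is randomly initialized, the whole elimination schedule is
restarted many times and only genes recurring in strictly more than a
threshold number of restarts are reported as key genes per category.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .datamodel import ExpressionMatrix, LabelSpec, LPFSConfig, ValidationError
from .solver import FitResult, lpfs_fit

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneRanking:
    """Per-gene rank-product values and the induced discriminability order."""

    gene_ids: tuple[str, ...]
    rp_value: np.ndarray  # geometric mean of per-column descending ranks, in [1, m]
    order: np.ndarray     # ascending rp_value (most discriminative first); stable ties


@dataclass(frozen=True)
class KeyGene:
    gene_id: str
    occurrence_count: int
    mean_score: float


@dataclass(frozen=True)
class KeyGeneSets:
    """Consensus key genes per category over repeated randomized runs."""

    per_category: tuple[tuple[KeyGene, ...], ...]
    repetitions: int
    threshold: int


@dataclass
class RoundResult:
    """Artifacts of one elimination round (fit on the pre-removal matrix)."""

    fit: FitResult
    ranking: GeneRanking
    survivors: ExpressionMatrix


@dataclass
class ProtocolResult:
    consensus: KeyGeneSets
    run_key_sets: list[list[list[tuple[str, float]]]]
    failed_runs: int
    seeds: list[int]


def rank_product(F: np.ndarray, gene_ids: tuple[str, ...] | None = None) -> GeneRanking:
    """Geometric-mean rank of each F row across category columns.

    Small values mark discriminative genes (dominant in at least one
    column); the sort is stable, so total ties fall back to input order.
    """
    F = np.asarray(F, dtype=float)
    if F.ndim != 2:
        raise ValidationError(f"F must be 2-D, got shape {F.shape}")
    if np.any(F < 0):
        raise ValidationError("rank_product requires a non-negative F")
    m = F.shape[0]
    if gene_ids is None:
        gene_ids = tuple(f"g{i}" for i in range(m))
    if len(gene_ids) != m:
        raise ValidationError(f"{len(gene_ids)} gene ids for {m} rows")
    ranks = rankdata(-F, axis=0, method="average")  # rank 1 = largest weight
    rp = np.exp(np.mean(np.log(ranks), axis=1))
    order = np.argsort(rp, kind="stable")
    return GeneRanking(gene_ids=tuple(gene_ids), rp_value=rp, order=order)


def remove_low_ranking(xm: ExpressionMatrix, ranking: GeneRanking, r: int) -> ExpressionMatrix:
    """Drop the ``r`` genes with the largest rank product.

    Surviving genes keep their input order.  Requests that would empty the
    matrix are clipped so one gene always survives (with a warning).
    """
    if r < 0:
        raise ValidationError(f"removal count must be >= 0, got {r}")
    if ranking.gene_ids != xm.gene_ids:
        raise ValidationError("ranking gene ids do not match the expression matrix")
    if r == 0:
        return xm
    m = xm.n_genes
    if r >= m:
        logger.warning("removal of %d genes clipped to %d to keep one gene", r, m - 1)
        r = m - 1
    keep = np.sort(ranking.order[: m - r])
    return xm.subset_genes(keep)


def iterate_lpfs(
    xm: ExpressionMatrix,
    spec: LabelSpec,
    cfg: LPFSConfig,
    *,
    rng: np.random.Generator | None = None,
) -> list[RoundResult]:
    """Run ``cfg.inner_rounds`` rounds of fit / rank / remove.

    Each round rebuilds the sample graph from the current (reduced) matrix,
    fits the alternating solver, ranks genes by rank product of the fitted
    F, and removes the ``cfg.removal_size`` least discriminative genes.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    rounds: list[RoundResult] = []
    current = xm
    for _ in range(cfg.inner_rounds):
        fit = lpfs_fit(current, spec, cfg, rng=rng)
        ranking = rank_product(fit.feature_selection.F, current.gene_ids)
        survivors = remove_low_ranking(current, ranking, cfg.removal_size)
        rounds.append(RoundResult(fit=fit, ranking=ranking, survivors=survivors))
        current = survivors
    return rounds


def extract_key_genes(
    F: np.ndarray,
    gene_ids: tuple[str, ...],
    s: int,
) -> list[list[tuple[str, float]]]:
    """Top-``s`` genes per category column of F (ties -> smaller row index).

    A gene may appear in several categories' sets; ``s >= m`` returns every
    gene for each category.
    """
    F = np.asarray(F, dtype=float)
    if s < 1:
        raise ValidationError(f"s must be >= 1, got {s}")
    m, c = F.shape
    if len(gene_ids) != m:
        raise ValidationError(f"{len(gene_ids)} gene ids for {m} rows")
    s = min(s, m)
    sets: list[list[tuple[str, float]]] = []
    for j in range(c):
        top = np.argsort(-F[:, j], kind="stable")[:s]
        sets.append([(gene_ids[i], float(F[i, j])) for i in top])
    return sets


def consensus(
    runs: list[list[list[tuple[str, float]]]],
    threshold: int,
) -> KeyGeneSets:
    """Keep genes appearing in at least ``threshold`` of the runs' key sets.

    ``threshold`` is the minimum occurrence count, so the "strictly more
    than 50 of 100 restarts" rule corresponds to ``threshold = 51``.
    Reported scores are each gene's mean per-category F weight over the
    runs in which it was selected; categories are sorted by descending mean
    score (ties by gene id).
    """
    if not runs:
        raise ValidationError("consensus requires at least one run")
    if not 1 <= threshold <= len(runs):
        raise ValidationError(
            f"threshold must lie in 1..{len(runs)} (number of runs), got {threshold}"
        )
    c = len(runs[0])
    if any(len(run) != c for run in runs):
        raise ValidationError("runs disagree on the number of categories")
    per_category: list[tuple[KeyGene, ...]] = []
    for j in range(c):
        counts: dict[str, int] = {}
        score_sums: dict[str, float] = {}
        for run in runs:
            for gene_id, score in run[j]:
                counts[gene_id] = counts.get(gene_id, 0) + 1
                score_sums[gene_id] = score_sums.get(gene_id, 0.0) + score
        kept = [
            KeyGene(gene_id=g, occurrence_count=n, mean_score=score_sums[g] / n)
            for g, n in counts.items()
            if n >= threshold
        ]
        kept.sort(key=lambda kg: (-kg.mean_score, kg.gene_id))
        per_category.append(tuple(kept))
    return KeyGeneSets(
        per_category=tuple(per_category),
        repetitions=len(runs),
        threshold=threshold,
    )


def run_protocol(
    xm: ExpressionMatrix,
    spec: LabelSpec,
    cfg: LPFSConfig,
) -> ProtocolResult:
    """Full randomized-restart protocol.

    Restart ``r`` runs the elimination schedule with seed ``cfg.seed + r``
    so every restart is individually reproducible.  Key sets are extracted
    from the final round's fitted F (``cfg.s`` genes per category, default:
    every gene surviving the final removal), and the consensus keeps genes
    recurring in at least ``cfg.consensus_min_count`` restarts.  A restart
    that raises is logged and skipped; the protocol aborts only if more
    than half of the restarts fail.
    """
    run_key_sets: list[list[list[tuple[str, float]]]] = []
    seeds = [cfg.seed + r for r in range(cfg.repetitions)]
    failed = 0
    for run_seed in seeds:
        try:
            rounds = iterate_lpfs(xm, spec, cfg, rng=np.random.default_rng(run_seed))
        except (ValidationError, FloatingPointError) as exc:  # pragma: no cover
            failed += 1
            logger.warning("restart with seed %d failed: %s", run_seed, exc)
            continue
        final = rounds[-1]
        fitted_gene_ids = final.ranking.gene_ids
        s = cfg.s if cfg.s is not None else final.survivors.n_genes
        run_key_sets.append(
            extract_key_genes(final.fit.feature_selection.F, fitted_gene_ids, s)
        )
    if failed > cfg.repetitions / 2:
        raise RuntimeError(
            f"{failed} of {cfg.repetitions} restarts failed; aborting protocol"
        )
    threshold = min(cfg.consensus_min_count, len(run_key_sets))
    result = consensus(run_key_sets, threshold)
    return ProtocolResult(
        consensus=result,
        run_key_sets=run_key_sets,
        failed_runs=failed,
        seeds=seeds,
    )


def gene_scores_from_consensus(
    key_sets: KeyGeneSets,
    gene_ids: tuple[str, ...],
) -> np.ndarray:
    """Per-gene prioritization score over a full gene universe.

    Each gene scores its maximum consensus mean-F weight across categories;
    genes absent from every consensus set score 0.  This is the default
    score used against a gold-standard gene list (ROC / PR evaluation).
    """
    best: dict[str, float] = {}
    for cat in key_sets.per_category:
        for kg in cat:
            best[kg.gene_id] = max(best.get(kg.gene_id, 0.0), kg.mean_score)
    return np.array([best.get(g, 0.0) for g in gene_ids], dtype=float)
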