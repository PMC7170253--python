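"""Signature discovery: top-K selection per cohort, multi-cohort
intersection, tuning-cohort retest, and signed-signature assembly."""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

from .errors import ConfigError, EmptyCohortError
from .screen import RankTable, fit_univariate_cox, rank_genes, screen_genes
from .expression_io import intersect_samples
from .types import ExpressionMatrix, Signature, SurvivalTable

logger = logging.getLogger(__name__)

DEFAULT_TOP_K = 500
DEFAULT_MIN_COHORTS = 2
DEFAULT_RETEST_ALPHA = 0.05


def top_k(rank_table: RankTable, k: int = DEFAULT_TOP_K) -> set[str]:
    """First ``k`` genes by ranksum, including all ties at the boundary."""
    if k < 1:
        raise ConfigError("k must be positive")
    table = rank_table.table
    if k >= len(table):
        if k > len(table):
            logger.warning("top_k: k=%d exceeds table size %d; returning all genes",
                           k, len(table))
        return set(table.index)
    boundary = table["ranksum"].iloc[k - 1]
    chosen = table.index[table["ranksum"] <= boundary]
    if len(chosen) > k:
        logger.info("top_k: ranksum tie at the k=%d boundary; returning %d genes",
                    k, len(chosen))
    return set(chosen)


def intersect_cohorts(
    sets: Sequence[set[str]], min_cohorts: int = DEFAULT_MIN_COHORTS
) -> set[str]:
    """Genes present in at least ``min_cohorts`` of the given top-K sets."""
    if min_cohorts < 1:
        raise ConfigError("min_cohorts must be positive")
    if min_cohorts > len(sets):
        raise ConfigError(
            f"min_cohorts={min_cohorts} exceeds number of cohort sets ({len(sets)})")
    counts: dict[str, int] = {}
    for s in sets:
        for g in s:
            counts[g] = counts.get(g, 0) + 1
    return {g for g, c in counts.items() if c >= min_cohorts}


def retest(
    candidates: set[str],
    tuning_expr: ExpressionMatrix,
    tuning_survival: SurvivalTable,
    alpha: float = DEFAULT_RETEST_ALPHA,
    discovery_signs: Mapping[str, int] | None = None,
    name: str = "discovered",
) -> Signature:
    """Refit each candidate univariately in the tuning cohort; keep genes with
    p < alpha and assign sign +1 (HR > 1, adverse) or -1 (HR < 1, favorable).

    If ``discovery_signs`` is given, genes whose tuning sign contradicts the
    discovery direction are excluded (with a logged warning): a signature
    whose members point in inconsistent directions is uninterpretable.
    """
    if not candidates:
        raise EmptyCohortError("no candidate genes to retest")
    expr, surv = intersect_samples(tuning_expr, tuning_survival)
    entries: list[tuple[str, float]] = []
    flipped: list[str] = []
    absent = sorted(g for g in candidates if g not in expr.values.index)
    if absent:
        logger.info("retest: %d candidate(s) absent from tuning cohort: %s",
                    len(absent), absent[:10])
    for gene in sorted(candidates):
        if gene not in expr.values.index:
            continue
        res = fit_univariate_cox(
            expr.values.loc[gene].to_numpy(dtype=float), surv, gene_id=gene)
        if res.degenerate or not res.p < alpha:
            continue
        sign = 1.0 if res.hr > 1 else -1.0
        if discovery_signs is not None and gene in discovery_signs:
            if discovery_signs[gene] * sign < 0:
                flipped.append(gene)
                continue
        entries.append((gene, sign))
    if flipped:
        logger.warning("retest: excluded %d gene(s) whose tuning direction "
                       "contradicts discovery: %s", len(flipped), flipped)
    if not entries:
        logger.warning("retest: no gene passed p < %g in the tuning cohort", alpha)
    return Signature(
        name=name,
        entries=tuple(entries),
        provenance={"alpha": alpha, "n_candidates": len(candidates),
                    "flipped_excluded": tuple(flipped)},
    )


def discover_signature(
    discovery: Sequence[tuple[ExpressionMatrix, SurvivalTable]],
    tuning: tuple[ExpressionMatrix, SurvivalTable],
    k: int = DEFAULT_TOP_K,
    min_cohorts: int = DEFAULT_MIN_COHORTS,
    alpha: float = DEFAULT_RETEST_ALPHA,
    name: str = "discovered",
) -> tuple[Signature, list[RankTable], set[str]]:
    """Full discovery pass: per-cohort screen+rank, top-K intersection, retest.

    Returns the signature, the per-cohort rank tables, and the intersected
    candidate set (for auditability of the top-K -> candidates -> signature
    funnel).
    """
    if len(discovery) < min_cohorts:
        raise ConfigError(
            f"need at least min_cohorts={min_cohorts} discovery cohorts, "
            f"got {len(discovery)}")
    rank_tables: list[RankTable] = []
    sets: list[set[str]] = []
    sign_votes: dict[str, int] = {}
    for expr, surv in discovery:
        rt = rank_genes(screen_genes(expr, surv))
        rank_tables.append(rt)
        chosen = top_k(rt, k)
        sets.append(chosen)
        for g in chosen:
            sign_votes[g] = sign_votes.get(g, 0) + (1 if rt.table.loc[g, "hr"] > 1 else -1)
    candidates = intersect_cohorts(sets, min_cohorts)
    logger.info("discovery funnel: %s top-%d sets -> %d candidates in >= %d cohorts",
                [len(s) for s in sets], k, len(candidates), min_cohorts)
    discovery_signs = {g: (1 if v > 0 else -1) for g, v in sign_votes.items() if v != 0}
    signature = retest(candidates, tuning[0], tuning[1], alpha=alpha,
                       discovery_signs=discovery_signs, name=name)
    provenance = dict(signature.provenance)
    provenance.update({"k": k, "min_cohorts": min_cohorts,
                       "n_discovery_cohorts": len(discovery)})
    signature = Signature(name=signature.name, entries=signature.entries,
                          provenance=provenance)
    return signature, rank_tables, candidates
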