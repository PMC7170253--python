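"""Signed-sum signature scores and median dichotomization.

A sample's score is the sum of sign (or coefficient) times log expression
over the signature genes present in the matrix. Genes absent from a
platform are dropped (and logged), never imputed; a minimum-coverage guard
rejects matrices containing too few signature genes for the score to mean
anything.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import ConfigError, CoverageError, DegenerateError
from .types import ExpressionMatrix, GroupAssignment, ScoreVector, Signature

logger = logging.getLogger(__name__)

DEFAULT_MIN_COVERAGE = 0.5


def compute_score(
    expr: ExpressionMatrix,
    signature: Signature,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
) -> ScoreVector:
    """Per-sample signed sum of expression over the signature's genes.

    ``min_coverage`` is the smallest tolerated fraction of signature genes
    present in the matrix (default 0.5); below it a :class:`CoverageError`
    is raised, at zero present genes always.
    """
    weights = signature.weights
    present = [g for g in signature.genes if g in expr.values.index]
    missing = [g for g in signature.genes if g not in expr.values.index]
    if not present:
        raise CoverageError(
            f"none of the {len(signature)} genes of {signature.name!r} are in the matrix")
    coverage = len(present) / len(signature)
    if coverage < min_coverage:
        raise CoverageError(
            f"{signature.name!r}: only {len(present)}/{len(signature)} genes present "
            f"(coverage {coverage:.2f} < {min_coverage:.2f})")
    if missing:
        logger.info("compute_score(%s): %d gene(s) absent, score computed without them: %s",
                    signature.name, len(missing), missing)
    w = np.array([weights[g] for g in present])
    sub = expr.values.loc[present].to_numpy(dtype=float)
    scores = pd.Series(w @ sub, index=expr.values.columns, name=signature.name)
    return ScoreVector(
        scores=scores,
        signature_name=signature.name,
        genes_used=present,
        genes_missing=missing,
    )


def dichotomize(
    scores: ScoreVector,
    cutoff_rule: str = "median",
    cutoff_value: float | None = None,
) -> GroupAssignment:
    """Split samples into high (score > cutoff) and low (score <= cutoff) groups.

    ``cutoff_rule`` is ``"median"`` (cutoff = cohort median score) or
    ``"value"`` (cutoff supplied via ``cutoff_value``). Samples exactly at
    the cutoff fall in the low group.
    """
    if len(scores) < 2:
        raise ConfigError("need at least 2 samples to dichotomize")
    if cutoff_rule == "median":
        cutoff = float(scores.scores.median())
    elif cutoff_rule == "value":
        if cutoff_value is None:
            raise ConfigError("cutoff_rule='value' requires cutoff_value")
        cutoff = float(cutoff_value)
    else:
        raise ConfigError(f"unknown cutoff rule {cutoff_rule!r}")
    high = scores.scores > cutoff
    if high.all() or (~high).all():
        raise DegenerateError(
            f"degenerate split at cutoff {cutoff}: one group is empty "
            f"(all scores {'above' if high.all() else 'at or below'} the cutoff)")
    groups = pd.Series(np.where(high, "high", "low"), index=scores.scores.index)
    return GroupAssignment(groups=groups, cutoff=cutoff, cutoff_rule=cutoff_rule)


def write_scores(scores: ScoreVector, groups: GroupAssignment | None, path,
                 delimiter: str = "\t") -> None:
    df = pd.DataFrame({"score": scores.scores})
    if groups is not None:
        df["group"] = groups.groups
    df.to_csv(path, sep=delimiter, index_label="sample_id")
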