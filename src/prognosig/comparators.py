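"""Adapters for previously published comparator signatures.

Two application modes are supported:

* ``weighted`` — score = sum of author-supplied coefficients times log
  expression, with platform-absent genes dropped (and logged);
* ``binary_cutoff`` — per-gene presence calls against transferred cut-offs,
  combined into a weighted 0/1 risk score and thresholded.

The cut-off transfer works by expressing each reference cut-off as a
multiple of the reference cohort's median for that gene, then rescaling by
the target cohort's median. It is an approximation: expression scales
differ across platforms and no further harmonization is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError, CoverageError
from .types import ExpressionMatrix, GroupAssignment, ScoreVector, Signature

logger = logging.getLogger(__name__)

DEFAULT_BINARY_THRESHOLD = 1.709


@dataclass
class ComparatorSpec:
    """A published signature plus how to apply it.

    ``mode`` is ``"weighted"`` (needs ``coefficients``) or ``"binary_cutoff"``
    (needs ``reference_cutoffs`` and ``reference_medians`` per gene plus a
    decision ``threshold``).
    """

    name: str
    genes: list[str]
    mode: str
    coefficients: dict[str, float] = field(default_factory=dict)
    reference_cutoffs: dict[str, float] = field(default_factory=dict)
    reference_medians: dict[str, float] = field(default_factory=dict)
    weights: dict[str, float] = field(default_factory=dict)
    threshold: float = DEFAULT_BINARY_THRESHOLD

    def __post_init__(self) -> None:
        if self.mode not in ("weighted", "binary_cutoff"):
            raise ConfigError(f"unknown comparator mode {self.mode!r}")
        if self.mode == "weighted":
            missing = [g for g in self.genes if g not in self.coefficients]
            if missing:
                raise ConfigError(f"{self.name}: no coefficient for {missing}")
        else:
            for g in self.genes:
                if g not in self.reference_cutoffs or g not in self.reference_medians:
                    raise ConfigError(f"{self.name}: missing reference cutoff/median for {g!r}")
                if self.reference_medians[g] <= 0:
                    raise ConfigError(
                        f"{self.name}: reference median for {g!r} must be > 0")


def weighted_score(expr: ExpressionMatrix, spec: ComparatorSpec) -> ScoreVector:
    """Coefficient-weighted sum of expression; platform-absent genes dropped."""
    if spec.mode != "weighted":
        raise ConfigError(f"{spec.name} is not a weighted-mode spec")
    sig = Signature(
        name=spec.name,
        entries=tuple((g, spec.coefficients[g]) for g in spec.genes),
    )
    from .scoring import compute_score

    # comparator re-application tolerates any non-zero coverage (the published
    # use drops single platform-absent genes)
    return compute_score(expr, sig, min_coverage=0.0)


def transfer_cutoffs(
    spec: ComparatorSpec, target_medians: Mapping[str, float]
) -> dict[str, float]:
    """Rescale reference per-gene cut-offs to a target cohort via median ratios.

    coefficient_g = reference_cutoff_g / reference_median_g;
    target_cutoff_g = coefficient_g * target_median_g.
    """
    if spec.mode != "binary_cutoff":
        raise ConfigError(f"{spec.name} is not a binary_cutoff-mode spec")
    out: dict[str, float] = {}
    for gene in spec.genes:
        if gene not in target_medians:
            raise ConfigError(f"no target median supplied for {gene!r}")
        tm = target_medians[gene]
        if tm <= 0:
            raise ConfigError(f"transfer failed: non-positive target median for {gene!r}")
        coefficient = spec.reference_cutoffs[gene] / spec.reference_medians[gene]
        out[gene] = coefficient * tm
    return out


def binary_risk_score(
    expr: ExpressionMatrix,
    cutoffs: Mapping[str, float],
    weights: Mapping[str, float],
    threshold: float = DEFAULT_BINARY_THRESHOLD,
) -> tuple[pd.Series, GroupAssignment]:
    """Presence/absence risk score: gene counts 1 when expression exceeds its
    cut-off, 0 otherwise; risk = weighted sum of indicators; group = high when
    risk > threshold."""
    genes = list(cutoffs)
    if set(genes) != set(weights):
        raise ConfigError("cutoffs and weights must cover the same genes")
    present = [g for g in genes if g in expr.values.index]
    if not present:
        raise CoverageError("no cut-off gene present in the expression matrix")
    absent = [g for g in genes if g not in expr.values.index]
    if absent:
        logger.info("binary_risk_score: %d gene(s) absent, treated as 0: %s",
                    len(absent), absent)
    risk = pd.Series(0.0, index=expr.values.columns)
    for g in present:
        indicator = (expr.values.loc[g] > cutoffs[g]).astype(float)
        risk += weights[g] * indicator
    groups = pd.Series(np.where(risk > threshold, "high", "low"), index=risk.index)
    return risk, GroupAssignment(groups=groups, cutoff=float(threshold),
                                 cutoff_rule="fixed_threshold")


def read_comparator_spec(path, delimiter: str = "\t") -> ComparatorSpec:
    """Read a comparator spec file: '# key = value' headers (name, mode,
    threshold) followed by per-gene columns.

    Weighted mode: columns gene, coefficient. Binary mode: columns gene,
    reference_cutoff, reference_median, weight.
    """
    from pathlib import Path

    meta: dict[str, str] = {}
    rows: list[list[str]] = []
    header: list[str] | None = None
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                k, v = body.split("=", 1)
                meta[k.strip()] = v.strip()
            continue
        parts = line.split(delimiter)
        if header is None:
            header = [p.strip().lower() for p in parts]
            continue
        rows.append(parts)
    if header is None or not rows:
        raise ConfigError(f"{path}: empty comparator spec")
    mode = meta.get("mode", "weighted")
    name = meta.get("name", Path(path).stem)
    table = pd.DataFrame(rows, columns=header).set_index("gene")
    genes = list(table.index)
    if mode == "weighted":
        return ComparatorSpec(
            name=name, genes=genes, mode=mode,
            coefficients=table["coefficient"].astype(float).to_dict(),
        )
    return ComparatorSpec(
        name=name, genes=genes, mode=mode,
        reference_cutoffs=table["reference_cutoff"].astype(float).to_dict(),
        reference_medians=table["reference_median"].astype(float).to_dict(),
        weights=table["weight"].astype(float).to_dict() if "weight" in table else {},
        threshold=float(meta.get("threshold", DEFAULT_BINARY_THRESHOLD)),
    )
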