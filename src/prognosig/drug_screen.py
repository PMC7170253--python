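"""Score-vs-cytotoxicity drug screen.

Filters compounds by testing breadth, correlates per-cell-line signature
scores with per-drug AUC (Pearson), and labels significant compounds by the
group they preferentially target.

Sign conventions: AUC summarises a dose-viability curve, so a LOWER AUC
means greater sensitivity. Under the default ``auc_low_is_sensitive``
convention a negative score-AUC correlation therefore marks a drug as
preferentially effective on high-score lines. The inverse ("literal")
convention is available for compatibility with sources that state the
opposite reading.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, EmptyCohortError
from .types import DrugResponseTable, ScoreVector

logger = logging.getLogger(__name__)

DEFAULT_MIN_LINES = 10
DEFAULT_REQUIRED_CONCENTRATIONS = 16
DEFAULT_ALPHA = 0.05

TARGETS_HIGH = "targets_high_score_group"
TARGETS_LOW = "targets_low_score_group"
NOT_SIGNIFICANT = "not_significant"


@dataclass
class DrugCorrelation:
    drug_id: str
    r: float
    p: float
    n: int
    skipped: bool = False
    reason: str = ""


def filter_drugs(
    table: DrugResponseTable,
    min_lines: int = DEFAULT_MIN_LINES,
    required_concentrations: int | None = DEFAULT_REQUIRED_CONCENTRATIONS,
) -> DrugResponseTable:
    """Keep drugs tested on >= ``min_lines`` cell lines (and, when metadata is
    present, screened at exactly ``required_concentrations`` concentrations)."""
    if table.auc.shape[1] == 0:
        raise ConfigError("empty drug-response table")
    tested = table.auc.notna().sum(axis=0)
    keep = tested >= min_lines
    if required_concentrations is not None and table.n_concentrations is not None:
        keep &= table.n_concentrations == required_concentrations
    kept = list(table.auc.columns[keep])
    dropped = table.auc.shape[1] - len(kept)
    if dropped:
        logger.info("filter_drugs: removed %d of %d drugs", dropped, table.auc.shape[1])
    if not kept:
        logger.warning("filter_drugs: no drug passed the filters")
    nconc = table.n_concentrations.loc[kept] if table.n_concentrations is not None else None
    return DrugResponseTable(auc=table.auc.loc[:, kept], n_concentrations=nconc)


def correlate_score_auc(
    scores: ScoreVector,
    table: DrugResponseTable,
    exclusions: list[str] | None = None,
) -> list[DrugCorrelation]:
    """Pearson correlation of signature score vs AUC per drug.

    ``exclusions`` removes named cell lines before correlating (outlier
    handling). Drugs with < 3 overlapping non-missing points, or zero
    variance in either variable, are skipped with a reason.
    """
    excluded = set(exclusions or [])
    score = scores.scores.drop(index=[s for s in excluded if s in scores.scores.index])
    lines = [l for l in table.cell_line_ids if l in set(score.index)]
    if not lines:
        raise EmptyCohortError("no overlap between scored lines and the AUC table")
    auc = table.auc.loc[lines]
    score = score.loc[lines]

    results: list[DrugCorrelation] = []
    for drug in table.drug_ids:
        col = auc[drug]
        ok = col.notna()
        n = int(ok.sum())
        if n < 3:
            results.append(DrugCorrelation(drug, np.nan, np.nan, n,
                                           skipped=True, reason="fewer than 3 points"))
            continue
        x = score[ok].to_numpy()
        y = col[ok].to_numpy()
        if np.std(x) == 0 or np.std(y) == 0:
            results.append(DrugCorrelation(drug, np.nan, np.nan, n,
                                           skipped=True, reason="zero variance"))
            continue
        r, p = stats.pearsonr(x, y)
        results.append(DrugCorrelation(drug, float(r), float(p), n))
    return results


def classify_targets(
    correlations: list[DrugCorrelation],
    alpha: float = DEFAULT_ALPHA,
    convention: str = "auc_low_is_sensitive",
    fdr: bool = False,
) -> pd.DataFrame:
    """Label significant drugs by the score group they preferentially target.

    Returns a DataFrame (one row per non-skipped drug, sorted by p) with
    columns r, p, n, label. ``convention`` is ``auc_low_is_sensitive``
    (default: negative r -> targets the high-score group) or ``literal``
    (the inverse sign reading). ``fdr=True`` applies Benjamini-Hochberg and
    labels on adjusted p-values.
    """
    if convention not in ("auc_low_is_sensitive", "literal"):
        raise ConfigError(f"unknown sign convention {convention!r}")
    rows = [c for c in correlations if not c.skipped]
    df = pd.DataFrame(
        {"r": [c.r for c in rows], "p": [c.p for c in rows], "n": [c.n for c in rows]},
        index=pd.Index([c.drug_id for c in rows], name="drug"),
    ).sort_values("p")
    pvals = df["p"].to_numpy()
    if fdr and len(df):
        m = len(pvals)
        adj = pvals * m / (np.arange(m) + 1)
        adj = np.minimum.accumulate(adj[::-1])[::-1]
        df["p_adj"] = np.minimum(adj, 1.0)
        sig = df["p_adj"] < alpha
    else:
        sig = df["p"] < alpha
    neg = df["r"] < 0
    if convention == "auc_low_is_sensitive":
        high_mask = sig & neg
        low_mask = sig & ~neg
    else:
        high_mask = sig & ~neg
        low_mask = sig & neg
    df["label"] = NOT_SIGNIFICANT
    df.loc[high_mask, "label"] = TARGETS_HIGH
    df.loc[low_mask, "label"] = TARGETS_LOW
    return df


def write_screen_report(report: pd.DataFrame, path, delimiter: str = "\t") -> None:
    report.to_csv(path, sep=delimiter, index_label="drug")
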