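"""Per-gene univariate Cox screening and rank-based prioritization.

Each gene is fit in a single-covariate Cox proportional-hazards model
(Efron tie handling, Newton-Raphson on the partial likelihood). Genes are
then ranked twice — ascending by Wald p-value and descending by folded
hazard ratio max(HR, 1/HR) — and prioritized by the sum of the two ranks
("ranksum", smaller = stronger candidate).

The dedicated solver here is ~100x faster than a generic fitter on a
one-column model, which matters when screening thousands of genes across
several cohorts; it is validated against lifelines and a brute-force
partial-likelihood oracle in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateError, EmptyCohortError
from .expression_io import intersect_samples
from .types import ExpressionMatrix, SurvivalTable

_Z975 = stats.norm.ppf(0.975)


@dataclass
class CoxResult:
    """Univariate Cox fit for one gene: HR per unit expression, Wald CI and p."""

    gene_id: str
    coef: float
    hr: float
    ci_low: float
    ci_high: float
    se: float
    p: float
    n: int
    n_events: int
    degenerate: bool = False
    reason: str = ""

    @classmethod
    def make_degenerate(cls, gene_id: str, n: int, n_events: int, reason: str) -> "CoxResult":
        nan = float("nan")
        return cls(gene_id, nan, nan, nan, nan, nan, nan, n, n_events,
                   degenerate=True, reason=reason)


@dataclass
class RankTable:
    """Per-gene Cox statistics plus p-rank, folded-HR rank and their sum.

    ``table`` is indexed by gene and sorted ascending by ranksum; ties in
    either rank receive average ranks.
    """

    table: pd.DataFrame
    degenerate_genes: list[str]

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)

    def __len__(self) -> int:
        return len(self.table)


class _EfronLayout:
    """Precomputed sort order and tie structure for one (time, event) pair.

    Samples are sorted ascending by time with events before censorings at
    tied times, so the risk set at each distinct event time is a suffix of
    the sorted array and the tied deaths are a contiguous run at its start.
    All per-coefficient quantities then reduce to cumulative sums, making a
    likelihood/derivative evaluation O(n) in numpy.
    """

    def __init__(self, time: np.ndarray, event: np.ndarray):
        self.order = np.lexsort((1 - event, time))
        self.t = time[self.order]
        self.e = event[self.order]
        event_times = np.unique(self.t[self.e == 1])
        self.starts = np.searchsorted(self.t, event_times, side="left")
        # deaths per distinct event time (contiguous from each start)
        self.m = np.array(
            [int(((self.t == tau) & (self.e == 1)).sum()) for tau in event_times]
        )
        self.ends = self.starts + self.m
        # one row per Efron term l = 0..m-1, expanded over all groups
        self.rep = np.repeat(np.arange(len(self.m)), self.m)
        self.frac = (np.concatenate([np.arange(m) / m for m in self.m])
                     if len(self.m) else np.array([]))
        self.dead_mask = np.zeros(len(self.t), dtype=bool)
        for s, e_ in zip(self.starts, self.ends):
            self.dead_mask[s:e_] = True
        self.z = np.zeros(len(self.t))
        self.sum_z_dead = 0.0

    def bind(self, x: np.ndarray) -> None:
        """Attach (already standardized) covariate values in original sample order."""
        self.z = x[self.order]
        self.sum_z_dead = float(self.z[self.dead_mask].sum())

    def _suffix(self, v: np.ndarray) -> np.ndarray:
        out = np.zeros(len(v) + 1)
        out[:-1] = np.cumsum(v[::-1])[::-1]
        return out

    def _terms(self, b: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        w = np.exp(b * self.z)
        wz = w * self.z
        wzz = wz * self.z
        c0, c1, c2 = self._suffix(w), self._suffix(wz), self._suffix(wzz)
        s, e = self.starts, self.ends
        # risk-set sums at each group start; tied-death sums via suffix differences
        r0, r1, r2 = c0[s], c1[s], c2[s]
        d0, d1, d2 = c0[s] - c0[e], c1[s] - c1[e], c2[s] - c2[e]
        g = self.rep
        f = self.frac
        A0 = r0[g] - f * d0[g]
        A1 = r1[g] - f * d1[g]
        A2 = r2[g] - f * d2[g]
        return A0, A1, A2

    def loglik(self, b: float) -> float:
        A0, _, _ = self._terms(b)
        return b * self.sum_z_dead - float(np.log(A0).sum())

    def grad_hess(self, b: float) -> tuple[float, float]:
        A0, A1, A2 = self._terms(b)
        ratio = A1 / A0
        grad = self.sum_z_dead - float(ratio.sum())
        hess = -float((A2 / A0 - ratio**2).sum())
        return grad, hess


def fit_univariate_cox(
    expression: np.ndarray | pd.Series,
    survival: SurvivalTable,
    gene_id: str = "",
    max_iter: int = 50,
    tol: float = 1e-10,
    _layout: _EfronLayout | None = None,
) -> CoxResult:
    """Fit survival on a single continuous covariate (Efron ties, Wald inference).

    Degenerate inputs (constant covariate, fewer than two events, or a
    non-converging monotone likelihood) return a flagged result instead of
    raising, so screens can simply set such genes aside.
    """
    x = np.asarray(expression, dtype=float)
    time, event = survival.time, survival.event
    if len(x) != len(time):
        raise DegenerateError(f"covariate length {len(x)} != survival rows {len(time)}")
    n, n_events = len(x), int(event.sum())
    if n_events < 2:
        return CoxResult.make_degenerate(gene_id, n, n_events, "fewer than 2 events")
    sd = float(np.std(x))
    if sd == 0 or not np.isfinite(sd):
        return CoxResult.make_degenerate(gene_id, n, n_events, "constant covariate")

    z = (x - x.mean()) / sd  # centering/scaling leaves the partial likelihood shape intact
    layout = _layout if _layout is not None else _EfronLayout(time, event)
    layout.bind(z)

    b = 0.0
    converged = False
    for _ in range(max_iter):
        grad, hess = layout.grad_hess(b)
        if hess >= 0 or not np.isfinite(hess):
            break
        step = -grad / hess
        # step-halving keeps Newton inside the concave region
        ll_old = layout.loglik(b)
        for _ in range(30):
            b_new = b + step
            if abs(b_new) < 50 and layout.loglik(b_new) >= ll_old - 1e-12:
                break
            step /= 2.0
        else:
            break
        b = b + step
        if abs(step) < tol:
            converged = True
            break
    grad, hess = layout.grad_hess(b)
    if not converged and abs(grad) > 1e-4:
        return CoxResult.make_degenerate(
            gene_id, n, n_events, "no convergence (monotone likelihood?)")
    if abs(b) >= 45:
        return CoxResult.make_degenerate(
            gene_id, n, n_events, "coefficient diverged (monotone likelihood)")
    if hess >= 0 or not np.isfinite(hess):
        return CoxResult.make_degenerate(gene_id, n, n_events, "non-concave at optimum")

    se_z = float(np.sqrt(-1.0 / hess))
    coef = b / sd  # back to per-unit-expression scale
    se = se_z / sd
    zstat = coef / se
    p = float(2.0 * stats.norm.sf(abs(zstat)))
    return CoxResult(
        gene_id=gene_id,
        coef=float(coef),
        hr=float(np.exp(coef)),
        ci_low=float(np.exp(coef - _Z975 * se)),
        ci_high=float(np.exp(coef + _Z975 * se)),
        se=float(se),
        p=p,
        n=n,
        n_events=n_events,
    )


def screen_genes(
    expr: ExpressionMatrix,
    survival: SurvivalTable,
) -> list[CoxResult]:
    """Univariate Cox fit of every gene against survival (samples intersected first)."""
    expr, survival = intersect_samples(expr, survival)
    if survival.n_samples == 0:
        raise EmptyCohortError("no samples to screen")
    values = expr.values.to_numpy(dtype=float)
    layout = _EfronLayout(survival.time, survival.event)  # shared across genes
    results = []
    for i, gene in enumerate(expr.gene_ids):
        results.append(fit_univariate_cox(values[i], survival, gene_id=gene, _layout=layout))
    return results


def rank_genes(results: list[CoxResult]) -> RankTable:
    """Rank genes by p-value and folded HR; prioritize by ranksum ascending.

    p_rank 1 = smallest p; hr_rank 1 = largest max(HR, 1/HR); ties get
    average ranks. Degenerate fits are excluded from ranking and listed
    separately.
    """
    usable = [r for r in results if not r.degenerate]
    degenerate = sorted(r.gene_id for r in results if r.degenerate)
    if not usable:
        raise DegenerateError("no non-degenerate Cox results to rank")
    df = pd.DataFrame(
        {
            "hr": [r.hr for r in usable],
            "ci_low": [r.ci_low for r in usable],
            "ci_high": [r.ci_high for r in usable],
            "p": [r.p for r in usable],
            "n": [r.n for r in usable],
        },
        index=pd.Index([r.gene_id for r in usable], name="gene"),
    )
    folded = np.maximum(df["hr"], 1.0 / df["hr"])
    df["folded_hr"] = folded
    df["p_rank"] = stats.rankdata(df["p"], method="average")
    df["hr_rank"] = stats.rankdata(-folded, method="average")
    df["ranksum"] = df["p_rank"] + df["hr_rank"]
    df = df.sort_values(["ranksum", "p", "gene"], kind="stable")
    return RankTable(table=df, degenerate_genes=degenerate)


def write_rank_table(rank_table: RankTable, path, delimiter: str = "\t") -> None:
    cols = ["hr", "ci_low", "ci_high", "p", "folded_hr", "p_rank", "hr_rank", "ranksum"]
    rank_table.table[cols].to_csv(path, sep=delimiter, index_label="gene")


def read_rank_table(path, delimiter: str = "\t") -> RankTable:
    df = pd.read_csv(path, sep=delimiter, index_col="gene")
    return RankTable(table=df, degenerate_genes=[])
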