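"""Independent brute-force oracles used by multiple test modules.

These deliberately share no code with the package: naive loops, closed-form
textbook formulas, and generic scalar optimization only.
"""

import numpy as np
from scipy import optimize, stats


def efron_negative_loglik(b, time, event, x):
    """Naive-loop Efron partial log-likelihood (negated) for one covariate."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    x = np.asarray(x, dtype=float)
    ll = 0.0
    for tau in sorted(set(time[event == 1])):
        at_risk = x[time >= tau]
        dead = x[(time == tau) & (event == 1)]
        m = len(dead)
        ll += b * dead.sum()
        for l in range(m):
            ll -= np.log(
                np.exp(b * at_risk).sum() - (l / m) * np.exp(b * dead).sum()
            )
    return -ll


def brute_force_cox_coef(time, event, x, bound=20.0):
    """Maximize the Efron partial likelihood by bounded scalar search."""
    res = optimize.minimize_scalar(
        efron_negative_loglik,
        args=(time, event, x),
        bounds=(-bound, bound),
        method="bounded",
        options={"xatol": 1e-13},
    )
    return float(res.x)


def hand_logrank(time, event, group):
    """Two-group log-rank by the observed-minus-expected tables."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    observed = expected = variance = 0.0
    for tau in sorted(set(time[event == 1])):
        n = int((time >= tau).sum())
        n1 = int(((time >= tau) & (group == 0)).sum())
        d = int(((time == tau) & (event == 1)).sum())
        d1 = int(((time == tau) & (event == 1) & (group == 0)).sum())
        observed += d1
        expected += d * n1 / n
        if n > 1:
            variance += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    stat = (observed - expected) ** 2 / variance
    return stat, float(stats.chi2.sf(stat, df=1))


def welch_t(x, y):
    """Textbook Welch t statistic, Satterthwaite df, two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    n1, n2 = len(x), len(y)
    se2 = v1 / n1 + v2 / n2
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    return t, float(2 * stats.t.sf(abs(t), df))


def yates_chi2(table):
    """Sum of (|O - E| - 0.5)^2 / E over a 2x2 table."""
    obs = np.asarray(table, dtype=float)
    expected = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
    stat = (((np.abs(obs - expected) - 0.5) ** 2) / expected).sum()
    return stat, float(stats.chi2.sf(stat, df=1))
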