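"""Synthetic multi-cohort expression/survival data with planted prognostic genes.

Counts follow a negative-binomial model with log-uniform library sizes.
Event times are exponential with hazard
``baseline_hazard * exp(sum_g beta_g * z_g)`` where ``z_g`` is the
standardized log-CPM of planted gene ``g``; censoring is independent
uniform on [0, T_max] with T_max solved numerically to hit a target
censoring fraction. Everything is a pure function of config + seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import ConfigError
from .expression_io import compute_cpm, log_transform
from .scoring import compute_score
from .types import DrugResponseTable, ExpressionMatrix, Signature, SurvivalTable


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters for one synthetic cohort."""

    n_genes: int
    n_samples: int
    n_planted_adverse: int = 0
    n_planted_favorable: int = 0
    beta_magnitude: float = 1.0
    baseline_hazard: float = 0.05  # events per month
    censor_rate_target: float = 0.3
    nb_dispersion: float = 0.4
    library_size_range: tuple[int, int] = (500_000, 2_000_000)
    #: loading of planted genes on a shared per-sample latent program
    #: (sign-consistent co-expression, as real signature genes exhibit); 0
    #: makes planted genes mutually independent, which dilutes the marginal
    #: per-gene effect badly when many genes are planted
    planted_coexpression: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_samples < 1:
            raise ConfigError("n_genes and n_samples must be positive")
        if self.n_planted_adverse < 0 or self.n_planted_favorable < 0:
            raise ConfigError("planted gene counts must be non-negative")
        if self.n_planted_adverse + self.n_planted_favorable > self.n_genes:
            raise ConfigError("more planted genes than genes")
        if self.baseline_hazard <= 0:
            raise ConfigError("baseline_hazard must be positive")
        if not 0 <= self.censor_rate_target < 1:
            raise ConfigError("censor_rate_target must be in [0, 1)")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be positive")
        if self.planted_coexpression < 0:
            raise ConfigError("planted_coexpression must be non-negative")
        lo, hi = self.library_size_range
        if lo <= 0 or hi < lo:
            raise ConfigError("library_size_range must be a positive (low, high) pair")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth for a generated cohort: which genes drive the hazard."""

    planted_genes: tuple[tuple[str, int, float], ...]  # (gene id, sign, beta)
    seed: int
    config: SyntheticConfig

    @property
    def gene_ids(self) -> list[str]:
        return [g for g, _, _ in self.planted_genes]

    @property
    def signs(self) -> dict[str, int]:
        return {g: s for g, s, _ in self.planted_genes}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "planted_genes": [list(p) for p in self.planted_genes],
            "config": asdict(self.config),
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def _gene_level_params(config: SyntheticConfig) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Gene abundances, ids and planted betas; a function of config.seed only,
    so cohorts sharing a config share planted genes and signs."""
    rng = np.random.default_rng(config.seed)
    log_abundance = rng.normal(loc=2.0, scale=1.5, size=config.n_genes)
    abundance = np.exp(log_abundance)
    abundance /= abundance.sum()
    gene_ids = [f"G{i:05d}" for i in range(config.n_genes)]
    n_planted = config.n_planted_adverse + config.n_planted_favorable
    planted_idx = rng.choice(config.n_genes, size=n_planted, replace=False)
    betas = np.zeros(config.n_genes)
    betas[planted_idx[: config.n_planted_adverse]] = config.beta_magnitude
    betas[planted_idx[config.n_planted_adverse:]] = -config.beta_magnitude
    return abundance, gene_ids, betas


def _solve_censor_horizon(rates: np.ndarray, target: float) -> float:
    """Horizon c of a Uniform(0, c) censoring time such that the mean
    probability of censoring, (1 - exp(-rate*c)) / (rate*c), hits ``target``."""

    def censored_fraction(log_c: float) -> float:
        c = np.exp(log_c)
        lam_c = rates * c
        return float(np.mean((1.0 - np.exp(-lam_c)) / lam_c)) - target

    lo, hi = -10.0, 10.0 - float(np.log(rates.mean()))
    while censored_fraction(hi) > 0:
        hi += 5.0
    while censored_fraction(lo) < 0:
        lo -= 5.0
    return float(np.exp(optimize.brentq(censored_fraction, lo, hi, xtol=1e-10)))


def _sample_cohort(
    config: SyntheticConfig, sample_seed: int
) -> tuple[ExpressionMatrix, SurvivalTable, SyntheticTruth]:
    abundance, gene_ids, betas = _gene_level_params(config)
    rng = np.random.default_rng((config.seed, sample_seed))
    n_g, n_s = config.n_genes, config.n_samples

    lo, hi = config.library_size_range
    lib_sizes = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_s))
    mu = abundance[:, None] * lib_sizes[None, :]
    planted_pre = np.nonzero(betas)[0]
    if len(planted_pre) and config.planted_coexpression > 0:
        # shared latent program: adverse genes load positively, favorable
        # negatively, so planted genes co-vary like a real expression module
        latent = rng.normal(size=n_s)
        for i in planted_pre:
            mu[i] *= np.exp(np.sign(betas[i]) * config.planted_coexpression * latent)
    r = 1.0 / config.nb_dispersion  # NB size parameter: var = mu + dispersion * mu^2
    counts = rng.negative_binomial(n=r, p=r / (r + mu), size=(n_g, n_s))

    sample_ids = [f"S{sample_seed}_{j:04d}" for j in range(n_s)]
    expr = ExpressionMatrix(
        values=pd.DataFrame(counts, index=gene_ids, columns=sample_ids, dtype=float),
        unit="counts",
    )

    log_cpm = log_transform(compute_cpm(expr)).values.to_numpy()
    planted = np.nonzero(betas)[0]
    linpred = np.zeros(n_s)
    for i in planted:
        row = log_cpm[i]
        sd = row.std()
        z = (row - row.mean()) / sd if sd > 0 else np.zeros(n_s)
        linpred += betas[i] * z
    rates = config.baseline_hazard * np.exp(linpred)
    t_event = rng.exponential(1.0 / rates)

    if config.censor_rate_target > 0:
        horizon = _solve_censor_horizon(rates, config.censor_rate_target)
        t_censor = rng.uniform(0.0, horizon, size=n_s)
        time = np.minimum(t_event, t_censor)
        event = (t_event <= t_censor).astype(int)
    else:
        time, event = t_event, np.ones(n_s, dtype=int)

    survival = SurvivalTable(
        data=pd.DataFrame({"time": time, "event": event}, index=sample_ids),
        time_unit="months",
    )
    truth = SyntheticTruth(
        planted_genes=tuple(
            (gene_ids[i], int(np.sign(betas[i])), float(betas[i])) for i in planted
        ),
        seed=sample_seed,
        config=config,
    )
    return expr, survival, truth


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[ExpressionMatrix, SurvivalTable, SyntheticTruth]:
    """One cohort of NB counts plus right-censored survival, per ``config``."""
    return _sample_cohort(config, sample_seed=config.seed)


def generate_multi_cohorts(
    config: SyntheticConfig,
    n_cohorts: int,
    cohort_seeds: Sequence[int],
) -> list[tuple[ExpressionMatrix, SurvivalTable, SyntheticTruth]]:
    """Independent cohorts sharing planted gene identities and signs."""
    if n_cohorts < 1:
        raise ConfigError("n_cohorts must be positive")
    if len(cohort_seeds) != n_cohorts:
        raise ConfigError(
            f"need {n_cohorts} cohort seeds, got {len(cohort_seeds)}")
    return [_sample_cohort(config, sample_seed=s) for s in cohort_seeds]


def generate_cellline_panel(
    signature: Signature,
    n_lines: int,
    n_drugs: int,
    effect_map: Sequence[tuple[str, float]],
    noise_sd: float,
    seed: int,
    n_extra_genes: int = 50,
    missing_fraction: float = 0.1,
    auc_intercept: float = 10.0,
) -> tuple[ExpressionMatrix, DrugResponseTable, SyntheticTruth]:
    """Cell-line panel whose per-drug AUC depends linearly on the signature score.

    Drugs named ``D0000``..; any drug listed in ``effect_map`` gets
    ``AUC = intercept + slope * score + N(0, noise_sd)``; all other drugs are
    score-independent noise around the intercept. A ``missing_fraction`` of
    cells is blanked to mimic incomplete screening.
    """
    if n_lines < 3:
        raise ConfigError("need at least 3 cell lines (correlation undefined below 3)")
    if n_drugs < 1:
        raise ConfigError("n_drugs must be positive")
    drug_ids = [f"D{j:04d}" for j in range(n_drugs)]
    unknown = [d for d, _ in effect_map if d not in set(drug_ids)]
    if unknown:
        raise ConfigError(f"effect_map references unknown drugs: {unknown}")
    if noise_sd < 0:
        raise ConfigError("noise_sd must be non-negative")

    rng = np.random.default_rng(seed)
    line_ids = [f"CL{j:03d}" for j in range(n_lines)]
    genes = list(signature.genes) + [f"X{j:04d}" for j in range(n_extra_genes)]
    values = rng.normal(loc=5.0, scale=1.5, size=(len(genes), n_lines))
    expr = ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=line_ids),
        unit="array_log",
    )
    score = compute_score(expr, signature).scores.to_numpy()

    slopes = dict(effect_map)
    auc = np.empty((n_lines, n_drugs))
    for j, drug in enumerate(drug_ids):
        noise = rng.normal(0.0, noise_sd, size=n_lines) if noise_sd > 0 else 0.0
        if drug in slopes:
            auc[:, j] = auc_intercept + slopes[drug] * score + noise
        else:
            auc[:, j] = auc_intercept + rng.normal(0.0, max(noise_sd, 1.0), size=n_lines)
    if missing_fraction > 0:
        mask = rng.random((n_lines, n_drugs)) < missing_fraction
        auc[mask] = np.nan
    table = DrugResponseTable(
        auc=pd.DataFrame(auc, index=line_ids, columns=drug_ids),
        n_concentrations=pd.Series(16, index=drug_ids),
    )
    truth = SyntheticTruth(
        planted_genes=tuple((d, int(np.sign(s)), float(s)) for d, s in effect_map),
        seed=seed,
        config=SyntheticConfig(n_genes=len(genes), n_samples=n_lines, seed=seed),
    )
    return expr, table, truth
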