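"""Core domain types shared across the pipeline.

All tabular containers wrap pandas objects: an expression matrix is a
genes x samples DataFrame plus an explicit unit tag, a survival table is a
samples x (time, event, covariates...) DataFrame plus a time unit.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, FormatError

#: Recognised expression units. ``counts``/``cpm``/``rsem`` are linear scale;
#: the rest are log scale.
UNITS = ("counts", "cpm", "rsem", "log_cpm", "log_rsem", "array_log")
LINEAR_UNITS = frozenset({"counts", "cpm", "rsem"})
LOG_UNITS = frozenset({"log_cpm", "log_rsem", "array_log"})


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with an explicit unit tag.

    Parameters
    ----------
    values
        DataFrame indexed by gene (or probe) id, columns are sample ids.
    unit
        One of :data:`UNITS`.
    """

    values: pd.DataFrame
    unit: str

    def __post_init__(self) -> None:
        if self.unit not in UNITS:
            raise ConfigError(f"unknown expression unit {self.unit!r}; expected one of {UNITS}")
        # zero genes is allowed (a filter may remove everything); zero samples is not
        if self.values.shape[1] == 0:
            raise FormatError("expression matrix must have at least one sample")
        cols = self.values.columns
        if cols.duplicated().any():
            dupes = sorted(set(cols[cols.duplicated()]))
            raise FormatError(f"duplicate sample ids: {dupes}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def is_log_scale(self) -> bool:
        return self.unit in LOG_UNITS

    def with_values(self, values: pd.DataFrame, unit: str | None = None) -> "ExpressionMatrix":
        return ExpressionMatrix(values=values, unit=unit or self.unit)

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise FormatError(f"samples not in matrix: {missing[:5]}")
        return self.with_values(self.values.loc[:, list(sample_ids)])


@dataclass
class SurvivalTable:
    """Per-sample right-censored survival data.

    ``data`` is indexed by sample id and must contain ``time`` (non-negative)
    and ``event`` (1 = event observed, 0 = censored); any further columns are
    treated as clinical covariates.
    """

    data: pd.DataFrame
    time_unit: str = "months"

    def __post_init__(self) -> None:
        if self.time_unit not in ("days", "months"):
            raise ConfigError(f"time_unit must be 'days' or 'months', got {self.time_unit!r}")
        for col in ("time", "event"):
            if col not in self.data.columns:
                raise FormatError(f"survival table missing required column {col!r}")
        if self.data.index.duplicated().any():
            raise FormatError("duplicate sample ids in survival table")
        if (self.data["time"] < 0).any():
            raise FormatError("negative survival times")
        ev = set(pd.unique(self.data["event"].dropna()))
        if not ev <= {0, 1}:
            raise FormatError(f"event column must be 0/1, found {sorted(ev)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def time(self) -> np.ndarray:
        return self.data["time"].to_numpy(dtype=float)

    @property
    def event(self) -> np.ndarray:
        return self.data["event"].to_numpy(dtype=int)

    @property
    def n_samples(self) -> int:
        return len(self.data)

    @property
    def n_events(self) -> int:
        return int(self.data["event"].sum())

    @property
    def covariate_names(self) -> list[str]:
        return [c for c in self.data.columns if c not in ("time", "event")]

    def subset(self, sample_ids: Sequence[str]) -> "SurvivalTable":
        return SurvivalTable(self.data.loc[list(sample_ids)].copy(), self.time_unit)


@dataclass(frozen=True)
class Signature:
    """An ordered gene list, each gene carrying a sign (+/-1) or coefficient.

    Signs follow the adverse/favorable convention: +1 (or a positive
    coefficient) marks genes whose high expression associates with worse
    outcome.
    """

    name: str
    entries: tuple[tuple[str, float], ...]
    provenance: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        genes = [g for g, _ in self.entries]
        if len(set(genes)) != len(genes):
            dupes = sorted({g for g in genes if genes.count(g) > 1})
            raise ConfigError(f"duplicate genes in signature {self.name!r}: {dupes}")

    @property
    def genes(self) -> list[str]:
        return [g for g, _ in self.entries]

    @property
    def weights(self) -> dict[str, float]:
        return dict(self.entries)

    @property
    def positive_genes(self) -> list[str]:
        return [g for g, w in self.entries if w > 0]

    @property
    def negative_genes(self) -> list[str]:
        return [g for g, w in self.entries if w < 0]

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_formula(cls, name: str, formula: str, **provenance: object) -> "Signature":
        """Parse a signed-sum formula like ``"A-B+C"`` into unit-weight entries.

        A leading term without an explicit sign is positive.
        """
        compact = formula.replace(" ", "")
        terms = re.findall(r"([+-]?)([A-Za-z0-9_.]+)", compact)
        if not terms or "".join(s + g for s, g in terms) != compact:
            raise FormatError(f"cannot parse signature formula: {formula!r}")
        entries = tuple((g, -1.0 if s == "-" else 1.0) for s, g in terms)
        return cls(name=name, entries=entries, provenance=dict(provenance))


@dataclass
class ScoreVector:
    """Per-sample signature scores plus the genes actually used."""

    scores: pd.Series
    signature_name: str
    genes_used: list[str]
    genes_missing: list[str] = field(default_factory=list)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.index)

    def __len__(self) -> int:
        return len(self.scores)


@dataclass
class GroupAssignment:
    """High/low group labels from dichotomizing a score vector."""

    groups: pd.Series  # values "high" / "low", index sample ids
    cutoff: float
    cutoff_rule: str

    @property
    def sample_ids(self) -> list[str]:
        return list(self.groups.index)

    @property
    def high_ids(self) -> list[str]:
        return list(self.groups.index[self.groups == "high"])

    @property
    def low_ids(self) -> list[str]:
        return list(self.groups.index[self.groups == "low"])

    def indicator(self) -> pd.Series:
        """1 for high, 0 for low."""
        return (self.groups == "high").astype(int)


@dataclass
class DrugResponseTable:
    """Cell line x compound AUC matrix; NaN marks untested combinations."""

    auc: pd.DataFrame  # index cell line ids, columns drug ids
    n_concentrations: pd.Series | None = None  # per-drug metadata

    def __post_init__(self) -> None:
        vals = self.auc.to_numpy(dtype=float)
        if np.isinf(vals).any():
            raise FormatError("AUC values must be finite where present")
        if self.n_concentrations is not None:
            self.n_concentrations = self.n_concentrations.reindex(self.auc.columns)

    @property
    def cell_line_ids(self) -> list[str]:
        return list(self.auc.index)

    @property
    def drug_ids(self) -> list[str]:
        return list(self.auc.columns)

    def subset_drugs(self, drug_ids: Sequence[str]) -> "DrugResponseTable":
        nconc = None
        if self.n_concentrations is not None:
            nconc = self.n_concentrations.loc[list(drug_ids)]
        return DrugResponseTable(self.auc.loc[:, list(drug_ids)], nconc)
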