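"""Reading, writing and preprocessing of expression matrices and survival tables.

Implements the cohort-processing rules used throughout the pipeline:
counts-per-million scaling, log(x + 0.001) transforms, removal of genes with
zero counts in more than 85% of samples, probe-to-gene collapsing by mean,
and exclusion of samples with a survival time of zero.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DegenerateError, EmptyCohortError, FormatError
from .types import ExpressionMatrix, LINEAR_UNITS, Signature, SurvivalTable

logger = logging.getLogger(__name__)

DEFAULT_PSEUDOCOUNT = 0.001
DEFAULT_MAX_ZERO_FRACTION = 0.85

_LOG_UNIT_OF = {"cpm": "log_cpm", "rsem": "log_rsem"}


def read_expression(
    path: str | Path,
    unit: str,
    delimiter: str = "\t",
    skip_prefix: int = 0,
) -> ExpressionMatrix:
    """Read a delimited genes x samples matrix (first column = gene/probe ids).

    ``skip_prefix`` skips leading metadata lines (GEO series-matrix style
    headers) before the sample-id header row.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"expression file not found: {path}")
    with open(path) as fh:
        for _ in range(skip_prefix):
            fh.readline()
        header = fh.readline().rstrip("\n").split(delimiter)
    samples = [h.strip().strip('"') for h in header[1:]]
    if len(samples) != len(set(samples)):
        dupes = sorted({s for s in samples if samples.count(s) > 1})
        raise FormatError(f"duplicate sample ids in {path}: {dupes}")
    df = pd.read_csv(path, sep=delimiter, index_col=0, skiprows=skip_prefix, dtype=str)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise FormatError(f"empty expression matrix in {path}")
    df.columns = samples
    df.index = [str(i).strip().strip('"') for i in df.index]
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        rows, cols = np.nonzero(bad.to_numpy())
        locs = [
            f"(gene {df.index[r]!r}, sample {df.columns[c]!r}: {df.iat[r, c]!r})"
            for r, c in list(zip(rows, cols))[:5]
        ]
        raise FormatError(f"malformed numeric cells in {path}: {', '.join(locs)}")
    return ExpressionMatrix(values=numeric.astype(float), unit=unit)


def write_expression(expr: ExpressionMatrix, path: str | Path, delimiter: str = "\t") -> None:
    expr.values.to_csv(path, sep=delimiter, index_label="gene")


def read_survival(
    path: str | Path,
    time_unit: str,
    delimiter: str = "\t",
) -> SurvivalTable:
    """Read a delimited survival table with columns sample_id, time, event [+covariates]."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"survival file not found: {path}")
    df = pd.read_csv(path, sep=delimiter)
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: survival table needs a 'sample_id' column")
    df = df.set_index("sample_id")
    df.index = df.index.astype(str).rename(None)
    return SurvivalTable(data=df, time_unit=time_unit)


def write_survival(table: SurvivalTable, path: str | Path, delimiter: str = "\t") -> None:
    table.data.to_csv(path, sep=delimiter, index_label="sample_id")


def read_probe_map(path: str | Path, delimiter: str = "\t") -> dict[str, str]:
    """Two-column probe-id -> gene-symbol map (header optional)."""
    df = pd.read_csv(path, sep=delimiter, header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise FormatError(f"{path}: probe map needs two columns")
    first = df.iloc[0]
    if first.iloc[0].lower() in ("probe", "probe_id", "id"):
        df = df.iloc[1:]
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def compute_cpm(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Counts-per-million: value[g,s] = counts[g,s] / total[s] * 1e6."""
    if counts.unit != "counts":
        raise ConfigError(f"compute_cpm expects counts, got {counts.unit!r}")
    totals = counts.values.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise DegenerateError(f"all-zero sample column(s): {list(zero.index)}")
    cpm = counts.values.div(totals, axis=1) * 1_000_000.0
    return ExpressionMatrix(values=cpm, unit="cpm")


def log_transform(
    expr: ExpressionMatrix,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    base: float = 2,
) -> ExpressionMatrix:
    """log_base(value + pseudocount) on a linear-scale matrix."""
    if expr.unit not in LINEAR_UNITS or expr.unit == "counts":
        raise ConfigError(f"log_transform expects cpm or rsem values, got {expr.unit!r}")
    if pseudocount <= 0:
        raise ConfigError("pseudocount must be positive")
    if (expr.values.to_numpy() < 0).any():
        raise DegenerateError("negative expression values cannot be log transformed")
    if base == 2:
        logged = np.log2(expr.values + pseudocount)
    elif base in (np.e, "e"):
        logged = np.log(expr.values + pseudocount)
    else:
        logged = np.log(expr.values + pseudocount) / np.log(base)
    return ExpressionMatrix(values=logged, unit=_LOG_UNIT_OF[expr.unit])


def filter_zero_genes(
    counts: ExpressionMatrix,
    max_zero_fraction: float = DEFAULT_MAX_ZERO_FRACTION,
) -> ExpressionMatrix:
    """Drop genes whose zero-count fraction strictly exceeds ``max_zero_fraction``."""
    if counts.unit != "counts":
        raise ConfigError(f"filter_zero_genes expects counts, got {counts.unit!r}")
    zero_frac = (counts.values == 0).mean(axis=1)
    keep = zero_frac <= max_zero_fraction
    removed = list(counts.values.index[~keep])
    if removed:
        logger.info("filter_zero_genes: removed %d genes (zero fraction > %.2f): %s%s",
                    len(removed), max_zero_fraction, removed[:10],
                    "..." if len(removed) > 10 else "")
    if keep.sum() == 0:
        logger.warning("filter_zero_genes removed every gene")
    return ExpressionMatrix(values=counts.values.loc[keep], unit="counts")


def collapse_probes(
    expr: ExpressionMatrix,
    probe_to_gene: Mapping[str, str],
) -> ExpressionMatrix:
    """One row per gene symbol = arithmetic mean of its probes' rows.

    Unmapped probes are dropped (and logged). Averaging happens on the stored
    scale, log or linear, as given.
    """
    if not probe_to_gene:
        raise FormatError("empty probe-to-gene mapping")
    mapped = expr.values.index.to_series().map(dict(probe_to_gene))
    unmapped = list(expr.values.index[mapped.isna()])
    if unmapped:
        logger.info("collapse_probes: dropping %d unmapped probes: %s%s",
                    len(unmapped), unmapped[:10], "..." if len(unmapped) > 10 else "")
    kept = expr.values.loc[mapped.notna()]
    if kept.empty:
        raise FormatError("no probes could be mapped to gene symbols")
    symbols = mapped.dropna()
    collapsed = kept.groupby(symbols.values, sort=False).mean()
    collapsed = collapsed.loc[:, expr.sample_ids]  # preserve sample order
    return expr.with_values(collapsed)


def prepare_survival(
    table: SurvivalTable,
    convert_to_months: bool = False,
    days_per_month: float = 30.0,
) -> SurvivalTable:
    """Apply the zero-time exclusion rule and (optionally) the day->month conversion.

    When converting, the original times are kept in a ``time_original`` column
    so that model fits can use the unconverted values.
    """
    df = table.data.copy()
    zero = df["time"] == 0
    if zero.any():
        logger.info("prepare_survival: excluding %d sample(s) with survival time 0: %s",
                    int(zero.sum()), list(df.index[zero])[:10])
        df = df.loc[~zero]
    if df.empty:
        raise EmptyCohortError("all samples excluded (every survival time was 0)")
    unit = table.time_unit
    if convert_to_months:
        if table.time_unit != "days":
            logger.info("prepare_survival: table already in %s; conversion skipped", table.time_unit)
        else:
            df["time_original"] = df["time"]
            df["time"] = df["time"] / days_per_month
            unit = "months"
    return SurvivalTable(data=df, time_unit=unit)


def intersect_samples(
    expr: ExpressionMatrix, survival: SurvivalTable
) -> tuple[ExpressionMatrix, SurvivalTable]:
    """Restrict both tables to their common samples (order from the expression matrix)."""
    common = [s for s in expr.sample_ids if s in set(survival.sample_ids)]
    if not common:
        raise EmptyCohortError("no overlapping samples between expression and survival tables")
    dropped = (expr.n_samples - len(common), survival.n_samples - len(common))
    if any(dropped):
        logger.info("sample intersection: kept %d samples (dropped %d expression-only, "
                    "%d survival-only)", len(common), *dropped)
    return expr.subset_samples(common), survival.subset(common)


def read_signature(path: str | Path, delimiter: str = "\t") -> Signature:
    """Read a two-column (gene, weight) signature file; '#' lines hold provenance."""
    path = Path(path)
    provenance: dict[str, object] = {}
    rows: list[tuple[str, float]] = []
    name = path.stem
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                k, v = body.split("=", 1)
                provenance[k.strip()] = v.strip()
                if k.strip() == "name":
                    name = v.strip()
            continue
        parts = line.split(delimiter)
        if parts[0].lower() == "gene":
            continue
        if len(parts) < 2:
            raise FormatError(f"{path}: signature rows need gene and weight columns")
        rows.append((parts[0], float(parts[1])))
    if not rows:
        raise FormatError(f"{path}: empty signature file")
    return Signature(name=name, entries=tuple(rows), provenance=provenance)


def write_signature(signature: Signature, path: str | Path, delimiter: str = "\t") -> None:
    lines = [f"# name = {signature.name}"]
    for k, v in signature.provenance.items():
        if k != "name":
            lines.append(f"# {k} = {v}")
    lines.append(delimiter.join(("gene", "weight")))
    for gene, weight in signature.entries:
        w = f"{int(weight)}" if float(weight).is_integer() else f"{weight!r}"
        lines.append(delimiter.join((gene, w)))
    Path(path).write_text("\n".join(lines) + "\n")
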