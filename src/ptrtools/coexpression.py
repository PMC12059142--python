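"""Percent-expressing, multi-marker co-expression and cross-tissue regression.

These statistics quantify the intermediate-cluster (IC) macrophage state — a
population bridging Kupffer-cell and SPP1-macrophage programs that
co-expresses SPP1, TGFBR1, IL6R, CSF1R, VSIG4 and CD163 — and relate
extrahepatic cytokine expression to hepatic SPP1/FN1 across patients.

"Expressing" means a normalized value strictly above the threshold (default
0, the upstream dot-plot convention); the same threshold applies to every
gene in a co-expression query.  Cross-tissue association uses ordinary least
squares per patient pair with a raw two-sided p-value for the slope.
"""

from __future__ import annotations

from typing import Callable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, GeneSet, logger
from .scoring import score_cells


def _percent_table(
    expr: ExpressionMatrix,
    expressing: np.ndarray,
    group_by: str | None,
    value_name: str,
) -> pd.DataFrame:
    keys = ["patient_id"] + ([group_by] if group_by and group_by != "patient_id" else [])
    df = expr.cell_meta[keys].copy()
    df["_expr"] = expressing
    out = (
        df.groupby(keys, observed=True)["_expr"]
        .agg(n_cells="size", n_expressing="sum")
        .reset_index()
    )
    out[value_name] = 100.0 * out["n_expressing"] / out["n_cells"]
    return out


def percent_expressing(
    expr: ExpressionMatrix,
    gene: str,
    group_by: str | None = "tissue",
    expression_threshold: float = 0.0,
) -> pd.DataFrame:
    """Percent of cells with ``gene > expression_threshold`` per patient × group."""
    if gene not in expr.gene_ids:
        raise KeyError(f"gene {gene!r} not in matrix")
    if group_by is not None and group_by != "patient_id" and group_by not in expr.cell_meta:
        raise KeyError(f"metadata column {group_by!r} not found")
    flags = expr.gene_values(gene) > expression_threshold
    out = _percent_table(expr, flags, group_by, "percent_expressing")
    out.insert(len(out.columns) - 3, "gene", gene)
    return out


def coexpression_frequency(
    expr: ExpressionMatrix,
    genes: Sequence[str],
    group_by: str | None = "tissue",
    expression_threshold: float = 0.0,
) -> pd.DataFrame:
    """Percent of cells expressing ALL listed genes, per patient × group.

    A single-gene list reduces to :func:`percent_expressing`; by the AND
    rule the result can never exceed any single marker's percent.
    """
    absent = [g for g in genes if g not in expr.gene_ids]
    if absent:
        raise KeyError(f"genes not in matrix: {absent}")
    if not genes:
        raise ValueError("empty gene list")
    flags = (expr.genes_values(list(genes)) > expression_threshold).all(axis=0)
    out = _percent_table(expr, flags, group_by, "percent_coexpressing")
    out.insert(len(out.columns) - 3, "genes", "+".join(genes))
    return out


def ic_enrichment_by_group(
    expr: ExpressionMatrix,
    ic_signature: GeneSet,
    cell_subset: np.ndarray | Callable[[pd.DataFrame], np.ndarray],
    group_by: str = "tissue",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """IC signature score per cell of a subset (e.g. CD68+ clusters), by group.

    ``cell_subset`` is a boolean mask over cells or a predicate over the cell
    metadata.  Returns ``(per_cell, medians)``: per-cell scores with their
    group, and the per-group median score.
    """
    mask = cell_subset(expr.cell_meta) if callable(cell_subset) else np.asarray(cell_subset)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (expr.n_cells,):
        raise ValueError("cell_subset mask must have one entry per cell")
    if not mask.any():
        raise ValueError("cell subset is empty")
    sub = expr.subset_cells(mask)
    scores = score_cells(sub, ic_signature)
    per_cell = pd.DataFrame(
        {
            "score": scores.to_numpy(),
            "group": sub.cell_meta[group_by].to_numpy(),
            "patient_id": sub.cell_meta["patient_id"].to_numpy(),
        },
        index=sub.cell_ids,
    )
    medians = (
        per_cell.groupby("group", observed=True)["score"]
        .agg(median_score="median", n_cells="size")
        .reset_index()
    )
    return per_cell, medians


class RegressionResult(NamedTuple):
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def paired_correlation(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Simple linear regression of per-patient y on per-patient x.

    Ordinary least squares with a two-sided p-value for slope ≠ 0.  Requires
    at least three paired observations and non-constant x.  NaN pairs are
    dropped with a warning (patients missing one tissue).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    if (~ok).any():
        logger.warning("paired_correlation: dropped %d incomplete pairs", int((~ok).sum()))
        x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.all(x == x[0]):
        raise ValueError("x is constant; slope undefined")
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        n=len(x),
    )
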