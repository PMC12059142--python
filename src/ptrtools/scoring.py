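"""Per-cell signature scoring and pTRT calling.

The pipeline mirrors common practice for identifying potentially
tumor-reactive (pTRT) CD8+ T cells in single-cell data: the raw per-cell
score is the mean log-normalized expression over the signature genes present
in the matrix; scores are z-standardized within each patient (sample
standard deviation, n−1); cells whose z-score strictly exceeds a threshold
(default 2 standard deviations) are called pTRT.  A negative control repeats
the whole pipeline on a uniformly sampled random gene set (default 500
genes), which should show no structure across tissues.

Aggregation by mean rather than sum is immaterial after per-patient
z-scaling for a fixed gene set, but keeps raw scores comparable when some
signature genes are absent from a matrix; the effective set size is recorded
on every result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneSet, logger


@dataclass
class ScoreResult:
    """Per-cell scores, z-scores and calls for one signature.

    ``table`` is indexed by cell id with columns ``raw_score``, ``z_score``,
    ``call``, ``patient_id`` and ``tissue``.  Within each patient the
    z-scores have mean 0 and (sample) standard deviation 1; ``call`` is
    strictly ``z_score > threshold``.
    """

    table: pd.DataFrame
    signature_name: str
    effective_set_size: int
    threshold: float = 2.0
    is_control: bool = False

    @property
    def calls(self) -> pd.Series:
        return self.table["call"]


def score_cells(expr: ExpressionMatrix, signature: GeneSet) -> pd.Series:
    """Mean expression of the signature genes present, per cell.

    Signature genes missing from the matrix are dropped with a warning; the
    effective set size is attached as ``scores.attrs['effective_set_size']``.
    Raises if no signature gene is present.
    """
    present = [g for g in signature.members if g in expr.gene_ids]
    if not present:
        raise ValueError(f"no gene of signature {signature.name!r} present in matrix")
    n_missing = len(signature) - len(present)
    if n_missing:
        logger.warning(
            "signature %s: %d of %d genes absent from matrix; scoring over %d",
            signature.name, n_missing, len(signature), len(present),
        )
    scores = pd.Series(
        expr.genes_values(present).mean(axis=0), index=expr.cell_ids, name="raw_score"
    )
    scores.attrs["effective_set_size"] = len(present)
    return scores


def zscale_by_patient(scores: pd.Series | np.ndarray, patient_ids) -> np.ndarray:
    """Z-standardize scores within each patient (sample sd, n−1 denominator)."""
    scores = np.asarray(scores, dtype=float)
    patient_ids = np.asarray(patient_ids)
    if scores.shape != patient_ids.shape:
        raise ValueError("scores and patient_ids must align")
    z = np.empty_like(scores)
    for pid in np.unique(patient_ids):
        mask = patient_ids == pid
        vals = scores[mask]
        if mask.sum() < 2:
            raise ValueError(f"patient {pid!r} has fewer than 2 cells")
        sd = vals.std(ddof=1)
        if sd == 0:
            raise ValueError(f"patient {pid!r} has zero score variance")
        z[mask] = (vals - vals.mean()) / sd
    return z


def call_ptrt(z_scores: np.ndarray, threshold: float = 2.0) -> np.ndarray:
    """pTRT call: z strictly above the threshold (a cell at exactly 2 is not called)."""
    z = np.asarray(z_scores, dtype=float)
    if not np.isfinite(z).all():
        raise ValueError("z-scores must be finite")
    return z > threshold


def score_pipeline(
    expr: ExpressionMatrix,
    signature: GeneSet,
    threshold: float = 2.0,
    is_control: bool = False,
) -> ScoreResult:
    """Run score → per-patient z-scale → call and assemble a ScoreResult."""
    raw = score_cells(expr, signature)
    patients = expr.cell_meta["patient_id"].to_numpy()
    z = zscale_by_patient(raw.to_numpy(), patients)
    calls = call_ptrt(z, threshold)
    table = pd.DataFrame(
        {
            "raw_score": raw.to_numpy(),
            "z_score": z,
            "call": calls,
            "patient_id": patients,
            "tissue": expr.cell_meta["tissue"].to_numpy(),
        },
        index=expr.cell_ids,
    )
    if "cluster" in expr.cell_meta.columns:
        table["cluster"] = expr.cell_meta["cluster"].to_numpy()
    return ScoreResult(
        table=table,
        signature_name=signature.name,
        effective_set_size=raw.attrs["effective_set_size"],
        threshold=threshold,
        is_control=is_control,
    )


def random_signature_control(
    expr: ExpressionMatrix,
    n_genes: int = 500,
    seed: int = 0,
    threshold: float = 2.0,
) -> ScoreResult:
    """Repeat the scoring pipeline on a random gene set (negative control).

    ``n_genes`` gene ids are sampled uniformly without replacement; the same
    seed reproduces the same set and calls.
    """
    if n_genes > expr.n_genes:
        raise ValueError(f"n_genes={n_genes} exceeds matrix genes {expr.n_genes}")
    rng = np.random.default_rng(seed)
    sampled = list(rng.choice(expr.gene_ids.to_numpy(), size=n_genes, replace=False))
    control = GeneSet(name=f"random_{n_genes}", members=sampled,
                      provenance=f"uniform sample, seed={seed}")
    return score_pipeline(expr, control, threshold=threshold, is_control=True)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------


def ptrt_frequency_by_group(calls: pd.Series, cell_meta: pd.DataFrame) -> pd.DataFrame:
    """Percent of cells called pTRT within each patient × tissue group."""
    if not calls.index.equals(cell_meta.index):
        raise ValueError("calls and cell_meta must share the same cell index")
    df = pd.DataFrame(
        {"call": calls.to_numpy(dtype=bool),
         "patient_id": cell_meta["patient_id"],
         "tissue": cell_meta["tissue"]}
    )
    out = (
        df.groupby(["patient_id", "tissue"], observed=True)["call"]
        .agg(n_cells="size", n_ptrt="sum")
        .reset_index()
    )
    out["frequency_pct"] = 100.0 * out["n_ptrt"] / out["n_cells"]
    return out


def ptrt_cluster_composition(
    calls: pd.Series, clusters: pd.Series, groups: pd.Series
) -> pd.DataFrame:
    """Within each group, the percent of pTRT cells falling in each cluster.

    Percentages sum to 100 per group; groups with zero pTRT cells yield no
    rows and a warning.  Raises if any called cell lacks a cluster label.
    """
    if not (calls.index.equals(clusters.index) and calls.index.equals(groups.index)):
        raise ValueError("calls, clusters and groups must share the same cell index")
    called = calls.astype(bool)
    if clusters[called].isna().any():
        raise ValueError("called cells with missing cluster labels")
    rows = []
    for group, sub in pd.DataFrame({"cluster": clusters, "group": groups})[called].groupby(
        "group", observed=True
    ):
        counts = sub["cluster"].value_counts()
        for cluster, n in counts.items():
            rows.append({
                "group": group, "cluster": cluster, "n_ptrt": int(n),
                "pct_of_ptrt": 100.0 * n / len(sub),
            })
    empty = set(groups.unique()) - {r["group"] for r in rows}
    if empty:
        logger.warning("groups with zero pTRT cells omitted: %s", sorted(map(str, empty)))
    return pd.DataFrame(rows, columns=["group", "cluster", "n_ptrt", "pct_of_ptrt"])
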