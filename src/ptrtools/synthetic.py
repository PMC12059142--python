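"""Seeded generators with known ground truth for every pipeline stage.

Three simulators are provided:

* :func:`simulate_expression` — multi-patient log-normalized expression with a
  planted signature-high ("reactive") subpopulation per tissue at a stated
  frequency and additive effect size;
* :func:`simulate_spatial` — 2-D cell maps (macrophage / CD8_T / NK / Treg)
  with annotated target (αSMA+) and matched control (αSMA−) polygons and a
  tunable macrophage–CD8 attraction within a radius;
* :func:`simulate_trajectory` — a latent-pseudotime toy in which informative
  genes vary monotonically along a noisy 1-D curve embedded in 2-D.

Every generator is deterministic given its seed and returns a
:class:`SyntheticTruth` holding one record per generated cell.  The baseline
expression model is per-gene log-normal with a per-patient additive location
shift clipped at zero — it mimics the scale of log-normalized data but makes
no attempt to match real datasets' gene-level moments or dropout structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon, box

from .io import ExpressionMatrix, GeneSet, logger
from .spatial import BACKGROUND, TARGET, RegionSet


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside simulated data.

    ``cells`` has one row per generated cell (reactive_flag, attraction_flag
    or latent_pseudotime depending on the generator); ``genes`` optionally
    carries per-gene truth such as an ``informative`` flag.
    """

    cells: pd.DataFrame
    genes: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def simulate_expression(
    n_patients: int,
    tissues: Sequence[str],
    cells_per_patient_tissue: int,
    n_genes: int,
    signature: GeneSet,
    reactive_fraction: float | Mapping[str, float],
    effect_size: float,
    seed: int,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Simulate a multi-patient, multi-tissue log-normalized matrix.

    Baseline expression of gene *g* in any cell is
    ``max(0, LogNormal(mu_g, sigma_g) + delta_p)`` with a per-patient shift
    ``delta_p ~ N(0, 0.15)`` providing batch structure.  In each patient ×
    tissue group, ``floor(reactive_fraction * n)`` cells are flagged reactive
    and each signature gene's value is increased by ``effect_size`` (additive
    on the log-normalized scale, matching how signature scores aggregate).
    ``reactive_fraction`` may be a single proportion or a per-tissue mapping.
    """
    if cells_per_patient_tissue <= 0 or n_patients <= 0 or not tissues:
        raise ValueError("need at least one patient, tissue, and cell per group")
    if n_genes < len(signature):
        raise ValueError(
            f"n_genes={n_genes} smaller than signature size {len(signature)}"
        )
    fractions = (
        dict(reactive_fraction)
        if isinstance(reactive_fraction, Mapping)
        else {t: float(reactive_fraction) for t in tissues}
    )
    for t in tissues:
        f = fractions.get(t, 0.0)
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"reactive_fraction for {t!r} must be in [0, 1]")

    rng = np.random.default_rng(seed)
    gene_ids = list(signature.members) + [
        f"G{i:05d}" for i in range(n_genes - len(signature))
    ]
    sig_rows = np.arange(len(signature))

    mu = rng.normal(-0.5, 0.5, size=n_genes)
    sigma = rng.uniform(0.3, 0.6, size=n_genes)
    patient_ids = [f"P{i + 1:02d}" for i in range(n_patients)]
    delta = rng.normal(0.0, 0.15, size=n_patients)

    blocks, meta_rows, reactive_all = [], [], []
    n = cells_per_patient_tissue
    for pi, pid in enumerate(patient_ids):
        for tissue in tissues:
            base = rng.lognormal(mu[:, None], sigma[:, None], size=(n_genes, n))
            block = np.maximum(base + delta[pi], 0.0)
            n_reactive = int(np.floor(fractions.get(tissue, 0.0) * n))
            reactive = np.zeros(n, dtype=bool)
            if n_reactive:
                reactive[rng.choice(n, size=n_reactive, replace=False)] = True
                block[np.ix_(sig_rows, np.flatnonzero(reactive))] += effect_size
            blocks.append(block)
            reactive_all.append(reactive)
            meta_rows.extend((pid, tissue) for _ in range(n))

    values = np.concatenate(blocks, axis=1)
    cell_ids = pd.Index([f"C{i:06d}" for i in range(values.shape[1])], name="cell_id")
    meta = pd.DataFrame(meta_rows, columns=["patient_id", "tissue"], index=cell_ids)
    expr = ExpressionMatrix(values=values, gene_ids=pd.Index(gene_ids),
                            cell_ids=cell_ids, cell_meta=meta)
    truth = SyntheticTruth(
        cells=pd.DataFrame(
            {"reactive_flag": np.concatenate(reactive_all)}, index=cell_ids
        ).join(meta)
    )
    return expr, truth


# ---------------------------------------------------------------------------
# spatial maps
# ---------------------------------------------------------------------------


def simulate_region_set(
    field_size_um: tuple[float, float],
    n_target: int = 2,
    n_background: int = 2,
    region_side_um: float = 800.0,
    seed: int = 0,
    sample_id: str = "S01",
) -> RegionSet:
    """Place non-overlapping square annotation polygons uniformly in the field.

    Target and control squares share one placement law, so under a null model
    the two region classes have identical spatial statistics (including edge
    exposure) in expectation.
    """
    w, h = field_size_um
    s = region_side_um
    if s > w or s > h:
        raise ValueError("region side exceeds field")
    rng = np.random.default_rng(seed)
    placed: list[Polygon] = []
    labels = [TARGET] * n_target + [BACKGROUND] * n_background
    polygons = []
    for label in labels:
        for _ in range(10_000):
            x0 = rng.uniform(0, w - s)
            y0 = rng.uniform(0, h - s)
            cand = box(x0, y0, x0 + s, y0 + s)
            if all(not cand.intersects(p) for p in placed):
                placed.append(cand)
                polygons.append((label, cand))
                break
        else:
            raise RuntimeError("could not place non-overlapping regions")
    return RegionSet(sample_id=sample_id, polygons=polygons)


def simulate_spatial(
    field_size_um: tuple[float, float],
    counts_per_type: Mapping[str, int],
    regions: RegionSet,
    attraction_radius_um: float = 100.0,
    attraction_prob: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Simulate a single-sample cell map with optional macrophage–CD8 attraction.

    All phenotypes are placed uniformly in the field.  Each macrophage that
    falls inside a target (αSMA+) polygon is then, with probability
    ``attraction_prob``, relocated to a uniform point within
    ``attraction_radius_um`` of a uniformly chosen CD8 cell inside that same
    polygon (flagged ``attraction_flag`` in the truth); if the polygon holds
    no CD8 cell the macrophage stays where it was.  Returns a cell table with
    region labels already assigned.
    """
    w, h = field_size_um
    if w <= 0 or h <= 0:
        raise ValueError("field must have positive extent")
    if attraction_radius_um <= 0:
        raise ValueError("attraction_radius_um must be positive")
    for _, poly in regions.polygons:
        if not box(0, 0, w, h).covers(poly):
            raise ValueError("region polygon outside field")
    rng = np.random.default_rng(seed)

    types = np.repeat(list(counts_per_type), list(counts_per_type.values()))
    xy = rng.uniform((0, 0), (w, h), size=(len(types), 2))
    cells = pd.DataFrame({"cell_type": types, "x_um": xy[:, 0], "y_um": xy[:, 1]})
    cells.insert(0, "sample_id", regions.sample_id)
    cells.insert(0, "cell_id", [f"{regions.sample_id}_c{i:05d}" for i in range(len(cells))])
    for ctype in counts_per_type:
        cells[ctype] = cells["cell_type"].eq(ctype)

    attraction = np.zeros(len(cells), dtype=bool)
    if "macrophage" in counts_per_type and "CD8_T" in counts_per_type:
        cd8_xy = cells.loc[cells["CD8_T"], ["x_um", "y_um"]].to_numpy(float)
        target_polys = [p for lab, p in regions.polygons if lab == TARGET]
        mac_idx = np.flatnonzero(cells["macrophage"].to_numpy())
        mac_xy = cells.loc[cells["macrophage"], ["x_um", "y_um"]].to_numpy(float)
        for poly in target_polys:
            in_poly_mac = shapely.intersects_xy(poly, mac_xy[:, 0], mac_xy[:, 1])
            cd8_in = cd8_xy[shapely.intersects_xy(poly, cd8_xy[:, 0], cd8_xy[:, 1])]
            if len(cd8_in) == 0:
                continue
            for j in np.flatnonzero(in_poly_mac):
                if rng.uniform() >= attraction_prob:
                    continue
                anchor = cd8_in[rng.integers(len(cd8_in))]
                # uniform in the disk, resampled until inside the field
                while True:
                    r = attraction_radius_um * np.sqrt(rng.uniform())
                    theta = rng.uniform(0, 2 * np.pi)
                    new = anchor + r * np.array([np.cos(theta), np.sin(theta)])
                    if 0 <= new[0] <= w and 0 <= new[1] <= h:
                        break
                row = mac_idx[j]
                cells.loc[cells.index[row], ["x_um", "y_um"]] = new
                attraction[row] = True

    from .spatial import assign_regions

    cells = assign_regions(cells, regions)
    truth = SyntheticTruth(
        cells=pd.DataFrame(
            {"attraction_flag": attraction},
            index=pd.Index(cells["cell_id"], name="cell_id"),
        )
    )
    return cells, truth


# ---------------------------------------------------------------------------
# trajectory toy
# ---------------------------------------------------------------------------


def simulate_trajectory(
    n_cells: int,
    n_genes: int,
    n_informative: int,
    seed: int = 0,
) -> tuple[ExpressionMatrix, np.ndarray, SyntheticTruth]:
    """Simulate expression varying along a latent pseudotime.

    Latent ``t ~ Uniform(0, 1)`` per cell.  The first ``n_informative`` genes
    have mean expression monotone in *t* (slope drawn from U(1.5, 3)) plus
    Gaussian noise; the rest are noise only.  The returned embedding is a
    noisy 1-D curve in 2-D, so a kNN graph on it tracks pseudotime order.
    """
    if n_cells <= 0:
        raise ValueError("need at least one cell")
    if n_informative > n_genes:
        raise ValueError("n_informative exceeds n_genes")
    rng = np.random.default_rng(seed)
    t = rng.uniform(0, 1, size=n_cells)
    values = np.maximum(0.5 + rng.normal(0, 0.4, size=(n_genes, n_cells)), 0.0)
    if n_informative:
        slopes = rng.uniform(1.5, 3.0, size=n_informative)
        values[:n_informative] = np.maximum(
            slopes[:, None] * t[None, :]
            + rng.normal(0, 0.3, size=(n_informative, n_cells)),
            0.0,
        )
    embedding = np.column_stack(
        [t + rng.normal(0, 0.02, n_cells), np.sin(np.pi * t) + rng.normal(0, 0.02, n_cells)]
    )
    cell_ids = pd.Index([f"T{i:05d}" for i in range(n_cells)], name="cell_id")
    gene_ids = pd.Index(
        [f"INF{i:04d}" for i in range(n_informative)]
        + [f"NOISE{i:04d}" for i in range(n_genes - n_informative)]
    )
    meta = pd.DataFrame({"patient_id": "P01", "tissue": "liver"}, index=cell_ids)
    expr = ExpressionMatrix(values=values, gene_ids=gene_ids, cell_ids=cell_ids,
                            cell_meta=meta)
    truth = SyntheticTruth(
        cells=pd.DataFrame({"latent_pseudotime": t}, index=cell_ids),
        genes=pd.DataFrame(
            {"informative": np.arange(n_genes) < n_informative}, index=gene_ids
        ),
    )
    return expr, embedding, truth
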