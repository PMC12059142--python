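"""Spatial statistics on multiplexed-imaging single-cell tables.

Inputs are HALO/CODEX-style exports: one row per segmented cell with slide
coordinates in µm, boolean phenotype flags (macrophage, CD8_T, NK, Treg, ...),
and manually annotated region polygons — profibrotic αSMA+ areas and, when
available, matched αSMA− control areas.  The module assigns each cell to a
region class, computes phenotype densities (cells/mm²), within-radius
proximity fractions and nearest-neighbour distances between two phenotypes,
and a two-sided paired t-test of any such metric across samples between the
αSMA+ and αSMA− classes.

Distances are Euclidean in slide µm; no 3-D or tissue-deformation correction
is applied.  Boundary cells count as inside a polygon.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import shapely
from scipy.spatial import cKDTree
from scipy.stats import ttest_rel
from shapely.geometry import Polygon, shape, mapping
from shapely.ops import unary_union

from .io import logger

UM2_PER_MM2 = 1_000_000.0

#: region labels used in CellTable.region_label
TARGET, BACKGROUND, UNASSIGNED = "target", "background", "unassigned"

#: columns every cell table must carry
CELL_TABLE_COLUMNS = ("cell_id", "sample_id", "x_um", "y_um")


def validate_cell_table(cells: pd.DataFrame, flags: Sequence[str] = ()) -> None:
    """Check required columns, finite coordinates, and one row per cell."""
    missing = [c for c in CELL_TABLE_COLUMNS if c not in cells.columns]
    if missing:
        raise ValueError(f"cell table missing columns: {missing}")
    xy = cells[["x_um", "y_um"]].to_numpy(float)
    if not np.isfinite(xy).all():
        raise ValueError("cell coordinates must be finite")
    if cells.duplicated(["sample_id", "cell_id"]).any():
        raise ValueError("duplicate (sample_id, cell_id) rows")
    for f in flags:
        if f not in cells.columns:
            raise ValueError(f"cell table missing phenotype flag {f!r}")


@dataclass
class RegionSet:
    """Labelled annotation polygons for one sample.

    ``polygons`` is a list of ``(label, Polygon)`` with label ``"target"``
    (αSMA+) or ``"background"`` (annotated αSMA− control region).  Overlapping
    polygons of the same label are unioned before area computation.
    """

    sample_id: str
    polygons: list[tuple[str, Polygon]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for label, poly in self.polygons:
            if label not in (TARGET, BACKGROUND):
                raise ValueError(f"unknown region label {label!r}")
            if poly.area <= 0 or len(poly.exterior.coords) < 4:
                raise ValueError(f"degenerate polygon in sample {self.sample_id}")

    def union(self, label: str):
        polys = [p for lab, p in self.polygons if lab == label]
        return unary_union(polys) if polys else None

    def area_mm2(self, label: str) -> float:
        geom = self.union(label)
        return geom.area / UM2_PER_MM2 if geom is not None else 0.0

    @property
    def has_background(self) -> bool:
        return any(lab == BACKGROUND for lab, _ in self.polygons)

    # -- GeoJSON round trip -------------------------------------------------

    def to_geojson(self, path: str | Path) -> None:
        features = [
            {"type": "Feature", "properties": {"label": lab, "sample_id": self.sample_id},
             "geometry": mapping(poly)}
            for lab, poly in self.polygons
        ]
        Path(path).write_text(
            json.dumps({"type": "FeatureCollection", "features": features})
        )

    @classmethod
    def from_geojson(cls, path: str | Path, sample_id: str | None = None) -> "RegionSet":
        doc = json.loads(Path(path).read_text())
        polys = []
        sid = sample_id
        for feat in doc["features"]:
            props = feat.get("properties", {})
            sid = sid or props.get("sample_id", "sample")
            polys.append((props.get("label", TARGET), shape(feat["geometry"])))
        return cls(sample_id=sid or "sample", polygons=polys)


@dataclass
class ProximityResult:
    """Proximity summary for one sample and one region class."""

    sample_id: str
    region_class: str
    type_a: str
    type_b: str
    radius_um: float
    fraction_within: float
    mean_nn_distance_um: float
    n_a: int
    n_b: int


# ---------------------------------------------------------------------------
# region assignment and density
# ---------------------------------------------------------------------------


def _covered(geom, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    # intersects == covers for point queries (boundary-inclusive), vectorised
    if geom is None:
        return np.zeros(len(x), dtype=bool)
    return shapely.intersects_xy(geom, x, y)


def assign_regions(cells: pd.DataFrame, regions: RegionSet) -> pd.DataFrame:
    """Label each cell with its region class.

    Cells inside (or on the boundary of) any target polygon get ``"target"``.
    If the RegionSet carries explicit background polygons, cells inside those
    get ``"background"`` and the remainder ``"unassigned"``; otherwise every
    non-target cell is ``"background"``.
    """
    validate_cell_table(cells)
    if not (cells["sample_id"] == regions.sample_id).all():
        raise ValueError("cell table and RegionSet sample_id mismatch")
    x = cells["x_um"].to_numpy(float)
    y = cells["y_um"].to_numpy(float)
    in_target = _covered(regions.union(TARGET), x, y)
    out = cells.copy()
    if regions.has_background:
        in_bg = _covered(regions.union(BACKGROUND), x, y) & ~in_target
        label = np.where(in_target, TARGET, np.where(in_bg, BACKGROUND, UNASSIGNED))
    else:
        label = np.where(in_target, TARGET, BACKGROUND)
    out["region_label"] = label
    return out


def cell_density(
    cells: pd.DataFrame,
    regions: RegionSet,
    cell_type: str,
    field_size_um: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Density (cells/mm²) of one phenotype per region class.

    With explicit background polygons the background area is their unioned
    area; otherwise it is the field area minus the target area, which needs
    the bounding field size from the run configuration.
    """
    validate_cell_table(cells, flags=[cell_type])
    if "region_label" not in cells.columns:
        cells = assign_regions(cells, regions)
    target_area = regions.area_mm2(TARGET)
    if regions.has_background:
        bg_area = regions.area_mm2(BACKGROUND)
    else:
        if field_size_um is None:
            raise ValueError("field_size_um required when no background polygons given")
        field_area = field_size_um[0] * field_size_um[1] / UM2_PER_MM2
        bg_area = field_area - target_area
    rows = []
    for cls, area in ((TARGET, target_area), (BACKGROUND, bg_area)):
        if area <= 0:
            raise ValueError(f"zero area for region class {cls}")
        n = int((cells["region_label"].eq(cls) & cells[cell_type]).sum())
        rows.append({
            "sample_id": regions.sample_id, "region_class": cls, "cell_type": cell_type,
            "n_cells": n, "area_mm2": area, "density_per_mm2": n / area,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# proximity
# ---------------------------------------------------------------------------


def nearest_neighbor_distances(
    a_xy: np.ndarray, b_xy: np.ndarray
) -> np.ndarray:
    """Distance from each A point to its nearest B point (kd-tree)."""
    a_xy = np.asarray(a_xy, float)
    b_xy = np.asarray(b_xy, float)
    if len(a_xy) == 0 or len(b_xy) == 0:
        raise ValueError("need at least one A and one B point")
    dist, _ = cKDTree(b_xy).query(a_xy, k=1)
    return np.asarray(dist, float)


def proximity_fraction(
    cells: pd.DataFrame,
    type_a: str,
    type_b: str,
    radius_um: float = 100.0,
    region_class: str = TARGET,
    restrict_b_to_region: bool = False,
) -> ProximityResult:
    """Fraction of region-class A cells with a B cell within ``radius_um``.

    Only the A cells' region membership is stratified; candidate B neighbours
    come from the whole sample unless ``restrict_b_to_region`` is set (HALO
    proximity counts neighbours regardless of annotation layer).  The mean
    nearest-neighbour distance is reported over the same A cells, uncapped.
    """
    validate_cell_table(cells, flags=[type_a, type_b])
    if "region_label" not in cells.columns:
        raise ValueError("run assign_regions first (region_label column missing)")
    a_mask = cells[type_a].astype(bool) & cells["region_label"].eq(region_class)
    b_mask = cells[type_b].astype(bool)
    if restrict_b_to_region:
        b_mask &= cells["region_label"].eq(region_class)
    a_xy = cells.loc[a_mask, ["x_um", "y_um"]].to_numpy(float)
    b_xy = cells.loc[b_mask, ["x_um", "y_um"]].to_numpy(float)
    if len(a_xy) == 0:
        raise ValueError(f"no {type_a} cells in region class {region_class!r}")
    if len(b_xy) == 0:
        raise ValueError(f"no {type_b} cells in sample")
    nn = nearest_neighbor_distances(a_xy, b_xy)
    sample_id = str(cells["sample_id"].iloc[0])
    return ProximityResult(
        sample_id=sample_id,
        region_class=region_class,
        type_a=type_a,
        type_b=type_b,
        radius_um=float(radius_um),
        fraction_within=float(np.mean(nn <= radius_um)),
        mean_nn_distance_um=float(np.mean(nn)),
        n_a=len(a_xy),
        n_b=len(b_xy),
    )


def paired_region_comparison(values: pd.DataFrame, metric: str) -> tuple[float, float, int]:
    """Two-sided paired t-test of a per-sample metric, αSMA+ vs αSMA−.

    ``values`` holds one row per (sample_id, region_class) with the metric in
    column ``metric``.  Returns ``(t_statistic, p_value, n_pairs)``; requires
    at least two samples with both region classes.  Identical values in both
    classes give t = 0, p = 1.
    """
    for col in ("sample_id", "region_class", metric):
        if col not in values.columns:
            raise ValueError(f"values missing column {col!r}")
    wide = values.pivot(index="sample_id", columns="region_class", values=metric)
    if TARGET not in wide.columns or BACKGROUND not in wide.columns:
        raise ValueError("need both region classes to compare")
    wide = wide.dropna(subset=[TARGET, BACKGROUND])
    n_pairs = len(wide)
    if n_pairs < 2:
        raise ValueError("need >= 2 complete sample pairs")
    diffs = wide[TARGET].to_numpy(float) - wide[BACKGROUND].to_numpy(float)
    if np.allclose(diffs, 0):
        return 0.0, 1.0, n_pairs
    t, p = ttest_rel(wide[TARGET], wide[BACKGROUND])
    return float(t), float(p), n_pairs
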