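# ptrtools

Analysis pipeline for three linked questions about the liver tumor
microenvironment, starting from processed single-cell tables rather than raw
data:

1. **Which CD8+ T cells are potentially tumor-reactive (pTRT)?**
   Per-cell gene-signature scoring with per-patient z-standardization, a
   2-standard-deviation call, and a 500-random-gene negative control.
2. **How prevalent is the intermediate (IC) macrophage state?**
   Percent-expressing and multi-marker co-expression frequencies (SPP1,
   TGFBR1, IL6R, CSF1R, VSIG4, CD163) per patient and group, IC signature
   enrichment in CD68+ subsets, and per-patient cross-tissue simple linear
   regression.
3. **Do macrophages co-locate with CD8+ T cells in profibrotic αSMA+
   regions?** Point-in-polygon region assignment of multiplexed-imaging
   (CODEX/HALO-style) cell tables, phenotype densities, within-100-µm
   proximity fractions and nearest-neighbour distances, and two-sided paired
   t-tests of αSMA+ vs αSMA− regions across samples.

A Moran's I module ranks genes by autocorrelation over a supplied cell–cell
graph (or a built-in kNN graph on an embedding), the statistic used to relate
gene expression to a differentiation trajectory.  A seeded synthetic-data
module generates expression matrices, spatial cell maps and trajectory toys
with known ground truth, so the whole pipeline is testable without downloads.

## The core statistics

**pTRT calling.** For cell *j* of patient *p* with log-normalized expression
*x<sub>gj</sub>* and signature *S* (restricted to genes present in the
matrix),

```
score_j = mean_{g in S} x_gj
z_j     = (score_j - mean_p) / sd_p          (sample sd within patient p)
pTRT_j  = [ z_j > 2 ]                        (strict inequality)
```

The negative control repeats the identical computation on 500 genes sampled
uniformly without replacement; on data without tissue structure its call
rates show no organ differences.

**Proximity.** For phenotypes A (e.g. macrophage) and B (e.g. CD8_T) and
radius *r* = 100 µm, `fraction_within` is the proportion of A cells in a
region class whose Euclidean nearest B cell (anywhere in the sample) lies
within *r*; the mean nearest-neighbour distance over the same A cells is
reported alongside.  Region classes come from annotated αSMA+ polygons and —
when provided — matched αSMA− control polygons.

**Moran's I.** For values *x* on a symmetric weighted graph
(weights *w<sub>ij</sub>*, total weight *W*):

```
I = (n / W) * sum_ij w_ij (x_i - x̄)(x_j - x̄) / sum_i (x_i - x̄)²
```

with permutation expectation −1/(n−1).

## Worked example

```python
from ptrtools import (GeneSet, simulate_expression, score_pipeline,
                      ptrt_frequency_by_group, random_signature_control)

sig = GeneSet("tumor_reactivity", [f"SIG{i:03d}" for i in range(50)])
expr, truth = simulate_expression(
    n_patients=3, tissues=["liver_met", "primary", "pbmc"],
    cells_per_patient_tissue=200, n_genes=1000, signature=sig,
    reactive_fraction={"liver_met": 0.08, "primary": 0.04, "pbmc": 0.01},
    effect_size=3.0, seed=11,
)
res = score_pipeline(expr, sig, threshold=2.0)
print(ptrt_frequency_by_group(res.calls, expr.cell_meta).to_string(index=False))
```

prints

```
patient_id    tissue  n_cells  n_ptrt  frequency_pct
       P01 liver_met      200      16            8.0
       P01      pbmc      200       2            1.0
       P01   primary      200       8            4.0
       P02 liver_met      200      16            8.0
       P02      pbmc      200       2            1.0
       P02   primary      200       8            4.0
       P03 liver_met      200      16            8.0
       P03      pbmc      200       2            1.0
       P03   primary      200       8            4.0
```

i.e. with a strong planted effect the per-tissue pTRT frequency recovers the
planted reactive fractions (8% / 4% / 1%) exactly in every patient.  The
matching control, `random_signature_control(expr, n_genes=500, seed=11)`,
calls 4.33% of cells with no tissue structure — slightly above the Gaussian
2.28% tail because a uniform 500-gene draw from this 1000-gene simulation
overlaps the planted signature and the score distribution is right-skewed.

The same simulators drive the spatial arm:

```python
from ptrtools import simulate_region_set, simulate_spatial, proximity_fraction

regions = simulate_region_set((3000, 3000), seed=3)
cells, truth = simulate_spatial(
    (3000, 3000), {"macrophage": 900, "CD8_T": 500, "NK": 150, "Treg": 150},
    regions, attraction_radius_um=100, attraction_prob=0.5, seed=4)
print(proximity_fraction(cells, "macrophage", "CD8_T", 100.0, "target"))
```

### Command line

Every stage is also exposed as a subcommand of the `ptrtools` console script
(`simulate`, `score`, `coexpress`, `spatial`, `autocorr`), each taking
`--config`, `--seed` and `--out-dir`, writing tables to CSV and logs to
stderr.  `ptrtools simulate` writes an MTX/TSV expression bundle, a cell
coordinate CSV, GeoJSON region polygons and truth tables that the other
subcommands can consume directly.

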