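# Methods

## pTRT identification

The raw per-cell score is the **mean** log-normalized expression over the
signature genes present in the matrix.  Mean versus sum is immaterial once
scores are z-standardized within a patient for a fixed gene set (z-scores are
invariant to positive affine maps of the raw score), but the mean keeps raw
scores comparable when some signature genes are absent; the effective set
size is recorded on every result and missing genes are logged.  Gene matching
is exact, case-sensitive string comparison — no symbol mapping is attempted.

Z-standardization uses the sample standard deviation (n−1) over **all cells
of a patient in the analyzed compartment**, pooling tissues; the alternative
(per patient × tissue) would make cross-tissue frequency comparisons
circular.  A patient needs at least two cells and non-zero score variance;
degenerate patients raise an error rather than yielding silent zeros.

The call is strict: a cell at exactly z = 2 is *not* called.  Under an
exchangeable null the call rate is the empirical upper-2-SD tail of the
per-patient score distribution — ≈ 2.28% when scores are approximately
Gaussian — and no multiple-testing adjustment is applied (none is standard
for this rule).  The negative control repeats the full score → z-scale → call
pipeline on a uniform sample of genes (default 500, without replacement,
seeded); its output is flagged `is_control`.

## QC filtering

Defaults retain cells with 200 ≤ n_features ≤ 3000, n_counts ≤ 10000,
log10 genes/UMI > 0.82 and mitochondrial percent < 10, with removal counts
logged per rule.  Published criteria state the UMI-count bound in both
directions for different datasets, so `counts_rule` exposes both readings
("max" retains ≤, "min" retains ≥).  Filtering is idempotent and only ever
subsets; the package never re-normalizes expression.

## Synthetic data

`simulate_expression` draws gene *g* in any cell as
`max(0, LogNormal(mu_g, sigma_g) + delta_p)` with `mu_g ~ N(-0.5, 0.5)`,
`sigma_g ~ U(0.3, 0.6)` and a per-patient batch shift
`delta_p ~ N(0, 0.15)`.  In each patient × tissue group,
`floor(reactive_fraction · n)` cells receive `+effect_size` on every
signature gene — additive on the log-normalized scale, matching how the
score aggregates.  Recovery benchmarks use the stated study-like conditions:
2000 cells, 5% reactive, effect size 3; null checks use effect size 0.  The
generator reproduces the *structure* the statistics assume (patient batches,
a signature-high subpopulation, right-skewed non-negative values) but not
real datasets' gene-level moments, dropout, or cluster topology, so passing
tests demonstrate correctness of the statistics, not biological validity on
any particular accession.

`simulate_spatial` places all phenotypes uniformly in the field, then
relocates each macrophage found inside a target (αSMA+) polygon, with the
stated probability, to a uniform point within the attraction radius of a
uniformly chosen CD8 cell *inside that polygon* (resampled until inside the
field; macrophages in CD8-free polygons stay put).  Target and control
(αSMA−) polygons are equal-size squares placed by one common uniform law
without overlap.  That symmetry is deliberate: comparing annotated regions
against the *complement* of the target area would make the background class
systematically more edge-exposed, and nearest-neighbour distances are
stochastically larger near the field border, biasing the paired null.  With
matched control polygons the paired t-test is calibrated (measured rejection
≈ 3–6% at nominal 5% over 400 replicates).

Default spatial conditions: 3000 × 3000 µm field, 900 macrophages, 500 CD8,
2 + 2 regions of 800 µm side, radius 100 µm — chosen so the baseline
within-100-µm fraction sits near 0.8 (CD8 intensity ≈ 56 /mm² gives
1 − exp(−λπr²) ≈ 0.83), leaving variance for both null calibration and
power.  The planted-attraction benchmark (probability 0.5, 15 samples)
rejects in essentially every replicate.

`simulate_trajectory` draws latent pseudotime t ~ U(0,1); informative genes
have mean slope U(1.5, 3) in t with N(0, 0.3) noise (clipped at 0), noise
genes are baseline-only, and the embedding is a noisy 1-D curve in 2-D so a
kNN graph on it tracks pseudotime order.

## Co-expression statistics

"Expressing" means strictly greater than the threshold, default 0 (the
upstream dot-plot convention); co-expression applies the same threshold to
every gene and ANDs the per-cell flags, so it can never exceed any single
marker's percent.  IC enrichment reuses the signature scorer on a cell
subset (e.g. CD68-expressing clusters) and reports per-group medians.
Cross-tissue association is ordinary least squares on per-patient pairs
(x from one tissue, y from the other, paired by patient id; incomplete pairs
dropped with a warning), with a raw two-sided slope p-value — no
multiple-testing correction, as panels are reported individually.  Which
genes enter a panel (e.g. whether "TGF-β" means TGFB1 alone) is a
configuration choice, not hard-coded.

## Spatial statistics

Region assignment is boundary-inclusive (a deterministic tie rule; at µm
resolution the boundary set has negligible mass).  When a RegionSet carries
only target polygons, every other cell is background; with explicit control
polygons, cells outside both classes are "unassigned" and excluded from the
paired comparison.  Overlapping same-label polygons are unioned before area
computation; background area in complement mode is field area minus target
area and requires the field size from configuration.  Nearest-B search is
*not* restricted to A's region (matching how imaging proximity tools count
neighbours across annotation layers); a flag restricts it when wanted.  The
published "proximity" readout is ambiguous between a within-radius fraction
and a distance, so both `fraction_within` and `mean_nn_distance_um` are
always reported and labelled.  Nearest neighbours use a kd-tree, verified
against the all-pairs oracle in tests.

## Graph autocorrelation

Moran's I accepts any symmetric, non-negative, zero-diagonal weighted graph.
The shipped builder is a mutual-ized (union) kNN graph with binary weights
and index tie-breaks; a row-standardized variant is provided since published
trajectory tools do not document their weighting.  Trajectory-graph
*learning* is out of scope — results are labelled with the graph's
provenance, and printed autocorrelation values from learned principal graphs
are not comparable targets for a kNN graph.  Zero-variance genes get a
missing I and are excluded from ranking with a warning; constant input to
the scalar statistic is an error.

## Numerical and design notes

* All generators and samplers take explicit seeds (`numpy.random.default_rng`);
  identical seeds give identical outputs.
* Scoring, co-expression and spatial results are invariant to cell and gene
  ordering (tested), and proximity/density to rigid translation.
* Problem sizes in tests and in `scripts/acceptance.py` (2000-cell recovery,
  50-replicate power runs, 400-replicate null calibration, 100-node graph
  oracles) were chosen to give tight Monte-Carlo error — e.g. 400 replicates
  put the SD of a 5% rejection-rate estimate near one percentage point —
  while keeping a full run to a few minutes on one CPU.
* Known limitations: no raw-count normalization, integration, clustering or
  UMAP; no ligand–receptor network inference; no trajectory learning or
  pseudotime ordering; no image processing or marker gating — the pipeline
  starts at exported tables.  The synthetic spatial model plants attraction
  by relocation, which slightly depletes the target-region macrophage count
  at high attraction probabilities when anchors sit near polygon edges.
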