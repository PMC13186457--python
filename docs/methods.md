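# Methods

## Scope and data model

`rankcomm` infers directed ligand–receptor communication between annotated
cell types from a genes × cells UMI count matrix. Cell-type labels are
consumed as input: clustering, marker finding and annotation happen
upstream in the user's preferred toolchain. Count matrices are held dense
in memory; the intended scale is desk-size studies (hundreds to a few tens
of thousands of cells), not atlas-scale corpora.

## Normalization

Counts are normalized with TMM (trimmed mean of M-values) scale factors
followed by a voom-style log2-CPM transform.

- **TMM.** The reference cell is the one whose upper-quartile CPM is
  closest to the mean upper-quartile. For each cell, gene-wise log-ratios
  M and log-abundances A are computed against the reference over genes
  positive in both; genes in the extreme 30% tails of M and 5% tails of A
  (two-sided; the published defaults) are trimmed; the factor is the
  precision-weighted mean of the surviving M-values, with weights the
  inverse asymptotic binomial variance; factors are rescaled to geometric
  mean one. The implementation reproduces edgeR's `calcNormFactors` to
  1e-10 on random matrices (cross-checked in the test suite via Rscript
  when R is available) and is additionally pinned by a literal loop
  transcription of the definition kept in the tests.
- **Per-cell vs pseudo-bulk.** By default factors are computed per cell.
  Per-cell TMM on very sparse data can be unstable (a cell sharing no
  positive genes with the reference is an error naming the cell); the
  `tmm_groupby="cell_type"` option computes factors on per-type summed
  counts and broadcasts them to member cells.
- **voom.** value = log2((count + 0.5) / (library × factor + 1) × 1e6).
  Optional precision weights follow the usual recipe — a lowess trend
  (span 0.5) of √standard-deviation against mean log2-count, evaluated at
  each entry's fitted log-count, raised to the −4th power — but downstream
  scoring uses the transformed values only, so weights are off by default.

Cells expressing fewer than `min_genes = 200` distinct genes are dropped
before normalization, the conventional droplet QC threshold for empty
droplets and low-quality cells.

## The DGBD rank model

Within one (gene, cell type), normalized values are min–max scaled to
[0, 1] (constant vectors map to 0), partitioned into `n_bins = 20`
equal-width bins (last bin right-closed), empty bins dropped, and the
occupied-bin cell counts sorted descending (ties broken by ascending bin
index, for determinism). The resulting rank–frequency vector z is modeled
as Multinomial(n, p(α, β)) with the DGBD mass function

p_λ = (N + 1 − λ)^β λ^(−α) / A(α, β),  λ = 1…N.

Working with bin-occupancy ranks rather than raw values is what buys
robustness to dropout and count noise: a zero-inflated gene and a shifted
gene with the same occupancy shape yield the same z.

Numerical choices:

- All pmf and likelihood computation is in log space (`logsumexp`); the
  pmf is exactly normalized to < 1e-12 across the full parameter box.
- Maximum likelihood by L-BFGS-B with analytic gradients inside the box
  [−5, 10]² (negative shapes allowed because empirical rank curves can
  invert; the box prevents overflow while staying far wider than values
  seen in practice). Tight tolerances (ftol 1e-13) keep the optimum within
  ~0.01 of an exhaustive 0.01-step grid search.
- Deterministic initialization: α₀ is minus the least-squares slope of
  log z against log λ over the first ⌈N/2⌉ ranks, β₀ the slope of log z
  against log(N + 1 − λ) over the last ⌈N/2⌉ ranks, both clipped to the
  box. A fixed 3×3 interior multi-start grid is tried if the first solve
  does not converge.
- N = 1 (a constant expression vector) is a point mass for every (α, β);
  the fit returns (0, 0) flagged `degenerate`.
- The likelihood surface can form a ridge (α and β strongly correlated
  through the normalizing constant), so the continuous optimum may sit
  slightly more than one lattice step from a grid argmax while strictly
  dominating every lattice point in likelihood; correctness checks
  therefore use likelihood dominance rather than per-coordinate matching.

**Goodness of fit.** Deviance 2(ℓ_sat − ℓ_fit) against the saturated
multinomial, referred to χ²(N − 3); undefined (NaN) below N = 4. Under
model data the p-values are uniform provided ranks are genuinely ordered;
when adjacent tail probabilities are nearly tied, the descending re-sort of
sampled counts makes the test mildly conservative — a caveat inherent to
fitting sorted occupancy counts.

## Interaction scoring

Per (gene, cell type) with at least `min_cells = 10` cells, a profile
records the mean rectified expression, the expressing fraction, and the
DGBD fit. **Rectified expression** is the voom value minus the global
matrix minimum, clamped at zero, with zero-count entries pinned to exactly
zero: voom values are signed logs, and a product score needs a
non-negative scale on which an unexpressed gene contributes nothing, while
expressed entries keep their library-size normalization.

strength(L, R, S, R′) = mean_expr(L, S) × mean_expr(R, R′), autocrine
(S = R′) included, gated on:

- breadth: expressing fraction ≥ `min_frac = 0.1` on both sides;
- shape: the DGBD goodness-of-fit screen. Because the screen runs over the
  whole profile family (every gene × type), its p-values are BH-adjusted
  and the gate rejects at adjusted q < `gof_alpha = 0.05`. A raw per-test
  gate would erroneously zero ≈ 1 − 0.95² ≈ 10% of perfectly modeled
  interactions by construction; the FDR-adjusted screen keeps the intended
  behavior — excluding only profiles whose rank shape the model genuinely
  cannot describe.

An alternative `score_mode="dgbd_weighted"` multiplies each side by
max(0, 1 + β̂ − α̂), folding the fitted rank-curve shape directly into the
score for users who want the fit to act as more than a filter.

**Significance.** Cell-type labels are permuted uniformly (type sizes
preserved) `n_perm = 1000` times; per permutation, strengths are
recomputed under the breadth gate only (the shape gate is frozen at its
observed value so the null does not refit thousands of DGBDs).
p = (1 + #{perm ≥ obs}) / (1 + n_perm); Benjamini–Hochberg across entries
with observed strength > 0 (zero-strength entries get p = 1, q = 1).
Permuting labels rather than expression preserves the per-type cell-count
structure and is the field-standard null.

**Co-receptors.** For each significant entry (q ≤ 0.05) whose database row
lists co-receptors, every co-receptor expressed in the receiver at
`min_frac` yields a triad scored strength × mean_expr(co-receptor,
receiver). Co-receptors come from the user's ligand–receptor table; no
external protein–protein interaction database is consulted. The packaged
demo table is a small curated set of tumor–immune axes (including
MIF–CD74 with CXCR4/CD44) and is a convenience default, not a curated
reference resource.

## Synthetic data

The generator emulates droplet scRNA-seq minimally: counts are negative
binomial with a common baseline mean (default 0.5 per gene, dispersion
size 2.0, 1000 genes — a typical cell then expresses a few hundred genes,
comfortably astride the 200-gene QC threshold), with independent Bernoulli
zero-inflation (default dropout 0.3). Planted programs multiply the
baseline mean for chosen (gene, type) pairs; ligand–receptor circuits
expand into a ligand program in the sender and a receptor program in the
receiver, giving exact ground truth. Fixed seeds make every dataset
bit-reproducible.

Not modeled: batch effects, doublets, per-gene baseline heterogeneity,
trajectory structure, UMI saturation, or correlated dropout. Passing the
synthetic benchmarks therefore demonstrates the statistical machinery —
calibration of the permutation null, detection power at a given effect
size, normalization correctness — not robustness to every artifact of
real tissue data.

## Benchmarks computed by the acceptance script

Problem sizes were chosen to exercise each property at meaningful
resolution while staying desk-scale: null calibration uses 6 types × 100
cells × 300 genes with 18 null pairs (648 tested entries, 199
permutations); detection power uses the planted-circuit setting of
fold-change 8, dropout 0.3, 200 cells/type and 999 permutations across 50
replicates × 3 circuits; parameter recovery uses N = 25 ranks and
n = 20 000 cells over a 3×3 grid of true shapes; the grid-search oracle
runs 20 instances at 0.01 resolution over the full parameter box. Typical
results: type-I error at nominal 0.05 within ±0.02, recovery rate of
planted circuits ≥ 99%, median shape-recovery error ≤ 0.03.

## Known limitations

- Per-cell TMM assumes every cell shares positive genes with the
  reference; extremely sparse cells require the pseudo-bulk option.
- The product score ignores co-expression structure within cells and
  cannot distinguish sub-population-driven signals within one labeled
  type.
- The permutation null conditions on observed per-type sizes; very small
  types (near `min_cells`) give coarse p-value granularity.
- Gene matching between the count matrix and the ligand–receptor table is
  exact case-insensitive symbol matching; alias and ortholog resolution is
  a data-curation task left to the user.
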