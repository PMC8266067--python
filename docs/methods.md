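# Methods

Models, conventions, and numerical choices in `paleopcs`. Everything here is
implemented in `src/paleopcs/`; the tests under `tests/` verify each claim
against independent oracles (brute-force computation, exhaustive
enumeration, closed-form expectations, and R `picante` in one cross-check).

## Phylogeny handling (`paleopcs.tree`)

Trees are rooted, with node **ages** (time before present) as the primary
currency; edge lengths are derived as `parent.age − child.age`. Reading a
Newick string with ultrametric branch lengths derives ages by placing tips
at age 0; non-ultrametric inputs keep their lengths but carry no ages. A
tree whose root has more than two children is rejected as unrooted.
Validation tolerates age discrepancies up to 1e-9 × tree height so that
serialization round-trips (branch lengths printed at 10 significant digits)
never create spurious age inversions.

**Taxon merging** collapses a named group of tips into one tip attached at
the group's most recent common ancestor with a zero-length stem, so the
merged taxon carries the clade's age. **Pruning** removes tips and
suppresses the resulting unifurcations.

**BLADJ dating**: given ages for the root and any subset of named internal
nodes (tips default to age 0), fixed nodes are processed oldest first; each
walks up to its nearest already-dated ancestor and the undated nodes on that
path receive evenly spaced ages between the two fixed ages. This guarantees
non-negative branch lengths, is idempotent, and preserves every fixed age
exactly. Sub-tolerance inversions between supplied ages and round-tripped
ages are clamped to the parent's age.

**Cophenetic distances** between tips are computed in one postorder pass:
`d(i, j) = 2·age(MRCA(i, j)) − age(i) − age(j)`.

## PCS metrics and the null model (`paleopcs.pcs`)

For an assemblage (one grid-cell × time-slice presence vector) with
pairwise patristic distances `D`:

- MPD = mean of `D[i, j]` over all unordered pairs of present taxa;
- MNTD = mean over present taxa of each one's distance to its nearest
  other present taxon.

Both are undefined (NaN) below richness 2, and MNTD ≤ MPD always.

The **independent-swap null** draws each randomized matrix by attempting a
fixed number of trial swaps from the *observed* matrix: a trial picks two
rows and two columns uniformly; if the 2×2 submatrix is a checkerboard it is
flipped, otherwise nothing happens. Every swap preserves all row and column
sums exactly, and the chain is a symmetric Markov chain over the
margin-preserving tables, so its stationary distribution is uniform. Each of
the `n_runs` null matrices uses an independent RNG substream spawned from
the run seed (`numpy.random.SeedSequence.spawn`), so results are independent
of execution order and reproducible.

SES values use the sample SD with `ddof=1`:
`NRI = −(MPD_obs − mean_null) / SD_null` (NTI analogously with MNTD).
When the null SD is numerically zero (relative tolerance
`1e-10 × max(1, |null mean|)`) the SES is reported missing rather than an
arbitrary large number.

Defaults are 999 null runs × 1,000 trial swaps, matching common practice in
existing implementations. Note that a *fixed* trial-swap count cannot mix an
arbitrarily large matrix to stationarity: for a matrix with `F` filled
cells, the calibration tests in this repository scale the chain length with
`F` (tens of times `F` trial swaps) and verify that SES of null-generated
data is mean 0, SD 1, with ~5% exceeding |1.96|. Users analyzing large
matrices should raise `trial_swaps` accordingly; the pipeline exposes it as
`trial_swaps` in the configuration. `numba`-compiled kernels (optional, with
an RNG-identical pure-Python fallback) keep long chains cheap.

An exhaustive enumerator of all margin-preserving tables (for matrices with
≤ 25 cells) serves as an oracle in tests.

## Gridding (`paleopcs.grid`)

Sites with quality strictly greater than the threshold (default 0.75) are
kept. Sites are assigned to cells by flooring coordinates to the grid
resolution (default 0.5°, half-open intervals). Within a (cell, slice,
taxon), relative abundances are averaged over *all* sites in the cell
(absences count as zero). The occurrence matrix per slice is binary
presence/absence over a fixed taxon list; taxa absent from a slice are
dropped from that slice's matrix. The collinearity screen greedily removes
the variable involved in the most |Pearson r| ≥ 0.75 pairs until none
remain.

## Spatial statistics (`paleopcs.spatial`)

**Weights**: binary distance-band adjacency (great-circle haversine
distance ≤ threshold, Earth radius 6371.0088 km), row-standardized.
Observations with no neighbor (islands) are flagged; the SAR model drops
them iteratively and reports the count.

**Moran's I**: `I = (n/S0)·z'Wz / z'z` on mean-centered values;
`E[I] = −1/(n−1)`; the analytic p-value uses the normality variance (S1/S2
formulas), and the permutation p-value is two-sided with
`p = (1 + #extreme)/(n_perm + 1)`.

**Spatial-error model**: `y = Xβ + u`, `u = λWu + ε`, ε i.i.d. normal.
Estimated by profile maximum likelihood over λ: for fixed λ, β and σ² have
closed forms on the whitened data `(I − λW)y`, `(I − λW)X`; the
log-determinant `log|I − λW|` comes from the eigenvalues of the symmetric
similar matrix `D^{-1/2} A D^{-1/2}` of the binary adjacency `A` (exact for
row-standardized weights). λ is searched on the open interval bounded by the
reciprocals of the extreme eigenvalues with a bounded scalar minimizer.
Reported: coefficients with conditional Wald standard errors (treating λ as
fixed at its MLE), the Nagelkerke pseudo-R²
`1 − exp((2/n)(ll_null − ll))`, a likelihood-ratio test against OLS
(λ = 0), and Moran's I of the whitened innovations `(I − λW)û` as the
residual-autocorrelation diagnostic. Monte-Carlo checks show mean coefficient
estimates within 0.05 of truth and ~95% Wald coverage at λ = 0.7 on a 15×15
lattice.

**IDW interpolation** (power 2) is presentation-only: exact at data points,
bounded by the data range.

## Stationarity framework (`paleopcs.stationarity`)

Time slices are categorical with the most recent slice as reference. The
three nested forms for metric `y` and climate variable `x` are:

1. `stable_relationship`: `y ~ 1 + x`
2. `stable_slope`: `y ~ 1 + x + time dummies` (intercept shifts only)
3. `changed_relationship`: adds `x × time` interactions (per-slice lines)

Slices with fewer than `min_sites_per_slice` (default 10) cells are excluded
before fitting. Forms are compared by partial *F*-tests under OLS and
likelihood-ratio χ² tests under SAR; the selected form is
`changed_relationship` if the slope-vs-changed test rejects at α (default
0.05), else `stable_slope` if the stable-vs-slope test rejects, else
`stable_relationship`. The per-slice intercepts and slopes implied by the
changed form equal independent per-slice simple regressions exactly.

For SAR, the weight distance is chosen per metric–variable pair from the
candidates (default 120/360/480 km) by minimizing |Moran's I| of the stable
form's residuals, ties going to the smallest distance; the chosen distance
is then used for all three forms. An equal-sample-size sensitivity utility
subsamples every slice to the same n.

## Deglaciation (`paleopcs.deglaciation`)

Ice layers dated off-slice are aligned to the nearest 1-ka slice, ties going
to the younger layer. A cell marked glaciated in a slice that contains an
assemblage is reclassified ice-free (reported count). **DEGLAC** for a cell
at slice `t` is `t_first_free − t`, where `t_first_free` is the first
ice-free slice after the last glaciation (or the record start for
never-glaciated cells): 0 in the first ice-free slice, incrementing by 1 per
subsequent ice-free slice, NaN while glaciated, resetting if a cell
re-glaciates. Heatmap tables average a PCS metric within (time, DEGLAC)
bins and report cell counts; the residualized variant first removes a pooled
OLS fit of the metric on all climate variables.

## Synthetic generator (`paleopcs.simulate`)

One `Scenario` fixes the whole study: a birth–death phylogeny (dendropy)
with a Brownian trait; seven climate variables, each a latitudinal gradient
plus a per-ka trend plus spatially correlated Gaussian noise (exponential
covariance, Cholesky draw) whose SD scales with that variable's systematic
spread; a linearly poleward-retreating ice margin whose masks extend four
slices before the assemblage record (so DEGLAC varies within the record's
oldest slice); and one site per ice-free cell per slice, with fixed richness
and Dirichlet(1) relative abundances, assembled by:

- **filtering** — admission weight `exp(−(trait − b(t)·x_std)² / (2τ²))`
  where `x_std` is the standardized focal climate variable; smaller τ means
  stronger filtering and more clustering;
- **neutral** — uniform draws;
- **limiting_similarity** — sequential admission rejecting candidates
  within trait distance δ of a member (overdispersion).

Ground truth (mechanism, b(t), noise parameters, traits) is written to
`truth.json`; bundles are byte-deterministic under the scenario seed.

**Realism limits**: sites sit exactly at cell centers with quality 1.0 (the
gridding and quality-filter paths are exercised by unit tests instead);
richness is constant rather than environmentally driven; climate noise is
independent across variables and slices (no temporal autocorrelation beyond
the trend); the ice margin is a latitude step function; taphonomy, sampling
effort, and dating error are not modeled.

## Problem sizes and reproducibility

Default sizes are chosen to keep a full run on one CPU in minutes: the
small preset is 20 taxa on a 10×10 half-degree grid over 8 slices; a
`study_like` preset (96 taxa, 24×20 cells, 22 slices) mirrors a
continental-scale study's proportions for heavier experiments. Every
stochastic stage derives an independent substream from one master seed, so
pipeline reruns are byte-identical (verified by checksum comparison), and
`scripts/acceptance.py --seed N --out f.json` regenerates the results
summary deterministically.
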