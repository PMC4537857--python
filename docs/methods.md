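# Methods

## Box-counting fractal estimation

A binary silhouette (foreground = root tissue, origin top-left) is padded
with background to the next power of two and tiled with grids of box side
*L* anchored at the origin; *N<sub>L</sub>* is the number of *L×L* cells
containing at least one foreground pixel. The default ladder is the ten
powers of two 1…512 px, spanning log₁₀(512) ≈ 2.7 orders of magnitude; it is
configurable (e.g. 1…256) but every size must divide the padded side. No
grid-offset averaging is performed — the estimate is the plain box count.

The power law *N<sub>L</sub> = K·L<sup>−D</sup>* is fitted by ordinary least
squares of ln *N<sub>L</sub>* on ln *L*. FD = −slope; FA = intercept = ln *K*
(natural logarithm; the raw-scale *K* = e^FA is reported alongside, since
both scales are in circulation for abundance). The fit R² and the per-scale
local slopes (−Δln N / Δln L between consecutive ladder points, nine values
for the default ladder) are retained as diagnostics: a flat local-slope
profile supports power-law behavior over the scale range.

Thresholding convention: a pixel is foreground iff its value is **strictly
greater** than the threshold, so a pixel exactly at the threshold is
background. Background-reference subtraction (absolute difference) precedes
thresholding when a reference frame is supplied.

## Root angle and stalk diameter

Both are measured on side-view silhouettes. The **stalk band** is the
contiguous top run of foreground rows whose width stays within
[ref/flare, ref·flare] of a reference width (median width of the top 5 % of
foreground rows; flare factor default 1.5, configurable); rows belonging to
the rounded cap at the very stem top are skipped. SD is the mean foreground
extent over the band. The band ends either at the flare of the root cone or
at a narrow waist — both occur in practice.

**RA** is measured on the root region below the stalk band. Per-row extreme
(min/max) foreground columns form left and right envelopes; because the
silhouette cone widens from the apex to its point of maximal extent and then
contracts toward the root tips, each envelope line is fitted by least
squares *only over its expanding span* (apex row to extreme-extent row). RA
is the angle between the two lines, clipped to (0, 180). A robust variant
uses the 5th/95th percentile columns per row instead of the strict extremes;
it is the recommended setting for heavily branched silhouettes, whose stray
laterals otherwise inflate the envelope.

Per sample, RA and SD are arithmetic means over the four side views; FD and
FA are taken from the single underside view (side views contain the stem,
which biases the fractal fit, and underside estimates from the same sample
are nearly perfectly correlated).

## Outlier filtering

Image processing occasionally fails (debris, broken silhouettes). A view is
dropped when its fractal fit R² < 0.95 or when any trait deviates more than
4 median absolute deviations from its plot's median; a plot whose views all
fail is retained as a missing record, never zero-filled. Thresholds are
package conventions (configurable), chosen to catch gross failures while
leaving ordinary biological variation untouched; every removal is logged
with its reason.

## The synthetic root generator

The generator is a stochastic recursive branching process, not a
biomechanical model; it exists to give the imaging stage controllable ground
truth. A vertical stem capsule (diameter `stem_diameter_px`, length
`stem_length_px`) carries `n_nodes` whorls in a compact band just above the
stem base, mirroring the crowded underground nodes that bear the shoot-borne
roots of a mature maize crown. Each whorl emits `roots_per_node` straight
shoot-borne roots *at* the cone half-angle from the downward vertical, with
evenly spaced azimuths rotated by a random offset per whorl. This "shell"
placement is deliberate: an orthographic side view shows a root at azimuth φ
under the projected angle atan(tan θ·cos φ), so only roots on the cone
surface near the viewing plane carry the cone angle into the silhouette.
With the shell model, measured RA recovers 2 × the cone half-angle to within
about 1–2° on average (tolerance 5°).

Each segment of order < `max_order` exposes `branch_sites` (default 3)
candidate sites, each spawning a lateral with probability `branch_prob`;
laterals deviate 30–60° from the parent direction at a random azimuth,
shrink geometrically (`length_decay`, default 0.55), and fill the cone
interior — mean underside FD increases monotonically with `branch_prob`.
All randomness flows through one explicit seed per call; rasterization is
alias-free (a pixel is foreground iff its center lies in a segment capsule),
keeping box counts integer-reproducible. Projections use exact integer
rotation matrices at multiples of 90°, so rotating the model and projecting
commute bit-identically.

What the generator does *not* emulate: root tissue loss during washing and
handling, soil/moisture response, curvature of real roots, diameter taper,
and the depth-limited sampling of a physical core. Tests passing on this
generator therefore validate the measurement and modeling machinery, not
field realism.

Fixture rasters with analytically known dimension anchor the fractal stage:
a full-width one-pixel row (dimension 1), a filled canvas (dimension 2), and
a Sierpinski-triangle pattern built by keeping blocks with `i & j == 0`
(dimension log 3 / log 2 ≈ 1.585, with exactly N(2^m) = 3^(ℓ−m) boxes on the
aligned ladder at level ℓ).

## The diallel model

The trial is a generation-block design: parental inbreds, their unordered
F1 crosses, and commercial checks blocked by entry class within each
replication of each environment. The fixed-effects model is

    Y = μ + e_i + r_ij + b_k + β(a_l + a_m) + γ(g_l + g_m) + δ·s_lm
          + eb_ik + rb_ijk + d_ilm + c_n + ec_in + ε

where e is environment, r replication within environment, b the entry-class
(generation block) means, a the per-line additive effects, g the GCAs, s the
SCAs, c the check effects, and the remaining terms the class and genetic
interactions with environment. Design coefficients: β = 1 for a parent row
on its own a, β = ½ for each parent of a cross, γ = δ = 1 only for cross
rows, all zero for checks. The additive × environment interaction inherits
the β weights. Genetic parameters are fixed effects — the parents are a
selected set, not a population sample — so estimation is OLS, not REML.

**Sum-to-zero reduction.** Every effect family is represented as its
full-level coefficient matrix times an orthonormal basis of the null space
of its constraint matrix (overall sum for main effects; per-environment sums
for nested replications; row and column sums for interactions; per-line sums
Σ_m s_lm = 0 for SCA). This yields the free-parameter structure directly:
for *p* = 12 parents, 11 additive + 11 GCA + 54 SCA = 76 genetic columns.
Estimates and standard errors of the full per-level effects are recovered
through the same basis. Rows with a missing trait value are dropped per
trait (unbalanced designs are the norm); a Moore–Penrose pseudoinverse
handles rank deficiency.

**Type III tests** compare the full model against the model with one
family's columns removed; the numerator df is the rank difference. Under
sum-to-zero coding this reproduces the classical Type III convention for
this design. The entry-class term is equivalently expressible as two 1-df
contrasts — mid-parent heterosis (F1-block mean − parent-block mean) and
F1 vs checks — which are reported with SEs from the coefficient covariance.
Entry-class least-square means are μ + b_k, since all other families average
to zero over their levels.

**Adaptive FDR.** q-values use the adaptive linear step-up: the number of
true nulls m₀ is estimated by the lowest-slope rule on the ordered p-values,
then the step-up is applied with m₀ in place of m and monotonicity enforced.
This keeps q-values free of a pre-chosen α (a single p maps to itself; all-
equal p's get equal q's; adaptive q ≤ plain step-up q whenever m₀ < m).
Significance is rendered as ***, **, *, + at q ≤ 0.001/0.01/0.05/0.1.

**Repeatability.** Within one entry class, variance components are taken
from the expected mean squares of the genotype × environment two-way ANOVA
(MS_G = σ²ε + r·σ²GE + r·e·σ²G etc.), negative estimates truncated at zero,
and combined on an entry-mean basis: R = σ²G / (σ²G + σ²GE/nE + σ²ε/(nE·nR)).
The plug-in formula is a package convention; it is labelled repeatability,
not heritability, because the genotypes are a selected set.

## Multivariate layer

Per-entry-class Pearson correlations use pairwise-complete observations
(matching the unbalanced design) and refuse constant traits. Maturity
adjustment regresses a trait on days to silking and keeps the residuals
re-centered at the trait mean — a covariate-residual convention, since only
"adjusted for maturity" is specified by practice. Z-scoring standardizes
columns to mean 0, sd 1 (ddof = 1). PCA is an eigendecomposition of the
trait Pearson correlation matrix (eigenvalues sum to the number of traits;
components ordered by eigenvalue; each component's sign fixed so its
largest-magnitude loading is positive; rank deficiency shows up as zero
eigenvalues). Hybrid clustering is agglomerative on Euclidean distances of
the standardized entry means; Ward linkage is the default for compact,
similarly sized groups and the linkage is configurable — cluster memberships
depend on that choice and are treated as exploratory output. Rows are sorted
by entry id before linkage so the partition is input-order invariant.

## Pipeline and problem sizes

The `run` pipeline stages are fixtures → image demo → diallel → multivariate,
writing CSVs whose bodies are byte-identical for a fixed config + seed; each
file carries `#`-prefixed provenance lines (package version, config hash,
seed). The bundled demo simulates the canonical 12-parent / 66-cross /
6-check design over 2 environments × 3 replications (504 plots) and renders
a handful of 512-px root systems for the imaging stage. Test ensembles use
256-px canvases and ~50 root systems, with Monte-Carlo suites at 200–400
replicates on a 5-parent design — sizes chosen so the whole suite runs in
well under a minute while keeping Monte-Carlo error far below the asserted
tolerances.

## Known limitations

* The RA/SD procedures are a faithful reading of "angle of the root cone"
  and "average stalk width", not a reverse-engineering of any specific
  imaging cabinet's code; absolute values on real images will depend on
  thresholding and cropping conventions.
* FA is reported on both ln K and K scales; consumers must pick one
  consistently.
* The repeatability formula and the outlier rule are package conventions
  (flagged as such in the API docs), since practice varies.
* Fixed-effects inference only: no BLUPs, reciprocal/maternal effects, or
  F2 generations.
* The adaptive m₀ estimator is conservative for very small test families
  (m ≤ 2 it degenerates to plain step-up behavior).
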