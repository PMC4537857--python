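# rootbox

Box-counting fractal phenotyping of maize root-core silhouettes, and a
fixed-effects diallel analysis of the resulting root architecture traits.

Mature field-grown maize root systems are hard to phenotype: excavated root
cores photographed from four side perspectives (90° apart) and one underside
view yield binary silhouettes from which four plot-level traits are measured —

* **FD**, the box-counting fractal dimension, a proxy for branching density.
  Tiling a silhouette with grids of box side *L* and counting occupied cells
  *N<sub>L</sub>* gives the power law *N<sub>L</sub> = K·L<sup>−D</sup>*, fitted
  as log *N<sub>L</sub>* = log *K* − *D* log *L* by least squares. For 2D images
  *D* runs from 1 (a single unbranched root) to 2 (a space-filling, highly
  branched system).
* **FA**, fractal abundance, the intercept ln *K* — the extent of soil-space
  exploration.
* **RA**, root angle: the full apex angle of the root cone in a side view.
* **SD**, stalk diameter: mean pixel width of the stem band of a side view.

Trait plot means from a trial of *p* inbred parents, all *p(p−1)/2* unordered
F1 crosses, and commercial check hybrids are then analyzed with a
generation-block diallel model:

```
Y = μ + e_i + r_ij + b_k + β(a_l + a_m) + γ(g_l + g_m) + δ·s_lm
      + eb_ik + rb_ijk + d_ilm + c_n + ec_in + ε
```

with β = 1 for a parent on its own additive effect a_l, β = ½ for each parent
of a cross, and γ = δ = 1 only for crosses, under the usual sum-to-zero
restrictions. The model yields per-line additive effects, general (GCA) and
specific (SCA) combining abilities, mid-parent heterosis (F1-block mean minus
parent-block mean), Type III F tests, and adaptive-FDR q-values. A
multivariate layer adds per-entry-class correlations, maturity adjustment,
Z-scores, PCA of the trait correlation matrix, and Ward clustering of hybrids.

Because raw root-core images from such trials are rarely deposited, the
package ships a synthetic-data module that generates (i) rasters with
analytically known box dimension, (ii) stochastic branching root systems with
controllable cone angle, stem width and branching density, projected to the
five standard views, and (iii) diallel phenotype tables with known genetic
effects — so every stage is testable against ground truth.

## Worked example

```sh
rootbox run --out demo --seed 2
```

runs the full pipeline: fractal fixtures, a small image-phenotyping demo, a
12-parent / 66-cross / 6-check diallel simulated in 2 environments × 3
replications with a planted FD heterosis of 0.4, the fixed-effects fit, and
the multivariate summary. Key output (`demo/contrasts.csv`):

```
name,estimate,se,...,stars,trait
heterosis,0.4026713733,0.006417681544,...,***,FD
F1_vs_checks,0.2139146188,0.00871991211,...,***,FD
env_difference,0.007905021605,0.007020196199,...,,FD
```

The fitted mid-parent heterosis 0.403 ± 0.006 recovers the planted 0.4; the
environment difference (no planted effect) is correctly non-significant. The
Type III table (`demo/term_tests.csv`) shows the design's degrees of freedom
emerge from the sum-to-zero design matrix — 11 for lines per se, 11 for GCA,
54 for SCA — with highly significant additive and SCA terms and a null GCA
term, exactly as simulated. `demo/pca_loadings.csv` and `demo/clusters.csv`
summarize the hybrid entry means.

Library use mirrors the CLI:

```python
from rootbox import synthetic as syn, imaging as im

img = syn.render_known_fractal(syn.FractalFixtureSpec("sierpinski_triangle", 512, 9))
est = im.fit_fractal(im.box_count(img))
print(est.fd)   # 1.5849625... = log 3 / log 2
```

## Layout

* `rootbox.synthetic` — fixtures, the branching-root generator, view
  projection, diallel simulation
* `rootbox.imaging` — preprocessing, box counting, fractal fit, RA/SD
  measurement, outlier filtering
* `rootbox.diallel` — design matrix, OLS fit, Type III tests, contrasts,
  genetic effect tables, adaptive FDR, repeatability
* `rootbox.multivariate` — correlations, maturity adjustment, Z-scores, PCA,
  clustering
* `rootbox.pipeline` / `rootbox.cli` — orchestration and the `rootbox`
  command

See `docs/methods.md` for the modeling choices and their rationale.
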