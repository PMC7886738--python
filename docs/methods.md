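# Methods

## The model

`boundedsteps` implements a null model of intermittent locomotion: an
uncorrelated (Markovian) random walk reduced to its sequence of stopping
locations inside a bounded convex domain Ω.  Temporal structure is
ignored entirely; the object of study is the displacement between
consecutive stops, the *step* ℓ.

In unbounded space the walker draws steps from an **intrinsic step law**
f_i, assumed symmetric (1D) or rotationally symmetric (2D).  Inside an
enclosure the observed (*transformed*) step law f_t differs from f_i in
a boundary-condition-specific way.  Three boundary conditions are
modelled:

- **no-go** — a proposed step landing outside Ω is rejected and redrawn
  (direction and magnitude both resampled);
- **stop-go** — the proposed segment is truncated at its first boundary
  crossing and the walker stops on the wall (1D only);
- **reflecting** — the overshoot is folded back by specular reflection,
  repeatedly if it spans several domain lengths (1D only).

The stationary stopping-location density g solves the homogeneous
Fredholm equation of the second kind g(x) = ∫ g(x′) P(x − x′ | x′) dx′,
with P the per-step kernel.  Closed forms used by the package:

- **no-go:** g ∝ 𝒩, where 𝒩(x) is the *acceptance mass* — the
  probability that a free step from x lands inside Ω.  Substituting
  g ∝ 𝒩 collapses the transformed step density to a product,
  f_t(ℓ) ∝ f_i(ℓ) · h(ℓ), with

      h(ℓ) = measure( Ω ∩ (Ω − ℓ) ),

  the **shaper function**: the set covariance (covariogram) of the
  domain.  h(0) equals the measure of Ω, h vanishes for |ℓ| ≥ diam Ω,
  and for convex Ω it decreases monotonically along every ray.  Closed
  forms: h(ℓ) = (L − |ℓ|)₊ for an interval of length L; the product of
  two interval shapers for the unit square; the two-disk lens area
  2 cos⁻¹(|ℓ|/2) − ½ √((4 − |ℓ|²) |ℓ|²) for the unit disk (R² scaling
  for general radius).  Arbitrary convex polygons are handled by exact
  polygon clipping.
- **reflecting (1D):** g is uniform for every f_i; f_t follows from the
  method of images (below).
- **stop-go (1D):** no closed form for g; the shipped analytic f_t
  assumes a uniform start and first-step statistics, giving
  f_t(ℓ) ∝ f_i(ℓ)(L − |ℓ|)₊ + (1 − F_i(|ℓ|)) θ(L − |ℓ|) with F_i the
  intrinsic CDF.  A numerical stationary density (boundary atoms
  included) is available through the Fredholm solver as an opt-in that
  goes beyond the analytic treatment.

For step magnitudes in 2D, f̃_i(ℓ) = 2πℓ f_i(ℓ, 0) and
f̃_t(ℓ) ∝ f_i(ℓ, 0) · ℓ · h̃(ℓ) with h̃ the angular integral of the
vector shaper.

**Reconstruction.** Because the no-go bias is multiplicative and purely
geometric, the intrinsic law is recovered bin-wise from an empirical
histogram: f_i ∝ f_t / h (vector form) or f̃_i ∝ f̃_t / h̃ (magnitude
form).  Information about steps with |ℓ| ≥ diam Ω is irretrievably lost
(h = 0 there), and bins where h is nearly zero amplify noise as 1/h²;
both are excluded and reported as missing, never as zero.

## Reflecting images

The reflecting step kernel is implemented through the landing-point
identity: folding x + ℓ into [0, L] gives density
Σ_k [ f_i(2kL + z − x) + f_i(2kL − z − x) ] at z.  The k = 0 and k = 1
terms reproduce the familiar single-reflection terms
f_i(ℓ) + f_i(ℓ + 2x) + f_i(2 − 2x − ℓ); higher k cover multiple
reflections and vanish once 2kL exceeds the support radius, so a single
image pair is exact for supports inside (−2L, 2L).  The simulator uses
the fold map directly, which provides an independent mechanism against
which the image-sum density is tested.

## Numerical choices

- **Quadrature.** Adaptive Gauss–Kronrod (`scipy.integrate.quad`,
  absolute tolerance 1e−11, with explicit breakpoints at support edges)
  normalises all analytic densities.  Angular integrals for h̃ use a
  uniform trapezoid rule with 720 angles, halved by the shaper's central
  symmetry; for a periodic integrand this rule converges faster than
  the bin error of any histogram it is compared with.
- **Fredholm solver.** Nyström discretisation on a uniform grid with an
  exactly integrated destination: the transition mass from node x_j
  into the cell around x_i is a CDF difference, so discontinuous step
  laws (e.g. the uniform family) lose no accuracy to point sampling.
  Outgoing columns are renormalised to unit mass, making the discrete
  chain exactly conservative; the stationary vector comes from power
  iteration (uniform start, sup-norm tolerance 1e−10, cap 10⁴
  iterations, spectral diagnostic on failure).  The equation is solved
  on a 4× refined grid and reported at the requested nodes, because
  kinks in the kernel contribute O(h) errors localised at matching
  nodes; end-node densities are extrapolated from cell centroids.  At
  201 reported nodes the stationary density matches the closed forms to
  a few 1e−4 in sup norm (the worst case being the discontinuous
  uniform kernel).
- **Disk solver.** Rotational symmetry reduces the 2D no-go kernel to a
  radial one; the angular average uses a 256-point midpoint rule and the
  polar measure 2πr dr supplies the quadrature weights.
- **Sampling.** Families with exact samplers (Gaussian, uniform) use
  them; the parabolic and tabulated families invert a cached 4096-node
  CDF grid — grid error is far below Monte-Carlo error at every sample
  size used here.  The Heaviside convention θ(0) = 0 is applied
  uniformly; all densities vanish at their support edge, which no
  statistic can detect.
- **Geometry.** Polygons are normalised to counter-clockwise order and
  validated for convexity on construction; membership tests use the
  half-plane representation (offset tolerance 1e−12), which unlike a
  slope/intercept line form also represents vertical edges.  Domains
  are closed sets: a step landing exactly on the boundary is accepted
  under no-go.  Boundary points carry zero probability for continuous
  step laws, so this convention is statistically invisible, but it
  makes stop-go termination points representable.  Polygon intersection
  is delegated to shapely; a 400×400 midpoint-grid integration of the
  indicator product serves as an independent oracle in the tests.
- **Simulator.** All M runs advance in lockstep from one seeded
  `numpy` generator, vectorising the rejection loop across runs.  An
  ensemble is reproducible from its root seed; runs are mutually
  independent because every run consumes from disjoint positions of the
  same stream at each step.  The rejection loop is guarded by a
  per-step attempt cap (default 10⁶) that raises with the stuck
  location — the acceptance mass 𝒩 can be arbitrarily small near
  corners for short-support kernels, and a hard error beats a silent
  hang.
- **Histograms.** Per-run histograms are normalised to unit mass and
  summarised by their per-bin ensemble mean and standard deviation; the
  reconstruction divides both by the shaper at bin centres (bin-centre
  bias is second order in bin width; the default 60 bins keep widths
  ≤ 1/50 of the cutoff).  Default shaper floor: bins with
  h < 0.01 · h(0) are excluded.

## Synthetic-data generator

The simulator doubles as the study's data generator; its defaults mirror
the reference experiment: unit-square domain, parabolic intrinsic kernel
f_i(ℓ) = 3(a² − ℓ²)θ(a² − ℓ²)/(4a³) with a = 0.75 (planar radial profile
2(a² − ℓ²)/(πa⁴) in 2D), no-go boundaries, burn-in 1% of N.  The
package's own reconstruction experiment (also run by
`tests/test_acceptance.py`) uses M = 200 runs of N = 10⁴ steps with a
100-step burn-in — a scale chosen so the whole suite runs on a laptop
core in well under a minute while leaving every per-bin envelope check
statistically meaningful.

What the generator emulates: stationarity after burn-in, ensemble
variability across independent runs, and the pure geometric bias of the
enclosure.  What it deliberately does not emulate: step–step
correlations (real organisms are persistent or anti-persistent),
behavioural responses to walls (thigmotaxis, wall-following), temporal
structure (stop durations, speeds), and measurement noise on stop
positions.  Passing tests therefore demonstrate that the estimators
recover the truth *under the null model's assumptions* — they do not
certify the null model as a description of any particular organism.

## Design choices where the design was open

- Shaper values are exposed un-normalised, as overlap measures, since
  every consumer divides by an explicit normalisation anyway.
- The reconstruction is left un-normalised by default (shape comparison
  is the primary use); renormalisation over retained bins is opt-in.
- Uncertainty propagation through the division is per-bin linear
  scaling of the ensemble standard deviation; no cross-bin covariance
  is modelled.
- The stop-go stationary density is exposed only through the numerical
  solver, clearly separated from the closed-form results.
- Histogram bin counts are free parameters of the configuration; there
  is no canonical choice, and the defaults (60) are stated above.

## Known limitations

- Only convex domains; only 1D and 2D (the multiplicative structure
  extends to higher dimensions, but no d ≥ 3 geometry is implemented).
- Stop-go and reflecting boundaries are 1D only; the reconstruction is
  valid only under no-go boundaries, where the bias is multiplicative.
- Heavy-tailed intrinsic laws are supported only via the tabulated
  family at finite truncation.
- The polygon acceptance mass uses a fixed midpoint grid (128²–256²);
  for polygons with extreme aspect ratios a finer grid may be needed.
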