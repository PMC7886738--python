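# boundedsteps

Random-walk null models of intermittent locomotion in bounded convex
domains, and the correction of the step-statistics bias the enclosure
introduces.

## The problem

Movement ecologists and behavioural biologists routinely record
locomotion inside enclosures — cages, arenas, Petri dishes.  An
organism moving intermittently produces a sequence of stopping
locations; the displacement between consecutive stops is a *step* ℓ.
When the organism's movement range is comparable to the arena size, the
boundary reshapes the observed step histogram in a geometry-specific
way: large steps are suppressed, the apparent step variance shrinks,
and a perfectly unbiased random walker can look as if it were
responding behaviourally to the enclosure.

`boundedsteps` provides the null model against which such data should
be compared: an uncorrelated random walk with a symmetric (1D) or
rotationally symmetric (2D) **intrinsic step law** f_i, confined by
**no-go** (rejected-and-redrawn steps), **stop-go** (steps truncated at
the wall, 1D) or **reflecting** (specularly folded steps, 1D)
boundaries.

## The core result

Under no-go boundaries the stationary stopping density is proportional
to the acceptance mass 𝒩(x) (the probability that a free step from x
stays inside), and the observed (*transformed*) step density
factorises:

    f_t(ℓ) ∝ f_i(ℓ) · h(ℓ),        h(ℓ) = measure( Ω ∩ (Ω − ℓ) ),

where h — the **shaper function** — is the set covariance of the
domain Ω and is independent of f_i.  It equals the domain measure at
ℓ = 0 and vanishes for |ℓ| ≥ diam Ω (√2 for the unit square, 2 for the
unit disk).  Closed forms are implemented for intervals, the unit
square, and disks; arbitrary convex polygons use exact polygon
clipping.  For step magnitudes in 2D, f̃_t(ℓ) ∝ f_i(ℓ,0) · ℓ · h̃(ℓ)
with h̃ the angular integral of h.

Because the bias is multiplicative and purely geometric, it can be
divided out of an empirical histogram:

    f_i(ℓ) ∝ f_t(ℓ) / h(ℓ),

recovering the intrinsic step law up to the domain diameter — beyond
it, the information is irretrievably lost.  The package implements the
simulator, the shaper functions, the stationary densities (closed
forms plus an independent Nyström/power-iteration Fredholm solver), and
this reconstruction with ensemble uncertainty envelopes.

## Worked example

The `demo` subcommand runs the whole pipeline on the reference setup —
unit square, parabolic kernel f_i(ℓ) = 3(a² − ℓ²)θ(a² − ℓ²)/(4a³) with
a = 0.75, no-go boundaries:

```sh
$ boundedsteps demo --outdir demo_out -M 50 -N 10000 --seed 0
square/parabolic(a=0.75)/no-go: M=50, N=10000; 48/60 bins retained; max |scaled reconstruction - truth| on retained bins = 0.0191 (4.1 s)
wrote demo_out/demo_reconstruction.csv
```

Reading: 50 independent runs of 10⁴ steps each were simulated; the
step-magnitude histogram was binned into 60 bins on [0, √2]; 48 bins
survived the shaper floor (bins where h̃ < 1% of h̃(0) are excluded
because the 1/h̃ division amplifies noise without bound); and after
dividing out the shaper, the reconstructed magnitude density deviates
from the known truth f̃_i(ℓ) = 2πℓ f_i(ℓ,0) by at most 0.019 (the
density peaks at ≈ 2.0, so ≈ 1% of peak) on the retained bins.

The same machinery is scriptable:

```python
import boundedsteps as bs

square = bs.unit_square()
dist = bs.Parabolic2D(a=0.75)
ens = bs.simulate(square, dist, bc="no_go", N=10_000, M=50, burn_in=100, seed=0)
ft = bs.estimate_step_density(ens, n_bins=60)        # mean ± std per bin
rec = bs.reconstruct_intrinsic(ft, bs.shaper_for(square), kind="magnitude")
```

Other subcommands (`simulate`, `shaper`, `steady-state`, `transformed`,
`reconstruct`) are driven by a YAML config; see
`examples/demo_square.yaml`.  Every command writes CSV artifacts plus a
JSON manifest (config echo, seed, version, wall time) from which the
run can be reproduced exactly.

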