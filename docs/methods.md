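# Methods

## The optimizer family

The package implements the firefly algorithm (FA) and an adaptive extension
(AdaFa) for box-constrained global minimization, plus the evaluation harness
used to compare them and a structural-biology application built on top.

**Standard FA.** A population of N candidate solutions ("fireflies") is
initialized uniformly in the box. Brightness is the negative objective
(minimization). In each generation every firefly is compared against every
other; toward each brighter peer it takes the step

    x_i <- x_i + beta0 * exp(-gamma * (r_ij / diag)^2) * (x_j - x_i) + alpha(t) * eps,

with `eps ~ N(0, I)`, `r_ij` the Euclidean distance and `diag` the box
diagonal. A firefly with no brighter peer takes only the random step. Moves
are applied in place and **the mover is re-evaluated after every move**, so
later comparisons in the same sweep see current brightness — the classic
formulation of the method's pseudocode. Positions are clamped to the box
after every move. `alpha(t)` decays linearly from `alpha0` to ~0 over the
budget (schedule S0).

Two conventions deserve comment because they fix the scale behavior:

* `gamma` acts on box-diagonal-normalized distance, making it dimensionless
  (default 1.0) across domains spanning `[-1.28, 1.28]` to `[-600, 600]`.
* the random step is `alpha(t) * N(0, I)` in raw coordinates (not scaled by
  the box width). With the linear decay this gives a long, slow anneal of
  the exploration radius through the O(1) scale, which is what lets the
  swarm settle into the unit cells of the Step function and finish with
  exact zeros; range-scaled noise provably cannot (the late-run noise is
  then far wider than a Step cell).

**AdaFa** adds three mechanisms, recomputed once per generation against the
best-so-far position at the start of the generation (the "reference"):

1. *Distance-adaptive absorption.* With `d_i` the distance of firefly i to
   the reference and `d_min`/`d_max` the extreme inter-firefly distances,
   the ratio `rho_i = (d_i - d_min) / (d_max - d_min)` (0 for a collapsed
   swarm) sets a per-firefly absorption coefficient

       gamma_i = exp(-lam * (1 - rho_i)) / delta.

   It is strictly positive, decreasing in both the amplitude factor `delta`
   and the contraction index `lam`, explodes when both are small, and is
   constant when the ratio's effect is removed — fireflies far from the
   best see a slightly more transparent medium, sharpening their pull.

2. *Gray-relational diversity control.* Deng's gray relational coefficient
   per dimension, `(Dmin + rho*Dmax) / (|x_ik - ref_k| + rho*Dmax)` with the
   extreme deviations taken over the whole population (distinguishing
   constant `rho = 0.5`), is averaged with uniform weights into a grade in
   (0, 1], then mapped affinely onto a contraction weight
   `g_i = g_max - grade * (g_max - g_min)` in `[g_min, g_max]`.

3. *Heterogeneous update rules.* Per move a fair coin selects either the
   FA-style attraction (with `gamma_i`) or a gray contraction toward the
   reference, `x_i <- best + g_i * (x_i - best) + alpha(t) * eps`. Fireflies
   similar to the best (high grade, small `g_i`) exploit aggressively;
   dissimilar ones keep a loose leash, preserving diversity. The coin is
   drawn per move (per firefly, per brighter peer), not per generation.

**Randomization schedules.** Six decays of `alpha(t)` at `u = (t-1)/T`:

| id | form | default constants |
|----|------|-------------------|
| S0 | `a0 * (1 - u)` (standard FA) | `a0 = 0.5` |
| S1 | `ac * exp(-c*u)` | `ac = 0.9`, `c = 35` |
| S2 | `ac * exp(-c*u^2)` | same `c` — slow start, steep finish |
| S3 | `ac * exp(-u*sqrt(N*D))` | population and problem size set the speed |
| S4 | `ac * exp(-u*N^k)` | `k = 0.9` |
| S5 | `ac * (1 + (N/D)*(1-u)) * exp(-u*D)` | endpoint depends on D only |

All five nonlinear schedules span a strictly larger range over a run than
S0, giving harder exploration early and far finer exploitation steps late;
S5's endpoint is independent of the population size. The effective value is
clamped into `[alpha_min, alpha_max]` (defaults 0 and 1) before scaling the
normal draw.

The governing constants (`ac`, the decay speeds, `k`, the gray bounds
`[0.4, 0.9]`, `delta = 1.5`, `lam = 0.1`) were fixed once against the
suite's qualitative behavior — exact Step zeros for every variant,
deep geometric convergence on the unimodal functions (Sphere final values
around 1e-25..1e-51, Ackley at its double-precision floor ~7.6e-15), and
the narrow premature-convergence plateau on Rosenbrock — and are all
exposed in `AdaptiveConfig`. `sensitivity_sweep` reruns the two-parameter
grids used to choose them.

**Problem sizes.** Benchmark experiments use 30 dimensions, population 40,
1000 generations and 30 independent trials (seeds `base_seed + trial`).
With per-move re-evaluation that is ~1.5M objective evaluations per trial;
the sweep, including the analytic objectives, runs inside a numba-compiled
kernel (~1 s per trial per CPU). A pure-Python sweep with identical update
rules serves arbitrary objectives (the 3-D placement problems below) and
keeps the package functional without numba; all randomness is pre-drawn per
generation from a `numpy.random.Generator`, so any run is reproducible
under its seed on either path.

## Benchmark suite

f1 Sphere, f2 Schwefel 2.22, f3 Quadric (Schwefel 1.2), f4 Schwefel 2.21,
f5 Rosenbrock, f6 Step, f7 noisy Quartic (additive U[0,1) per evaluation),
f8 Schwefel 2.26, f9 Rastrigin, f10 Ackley, f11 Griewank, f12 Penalized —
the classic Yao/Liu selection with its conventional boxes, except that
Rosenbrock uses De Jong's `[-2.048, 2.048]`. That choice is deliberate: on
`[-30, 30]` a late-stage anneal occasionally follows the valley onto the
exploding branch `x_{k+1} = x_k^2 > 1` and strands a tail coordinate far
out, producing rare large outliers that the tiny across-trial spread of the
reference results excludes; the tight box reproduces the narrow plateau at
the valley entrance (mean ~25, spread ~1). Success thresholds follow the
adaptive-PSO literature's conventional accuracy levels and are editable in
the registry; f8's success is measured as closeness to its (negative) known
optimum.

## Rank-test battery

`friedman`, `aligned_friedman` and `quade` implement the Garcia/Derrac
omnibus battery over an algorithms-by-functions table of mean final values,
with tie-averaged ranks, chi-square (Friedman, aligned) and F (Quade)
reference distributions. Ranking is ascending by raw mean by default;
ranking by |mean − optimum| is a flag (`orientation="gap"`) and differs
only on functions with non-zero optima. Friedman is invariant to any
within-block order-preserving transform; the aligned and Quade tests also
consume the values (block means and ranges), so only global positive affine
invariance holds for them.

`load_reference_table` ships the published 9x12 mean table this battery is
demonstrated on. Its reproduction quirk: the published per-algorithm scores
are recovered exactly only when the means are carried at 12-decimal fixed
precision, so values below 1e-12 underflow to zero and tie (eight of the
published scores then match to the printed digit, and the Friedman
statistic agrees to 0.13%). The residual discrepancies in the five adaptive
variants' scores trace to tie orders inside those underflow groups that the
printed table cannot resolve; they are not recoverable from the published
data, and the bundled table documents this in its loader.

## Backbone reconstruction

A C-alpha trace is summarized by its virtual-bond internal coordinates:
consecutive distances `b_i` (~3.8 A), planar pseudo-angles `theta_i`, and
signed pseudo-dihedrals `tau_i`. `geometry_to_distances` converts them into
per-atom targets: atom i (from the fifth onward) must sit at prescribed
distances from atoms i-1..i-4, the distances implied by four bond lengths,
three bond angles and two dihedrals (computed by exact NeRF construction of
the 5-atom fragment). The chain is rebuilt sequentially: the first atom is
placed at a random origin, atoms 2-4 by exact geometric construction, and
each later atom by minimizing the constraint energy

    E(x) = sum_{j=1..4} ( |x - x_{i-j}| - d_hat(i, i-j) )^2

over a cube of side four times the largest target centered on the previous
atom, using AdaFa (population 12, 100 generations per atom). The energy's
two basins (the mirror pair cut out by the three nearest spheres, split by
the fourth distance) are handled with up to 6 restarts, keeping the lowest
energy and stopping early below 1e-8; an absolute-deviation energy is
available by flag. Energies sum over the newest atom's four constraints
only, matching the sequential formulation. Noise robustness is probed by
perturbing each internal coordinate with zero-mean Gaussian noise of
standard deviation `fraction * |value|` (angles re-wrapped into their
ranges); perturbing the derived distances instead is the documented
alternative (`noise_on="distances"`).

The synthetic ideal helix (rise 1.5 A, radius 2.3 A, twist 100 deg/residue;
consecutive Ca-Ca distance 3.83 A) is the built-in test article spanning
the 13-70 residue range of real trans-membrane helices. It emulates the
uniform internal geometry of an idealized helix only: real chains have
heterogeneous angles/dihedrals, kinks and loop regions, so passing
reconstruction tests on it demonstrates the constraint-to-coordinates
machinery and the optimizer, not performance on experimental structures.
Noise-free reconstructions of 13-70-residue helices superpose on the source
at RMSD below 1e-3 A; 10% noise degrades the global RMSD to several A
(noise in every internal coordinate compounds along the chain), which the
scores report faithfully.

Model quality is scored by Kabsch superposition RMSD (proper rotations
only), TM-Score (`d0 = 1.24 (L-15)^(1/3) - 1.8`, clamped at 0.5 A for short
chains) maximized with the standard seed-superpose-extend iteration, and
GDT-TS/GDT-HA (cutoff sets {1,2,4,8} and {0.5,1,2,4} A). The GDT fraction
search is exact (exhaustive over subsets) for chains of up to 10 residues
and a windows-plus-extension heuristic with a greedy shrink pass beyond.

## Numerical and degenerate-case policy

Non-finite objective values are recorded as `+inf` (the firefly is kept).
A collapsed swarm defines the distance ratio as 0 and the gray coefficient
via unit grade. Out-of-box moves are clamped. Collinear triples make the
pseudo-dihedral undefined: extraction raises with the residue index, while
the NeRF builder accepts 180-degree bond angles by choosing an arbitrary
torsion reference plane. Ranks use average ties throughout.

## Known limitations

The optimizer constants were reconstructed from behavior, not transcribed;
other constants reproduce the same qualitative regimes on different depth
scales. On 30-D Rosenbrock the package converges slightly deeper (mean ~25)
than the published plateau (28.7-28.8). Rastrigin is the one suite member
where the adaptive variants' published means (3-7) are clearly better than
this reconstruction's (~50-70); its basin-hopping evidently benefited from
implementation details the extraction does not pin down. The TM-Score and
GDT searches are heuristics beyond tiny chains and report lower bounds of
their true maxima.
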