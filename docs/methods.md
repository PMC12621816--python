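# Methods

## Scope and units

The simulator represents a suspended multicellular aggregate as point cells
in free 3D space (no boundary). All lengths are measured in cell radii
(`l = 1` for every cell by default), so the contact scale of a pair is
`l_m + l_n = 2` and the connectivity scale used by the pattern metrics is
`2l = 2`. Time and force units are absorbed into the stiffness and friction
constants (`k_s = 1`, `γ = 1`); only the balance-distance factors α, the
long-range strengths β and the integration constants carry scientific
meaning.

## Mechanics

**Short-range contact force.** For a pair at separation `r` the force on
cell m is `k_s (r − r_b)` along the unit vector toward its partner, with
balance distance `r_b = α (l_m + l_n)`; it is repulsive below `r_b`
(volume exclusion), attractive above it (adhesion), and exactly zero at and
beyond the cutoff `r_c = cutoff_factor (l_m + l_n)`. The default
`cutoff_factor = 1` makes the force vanish at `r = 2l`, deliberately
coinciding with the metric connectivity threshold, so "interacting" and
"connected" mean the same thing. α is keyed by the unordered type pair;
the sweep range 0.65–0.95 spans strong to weak adhesion. Exactly coincident
cells (a measure-zero degeneracy that can only arise from extreme noise)
are separated deterministically: the lower-index cell is pushed along +x
with the balance-distance magnitude.

**Long-range force.** A phenomenological, gravitation-like channel
`|β| / r^p` (default `p = 2`) acts only beyond the contact cutoff and only
on the *responder*: the channel is keyed (signaler type → responder type)
and momentum is deliberately not conserved, as appropriate for chemotaxis
up a morphogen gradient rather than a mechanical pair interaction. The four
directed channels are independent; positive β attracts the responder toward
the signaler.

**Integration.** Overdamped Euler: `x += Δt F / γ` plus independent
Gaussian noise per axis and step. Defaults: `Δt = 0.2`, `T_total = 150`
(750 steps), noise standard deviation `0.02 = Δt · κ_M` with `κ_M = 0.1`.
The noise has zero mean: a nonzero per-axis mean would impose a constant
diagonal drift on every cell, which contradicts the isotropic setting; a
`noise_mean` switch exposes the literal mean-equals-sigma variant for
comparison. Force accumulation is a numba kernel that is exactly
antisymmetric over short-range pairs, so with long-range channels off and
noise off the center of mass is conserved to accumulation error (tested
below 1e-9 per step).

## Aggregate initialization

Cells are sampled uniformly in a ball of radius
`R = l (N / packing_fraction)^(1/3)` (default packing fraction 0.5, i.e. a
loose random packing) and relaxed with repulsion-only springs (target
spacing `1.5 l`) until no pair is closer than `1.0 l`; stray connected
components, if any, are translated toward the main cluster and the
relax/merge cycle repeats until the aggregate is a single component under
the `2l` rule. This guarantees the postconditions (minimum spacing, single
contacting aggregate) for any seed rather than relying on density
heuristics. The radial prepattern assigns the `ceil(f·N)` cells farthest
from the centroid to the outer type (default `f = 0.25`, 375 of 1500),
ties broken by cell index so runs are bit-reproducible.

## Pattern metrics

`L` and `A` follow the two-type pattern description: the largest connected
aggregate is found under strict `distance < 2l` adjacency (ties between
equal components resolved toward the one containing the smallest cell
index); `L` is the fraction of cells outside it; `A` is the distance
between the two type centroids inside the aggregate, divided by the mean
member distance to the aggregate centroid, times the two retention
fractions. The normalization `D̄` is implemented as the *mean of per-cell
distances* to the centroid: the alternative reading (norm of the summed
deviations) is identically zero, which would leave `A` undefined, and the
mean-distance reading reproduces the analytic two-cluster limits
(`A = 1/(2f(1−f))`, i.e. 2 at equal sizes and 8/3 at `f = 0.25`) used as
test oracles. Degenerate patterns (a type absent from the aggregate, or all
members coincident) score `A = 0`, i.e. unbroken symmetry.

**Shape descriptors.** Twelve grain-shape statistics are computed from the
convex hull (volume `V`, surface area `S`) and the principal semi-extents
`a ≥ b ≥ c` (half peak-to-peak ranges of the member positions projected on
the covariance eigenvectors):

| descriptor | formula |
| --- | --- |
| General Sphericity | π^(1/3) (6V)^(2/3) / S |
| Diameter Sphericity | (6V/π)^(1/3) / (2a) |
| Intercept Sphericity | (bc/a²)^(1/3) |
| Maximum Projection Sphericity | (c²/(ab))^(1/3) |
| Hayakawa Roundness | V / ((4/3)π a b c) |
| Spreading Index | (a − c)/a |
| Elongation Ratio | a/b |
| Pivotability Index | c/a |
| Wilson Flatness Index | (a + b)/(2c) |
| Hayakawa Flatness Ratio | c/b |
| Huang Shape Factor | c·a/b² |
| Corey Shape Factor | c/√(ab) |

These are standard sedimentology/grain-shape definitions; each value is
isolated behind its named key so an alternative definition can be swapped
without touching callers. Coplanar or collinear inputs set a degenerate
flag and take the flat limit where it is finite (NaN otherwise).

## Morphogenetic landscape

The sweep enumerates the Cartesian product of the adhesion grid (default
13 values, 0.650:0.025:0.950 — chosen so that 13³ triples × (1 baseline +
4 channels × 2 signs × 10 magnitudes) = 177,957 points) with at most one
active long-range channel per point. The β magnitude ladder
{0.05, 0.1, 0.2, 0.3, 0.5, 0.75, 1, 1.5, 2, 3} is this package's choice of
a roughly logarithmic range from "barely perceptible" to "dominating the
contact forces at typical aggregate scales"; it is fully configurable.
Replicate seeds derive deterministically from
`SeedSequence([base_seed, point_index, replicate])`, so rows are
reproducible bit-for-bit regardless of execution order, partial sweeps can
be resumed without recomputation drift, and points are embarrassingly
parallel. Each replicate runs initialization + simulation, then scores the
*final* state; feasibility uses the robust-symmetry-breaking definition
`A > 1` and `L < 0.1`; top-fraction statistics rank by mean `A` (ties in
enumeration order) and report the share of selected rows with attractive
`o→o` coupling plus per-α mean ± SD.

Desk-scale defaults: the behavioral/acceptance checks sweep a 5×5×5 α
subgrid spanning the full range at 300 cells and 3 seeds per point
(375 runs, a few minutes on one CPU), and the paired long-range comparison
uses 5 seeds at 300 cells. These sizes were chosen as the smallest at which
the landscape contrasts (adhesion-only `A < 1` everywhere vs. `o→o`
rescue) are reproducible across seeds; the full 13³ × 81 × 5-replicate
production sweep at 1500 cells is cluster-scale and exposed through the
same API but not exercised by the test suite.

## Genetic–mechanical network

Gene levels live in [0, 1] per cell and update synchronously (all inputs
read from the previous step) with
`ΔG = Δt (amplitude · H(u) + leak − δ G) + noise`, clipped to [0, 1], where
`H(u) = u^h / (K^h + u^h)` for positive net input and 0 otherwise.
Intracellular edges contribute `w · G_source` to the net input;
intercellular edges contribute `w · Σ_{k≠m} G_source,k · exp(−r_mk / λ)` —
an exponentially decaying morphogen-like cue (decay length λ = 2 cell radii
by default, so core cells, having more near neighbors, receive more cue
than peripheral ones). Inhibition enters as negative net input before the
Hill function. Edges may be gated per cell by a predicate on one of the
cell's own genes (above/below a threshold).

The default three-gene network realizes symmetry breaking from a fully
homogeneous start (all genes at 1):

1. **Timer (G1).** Self-activation (w = 1, h = 8, K = 0.7, amplitude
   0.142, δ = 0.15): production is tuned just below degradation over the
   whole range, so G1 decays monotonically from its high initial state and
   crosses the stage threshold 0.5 around t ≈ 30 of 150. The sharp Hill
   exponent keeps the early plateau high (mean > 0.9 over the first tenth
   of the run) while guaranteeing a decisive collapse afterwards; with
   h = 4 the same ratio of amplitude to degradation either stalls at a
   stable intermediate fixed point or decays too fast to show two stages.
2. **Diffusion-driven differentiation.** G1 emits the intercellular cue
   activating G2 (w = 0.15, λ = 2), gated to the establishment stage.
3. **Bistability.** G2 and G3 mutually inhibit (w = −1.0) while the timer
   is high; G3 is additionally driven by the timer (w = 1.3) so the outer
   branch has a source while G2 is still falling. Core cells receive
   enough cue to keep G2 high and squash G3; peripheral cells lose G2 and
   keep G3.
4. **Lockers.** Once the timer falls below 0.5 the establishment edges
   switch off and self-activation edges on G2 and G3 (w = 1, K = 0.7)
   switch on, freezing each cell's state; the basins are deep enough that
   doubling the gene noise flips no cell's class (tested).
5. **Force readout.** Cells with a high timer interact with the
   homogeneous baseline adhesion (α_hom = 0.80) and no long-range force;
   once the timer has elapsed a cell is classed outer (G2 < 0.5) or inner
   and the two-type tables apply — α = (i−i 0.72, o−o 0.79, i−o 0.88),
   values in the region the landscape analysis identifies as favorable,
   plus peripheral attraction β_o→o = 0.3. Mixed-stage pairs use the
   baseline.

All kinetic constants (amplitudes, Hill h/K per gene, leak 0.01 per
differentiation gene, degradations, gate thresholds θ_T = θ_C = 0.5, gene
noise 0.01) are this package's instantiation, tuned once so that the
qualitative behavioral repertoire — timer high-then-low, bimodal class gene
with higher inner expression, anticorrelated bistable pair, class lock-in,
asymmetry growing over the run — holds across seeds; everything is exposed
in `GRNSpec` and serializable to YAML/JSON. The G1→G3 establishment drive
is an addition to the minimal motif list: under the net-input convention a
mutual-inhibition pair with no positive input on one side cannot hold that
side high, so the timer doubles as the transient source of the outer
branch.

The default genetically regulated run uses 400 cells — large enough for a
clear core/shell cue contrast and a well-defined axis, small enough that
the full coupled run takes seconds.

## Numerical choices and degenerate inputs

* Synchronous gene updates (order-independence, determinism); per-call
  caching of the distance kernel per decay length.
* Gene matrix clipped to [0, 1] after every update; the Hill input is
  floored at 0 (no production from net-inhibitory input).
* Class ties (`gene = threshold`) resolve to the inner class; timer ties
  (`timer = threshold`) count as establishment stage.
* Strict `<` in the connectivity rule; equal-size component ties pick the
  component containing the smallest index.
* Simulation failures inside a sweep are recorded per row (`error` column,
  NaN scores) instead of aborting the run.
* All randomness flows through `numpy.random.Generator` objects seeded
  explicitly; identical seeds give bit-identical trajectories.

## What the synthetic data does and does not show

All inputs are generated in silico: near-spherical random packings with a
radial two-type prepattern (or a homogeneous gene state). The generator
reproduces the *geometry* of the modeled system — cell number (default
1500; 300 in scaled-down sweeps), 25% outer fraction, contact-scale
packing — but none of the biological complexity it abstracts away: no cell
division or death, no explicit morphogen reaction–diffusion field, no cell
polarity or run-and-tumble motility, fixed uniform cell radii, and a
literal point-cell contact law rather than deformable interfaces. Passing
tests therefore demonstrate the *design-principle* claims (differential
adhesion alone is insufficient; peripheral long-range attraction yields
robust single-axis symmetry breaking; a timer + cue + toggle + locker
network can drive it cell-autonomously) within this coarse-grained model,
not quantitative agreement with any particular gastruloid experiment.

## Known limitations

* The contact force law's fitted constants are conventions here
  (`k_s = 1`, cutoff at `2l`); only α is swept.
* Scaled-down sweeps (300 cells, 3 seeds) estimate landscape statistics
  with sampling noise; the full production landscape needs cluster-scale
  compute.
* Six of the twelve shape descriptors have multiple definitions in the
  literature; the formulas above are the package's documented choice.
* The long-range channel is an instantaneous pairwise force; it does not
  model the build-up or depletion of a real morphogen field.
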