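# Methods

This note documents the models behind each analysis stage, the defaults
and why they hold, the numerical choices, and what the synthetic-data
generator does and does not emulate.

## Synthetic-data models

**Pocket hopping (CTMC).** The gas particle is a continuous-time Markov
chain over `n` pocket centers with rate matrix `K` (ns⁻¹, off-diagonal
`k_ij ≥ 0`). The chain is simulated by exact Gillespie event times and
then *observed* on the frame grid, so the frame stride (default 50 ps, the
standard gas-position sampling interval) is purely an observation
parameter: changing it cannot change the law of the dynamics, a property
the tests check by comparing coarse and fine observations of the same
event sequence. Each frame's position is the current pocket center plus
isotropic Gaussian noise (default s.d. 1 Å) truncated at ±3 s.d., which
keeps every frame unambiguously assignable to its generating site and so
makes the truth labels exact. The analytic stationary distribution (null
space of the generator) is exposed for validation; empirical occupancies
converge to it with total-variation distance < 0.02 by 10⁵ frames.

**Escape times.** Each run contributes a single exponential residence time
with mean `m` (the true `k_off⁻¹`); draws at or beyond the cutoff `c` are
recorded as censored at `c`. Defaults mirror the water-competition
protocol: 30 runs, 50 ns cutoff, `m = 15 ns`. The cutoff is optional
(`inf` disables censoring) because gas-residence protocols do not always
impose one.

**Rotamer chain.** A hidden two-state chain (*plus* ↔ *trans*) propagates
frame by frame with the exact two-state transition probability over the
stride, using different switch rates on frames where the gas occupies a
coupled region — this emulates occupancy-conditioned rotamer statistics
without restraint machinery. Emitted χ1 is the mode angle (+60° or 180°)
plus von Mises noise; the default concentration κ = 33 gives a mode s.d.
of ≈10°, matching tight rotamer lobes. The *minus* mode is carried in the
model but not populated by the two-state dynamics, reflecting how rarely
it occurs for serines at tight turns.

**Structure fixtures.** `make_fixture_complex(phi, plane_offset)` builds a
planar six-membered ring with a diatomic placed so the ring–gas dihedral
Φ(C4–C2–O2–O1) equals `phi` exactly (natural-extension-reference-frame
placement) and the gas atom sits exactly `plane_offset` Å from the ring
plane. Construction is exact to 10⁻⁶ in both quantities and is
self-checked at build time. `simulate_structure_jitter` adds per-atom
Gaussian displacement and optional global rototranslation for
superposition/RMSF validation; the jitter is drawn before the global
motion so the same seed yields the same internal noise with or without it.

All generators use NumPy's PCG64 (`numpy.random.default_rng`), recorded in
trajectory provenance; identical seeds give bit-identical output.

## Occupancy mapping and free energies

Sampled positions are binned on a cubic voxel grid (default spacing
0.5 Å — fine enough to resolve pocket volumes of ~15 Å³). Voxel
probability is counts/total. Pockets are 26-connected components of
voxels above an iso-level; because no universal threshold exists for
cluster extraction, the iso-level is a required user parameter (the
pipeline expresses it as a fraction of the peak voxel probability, default
0.15). Clusters report probability-weighted centers, volumes
(voxels × spacing³) and masses, sorted by mass and labelled with Roman
numerals, so the output is independent of voxel iteration order. Note
that an iso-surface volume on a lattice is the count of voxel centers
clearing the threshold; for small pockets (radius ~3 voxels) this
discretization alone shifts volumes by one-to-two voxel shells.

Free energy is Boltzmann inversion `G = −k_BT ln(p/p_max)` with
`k_B = 1.9872×10⁻³ kcal mol⁻¹ K⁻¹`; the reference is the most occupied
voxel (minimum 0), since only relative barriers are meaningful here.
Zero-count voxels are masked, never imputed: finite sampling must not
silently fabricate infinite barriers.

Biased (metadynamics-style) sampling is consumed as a per-frame bias
energy series; samples are weighted by `exp(+V/k_BT)` (max-shifted before
exponentiation for overflow safety) and renormalized. Zero or constant
bias reduces exactly to plain accumulation.

The entry barrier between two pockets is the *bottleneck* (minimax) free
energy along the best 26-connected path between the pockets'
lowest-free-energy voxels, minus the free energy at the start — the saddle
estimate a voxel grid supports, implemented by sorted-threshold union-find
(voxels activated in increasing free-energy order until the endpoints
join). It is verified against two independent oracles: a brute-force
threshold sweep with flood fill, and the minimax path through the
minimum spanning tree of the voxel graph. The Boltzmann probability ratio
of two barriers, `exp(−Δ barrier/k_BT)`, is exposed separately; note that
for barriers of 4.1 vs 6.5 kcal/mol this factor is ≈56 at 300 K, not ~5 —
reported "few-fold" preferences in the literature typically follow from a
different (kinetic, temperature-broadened or error-weighted) definition,
so the package implements only the plain Boltzmann ratio and leaves any
other convention to the caller.

## Residence statistics

Event detection uses hysteresis: an event opens when the particle comes
within the inner radius and closes only when it passes beyond the outer
radius (default inner + 1 Å). This suppresses single-frame boundary
flicker without biasing long dwells; events shorter than
`min_frames_inside` × stride (default 2 frames ≈ 100 ps at 50 ps stride)
are discarded as sampling noise. An event still open at the last frame is
censored — the observation ended, not the dwell.

Summaries follow the reporting convention of residence-time panels: mean
and s.e.m. over *uncensored* events only; censoring enters through the
escape percentage (100 × escapes/runs) and the rate estimate. Percentages
are kept exact and rounded only at presentation (29/30 = 96.67% prints as
96.7; a printed 96.6 is consistent at the 0.1-point level, so tests accept
either).

Two `k_off⁻¹` estimators are provided and labelled. The default is the
censored-exponential MLE, `Σ(all durations, censored included)/n_escapes`,
with standard error `k_off⁻¹/√n_escapes`; it equals the sample mean when
nothing is censored, is invariant to event order, and with zero escapes
only the lower bound (total observed time) is reported. The alternative
fits `1 − exp(−t/τ)` to the empirical cumulative escape fraction by least
squares — the "cumulative event curve follows Poisson statistics"
procedure; whether that historical procedure weighted censored runs is not
documented, which is exactly why both estimators are exposed. They
converge to each other at large `n` (checked within 2% at n = 5000).

The truncated mean `E[T | T < c] = m − c e^{−c/m}/(1 − e^{−c/m})`
(computed with `expm1` for stability at `c ≪ m`, where it tends to `c/2`)
bridges the two reporting styles: with `m = 15 ns` and `c = 50 ns` the
expected mean over escapes is 13.15 ns — an estimate near 13 ± 2 ns over
30 runs is fully consistent with a fitted `k_off⁻¹` of 15 ns.

## Rotamer and fluctuation analysis

χ1 is the signed N–CA–CB–OG torsion in the IUPAC convention, range
(−180°, 180°], computed by the numerically stable atan2 form and verified
against an independently coded projection implementation to 10⁻⁹° (and
against MDAnalysis during development). Degenerate (colinear) frames are
flagged per frame rather than aborting the series. Classification
partitions the circle into three 120° sectors centered on +60°/180°/−60°,
half-open toward increasing angle (so exactly 120° is *trans*, −120° is
*minus*); every finite angle maps to exactly one state and the map is
invariant under ±360°. A fixed-sector rule is used rather than a
rotamer-library lookup because the three serine modes are the entire
state space of interest.

Histograms are per-replica normalized to unit mass, then averaged, with
the population s.d. (ddof = 0) across the replicas actually run as the
per-bin spread; both per-bin mass and density (mass per degree) are
reported since "normalized distribution" is ambiguous between the two.
Default bin width 5°, resolving 10°-wide lobes without noise.

RMSF uses iterative mean-structure superposition: frames are Kabsch-fitted
to the selection mean, the mean recomputed, and the loop repeated until
the reference shifts < 10⁻⁶ Å (≤10 iterations) — the self-consistent
"average structure". RMSF is the per-atom r.m.s. deviation from that mean;
it is zero under pure global rototranslation and invariant (up to the
noise realization) to overlaying one.

## Spin-crossing kinetics

For a spin-forbidden step, the hopping probability `p` per crossing
attempt acts as a transmission coefficient on the rate; an equivalent
picture raises the crossing-point barrier by `−k_BT ln p`, which is the
documented interpretation implemented here (exactly invertible, strictly
decreasing in `p`, linear in `T`). The default temperature is 298.15 K;
at `p = 0.005` this gives 3.14 kcal/mol (3.1 to one decimal), whereas
300 K would give 3.16 — the one-decimal output fixes the convention.
The effective crossing barrier `E_MECP − k_BT ln p` is compared with the
competing adiabatic barrier; equality within 10⁻⁹ kcal/mol is flagged as
a tie, never silently broken.

`lz_hop_probability` is a secondary utility: double-passage weak-coupling
Landau–Zener, `P = 1 − (1 − p₁)²` with
`p₁ = 1 − exp(−2π H₁₂²/(ħ v |ΔF|))`, using the 1-D thermal mean crossing
speed `v = √(2k_BT/(πμ))`. All conversions (cm⁻¹ → J via `hcν̃`,
kcal mol⁻¹ Å⁻¹ → J m⁻¹ per molecule, amu → kg) use CODATA constants. It is
quadratic in the coupling at weak coupling and saturates at 1. Because
published crossing-seam parameters (slopes, reduced mass) are rarely
available, a literature hopping probability is consumed as an input to the
barrier comparison, never re-derived from a SOC value.

## Pipeline and problem sizes

The `demo` pipeline generates a 2 μs-equivalent hopping trajectory at
50 ps stride (40 001 frames, three pockets 5 Å apart, noise s.d. 1 Å — close
enough that the inter-pocket channel is sampled and the barrier is
finite), 30 escape runs at `m = 15 ns`/`c = 50 ns`, two rotamer replicas
coupled to the pocket-I occupancy, and a 200-frame jittered-structure
trajectory for RMSF. These sizes keep a full end-to-end run around a
second while leaving every estimator in its working regime. Per-stage
seeds are spawned from the single config seed (`SeedSequence.spawn`), so
stages are independently reproducible and the whole report is
byte-identical across reruns with the same seed.

## What the generator does not emulate

No force-field physics, solvent, protein topology or periodic boundaries;
pocket geometry is isotropic and hopping is memoryless, so non-Markovian
recrossing, anisotropic channels and conformational gating beyond the
binary rotamer coupling are absent. Escape times are exactly exponential —
real dwell distributions can be heavy-tailed. Passing tests therefore
demonstrate that the *estimators and descriptors* are correct and
internally consistent at realistic sample sizes, not that any particular
protein behaves this way; conclusions about a real system still require
real trajectories as input.

## Known limitations

* The minimax barrier is a lower bound on the true saddle when sampling
  leaves the transition region unvisited (masked voxels can force detours)
  and inherits grid-discretization error of about one voxel's
  free-energy step.
* The cumulative-distribution fit treats the empirical escape fractions
  as homoscedastic; for small `n` its variance is larger than the MLE's.
* `detect_events` assumes one tracked particle; indistinguishable-particle
  bookkeeping (identity swaps at a site) is out of scope.
* DX export writes voxel-center grid positions; tools that interpret the
  origin as a voxel corner will see a half-spacing offset.
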