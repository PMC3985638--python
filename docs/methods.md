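# Methods

## Model

Each chromosome copy is a linear bead-spring chain, one bead per 1 Mb of
sequence ("spherical chromatin domain" coarse-graining). Reduced units
throughout: monomer diameter σ = 1 (≈0.5 µm), k_B·T_eq = 1, drag ζ = 1, so
time is measured in τ = ζσ²/k_BT_eq and the nuclear radius R₀ = 10σ
corresponds to a 10 µm nucleus. The default karyotype is the diploid female
human genome discretized to 3049 haploid Mb (6098 monomers): the four
chromosome lengths the model is usually read out on are fixed at their
published sizes (chr12 134, chr18 78, chr19 60, chr20 63 Mb), the rest are
GRCh37 lengths rounded to the Mb, with chr1 absorbing the rounding
remainder.

Deterministic interactions:

| term | form | default | rationale |
|---|---|---|---|
| bond | (k/2)(d−r₀)² | k = 5, r₀ = 1σ | largest k that keeps explicit Euler stable with 10× loop springs (see below) |
| loop spring | (10k/2)(d−r₀)² | multiplier 10 | loops are 10× stiffer than backbone bonds |
| pair | V₀e^(−d²/2σ²), shifted, cut at r_cut | V₀ = 2, r_cut = 3σ | Gaussian core of interpenetrating polymer blobs; V₀ of order k_BT_eq |
| wall | (k_wall/2)d_out² outside, 0 inside | k_wall = 100 | d_out is Euclidean distance to the surface, so ellipsoid equipotentials follow surface distance; k_wall·dt = 1 is critically damped |
| NE attraction | −ε·e^(−s²/2λ²) on active monomers | ε = 80, λ = 1σ | see calibration below |

The pair energy is shifted by V₀e^(−r_cut²/2σ²) (≈1.1% of V₀) so the
truncation is continuous; forces are unaffected. There is no hard core, no
bending stiffness and no chain-uncrossability: interpenetration is only
penalized by the soft Gaussian core, consistent with the abundance of
topology-relaxing enzymes in nuclei.

Dynamics: explicit Euler discretization of overdamped Langevin motion with
per-monomer noise amplitude √(2k_BTᵢdt/ζ) per Cartesian component, dt =
0.01τ. Effective temperatures: `inhomogeneous` mode assigns T_a (default
20 T_eq, the ATP-hydrolysis energy scale) to the top `active_fraction`
(default 5%) of monomers by gene content — exactly
round-half-away-from-zero(f·N) monomers, ties broken by gene content then
id, so the assignment is deterministic; `homogeneous` heats every monomer
to T_a; `equilibrium` is the passive control. The cutoff between active and
inactive is therefore the (1−f) quantile of the gene-content distribution,
taken globally over all monomers. ζ is the same for all monomers; the
euchromatin/heterochromatin drag difference is neglected (weak dependence
of Stokes drag on effective monomer size).

## Synthetic gene-density tracks

Real per-Mb gene counts are heavy-tailed and non-negative; the generator
draws per-bin contents from a lognormal (shape σ_log = 1) and rescales each
chromosome multiplicatively so constrained chromosomes hit their published
mean densities *exactly* (chr19 62.03, chr18 18.64, chr12 30.92, chr20
29.71 genes/Mb; unconstrained chromosomes default to 20 genes/Mb).
Homologous copies carry identical per-bin contents. What the fixture does
**not** emulate: the true *positional* arrangement of gene-rich bins along
each chromosome (real gene deserts and ridges are long-range correlated;
synthetic bins are i.i.d.), isochore structure, or any cell-type-specific
transcription. Consequently, tests that pass on synthetic tracks validate
the *mechanism* (segregation by noise amplitude, loop-driven
territoriality) and the published per-chromosome density contrasts, not
intra-chromosomal positioning detail.

## Numerical stability and the drift guard

For explicit Euler, a harmonic stiffness k is stable only while
k_eff·dt/ζ < 2. The stiffest internal mode of a bonded chain has
k_eff = 4k_bond, and a loop anchor can additionally carry one or more 10×
springs, so with dt = 0.01 pinned by the model definition the backbone
constant is capped near k_bond ≈ 5 (4·5·0.01 = 0.2; a triple-anchored loop
monomer reaches ~1.6). The wall and loop springs are chosen *critically
damped or below* (k_wall·dt = 1, 2k_loop·dt = 1): their single-step drift
can be large after a deep noise excursion but is self-limiting — it never
overshoots the target, hence never amplifies.

The integrator aborts when the deterministic drift (dt·F/ζ) of any monomer
**inside** the confinement exceeds `max_drift` monomer diameters in one
step (default 1σ). Two deliberate exemptions follow from the noise scale of
the model (at T_a = 20 the per-step noise displacement is ≈1σ on average):
monomers outside the boundary are exempt, because the wall's pull-back
drift is benign by the argument above; and runs with permanent loops should
set `max_drift ≈ 10`, because a critically damped loop spring between two
hot monomers has a heavy-tailed but stationary drift distribution (measured
p90 ≈ 1.5σ) that a 1σ guard misreads as instability within ~10⁴ steps. A
genuinely unstable time step diverges exponentially and crosses any such
threshold within a few steps, so the guard retains its diagnostic value.
`Schedule.n_relax` steepest-descent iterations (displacement capped at
0.2σ) remove the large initial stretch of freshly drawn loops before
stochastic dynamics start.

## NE attraction calibration

The selective envelope attraction must hold active monomers at the
periphery against their own noise: a quasi-Boltzmann estimate of the
surface enhancement is e^(ε/T_a), so ε must exceed ~2·T_a to matter, while
curvature stability requires ε·dt/λ² < 2. Within that window the defaults
ε = 80 (= 4 T_a), λ = 1σ were calibrated by a pilot switch-on run: ε = 40
and 60 produced marginal or non-persistent inversion of the radial
ordering, ε = 80 a stable one. Both are configuration keys, not fitted
quantities, and should be re-benchmarked for other T_a.

## Accelerated force evaluation

Pairwise Gaussian-core forces use a *sorted-window list*: monomers are kept
sorted by z (the permutation is maintained by insertion sort, amortized
O(N) between steps), and each monomer scans only the contiguous run of
partners within r_cut in z, in two passes (a vectorizable distance pass,
then the force pass over hits). At the model's density a 3-D cell grid
degenerates to near-all-pairs (r_cut = 3σ vs R₀ ≈ 5σ in the scaled system)
and measured slower. The Gaussian is evaluated from a 4096-point
linearly-interpolated table of exp(−d²/2σ²) (absolute error < 2×10⁻⁷),
identical in the accelerated and the direct O(N²) reference paths, which
therefore agree to summation round-off (~10⁻¹⁴); the scalar reference
functions in `potentials` keep the analytic exponential. Each pair is
visited exactly once, so action–reaction holds exactly and the total
internal force is a zero vector to round-off.

Ellipsoidal confinement needs the Euclidean (not algebraic) surface
distance so that equidistant points feel equal potentials. The nearest
point is found by a safeguarded Newton iteration on the Lagrange parameter
t of q_i = a_i²p_i/(a_i²+t) (unique root in (−min a_i², ∞)), converged to
≤10⁻¹⁰, with explicit handling of exact-zero coordinates (the off-plane
branch at t = −a_k² is compared against the in-plane critical point) and of
the center. Volume-matched ellipsoids of revolution use a = b = R₀·γ^(−1/3),
c = γa for aspect ratio γ, preserving abc = R₀³ exactly.

## Analysis conventions

- **S(R)** is a probability density over the (effective) radial coordinate,
  normalized so ∫S dR = 1 (the source curves' normalization is not stated;
  a density is the convention that makes chromosomes of different length
  comparable). Radii beyond R₀ (transient wall penetration) are excluded
  before normalization. Standard errors come from 10 frame blocks.
- **Effective radius** in an ellipsoid: r_eff = R₀(1 + s/d_max) with s the
  signed surface distance and d_max the center depth (min semi-axis), so
  points equidistant from the envelope average together; for a sphere this
  is identically |r|.
- **Activity profile**: per-shell configurational mean of T_eff, optionally
  rescaled to (0:1) with T_eq ↦ 0; empty shells are NaN, never zero.
- **Territory index N_c**: self excluded (keeps the small-radius limit at
  0); membership is strict (< R_sphere); homologous copies count as
  *different* chains by default (territories are per-homolog in FISH
  images) with a `per_homolog=False` switch to pool them. The accelerated
  path uses a k-d tree and is validated against the exhaustive double loop.
- Default 50 radial bins over [0, R₀].

## Scaled test system

Desk-scale validation uses 8 chains × 100 monomers in a sphere of
R₀ = 10·(800/6098)^{1/3} ≈ 5.08σ (the full system's volume fraction), 10%
active at T_a = 20, with one gene-rich (62 genes/Mb) and one gene-poor
(18.6 genes/Mb) chain mirroring the chr19/chr18 contrast. Segregation runs
are 2×10⁵ steps × 5 seeds; NE switch-on continuations, the equilibrium
control and the high-loop territory run use (2.5–5)×10⁴ steps, which pilot
traces show is several times the relaxation time of their observables at
this size. These sizes validate directions and mechanisms; quantitative
S(R) shapes at full scale require the 6098-monomer system and ≥10⁷ steps.

## Known limitations

- The steady state is defined by the discrete update rule, not a target
  ensemble: at stiffness k the discrete stationary variance exceeds the
  continuum k_BT/k by a factor 1/(1 − k·dt/2) (≈2.5% for the tethered-
  monomer check at k·dt = 0.05). No metric correction is applied.
- No hydrodynamic interactions, no inertia, no chain-crossing constraints,
  no cell-type-specific activity.
- Loop anchors are drawn uniformly along the chain (no genomic-distance
  weighting); sub-Mb loops are considered absorbed into the pair potential.
- Trajectories are text (extended-XYZ + CSV sidecars) only; no binary
  container is provided.
- The τ↔seconds conversion depends on the assumed nucleoplasmic viscosity
  and is not reported by the code.
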