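# actseg — activity-based segregation of interphase chromosomes

`actseg` simulates the radial positioning of chromosomes inside the
interphase nucleus with a coarse-grained *active* polymer model, for
researchers in nuclear organization and chromatin biophysics who want a
minimal, reproducible model of why gene-rich chromosomes sit toward the
nuclear interior and gene-poor ones toward the periphery — and why
chromosomes form territories.

## The model

The diploid female human genome (22 autosomal pairs + 2 X; 6098 monomers)
is coarse-grained at 1 Mb per monomer into bead-spring chains confined to a
sphere (or volume-matched ellipsoid) of radius R₀ = 10σ. Monomers interact
through

- harmonic bonds, U = (k/2)(d − r₀)²,
- a soft Gaussian-core repulsion, U = V₀ exp(−d²/2σ²),
- a harmonic confining wall, U = (k_wall/2)·d_out², acting on the Euclidean
  distance outside the bounding surface,
- optional permanent random loops (springs 10× the backbone constant,
  drawn once between random intra-chromosomal pairs),
- an optional short-ranged nuclear-envelope (NE) attraction acting on
  active monomers only, with its minimum on the envelope.

Positions evolve by an Euler-discretized overdamped Langevin equation,

    rᵢ(t+dt) = rᵢ(t) + (dt/ζ)·Fᵢ + √(2 k_B Tᵢ dt/ζ)·ηᵢ ,

with independent unit-normal ηᵢ. The single non-equilibrium ingredient is
the per-monomer *effective temperature* Tᵢ: the top 5% of monomers by gene
content (a proxy for ATP-consuming remodeling/transcription activity) are
"active" at T_a = 20 T_eq; the rest stay at the physiological temperature
T_eq. That inhomogeneous noise alone segregates gene-dense chromatin toward
the nuclear center; adding random loops compactifies chromosomes and yields
territories; making the NE selectively attractive to active monomers
inverts the radial order, as in nuclei with inverted architecture.

Because the original per-Mb gene counts come from a proprietary catalogue,
the package ships a constrained synthetic-track generator whose
per-chromosome means reproduce the published densities exactly
(chr19: 62.03 genes/Mb, chr18: 18.64, chr12: 30.92, chr20: 29.71).

Analysis observables: the normalized radial distribution S(R) per
chromosome (∝ R² for a uniform melt), shell-averaged activity, total and
gene-density profiles, an effective radial coordinate for ellipsoids, and
the territory index N_c(R_sphere) (+1 per same-chain neighbor, −1 per
other-chain neighbor within R_sphere, averaged over monomers).

## Worked example

A scaled melt (8 chains × 100 monomers at the full system's volume
fraction, 10% active at T_a = 20, chain `c0` gene-rich and `c1` gene-poor):

```python
import numpy as np
from actseg import *

karyotype = [ChromosomeSpec(f"c{i}", 100, copies=1) for i in range(8)]
track = synthesize_gene_track(
    karyotype, density_constraints={"c0": 62.0, "c1": 18.6},
    default_mean=25.0, seed=2024,
)
table = assign_activity(build_monomer_table(karyotype, track),
                        "inhomogeneous", active_fraction=0.10, T_a=20.0)
geometry = Geometry.sphere(10.0 * (len(table) / 6098) ** (1 / 3))
schedule = Schedule(n_steps=50_000, n_burnin=30_000, sample_every=5_000, seed=1)
result = simulate(table, None, geometry, ForceField(), schedule, init_seed=1)

radii = np.concatenate([np.linalg.norm(f, axis=1) for f in result.frames])
act = np.tile(table.is_active, len(result.frames))
print(f"mean radius (active):   {radii[act].mean():.2f}")
print(f"mean radius (inactive): {radii[~act].mean():.2f}")
```

prints (≈1 minute on one core):

```
mean radius (active):   3.75
mean radius (inactive): 4.47
```

— the active (gene-dense) monomers sit ~16% deeper in the R₀ = 5.08σ
nucleus than the inactive ones: activity-based segregation. The radial
distribution of the gene-rich chain, `radial_S(result.frames, table,
chromosome="c0", geometry=geometry)`, peaks at R ≈ 3.3σ, well inside the
quadratic-rise profile a uniform chain would show.

The same workflow is available from the shell:

```bash
actseg synthesize-genome --out track.bed --seed 1
actseg simulate --config run.yaml --out out/
actseg analyze --traj out/trajectory.xyz --what S,activity --chroms chr18,chr19 --out profiles
actseg territory --traj out/trajectory.xyz --out nc.csv
actseg ne-switch --config run.yaml --times 0,100000,1000000 --out switch/
```

Every output directory contains the fully-defaulted config echo, the seeds
and the trajectory (extended-XYZ + CSV sidecars), so a run is reproducible
bit-for-bit from its own outputs.

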