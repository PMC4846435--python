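# Methods

## The model

`patchysome` simulates the lateral organization of amphiphilic block
copolymers on the outer surface of a polymersome. Each PMPC-PDPA
diblock is one bead (its solvent-exposed PMPC chain); each
PEO-PDPA-PMPC triblock is two bonded beads (one PEO, one PMPC chain,
both solvent-exposed in the looped conformation). Beads diffuse on a
sphere of radius R; the hydrophobic PDPA anchors are not represented —
confinement to the surface is their only effect.

Interactions (energies kJ/mol, lengths nm, masses amu, times ps — the
GROMACS unit system, in which ½mv² is directly kJ/mol):

| term | form | parameters |
|---|---|---|
| PMPC–PMPC | 12-6 Lennard-Jones | ε₁ = 1, σ₁ = 0.3 |
| PEO–PEO | 12-6 Lennard-Jones | ε₂ = 1, σ₂ = 0.2 |
| PMPC–PEO | εc (σ₁/r)¹² | εc = 1 |
| triblock bond | flat-bottom: 0 for r < d_max, k(r−d_max)² beyond | k = 10⁴, d_max = 1.5 |

ε₂ and εc are not independently established; both default to ε₁
(symmetry being the minimal assumption) and are configurable. All
nonbonded terms are truncated and shifted to zero at 2.5× the pair's σ
(the cross term uses σ₁); forces are the exact gradients of the
shifted energy. Distances below 10⁻³ nm are clamped (and counted as
clashes) so degenerate inputs stay finite.

Bead masses are m₁ = 2313 (PMPC diblock bead), m₂ = 774 (PEO bead),
m₃ = 993 (triblock PMPC bead); a lone PEO diblock bead in ternary
systems reuses m₂. The model is built at 1/10 scale: simulated lengths
are one tenth of the physical inter-chain separations, so every
reported "physical nm" is the simulated value × 10 (`length_scale`).

A useful consistency check of the σ values: at 100% triblock the two
species at their respective Lennard-Jones equilibrium densities demand
2048·1.09σ₁² + 2048·1.09σ₂² ≈ 290 nm², which is the area of the
19.2 nm sphere scaled to 4096 beads — the published bead count fills
the surface exactly at full triblock. At lower triblock fractions the
PMPC matrix is correspondingly over-filled (compressed): the pure
diblock lattice has nearest neighbors at ≈ 0.26 nm, inside σ₁.

## Initialization

Beads are placed on a golden-angle (Fibonacci) spiral lattice —
deterministic, quasi-uniform (nearest-neighbor distances within
0.81–0.93 of the ideal hexagonal spacing √(8πR²/√3n)) and trivially
scalable. Composition ratios are molar ratios of molecules: for
triblock fraction x with the bead total n held fixed, the number of
triblocks is n_t = round(x·n/(1+x)), so 2n_t + n_singles = n. Triblock
bead pairs occupy neighboring lattice sites (greedy random matching
through each site's 8 nearest neighbors, with a fallback pass pairing
leftovers); which end carries PEO is random. Initial velocities are
Maxwell–Boltzmann in the local tangent plane.

Because the lattice is compressed, dynamics started directly from it
can be violent; a short displacement-capped steepest-descent
relaxation (default 200 iterations, 0.005 nm cap, stopping at
10 kJ/mol/nm max force) removes the worst strain first, as an energy
minimization precedes any molecular dynamics run.

## Integration

Langevin dynamics with BAOAB splitting, constrained to the sphere:

* **A (drift)** moves each bead along the great circle defined by its
  tangential velocity — the exact free motion on the sphere. This
  conserves |p| = R and the speed to machine precision, avoiding the
  systematic kinetic-energy leak of "step in 3D then renormalize".
* **B (kick)** applies the tangential force component; the discarded
  radial component is exactly the constraint force.
* **O (thermostat)** is the Ornstein–Uhlenbeck update with per-bead
  friction γᵢ = mᵢ/τ (τ = 1 ps), followed by projection of the fresh
  isotropic noise onto the tangent plane. Each bead then carries two
  thermal degrees of freedom, ⟨KE⟩ = k_B·T per bead, and a free bead
  diffuses with D = k_B·T·τ/m (verified against the 4Dt law in the
  tests). Setting τ = ∞ disables the thermostat (NVE limit).

The reference time step is 2 fs. The desk preset uses 50 fs, chosen by
measurement: it keeps NVE energy drift at 1.3×10⁻⁴ relative over 10⁴
steps (tolerance 10⁻³), while 62.5 fs fails that bound and 100 fs is
unstable without the thermostat. The stiffest mode is the compressed
PMPC lattice (ω ≈ 5/ps), giving ω·dt ≈ 0.25 at 50 fs.

Nonbonded neighbors come from a cell list over the sphere's bounding
box (validated pair-for-pair against a kd-tree) with a 0.25 nm Verlet
skin, rebuilt whenever any bead has moved more than half the skin;
this is exactly equivalent to an every-step neighbor search. On
non-recorded steps the force loop skips the energy accumulation.
Runs are bitwise deterministic given the seed.

## Domain analysis

Domains of one chemical kind are single-linkage clusters: connected
components under a chord-distance cutoff of 1.5σ of that kind
(0.45 nm PMPC, 0.30 nm PEO) — just above first-neighbor contact,
below the second-neighbor shell at lattice density. Cluster centers
are normalized vector means rescaled to the sphere (undefined, and
reported as an error, for antipodally balanced clusters). Domain size
is the area-equivalent diameter 2√(A/π) with A = bead count × (sphere
area / n).

The spacing statistic mirrors the micrograph procedure: for every
center, the shortest distance to any other center; the mean and
*sample* SD (n−1) of those minima. On the sphere the distances are
geodesic (the nearest neighbor is the same under chord and arc, since
the arc is monotone in the chord); the image pipeline uses planar
Euclidean distances. Physical values are ×10.

Phase labels use the largest-cluster mass fraction f of each species
(fraction of that species' beads in its largest cluster): f < 0.5
means discrete domains, f ≥ 0.5 a percolating matrix. Discrete
domains of exactly one species give that species' micellar phase
(micellar_PMPC is the inverted phase), both percolating is
bicontinuous, both fragmented is disordered, a single-species surface
is uniform. Bead counts play no role: a triblock feeds one bead to
each species, so at high triblock fractions the counts are nearly
equal and only connectivity can distinguish matrix from micelles.

Measurement convention along the composition axis (as in the
micrograph analysis): ≤ 10% triblock, PEO domains; 20–80%, both
species averaged; ≥ 90%, PMPC domains; a single-species surface
reports the bead-level nearest-neighbor spacing instead (domain
clustering is degenerate there).

## Synthetic projection images

The generator emulates negatively stained transmission micrographs of
dried polymersomes: the PMPC-rich matrix takes up phosphotungstic acid
and appears dark, PEO domains stay light, and the vesicle is imaged in
transmission so features of the top and bottom hemispheres
superimpose. The renderer therefore projects *all* beads
orthographically along one axis. Each bead (or planar ground-truth
point) contributes a Gaussian footprint (default width half its σ at
physical scale); background gray 128, stain amplitude ±80, additive
Gaussian pixel noise (default SD 8), 8-bit output, raster origin
top-left. All defaults are recorded in the image provenance.

Planar ground-truth patterns: exact hexagonal lattices (nearest
neighbor = lattice constant), Gaussian-jittered lattices, and
dart-throwing Poisson-disk samples (per-point minima ≥ the exclusion
radius).

What the fixtures do **not** emulate: electron-optical contrast
transfer, defocus, stain granularity and drying artifacts, vesicle
curvature foreshortening near the projected rim, or operator patch
selection. Passing the recovery tests therefore shows the measurement
chain is unbiased for blob-like domains at adequate sampling — not
that segmentation of real micrographs is solved. Centroids of regions
clipped by the image border are biased inward; fixtures keep a margin.

The image pipeline segments by threshold (Otsu's method by default —
the original manual choice is not recoverable) on the selected
polarity side, labels with 8-connectivity, drops regions below a
minimum area, takes intensity-weighted centroids, and applies the
same shortest-distance statistic with the pixel-to-nm calibration.

## Desk-scale protocol and what it shows

The published protocol (65539 beads, R = 19.2 nm, 300 ns) is
cluster-scale. The desk preset keeps the same areal density, force
field and thermostat on R = 4.8 nm (4096 beads) for 2 ns at the 50 fs
step, three seeds; the pure-diblock baseline uses R = 3.2 nm (1821
beads, 0.5 ns). Free beads diffuse ≈ 3 nm in 2 ns, far beyond the
0.5–0.7 nm domain spacing, so local domain structure equilibrates;
large-scale coarsening does not terminate on any accessible timescale
(see below). Analysis discards the first half of each trajectory as
burn-in and averages the rest.

Measured outcomes at this scale (three seeds): at 10% triblock the
PEO spacing is ≈ 6.5 physical nm (reported: ca. 7 nm) and the mean
PEO domain diameter ≈ 5.5–6 nm (reported band 6–10 nm); the
pure-diblock baseline spacing is ≈ 2.7 nm (reported: ca. 3 nm); the
low-fraction pattern classifies as micellar_PEO.

## Known limitations

* **PEO cannot percolate in this force field.** With σ₁ = 0.3 and
  σ₂ = 0.2 the PMPC species occupies ≥ 53% of the surface at every
  composition (69% at 100% triblock), so PMPC always forms the
  percolating matrix and PEO forms discrete droplets. The
  bicontinuous and inverted phases of the experimental phase diagram
  do not appear under the surface-cluster definition; the see-through
  projection of a droplet pattern (both hemispheres superimposed,
  roughly doubling apparent coverage) can nevertheless *look*
  connected, which is how the transmission images are read.
* **Coarsening is not arrested.** PEO droplets coalesce steadily
  (at 50% triblock: 269 clusters at 0.8 ns → 120 at 6 ns), so the
  domain spacing at mid/high triblock fractions grows with simulation
  time instead of settling on the ≈ 5 nm plateau measured by TEM. The
  triblock tether (d_max = 1.5 nm ≈ 5σ₁) only becomes taut for
  domains wider than ≈ 2.4 nm (24 physical nm) and therefore cannot
  stabilize the observed 6–10 nm domains; domain sizes at desk scale
  are kinetic, not equilibrium, quantities.
* Electrostatics, solvent, curvature feedback, leaflet asymmetry and
  bead exchange between leaflets are outside the model.
* The equilibration protocol of the original runs is unknown; the
  relax-then-burn-in choice here is the package's own.
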