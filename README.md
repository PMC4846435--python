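# patchysome

Coarse-grained Langevin dynamics of amphiphilic block copolymers
confined to a polymersome surface, for studying membrane-confined
self-assembly: the formation of 2D micelles, their spacing, and the
composition-driven evolution of surface patterns in
PMPC-PDPA / PEO-PDPA-PMPC (and ternary PEO-PDPA) copolymer vesicles.
It is aimed at soft-matter and structural-bioinformatics researchers
who want a desk-scale, fully scripted counterpart to stained
transmission-EM measurements of patchy polymersomes.

## Model

Each PMPC-PDPA diblock is a single bead (its solvent-exposed PMPC
chain); each PEO-PDPA-PMPC triblock is two bonded beads. Beads move on
a sphere of radius *R* under Langevin dynamics (BAOAB, friction
γᵢ = mᵢ/τ, τ = 1 ps, T = 300 K) with

- same-kind pairs: 12-6 Lennard-Jones, U(r) = 4ε((σ/r)¹² − (σ/r)⁶),
  with (ε₁, σ₁) = (1 kJ/mol, 0.3 nm) for PMPC and
  (ε₂, σ₂) = (1 kJ/mol, 0.2 nm) for PEO,
- unlike pairs: soft repulsion U(r) = εc·(σ₁/r)¹²,
- triblock bonds: flat-bottom restraint, 0 below d_max = 1.5 nm and
  k(r − d_max)² with k = 10⁴ kJ/mol/nm² beyond.

The model is built at 1/10 length/mass scale; simulated distances × 10
compare with micrograph nanometers. Domains are single-linkage bead
clusters; the spacing statistic is the per-domain-center shortest
distance to any other center, reported as mean ± SD — the same
procedure the image pipeline applies to (synthetic) stained projection
images after segmentation, centroid extraction and pixel-to-nm
conversion.

## Worked example

```python
from patchysome.pipeline import run_composition, PRESETS
from patchysome.sphere_init import CompositionSpec

row = run_composition(
    CompositionSpec(frac_triblock=0.10,
                    n_beads=PRESETS["desk_reduced"].n_beads),
    seed=1, preset="desk_reduced")
print(row["phase"], row["spacing_peo_nm"], row["domain_diam_peo_nm"])
```

prints (seed 1):

```
micellar_PEO 6.762 5.494
```

A 4096-bead sphere (R = 4.8 nm, the published areal density) with 10%
triblock, relaxed and run for 2 ns, self-assembles into discrete PEO
2D micelles in the PMPC matrix (`micellar_PEO`); their centers sit
6.8 physical nm apart (measured: ca. 7 nm) with a mean area-equivalent
domain diameter of 5.5 nm (measured band 6–10 nm). The pure-diblock
baseline gives ≈ 2.7 nm bead spacing (measured: ca. 3 nm).

The same machinery is scriptable from the shell:

```
patchysome sweep --fractions 0.05,0.1,0.5 --preset desk_reduced --out out/
patchysome image-spacing --in image.png --px-size 0.5 --polarity light
patchysome geometry
```

`patchysome geometry` prints the closed-form 2D packing relations:
the PEO-cored micelle diameter 8·r_PDPA = 7.0 nm, the inverted
(PMPC-cored) micelle diameter 2·r_PMPC = 5.5 nm, and the hydrophilic
area mismatch 0.6.

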