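# Methods

## The hydration field

All four membrane geometries are built from one rational sigmoid
`σ(u) = uⁿ/(1+uⁿ)` applied to a geometry-specific depth coordinate
normalised by the hydrophobic half-thickness `t`. Parameters, units and
defaults:

| parameter | meaning | default | notes |
|---|---|---|---|
| `t` (half_thickness) | hydrophobic half-width, Å | 15 | σ = 0.5 at depth t; typical phospholipid bilayer half-width |
| `n` (steepness) | sigmoid exponent | 10 | interface width ≈ 4t/n ≈ 6 Å; must be > 1 for smooth gradients at depth 0 |
| `ρ₀` (pore radius) | lateral 0.5-crossing of the pore, Å | — | user-set per structure |
| `m` (pore steepness) | pore sigmoid exponent | 10 | same family as the membrane transition |

The implementation evaluates `σ` as `1/(1+u⁻ⁿ)` for `u > 1`, so arbitrarily
large depths (e.g. a 10⁶ Å vesicle radius) cannot overflow.

**Slab.** `f = σ(|z|/t)`. Even in z, monotone in depth, 0 at the
mid-plane.

**Ellipsoid (micelle/bicelle).** The hydrophobic region is a planar disc
of radius `inner_radius` with a rounded rim. The lateral coordinate is
measured from the disc edge:

```
s      = sqrt(max(0, ρ − inner_radius)² + z²)
r′     = (inner_radius + s) / outer_radius
h      = σ(r′)
f      = f_z + h − f_z·h,   f_z = σ(|z|/t)
```

with `outer_radius = inner_radius + t` unless set explicitly (reading "the
thickness of the membrane" as the hydrophobic half-thickness keeps the rim
transition on the same 15 Å scale as the slab — a genuinely open choice,
flagged here). The micelle is the special case `inner_radius = 0`, where
`r′` reduces to the plain spherical distance over the outer radius and the
field is exactly the spherical composition. Two consequences of the
disc-edge metric are worth knowing: (i) the radial factor is *constant*
over the planar disc (the core is flat by construction); (ii) that
constant, `σ(inner_radius/outer_radius)`, is not zero — it grows toward
0.5 as the bicelle gets large relative to `t`, so very wide bicelles are
better modelled as a slab. The field also has a gradient discontinuity
across the disc interior at `z = 0` (the kink of `|z|` inside `s`);
gradients exactly on the disc return the symmetric subgradient 0 with a
warning.

**Vesicle.** Sphere centre at `(0, 0, ∓R)` ("down" places the centre below
the protein). Depth is `|x − c| − R`; the origin, where a membrane-framed
structure sits, is on the mid-surface by construction. At `R = 10⁶ Å` the
field matches the slab to better than 10⁻⁴ over a 50 Å box (the sag of a
sphere over lateral distance ρ is ρ²/2R ≈ 3·10⁻⁴ Å).

**Double vesicle.** Two concentric spheres. The user sets the inner
mid-surface radius and the *edge-to-edge* aqueous gap `d`; the outer
mid-surface is then `inner + 2t + d`, which makes membrane overlap
impossible by construction. The common centre is placed at
`z = ∓(inner + t + d/2)` so the gap is centred on the origin — the
placement implied by a protein spanning both membranes (gap junctions).
The two single-sphere fields combine by the product rule `f = f₁·f₂`
(hydrophobic inside either membrane), the De Morgan dual of the pore's
union rule. At large radius this converges to the product of two parallel
slabs at `z = ∓(t + d/2)`.

**Pore.** `f_cavity = 1/(1 + (ρ/ρ₀)ᵐ)` with ρ the lateral distance to an
axis parallel to z: 1 on the axis, 0.5 at ρ₀. This is a deliberate
simplification — production membrane frameworks model the pore as stacked
per-slab ellipses fit to the structure — but it preserves the composition
contract (`f_hyd = f_thk + f_cavity − f_thk·f_cavity`) and the
pore-facing classification semantics, which is what the rest of the
package depends on. The union composition is implemented so 1 is exactly
absorbing and rounding can never push the result outside [0, 1].

**Gradients.** Every geometry supplies its analytic spatial gradient,
composed by the same union/product rules. Removable singularities (sphere
centres, the pore axis, the ellipsoid mid-plane disc) are defined as zero
gradient, with a warning where the limit is genuinely direction-dependent.
Correctness is verified against central finite differences (step 10⁻⁴ Å)
at random points restricted to the transition shell where the
finite-difference gradient magnitude exceeds 10⁻³ /Å; outside that shell
both gradients vanish to below finite-difference round-off (~10⁻¹²), where
a relative comparison measures noise rather than correctness. The filter
is applied to the finite-difference oracle, not to the analytic values, so
it does not mask implementation error.

## Burial energetics

`ΔG_memb = Σ (1 − f_hyd)·ΔG_w,l` over atoms. The transfer-energy table is
pluggable (`RES:ATOM` entries, element-level fallback, text-file loader).
The bundled default is a demonstration parameterisation: residue-level
side-chain transfer values on the scale of the Moon–Fleming hydrophobicity
measurements, spread evenly over side-chain heavy atoms, with backbone
atoms at zero. It makes hydrophobics favourable in the core and charged
residues unfavourable, which is all the surrounding mechanics (linearity,
zero in water, per-residue decomposition) require; quantitative work
should load a purpose-fit table.

## Residue classification

Pore-facing: `f_cavity > 0.1` AND `f_thk < 0.75` (strict inequalities) at
the representative atom — CA by default, switchable to the side-chain
centroid. Remaining residues: lipid-facing when `f_hyd < 0.25`, aqueous
when `f_hyd > 0.75`, otherwise interface. The 0.25/0.75 environment
cut-offs are symmetric about the 0.5 mid-transition and are package
choices; the pore-facing thresholds are the established classification
rule.

## Geometry-parameter estimation

The optimiser matches the residues the field scores as membrane-embedded
(CA `f_hyd < 0.5`) against the spanfile residue set over an exhaustive
kind-specific grid (ellipsoid inner radius 10–100 Å step 5; vesicle radius
80–600 Å step 20 plus near-flat sentinels 1000 Å and 10⁶ Å, both
curvature signs; double-vesicle gap 10–300 Å step 10). The objective is
the Jaccard index — symmetric, bounded, and indifferent to residue order —
with balanced accuracy available as an alternative; ties resolve
deterministically to the smallest parameters (grids are ordered
smallest-first). Note the degenerate case: a structure that is rotationally
thin around the z-axis (e.g. a single axial helix) cannot distinguish
curvature radii — all candidates tie and the smallest is returned; the
optimiser is only as informative as the structure's lateral extent, and it
is sensitive to which residues the spanfile declares (a ±2-residue
boundary shift can move the optimum). The bicelle helpers implement the
estimation rule (1.5 × the largest CA–CA distance among CAs with
|z| ≤ 3 Å) and the size warning (inner radius < half the widest atom-pair
distance near the mid-plane).

## Discrimination metrics

Enrichment uses `k = ceil(fraction·N)` with ties broken by a stable sort
on model id, so results are platform-independent. Pnear follows the
Boltzmann-weighted convention `Σ exp(−r²/λ²)·exp(−E/kT) / Σ exp(−E/kT)`
with defaults λ = 2 Å (an interface/backbone RMSD scale) and kT = 1 in
score units, both CLI-exposed since published uses do not print them;
energies are shifted by their minimum before exponentiation (exactly
invariant, overflow-safe). KL divergence is computed as
D(designed ‖ native) over the 20 amino-acid compositions with a 10⁻⁴
pseudocount; direction and smoothing are package choices.

## Synthetic data

The generators produce idealised α-helical CA traces (rise 1.5 Å, twist
100°, helix radius 2.3 Å) in membrane coordinates with known ground truth:
a single TM helix with its spanfile; a helix bundle around a pore of known
radius (helix axes on a circle `pore_radius + 3 Å`, so the inward-facing
CAs are guaranteed `f_cavity > 0.1`); a bundle on a sphere of known
curvature radius (midpoints on the sphere, axes along local normals,
lateral extent 200 Å by default — wide enough that a 20 Å grid resolves
a 120 Å radius); and score/RMSD ensembles with tunable funnel quality
(`score = q·rmsd + (1−q)·noise`, rmsd half-normal with σ = 5 Å). All
generators are byte-reproducible under a fixed seed. What they do *not*
emulate: side-chain packing, loops, non-ideal helix geometry, real
score-function noise structure, or membrane-coordinate misalignment — so
passing tests demonstrate the correctness of the fields, estimators and
metrics, not the accuracy of any energy model on real proteins.

## Numerical and format choices

PDB I/O is fixed-column v3.3 (coordinates 31–54 at %8.3f, B-factor 61–66
at %6.2f); reading is delegated to gemmi (first model, first alternate
conformer, HETATM flagged), writing is deterministic so re-runs are
byte-identical. B-factor annotation rounds `f_hyd` to two decimals and
never touches coordinates. Spanfiles use the widely adopted dialect
(header line; `<n_spans> <n_res>`; `antiparallel`; `n2c`; one 1-based
inclusive `start end` per span) with overlapping spans merged under a
warning. Residues are indexed 1..N in order of first appearance, matching
spanfile semantics, with original PDB numbering preserved for output.

## Problem sizes

The test suite exercises 10⁵ random pairs for the composition algebra,
10⁴ random ensembles for the metric bounds, 1000 qualifying points per
geometry for gradient checks, and grids of tens of candidates for
parameter recovery; the whole suite runs in a few seconds on one CPU.

## Known limitations

Only the geometry-dependent burial term is implemented — not any complete
membrane score function. The pore is a single straight cylinder-like
sigmoid (no per-depth ellipses, no curved pores). The ellipsoid is
axially symmetric (a disc with a rim), not a general triaxial ellipsoid.
Structures must be pre-transformed into membrane coordinates; no membrane
positioning/optimisation is performed.
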