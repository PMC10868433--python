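# memgeom

Implicit-membrane geometry fields for membrane-protein modelling: transition
functions for flat bilayers (slab), micelles/bicelles (ellipsoid), curved
membranes (vesicle) and double membranes (two concentric spheres), with an
aqueous-pore composition, analytic gradients, burial energetics,
geometry-parameter estimation, PDB B-factor annotation, and the
decoy-discrimination metrics used to evaluate sampling runs.

## Who this is for

Structural modellers who score membrane proteins with an implicit membrane
and need the membrane's *shape* to match the experimental system — a
detergent micelle around an NMR construct, a bicelle, a highly curved
vesicle, or the two membranes of a gap junction — rather than the default
infinite flat slab.

## The model

The membrane is a scalar hydration field `f_hyd(x) ∈ [0, 1]`: 0 in the
hydrophobic core, 1 in bulk water. Membrane-dependent energy terms weight
per-atom transfer energies by burial,

```
ΔG_memb = Σ_residues Σ_atoms (1 − f_hyd) · ΔG_w,l
```

so the field *is* the membrane. All geometries use one rational-sigmoid
transition family `σ(u) = uⁿ/(1 + uⁿ)` with hydrophobic half-thickness
`t = 15 Å` and steepness `n = 10`:

* **slab** — `f = σ(|z|/t)`; depends only on depth along the membrane normal.
* **ellipsoid** (micelle/bicelle) — the slab factor composes with a radial
  factor `h = σ(r′)` by the union rule `f = f_z + h − f_z·h`; the inner
  radius is the planar disc of the bicelle, the micelle is `inner_radius = 0`.
* **vesicle** — a sphere of radius `R` centred at `(0, 0, −R)` (or `+R`);
  the signed radial depth replaces `z`, so the protein origin sits on the
  membrane mid-surface. `R = 10⁶ Å` reproduces the slab to `< 10⁻⁴`.
* **double vesicle** — two concentric spheres separated edge-to-edge by a
  distance `d`; their fields multiply, so the gap between the membranes is
  aqueous and each membrane core is hydrophobic.
* **aqueous pore** — `f_cavity = 1/(1 + (ρ/ρ₀)ᵐ)` around an axis parallel
  to z, composed with any geometry by
  `f_hyd = f_thk + f_cavity − f_thk·f_cavity`.

Residues are classified *pore-facing* when `f_cavity > 0.1` and
`f_thk < 0.75` at the representative atom. Ensembles of sampled models are
summarised by **enrichment** (10 × overlap of the best-score and best-RMSD
deciles, range 0–10) and **Pnear**
(`Σ exp(−r²/λ²)·exp(−E/kT) / Σ exp(−E/kT)`, range 0–1).

## Worked example

Recover the curvature radius of a synthetic helix bundle built in a
membrane of known curvature (R = 120 Å), then score a decoy ensemble:

```python
import numpy as np
import memgeom as mg
from memgeom.synthetic import make_curved_bundle, make_funnel_ensemble

st, span = make_curved_bundle(R_true=120.0, seed=2)
report = mg.optimize_geometry_params(
    st, span, "vesicle",
    grid=[mg.GeometrySpec.vesicle(r) for r in np.arange(80.0, 201.0, 20.0)])
print(report.to_text())

t = make_funnel_ensemble(n_models=500, funnel_quality=0.8, seed=1)
print("enrichment:", mg.enrichment(t))
print("pnear:", round(mg.pnear(t, lambda_=2.0, kT=1.0), 4))
```

prints

```
geometry: vesicle
objective: jaccard
best_objective: 1.0000
recommended radius: 120
recommended curvature: down

candidates (params -> objective):
  radius=80 curvature=down -> 0.6562
  radius=100 curvature=down -> 0.8355
  radius=120 curvature=down -> 1.0000
  ...

enrichment: 4.0
pnear: 0.7528
```

The optimiser matched the residues the field scores as membrane-embedded
(CA `f_hyd < 0.5`) against the spanfile and found a perfect Jaccard match
exactly at the true radius. The moderately funnel-shaped ensemble
(quality 0.8) gets an enrichment of 4.0 — 40 % of the best-scoring decile
is also in the lowest-RMSD decile — and a Pnear of 0.75, meaning most of
the Boltzmann weight sits near the reference conformation.

## Command line

```bash
# visualise how a structure is scored: f_hyd -> B-factor column
memgeom map-transition --pdb in.pdb --out anno.pdb --geometry vesicle --radius 120

# micelle/bicelle with an estimated inner radius and a pore
memgeom map-transition --pdb in.pdb --out anno.pdb --geometry micelle --has-pore --pore-radius 6

# double membrane (e.g. gap junction): inner sphere 1000 Å, 40 Å gap
memgeom map-transition --pdb in.pdb --out anno.pdb \
    --geometry double_vesicle --inner-radius 1000 --distance 40

# recommend geometry parameters from a spanfile
memgeom optimize-params --pdb in.pdb --spanfile in.span --geometry vesicle --out report.txt

# decoy-discrimination metrics from a score/RMSD table
memgeom metrics --table scores.txt --out metrics.json
```

Flag vocabulary follows the conventions of membrane-framework tooling:
`--inner-radius` plays the role of a bicelle-radius option (and of the
inner-sphere radius for `double_vesicle`), `--has-pore/--no-pore` toggles
the pore, `--curvature down|up` selects the sphere-centre side. Defaults
can live in a flat TOML file (`memgeom write-config`), with flags taking
precedence. Input errors exit with status 2.

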