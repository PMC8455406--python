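# trilayer

Tri-layered arterial wall mechanics from layer-specific uniaxial testing.

Arteries are three-layered composites — intima, media, adventitia — whose
layers sit in mechanical conflict: isolated from the wall, each layer
relaxes to a different natural state, so the intact unloaded vessel
carries residual stresses that profoundly reshape how load is shared
in vivo. `trilayer` implements a complete modelling workflow that needs
nothing more than uniaxial tensile tests (the cheapest and most widely
available soft-tissue experiment): it fits a fibre-reinforced hyperelastic
model to each isolated layer, estimates the prestretch each layer carries
inside the intact flat wall, computationally closes the composite into a
cylindrical vessel, and simulates physiological tension–inflation to
report layer-specific stresses, stiffnesses, load bearing and stored
elastic energy. It is written for vascular biomechanics researchers who
want layer-resolved in-vivo mechanics without biaxial rigs, multiphoton
imaging or thick-walled finite-element machinery.

## Model

Each layer `k` is an incompressible membrane obeying the
Holzapfel–Gasser–Ogden (HGO) strain-energy function with two symmetric
fibre families at ±α from the circumferential direction and dispersion ρ:

```
Ψ = μ (I₁ − 3) + (c₁/c₂) · ( exp( c₂ [ ρ I₁ + (1 − 3ρ) I₄ − 1 ]² ) − 1 )

I₁ = λ_θ² + λ_r² + λ_z²,    I₄ = λ_θ² cos²α + λ_z² sin²α
```

(the isotropic term is `μ(I₁ − 3)`, not `μ/2(I₁ − 3)` — both conventions
exist in the literature; this package follows the former throughout).
Cauchy stresses follow from `t = −p I + 2 F (∂Ψ/∂C) Fᵀ` with the Lagrange
multiplier `p` eliminated by the membrane condition `t_rr = 0`.

The kinematic chain from isolated layer to pressurised vessel is a
product of diagonal, volume-preserving deformation gradients

```
F_total,k = F₂ · F₁ · Gᵏ
```

where `Gᵏ = diag(λ̂ₓ, 1/(λ̂ₓλ̂_z), λ̂_z)` is the layer prestretch inside the
flat composite wall (estimated from whole-wall uniaxial curves inside an
experimentally measured constraint box), `F₁` closes the flat wall into a
traction-free cylinder (two unknowns solved so the thickness-averaged
circumferential and axial stresses vanish), and `F₂` applies axial
stretch and pressurisation with the luminal radius solved from the
thin-wall equilibrium `P = t_θθ (r_ext − r_int)/r_int`. The in-vivo axial
stretch is the mean of the pairwise cross-over stretches of the reduced
axial force `F_z = π t_zz (r_ext² − r_int²) − π r_int² P` computed at 60,
100 and 140 mmHg. Loaded states yield the tangent modulus
`K = ∂t_θθ/∂ε_θθ` along the inflation path, the small-on-large stiffness
`C = 2(t_θθ + p) + 4λ_θ⁴ ∂²Ψ/∂(λ_θ²)²`, circumferential load shares
`(t_θθᵏ hᵏ)/(t_θθ^wall h^wall)`, and the stored elastic energy change
ΔΨ over a cardiac cycle.

## Worked example

The package ships a reference dataset for the porcine upper thoracic
aorta: per-layer HGO parameters (a cohort of ten animals plus a single
average-response set), modelled layer prestretches and mean geometry
(layer thicknesses 0.33/1.35/0.61 mm, unloaded internal radius 8.66 mm).

```python
from trilayer import (close_vessel, estimate_in_vivo_stretch, inflate,
                      load_bearing, reference_wall_model)

wall = reference_wall_model()
tube = close_vessel(wall)              # traction-free unloaded cylinder
lam_z = estimate_in_vivo_stretch(tube) # reduced-axial-force cross-over
state = inflate(tube, 100.0, lam_z)    # 100 mmHg at the in-vivo stretch
print(round(tube.Lam_Theta[0] * wall.layers[0].prestretch_circ, 3))
print(round(state.wall_stress.t_circ, 1), {k: round(v) for k, v in load_bearing(state).items()})
```

prints

```
0.91
77.3 {'intima': 7, 'media': 58, 'adventitia': 35}
```

— the unloaded vessel's intima sits at a compressive circumferential
residual stretch of ~0.91 (arteries spring open when cut radially), and
at 100 mmHg the wall carries ~77 kPa of circumferential stress of which
the media bears the largest share. `examples/` contains one short script
per capability (layer fitting, prestretch estimation, closure and
inflation, the layer mechanics report, cohort group means); a thin CLI
(`trilayer simulate-data | fit-layer | fit-wall | close | inflate |
invivo-stretch | report | full-pipeline`) wraps the same functions for
shell use.

## Limitations

Thin-walled membrane layers (no transmural gradients within a layer, no
opening-angle kinematics), purely passive hyperelasticity (no smooth
muscle tone or viscoelasticity), no shear deformations. The fibre angle α
and dispersion ρ are only weakly identifiable from two uniaxial
directions; predicted stresses are robust, individual parameter values
less so. See `docs/methods.md` for the full methods note.
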