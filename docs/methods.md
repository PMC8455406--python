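# Methods

## Model and assumptions

The arterial wall is treated as three concentric, adequately spaced
membranes — intima, media, adventitia — each incompressible and
hyperelastic, with negligible shear so every deformation gradient is
diagonal and volume-preserving. Each layer follows the
Holzapfel–Gasser–Ogden (HGO) strain-energy density

Ψ = μ(I₁ − 3) + (c₁/c₂)(exp(c₂[ρI₁ + (1 − 3ρ)I₄ − 1]²) − 1)   [kPa],

with I₁ the first invariant of C = FᵀF and I₄ = λ_θ²cos²α + λ_z²sin²α the
(shared) fourth invariant of two symmetric fibre families at ±α from the
circumferential direction. Two conventions deserve emphasis because both
circulate in the literature and silently differ by a factor of two:

* the isotropic term here is **μ(I₁ − 3)**, not μ/2(I₁ − 3);
* the fibre factor **c₁/c₂** is the sum of the two half-weight families.

The exponent argument ρI₁ + (1 − 3ρ)I₄ − 1 vanishes identically at the
identity, so Ψ(I) = 0 for every admissible parameter set (verified in
tests). Fibres contribute in compression as well as tension; a
tension-only switch is available (`fiber_tension_only=True`) but off by
default, since the base formulation states none.

Cauchy stress is t = −pI + 2F(∂Ψ/∂C)Fᵀ with the Lagrange multiplier p
eliminated through the membrane condition t_rr = 0, giving closed-form
in-plane stresses. These are verified against central finite differences
of Ψ to 1e−5 relative over random parameter/deformation samples.

### Parameters

| symbol | meaning | units | admissible | porcine defaults (intima/media/adventitia) |
|---|---|---|---|---|
| μ | matrix (elastin-like) stiffness | kPa | > 0 | 23.5 / 22.3 / 21.2 |
| c₁ | collagen stiffness scale | kPa | > 0 | 124.7 / 134.8 / 25.7 |
| c₂ | collagen nonlinearity | – | > 0 | 11.0 / 9.5 / 67.3 |
| α | fibre angle from circumferential | deg | [0, 90] | 39.5 / 33.4 / 42.9 |
| ρ | fibre dispersion | – | [0, 1/3] | 0.24 / 0.24 / 0.18 |

Angles are degrees at every public interface, radians internally.
Pressures are mmHg at interfaces (1 mmHg = 0.133322 kPa), lengths mm,
stresses kPa, stiffnesses MPa, forces N (kPa·mm² = 10⁻³ N).

## Kinematic chain

Four configurations are linked by diagonal maps: isolated layer →
(Gᵏ) flat composite wall → (F₁) unloaded closed vessel → (F₂) pressurised
axially stretched vessel. The total per-layer deformation is F₂F₁Gᵏ, and
every map and product is volume-preserving to 1e−10.

**Prestretch Gᵏ** carries the in-plane stretches (λ̂ₓᵏ, λ̂_zᵏ) a layer
acquires when constrained inside the intact flat wall; the radial
component follows from incompressibility. Layer thicknesses in the
composite are hᵏ = Hᵏ/(λ̂ₓᵏλ̂_zᵏ) from the isolated thicknesses Hᵏ.

**Closure F₁** bends the flat wall (circumferential length l_x) into a
cylinder: a through-thickness point y (from the luminal face) maps to
radius R(y) = √(R_int² + l_x·y/(πΛ_Z)), so Λ_Θ(y) = 2πR(y)/l_x varies
transmurally while Λ_Z is shared. Each layer is evaluated at its
mid-thickness coordinate (membrane assumption). Closure has two unknowns
solved by bounded least squares so that the thickness-averaged
circumferential and axial stresses vanish (|residual| < 1e−6 kPa; the
radial condition holds identically for membranes).

*Radius anchor.* The measured unloaded radius is a property of the intact
vessel — it cannot be read off a flattened strip — so by default the
closed vessel's internal radius is pinned to the measurement and the
flat-wall length l_x is the second unknown (`anchor="closed_radius"`).
The alternative reading, l_x = 2π·(measured radius) with R_int solved
(`anchor="flat_length"`), is retained as an option; it leaves the model's
unloaded radius ≈ 13% below the measured value and systematically shifts
the pressurised stresses.

Mid-layer evaluation leaves a discretisation residual when the closed
state is re-averaged by fine transmural quadrature: ≈ 0.15 kPa in the
axial direction for the 1.35 mm media at this geometry — three orders of
magnitude below physiological stresses, but not zero; tests bound it at
0.25 kPa.

**Tension–inflation F₂** applies a uniform axial stretch λ_z and an
internal pressure; λ_θ(R) = r/R follows from volume conservation and the
luminal radius is found by bracketed root-finding on the thin-wall
equilibrium P = t_θθ(r_ext − r_int)/r_int with the thickness-averaged
circumferential stress (|P − target| < 1e−3 mmHg). Deformed layer
thicknesses are successive interface-radius differences, so they
partition the deformed wall exactly.

## Parameter and prestretch estimation

Layer fitting resamples each uniaxial curve at 50 equally spaced
stretches (linear interpolation, endpoints exact) and minimises the
pooled squared stress error of both directions simultaneously — equal
weights, 100 residuals — by bounded nonlinear least squares. Because c₂
spans two orders of magnitude across layers the landscape is multi-modal:
the optimiser uses Latin-hypercube restarts (default 10; log-spaced in μ,
c₁, c₂) seeded for bit-reproducibility, discards restarts that terminate
in regions without a uniaxial equilibrium, and reports the pooled
R² = 1 − SS_res/SS_tot about the pooled mean. Default bounds:
μ ∈ [0.1, 200] kPa, c₁ ∈ [1, 1000] kPa, c₂ ∈ [0.1, 300], α ∈ [0°, 90°],
ρ ∈ [0, 1/3]. α and ρ trade off against each other in uniaxial data; the
recovery guarantee is on predicted stresses (pointwise < 0.5 kPa on
noise-free data), not on raw parameters.

The transverse stretch of a uniaxial state solves t_transverse = 0 by
Brent's method on [0.3, 1.5] (stretch tolerance 1e−10); this is
equivalent to minimising Ψ over the transverse stretch at fixed load,
which the tests exploit as an independent oracle.

Prestretch estimation minimises the same style of cost on whole-wall
curves over the six in-plane components of Gᵏ, with the wall's transverse
stretch solved so the *average* transverse wall stress vanishes (layers
carry self-equilibrating individual stresses). The search is confined to
an experimentally measured box (means ± 3 SD per component, e.g.
adventitial circumferential [0.87, 0.99]) with seeded multi-start.

## In-vivo axial stretch and derived metrics

The reduced axial force F_z = π t_zz^wall(r_ext² − r_int²) − π r_int²P
(thickness-averaged t_zz, exactly zero in the closed unloaded state) is
computed as a function of λ_z at 60, 100 and 140 mmHg; the in-vivo
stretch is the mean of the three pairwise cross-over stretches found by
root-finding on curve differences over λ_z ∈ [1.0, 1.3] (configurable).
At the cohort-mean parameter set the three crossings nearly coincide and
F_z varies by < 5% across the pressure range at the returned stretch; for
individual stiff-collagen parameter sets the crossings spread more. The
membrane form of the wall term tracks the exact annular integral of the
layerwise stresses to within a few percent at this wall-to-radius ratio.

**Tangent modulus K** (Eq.-style ∂t_θθ/∂ε_θθ, ε_θθ = λ_θ − 1) is a
central finite difference ±2 mmHg around the reference pressure along the
inflation path — small against the 60 mmHg inter-reference span, large
enough for numerical stability. Per-layer K uses each layer's mid-layer
inflation stretch; wall K uses the luminal stretch r_int/R_int, the
strain measure of the wall pressure–stretch relationship.

**Small-on-large stiffness C** = 2(t_θθ + p) + 4λ_θ⁴·∂²Ψ/∂(λ_θ²)², with p
the membrane Lagrange multiplier, λ_θ the layer's *total* circumferential
stretch from its stress-free isolated configuration, and the second
derivative taken analytically at fixed total axial stretch with the
radial stretch following incompressibility (verified against finite
differences to 1e−4 relative; at the stress-free isotropic limit C
reduces to 12μ). The wall value is the deformed-thickness-weighted layer
average. C computed with stretches treated as independent (incompressibility
enforced only through p) would be ~20% higher; the constrained form is used.

**Load bearing** per layer is (t_θθᵏhᵏ)/(t_θθ^wall·h^wall)·100% with
deformed thicknesses; the three shares sum to 100% by construction.

**Stored elastic energy** over a cardiac cycle is
ΔΨᵏ = Ψᵏ(systolic) − Ψᵏ(diastolic), an energy per unit
isolated-configuration volume (kPa ≡ mJ/cm³); per-unit-length values
multiply by the isolated-configuration cross-sectional area
Hᵏ·l_x/λ̂ₓᵏ (mJ/mm). Both cycle pressures use the single in-vivo λ_z
(isometric axial tether). Equal systolic and diastolic pressures give
ΔΨ = 0; a reversed cycle is an error.

## Reference dataset and group statistics

The packaged porcine upper thoracic aorta dataset (n = 10) provides two
views: ten per-animal HGO parameter sets, and one "average-response" set
per layer fitted to the cohort-average curves. Cohort-level results are
defined as **means of the per-animal model outcomes**, and the acceptance
script reproduces them that way: it evaluates the full pipeline on each
per-animal model (per-animal parameters; prestretches and geometry enter
as their cohort means, the only form in which they are tabulated) and
averages. The average-response set is *not* a substitute for this
ensemble: fitting averaged curves yields systematically higher c₂ (a
sharper collagen knee) than the mean of per-animal c₂, and the
reduced-axial-force cross-over is hypersensitive to c₂, so the
average-response model alone underestimates the group-mean in-vivo axial
stretch by ≈ 0.05. It remains the packaged single-model fixture because
it is a clean, self-consistent input for examples and synthetic data.

## Synthetic data generator

`synthetic_data` runs the forward model (uniaxial membrane states for
layers; composite-average states for the whole wall) from stretch 1 up to
the stretch where the noise-free stress reaches a 250 kPa cap (located by
root-finding, matching the cyclic-test protocol the curves emulate), then
applies multiplicative Gaussian noise of CV 2% by default — the relative
error regime of a uniaxial load cell — with a 0.1 kPa floor on the noise
scale near zero stress and clipping at zero; the unloaded point stays
exact. Noise streams are seeded per curve family, so generation is
bit-reproducible and order-insensitive. The generator emulates ideal
homogeneous strips: it does **not** simulate preconditioning hysteresis,
peeling damage, jaw-mounting artefacts or sample-to-sample geometric
variability, so a passing recovery test demonstrates correctness of the
estimation machinery, not robustness to every experimental pathology.

## Numerical choices

* Root solves: Brent's method with tight tolerances (stretch 1e−10,
  pressure 1e−3 mmHg); brackets as stated above, errors name the bracket
  and the offending quantity.
* Closure solve: bounded least squares from (1.1·R_ref, Λ_Z = 1), bounds
  [0.2, 2]·R_ref × [0.7, 1.4]; residual verified < 1e−6 kPa.
* Optimiser restarts: seeded `numpy` Generators and scipy Latin
  hypercubes; identical seeds give bit-identical fits.
* Fibre exponential overflow (exponent > 700) raises a dedicated error
  carrying the exponent; fitting treats such regions as infeasible.
* Degenerate inputs: all-zero stress curves (undefined R²), infeasible
  constraint boxes, reversed cardiac cycles and unreachable stress caps
  raise typed errors rather than returning silent values.

## Known limitations

Membrane layers exclude transmural stress gradients within a layer,
bending stiffness and opening-angle kinematics; a thick-walled treatment
would refine the closed-state residual field at the cost of layer-specific
opening-angle data. Biaxial coupling is inferred from two uniaxial
directions rather than measured. The small-on-large wall stiffness is the
metric most sensitive to the stacked conventions (total-stretch factor,
constrained second derivative, thickness averaging); its absolute level
should be compared across studies only with those conventions aligned.
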