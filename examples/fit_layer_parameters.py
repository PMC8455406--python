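"""Recover HGO constitutive parameters from uniaxial stress-stretch curves.

Generates noise-free synthetic circumferential and axial uniaxial tests
for the medial layer (forward model capped at 250 kPa), then fits the
five-parameter HGO model to both curves simultaneously.
"""

from trilayer import fit_layer
from trilayer.synthetic_data import SyntheticSpec, generate_layer_curves

spec = SyntheticSpec(noise_cv=0.0, n_points=50, seed=0)
circ, ax = generate_layer_curves(spec, "media")
truth = spec.layer("media").params

fit = fit_layer(circ, ax, n_restarts=3, seed=0)
p = fit.params

print("parameter      truth    fitted")
for name, tv, fv in [
    ("mu (kPa)", truth.mu, p.mu),
    ("c1 (kPa)", truth.c1, p.c1),
    ("c2 (-)", truth.c2, p.c2),
    ("alpha (deg)", truth.alpha_deg, p.alpha_deg),
    ("rho (-)", truth.rho, p.rho),
]:
    print(f"{name:12s} {tv:8.2f} {fv:9.3f}")
print(f"pooled R^2 over both directions: {fit.r_squared:.6f}")
print(
    "\nA pooled R^2 of ~1 means the fitted model reproduces both uniaxial\n"
    "curves; on noise-free data the generating parameters are recovered.\n"
    "On real data alpha and rho trade off, so trust predicted stresses\n"
    "more than individual parameter values."
)
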