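"""Stiffness measures, load partitioning and cyclic stored energy."""

import math

import numpy as np
import pytest

from trilayer import (
    HGOParams,
    DiagonalDeformation,
    close_vessel,
    hgo_energy,
    inflate,
    load_bearing,
    mechanics_report,
    small_on_large_stiffness,
    stored_energy,
    tangent_stiffness,
)
from trilayer.metrics import _d2psi_du2

from test_tube_mechanics import homogeneous_wall


class TestTangentStiffness:
    def test_matches_path_slope_oracle(self, ref_wall, ref_tube, ref_lamz):
        """Independent oracle: sample the inflation path densely around the
        reference pressure, fit a quadratic to stress vs stretch, and
        compare its derivative with the +/- 2 mmHg finite difference."""
        k = tangent_stiffness(ref_tube, 100.0, ref_lamz)
        pressures = np.linspace(92.0, 108.0, 9)
        states = [inflate(ref_tube, float(P), ref_lamz) for P in pressures]
        for j, name in enumerate(("intima", "media", "adventitia")):
            lam = np.array([s.lam_theta[j] for s in states])
            t = np.array([s.layer_stresses[j].t_circ for s in states])
            slope = np.polyfit(lam, t, 3)
            mid = np.polyval(np.polyder(slope), lam[4])
            assert k[name] == pytest.approx(1e-3 * mid, rel=1e-2)
        lam_w = np.array([s.luminal_circ_stretch for s in states])
        t_w = np.array([s.wall_stress.t_circ for s in states])
        mid = np.polyval(np.polyder(np.polyfit(lam_w, t_w, 3)), lam_w[4])
        assert k["wall"] == pytest.approx(1e-3 * mid, rel=1e-2)

    def test_stiffens_with_pressure(self, ref_tube, ref_lamz):
        k100 = tangent_stiffness(ref_tube, 100.0, ref_lamz)
        k160 = tangent_stiffness(ref_tube, 160.0, ref_lamz)
        for name in k100:
            assert k160[name] > k100[name]

    def test_adventitia_stiffens_most(self, ref_tube, ref_lamz):
        k100 = tangent_stiffness(ref_tube, 100.0, ref_lamz)
        k160 = tangent_stiffness(ref_tube, 160.0, ref_lamz)
        ratio = {n: k160[n] / k100[n] for n in ("media", "adventitia", "wall")}
        assert ratio["adventitia"] > ratio["media"]
        assert 1.8 < ratio["wall"] < 3.0  # roughly doubles over 100->160 mmHg

    def test_pressure_step_must_stay_positive(self, ref_tube, ref_lamz):
        with pytest.raises(ValueError):
            tangent_stiffness(ref_tube, 1.0, ref_lamz, dP=2.0)


class TestSmallOnLarge:
    def test_second_derivative_matches_finite_differences(self):
        """Analytic d2Psi/d(lam_theta^2)^2 vs central second difference of
        the energy along the constrained path (fixed axial stretch, radial
        from incompressibility)."""
        rng = np.random.default_rng(5)
        for _ in range(40):
            p = HGOParams(
                mu=rng.uniform(5, 40), c1=rng.uniform(20, 200),
                c2=rng.uniform(1, 60), alpha_deg=rng.uniform(15, 60),
                rho=rng.uniform(0, 1 / 3),
            )
            lam_t = rng.uniform(1.0, 1.3)
            lam_z = rng.uniform(1.0, 1.15)

            def psi_of_u(u):
                return hgo_energy(
                    p, DiagonalDeformation.from_in_plane(math.sqrt(u), lam_z)
                )

            u = lam_t**2
            h = 1e-4 * u
            fd = (psi_of_u(u + h) - 2 * psi_of_u(u) + psi_of_u(u - h)) / h**2
            assert _d2psi_du2(p, lam_t, lam_z) == pytest.approx(fd, rel=1e-4)

    def test_isotropic_stress_free_reference_value(self):
        """At the identity with fully dispersed fibres the linearised
        stiffness reduces to the matrix value 12 mu (fibre term drops out
        of the constrained second derivative)."""
        mu = 25.0
        p = HGOParams(mu, 80.0, 10.0, 45.0, 1 / 3)
        F = DiagonalDeformation(1.0, 1.0, 1.0)
        from trilayer import lagrange_multiplier, membrane_stress

        t = membrane_stress(p, F).t_circ
        c = 2.0 * (t + lagrange_multiplier(p, F)) + 4.0 * _d2psi_du2(p, 1.0, 1.0)
        assert c == pytest.approx(12.0 * mu, rel=1e-12)

    def test_exceeds_tangent_modulus_at_matched_state(self, ref_tube, ref_lamz):
        k = tangent_stiffness(ref_tube, 100.0, ref_lamz)
        c = small_on_large_stiffness(ref_tube, 100.0, ref_lamz)
        assert c["wall"] > k["wall"]

    def test_rises_with_pressure_most_in_adventitia(self, ref_tube, ref_lamz):
        c100 = small_on_large_stiffness(ref_tube, 100.0, ref_lamz)
        c160 = small_on_large_stiffness(ref_tube, 160.0, ref_lamz)
        ratio = {n: c160[n] / c100[n] for n in c100}
        assert ratio["adventitia"] > ratio["media"]
        assert 1.8 < ratio["wall"] < 3.0


class TestLoadBearing:
    def test_homogeneous_thin_wall_shares_equal_thickness_fractions(self):
        """Identical layers without prestretch split the load by thickness;
        exact only in the thin-wall limit where the transmural stretch
        gradient vanishes."""
        wall = homogeneous_wall(thickness_total=0.02)
        tube = close_vessel(wall)
        state = inflate(tube, 2.0, 1.02)
        shares = load_bearing(state)
        h = state.deformed_thicknesses
        fractions = 100.0 * h / h.sum()
        for j, name in enumerate(("intima", "media", "adventitia")):
            assert shares[name] == pytest.approx(fractions[j], abs=0.5)

    def test_normalisation_exact_across_states(self, ref_tube, ref_lamz):
        for P in (20.0, 60.0, 100.0, 160.0, 200.0):
            shares = load_bearing(inflate(ref_tube, P, ref_lamz))
            assert sum(shares.values()) == pytest.approx(100.0, abs=1e-6)

    def test_zero_wall_stress_is_undefined(self, ref_wall):
        tube0 = close_vessel(ref_wall, prestretch=False)  # exactly stress-free
        with pytest.raises(ZeroDivisionError):
            load_bearing(tube0)


class TestStoredEnergy:
    def test_zero_for_degenerate_cycle(self, ref_tube, ref_lamz):
        e = stored_energy(ref_tube, 100.0, 100.0, ref_lamz)
        for layer in e.values():
            assert layer["delta_psi"] == pytest.approx(0.0, abs=1e-12)

    def test_reversed_cycle_rejected(self, ref_tube, ref_lamz):
        with pytest.raises(ValueError):
            stored_energy(ref_tube, 120.0, 80.0, ref_lamz)

    def test_positive_and_grows_with_wider_cycle(self, ref_tube, ref_lamz):
        normo = stored_energy(ref_tube, 80.0, 120.0, ref_lamz)
        hyper = stored_energy(ref_tube, 100.0, 160.0, ref_lamz)
        for name in ("intima", "media", "adventitia"):
            assert normo[name]["delta_psi"] > 0
            assert hyper[name]["delta_psi"] > normo[name]["delta_psi"]

    def test_fractions_sum_to_hundred(self, ref_tube, ref_lamz):
        e = stored_energy(ref_tube, 80.0, 120.0, ref_lamz)
        assert sum(l["fraction"] for l in e.values()) == pytest.approx(100.0, abs=1e-9)

    def test_per_length_consistent_with_density_and_area(self, ref_wall, ref_tube, ref_lamz):
        e = stored_energy(ref_tube, 80.0, 120.0, ref_lamz)
        for layer in ref_wall.layers:
            area = layer.thickness * ref_tube.l_x / layer.prestretch_circ
            assert e[layer.name]["per_length"] == pytest.approx(
                1e-3 * e[layer.name]["delta_psi"] * area, rel=1e-12
            )


class TestReport:
    def test_report_is_complete_and_consistent(self, ref_tube, ref_lamz):
        rep = mechanics_report(ref_tube, 100.0, ref_lamz)
        rows = rep.to_rows()
        assert [r["component"] for r in rows] == [
            "intima", "media", "adventitia", "wall",
        ]
        assert sum(rep.load_bearing.values()) == pytest.approx(100.0, abs=1e-6)
        text = rep.to_text()
        assert "t_circ" in text and "wall" in text
        # structural stiffness = material stiffness x deformed thickness
        state = inflate(ref_tube, 100.0, ref_lamz)
        h_wall = state.deformed_thicknesses.sum()
        assert rep.structural_tangent["wall"] == pytest.approx(
            rep.tangent_stiffness["wall"] * h_wall, rel=1e-12
        )
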