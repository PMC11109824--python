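"""SDP electron-density model: occupancies, form factors, structure,
fitting and peptide placement selection."""

import copy

import numpy as np
import pytest

from ampscat import sdp, synth
from ampscat.sdp import (FormFactorData, PeptideEnvelope, SDPFormFactorModel,
                         SDPModel, derive_structure, electron_density,
                         form_factor, model_from_structure,
                         volume_probabilities)

WIDTHS = ("sigma_P", "sigma_CG", "sigma_M", "sigma_HC")


class TestVolumeProbabilities:
    def test_water_fills_far_field(self, control_sdp):
        P = volume_probabilities(control_sdp, np.array([60.0, 80.0]))
        assert P["water"] == pytest.approx(1.0, abs=1e-9)

    def test_total_probability_is_one_everywhere(self, control_sdp):
        z = np.linspace(-45.0, 45.0, 901)
        P = volume_probabilities(control_sdp, z)
        total = sum(v for k, v in P.items() if not k.startswith("_"))
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_peptide_removal_returns_volume_to_water_and_chains(
            self, control_sdp, le53_envelope):
        z = np.linspace(-40.0, 40.0, 801)
        with_pep = copy.deepcopy(control_sdp)
        with_pep.peptide = copy.deepcopy(le53_envelope)
        P1 = volume_probabilities(with_pep, z)
        P0 = volume_probabilities(control_sdp, z)
        # hydrocarbon-placed peptide displaces CH2; removing it restores CH2
        # (tolerance covers the clipped peptide tail beyond the slab edge)
        assert P0["ch2"] - P1["ch2"] == pytest.approx(P1["peptide"], abs=1e-5)
        assert P0["water"] == pytest.approx(P1["water"], abs=1e-5)

    def test_overpacked_component_rejected(self, control_sdp):
        bad = copy.deepcopy(control_sdp)
        bad.A_L = 41.0  # headgroup Gaussians exceed unit occupancy
        bad.sigma_P = 1.0
        with pytest.raises(ValueError, match="overpacked"):
            volume_probabilities(bad, np.linspace(-40, 40, 801))


class TestElectronDensity:
    def test_far_field_is_water_density(self, control_sdp):
        total, _ = electron_density(control_sdp, np.array([70.0]))
        v, n = control_sdp.components["water"]
        assert total[0] == pytest.approx(n / v, abs=1e-9)  # 0.333 e/A^3

    def test_mirror_symmetry(self, control_sdp):
        z = np.linspace(0.1, 40.0, 200)
        t_pos, _ = electron_density(control_sdp, z)
        t_neg, _ = electron_density(control_sdp, -z)
        assert t_pos == pytest.approx(t_neg, abs=1e-12)

    def test_excess_electron_conservation(self, control_sdp):
        """integral of (rho - rho_w) over z equals F(0), the excess
        electrons per unit area."""
        z = np.linspace(-120.0, 120.0, 24001)
        total, _ = electron_density(control_sdp, z)
        excess = np.trapezoid(total - control_sdp.rho_water, z)
        assert form_factor(control_sdp, np.array([0.0]))[0] == pytest.approx(
            excess, abs=1e-6)


class TestFormFactor:
    def test_analytic_transform_matches_quadrature(self, control_sdp,
                                                   le53_envelope):
        """Gaussian/slab closed forms vs Simpson quadrature of the density.

        The headgroup-placed envelope keeps the density construction exactly
        consistent with the closed form (no clipping of the chain slab)."""
        from scipy.integrate import simpson

        model = copy.deepcopy(control_sdp)
        pep = copy.deepcopy(le53_envelope)
        # narrow envelope well outside the chain slab: no occupancy clipping
        pep.placement, pep.z, pep.sigma = "headgroup", 21.0, 3.0
        model.peptide = pep
        q = np.linspace(0.0, 0.8, 41)
        z = np.linspace(-150.0, 150.0, 60001)
        total, _ = electron_density(model, z)
        excess = total - model.rho_water
        quad = np.array([simpson(excess * np.cos(qi * z), x=z) for qi in q])
        assert form_factor(model, q) == pytest.approx(quad, abs=1e-9)

    def test_hydrocarbon_envelope_transform_close_despite_tail_clip(
            self, control_sdp, le53_envelope):
        from scipy.integrate import simpson

        model = copy.deepcopy(control_sdp)
        model.peptide = copy.deepcopy(le53_envelope)
        q = np.linspace(0.0, 0.8, 21)
        z = np.linspace(-150.0, 150.0, 60001)
        total, _ = electron_density(model, z)
        excess = total - model.rho_water
        quad = np.array([simpson(excess * np.cos(qi * z), x=z) for qi in q])
        assert form_factor(model, q) == pytest.approx(quad, abs=5e-6)

    def test_sharp_slab_closed_form(self):
        """With vanishing roughness and all non-slab contrasts switched off,
        F reduces to 2 dRho sin(q D_C)/q."""
        comp = sdp.default_component_table()
        rho_w = comp["water"][1] / comp["water"][0]
        # neutralise everything except the CH2 slab
        comp["phos"] = (comp["phos"][0], rho_w * comp["phos"][0])
        comp["cg"] = (comp["cg"][0], rho_w * comp["cg"][0])
        v_ch2 = comp["ch2"][0]
        comp["ch3"] = (comp["ch3"][0],
                       comp["ch2"][1] / v_ch2 * comp["ch3"][0])
        m = SDPModel(A_L=70.8, z_P=21.0, sigma_P=3.0, z_CG=16.0, sigma_CG=2.6,
                     sigma_HC=1e-6, components=comp)
        d_rho = comp["ch2"][1] / v_ch2 - rho_w
        q = np.linspace(0.02, 0.6, 30)
        expected = 2.0 * d_rho * np.sin(q * m.D_C) / q
        assert form_factor(m, q) == pytest.approx(expected, abs=1e-12)

    def test_parseval_consistency(self, control_sdp):
        """int_0^inf F^2 dq = pi * int (rho - rho_w)^2 dz (Plancherel)."""
        q = np.linspace(0.0, 6.0, 60001)
        F = form_factor(control_sdp, q)
        lhs = np.trapezoid(F**2, q)
        z = np.linspace(-80.0, 80.0, 32001)
        total, _ = electron_density(control_sdp, z)
        rhs = np.pi * np.trapezoid((total - control_sdp.rho_water) ** 2, z)
        assert lhs == pytest.approx(rhs, rel=1e-6)


class TestDeriveStructure:
    def test_control_targets_reproduced(self, control_sdp):
        s = derive_structure(control_sdp)
        assert round(s.A_L, 1) == 70.8
        assert round(s.D_HH, 1) == 39.2
        assert round(s.two_D_C, 1) == 29.1

    def test_sharp_slab_direct_readout(self):
        comp = sdp.default_component_table()
        comp["ch2"] = (14.55 * 70.8 - comp["ch3"][0], comp["ch2"][1])
        m = SDPModel(A_L=70.8, z_P=21.0, sigma_P=3.0, z_CG=16.2, sigma_CG=2.6,
                     sigma_HC=0.5, components=comp)
        assert derive_structure(m).two_D_C == pytest.approx(29.1, abs=1e-6)

    def test_outward_shift_raises_dhh_by_twice(self, control_sdp):
        shifted = copy.deepcopy(control_sdp)
        delta = 1.7
        shifted.z_P += delta
        shifted.z_CG += delta
        s0 = derive_structure(control_sdp)
        s1 = derive_structure(shifted)
        assert s1.D_HH - s0.D_HH == pytest.approx(2 * delta, abs=1e-3)


class TestFit:
    def test_noiseless_round_trip_within_printed_uncertainty(self, control_sdp):
        data, truth = synth.gen_formfactor(control_sdp, noise=0.0)
        init = copy.deepcopy(control_sdp)
        init.A_L = 67.0
        init.z_P += 1.0
        res = SDPFormFactorModel(data, init).fit()
        assert abs(res.structure.A_L - truth["A_L"]) <= 1.0
        assert abs(res.structure.D_HH - truth["D_HH"]) <= 0.5
        assert abs(res.structure.two_D_C - truth["two_D_C"]) <= 0.5

    def test_placement_scan_selects_generating_mode(self, control_sdp,
                                                    le53_envelope):
        gen = copy.deepcopy(control_sdp)
        gen.peptide = copy.deepcopy(le53_envelope)
        hits = 0
        for seed in range(8):
            data, _ = synth.gen_formfactor(gen, noise=0.03, seed=seed)
            init = copy.deepcopy(gen)
            init.A_L = 69.0
            res = SDPFormFactorModel(data, init, placement="scan",
                                     fix=WIDTHS).fit()
            hits += res.selected_placement == "hydrocarbon"
        assert hits == 8

    def test_wrong_placement_has_larger_chi2_noiseless(self, control_sdp,
                                                       le53_envelope):
        gen = copy.deepcopy(control_sdp)
        gen.peptide = copy.deepcopy(le53_envelope)
        data, _ = synth.gen_formfactor(gen, noise=0.0)
        data.sigma[:] = 0.03 * data.absF.max()
        init = copy.deepcopy(gen)
        res = SDPFormFactorModel(data, init, placement="scan", fix=WIDTHS).fit()
        chi2 = res.chi2_by_placement
        assert chi2["hydrocarbon"] < chi2["headgroup"]
        assert chi2["hydrocarbon"] == pytest.approx(0.0, abs=1e-3)

    def test_insufficient_lobes_rejected(self, control_sdp):
        data = FormFactorData(np.linspace(0.02, 0.1, 30),
                              np.abs(form_factor(control_sdp,
                                                 np.linspace(0.02, 0.1, 30))),
                              np.full(30, 0.01))
        with pytest.raises(ValueError, match="lobes"):
            SDPFormFactorModel(data, control_sdp)


class TestPeptideBookkeeping:
    def test_electron_and_volume_tables(self):
        # LE-53: 6 R + 4 W + 2 V (+ one water for the termini)
        assert sdp.peptide_electrons("RRRRRRWWWWVV") == 6 * 84 + 4 * 98 + 2 * 54 + 10
        assert sdp.peptide_volume("RRRRRRWWWWVV") == pytest.approx(
            6 * 173.4 + 4 * 227.8 + 2 * 140.0)

    def test_model_from_structure_hits_targets(self):
        m = model_from_structure(A_L=73.4, D_HH=38.5)
        s = derive_structure(m)
        assert s.D_HH == pytest.approx(38.5, abs=1e-6)
        assert s.A_L == 73.4

    def test_both_placement_requires_two_centers(self):
        with pytest.raises(ValueError):
            PeptideEnvelope(placement="both", z=5.0, sigma=4.0,
                            n_electrons=100.0, volume=500.0, per_lipid=0.01)
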