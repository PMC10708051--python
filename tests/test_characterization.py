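"""Benesi-Hildebrand, Tauc, Job's method, electronic constants and
donor-site ranking."""

import numpy as np
import pytest

from ctcspectro.characterization import (
    BHModelError,
    JobSeries,
    TaucFitError,
    TitrationSeries,
    benesi_hildebrand,
    ct_transition_energy,
    donor_site_ranking,
    ionization_potential,
    jobs_ratio,
    molar_to_ug_per_ml,
    oscillator_strength,
    read_edge_csv,
    read_job_csv,
    read_titration_csv,
    resonance_energy,
    standard_free_energy,
    tauc_band_gap,
    transition_dipole,
    ug_per_ml_to_molar,
    write_edge_csv,
    write_job_csv,
    write_titration_csv,
)
from ctcspectro.synth import (
    EquilibriumSystem,
    NoiseModel,
    make_job_series,
    make_tauc_edge,
    make_titration,
)


class TestBenesiHildebrand:
    def test_recovers_generating_constants_exactly(self, cla_system, cla_donor_concs):
        t = make_titration(cla_system, cla_donor_concs, mode="bh_exact")
        res = benesi_hildebrand(t)
        assert res.K == pytest.approx(147.0, rel=1e-6)
        assert res.epsilon == pytest.approx(1.29e4, rel=1e-6)
        assert res.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_unit_line_gives_unit_constants(self):
        # y = [A0]/A = 1 + 1*x  ->  intercept 1, slope 1  ->  eps = K = 1
        d = np.array([0.5, 1.0, 2.0, 4.0, 8.0])
        x = 1.0 / d
        a0 = 1.0
        absorb = a0 / (1.0 + x)
        t = TitrationSeries(d, a0, absorb)
        res = benesi_hildebrand(t)
        assert res.K == pytest.approx(1.0, rel=1e-9)
        assert res.epsilon == pytest.approx(1.0, rel=1e-9)

    def test_linearization_bias_small_when_free_acceptor_dominates(self):
        # exact-equilibrium data; K*A0 = 0.0075 keeps the B-H bias under 2%
        # (measured ~1.5%: the linearization bias grows like K*A0/(1+K*A0))
        donors = np.array([1, 2, 3, 4, 5]) * 5e-8
        sys = EquilibriumSystem(K=500.0, epsilon=1e4,
                                acceptor_total=100 * donors.mean())
        t = make_titration(sys, donors, mode="equilibrium")
        res = benesi_hildebrand(t)
        assert res.K == pytest.approx(500.0, rel=0.02)

    def test_exact_recovery_for_any_positive_constants(self):
        for k, eps in [(0.3, 5.0), (12.0, 2e3), (9.9e4, 4.4e5)]:
            sys = EquilibriumSystem(K=k, epsilon=eps, acceptor_total=1e-3)
            t = make_titration(sys, np.linspace(1e-5, 1e-4, 7), mode="bh_exact")
            res = benesi_hildebrand(t)
            assert res.K == pytest.approx(k, rel=1e-6)
            assert res.epsilon == pytest.approx(eps, rel=1e-6)

    def test_inapplicable_model_raises(self):
        # absorbance decreasing in donor -> negative slope in B-H space
        d = np.array([1e-5, 2e-5, 3e-5, 4e-5, 5e-5])
        a = np.array([0.5, 0.52, 0.55, 0.59, 0.64])[::-1]
        with pytest.raises(BHModelError):
            benesi_hildebrand(TitrationSeries(d, 1e-3, a))

    def test_nonpositive_absorbance_rejected(self):
        d = np.array([1e-5, 2e-5, 3e-5, 4e-5, 5e-5])
        a = np.array([0.1, 0.2, -0.3, 0.4, 0.5])
        with pytest.raises(BHModelError):
            benesi_hildebrand(TitrationSeries(d, 1e-3, a))


class TestTaucBandGap:
    def test_exact_edge_recovered_to_float_tolerance(self, tauc_grid):
        for eg, b in [(2.0, 1.0), (2.0, 3.7), (1.9, 0.2)]:
            e, alpha = make_tauc_edge(eg, b, tauc_grid)
            res = tauc_band_gap(e, alpha)
            assert res.eg == pytest.approx(eg, abs=1e-6)

    def test_cla_band_gap_recovered(self, tauc_grid):
        e, alpha = make_tauc_edge(1.9, 1.0, tauc_grid)
        assert tauc_band_gap(e, alpha).eg == pytest.approx(1.9, abs=0.02)

    def test_mean_error_under_one_percent_noise(self, tauc_grid):
        errors = []
        for seed in range(50):
            e, alpha = make_tauc_edge(
                2.1, 1.0, tauc_grid, NoiseModel(0.0, 0.01, seed=seed)
            )
            errors.append(tauc_band_gap(e, alpha).eg - 2.1)
        assert np.mean(np.abs(errors)) < 0.05

    def test_no_linear_region_raises_with_diagnostics(self):
        rng = np.random.default_rng(1)
        e = np.linspace(1.5, 3.5, 60)
        alpha = rng.uniform(0.5, 1.5, size=60)  # pure noise, no edge
        with pytest.raises(TaucFitError, match="R\\^2"):
            tauc_band_gap(e, alpha)

    def test_too_few_points_rejected(self):
        with pytest.raises(TaucFitError):
            tauc_band_gap([2.0, 2.1, 2.2], [0.1, 0.2, 0.3], window_min_points=5)


class TestElectronicConstants:
    def test_ct_transition_energies(self):
        assert ct_transition_energy(530.0) == pytest.approx(2.339, abs=5e-4)
        assert ct_transition_energy(470.0) == pytest.approx(2.638, abs=5e-4)
        assert ct_transition_energy(1239.84) == pytest.approx(1.0, rel=1e-12)

    def test_ionization_potential_at_reported_maxima(self):
        assert round(ionization_potential(530.0), 2) == 8.65
        assert round(ionization_potential(470.0), 2) == 9.02

    def test_ionization_potential_limit_and_monotonicity(self):
        assert ionization_potential(1e12) == pytest.approx(5.76, abs=1e-6)
        lams = np.linspace(200.0, 800.0, 50)
        ips = [ionization_potential(l) for l in lams]
        assert np.all(np.diff(ips) < 0)

    def test_free_energy_reference_values(self):
        assert round(standard_free_energy(147.0, 298.0), 2) == -12.36
        assert standard_free_energy(1.0) == pytest.approx(0.0, abs=1e-12)
        assert round(standard_free_energy(137.0, 298.0), 2) == -12.19

    def test_free_energy_decreasing_in_k_and_sign_flip(self):
        ks = np.logspace(-2, 4, 30)
        dgs = [standard_free_energy(k) for k in ks]
        assert np.all(np.diff(dgs) < 0)
        assert standard_free_energy(0.5) > 0 > standard_free_energy(2.0)

    def test_oscillator_strength_formula(self):
        assert oscillator_strength(1e4, 1e4) == pytest.approx(0.432, rel=1e-9)
        assert oscillator_strength(1e4, 0.0) == 0.0

    def test_transition_dipole_formula(self):
        # mu = 0.0958 * sqrt(eps * dnu / nu)
        assert transition_dipole(1e4, 1e4, 2e4) == pytest.approx(
            0.0958 * np.sqrt(5e3), rel=1e-9
        )
        assert transition_dipole(1e4, 0.0, 2e4) == 0.0

    def test_resonance_energy_inversion(self):
        # R_N = hnu_CT - Ip + (EA + W); recovering R_N = 0.32 from Ip = 8.65
        # and hnu = 2.339 pins the unprinted sum EA + W at 6.631 eV
        ea_w = 0.32 - 2.339 + 8.65
        assert ea_w == pytest.approx(6.631, abs=1e-3)
        rn = resonance_energy(8.65, ea_w, 0.0, 2.339)
        assert rn == pytest.approx(0.32, abs=1e-9)

    def test_missing_auxiliary_inputs_rejected(self):
        with pytest.raises(ValueError, match="insufficient"):
            oscillator_strength(None, 1e4)
        with pytest.raises(ValueError, match="insufficient"):
            transition_dipole(1e4, None, 2e4)
        with pytest.raises(ValueError, match="insufficient"):
            resonance_energy(8.65, None, 0.0, 2.339)

    def test_concentration_conversion_reconciles_units(self):
        # 11.25-37.5 ug/mL at 306.37 g/mol spans 3.67e-5 to 1.22e-4 M
        assert ug_per_ml_to_molar(11.25) == pytest.approx(3.67e-5, rel=5e-3)
        assert ug_per_ml_to_molar(37.5) == pytest.approx(1.22e-4, rel=5e-3)
        back = molar_to_ug_per_ml(ug_per_ml_to_molar(60.0))
        assert back == pytest.approx(60.0, rel=1e-12)


class TestJobsRatio:
    def test_noiseless_one_to_one(self):
        j = make_job_series(2e-3, 150.0, 1.29e4, np.linspace(0.1, 0.9, 9))
        x_star, ratio, label = jobs_ratio(j)
        assert x_star == pytest.approx(0.5, abs=1e-9)
        assert ratio == pytest.approx(1.0, abs=1e-9)
        assert label == "1:1"

    def test_peak_at_one_third_gives_half_ratio(self):
        # parabola with vertex at x = 1/3
        x = np.linspace(0.1, 0.9, 9)
        y = 1.0 - (x - 1.0 / 3.0) ** 2
        x_star, ratio, label = jobs_ratio(JobSeries(x, y, 2e-3))
        assert x_star == pytest.approx(1.0 / 3.0, abs=1e-9)
        assert ratio == pytest.approx(0.5, abs=1e-6)
        assert label == "1:2"

    def test_noisy_recovery_of_one_to_one(self):
        hits = 0
        for seed in range(20):
            j = make_job_series(
                2e-3, 147.0, 1.29e4, np.linspace(0.1, 0.9, 9),
                NoiseModel(0.002, 0.005, seed=seed),
            )
            x_star, _, _ = jobs_ratio(j)
            hits += abs(x_star - 0.5) <= 0.03
        assert hits >= 18

    def test_invariant_under_uniform_scaling(self):
        j = make_job_series(2e-3, 150.0, 1.29e4, np.linspace(0.1, 0.9, 9))
        x1, r1, _ = jobs_ratio(j)
        scaled = JobSeries(j.mole_fractions, j.absorbances * 37.0, j.total_conc)
        x2, r2, _ = jobs_ratio(scaled)
        assert x2 == pytest.approx(x1, rel=1e-12)
        assert r2 == pytest.approx(r1, rel=1e-12)

    def test_boundary_maximum_rejected(self):
        x = np.linspace(0.1, 0.9, 9)
        y = x.copy()  # monotone: maximum at the boundary
        with pytest.raises(ValueError, match="interior"):
            jobs_ratio(JobSeries(x, y, 2e-3))


class TestDonorSiteRanking:
    def test_reported_site_assignment(self, rux_charges):
        ranked = donor_site_ranking(
            rux_charges,
            {"pyrimidinyl-pyrazole N6+N7": [6, 7], "pyrrole N12": [12]},
        )
        scores = dict(ranked)
        assert scores["pyrimidinyl-pyrazole N6+N7"] == pytest.approx(0.735, abs=1e-9)
        assert scores["pyrrole N12"] == pytest.approx(0.7068, abs=1e-9)
        assert ranked[0][0] == "pyrimidinyl-pyrazole N6+N7"

    def test_empty_site_scores_zero(self, rux_charges):
        assert donor_site_ranking(rux_charges, {"empty": []}) == [("empty", 0.0)]

    def test_unknown_atom_named_in_error(self, rux_charges):
        with pytest.raises(KeyError, match="99"):
            donor_site_ranking(rux_charges, {"bad": [6, 99]})

    def test_invariant_under_row_permutation(self, rux_charges):
        from ctcspectro.characterization import ChargeTable

        shuffled = ChargeTable(
            rux_charges.table.sample(frac=1.0, random_state=5).reset_index(drop=True)
        )
        sites = {"a": [6, 7], "b": [12], "c": [2, 23]}
        assert donor_site_ranking(rux_charges, sites) == donor_site_ranking(shuffled, sites)


class TestSeriesCsvIO:
    def test_titration_round_trip(self, tmp_path, cla_system, cla_donor_concs):
        t = make_titration(cla_system, cla_donor_concs, mode="bh_exact")
        p = tmp_path / "t.csv"
        write_titration_csv(t, p)
        back = read_titration_csv(p)
        np.testing.assert_allclose(back.donor_concs, t.donor_concs, rtol=1e-9)
        np.testing.assert_allclose(back.absorbances, t.absorbances, rtol=1e-9)
        assert back.acceptor_conc == pytest.approx(t.acceptor_conc, rel=1e-9)

    def test_job_round_trip(self, tmp_path):
        j = make_job_series(2e-3, 150.0, 1.29e4, np.linspace(0.1, 0.9, 9))
        p = tmp_path / "j.csv"
        write_job_csv(j, p)
        back = read_job_csv(p)
        np.testing.assert_allclose(back.absorbances, j.absorbances, rtol=1e-9)

    def test_edge_round_trip(self, tmp_path, tauc_grid):
        e, alpha = make_tauc_edge(1.9, 1.0, tauc_grid)
        p = tmp_path / "e.csv"
        write_edge_csv(e, alpha, p)
        e2, a2 = read_edge_csv(p)
        np.testing.assert_allclose(a2, alpha, rtol=1e-9, atol=1e-15)
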