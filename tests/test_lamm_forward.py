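"""Lamm solver: analytic limits, conservation, hydrodynamic conversions."""

import numpy as np
import pytest

from helixmer._constants import ETA_20W, RHO_20W, water_density, water_viscosity
from helixmer.equilibria import AssociationScheme
from helixmer.lamm_forward import (
    CellExperiment,
    HydroSpecies,
    LammError,
    ScanSet,
    d_from_s_ff0,
    mass_from_s,
    simulate_boundaries,
    sphere_hydrodynamics,
    standardize_s,
)


class TestCellExperiment:
    def test_rejects_bad_geometry(self):
        with pytest.raises(LammError):
            CellExperiment(7.2, 6.0, 50000, (100.0,))

    def test_rejects_unsorted_times(self):
        with pytest.raises(LammError):
            CellExperiment(6.0, 7.2, 50000, (200.0, 100.0))

    def test_water_properties_default(self):
        exp = CellExperiment(6.0, 7.2, 50000, (100.0,), temperature_c=20.0)
        assert exp.solvent_density == pytest.approx(RHO_20W, rel=1e-4)
        assert exp.solvent_viscosity == pytest.approx(ETA_20W, rel=1e-3)


class TestForwardSolver:
    def test_no_rotation_leaves_profile_unchanged(self):
        exp = CellExperiment(6.0, 7.2, 0.0, (1000.0, 5000.0))
        sp = HydroSpecies("x", 2.0, d_cm2_s=0.0)
        scans = simulate_boundaries(exp, [sp], [50.0], n_cells=100)
        assert np.allclose(scans.signal_au, scans.signal_au[0, 0])

    def test_zero_diffusion_boundary_law(self):
        """With D→0 the boundary midpoint sits at r_m·exp(s w² t) and the
        plateau is diluted by exp(−2 s w² t) (radial dilution law)."""
        exp = CellExperiment(6.0, 7.2, 50000, (3600.0,))
        s = 2.0  # S
        sp = HydroSpecies("x", s, d_cm2_s=1e-12)
        scans = simulate_boundaries(exp, [sp], [50.0], n_cells=2000)
        omega2 = exp.omega**2
        r_true = 6.0 * np.exp(s * 1e-13 * omega2 * 3600.0)
        dilution_true = np.exp(-2.0 * s * 1e-13 * omega2 * 3600.0)
        sig = scans.signal_au[0]
        r = scans.radii_cm
        plateau_mask = (r > 6.3) & (r < 6.9)
        plateau = float(np.median(sig[plateau_mask]))
        r_mid = r[r < 6.5][np.argmin(np.abs(sig[r < 6.5] - plateau / 2))]
        assert r_mid == pytest.approx(r_true, rel=0.005)
        loading_signal = 50.0 * sp.signal_coeff * scans.pathlength_cm
        assert plateau / loading_signal == pytest.approx(dilution_true, rel=0.005)

    def test_mass_conservation_reacting(self, sv_experiment, mdt_species, mdt_scheme):
        _, det = simulate_boundaries(
            sv_experiment,
            mdt_species,
            107.0,
            scheme=mdt_scheme,
            n_cells=200,
            s_cap_svedberg=8.0,
            return_details=True,
        )
        drift = abs(det["sector_mass_final"] - det["sector_mass_initial"])
        assert drift <= 1e-3 * det["sector_mass_initial"]

    def test_grid_convergence(self, sv_experiment_small, mdt_species, mdt_scheme, fit_radii):
        """Halving the cell width changes scan signals by < 0.2% rms of
        the plateau inside the usable window."""
        kw = dict(scheme=mdt_scheme, s_cap_svedberg=8.0, radii_cm=fit_radii)
        coarse = simulate_boundaries(
            sv_experiment_small, mdt_species, 107.0, n_cells=150, **kw
        )
        fine = simulate_boundaries(
            sv_experiment_small, mdt_species, 107.0, n_cells=300, **kw
        )
        plateau = 107.0 * 0.014 * 0.3
        rms = np.sqrt(np.mean((coarse.signal_au - fine.signal_au) ** 2))
        assert rms < 0.002 * plateau

    def test_weak_association_matches_independent_solver(
        self, sv_experiment_small, mdt_species, fit_radii
    ):
        """With Kds → ∞ the reacting solver reproduces the uncoupled
        monomer run bit for bit."""
        weak = AssociationScheme.monomer_dimer_tetramer(1e30, 1e30)
        coupled = simulate_boundaries(
            sv_experiment_small,
            mdt_species,
            50.0,
            scheme=weak,
            n_cells=120,
            s_cap_svedberg=8.0,
            radii_cm=fit_radii,
        )
        independent = simulate_boundaries(
            sv_experiment_small,
            [mdt_species[0]],
            [50.0],
            n_cells=120,
            s_cap_svedberg=8.0,
            radii_cm=fit_radii,
        )
        assert np.array_equal(coupled.signal_au, independent.signal_au)

    def test_concentration_drives_faster_sedimentation(
        self, sv_experiment_small, mdt_species, mdt_scheme, fit_radii
    ):
        """Self-association shifts signal outward at higher loading: the
        late-scan signal-weighted mean radius (normalized by loading)
        grows with concentration."""
        def late_center(load):
            scans = simulate_boundaries(
                sv_experiment_small,
                mdt_species,
                load,
                scheme=mdt_scheme,
                n_cells=150,
                s_cap_svedberg=8.0,
                radii_cm=fit_radii,
            )
            sig = scans.signal_au[-1]
            return float(np.sum(scans.radii_cm * sig) / np.sum(sig))

        assert late_center(107.0) > late_center(17.0) + 1e-3

    def test_s_cap_below_species_s_rejected(self, sv_experiment_small, mdt_species):
        with pytest.raises(LammError):
            simulate_boundaries(
                sv_experiment_small,
                mdt_species,
                [10.0, 0.0, 0.0],
                n_cells=50,
                s_cap_svedberg=1.0,
            )


class TestScanSet:
    def test_rejects_nonmonotone_radii(self):
        with pytest.raises(LammError):
            ScanSet(
                radii_cm=np.array([6.0, 6.2, 6.1]),
                times_s=np.array([100.0]),
                signal_au=np.zeros((1, 3)),
                rpm=50000,
                meniscus_cm=6.0,
                bottom_cm=7.2,
            )

    def test_skip_early(self):
        scans = ScanSet(
            radii_cm=np.linspace(6, 7, 5),
            times_s=np.array([1.0, 2.0, 3.0]),
            signal_au=np.arange(15.0).reshape(3, 5),
            rpm=50000,
            meniscus_cm=6.0,
            bottom_cm=7.2,
        )
        late = scans.skip_early(2)
        assert late.n_scans == 1
        assert late.times_s[0] == 3.0


class TestStandardizeS:
    def test_identity_at_standard_conditions(self):
        assert standardize_s(1.4, RHO_20W, ETA_20W, 0.73) == pytest.approx(1.4, rel=1e-12)

    def test_water_25c_correction(self):
        # formula oracle with standard water density/viscosity tables
        rho25, eta25 = water_density(25.0), water_viscosity(25.0)
        expected = 1.40 * (eta25 / ETA_20W) * (1 - 0.73 * RHO_20W) / (1 - 0.73 * rho25)
        got = standardize_s(1.40, rho25, eta25, 0.73)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(1.240, abs=0.004)

    def test_zero_buoyancy_rejected(self):
        with pytest.raises(LammError):
            standardize_s(1.4, 1.0, ETA_20W, 1.0)


class TestSphereHydrodynamics:
    def test_14kDa_compact_sphere(self):
        # formula oracle evaluated independently
        from helixmer._constants import K_B, N_A

        r0_cm = (3 * 14000 * 0.73 / (4 * np.pi * N_A)) ** (1 / 3)
        f = 6 * np.pi * ETA_20W * r0_cm
        s_expected = 14000 * (1 - 0.73 * RHO_20W) / (N_A * f) / 1e-13
        r0, d, s = sphere_hydrodynamics(14000, 0.73, 1.0)
        assert s == pytest.approx(s_expected, rel=1e-12)
        assert s == pytest.approx(2.1, abs=0.05)
        assert d == pytest.approx(K_B * 293.15 / f, rel=1e-12)

    def test_mass_doubling_scales_s_by_2_to_2_3(self):
        _, _, s1 = sphere_hydrodynamics(14000, 0.73, 1.0)
        _, _, s2 = sphere_hydrodynamics(28000, 0.73, 1.0)
        assert s2 / s1 == pytest.approx(2 ** (2 / 3), rel=1e-10)

    def test_mass_round_trip(self):
        _, _, s = sphere_hydrodynamics(14000, 0.73, 1.4)
        assert mass_from_s(s, 0.73, 1.4) == pytest.approx(14000, rel=1e-6)

    def test_elevated_friction_slows_diffusion(self):
        d_compact = d_from_s_ff0(1.54, 1.0)
        d_extended = d_from_s_ff0(1.54, 1.6)
        assert d_extended < d_compact

    def test_nonphysical_buoyancy_rejected(self):
        with pytest.raises(LammError):
            sphere_hydrodynamics(14000, 1.1, 1.0, density=1.0)
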