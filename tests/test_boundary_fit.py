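"""Global boundary fitting, profile intervals, model comparison.

Fits here run on deliberately small grids and scan counts; the fitted
quantities are still resolved well above noise.
"""

import numpy as np
import pytest
from scipy import stats
from scipy.optimize import least_squares

from helixmer.boundary_fit import (
    FitError,
    compare_schemes,
    estimate_sw,
    fit_association_model,
    profile_interval,
)
from helixmer.equilibria import AssociationScheme
from helixmer.lamm_forward import HydroSpecies
from helixmer.synthetic_data import gen_auc_scans


@pytest.fixture(scope="module")
def single_species_scans(sv_experiment_small, fit_radii):
    sets, _ = gen_auc_scans(
        seed=0,
        experiment=sv_experiment_small,
        species=[HydroSpecies("monomer", 2.0, mass_da=14000.0)],
        loadings_uM=[50.0],
        noise_sd_au=0.0,
        n_cells=120,
        radii_cm=fit_radii[::2],
    )
    return sets


@pytest.fixture(scope="module")
def tetramer_scans(sv_experiment_small, mdt_species, mdt_scheme, fit_radii):
    """One 107 µM set where ~13% of the material is tetrameric."""
    sets, _ = gen_auc_scans(
        seed=2,
        experiment=sv_experiment_small,
        species=mdt_species,
        loadings_uM=[107.0],
        scheme=mdt_scheme,
        noise_sd_au=0.005,
        n_cells=150,
        radii_cm=fit_radii[::2],
    )
    return sets


class TestFitAssociationModel:
    def test_noise_free_single_species_self_fit(self, single_species_scans):
        scheme = AssociationScheme([("monomer", 1)], [])
        fit = fit_association_model(
            single_species_scans, scheme, n_starts=1, n_cells=120, s_init=[1.5]
        )
        assert fit.rmsd_au < 1e-6
        assert fit.s_svedberg["monomer"] == pytest.approx(2.0, abs=5e-4)
        assert fit.loadings_uM[0] == pytest.approx(50.0, rel=1e-3)

    def test_self_consistency_of_reported_rmsd(self, single_species_scans):
        scheme = AssociationScheme([("monomer", 1)], [])
        fit = fit_association_model(
            single_species_scans, scheme, n_starts=1, n_cells=120, s_init=[1.5]
        )
        resid = fit._objective(fit.x)
        assert np.sqrt(np.mean(resid**2)) == pytest.approx(fit.rmsd_au, rel=1e-6)

    def test_misspecified_dimer_model_fails_or_goes_unphysical(self, tetramer_scans):
        """A monomer-dimer model cannot honestly reproduce
        tetramer-containing boundaries: either the residuals stay well
        above the noise floor, or the fit escapes to a physically
        unreasonable s-ladder (the dimer s blown far past the n^(2/3)
        expectation to mimic the faster species)."""
        from helixmer.boundary_fit import plausibility_flags

        md = AssociationScheme([("monomer", 1), ("dimer", 2)], [1000.0])
        fit = fit_association_model(
            tetramer_scans, md, n_starts=1, n_cells=150, max_nfev=40
        )
        flags = plausibility_flags(md, [fit.s_svedberg["monomer"], fit.s_svedberg["dimer"]])
        assert fit.rmsd_au >= 2 * 0.005 or flags

    def test_sw_estimate_seeds_fit_sensibly(self, tetramer_scans):
        sw = estimate_sw(tetramer_scans[0])
        assert 0.8 < sw < 3.0

    def test_empty_scan_sets_rejected(self):
        scheme = AssociationScheme([("monomer", 1)], [])
        with pytest.raises(FitError):
            fit_association_model([], scheme)


class TestProfileInterval:
    def test_quadratic_surface_matches_analytic_interval(self):
        """On an exactly quadratic error surface the projected interval
        has the closed form  x0 ± sigma*sqrt(chi2_min*p/(N-p)*F)."""
        sigma0, sigma1 = 0.5, 0.2
        const = np.array([2.0, 2.0])

        def objective(x):
            return np.array(
                [(x[0] - 3.0) / sigma0, (x[1] - 1.0) / sigma1, *const]
            )

        x_best = np.array([3.0, 1.0])
        p, n = 2, 4
        chi2_min = float(const @ const)
        f_crit = stats.f.ppf(0.683, p, n - p)
        half_width = sigma0 * np.sqrt(chi2_min * p / (n - p) * f_crit)
        lo, hi, flags = profile_interval(objective, x_best, 0)
        assert flags == (False, False)
        assert lo == pytest.approx(3.0 - half_width, rel=0.02)
        assert hi == pytest.approx(3.0 + half_width, rel=0.02)

    def test_insensitive_parameter_reports_open_interval(self):
        def objective(x):
            return np.array([(x[0] - 1.0), 1.0])

        lo, hi, flags = profile_interval(
            objective,
            np.array([1.0, 5.0]),
            1,
            bounds=(np.array([-10.0, 0.0]), np.array([10.0, 10.0])),
        )
        assert flags == (True, True)

    def test_coverage_on_seeded_nonlinear_regressions(self):
        """Exponential-decay fits: the true rate lies inside the
        projected interval in at least 90% of 20 seeded replicates (the
        joint-F threshold is conservative for one parameter)."""
        t = np.linspace(0.0, 2.0, 12)
        a_true, b_true, noise = 2.0, 1.3, 0.05
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            y = a_true * np.exp(-b_true * t) + rng.normal(0, noise, t.size)

            def objective(x):
                return (x[0] * np.exp(-x[1] * t) - y) / noise

            sol = least_squares(objective, [1.0, 1.0])
            lo, hi, flags = profile_interval(
                objective,
                sol.x,
                1,
                bounds=(np.array([0.0, 0.0]), np.array([10.0, 10.0])),
            )
            if flags == (False, False) and lo <= b_true <= hi:
                hits += 1
        assert hits >= 18


class TestCompareSchemes:
    def test_tetramer_model_outranks_dimer_model(self, tetramer_scans):
        md = AssociationScheme([("monomer", 1), ("dimer", 2)], [1000.0])
        mdt = AssociationScheme.monomer_dimer_tetramer(1000.0, 30.0)
        ranking = compare_schemes(
            tetramer_scans, [md, mdt], n_starts=1, n_cells=150, max_nfev=40
        )
        assert ranking[0]["scheme"].stoichiometries == (1, 2, 4)
        assert ranking[0]["rmsd_au"] < ranking[1]["rmsd_au"]

    def test_monomer_tetramer_is_comparable_to_three_state(self, tetramer_scans):
        """A two-state monomer-tetramer model reaches similar fit
        quality (rmsd within 10%) on tetramer-containing data."""
        mdt = AssociationScheme.monomer_dimer_tetramer(1000.0, 30.0)
        mt = AssociationScheme([("monomer", 1), ("tetramer", 4)], [2e7])
        ranking = compare_schemes(
            tetramer_scans,
            [mdt, mt],
            n_starts=1,
            n_cells=150,
            max_nfev=40,
            log10_kd_bounds=(-1.0, 12.0),
        )
        rmsds = sorted(e["rmsd_au"] for e in ranking)
        assert rmsds[1] / rmsds[0] < 1.10

    def test_needs_two_schemes(self, tetramer_scans):
        with pytest.raises(FitError):
            compare_schemes(tetramer_scans, [AssociationScheme([("monomer", 1)], [])])

    def test_unreasonable_s_scaling_flagged(self):
        from helixmer.boundary_fit import plausibility_flags

        scheme = AssociationScheme([("monomer", 1), ("dimer", 2)], [100.0])
        assert plausibility_flags(scheme, [1.5, 4.5])  # ratio 3.0x vs 1.59 expected
        assert plausibility_flags(scheme, [1.5, 1.2])  # shrinking s
        assert not plausibility_flags(scheme, [1.54, 2.43])  # the fitted ladder
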