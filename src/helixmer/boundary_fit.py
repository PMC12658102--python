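"""Direct global fitting of self-association models to boundary data.

Fits a mass-action :class:`~helixmer.equilibria.AssociationScheme` to
one or more multi-scan sedimentation-velocity data sets by nonlinear
least squares on the full radial profiles, using the reacting
finite-volume Lamm solver as the forward model.  Stepwise Kds are fitted
in log space (their plausible range spans mM to µM); per-set loading
concentrations are free nuisance parameters; species diffusion
coefficients follow from the fitted s via the Svedberg relation with the
known monomer mass.  An optional slow "aggregate" species that does not
participate in the equilibrium can be co-fitted in trace amounts.

Confidence intervals use error-surface projection: the parameter of
interest is scanned while all others are re-optimized, and the interval
is bounded where chi-square crosses

    chi2_min * (1 + p/(N-p) * F(p, N-p; level))

with ``p`` free parameters, ``N`` data points and ``level`` the
confidence level (0.683 for one standard deviation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import stats
from scipy.optimize import least_squares

from .equilibria import AssociationScheme, expected_s_nmer
from .lamm_forward import (
    DEFAULT_SIGNAL_COEFF,
    CellExperiment,
    HydroSpecies,
    ScanSet,
    simulate_boundaries,
)

__all__ = [
    "FitResult",
    "fit_association_model",
    "profile_interval",
    "compare_schemes",
    "estimate_sw",
]


class FitError(RuntimeError):
    pass


def estimate_sw(scans: ScanSet) -> float:
    """Quick weighted-average s (S) from boundary midpoint motion.

    For each scan the boundary midpoint radius (half-plateau crossing)
    is located; the slope of ln(r_mid) against w^2 t estimates the
    signal-average sedimentation coefficient.  Used only to seed the
    nonlinear fit, never as a fitted quantity.
    """
    omega2 = (2.0 * np.pi * scans.rpm / 60.0) ** 2
    r = scans.radii_cm
    outer = (r > r[0] + 0.55 * (r[-1] - r[0])) & (r < r[0] + 0.9 * (r[-1] - r[0]))
    xs, ys = [], []
    for t, sig in zip(scans.times_s, scans.signal_au):
        plateau = float(np.median(sig[outer]))
        if plateau <= 0:
            continue
        above = np.nonzero(sig >= 0.5 * plateau)[0]
        if above.size == 0 or above[0] == 0:
            continue
        xs.append(omega2 * t)
        ys.append(np.log(r[above[0]]))
    if len(xs) < 2:
        raise FitError("cannot locate boundary midpoints for sw estimate")
    slope = np.polyfit(xs, ys, 1)[0]
    return float(slope / 1e-13)


@dataclass
class FitResult:
    """Best-fit parameters and diagnostics of one global fit."""

    scheme: AssociationScheme
    s_svedberg: dict[str, float]
    stepwise_kds_uM: tuple[float, ...]
    loadings_uM: tuple[float, ...]
    aggregate: Optional[dict] = None
    rmsd_au: float = np.nan
    cost: float = np.nan
    n_data: int = 0
    n_free: int = 0
    success: bool = False
    message: str = ""
    nfev: int = 0
    seed: Optional[int] = None
    residuals: Optional[np.ndarray] = None
    at_bounds: tuple[str, ...] = ()
    x: np.ndarray = field(default_factory=lambda: np.array([]))
    # re-optimization hooks used by profile_interval (not serialized)
    _objective: Optional[Callable] = field(default=None, repr=False)
    _param_names: tuple[str, ...] = ()

    @property
    def chi2(self) -> float:
        return 2.0 * self.cost

    def fitted_scheme(self) -> AssociationScheme:
        return AssociationScheme(self.scheme.species, self.stepwise_kds_uM)

    def to_dict(self) -> dict:
        out = {
            "species": [list(sp) for sp in self.scheme.species],
            "s_svedberg": self.s_svedberg,
            "stepwise_kds_uM": list(self.stepwise_kds_uM),
            "loadings_uM": list(self.loadings_uM),
            "rmsd_au": self.rmsd_au,
            "n_data": self.n_data,
            "n_free": self.n_free,
            "success": self.success,
            "nfev": self.nfev,
            "seed": self.seed,
            "at_bounds": list(self.at_bounds),
        }
        if self.aggregate is not None:
            out["aggregate"] = self.aggregate
        return out


def _pack_experiment(scans: ScanSet) -> CellExperiment:
    return CellExperiment(
        meniscus_cm=scans.meniscus_cm,
        bottom_cm=scans.bottom_cm,
        rpm=scans.rpm,
        scan_times_s=tuple(scans.times_s),
        temperature_c=scans.temperature_c,
    )


def fit_association_model(
    scan_sets: Sequence[ScanSet],
    scheme: AssociationScheme,
    monomer_mass_da: float = 14000.0,
    vbar_ml_g: float = 0.73,
    signal_coeff: float = DEFAULT_SIGNAL_COEFF,
    s_init: Optional[Sequence[float]] = None,
    fit_s: bool = True,
    fit_kds: bool = True,
    aggregate: bool = False,
    n_starts: int = 5,
    seed: int = 0,
    n_cells: int = 300,
    cfl: float = 0.8,
    s_bounds: tuple[float, float] = (0.3, 8.0),
    log10_kd_bounds: tuple[float, float] = (-1.0, 7.0),
    max_nfev: Optional[int] = None,
    ftol: float = 1e-8,
) -> FitResult:
    """Globally fit a self-association scheme to one or more scan sets.

    The ``scheme`` supplies the species list and starting stepwise Kds;
    Kds (log space), per-species s values, and per-set loadings are
    free unless masked.  Multistart: the first start uses data-driven
    heuristics (boundary-midpoint sw estimates and plateau loadings),
    the rest are seeded perturbations of it; the best final cost wins.
    """
    scan_sets = list(scan_sets)
    if not scan_sets:
        raise FitError("need at least one scan set")
    labels = scheme.labels
    ns = np.asarray(scheme.stoichiometries, dtype=float)
    n_sets = len(scan_sets)
    experiments = [_pack_experiment(sc) for sc in scan_sets]
    data = [sc.signal_au.ravel() for sc in scan_sets]
    n_data = int(sum(d.size for d in data))

    # --- data-driven heuristics -------------------------------------------
    sws = np.array([estimate_sw(sc) for sc in scan_sets])
    if s_init is None:
        s1 = float(np.clip(0.9 * sws.min(), *s_bounds))
        s_init = [np.clip(s1 * expected_s_nmer(int(n)), *s_bounds) for n in ns]
    s_init = np.asarray(s_init, dtype=float)
    load_init = np.array(
        [
            max(
                float(np.max(sc.signal_au[0])) / (signal_coeff * sc.pathlength_cm),
                1e-3,
            )
            for sc in scan_sets
        ]
    )
    kd_init = np.asarray(scheme.stepwise_kds_uM, dtype=float)

    x0_parts, lo_parts, hi_parts, names = [], [], [], []
    if fit_s:
        x0_parts.append(s_init)
        lo_parts.append(np.full(len(labels), s_bounds[0]))
        hi_parts.append(np.full(len(labels), s_bounds[1]))
        names += [f"s_{lab}" for lab in labels]
    if fit_kds:
        x0_parts.append(np.log10(kd_init))
        lo_parts.append(np.full(kd_init.size, log10_kd_bounds[0]))
        hi_parts.append(np.full(kd_init.size, log10_kd_bounds[1]))
        names += [f"log10_kd_{j}" for j in range(kd_init.size)]
    x0_parts.append(load_init)
    lo_parts.append(0.3 * load_init)
    hi_parts.append(3.0 * load_init)
    names += [f"loading_{j}" for j in range(n_sets)]
    if aggregate:
        # trace non-participating aggregate: s and per-set signal amplitude
        x0_parts.append(np.array([1.5 * s_init[-1]]))
        lo_parts.append(np.array([s_init[-1]]))
        hi_parts.append(np.array([30.0]))
        names += ["s_aggregate"]
        x0_parts.append(np.full(n_sets, 0.01 * load_init.mean()))
        lo_parts.append(np.zeros(n_sets))
        hi_parts.append(np.full(n_sets, 0.2 * load_init.mean()))
        names += [f"aggregate_loading_{j}" for j in range(n_sets)]
    x0 = np.concatenate(x0_parts)
    lo = np.concatenate(lo_parts)
    hi = np.concatenate(hi_parts)
    names = tuple(names)

    def unpack(x):
        i = 0
        if fit_s:
            s_vals = x[i : i + len(labels)]
            i += len(labels)
        else:
            s_vals = s_init
        if fit_kds:
            kds = 10.0 ** x[i : i + kd_init.size]
            i += kd_init.size
        else:
            kds = kd_init
        loads = x[i : i + n_sets]
        i += n_sets
        agg = None
        if aggregate:
            agg = (float(x[i]), np.asarray(x[i + 1 : i + 1 + n_sets]))
        return np.asarray(s_vals), np.asarray(kds), np.asarray(loads), agg

    s_cap = max(30.0 if aggregate else s_bounds[1], s_bounds[1])

    def residuals(x):
        s_vals, kds, loads, agg = unpack(x)
        try:
            sch = AssociationScheme(scheme.species, kds)
        except ValueError:
            return np.full(n_data, 1e3)
        out = []
        for j, (ex, sc) in enumerate(zip(experiments, scan_sets)):
            species = [
                HydroSpecies(
                    lab,
                    float(s),
                    mass_da=monomer_mass_da * n,
                    vbar_ml_g=vbar_ml_g,
                    signal_coeff=signal_coeff,
                )
                for lab, s, n in zip(labels, s_vals, ns)
            ]
            sim = simulate_boundaries(
                ex,
                species,
                float(loads[j]),
                scheme=sch,
                n_cells=n_cells,
                cfl=cfl,
                s_cap_svedberg=s_cap,
                pathlength_cm=sc.pathlength_cm,
                radii_cm=sc.radii_cm,
            ).signal_au
            if agg is not None and agg[1][j] > 0:
                s_agg, amps = agg
                agg_sp = HydroSpecies(
                    "aggregate",
                    s_agg,
                    f_f0=1.4,
                    vbar_ml_g=vbar_ml_g,
                    signal_coeff=signal_coeff,
                )
                sim = sim + simulate_boundaries(
                    ex,
                    [agg_sp],
                    [float(amps[j])],
                    n_cells=n_cells,
                    cfl=cfl,
                    s_cap_svedberg=s_cap,
                    pathlength_cm=sc.pathlength_cm,
                    radii_cm=sc.radii_cm,
                ).signal_au
            out.append((sim.ravel() - data[j]))
        return np.concatenate(out)

    rng = np.random.default_rng(seed)
    best = None
    for start in range(max(1, n_starts)):
        x_start = x0.copy()
        if start > 0:
            i = 0
            if fit_s:
                x_start[i : i + len(labels)] *= rng.uniform(0.85, 1.15, len(labels))
                i += len(labels)
            if fit_kds:
                x_start[i : i + kd_init.size] += rng.uniform(-1, 1, kd_init.size)
                i += kd_init.size
            x_start[i : i + n_sets] *= rng.uniform(0.9, 1.1, n_sets)
            x_start = np.clip(x_start, lo, hi)
        try:
            sol = least_squares(
                residuals,
                x_start,
                bounds=(lo, hi),
                method="trf",
                x_scale="jac",
                ftol=ftol,
                max_nfev=max_nfev,
            )
        except Exception:  # keep trying other starts
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise FitError("no start converged")

    s_vals, kds, loads, agg = unpack(best.x)
    at_bounds = tuple(
        name
        for name, xv, l, h in zip(names, best.x, lo, hi)
        if np.isclose(xv, l) or np.isclose(xv, h)
    )
    rmsd = float(np.sqrt(np.mean(best.fun**2)))
    agg_dict = None
    if agg is not None:
        agg_dict = {"s_svedberg": agg[0], "loadings_uM": list(map(float, agg[1]))}
    result = FitResult(
        scheme=scheme,
        s_svedberg={lab: float(s) for lab, s in zip(labels, s_vals)},
        stepwise_kds_uM=tuple(float(k) for k in kds),
        loadings_uM=tuple(float(v) for v in loads),
        aggregate=agg_dict,
        rmsd_au=rmsd,
        cost=float(best.cost),
        n_data=n_data,
        n_free=int(best.x.size),
        success=bool(best.status > 0),
        message=str(best.message),
        nfev=int(best.nfev),
        seed=seed,
        residuals=best.fun,
        at_bounds=at_bounds,
        x=best.x,
        _objective=residuals,
        _param_names=names,
    )
    return result


# ---------------------------------------------------------------------------
# confidence intervals by error-surface projection
# ---------------------------------------------------------------------------


def _chi2_threshold(chi2_min: float, p: int, n: int, level: float) -> float:
    dof = max(n - p, 1)
    return chi2_min * (1.0 + p / dof * stats.f.ppf(level, p, dof))


def profile_interval(
    objective: Callable[[np.ndarray], np.ndarray],
    x_best,
    index: int,
    level: float = 0.683,
    bounds: Optional[tuple[np.ndarray, np.ndarray]] = None,
    rel_step: float = 0.05,
    max_steps: int = 60,
    rtol: float = 1e-3,
):
    """One-parameter confidence interval by error-surface projection.

    ``objective`` maps a parameter vector to a residual vector; the
    parameter ``index`` is scanned away from ``x_best`` while the others
    are re-optimized, and the crossing of the F-ratio chi-square
    threshold is bisected.  Returns ``(lower, upper, open_flags)`` where
    ``open_flags`` marks bounds not reached within the scan range.
    """
    x_best = np.asarray(x_best, dtype=float)
    p = x_best.size
    r0 = objective(x_best)
    n = r0.size
    chi2_min = float(r0 @ r0)
    threshold = _chi2_threshold(chi2_min, p, n, level)
    if bounds is None:
        lo = np.full(p, -np.inf)
        hi = np.full(p, np.inf)
    else:
        lo, hi = (np.asarray(b, dtype=float) for b in bounds)

    free = [i for i in range(p) if i != index]

    def chi2_fixed(value: float) -> float:
        if not free:
            x = x_best.copy()
            x[index] = value
            r = objective(x)
            return float(r @ r)

        def reduced(z):
            x = x_best.copy()
            x[free] = z
            x[index] = value
            return objective(x)

        z0 = x_best[free]
        sol = least_squares(
            reduced,
            z0,
            bounds=(lo[free], hi[free]),
            method="trf",
            x_scale="jac",
            ftol=1e-10,
        )
        return 2.0 * float(sol.cost)

    scale = max(abs(x_best[index]), 1e-8)

    def find_bound(direction: int):
        prev = x_best[index]
        prev_chi = chi2_min
        step = direction * rel_step * scale
        for k in range(max_steps):
            cand = prev + step
            if cand <= lo[index] or cand >= hi[index]:
                return None  # open: threshold not crossed inside bounds
            chi = chi2_fixed(cand)
            if chi >= threshold:
                a, b = prev, cand
                fa, fb = prev_chi, chi
                for _ in range(60):
                    mid = 0.5 * (a + b)
                    fm = chi2_fixed(mid)
                    if fm >= threshold:
                        b, fb = mid, fm
                    else:
                        a, fa = mid, fm
                    if abs(b - a) <= rtol * max(abs(b), 1e-12):
                        break
                return 0.5 * (a + b)
            prev, prev_chi = cand, chi
            step *= 1.6
        return None

    lower = find_bound(-1)
    upper = find_bound(+1)
    open_flags = (lower is None, upper is None)
    return lower, upper, open_flags


def profile_interval_fit(fit: FitResult, param: str, level: float = 0.683, **kw):
    """Profile interval for a named parameter of a FitResult."""
    if fit._objective is None:
        raise FitError("fit does not carry its objective (was it deserialized?)")
    if param not in fit._param_names:
        raise FitError(f"unknown parameter {param!r}; have {fit._param_names}")
    idx = fit._param_names.index(param)
    return profile_interval(fit._objective, fit.x, idx, level=level, **kw)


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------


def plausibility_flags(
    scheme: AssociationScheme, s_values: Sequence[float], s_ratio_factor: float = 1.5
) -> list[str]:
    """Physical-plausibility screen for fitted s ladders.

    Flags an s-ratio deviating from the smooth-sphere n^(2/3)
    expectation by more than ``s_ratio_factor`` either way, and any s
    that fails to grow with stoichiometry.
    """
    flags = []
    ns = scheme.stoichiometries
    s1 = s_values[0]
    for s, n in zip(s_values[1:], ns[1:]):
        if s <= s1:
            flags.append(f"s({n}-mer) not larger than monomer s")
            continue
        ratio = (s / s1) / expected_s_nmer(int(n))
        if ratio > s_ratio_factor or ratio < 1.0 / s_ratio_factor:
            flags.append(
                f"s({n}-mer)/s(monomer) off n^(2/3) by factor {max(ratio, 1 / ratio):.2f}"
            )
    if any(b <= a for a, b in zip(s_values, s_values[1:])):
        flags.append("s does not increase with stoichiometry")
    return flags


def compare_schemes(
    scan_sets: Sequence[ScanSet],
    schemes: Sequence[AssociationScheme],
    s_ratio_factor: float = 1.5,
    **fit_kwargs,
) -> list[dict]:
    """Fit several association schemes and rank them by rmsd.

    Each entry carries a ``physically_unreasonable`` flag raised when a
    fitted s-ratio deviates from the smooth-sphere n^(2/3) expectation
    by more than ``s_ratio_factor`` in either direction, or when s does
    not increase with stoichiometry.  Failed fits are reported with
    their error; successful fits are still ranked.
    """
    if len(schemes) < 2:
        raise FitError("need at least two schemes to compare")
    entries = []
    for scheme in schemes:
        entry: dict = {"scheme": scheme}
        try:
            fit = fit_association_model(scan_sets, scheme, **fit_kwargs)
        except Exception as err:
            entry["error"] = repr(err)
            entry["fit"] = None
            entry["rmsd_au"] = np.inf
            entries.append(entry)
            continue
        entry["fit"] = fit
        entry["rmsd_au"] = fit.rmsd_au
        flags = plausibility_flags(
            scheme, [fit.s_svedberg[lab] for lab in scheme.labels], s_ratio_factor
        )
        entry["physically_unreasonable"] = bool(flags)
        entry["flags"] = flags
        entries.append(entry)
    entries.sort(key=lambda e: e["rmsd_au"])
    return entries
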