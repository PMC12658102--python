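"""Forward simulation of sedimentation-velocity boundaries.

Solves the Lamm equation

    dc/dt = (1/r) d/dr [ r D dc/dr - s w^2 r^2 c ]

for each species on a conservative finite-volume grid spanning the
sector-shaped cell from meniscus to bottom, with zero total flux at both
walls.  Advection uses an explicit second-order MUSCL scheme with a van
Leer limiter; diffusion is integrated with a Crank–Nicolson step whose
tridiagonal operator is factorized once per run.  For self-associating
systems the species are coupled in the rapid-equilibrium limit: after
each transport step the local composition in every cell is projected
back onto the mass-action manifold, conserving monomer-equivalents
cell by cell (operator splitting, Claverie-style).

Also provides the standard hydrodynamic conversions: the
Svedberg/Stokes–Einstein/sphere-volume triplet relating (M, vbar, f/f0)
to (R0, D, s), and correction of experimental s to standard conditions
(water, 20 °C).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.sparse import csc_matrix, diags, identity
from scipy.sparse.linalg import splu

from ._constants import (
    ETA_20W,
    K_B,
    N_A,
    RHO_20W,
    R_GAS,
    SVEDBERG,
    rpm_to_omega,
    water_density,
    water_viscosity,
)
from .equilibria import AssociationScheme, solve_speciation

__all__ = [
    "CellExperiment",
    "HydroSpecies",
    "ScanSet",
    "simulate_boundaries",
    "standardize_s",
    "sphere_hydrodynamics",
    "mass_from_s",
    "d_from_s_ff0",
]

#: default per-monomer signal coefficient, AU / (µM · cm); roughly a
#: 14 kDa single-tryptophan protein at 280 nm (eps ~ 14,000 1/(M cm))
DEFAULT_SIGNAL_COEFF = 0.014

MASS_CONSERVATION_RTOL = 1e-3


class LammError(RuntimeError):
    """Solver failure (instability, negative concentrations, bad input)."""


@dataclass(frozen=True)
class CellExperiment:
    """Geometry, rotor speed, solvent and scan schedule of one SV run."""

    meniscus_cm: float
    bottom_cm: float
    rpm: float
    scan_times_s: tuple[float, ...]
    temperature_c: float = 20.0
    density_g_ml: Optional[float] = None
    viscosity_poise: Optional[float] = None

    def __post_init__(self):
        if not (0 < self.meniscus_cm < self.bottom_cm):
            raise LammError(
                f"need 0 < meniscus < bottom, got {self.meniscus_cm}, {self.bottom_cm}"
            )
        if self.rpm < 0:
            raise LammError(f"rotor speed must be >= 0 rpm, got {self.rpm}")
        times = tuple(float(t) for t in self.scan_times_s)
        if any(t < 0 for t in times) or any(
            b <= a for a, b in zip(times, times[1:])
        ):
            raise LammError("scan times must be nonnegative and strictly increasing")
        object.__setattr__(self, "scan_times_s", times)

    @property
    def omega(self) -> float:
        """Angular velocity, rad/s."""
        return rpm_to_omega(self.rpm)

    @property
    def solvent_density(self) -> float:
        if self.density_g_ml is not None:
            return self.density_g_ml
        return water_density(self.temperature_c)

    @property
    def solvent_viscosity(self) -> float:
        if self.viscosity_poise is not None:
            return self.viscosity_poise
        return water_viscosity(self.temperature_c)


@dataclass(frozen=True)
class HydroSpecies:
    """Hydrodynamic description of one sedimenting species.

    ``d_cm2_s`` may be given directly; otherwise it is derived from the
    molar mass via the Svedberg relation when ``mass_da`` is set, or
    from ``f_f0`` via the sphere relations.  ``signal_coeff`` is the
    absorbance signal per µM of monomer units per cm of optical path.
    """

    label: str
    s_svedberg: float
    mass_da: Optional[float] = None
    d_cm2_s: Optional[float] = None
    f_f0: Optional[float] = None
    vbar_ml_g: float = 0.73
    signal_coeff: float = DEFAULT_SIGNAL_COEFF

    def __post_init__(self):
        if self.s_svedberg <= 0:
            raise LammError(f"s must be > 0 S, got {self.s_svedberg}")
        if self.f_f0 is not None and self.f_f0 < 1.0:
            raise LammError(f"f/f0 must be >= 1, got {self.f_f0}")
        if self.d_cm2_s is None and self.mass_da is None and self.f_f0 is None:
            raise LammError(f"species {self.label!r}: give D, mass, or f/f0")

    def diffusion_coefficient(
        self, density: float, viscosity: float, temperature_c: float
    ) -> float:
        """Diffusion coefficient in cm²/s under the given solvent."""
        if self.d_cm2_s is not None:
            return self.d_cm2_s
        if self.mass_da is not None:
            buoy = 1.0 - self.vbar_ml_g * density
            if buoy <= 0:
                raise LammError(f"non-positive buoyancy for species {self.label!r}")
            temp_k = temperature_c + 273.15
            return (
                self.s_svedberg
                * SVEDBERG
                * R_GAS
                * temp_k
                / (self.mass_da * buoy)
            )
        return d_from_s_ff0(
            self.s_svedberg, self.f_f0, self.vbar_ml_g, density, viscosity, temperature_c
        )


@dataclass
class ScanSet:
    """One sedimentation-velocity experiment: timed radial signal profiles."""

    radii_cm: np.ndarray
    times_s: np.ndarray
    signal_au: np.ndarray  # shape (n_times, n_radii)
    rpm: float
    meniscus_cm: float
    bottom_cm: float
    temperature_c: float = 20.0
    pathlength_cm: float = 0.3
    wavelength_nm: float = 280.0
    label: str = ""

    def __post_init__(self):
        self.radii_cm = np.asarray(self.radii_cm, dtype=float)
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.signal_au = np.asarray(self.signal_au, dtype=float)
        if np.any(np.diff(self.radii_cm) <= 0):
            raise LammError("scan radii must be strictly increasing")
        if self.signal_au.shape != (self.times_s.size, self.radii_cm.size):
            raise LammError(
                f"signal shape {self.signal_au.shape} does not match "
                f"{self.times_s.size} times x {self.radii_cm.size} radii"
            )

    @property
    def n_scans(self) -> int:
        return int(self.times_s.size)

    def skip_early(self, n: int) -> "ScanSet":
        """Drop the first ``n`` scans (e.g. to remove aggregate signal)."""
        return ScanSet(
            self.radii_cm,
            self.times_s[n:],
            self.signal_au[n:],
            self.rpm,
            self.meniscus_cm,
            self.bottom_cm,
            self.temperature_c,
            self.pathlength_cm,
            self.wavelength_nm,
            self.label,
        )


# ---------------------------------------------------------------------------
# hydrodynamic conversions
# ---------------------------------------------------------------------------


def standardize_s(
    s_exp_svedberg: float,
    density_exp: float,
    viscosity_exp: float,
    vbar_ml_g: float,
) -> float:
    """Correct an experimental s to standard conditions (water, 20 °C).

    s20,w = s_exp · (η_exp/η_20,w) · (1 − v̄ρ_20,w)/(1 − v̄ρ_exp)
    """
    for name, v in (
        ("s", s_exp_svedberg),
        ("density", density_exp),
        ("viscosity", viscosity_exp),
        ("vbar", vbar_ml_g),
    ):
        if not np.isfinite(v) or v <= 0:
            raise LammError(f"{name} must be positive and finite, got {v}")
    buoy_exp = 1.0 - vbar_ml_g * density_exp
    buoy_std = 1.0 - vbar_ml_g * RHO_20W
    if buoy_exp <= 0 or buoy_std <= 0:
        raise LammError("non-positive buoyancy 1 - vbar*rho; check vbar and density")
    return s_exp_svedberg * (viscosity_exp / ETA_20W) * buoy_std / buoy_exp


def sphere_hydrodynamics(
    mass_da: float,
    vbar_ml_g: float = 0.73,
    f_f0: float = 1.0,
    density: float = RHO_20W,
    viscosity: float = ETA_20W,
    temperature_c: float = 20.0,
) -> tuple[float, float, float]:
    """Svedberg/Stokes–Einstein/sphere-volume triplet.

    Returns ``(R0_nm, D_cm2_s, s_svedberg)`` for a particle of molar
    mass M with the stated partial specific volume and frictional ratio:
    R0 = (3 M v̄ / 4π N_A)^(1/3), f = 6π η (f/f0) R0, D = k_B T / f,
    s = M (1 − v̄ρ) / (N_A f).
    """
    if mass_da <= 0:
        raise LammError(f"mass must be positive, got {mass_da}")
    if f_f0 < 1.0:
        raise LammError(f"f/f0 must be >= 1, got {f_f0}")
    buoy = 1.0 - vbar_ml_g * density
    if buoy <= 0:
        raise LammError("non-positive buoyancy 1 - vbar*rho")
    r0_cm = (3.0 * mass_da * vbar_ml_g / (4.0 * np.pi * N_A)) ** (1.0 / 3.0)
    friction = 6.0 * np.pi * viscosity * f_f0 * r0_cm
    d = K_B * (temperature_c + 273.15) / friction
    s = mass_da * buoy / (N_A * friction) / SVEDBERG
    return r0_cm * 1e7, d, s


def mass_from_s(
    s_svedberg: float,
    vbar_ml_g: float = 0.73,
    f_f0: float = 1.0,
    density: float = RHO_20W,
    viscosity: float = ETA_20W,
) -> float:
    """Inverse sphere relation: molar mass (Da) from (s, f/f0).

    From s = 2 R0² (1 − v̄ρ) / (9 v̄ η (f/f0)):
    R0 = sqrt(9 s v̄ η (f/f0) / (2 (1 − v̄ρ))), then M = 4π R0³ N_A/(3 v̄).
    """
    buoy = 1.0 - vbar_ml_g * density
    if buoy <= 0:
        raise LammError("non-positive buoyancy 1 - vbar*rho")
    r0 = np.sqrt(
        9.0 * s_svedberg * SVEDBERG * vbar_ml_g * viscosity * f_f0 / (2.0 * buoy)
    )
    return 4.0 * np.pi * r0**3 * N_A / (3.0 * vbar_ml_g)


def d_from_s_ff0(
    s_svedberg: float,
    f_f0: float,
    vbar_ml_g: float = 0.73,
    density: float = RHO_20W,
    viscosity: float = ETA_20W,
    temperature_c: float = 20.0,
) -> float:
    """Diffusion coefficient implied by (s, f/f0) via the sphere relations."""
    buoy = 1.0 - vbar_ml_g * density
    if buoy <= 0:
        raise LammError("non-positive buoyancy 1 - vbar*rho")
    r0 = np.sqrt(
        9.0 * s_svedberg * SVEDBERG * vbar_ml_g * viscosity * f_f0 / (2.0 * buoy)
    )
    friction = 6.0 * np.pi * viscosity * f_f0 * r0
    return K_B * (temperature_c + 273.15) / friction


# ---------------------------------------------------------------------------
# finite-volume Lamm solver
# ---------------------------------------------------------------------------


class _LammGrid:
    """Uniform finite-volume grid on [meniscus, bottom]."""

    def __init__(self, meniscus: float, bottom: float, n_cells: int):
        self.n = int(n_cells)
        self.dr = (bottom - meniscus) / self.n
        self.faces = meniscus + self.dr * np.arange(self.n + 1)
        self.centers = 0.5 * (self.faces[:-1] + self.faces[1:])
        # cell "volume" per unit angle and height: r dr (sector geometry)
        self.vol = self.centers * self.dr

    def sector_mass(self, conc: np.ndarray) -> float:
        """∫ c r dr over the cell (the conserved quantity)."""
        return float(np.sum(conc * self.vol, axis=-1))


class _TransportOps:
    """Transport operators for all species at once on a fixed grid/step."""

    def __init__(
        self,
        grid: _LammGrid,
        s_cm: np.ndarray,
        d: np.ndarray,
        omega: float,
        dt: float,
    ):
        self.grid = grid
        self.dt = dt
        self.k = len(s_cm)
        n = grid.n
        # r^2 * v at interior faces, per species: shape (k, n-1)
        self.rv_face = (
            s_cm[:, None] * omega**2 * grid.faces[None, 1:-1] ** 2
        )
        # Crank–Nicolson diffusion with zero-flux walls; one tridiagonal
        # operator per species so a species' update is independent of
        # which other species are present (the infinitely-weak coupled
        # run then reproduces the single-species run bit for bit)
        inner = grid.faces[1:-1]
        theta = 0.5
        self._lus = []
        self._b_ops = []
        for dk in d:
            w = dk * inner / grid.dr  # face conductances
            lower = w / grid.vol[1:]
            upper = w / grid.vol[:-1]
            main = np.zeros(n)
            main[:-1] -= upper
            main[1:] -= lower
            lap = diags([lower, main, upper], offsets=[-1, 0, 1], format="csc")
            ident = identity(n, format="csc")
            self._lus.append(splu(csc_matrix(ident - dt * theta * lap)))
            self._b_ops.append((ident + dt * (1.0 - theta) * lap).tocsr())

    def advect(self, conc: np.ndarray) -> np.ndarray:
        """Explicit MUSCL/van Leer step of the sedimentation flux.

        ``conc`` has shape (k, n); flow is outward (toward the bottom),
        so the upwind cell is always the inner neighbor.
        """
        g = self.grid
        dc = np.diff(conc, axis=1)  # (k, n-1)
        face_c = conc[:, :-1].copy()
        if g.n > 2:
            denom = dc[:, 1:]
            num = dc[:, :-1]
            ratio = np.where(denom != 0, num, 0.0) / np.where(denom != 0, denom, 1.0)
            pos = ratio > 0
            phi = np.where(pos, 2.0 * ratio, 0.0) / np.where(pos, 1.0 + ratio, 1.0)
            face_c[:, 1:] += 0.5 * phi * denom
        flux = self.rv_face * face_c  # r^2 w^2 s c at interior faces
        out = conc.copy()
        out[:, :-1] -= self.dt * flux / g.vol[:-1]
        out[:, 1:] += self.dt * flux / g.vol[1:]
        return out

    def diffuse(self, conc: np.ndarray) -> np.ndarray:
        out = np.empty_like(conc)
        for j, (lu, b_op) in enumerate(zip(self._lus, self._b_ops)):
            out[j] = lu.solve(b_op @ conc[j])
        return out


class _Equilibrator:
    """Warm-started per-cell projection onto the mass-action manifold.

    Keeps the free-monomer field between calls so the Newton solve
    typically converges in two or three vectorized iterations.
    """

    def __init__(self, scheme: AssociationScheme):
        self.ns = np.asarray(scheme.stoichiometries, dtype=int)
        self.kcum = scheme.cumulative_constants()
        self._m: Optional[np.ndarray] = None

    def __call__(self, conc: np.ndarray) -> np.ndarray:
        totals = conc.sum(axis=0)
        pos = np.maximum(totals, 0.0)
        m = pos.copy() if self._m is None else np.minimum(self._m, pos)
        ns, kcum = self.ns, self.kcum
        for _ in range(40):
            f = -pos
            df = np.zeros_like(m)
            for n, k in zip(ns, kcum):
                p = m ** int(n - 1)
                f = f + (n / k) * p * m
                df = df + (n * n / k) * p
            step = f / np.maximum(df, 1e-300)
            m = np.clip(m - step, 0.0, pos)
            if np.max(np.abs(step)) <= 1e-13 * max(float(np.max(m)), 1e-300):
                break
        self._m = m
        equiv = np.empty_like(conc)
        for j, (n, k) in enumerate(zip(ns, kcum)):
            equiv[j] = (n / k) * m ** int(n)
        oligomer = pos - equiv[0]
        scale = max(float(np.max(pos)), 1e-300)
        if np.max(oligomer) <= 1e-15 * scale:
            # infinitely weak association: leave channels untouched so the
            # monomer field matches the uncoupled solver bit for bit
            return conc
        neg = totals < 0
        if np.any(neg):
            equiv[:, neg] = 0.0
            equiv[0, neg] = totals[neg]
        return equiv


def _resolve_scan_radii(radii, grid: _LammGrid):
    if radii is None:
        return grid.centers
    return np.asarray(radii, dtype=float)


def simulate_boundaries(
    experiment: CellExperiment,
    species: Sequence[HydroSpecies],
    loading_uM,
    scheme: Optional[AssociationScheme] = None,
    n_cells: int = 500,
    cfl: float = 0.5,
    s_cap_svedberg: Optional[float] = None,
    pathlength_cm: float = 0.3,
    radii_cm: Optional[np.ndarray] = None,
    return_details: bool = False,
):
    """Simulate noise-free absorbance boundaries for one cell loading.

    Parameters
    ----------
    loading_uM:
        With a ``scheme``: total µM of monomer-equivalents loaded
        uniformly; the initial profile is the bulk equilibrium mixture.
        Without a scheme: a scalar (single species) or one
        monomer-equivalent loading per independent species.
    scheme:
        Optional self-association scheme mapping one-to-one onto
        ``species``; couples the species in the rapid-equilibrium limit.
    s_cap_svedberg:
        Optional fixed upper bound on s used to choose the time step.
        Pinning it makes the discretization independent of the species
        parameters, which keeps least-squares objectives smooth during
        fitting.  Must be >= the largest species s.
    """
    species = list(species)
    if scheme is not None:
        if len(species) != scheme.n_species:
            raise LammError(
                f"{len(species)} species for a {scheme.n_species}-species scheme"
            )
        total = float(loading_uM)
        if total <= 0:
            raise LammError("loading must be positive")
        bulk = solve_speciation(total, scheme)
        init_equiv = bulk.monomer_equiv_uM  # per species, µM monomer-equivalents
        if total - init_equiv[0] <= 1e-15 * total:
            # infinitely weak association: load pure monomer exactly
            init_equiv = np.zeros_like(init_equiv)
            init_equiv[0] = total
    else:
        init_equiv = np.atleast_1d(np.asarray(loading_uM, dtype=float))
        if init_equiv.size != len(species):
            raise LammError(
                f"{init_equiv.size} loadings for {len(species)} independent species"
            )
        if np.any(init_equiv < 0):
            raise LammError("loadings must be nonnegative")

    grid = _LammGrid(experiment.meniscus_cm, experiment.bottom_cm, n_cells)
    omega = experiment.omega
    rho = experiment.solvent_density
    eta = experiment.solvent_viscosity
    s_cm = np.array([sp.s_svedberg * SVEDBERG for sp in species])
    d_arr = np.array(
        [sp.diffusion_coefficient(rho, eta, experiment.temperature_c) for sp in species]
    )
    coeff = np.array([sp.signal_coeff for sp in species])

    times = np.asarray(experiment.scan_times_s, dtype=float)
    t_end = times[-1] if times.size else 0.0

    s_max = max((sp.s_svedberg for sp in species), default=0.0)
    if s_cap_svedberg is not None:
        if s_cap_svedberg < s_max:
            raise LammError(
                f"s_cap {s_cap_svedberg} S below largest species s {s_max} S"
            )
        s_max = s_cap_svedberg
    v_max = s_max * SVEDBERG * omega**2 * experiment.bottom_cm
    if v_max > 0 and t_end > 0:
        dt = cfl * grid.dr / v_max
        n_steps = int(np.ceil(t_end / dt))
        dt = t_end / n_steps
    else:
        dt = max(t_end, 1.0)
        n_steps = 1 if t_end > 0 else 0

    ops = _TransportOps(grid, s_cm, d_arr, omega, dt)
    equilibrate = _Equilibrator(scheme) if scheme is not None else None
    conc = np.tile(init_equiv[:, None], (1, grid.n)).astype(float)
    mass0 = sum(grid.sector_mass(conc[k]) for k in range(len(species)))

    scan_radii = _resolve_scan_radii(radii_cm, grid)
    signal_out = np.empty((times.size, scan_radii.size))
    next_scan = 0

    def record(upto_time, c_prev, c_now, t_prev, t_now):
        nonlocal next_scan
        while next_scan < times.size and times[next_scan] <= upto_time + 1e-9:
            tt = times[next_scan]
            if t_now == t_prev:
                c_at = c_now
            else:
                w = (tt - t_prev) / (t_now - t_prev)
                c_at = (1.0 - w) * c_prev + w * c_now
            sig = pathlength_cm * np.einsum("k,kr->r", coeff, c_at)
            signal_out[next_scan] = np.interp(scan_radii, grid.centers, sig)
            next_scan += 1

    record(0.0, conc, conc, 0.0, 0.0)
    t = 0.0
    for _ in range(n_steps):
        t_new = t + dt
        need_scan = next_scan < times.size and times[next_scan] <= t_new + 1e-9
        c_prev = conc if not need_scan else conc.copy()
        conc = ops.diffuse(ops.advect(conc))
        if equilibrate is not None:
            conc = equilibrate(conc)
        if need_scan:
            record(t_new, c_prev, conc, t, t_new)
        t = t_new

    if np.min(conc) < -1e-6 * max(np.max(init_equiv), 1e-12):
        raise LammError(
            f"negative concentrations beyond tolerance (min {np.min(conc):.3e})"
        )
    mass1 = sum(grid.sector_mass(conc[k]) for k in range(len(species)))
    if mass0 > 0 and abs(mass1 - mass0) > MASS_CONSERVATION_RTOL * mass0:
        raise LammError(
            f"sector mass drifted by {abs(mass1 - mass0) / mass0:.2e} (limit 1e-3)"
        )

    scans = ScanSet(
        radii_cm=scan_radii,
        times_s=times,
        signal_au=signal_out,
        rpm=experiment.rpm,
        meniscus_cm=experiment.meniscus_cm,
        bottom_cm=experiment.bottom_cm,
        temperature_c=experiment.temperature_c,
        pathlength_cm=pathlength_cm,
    )
    if return_details:
        details = {
            "grid_centers_cm": grid.centers,
            "final_conc_uM": conc,
            "sector_mass_initial": mass0,
            "sector_mass_final": mass1,
            "dt_s": dt,
            "n_steps": n_steps,
        }
        return scans, details
    return scans
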