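"""Continuous c(s) distribution analysis of sedimentation-velocity data.

A scan set is modeled as a nonnegative superposition of noise-free
single-species Lamm solutions sharing one frictional ratio:

    a(r, t) ≈ Σ_j c(s_j) Δs_j · L(r, t; s_j, D(s_j, f/f0))

The amplitudes are found by nonnegative linear least squares with a
second-derivative (Tikhonov) roughness penalty.  The penalty strength is
scaled so that the penalized chi-square exceeds the unpenalized minimum
by the one-standard-deviation F-ratio (P = 0.683 by default), the usual
regularization criterion for sedimentation-coefficient distributions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy import stats
from scipy.optimize import nnls

from .lamm_forward import (
    CellExperiment,
    HydroSpecies,
    ScanSet,
    simulate_boundaries,
)

__all__ = ["CsDistribution", "fit_cs", "integrate_cs", "default_s_grid"]


class CsError(ValueError):
    """Invalid input to the c(s) analysis."""


def default_s_grid(s_min: float = 0.5, s_max: float = 10.0, n: int = 100) -> np.ndarray:
    return np.linspace(s_min, s_max, n)


@dataclass
class CsDistribution:
    """Regularized distribution of sedimentation coefficients.

    ``amplitudes`` is the density c(s) in signal units per Svedberg, so
    that ``∫ c(s) ds`` over a peak is the loading signal of that peak.
    """

    s_grid: np.ndarray
    amplitudes: np.ndarray
    f_f0: float
    regularization: float
    rmsd_au: float
    degenerate: bool = False

    def __post_init__(self):
        self.s_grid = np.asarray(self.s_grid, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if np.any(np.diff(self.s_grid) <= 0):
            raise CsError("s grid must be strictly increasing")
        if self.amplitudes.shape != self.s_grid.shape:
            raise CsError("amplitudes and s grid shapes differ")
        if np.any(self.amplitudes < -1e-12):
            raise CsError("c(s) amplitudes must be nonnegative")

    def peaks(self) -> list[tuple[int, int]]:
        """Peak intervals [lo, hi) split at local minima of c(s).

        Ties are broken toward lower s (the split index is the first
        index attaining the local minimum).
        """
        c = self.amplitudes
        active = c > 1e-12 * max(c.max(), 1e-300)
        if not active.any():
            return []
        # find contiguous support blocks, then split each at interior minima
        blocks = []
        i = 0
        n = c.size
        while i < n:
            if not active[i]:
                i += 1
                continue
            j = i
            while j < n and active[j]:
                j += 1
            blocks.append((i, j))
            i = j
        out = []
        for lo, hi in blocks:
            seg = c[lo:hi]
            mins = [
                k
                for k in range(1, len(seg) - 1)
                if seg[k] <= seg[k - 1] and seg[k] < seg[k + 1]
            ]
            edges = [0] + mins + [len(seg)]
            for a, b in zip(edges[:-1], edges[1:]):
                out.append((lo + a, lo + b))
        return out


def _species_for(s: float, f_f0: float, vbar: float) -> HydroSpecies:
    return HydroSpecies(
        label=f"s={s:.4g}", s_svedberg=s, f_f0=f_f0, vbar_ml_g=vbar, signal_coeff=1.0
    )


def _simulate_library(
    scans: ScanSet,
    s_grid: np.ndarray,
    f_f0: float,
    vbar: float,
    n_cells: int,
) -> np.ndarray:
    """Noise-free unit-loading Lamm solutions, flattened over (t, r)."""
    experiment = CellExperiment(
        meniscus_cm=scans.meniscus_cm,
        bottom_cm=scans.bottom_cm,
        rpm=scans.rpm,
        scan_times_s=tuple(scans.times_s),
        temperature_c=scans.temperature_c,
    )
    cols = []
    s_cap = float(s_grid[-1])
    for s in s_grid:
        sim = simulate_boundaries(
            experiment,
            [_species_for(float(s), f_f0, vbar)],
            [1.0],
            n_cells=n_cells,
            s_cap_svedberg=s_cap,
            # unit boundary (plateau 1): amplitudes come out in AU
            pathlength_cm=1.0,
            radii_cm=scans.radii_cm,
        )
        cols.append(sim.signal_au.ravel())
    return np.column_stack(cols)


def _second_difference(n: int) -> np.ndarray:
    if n < 3:
        return np.zeros((0, n))
    mat = np.zeros((n - 2, n))
    for i in range(n - 2):
        mat[i, i : i + 3] = (1.0, -2.0, 1.0)
    return mat


def fit_cs(
    scans: ScanSet,
    s_grid: Optional[np.ndarray] = None,
    f_f0: Union[float, str] = 1.4,
    vbar_ml_g: float = 0.73,
    confidence: float = 0.683,
    skip_scans: int = 0,
    n_cells: int = 200,
    f_f0_grid: Optional[Sequence[float]] = None,
) -> CsDistribution:
    """Fit a regularized c(s) distribution to a scan set.

    Parameters
    ----------
    f_f0:
        Common frictional ratio of the distribution, or ``"fit"`` to
        scan over ``f_f0_grid`` (default 1.2–2.0) and keep the best.
    confidence:
        F-statistic confidence level for the regularization criterion;
        0.683 corresponds to one standard deviation.
    skip_scans:
        Drop this many early scans before fitting (large aggregates
        sediment quickly and contaminate early scans).
    """
    if skip_scans:
        scans = scans.skip_early(skip_scans)
    if scans.n_scans < 5:
        raise CsError(f"need at least 5 scans, got {scans.n_scans}")
    if s_grid is None:
        s_grid = default_s_grid()
    s_grid = np.asarray(s_grid, dtype=float)
    if np.any(np.diff(s_grid) <= 0):
        raise CsError("s grid must be strictly increasing (no duplicate s)")
    data = scans.signal_au.ravel()
    if not np.any(np.abs(data) > 0):
        raise CsError("all-zero signal; nothing to fit")

    if f_f0 == "fit":
        grid = list(f_f0_grid) if f_f0_grid is not None else [1.2, 1.4, 1.6, 1.8, 2.0]
        fits = [
            fit_cs(scans, s_grid, ff, vbar_ml_g, confidence, 0, n_cells)
            for ff in grid
        ]
        return min(fits, key=lambda d: d.rmsd_au)

    library = _simulate_library(scans, s_grid, float(f_f0), vbar_ml_g, n_cells)
    n_data, n_s = library.shape

    amps0, _ = nnls(library, data)
    resid0 = library @ amps0 - data
    chi2_0 = float(resid0 @ resid0)
    if chi2_0 == 0.0 and not np.any(amps0):
        return CsDistribution(
            s_grid, np.zeros(n_s), float(f_f0), 0.0, 0.0, degenerate=True
        )

    # target chi2 from the one-sigma F-ratio criterion
    dof = max(n_data - n_s, 1)
    f_crit = stats.f.ppf(confidence, n_s, dof)
    target = chi2_0 * (1.0 + n_s / dof * f_crit)

    smooth = _second_difference(n_s)
    col_scale = float(np.linalg.norm(library) / max(np.linalg.norm(smooth), 1e-300))

    def chi2_at(alpha: float) -> tuple[float, np.ndarray]:
        aug = np.vstack([library, alpha * col_scale * smooth])
        rhs = np.concatenate([data, np.zeros(smooth.shape[0])])
        amps, _ = nnls(aug, rhs)
        r = library @ amps - data
        return float(r @ r), amps

    lo, hi = 1e-6, 1.0
    chi_hi, amps_hi = chi2_at(hi)
    while chi_hi < target and hi < 1e6:
        hi *= 10.0
        chi_hi, amps_hi = chi2_at(hi)
    best_alpha, best_amps = hi, amps_hi
    for _ in range(40):
        mid = np.sqrt(lo * hi)
        chi_mid, amps_mid = chi2_at(mid)
        if chi_mid < target:
            lo = mid
        else:
            hi = mid
            best_alpha, best_amps = mid, amps_mid
        if hi / lo < 1.01:
            break

    ds = np.gradient(s_grid)
    density = best_amps / ds
    resid = library @ best_amps - data
    rmsd = float(np.sqrt(np.mean(resid**2)))
    return CsDistribution(
        s_grid,
        density,
        float(f_f0),
        float(best_alpha),
        rmsd,
        degenerate=not np.any(best_amps),
    )


def integrate_cs(
    dist: CsDistribution, s_range: Optional[tuple[float, float]] = None
) -> tuple[float, float]:
    """Integrate c(s): returns ``(loading signal in AU, sw in S)``.

    ``loading = ∫ c(s) ds`` and ``sw = ∫ s c(s) ds / ∫ c(s) ds`` over the
    requested range (default: the full grid).  Loading signal divided by
    the per-monomer signal coefficient and pathlength gives the µM
    loading concentration.
    """
    s = dist.s_grid
    c = dist.amplitudes
    if s_range is None:
        mask = np.ones_like(s, dtype=bool)
    else:
        lo, hi = s_range
        if lo > hi or hi < s[0] or lo > s[-1]:
            raise CsError(f"empty or out-of-grid s range {s_range}")
        mask = (s >= lo) & (s <= hi)
    if mask.sum() < 2:
        raise CsError("s range must cover at least two grid points")
    loading = float(np.trapezoid(c[mask], s[mask]))
    if loading <= 0:
        raise CsError("no signal in the requested s range")
    sw = float(np.trapezoid(s[mask] * c[mask], s[mask]) / loading)
    return loading, sw
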