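"""Mass-action speciation for self-associating proteins.

The central object is an :class:`AssociationScheme`: an ordered list of
oligomeric species (monomer, dimer, tetramer, ...) linked by *stepwise*
dissociation constants expressed in species molar concentrations.  Step
``j`` is the reaction ``p · reactant ⇌ product`` with
``p = n_product / n_reactant`` and

    Kd_j = [reactant]^p / [product]          (µM^(p-1))

so for the canonical monomer–dimer–tetramer chain the stepwise constants
are ``Kd1 = [M]^2/[D]`` and ``Kd2 = [D]^2/[T]``.  Under this convention a
weak monomer–dimer constant in the mM range can coexist with a µM-tight
dimer–tetramer step, producing a cooperatively formed tetramer: e.g. with
``Kd1 = 2.4 mM`` and ``Kd2 = 2.7 µM`` at 107 µM total, roughly 6 µM of
monomer-equivalents sit in the dimer and 14 µM in the tetramer.

All concentrations are handled in µM; mM values may be passed through the
``mM`` keyword helpers and are converted at the interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "AssociationScheme",
    "Speciation",
    "solve_speciation",
    "expected_s_nmer",
    "signal_weighted_s",
    "equal_population_total",
]

#: relative tolerance on the mass balance of a solved speciation
MASS_BALANCE_RTOL = 1e-9


class SchemeError(ValueError):
    """Invalid association scheme or speciation request."""


@dataclass(frozen=True)
class AssociationScheme:
    """Self-association scheme: species stoichiometries + stepwise Kds.

    Parameters
    ----------
    species:
        ``(label, n)`` pairs with ``n`` the number of monomer units per
        species.  Stoichiometries must be strictly increasing and start
        with the monomer (``n == 1``).
    stepwise_kds_uM:
        One stepwise dissociation constant per adjacent species pair, in
        µM (see module docstring for the convention).
    """

    species: tuple[tuple[str, int], ...]
    stepwise_kds_uM: tuple[float, ...]

    def __init__(self, species, stepwise_kds_uM):
        species = tuple((str(lab), int(n)) for lab, n in species)
        kds = tuple(float(k) for k in stepwise_kds_uM)
        ns = [n for _, n in species]
        if not ns or ns[0] != 1:
            raise SchemeError("scheme must contain the monomer (n=1) first")
        if any(b <= a for a, b in zip(ns, ns[1:])):
            raise SchemeError(f"stoichiometries must be strictly increasing, got {ns}")
        if len(kds) != len(species) - 1:
            raise SchemeError(
                f"need {len(species) - 1} stepwise Kds for {len(species)} species, got {len(kds)}"
            )
        if any(not np.isfinite(k) or k <= 0 for k in kds):
            raise SchemeError(f"all stepwise Kds must be positive and finite, got {kds}")
        object.__setattr__(self, "species", species)
        object.__setattr__(self, "stepwise_kds_uM", kds)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(lab for lab, _ in self.species)

    @property
    def stoichiometries(self) -> tuple[int, ...]:
        return tuple(n for _, n in self.species)

    @property
    def n_species(self) -> int:
        return len(self.species)

    def cumulative_constants(self) -> np.ndarray:
        """Overall constants K_j with [S_j] = [M]^{n_j} / K_j (µM^{n_j-1}).

        Built by chaining the stepwise constants:
        ``K_{j+1} = K_j^{p} · Kd_j`` with ``p = n_{j+1}/n_j``.
        """
        ns = self.stoichiometries
        out = np.empty(len(ns))
        out[0] = 1.0
        for j, kd in enumerate(self.stepwise_kds_uM):
            p = ns[j + 1] / ns[j]
            out[j + 1] = out[j] ** p * kd
        return out

    @classmethod
    def monomer_dimer_tetramer(
        cls, kd_mon_dim_uM: float, kd_dim_tet_uM: float
    ) -> "AssociationScheme":
        """The canonical weak-dimer / cooperative-tetramer scheme."""
        return cls(
            [("monomer", 1), ("dimer", 2), ("tetramer", 4)],
            [kd_mon_dim_uM, kd_dim_tet_uM],
        )


def mM(value: float) -> float:
    """Convert mM to the internal µM unit."""
    return float(value) * 1e3


@dataclass(frozen=True)
class Speciation:
    """Equilibrium composition at one total concentration.

    ``molar_uM`` are species molar concentrations; ``monomer_equiv_uM``
    are ``n × molar`` (the scale on which e.g. "6.2 µM is in the dimer
    form" is reported).
    """

    scheme: AssociationScheme
    total_uM: float
    molar_uM: np.ndarray
    monomer_equiv_uM: np.ndarray = field(init=False)

    def __post_init__(self):
        eq = self.molar_uM * np.asarray(self.scheme.stoichiometries, dtype=float)
        object.__setattr__(self, "monomer_equiv_uM", eq)

    @property
    def free_monomer_uM(self) -> float:
        return float(self.molar_uM[0])

    def monomer_equiv(self, label: str) -> float:
        """Monomer-equivalent concentration (µM) of one species by label."""
        return float(self.monomer_equiv_uM[self.scheme.labels.index(label)])

    def fraction(self, label: str) -> float:
        """Fraction of total monomer-equivalents in one species."""
        if self.total_uM == 0.0:
            return 1.0 if self.scheme.labels.index(label) == 0 else 0.0
        return self.monomer_equiv(label) / self.total_uM


def _free_monomer(total: float, ns: np.ndarray, kcum: np.ndarray) -> float:
    """Root of the mass balance  Σ n_j M^{n_j}/K_j = total  on [0, total]."""
    if total == 0.0:
        return 0.0

    def balance(m):
        return float(np.sum(ns * m**ns / kcum) - total)

    # the balance is strictly increasing in M; monomer alone gives balance(total) >= 0
    m = brentq(balance, 0.0, total, xtol=1e-300, rtol=8.9e-16)
    # one Newton polish (derivative is available in closed form)
    deriv = float(np.sum(ns**2 * m ** (ns - 1) / kcum))
    if deriv > 0:
        m -= balance(m) / deriv
    return min(max(m, 0.0), total)


def solve_speciation(total_uM: float, scheme: AssociationScheme) -> Speciation:
    """Solve the mass-action equilibrium at ``total_uM`` monomer-equivalents.

    Uses bracketed root finding on the monotone mass-balance function
    followed by a Newton polish; the returned composition satisfies the
    mass balance to a relative tolerance of 1e-9.
    """
    total = float(total_uM)
    if not np.isfinite(total) or total < 0:
        raise SchemeError(f"total concentration must be >= 0 and finite, got {total_uM}")
    ns = np.asarray(scheme.stoichiometries, dtype=float)
    kcum = scheme.cumulative_constants()
    m = _free_monomer(total, ns, kcum)
    molar = m**ns / kcum
    spec = Speciation(scheme=scheme, total_uM=total, molar_uM=molar)
    recon = float(np.sum(spec.monomer_equiv_uM))
    if total > 0 and abs(recon - total) > MASS_BALANCE_RTOL * total:
        raise RuntimeError(
            f"speciation root finding failed: mass balance {recon} vs total {total}"
        )
    return spec


def speciate_many(totals_uM: np.ndarray, scheme: AssociationScheme) -> np.ndarray:
    """Vectorized free-monomer solve; returns molar concentrations.

    Newton iteration on the free monomer with a bisection-safe clamp,
    operating on an array of totals at once (used per radial cell by the
    reacting Lamm solver).  Returns an array of shape
    ``(n_totals, n_species)`` of species molar concentrations in µM.
    """
    totals = np.asarray(totals_uM, dtype=float)
    ns = np.asarray(scheme.stoichiometries, dtype=float)
    kcum = scheme.cumulative_constants()
    m = totals.copy()  # start from all-monomer (upper bound of the root)
    pos = totals > 0
    for _ in range(60):
        if not pos.any():
            break
        mp = m[pos]
        powers = mp[:, None] ** ns[None, :]
        f = (powers * (ns / kcum)).sum(axis=1) - totals[pos]
        df = (mp[:, None] ** (ns[None, :] - 1.0) * (ns**2 / kcum)).sum(axis=1)
        step = f / df
        mp_new = np.clip(mp - step, 0.0, totals[pos])
        converged = np.abs(step) <= 1e-14 * np.maximum(mp_new, 1e-300)
        m[pos] = mp_new
        sub = np.zeros_like(pos)
        sub[pos] = ~converged
        pos = sub
    molar = m[:, None] ** ns[None, :] / kcum[None, :]
    molar[totals == 0] = 0.0
    return molar


def expected_s_nmer(n: int) -> float:
    """Smooth-sphere expectation for the s-ratio of an n-mer to its monomer.

    At equal partial specific volume and frictional ratio, mass scales as
    n and the Stokes radius as n^(1/3), so s scales as n^(2/3): a dimer
    is expected at ~1.587× the monomer s, a tetramer at ~2.52×.
    """
    if int(n) != n or n < 1:
        raise SchemeError(f"stoichiometry must be an integer >= 1, got {n!r}")
    return float(n) ** (2.0 / 3.0)


def signal_weighted_s(speciation: Speciation, s_values) -> float:
    """Signal-weighted average sedimentation coefficient, in S.

    Assumes an equal per-monomer signal coefficient across species (same
    chromophore count per monomer unit), so weights are the
    monomer-equivalent concentrations:  sw = Σ s_j n_j c_j / Σ n_j c_j.
    """
    s = np.asarray(s_values, dtype=float)
    if s.shape != (speciation.scheme.n_species,):
        raise SchemeError(
            f"need one s per species ({speciation.scheme.n_species}), got shape {s.shape}"
        )
    w = speciation.monomer_equiv_uM
    wsum = float(np.sum(w))
    if wsum <= 0:
        raise SchemeError("total signal is zero; weighted-average s undefined")
    return float(np.sum(s * w) / wsum)


def equal_population_total(
    scheme: AssociationScheme, label_a: str, label_b: str, upper_uM: float = 1e9
) -> float:
    """Total concentration (µM) at which two species hold equal
    monomer-equivalent concentrations (e.g. the monomer/tetramer
    crossover concentration of a two-state model)."""

    def gap(total):
        sp = solve_speciation(total, scheme)
        return sp.monomer_equiv(label_a) - sp.monomer_equiv(label_b)

    lo, hi = 1e-9, float(upper_uM)
    if gap(lo) * gap(hi) > 0:
        raise SchemeError("species populations do not cross within the search range")
    return float(brentq(gap, lo, hi, rtol=1e-12))
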