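"""Synthetic data generators for every pipeline stage.

These emulate the statistical structure of the study's raw data so the
whole analysis chain is testable without downloads: noisy absorbance
boundaries from a known association scheme, ideal helical-bundle
coordinate trajectories with controllable jitter and scripted
dissociation, and mutant tables with a prescribed true correlation.
Every generator is deterministic for a given seed and returns a
ground-truth manifest alongside the data.

The helix builder uses textbook α-helix geometry (1.5 Å rise and 100°
twist per residue emerge from standard backbone internal coordinates
with φ = −57°, ψ = −47°), so the generated bundles are ideal reference
structures, not physically realistic MD ensembles.
"""

from __future__ import annotations


from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .equilibria import AssociationScheme
from .lamm_forward import CellExperiment, HydroSpecies, ScanSet, simulate_boundaries
from .traj_analysis import TrajectoryEnsemble

__all__ = [
    "gen_auc_scans",
    "gen_helical_bundle",
    "gen_mutant_table",
    "build_ideal_helix",
    "THREE_LETTER",
]


class GeneratorError(ValueError):
    pass


# ---------------------------------------------------------------------------
# SV-AUC scan sets
# ---------------------------------------------------------------------------


def default_scan_radii(meniscus_cm: float, bottom_cm: float, n: int = 220) -> np.ndarray:
    """Radii of the usable optical window: the immediate meniscus and
    the steep back-diffusion region at the bottom are excluded, as in a
    routine fit range."""
    return np.linspace(meniscus_cm + 0.03, bottom_cm - 0.15, n)


def gen_auc_scans(
    seed: int,
    experiment: CellExperiment,
    species: Sequence[HydroSpecies],
    loadings_uM: Sequence[float],
    scheme: Optional[AssociationScheme] = None,
    noise_sd_au: float = 0.005,
    baseline_au: float = 0.0,
    n_cells: int = 300,
    cfl: float = 0.8,
    s_cap_svedberg: Optional[float] = 8.0,
    pathlength_cm: float = 0.3,
    radii_cm: Optional[np.ndarray] = None,
) -> tuple[list[ScanSet], dict]:
    """Forward-simulate scan sets and add i.i.d. Gaussian noise.

    One ScanSet is produced per loading concentration.  With a scheme,
    loadings are total µM monomer-equivalents of the equilibrium
    mixture; without, each loading is applied to a single species run.
    Returns ``(scan_sets, manifest)`` with the ground truth recorded.
    """
    if noise_sd_au < 0:
        raise GeneratorError("noise SD must be >= 0")
    rng = np.random.default_rng(seed)
    if radii_cm is None:
        radii_cm = default_scan_radii(experiment.meniscus_cm, experiment.bottom_cm)
    sets = []
    for load in loadings_uM:
        if scheme is not None:
            scans = simulate_boundaries(
                experiment,
                species,
                float(load),
                scheme=scheme,
                n_cells=n_cells,
                cfl=cfl,
                s_cap_svedberg=s_cap_svedberg,
                pathlength_cm=pathlength_cm,
                radii_cm=radii_cm,
            )
        else:
            scans = simulate_boundaries(
                experiment,
                species,
                [float(load)] * len(species) if np.isscalar(load) else load,
                n_cells=n_cells,
                cfl=cfl,
                s_cap_svedberg=s_cap_svedberg,
                pathlength_cm=pathlength_cm,
                radii_cm=radii_cm,
            )
        scans.signal_au = (
            scans.signal_au
            + baseline_au
            + rng.normal(0.0, noise_sd_au, scans.signal_au.shape)
        )
        scans.label = f"loading_{load}uM"
        sets.append(scans)
    manifest = {
        "seed": seed,
        "noise_sd_au": noise_sd_au,
        "baseline_au": baseline_au,
        "loadings_uM": [
            float(v) if np.isscalar(v) else [float(u) for u in v] for v in loadings_uM
        ],
        "species": [
            {"label": sp.label, "s_svedberg": sp.s_svedberg, "mass_da": sp.mass_da}
            for sp in species
        ],
        "scheme": None
        if scheme is None
        else {
            "species": [list(s) for s in scheme.species],
            "stepwise_kds_uM": list(scheme.stepwise_kds_uM),
        },
        "n_cells": n_cells,
        "pathlength_cm": pathlength_cm,
    }
    return sets, manifest


# ---------------------------------------------------------------------------
# ideal helical bundles
# ---------------------------------------------------------------------------

THREE_LETTER = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

# backbone internal coordinates (Å, degrees), Engh–Huber-like values
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_CA_CB = 1.458, 1.525, 1.329, 1.231, 1.530
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.8
_PHI_HELIX, _PSI_HELIX = -57.0, -47.0
_PHI_EXT, _PSI_EXT = 180.0, 180.0


def _nerf(a, b, c, bond, angle_deg, torsion_deg):
    """Place atom D given A-B-C with |CD|=bond, angle(BCD), dihedral(ABCD)."""
    angle = np.deg2rad(angle_deg)
    torsion = np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array(
        [
            -np.cos(angle),
            np.sin(angle) * np.cos(torsion),
            np.sin(angle) * np.sin(torsion),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_ideal_helix(
    sequence: str,
    first_resid: int = 1,
    phi: float = _PHI_HELIX,
    psi: float = _PSI_HELIX,
    with_cb: bool = True,
):
    """Build one chain with uniform (φ, ψ); returns atom records in Å.

    Output: list of (resid, resname, atom_name, element, xyz).  The
    default torsions give an ideal α-helix; φ = ψ = 180° gives a fully
    extended chain.  The helix axis is aligned with z and the first Cα
    placed near the origin after construction.
    """
    seq = sequence.upper()
    if any(aa not in THREE_LETTER for aa in seq):
        bad = sorted({aa for aa in seq if aa not in THREE_LETTER})
        raise GeneratorError(f"unknown residue letters {bad}")
    n_res = len(seq)
    if n_res < 2:
        raise GeneratorError("need at least two residues")
    # seed atoms of residue 0
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([_B_N_CA, 0.0, 0.0])
    ang = np.deg2rad(_A_N_CA_C)
    c0 = ca0 + _B_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    backbone = [(n0, ca0, c0)]
    for _ in range(1, n_res):
        n_prev, ca_prev, c_prev = backbone[-1]
        n_next = _nerf(n_prev, ca_prev, c_prev, _B_C_N, _A_CA_C_N, psi)
        ca_next = _nerf(ca_prev, c_prev, n_next, _B_N_CA, _A_C_N_CA, 180.0)
        c_next = _nerf(c_prev, n_next, ca_next, _B_CA_C, _A_N_CA_C, phi)
        backbone.append((n_next, ca_next, c_next))
    # virtual next N for the last carbonyl oxygen
    n_virt = _nerf(*backbone[-1], _B_C_N, _A_CA_C_N, psi)
    records = []
    for i, (aa, (n_xyz, ca_xyz, c_xyz)) in enumerate(zip(seq, backbone)):
        resid = first_resid + i
        resname = THREE_LETTER[aa]
        n_follow = backbone[i + 1][0] if i + 1 < n_res else n_virt
        o_xyz = _nerf(n_follow, ca_xyz, c_xyz, _B_C_O, _A_CA_C_O, 180.0)
        records.append((resid, resname, "N", "N", n_xyz))
        records.append((resid, resname, "CA", "C", ca_xyz))
        records.append((resid, resname, "C", "C", c_xyz))
        records.append((resid, resname, "O", "O", o_xyz))
        if with_cb and aa != "G":
            cb_xyz = _nerf(c_xyz, n_xyz, ca_xyz, _B_CA_CB, 110.5, -122.6)
            records.append((resid, resname, "CB", "C", cb_xyz))
    # align the principal axis of the Ca trace with z
    ca = np.array([r[4] for r in records if r[2] == "CA"])
    center = ca.mean(axis=0)
    _, _, vt = np.linalg.svd(ca - center)
    axis = vt[0]
    if axis[2] < 0:
        axis = -axis
    zhat = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis, zhat)
    s = np.linalg.norm(v)
    if s > 1e-12:
        c = float(axis @ zhat)
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        rot = np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)
    else:
        rot = np.eye(3)
    records = [
        (rid, rn, an, el, rot @ (xyz - center)) for rid, rn, an, el, xyz in records
    ]
    return records


def gen_helical_bundle(
    seed: int,
    n_chains: int = 4,
    arrangement: str = "antiparallel",
    inter_axis_nm: float = 1.0,
    sequence: str = "A" * 41,
    first_resid: int = 310,
    n_frames: int = 10,
    jitter_nm: float = 0.0,
    dissociation: Optional[dict] = None,
    extended: bool = False,
) -> tuple[TrajectoryEnsemble, dict]:
    """Generate an ideal helical-bundle trajectory.

    Chains are ideal α-helices (or fully extended strands with
    ``extended=True``) placed on a regular polygon with the given
    axis-to-axis spacing; in the ``antiparallel`` arrangement adjacent
    chains alternate direction (the four-fold tetramer topology with
    antiparallel neighbors), in ``parallel`` all run the same way.
    Frames add i.i.d. Gaussian coordinate jitter; an optional
    ``dissociation`` script ``{"chain": k, "start": f0, "stop": f1,
    "displacement_nm": d}`` translates one chain radially outward for a
    frame window, providing ground truth for episode detection.
    """
    if n_chains < 1:
        raise GeneratorError("need at least one chain")
    if inter_axis_nm <= 0:
        raise GeneratorError("inter-axis spacing must be positive")
    if jitter_nm < 0:
        raise GeneratorError("jitter must be >= 0")
    rng = np.random.default_rng(seed)
    phi, psi = (_PHI_EXT, _PSI_EXT) if extended else (_PHI_HELIX, _PSI_HELIX)
    chain_records = build_ideal_helix(sequence, first_resid, phi=phi, psi=psi)
    base_xyz_nm = np.array([r[4] for r in chain_records]) / 10.0
    chain_ids, resids, resnames, atom_names, elements = [], [], [], [], []
    coords0 = []
    if n_chains == 1:
        centers = [np.zeros(2)]
    else:
        radius = inter_axis_nm / (2.0 * np.sin(np.pi / n_chains))
        angles = 2.0 * np.pi * np.arange(n_chains) / n_chains
        centers = [radius * np.array([np.cos(a), np.sin(a)]) for a in angles]
    flip = np.diag([1.0, -1.0, -1.0])  # 180° about x: reverses chain direction
    for k in range(n_chains):
        xyz = base_xyz_nm.copy()
        if arrangement == "antiparallel" and k % 2 == 1:
            xyz = xyz @ flip.T
        elif arrangement not in ("antiparallel", "parallel"):
            raise GeneratorError(f"arrangement must be parallel|antiparallel, got {arrangement!r}")
        xyz = xyz + np.array([centers[k][0], centers[k][1], 0.0])
        coords0.append(xyz)
        cid = chr(ord("A") + k)
        for rid, rn, an, el, _ in chain_records:
            chain_ids.append(cid)
            resids.append(rid)
            resnames.append(rn)
            atom_names.append(an)
            elements.append(el)
    coords0 = np.concatenate(coords0, axis=0)

    if n_chains > 1:
        from scipy.spatial.distance import cdist

        per_chain = base_xyz_nm.shape[0]
        for i in range(n_chains):
            for j in range(i + 1, n_chains):
                d = cdist(
                    coords0[i * per_chain : (i + 1) * per_chain],
                    coords0[j * per_chain : (j + 1) * per_chain],
                ).min()
                if d < 0.15:
                    raise GeneratorError(
                        f"chains {i} and {j} clash at {d:.3f} nm; "
                        "increase inter_axis_nm"
                    )

    frames = np.tile(coords0[None], (n_frames, 1, 1))
    if jitter_nm > 0:
        frames = frames + rng.normal(0.0, jitter_nm, frames.shape)
    episodes_truth = []
    if dissociation is not None:
        k = int(dissociation["chain"])
        f0, f1 = int(dissociation["start"]), int(dissociation["stop"])
        disp = float(dissociation["displacement_nm"])
        per_chain = base_xyz_nm.shape[0]
        direction = np.append(centers[k], 0.0)
        norm = np.linalg.norm(direction)
        direction = direction / norm if norm > 0 else np.array([1.0, 0.0, 0.0])
        frames[f0:f1, k * per_chain : (k + 1) * per_chain] += disp * direction
        episodes_truth.append((f0, f1))
    traj = TrajectoryEnsemble(
        coords_nm=frames,
        chain_ids=np.array(chain_ids),
        resids=np.array(resids),
        resnames=np.array(resnames),
        atom_names=np.array(atom_names),
        elements=np.array(elements),
    )
    manifest = {
        "seed": seed,
        "n_chains": n_chains,
        "arrangement": arrangement,
        "inter_axis_nm": inter_axis_nm,
        "sequence": sequence,
        "first_resid": first_resid,
        "n_frames": n_frames,
        "jitter_nm": jitter_nm,
        "extended": extended,
        "dissociation_episodes": episodes_truth,
    }
    return traj, manifest


# ---------------------------------------------------------------------------
# mutant tables
# ---------------------------------------------------------------------------


def gen_mutant_table(
    seed: int,
    n_variants: int = 18,
    true_rho: float = -0.94,
    noise_sd: float = 0.0,
    spread: float = 0.15,
) -> tuple["pd.DataFrame", dict]:
    """Mutant panel with a prescribed true correlation structure.

    Variant pairs (c_sat, CSP_norm) are drawn from a bivariate normal
    with correlation ``true_rho`` and mapped affinely onto positive
    WT-normalized scales centered at 1 (relative spread ``spread``), so
    the population Pearson correlation is exactly ``true_rho`` when
    ``noise_sd`` is zero.  A WT row anchored at exactly (1, 1) is
    included as the normalization anchor, flagged so it does not enter
    correlations as a datum.
    """
    if not -1.0 <= true_rho <= 1.0:
        raise GeneratorError(f"true correlation must lie in [-1, 1], got {true_rho}")
    if noise_sd < 0:
        raise GeneratorError("noise must be >= 0")
    rng = np.random.default_rng(seed)
    z1 = rng.standard_normal(n_variants)
    if abs(true_rho) == 1.0:
        z2 = np.sign(true_rho) * z1
    else:
        z2 = true_rho * z1 + np.sqrt(1.0 - true_rho**2) * rng.standard_normal(n_variants)
    if noise_sd > 0:
        z1 = z1 + rng.normal(0.0, noise_sd, n_variants)
        z2 = z2 + rng.normal(0.0, noise_sd, n_variants)
    csat = 1.0 + spread * z1
    csp = 1.0 + spread * z2
    rows = [
        {
            "variant": "WT",
            "csat_mean": 1.0,
            "csat_sd": 0.0,
            "csp_norm": 1.0,
            "n_contact": np.nan,
            "toxicity": np.nan,
            "excluded": True,
            "exclusion_reason": "normalization_anchor",
        }
    ]
    for i in range(n_variants):
        rows.append(
            {
                "variant": f"V{i + 1:02d}A",
                "csat_mean": float(csat[i]),
                "csat_sd": float(abs(spread * 0.1)),
                "csp_norm": float(csp[i]),
                "n_contact": np.nan,
                "toxicity": np.nan,
                "excluded": False,
                "exclusion_reason": "",
            }
        )
    table = pd.DataFrame(rows)
    manifest = {
        "seed": seed,
        "n_variants": n_variants,
        "true_rho": true_rho,
        "noise_sd": noise_sd,
        "spread": spread,
    }
    return table, manifest
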