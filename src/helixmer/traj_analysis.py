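"""Structural statistics over multimer coordinate ensembles.

Operations used to characterize helical-bundle assemblies from
molecular-dynamics trajectories and predicted multimer models:
superposition-free distance-RMS deviation (dRMS), heavy-atom contact
maps and per-residue contact totals, Kabsch–Sander α-helix assignment,
minimum inter-chain distances with dissociation-episode detection,
GROMOS conformational clustering, and the AlphaFold2-Multimer model
confidence score.

Coordinates are stored in nm with UniProt-based residue numbering kept
verbatim (e.g. the conserved region of the TDP-43 C-terminal domain is
residues 319–341 of a 310–350 fragment).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist, pdist

__all__ = [
    "TrajectoryEnsemble",
    "ContactMap",
    "drms_series",
    "contact_map",
    "contact_totals",
    "helix_fraction",
    "min_interchain_distance",
    "cluster_gromos",
    "af2_confidence",
    "kabsch_rmsd",
]

#: heavy-atom contact cutoff, nm
CONTACT_CUTOFF_NM = 0.6
#: minimum intra-chain sequence separation for a countable contact
CONTACT_MIN_SEP = 3
#: dRMS above which a multimer is considered to have lost its fold, nm
DRMS_INSTABILITY_NM = 1.0

_HYDROGEN = {"H", "D"}


class TrajError(ValueError):
    pass


@dataclass
class TrajectoryEnsemble:
    """Frames x atoms coordinate ensemble with chain/residue metadata.

    ``coords_nm`` has shape (n_frames, n_atoms, 3).  ``resids`` carry
    the author-assigned (UniProt-based) numbering; atoms are grouped by
    (chain, resid) into residues in order of first appearance.
    """

    coords_nm: np.ndarray
    chain_ids: np.ndarray
    resids: np.ndarray
    resnames: np.ndarray
    atom_names: np.ndarray
    elements: np.ndarray
    times_ns: Optional[np.ndarray] = None

    def __post_init__(self):
        self.coords_nm = np.asarray(self.coords_nm, dtype=float)
        if self.coords_nm.ndim == 2:
            self.coords_nm = self.coords_nm[None]
        for name in ("chain_ids", "resids", "resnames", "atom_names", "elements"):
            setattr(self, name, np.asarray(getattr(self, name)))
        n_atoms = self.coords_nm.shape[1]
        for name in ("chain_ids", "resids", "resnames", "atom_names", "elements"):
            if getattr(self, name).shape != (n_atoms,):
                raise TrajError(f"{name} must have one entry per atom ({n_atoms})")
        if not np.all(np.isfinite(self.coords_nm)):
            raise TrajError("coordinates must be finite")
        if self.times_ns is not None:
            self.times_ns = np.asarray(self.times_ns, dtype=float)
            if self.times_ns.shape != (self.n_frames,):
                raise TrajError("times must have one entry per frame")

    @property
    def n_frames(self) -> int:
        return int(self.coords_nm.shape[0])

    @property
    def n_atoms(self) -> int:
        return int(self.coords_nm.shape[1])

    @property
    def heavy(self) -> np.ndarray:
        """Boolean mask of non-hydrogen atoms."""
        return ~np.isin(np.char.upper(self.elements.astype(str)), list(_HYDROGEN))

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chain_ids:
            seen.setdefault(str(c), None)
        return list(seen)

    def residue_index(self) -> tuple[np.ndarray, list[tuple[str, int]]]:
        """Per-atom residue index and the (chain, resid) residue list."""
        keys: dict[tuple[str, int], int] = {}
        idx = np.empty(self.n_atoms, dtype=int)
        for i, (c, r) in enumerate(zip(self.chain_ids, self.resids)):
            key = (str(c), int(r))
            idx[i] = keys.setdefault(key, len(keys))
        return idx, list(keys)

    def select(
        self,
        residue_range: Optional[tuple[int, int]] = None,
        chains: Optional[Sequence[str]] = None,
        heavy_only: bool = False,
        atom_names: Optional[Sequence[str]] = None,
    ) -> np.ndarray:
        """Boolean atom mask by residue range, chain, heaviness, name."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if residue_range is not None:
            lo, hi = residue_range
            mask &= (self.resids.astype(int) >= lo) & (self.resids.astype(int) <= hi)
        if chains is not None:
            mask &= np.isin(self.chain_ids.astype(str), list(chains))
        if heavy_only:
            mask &= self.heavy
        if atom_names is not None:
            mask &= np.isin(self.atom_names.astype(str), list(atom_names))
        return mask

    def subset_atoms(self, mask: np.ndarray) -> "TrajectoryEnsemble":
        return TrajectoryEnsemble(
            self.coords_nm[:, mask],
            self.chain_ids[mask],
            self.resids[mask],
            self.resnames[mask],
            self.atom_names[mask],
            self.elements[mask],
            self.times_ns,
        )

    def subset_frames(self, frames) -> "TrajectoryEnsemble":
        return TrajectoryEnsemble(
            self.coords_nm[frames],
            self.chain_ids,
            self.resids,
            self.resnames,
            self.atom_names,
            self.elements,
            None if self.times_ns is None else self.times_ns[frames],
        )


@dataclass
class ContactMap:
    """Residue x residue contact probabilities in [0, 1]."""

    matrix: np.ndarray
    residues: list[tuple[str, int]]
    cutoff_nm: float = CONTACT_CUTOFF_NM
    min_sep: int = CONTACT_MIN_SEP
    mode: str = "both"
    per_replica: Optional[np.ndarray] = None  # (n_replicas, n_res, n_res)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.residues)
        if self.matrix.shape != (n, n):
            raise TrajError("contact matrix shape does not match residue list")
        if not np.allclose(self.matrix, self.matrix.T):
            raise TrajError("contact matrix must be symmetric")
        if self.matrix.min() < -1e-12 or self.matrix.max() > 1 + 1e-12:
            raise TrajError("contact probabilities must lie in [0, 1]")


# ---------------------------------------------------------------------------
# dRMS
# ---------------------------------------------------------------------------


def drms_series(
    traj: TrajectoryEnsemble,
    reference: Optional[np.ndarray] = None,
    residue_range: tuple[int, int] = (320, 341),
    heavy_only: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Superposition-free distance-RMS deviation per frame, in nm.

    dRMS(t) = sqrt( 2/(N(N-1)) * sum_{i<j} (d_ij(t) - d_ij(ref))^2 )
    over all selected atom pairs, intra- and inter-chain, so it is
    invariant under rigid-body motion of the whole assembly.  Returns
    ``(drms, unstable)`` where ``unstable`` flags frames with
    dRMS > 1 nm (loss of the starting fold).
    """
    mask = traj.select(residue_range=residue_range, heavy_only=heavy_only)
    if not mask.any():
        raise TrajError("empty atom selection for dRMS")
    coords = traj.coords_nm[:, mask]
    if reference is None:
        ref = coords[0]
    else:
        ref = np.asarray(reference, dtype=float)
        if ref.ndim == 3:
            ref = ref[0]
        if ref.shape[0] == traj.n_atoms:
            ref = ref[mask]
        if ref.shape != coords.shape[1:]:
            raise TrajError(
                f"reference atom set {ref.shape} does not match selection "
                f"{coords.shape[1:]}"
            )
    d_ref = pdist(ref)
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        diff = pdist(coords[f]) - d_ref
        out[f] = np.sqrt(np.mean(diff**2))
    return out, out > DRMS_INSTABILITY_NM


# ---------------------------------------------------------------------------
# contacts
# ---------------------------------------------------------------------------


def _frame_contacts(
    coords: np.ndarray,
    res_idx: np.ndarray,
    n_res: int,
) -> np.ndarray:
    """Boolean residue-pair contact matrix for one frame (min-distance)."""
    d = cdist(coords, coords)
    mins = np.full((n_res, n_res), np.inf)
    np.minimum.at(mins, (res_idx[:, None], res_idx[None, :]), d)
    return mins


def contact_map(
    traj: TrajectoryEnsemble | Sequence[TrajectoryEnsemble],
    cutoff_nm: float = CONTACT_CUTOFF_NM,
    min_sep: int = CONTACT_MIN_SEP,
    mode: str = "both",
    drop_frames: int = 0,
    equilibration_ns: Optional[float] = None,
    average_replicas: bool = True,
) -> ContactMap:
    """Residue-residue contact probability map.

    Two residues are in contact in a frame when any two of their heavy
    atoms are within ``cutoff_nm`` (0.6 nm default).  The sequence
    separation rule |i-j| > ``min_sep`` applies within a chain only;
    inter-chain pairs are always eligible.  ``mode`` selects ``inter``,
    ``intra`` or ``both`` kinds of pairs.  Frames before
    ``equilibration_ns`` (or the first ``drop_frames`` frames) are
    discarded as equilibration.  A list of trajectories is treated as
    replicas; the returned matrix is their mean, with the per-replica
    stack attached.
    """
    if cutoff_nm <= 0:
        raise TrajError("cutoff must be positive")
    if isinstance(traj, TrajectoryEnsemble):
        replicas = [traj]
    else:
        replicas = list(traj)
    mats = []
    residues = None
    for rep in replicas:
        if equilibration_ns is not None:
            if rep.times_ns is None:
                raise TrajError("equilibration_ns given but frames carry no times")
            keep = rep.times_ns >= equilibration_ns
            rep = rep.subset_frames(np.nonzero(keep)[0])
        elif drop_frames:
            rep = rep.subset_frames(slice(drop_frames, None))
        if rep.n_frames == 0:
            raise TrajError("no frames left after equilibration drop")
        heavy = rep.subset_atoms(rep.heavy)
        res_idx, res_list = heavy.residue_index()
        if residues is None:
            residues = res_list
        elif res_list != residues:
            raise TrajError("replicas have differing residue sets")
        n_res = len(res_list)
        chains = np.array([c for c, _ in res_list])
        nums = np.array([r for _, r in res_list])
        same_chain = chains[:, None] == chains[None, :]
        sep_ok = np.abs(nums[:, None] - nums[None, :]) > min_sep
        eligible = np.where(same_chain, sep_ok, True)
        if mode == "inter":
            eligible &= ~same_chain
        elif mode == "intra":
            eligible &= same_chain
        elif mode != "both":
            raise TrajError(f"mode must be inter|intra|both, got {mode!r}")
        acc = np.zeros((n_res, n_res))
        for f in range(heavy.n_frames):
            mins = _frame_contacts(heavy.coords_nm[f], res_idx, n_res)
            acc += (mins < cutoff_nm) & eligible
        mats.append(acc / heavy.n_frames)
    stack = np.stack(mats)
    mean = stack.mean(axis=0) if average_replicas else stack[0]
    return ContactMap(
        matrix=mean,
        residues=residues,
        cutoff_nm=cutoff_nm,
        min_sep=min_sep,
        mode=mode,
        per_replica=stack,
    )


def contact_totals(
    maps: ContactMap | Sequence[ContactMap],
    n_blocks: Optional[int] = None,
) -> dict:
    """Per-residue total contacts N_contact(i) = sum_j map(i, j), ±SEM.

    SEM is taken across replicas (the per-replica stack of a single
    averaged map, or a sequence of maps, e.g. one per time block).
    """
    if isinstance(maps, ContactMap):
        if maps.per_replica is None or maps.per_replica.shape[0] < 2:
            raise TrajError("need >= 2 replicas or blocks to compute a SEM")
        stack = maps.per_replica
        residues = maps.residues
    else:
        maps = list(maps)
        if len(maps) < 2:
            raise TrajError("need >= 2 replicas or blocks to compute a SEM")
        residues = maps[0].residues
        for m in maps[1:]:
            if m.residues != residues:
                raise TrajError("contact maps cover different residue sets")
        stack = np.stack([m.matrix for m in maps])
    if n_blocks is not None and stack.shape[0] != n_blocks:
        raise TrajError(f"expected {n_blocks} blocks, got {stack.shape[0]}")
    totals = stack.sum(axis=2)  # (n_rep, n_res)
    mean = totals.mean(axis=0)
    sem = totals.std(axis=0, ddof=1) / np.sqrt(totals.shape[0])
    return {"residues": residues, "mean": mean, "sem": sem, "per_replica": totals}


def block_contact_maps(
    traj: TrajectoryEnsemble,
    n_blocks: int = 5,
    **kwargs,
) -> list[ContactMap]:
    """Contact maps over contiguous equal time blocks of a single run."""
    drop = kwargs.pop("drop_frames", 0)
    work = traj.subset_frames(slice(drop, None))
    edges = np.linspace(0, work.n_frames, n_blocks + 1).astype(int)
    if np.any(np.diff(edges) == 0):
        raise TrajError(f"too few frames ({work.n_frames}) for {n_blocks} blocks")
    return [
        contact_map(work.subset_frames(slice(a, b)), **kwargs)
        for a, b in zip(edges[:-1], edges[1:])
    ]


# ---------------------------------------------------------------------------
# Kabsch–Sander helix assignment
# ---------------------------------------------------------------------------

_HB_ENERGY_CUT = -0.5  # kcal/mol
_Q_FACTOR = 0.084 * 332.0  # kcal/mol * Angstrom, Kabsch–Sander constant


def _place_amide_h(n_xyz, ca_xyz, c_prev_xyz) -> np.ndarray:
    """Geometric amide hydrogen: 1.01 Å from N, opposite the
    bisector of the N–C(prev) and N–CA bonds."""
    d1 = n_xyz - c_prev_xyz
    d2 = n_xyz - ca_xyz
    d1 /= np.linalg.norm(d1, axis=-1, keepdims=True)
    d2 /= np.linalg.norm(d2, axis=-1, keepdims=True)
    bis = d1 + d2
    bis /= np.linalg.norm(bis, axis=-1, keepdims=True)
    return n_xyz + 0.101 * bis  # nm


def helix_fraction(
    traj: TrajectoryEnsemble,
    residue_range: Optional[tuple[int, int]] = None,
) -> dict:
    """Per-residue α-helix fraction by Kabsch–Sander rules.

    A backbone hydrogen bond CO(i)...HN(j) is assigned when the
    electrostatic energy

        E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)  kcal/mol

    falls below −0.5 kcal/mol (distances in Å).  A minimal α-helix
    requires two consecutive i→i+4 turns; residues of such stretches
    count as helical (DSSP state H; 3_10 and π helices are not counted).
    Amide hydrogens are placed geometrically when absent.  Residues with
    missing backbone atoms are reported as NaN, never silently zero.
    """
    chains = traj.chains
    per_res: dict[tuple[str, int], list] = {}
    counts: dict[tuple[str, int], float] = {}
    order: list[tuple[str, int]] = []
    for chain in chains:
        cmask = traj.chain_ids.astype(str) == chain
        resids = np.unique(traj.resids[cmask].astype(int))
        resids.sort()
        atom_idx = {}
        ok = {}
        for rid in resids:
            rmask = cmask & (traj.resids.astype(int) == rid)
            names = traj.atom_names[rmask].astype(str)
            pos = np.nonzero(rmask)[0]
            entry = {}
            for needed in ("N", "CA", "C", "O"):
                hit = pos[names == needed]
                entry[needed] = int(hit[0]) if hit.size else None
            hpos = pos[np.isin(names, ["H", "HN", "H1"])]
            entry["H"] = int(hpos[0]) if hpos.size else None
            atom_idx[rid] = entry
            ok[rid] = all(entry[a] is not None for a in ("N", "CA", "C", "O"))
            order.append((chain, int(rid)))
        nres = len(resids)
        helical = np.zeros((traj.n_frames, nres), dtype=bool)
        assignable = np.array([ok[r] for r in resids])
        # i -> i+4 backbone hydrogen bonds, then two consecutive turns
        turn = np.zeros((traj.n_frames, nres), dtype=bool)
        for k in range(nres - 4):
            rid_a, rid_d = resids[k], resids[k + 4]
            if rid_d - rid_a != 4:
                continue  # chain break in numbering
            a, d = atom_idx[rid_a], atom_idx[rid_d]
            if not (ok[rid_a] and ok[rid_d]):
                continue
            prev_rid = resids[k + 3]
            prev = atom_idx.get(prev_rid)
            c_xyz = traj.coords_nm[:, a["C"]]
            o_xyz = traj.coords_nm[:, a["O"]]
            n_xyz = traj.coords_nm[:, d["N"]]
            if d["H"] is not None:
                h_xyz = traj.coords_nm[:, d["H"]]
            else:
                if prev is None or prev["C"] is None or d["CA"] is None:
                    continue
                h_xyz = _place_amide_h(
                    n_xyz, traj.coords_nm[:, d["CA"]], traj.coords_nm[:, prev["C"]]
                )
            # Kabsch–Sander energy; distances converted nm -> Å
            def inv(a_xyz, b_xyz):
                return 1.0 / (10.0 * np.linalg.norm(a_xyz - b_xyz, axis=-1))

            energy = _Q_FACTOR * (
                inv(o_xyz, n_xyz) + inv(c_xyz, h_xyz) - inv(o_xyz, h_xyz) - inv(c_xyz, n_xyz)
            )
            turn[:, k] = energy < _HB_ENERGY_CUT
        for k in range(1, nres - 4):
            both = turn[:, k - 1] & turn[:, k]
            helical[:, k : k + 4] |= both[:, None]
        frac = helical.mean(axis=0)
        for j, rid in enumerate(resids):
            key = (chain, int(rid))
            counts[key] = float(frac[j]) if assignable[j] else np.nan
    if residue_range is not None:
        lo, hi = residue_range
        order = [(c, r) for c, r in order if lo <= r <= hi]
    return {
        "residues": order,
        "fraction": np.array([counts[k] for k in order]),
    }


# ---------------------------------------------------------------------------
# inter-chain distances
# ---------------------------------------------------------------------------


def min_interchain_distance(
    traj: TrajectoryEnsemble,
    chain_a: str,
    chain_b: str,
    threshold_nm: float = CONTACT_CUTOFF_NM,
    min_dwell_frames: int = 1,
) -> dict:
    """Per-frame minimum heavy-atom distance between two chains, in nm.

    Dissociation episodes are maximal runs of frames with the minimum
    distance above ``threshold_nm`` lasting at least
    ``min_dwell_frames``; reported as (start, stop) frame slices.
    """
    if chain_a == chain_b:
        raise TrajError("need two distinct chains")
    mask_a = traj.select(chains=[chain_a], heavy_only=True)
    mask_b = traj.select(chains=[chain_b], heavy_only=True)
    if not mask_a.any():
        raise TrajError(f"chain {chain_a!r} absent or has no heavy atoms")
    if not mask_b.any():
        raise TrajError(f"chain {chain_b!r} absent or has no heavy atoms")
    a = traj.coords_nm[:, mask_a]
    b = traj.coords_nm[:, mask_b]
    mins = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        mins[f] = cdist(a[f], b[f]).min()
    apart = mins > threshold_nm
    episodes = []
    start = None
    for f, flag in enumerate(apart):
        if flag and start is None:
            start = f
        elif not flag and start is not None:
            if f - start >= min_dwell_frames:
                episodes.append((start, f))
            start = None
    if start is not None and traj.n_frames - start >= min_dwell_frames:
        episodes.append((start, traj.n_frames))
    return {"min_distance_nm": mins, "episodes": episodes}


# ---------------------------------------------------------------------------
# GROMOS clustering
# ---------------------------------------------------------------------------


def kabsch_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """RMSD after optimal least-squares superposition (Kabsch), nm."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    h = a.T @ b
    u, _, vt = np.linalg.svd(h)
    sign = np.sign(np.linalg.det(u @ vt))
    d = np.diag([1.0, 1.0, sign])
    rot = u @ d @ vt
    diff = a @ rot - b
    return float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))


def cluster_gromos(
    traj: TrajectoryEnsemble,
    residue_range: tuple[int, int] = (320, 341),
    atom_names: Sequence[str] = ("N", "CA", "C", "O"),
    cutoff_nm: float = 0.3,
    window: Optional[slice] = None,
) -> list[dict]:
    """GROMOS conformational clustering on backbone RMSD.

    Pairwise RMSDs (after Kabsch superposition) are computed over the
    selected atoms within the analysis ``window`` (e.g. the last
    microsecond).  Iteratively, the frame with the most neighbors
    within ``cutoff_nm`` becomes a cluster center (ties broken toward
    the earliest frame), the cluster is removed, and the process
    repeats.  Clusters are returned sorted by size, each with its
    center frame and member list (original frame indices).
    """
    work = traj if window is None else traj.subset_frames(window)
    offset = window.start or 0 if window is not None else 0
    mask = work.select(residue_range=residue_range, atom_names=atom_names)
    if not mask.any():
        raise TrajError("empty atom selection for clustering")
    coords = work.coords_nm[:, mask]
    n = coords.shape[0]
    if n == 0:
        raise TrajError("no frames in clustering window")
    rmsd = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            rmsd[i, j] = rmsd[j, i] = kabsch_rmsd(coords[i], coords[j])
    neighbor = rmsd <= cutoff_nm
    remaining = np.ones(n, dtype=bool)
    clusters = []
    while remaining.any():
        counts = (neighbor & remaining[None, :]).sum(axis=1)
        counts[~remaining] = -1
        center = int(np.argmax(counts))  # argmax takes the earliest on ties
        members = np.nonzero(neighbor[center] & remaining)[0]
        clusters.append(
            {
                "center_frame": center + offset,
                "members": [int(m) + offset for m in members],
                "size": int(members.size),
            }
        )
        remaining[members] = False
    clusters.sort(key=lambda c: (-c["size"], c["center_frame"]))
    return clusters


def af2_confidence(iptm: float, ptm: float) -> float:
    """AlphaFold2-Multimer model confidence: 0.8·ipTM + 0.2·pTM."""
    for name, v in (("iptm", iptm), ("ptm", ptm)):
        if not (0.0 <= v <= 1.0):
            raise TrajError(f"{name} must lie in [0, 1], got {v}")
    return 0.8 * iptm + 0.2 * ptm
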