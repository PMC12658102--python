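"""dRMS, contacts, helicity, mindist, clustering: oracles and invariants."""

import numpy as np
import pytest

from helixmer.synthetic_data import gen_helical_bundle
from helixmer.traj_analysis import (
    ContactMap,
    TrajectoryEnsemble,
    TrajError,
    af2_confidence,
    cluster_gromos,
    contact_map,
    contact_totals,
    block_contact_maps,
    drms_series,
    helix_fraction,
    kabsch_rmsd,
    min_interchain_distance,
)


def make_traj(coords, chains=None, resids=None, names=None, elements=None):
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    n = coords.shape[1]
    return TrajectoryEnsemble(
        coords_nm=coords,
        chain_ids=np.array(chains if chains is not None else ["A"] * n),
        resids=np.array(resids if resids is not None else np.arange(320, 320 + n)),
        resnames=np.array(["ALA"] * n),
        atom_names=np.array(names if names is not None else ["CA"] * n),
        elements=np.array(elements if elements is not None else ["C"] * n),
    )


def random_rotation(rng):
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


class TestDrms:
    def test_identical_frame_gives_zero(self):
        rng = np.random.default_rng(0)
        xyz = rng.uniform(0, 2, (8, 3))
        traj = make_traj(np.stack([xyz, xyz]))
        drms, unstable = drms_series(traj)
        assert np.allclose(drms, 0.0)
        assert not unstable.any()

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(1)
        xyz = rng.uniform(0, 2, (10, 3))
        frames = [xyz]
        for _ in range(5):
            frames.append(xyz @ random_rotation(rng).T + rng.uniform(-3, 3, 3))
        drms, _ = drms_series(make_traj(np.stack(frames)))
        assert np.all(drms < 1e-12)

    def test_frame_order_permutation(self):
        rng = np.random.default_rng(2)
        frames = rng.uniform(0, 2, (6, 7, 3))
        ref = frames[0]
        traj = make_traj(frames)
        perm = [0, 3, 1, 5, 2, 4]
        shuffled = make_traj(frames[perm])
        a, _ = drms_series(traj, reference=ref)
        b, _ = drms_series(shuffled, reference=ref)
        assert np.allclose(a[perm], b)

    def test_two_atom_single_pair(self):
        ref = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        frame = np.array([[0.0, 0, 0], [1.5, 0, 0]])
        drms, unstable = drms_series(make_traj(np.stack([ref, frame])))
        assert drms[1] == pytest.approx(0.5, rel=1e-12)
        assert not unstable[1]

    def test_instability_flag_above_1nm(self):
        ref = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        frame = np.array([[0.0, 0, 0], [2.5, 0, 0]])
        drms, unstable = drms_series(make_traj(np.stack([ref, frame])))
        assert drms[1] == pytest.approx(1.5)
        assert unstable[1]

    def test_mismatched_reference_rejected(self):
        traj = make_traj(np.zeros((1, 4, 3)))
        with pytest.raises(TrajError):
            drms_series(traj, reference=np.zeros((9, 3)))


def brute_force_contacts(traj, cutoff, min_sep, mode="both"):
    """Exhaustive O(N^2) oracle over heavy-atom pairs."""
    heavy = traj.subset_atoms(traj.heavy)
    idx, residues = heavy.residue_index()
    n = len(residues)
    out = np.zeros((n, n))
    for f in range(heavy.n_frames):
        hit = np.zeros((n, n), dtype=bool)
        xyz = heavy.coords_nm[f]
        for a in range(heavy.n_atoms):
            for b in range(heavy.n_atoms):
                i, j = idx[a], idx[b]
                ci, ri = residues[i]
                cj, rj = residues[j]
                if ci == cj:
                    if mode == "inter" or abs(ri - rj) <= min_sep:
                        continue
                elif mode == "intra":
                    continue
                if np.linalg.norm(xyz[a] - xyz[b]) < cutoff:
                    hit[i, j] = hit[j, i] = True
        out += hit
    return out / heavy.n_frames


class TestContactMap:
    def test_cutoff_bracketing(self):
        for dist, expected in ((0.59, 1.0), (0.61, 0.0)):
            coords = np.array([[0.0, 0, 0], [dist, 0, 0]])
            traj = make_traj(coords, chains=["A", "B"], resids=[320, 320])
            cm = contact_map(traj)
            assert cm.matrix[0, 1] == expected

    def test_sequence_separation_rule_intra_chain(self):
        coords = np.array([[0.0, 0, 0], [0.1, 0, 0]])
        close_pair = make_traj(coords, resids=[320, 323])  # |i-j| = 3
        assert contact_map(close_pair).matrix.sum() == 0.0
        eligible = make_traj(coords, resids=[320, 324])  # |i-j| = 4
        assert contact_map(eligible).matrix[0, 1] == 1.0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        n = 50
        coords = rng.uniform(0, 1.5, (2, n, 3))
        chains = ["A"] * (n // 2) + ["B"] * (n - n // 2)
        resids = list(range(310, 310 + n // 2)) + list(range(310, 310 + n - n // 2))
        elements = rng.choice(["C", "N", "O", "H"], n)
        traj = make_traj(coords, chains=chains, resids=resids, elements=elements)
        for mode in ("both", "inter", "intra"):
            cm = contact_map(traj, mode=mode)
            oracle = brute_force_contacts(traj, 0.6, 3, mode=mode)
            assert np.array_equal(cm.matrix, oracle)

    def test_equilibration_drop(self):
        near = np.array([[0.0, 0, 0], [0.3, 0, 0]])
        far = np.array([[0.0, 0, 0], [5.0, 0, 0]])
        traj = make_traj(np.stack([near, far]), chains=["A", "B"], resids=[320, 320])
        assert contact_map(traj).matrix[0, 1] == 0.5
        assert contact_map(traj, drop_frames=1).matrix[0, 1] == 0.0
        with pytest.raises(TrajError):
            contact_map(traj, drop_frames=2)

    def test_replica_averaging(self):
        near = make_traj(
            np.array([[0.0, 0, 0], [0.3, 0, 0]]), chains=["A", "B"], resids=[320, 320]
        )
        far = make_traj(
            np.array([[0.0, 0, 0], [5.0, 0, 0]]), chains=["A", "B"], resids=[320, 320]
        )
        cm = contact_map([near, far])
        assert cm.matrix[0, 1] == 0.5
        assert cm.per_replica.shape[0] == 2


class TestContactTotals:
    def test_single_pair(self):
        residues = [("A", 320), ("A", 330)]
        m = np.array([[0.0, 1.0], [1.0, 0.0]])
        maps = [ContactMap(m, residues), ContactMap(m, residues)]
        out = contact_totals(maps)
        assert np.allclose(out["mean"], [1.0, 1.0])
        assert np.allclose(out["sem"], 0.0)

    def test_mean_and_sem_two_replicas(self):
        residues = [("A", 320), ("A", 330)]
        m1 = np.array([[0.0, 1.0], [1.0, 0.0]])
        m2 = np.array([[0.0, 2.0], [2.0, 0.0]]) / 2 + np.array([[1.0, 0], [0, 1.0]])
        out = contact_totals([ContactMap(m1, residues), ContactMap(np.array([[1.0,1.0],[1.0,1.0]]), residues)])
        # replica totals per residue: (1, 1) and (2, 2) -> mean 1.5, SEM 0.5
        assert np.allclose(out["mean"], [1.5, 1.5])
        assert np.allclose(out["sem"], [0.5, 0.5])

    def test_single_replica_sem_rejected(self):
        residues = [("A", 320), ("A", 330)]
        cm = ContactMap(np.zeros((2, 2)), residues)
        with pytest.raises(TrajError):
            contact_totals(cm)

    def test_block_averaging(self):
        traj, _ = gen_helical_bundle(seed=4, n_chains=2, inter_axis_nm=1.0,
                                     n_frames=10, jitter_nm=0.01, sequence="A" * 12,
                                     first_resid=320)
        blocks = block_contact_maps(traj, n_blocks=5, mode="inter")
        out = contact_totals(blocks, n_blocks=5)
        assert out["mean"].shape == (len(blocks[0].residues),)
        assert np.all(out["sem"] >= 0)


class TestHelixFraction:
    def test_ideal_helix_interior_is_fully_helical(self):
        traj, _ = gen_helical_bundle(seed=0, n_chains=1, n_frames=1, sequence="A" * 20, first_resid=1)
        out = helix_fraction(traj)
        interior = out["fraction"][2:-2]
        assert np.all(interior >= 0.95)

    def test_extended_chain_has_no_helix(self):
        traj, _ = gen_helical_bundle(
            seed=0, n_chains=1, n_frames=1, sequence="A" * 20, extended=True
        )
        assert np.nanmax(helix_fraction(traj)["fraction"]) == 0.0

    def test_alternating_frames_give_half(self):
        helix, _ = gen_helical_bundle(seed=0, n_chains=1, n_frames=1, sequence="A" * 20)
        ext, _ = gen_helical_bundle(
            seed=0, n_chains=1, n_frames=1, sequence="A" * 20, extended=True
        )
        frames = np.concatenate([helix.coords_nm, ext.coords_nm, helix.coords_nm, ext.coords_nm])
        traj = TrajectoryEnsemble(
            frames, helix.chain_ids, helix.resids, helix.resnames,
            helix.atom_names, helix.elements,
        )
        out = helix_fraction(traj)
        assert np.all(out["fraction"][4:-4] == pytest.approx(0.5))

    def test_matches_reference_dssp_implementation(self):
        """Cross-check H assignment against mdtraj's DSSP on the same
        generated coordinates (helix and extended)."""
        mdtraj = pytest.importorskip("mdtraj")
        for extended in (False, True):
            traj, _ = gen_helical_bundle(
                seed=0, n_chains=1, n_frames=1, sequence="A" * 16, first_resid=1,
                extended=extended,
            )
            top = mdtraj.Topology()
            chain = top.add_chain()
            residues = {}
            for i in range(traj.n_atoms):
                rid = int(traj.resids[i])
                if rid not in residues:
                    residues[rid] = top.add_residue("ALA", chain, resSeq=rid)
                top.add_atom(
                    traj.atom_names[i],
                    mdtraj.core.element.get_by_symbol(str(traj.elements[i])),
                    residues[rid],
                )
            mtraj = mdtraj.Trajectory(traj.coords_nm.copy(), top)
            codes = mdtraj.compute_dssp(mtraj, simplified=False)[0]
            ours = helix_fraction(traj)["fraction"]
            theirs = (codes == "H").astype(float)
            # interior residues must agree exactly; DSSP edge conventions
            # (first/last assignable residue) may differ by one
            assert np.array_equal(ours[2:-2], theirs[2:-2])

    def test_missing_backbone_reported_not_zero(self):
        traj = make_traj(np.zeros((1, 3, 3)), names=["N", "CA", "C"], resids=[1, 1, 1])
        out = helix_fraction(traj)
        assert np.isnan(out["fraction"][0])


class TestMinInterchainDistance:
    def test_shared_position_gives_zero(self):
        coords = np.array([[1.0, 1, 1], [1.0, 1, 1]])
        traj = make_traj(coords, chains=["A", "B"], resids=[320, 320])
        out = min_interchain_distance(traj, "A", "B")
        assert out["min_distance_nm"][0] == 0.0

    def test_matches_brute_force_min(self):
        rng = np.random.default_rng(5)
        coords = rng.uniform(0, 3, (2, 20, 3))
        coords[:, 10:, 0] += 5.0
        chains = ["A"] * 10 + ["B"] * 10
        traj = make_traj(coords, chains=chains, resids=list(range(320, 330)) * 2)
        out = min_interchain_distance(traj, "A", "B")
        for f in range(2):
            oracle = min(
                np.linalg.norm(coords[f, a] - coords[f, b])
                for a in range(10)
                for b in range(10, 20)
            )
            assert out["min_distance_nm"][f] == pytest.approx(oracle, rel=1e-12)

    def test_scripted_dissociation_episode_detected(self):
        traj, manifest = gen_helical_bundle(
            seed=6, n_chains=2, inter_axis_nm=0.9, sequence="A" * 14, first_resid=320,
            n_frames=12, jitter_nm=0.0,
            dissociation={"chain": 1, "start": 4, "stop": 9, "displacement_nm": 5.0},
        )
        out = min_interchain_distance(traj, "A", "B", threshold_nm=0.6, min_dwell_frames=2)
        assert out["episodes"] == manifest["dissociation_episodes"]

    def test_missing_chain_rejected(self):
        traj = make_traj(np.zeros((1, 2, 3)), chains=["A", "B"], resids=[1, 2])
        with pytest.raises(TrajError):
            min_interchain_distance(traj, "A", "C")


class TestClusterGromos:
    def test_identical_frames_form_one_cluster(self):
        rng = np.random.default_rng(7)
        xyz = rng.uniform(0, 2, (10, 3))
        traj = make_traj(np.tile(xyz, (6, 1, 1)), resids=list(range(320, 330)))
        clusters = cluster_gromos(traj)
        assert len(clusters) == 1
        assert clusters[0]["size"] == 6
        assert clusters[0]["center_frame"] == 0

    def test_two_conformations_give_two_clusters(self):
        rng = np.random.default_rng(8)
        a = rng.uniform(0, 1, (10, 3))
        b = a + np.array([2.0, 0, 0]) * (np.arange(10) % 2)[:, None]  # ~1 nm RMSD shape change
        frames = np.stack([a, a, b, a, b])
        traj = make_traj(frames, resids=list(range(320, 330)))
        clusters = cluster_gromos(traj, cutoff_nm=0.3)
        assert len(clusters) == 2
        assert clusters[0]["size"] == 3  # frames 0,1,3
        assert sorted(clusters[0]["members"]) == [0, 1, 3]

    def test_rigid_motions_cluster_together(self):
        rng = np.random.default_rng(9)
        xyz = rng.uniform(0, 1, (8, 3))
        frames = [xyz @ random_rotation(rng).T + rng.uniform(-2, 2, 3) for _ in range(5)]
        traj = make_traj(np.stack(frames), resids=list(range(320, 328)))
        assert len(cluster_gromos(traj, cutoff_nm=0.05)) == 1

    def test_cluster_count_non_increasing_in_cutoff(self):
        rng = np.random.default_rng(10)
        frames = rng.uniform(0, 1, (8, 9, 3))
        traj = make_traj(frames, resids=list(range(320, 329)))
        counts = [len(cluster_gromos(traj, cutoff_nm=c)) for c in (0.05, 0.2, 0.5, 1.5)]
        assert counts == sorted(counts, reverse=True)

    def test_kabsch_rmsd_zero_under_rigid_motion(self):
        rng = np.random.default_rng(11)
        a = rng.uniform(0, 1, (12, 3))
        b = a @ random_rotation(rng).T + np.array([3.0, -1.0, 2.0])
        assert kabsch_rmsd(a, b) < 1e-12


class TestAf2Confidence:
    @pytest.mark.parametrize(
        "iptm,ptm,expected", [(0.5, 0.5, 0.5), (1.0, 0.0, 0.8), (0.2, 0.7, 0.30)]
    )
    def test_values(self, iptm, ptm, expected):
        assert af2_confidence(iptm, ptm) == pytest.approx(expected)

    @pytest.mark.parametrize("iptm,ptm", [(-0.1, 0.5), (0.5, 1.2)])
    def test_out_of_range(self, iptm, ptm):
        with pytest.raises(TrajError):
            af2_confidence(iptm, ptm)
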