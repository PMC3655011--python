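import itertools

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from gtusc import synthgen as sg
from gtusc.contacts import (
    ContactAtom,
    PersistentContact,
    cluster_frames,
    donor_acceptor_subset,
    find_contacts,
    interface_residues,
    persistent_contacts,
    residue_histogram,
    rmsd_series,
    superpose,
)
from gtusc.errors import EmptyInputError, GeometryError, UnknownChainError
from gtusc.structio import Frame, Trajectory

from conftest import make_atom, two_chain_frame


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def brute_force_contacts(frame, chain_pair, threshold):
    """O(n^2) scan over all cross-chain atom pairs (inclusive threshold)."""
    ca, cb = chain_pair
    pairs = set()
    for i, ai in enumerate(frame.atoms):
        if ai.chain_id != ca:
            continue
        for j, aj in enumerate(frame.atoms):
            if aj.chain_id != cb:
                continue
            if np.linalg.norm(ai.position - aj.position) <= threshold:
                pairs.add((i, j))
    return pairs


def brute_force_min_rmsd(mobile, reference):
    """Minimum RMSD over all proper rotations: coarse grid + local refine."""
    mob = mobile - mobile.mean(axis=0)
    ref = reference - reference.mean(axis=0)

    def rmsd_of(rotvec):
        R = Rotation.from_rotvec(rotvec).as_matrix()
        d = mob @ R.T - ref
        return np.sqrt(np.mean(np.sum(d * d, axis=1)))

    best = np.inf
    grid = np.linspace(-np.pi, np.pi, 7)
    for rx, ry, rz in itertools.product(grid, grid, grid):
        res = minimize(rmsd_of, x0=[rx, ry, rz], method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-14,
                                "maxiter": 4000})
        best = min(best, res.fun)
    return best


def random_two_chain_frame(rng, n_per_chain, spread=8.0, index=0):
    coords_a = rng.uniform(0, spread, size=(n_per_chain, 3))
    coords_b = rng.uniform(0, spread, size=(n_per_chain, 3))
    return two_chain_frame(coords_a, coords_b, index=index)


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------

class TestSuperpose:
    def test_identical_frames_rmsd_zero(self, rng):
        fr = random_two_chain_frame(rng, 5)
        _, rmsd = superpose(fr, fr)
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_is_removed(self, rng):
        fr = random_two_chain_frame(rng, 6)
        R = Rotation.from_euler("z", 30, degrees=True).as_matrix()
        moved = fr.with_coords(fr.coords @ R.T + np.array([1.0, 2.0, 3.0]))
        tf, rmsd = superpose(moved, fr)
        assert rmsd == pytest.approx(0.0, abs=1e-6)
        np.testing.assert_allclose(tf.apply(moved.coords), fr.coords,
                                   atol=1e-6)

    def test_matches_brute_force_rotation_search(self, rng):
        # 4-atom configurations that cannot be superposed exactly
        mob = rng.normal(size=(4, 3))
        ref = rng.normal(size=(4, 3))
        _, rmsd = superpose(mob, ref)
        assert rmsd == pytest.approx(brute_force_min_rmsd(mob, ref), abs=1e-6)

    def test_reflection_not_used(self):
        # mirror image of a chiral 4-point set: best proper-rotation fit
        # cannot reach zero
        coords = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.5]],
                          dtype=float)
        mirrored = coords * np.array([1, 1, -1])
        tf, rmsd = superpose(mirrored, coords)
        assert np.linalg.det(tf.rotation) == pytest.approx(1.0, abs=1e-9)
        assert rmsd > 0.1

    @pytest.mark.parametrize("coords", [
        np.array([[0.0, 0, 0], [1, 0, 0]]),                 # too few atoms
        np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0]]),      # collinear
    ])
    def test_degenerate_selection_is_geometry_error(self, coords):
        with pytest.raises(GeometryError):
            superpose(coords, coords + 1.0)


class TestRmsdSeries:
    def test_rigid_trajectory_reports_zero_everywhere(self, rng):
        fr0 = random_two_chain_frame(rng, 5)
        frames = [fr0]
        for t in range(1, 5):
            R = Rotation.from_euler("xyz", rng.uniform(-40, 40, 3),
                                    degrees=True).as_matrix()
            coords = fr0.coords @ R.T + rng.uniform(-5, 5, 3)
            frames.append(Frame(t, fr0.atoms).with_coords(coords))
        traj = Trajectory(frames=frames)
        table = rmsd_series(traj, 0, {"chainA": range(5), "chainB": range(5, 10)})
        assert np.allclose(table.to_numpy(), 0.0, atol=1e-9)

    def test_equals_per_frame_composition_oracle(self, rng):
        fr0 = random_two_chain_frame(rng, 5)
        frames = [fr0]
        for t in range(1, 5):
            frames.append(Frame(t, fr0.atoms).with_coords(
                fr0.coords + rng.normal(0, 0.5, size=(10, 3))))
        traj = Trajectory(frames=frames)
        groups = {"g1": list(range(4)), "g2": list(range(4, 10))}
        table = rmsd_series(traj, 0, groups)
        ref = fr0.coords
        for fr in traj.frames:
            tf, _ = superpose(fr.coords, ref)
            fitted = tf.apply(fr.coords)
            for name, sel in groups.items():
                sel = np.asarray(sel)
                expected = np.sqrt(np.mean(
                    np.sum((fitted[sel] - ref[sel]) ** 2, axis=1)))
                assert table.loc[fr.index, name] == pytest.approx(expected,
                                                                  abs=1e-12)
        assert table.loc[0].max() == pytest.approx(0.0, abs=1e-12)

    def test_reference_index_out_of_range(self, rng):
        traj = Trajectory(frames=[random_two_chain_frame(rng, 4)])
        with pytest.raises(IndexError):
            rmsd_series(traj, 3)


# ---------------------------------------------------------------------------
# contacts
# ---------------------------------------------------------------------------

class TestFindContacts:
    def test_cross_chain_pair_within_threshold(self):
        fr = two_chain_frame([(0, 0, 0)], [(2.5, 0, 0)])
        events = find_contacts(fr, ("A", "B"), threshold_A=3.0)
        assert len(events) == 1
        assert events[0].distance_A == pytest.approx(2.5)

    def test_same_chain_pairs_excluded(self):
        fr = two_chain_frame([(0, 0, 0), (1, 0, 0)], [(50, 0, 0)])
        assert find_contacts(fr, ("A", "B"), threshold_A=3.0) == []

    def test_threshold_is_inclusive(self):
        fr = two_chain_frame([(0, 0, 0)], [(3.0, 0, 0)])
        assert len(find_contacts(fr, ("A", "B"), threshold_A=3.0)) == 1

    def test_equals_brute_force_on_random_frames(self, rng):
        for trial in range(20):
            fr = random_two_chain_frame(rng, 25, index=trial)
            events = find_contacts(fr, ("A", "B"), threshold_A=3.0)
            got = {(e.atom_i.residue_number, e.atom_j.residue_number)
                   for e in events}
            expected = {(fr.atoms[i].residue_number, fr.atoms[j].residue_number)
                        for i, j in brute_force_contacts(fr, ("A", "B"), 3.0)}
            assert got == expected

    def test_unknown_chain(self):
        fr = two_chain_frame([(0, 0, 0)], [(1, 0, 0)])
        with pytest.raises(UnknownChainError):
            find_contacts(fr, ("A", "Z"), threshold_A=3.0)

    def test_threshold_monotonicity(self, rng):
        fr = random_two_chain_frame(rng, 20)
        small = len(find_contacts(fr, ("A", "B"), threshold_A=2.0))
        large = len(find_contacts(fr, ("A", "B"), threshold_A=4.0))
        assert small <= large


class TestPersistentContacts:
    @staticmethod
    def _planted_traj(fractions, n_frames=200, seed=11):
        spec = sg.TrajectorySpec(
            n_frames=n_frames,
            chains=(sg.ChainSpec("B", max(len(fractions), 1)),
                    sg.ChainSpec("D", max(len(fractions), 1))),
            planted_contacts=tuple(sg.PlantedContact(f) for f in fractions),
            seed=seed,
        )
        return sg.gen_trajectory(spec)

    def test_full_occupancy_reported_with_fraction_one(self):
        traj, _ = self._planted_traj([1.0], n_frames=50)
        out = persistent_contacts(traj, ("B", "D"), window=(0, 50))
        assert len(out) == 1
        assert out[0].persistence_fraction == pytest.approx(1.0)

    def test_exactly_at_threshold_is_not_persistent(self):
        """A pair present in 89 or exactly 90 of 100 frames must be excluded:
        the fraction has to exceed 0.90 strictly."""
        traj, truth = self._planted_traj([0.89, 0.90, 0.95, 1.0],
                                         n_frames=100)
        assert sorted(truth.contacts["n_frames_in_contact"]) == [89, 90, 95, 100]
        out = persistent_contacts(traj, ("B", "D"), persistence=0.90,
                                  window=(0, 100))
        assert sorted(c.persistence_fraction for c in out) == [0.95, 1.0]

    def test_matches_frame_by_frame_counting(self):
        fractions = [1.0, 0.95, 0.60, 0.10]
        traj, _ = self._planted_traj(fractions, n_frames=200, seed=4)
        out = persistent_contacts(traj, ("B", "D"), window=(0, 200))
        assert sorted(c.persistence_fraction for c in out) == [0.95, 1.0]
        # oracle: count per atom pair with the brute-force scan in each frame
        counts = {}
        for fr in traj.frames:
            for key in brute_force_contacts(fr, ("B", "D"), 3.0):
                counts[key] = counts.get(key, 0) + 1
        expected = sorted(c / 200 for c in counts.values() if c / 200 > 0.90)
        assert sorted(c.persistence_fraction for c in out) == expected

    def test_subset_of_per_frame_contacts(self):
        traj, _ = self._planted_traj([0.95, 0.5], n_frames=60, seed=9)
        out = persistent_contacts(traj, ("B", "D"), window=(0, 60))
        union = set()
        for fr in traj.frames:
            for e in find_contacts(fr, ("B", "D"), 3.0):
                union.add(((e.atom_i.chain_id, e.atom_i.residue_number,
                            e.atom_i.name),
                           (e.atom_j.chain_id, e.atom_j.residue_number,
                            e.atom_j.name)))
        for c in out:
            key = ((c.atom_i.chain_id, c.atom_i.residue_number, c.atom_i.name),
                   (c.atom_j.chain_id, c.atom_j.residue_number, c.atom_j.name))
            assert key in union

    def test_raising_persistence_never_grows_the_set(self):
        traj, _ = self._planted_traj([1.0, 0.95, 0.92, 0.5], n_frames=100,
                                     seed=2)
        sizes = [len(persistent_contacts(traj, ("B", "D"), persistence=p,
                                         window=(0, 100)))
                 for p in (0.5, 0.91, 0.94, 0.99)]
        assert sizes == sorted(sizes, reverse=True)

    def test_empty_window_rejected(self):
        traj, _ = self._planted_traj([1.0], n_frames=10)
        with pytest.raises(EmptyInputError):
            persistent_contacts(traj, ("B", "D"), window=(5, 5))

    def test_default_window_skips_equilibration(self):
        # planted 'always-on after burn-in' behaviour: full-window fraction
        # and skipped-window fraction differ when contacts fall early
        traj, truth = self._planted_traj([0.6], n_frames=100, seed=5)
        full = persistent_contacts(traj, ("B", "D"), persistence=0.0,
                                   window=(0, 100))
        skipped = persistent_contacts(traj, ("B", "D"), persistence=0.0)
        assert full[0].n_frames_total == 100
        assert skipped[0].n_frames_total == 70


class TestResidueHistogram:
    def test_single_pair_every_frame(self):
        ai = ContactAtom("B", 518, "ASN", "ND2", "N")
        aj = ContactAtom("D", 2, "ARG", "NH1", "N")
        from gtusc.contacts import ContactEvent
        events = [ContactEvent(ai, aj, t, 2.5) for t in range(10)]
        hist = residue_histogram(events, n_frames=10, persistence=0.9)
        key = (("B", 518, "ASN"), ("D", 2, "ARG"))
        assert hist.bins[key] == pytest.approx(1.0)
        assert hist.persistent[key] is True

    def test_union_over_atom_pairs(self):
        """Two atom pairs of one residue pair covering disjoint frame halves
        give a residue-level fraction of 1.0 although each atom pair has 0.5."""
        from gtusc.contacts import ContactEvent
        a1 = ContactAtom("B", 518, "ASN", "ND2", "N")
        a2 = ContactAtom("B", 518, "ASN", "OD1", "O")
        b = ContactAtom("D", 2, "ARG", "NH1", "N")
        events = [ContactEvent(a1, b, t, 2.0) for t in range(5)]
        events += [ContactEvent(a2, b, t, 2.0) for t in range(5, 10)]
        hist = residue_histogram(events, n_frames=10, persistence=0.9)
        key = (("B", 518, "ASN"), ("D", 2, "ARG"))
        assert hist.bins[key] == pytest.approx(1.0)

    def test_histogram_fraction_at_least_atom_fraction(self):
        traj, _ = TestPersistentContacts._planted_traj([0.95, 0.6],
                                                       n_frames=100, seed=3)
        events = []
        for fr in traj.frames:
            events.extend(find_contacts(fr, ("B", "D"), 3.0))
        hist = residue_histogram(events, n_frames=100)
        atom_level = persistent_contacts(traj, ("B", "D"), persistence=0.0,
                                         window=(0, 100))
        for c in atom_level:
            key = ((c.atom_i.chain_id, c.atom_i.residue_number,
                    c.atom_i.residue_name),
                   (c.atom_j.chain_id, c.atom_j.residue_number,
                    c.atom_j.residue_name))
            assert hist.bins[key] >= c.persistence_fraction - 1e-12

    def test_no_events_empty_histogram(self):
        hist = residue_histogram([], n_frames=10)
        assert hist.bins == {}

    def test_nonpositive_frames_rejected(self):
        with pytest.raises(ValueError):
            residue_histogram([], n_frames=0)


# residue lists printed for the first GCP4/γ-tubulin dimer interface
GCP4_DIMER1 = [
    ("GLU", 367), ("GLN", 370), ("LEU", 404), ("GLN", 508), ("ARG", 515),
    ("ARG", 517), ("ASN", 518), ("ASP", 525), ("LEU", 531), ("GLN", 532),
    ("VAL", 533), ("LEU", 536), ("GLU", 537), ("SER", 538),
]
GTUB_DIMER1 = [
    ("ARG", 2), ("ARG", 46), ("ASP", 48), ("PRO", 245), ("GLY", 246),
    ("MET", 248), ("ASN", 249), ("ILE", 260), ("ILE", 317), ("ILE", 328),
    ("ALA", 329), ("ILE", 330), ("LEU", 331), ("ASN", 332), ("GLN", 356),
    ("ILE", 443), ("TRP", 445),
]


class TestInterfaceResidues:
    def test_empty_input(self):
        assert interface_residues([]) == {}

    def test_dimer_interface_lists(self):
        """The dimer-1 interface: 14 GCP4 residues Glu367..Ser538 paired with
        17 γ-tubulin residues Arg2..Trp445."""
        contacts = []
        for k in range(max(len(GCP4_DIMER1), len(GTUB_DIMER1))):
            rn_b, nb = GCP4_DIMER1[k % len(GCP4_DIMER1)]
            rn_d, nd = GTUB_DIMER1[k % len(GTUB_DIMER1)]
            contacts.append(PersistentContact(
                atom_i=ContactAtom("B", nb, rn_b, "CA", "C"),
                atom_j=ContactAtom("D", nd, rn_d, "CA", "C"),
                n_frames_present=95, n_frames_total=100))
        lists = interface_residues(contacts)
        assert len(lists["B"]) == 14
        assert lists["B"][0] == "Glu367" and lists["B"][-1] == "Ser538"
        assert len(lists["D"]) == 17
        assert lists["D"][0] == "Arg2" and lists["D"][-1] == "Trp445"

    def test_planted_trajectory_ground_truth(self):
        traj, truth = TestPersistentContacts._planted_traj([1.0, 0.95],
                                                           n_frames=50, seed=8)
        out = persistent_contacts(traj, ("B", "D"), window=(0, 50))
        lists = interface_residues(out)
        expected_b = sorted(set(zip(truth.contacts["residue_name_i"],
                                    truth.contacts["residue_number_i"])))
        assert lists["B"] == [f"{rn.capitalize()}{num}"
                              for rn, num in expected_b]


def test_donor_acceptor_subset_is_subset():
    contacts = [
        PersistentContact(ContactAtom("B", 1, "ALA", "N", "N"),
                          ContactAtom("D", 1, "ALA", "O", "O"), 95, 100),
        PersistentContact(ContactAtom("B", 2, "ALA", "CA", "C"),
                          ContactAtom("D", 2, "ALA", "CB", "C"), 99, 100),
        PersistentContact(ContactAtom("B", 3, "SER", "OG", "O"),
                          ContactAtom("D", 3, "ALA", "H", "H"), 92, 100),
    ]
    sub = donor_acceptor_subset(contacts)
    assert set(id(c) for c in sub) <= set(id(c) for c in contacts)
    assert len(sub) == 2  # the carbon-carbon pair drops out


# ---------------------------------------------------------------------------
# frame clustering
# ---------------------------------------------------------------------------

class TestClusterFrames:
    def test_identical_frames_single_cluster(self, rng):
        fr0 = random_two_chain_frame(rng, 5)
        frames = [Frame(t, fr0.atoms).with_coords(fr0.coords)
                  for t in range(6)]
        cl = cluster_frames(Trajectory(frames=frames), window=(0, 6),
                            cutoff_A=1.5)
        assert cl.n_clusters == 1
        assert cl.dispersion_A[0] == pytest.approx(0.0, abs=1e-6)

    def test_two_conformer_families(self, rng):
        fr0 = random_two_chain_frame(rng, 8)
        shifted = fr0.coords + np.array([0, 0, 12.0]) * np.sign(
            np.arange(16) % 2 - 0.5)[:, None]  # internal rearrangement
        frames = []
        for t in range(9):
            base = fr0.coords if t % 3 else shifted
            frames.append(Frame(t, fr0.atoms).with_coords(
                base + rng.normal(0, 0.05, size=base.shape)))
        cl = cluster_frames(Trajectory(frames=frames), window=(0, 9),
                            cutoff_A=2.0)
        assert cl.n_clusters == 2
        assert sorted(cl.sizes.values()) == [3, 6]

    def test_single_family_dispersion_matches_direct_mean(self, rng):
        fr0 = random_two_chain_frame(rng, 6)
        frames = [Frame(t, fr0.atoms).with_coords(
            fr0.coords + rng.normal(0, 0.2, size=(12, 3)))
            for t in range(8)]
        traj = Trajectory(frames=frames)
        cl = cluster_frames(traj, window=(0, 8), cutoff_A=2.0)
        assert cl.n_clusters == 1
        centroid = cl.centroids[0]
        rmsds = [superpose(fr.coords, centroid)[1] for fr in frames]
        assert cl.dispersion_A[0] == pytest.approx(np.mean(rmsds), abs=1e-9)

    def test_every_frame_assigned_once(self, rng):
        fr0 = random_two_chain_frame(rng, 5)
        frames = [Frame(t, fr0.atoms).with_coords(
            fr0.coords + rng.normal(0, 1.0, size=(10, 3)))
            for t in range(10)]
        cl = cluster_frames(Trajectory(frames=frames), window=(0, 10),
                            cutoff_A=1.0)
        assert sorted(cl.assignments) == list(range(10))
        assert sum(cl.sizes.values()) == 10

    def test_empty_window(self, rng):
        traj = Trajectory(frames=[random_two_chain_frame(rng, 4)])
        with pytest.raises(EmptyInputError):
            cluster_frames(traj, window=(1, 1))
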