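import math

import numpy as np
import pytest

from ramamix.ensemble_geometry import (
    Conformation,
    GyrationProfile,
    backbone_dihedrals,
    ensemble_rg,
    local_gyration_profile,
    max_diameter,
    min_cross_distances,
    profile_distance,
    radius_of_gyration,
    read_ensemble,
    rmsd,
    write_ensemble,
)

# ideal peptide backbone geometry (lengths in Angstrom, angles in degrees)
BOND = {"N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329}
ANGLE = {"C-N-CA": 121.7, "N-CA-C": 111.2, "CA-C-N": 116.2}


def place_atom(a, b, c, bond, angle_deg, torsion_deg):
    """NeRF: place atom D given chain A-B-C, |CD|, angle BCD and torsion ABCD."""
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * math.cos(angle),
            bond * math.sin(angle) * math.cos(torsion),
            bond * math.sin(angle) * math.sin(torsion),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_chain(phi_psi, mirror=False):
    """Backbone (N, CA, C) coordinates from (phi, psi) per residue, built
    with an internal-to-Cartesian construction independent of the
    dihedral-measuring code; omega fixed at 180 degrees."""
    n_res = len(phi_psi)
    coords = [
        np.array([0.0, 0.0, 0.0]),
        np.array([BOND["N-CA"], 0.0, 0.0]),
    ]
    ang = math.radians(180.0 - ANGLE["N-CA-C"])
    coords.append(
        coords[1] + BOND["CA-C"] * np.array([math.cos(ang), math.sin(ang), 0.0])
    )
    for i in range(1, n_res):
        phi, _ = phi_psi[i]
        _, psi_prev = phi_psi[i - 1]
        n_new = place_atom(coords[-3], coords[-2], coords[-1], BOND["C-N"],
                           ANGLE["CA-C-N"], psi_prev)
        ca_new = place_atom(coords[-2], coords[-1], n_new, BOND["N-CA"],
                            ANGLE["C-N-CA"], 180.0)
        c_new = place_atom(coords[-1], n_new, ca_new, BOND["CA-C"],
                           ANGLE["N-CA-C"], phi)
        coords += [n_new, ca_new, c_new]
    coords = np.array(coords)
    if mirror:
        coords = coords * np.array([1.0, 1.0, -1.0])
    res_idx = np.repeat(np.arange(1, n_res + 1), 3)
    names = np.tile(["N", "CA", "C"], n_res).astype(object)
    return Conformation("built", res_idx, names, coords)


def random_conformation(rng, n_res=30, label="rand"):
    res_idx = np.repeat(np.arange(1, n_res + 1), 4)
    names = np.tile(["N", "CA", "C", "O"], n_res).astype(object)
    coords = rng.normal(scale=8.0, size=(4 * n_res, 3))
    return Conformation(label, res_idx, names, coords)


def rigid_transform(c, rng, label="moved"):
    from scipy.spatial.transform import Rotation

    rot = Rotation.random(rng=rng).as_matrix()
    shift = rng.uniform(-20, 20, 3)
    return Conformation(label, c.residue_index, c.atom_name, c.coords @ rot.T + shift)


class TestDihedrals:
    def test_recovers_helix_angles(self):
        chain = build_chain([(-57.0, -47.0)] * 6)
        angles = backbone_dihedrals(chain)
        np.testing.assert_allclose(angles[1:-1, 0], -57.0, atol=0.1)
        np.testing.assert_allclose(angles[1:-1, 1], -47.0, atol=0.1)

    def test_termini_undefined(self):
        angles = backbone_dihedrals(build_chain([(-57.0, -47.0)] * 4))
        assert math.isnan(angles[0, 0])  # no preceding C for phi
        assert math.isnan(angles[-1, 1])  # no following N for psi

    def test_mirror_flips_signs(self):
        target = [(-57.0, -47.0)] * 5
        a = backbone_dihedrals(build_chain(target))
        b = backbone_dihedrals(build_chain(target, mirror=True))
        np.testing.assert_allclose(a[1:-1], -b[1:-1], atol=1e-9)

    def test_agrees_with_biotite(self):
        import biotite.structure as struc
        from ramamix.ensemble_geometry import _to_atom_array

        chain = build_chain([(-57.0, -47.0), (-139.0, 135.0), (-60.0, -30.0),
                             (57.0, 47.0), (-80.0, 100.0)])
        ours = backbone_dihedrals(chain)
        phi, psi, _ = struc.dihedral_backbone(_to_atom_array(chain))
        np.testing.assert_allclose(ours[1:, 0], np.degrees(phi[1:]), atol=1e-3)
        np.testing.assert_allclose(ours[:-1, 1], np.degrees(psi[:-1]), atol=1e-3)


class TestGyrationProfile:
    def test_coincident_atoms_give_zero(self):
        c = Conformation(
            "point",
            np.repeat(np.arange(1, 4), 2),
            np.tile(["N", "CA"], 3).astype(object),
            np.zeros((6, 3)),
        )
        prof = local_gyration_profile(c)
        np.testing.assert_allclose(prof.values, 0.0)

    def test_two_atom_window_is_half_distance(self):
        d = 3.0
        c = Conformation(
            "pair", np.array([1, 2]), np.array(["CA", "CA"], dtype=object),
            np.array([[0.0, 0, 0], [d, 0, 0]]),
        )
        prof = local_gyration_profile(c, n_win=5)
        np.testing.assert_allclose(prof.values, d / 2.0)

    def test_matches_brute_force_formula(self, rng):
        c = random_conformation(rng)
        prof = local_gyration_profile(c, n_win=5)
        # independent brute-force evaluation, atom by atom
        for i, rid in enumerate(c.residue_ids):
            pts = []
            for j in range(len(c.residue_index)):
                if (
                    abs(int(c.residue_index[j]) - int(rid)) <= 5
                    and str(c.atom_name[j]) in ("N", "CA", "C", "O")
                ):
                    pts.append(c.coords[j])
            pts = np.array(pts)
            centroid = pts.mean(axis=0)
            expected = math.sqrt(np.mean(np.sum((pts - centroid) ** 2, axis=1)))
            assert prof.values[i] == pytest.approx(expected, abs=1e-10)

    def test_full_window_equals_backbone_rg(self, rng):
        c = random_conformation(rng, n_res=7)
        prof = local_gyration_profile(c, n_win=10)  # covers the whole chain
        np.testing.assert_allclose(
            prof.values, radius_of_gyration(c, backbone_only=True), atol=1e-12
        )


class TestProfileDistance:
    def test_identity_and_hand_example(self):
        a = GyrationProfile(np.array([1.0, 2.0, 2.0]))
        b = GyrationProfile(np.array([1.0, 0.0, 2.0]))
        assert profile_distance(a, a) == 0.0
        assert profile_distance(a, b) == pytest.approx(2.0)

    def test_invariant_under_rigid_motion(self, rng):
        c = random_conformation(rng)
        moved = rigid_transform(c, rng)
        pa = local_gyration_profile(c)
        pb = local_gyration_profile(moved)
        assert profile_distance(pa, pb) == pytest.approx(0.0, abs=1e-9)

    def test_metric_axioms(self, rng):
        profs = [GyrationProfile(rng.random(12)) for _ in range(3)]
        a, b, c = profs
        assert profile_distance(a, b) == pytest.approx(profile_distance(b, a))
        assert profile_distance(a, c) <= profile_distance(a, b) + profile_distance(b, c)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            profile_distance(GyrationProfile(np.ones(3)), GyrationProfile(np.ones(4)))


class TestGlobalDescriptors:
    def test_two_atom_rg_and_dmax(self):
        c = Conformation(
            "pair", np.array([1, 1]), np.array(["N", "CA"], dtype=object),
            np.array([[0.0, 0, 0], [2.0, 0, 0]]),
        )
        assert radius_of_gyration(c) == pytest.approx(1.0)
        assert max_diameter(c) == pytest.approx(2.0)

    def test_dmax_345_triangle(self):
        c = Conformation(
            "tri", np.array([1, 1, 1]), np.array(["N", "CA", "C"], dtype=object),
            np.array([[0.0, 0, 0], [3.0, 0, 0], [0.0, 4.0, 0]]),
        )
        assert max_diameter(c) == pytest.approx(5.0)

    def test_rg_rotation_invariant(self, rng):
        c = random_conformation(rng)
        moved = rigid_transform(c, rng)
        assert radius_of_gyration(moved) == pytest.approx(radius_of_gyration(c), abs=1e-9)

    def test_dmax_needs_two_atoms(self):
        c = Conformation("one", np.array([1]), np.array(["CA"], dtype=object),
                         np.zeros((1, 3)))
        with pytest.raises(ValueError):
            max_diameter(c)


class TestRmsd:
    def test_identical_is_zero(self, rng):
        c = random_conformation(rng)
        assert rmsd(c, c) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_copy_is_zero(self, rng):
        c = random_conformation(rng)
        assert rmsd(c, rigid_transform(c, rng)) == pytest.approx(0.0, abs=1e-9)

    def test_symmetry(self, rng):
        a = random_conformation(rng, label="a")
        b = random_conformation(rng, label="b")
        assert rmsd(a, b) == pytest.approx(rmsd(b, a), abs=1e-9)

    def test_matches_rotation_search_oracle(self, rng):
        """Coarse Euler-grid search refined by Nelder-Mead, independent of
        the Kabsch solution."""
        from scipy.optimize import minimize
        from scipy.spatial.transform import Rotation

        a = Conformation(
            "a", np.array([1, 1, 1, 1]), np.array(["N", "CA", "C", "O"], dtype=object),
            rng.normal(size=(4, 3)),
        )
        b = Conformation("b", a.residue_index, a.atom_name, rng.normal(size=(4, 3)))
        xa = a.coords - a.coords.mean(axis=0)
        xb = b.coords - b.coords.mean(axis=0)

        def cost(euler):
            rot = Rotation.from_euler("zyz", euler).as_matrix()
            return math.sqrt(np.mean(np.sum((xa - xb @ rot.T) ** 2, axis=1)))

        grid = np.deg2rad(np.arange(0, 360, 20))
        half = np.deg2rad(np.arange(0, 181, 20))
        best = min(
            ((cost((u, v, w)), (u, v, w)) for u in grid for v in half for w in grid),
            key=lambda t: t[0],
        )
        refined = minimize(cost, best[1], method="Nelder-Mead",
                           options={"xatol": 1e-10, "fatol": 1e-12})
        assert rmsd(a, b) == pytest.approx(refined.fun, abs=0.01)

    def test_atom_mismatch_rejected(self, rng):
        a = random_conformation(rng, n_res=4)
        b = random_conformation(rng, n_res=5)
        with pytest.raises(ValueError):
            rmsd(a, b)


class TestCrossDistances:
    def test_same_sets_give_zero(self, rng):
        confs = [random_conformation(rng, label=f"c{i}") for i in range(3)]
        fwd, back = min_cross_distances(confs, confs, metric="rmsd")
        np.testing.assert_allclose(fwd, 0.0, atol=1e-9)
        np.testing.assert_allclose(back, 0.0, atol=1e-9)

    def test_singletons(self, rng):
        a = [random_conformation(rng, label="a")]
        b = [random_conformation(rng, label="b")]
        fwd, back = min_cross_distances(a, b, metric="rmsd")
        assert fwd[0] == pytest.approx(back[0])

    def test_minima_bounded_by_any_pair(self, rng):
        set_a = [local_gyration_profile(random_conformation(rng)) for _ in range(3)]
        set_b = [local_gyration_profile(random_conformation(rng)) for _ in range(2)]
        fwd, _ = min_cross_distances(set_a, set_b, metric="profile")
        for i, pa in enumerate(set_a):
            for pb in set_b:
                assert fwd[i] <= profile_distance(pa, pb) + 1e-12

    def test_empty_set_rejected(self, rng):
        with pytest.raises(ValueError):
            min_cross_distances([], [random_conformation(rng)])


class TestEnsembleRg:
    def test_examples(self):
        assert ensemble_rg([1.0], [27.8]) == pytest.approx(27.8)
        assert ensemble_rg([0.5, 0.5], [20.0, 30.0], mode="linear") == pytest.approx(25.0)
        assert ensemble_rg([0.5, 0.5], [20.0, 30.0], mode="rms") == pytest.approx(
            math.sqrt(650.0)
        )

    def test_rms_dominates_linear(self, rng):
        gamma = rng.dirichlet(np.ones(5))
        rgs = rng.uniform(15, 40, 5)
        assert ensemble_rg(gamma, rgs, "rms") >= ensemble_rg(gamma, rgs, "linear")

    def test_off_simplex_rejected(self):
        with pytest.raises(ValueError):
            ensemble_rg([0.6, 0.6], [20.0, 30.0])


class TestPdbIO:
    def test_round_trip(self, tmp_path, rng):
        confs = [random_conformation(rng, n_res=5, label=f"m{i}") for i in range(2)]
        path = tmp_path / "ens.pdb"
        write_ensemble(confs, path)
        back = read_ensemble(path)
        assert len(back) == 2
        for orig, rt in zip(confs, back):
            np.testing.assert_allclose(rt.coords, orig.coords, atol=1e-3)

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("")
        with pytest.raises(Exception):
            read_ensemble(path)
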