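"""Coordinate metrics vs brute-force and closed-form oracles."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from betahelix import (
    RegionSpec,
    backbone_dihedrals,
    dihedral,
    distance_map,
    kabsch_rmsd,
    measure_axial_rise,
    radius_of_gyration,
    rama_classify,
    region_stats,
)
from betahelix.errors import DomainError, EmptyRegionError

from conftest import random_rigid_transform


class TestDistanceMap:
    def test_two_atoms(self):
        dm = distance_map(np.array([[0.0, 0, 0], [1.0, 0, 0]]))
        assert dm.matrix[0, 1] == 1.0 and dm.matrix[1, 0] == 1.0
        assert dm.matrix[0, 0] == 0.0

    def test_matches_double_loop_oracle(self, rng):
        pts = rng.normal(size=(50, 3))
        dm = distance_map(pts)
        for i in range(50):
            for j in range(50):
                assert dm.matrix[i, j] == pytest.approx(
                    np.linalg.norm(pts[i] - pts[j]), abs=1e-12
                )

    def test_consecutive_rung_distances_bounded_by_rise(self, helix7, params):
        dm = distance_map(helix7)
        labels = {lab: i for i, lab in enumerate(dm.labels)}
        for resi in range(1, 19):
            for rung in range(1, 7):
                d = dm.matrix[
                    labels[("A", rung, resi)], labels[("A", rung + 1, resi)]
                ]
                assert d >= params.rise - 1e-12

    def test_rigid_invariance(self, rng):
        pts = rng.normal(size=(20, 3))
        rot, trans = random_rigid_transform(rng)
        dm1 = distance_map(pts)
        dm2 = distance_map(pts @ rot.T + trans)
        np.testing.assert_allclose(dm1.matrix, dm2.matrix, atol=1e-9)

    def test_duplicate_labels_rejected(self):
        with pytest.raises(DomainError, match="duplicate"):
            distance_map(np.zeros((2, 3)) + [[0, 0, 0], [1, 0, 0]],
                         labels=[("A", 1, 1), ("A", 1, 1)])


class TestRegionStats:
    def test_single_pair(self, trimer7):
        dm = distance_map(trimer7)
        spec = RegionSpec(
            "pair",
            {"chain": "A", "rung": 1, "resi": 1},
            {"chain": "B", "rung": 1, "resi": 1},
            "mean",
        )
        got = region_stats(dm, spec)
        a = trimer7.select(chain="A", rung=1, resi=1)[["x", "y", "z"]].to_numpy()[0]
        b = trimer7.select(chain="B", rung=1, resi=1)[["x", "y", "z"]].to_numpy()[0]
        assert got == pytest.approx(np.linalg.norm(a - b))

    def test_mean_matches_enumeration_oracle(self, trimer7):
        dm = distance_map(trimer7)
        spec = RegionSpec(
            "w9-n7", {"chain": "A", "resi": 9}, {"chain": {"B", "C"}, "resi": 7}
        )
        got = region_stats(dm, spec)
        idx = {lab: i for i, lab in enumerate(dm.labels)}
        vals = [
            dm.matrix[idx[("A", r1, 9)], idx[(c, r2, 7)]]
            for r1 in range(1, 8)
            for c in ("B", "C")
            for r2 in range(1, 8)
        ]
        assert got == pytest.approx(np.mean(vals), abs=1e-12)

    def test_interface_contact_window(self, trimer7):
        dm = distance_map(trimer7)
        spec = RegionSpec(
            "w9-n7", {"chain": "A", "resi": 9}, {"chain": {"B", "C"}, "resi": 7},
            "min",
        )
        assert 0.8 <= region_stats(dm, spec) <= 1.4

    def test_empty_selection(self, trimer7):
        dm = distance_map(trimer7)
        with pytest.raises(EmptyRegionError):
            region_stats(dm, RegionSpec("none", {"chain": "Z"}, {"chain": "A"}))


def rmsd_oracle(a, b):
    """Direct minimisation of the superposition objective over rotations,
    multi-started from a quaternion grid — independent of the SVD route."""
    a0 = a - a.mean(axis=0)
    b0 = b - b.mean(axis=0)

    def objective(rotvec):
        r = Rotation.from_rotvec(rotvec).as_matrix()
        return np.sqrt(np.mean(np.sum((b0 @ r.T - a0) ** 2, axis=1)))

    best = np.inf
    rng = np.random.default_rng(7)
    starts = [np.zeros(3)] + [
        Rotation.from_quat(q / np.linalg.norm(q)).as_rotvec()
        for q in rng.normal(size=(40, 4))
    ]
    for s in starts:
        res = minimize(objective, s, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 2000})
        best = min(best, res.fun)
    return best


class TestKabsch:
    def test_identical_sets_zero(self, rng):
        pts = rng.normal(size=(10, 3))
        assert kabsch_rmsd(pts, pts)["rmsd"] == pytest.approx(0.0, abs=1e-12)

    def test_rigid_copy_zero(self, rng):
        pts = rng.normal(size=(12, 3))
        rot, trans = random_rigid_transform(rng)
        out = kabsch_rmsd(pts, pts @ rot.T + trans)
        assert out["rmsd"] < 1e-9
        assert np.linalg.det(out["rotation"]) == pytest.approx(1.0)

    def test_four_point_sets_match_minimisation_oracle(self, rng):
        for _ in range(5):
            a = rng.normal(size=(4, 3))
            b = a + rng.normal(scale=0.1, size=(4, 3))
            got = kabsch_rmsd(a, b)["rmsd"]
            assert got == pytest.approx(rmsd_oracle(a, b), abs=1e-6)

    def test_symmetry(self, rng):
        a, b = rng.normal(size=(8, 3)), rng.normal(size=(8, 3))
        assert kabsch_rmsd(a, b)["rmsd"] == pytest.approx(
            kabsch_rmsd(b, a)["rmsd"], abs=1e-9
        )

    def test_reflection_guard_keeps_proper_rotation(self, rng):
        a = rng.normal(size=(6, 3))
        b = a.copy()
        b[:, 2] *= -1  # mirrored copy: optimum orthogonal map is improper
        out = kabsch_rmsd(a, b)
        assert np.linalg.det(out["rotation"]) == pytest.approx(1.0)
        assert out["rmsd"] > 0

    def test_shape_mismatch(self, rng):
        with pytest.raises(DomainError):
            kabsch_rmsd(rng.normal(size=(4, 3)), rng.normal(size=(5, 3)))


class TestRadiusOfGyration:
    def test_single_point(self):
        assert radius_of_gyration([[1.0, 2.0, 3.0]]) == 0.0

    def test_two_points(self):
        assert radius_of_gyration([[0, 0, 0], [0, 0, 2.0]]) == pytest.approx(1.0)

    def test_ring(self):
        theta = np.linspace(0, 2 * np.pi, 4096, endpoint=False)
        ring = np.column_stack([3 * np.cos(theta), 3 * np.sin(theta), 0 * theta])
        assert radius_of_gyration(ring) == pytest.approx(3.0, rel=1e-6)

    def test_rigid_invariance(self, rng):
        pts = rng.normal(size=(30, 3))
        rot, trans = random_rigid_transform(rng)
        assert radius_of_gyration(pts @ rot.T + trans) == pytest.approx(
            radius_of_gyration(pts), abs=1e-9
        )


def place_atom(a, b, c, bond, angle_deg, dihedral_deg):
    """NeRF construction: position d with given internal coordinates."""
    a, b, c = map(np.asarray, (a, b, c))
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    ang = np.radians(angle_deg)
    tor = np.radians(dihedral_deg)
    d_local = np.array(
        [
            -bond * np.cos(ang),
            -bond * np.sin(ang) * np.cos(tor),
            -bond * np.sin(ang) * np.sin(tor),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_chain(phi_psi, n_ca=0.1455, ca_c=0.1524, c_n=0.1329):
    """Backbone with prescribed (φ, ψ) and ω = 180°, bond lengths in nm."""
    residues = [
        {
            "N": np.array([0.0, 0.0, 0.0]),
            "CA": np.array([n_ca, 0.0, 0.0]),
        }
    ]
    residues[0]["C"] = place_atom(
        residues[0]["N"] + [0, 0.1, 0], residues[0]["N"], residues[0]["CA"],
        ca_c, 111.0, 133.0,
    )
    for i, (phi, psi) in enumerate(phi_psi):
        prev = residues[i]
        # psi of residue i positions N(i+1); omega positions CA(i+1);
        # phi of residue i+1 positions C(i+1)
        n_next = place_atom(prev["N"], prev["CA"], prev["C"], c_n, 116.0, psi)
        ca_next = place_atom(prev["CA"], prev["C"], n_next, n_ca, 121.0, 180.0)
        c_next = place_atom(prev["C"], n_next, ca_next, ca_c, 111.0, phi)
        residues.append({"N": n_next, "CA": ca_next, "C": c_next})
    return residues


class TestDihedrals:
    def test_round_trip_recovers_generating_angles(self):
        # build_chain pair i prescribes (phi of residue i+1, psi of residue i)
        pairs = [(-120.0, 120.0), (-60.0, -45.0), (60.0, 45.0), (-139.0, 135.0)]
        chain = build_chain(pairs)
        out = backbone_dihedrals(chain)
        for i, (phi_next, psi_here) in enumerate(pairs):
            assert out["psi"].iloc[i] == pytest.approx(psi_here, abs=1e-6)
            assert out["phi"].iloc[i + 1] == pytest.approx(phi_next, abs=1e-6)

    def test_termini_are_undefined(self):
        chain = build_chain([(-120.0, 120.0), (-120.0, 120.0)])
        out = backbone_dihedrals(chain)
        assert np.isnan(out["phi"][0]) and np.isnan(out["psi"].iloc[-1])

    def test_mirror_reflection_negates_angles(self):
        chain = build_chain([(-120.0, 120.0), (-60.0, -40.0)])
        mirrored = [
            {k: v * np.array([1.0, 1.0, -1.0]) for k, v in r.items()} for r in chain
        ]
        a = backbone_dihedrals(chain)
        b = backbone_dihedrals(mirrored)
        np.testing.assert_allclose(a["phi"], -b["phi"], atol=1e-9)
        np.testing.assert_allclose(a["psi"], -b["psi"], atol=1e-9)

    def test_reversed_atom_order_preserves_dihedral(self, rng):
        p = rng.normal(size=(4, 3))
        assert dihedral(*p) == pytest.approx(dihedral(*p[::-1]), abs=1e-9)

    def test_short_chain_empty(self):
        out = backbone_dihedrals(
            [{"N": [0, 0, 0], "CA": [0.15, 0, 0], "C": [0.3, 0.1, 0]}]
        )
        assert np.isnan(out.to_numpy()).all()

    def test_gap_is_skipped_with_warning(self):
        chain = build_chain([(-120.0, 120.0), (-120.0, 120.0), (-120.0, 120.0)])
        chain[2] = None
        with pytest.warns(UserWarning):
            out = backbone_dihedrals(chain)
        assert np.isnan(out["phi"][2]) and np.isnan(out["psi"][1])


class TestRamaClassify:
    @pytest.mark.parametrize(
        "phi, psi, label",
        [
            (-120.0, 120.0, "beta"),
            (-120.0, -160.0, "beta"),  # psi wrap-around branch
            (60.0, 45.0, "left_handed"),
            (-60.0, -45.0, "right_alpha"),
            (100.0, 170.0, "other"),
        ],
    )
    def test_canonical_points(self, phi, psi, label):
        assert rama_classify(phi, psi) == label

    def test_out_of_range_rejected(self):
        with pytest.raises(DomainError):
            rama_classify(-200.0, 0.0)


class TestAxialRise:
    def test_built_model_rise_is_exact(self, helix7, trimer7, params):
        assert measure_axial_rise(helix7) == pytest.approx(params.rise, abs=1e-12)
        assert measure_axial_rise(trimer7) == pytest.approx(params.rise, abs=1e-12)

    def test_z_stretch_scales_linearly(self, helix7):
        import dataclasses

        stretched_atoms = helix7.atoms.copy()
        stretched_atoms["z"] *= 2
        stretched = dataclasses.replace(helix7, atoms=stretched_atoms)
        assert measure_axial_rise(stretched) == pytest.approx(0.94)

    def test_matches_per_pair_oracle(self, helix7):
        got = measure_axial_rise(helix7)
        deltas = []
        for resi in range(1, 19):
            z = helix7.select(resi=resi).sort_values("rung")["z"].to_numpy()
            deltas.extend(z[1:] - z[:-1])
        assert got == pytest.approx(np.mean(deltas), abs=1e-12)

    def test_single_rung_rejected(self, layout, params):
        from betahelix import build_helix

        with pytest.raises(DomainError):
            measure_axial_rise(build_helix(layout, params, 1))
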