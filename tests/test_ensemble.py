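"""Order parameters, TCFs, dihedrals and superposition."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from methylscape import (
    RotamerJumpSpec,
    TrajectoryEnsemble,
    average_tcf,
    axis_vector_from_angles,
    bond_angle,
    compute_dihedral,
    internal_tcf,
    o2_tensor,
    simulate_rotamer_trajectory,
    superpose_frames,
    tcf_plateau,
)
from methylscape.ensemble import TimeCorrelation

from conftest import MET_WELLS, THETA_TET


class TestSuperposition:
    def make_coords(self, n=12, seed=0):
        return np.random.default_rng(seed).standard_normal((n, 3)) * 5.0

    def test_identity_transform(self):
        ref = self.make_coords()
        aligned, rmsd = superpose_frames(ref[None], ref)
        np.testing.assert_allclose(aligned[0], ref, atol=1e-9)
        assert rmsd[0] == pytest.approx(0.0, abs=1e-9)

    def test_known_rotation_recovered(self):
        ref = self.make_coords()
        rot = Rotation.from_euler("zyx", [40.0, -25.0, 66.0], degrees=True)
        moved = rot.apply(ref) + np.array([1.0, -2.0, 3.0])
        aligned, rmsd = superpose_frames(moved[None], ref)
        np.testing.assert_allclose(aligned[0], ref, atol=1e-6)
        assert rmsd[0] == pytest.approx(0.0, abs=1e-6)

    def test_collinear_selection_rejected(self):
        ref = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError, match="collinear"):
            superpose_frames(ref[None], ref)

    def test_matches_brute_force_rotation_grid(self):
        # coarse oracle: minimum RMSD over a dense grid of rotations can
        # never beat the closed-form optimal superposition
        ref = self.make_coords(8, seed=3)
        frame = Rotation.from_euler("zyx", [10, 33, -70], degrees=True).apply(
            ref
        ) + np.random.default_rng(4).normal(0, 0.3, ref.shape)
        _, rmsd = superpose_frames(frame[None], ref)
        fc = frame - frame.mean(0)
        rc = ref - ref.mean(0)
        best = np.inf
        for a in np.linspace(0, 360, 25, endpoint=False):
            for b in np.linspace(-90, 90, 13):
                for c in np.linspace(0, 360, 25, endpoint=False):
                    r = Rotation.from_euler("zyx", [a, b, c], degrees=True)
                    best = min(best, np.sqrt(np.mean((r.apply(fc) - rc) ** 2) * 3))
        assert rmsd[0] <= best + 1e-9


class TestDihedral:
    def test_planar_cis_is_zero(self):
        ang = compute_dihedral([1, 1, 0], [1, 0, 0], [0, 0, 0], [0, 1, 0])
        assert float(ang) == pytest.approx(0.0, abs=1e-9)

    def test_trans_is_180(self):
        ang = compute_dihedral([1, 1, 0], [1, 0, 0], [0, 0, 0], [0, -1, 0])
        assert abs(float(ang)) == pytest.approx(180.0, abs=1e-9)

    def test_staggered_gauche_plus_is_60(self):
        c = np.cos(np.radians(60)); s = np.sin(np.radians(60))
        ang = compute_dihedral([1, 1, 0], [1, 0, 0], [0, 0, 0], [0, c, -s])
        assert float(ang) == pytest.approx(60.0, abs=1e-9)

    def test_sign_convention_matches_mdanalysis(self):
        mda = pytest.importorskip("MDAnalysis")
        from MDAnalysis.lib.distances import calc_dihedrals

        rng = np.random.default_rng(3)
        for _ in range(5):
            pts = rng.standard_normal((4, 3)) * 2.0
            ref = np.degrees(
                calc_dihedrals(pts[0][None], pts[1][None], pts[2][None], pts[3][None])
            )[0]
            assert float(compute_dihedral(*pts)) == pytest.approx(ref, abs=1e-4)

    def test_mirror_image_flips_sign(self):
        p = [np.array([1.0, 1, 0]), np.array([1.0, 0, 0]), np.array([0.0, 0, 0]),
             np.array([0.0, 0.5, 0.866])]
        ang = compute_dihedral(*p)
        mirrored = [q * np.array([1, 1, -1]) for q in p]
        assert float(compute_dihedral(*mirrored)) == pytest.approx(-float(ang), abs=1e-9)

    def test_degenerate_geometry_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            compute_dihedral([0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0])


class TestTensorO2:
    def test_constant_vector_is_rigid(self):
        v = np.tile([0.0, 0.0, 1.0], (10, 1))
        assert o2_tensor(v) == pytest.approx(1.0, abs=1e-12)

    def test_isotropic_vectors_give_zero(self):
        rng = np.random.default_rng(0)
        v = rng.standard_normal((100_000, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        assert abs(o2_tensor(v)) < 0.01

    def test_exact_three_site_average_is_one_ninth(self):
        v = axis_vector_from_angles(THETA_TET, np.array(MET_WELLS))
        o2 = o2_tensor(v, np.full(3, 1 / 3))
        assert o2 == pytest.approx(1.0 / 9.0, abs=1e-12)

    def test_global_rotation_invariance(self):
        spec = RotamerJumpSpec(n_frames=3000, seed=2)
        v, _, _ = simulate_rotamer_trajectory(spec)
        rot = Rotation.from_euler("zyx", [11.0, 47.0, -3.0], degrees=True)
        assert o2_tensor(rot.apply(v)) == pytest.approx(o2_tensor(v), abs=1e-12)

    def test_unnormalized_weights_warn_but_normalize(self):
        v = axis_vector_from_angles(90.0, np.array([0.0, 90.0]))
        with pytest.warns(UserWarning, match="normaliz"):
            o2 = o2_tensor(v, np.array([2.0, 2.0]))
        assert o2 == pytest.approx(0.25, abs=1e-12)


class TestTCF:
    def test_constant_vector_tcf_is_one(self):
        v = np.tile([0.0, 0.0, 1.0], (100, 1))
        tcf = internal_tcf(v, 10)
        np.testing.assert_allclose(tcf.values, 1.0, atol=1e-12)

    def test_alternating_orthogonal_vectors(self):
        v = np.tile([[1.0, 0, 0], [0, 1.0, 0]], (50, 1))
        tcf = internal_tcf(v, 6)
        np.testing.assert_allclose(tcf.values[1::2], -0.5, atol=1e-12)
        np.testing.assert_allclose(tcf.values[0::2], 1.0, atol=1e-12)

    def test_fast_jump_plateau_matches_tensor(self):
        spec = RotamerJumpSpec(
            well_angles=MET_WELLS, populations=(1 / 3, 1 / 3, 1 / 3),
            exchange_prob=0.8, libration_sd=0.0, theta_bond=THETA_TET,
            n_frames=100_000, seed=6,
        )
        v, _, _ = simulate_rotamer_trajectory(spec)
        tcf = internal_tcf(v, 300)
        assert tcf_plateau(tcf) == pytest.approx(o2_tensor(v), abs=0.02)
        assert tcf_plateau(tcf) == pytest.approx(1.0 / 9.0, abs=0.02)

    def test_plateau_modes(self):
        tcf = TimeCorrelation(lags=np.arange(11), values=np.r_[1.0, np.full(10, 0.4)])
        tcf2 = TimeCorrelation(lags=np.arange(100), values=np.r_[1.0, np.full(99, 0.4)])
        assert tcf_plateau(tcf, "last_point") == pytest.approx(0.4)
        assert tcf_plateau(tcf2, "tail_mean", window=0.1) == pytest.approx(0.4)
        lin = np.r_[1.0, np.full(89, 0.5), np.linspace(0.30, 0.20, 10)]
        tcf3 = TimeCorrelation(lags=np.arange(100), values=lin)
        assert tcf_plateau(tcf3, "tail_mean", window=0.1) == pytest.approx(0.25, abs=0.006)

    def test_max_lag_too_large_rejected(self):
        v = np.tile([0.0, 0.0, 1.0], (20, 1))
        with pytest.raises(ValueError, match="max_lag"):
            internal_tcf(v, 10)

    def test_replica_average_matches_pooled_origins(self):
        specs = [RotamerJumpSpec(n_frames=20_000, seed=s, libration_sd=0.0,
                                 exchange_prob=0.7) for s in (1, 2, 3)]
        tcfs = [internal_tcf(simulate_rotamer_trajectory(s)[0], 50) for s in specs]
        avg = average_tcf(tcfs)
        assert len(avg.replicas) == 3
        for t in tcfs:
            np.testing.assert_allclose(avg.values, t.values, atol=0.05)


class TestParameterizations:
    def test_angle_route_immune_to_residual_global_motion(self):
        # small random global rotations mimic imperfect superposition: the
        # Cartesian-vector O2 drops, the (theta, chi) internal route does not
        spec = RotamerJumpSpec(n_frames=20_000, seed=8, libration_sd=5.0)
        v, chi, _ = simulate_rotamer_trajectory(spec)
        rng = np.random.default_rng(9)
        wobble = Rotation.from_rotvec(rng.normal(0, 0.12, (v.shape[0], 3)))
        v_wobbled = np.einsum("nij,nj->ni", wobble.as_matrix(), v)
        o2_vector = o2_tensor(v_wobbled)
        o2_angle = o2_tensor(axis_vector_from_angles(spec.theta_bond, chi))
        assert o2_angle > o2_vector
        assert o2_angle == pytest.approx(o2_tensor(v), abs=1e-12)

    def test_spherical_parameterization_geometry(self):
        # theta_bond = 100 deg, chi = 180 deg: polar angle is pi - theta
        v = axis_vector_from_angles(100.0, 180.0)
        assert v @ np.array([0, 0, 1.0]) == pytest.approx(
            np.cos(np.radians(180.0 - 100.0)), abs=1e-12
        )
        assert np.degrees(np.arctan2(v[1], v[0])) == pytest.approx(180.0, abs=1e-9)


class TestMethylExtraction:
    def _write_pdb(self, path, frames):
        # minimal 2-model methionine fragment: CB, CG, SD, CE (+3 CA for fitting)
        lines = []
        for m, coords in enumerate(frames, start=1):
            lines.append(f"MODEL     {m:4d}")
            atoms = ["CA", "CA", "CA", "N", "CA", "CB", "CG", "SD", "CE"]
            resids = [1, 2, 3, 4, 4, 4, 4, 4, 4]
            resnames = ["GLY", "GLY", "GLY", "MET", "MET", "MET", "MET", "MET", "MET"]
            for i, (name, xyz) in enumerate(zip(atoms, coords), start=1):
                lines.append(
                    f"ATOM  {i:5d} {name:^4s}{resnames[i-1]:>4s} A{resids[i-1]:4d}    "
                    f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00"
                )
            lines.append("ENDMDL")
        lines.append("END")
        path.write_text("\n".join(lines) + "\n")

    def make_frame(self, chi3=180.0, angle=100.0):
        # place CB-CG along x, SD at origin; CE from the internal coordinates
        cb = np.array([3.0, 1.0, 0.0])
        cg = np.array([1.5, 0.0, 0.0])
        sd = np.array([0.0, 0.0, 0.0])
        d = 1.8
        th = np.radians(180.0 - angle)
        ph = np.radians(chi3)
        axis = (sd - cg) / np.linalg.norm(sd - cg)
        # local frame: z along CG->SD, x in the CB-CG-SD plane
        zloc = axis
        xref = cb - cg
        xloc = xref - (xref @ zloc) * zloc
        xloc /= np.linalg.norm(xloc)
        yloc = np.cross(zloc, xloc)
        ce = sd + d * (
            np.sin(th) * np.cos(ph) * xloc + np.sin(th) * np.sin(ph) * yloc + np.cos(th) * zloc
        )
        cas = [np.array([8.0, 0, 0]), np.array([0, 8.0, 0]), np.array([0, 0, 8.0])]
        n = cb + np.array([0.0, 1.4, 0.3])
        ca = cb + np.array([1.2, 0.9, 0.1])
        return np.array(cas + [n, ca, cb, cg, sd, ce])

    def test_hand_built_geometry_recovers_internal_coordinates(self, tmp_path):
        pytest.importorskip("MDAnalysis")
        from methylscape.ensemble import extract_methyl_axes

        path = tmp_path / "met.pdb"
        f1 = self.make_frame(chi3=180.0, angle=100.0)
        f2 = self.make_frame(chi3=60.0, angle=100.0)
        self._write_pdb(path, [f1, f2])
        ens = extract_methyl_axes(str(path))
        assert ens.residue_ids == ["M4"]
        assert ens.n_frames == 2
        chi3 = ens.chi[0, :, 2]
        assert abs(chi3[0]) == pytest.approx(180.0, abs=0.1)
        assert chi3[1] == pytest.approx(60.0, abs=0.1)
        assert ens.theta_bond[0, 0] == pytest.approx(100.0, abs=0.1)

    def test_rigid_rotation_leaves_internal_coordinates_unchanged(self, tmp_path):
        pytest.importorskip("MDAnalysis")
        from methylscape.ensemble import extract_methyl_axes

        f1 = self.make_frame(chi3=-60.0, angle=97.0)
        rot = Rotation.from_euler("zyx", [30.0, 10.0, -45.0], degrees=True)
        p1, p2 = tmp_path / "a.pdb", tmp_path / "b.pdb"
        self._write_pdb(p1, [f1, f1])
        self._write_pdb(p2, [f1, rot.apply(f1)])
        a = extract_methyl_axes(str(p1), superpose=False)
        b = extract_methyl_axes(str(p2), superpose=False)
        # PDB fields carry 3 decimals, so internal coordinates match to ~0.05 deg
        np.testing.assert_allclose(b.chi[0, 1, 2], a.chi[0, 0, 2], atol=0.05)
        np.testing.assert_allclose(b.theta_bond[0, 1], a.theta_bond[0, 0], atol=0.05)


class TestEnsembleIO:
    def test_tsv_round_trip(self, tmp_path):
        spec = RotamerJumpSpec(n_frames=50, seed=1)
        v, chi, _ = simulate_rotamer_trajectory(spec)
        ens = TrajectoryEnsemble(
            residue_ids=["M244"], vectors=v[None], chi=chi[None], residue_names=["MET"]
        )
        path = tmp_path / "ens.tsv"
        ens.to_tsv(path)
        back = TrajectoryEnsemble.from_tsv(path)
        np.testing.assert_allclose(back.vectors, ens.vectors, atol=1e-9)
        np.testing.assert_allclose(back.chi[:, :, 0], ens.chi[:, :, 0], atol=1e-8)
        assert back.residue_ids == ["M244"]

    def test_invariants_enforced(self):
        v = np.tile([0.0, 0.0, 2.0], (5, 1))[None]  # not unit length
        with pytest.raises(ValueError, match="unit"):
            TrajectoryEnsemble(residue_ids=["M1"], vectors=v, chi=np.zeros((1, 5)))
        with pytest.raises(ValueError, match="non-negative"):
            TrajectoryEnsemble(
                residue_ids=["M1"],
                vectors=np.tile([0.0, 0.0, 1.0], (5, 1))[None],
                chi=np.zeros((1, 5)),
                weights=np.array([1, 1, 1, 1, -1.0]),
            )


    def test_parquet_round_trip(self, tmp_path):
        pytest.importorskip("pyarrow")
        spec = RotamerJumpSpec(n_frames=30, seed=2)
        v, chi, _ = simulate_rotamer_trajectory(spec)
        ens = TrajectoryEnsemble(residue_ids=["M1"], vectors=v[None], chi=chi[None])
        path = tmp_path / "ens.parquet"
        ens.to_parquet(path)
        back = TrajectoryEnsemble.from_parquet(path)
        np.testing.assert_allclose(back.vectors, ens.vectors, atol=1e-12)
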