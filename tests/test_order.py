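"""Hydrogen-bond criterion, translational order zeta, tetrahedral order q."""

import numpy as np
import pytest

from _oracles import (
    h_away,
    h_between,
    q_oracle,
    random_dense_waters,
    shell_oracle,
    water_system,
    zeta_oracle,
)
from hydrocouple import order, shell, synthetic
from hydrocouple.exceptions import InsufficientNeighborsError
from hydrocouple.trajectory import Frame

BIG = 200.0  # box large enough that wrapping never matters
C = np.array([100.0, 100.0, 100.0])


def _pair(d, angle_deg):
    """Two waters at O-O distance d with one donor at an exact angle."""
    o = np.array([C, C + [d, 0, 0]])
    h = np.array(
        [
            [h_between(o[0], o[1], angle_deg), h_away(o[0], o[1])],
            [h_away(o[1], o[0]), h_away(o[1], o[0])],
        ]
    )
    return water_system(o, h, BIG)


class TestHydrogenBond:
    @pytest.mark.parametrize(
        "dist,angle,expected",
        [
            (3.4, 170.0, True),   # inside both criteria
            (3.6, 180.0, False),  # too far despite perfect linearity
            (3.0, 135.0, False),  # 45 deg deviation exceeds 40 deg
            (3.4, 140.01, True),  # just inside the angular limit
            (3.4, 139.99, False),  # just outside the angular limit
        ],
    )
    def test_distance_and_angle_criteria(self, dist, angle, expected):
        top, frame = _pair(dist, angle)
        assert order.is_hydrogen_bonded(0, 1, frame, top) is expected

    def test_symmetric_either_molecule_may_donate(self):
        # donor hydrogen sits on water B, pointing at A
        o = np.array([C, C + [3.0, 0, 0]])
        h = np.array(
            [
                [h_away(o[0], o[1]), h_away(o[0], o[1])],
                [h_between(o[1], o[0], 175.0), h_away(o[1], o[0])],
            ]
        )
        top, frame = water_system(o, h, BIG)
        assert order.is_hydrogen_bonded(0, 1, frame, top)
        assert order.is_hydrogen_bonded(1, 0, frame, top)

    def test_adjacency_matrix_is_symmetric(self):
        o, h = random_dense_waters(30, 12.0, seed=31)
        top, frame = water_system(o, h, 12.0)
        adj = order.hbond_adjacency(frame, top)
        assert (adj == adj.T).all()
        assert not adj.diagonal().any()


class TestZeta:
    def test_definition_arithmetic(self):
        # bonded partners at 2.7 and 2.9, nearest non-bonded at 3.8
        o = np.array([C, C + [2.7, 0, 0], C + [-2.9, 0, 0], C + [0, 3.8, 0]])
        h = np.array(
            [
                [h_between(o[0], o[1], 175.0), h_between(o[0], o[2], 175.0)],
                [h_away(o[1], o[0]), h_away(o[1], o[0])],
                [h_away(o[2], o[0]), h_away(o[2], o[0])],
                [h_away(o[3], o[0]), h_away(o[3], o[0])],
            ]
        )
        top, frame = water_system(o, h, BIG)
        assert order.zeta(0, frame, top) == pytest.approx(
            3.8 - 2.9, abs=1e-12
        )

    def test_penetration_gives_negative_zeta(self):
        # farthest bonded at 3.4, nearest non-bonded inside it at 3.0
        o = np.array([C, C + [3.4, 0, 0], C + [0, 3.0, 0], C + [0, -8.0, 0]])
        h = np.array(
            [
                [h_between(o[0], o[1], 175.0), h_away(o[0], o[2])],
                [h_away(o[1], o[0]), h_away(o[1], o[0])],
                [h_away(o[2], o[0]), h_away(o[2], o[0])],
                [h_away(o[3], o[0]), h_away(o[3], o[0])],
            ]
        )
        top, frame = water_system(o, h, BIG)
        assert order.zeta(0, frame, top) == pytest.approx(-0.4, abs=1e-12)

    def test_undefined_without_partner_or_without_nonbonded(self):
        # isolated molecules: no hydrogen bonds at all
        o = np.array([C, C + [50, 0, 0], C + [0, 50, 0]])
        h = np.stack([[h_away(p, p + [1, 0, 0]), h_away(p, p + [0, 1, 0])]
                      for p in o])
        top, frame = water_system(o, h, BIG)
        rec = order.zeta_frame(frame, top)
        assert np.isnan(rec.zeta).all()
        assert rec.n_undefined == 3
        # fully bonded triangle: no non-bonded neighbor exists
        o2 = np.array([C, C + [2.8, 0, 0], C + [1.4, 2.4, 0]])
        h2 = np.array(
            [
                [h_between(o2[0], o2[1], 175.0), h_between(o2[0], o2[2], 175.0)],
                [h_between(o2[1], o2[2], 175.0), h_away(o2[1], o2[0])],
                [h_away(o2[2], o2[0]), h_away(o2[2], o2[0])],
            ]
        )
        top2, frame2 = water_system(o2, h2, BIG)
        assert np.isnan(order.zeta_frame(frame2, top2).zeta).all()


class TestTetrahedralQ:
    def _with_neighbors(self, dirs, dist=2.8):
        o = np.vstack([C, C + dist * np.asarray(dirs, float)])
        h = np.stack(
            [[p + [0.6, 0.6, 0.3], p + [-0.6, 0.6, 0.3]] for p in o]
        )
        return water_system(o, h, BIG)

    def test_perfect_tetrahedron(self):
        dirs = np.array(
            [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]]
        ) / np.sqrt(3)
        top, frame = self._with_neighbors(dirs)
        assert order.tetrahedral_q(0, frame, top) == pytest.approx(
            1.0, abs=1e-9
        )

    def test_square_planar(self):
        dirs = [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0]]
        top, frame = self._with_neighbors(dirs)
        assert order.tetrahedral_q(0, frame, top) == pytest.approx(
            0.5, abs=1e-9
        )

    def test_collinear_neighbors(self):
        o = np.vstack([C] + [C + [d, 0, 0] for d in (2.5, 2.6, 2.7, 2.8)])
        h = np.stack(
            [[p + [0.6, 0.6, 0.3], p + [-0.6, 0.6, 0.3]] for p in o]
        )
        top, frame = water_system(o, h, BIG)
        assert order.tetrahedral_q(0, frame, top) == pytest.approx(
            -3.0, abs=1e-9
        )

    def test_requires_four_other_waters(self):
        o = np.vstack([C, C + [3, 0, 0], C + [0, 3, 0], C + [0, 0, 3]])
        h = np.stack(
            [[p + [0.6, 0.6, 0.3], p + [-0.6, 0.6, 0.3]] for p in o]
        )
        top, frame = water_system(o, h, BIG)
        with pytest.raises(InsufficientNeighborsError):
            order.tetrahedral_q(0, frame, top)


class TestOracleEquivalence:
    """Vectorized zeta/q equal a pure-python exhaustive re-implementation."""

    @pytest.mark.parametrize("seed", [41, 42])
    def test_random_box(self, seed):
        o, h = random_dense_waters(30, 11.5, seed=seed)
        top, frame = water_system(o, h, 11.5)
        rec = order.zeta_frame(frame, top, with_q=True)
        z_ref = zeta_oracle(o, h, frame.box)
        assert np.isnan(rec.zeta).tolist() == np.isnan(z_ref).tolist()
        np.testing.assert_allclose(rec.zeta, z_ref, atol=1e-10)
        np.testing.assert_allclose(
            rec.q, q_oracle(o, frame.box), atol=1e-10
        )
        # record invariants
        defined = np.isfinite(rec.zeta)
        assert (rec.n_hbonds[defined] >= 1).all()
        assert (rec.r_hb[defined] < 3.5).all()
        assert (rec.r_hb[defined] > 0).all()
        np.testing.assert_allclose(
            rec.zeta[defined],
            rec.r_nhb[defined] - rec.r_hb[defined],
            atol=1e-12,
        )
        assert (rec.q <= 1.0 + 1e-12).all()

    def test_rigid_motion_invariance(self):
        o, h = random_dense_waters(20, 40.0, seed=43)
        # keep the cloud compact so rotation cannot cross the boundary
        o = o * 0.25 + 15.0
        h = h * 0.25 + 15.0
        top, frame = water_system(o, h, 40.0)
        rec = order.zeta_frame(frame, top, with_q=True)
        rng = np.random.default_rng(44)
        a = rng.normal(size=(3, 3))
        rot, _ = np.linalg.qr(a)
        if np.linalg.det(rot) < 0:
            rot[:, 0] *= -1
        centre = np.full(3, 20.0)
        moved = (frame.coordinates - centre) @ rot.T + centre
        rec2 = order.zeta_frame(Frame(moved, frame.box), top, with_q=True)
        np.testing.assert_allclose(rec.zeta, rec2.zeta, atol=1e-9)
        np.testing.assert_allclose(rec.q, rec2.q, atol=1e-9)


class TestResidueSeriesAndBulk:
    def test_series_equals_frame_by_frame_recomputation(self):
        toy = synthetic.gen_toy_system(n_residues=8, n_frames=20, seed=3)
        fs = toy.frames
        assignments = shell.assign_all(fs)
        result = order.residue_zeta_series(fs, assignments)
        water_pos = {int(w): k for k, w in enumerate(fs.topology.water_residues)}
        for i in range(fs.n_frames):
            frame = fs.frame(i)
            oref = shell_oracle(frame, fs.topology)
            assert oref == set(assignments[i].shell_waters)
            rec = order.zeta_frame(frame, fs.topology)
            per_res: dict[int, list] = {}
            for w, r in assignments[i].contact_map.items():
                z = rec.zeta[water_pos[w]]
                if np.isfinite(z):
                    per_res.setdefault(r, []).append(z)
            for r, s in result.series.items():
                if r in per_res:
                    assert s.values[i] == pytest.approx(
                        np.mean(per_res[r]), abs=1e-12
                    )
                else:
                    assert np.isnan(s.values[i])

    def test_bulk_reference_constant_lattice(self):
        fs = synthetic.gen_water_box("lattice", 64, seed=5)
        mean_z, mean_q = order.bulk_reference(fs, "pure_system")
        assert mean_q == pytest.approx(1.0, abs=1e-9)
        assert mean_z == pytest.approx(1.7407, abs=1e-3)
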