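"""RMSF, SASA, per-residue RMSD and chemical classification."""

import numpy as np
import pytest

from _oracles import quaternion_superpose
from hydrocouple import descriptors
from hydrocouple.exceptions import ClassificationError, ConfigurationError
from hydrocouple.trajectory import Frame, FrameSet, Topology


def _protein_topology(n_atoms, atoms_per_res=1, element="C"):
    names = [f"C{i + 1}" for i in range(n_atoms)]
    residx = [i // atoms_per_res for i in range(n_atoms)]
    n_res = residx[-1] + 1
    return Topology(
        np.array(names, dtype=object),
        np.array([element] * n_atoms, dtype=object),
        np.array(residx),
        np.array(["ALA"] * n_res, dtype=object),
    )


def _frameset(top, coords, dt=1.0):
    coords = np.asarray(coords, float)
    n = len(coords)
    return FrameSet(
        top,
        coords,
        np.full((n, 3), 500.0),
        dt * np.arange(n, dtype=float),
    )


class TestResidueClass:
    @pytest.mark.parametrize(
        "name,expected",
        [
            ("LYS", "charged"),
            ("SER", "polar"),
            ("LEU", "non-polar"),
            ("GLY", "excluded"),
            ("TRP", "non-polar"),
            ("ASP", "charged"),
        ],
    )
    def test_standard_assignments(self, name, expected):
        assert descriptors.residue_class(name) == expected

    def test_histidine_is_configurable(self):
        assert descriptors.residue_class("HIS") == "charged"
        assert descriptors.residue_class("HIS", histidine="polar") == "polar"

    def test_unknown_name_rejected(self):
        with pytest.raises(ClassificationError, match="UNK"):
            descriptors.residue_class("UNK")


class TestRmsf:
    def test_static_atom_is_zero(self):
        top = _protein_topology(2)
        coords = np.tile(
            np.array([[10.0, 10, 10], [14.0, 10, 10]]), (5, 1, 1)
        )
        out = descriptors.rmsf(_frameset(top, coords))
        assert np.allclose(out.values, 0.0, atol=1e-12)

    def test_alternating_unit_displacement(self):
        # one atom oscillating +-1 A about its mean, fit disabled
        top = _protein_topology(2)
        coords = np.tile(
            np.array([[10.0, 10, 10], [14.0, 10, 10]]), (6, 1, 1)
        )
        coords[::2, 0, 0] += 1.0
        coords[1::2, 0, 0] -= 1.0
        out = descriptors.rmsf(_frameset(top, coords), superpose=False)
        assert out.iloc[0] == pytest.approx(1.0, abs=1e-12)
        assert out.iloc[1] == pytest.approx(0.0, abs=1e-12)

    def test_matches_independent_superposition_oracle(self):
        rng = np.random.default_rng(51)
        top = _protein_topology(5)
        base = rng.uniform(5, 15, (5, 3))
        coords = base + np.cumsum(rng.normal(0, 0.1, (100, 5, 3)), axis=0)
        fs = _frameset(top, coords)
        got = descriptors.rmsf(fs)
        # oracle: quaternion superposition then the direct formula
        aligned = np.stack(
            [quaternion_superpose(c, coords[0]) for c in coords]
        )
        mean_pos = aligned.mean(axis=0)
        expected = np.sqrt(
            np.mean(np.sum((aligned - mean_pos) ** 2, axis=2), axis=0)
        )
        np.testing.assert_allclose(got.values, expected, atol=1e-8)

    def test_invariant_under_rigid_motion_per_frame(self):
        rng = np.random.default_rng(52)
        top = _protein_topology(6)
        coords = rng.uniform(5, 15, (1, 6, 3)) + rng.normal(
            0, 0.2, (30, 6, 3)
        )
        ref = descriptors.rmsf(_frameset(top, coords))
        moved = coords.copy()
        for t in range(len(moved)):
            a = rng.normal(size=(3, 3))
            rot, _ = np.linalg.qr(a)
            if np.linalg.det(rot) < 0:
                rot[:, 0] *= -1
            moved[t] = moved[t] @ rot.T + rng.uniform(-20, 20, 3)
        got = descriptors.rmsf(_frameset(top, moved))
        np.testing.assert_allclose(got.values, ref.values, atol=1e-8)

    def test_requires_two_frames(self):
        top = _protein_topology(2)
        with pytest.raises(ConfigurationError):
            descriptors.rmsf(
                _frameset(top, np.zeros((1, 2, 3)) + 10.0)
            )


class TestSasa:
    def test_isolated_carbon_closed_form(self):
        top = _protein_topology(1)
        frame = Frame(np.array([[10.0, 10, 10]]), np.array([50.0] * 3))
        got = float(descriptors.sasa_frame(frame, top).iloc[0])
        exact = 4 * np.pi * (1.7 + 1.4) ** 2
        assert got == pytest.approx(exact, rel=0.01)

    def test_coincident_atoms_count_once(self):
        top = _protein_topology(2)
        frame = Frame(
            np.array([[10.0, 10, 10], [10.0, 10, 10]]), np.array([50.0] * 3)
        )
        total = float(descriptors.sasa_frame(frame, top).sum())
        assert total == pytest.approx(4 * np.pi * 3.1**2, rel=0.01)

    def test_two_spheres_match_cap_formula(self):
        top = _protein_topology(2)
        frame = Frame(
            np.array([[10.0, 10, 10], [13.0, 10, 10]]), np.array([50.0] * 3)
        )
        total = float(descriptors.sasa_frame(frame, top).sum())
        r, d = 3.1, 3.0
        analytic = 2 * (4 * np.pi * r * r - 2 * np.pi * r * (r - d / 2))
        assert total == pytest.approx(analytic, rel=0.02)

    def test_burial_monotone_as_neighbor_approaches(self):
        top = _protein_topology(2)
        areas = []
        for d in (8.0, 6.0, 5.0, 4.0, 3.0, 2.0):
            frame = Frame(
                np.array([[10.0, 10, 10], [10.0 + d, 10, 10]]),
                np.array([50.0] * 3),
            )
            areas.append(float(descriptors.sasa_frame(frame, top).iloc[0]))
        assert areas == sorted(areas, reverse=True)

    def test_per_residue_sums_to_total(self):
        rng = np.random.default_rng(53)
        top = _protein_topology(12, atoms_per_res=3)
        frame = Frame(rng.uniform(8, 16, (12, 3)), np.array([50.0] * 3))
        per_res = descriptors.sasa_frame(frame, top)
        all_in_one = descriptors.sasa_frame(
            frame,
            _protein_topology(12, atoms_per_res=12),
        )
        assert float(per_res.sum()) == pytest.approx(
            float(all_in_one.sum()), abs=1e-9
        )

    def test_unknown_element_rejected(self):
        top = Topology(
            np.array(["XX1"], dtype=object),
            np.array(["X"], dtype=object),
            np.array([0]),
            np.array(["ALA"], dtype=object),
        )
        frame = Frame(np.array([[10.0, 10, 10]]), np.array([50.0] * 3))
        with pytest.raises(ConfigurationError):
            descriptors.sasa_frame(frame, top)


class TestResidueRmsd:
    def test_identity_frames_give_zero(self):
        top = _protein_topology(6, atoms_per_res=2)
        coords = np.tile(np.random.default_rng(0).uniform(5, 15, (6, 3)),
                         (4, 1, 1))
        series = descriptors.residue_rmsd_series(_frameset(top, coords))
        for s in series.values():
            assert np.allclose(s.values, 0.0, atol=1e-10)

    def test_rigidly_displaced_residue(self):
        # many anchor residues dominate the fit; one residue shifts by 2 A
        rng = np.random.default_rng(54)
        top = _protein_topology(200, atoms_per_res=2)
        base = rng.uniform(0, 60, (200, 3)) + 10.0
        coords = np.tile(base, (3, 1, 1))
        coords[2, :2, :] += np.array([2.0, 0.0, 0.0])
        series = descriptors.residue_rmsd_series(_frameset(top, coords))
        # the global fit absorbs a little of the shift (1/100 of atoms moved)
        assert series[0].values[2] == pytest.approx(2.0, rel=0.05)
        assert series[5].values[2] == pytest.approx(0.0, abs=0.1)

    def test_matches_quaternion_oracle(self):
        rng = np.random.default_rng(55)
        top = _protein_topology(9, atoms_per_res=3)
        coords = rng.uniform(5, 15, (1, 9, 3)) + np.cumsum(
            rng.normal(0, 0.15, (50, 9, 3)), axis=0
        )
        fs = _frameset(top, coords)
        got = descriptors.residue_rmsd_series(fs)
        for t in range(50):
            aligned = quaternion_superpose(coords[t], coords[0])
            for r in range(3):
                atoms = slice(3 * r, 3 * r + 3)
                expected = np.sqrt(
                    np.mean(
                        np.sum(
                            (aligned[atoms] - coords[0, atoms]) ** 2, axis=1
                        )
                    )
                )
                assert got[r].values[t] == pytest.approx(expected, abs=1e-8)
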