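"""Helix axis, local bilayer normal, and tilt classification."""

import numpy as np
import pytest

import vesitraj as vt
from vesitraj.errors import VesitrajError
from vesitraj.peptide import (
    classify_tilt,
    local_bilayer_normal,
    peptide_axis,
    tilt_angle,
    tilt_series,
)
from vesitraj.synthetic import rotation_about
from vesitraj.topology import Molecule, MoleculeMap


def _ca_map(n, offset=0):
    idx = np.arange(offset, offset + n)
    return MoleculeMap(molecules=[Molecule(0, "peptide", idx)], peptide_calphas=idx)


class TestAxis:
    def test_trace_along_z(self):
        coords = np.zeros((16, 3))
        coords[:, 2] = 1.5 * np.arange(16)
        fr = vt.Frame(coords)
        np.testing.assert_allclose(peptide_axis(fr, _ca_map(16)), [0, 0, 1], atol=1e-9)

    def test_reversed_residue_order_negates_axis(self, rng):
        coords = rng.normal(size=(12, 3)) + np.linspace(0, 20, 12)[:, None]
        fr = vt.Frame(coords)
        fwd = peptide_axis(fr, _ca_map(12))
        rev_map = MoleculeMap(
            molecules=[Molecule(0, "peptide", np.arange(12))],
            peptide_calphas=np.arange(11, -1, -1),
        )
        np.testing.assert_allclose(peptide_axis(fr, rev_map), -fwd, atol=1e-12)

    def test_bent_trace_equals_normalized_end_to_end(self, rng):
        coords = np.cumsum(rng.normal(size=(10, 3)), axis=0)
        fr = vt.Frame(coords)
        e = coords[-1] - coords[0]
        np.testing.assert_allclose(peptide_axis(fr, _ca_map(10)), e / np.linalg.norm(e), atol=1e-12)

    def test_too_few_calphas_raise(self):
        with pytest.raises(VesitrajError):
            peptide_axis(vt.Frame(np.zeros((1, 3))), _ca_map(1))


class TestLocalNormal:
    def test_normal_matches_planted_radial_direction(self, da25_vesicle):
        traj, mmap, truth = da25_vesicle
        t2, m2, tr2 = vt.make_peptide(vt.PeptideSpec(planted_tilt=90, seed=31), traj, mmap, truth)
        fr = t2.frame(0)
        c = vt.vesicle_center(fr, m2, t2.elements)
        normal, support = local_bilayer_normal(fr, m2, c)
        w = np.asarray(tr2.peptide_normal)
        ang = np.degrees(np.arccos(np.clip(np.dot(normal, w), -1, 1)))
        assert ang < 2.0
        assert support >= 5

    def test_support_counts_match_brute_force_scan(self, da25_vesicle):
        traj, mmap, truth = da25_vesicle
        t2, m2, _ = vt.make_peptide(vt.PeptideSpec(planted_tilt=45, seed=32), traj, mmap, truth)
        fr = t2.frame(0)
        _, support = local_bilayer_normal(fr, m2, np.zeros(3), cutoff=8.0)
        pep = fr.coords[m2.atoms_by_species("peptide")]
        count = 0
        for m in range(m2.n_amphiphiles):
            atoms = fr.coords[m2.amphiphile_atom_matrix[m]]
            d = np.linalg.norm(atoms[:, None, :] - pep[None, :, :], axis=2)
            count += bool((d < 8.0).any())
        assert support == count

    def test_isolated_peptide_has_no_normal(self, small_vesicle):
        traj, mmap, truth = small_vesicle
        t2, m2, _ = vt.make_peptide(
            vt.PeptideSpec(planted_tilt=0, insertion_depth=30.0, seed=33), traj, mmap, truth
        )
        fr = t2.frame(0)
        normal, support = local_bilayer_normal(fr, m2, np.zeros(3))
        assert normal is None
        ts = tilt_series(t2, m2)
        assert ts.missing[0]
        assert np.isnan(ts.tilt_deg[0])
        assert ts.tilt_class[0] == "missing"


class TestTiltAngle:
    @pytest.mark.parametrize(
        "axis,angle,cls",
        [
            ([0, 0, 1], 0.0, "inserted C->N"),
            ([1, 0, 0], 90.0, "surface"),
            ([0, 0, -1], 180.0, "inserted N->C"),
        ],
    )
    def test_anchor_geometries(self, axis, angle, cls):
        got, got_cls = tilt_angle(np.asarray(axis, dtype=float), np.array([0.0, 0, 1]))
        assert got == pytest.approx(angle, abs=1e-9)
        assert got_cls == cls

    def test_class_is_pure_function_of_windows(self):
        assert classify_tilt(45.0) == "intermediate"
        assert classify_tilt(29.9) == "inserted C->N"
        assert classify_tilt(135.0) == "intermediate"
        custom = ((0, 10, "in"), (10, 170, "mid"), (170, 180, "out"))
        assert classify_tilt(45.0, custom) == "mid"

    def test_zero_vector_rejected(self):
        with pytest.raises(VesitrajError):
            tilt_angle(np.zeros(3), np.array([0.0, 0, 1]))


class TestRecovery:
    @pytest.mark.parametrize("tilt", [0.0, 30.0, 54.74, 90.0, 120.0, 180.0])
    def test_planted_tilt_recovered_within_two_degrees(self, da25_vesicle, tilt):
        traj, mmap, truth = da25_vesicle
        t2, m2, _ = vt.make_peptide(vt.PeptideSpec(planted_tilt=tilt, seed=7), traj, mmap, truth)
        ts = tilt_series(t2, m2)
        assert ts.tilt_deg[0] == pytest.approx(tilt, abs=2.0)
        expected_class = {0.0: "inserted C->N", 90.0: "surface", 180.0: "inserted N->C"}.get(tilt)
        if expected_class:
            assert ts.tilt_class[0] == expected_class

    def test_tilt_invariant_under_global_rotation(self, da25_vesicle, rng):
        traj, mmap, truth = da25_vesicle
        t2, m2, _ = vt.make_peptide(vt.PeptideSpec(planted_tilt=60, seed=8), traj, mmap, truth)
        base = tilt_series(t2, m2).tilt_deg[0]
        rot = rotation_about(rng.normal(size=3), 2.1)
        turned = vt.Trajectory(t2.coords @ rot.T, t2.timestep, list(t2.elements))
        assert tilt_series(turned, m2).tilt_deg[0] == pytest.approx(base, abs=1e-6)
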