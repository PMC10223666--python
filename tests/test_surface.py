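"""SASA, chain order parameters, density maps, and RDF."""

import numpy as np
import pytest
from scipy import stats

import vesitraj as vt
from vesitraj.errors import ConfigurationError
from vesitraj.radii import AtomRadiusTable
from vesitraj.surface import (
    density_map,
    order_parameter_from_cosines,
    order_parameters,
    rdf,
    sasa,
)
from vesitraj.synthetic import fibonacci_sphere, rotation_about


def _mc_sasa(xyz, radii, probe, n_samples, rng):
    """Independent Monte-Carlo surface oracle: random directions per atom."""
    r = radii + probe
    per_atom = n_samples // len(xyz)
    total = 0.0
    for i in range(len(xyz)):
        dirs = rng.normal(size=(per_atom, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        pts = xyz[i] + r[i] * dirs
        buried = np.zeros(per_atom, dtype=bool)
        for j in range(len(xyz)):
            if j == i:
                continue
            buried |= np.sum((pts - xyz[j]) ** 2, axis=1) < r[j] ** 2
        total += (1.0 - buried.mean()) * 4.0 * np.pi * r[i] ** 2
    return total


class TestSASA:
    def test_isolated_sphere_closed_form(self):
        res = sasa(vt.Frame(np.zeros((1, 3))), ["C"], n_points=960)
        expected = 4.0 * np.pi * (1.7 + 1.4) ** 2  # A^2
        assert res.total * 100.0 == pytest.approx(expected, rel=1e-4)

    def test_non_overlapping_atoms_are_additive(self):
        frame = vt.Frame(np.array([[0.0, 0, 0], [50.0, 0, 0]]))
        res = sasa(frame, ["C", "O"], n_points=500)
        lone = sum(
            sasa(vt.Frame(np.zeros((1, 3))), [e], n_points=500).total for e in ("C", "O")
        )
        assert res.total == pytest.approx(lone, rel=1e-12)

    def test_monotone_decrease_on_approach(self):
        prev = np.inf
        for d in (7.0, 5.0, 3.0, 1.5, 0.5):
            frame = vt.Frame(np.array([[0.0, 0, 0], [d, 0, 0]]))
            tot = sasa(frame, ["C", "C"], n_points=960).total
            assert tot <= prev + 1e-9
            prev = tot

    @pytest.mark.parametrize("seed", [0, 1])
    def test_five_atom_cluster_matches_monte_carlo_oracle(self, seed):
        rng = np.random.default_rng(seed)
        xyz = rng.normal(scale=1.8, size=(5, 3))
        elements = ["C", "O", "N", "C", "O"]
        res = sasa(vt.Frame(xyz), elements, n_points=960)
        table = AtomRadiusTable()
        ref = _mc_sasa(xyz, table.radii_for(elements), table.probe_radius, 10**6, rng)
        assert res.total * 100.0 == pytest.approx(ref, rel=0.02)

    def test_rotation_invariance(self, rng):
        xyz = rng.normal(scale=2.0, size=(8, 3))
        elements = ["C"] * 8
        base = sasa(vt.Frame(xyz), elements, n_points=960).total
        rot = rotation_about(np.array([1.0, -2.0, 0.5]), 0.9)
        turned = sasa(vt.Frame(xyz @ rot.T + 3.0), elements, n_points=960).total
        assert abs(turned - base) / base < 1e-3

    def test_missing_element_radius_lists_offenders(self):
        with pytest.raises(ConfigurationError, match="XX"):
            sasa(vt.Frame(np.zeros((1, 3))), ["XX"])

    def test_fluid_exceeds_gel_at_identical_composition(self):
        totals = {}
        for state in ("gel", "fluid"):
            spec = vt.VesicleSpec(
                r_inner=2.0, r_outer=3.5, n_inner=110, n_outer=390, tail_state=state, seed=21
            )
            traj, mmap, _ = vt.make_vesicle(spec)
            totals[state] = sasa(
                traj.frame(0), traj.elements, n_points=500, selection=mmap.amphiphile_atoms
            ).total
        assert totals["fluid"] > totals["gel"]


class TestOrderParameters:
    def test_all_trans_aligned_chains_give_minus_half(self, gel_vesicle):
        traj, mmap, truth = gel_vesicle
        prof = order_parameters(traj, mmap, center=np.zeros(3))
        np.testing.assert_array_equal(prof.carbon_index, np.arange(2, 10))
        np.testing.assert_allclose(prof.s, -0.5, atol=1e-9)
        assert prof.n_samples.sum() == 8 * mmap.n_amphiphiles

    def test_isotropic_orientations_average_to_zero(self, rng):
        cos = rng.uniform(-1.0, 1.0, size=10**5)
        assert abs(order_parameter_from_cosines(cos)) < 0.02

    def test_magic_angle_is_exact_zero(self):
        c = np.cos(np.radians(54.735610317245346))
        assert order_parameter_from_cosines(np.full(100, c)) == pytest.approx(0.0, abs=1e-9)

    def test_bounds_and_extremes(self, rng):
        cos = rng.uniform(-1, 1, size=1000)
        assert -0.5 <= order_parameter_from_cosines(cos) <= 1.0
        assert order_parameter_from_cosines(np.ones(10)) == pytest.approx(1.0)
        assert order_parameter_from_cosines(np.zeros(10)) == pytest.approx(-0.5)

    def test_gel_more_ordered_than_fluid_at_every_mid_chain_carbon(self):
        mags = {}
        for state in ("gel", "fluid"):
            spec = vt.VesicleSpec(
                r_inner=3.0, r_outer=4.5, n_inner=100, n_outer=300,
                tail_state=state, jitter=0.0, seed=22,
            )
            traj, mmap, _ = vt.make_vesicle(spec)
            mags[state] = np.abs(order_parameters(traj, mmap, center=np.zeros(3)).s)
        assert np.all(mags["gel"] > mags["fluid"])


class TestDensityMap:
    def test_counts_are_conserved(self, small_vesicle):
        traj, mmap, truth = small_vesicle
        labels = truth.label_codes
        dm = density_map(traj, mmap, labels, leaflet="outer")
        assert dm.total_count == truth.n_outer

    def test_point_mass_occupies_single_cell(self, small_vesicle):
        traj, mmap, truth = small_vesicle
        coords = traj.coords.copy()
        # collapse all outer headgroups onto the north pole
        sel = truth.label_codes == 2
        for arr in (mmap.headgroup_o1[sel], mmap.headgroup_o2[sel]):
            coords[0, arr] = [0.0, 0.0, 35.0]
        t2 = vt.Trajectory(coords, 0.01, list(traj.elements))
        dm = density_map(t2, mmap, truth.label_codes, leaflet="outer", n_lat=6, n_lon=6)
        assert (dm.counts > 0).sum() == 1
        assert dm.counts.max() == truth.n_outer

    def test_uniform_shell_is_uniform_by_chi_square(self, gel_vesicle):
        traj, mmap, truth = gel_vesicle
        dm = density_map(traj, mmap, truth.label_codes, leaflet="outer", n_lat=6, n_lon=6)
        chi2, p = stats.chisquare(dm.counts.ravel())
        assert p > 0.01


class TestRDF:
    def test_uniform_ball_reference_is_flat(self, rng):
        n, R, frames = 2000, 30.0, 4
        pts = np.empty((frames, n, 3))
        for f in range(frames):
            u = rng.normal(size=(n, 3))
            u /= np.linalg.norm(u, axis=1, keepdims=True)
            pts[f] = u * R * rng.random(n)[:, None] ** (1 / 3)
        traj = vt.Trajectory(pts, 0.01, ["C"] * n)
        idx = np.arange(n)
        curve = rdf(traj, idx, idx, r_max=20.0, bin_width=1.0)
        mid = (curve.r > 4.0) & (curve.r < 16.0)
        assert np.abs(curve.g[mid] - 1.0).max() < 0.05

    def test_two_atoms_give_single_occupied_bin(self):
        traj = vt.Trajectory(np.array([[[0.0, 0, 0], [0, 0, 5.2]]]), 0.01, ["C", "C"])
        curve = rdf(traj, [0], [1], r_max=8.0, bin_width=0.5)
        occupied = curve.r[curve.counts > 0]
        assert len(occupied) == 1
        assert occupied[0] == pytest.approx(5.25)

    def test_histogram_matches_brute_force_oracle(self, rng):
        xyz = rng.uniform(-6, 6, size=(10, 3))
        traj = vt.Trajectory(xyz[None], 0.01, ["C"] * 10)
        a, b = np.arange(5), np.arange(3, 10)
        curve = rdf(traj, a, b, r_max=15.0, bin_width=0.75)
        edges = np.arange(0.0, 15.0 + 0.75, 0.75)
        edges = edges[edges <= 15.0 + 1e-9]
        ref = np.zeros(len(edges) - 1)
        for i in a:
            for j in b:
                if i == j:
                    continue
                d = np.linalg.norm(xyz[i] - xyz[j])
                k = np.searchsorted(edges, d, side="right") - 1
                if 0 <= k < len(ref):
                    ref[k] += 1
        np.testing.assert_array_equal(curve.counts, ref)

    def test_totals_conserved(self, rng):
        xyz = rng.uniform(-5, 5, size=(20, 3))
        traj = vt.Trajectory(xyz[None], 0.01, ["C"] * 20)
        idx = np.arange(20)
        curve = rdf(traj, idx, idx, r_max=40.0, bin_width=1.0)
        assert curve.counts.sum() == 20 * 19  # ordered distinct pairs
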