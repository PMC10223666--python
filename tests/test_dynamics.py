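"""MSD, Einstein diffusion, anomalous flagging, and flip-flop hysteresis."""

import numpy as np
import pytest

import vesitraj as vt
from vesitraj.dynamics import _msd_fft, detect_flip_flops, diffusion_coefficient, msd
from vesitraj.errors import FitError
from vesitraj.labels import INNER, OUTER, UNASSIGNED


def _brute_force_msd(pos):
    """Double loop over all (origin, lag) pairs; pos is (frames, particles, 3)."""
    f = pos.shape[0]
    out = np.zeros(f)
    for lag in range(1, f):
        acc, n = 0.0, 0
        for t0 in range(f - lag):
            d = pos[t0 + lag] - pos[t0]
            acc += np.sum(d * d)
            n += pos.shape[1]
        out[lag] = acc / n
    return out


class TestMSD:
    def test_stationary_particles_have_zero_msd(self, small_vesicle):
        traj, mmap, truth = small_vesicle
        out, _ = vt.make_dynamic_trajectory(traj, mmap, truth, vt.MotionSpec(n_frames=30))
        curve = msd(out, mmap)
        np.testing.assert_allclose(curve.msd, 0.0, atol=1e-12)

    def test_ballistic_closed_form(self):
        v = 0.7  # nm per ns
        t = np.arange(50) * 0.01
        pos = np.zeros((50, 1, 3))
        pos[:, 0, 0] = v * t * 10.0  # angstrom
        curve_msd, _ = _msd_fft(pos * 0.1)
        np.testing.assert_allclose(curve_msd, (v * t) ** 2, atol=1e-10)

    @pytest.mark.parametrize("f,n", [(5, 3), (100, 7)])
    def test_fast_msd_equals_brute_force_oracle(self, rng, f, n):
        pos = rng.uniform(-3, 3, size=(f, n, 3))
        fast, n_pairs = _msd_fft(pos)
        ref = _brute_force_msd(pos)
        assert np.abs(fast - ref).max() <= 1e-12
        np.testing.assert_array_equal(n_pairs, (f - np.arange(f)) * n)

    def test_translation_invariance(self, rng):
        pos = rng.uniform(-3, 3, size=(40, 4, 3))
        shifted = pos + np.array([123.0, -45.0, 6.0])
        np.testing.assert_allclose(_msd_fft(pos)[0], _msd_fft(shifted)[0], atol=1e-10)

    def test_max_lag_truncates_with_warning(self, small_vesicle):
        traj, mmap, truth = small_vesicle
        out, _ = vt.make_dynamic_trajectory(
            traj, mmap, truth, vt.MotionSpec(d_true=0.1, n_frames=30, seed=4)
        )
        with pytest.warns(UserWarning, match="truncat"):
            curve = msd(out, mmap, max_lag=10.0)
        assert len(curve.lags) == 30


class TestDiffusion:
    def test_linear_msd_closed_form(self):
        tau = np.arange(100) * 0.01
        curve = vt.MSDCurve(lags=tau, msd=6.0 * tau, n_pairs=np.full(100, 10.0))
        res = diffusion_coefficient(curve, e_dim=3)
        assert res.d == pytest.approx(1.0, abs=1e-9)
        assert res.alpha_hat == pytest.approx(1.0, abs=1e-9)
        assert not res.anomalous

    def test_recovery_and_linearity_in_planted_d(self, small_vesicle):
        traj, mmap, truth = small_vesicle
        recovered = {0.25: [], 0.5: []}
        for d_true in recovered:
            for seed in range(3):
                motion = vt.MotionSpec(d_true=d_true, n_frames=800, seed=seed)
                out, _ = vt.make_dynamic_trajectory(traj, mmap, truth, motion)
                res = diffusion_coefficient(msd(out, mmap))
                recovered[d_true].append(res.d)
        for d_true, vals in recovered.items():
            assert np.mean(vals) == pytest.approx(d_true, rel=0.1)
        ratio = np.mean(recovered[0.5]) / np.mean(recovered[0.25])
        assert ratio == pytest.approx(2.0, rel=0.15)

    def test_subdiffusion_flags_anomalous_and_suppresses_d(self, small_vesicle):
        traj, mmap, truth = small_vesicle
        motion = vt.MotionSpec(d_true=0.5, alpha=0.5, n_frames=600, seed=11)
        out, _ = vt.make_dynamic_trajectory(traj, mmap, truth, motion)
        res = diffusion_coefficient(msd(out, mmap))
        assert res.anomalous
        assert res.d is None
        assert res.alpha_hat == pytest.approx(0.5, abs=0.15)

    def test_degenerate_window_raises(self):
        tau = np.arange(100) * 0.01
        curve = vt.MSDCurve(lags=tau, msd=np.zeros(100), n_pairs=np.full(100, 1.0))
        with pytest.raises(FitError):
            diffusion_coefficient(curve)


def _oracle_flip_count(seq, min_dwell):
    """Independent state machine over one monomer's label sequence."""
    events = []
    confirmed = None
    for t, lab in enumerate(seq):
        if confirmed is None:
            if lab in (INNER, OUTER):
                confirmed = lab
            continue
        other = INNER if confirmed == OUTER else OUTER
        if lab == other:
            run = 1
            k = t + 1
            while k < len(seq) and seq[k] == other and run < min_dwell:
                run += 1
                k += 1
            if run >= min_dwell and not any(e[0] <= t <= e[1] for e in events):
                events.append((t, t + min_dwell - 1, confirmed, other))
                confirmed = other
    return events


class TestFlipFlops:
    def test_planted_transits_are_counted_with_ids_and_directions(self, small_vesicle):
        traj, mmap, truth = small_vesicle
        flips = [(5, 40), (100, 80), (7, 120), (200, 160), (30, 200), (150, 240)]
        motion = vt.MotionSpec(n_frames=300, flip_events=flips, seed=6)
        out, truth2 = vt.make_dynamic_trajectory(traj, mmap, truth, motion)
        labels = vt.label_timeseries(out, mmap)
        rep = detect_flip_flops(labels, min_dwell=20)
        assert rep.count == 6
        got = {(e["molecule_id"], e["direction"]) for e in rep.events}
        want = {(e["molecule_id"], e["direction"]) for e in truth2.flip_events}
        assert got == want

    def test_flicker_shorter_than_dwell_is_ignored(self):
        seq = np.full((100, 1), INNER, dtype=np.int8)
        seq[40:45, 0] = UNASSIGNED
        seq[50:60, 0] = OUTER  # 10 < min_dwell
        rep = detect_flip_flops(seq, min_dwell=20)
        assert rep.count == 0

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_independent_state_machine_under_noise(self, seed):
        rng = np.random.default_rng(seed)
        n_frames, n_mol = 400, 30
        seq = np.full((n_frames, n_mol), INNER, dtype=np.int8)
        seq[:, 15:] = OUTER
        noise = rng.random(seq.shape) < 0.01
        seq[noise] = rng.choice([UNASSIGNED, INNER, OUTER], size=noise.sum())
        # a few genuine long switches
        for m, t in [(0, 100), (20, 250)]:
            seq[t:, m] = INNER if seq[0, m] == OUTER else OUTER
        rep = detect_flip_flops(seq, min_dwell=20)
        expected = sum(len(_oracle_flip_count(seq[:, m], 20)) for m in range(n_mol))
        assert rep.count == expected
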