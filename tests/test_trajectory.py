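"""Trajectory observables: loading, salt-bridge traces, flip detection,
RMSD, switch dispersion and the TM3-TM5 contraction series."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation
from scipy.stats import poisson

from necroscan.synthetic import (
    ToyComplexConfig,
    TrajectoryConfig,
    make_toy_complex,
    make_trajectory,
)
from necroscan.trajectory import (
    Trajectory,
    TrajectoryError,
    assignment_series,
    classify_state_stability,
    detect_flips,
    load_trajectory,
    rmsd_series,
    saltbridge_traces,
    snapshot_indices,
    switch_dispersion,
    tm3_tm5_series,
)


def static_trajectory(n_frames=10, dt=1.0, **toy_kwargs):
    toy = make_toy_complex(ToyComplexConfig(**toy_kwargs))
    coords = np.repeat(toy.structure.coords[None], n_frames, axis=0)
    return Trajectory(topology=toy.structure, coords=coords,
                      times=np.arange(n_frames) * dt)


class TestLoadTrajectory:
    def test_frame_count_and_times(self, tmp_path):
        st_ = make_trajectory(TrajectoryConfig.active(n_frames=40, seed=0))
        path = tmp_path / "t.pdb"
        st_.write(path)
        traj = load_trajectory(path, dt=0.1)
        assert traj.n_frames == 40
        assert traj.times[-1] == pytest.approx(3.9)

    def test_single_frame_rejected(self, tmp_path, active_toy):
        path = tmp_path / "one.pdb"
        active_toy.write(path)
        with pytest.raises(TrajectoryError, match="at least 2"):
            load_trajectory(path)

    def test_inconsistent_atom_count_names_frame(self, tmp_path):
        st_ = make_trajectory(TrajectoryConfig.active(n_frames=3, seed=0))
        path = tmp_path / "bad.pdb"
        st_.write(path)
        text = path.read_text().splitlines(keepends=True)
        # drop one atom line from the second MODEL
        second_model = [i for i, l in enumerate(text)
                        if l.startswith("MODEL")][1]
        atom_line = next(i for i in range(second_model, len(text))
                         if text[i].startswith(("ATOM", "HETATM")))
        del text[atom_line]
        path.write_text("".join(text))
        with pytest.raises(TrajectoryError, match="frame 2"):
            load_trajectory(path)

    def test_two_frames_minimum_ok(self):
        traj = static_trajectory(n_frames=2)
        assert traj.n_frames == 2


class TestSaltbridgeTraces:
    def test_stable_active_means_recover_planted(self):
        st_ = make_trajectory(TrajectoryConfig.active(n_frames=1000, seed=21))
        traces = saltbridge_traces(st_.trajectory)
        n = 1000
        tol = 3 * 0.2 / math.sqrt(n)
        # autocorrelated noise widens the CI; allow 3x the i.i.d. band
        assert traces["N1-3.32"].mean == pytest.approx(2.8, abs=3 * tol)
        assert traces["N2-5.43"].mean == pytest.approx(2.8, abs=3 * tol)
        assert traces["N1-5.43"].values.mean() > 6.0

    def test_static_trajectory_constant_traces(self):
        traj = static_trajectory(n_frames=5)
        traces = saltbridge_traces(traj)
        for t in traces.values():
            assert np.ptp(t.values) == 0.0

    def test_flipping_trajectory_bimodal(self):
        st_ = make_trajectory(TrajectoryConfig.inactive(
            n_frames=1000, seed=5, flip_rate=0.02))
        vals = np.sort(saltbridge_traces(st_.trajectory)["N1-3.32"].values)
        # 2-means split: levels must straddle the bound/far planted levels
        split = np.argmin([vals[:k].var() * k + vals[k:].var() * (len(vals) - k)
                           for k in range(1, len(vals))]) + 1
        lo, hi = vals[:split].mean(), vals[split:].mean()
        assert lo == pytest.approx(2.8, abs=0.3)
        assert hi == pytest.approx(11.6 - 2.8, abs=0.5)

    def test_four_traces_labelled(self):
        traj = static_trajectory()
        assert set(saltbridge_traces(traj)) == \
            {"N1-3.32", "N1-5.43", "N2-3.32", "N2-5.43"}


def brute_force_flip_count(states, times, dwell_min):
    """Independent recount from the generator's true state sequence."""
    runs = []
    start = 0
    dt = float(np.median(np.diff(times)))
    for i in range(1, len(states) + 1):
        if i == len(states) or states[i] != states[start]:
            t_end = times[i] if i < len(states) else times[-1] + dt
            runs.append((states[start], t_end - times[start]))
            start = i
    persistent = [v for v, dur in runs if dur >= dwell_min]
    return sum(1 for a, b in zip(persistent, persistent[1:]) if a != b)


class TestDetectFlips:
    def test_active_trajectory_no_events(self):
        st_ = make_trajectory(TrajectoryConfig.active(n_frames=500, seed=2))
        assert detect_flips(saltbridge_traces(st_.trajectory)) == []

    def test_planted_persistent_swaps_counted_exactly(self):
        switch_times = (100.0, 250.0, 400.0, 600.0, 800.0)
        st_ = make_trajectory(TrajectoryConfig.inactive(
            n_frames=1000, seed=9, switch_times=switch_times))
        events = detect_flips(saltbridge_traces(st_.trajectory), dwell_min=5.0)
        assert len(events) == 5
        for prev, nxt in zip(events, events[1:]):
            assert prev.after == nxt.before  # alternation
            assert nxt.start >= prev.end

    def test_markov_switching_consistent_with_poisson(self):
        lam, T = 0.02, 1000.0
        counts = []
        for seed in range(20):
            st_ = make_trajectory(TrajectoryConfig.inactive(
                n_frames=1000, seed=seed, flip_rate=lam))
            counts.append(len(detect_flips(
                saltbridge_traces(st_.trajectory), dwell_min=5.0)))
        lo, hi = poisson.ppf([0.025, 0.975], lam * T)
        assert lo <= np.mean(counts) <= hi

    def test_event_count_equals_brute_force_recount(self):
        for seed in range(5):
            st_ = make_trajectory(TrajectoryConfig.inactive(
                n_frames=800, seed=seed, flip_rate=0.02))
            events = detect_flips(saltbridge_traces(st_.trajectory),
                                  dwell_min=5.0)
            expected = brute_force_flip_count(
                st_.states, st_.trajectory.times, 5.0)
            assert len(events) == expected

    def test_assignment_series_matches_planted_states(self):
        st_ = make_trajectory(TrajectoryConfig.inactive(
            n_frames=600, seed=4, flip_rate=0.02))
        assign = assignment_series(saltbridge_traces(st_.trajectory))
        np.testing.assert_array_equal(assign, st_.states)


@settings(max_examples=10, deadline=None)
@given(seed=st.integers(0, 1000))
def test_flip_recount_property(seed):
    st_ = make_trajectory(TrajectoryConfig.inactive(
        n_frames=300, seed=seed, flip_rate=0.03))
    events = detect_flips(saltbridge_traces(st_.trajectory), dwell_min=5.0)
    assert len(events) == brute_force_flip_count(
        st_.states, st_.trajectory.times, 5.0)


class TestRmsdSeries:
    def test_identical_frames_zero(self):
        traj = static_trajectory(n_frames=4)
        np.testing.assert_allclose(rmsd_series(traj), 0.0, atol=1e-9)

    def test_rigidly_transformed_copies_zero_after_fit(self, rng):
        toy = make_toy_complex(ToyComplexConfig())
        frames = [toy.structure.coords]
        for k in range(3):
            R = Rotation.random(random_state=k).as_matrix()
            frames.append(toy.structure.coords @ R.T + rng.normal(size=3) * 5)
        traj = Trajectory(topology=toy.structure, coords=np.stack(frames),
                          times=np.arange(4.0))
        np.testing.assert_allclose(
            rmsd_series(traj, fit_selection="backbone",
                        report_selection="all"), 0.0, atol=1e-6)

    def test_gaussian_jitter_rmsd_closed_form(self, rng):
        sigma = 0.5
        toy = make_toy_complex(ToyComplexConfig())
        base = toy.structure.coords
        frames = np.stack([base] + [
            base + rng.normal(0, sigma, base.shape) for _ in range(60)])
        traj = Trajectory(topology=toy.structure, coords=frames,
                          times=np.arange(61.0))
        series = rmsd_series(traj, ref=0, fit_selection=None,
                             report_selection="all")
        assert series[0] == 0.0
        assert series[1:].mean() == pytest.approx(sigma * math.sqrt(3),
                                                  rel=0.07)

    def test_empty_selection_rejected(self):
        traj = static_trajectory()
        with pytest.raises(TrajectoryError, match="empty"):
            rmsd_series(traj, report_selection="NOSUCH")


class TestSwitchDispersion:
    def test_static_trajectory_zero_sd(self):
        traj = static_trajectory(n_frames=120)
        stats = switch_dispersion(traj, n_snapshots=100)
        for disp in stats.residues.values():
            assert disp.sd == pytest.approx(0.0, abs=1e-9)
            assert disp.n_snapshots == 100

    def test_planted_jitter_matches_closed_form(self):
        sigma = 0.6
        st_ = make_trajectory(TrajectoryConfig.active(
            n_frames=1200, seed=10, switch_jitter_sigma=sigma))
        stats = switch_dispersion(st_.trajectory, n_snapshots=1000)
        expected = sigma * math.sqrt(3)  # ~1.04 Å
        for disp in stats.residues.values():
            assert disp.sd == pytest.approx(expected, rel=0.08)

    def test_estimator_bias_shrinks_with_snapshots(self):
        sigma = 0.6
        expected = sigma * math.sqrt(3)
        st_ = make_trajectory(TrajectoryConfig.active(
            n_frames=10_000, seed=11, switch_jitter_sigma=sigma))
        few = switch_dispersion(st_.trajectory, n_snapshots=100)
        many = switch_dispersion(st_.trajectory, n_snapshots=10_000)
        err_few = np.mean([abs(d.sd - expected)
                           for d in few.residues.values()])
        err_many = np.mean([abs(d.sd - expected)
                            for d in many.residues.values()])
        assert err_many < err_few
        assert err_many / expected < 0.05

    def test_active_vs_inactive_classification(self):
        st_a = make_trajectory(TrajectoryConfig.active(n_frames=200, seed=3))
        st_i = make_trajectory(TrajectoryConfig.inactive(n_frames=200, seed=3))
        cls_a = classify_state_stability(
            switch_dispersion(st_a.trajectory, n_snapshots=100))
        cls_i = classify_state_stability(
            switch_dispersion(st_i.trajectory, n_snapshots=100))
        assert set(cls_a.values()) == {"stable"}
        assert set(cls_i.values()) == {"fluctuating"}

    def test_glycine_switch_rejected(self):
        toy = make_toy_complex(ToyComplexConfig())
        atoms = toy.structure.atoms.copy()
        resid = toy.config.layout.index_of("3.40")
        atoms.loc[atoms["resid"] == resid, "resname"] = "GLY"
        struct = type(toy.structure)(atoms=atoms, bw_map=toy.bw_map)
        traj = Trajectory(topology=struct,
                          coords=np.repeat(struct.coords[None], 4, 0),
                          times=np.arange(4.0))
        with pytest.raises(TrajectoryError, match="glycine"):
            switch_dispersion(traj, n_snapshots=4)

    def test_snapshot_indices_include_endpoints(self):
        idx = snapshot_indices(1000, 100)
        assert idx[0] == 0 and idx[-1] == 999 and len(idx) == 100


class TestClassifyStability:
    @pytest.mark.parametrize("sd,expected", [
        (0.5, "stable"),
        (1.0, "fluctuating"),  # boundary inclusive
        (1.7, "fluctuating"),
    ])
    def test_threshold_boundary(self, sd, expected):
        from necroscan.trajectory import ResidueDispersion, SwitchStats

        stats = SwitchStats(residues={"5.50": ResidueDispersion(
            label="5.50", centroid=(0, 0, 0), sd=sd, n_snapshots=100)})
        assert classify_state_stability(stats)["5.50"] == expected


class TestTm3Tm5:
    def test_decaying_active_pocket_contracts_below_10(self):
        st_ = make_trajectory(TrajectoryConfig.active(
            n_frames=1000, seed=6, distance_decay=(10.2, 9.5, 200.0)))
        res = tm3_tm5_series(st_.trajectory)
        assert res.contracted
        assert res.min == pytest.approx(9.5, abs=0.1)

    def test_static_inactive_pocket_stays_above(self):
        st_ = make_trajectory(TrajectoryConfig.inactive(n_frames=200, seed=6))
        res = tm3_tm5_series(st_.trajectory)
        assert not res.contracted
        assert res.min == pytest.approx(11.6, abs=1e-6)

    def test_monotone_decay_series_non_increasing(self):
        st_ = make_trajectory(TrajectoryConfig.active(
            n_frames=400, seed=1, distance_decay=(10.2, 9.5, 100.0)))
        res = tm3_tm5_series(st_.trajectory)
        assert np.all(np.diff(res.values) <= 1e-9)


class TestRigidInvariance:
    def test_observables_invariant_under_frame_transform(self, rng):
        st_ = make_trajectory(TrajectoryConfig.inactive(
            n_frames=200, seed=13, flip_rate=0.02))
        traj = st_.trajectory
        R = Rotation.random(random_state=99).as_matrix()
        moved = traj.transformed(R, rng.normal(size=3) * 8)
        t0 = saltbridge_traces(traj)
        t1 = saltbridge_traces(moved)
        for key in t0:
            np.testing.assert_allclose(t1[key].values, t0[key].values,
                                       atol=1e-8)
        assert len(detect_flips(t1)) == len(detect_flips(t0))
        s0 = switch_dispersion(traj, n_snapshots=100)
        s1 = switch_dispersion(moved, n_snapshots=100)
        for lab in s0.residues:
            assert s1.sd(lab) == pytest.approx(s0.sd(lab), abs=1e-6)
        np.testing.assert_allclose(tm3_tm5_series(moved).values,
                                   tm3_tm5_series(traj).values, atol=1e-8)
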