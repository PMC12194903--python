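"""σ_Z, equilibration windows, transition/hysteresis detection, full scans."""

import numpy as np
import pytest

import bilayerkit as bk
from bilayerkit.synthetic import replace_positions


def _traj(frame, n=1):
    return bk.Trajectory([replace_positions(frame, frame.positions.copy(),
                                            time=0.1 * k) for k in range(n)])


class TestSigmaZ:
    def test_gaussian_jitter_variance(self):
        spec = bk.SyntheticSpec(n_lipids_per_leaflet=4096, target_apl=0.61,
                                waters_per_lipid=0, chain_length=2,
                                positional_jitter=0.2, seed=12)
        frame, topo = bk.build_bilayer(spec)
        assert bk.sigma_z(_traj(frame), topo) == pytest.approx(0.04, rel=0.05)

    def test_sinusoid_half_amplitude_squared(self):
        spec = bk.SyntheticSpec(n_lipids_per_leaflet=256, target_apl=0.61,
                                waters_per_lipid=0, chain_length=2,
                                undulation_amplitude=0.8)
        frame, topo = bk.build_bilayer(spec)
        assert bk.sigma_z(_traj(frame), topo) == pytest.approx(0.32, rel=0.01)

    def test_flat_leaflet_zero(self, small_planar):
        _, frame, topo = small_planar
        assert bk.sigma_z(_traj(frame), topo) == pytest.approx(0.0, abs=1e-12)

    def test_std_flag(self):
        spec = bk.SyntheticSpec(n_lipids_per_leaflet=256, target_apl=0.61,
                                waters_per_lipid=0, chain_length=2,
                                undulation_amplitude=0.8)
        frame, topo = bk.build_bilayer(spec)
        assert bk.sigma_z(_traj(frame), topo, as_std=True) == pytest.approx(
            np.sqrt(0.32), rel=0.01)

    def test_linear_in_pressure_for_planar_scans(self):
        base = bk.SyntheticSpec(n_lipids_per_leaflet=16384, target_apl=0.61,
                                waters_per_lipid=0, chain_length=2, seed=2)
        pressures = list(range(-150, 50, 20))
        scan = bk.build_pressure_scan(base, pressures, transition_pressure=None)
        sig = np.array([bk.sigma_z(s.trajectory, s.topology)
                        for s in scan.values()])
        p = np.array(pressures, dtype=float)
        design = np.vstack([p, np.ones_like(p)]).T
        coef, *_ = np.linalg.lstsq(design, sig, rcond=None)
        resid = design @ coef - sig
        r2 = 1 - resid @ resid / np.sum((sig - sig.mean()) ** 2)
        assert r2 > 0.99


class TestEquilibrationWindow:
    def test_fixed_discard(self):
        t = np.linspace(0, 400, 401)
        assert bk.equilibration_window(t, mode="fixed", discard=50.0) == (50.0, 400.0)

    def test_auto_finds_step(self):
        t = np.linspace(0, 400, 401)
        v = np.where(t < 200, 1.0, 0.5)
        start, end = bk.equilibration_window(t, v, mode="auto", tolerance=1e-6)
        assert start >= 200.0
        assert end == 400.0

    def test_constant_series_starts_at_zero(self):
        t = np.linspace(0, 100, 101)
        assert bk.equilibration_window(t, np.ones(101), mode="auto",
                                       tolerance=0.01)[0] == 0.0

    def test_span_not_exceeding_discard_raises(self):
        with pytest.raises(ValueError):
            bk.equilibration_window(np.array([0.0, 10.0]), mode="fixed",
                                    discard=20.0)

    def test_unreachable_tolerance_raises(self):
        t = np.linspace(0, 10, 11)
        with pytest.raises(ValueError, match="no window"):
            bk.equilibration_window(t, t, mode="auto", tolerance=1e-12)


class TestTransitionDetection:
    def test_constructed_jump_located(self):
        p = np.arange(0, 130, 10)
        v = 0.61 - 0.0015 * p - np.where(p >= 50, 0.1, 0.0)
        assert bk.detect_transition(p, v) == (40.0, 50.0)

    def test_linear_series_none(self):
        p = np.arange(0, 130, 10)
        assert bk.detect_transition(p, 0.61 - 0.0015 * p) is None

    def test_non_uniform_grid_raises(self):
        with pytest.raises(ValueError, match="non-uniform"):
            bk.detect_transition([0, 10, 30, 40], [1, 2, 3, 4])

    def test_calibration_over_random_placements(self):
        rng = np.random.default_rng(42)
        grid = list(range(0, 130, 10))
        hits = 0
        for _ in range(100):
            t_p = float(rng.choice(grid[1:]))
            base = bk.SyntheticSpec(n_lipids_per_leaflet=16, waters_per_lipid=0,
                                    chain_length=2,
                                    seed=int(rng.integers(1 << 30)))
            scan = bk.build_pressure_scan(base, grid, transition_pressure=t_p)
            vals = [bk.projected_apl(s.trajectory[0], 16)
                    for s in scan.values()]
            if bk.detect_transition(grid, vals) == (t_p - 10, t_p):
                hits += 1
        assert hits >= 95

    def test_no_false_positives_without_transition(self):
        grid = list(range(0, 130, 10))
        for seed in range(100):
            base = bk.SyntheticSpec(n_lipids_per_leaflet=16, waters_per_lipid=0,
                                    chain_length=2, seed=seed)
            scan = bk.build_pressure_scan(base, grid, transition_pressure=None)
            vals = [bk.projected_apl(s.trajectory[0], 16)
                    for s in scan.values()]
            assert bk.detect_transition(grid, vals) is None


def _branch(name, intervals, pressures=None, values=None):
    pts = [bk.ScanPoint(pressure=float(p), branch=name,
                        a_xy_mean=float(v) if values is not None else 0.5)
           for p, v in zip(pressures or [0, 10, 20, 30],
                           values if values is not None else [0] * 4)]
    return bk.BranchResult(name=name, points=pts, transition_interval=intervals)


class TestHysteresis:
    def test_ten_bar_shift(self):
        fw = _branch("fw", (40.0, 50.0))
        rv = _branch("rv", (30.0, 40.0))
        assert bk.hysteresis_shift(fw, rv).shift_bar == pytest.approx(10.0)

    def test_identical_branches_zero(self):
        fw = _branch("fw", (40.0, 50.0))
        rv = _branch("rv", (40.0, 50.0))
        assert bk.hysteresis_shift(fw, rv).shift_bar == 0.0

    def test_reversible_branches_report_deviation(self):
        p = [0, 10, 20, 30]
        fw = _branch("fw", None, p, [0.61, 0.62, 0.63, 0.64])
        rv = _branch("rv", None, p, [0.612, 0.621, 0.635, 0.641])
        res = bk.hysteresis_shift(fw, rv)
        assert res.shift_bar is None
        assert res.max_pointwise_deviation == pytest.approx(0.005)

    def test_disjoint_ranges_raise(self):
        fw = _branch("fw", None, [0, 10, 20, 30])
        rv = _branch("rv", None, [100, 110, 120, 130])
        with pytest.raises(ValueError):
            bk.hysteresis_shift(fw, rv)


class TestRunScan:
    @pytest.fixture(scope="class")
    def scan_result(self):
        base = bk.SyntheticSpec(n_lipids_per_leaflet=128, waters_per_lipid=0,
                                chain_length=4, seed=11)
        grid = list(range(0, 130, 10))
        fw = bk.build_pressure_scan(base, grid, transition_pressure=50)
        rv = bk.build_pressure_scan(base, grid[::-1], transition_pressure=40)
        branches = {
            "compression": {p: (s.trajectory, s.topology) for p, s in fw.items()},
            "decompression": {p: (s.trajectory, s.topology) for p, s in rv.items()},
        }
        return bk.run_scan(branches,
                           branch_pairs=[("compression", "decompression")])

    def test_recovers_generator_truth(self, scan_result):
        assert scan_result.branches["compression"].transition_interval == (40.0, 50.0)
        assert scan_result.branches["decompression"].transition_interval == (30.0, 40.0)
        shift = scan_result.hysteresis["compression->decompression"]["shift_bar"]
        assert shift == pytest.approx(10.0)

    def test_projected_apl_sharp_but_3d_smooth(self, scan_result):
        br = scan_result.branches["compression"]
        a3 = br.metric("apl3d_mean")
        assert bk.detect_transition(br.pressures, a3) is None
        assert np.all(a3 >= br.metric("a_xy_mean") - 1e-6)

    def test_failed_point_flagged_scan_continues(self):
        base = bk.SyntheticSpec(n_lipids_per_leaflet=16, waters_per_lipid=0,
                                chain_length=4, seed=1)
        scan = bk.build_pressure_scan(base, [0, 10, 20, 30, 40], None)
        branches = {"b": {p: (s.trajectory, s.topology)
                          for p, s in scan.items()}}
        # sabotage one point with a single-leaflet topology
        traj, topo = branches["b"][20]
        branches["b"][20] = (traj, bk.LipidTopology(lipids=topo.lipids[:16]))
        res = bk.run_scan(branches, compute_3d=False, compute_order=False)
        pts = {pt.pressure: pt for pt in res.branches["b"].points}
        assert pts[20].error is not None
        assert all(pts[p].error is None for p in (0, 10, 30, 40))

    def test_replica_rupture_table_matches_injected_truth(self):
        replicas = {}
        truth = {}
        for p, flags in ((-180.0, [True, True, True, False]),
                         (-170.0, [False] * 4)):
            reps = []
            for i, ruptures in enumerate(flags):
                spec = bk.SyntheticSpec(
                    n_lipids_per_leaflet=32, waters_per_lipid=30,
                    chain_length=16, pore_radius=1.0 if ruptures else 1.0,
                    n_frames=30, seed=100 + i)
                onset = 10 + 3 * i
                traj, topo = bk.build_rupture_trajectory(
                    spec, onset_frame=onset if ruptures else 1000)
                reps.append((traj, topo))
                truth[(p, i + 1)] = (ruptures, onset * 0.1 if ruptures else None)
            replicas[p] = reps
        res = bk.run_scan({}, replicas=replicas)
        assert len(res.rupture_table) == 8
        for row in res.rupture_table:
            want_flag, want_onset = truth[(row["pressure_bar"], row["replica"])]
            assert row["ruptured"] == want_flag
            if want_flag:
                assert row["onset_time_ns"] == pytest.approx(want_onset, abs=0.05)

    def test_report_deterministic_json(self, tmp_path):
        def make():
            base = bk.SyntheticSpec(n_lipids_per_leaflet=16, waters_per_lipid=0,
                                    chain_length=4, seed=5)
            scan = bk.build_pressure_scan(base, [0, 10, 20, 30], None)
            return bk.run_scan({"b": {p: (s.trajectory, s.topology)
                                      for p, s in scan.items()}},
                               compute_3d=False)

        assert make().to_json() == make().to_json()
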