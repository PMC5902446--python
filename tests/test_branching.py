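import numpy as np
import pytest

import pausekin as pk
from pausekin.branching import pretranslocated_slowdown
from pausekin.segment import LabeledPath, LabeledSegment


def _path(spec, trace_id="t"):
    t, segs = 0.0, []
    for lab, dur in spec:
        segs.append(LabeledSegment(lab, t, dur))
        t += dur
    return LabeledPath(trace_id, segs)


class TestClassify:
    def test_single_scrunch_with_pause(self):
        cls = pk.classify_trajectories(
            [_path([("US", 20), ("PS", 20), ("FS", 100)])], t_injection=20.0
        )[0]
        assert cls.cls == "single_scrunch_with_pause"
        assert cls.n_attempts == 0
        assert cls.paused

    def test_cycling_then_fs_counts_attempts(self):
        cls = pk.classify_trajectories(
            [_path([("US", 20), ("PS", 5), ("US", 8), ("PS", 5), ("FS", 50)])],
            t_injection=20.0,
        )[0]
        assert cls.cls == "cycling_then_FS"
        assert cls.n_attempts == 1

    def test_undetectable_pause_is_no_pause(self):
        cls = pk.classify_trajectories(
            [_path([("US", 20), ("PS", 0.2), ("FS", 50)])],
            min_pause_frames=2, frame_time=0.2, t_injection=20.0,
        )[0]
        assert cls.cls == "single_scrunch_no_pause"

    def test_flat_trace_inactive(self):
        cls = pk.classify_trajectories([_path([("US", 200)])], t_injection=20.0)[0]
        assert cls.cls == "inactive"

    def test_truncated_first_pause_withheld(self):
        cls = pk.classify_trajectories(
            [_path([("US", 20), ("PS", 30)])], t_injection=20.0
        )[0]
        assert cls.cls is None
        assert cls.reason == "unresolved"

    def test_classification_is_a_partition(self):
        scheme = pk.build_default_scheme(ntp=30.0)
        paths = pk.gillespie_simulate(scheme, 400.0, 200, seed=13)
        labeled = [pk.labeled_from_statepath(p) for p in paths]
        classes = pk.classify_trajectories(labeled, t_injection=0.0)
        assert len(classes) == len(labeled)
        for c in classes:
            assert (c.cls in pk.branching.CLASSES) != (c.cls is None)


class TestFirstAttempt:
    def _classes(self, n_single, n_cycling):
        out = []
        for i in range(n_single):
            out.append(pk.TrajectoryClass(f"s{i}", "single_scrunch_with_pause"))
        for i in range(n_cycling):
            out.append(pk.TrajectoryClass(f"c{i}", "cycling_only"))
        return out

    def test_wilson_interval_80_of_100(self):
        p, (lo, hi), n = pk.first_attempt_probability(self._classes(80, 20))
        assert p == 0.80
        assert lo == pytest.approx(0.711, abs=0.005)
        assert hi == pytest.approx(0.867, abs=0.005)

    def test_all_cycling_gives_zero(self):
        p, _, _ = pk.first_attempt_probability(self._classes(0, 30))
        assert p == 0.0

    def test_invariant_under_ordering_and_duplication(self):
        cls = self._classes(7, 13)
        p1, _, _ = pk.first_attempt_probability(cls)
        p2, _, _ = pk.first_attempt_probability(cls[::-1])
        p3, _, _ = pk.first_attempt_probability(cls + cls)
        assert p1 == p2 == p3

    def test_empty_denominator_errors(self):
        with pytest.raises(ValueError, match="probability"):
            pk.first_attempt_probability([pk.TrajectoryClass("x", "inactive")])

    def test_saturating_ntp_first_attempt_near_pmax(self):
        scheme = pk.build_default_scheme(ntp=1e6)
        paths = pk.gillespie_simulate(scheme, 600.0, 500, seed=14)
        labeled = [pk.labeled_from_statepath(p) for p in paths]
        p, (lo, hi), n = pk.first_attempt_probability(
            pk.classify_trajectories(labeled, t_injection=0.0)
        )
        assert lo <= 0.79 <= hi


class TestIsotherm:
    def test_noiseless_points_recovered_to_machine_precision(self):
        K, pmax = 28.0, 0.79
        pts = [(c, pmax * c / (c + K), None) for c in (1, 5, 10, 30, 80, 500)]
        fit = pk.fit_isotherm(pts, weighted=False)
        assert fit.K_ntp == pytest.approx(K, rel=1e-8)
        assert fit.P_max == pytest.approx(pmax, rel=1e-8)
        assert np.allclose(fit.residuals, 0.0, atol=1e-10)

    def test_saturated_points_not_identifiable(self):
        with pytest.raises(ValueError):
            pk.fit_isotherm([(100, 0.78, None), (500, 0.79, None)])
        with pytest.raises(ValueError, match="saturated"):
            pk.fit_isotherm(
                [(100, 0.79, None), (200, 0.79, None), (500, 0.79, None),
                 (1000, 0.79, None)]
            )

    def test_local_optimality_of_truth_on_exact_points(self):
        K, pmax = 28.0, 0.79
        pts = [(c, pmax * c / (c + K), None) for c in (1, 5, 10, 30, 80, 500)]
        fit = pk.fit_isotherm(pts, weighted=False)
        sse_fit = np.sum(fit.residuals**2)
        for dK, dp in ((2.0, 0.0), (-2.0, 0.0), (0.0, 0.04), (0.0, -0.04)):
            pert = pk.IsothermFit(fit.K_ntp + dK, fit.P_max + dp, 0, 0,
                                  np.zeros(6), fit.ntp)
            sse_pert = np.sum(
                (np.array([p for _, p, _ in pts]) - pert.predict(fit.ntp)) ** 2
            )
            assert sse_fit <= sse_pert


class TestTransitions:
    def test_ordered_pair_counting(self):
        path = _path([("US", 1), ("FS", 1), ("US", 1), ("FS", 1)])
        tc = pk.transition_histogram([path])
        assert tc.count("US", "FS") == 2
        assert tc.count("FS", "US") == 1
        assert tc.count("US", "PS") == 0

    def test_empty_paths_zero_matrix(self):
        tc = pk.transition_histogram([])
        assert tc.counts.sum() == 0

    def test_diagonal_always_zero(self):
        path = _path([("US", 1), ("PS", 1), ("US", 2), ("FS", 1)])
        tc = pk.transition_histogram([path])
        assert np.all(np.diag(tc.counts) == 0)

    def test_dominant_us_fs_exchange_in_withdrawal_cyclers(self):
        scheme = pk.build_withdrawal_scheme("US/PS/FS")
        paths = pk.gillespie_simulate(scheme, 300.0, 60, seed=15)
        labeled = [pk.labeled_from_statepath(p) for p in paths]
        tc = pk.transition_histogram(labeled)
        us_fs = tc.count("US", "FS") + tc.count("FS", "US")
        us_ps = tc.count("US", "PS") + tc.count("PS", "US")
        ps_fs = tc.count("PS", "FS") + tc.count("FS", "PS")
        assert us_fs > 2.5 * us_ps
        assert ps_fs < us_ps


class TestMemoryTest:
    def test_memoryless_generator_uncorrelated(self):
        scheme = pk.build_withdrawal_scheme("US/PS")
        paths = pk.gillespie_simulate(scheme, 600.0, 80, seed=16)
        labeled = [pk.labeled_from_statepath(p) for p in paths]
        res = pk.dwell_memory_test(labeled, "US", n_perm=2000, seed=0)
        assert abs(res.rho) < 0.1
        assert res.p_value > 0.05

    def test_alternating_generator_detected(self):
        """Deterministic slow/fast alternation of US dwells -> negative rho."""
        paths = []
        for i in range(30):
            spec = [("PS", 1.0)]
            for j in range(8):
                spec.append(("US", 1.0 if j % 2 == 0 else 40.0))
                spec.append(("PS", 2.0))
            paths.append(_path(spec, f"alt{i}"))
        res = pk.dwell_memory_test(paths, "US", n_perm=2000, seed=0)
        assert res.rho < -0.5
        assert res.p_value < 0.01

    def test_degenerate_dwells_reported_na(self):
        paths = [
            _path([("PS", 1)] + [("US", 5.0), ("PS", 5.0)] * 60 + [("FS", 1)], "d")
        ]
        res = pk.dwell_memory_test(paths, "US", n_perm=100, seed=0)
        assert np.isnan(res.rho)
        assert "degenerate" in res.reason

    def test_insufficient_pairs_errors(self):
        with pytest.raises(ValueError, match="pairs"):
            pk.dwell_memory_test([_path([("US", 1), ("PS", 1), ("US", 1)])], "US")


@pytest.fixture(scope="module")
def mixed_population():
    rng_seed = 18
    us_ps = pk.gillespie_simulate(
        pk.build_withdrawal_scheme("US/PS"), 400.0, 60, seed=rng_seed,
        trace_prefix="a",
    )
    us_ps_fs = pk.gillespie_simulate(
        pk.build_withdrawal_scheme("US/PS/FS"), 400.0, 60, seed=rng_seed + 1,
        trace_prefix="b",
    )
    return [pk.labeled_from_statepath(p) for p in us_ps + us_ps_fs]


class TestWithdrawal:

    def test_subpopulation_fractions_within_ci(self, mixed_population):
        res = pk.withdrawal_subpopulations(mixed_population, restarts=5)
        frac, (lo, hi) = res.fractions["US/PS"]
        assert lo <= 0.5 <= hi

    def test_us_ps_fs_population_faster(self, mixed_population):
        res = pk.withdrawal_subpopulations(mixed_population, restarts=8, seed=2)
        k1_slow = res.fits[("US/PS", "US")].k[0]
        k1_fast = res.fits[("US/PS/FS", "US")].k[0]
        assert k1_fast / k1_slow == pytest.approx(0.96 / 0.16, rel=0.25)

    def test_single_level_trace_excluded(self):
        only_us = _path([("US", 100)], "flat")
        res = pk.withdrawal_subpopulations([only_us])
        assert res.assignments["flat"] == "none"
        assert res.n_cyclers == 0


def test_pretranslocated_slowdown_matches_reported_fold():
    assert pretranslocated_slowdown() == pytest.approx(265, rel=0.01)
    with pytest.raises(ValueError):
        pretranslocated_slowdown(0.0, 1.0)
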