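import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pausekin as pk
from pausekin.fret import IntensityTrace, SelectionPolicy, find_intensity_steps


def _trace(i_dd, i_da, i_aa=None, frame_time=0.2, trace_id="t"):
    i_dd = np.asarray(i_dd, dtype=float)
    i_da = np.asarray(i_da, dtype=float)
    if i_aa is None:
        i_aa = np.full_like(i_dd, 200.0)
    return IntensityTrace(trace_id, frame_time, i_dd, i_da, i_aa)


class TestComputeFret:
    @pytest.mark.parametrize(
        "i_da, i_dd, expected",
        [(80.0, 80.0, 0.5), (0.0, 100.0, 0.0), (49.0, 51.0, 0.49)],
    )
    def test_ratio_formula(self, i_da, i_dd, expected):
        ft = pk.compute_fret(_trace([i_dd] * 5, [i_da] * 5))
        assert np.allclose(ft.E, expected)

    def test_nonpositive_total_masked(self):
        ft = pk.compute_fret(_trace([50, 0, 50], [50, 0, 50]))
        assert list(ft.mask) == [True, False, True]

    def test_all_masked_errors(self):
        with pytest.raises(ValueError, match="no usable frames"):
            pk.compute_fret(_trace([0, 0], [0, 0]))

    @settings(derandomize=True, max_examples=50)
    @given(
        i_dd=st.floats(1.0, 1e4),
        i_da=st.floats(0.0, 1e4),
        c=st.floats(1e-3, 1e3),
    )
    def test_scale_invariance(self, i_dd, i_da, c):
        e1 = pk.compute_fret(_trace([i_dd], [i_da])).E[0]
        e2 = pk.compute_fret(_trace([i_dd * c], [i_da * c])).E[0]
        assert abs(e1 - e2) < 1e-12

    def test_monotone_in_acceptor_channel(self):
        i_da = np.linspace(0, 200, 30)
        ft = pk.compute_fret(_trace(np.full(30, 100.0), i_da))
        assert np.all(np.diff(ft.E) > 0)


class TestStepDetection:
    def test_single_step_found(self):
        rng = np.random.default_rng(0)
        y = np.r_[np.full(100, 200.0), np.full(100, 5.0)] + rng.normal(0, 5, 200)
        steps = find_intensity_steps(y)
        assert len(steps) == 1
        assert abs(steps[0][0] - 100) <= 2
        assert steps[0][1] < -150

    def test_flat_series_has_no_steps(self):
        rng = np.random.default_rng(1)
        y = 200.0 + rng.normal(0, 5, 300)
        assert find_intensity_steps(y) == []


class TestSelection:
    def _clean(self, n=400, seed=0, bleach_at=None):
        rng = np.random.default_rng(seed)
        i_aa = np.full(n, 200.0)
        i_dd = np.full(n, 100.0)
        i_da = np.full(n, 100.0)
        if bleach_at is not None:
            i_aa[bleach_at:] = 0.0
            i_dd[bleach_at:] = 200.0
            i_da[bleach_at:] = 0.0
        noise = rng.normal(0, 8, (3, n))
        return IntensityTrace("c", 0.2, i_dd + noise[0], i_da + noise[1], i_aa + noise[2])

    def test_single_acceptor_bleach_kept_with_window(self):
        tr = self._clean(bleach_at=250)
        kept, rep = pk.select_traces([tr])
        assert len(kept) == 1
        assert abs(kept[0].metadata["analysis_end_frame"] - 250) <= 3

    def test_two_step_donor_bleach_rejected(self):
        rng = np.random.default_rng(2)
        n = 400
        tot = np.full(n, 400.0)
        tot[150:] -= 200.0  # first dye gone
        tot[300:] -= 195.0  # second dye gone
        i_dd = tot / 2 + rng.normal(0, 8, n)
        i_da = tot / 2 + rng.normal(0, 8, n)
        i_aa = np.full(n, 200.0) + rng.normal(0, 8, n)
        kept, rep = pk.select_traces([IntensityTrace("m", 0.2, i_dd, i_da, i_aa)])
        assert kept == []
        assert rep.rows[0][2] == "multistep_donor"

    def test_excessive_blinking_rejected(self):
        rng = np.random.default_rng(3)
        n = 400
        i_aa = np.full(n, 200.0)
        for start in (50, 120, 200, 280):  # four recovering dropouts
            i_aa[start : start + 12] = 0.0
        tr = IntensityTrace(
            "b", 0.2,
            np.full(n, 100.0) + rng.normal(0, 8, n),
            np.full(n, 100.0) + rng.normal(0, 8, n),
            i_aa + rng.normal(0, 8, n),
        )
        kept, rep = pk.select_traces([tr], SelectionPolicy(max_blinks=2))
        assert kept == []
        assert rep.rows[0][2] == "blinking"

    def test_selection_is_idempotent(self, small_experiment):
        traces, _ = small_experiment
        kept1, _ = pk.select_traces(traces)
        kept2, _ = pk.select_traces(kept1)
        assert [t.trace_id for t in kept1] == [t.trace_id for t in kept2]

    def test_doped_double_dye_traces_rejected(self, em_default):
        """In a 500-trace set with 10% summed two-molecule artifacts, at
        least 95% of the artifacts are rejected (multistep bleaching or
        brightness far above the single-molecule population)."""
        scheme = pk.build_default_scheme(ntp=500.0)
        em = pk.EmissionParams(donor_bleach_rate=0.004, acceptor_bleach_rate=0.004)
        traces, _ = pk.simulate_experiment(scheme, 550, 300.0, em, seed=21)
        clean, partners = traces[:450], traces[450:]
        doped = []
        for j in range(50):
            a, b = partners[2 * j], partners[2 * j + 1]
            n = min(len(a), len(b))
            doped.append(
                IntensityTrace(
                    f"doped{j}", a.frame_time,
                    a.I_DD[:n] + b.I_DD[:n],
                    a.I_DA[:n] + b.I_DA[:n],
                    a.I_AA[:n] + b.I_AA[:n],
                )
            )
        kept, rep = pk.select_traces(clean + doped)
        kept_ids = {t.trace_id for t in kept}
        n_doped_kept = sum(1 for d in doped if d.trace_id in kept_ids)
        assert n_doped_kept / len(doped) <= 0.05
        # the screen keeps the bulk of genuine single-pair traces
        assert sum(1 for t in clean if t.trace_id in kept_ids) >= 0.7 * len(clean)


class TestDetectActive:
    def test_flat_traces_inactive(self):
        rng = np.random.default_rng(4)
        fts = [
            pk.FretTrace(f"f{i}", 0.2, 0.49 + rng.normal(0, 0.03, 300),
                         np.ones(300, bool))
            for i in range(10)
        ]
        frac, ci, flags = pk.detect_active(fts, injection_frame=100)
        assert frac == 0.0

    def test_stepped_traces_active(self):
        rng = np.random.default_rng(5)
        e = np.r_[np.full(100, 0.49), np.full(200, 0.37)]
        fts = [
            pk.FretTrace(f"a{i}", 0.2, e + rng.normal(0, 0.03, 300), np.ones(300, bool))
            for i in range(10)
        ]
        frac, ci, flags = pk.detect_active(fts, injection_frame=100)
        assert frac == 1.0

    def test_partially_inactive_population_recovered(self, em_default):
        scheme = pk.build_default_scheme(ntp=80.0)
        traces, _ = pk.simulate_experiment(
            scheme, 80, 200.0, em_default, seed=33, inactive_fraction=0.30
        )
        fts = [pk.compute_fret(t) for t in traces]
        frac, (lo, hi), _ = pk.detect_active(fts, injection_frame=100)
        assert lo <= 0.70 <= hi

    def test_injection_outside_record_errors(self):
        ft = pk.FretTrace("x", 0.2, np.full(50, 0.5), np.ones(50, bool))
        with pytest.raises(ValueError, match="injection frame"):
            pk.detect_active([ft], injection_frame=50)


class TestLevelCalibration:
    def test_noiseless_levels_exact(self):
        vals = np.r_[np.full(200, 0.37), np.full(200, 0.49), np.full(200, 0.80)]
        table = pk.fit_fret_levels(vals)
        assert table.center("PS") == 0.37
        assert table.center("US") == 0.49
        assert table.center("FS") == 0.80

    def test_noisy_centers_within_0p01(self):
        rng = np.random.default_rng(6)
        vals = np.concatenate([
            rng.normal(0.37, 0.02, 400),
            rng.normal(0.49, 0.02, 400),
            rng.normal(0.80, 0.02, 400),
        ])
        frames = np.concatenate([
            rng.normal(0.37, 0.05, 4000),
            rng.normal(0.49, 0.05, 4000),
            rng.normal(0.80, 0.05, 4000),
        ])
        table = pk.fit_fret_levels(vals, frame_values=frames)
        for lab, truth in (("PS", 0.37), ("US", 0.49), ("FS", 0.80)):
            assert abs(table.center(lab) - truth) < 0.01
            assert 0.03 < table.sd(lab) < 0.08  # per-frame width, not segment-mean

    def test_overlapping_peaks_flagged(self):
        rng = np.random.default_rng(7)
        vals = np.concatenate([
            rng.normal(0.40, 0.05, 500),
            rng.normal(0.46, 0.05, 500),
            rng.normal(0.80, 0.03, 500),
        ])
        with pytest.warns(UserWarning, match="overlap"):
            table = pk.fit_fret_levels(vals)
        assert table.merged_flag

    def test_sample_size_guard(self):
        with pytest.raises(ValueError, match="pooled level samples"):
            pk.fit_fret_levels(np.linspace(0, 1, 60))

    def test_level_table_ordering_enforced(self):
        with pytest.raises(ValueError, match="PS < US < FS"):
            pk.LevelTable([("PS", 0.5, 0.02, 0.0), ("US", 0.4, 0.02, 0.0),
                           ("FS", 0.8, 0.02, 0.0)])
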