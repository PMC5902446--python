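import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

import pausekin as pk
from pausekin.dwells import DwellSet, exp_mixture_pdf, fit_exp_mixture
from pausekin.segment import LabeledPath, LabeledSegment


def _path(spec, trace_id="t"):
    """spec: list of (label, duration_s)."""
    t, segs = 0.0, []
    for lab, dur in spec:
        segs.append(LabeledSegment(lab, t, dur))
        t += dur
    return LabeledPath(trace_id, segs)


class TestExtractDwells:
    def test_only_interior_dwells_pooled(self):
        ds = pk.extract_dwells([_path([("A", 5), ("B", 3), ("A", 7)])], "B")
        assert list(ds.tau) == [3.0]

    def test_last_dwell_excluded(self):
        with pytest.raises(ValueError, match="no interior dwells"):
            pk.extract_dwells([_path([("A", 5), ("B", 3)])], "B")

    def test_counting_identity_on_generated_paths(self):
        """Interior dwells over all states = total dwells - 2 per trace."""
        scheme = pk.build_default_scheme(ntp=5.0)
        paths = pk.gillespie_simulate(scheme, 500.0, 25, seed=11)
        labeled = [pk.labeled_from_statepath(p) for p in paths]
        total = sum(len(p.segments) for p in labeled)
        interior = 0
        for state in ("US", "PS", "FS"):
            try:
                interior += pk.extract_dwells(labeled, state).N
            except ValueError:
                pass
        assert interior == total - 2 * len(labeled)

    def test_skip_first_visit(self):
        p = _path([("A", 1), ("B", 2), ("C", 9), ("B", 4), ("A", 1)])
        ds = pk.extract_dwells([p], "B", skip_first_visit=True)
        assert list(ds.tau) == [4.0]

    def test_unassigned_never_contributes(self):
        p = _path([("A", 1), ("unassigned", 5), ("B", 2), ("A", 1)])
        ds = pk.extract_dwells([p], "B")
        assert list(ds.tau) == [2.0]


class TestFitExpMixture:
    def test_single_exponential_closed_form(self):
        fit = fit_exp_mixture(DwellSet("x", [2.0, 2.0, 2.0, 2.0, 2.0]), 1)
        assert fit.k[0] == pytest.approx(0.5)
        assert fit.p[0] == 1.0

    def test_single_rate_recovery_within_3se(self):
        rng = np.random.default_rng(1)
        k = 0.15
        tau = rng.exponential(1 / k, 10_000)
        fit = fit_exp_mixture(DwellSet("x", tau), 1)
        se = k / np.sqrt(len(tau))
        assert abs(fit.k[0] - k) < 3 * se

    def test_two_component_recovery(self):
        rng = np.random.default_rng(2)
        k1, k2, p = 0.15, 0.02, 0.6
        comp = rng.uniform(size=5000) < p
        tau = np.where(comp, rng.exponential(1 / k1, 5000), rng.exponential(1 / k2, 5000))
        fit = fit_exp_mixture(DwellSet("x", tau), 2, restarts=10, seed=0)
        assert fit.k[0] == pytest.approx(k1, rel=0.15)
        assert fit.k[1] == pytest.approx(k2, rel=0.15)
        assert fit.p[0] == pytest.approx(p, rel=0.15)

    def test_left_truncated_fit_unbiased(self):
        rng = np.random.default_rng(3)
        k, t_min = 0.5, 0.6
        tau = rng.exponential(1 / k, 20_000)
        tau = tau[tau > t_min]
        fit = fit_exp_mixture(DwellSet("x", tau), 1, t_min=t_min)
        se = k / np.sqrt(len(tau))
        assert abs(fit.k[0] - k) < 3 * se
        naive = fit_exp_mixture(DwellSet("x", tau), 1)
        assert naive.k[0] < fit.k[0]  # naive fit is biased slow

    def test_sample_size_guard(self):
        with pytest.raises(ValueError, match="need N >="):
            fit_exp_mixture(DwellSet("x", np.ones(10)), 2)

    def test_m_zero_invalid(self):
        with pytest.raises(ValueError, match="m must be >= 1"):
            fit_exp_mixture(DwellSet("x", np.ones(10)), 0)

    def test_seed_invariance_on_well_separated_mixture(self):
        rng = np.random.default_rng(4)
        tau = np.r_[rng.exponential(1.0, 2000), rng.exponential(100.0, 2000)]
        fits = [fit_exp_mixture(DwellSet("x", tau), 2, restarts=8, seed=s)
                for s in (0, 99)]
        assert fits[0].k == pytest.approx(fits[1].k, rel=1e-4)
        assert fits[0].p == pytest.approx(fits[1].p, rel=1e-4)
        assert np.all(np.diff(fits[0].k) < 0)  # reported rates sorted descending


@settings(derandomize=True, max_examples=25, deadline=None)
@given(
    logk=st.lists(st.floats(-3.0, 2.0), min_size=1, max_size=3),
    raw_p=st.lists(st.floats(0.05, 1.0), min_size=3, max_size=3),
)
def test_mixture_density_integrates_to_one(logk, raw_p):
    k = np.sort(10.0 ** np.array(logk))[::-1]
    p = np.array(raw_p[: len(k)])
    p = p / p.sum()
    total, _ = quad(lambda t: exp_mixture_pdf(t, k, p)[0], 0, np.inf, limit=200)
    assert total == pytest.approx(1.0, abs=1e-6)


class TestSelectMBIC:
    def test_single_exponential_selects_m1(self):
        rng = np.random.default_rng(5)
        ds = DwellSet("x", rng.exponential(5.0, 10_000))
        m_star, fits, _ = pk.select_m_bic(ds, m_max=2, restarts=5, seed=0)
        assert m_star == 1

    def test_separated_mixture_selects_m2(self):
        rng = np.random.default_rng(6)
        tau = np.r_[rng.exponential(1 / 0.5, 6000), rng.exponential(1 / 0.01, 4000)]
        ds = DwellSet("x", tau)
        m_star, fits, _ = pk.select_m_bic(ds, m_max=3, restarts=5, seed=0)
        assert m_star == 2

    def test_undersized_candidates_skipped_with_notice(self):
        rng = np.random.default_rng(7)
        ds = DwellSet("x", rng.exponential(5.0, 20))
        m_star, fits, notices = pk.select_m_bic(ds, m_max=3)
        assert 3 not in fits
        assert any("m=3 skipped" in n for n in notices)

    def test_bic_selection_sharpens_with_sample_size(self):
        """Accuracy of m=2 detection increases monotonically with N."""
        k1, k2, p = 0.3, 0.02, 0.5
        hits = []
        for n in (100, 400, 1600):
            ok = 0
            for rep in range(12):
                rng = np.random.default_rng(1000 * n + rep)
                comp = rng.uniform(size=n) < p
                tau = np.where(comp, rng.exponential(1 / k1, n),
                               rng.exponential(1 / k2, n))
                m_star, _, _ = pk.select_m_bic(DwellSet("x", tau), 2,
                                               restarts=5, seed=rep)
                ok += m_star == 2
            hits.append(ok)
        assert hits[0] <= hits[1] <= hits[2]
        assert hits[2] == 12


class TestBootstrap:
    def test_degenerate_dwells_zero_sd(self):
        ds = DwellSet("x", np.full(50, 3.0))
        fit = pk.bootstrap_sd(ds, 1, B=100, seed=0)
        assert fit.k_sd[0] == pytest.approx(0.0, abs=1e-12)

    def test_reproducible_under_seed(self):
        rng = np.random.default_rng(8)
        ds = DwellSet("x", rng.exponential(4.0, 400))
        a = pk.bootstrap_sd(ds, 1, B=200, seed=3)
        b = pk.bootstrap_sd(ds, 1, B=200, seed=3)
        assert a.k_sd[0] == b.k_sd[0]

    def test_sd_scales_as_inverse_sqrt_n(self):
        rng = np.random.default_rng(9)
        k = 0.2
        sds = []
        for n in (1000, 4000):
            ds = DwellSet("x", rng.exponential(1 / k, n))
            sds.append(pk.bootstrap_sd(ds, 1, B=300, seed=1).k_sd[0])
        assert sds[0] / sds[1] == pytest.approx(2.0, rel=0.20)


class TestPauseExitRate:
    def test_closed_form_rate(self):
        paths = [
            _path([("US", 1.0), ("PS", 10.0), ("FS", 5.0)], f"t{i}")
            for i in range(40)
        ]
        fit = pk.pause_exit_rate(paths, B=50, seed=0)
        assert fit.k[0] == pytest.approx(0.1)

    def test_recovery_from_simulated_pause(self):
        """Productive-only pause exit: k recovered within 3 bootstrap SD."""
        for k_true in (0.11, 0.26):
            scheme = pk.build_default_scheme(k_itc6=k_true, ntp=1e6)  # p -> P_max
            paths = pk.gillespie_simulate(scheme, 2000.0, 300, seed=12, t_start=10.0)
            labeled = []
            for p in paths:
                lp = pk.labeled_from_statepath(p)
                lp.segments.insert(0, LabeledSegment("US", 0.0, 10.0))
                labeled.append(lp)
            cls = pk.classify_trajectories(labeled, t_injection=0.0)
            single = {c.trace_id for c in cls
                      if (c.cls or "").startswith("single_scrunch")}
            fit = pk.pause_exit_rate([p for p in labeled if p.trace_id in single],
                                     B=200, seed=1)
            assert abs(fit.k[0] - k_true) < 3 * max(fit.k_sd[0], 1e-4)

    def test_empty_classification_errors(self):
        with pytest.raises(ValueError, match="single-scrunch"):
            pk.pause_exit_rate([])
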