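"""Active detection: projection, densities, LLR, CUSUM, sweep, trend."""

from datetime import datetime, timedelta

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

import typefatigue as tf
from typefatigue.afd import (
    AFDState,
    estimate_densities,
    evaluate_afd,
    llr,
    project_to_scalar,
    run_cusum,
    update_cusum,
)
from typefatigue.sessions import KeystrokeEvent, KeystrokeSession


class TestProjection:
    def test_centroid_axis_geometry(self):
        cr = np.zeros(8)
        cf = np.zeros(8)
        cf[0] = 1.0
        g = np.zeros(8)
        g[0] = 0.75
        s = project_to_scalar(g, rest_centroid=cr, fatigue_centroid=cf)
        assert s[0] == pytest.approx(0.75)

    def test_orthogonal_component_ignored(self):
        cr, cf = np.zeros(4), np.array([2.0, 0, 0, 0])
        g = np.array([0.5, 9.0, -3.0, 1.0])
        s = project_to_scalar(g, rest_centroid=cr, fatigue_centroid=cf)
        assert s[0] == pytest.approx(0.5)

    def test_coincident_centroids_rejected(self):
        with pytest.raises(ValueError, match="coincide"):
            project_to_scalar(np.ones(3), rest_centroid=np.ones(3), fatigue_centroid=np.ones(3))

    def test_tsne1d_seeded_reproducible(self):
        rng = np.random.default_rng(0)
        E = np.vstack([rng.normal(0, 1, (20, 5)), rng.normal(4, 1, (20, 5))])
        a = project_to_scalar(E, method="tsne1d", random_state=3)
        b = project_to_scalar(E, method="tsne1d", random_state=3)
        np.testing.assert_array_equal(a, b)
        # the two clusters stay separated in 1-D
        assert abs(a[:20].mean() - a[20:].mean()) > np.std(a) / 2


class TestDensitiesAndLLR:
    def test_kde_matches_normal_pdf_at_mode(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 10_000)
        dens = estimate_densities(x, x + 10)
        assert dens.eval_rest(0.0)[0] == pytest.approx(norm.pdf(0.0), rel=0.05)

    def test_density_integrates_to_one(self):
        rng = np.random.default_rng(2)
        dens = estimate_densities(rng.normal(0, 1, 2000), rng.normal(1, 1, 2000))
        grid = np.linspace(-6, 7, 2000)
        area = np.trapezoid(dens.eval_rest(grid), grid)
        assert area == pytest.approx(1.0, abs=0.01)

    def test_too_few_or_degenerate_scores(self):
        with pytest.raises(ValueError, match=">= 5"):
            estimate_densities([1, 2], [1, 2, 3, 4, 5])
        with pytest.raises(ValueError, match="degenerate"):
            estimate_densities([1.0] * 10, [1, 2, 3, 4, 5.0])

    def test_llr_sign_convention(self):
        rng = np.random.default_rng(3)
        dens = estimate_densities(rng.normal(0, 1, 5000), rng.normal(2, 1, 5000))
        assert llr(0.0, dens) < 0 < llr(2.0, dens)
        assert llr(1.0, dens) == pytest.approx(0.0, abs=0.1)  # equidistant symmetry

    def test_llr_identical_densities_zero(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 1000)
        dens = estimate_densities(x, x)
        for s in (-1.0, 0.0, 2.0):
            assert llr(s, dens) == pytest.approx(0.0, abs=1e-9)

    def test_floor_prevents_infinite_llr(self):
        rng = np.random.default_rng(5)
        dens = estimate_densities(rng.normal(0, 0.1, 100), rng.normal(5, 0.1, 100))
        assert np.isfinite(llr(-50.0, dens))


def _brute_cusum(L):
    """Clamped CUSUM as max over clamp points (independent oracle)."""
    out = np.empty(len(L))
    for j in range(len(L)):
        suffixes = [sum(L[k : j + 1]) for k in range(j + 1)] + [0.0]
        out[j] = max(suffixes)
    return out


class TestCUSUM:
    def test_hand_recursion(self):
        S, _ = run_cusum([-1, -1, 2, 3])
        np.testing.assert_allclose(S, [0, 0, 2, 5])

    def test_rest_regime_stays_zero(self):
        S, crossed = run_cusum([-0.5] * 20, tau=1.0)
        assert np.all(S == 0.0) and crossed is None

    def test_equals_bruteforce_on_random_sequences(self):
        rng = np.random.default_rng(6)
        for _ in range(100):
            L = rng.normal(0, 1, size=rng.integers(1, 40))
            S, _ = run_cusum(L)
            np.testing.assert_allclose(S, _brute_cusum(L), atol=1e-9)

    @given(st.lists(st.floats(-5, 5), min_size=1, max_size=30))
    @settings(deadline=None, derandomize=True)
    def test_nonnegativity_property(self, L):
        S, _ = run_cusum(L)
        assert np.all(S >= 0.0)

    def test_state_history_append_only(self):
        state = AFDState(tau=10.0)
        for L in (1.0, -2.0, 0.5):
            update_cusum(state, L)
        assert len(state.history) == 3
        assert state.j == 3
        np.testing.assert_allclose([h[2] for h in state.history], [1.0, 0.0, 0.5])


class TestEvaluateAFD:
    def _toy(self):
        L = np.array([-0.5] * 5 + [1.0] * 6)
        return [(L, 5)]

    def test_extreme_thresholds(self):
        m = evaluate_afd(self._toy(), thresholds=np.array([0.0, 1e9]))
        assert m.pfd[0] == 1.0 and m.pnd[0] == 0.0  # tau=0 fires immediately
        assert m.pfd[-1] == 0.0 and m.pnd[-1] == 1.0

    def test_deterministic_delay(self):
        m = evaluate_afd(self._toy(), thresholds=np.array([2.5]))
        assert m.pfd[0] == 0.0 and m.pnd[0] == 0.0
        assert m.add[0] == pytest.approx(3.0)  # third post-change session crosses

    def test_monotone_tradeoff_curves(self):
        rng = np.random.default_rng(7)
        seqs = [
            (rng.normal(-0.3, 1, 30), 15) for _ in range(10)
        ] + [(np.concatenate([rng.normal(-1, 1, 15), rng.normal(1, 1, 15)]), 15) for _ in range(10)]
        m = evaluate_afd(seqs, n_thresholds=60)
        assert np.all(np.diff(m.pfd) <= 1e-12)
        assert np.all(np.diff(m.pnd) >= -1e-12)
        assert np.all(np.diff(m.add) >= -1e-9)

    def test_no_sequences_rejected(self):
        with pytest.raises(ValueError):
            evaluate_afd([])


class TestDailyTrend:
    def _sessions(self, hours, day=0, pid="p"):
        out = []
        for h in hours:
            start = datetime(2022, 5, 1 + day) + timedelta(hours=h)
            ev = [KeystrokeEvent(0.0, 0.1), KeystrokeEvent(0.3, 0.4)]
            out.append(KeystrokeSession(pid, ev, start_time=start))
        return out

    def test_eligibility_rules(self):
        """90-minute gaps pair; >=2-hour gaps and midnight crossings do not."""
        sessions = self._sessions([9.0, 10.5, 13.5]) + self._sessions([23.5], day=0) + self._sessions([0.5], day=1)
        df = tf.daily_fatigue_trend(sessions, scorer=lambda s: s.start_time.hour * 1.0)
        assert set(df["hour"]) == {10}  # only 09:00->10:30 eligible

    def test_missing_hours_absent_not_zero(self):
        sessions = self._sessions([9.0, 10.5])
        df = tf.daily_fatigue_trend(sessions, scorer=lambda s: 1.0)
        assert list(df["hour"]) == [10]
        assert 11 not in set(df["hour"])

    def test_requires_wall_clock(self):
        s = KeystrokeSession("p", [KeystrokeEvent(0, 0.1)])
        with pytest.raises(ValueError, match="wall-clock"):
            tf.daily_fatigue_trend([s], scorer=lambda s: 0.0)
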