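"""OU fitting and the two-part (autocorrelation x Argos-error) KDE weights."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from mpaud.track_io import AzimuthalEquidistant, LocationClass, ProjectedTrack
from mpaud.movement_weights import (
    LCErrorTable,
    argos_error_weights,
    autocorr_weights,
    combine_weights,
    fit_ou,
    weights_for_track,
    _ou_profile_loglik,
)

PROJ = AzimuthalEquidistant(0.0, 0.0)


def _ptrack(times, xy, lcs=None):
    times = np.asarray(times, dtype=float)
    xy = np.asarray(xy, dtype=float)
    lcs = lcs or [LocationClass.LC1] * len(times)
    return ProjectedTrack("t1", times, xy, lcs, PROJ)


def _simulate_ou(rng, n, dt, tau, sigma, mu=(0.0, 0.0)):
    """Exact OU transition sampling; the simulator is independent of the fitter."""
    mu = np.asarray(mu, dtype=float)
    xy = np.empty((n, 2))
    xy[0] = mu + rng.normal(scale=sigma, size=2)
    phi = math.exp(-dt / tau)
    sd = sigma * math.sqrt(1.0 - phi**2)
    for i in range(1, n):
        xy[i] = mu + phi * (xy[i - 1] - mu) + rng.normal(scale=sd, size=2)
    return np.arange(n) * dt, xy


class TestLCErrorTable:
    def test_csv_round_trip(self, tmp_path):
        table = LCErrorTable.default()
        p = tmp_path / "lc.csv"
        table.to_csv(p)
        assert LCErrorTable.from_csv(p).errors_m == table.errors_m

    def test_nonmonotone_table_rejected(self):
        with pytest.raises(ValueError, match="non-decreasing"):
            LCErrorTable({LocationClass.LC3: 1000.0, LocationClass.LC2: 500.0})

    def test_missing_lc_is_hard_error(self):
        table = LCErrorTable({LocationClass.LC3: 500.0})
        with pytest.raises(KeyError, match="B"):
            argos_error_weights([LocationClass.B], table)


class TestFitOU:
    def test_white_noise_gives_tau_below_min_dt(self, rng):
        dt = 6 * 3600.0
        times = np.arange(100) * dt
        xy = rng.normal(scale=2000.0, size=(100, 2))
        fit = fit_ou(_ptrack(times, xy))
        assert fit.tau < dt

    def test_coincident_points_flagged_degenerate(self):
        times = np.arange(6) * 3600.0
        xy = np.tile([100.0, 200.0], (6, 1))
        fit = fit_ou(_ptrack(times, xy))
        assert fit.degenerate and fit.sigma2 <= 1e-6

    def test_too_few_fixes_directs_to_iid_fallback(self):
        with pytest.raises(ValueError, match="IID fallback"):
            fit_ou(_ptrack([0, 1, 2, 3], np.zeros((4, 2))))

    def test_likelihood_at_tau_zero_equals_iid_normal_product(self, rng):
        """Closed-form check: the tau->0 OU likelihood is the IID Gaussian one."""
        times = np.arange(20) * 3600.0
        xy = rng.normal(scale=1500.0, size=(20, 2))
        ll, mu, sigma2 = _ou_profile_loglik(1e-12, times, xy)
        mu_hat = xy.mean(axis=0)
        s2_hat = ((xy - mu_hat) ** 2).mean()  # pooled over both axes, MLE
        oracle = sum(
            stats.norm.logpdf(xy[:, ax], loc=mu_hat[ax], scale=math.sqrt(s2_hat)).sum()
            for ax in range(2)
        )
        np.testing.assert_allclose(mu, mu_hat, atol=1e-6)
        assert ll == pytest.approx(oracle, rel=1e-9)

    def test_recovers_tau_within_factor_two(self, rng):
        tau, sigma = 12 * 3600.0, 2000.0
        times, xy = _simulate_ou(rng, 400, 6 * 3600.0, tau, sigma)
        fit = fit_ou(_ptrack(times, xy))
        assert 0.5 * tau <= fit.tau <= 2.0 * tau
        assert fit.converged


class TestAutocorrWeights:
    def test_iid_limit_is_uniform(self):
        w = autocorr_weights(None, np.arange(7.0))
        np.testing.assert_allclose(w, np.full(7, 1 / 7))

    def test_single_fix_gets_weight_one(self):
        fit = fit_ou(_ptrack(np.arange(5) * 3600.0,
                             np.random.default_rng(0).normal(size=(5, 2)) * 1000))
        assert autocorr_weights(fit, np.array([0.0]))[0] == 1.0

    def test_clustered_pair_downweighted_vs_explicit_inverse(self):
        """n=3 at (0, 0.01 tau, 10 tau): oracle is the explicit 3x3 C^-1 1."""
        tau = 1000.0
        times = np.array([0.0, 0.01 * tau, 10 * tau])
        fit_stub = type("F", (), {"tau": tau})()
        w = autocorr_weights(fit_stub, times)
        C = np.exp(-np.abs(times[:, None] - times[None, :]) / tau)
        oracle = np.linalg.inv(C) @ np.ones(3)
        oracle = np.clip(oracle, 0, None)
        oracle /= oracle.sum()
        np.testing.assert_allclose(w, oracle, atol=1e-10)
        assert w[0] < w[2] and w[1] < w[2]
        assert w[2] == pytest.approx(0.5, abs=0.01)  # clustered pair splits a half

    def test_sums_to_one(self, rng):
        fit_stub = type("F", (), {"tau": 500.0})()
        w = autocorr_weights(fit_stub, np.sort(rng.uniform(0, 1e4, 40)))
        assert w.sum() == pytest.approx(1.0, abs=1e-9)
        assert (w >= 0).all()

    def test_duplicate_times_handled_with_jitter(self):
        fit_stub = type("F", (), {"tau": 100.0})()
        w = autocorr_weights(fit_stub, np.array([0.0, 0.0, 50.0]))
        assert w.sum() == pytest.approx(1.0, abs=1e-9)


class TestArgosErrorWeights:
    def test_inverse_proportionality(self):
        table = LCErrorTable({LocationClass.LC3: 500.0, LocationClass.A: 1000.0})
        w = argos_error_weights([LocationClass.LC3, LocationClass.A], table)
        np.testing.assert_allclose(w, [1.0, 0.5])

    def test_single_class_all_ones(self):
        table = LCErrorTable.default()
        w = argos_error_weights([LocationClass.B] * 5, table)
        np.testing.assert_allclose(w, 1.0)

    def test_ratio_matches_error_ratio(self):
        table = LCErrorTable({LocationClass.LC1: 1000.0, LocationClass.A: 2000.0})
        w = argos_error_weights([LocationClass.LC1, LocationClass.A], table)
        assert w[0] / w[1] == pytest.approx(2.0)


class TestCombineWeights:
    def test_unit_error_weights_preserve_autocorr_pattern(self, rng):
        w_auto = rng.dirichlet(np.ones(10))
        wset = combine_weights("t1", rng.normal(size=(10, 2)), w_auto, np.ones(10))
        np.testing.assert_allclose(wset.w, w_auto, atol=1e-12)

    def test_mismatched_lengths_error(self):
        with pytest.raises(ValueError, match="mismatch"):
            combine_weights("t1", np.zeros((3, 2)), np.ones(3), np.ones(2))

    @settings(derandomize=True, max_examples=30)
    @given(n=st.integers(2, 25), seed=st.integers(0, 1000))
    def test_normalized_sum_is_one(self, n, seed):
        r = np.random.default_rng(seed)
        wset = combine_weights("t1", r.normal(size=(n, 2)),
                               r.uniform(0.1, 1, n), r.uniform(0.1, 1, n))
        assert wset.w.sum() == pytest.approx(1.0, abs=1e-9)


class TestEqualWeightLimits:
    def test_iid_single_lc_gives_exact_uniform(self, rng):
        """White-noise track + one LC class: every combined weight = 1/n."""
        n = 40
        times = np.arange(n) * 6 * 3600.0
        xy = rng.normal(scale=2000.0, size=(n, 2))
        pt = _ptrack(times, xy, lcs=[LocationClass.A] * n)
        fit = fit_ou(pt)
        w_auto = autocorr_weights(None if fit.tau == 0 else fit, pt.times)
        # force the IID fallback branch explicitly for the exactness claim
        w_auto_iid = autocorr_weights(None, pt.times)
        w_err = argos_error_weights(pt.lcs, LCErrorTable.default())
        wset = combine_weights("t1", xy, w_auto_iid, w_err)
        np.testing.assert_allclose(wset.w, 1.0 / n, atol=1e-12)

    def test_pooling_equity_across_animals(self, rng):
        """After per-animal normalization the population pool sums to k."""
        total = 0.0
        for k in range(4):
            n = 5 + 3 * k
            pt = _ptrack(np.arange(n) * 3600.0, rng.normal(scale=1000, size=(n, 2)),
                         lcs=[LocationClass.LC1, LocationClass.A][:1] * n)
            total += weights_for_track(pt).w.sum()
        assert total == pytest.approx(4.0, abs=1e-9)

    def test_permutation_equivariance(self, rng):
        n = 12
        times = np.sort(rng.uniform(0, 1e5, n))
        xy = rng.normal(scale=1000, size=(n, 2))
        lcs = [LocationClass.LC1 if i % 2 else LocationClass.A for i in range(n)]
        fit_stub = type("F", (), {"tau": 2000.0})()
        w1 = autocorr_weights(fit_stub, times)
        e1 = argos_error_weights(lcs, LCErrorTable.default())
        perm = rng.permutation(n)
        w2 = autocorr_weights(fit_stub, times[perm])
        e2 = argos_error_weights([lcs[i] for i in perm], LCErrorTable.default())
        np.testing.assert_allclose(w2, w1[perm], atol=1e-9)
        np.testing.assert_allclose(e2, e1[perm], atol=1e-12)
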