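"""Haplotype-copying HMM: exact likelihood, generative sampling, MLE fits,
finite-difference standard errors."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from stratld.copying import (
    CopyingFit,
    CopyingPanel,
    CopyingParams,
    fit_joint,
    fit_profile_lambda,
    fit_standard_errors,
    forward_loglik,
    sample_generative,
    transition_prob,
)
from stratld.fixtures import random_panel


def brute_force_loglik(panel, query, map_pos, lam, eps):
    """Explicit sum over all K^S hidden paths (oracle for the forward pass)."""
    k, s = panel.shape
    g = np.diff(map_pos)
    total = 0.0
    for path in itertools.product(range(k), repeat=s):
        p = 1.0 / k
        for l in range(s):
            if query[l] >= 0:
                p *= (1.0 - eps) if panel[path[l], l] == query[l] else eps
            if l > 0:
                stay = np.exp(-lam * g[l - 1])
                p *= stay + (1.0 - stay) / k if path[l] == path[l - 1] else (1.0 - stay) / k
        total += p
    return np.log(total)


class TestTransitions:
    def test_frozen_value(self):
        p = transition_prob(CopyingParams(100.0, 0.01), 0.01, 4, same_state=True)
        assert p == pytest.approx(np.exp(-1) + (1 - np.exp(-1)) / 4)  # 0.52591...

    def test_zero_jump_rate_never_moves(self):
        assert transition_prob(CopyingParams(0.0, 0.1), 0.01, 5, True) == 1.0
        assert transition_prob(CopyingParams(0.0, 0.1), 0.01, 5, False) == 0.0

    def test_long_distance_reaches_uniform(self):
        p_same = transition_prob(CopyingParams(10.0, 0.0), 1e4, 8, True)
        p_move = transition_prob(CopyingParams(10.0, 0.0), 1e4, 8, False)
        assert p_same == pytest.approx(1 / 8) and p_move == pytest.approx(1 / 8)

    @given(
        lam=st.floats(0.0, 1e4),
        g=st.floats(0.0, 1.0),
        k=st.integers(1, 50),
    )
    def test_rows_sum_to_one(self, lam, g, k):
        params = CopyingParams(lam, 0.01)
        same = transition_prob(params, g, k, True)
        move = transition_prob(params, g, k, False)
        assert same + (k - 1) * move == pytest.approx(1.0)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            transition_prob(CopyingParams(1.0, 0.0), -1e-3, 2, True)


class TestForwardLikelihood:
    def test_single_haplotype_identical_query_closed_form(self):
        s, eps = 17, 0.03
        panel = np.ones((1, s), dtype=np.int8)
        data = CopyingPanel(panel, panel[0], np.linspace(0, 0.1, s))
        ll = forward_loglik(data, CopyingParams(50.0, eps))
        assert ll == pytest.approx(s * np.log(1 - eps), rel=1e-12)

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(7)
        worst = 0.0
        for _ in range(100):
            k = int(rng.integers(1, 4))
            s = int(rng.integers(1, 12 // k + 1))
            panel = rng.integers(0, 2, (k, s)).astype(np.int8)
            query = rng.integers(0, 2, s).astype(np.int8)
            if s > 1 and rng.random() < 0.3:
                query[rng.integers(s)] = -1
            map_pos = np.sort(rng.random(s))
            lam = float(rng.uniform(0, 50))
            eps = float(rng.uniform(1e-3, 0.4))
            got = forward_loglik(CopyingPanel(panel, query, map_pos), CopyingParams(lam, eps))
            want = brute_force_loglik(panel, query, map_pos, lam, eps)
            worst = max(worst, abs(got - want) / abs(want))
        assert worst <= 1e-10

    def test_all_missing_query_has_zero_loglik(self):
        panel = np.zeros((3, 5), dtype=np.int8)
        query = np.full(5, -1, dtype=np.int8)
        data = CopyingPanel(panel, query, np.linspace(0, 1, 5))
        assert forward_loglik(data, CopyingParams(10.0, 0.1)) == 0.0

    def test_impossible_data_gives_minus_inf(self):
        panel = np.zeros((1, 3), dtype=np.int8)
        query = np.array([1, 0, 0], dtype=np.int8)
        data = CopyingPanel(panel, query, np.linspace(0, 1, 3))
        assert forward_loglik(data, CopyingParams(1.0, 0.0)) == -np.inf

    def test_invariant_under_panel_row_permutation(self):
        rng = np.random.default_rng(8)
        panel = rng.integers(0, 2, (6, 40)).astype(np.int8)
        query = rng.integers(0, 2, 40).astype(np.int8)
        mp = np.sort(rng.random(40))
        params = CopyingParams(30.0, 0.02)
        base = forward_loglik(CopyingPanel(panel, query, mp), params)
        perm = forward_loglik(CopyingPanel(panel[::-1], query, mp), params)
        assert base == pytest.approx(perm, rel=1e-12)


class TestGenerativeSampler:
    def test_no_jumps_no_errors_copies_one_row(self):
        rng = np.random.default_rng(9)
        panel = rng.integers(0, 2, (5, 30)).astype(np.int8)
        mp = np.linspace(0, 0.3, 30)
        query, path = sample_generative(panel, mp, CopyingParams(0.0, 0.0), 1)
        assert len(set(path)) == 1
        np.testing.assert_array_equal(query, panel[path[0]])

    def test_stay_frequency_matches_transition_probability(self):
        k, s, lam, g = 4, 20_001, 120.0, 2e-4
        panel = np.zeros((k, s), dtype=np.int8)
        mp = np.arange(s) * g
        _, path = sample_generative(panel, mp, CopyingParams(lam, 0.0), 2)
        stay_hat = np.mean(path[1:] == path[:-1])
        p_stay = transition_prob(CopyingParams(lam, 0.0), g, k, True)
        assert abs(stay_hat - p_stay) < 3 * np.sqrt(p_stay * (1 - p_stay) / (s - 1))

    def test_error_rate_matches_eps(self):
        rng = np.random.default_rng(10)
        panel = rng.integers(0, 2, (3, 20_000)).astype(np.int8)
        mp = np.linspace(0, 2.0, 20_000)
        eps = 0.49
        query, path = sample_generative(panel, mp, CopyingParams(5.0, eps), 3)
        copied = panel[path, np.arange(20_000)]
        mismatch = np.mean(query != copied)
        assert abs(mismatch - eps) < 3 * np.sqrt(eps * (1 - eps) / 20_000)

    def test_eps_half_rejected(self):
        with pytest.raises(ValueError):
            CopyingParams(1.0, 0.5)


class TestFits:
    def test_recovery_small_batch(self):
        rng = np.random.default_rng(11)
        panel, _, mp = random_panel(50, 800, 0.4, rng)
        hits = 0
        for i in range(5):
            query, _ = sample_generative(panel, mp, CopyingParams(100.0, 0.01), 200 + i)
            data = CopyingPanel(panel, query, mp)
            fit = fit_standard_errors(data, fit_joint(data))
            prof = fit_profile_lambda(data, 0.01)
            assert fit.converged and fit.se_lam is not None
            assert abs(prof.lam_hat - fit.lam_hat) < 2 * fit.se_lam
            if abs(fit.lam_hat - 100.0) <= 2 * fit.se_lam:
                hits += 1
        assert hits >= 4

    def test_perfect_copy_drives_both_rates_to_floor(self):
        panel = np.zeros((4, 300), dtype=np.int8)
        panel[0] = 1  # query matches row 0 exactly; others maximally different
        data = CopyingPanel(panel, panel[0], np.linspace(0, 0.4, 300))
        fit = fit_joint(data)
        assert fit.lam_hat < 5.0 and fit.eps_hat < 1e-3
        assert fit.at_bound  # boundary estimates flagged -> SEs withheld
        assert fit_standard_errors(data, fit).se_lam is None

    def test_zero_jump_rate_recovered_at_boundary(self):
        rng = np.random.default_rng(12)
        panel, _, mp = random_panel(20, 2000, 0.4, rng)
        query, _ = sample_generative(panel, mp, CopyingParams(0.0, 0.01), 13)
        fit = fit_profile_lambda(CopyingPanel(panel, query, mp), 0.01)
        assert fit.lam_hat < 5.0

    def test_all_missing_query_flagged_unconverged(self):
        panel = np.zeros((3, 10), dtype=np.int8)
        query = np.full(10, -1, dtype=np.int8)
        data = CopyingPanel(panel, query, np.linspace(0, 1, 10))
        assert not fit_joint(data).converged
        assert not fit_profile_lambda(data).converged

    def test_eps_fixed_out_of_range_rejected(self):
        panel = np.zeros((2, 4), dtype=np.int8)
        data = CopyingPanel(panel, panel[0], np.linspace(0, 1, 4))
        with pytest.raises(ValueError):
            fit_profile_lambda(data, 0.7)


class TestStandardErrors:
    def test_quadratic_surface_gives_exact_ses(self):
        # inject a quadratic log-likelihood with known curvature in the
        # transformed coordinates; the differencing must recover it exactly
        a, b = 4.0, 25.0
        x0 = (np.log(50.0), 0.0)  # eps_hat = expit(0) = 0.5 is out of range; use 0.1

        def loglik(lam, eps):
            from scipy.special import logit
            x = np.log(lam)
            y = logit(eps)
            return -0.5 * a * (x - np.log(50.0)) ** 2 - 0.5 * b * (y - logit(0.1)) ** 2

        fit = CopyingFit(
            lam_hat=50.0, eps_hat=0.1, loglik=0.0, mode="joint", converged=True,
            n_sites=10,
        )
        out = fit_standard_errors(None, fit, loglik_fn=loglik)
        assert out.se_lam == pytest.approx(50.0 / np.sqrt(a), rel=1e-5)
        assert out.se_eps == pytest.approx(0.1 * 0.9 / np.sqrt(b), rel=1e-5)

    def test_non_concave_surface_reports_missing(self):
        fit = CopyingFit(
            lam_hat=50.0, eps_hat=0.1, loglik=0.0, mode="joint", converged=True,
            n_sites=10,
        )
        out = fit_standard_errors(None, fit, loglik_fn=lambda lam, eps: (np.log(lam)) ** 2)
        assert out.se_lam is None and out.se_ok is False


class TestMAFAscertainment:
    def test_restriction_keeps_map_monotone(self):
        rng = np.random.default_rng(14)
        panel, _, mp = random_panel(40, 300, 0.2, rng, maf_min=0.0)
        query = rng.integers(0, 2, 300).astype(np.int8)
        data = CopyingPanel(panel, query, mp).restrict_maf(0.05)
        assert np.all(data.g >= 0)
        freq = data.panel.mean(axis=0)
        assert np.all(np.minimum(freq, 1 - freq) > 0.05)
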