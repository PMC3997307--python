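import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from reedcmr import (
    EncounterHistoryMatrix,
    ModelParameters,
    build_marray,
    cjs_loglik_marray,
    history_loglik,
    observation_row,
    total_loglik,
    transition_matrix,
)
from reedcmr.cmr_model import STATE_DEAD, STATE_INITIAL, STATE_RESIDENT
from conftest import enumerate_history_prob


class TestMatrices:
    def test_transition_entries(self):
        m = transition_matrix(0.5, 0.5)
        np.testing.assert_allclose(
            m, [[0, 0.25, 0.75], [0, 0.5, 0.5], [0, 0, 1]]
        )

    def test_certain_settlement_limit(self):
        m = transition_matrix(1.0, 1.0)
        assert m[STATE_INITIAL, STATE_RESIDENT] == 1.0

    def test_zero_survival_absorbs_to_dead(self):
        m = transition_matrix(0.0, 0.7)
        assert m[STATE_INITIAL, STATE_DEAD] == 1.0
        assert m[STATE_RESIDENT, STATE_DEAD] == 1.0

    @given(phi=st.floats(0, 1), psi=st.floats(0, 1))
    @settings(max_examples=50, deadline=None)
    def test_rows_stochastic_and_initial_never_reentered(self, phi, psi):
        m = transition_matrix(phi, psi)
        np.testing.assert_allclose(m.sum(axis=1), 1.0)
        assert (m[:, STATE_INITIAL] == 0).all()
        np.testing.assert_array_equal(m[STATE_DEAD], [0, 0, 1])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            transition_matrix(1.2, 0.5)
        with pytest.raises(ValueError):
            transition_matrix(0.5, -0.1)

    def test_observation_rows(self):
        assert observation_row(0.12, STATE_RESIDENT) == pytest.approx((0.12, 0.88))
        assert observation_row(0.9, STATE_DEAD) == (0.0, 1.0)
        assert observation_row(0.9, STATE_INITIAL) == (0.0, 1.0)
        assert observation_row(1.0, STATE_RESIDENT) == (1.0, 0.0)


class TestHistoryLoglik:
    def test_closed_form_products(self):
        # [1,1]: phi*psi*p
        ll = history_loglik(np.array([1, 1]), 0, [0.8], [0.0, 0.3], 0.7)
        assert np.exp(ll) == pytest.approx(0.8 * 0.7 * 0.3)
        # [1,0,1]: phi*psi*(1-p) * phi*p
        ll = history_loglik(np.array([1, 0, 1]), 0, [0.5, 0.5], [0, 0.5, 0.5], 0.5)
        assert np.exp(ll) == pytest.approx(0.03125)
        # [1,0,0] by complement
        ll = history_loglik(np.array([1, 0, 0]), 0, [0.5, 0.5], [0, 0.5, 0.5], 0.5)
        assert np.exp(ll) == pytest.approx(0.84375)

    def test_impossible_history_returns_neg_inf(self):
        ll = history_loglik(np.array([1, 1]), 0, [0.0], [0.0, 0.5], 1.0)
        assert ll == -np.inf

    def test_forward_equals_path_enumeration(self):
        rng = np.random.default_rng(123)
        for _ in range(300):
            T = int(rng.integers(2, 7))
            f = int(rng.integers(0, T - 1))
            phi = rng.uniform(0.01, 0.99, size=T - 1)
            p = rng.uniform(0.01, 0.99, size=T)
            psi = float(rng.uniform(0, 1))
            hist = np.zeros(T, dtype=int)
            hist[f] = 1
            hist[f + 1 :] = rng.random(T - f - 1) < 0.5
            expected = enumerate_history_prob(hist, f, phi, p, psi)
            got = np.exp(history_loglik(hist, f, phi, p, psi))
            assert got == pytest.approx(expected, rel=1e-10)

    @given(
        phi0=st.floats(0.05, 0.95),
        psi=st.floats(0.05, 0.95),
        p_seed=st.integers(0, 10_000),
    )
    @settings(max_examples=40, deadline=None)
    def test_probability_conservation(self, phi0, psi, p_seed):
        rng = np.random.default_rng(p_seed)
        T = 5
        phi = rng.uniform(0.05, 0.95, T - 1) * 0 + phi0
        p = rng.uniform(0.05, 0.95, T)
        total = 0.0
        for pattern in itertools.product((0, 1), repeat=T - 1):
            hist = np.array((1,) + pattern)
            total += np.exp(history_loglik(hist, 0, phi, p, psi))
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_monotone_in_survival_when_last_occasion_detected(self):
        # a detection at the final occasion removes the never-seen-again
        # tail, so the likelihood carries only phi factors
        hist = np.array([1, 0, 1, 1])
        lls = [
            history_loglik(hist, 0, [phi] * 3, [0, 0.3, 0.3, 0.3], 0.8)
            for phi in np.linspace(0.05, 0.95, 10)
        ]
        assert all(b >= a for a, b in zip(lls, lls[1:]))

    def test_monotone_in_p_for_fully_detected_history(self):
        hist = np.array([1, 1, 1, 1])
        lls = [
            history_loglik(hist, 0, [0.7] * 3, [0, p, p, p], 0.8)
            for p in np.linspace(0.05, 0.95, 10)
        ]
        assert all(b >= a for a, b in zip(lls, lls[1:]))


def _random_histories(rng, n, T, sites):
    det = (rng.random((n, T)) < 0.4).astype(np.int8)
    det[det.sum(axis=1) == 0, 0] = 1
    det[det.argmax(axis=1) == T - 1, 0] = 1
    return EncounterHistoryMatrix(det, rng.choice(sites, size=n), det.argmax(axis=1))


def _random_params(rng, S, T):
    return ModelParameters(
        mu=rng.normal(),
        eta=rng.normal(size=S),
        eps=rng.normal(size=T - 1),
        sigma_space=1.0,
        sigma_time=1.0,
        beta=rng.normal(),
        gamma=rng.normal(size=(S, T - 1)),
        sigma_gamma=1.0,
        psi=rng.uniform(0.1, 0.9, size=S),
    )


class TestTotalLoglik:
    def test_single_individual_equals_history_loglik(self):
        rng = np.random.default_rng(1)
        h = _random_histories(rng, 1, 5, [3])
        params = _random_params(rng, 1, 5)
        phi = params.survival()[0]
        p = np.concatenate(([0.0], params.recapture()[0]))
        expected = history_loglik(
            h.detections[0], int(h.first_capture[0]), phi, p, float(params.psi[0])
        )
        assert total_loglik(h, params) == pytest.approx(expected)

    def test_duplicating_histories_doubles_loglik(self):
        rng = np.random.default_rng(2)
        h = _random_histories(rng, 20, 5, [1, 2])
        params = _random_params(rng, 2, 5)
        h2 = EncounterHistoryMatrix(
            np.vstack([h.detections] * 2),
            np.concatenate([h.site_index] * 2),
            np.concatenate([h.first_capture] * 2),
        )
        assert total_loglik(h2, params) == pytest.approx(2 * total_loglik(h, params))

    def test_matches_per_individual_enumeration(self):
        rng = np.random.default_rng(3)
        h = _random_histories(rng, 50, 6, [1, 2, 3])
        params = _random_params(rng, 3, 6)
        phi = params.survival()
        p = params.recapture()
        pos = {sid: k for k, sid in enumerate(h.site_ids)}
        expected = sum(
            np.log(
                enumerate_history_prob(
                    h.detections[i],
                    int(h.first_capture[i]),
                    phi[pos[h.site_index[i]]],
                    np.concatenate(([0.0], p[pos[h.site_index[i]]])),
                    float(params.psi[pos[h.site_index[i]]]),
                )
            )
            for i in range(h.n_individuals)
        )
        assert total_loglik(h, params) == pytest.approx(expected, rel=1e-10)

    def test_dimension_mismatch_raises(self):
        rng = np.random.default_rng(4)
        h = _random_histories(rng, 10, 5, [1, 2])
        with pytest.raises(ValueError, match="site"):
            total_loglik(h, _random_params(rng, 3, 5))
        with pytest.raises(ValueError, match="occasions"):
            total_loglik(h, _random_params(rng, 2, 6))


class TestCjsOracle:
    def test_single_cell_probability(self):
        h = EncounterHistoryMatrix(
            np.array([[1, 1]], dtype=np.int8), np.array([1]), np.array([0])
        )
        ma = build_marray(h)
        ll = cjs_loglik_marray(ma, [0.8], [0.0, 0.3])
        assert np.exp(ll) == pytest.approx(0.8 * 0.3)

    def test_perfect_detection_limit(self):
        # p = 1: never-seen-again mass is 1 - phi per release
        h = EncounterHistoryMatrix(
            np.array([[1, 0, 0], [1, 1, 1]], dtype=np.int8),
            np.array([1, 1]),
            np.array([0, 0]),
        )
        ma = build_marray(h)
        phi = 0.6
        ll = cjs_loglik_marray(ma, [phi, phi], [0.0, 1.0, 1.0])
        # history [1,0,0]: (1-phi); [1,1,1]: phi * phi at both releases
        assert np.exp(ll) == pytest.approx((1 - phi) * phi * phi)

    def test_loglik_differences_match_multistate_at_psi_one(self):
        rng = np.random.default_rng(5)
        h = _random_histories(rng, 80, 6, [1])
        ma = build_marray(h)

        def pair(seed):
            r = np.random.default_rng(seed)
            params = ModelParameters(
                mu=r.normal(), eta=[0.0], eps=r.normal(size=5),
                sigma_space=0.0, sigma_time=1.0, beta=r.normal(),
                gamma=r.normal(size=(1, 5)), sigma_gamma=1.0, psi=[1.0],
            )
            phi = params.survival()[0]
            p = np.concatenate(([0.0], params.recapture()[0]))
            return total_loglik(h, params), cjs_loglik_marray(ma, phi, p)

        ms_a, cjs_a = pair(10)
        ms_b, cjs_b = pair(20)
        assert (ms_a - ms_b) == pytest.approx(cjs_a - cjs_b, abs=1e-8)
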