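"""Observer-model densities: closed forms, reductions, sampler consistency."""

import numpy as np
import pytest

from vpwm.circular import FeatureSpace, J_to_kappa, vm_convolve_kappa, vm_pdf
from vpwm.models import (
    MODEL_NAMES,
    cossa_error_pdf,
    ep_error_pdf,
    error_pdf,
    get_model,
    il_error_pdf,
    mix_error_pdf,
    resource_decay,
    sa_error_pdf,
    simulate_responses,
    vp_error_pdf,
    vpcap_error_pdf,
)

GRID = np.linspace(-np.pi, np.pi, 1441)
VP_PARAMS = dict(J1_bar=60.0, a=1.0, tau=30.0, kappa_r=50.0)


def tv_distance(p, q, x=GRID):
    return 0.5 * np.trapezoid(np.abs(p - q), x)


class TestResourceDecay:
    @pytest.mark.parametrize(
        "J1,a,N,expected", [(60, 0, 6, 60), (60, 1, 3, 20), (60, 2, 2, 15)]
    )
    def test_power_law(self, J1, a, N, expected):
        assert resource_decay(J1, a, N) == pytest.approx(expected)

    def test_non_increasing_in_N(self):
        for a in (0.0, 0.5, 2.0):
            J = [resource_decay(60.0, a, N) for N in range(1, 9)]
            assert np.all(np.diff(J) <= 0)

    def test_invalid(self):
        with pytest.raises(ValueError):
            resource_decay(-1.0, 1.0, 2)
        with pytest.raises(ValueError):
            resource_decay(10.0, -0.5, 2)


class TestItemLimitFamily:
    def test_il_no_guessing_at_setsize_one(self):
        p = il_error_pdf(GRID, 1, dict(K=4, kappa_r=20.0))
        np.testing.assert_allclose(p, vm_pdf(GRID, 0.0, 20.0))

    def test_il_guess_weight(self):
        # K=2, N=4 -> half the mass is uniform
        p = il_error_pdf(np.pi, 4, dict(K=2, kappa_r=20.0))
        expected = 0.5 * vm_pdf(np.pi, 0.0, 20.0) + 0.5 / (2 * np.pi)
        assert p == pytest.approx(expected)

    def test_il_kappa_zero_is_uniform(self):
        p = il_error_pdf(GRID, 3, dict(K=2, kappa_r=0.0))
        np.testing.assert_allclose(p, 1.0 / (2 * np.pi))

    def test_mix_reduces_to_il_with_shared_kappa(self):
        params = dict(K=2, kappa_N1=15.0, kappa_N3=15.0)
        for N in (1, 3):
            np.testing.assert_allclose(
                mix_error_pdf(GRID, N, params),
                il_error_pdf(GRID, N, dict(K=2, kappa_r=15.0)),
            )

    def test_mix_weights(self):
        p = mix_error_pdf(GRID, 3, dict(K=2, kappa_N3=12.0, kappa_N1=40.0))
        expected = (2 / 3) * vm_pdf(GRID, 0, 12.0) + (1 / 3) / (2 * np.pi)
        np.testing.assert_allclose(p, expected)

    def test_mix_missing_level_rejected(self):
        with pytest.raises(ValueError, match="set size 5"):
            mix_error_pdf(GRID, 5, dict(K=2, kappa_N1=10.0))


class TestSlotModels:
    def test_even_slots_single_component(self):
        # K = N = 3: every item holds exactly one slot
        params = dict(K=3, J_slot=20.0, kappa_r=50.0)
        kc = vm_convolve_kappa(J_to_kappa(20.0), 50.0)
        np.testing.assert_allclose(
            sa_error_pdf(GRID, 3, params), vm_pdf(GRID, 0.0, kc)
        )

    def test_uneven_slot_mixture(self):
        # K=4, N=3: one item gets 2 slots (w=1/3), two get 1 slot (w=2/3)
        params = dict(K=4, J_slot=10.0, kappa_r=50.0)
        k2 = vm_convolve_kappa(J_to_kappa(20.0), 50.0)
        k1 = vm_convolve_kappa(J_to_kappa(10.0), 50.0)
        expected = (1 / 3) * vm_pdf(GRID, 0, k2) + (2 / 3) * vm_pdf(GRID, 0, k1)
        np.testing.assert_allclose(sa_error_pdf(GRID, 3, params), expected)

    def test_overloaded_guess_weight(self):
        # N=6, K=3 -> half the probes are unstored
        p = sa_error_pdf(np.pi, 6, dict(K=3, J_slot=20.0, kappa_r=50.0))
        kc = vm_convolve_kappa(J_to_kappa(20.0), 50.0)
        assert p == pytest.approx(0.5 * vm_pdf(np.pi, 0, kc) + 0.5 / (2 * np.pi))

    def test_cossa_reduces_to_sa_with_zero_amplitudes(self):
        params = dict(
            K=3, J_slot=20.0, kappa_r=50.0, amp_1=0.0, phase_1=0.3, amp_2=0.0, phase_2=0.0
        )
        stim = np.full_like(GRID, 1.1)
        np.testing.assert_allclose(
            cossa_error_pdf(GRID, stim, 3, params),
            sa_error_pdf(GRID, 3, params),
        )

    def test_cossa_bias_shifts_mode(self):
        params = dict(
            K=2, J_slot=40.0, kappa_r=200.0, amp_1=0.2, phase_1=0.0, amp_2=0.0, phase_2=0.0
        )
        s = np.pi / 2  # sin(s) = 1 -> bias = +0.2 rad
        dens = cossa_error_pdf(GRID, np.full_like(GRID, s), 2, params)
        assert GRID[np.argmax(dens)] == pytest.approx(0.2, abs=0.01)

    def test_cossa_requires_stimulus(self):
        with pytest.raises(ValueError):
            cossa_error_pdf(GRID, None, 2, dict(K=2, J_slot=10.0, kappa_r=50.0))

    def test_cossa_normalizes_under_bias(self):
        params = dict(
            K=3, J_slot=15.0, kappa_r=60.0, amp_1=0.3, phase_1=1.0, amp_2=-0.2, phase_2=0.5
        )
        dens = cossa_error_pdf(GRID, np.full_like(GRID, 2.0), 3, params)
        assert np.trapezoid(dens, GRID) == pytest.approx(1.0, abs=1e-3)


class TestContinuousResourceModels:
    def test_ep_independent_of_N_without_decay(self):
        params = dict(J1_bar=30.0, a=0.0, kappa_r=50.0)
        np.testing.assert_allclose(
            ep_error_pdf(GRID, 1, params), ep_error_pdf(GRID, 6, params)
        )

    def test_vp_reduces_to_ep_as_tau_vanishes(self):
        for N in (1, 3):
            ep = ep_error_pdf(GRID, N, dict(J1_bar=60.0, a=1.0, kappa_r=50.0))
            vp = vp_error_pdf(
                GRID, N, dict(J1_bar=60.0, a=1.0, tau=60e-3, kappa_r=50.0)
            )
            assert tv_distance(ep, vp) < 0.01

    def test_vp_matches_monte_carlo_oracle(self):
        """Quadrature equals brute-force gamma-draw averaging of the same
        integrand, within 3 Monte-Carlo standard errors."""
        rng = np.random.default_rng(0)
        n_draws = 200_000
        eps = np.array([0.0, 0.5, 1.5, np.pi * 0.9])
        for N in (1, 3):
            J_bar = VP_PARAMS["J1_bar"] * N ** (-VP_PARAMS["a"])
            J = rng.gamma(J_bar / VP_PARAMS["tau"], VP_PARAMS["tau"], n_draws)
            kc = vm_convolve_kappa(J_to_kappa(J), VP_PARAMS["kappa_r"])
            samples = vm_pdf(eps[:, None], 0.0, kc[None, :])
            mc = samples.mean(axis=1)
            se = samples.std(axis=1, ddof=1) / np.sqrt(n_draws)
            quad = vp_error_pdf(eps, N, VP_PARAMS)
            assert np.all(np.abs(quad - mc) < 3 * se)

    def test_vp_tail_grows_with_tau(self):
        tails = [
            vp_error_pdf(np.array([np.pi]), 1, dict(VP_PARAMS, tau=t))[0]
            for t in (1.0, 10.0, 40.0)
        ]
        assert tails[0] < tails[1] < tails[2]

    def test_vpcap_reduces_to_vp_when_capacity_suffices(self):
        p_vp = vp_error_pdf(GRID, 3, VP_PARAMS)
        p_cap = vpcap_error_pdf(GRID, 3, dict(VP_PARAMS, K=3))
        np.testing.assert_allclose(p_cap, p_vp)

    def test_vpcap_guess_weight(self):
        p_vp = vp_error_pdf(GRID, 3, VP_PARAMS)
        p_cap = vpcap_error_pdf(GRID, 3, dict(VP_PARAMS, K=1))
        np.testing.assert_allclose(p_cap, p_vp / 3 + (2 / 3) / (2 * np.pi))


@pytest.mark.parametrize("name", MODEL_NAMES)
def test_pdf_normalizes_over_random_parameters(name):
    """Each density integrates to 1 for random in-bounds parameters."""
    rng = np.random.default_rng(hash(name) % 2**32)
    spec = get_model(name, (1, 3))
    for _ in range(10):
        params = {
            p: float(np.exp(rng.uniform(*np.log(spec.bounds[p]))))
            if spec.log_scale(p)
            else float(rng.uniform(*spec.bounds[p]))
            for p in spec.param_names
        }
        if spec.has_capacity:
            params["K"] = int(rng.integers(1, spec.k_max + 1))
        for N in (1, 3):
            dens = error_pdf(spec, GRID, N, params, stimulus=np.full_like(GRID, 0.5))
            assert np.trapezoid(dens, GRID) == pytest.approx(1.0, abs=1e-3)


class TestSimulator:
    def test_reproducible_under_seed(self):
        trials = [(1, 0.3)] * 50 + [(3, -1.0)] * 50
        a = simulate_responses("VP", VP_PARAMS, trials, seed=9)
        b = simulate_responses("VP", VP_PARAMS, trials, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_noiseless_limit(self):
        params = dict(J1_bar=5e3, a=0.0, tau=1e-2, kappa_r=1e5)
        resp = simulate_responses("VP", params, [(1, 0.7)] * 200, seed=1)
        assert np.max(np.abs(resp - 0.7)) < 0.15

    def test_il_guess_mass(self):
        # K=2, N=4: half the trials guess; |error| > 90 deg has mass
        # g/2 + (1-g)*tail ~ 0.25 for a concentrated VM
        resp = simulate_responses(
            "IL", dict(K=2, kappa_r=50.0), [(4, 0.0)] * 10_000, seed=3
        )
        frac = np.mean(np.abs(resp) > np.pi / 2)
        assert frac == pytest.approx(0.25, abs=0.02)

    @pytest.mark.parametrize("name", MODEL_NAMES)
    def test_sampler_matches_density(self, name):
        """Empirical histogram of simulated errors tracks the model pdf."""
        spec = get_model(name, (1, 3))
        params = dict(
            J1_bar=60.0, a=1.0, tau=30.0, kappa_r=50.0, K=2, J_slot=20.0,
            kappa_N1=40.0, kappa_N3=15.0, amp_1=0.1, phase_1=0.4,
            amp_2=-0.05, phase_2=1.0,
        )
        params = {k: params[k] for k in list(spec.param_names) + (["K"] if spec.has_capacity else [])}
        N, stim = 3, 0.9
        n = 40_000
        resp = simulate_responses(spec, params, [(N, stim)] * n, seed=21)
        err = np.angle(np.exp(1j * (resp - stim)))
        edges = np.linspace(-np.pi, np.pi, 73)
        hist, _ = np.histogram(err, bins=edges, density=True)
        centers = (edges[:-1] + edges[1:]) / 2
        dens = error_pdf(spec, centers, N, params, stimulus=np.full_like(centers, stim))
        tv = 0.5 * np.sum(np.abs(hist - dens)) * (edges[1] - edges[0])
        assert tv < 0.02
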