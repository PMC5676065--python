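"""Unit tests for single-mitochondrion dynamics."""

import numpy as np
import pytest

from mitosim import MitoEnvironment, MitoState, replicate_mtdna, step_mito, superoxide_production
from mitosim.mito import (
    classify_stress_state,
    mutant_allocation_probability,
    oxphos_defect_fraction,
    stress_transition_step,
    target_band_kernel,
)
from mitosim.params import MitoRates


class TestDefectFraction:
    @pytest.mark.parametrize(
        "mito, expected",
        [
            (MitoState(F=1.0, n_wt=10, n_mut=0), 0.0),  # undamaged organelle
            (MitoState(F=0.0, n_wt=5, n_mut=5), 1.0),  # no functional capacity
            (MitoState(F=0.5, n_wt=5, n_mut=5), 0.625),  # 1 - 0.5*(1 - 0.5*0.5)
        ],
    )
    def test_values(self, mito, expected):
        assert oxphos_defect_fraction(mito, w_h=0.5) == pytest.approx(expected)

    def test_monotone_in_heteroplasmy(self):
        defects = [
            oxphos_defect_fraction(MitoState(F=0.8, n_wt=10 - m, n_mut=m)) for m in range(11)
        ]
        assert all(b >= a for a, b in zip(defects, defects[1:]))

    def test_invalid_state_rejected(self):
        with pytest.raises(ValueError):
            oxphos_defect_fraction(MitoState(F=1.2))
        with pytest.raises(ValueError):
            oxphos_defect_fraction(MitoState(n_wt=0, n_mut=0))


class TestSuperoxideProduction:
    def test_no_respiration_no_leak(self):
        assert superoxide_production(MitoState(), respiration_flux=0.0) == 0.0

    def test_paraquat_term_additive_at_zero_flux(self):
        assert superoxide_production(MitoState(), 0.0, pq_boost=3.5) == pytest.approx(3.5)

    def test_defect_amplifies_leak(self):
        rates = MitoRates(leak_gain=1.0)
        healthy = superoxide_production(MitoState(F=1.0), 1.0, rates=rates)
        # defect 0.5 via F=0.5 with no heteroplasmy
        damaged = superoxide_production(MitoState(F=0.5), 1.0, rates=rates)
        assert damaged / healthy == pytest.approx(1.5)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            superoxide_production(MitoState(), -1.0)
        with pytest.raises(ValueError):
            superoxide_production(MitoState(), 1.0, pq_boost=-0.1)


class TestReplicateMtdna:
    def test_no_mutants_breed_true(self, rng):
        n_wt, n_mut = replicate_mtdna(10, 0, 5, rng=rng)
        assert (n_wt, n_mut) == (15, 0)

    def test_totals_grow_by_exactly_n_new(self, rng):
        for _ in range(50):
            n_wt, n_mut = replicate_mtdna(7, 3, 4, adv_mut=1.3, rng=rng)
            assert n_wt + n_mut == 14

    def test_allocation_probability_formula(self):
        # equal pools with advantage 1.1: p_mut = 11/21
        assert mutant_allocation_probability(10, 10, 1.1) == pytest.approx(11 / 21)
        assert mutant_allocation_probability(10, 10, 1.0) == pytest.approx(0.5)

    def test_neutral_allocation_matches_binomial(self, rng):
        # N_wt = N_mut, adv = 1 -> each copy mutant with p = 1/2
        draws = np.array([replicate_mtdna(10, 10, 1, adv_mut=1.0, rng=rng)[1] - 10 for _ in range(40_000)])
        p_hat = draws.mean()
        se = np.sqrt(0.25 / len(draws))
        assert abs(p_hat - 0.5) < 3 * se

    def test_empty_pool_rejected(self, rng):
        with pytest.raises(ValueError):
            replicate_mtdna(0, 0, 3, rng=rng)


class TestStepMito:
    def test_frozen_environment_is_fixed_point(self, rng):
        mito = MitoState(F=0.8, Pdam=0.2, n_wt=10, n_mut=0)
        env = MitoEnvironment(ros_dmg=0.0, chaperones=0.0, upr=0.0, nad=1.0)
        rates = MitoRates(k_repl=0.0, k_deg_dna=0.0)
        out = step_mito(mito, env, dt=1.0, rng=rng, rates=rates)
        assert out.F == pytest.approx(mito.F)
        assert (out.n_wt, out.n_mut) == (mito.n_wt, mito.n_mut)

    def test_poisson_damage_hits_match_analytic_mean(self):
        # choose rates so the per-step hit mean is lambda = 2
        rates = MitoRates(k_dmg_dna=0.02, k_repl=0.0, k_deg_dna=0.0)
        env = MitoEnvironment(ros_dmg=1.0, chaperones=0.0)
        rng = np.random.default_rng(7)
        lam = rates.k_dmg_dna * env.ros_dmg * 100
        hits = []
        for _ in range(30_000):
            out = step_mito(MitoState(n_wt=100, n_mut=0), env, 1.0, rng, rates)
            hits.append(out.n_mut)
        hits = np.asarray(hits)
        se = np.sqrt(lam / len(hits))
        assert abs(hits.mean() - lam) < 3 * se
        assert abs(hits.var() - lam) < 5 * se * np.sqrt(2 * lam)

    def test_fixed_seed_bit_identical(self):
        mito = MitoState(F=0.7, n_wt=8, n_mut=2)
        env = MitoEnvironment(ros_dmg=50.0, chaperones=1.0, upr=0.3, nad=0.8)
        a = step_mito(mito, env, 1.0, np.random.default_rng(42))
        b = step_mito(mito, env, 1.0, np.random.default_rng(42))
        assert a == b

    def test_invalid_dt_rejected(self, rng):
        with pytest.raises(ValueError):
            step_mito(MitoState(), MitoEnvironment(), 0.0, rng)


class TestStressStates:
    def test_band_targets(self):
        assert list(target_band_kernel(np.array([0.0, 0.29, 0.3, 0.59, 0.6, 0.89, 0.9, 1.0]))) == [
            0, 0, 1, 1, 2, 2, 3, 3,
        ]

    def test_healthy_band_is_absorbing(self, rng):
        mito = MitoState(F=1.0, state=1)
        states = []
        for _ in range(2000):
            mito.state = classify_stress_state(mito, rng, dt=1.0)
            states.append(mito.state)
        assert states[-1] == 0
        settled = np.asarray(states[500:])
        assert (settled == 0).all()

    def test_severe_defect_reaches_s3(self, rng):
        mito = MitoState(F=0.02, n_wt=1, n_mut=9, state=0)  # defect >= 0.90
        for _ in range(5000):
            mito.state = classify_stress_state(mito, rng, dt=1.0)
            if mito.state == 3:
                break
        assert mito.state == 3

    def test_moves_at_most_one_band(self, rng):
        mito = MitoState(F=0.02, n_wt=1, n_mut=9, state=0)
        prev = 0
        for _ in range(3000):
            mito.state = classify_stress_state(mito, rng, dt=1.0)
            assert abs(mito.state - prev) <= 1
            prev = mito.state

    def test_stationary_distribution_matches_birth_death_chain(self, rng):
        # symmetric per-step probabilities: analytic stationary law of the
        # 4-state birth-death chain via its transition-matrix eigenvector
        p_up, p_down = 0.05, 0.08
        P = np.zeros((4, 4))
        for s in range(4):
            if s < 3:
                P[s, s + 1] = p_up
            if s > 0:
                P[s, s - 1] = p_down
            P[s, s] = 1.0 - P[s].sum()
        w, v = np.linalg.eig(P.T)
        pi = np.real(v[:, np.argmax(np.real(w))])
        pi /= pi.sum()

        state = np.zeros(2000, dtype=np.int8)
        counts = np.zeros(4)
        n_steps = 3000
        burn = 500
        for step in range(n_steps):
            state = stress_transition_step(state, p_up, p_down, rng.random(state.shape))
            if step >= burn:
                counts += np.bincount(state, minlength=4)
        empirical = counts / counts.sum()
        assert np.allclose(empirical, pi, atol=0.01)
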