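"""Unit tests for cell-level dynamics and the life-state machine."""

import numpy as np
import pytest

from mitosim import (
    CellEnvironment,
    CellState,
    MitoState,
    biogenesis_event,
    check_life_transition,
    mitophagy_hazard,
    sample_compromise_threshold,
    step_cell,
)
from mitosim.params import CellRates, MitoRates


def make_cell(n_mitos=10, F=1.0, state=0, **kwargs):
    mitos = [MitoState(id=i, F=F, n_wt=10, state=state) for i in range(n_mitos)]
    return CellState(mitos=mitos, **kwargs)


class TestStepCell:
    def test_full_import_silences_upr(self, rng):
        cell = make_cell(F=1.0)
        step_cell(cell, 1.0, rng=rng)
        assert cell.atfs1_nuc == pytest.approx(0.0, abs=1e-12)
        assert cell.upr == pytest.approx(0.0, abs=1e-9)

    def test_failed_import_maximizes_upr(self, rng):
        cell = make_cell(F=0.0)
        # no fresh organelles and no OXPHOS re-synthesis: import stays broken
        cr = CellRates(k_biog=0.0)
        mr = MitoRates(k_rep_F=0.0)
        for _ in range(50):
            step_cell(cell, 1.0, rng=np.random.default_rng(0), mito_rates=mr, cell_rates=cr)
        assert cell.atfs1_nuc == pytest.approx(1.0)
        assert cell.upr > 0.9

    def test_fixed_seed_identical_successors(self):
        a, b = make_cell(), make_cell()
        env = CellEnvironment(pq_boost=0.01)
        step_cell(a, 1.0, env, np.random.default_rng(3))
        step_cell(b, 1.0, env, np.random.default_rng(3))
        assert a == b

    def test_dead_cell_rejected(self, rng):
        cell = make_cell()
        cell.life = "dead"
        with pytest.raises(ValueError):
            step_cell(cell, 1.0, rng=rng)

    def test_pools_remain_nonnegative(self):
        cell = make_cell(F=0.3)
        rng = np.random.default_rng(5)
        env = CellEnvironment(pq_boost=0.2)
        for _ in range(500):
            if cell.life == "dead":
                break
            step_cell(cell, 1.0, env, rng)
            assert cell.sox >= 0 and cell.h2o2 >= 0 and cell.nad >= 0 and cell.atp >= 0
            for x in (cell.upr, cell.daf16, cell.skn1, cell.atfs1_nuc):
                assert 0.0 <= x <= 1.0


class TestMitophagyHazard:
    def test_baseline_formula(self):
        cr = CellRates(state_mult=(1.0, 2.0, 5.0, 20.0))
        cell = make_cell(daf16=0.4)
        hz = mitophagy_hazard(MitoState(state=0), cell, rates=cr)
        assert hz == pytest.approx(cr.k_mitophagy * 1.0 * (1 + cr.d_daf * 0.4))

    def test_drug_multiplier_scales_linearly(self):
        cell = make_cell()
        mito = MitoState(state=1)
        base = mitophagy_hazard(mito, cell, CellEnvironment(phagy_mult=1.0))
        doubled = mitophagy_hazard(mito, cell, CellEnvironment(phagy_mult=2.0))
        assert doubled == pytest.approx(2 * base)

    def test_selectivity_ratio(self):
        cr = CellRates()
        cell = make_cell()
        h0 = mitophagy_hazard(MitoState(state=0), cell, rates=cr)
        h3 = mitophagy_hazard(MitoState(state=3), cell, rates=cr)
        assert h3 / h0 == pytest.approx(cr.state_mult[3] / cr.state_mult[0])
        assert h3 >= h0


class TestBiogenesis:
    def test_capacity_limit_blocks_births(self, rng):
        cr = CellRates(mito_cap=10)
        cell = make_cell(n_mitos=10)
        for _ in range(200):
            biogenesis_event(cell, 1.0, rng, rates=cr)
        assert len(cell.mitos) == 10

    def test_clean_pool_breeds_clean_organelles(self, rng):
        cell = make_cell(n_mitos=2)
        cr = CellRates(k_biog=50.0)  # force an event
        biogenesis_event(cell, 1.0, rng, rates=cr)
        assert len(cell.mitos) == 3
        assert cell.mitos[-1].n_mut == 0
        assert cell.mitos[-1].F >= 0.9

    def test_event_frequency_matches_hazard(self):
        # lambda*dt = 0.1 -> event probability 1 - exp(-0.1)
        cr = CellRates(k_biog=0.2, mito_cap=10, b_tf=0.0, b_nad=0.0)
        rng = np.random.default_rng(11)
        n, hits = 30_000, 0
        for _ in range(n):
            cell = make_cell(n_mitos=5)
            biogenesis_event(cell, 1.0, rng, rates=cr)
            hits += len(cell.mitos) == 6
        p = 1 - np.exp(-0.1)
        se = np.sqrt(p * (1 - p) / n)
        assert abs(hits / n - p) < 3 * se


class TestCompromiseThreshold:
    def test_support(self, rng):
        draws = np.array([sample_compromise_threshold(rng) for _ in range(10_000)])
        assert draws.min() >= 0.60 and draws.max() <= 0.75

    def test_mean_matches_closed_form(self, rng):
        draws = np.array([sample_compromise_threshold(rng) for _ in range(50_000)])
        mean = (0.60 + 0.625 + 0.75) / 3
        se = draws.std() / np.sqrt(len(draws))
        assert abs(draws.mean() - mean) < 4 * se


class TestLifeTransitions:
    def test_below_distribution_minimum_never_compromises(self, rng):
        # 59% defective is below every possible triangular threshold
        cell = make_cell(n_mitos=100)
        for m in cell.mitos[:59]:
            m.state = 3
        cell.threshold_c = 0.60
        for _ in range(100):
            check_life_transition(cell, 1.0, rng)
            assert cell.life == "healthy"

    def test_above_distribution_maximum_compromises_immediately(self, rng):
        cell = make_cell(n_mitos=100)
        for m in cell.mitos[:76]:
            m.state = 3
        cell.threshold_c = 0.75
        check_life_transition(cell, 1.0, rng)
        assert cell.life == "compromised"

    def test_zero_death_hazard_conserves_cells(self, rng):
        cr = CellRates(k_death=0.0)
        cell = make_cell(n_mitos=10)
        for m in cell.mitos:
            m.state = 3
        cell.threshold_c = 0.61
        for _ in range(2000):
            check_life_transition(cell, 1.0, rng, cr)
        assert cell.life == "compromised"

    def test_hysteresis_guards_are_exclusive(self, rng):
        # with the defective fraction between the recovery bound and the
        # threshold, neither transition can fire: no flip-flop within a step
        cell = make_cell(n_mitos=100)
        for m in cell.mitos[:65]:
            m.state = 3
        cell.threshold_c = 0.70
        cr = CellRates(k_death=0.0)
        check_life_transition(cell, 1.0, rng, cr)
        assert cell.life == "healthy"
        cell.life = "compromised"
        check_life_transition(cell, 1.0, rng, cr)
        assert cell.life == "compromised"


class TestAntioxidantMonotonicity:
    def test_steady_state_ros_never_increases_with_clearance(self):
        # closed-form steady state of the two-species linear clearance chain:
        # sox* = P/A_sod, h2o2* = P/A_cat; total strictly decreasing in both
        P = 3.0
        grid = np.linspace(0.2, 3.0, 50)
        total = P / grid + P / (0.4 * grid)
        assert all(b <= a for a, b in zip(total, total[1:]))

    def test_simulated_cell_matches_linear_steady_state(self):
        # freeze everything except the ROS pools and compare to closed form
        cr = CellRates(tf_basal=0.0, a_upr=0.0, a_daf=0.0, a_skn=0.0)
        mr = MitoRates(k_dmg_F=0.0, k_dmg_dna=0.0, k_deg_dna=0.0, leak_gain=0.0)
        cell = make_cell(n_mitos=5, F=1.0)
        rng = np.random.default_rng(0)
        crates = CellRates(**{**vars(cr), "k_mitophagy": 0.0, "k_biog": 0.0})
        for _ in range(3000):
            step_cell(cell, 1.0, rng=rng, mito_rates=mr, cell_rates=crates)
        g = cell.nad * (1 + crates.K_nad) / (crates.K_nad + cell.nad)
        prod = sum(mr.k_sox_base * g * (mr.flux_floor + (1 - mr.flux_floor) * m.F) for m in cell.mitos)
        enz = (cell.atp**crates.n_enz / (crates.K_enz**crates.n_enz + cell.atp**crates.n_enz)) / (
            crates.atp_ref**crates.n_enz / (crates.K_enz**crates.n_enz + crates.atp_ref**crates.n_enz)
        )
        enz_ax = crates.e_antiox + (1 - crates.e_antiox) * enz
        A_sod = crates.k_sod * cell.constitution * enz_ax + crates.k_spont_sod
        A_cat = crates.k_cat * cell.constitution * enz_ax + crates.k_spont_cat
        assert cell.sox == pytest.approx(prod / A_sod, rel=1e-3)
        assert cell.h2o2 == pytest.approx(prod / A_cat, rel=1e-3)
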