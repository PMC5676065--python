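"""Normalized sensitivity coefficients and the one-at-a-time analysis."""

import numpy as np
import pytest

from mitosim import SimulationConfig, flag_significant, global_sensitivity, sensitivity_coefficient
from mitosim.params import get_parameter, iter_parameters, set_parameter
from mitosim.sensitivity import SensitivityResult, results_to_dataframe
from mitosim.testing import PowerLawSurrogate, make_fixture


class TestCoefficientFormula:
    def test_proportional_output_gives_exactly_one(self):
        assert sensitivity_coefficient(10.0, 9.5) == 1.0

    def test_insensitive_output_gives_zero(self):
        assert sensitivity_coefficient(10.0, 10.0) == 0.0

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_power_law_closed_form(self, k):
        O_base = 4.2
        O_pert = O_base * 0.95**k
        expected = (1 - 0.95**k) / 0.05
        assert sensitivity_coefficient(O_base, O_pert) == pytest.approx(expected, abs=1e-12)

    def test_negative_relationship_gives_negative_sc(self):
        assert sensitivity_coefficient(10.0, 11.0) < 0

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            sensitivity_coefficient(0.0, 1.0)


class TestSurrogateAnalysis:
    @pytest.mark.parametrize("k", [1.0, 2.0, 3.0])
    def test_power_law_surrogate_recovers_exponent(self, k):
        surrogate = PowerLawSurrogate(exponent=k)
        cfg = make_fixture("tiny_population")
        results = global_sensitivity(
            cfg,
            parameter_list=["mitochondrion.k_sox_base"],
            response_list=["value"],
            age_points=[0.0],
            n_reps=1,
            runner=surrogate.runner,
            response_fn=surrogate.response_fn,
        )
        assert len(results) == 1
        assert results[0].SC == pytest.approx((1 - 0.95**k) / 0.05, abs=1e-12)

    def test_inert_parameter_has_zero_sc(self):
        surrogate = PowerLawSurrogate(exponent=2.0)
        cfg = make_fixture("tiny_population")
        results = global_sensitivity(
            cfg,
            parameter_list=["cell.k_sod"],  # surrogate ignores it
            response_list=["value"],
            age_points=[0.0],
            n_reps=1,
            runner=surrogate.runner,
            response_fn=surrogate.response_fn,
        )
        assert results[0].SC == 0.0

    def test_common_random_numbers_reduce_sc_variance(self):
        # multiplicative run-to-run noise cancels from SC when the control
        # and perturbed replicates share seeds, and does not when they don't
        def noisy_output(p, seed):
            return p * (1.0 + 0.1 * np.random.default_rng(seed).standard_normal())

        p0, p1 = 2.0, 2.0 * 0.95
        paired = [
            sensitivity_coefficient(noisy_output(p0, s), noisy_output(p1, s))
            for s in range(40)
        ]
        unpaired = [
            sensitivity_coefficient(noisy_output(p0, s), noisy_output(p1, 1000 + s))
            for s in range(40)
        ]
        assert np.var(paired) < np.var(unpaired)

    def test_unknown_names_rejected(self):
        cfg = make_fixture("tiny_population")
        with pytest.raises(KeyError):
            global_sensitivity(cfg, parameter_list=["cell.not_a_rate"], n_reps=1)
        with pytest.raises(KeyError):
            global_sensitivity(
                cfg, parameter_list=["cell.k_sod"], response_list=["entropy"], n_reps=1
            )


class TestSimulatorAnalysis:
    def test_table_shape_and_flags(self):
        cfg = make_fixture("tiny_population")
        params = ["mitochondrion.k_sox_base", "cell.k_mitophagy"]
        responses = ["ros", "mito_count"]
        ages = [50.0, 100.0]
        results = global_sensitivity(cfg, params, responses, ages, n_reps=2, seed=3)
        assert len(results) == len(params) * len(responses) * len(ages)
        df = results_to_dataframe(results)
        assert set(df["parameter"]) == set(params)
        flagged = flag_significant(results)
        assert all(abs(r.SC) >= 1.0 for r in flagged)

    def test_superoxide_rate_is_proportional_with_feedbacks_frozen(self):
        # with damage accumulation and organelle turnover frozen, steady
        # tissue ROS is exactly proportional to the production constant, so
        # the full simulate-and-measure pipeline must return SC = 1
        cfg = make_fixture("tiny_population")
        cfg = SimulationConfig.from_dict({**cfg.to_dict(), "t_end": 1000, "n_record": 20})
        for name in ("k_dmg_F", "k_dmg_dna", "k_deg_dna"):
            setattr(cfg.mito, name, 0.0)
        cfg.cell.k_mitophagy = 0.0
        cfg.cell.k_biog = 0.0
        results = global_sensitivity(
            cfg, ["mitochondrion.k_sox_base"], ["ros"], [1000.0], n_reps=2, seed=1
        )
        assert results[0].SC == pytest.approx(1.0, abs=0.05)


class TestSignificanceFlagging:
    def make(self, sc):
        return SensitivityResult("p", "ros", 5000.0, 1.0, 1.0, sc)

    def test_boundary_inclusive(self):
        assert self.make(1.0).significant
        assert self.make(-1.2).significant
        assert not self.make(0.999).significant

    def test_idempotent_and_order_independent(self):
        rows = [self.make(s) for s in (0.5, -1.5, 1.0, 0.0)]
        once = flag_significant(rows)
        assert flag_significant(once) == once
        assert set(id(r) for r in flag_significant(rows[::-1])) == set(id(r) for r in once)


class TestParameterRegistry:
    def test_roundtrip_get_set(self):
        cfg = make_fixture("tiny_population")
        for name in list(iter_parameters(cfg))[:10]:
            value = get_parameter(cfg, name)
            set_parameter(cfg, name, value * 0.95)
            assert get_parameter(cfg, name) == pytest.approx(value * 0.95)

    def test_state_mult_entries_addressable(self):
        cfg = make_fixture("tiny_population")
        set_parameter(cfg, "cell.state_mult[3]", 8.0)
        assert cfg.cell.state_mult[3] == 8.0
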