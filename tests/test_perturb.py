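"""Dosing schedules, pharmacodynamic multipliers, and genetic ablations."""

import numpy as np
import pytest

from mitosim import (
    AblationScheme,
    DrugParams,
    PerturbationScheme,
    apply_ablation,
    drug_level,
    get_preset,
    mitophagy_modulation,
    paraquat_boost,
    pterostilbene_effects,
)
from mitosim.params import ConfigError


class TestDrugLevel:
    def test_zero_before_window(self):
        s = PerturbationScheme("rapamycin", dose=15.0, t_start=100.0, t_end=1e5)
        assert drug_level(s, 50.0) == 0.0

    def test_constant_dosing_without_decay(self):
        s = PerturbationScheme("rapamycin", dose=15.0)
        for t in (0.0, 1234.5, 2500.0, 29_999.0):
            assert drug_level(s, t) == pytest.approx(15.0)

    def test_first_order_decay_between_refreshes(self):
        s = PerturbationScheme("bafilomycin", dose=10.0, refresh_every=2500.0, decay_halflife=2500.0)
        assert drug_level(s, 2499.999) == pytest.approx(5.0, rel=1e-3)
        assert drug_level(s, 2500.0) == pytest.approx(10.0)

    def test_invalid_scheme_rejected(self):
        with pytest.raises(ConfigError):
            drug_level(PerturbationScheme("rapamycin", dose=-1.0), 0.0)
        with pytest.raises(ConfigError):
            drug_level(PerturbationScheme("ouabain", dose=1.0), 0.0)


class TestMitophagyModulation:
    def test_no_drug_is_identity(self):
        assert mitophagy_modulation(0.0, 0.0) == 1.0

    def test_hill_midpoints(self):
        d = DrugParams()
        assert mitophagy_modulation(d.EC50_r, 0.0, d) == pytest.approx(1 + d.E_r / 2)
        assert mitophagy_modulation(0.0, d.IC50_b, d) == pytest.approx(0.5)

    def test_direction_of_effects(self):
        assert mitophagy_modulation(15.0, 0.0) > 1.0
        assert mitophagy_modulation(0.0, 10.0) < 1.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            mitophagy_modulation(-1.0, 0.0)


class TestParaquat:
    def test_zero_dose(self):
        assert paraquat_boost(0.0) == 0.0

    def test_linearity(self):
        assert paraquat_boost(100.0) / paraquat_boost(5.0) == pytest.approx(20.0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            paraquat_boost(-5.0)


class TestPterostilbene:
    def test_zero_dose_identity(self):
        assert pterostilbene_effects(0.0) == (0.0, 0.0, 1.0)

    def test_monotone_in_dose(self):
        grid = np.linspace(0, 200, 41)
        effects = np.array([pterostilbene_effects(c) for c in grid])
        assert np.all(np.diff(effects[:, 0]) >= 0)
        assert np.all(np.diff(effects[:, 1]) >= 0)
        assert np.all(np.diff(effects[:, 2]) >= 0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            pterostilbene_effects(-1.0)


class TestAblation:
    def test_zero_fraction_is_identity(self):
        cfg = get_preset("control")
        out = apply_ablation(cfg, AblationScheme("sod-2", 0.0))
        assert out.to_dict() == cfg.to_dict()

    def test_full_sod2_knockout_removes_dismutation(self):
        cfg = get_preset("control")
        out = apply_ablation(cfg, AblationScheme("sod-2", 1.0))
        assert out.cell.k_sod == 0.0

    def test_ninety_percent_scales_by_point_one(self):
        cfg = get_preset("control")
        out = apply_ablation(cfg, AblationScheme("sod-2", 0.9))
        assert out.cell.k_sod == pytest.approx(0.1 * cfg.cell.k_sod)
        out = apply_ablation(cfg, AblationScheme("daf-16", 0.9))
        assert out.cell.daf16_scale == pytest.approx(0.1)
        out = apply_ablation(cfg, AblationScheme("skn-1", 0.9))
        assert out.cell.skn1_scale == pytest.approx(0.1)

    def test_unknown_gene_rejected(self):
        with pytest.raises(ConfigError):
            apply_ablation(get_preset("control"), AblationScheme("mev-1", 0.5))


class TestPresets:
    def test_quoted_dosing_constants(self):
        """The preset schedule constants echo the published dosing schemes."""
        rapa = get_preset("rapamycin15nM").perturbations[0]
        assert (rapa.agent, rapa.dose, rapa.refresh_every) == ("rapamycin", 15.0, 2500.0)
        baf = get_preset("bafilomycin10nM").perturbations[0]
        assert (baf.agent, baf.dose, baf.refresh_every) == ("bafilomycin", 10.0, 2500.0)
        assert get_preset("pq5uM").perturbations[0].dose == 5.0
        assert get_preset("pq100uM").perturbations[0].dose == 100.0
        assert get_preset("pt100uM").perturbations[0].dose == 100.0
        assert get_preset("sod2_90").ablations[0].fraction == 0.9

    def test_unknown_preset_rejected(self):
        with pytest.raises(KeyError):
            get_preset("metformin")
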