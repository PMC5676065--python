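"""Pharmacological dosing schedules and genetic ablations.

Four agents map onto model rates: rapamycin induces and bafilomycin inhibits
selective mitophagy (a shared multiplier on the mitophagy hazard), paraquat
redox-cycles at the electron transport chain and adds superoxide production,
and pterostilbene drives DAF-16/SKN-1 activation and NAD+-dependent sirtuin
activity.  Genetic ablations scale the expression of sod-2 (matrix MnSOD),
daf-16, or skn-1 by a fractional knockdown.

Presets reproduce the virtual experiments the model was exercised with:
constant 15 nM rapamycin or 10 nM bafilomycin refreshed every 2500 min,
constant 5 or 100 uM paraquat, constant 100 uM pterostilbene, and 90% (or
complete) ablations of sod-2 / daf-16 / skn-1.
"""

from __future__ import annotations

import math

import numpy as np

from .params import (
    AblationScheme,
    ConfigError,
    DrugParams,
    PerturbationScheme,
    SimulationConfig,
)

__all__ = [
    "drug_level",
    "mitophagy_modulation",
    "paraquat_boost",
    "pterostilbene_effects",
    "apply_ablation",
    "PRESETS",
    "get_preset",
    "preset_names",
]


def drug_level(scheme: PerturbationScheme, t) -> float | np.ndarray:
    """Drug level at time ``t`` (minutes) under a refresh-and-decay schedule.

    Zero outside [t_start, t_end].  Inside the window the level resets to the
    nominal dose at every refresh boundary and decays first order with
    ``decay_halflife`` in between; without a half-life the exposure is a
    constant-level dosing.
    """
    scheme.validate()
    t = np.asarray(t, dtype=np.float64)
    inside = (t >= scheme.t_start) & (t <= scheme.t_end)
    if scheme.decay_halflife is None:
        level = np.where(inside, scheme.dose, 0.0)
    else:
        since = np.mod(t - scheme.t_start, scheme.refresh_every)
        decay = np.exp2(-since / scheme.decay_halflife)
        level = np.where(inside, scheme.dose * decay, 0.0)
    return float(level) if level.ndim == 0 else level


def mitophagy_modulation(rapa: float, baf: float, drugs: DrugParams | None = None) -> float:
    """Multiplier on the mitophagy hazard under rapamycin and bafilomycin.

    multiplier = (1 + E_r*rapa/(EC50_r + rapa)) / (1 + baf/IC50_b): >1 under
    rapamycin alone, <1 under bafilomycin alone, exactly 1 with neither.
    """
    if rapa < 0 or baf < 0:
        raise ValueError("drug concentrations must be >= 0")
    drugs = drugs or DrugParams()
    induction = 1.0 + drugs.E_r * rapa / (drugs.EC50_r + rapa)
    inhibition = 1.0 + baf / drugs.IC50_b
    return induction / inhibition


def paraquat_boost(conc_uM: float, drugs: DrugParams | None = None) -> float:
    """Per-organelle superoxide production add-on (nM/min) at ``conc_uM`` paraquat.

    Linear redox-cycling term k_pq * conc; only two calibration doses are on
    record, so linearity is the minimal model with one free constant.
    """
    if conc_uM < 0:
        raise ValueError("paraquat concentration must be >= 0")
    drugs = drugs or DrugParams()
    return drugs.k_pq * conc_uM


def pterostilbene_effects(conc_uM: float, drugs: DrugParams | None = None) -> tuple[float, float, float]:
    """(daf16_drive, skn1_drive, sirtuin_scale) at ``conc_uM`` pterostilbene.

    Saturating (Hill, n=1) drives on DAF-16/SKN-1 activation plus a sirtuin
    activity multiplier; (0, 0, 1) at zero dose and monotone in dose.
    """
    if conc_uM < 0:
        raise ValueError("pterostilbene concentration must be >= 0")
    drugs = drugs or DrugParams()
    hill = conc_uM / (drugs.pt_EC50 + conc_uM)
    return (
        drugs.pt_daf_max * hill,
        drugs.pt_skn_max * hill,
        1.0 + drugs.pt_sirt_max * hill,
    )


def apply_ablation(config: SimulationConfig, scheme: AblationScheme) -> SimulationConfig:
    """Return a copy of ``config`` with a fractional gene knockdown applied.

    sod-2 scales the enzymatic (SOD) dismutation channel, including its
    UPRmt/TF-driven induction, by (1 - fraction); daf-16 and skn-1 scale the
    respective transcription-factor activation drives (and thereby their
    antioxidant and mitophagy contributions) by (1 - fraction).
    """
    scheme.validate()
    out = config.copy()
    keep = 1.0 - scheme.fraction
    if scheme.gene == "sod-2":
        out.cell.k_sod *= keep
    elif scheme.gene == "daf-16":
        out.cell.daf16_scale *= keep
    elif scheme.gene == "skn-1":
        out.cell.skn1_scale *= keep
    else:  # pragma: no cover - validate() already rejects
        raise ConfigError(f"unknown gene {scheme.gene!r}")
    return out


def _scheme(agent: str, dose: float) -> dict:
    return {"agent": agent, "dose": dose, "refresh_every": 2500.0, "t_start": 0.0, "t_end": math.inf}


#: named virtual-experiment presets (config-dict overlays)
PRESETS: dict[str, dict] = {
    "control": {},
    "rapamycin15nM": {"perturbations": [_scheme("rapamycin", 15.0)]},
    "bafilomycin10nM": {"perturbations": [_scheme("bafilomycin", 10.0)]},
    "pq5uM": {"perturbations": [_scheme("paraquat", 5.0)]},
    "pq100uM": {"perturbations": [_scheme("paraquat", 100.0)]},
    "pt100uM": {"perturbations": [_scheme("pterostilbene", 100.0)]},
    "sod2_90": {"ablations": [{"gene": "sod-2", "fraction": 0.9}]},
    "sod2_100": {"ablations": [{"gene": "sod-2", "fraction": 1.0}]},
    "daf16_90": {"ablations": [{"gene": "daf-16", "fraction": 0.9}]},
    "skn1_90": {"ablations": [{"gene": "skn-1", "fraction": 0.9}]},
    "skn1_100": {"ablations": [{"gene": "skn-1", "fraction": 1.0}]},
}

#: sod-2 knockdown sweep used for the expression-level dose response
PRESETS.update(
    {
        f"sod2_{int(f * 100)}": {"ablations": [{"gene": "sod-2", "fraction": f}]}
        for f in (0.25, 0.5, 0.75)
    }
)


def preset_names() -> list[str]:
    return sorted(PRESETS)


def get_preset(name: str, seed: int | None = None, **overrides) -> SimulationConfig:
    """Build a validated :class:`SimulationConfig` for a named preset.

    ``overrides`` (e.g. ``n_cells=16, t_end=5000``) are applied on top of the
    preset overlay; the calibrated rate defaults are shared by all presets.
    """
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; known presets: {preset_names()}")
    data: dict = {**PRESETS[name]}
    data.update(overrides)
    if seed is not None:
        data["seed"] = seed
    return SimulationConfig.from_dict(data)
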