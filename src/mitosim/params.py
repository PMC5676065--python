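"""Parameter blocks and the top-level simulation configuration.

All rate constants of the model live in three flat dataclasses
(:class:`MitoRates`, :class:`CellRates`, :class:`DrugParams`) so that a
configuration file, a perturbation scheme, or the sensitivity analysis can
address any of them by a dotted name such as ``"cell.k_mitophagy"``.

Defaults encode the calibrated control condition: a population of 65
post-mitotic cells, 50 mitochondria each, simulated over 30 000 min of
nematode life at 20 degC with 500 recording points.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Any, Iterator

__all__ = [
    "MitoRates",
    "CellRates",
    "DrugParams",
    "PerturbationScheme",
    "AblationScheme",
    "SimulationConfig",
    "ConfigError",
    "iter_parameters",
    "get_parameter",
    "set_parameter",
]

GENES = ("sod-2", "daf-16", "skn-1")
AGENTS = ("rapamycin", "bafilomycin", "paraquat", "pterostilbene")


class ConfigError(ValueError):
    """Raised when a configuration violates an invariant; names the offending key."""


@dataclass
class MitoRates:
    """Rate constants of the intramitochondrial reaction network.

    Units are per-minute rate constants unless noted; ROS concentrations are
    nM, mtDNA in copies per organelle.
    """

    #: superoxide production per unit respiration flux (nM/min per flux unit)
    k_sox_base: float = 0.019
    #: maximal cellular ATP synthesis at full capacity (mM/min, see cell step)
    k_atp: float = 0.0357
    #: ROS-driven OXPHOS damage rate constant (1/min per nM damaging ROS)
    k_dmg_F: float = 5.0e-5
    #: chaperone-dependent OXPHOS repair/synthesis rate constant (1/min)
    k_rep_F: float = 1.05e-2
    #: ROS-driven matrix-protein damage rate constant (1/min per nM)
    k_dmg_P: float = 2.0e-5
    #: chaperone-dependent protein repair rate constant (1/min)
    k_rep_P: float = 4.0e-3
    #: ROS-driven mtDNA hit rate (hits/min per nM per wt copy)
    k_dmg_dna: float = 5.6e-7
    #: mtDNA replication rate per missing copy (1/min)
    k_repl: float = 0.02
    #: mtDNA copy turnover (degradation) rate (1/min per copy)
    k_deg_dna: float = 1.0e-4
    #: replicative advantage multiplier for deletion-bearing mtDNA
    adv_mut: float = 1.1
    #: extra superoxide per unit OXPHOS defect (electron leak amplification)
    leak_gain: float = 50.0
    #: weight of heteroplasmy in the OXPHOS defect fraction
    w_h: float = 0.5
    #: fraction of respiration flux that persists at F=0 (uncoupled leak flux)
    flux_floor: float = 0.5
    #: UPRmt suppression of new OXPHOS subunit synthesis (0..1)
    s_upr: float = 0.5
    #: exponent of the intact-genome fraction (1-h) in OXPHOS repair/synthesis
    rep_h_exp: float = 2.0
    #: weight of superoxide (vs peroxide) in the damaging-ROS pool
    w_sox_dmg: float = 0.02
    #: mtDNA copies per organelle at homeostasis
    n0_copies: int = 10
    #: stress-state progression rate toward a worse band (1/min)
    r_up: float = 0.02
    #: stress-state recovery rate toward a better band (1/min)
    r_down: float = 0.008

    def validate(self) -> None:
        for name in (
            "k_sox_base", "k_atp", "k_dmg_F", "k_rep_F", "k_dmg_P", "k_rep_P",
            "k_dmg_dna", "k_repl", "k_deg_dna", "leak_gain", "s_upr",
            "w_sox_dmg", "r_up", "r_down",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"mitochondrion.{name} must be >= 0")
        if self.adv_mut < 1:
            raise ConfigError("mitochondrion.adv_mut must be >= 1")
        if not 0 <= self.w_h <= 1:
            raise ConfigError("mitochondrion.w_h must lie in [0, 1]")
        if not 0 <= self.flux_floor <= 1:
            raise ConfigError("mitochondrion.flux_floor must lie in [0, 1]")
        if self.n0_copies < 1:
            raise ConfigError("mitochondrion.n0_copies must be >= 1")


@dataclass
class CellRates:
    """Rate constants of the cell-level network and agent-based state machines."""

    # -- ROS pools -----------------------------------------------------------
    #: SOD dismutation rate constant (1/min)
    k_sod: float = 0.8
    #: spontaneous (non-enzymatic) superoxide dismutation (1/min)
    k_spont_sod: float = 0.05
    #: peroxide clearance (catalase/peroxidase) rate constant (1/min)
    k_cat: float = 0.27
    #: non-enzymatic peroxide removal floor (diffusion/leak, 1/min)
    k_spont_cat: float = 0.04
    # -- NAD+ ----------------------------------------------------------------
    #: NAD+ salvage/synthesis rate (relative units/min)
    k_nad_syn: float = 8.0e-4
    #: baseline NAD+ consumption rate (1/min)
    k_nad_decay: float = 8.0e-4
    #: stress amplification of NAD+ consumption (per unit excess mean defect)
    c_stress: float = 22.0
    #: mean-defect threshold below which NAD+ consumption stays basal
    d_ref: float = 0.17
    #: half-saturation of respiration/sirtuin activity in NAD+ (relative units)
    K_nad: float = 0.5
    K_sirt: float = 0.3
    # -- ATP -----------------------------------------------------------------
    #: cellular ATP consumption rate (1/min)
    k_atp_use: float = 0.01
    #: half-saturation of ATP synthesis in total functional capacity (F units)
    F_half: float = 20.0
    #: reference ATP level used to normalize enzyme-renewal capacity (mM)
    atp_ref: float = 2.5
    #: half-saturation (mM) and Hill exponent of enzyme renewal in ATP
    K_enz: float = 1.8
    n_enz: float = 4.0
    #: persistent fraction of antioxidant enzyme capacity (long-lived pools)
    e_antiox: float = 0.06
    #: s.d. of the per-cell constitution factor scaling antioxidant capacity
    sigma_const: float = 0.04
    # -- UPRmt / ATFS-1 ------------------------------------------------------
    #: ATFS-1 mitochondrial import capacity per unit mean OXPHOS capacity
    k_import: float = 1.0
    #: Hill parameters of UPRmt activation by nuclear ATFS-1
    hill_upr_K: float = 0.35
    hill_upr_n: float = 3.0
    # -- DAF-16 / SKN-1 ------------------------------------------------------
    #: basal (constitutive) DAF-16/SKN-1 activity tone
    tf_basal: float = 0.25
    #: maximal ROS-driven activation of DAF-16/SKN-1
    tf_max: float = 0.8
    #: half-activation ROS level (nM, combined sox+h2o2) and Hill exponent
    K_tf: float = 120.0
    n_tf: float = 2.0
    #: relaxation time of TF activities toward their targets (min)
    tau_tf: float = 300.0
    #: expression scales modified by genetic ablation (1 = wild type)
    daf16_scale: float = 1.0
    skn1_scale: float = 1.0
    # -- antioxidant / chaperone output --------------------------------------
    a_upr: float = 0.25
    a_daf: float = 0.5
    a_skn: float = 0.5
    c_upr: float = 0.5
    # -- mitochondrial population dynamics -----------------------------------
    #: baseline biogenesis rate (events/min at empty capacity)
    k_biog: float = 0.024
    #: biogenesis boost per unit mean DAF-16/SKN-1 activity
    b_tf: float = 2.0
    #: biogenesis sensitivity to sirtuin activity (NAD+- and PT-dependent)
    b_nad: float = 0.5
    #: soft carrying capacity for the mitochondrial population (count)
    mito_cap: int = 80
    #: baseline mitophagy hazard (1/min)
    k_mitophagy: float = 1.5e-4
    #: per-stress-state mitophagy multipliers (S0..S3), non-decreasing
    state_mult: tuple[float, float, float, float] = (1.0, 1.5, 3.0, 12.0)
    #: DAF-16 boost of mitophagy
    d_daf: float = 1.0
    #: optional transient UPRmt suppression of mitophagy (TIMM-23/PINK-1), off by default
    upr_phagy_inhibit: float = 0.0
    # -- compromised/death state machine -------------------------------------
    #: death hazard scale in the compromised state (1/min)
    k_death: float = 3.2e-5
    #: time scale of death-hazard escalation while compromised (min)
    tau_d: float = 8000.0
    #: defective fraction below which a compromised cell recovers (hysteresis)
    recover_frac: float = 0.60
    #: triangular(a, mode, b) law for the per-cell compromise threshold
    compromise_tri: tuple[float, float, float] = (0.60, 0.625, 0.75)
    #: stress states counted as "defective" for the compromise trigger
    defective_states: tuple[int, ...] = (3,)

    def validate(self) -> None:
        for name in (
            "k_sod", "k_spont_sod", "k_cat", "k_nad_syn", "k_nad_decay",
            "c_stress", "d_ref", "k_atp_use", "F_half", "k_import", "tf_max",
            "K_tf", "tau_tf", "tf_basal", "a_upr", "a_daf", "a_skn", "c_upr", "k_biog",
            "b_tf", "b_nad", "k_mitophagy", "d_daf", "k_death", "tau_d",
            "daf16_scale", "skn1_scale",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"cell.{name} must be >= 0")
        if len(self.state_mult) != 4:
            raise ConfigError("cell.state_mult must have one multiplier per stress state")
        if any(m < 0 for m in self.state_mult):
            raise ConfigError("cell.state_mult entries must be >= 0")
        if any(b > a for a, b in zip(self.state_mult[1:], self.state_mult[:-1])):
            raise ConfigError("cell.state_mult must be non-decreasing from S0 to S3")
        a, c, b = self.compromise_tri
        if not (a <= c <= b):
            raise ConfigError("cell.compromise_tri must satisfy a <= mode <= b")
        if self.mito_cap < 1:
            raise ConfigError("cell.mito_cap must be >= 1")
        if not set(self.defective_states) <= {0, 1, 2, 3}:
            raise ConfigError("cell.defective_states must be stress-state indices 0..3")


@dataclass
class DrugParams:
    """Pharmacodynamic constants mapping drug levels onto model rates."""

    #: rapamycin: maximal mitophagy induction and EC50 (nM)
    E_r: float = 1.5
    EC50_r: float = 15.0
    #: bafilomycin mitophagy IC50 (nM)
    IC50_b: float = 10.0
    #: paraquat redox-cycling superoxide add-on (nM/min per uM, per organelle)
    k_pq: float = 6.0e-4
    #: pterostilbene EC50 (uM) and effect ceilings
    pt_EC50: float = 25.0
    pt_daf_max: float = 0.27
    pt_skn_max: float = 0.27
    pt_sirt_max: float = 0.18

    def validate(self) -> None:
        for name in dataclasses.fields(self):
            if getattr(self, name.name) < 0:
                raise ConfigError(f"drugs.{name.name} must be >= 0")
        if self.EC50_r <= 0 or self.IC50_b <= 0 or self.pt_EC50 <= 0:
            raise ConfigError("drugs half-max concentrations must be > 0")


@dataclass
class PerturbationScheme:
    """A pharmacological dosing schedule.

    ``dose`` is in nM for rapamycin/bafilomycin and uM for paraquat and
    pterostilbene, matching the units the presets are quoted in.  The level
    resets to ``dose`` at every refresh boundary and, if ``decay_halflife``
    is set, decays first order in between; the default (no decay) is a
    constant-level exposure.
    """

    agent: str
    dose: float
    refresh_every: float = 2500.0
    t_start: float = 0.0
    t_end: float = math.inf
    decay_halflife: float | None = None

    def validate(self) -> None:
        if self.agent not in AGENTS:
            raise ConfigError(f"perturbations.agent must be one of {AGENTS}, got {self.agent!r}")
        if self.dose < 0:
            raise ConfigError("perturbations.dose must be >= 0")
        if self.refresh_every <= 0:
            raise ConfigError("perturbations.refresh_every must be > 0")
        if not self.t_start < self.t_end:
            raise ConfigError("perturbations.t_start must be < t_end")
        if self.decay_halflife is not None and self.decay_halflife <= 0:
            raise ConfigError("perturbations.decay_halflife must be > 0 or null")


@dataclass
class AblationScheme:
    """A fractional genetic ablation (RNAi-style expression knockdown)."""

    gene: str
    fraction: float

    def validate(self) -> None:
        if self.gene not in GENES:
            raise ConfigError(f"ablations.gene must be one of {GENES}, got {self.gene!r}")
        if not 0 <= self.fraction <= 1:
            raise ConfigError("ablations.fraction must lie in [0, 1]")


@dataclass
class SimulationConfig:
    """Full description of one virtual experiment."""

    t_end: float = 30_000.0
    dt: float = 1.0
    n_cells: int = 65
    n_mito_init: int = 50
    n_record: int = 500
    seed: int = 0
    #: informational only: the simulated environment is isothermal at 20 degC
    temperature_C: float = 20.0
    mito: MitoRates = field(default_factory=MitoRates)
    cell: CellRates = field(default_factory=CellRates)
    drugs: DrugParams = field(default_factory=DrugParams)
    perturbations: list[PerturbationScheme] = field(default_factory=list)
    ablations: list[AblationScheme] = field(default_factory=list)

    def validate(self) -> "SimulationConfig":
        if self.t_end <= 0:
            raise ConfigError("t_end must be > 0")
        if self.dt <= 0:
            raise ConfigError("dt must be > 0")
        if self.n_record < 2:
            raise ConfigError("n_record must be >= 2")
        if self.n_cells < 1:
            raise ConfigError("n_cells must be >= 1")
        if self.n_mito_init < 1:
            raise ConfigError("n_mito_init must be >= 1")
        if self.dt > self.t_end / self.n_record:
            raise ConfigError("dt must be <= t_end / n_record (dt too large for the recording grid)")
        self.mito.validate()
        self.cell.validate()
        self.drugs.validate()
        for p in self.perturbations:
            p.validate()
        for a in self.ablations:
            a.validate()
        return self

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        for p in d["perturbations"]:
            if p["t_end"] == math.inf:
                p["t_end"] = "inf"
        return d

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "SimulationConfig":
        data = dict(data or {})
        kwargs: dict[str, Any] = {}
        for name in ("t_end", "dt", "n_cells", "n_mito_init", "n_record", "seed", "temperature_C"):
            if name in data:
                kwargs[name] = data.pop(name)
        kwargs["mito"] = _build(MitoRates, data.pop("mitochondrion", data.pop("mito", {})))
        kwargs["cell"] = _build(CellRates, data.pop("cell", {}))
        kwargs["drugs"] = _build(DrugParams, data.pop("drugs", {}))
        perts = []
        for p in data.pop("perturbations", []) or []:
            p = dict(p)
            if p.get("t_end") in ("inf", ".inf", None):
                p["t_end"] = math.inf
            perts.append(PerturbationScheme(**p))
        kwargs["perturbations"] = perts
        kwargs["ablations"] = [AblationScheme(**dict(a)) for a in data.pop("ablations", []) or []]
        if data:
            import warnings

            warnings.warn(f"unknown configuration keys ignored: {sorted(data)}", stacklevel=2)
        return cls(**kwargs).validate()

    def config_hash(self) -> str:
        """Deterministic hash over the semantic content of the configuration."""
        payload = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def copy(self) -> "SimulationConfig":
        return SimulationConfig.from_dict(self.to_dict())


def _build(cls, data):
    if isinstance(data, cls):
        return data
    data = dict(data or {})
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        import warnings

        warnings.warn(f"unknown {cls.__name__} keys ignored: {sorted(unknown)}", stacklevel=3)
        for k in unknown:
            data.pop(k)
    for f in dataclasses.fields(cls):
        if f.name in data and isinstance(f.default, tuple):
            data[f.name] = tuple(data[f.name])
    return cls(**data)


# -- dotted-name parameter access (used by sensitivity and ablations) ---------

_BLOCKS = {"mitochondrion": "mito", "cell": "cell", "drugs": "drugs"}


def iter_parameters(config: SimulationConfig) -> Iterator[str]:
    """Yield dotted names of every scalar rate parameter in the configuration."""
    for public, attr in _BLOCKS.items():
        block = getattr(config, attr)
        for f in dataclasses.fields(block):
            value = getattr(block, f.name)
            if isinstance(value, (int, float)) and not isinstance(value, bool):
                yield f"{public}.{f.name}"
            elif isinstance(value, tuple) and all(isinstance(v, (int, float)) for v in value):
                for i in range(len(value)):
                    yield f"{public}.{f.name}[{i}]"


def _resolve(config: SimulationConfig, name: str):
    try:
        block_name, field_name = name.split(".", 1)
        block = getattr(config, _BLOCKS[block_name])
    except (ValueError, KeyError) as exc:
        raise KeyError(f"unknown parameter {name!r}") from exc
    index = None
    if field_name.endswith("]"):
        field_name, _, idx = field_name[:-1].partition("[")
        index = int(idx)
    if not hasattr(block, field_name):
        raise KeyError(f"unknown parameter {name!r}")
    return block, field_name, index


def get_parameter(config: SimulationConfig, name: str) -> float:
    block, field_name, index = _resolve(config, name)
    value = getattr(block, field_name)
    return value[index] if index is not None else value


def set_parameter(config: SimulationConfig, name: str, value: float) -> None:
    block, field_name, index = _resolve(config, name)
    if index is not None:
        current = list(getattr(block, field_name))
        current[index] = value
        setattr(block, field_name, tuple(current))
    else:
        setattr(block, field_name, type(getattr(block, field_name))(value))
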