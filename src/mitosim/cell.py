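"""Cell-level dynamics: ROS pools, NAD+/ATP bioenergetics, the ATFS-1/UPRmt
axis, DAF-16 and SKN-1 activities, mitochondrial population management
(biogenesis, selective mitophagy), and the compromised/death state machine.

This module is the scalar, per-agent reference implementation of the cell
update; :mod:`mitosim.engine` advances whole populations with the same
update rules vectorized over arrays.  The scalar path is the readable
contract (and is what the unit tests probe agent by agent); the engine is
the path used for full virtual experiments.

A cell is compromised once the fraction of severely damaged (S3)
mitochondria exceeds its personal threshold, drawn once at creation from a
triangular(0.60, 0.625, 0.75) law; a compromised cell recovers if the
fraction falls back below 0.60 (hysteresis) and otherwise accrues an
escalating death hazard.  Death is absorbing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._random import triangular_ppf
from .mito import (
    MitoEnvironment,
    MitoState,
    classify_stress_state,
    oxphos_defect_fraction,
    replicate_mtdna,
    step_mito,
)
from .params import CellRates, MitoRates

__all__ = [
    "CellState",
    "CellEnvironment",
    "step_cell",
    "mitophagy_hazard",
    "biogenesis_event",
    "sample_compromise_threshold",
    "check_life_transition",
]

LIFE_STATES = ("healthy", "compromised", "dead")


def _relax(x: float, inflow: float, rate: float, dt: float) -> float:
    """Exact update of dx/dt = inflow - rate*x; plain accumulation at rate 0."""
    if rate <= 0.0:
        return x + inflow * dt
    ss = inflow / rate
    return ss + (x - ss) * math.exp(-rate * dt)



@dataclass
class CellEnvironment:
    """Perturbation environment seen by one cell during one step."""

    phagy_mult: float = 1.0
    pq_boost: float = 0.0
    pt_daf_drive: float = 0.0
    pt_skn_drive: float = 0.0
    sirtuin_scale: float = 1.0


@dataclass
class CellState:
    """State of one post-mitotic cell agent and its mitochondrial population."""

    id: int = 0
    sox: float = 0.0
    h2o2: float = 0.0
    nad: float = 1.0
    atp: float = 2.5
    atfs1_nuc: float = 0.0
    upr: float = 0.0
    daf16: float = 0.0
    skn1: float = 0.0
    antiox: float = 1.0
    chap: float = 1.0
    mitos: list[MitoState] = field(default_factory=list)
    life: str = "healthy"
    threshold_c: float = 0.65
    t_compromised: float = 0.0
    #: stable per-cell constitution factor on antioxidant capacity
    constitution: float = 1.0

    @property
    def ros(self) -> float:
        """Combined superoxide + peroxide (nM), the signalling/threshold pool."""
        return self.sox + self.h2o2

    def defective_fraction(self, rates: CellRates | None = None) -> float:
        rates = rates or CellRates()
        if not self.mitos:
            return 0.0
        bad = sum(1 for m in self.mitos if m.state in rates.defective_states)
        return bad / len(self.mitos)

    def mtdna_pools(self) -> tuple[int, int]:
        return sum(m.n_wt for m in self.mitos), sum(m.n_mut for m in self.mitos)


def sample_compromise_threshold(
    rng: np.random.Generator, tri: tuple[float, float, float] = (0.60, 0.625, 0.75)
) -> float:
    """Draw a cell's compromise threshold from the triangular(0.60, 0.625, 0.75) law."""
    a, c, b = tri
    return float(triangular_ppf(rng.random(), a, c, b))


def mitophagy_hazard(
    mito: MitoState,
    cell: CellState,
    env: CellEnvironment | None = None,
    rates: CellRates | None = None,
) -> float:
    """Per-minute removal hazard of one organelle under selective mitophagy.

    hazard = k_mitophagy * state_mult[state] * drug_multiplier * (1 + d_daf*daf16),
    optionally damped by UPRmt (off by default) and scaled by the cell's
    ATP-dependent enzyme-renewal capacity (autophagy consumes energy, so
    the achievable flux collapses with the energy state).  The state
    multipliers are non-decreasing from S0 to S3: quality control
    preferentially digests damaged organelles.
    """
    env = env or CellEnvironment()
    rates = rates or CellRates()
    enz = (cell.atp**rates.n_enz / (rates.K_enz**rates.n_enz + cell.atp**rates.n_enz)) / (
        rates.atp_ref**rates.n_enz / (rates.K_enz**rates.n_enz + rates.atp_ref**rates.n_enz)
    )
    return (
        rates.k_mitophagy
        * rates.state_mult[mito.state]
        * env.phagy_mult
        * (1.0 + rates.d_daf * cell.daf16)
        * (1.0 - rates.upr_phagy_inhibit * cell.upr)
        * enz
    )


def biogenesis_event(
    cell: CellState,
    dt: float,
    rng: np.random.Generator,
    rates: CellRates | None = None,
    mito_rates: MitoRates | None = None,
    env: CellEnvironment | None = None,
) -> CellState:
    """Possibly append one newly synthesized mitochondrion.

    The event rate k_biog*(1 - count/mito_cap)+ * boost vanishes at the soft
    carrying capacity and is raised by DAF-16/SKN-1 activity and sirtuin
    (NAD+-dependent) signalling.  A new organelle starts with OXPHOS capacity
    near 1 and an mtDNA complement sampled from the cell-wide pool
    proportions via the replication kernel.
    """
    if cell.life == "dead":
        raise ValueError("cannot run biogenesis in a dead cell")
    rates = rates or CellRates()
    mito_rates = mito_rates or MitoRates()
    env = env or CellEnvironment()
    count = len(cell.mitos)
    sirt = env.sirtuin_scale * cell.nad * (1.0 + rates.K_sirt) / (rates.K_sirt + cell.nad)
    boost = max(0.0, 1.0 + rates.b_tf * 0.5 * (cell.daf16 + cell.skn1) + rates.b_nad * (sirt - 1.0))
    enz = (cell.atp**rates.n_enz / (rates.K_enz**rates.n_enz + cell.atp**rates.n_enz)) / (
        rates.atp_ref**rates.n_enz / (rates.K_enz**rates.n_enz + rates.atp_ref**rates.n_enz)
    )
    lam = rates.k_biog * max(0.0, 1.0 - count / rates.mito_cap) * boost * enz
    if count < 2 * rates.mito_cap and rng.random() < 1.0 - math.exp(-lam * dt):
        pool_wt, pool_mut = cell.mtdna_pools()
        if pool_wt + pool_mut == 0:
            n_wt, n_mut = mito_rates.n0_copies, 0
        else:
            grown_wt, grown_mut = replicate_mtdna(
                pool_wt, pool_mut, mito_rates.n0_copies, 1.0, rng
            )
            n_wt, n_mut = grown_wt - pool_wt, grown_mut - pool_mut
        new_id = max((m.id for m in cell.mitos), default=-1) + 1
        cell.mitos.append(
            MitoState(id=new_id, F=0.93 + 0.05 * rng.random(), n_wt=n_wt, n_mut=n_mut)
        )
    return cell


def check_life_transition(
    cell: CellState,
    dt: float,
    rng: np.random.Generator,
    rates: CellRates | None = None,
) -> CellState:
    """Advance the healthy/compromised/dead machine by one check.

    healthy -> compromised when the defective-organelle fraction exceeds the
    cell's triangular threshold; compromised -> healthy when it falls below
    the recovery bound (0.60, the distribution minimum), giving hysteresis;
    a compromised cell dies with hazard k_death*(1 + t_compromised/tau_d).
    """
    if cell.life == "dead":
        raise ValueError("cannot step a dead cell")
    rates = rates or CellRates()
    frac = cell.defective_fraction(rates)
    if cell.life == "healthy" and frac > cell.threshold_c:
        cell.life = "compromised"
        cell.t_compromised = 0.0
        return cell
    if cell.life == "compromised":
        if frac < rates.recover_frac:
            cell.life = "healthy"
            cell.t_compromised = 0.0
            return cell
        hazard = rates.k_death * (1.0 + cell.t_compromised / rates.tau_d)
        if rng.random() < 1.0 - math.exp(-hazard * dt):
            cell.life = "dead"
        else:
            cell.t_compromised += dt
    return cell


def step_cell(
    cell: CellState,
    dt: float,
    env: CellEnvironment | None = None,
    rng: np.random.Generator | None = None,
    mito_rates: MitoRates | None = None,
    cell_rates: CellRates | None = None,
) -> CellState:
    """Advance one cell and its mitochondria by ``dt`` minutes (in place).

    Update order: (1) pool per-organelle superoxide production into the cell
    superoxide pool, (2) dismutation and peroxide clearance, (3) nuclear
    ATFS-1 from failed mitochondrial import, (4) UPRmt activation, (5)
    DAF-16/SKN-1 relaxation toward their ROS- and drug-driven targets, (6)
    antioxidant and chaperone outputs, (7) NAD+, (8) ATP, (9) organelle
    sub-steps, (10) mitophagy and biogenesis draws, (11) life-state check.
    """
    if cell.life == "dead":
        raise ValueError("cannot step a dead cell")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    env = env or CellEnvironment()
    rng = rng if rng is not None else np.random.default_rng()
    mr = mito_rates or MitoRates()
    cr = cell_rates or CellRates()

    g_nad = cell.nad * (1.0 + cr.K_nad) / (cr.K_nad + cell.nad)
    enz = (cell.atp**cr.n_enz / (cr.K_enz**cr.n_enz + cell.atp**cr.n_enz)) / (
        cr.atp_ref**cr.n_enz / (cr.K_enz**cr.n_enz + cr.atp_ref**cr.n_enz)
    )
    sirt = env.sirtuin_scale * cell.nad * (1.0 + cr.K_sirt) / (cr.K_sirt + cell.nad)
    ros_dmg = cell.h2o2 + mr.w_sox_dmg * cell.sox

    # (1)-(2) ROS pools
    prod = 0.0
    for m in cell.mitos:
        flux = g_nad * (mr.flux_floor + (1.0 - mr.flux_floor) * m.F)
        d = oxphos_defect_fraction(m, mr.w_h)
        prod += mr.k_sox_base * flux * (1.0 + mr.leak_gain * d) + env.pq_boost
    antiox_factor = (1.0 + cr.a_upr * cell.upr + cr.a_daf * cell.daf16 + cr.a_skn * cell.skn1) * cell.constitution
    enz_ax = cr.e_antiox + (1.0 - cr.e_antiox) * enz
    A_sod = cr.k_sod * antiox_factor * enz_ax + cr.k_spont_sod
    A_cat = cr.k_cat * antiox_factor * enz_ax + cr.k_spont_cat
    cell.sox = _relax(cell.sox, prod, A_sod, dt)
    cell.h2o2 = _relax(cell.h2o2, A_sod * cell.sox, A_cat, dt)

    # (3)-(4) ATFS-1 import competition and UPRmt
    mean_F = sum(m.F for m in cell.mitos) / len(cell.mitos) if cell.mitos else 0.0
    cell.atfs1_nuc = min(1.0, max(0.0, 1.0 - cr.k_import * mean_F))
    cell.upr = cell.atfs1_nuc**cr.hill_upr_n / (cr.hill_upr_K**cr.hill_upr_n + cell.atfs1_nuc**cr.hill_upr_n)

    # (5) DAF-16 / SKN-1
    ros_sig = cell.ros
    tf_base = cr.tf_basal + cr.tf_max * ros_sig**cr.n_tf / (cr.K_tf**cr.n_tf + ros_sig**cr.n_tf)
    relax = 1.0 - math.exp(-dt / cr.tau_tf)
    cell.daf16 += (min(1.0, (tf_base + env.pt_daf_drive) * cr.daf16_scale) - cell.daf16) * relax
    cell.skn1 += (min(1.0, (tf_base + env.pt_skn_drive) * cr.skn1_scale) - cell.skn1) * relax

    # (6) effector outputs
    cell.antiox = antiox_factor * enz
    cell.chap = enz * (1.0 + cr.c_upr * cell.upr)

    # (7) NAD+
    if cell.mitos:
        d_mean = sum(oxphos_defect_fraction(m, mr.w_h) for m in cell.mitos) / len(cell.mitos)
    else:
        d_mean = 1.0
    decay = cr.k_nad_decay * (1.0 + cr.c_stress * max(0.0, d_mean - cr.d_ref))
    cell.nad = _relax(cell.nad, cr.k_nad_syn * env.sirtuin_scale, decay, dt)

    # (8) ATP
    sum_F = sum(m.F for m in cell.mitos)
    prod_atp = mr.k_atp * g_nad * sum_F / (sum_F + cr.F_half)
    cell.atp = _relax(cell.atp, prod_atp, cr.k_atp_use, dt)

    # (9) organelle sub-steps and stress states
    menv = MitoEnvironment(ros_dmg=ros_dmg, chaperones=cell.chap, upr=cell.upr, nad=cell.nad)
    for i, m in enumerate(cell.mitos):
        m = step_mito(m, menv, dt, rng, mr)
        m.state = classify_stress_state(m, rng, dt, mr)
        cell.mitos[i] = m

    # (10) mitophagy then biogenesis
    survivors = []
    for m in cell.mitos:
        hz = mitophagy_hazard(m, cell, env, cr)
        if rng.random() >= 1.0 - math.exp(-hz * dt):
            survivors.append(m)
    if not survivors and cell.mitos:
        survivors = [max(cell.mitos, key=lambda m: m.F)]
    cell.mitos = survivors
    biogenesis_event(cell, dt, rng, cr, mr, env)

    # (11) life state
    return check_life_transition(cell, dt, rng, cr)
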