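"""Single-mitochondrion dynamics: oxidative metabolism, proteostasis,
mtDNA damage/replication, and the agent-based stress-state machine.

One organelle carries a functional OXPHOS capacity fraction ``F``, a damaged
matrix-protein fraction ``Pdam``, and its own mtDNA pool (``n_wt`` intact
copies, ``n_mut`` deletion-bearing copies).  The OXPHOS defect fraction

    d = 1 - F * (1 - w_h * h),    h = n_mut / (n_wt + n_mut)

combines lost respiratory capacity with heteroplasmy and drives both the
electron-leak amplification of superoxide production (the free-radical
feedback loop of the MFRTA) and the four stress-state bands used for
selective mitophagy:

    S0 healthy            d < 0.30
    S1 slightly stressed  0.30 <= d < 0.60
    S2 significantly stressed  0.60 <= d < 0.90
    S3 severely damaged   d >= 0.90

The upper two band edges anchor to the 60-90% defect window reported for
deleterious senescence states; the state label moves at most one band per
update, so recovery through the bands is as possible as progression.

The functions here are numpy kernels usable on scalars or arrays; the
population engine applies them to whole (cell x organelle) arrays, while the
scalar :class:`MitoState` wrappers expose the per-organelle contracts.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ._random import binomial_counts, poisson_counts
from .params import MitoRates

__all__ = [
    "STRESS_LABELS",
    "STRESS_BAND_EDGES",
    "MitoState",
    "MitoEnvironment",
    "oxphos_defect_fraction",
    "superoxide_production",
    "classify_stress_state",
    "stress_transition_step",
    "replicate_mtdna",
    "mutant_allocation_probability",
    "step_mito",
    "defect_fraction_kernel",
    "superoxide_rate_kernel",
    "target_band_kernel",
]

STRESS_LABELS = ("S0_healthy", "S1_slightly_stressed", "S2_significantly_stressed", "S3_severely_damaged")
#: lower edges of bands S1..S3 on the OXPHOS defect fraction
STRESS_BAND_EDGES = (0.30, 0.60, 0.90)


@dataclass
class MitoState:
    """State of one mitochondrion agent."""

    id: int = 0
    F: float = 1.0
    Pdam: float = 0.0
    n_wt: int = 10
    n_mut: int = 0
    state: int = 0  # index into STRESS_LABELS
    age: float = 0.0

    def validate(self) -> None:
        if not 0.0 <= self.F <= 1.0:
            raise ValueError("F must lie in [0, 1]")
        if not 0.0 <= self.Pdam <= 1.0:
            raise ValueError("Pdam must lie in [0, 1]")
        if self.n_wt < 0 or self.n_mut < 0:
            raise ValueError("mtDNA counts must be >= 0")
        if self.n_wt + self.n_mut < 1:
            raise ValueError("a mitochondrion must hold at least one mtDNA copy")
        if self.state not in range(4):
            raise ValueError("state must be one of 0..3")

    @property
    def heteroplasmy(self) -> float:
        return self.n_mut / (self.n_wt + self.n_mut)

    @property
    def state_label(self) -> str:
        return STRESS_LABELS[self.state]


@dataclass
class MitoEnvironment:
    """Cell-side quantities a mitochondrion sees during one step.

    ``ros_dmg`` is the damaging (peroxide-weighted) ROS exposure in nM;
    ``chaperones`` the cell chaperone pool (1 = unstressed baseline);
    ``upr`` the UPRmt transcriptional activity in [0, 1]; ``nad`` the
    relative NAD+ level.
    """

    ros_dmg: float = 0.0
    chaperones: float = 1.0
    upr: float = 0.0
    nad: float = 1.0


# ---------------------------------------------------------------------------
# numpy kernels (scalar- and array-compatible)
# ---------------------------------------------------------------------------

def defect_fraction_kernel(F, n_wt, n_mut, w_h: float):
    total = np.asarray(n_wt, dtype=np.float64) + np.asarray(n_mut, dtype=np.float64)
    h = np.divide(n_mut, total, out=np.zeros_like(total), where=total > 0)
    return np.clip(1.0 - np.asarray(F) * (1.0 - w_h * h), 0.0, 1.0)


def superoxide_rate_kernel(flux, defect, k_sox: float, leak_gain: float, pq_boost):
    return k_sox * np.asarray(flux) * (1.0 + leak_gain * np.asarray(defect)) + pq_boost


def target_band_kernel(defect):
    """Stress band (0..3) the defect fraction points at."""
    edges = np.asarray(STRESS_BAND_EDGES)
    return np.searchsorted(edges, np.asarray(defect), side="right").astype(np.int8)


def mutant_allocation_probability(n_wt, n_mut, adv_mut: float):
    """Probability that a newly replicated copy is a deletion-bearing copy."""
    n_wt = np.asarray(n_wt, dtype=np.float64)
    n_mut = np.asarray(n_mut, dtype=np.float64)
    denom = adv_mut * n_mut + n_wt
    return np.divide(adv_mut * n_mut, denom, out=np.zeros_like(denom), where=denom > 0)


def _oxphos_relaxation(F, ros_dmg, repair_scale, rates: MitoRates, dt: float):
    """Exponential-integrator update of dF/dt = a(1-F) - b F."""
    a = rates.k_rep_F * repair_scale
    b = rates.k_dmg_F * np.asarray(ros_dmg)
    total = a + b
    with np.errstate(invalid="ignore", divide="ignore"):
        target = np.where(total > 0, a / np.where(total > 0, total, 1.0), F)
    return np.clip(target + (F - target) * np.exp(-total * dt), 0.0, 1.0)


# ---------------------------------------------------------------------------
# per-organelle operations
# ---------------------------------------------------------------------------

def oxphos_defect_fraction(mito: MitoState, w_h: float = 0.5) -> float:
    """OXPHOS defect fraction d = 1 - F*(1 - w_h*h) in [0, 1]."""
    mito.validate()
    return float(defect_fraction_kernel(mito.F, mito.n_wt, mito.n_mut, w_h))


def superoxide_production(
    mito: MitoState,
    respiration_flux: float,
    pq_boost: float = 0.0,
    rates: MitoRates | None = None,
) -> float:
    """Superoxide production rate (nM/min) of one organelle.

    Production scales with respiration flux and is amplified by the OXPHOS
    defect fraction through the electron-leak gain; paraquat redox cycling
    adds ``pq_boost`` on top.  Strictly increasing in the defect fraction.
    """
    if respiration_flux < 0:
        raise ValueError("respiration_flux must be >= 0")
    if pq_boost < 0:
        raise ValueError("pq_boost must be >= 0")
    rates = rates or MitoRates()
    d = oxphos_defect_fraction(mito, rates.w_h)
    return float(superoxide_rate_kernel(respiration_flux, d, rates.k_sox_base, rates.leak_gain, pq_boost))


def stress_transition_step(state, p_up, p_down, u):
    """One step of the 4-state stress chain: move at most one band.

    ``p_up``/``p_down`` are per-step transition probabilities (p_up + p_down
    must not exceed 1); a single uniform decides the move, with the upward
    move on the lower tail and the downward move on the upper tail so both
    probabilities are realized exactly.
    """
    state = np.asarray(state, dtype=np.int8)
    u = np.asarray(u)
    up = (u < p_up) & (state < 3)
    down = (u > 1.0 - p_down) & (state > 0) & ~up
    return (state + up.astype(np.int8) - down.astype(np.int8)).astype(np.int8)


def classify_stress_state(
    mito: MitoState,
    rng: np.random.Generator,
    dt: float = 1.0,
    rates: MitoRates | None = None,
) -> int:
    """Advance the stress-state label one (stochastic) update.

    The defect fraction selects a target band; the label steps one band
    toward it with probability 1-exp(-r*dt) per call (progression rate
    ``r_up``, recovery rate ``r_down``), so both decline and recovery of an
    organelle's phenotype are possible but never jump bands.
    """
    rates = rates or MitoRates()
    d = oxphos_defect_fraction(mito, rates.w_h)
    target = int(target_band_kernel(d))
    p_up = (1.0 - np.exp(-rates.r_up * dt)) if target > mito.state else 0.0
    p_down = (1.0 - np.exp(-rates.r_down * dt)) if target < mito.state else 0.0
    new = stress_transition_step(mito.state, p_up, p_down, rng.random())
    return int(new)


def replicate_mtdna(
    n_wt: int,
    n_mut: int,
    n_new: int,
    adv_mut: float = 1.1,
    rng: np.random.Generator | None = None,
) -> tuple[int, int]:
    """Replicate ``n_new`` mtDNA copies with a replicative advantage for
    deletion-bearing templates (clonal expansion).

    Each new copy is mutant with probability
    adv_mut*n_mut / (adv_mut*n_mut + n_wt); totals grow by exactly ``n_new``.
    """
    if n_wt + n_mut == 0:
        raise ValueError("cannot replicate from an empty mtDNA pool")
    if n_new < 0:
        raise ValueError("n_new must be >= 0")
    if n_new == 0:
        return n_wt, n_mut
    rng = rng if rng is not None else np.random.default_rng()
    p = float(mutant_allocation_probability(n_wt, n_mut, adv_mut))
    new_mut = int(binomial_counts(np.asarray(rng.random()), n_new, p))
    return n_wt + (n_new - new_mut), n_mut + new_mut


def step_mito(
    mito: MitoState,
    env: MitoEnvironment,
    dt: float,
    rng: np.random.Generator,
    rates: MitoRates | None = None,
) -> MitoState:
    """Advance one mitochondrion by ``dt`` minutes.

    Deterministic sub-step: OXPHOS capacity relaxes under ROS-driven damage
    and chaperone-dependent repair, where the repair/synthesis term requires
    intact mtDNA templates (scales with 1-h) and is damped by UPRmt-driven
    suppression of new OXPHOS subunit expression; the damaged-protein
    fraction mirrors it.  Stochastic sub-step: Poisson mtDNA damage hits
    (mean k_dmg_dna * ROS * n_wt * dt) convert intact copies to deletion
    copies, copy turnover removes copies, and replication refills the pool
    toward its homeostatic size with a clonal-expansion bias ``adv_mut``.
    With the same rng state and inputs the successor state is bit-identical.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    mito.validate()
    rates = rates or MitoRates()

    h = mito.heteroplasmy
    syn_scale = max(0.0, 1.0 - rates.s_upr * env.upr)
    repair = env.chaperones * syn_scale * (1.0 - h) ** rates.rep_h_exp
    F = float(_oxphos_relaxation(mito.F, env.ros_dmg, repair, rates, dt))

    a = rates.k_dmg_P * env.ros_dmg
    b = rates.k_rep_P * env.chaperones
    total = a + b
    if total > 0:
        target = a / total
        Pdam = float(np.clip(target + (mito.Pdam - target) * np.exp(-total * dt), 0.0, 1.0))
    else:
        Pdam = mito.Pdam

    n_wt, n_mut = mito.n_wt, mito.n_mut
    u = rng.random(4)
    hits = int(poisson_counts(u[0], rates.k_dmg_dna * env.ros_dmg * n_wt * dt))
    hits = min(hits, n_wt)
    n_wt -= hits
    n_mut += hits
    # copy turnover, guarded so the organelle never loses its last copy
    deg_w = min(int(poisson_counts(u[1], rates.k_deg_dna * n_wt * dt)), n_wt)
    deg_m = min(int(poisson_counts(u[2], rates.k_deg_dna * n_mut * dt)), n_mut)
    if n_wt + n_mut - deg_w - deg_m >= 1:
        n_wt -= deg_w
        n_mut -= deg_m
    deficit = max(0, rates.n0_copies - (n_wt + n_mut))
    n_new = int(poisson_counts(u[3], rates.k_repl * deficit * dt))
    if n_new:
        n_wt, n_mut = replicate_mtdna(n_wt, n_mut, n_new, rates.adv_mut, rng)

    return replace(mito, F=F, Pdam=Pdam, n_wt=n_wt, n_mut=n_mut, age=mito.age + dt)
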