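"""Hierarchical population engine.

Advances a population of post-mitotic cell agents, each holding its own
population of mitochondrion agents, over the simulation horizon with a fixed
time increment (default 1 min over 0..30 000 min).  The continuous parts
(ROS pools, NAD+, ATP, transcription-factor activities, OXPHOS capacity) are
integrated with exponential (exact linear-relaxation) sub-steps; the
discrete agent-based parts (mtDNA hits and turnover, stress-state moves,
mitophagy, biogenesis, compromise and death) fire per step from per-cell
uniform streams, so stepping cells in any order yields the same per-cell
draws and the whole population can be advanced as flat arrays.

Internally the state is a struct-of-arrays over (cell, organelle-slot);
removed organelles free their slot for later biogenesis.  Observables are
recorded on a fixed output grid (default 500 points).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._random import binomial_counts, triangular_ppf
from ._kernel import organelle_step
from .params import SimulationConfig
from .perturb import (
    apply_ablation,
    drug_level,
    mitophagy_modulation,
    paraquat_boost,
    pterostilbene_effects,
)

__all__ = ["run_simulation", "rng_streams", "triangular_sample", "TrajectorySet"]

#: uniform channels consumed per organelle slot per step
_NU = 7
_U_HITS, _U_DEGW, _U_DEGM, _U_REPL, _U_ALLOC, _U_STATE, _U_PHAGY = range(_NU)
#: channels of the extra per-cell row: biogenesis event, new-organelle F,
#: new-organelle mtDNA allocation, death
_C_BIOG, _C_BIOGF, _C_ALLOC, _C_DEATH = range(4)

LIFE_HEALTHY, LIFE_COMPROMISED, LIFE_DEAD = 0, 1, 2


def rng_streams(seed: int, n_cells: int) -> tuple[list[np.random.Generator], np.random.Generator]:
    """One independent, reproducible stream per cell plus one engine stream.

    Streams are spawned from a single seed sequence, so the per-cell draws do
    not depend on the order in which cells are stepped.
    """
    children = np.random.SeedSequence(seed).spawn(n_cells + 1)
    gens = [np.random.Generator(np.random.PCG64(ss)) for ss in children]
    return gens[:-1], gens[-1]


def triangular_sample(a: float, c: float, b: float, rng: np.random.Generator):
    """Inverse-CDF sample from the triangular(a, mode=c, b) law."""
    if not (a <= c <= b):
        raise ValueError("triangular parameters must satisfy a <= c <= b")
    return float(triangular_ppf(rng.random(), a, c, b))


class _BlockRNG:
    """Chunked per-cell uniform blocks of shape (n_cells, W+1, NU) per step."""

    def __init__(self, gens: list[np.random.Generator], width: int, chunk: int = 64):
        self._gens = gens
        self._shape = (chunk, width + 1, _NU)
        self._chunk = chunk
        self._buf = np.empty((len(gens), chunk, width + 1, _NU), dtype=np.float32)
        self._pos = chunk  # trigger refill on first use

    def next_step(self) -> np.ndarray:
        if self._pos >= self._chunk:
            for i, g in enumerate(self._gens):
                self._buf[i] = g.random(self._shape, dtype=np.float32)
            self._pos = 0
        block = self._buf[:, self._pos]
        self._pos += 1
        return block


@dataclass
class TrajectorySet:
    """Recorded per-cell observables on the fixed output grid.

    All per-cell series have shape (n_record, n_cells); ``state_frac`` has a
    trailing stress-state axis of length 4 and sums to 1 per cell per time.
    Tissue aggregates are means over cells alive at each time.
    """

    time: np.ndarray
    sox: np.ndarray
    h2o2: np.ndarray
    nad: np.ndarray
    atp: np.ndarray
    daf16: np.ndarray
    skn1: np.ndarray
    upr: np.ndarray
    atfs1: np.ndarray
    resp: np.ndarray
    count: np.ndarray
    n_wt: np.ndarray
    n_mut: np.ndarray
    cum_mitophagy: np.ndarray
    life: np.ndarray
    state_frac: np.ndarray
    threshold_c: np.ndarray
    seed: int = 0
    config_hash: str = ""
    config: SimulationConfig | None = field(default=None, repr=False)

    # -- derived views -------------------------------------------------------

    @property
    def n_cells(self) -> int:
        return self.life.shape[1]

    @property
    def ros(self) -> np.ndarray:
        """Combined superoxide + peroxide per cell (nM)."""
        return self.sox + self.h2o2

    @property
    def alive(self) -> np.ndarray:
        return self.life < LIFE_DEAD

    def tissue_mean(self, name: str) -> np.ndarray:
        """Mean of a per-cell series over cells alive at each grid time."""
        values = self.ros if name == "ros" else getattr(self, name)
        alive = self.alive
        n = alive.sum(axis=1)
        total = np.where(alive, values, 0.0).sum(axis=1)
        return np.divide(total, n, out=np.full(len(n), np.nan), where=n > 0)

    def life_counts(self) -> dict[str, np.ndarray]:
        return {
            "healthy": (self.life == LIFE_HEALTHY).sum(axis=1),
            "compromised": (self.life == LIFE_COMPROMISED).sum(axis=1),
            "dead": (self.life == LIFE_DEAD).sum(axis=1),
        }

    def heteroplasmy_percent_per_cell(self) -> np.ndarray:
        total = self.n_wt + self.n_mut
        return 100.0 * np.divide(self.n_mut, total, out=np.zeros_like(total, dtype=float), where=total > 0)

    def to_cells_dataframe(self):
        """Tidy per-cell table: one row per cell per grid time."""
        import pandas as pd

        T, C = self.life.shape
        idx_t = np.repeat(np.arange(T), C)
        idx_c = np.tile(np.arange(C), T)
        cols = {
            "time_min": self.time[idx_t],
            "cell": idx_c,
            "ros_nM": self.ros.ravel(),
            "sox_nM": self.sox.ravel(),
            "h2o2_nM": self.h2o2.ravel(),
            "nad_rel": self.nad.ravel(),
            "atp_mM": self.atp.ravel(),
            "mito_count": self.count.ravel(),
            "mtdna_wt": self.n_wt.ravel(),
            "mtdna_mut": self.n_mut.ravel(),
            "life_state": self.life.ravel(),
            "cum_mitophagy": self.cum_mitophagy.ravel(),
        }
        for s in range(4):
            cols[f"state_frac_s{s}"] = self.state_frac[:, :, s].ravel()
        return pd.DataFrame(cols)

    def to_tissue_dataframe(self):
        """Tissue-level aggregate table (means over alive cells + life counts)."""
        import pandas as pd

        counts = self.life_counts()
        data = {"time_min": self.time}
        for name in ("ros", "sox", "h2o2", "nad", "atp", "count", "resp"):
            data[f"mean_{name}"] = self.tissue_mean(name)
        het = self.heteroplasmy_percent_per_cell()
        alive = self.alive
        n = alive.sum(axis=1)
        data["mean_heteroplasmy_pct"] = np.divide(
            np.where(alive, het, 0.0).sum(axis=1), n, out=np.full(len(n), np.nan), where=n > 0
        )
        data.update({f"n_{k}": v for k, v in counts.items()})
        data["survival_fraction"] = 1.0 - counts["dead"] / self.n_cells
        return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _relax(x, inflow, rate, dt):
    """Exact update of dx/dt = inflow - rate*x; plain accumulation at rate 0."""
    rate = np.asarray(rate, dtype=np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        ss = np.where(rate > 0, inflow / np.where(rate > 0, rate, 1.0), 0.0)
    return np.where(rate > 0, ss + (x - ss) * np.exp(-rate * dt), x + inflow * dt)


def _drug_timelines(config: SimulationConfig, times: np.ndarray) -> dict[str, np.ndarray]:
    levels = {agent: np.zeros(len(times)) for agent in ("rapamycin", "bafilomycin", "paraquat", "pterostilbene")}
    for scheme in config.perturbations:
        levels[scheme.agent] = levels[scheme.agent] + drug_level(scheme, times)
    return levels


def run_simulation(config: SimulationConfig) -> TrajectorySet:
    """Run one virtual experiment and record it on the output grid.

    Identical seed and configuration produce a bit-identical TrajectorySet.
    """
    config.validate()
    working = config
    for scheme in config.ablations:
        working = apply_ablation(working, scheme)
    mr, cr, dr = working.mito, working.cell, working.drugs

    C = config.n_cells
    W = max(config.n_mito_init, cr.mito_cap)
    dt = float(config.dt)
    n_steps = int(round(config.t_end / dt))
    grid = np.linspace(0.0, config.t_end, config.n_record)

    cell_gens, _engine_gen = rng_streams(config.seed, C)

    # -- initial state -------------------------------------------------------
    F = np.zeros((C, W))
    Pd = np.zeros((C, W))
    Nw = np.zeros((C, W), dtype=np.int64)
    Nm = np.zeros((C, W), dtype=np.int64)
    S = np.zeros((C, W), dtype=np.int8)
    age = np.zeros((C, W))
    alive = np.zeros((C, W), dtype=bool)
    alive[:, : config.n_mito_init] = True
    Nw[:, : config.n_mito_init] = mr.n0_copies

    thr_c = np.empty(C)
    const = np.empty(C)
    a_tri, c_tri, b_tri = cr.compromise_tri
    for i, g in enumerate(cell_gens):
        thr_c[i] = triangular_ppf(g.random(), a_tri, c_tri, b_tri)
        # per-cell constitution: stable inter-individual variation in
        # constitutive antioxidant capacity
        const[i] = float(np.clip(1.0 + cr.sigma_const * g.standard_normal(), 0.5, 1.7))
        F[i, : config.n_mito_init] = 0.93 + 0.05 * g.random(config.n_mito_init)

    sox = np.zeros(C)
    h2o2 = np.zeros(C)
    nad = np.ones(C)
    daf16 = np.zeros(C)
    skn1 = np.zeros(C)
    upr = np.zeros(C)
    atfs1 = np.zeros(C)
    t_comp = np.zeros(C)
    life = np.zeros(C, dtype=np.int8)
    cum_phagy = np.zeros(C, dtype=np.int64)
    # start ATP at its unstressed steady state (reference level if the
    # consumption rate is zero, e.g. in frozen test configurations)
    sumF0 = (F * alive).sum(axis=1)
    g1 = 1.0  # g_nad(nad=1) is normalized to 1
    if cr.k_atp_use > 0:
        atp = mr.k_atp * g1 * sumF0 / (sumF0 + cr.F_half) / cr.k_atp_use
    else:
        atp = np.full(C, cr.atp_ref)

    # -- per-step drug effects ----------------------------------------------
    step_times = np.arange(n_steps) * dt
    levels = _drug_timelines(working, step_times)
    phagy_mult_t = np.array(
        [mitophagy_modulation(r, b, dr) for r, b in zip(levels["rapamycin"], levels["bafilomycin"])]
    )
    pq_boost_t = np.array([paraquat_boost(p, dr) for p in levels["paraquat"]])
    pt_fx = [pterostilbene_effects(p, dr) for p in levels["pterostilbene"]]
    pt_daf_t = np.array([f[0] for f in pt_fx])
    pt_skn_t = np.array([f[1] for f in pt_fx])
    sirt_drug_t = np.array([f[2] for f in pt_fx])

    # -- recording -----------------------------------------------------------
    T = config.n_record
    rec = {
        name: np.zeros((T, C))
        for name in (
            "sox", "h2o2", "nad", "atp", "daf16", "skn1", "upr", "atfs1",
            "resp", "count", "n_wt", "n_mut", "cum_mitophagy",
        )
    }
    rec_life = np.zeros((T, C), dtype=np.int8)
    rec_sf = np.zeros((T, C, 4))

    def snapshot(k: int) -> None:
        rec["sox"][k] = sox
        rec["h2o2"][k] = h2o2
        rec["nad"][k] = nad
        rec["atp"][k] = atp
        rec["daf16"][k] = daf16
        rec["skn1"][k] = skn1
        rec["upr"][k] = upr
        rec["atfs1"][k] = atfs1
        g_nad = nad * (1.0 + cr.K_nad) / (cr.K_nad + nad)
        rec["resp"][k] = (g_nad[:, None] * (mr.flux_floor + (1 - mr.flux_floor) * F) * alive).sum(axis=1)
        n = alive.sum(axis=1)
        rec["count"][k] = n
        rec["n_wt"][k] = (Nw * alive).sum(axis=1)
        rec["n_mut"][k] = (Nm * alive).sum(axis=1)
        rec["cum_mitophagy"][k] = cum_phagy
        rec_life[k] = life
        safe_n = np.maximum(n, 1)
        for s in range(4):
            rec_sf[k, :, s] = ((S == s) & alive).sum(axis=1) / safe_n

    snapshot(0)
    next_rec = 1

    brng = _BlockRNG(cell_gens, W)
    mult = np.asarray(cr.state_mult, dtype=np.float64)
    p_up = 1.0 - np.exp(-mr.r_up * dt)
    p_down = 1.0 - np.exp(-mr.r_down * dt)
    defective = np.zeros(4, dtype=np.bool_)
    defective[list(cr.defective_states)] = True

    # per-cell reduction buffers filled by the organelle kernel
    prod_cell = np.zeros(C)
    sumF = np.zeros(C)
    d_sum = np.zeros(C)
    n_pre = np.zeros(C, dtype=np.int64)
    n_post = np.zeros(C, dtype=np.int64)
    n_def = np.zeros(C, dtype=np.int64)
    removed = np.zeros(C, dtype=np.int64)

    for step in range(n_steps):
        block = brng.next_step()
        cell_alive = life < LIFE_DEAD

        # cell-level coefficients from the current state
        g_nad = nad * (1.0 + cr.K_nad) / (cr.K_nad + nad)
        enz = (atp**cr.n_enz / (cr.K_enz**cr.n_enz + atp**cr.n_enz)) / (
            cr.atp_ref**cr.n_enz / (cr.K_enz**cr.n_enz + cr.atp_ref**cr.n_enz)
        )
        sirt = sirt_drug_t[step] * nad * (1.0 + cr.K_sirt) / (cr.K_sirt + nad)
        antiox_factor = (1.0 + cr.a_upr * upr + cr.a_daf * daf16 + cr.a_skn * skn1) * const
        # antioxidant enzymes are long-lived: a persistent fraction e_antiox
        # of the capacity survives energetic collapse; the spontaneous terms
        # are the non-enzymatic floors
        enz_ax = cr.e_antiox + (1.0 - cr.e_antiox) * enz
        A_sod = cr.k_sod * antiox_factor * enz_ax + cr.k_spont_sod
        A_cat = cr.k_cat * antiox_factor * enz_ax + cr.k_spont_cat
        chap = enz * (1.0 + cr.c_upr * upr)
        ros_dmg = h2o2 + mr.w_sox_dmg * sox
        syn = np.clip(1.0 - mr.s_upr * upr, 0.0, None)
        # autophagy is ATP-dependent: enzyme-renewal capacity scales the
        # achievable mitophagy flux, so quality control falters in
        # energetically collapsing cells
        k_phagy_eff = (
            cr.k_mitophagy
            * phagy_mult_t[step]
            * (1.0 + cr.d_daf * daf16)
            * (1.0 - cr.upr_phagy_inhibit * upr)
            * enz
        )

        # -- organelle dynamics (numba kernel or numpy fallback) -------------
        organelle_step(
            F, Pd, Nw, Nm, S, age, alive, cell_alive, block[:, :W, :],
            ros_dmg, chap, syn, g_nad, k_phagy_eff, mult, defective,
            pq_boost_t[step], p_up, p_down, dt,
            mr.w_h, mr.flux_floor, mr.k_sox_base, mr.leak_gain,
            mr.k_rep_F, mr.k_dmg_F, mr.rep_h_exp,
            mr.k_rep_P, mr.k_dmg_P, mr.k_dmg_dna, mr.k_deg_dna, mr.k_repl,
            mr.n0_copies, mr.adv_mut,
            prod_cell, sumF, d_sum, n_pre, n_post, n_def, removed,
        )
        cum_phagy += removed

        # -- biogenesis -------------------------------------------------------
        boost = 1.0 + cr.b_tf * 0.5 * (daf16 + skn1) + cr.b_nad * (sirt - 1.0)
        # organelle synthesis is energy-limited like mitophagy (enz factor)
        lam = cr.k_biog * np.clip(1.0 - n_post / cr.mito_cap, 0.0, None) * np.clip(boost, 0.0, None) * enz
        birth = (block[:, W, _C_BIOG] < 1.0 - np.exp(-lam * dt)) & cell_alive & (n_post < W)
        if birth.any():
            idx = np.where(birth)[0]
            slot = np.argmin(alive[idx], axis=1)  # first free slot
            pool_w = (Nw * alive).sum(axis=1)[idx]
            pool_m = (Nm * alive).sum(axis=1)[idx]
            # biogenesis copies the pool proportions (no replicative bias;
            # the adv_mut advantage acts in intra-organelle replication)
            denom = pool_m + pool_w
            p_pool = np.divide(pool_m, denom, out=np.zeros_like(denom, dtype=float), where=denom > 0)
            new_mut = binomial_counts(block[idx, W, _C_ALLOC], mr.n0_copies, p_pool)
            alive[idx, slot] = True
            new_F = 0.93 + 0.05 * block[idx, W, _C_BIOGF].astype(np.float64)
            F[idx, slot] = new_F
            Pd[idx, slot] = 0.0
            Nm[idx, slot] = new_mut
            Nw[idx, slot] = mr.n0_copies - new_mut
            S[idx, slot] = 0
            age[idx, slot] = 0.0
            n_post[idx] += 1
            sumF[idx] += new_F

        # -- cell-level pools (exponential relaxation sub-steps; a zero
        # clearance/consumption rate degenerates to plain accumulation) -----
        sox = np.where(cell_alive, _relax(sox, prod_cell, A_sod, dt), sox)
        in_flux = A_sod * sox
        h2o2 = np.where(cell_alive, _relax(h2o2, in_flux, A_cat, dt), h2o2)
        ros_sig = sox + h2o2

        d_mean = d_sum / np.maximum(n_pre, 1)
        stress = np.maximum(d_mean - cr.d_ref, 0.0)
        decay = cr.k_nad_decay * (1.0 + cr.c_stress * stress)
        nad = np.where(cell_alive, _relax(nad, cr.k_nad_syn * sirt_drug_t[step], decay, dt), nad)

        prod_atp = mr.k_atp * g_nad * sumF / (sumF + cr.F_half)
        atp = np.where(cell_alive, _relax(atp, prod_atp, np.broadcast_to(cr.k_atp_use, atp.shape), dt), atp)

        safe_n = np.maximum(n_post, 1)
        meanF = sumF / safe_n
        atfs1 = np.where(cell_alive, np.clip(1.0 - cr.k_import * meanF, 0.0, 1.0), atfs1)
        upr = np.where(
            cell_alive,
            atfs1**cr.hill_upr_n / (cr.hill_upr_K**cr.hill_upr_n + atfs1**cr.hill_upr_n),
            upr,
        )

        tf_base = cr.tf_basal + cr.tf_max * ros_sig**cr.n_tf / (cr.K_tf**cr.n_tf + ros_sig**cr.n_tf)
        relax = 1.0 - np.exp(-dt / cr.tau_tf)
        targ_daf = np.clip((tf_base + pt_daf_t[step]) * cr.daf16_scale, 0.0, 1.0)
        targ_skn = np.clip((tf_base + pt_skn_t[step]) * cr.skn1_scale, 0.0, 1.0)
        daf16 = np.where(cell_alive, daf16 + (targ_daf - daf16) * relax, daf16)
        skn1 = np.where(cell_alive, skn1 + (targ_skn - skn1) * relax, skn1)

        # -- life-state machine ----------------------------------------------
        frac_def = n_def / safe_n
        to_comp = (life == LIFE_HEALTHY) & cell_alive & (frac_def > thr_c)
        to_healthy = (life == LIFE_COMPROMISED) & (frac_def < cr.recover_frac)
        life = np.where(to_comp, LIFE_COMPROMISED, life).astype(np.int8)
        life = np.where(to_healthy, LIFE_HEALTHY, life).astype(np.int8)
        t_comp = np.where(to_healthy | to_comp, 0.0, t_comp)
        compromised = life == LIFE_COMPROMISED
        death_p = 1.0 - np.exp(-cr.k_death * (1.0 + t_comp / cr.tau_d) * dt)
        dies = compromised & (block[:, W, _C_DEATH] < death_p)
        life = np.where(dies, LIFE_DEAD, life).astype(np.int8)
        t_comp = np.where(compromised & ~dies, t_comp + dt, t_comp)

        t_now = (step + 1) * dt
        while next_rec < T and grid[next_rec] <= t_now + 1e-9:
            snapshot(next_rec)
            next_rec += 1

    while next_rec < T:  # pragma: no cover - guard against fp edge at t_end
        snapshot(next_rec)
        next_rec += 1

    return TrajectorySet(
        time=grid,
        life=rec_life,
        state_frac=rec_sf,
        threshold_c=thr_c,
        seed=config.seed,
        config_hash=config.config_hash(),
        config=config,
        **rec,
    )
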