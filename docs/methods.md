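# Methods

`mitosim` simulates degenerative aging in a population of post-mitotic,
energetically demanding *C. elegans* cells as a hybrid of continuous
reaction networks and discrete agent-based events, organized hierarchically:
a tissue holds cell agents, each cell holds its own population of
mitochondrion agents, and every level feeds back on the others.  The
environment is isothermal at 20 °C (an informational constant; temperature
has no dynamics).

## Model structure

### Mitochondrion level

Each organelle carries a functional OXPHOS capacity fraction `F ∈ [0,1]`, a
damaged matrix-protein fraction `Pdam`, and an mtDNA pool of `n_wt` intact
and `n_mut` deletion-bearing copies (heteroplasmy `h = n_mut/(n_wt+n_mut)`).
Its OXPHOS defect fraction

    d = 1 − F·(1 − w_h·h),      w_h = 0.5

drives everything downstream:

- **Superoxide production** `k_sox_base·flux·(1 + leak_gain·d) + pq_boost`,
  where `flux = g(NAD⁺)·(c₀ + (1−c₀)·F)` is the respiration flux (a floor
  `c₀ = 0.5` keeps electron flow, hence leak, partially alive in damaged
  organelles) and `leak_gain = 50` is the electron-leak amplification — the
  positive feedback loop of the mitochondrial free radical theory of aging.
- **Capacity dynamics** `dF/dt = −k_dmg_F·ROS_dmg·F +
  k_rep_F·chap·syn(UPR)·(1−h)²·(1−F)`.  Repair/new synthesis requires
  chaperones, is suppressed by the UPRmt (`syn = 1 − 0.5·upr`, reflecting
  down-regulation of OXPHOS subunit expression under mitochondrial stress),
  and needs intact mtDNA templates; the quadratic `(1−h)²` encodes that
  respiratory-complex assembly needs several mtDNA-encoded subunits at
  once.  `Pdam` relaxes analogously (damage up, chaperone repair down).
- **mtDNA events** per step: Poisson damage hits with mean
  `k_dmg_dna·ROS_dmg·n_wt·dt` convert intact copies; slow copy turnover
  (`k_deg_dna`) plus deficit-driven replication toward `n0 = 10` copies,
  with new copies templated mutant with probability
  `adv_mut·n_mut/(adv_mut·n_mut + n_wt)` (`adv_mut = 1.1`) — the clonal
  expansion ratchet.
- **Stress states** S0–S3 band the defect fraction at 0.30 / 0.60 / 0.90
  (the two upper edges anchor the reported 60–90% defect window for
  deleterious senescence; 0.30 mirrors the band width below it).  The label
  moves at most one band per step toward the band its current defect points
  at, with progression rate `r_up = 0.02 /min` and recovery rate
  `r_down = 0.008 /min`, so organelle phenotypes can both decay and recover.

### Cell level

Superoxide is produced per organelle but pooled per cell; per-organelle ROS
exposure uses the cell pools.  The two-pool clearance chain is

    d(sox)/dt  = Σ production − A_sod·sox
    d(h2o2)/dt = A_sod·sox − A_cat·h2o2

with `A_sod = k_sod·antiox·enz_ax + k_spont_sod` and analogously for
catalase/peroxidase.  Two ROS roles are distinguished: the *signalling*
pool `sox + h2o2` (drives DAF-16/SKN-1, defines the 100 nM aged threshold)
and the *damaging* pool `h2o2 + 0.02·sox` (peroxide-centred chemistry; the
small superoxide weight matters for the sod-2 ablation phenotype, below).

Energy state couples every protective process:

- `enz = Hill₄(ATP; K = 1.8 mM)` normalized to 1 at the 2.5 mM reference is
  the ATP-dependent *enzyme renewal capacity*.  Chaperones, mitophagy flux
  and biogenesis scale with `enz`; antioxidant enzymes, being long-lived
  proteins, retain a persistent floor
  `enz_ax = 0.06 + 0.94·enz`, and non-enzymatic clearance floors
  (`k_spont_*`) bound aged ROS.
- NAD⁺ (relative to t = 0) follows `d(nad)/dt = k_syn·sirt_drug −
  k_decay·(1 + c_stress·max(0, d̄ − d_ref))·nad`: consumption stays basal
  while the cell-mean defect `d̄` is below `d_ref = 0.17` and escalates
  steeply above it (`c_stress = 22`), producing the plateau-then-decline
  NAD⁺ trajectory.
- ATP relaxes toward `k_atp·g(nad)·ΣF/(ΣF + F_half)/k_use`: production is
  substrate- (NAD⁺-) limited and demand-saturating in the total functional
  capacity `ΣF`.  The saturating form (rather than a plain linear sum over
  organelles) keeps tissue ATP flat across the midlife rise in organelle
  count and lets it collapse only when functional capacity is truly lost.
- ATFS-1 is a conserved two-compartment fraction: nuclear fraction
  `1 − k_import·mean(F)`, and `upr = Hill₃(atfs1; K = 0.35)`.  DAF-16 and
  SKN-1 are scalar activities relaxing (τ = 300 min) toward
  `basal (0.25) + Hill₂(ROS_signal; K = 120 nM)` plus drug drives; the
  basal tone is what a *daf-16/skn-1* knockdown removes in young cells.
- Antioxidant output `(1 + a_upr·upr + a_daf·daf16 + a_skn·skn1)·const_i`,
  where `const_i ~ N(1, 0.04)` is a per-cell constitution factor drawn once
  per cell — stable inter-individual variation that spreads collapse times.

**Mitochondrial population management.**  Per-organelle mitophagy hazard
`k_mitophagy·state_mult[S]·drug·(1 + daf16)·enz` with non-decreasing state
multipliers (1, 1.5, 3, 12): quality control is selective, drug-modulated,
DAF-16-boosted, and ATP-dependent — the last coupling is what lets severely
damaged organelles pile up in energetically collapsing cells.  A cell never
digests its last organelle.  Biogenesis fires at
`k_biog·(1 − n/cap)₊·(1 + b_tf·TF + b_nad·(sirt−1))·enz`, appending a fresh
organelle (`F ≈ 0.93–0.98`) whose mtDNA copies sample the cell-wide pool
*proportions* (no replicative bias at biogenesis; the `adv_mut` advantage
acts in intra-organelle replication — otherwise raising turnover would
accelerate, not slow, clonal expansion, inverting the rapamycin phenotype).

**Compromise and death.**  Each cell draws a threshold once from
triangular(0.60, 0.625, 0.75).  It becomes *compromised* when its fraction
of severely damaged (S3) organelles exceeds that threshold, recovers if the
fraction falls below 0.60 (hysteresis at the distribution minimum; the two
guards cannot both fire in one step), and while compromised accrues death
hazard `k_death·(1 + t_comp/τ_d)` (linear escalation, τ_d = 8000 min — the
simplest monotone law).  Death is absorbing; dead cells stop being stepped
and are excluded from tissue means (rather than held at last value).

### Perturbations

- Dosing schedules: level = dose inside the window, refreshed every
  2500 min; optional first-order decay between refreshes (off by default —
  constant-level dosing).
- Rapamycin/bafilomycin act through one mitophagy multiplier
  `(1 + E_r·rapa/(EC50_r + rapa)) / (1 + baf/IC50_b)` with E_r = 1.5,
  EC50_r = 15 nM, IC50_b = 10 nM — free pharmacodynamic constants set so the
  15 nM / 10 nM presets produce the reported count/ROS/damage orderings.
- Paraquat adds a linear redox-cycling superoxide term `k_pq·conc` per
  organelle (two reported doses support only a one-constant law);
  `k_pq = 6×10⁻⁴ nM·min⁻¹·µM⁻¹` puts 5 µM at a <1.3× and 100 µM at a >3×
  baseline-ROS rise.
- Pterostilbene provides saturating DAF-16/SKN-1 drives and a sirtuin
  multiplier on NAD⁺ synthesis and biogenesis (EC50 = 25 µM), calibrated so
  100 µM trims the aged-state tissue ROS by ~20–25%.
- Ablations scale expression: *sod-2* scales the enzymatic dismutation
  channel (including its stress-induced part), *daf-16*/*skn-1* scale the
  respective activation drives, by (1 − fraction).

The *sod-2* phenotype is emergent hormesis: ablation inflates the
superoxide pool ~an order of magnitude, which barely raises damage (the
damaging pool is peroxide-weighted, and dismutation-flux conservation keeps
steady-state peroxide almost unchanged) but strongly raises the ROS signal
driving DAF-16/SKN-1 and the UPRmt.  At 90% knockdown the signal gain is
sub-threshold (Hill₂ with K = 120 nM) and the survival benefit marginal;
only complete ablation pushes the signal into the responsive range and
maximizes the longevity effect among ablation levels.  Low-dose paraquat
sits below that response threshold and is approximately neutral here: its
slight late-life ATP *improvement* over control is not reproduced (the arm
is ATP-neutral within ~25%), which is the one perturbation sub-claim the
default calibration does not capture.

## Numerics

Fixed-increment time stepping, dt = 1 min over 0–30 000 min.  Continuous
parts use exact linear-relaxation (exponential-integrator) sub-steps, so
they are unconditionally stable; `Pdam` (diagnostic only) uses forward
Euler.  Discrete events fire per step from per-cell uniform streams
(PCG64 spawned from one seed sequence): every event count is an exact
inverse-CDF transform (Poisson, binomial, triangular) of a single uniform,
which makes the whole population advanceable as flat arrays while per-cell
draws stay independent of cell-update order.  A numba-compiled organelle
kernel is used when numba is importable, with a vectorized numpy fallback
implementing the identical map (event counts agree exactly; floating sums
to rounding level, pinned by a consistency test).  Runs are bit-identical
for identical seed + configuration on a given path.

Discretization fidelity is assessed by dt-halving in two parts: on the
continuous backbone (discrete event rates zeroed) the sup-norm change of
tissue ATP/ROS is required to stay below 2%, isolating integrator error;
on the full stochastic model the halving difference of seed-mean
trajectories is required to stay within the same-dt seed-to-seed noise
envelope, i.e. the time step contributes no detectable bias.  A plain
sup-norm on stochastic runs would measure Monte-Carlo noise (which for a
small tissue mean exceeds 2% already pre-collapse), not solver error.  Degenerate inputs are guarded: organelles keep
≥1 mtDNA copy (turnover skips would-be-empty pools), cells keep ≥1
organelle (mitophagy spares the fittest), dead cells are masked out, and
recording uses a strictly increasing 500-point grid (one point per hour).

## Calibration

The per-reaction constants of the source model are not published, so all
rate defaults were fixed by calibrating this network to the printed
timeline anchors of the unperturbed condition: first-day tissue ROS
~10 nM; NAD⁺ decline onset near 7500 min with the sharp ATP decline
following; first compromised cells near 10 000 min; ATP decline ~80%
complete near 20 000–22 000 min; a modest midlife peak in organelle count;
aged tissue ROS approaching the 100 nM (≈10-fold) aged threshold; and the
perturbation orderings and effect sizes listed above.  With the default
seed set the calibrated model lands at onset ≈ 7900 min, first compromise
≈ 10 800 min, ATP 80%-decline ≈ 22 000 min, and an aged/baseline ROS ratio
≈ 8 (65 cells, 5–10 seeds).

Derived endpoint definitions (all on seed-mean tissue curves): *decline
onset* = first grid time followed by 2000 min of monotone decrease losing
≥2% of the early plateau; *saturation* = first time 80% of the total
decline (peak to late floor) is complete; *aged-state ROS reduction* of a
treatment = percentage reduction vs control over times after both arms have
reached 90% of their own late ROS plateau (so a drug is credited for
lowering the aged burden, not merely delaying it), reported as the maximal
and mean reduction; *heteroplasmy half-rise* = time to reach half of the
control end-state damage level (a common absolute scale — rapamycin stunts
the curve below its own plateau, which would make a half-of-own-final time
meaningless); *restricted mean survival time* = area under the survival
curve over the horizon.

## Validation scales and what they show

The test suite runs whole experiments at reduced sizes: perturbation arms
at 24 cells × 3 seeds, control anchors at 65 cells × 3 seeds, dt-halving at
16 cells × 4 seeds over 6000 min.  These sizes keep the orderings and
anchor windows resolvable (margins are several seed-level standard
deviations) while the full published scale — 65 cells, 30 000 min, 10
seeds — is exercised by `scripts/acceptance.py`.  The synthetic populations
are homogeneous post-mitotic cells with identical rate constants (apart
from the constitution factor); passing tests therefore demonstrate the
internal consistency and calibrated phenomenology of the model, not
fidelity to any particular worm tissue: there is no cell division,
intercellular signalling, fission/fusion, spatial structure, or upstream
insulin signalling, and drug pharmacokinetics reduce to refresh-and-decay
culture levels.

## Known limitations

- Absolute concentrations (nM ROS, mM ATP) are calibrated to reported
  fold-changes and thresholds, not to enzyme-kinetic first principles.
- The low-dose paraquat ATP benefit is not reproduced (see above).
- The sensitivity analysis reproduces the procedure (5% one-at-a-time
  reductions, SC = (ΔO/O)×20, |SC| ≥ 1 flag) but the original coefficient
  table is unavailable for numeric comparison; on this model mitophagy- and
  biogenesis-related parameters dominate late-age mitochondrial-content
  sensitivity, matching the qualitative headline.
- Tissue means are averages over alive cells; with substantial late-life
  death the aged-state aggregates carry survivor bias by construction.
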