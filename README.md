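# mitosim

Hybrid agent-based / ODE simulation of mitochondrial function and
dysfunction in aging *C. elegans* cells.

Loss of mitochondrial function is a defining feature of biological aging,
but the free-radical theory of aging (MFRTA) alone — respiration produces
reactive oxygen species (ROS), ROS damage mtDNA and matrix proteins,
damaged mitochondria leak more ROS — does not explain why small ROS
increases can be harmless or even protective. `mitosim` embeds that
feedback loop in the stress-response network that shapes it in the worm:
the mitochondrial unfolded protein response (UPR^mt, via nuclear ATFS-1
accumulation when import fails), DAF-16/FOXO and SKN-1/NRF activation,
NAD⁺-dependent sirtuin signalling, and selective mitophagy balanced against
biogenesis.  It is written for systems-biology and biogerontology
researchers who want a transparent, seedable, perturbable model of cellular
aging timelines rather than a fit to any single dataset.

## Model sketch

A tissue of 65 post-mitotic cell agents is simulated for 30 000 min (about
a worm lifespan) at 1-min steps.  Each cell holds ~50 mitochondrion agents.
Each organelle carries an OXPHOS capacity `F`, damaged-protein fraction,
and an mtDNA pool of intact/deleted copies (heteroplasmy `h`); its defect
fraction

    d = 1 − F·(1 − 0.5·h)

drives superoxide leak (`∝ 1 + leak_gain·d`), a four-band stress-state
machine (S0 healthy → S3 severely damaged, band edges 0.30/0.60/0.90),
and selective, ATP-dependent mitophagy.  Cell-level ODEs track superoxide
and peroxide pools, NAD⁺, ATP, ATFS-1/UPR^mt, and DAF-16/SKN-1.  A cell
whose fraction of severely damaged mitochondria exceeds a personal
threshold drawn from triangular(0.60, 0.625, 0.75) becomes *compromised*
and accrues an escalating death hazard; falling back below 0.60 lets it
recover.  Pharmacological schemes (rapamycin, bafilomycin, paraquat,
pterostilbene) and fractional gene knockdowns (*sod-2*, *daf-16*, *skn-1*)
map onto these rates.  A one-at-a-time global sensitivity analysis reduces
each parameter by 5% and reports normalized sensitivity coefficients
SC = (ΔO/O) × 20, flagging |SC| ≥ 1.

See `docs/methods.md` for the full equations, parameter meanings, and
calibration rationale.

## Worked example

```python
import mitosim

cfg = mitosim.get_preset("control", seed=1, n_cells=16)
traj = mitosim.run_simulation(cfg)
```

`examples/run_control_aging.py` does exactly this and prints:

```
NAD+ decline onset:            8898 min
first compromised cell:       11844 min
ATP decline saturates at:     21944 min
tissue ROS: 9.6 nM on day 1 -> 75.8 nM aged (7.9-fold)
survivors at 30 000 min:   12/16 cells
```

Reading: the tissue is quiescent for the first ~5 days while mtDNA damage
slowly accumulates; once the mean organelle defect crosses the NAD⁺ stress
threshold, NAD⁺ and then ATP decline sharply, energy-dependent quality
control falters, severely damaged organelles accumulate, and cells begin
crossing their compromise thresholds and dying — with combined
superoxide + peroxide rising toward the ~100 nM aged phenotype, an order
of magnitude above the young baseline.

Other narrative scripts in `examples/`: `mitophagy_drugs.py` (rapamycin vs
bafilomycin orderings), `sensitivity_analysis.py` (SC table on a miniature
population), `single_cell_walkthrough.py` (the scalar per-agent API).

There is also a thin CLI:

```bash
mitosim run --preset control --seed 1 --outdir out/        # cells.csv, tissue.csv, summary.json
mitosim perturb --preset rapamycin15nM --seed 1 --outdir out/
mitosim sensitivity --preset control --parameters cell.k_mitophagy --n-reps 3 --outdir out/
```

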