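"""One-at-a-time global sensitivity analysis on a miniature population.

Each chosen rate parameter is reduced by 5% and the normalized sensitivity
coefficient SC = (dO/O) x 20 is computed for tissue ROS and mitochondrial
count at two age points, with common random numbers across the paired
replicates.  |SC| >= 1 marks significant sensitive control.
"""

import mitosim
from mitosim.sensitivity import global_sensitivity, results_to_dataframe

cfg = mitosim.SimulationConfig.from_dict(
    {"t_end": 4000, "n_cells": 6, "n_mito_init": 20, "n_record": 40}
)

results = global_sensitivity(
    cfg,
    parameter_list=[
        "mitochondrion.k_sox_base",
        "mitochondrion.k_dmg_dna",
        "cell.k_mitophagy",
        "cell.k_biog",
    ],
    response_list=["ros", "mito_count"],
    age_points=[2000.0, 4000.0],
    n_reps=3,
    seed=1,
)

table = results_to_dataframe(results)
print(table.to_string(index=False, float_format=lambda x: f"{x:9.3f}"))
print()
print("Positive SC: reducing the parameter reduces the output.  The")
print("superoxide production constant controls ROS with SC > 1 (the")
print("free-radical feedback loop amplifies it beyond proportionality);")
print("biogenesis and mitophagy rates control the organelle count.")
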