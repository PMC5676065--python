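"""Deterministic miniature inputs for tests, examples and quick checks.

Every fixture is generated programmatically (no stored data) and completes
in well under a second:

``tiny_population``
    3 cells x 5 mitochondria over 100 min, full dynamics.
``frozen``
    all rates zero: every observable is constant over the horizon.
``surrogate_powerlaw``
    a closed-form "simulator" O = c * P**k used as the analytic oracle for
    the sensitivity machinery (SC = (1 - 0.95**k)/0.05 at a 5% reduction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import SimulationConfig

__all__ = ["make_fixture", "FIXTURE_KINDS", "PowerLawSurrogate"]

FIXTURE_KINDS = ("tiny_population", "frozen", "surrogate_powerlaw")


@dataclass
class PowerLawSurrogate:
    """Deterministic surrogate model O = c * P**k on one tunable parameter.

    Exposes the same (runner, response_fn) shape that
    :func:`mitosim.sensitivity.global_sensitivity` accepts, with the
    parameter routed through ``config.mito.k_sox_base``.
    """

    exponent: float = 2.0
    scale: float = 3.0

    def runner(self, config: SimulationConfig) -> float:
        return self.scale * config.mito.k_sox_base**self.exponent

    @staticmethod
    def response_fn(output: float, response: str, age_min: float) -> float:
        return float(output)


def make_fixture(kind: str, seed: int = 0):
    """Build one of the named miniature inputs (see module docstring)."""
    if kind == "tiny_population":
        return SimulationConfig.from_dict(
            {"t_end": 100, "dt": 1, "n_cells": 3, "n_mito_init": 5, "n_record": 10, "seed": seed}
        )
    if kind == "frozen":
        cfg = SimulationConfig.from_dict(
            {"t_end": 200, "dt": 1, "n_cells": 2, "n_mito_init": 4, "n_record": 5, "seed": seed}
        )
        for block in (cfg.mito, cfg.cell):
            for name in vars(block):
                value = getattr(block, name)
                if name.startswith(("k_",)) and isinstance(value, float):
                    setattr(block, name, 0.0)
        cfg.mito.r_up = cfg.mito.r_down = 0.0
        cfg.cell.k_spont_sod = cfg.cell.k_spont_cat = 0.0
        return cfg
    if kind == "surrogate_powerlaw":
        return PowerLawSurrogate(exponent=2.0)
    raise KeyError(f"unknown fixture kind {kind!r}; known kinds: {FIXTURE_KINDS}")
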