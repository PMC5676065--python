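"""Reported endpoints computed from raw trajectories, including the
literature unit conversions for whole-worm comparisons.

Conversion constants: experimental ATP content is expressed per worm and
converted to a concentration with an average worm body volume of
3.5e-9 L; oxygen-consumption rates quoted per mg protein are converted to
per-worm rates with an average protein mass of 0.681 ug per worm.  The
"aged" oxidative-stress phenotype is a 10-fold rise of combined
superoxide + peroxide to 100 nM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import TrajectorySet

__all__ = [
    "ConversionConstants",
    "atp_mM",
    "o2_per_worm",
    "o2_per_mg_protein",
    "heteroplasmy_percent",
    "time_to_ros_threshold",
    "survival_and_state_curves",
    "baseline_ros",
    "decline_onset_time",
    "saturation_time",
    "aged_ros_reduction",
    "half_rise_time",
]


@dataclass(frozen=True)
class ConversionConstants:
    """Worm-scale constants used for unit conversions and the aged threshold."""

    protein_mass_per_worm_ug: float = 0.681
    worm_volume_L: float = 3.5e-9
    ros_aged_threshold_nM: float = 100.0
    ros_fold_increase: float = 10.0

    def __post_init__(self):
        for f in ("protein_mass_per_worm_ug", "worm_volume_L", "ros_aged_threshold_nM", "ros_fold_increase"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be > 0")


CONSTANTS = ConversionConstants()


def atp_mM(mol_per_worm: float, constants: ConversionConstants = CONSTANTS) -> float:
    """Convert ATP content (mol per worm) to a concentration in mM."""
    if np.any(np.asarray(mol_per_worm) < 0):
        raise ValueError("ATP content must be >= 0")
    molar = np.asarray(mol_per_worm) / constants.worm_volume_L
    out = molar * 1e3
    return float(out) if out.ndim == 0 else out


def o2_per_worm(rate_per_mg_protein: float, constants: ConversionConstants = CONSTANTS) -> float:
    """Convert an O2 consumption rate from pmol/min/mg protein to pmol/min/worm."""
    if np.any(np.asarray(rate_per_mg_protein) < 0):
        raise ValueError("O2 consumption rate must be >= 0")
    out = np.asarray(rate_per_mg_protein) * (constants.protein_mass_per_worm_ug * 1e-3)
    return float(out) if out.ndim == 0 else out


def o2_per_mg_protein(rate_per_worm: float, constants: ConversionConstants = CONSTANTS) -> float:
    """Inverse of :func:`o2_per_worm` (round-trips exactly up to float error)."""
    if np.any(np.asarray(rate_per_worm) < 0):
        raise ValueError("O2 consumption rate must be >= 0")
    out = np.asarray(rate_per_worm) / (constants.protein_mass_per_worm_ug * 1e-3)
    return float(out) if out.ndim == 0 else out


def heteroplasmy_percent(n_wt, n_mut) -> float:
    """Deleterious heteroplasmy, 100 * sum(mut) / sum(wt + mut), over a cell.

    Accepts scalars or per-organelle arrays; the result depends only on the
    pooled totals, not on how copies are distributed among organelles.
    """
    wt = float(np.sum(n_wt))
    mut = float(np.sum(n_mut))
    if wt + mut < 1:
        raise ValueError("heteroplasmy undefined for an empty mtDNA pool")
    return 100.0 * mut / (wt + mut)


def time_to_ros_threshold(time: np.ndarray, ros: np.ndarray, threshold: float) -> float | None:
    """First grid time at which combined ROS reaches ``threshold`` (nM).

    Returns None when the trace never crosses; cells that never cross count
    in downstream summaries rather than being dropped.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    ros = np.asarray(ros)
    above = np.nonzero(ros >= threshold)[0]
    if len(above) == 0:
        return None
    return float(np.asarray(time)[above[0]])


def survival_and_state_curves(traj: TrajectorySet):
    """Viable/compromised/dead counts and the survival fraction over time.

    survival = 1 - dead/n_cells is non-increasing because death is absorbing.
    """
    import pandas as pd

    counts = traj.life_counts()
    return pd.DataFrame(
        {
            "time_min": traj.time,
            "healthy": counts["healthy"],
            "compromised": counts["compromised"],
            "dead": counts["dead"],
            "survival_fraction": 1.0 - counts["dead"] / traj.n_cells,
        }
    )


def baseline_ros(traj: TrajectorySet, window_min: float = 1440.0) -> float:
    """Population-mean combined ROS over the first simulated day."""
    sel = traj.time <= window_min
    return float(np.nanmean(traj.tissue_mean("ros")[sel]))


def decline_onset_time(
    time: np.ndarray,
    series: np.ndarray,
    window_min: float = 2000.0,
    drop_frac: float = 0.02,
) -> float | None:
    """Onset of a sustained decline in a (seed-mean) trajectory.

    The onset is the first grid time after which the series decreases
    monotonically over the next ``window_min`` minutes and loses at least
    ``drop_frac`` of its early plateau over that window; returns None if no
    such time exists.  The drop requirement keeps flat, noise-level wiggles
    from registering as an onset.
    """
    time = np.asarray(time, dtype=float)
    series = np.asarray(series, dtype=float)
    if len(time) < 3:
        return None
    step = np.median(np.diff(time))
    k = max(2, int(round(window_min / step)))
    ref = np.nanmax(series[: max(2, k // 2)])
    diffs = np.diff(series)
    for i in range(0, len(series) - k):
        if np.all(diffs[i : i + k] < 0) and (series[i] - series[i + k]) >= drop_frac * abs(ref):
            return float(time[i])
    return None


def saturation_time(
    time: np.ndarray,
    series: np.ndarray,
    frac: float = 0.80,
    tail_min: float = 3000.0,
) -> float | None:
    """Time at which a declining trajectory has essentially saturated.

    Saturation is the first time the series has completed ``frac`` of its
    total decline from its maximum to its late floor (the mean over the last
    ``tail_min`` minutes).  None if the series never declines.
    """
    time = np.asarray(time, dtype=float)
    series = np.asarray(series, dtype=float)
    tail = time >= time[-1] - tail_min
    floor = np.nanmean(series[tail])
    peak = np.nanmax(series)
    if peak <= floor:
        return None
    target = peak - frac * (peak - floor)
    below = np.nonzero(series <= target)[0]
    if len(below) == 0:
        return None
    return float(time[below[0]])


def aged_ros_reduction(
    time: np.ndarray,
    ros_control: np.ndarray,
    ros_treated: np.ndarray,
    plateau_frac: float = 0.90,
    tail_min: float = 5000.0,
) -> tuple[float, float]:
    """(maximal, mean) percent reduction in tissue ROS after the aged state.

    The aged state of each arm is the first time its (seed-mean) tissue ROS
    reaches ``plateau_frac`` of that arm's own late plateau (mean over the
    last ``tail_min`` minutes); the comparison window starts once both arms
    are aged, so a treatment is credited for lowering the aged oxidative
    burden rather than merely delaying its onset.
    """
    time = np.asarray(time, dtype=float)

    def t_aged(ros):
        plateau = np.nanmean(ros[time >= time[-1] - tail_min])
        above = np.nonzero(ros >= plateau_frac * plateau)[0]
        return time[above[0]] if len(above) else time[-1]

    start = max(t_aged(ros_control), t_aged(ros_treated))
    window = time >= start
    reduction = 100.0 * (ros_control[window] - ros_treated[window]) / ros_control[window]
    return float(np.nanmax(reduction)), float(np.nanmean(reduction))


def half_rise_time(time: np.ndarray, series: np.ndarray, level: float) -> float | None:
    """First grid time a rising series reaches ``level``; None if never.

    Used for the heteroplasmy half-rise comparison across perturbation
    arms, where ``level`` is half the unperturbed (control) end-state so
    that arms whose accumulation is stunted below their own plateau are
    compared on a common damage scale.
    """
    series = np.asarray(series, dtype=float)
    above = np.nonzero(series >= level)[0]
    if len(above) == 0:
        return None
    return float(np.asarray(time)[above[0]])
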