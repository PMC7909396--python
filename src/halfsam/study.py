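"""Convenience layer for the standard power-study grid.

The canonical study design: 1000-gene datasets, 10 samples per group,
control SD 15, mean shift ``md`` in {0, 10, 15} and case/control SD
ratio ``r`` in {1, 1.5, 2}, under each generative family.  These helpers
build the matching :class:`~halfsam.simulation.SimulationConfig` objects,
share one Monte Carlo null calibration per (family, statistic) across
all cells of a grid, and return rejection rates per cell.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .simulation import (MonteCarloCalibration, PowerEstimate,
                         SimulationConfig, estimate_type1_power)

__all__ = ["study_config", "calibrate_methods", "power_cell"]


def study_config(distribution: str, md: float, r: float, *, reps: int,
                 seed: int, n0: int = 10, n1: int = 10, s0: float = 15.0,
                 mu0: float = 100.0, n_genes: int = 1000,
                 alpha: float = 0.05, B: int = 200,
                 gamma_shape: float = 4.0) -> SimulationConfig:
    """One cell of the standard grid as a SimulationConfig."""
    return SimulationConfig(n0=n0, n1=n1, md=md, r=r, s0=s0, mu0=mu0,
                            distribution=distribution, gamma_shape=gamma_shape,
                            n_genes=n_genes, reps=reps, alpha=alpha, B=B,
                            seed=seed)


def calibrate_methods(distribution: str, methods: Sequence[str], *,
                      reps: int, seed: int, **kwargs) -> dict:
    """Null-calibrate each score statistic once for a whole grid.

    Runs the family's md = 0, r = 1 null scenario and freezes, per
    statistic, the fudge factor and the two-sided critical value.
    """
    cfg = study_config(distribution, 0.0, 1.0, reps=reps, seed=seed, **kwargs)
    rng = np.random.default_rng(seed)
    return {m: MonteCarloCalibration.calibrate(cfg, m, rng) for m in methods}


def power_cell(distribution: str, md: float, r: float,
               methods: Sequence[str], *, reps: int, seed: int,
               calibration: str = "auto",
               calibrations: Optional[dict] = None,
               **kwargs) -> dict:
    """Rejection rate of each statistic in one grid cell.

    Returns ``{method: PowerEstimate}``; rates are proportions (multiply
    by 100 for the conventional percent scale).
    """
    cfg = study_config(distribution, md, r, reps=reps, seed=seed, **kwargs)
    rng = np.random.default_rng(seed)
    return estimate_type1_power(cfg, methods, calibration=calibration,
                                calibrations=calibrations, rng=rng)
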