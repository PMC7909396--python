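"""Monte Carlo engine: type I error and power of the four statistics.

The study design mirrors a two-group expression experiment with 1000
genes and 10 samples per group: every gene in the control group is drawn
with mean ``mu0`` and SD ``s0`` (default 15), every case-group gene with
mean ``mu0 + md`` and SD ``r * s0``.  Four generative families are
supported -- normal, moment-matched uniform (symmetric non-normal),
right-skewed gamma, and its reflection (left-skewed) -- plus a mixture
scenario in which the case group blends two normal components to emulate
etiological subgroups of a heterogeneous disease.

Rejection rules
---------------
* ``student_t`` / ``half_t``: two-sided t critical value at ``alpha``
  with df = n1+n0-2 and n0-1 respectively (the parametric rule).
* ``sam`` / ``half_sam``: these scores have no closed-form null, so the
  default is a Monte Carlo null calibration -- the fudge factor c0 and
  the two-sided critical value are both frozen from a simulated null run
  (md = 0, r = 1, same distribution family) and applied unchanged to
  every scenario.  Freezing c0 matters: re-estimating it on each dataset
  rescales the score with the data and cancels the variance-detection
  signal the score tests otherwise show at md = 0, r > 1.  A per-gene or
  pooled label-permutation rule (p <= alpha, B permutations per dataset)
  is available via ``calibration="permutation"``; it is markedly
  conservative when the case variance is inflated, because permuted
  "control" groups absorb case samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from .data import LabeledExpressionMatrix
from .inference import bh_fdr, permutation_null, permutation_pvalues
from .stats import SCORE_STATISTICS, STATISTICS, fudge_factor_for, summarize_groups

__all__ = [
    "SimulationConfig",
    "MixtureSpec",
    "PowerEstimate",
    "MonteCarloCalibration",
    "draw_group",
    "simulate_dataset",
    "estimate_type1_power",
    "fdr_power_comparison",
    "run_scenario_grid",
    "load_scenario_grid",
]

DISTRIBUTIONS = ("normal", "uniform", "gamma_right", "gamma_left", "mixture")


@dataclass
class MixtureSpec:
    """Case-group mixture: weights, mean offsets from mu0, and SDs."""

    weights: Sequence[float]
    mean_offsets: Sequence[float]
    sds: Sequence[float]

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.mean_offsets = np.asarray(self.mean_offsets, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        if not (self.weights.size == self.mean_offsets.size == self.sds.size):
            raise ValueError("mixture_spec: component lists must align")
        if not math.isclose(self.weights.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("mixture_spec: weights must sum to 1")
        if (self.weights < 0).any() or (self.sds <= 0).any():
            raise ValueError("mixture_spec: weights must be >= 0 and sds > 0")

    @classmethod
    def default_for(cls, md: float, s0: float) -> "MixtureSpec":
        """Half the cases unshifted, half shifted by 2*md: marginal shift md."""
        return cls(weights=(0.5, 0.5), mean_offsets=(0.0, 2.0 * md),
                   sds=(s0, s0))


@dataclass
class SimulationConfig:
    """Complete parameterization of one Monte Carlo scenario.

    ``reps`` counts simulated gene-level tests; datasets of ``n_genes``
    genes are generated until ``reps`` tests have been accumulated.
    ``nonnull_fraction``, when set, plants the mean shift ``md`` in only
    that leading fraction of genes (the rest are null), for FDR-power
    studies.
    """

    n0: int = 10
    n1: int = 10
    md: float = 0.0
    r: float = 1.0
    s0: float = 15.0
    mu0: float = 100.0
    distribution: str = "normal"
    gamma_shape: float = 4.0
    mixture_spec: Optional[MixtureSpec] = None
    n_genes: int = 1000
    reps: int = 100_000
    alpha: float = 0.05
    B: int = 200
    seed: int = 0
    nonnull_fraction: Optional[float] = None

    def __post_init__(self):
        for name in ("n0", "n1"):
            if getattr(self, name) < 2:
                raise ValueError(f"{name} must be >= 2, got {getattr(self, name)}")
        if self.r <= 0:
            raise ValueError(f"r must be > 0, got {self.r}")
        if self.s0 <= 0:
            raise ValueError(f"s0 must be > 0, got {self.s0}")
        if self.n_genes < 1:
            raise ValueError(f"n_genes must be >= 1, got {self.n_genes}")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.B < 1:
            raise ValueError(f"B must be >= 1, got {self.B}")
        if self.distribution not in DISTRIBUTIONS:
            raise ValueError(
                f"distribution must be one of {DISTRIBUTIONS}, got "
                f"{self.distribution!r}")
        if self.gamma_shape <= 0:
            raise ValueError(f"gamma_shape must be > 0, got {self.gamma_shape}")
        if self.nonnull_fraction is not None and not 0 <= self.nonnull_fraction <= 1:
            raise ValueError(
                f"nonnull_fraction must be in [0, 1], got {self.nonnull_fraction}")
        if self.distribution == "mixture" and self.mixture_spec is None:
            self.mixture_spec = MixtureSpec.default_for(self.md, self.s0)

    @property
    def n_datasets(self) -> int:
        return max(1, math.ceil(self.reps / self.n_genes))

    def null_config(self) -> "SimulationConfig":
        """The matched null scenario: md = 0, r = 1, no mixture."""
        dist = "normal" if self.distribution == "mixture" else self.distribution
        return replace(self, md=0.0, r=1.0, distribution=dist,
                       mixture_spec=None, nonnull_fraction=None)


@dataclass
class PowerEstimate:
    """A rejection rate with its binomial Monte Carlo standard error."""

    method: str
    rejection_rate: float
    mc_se: float
    reps: int
    metric: str
    config: SimulationConfig = field(repr=False, default=None)


def _mc_se(p: float, n: int) -> float:
    return math.sqrt(max(p * (1.0 - p), 0.0) / n) if n else float("nan")


def draw_group(distribution: str, size, mean: float, sd: float,
               shape: float = 4.0, rng: np.random.Generator = None) -> np.ndarray:
    """Draw expression values with the requested population mean and SD.

    ``uniform`` is the moment-matched U(mean - sqrt(3)*sd, mean + sqrt(3)*sd);
    ``gamma_right`` is a Gamma(shape) scaled to SD ``sd`` and shifted to
    mean ``mean`` (skewness 2/sqrt(shape)); ``gamma_left`` is its
    reflection about the mean, so only the sign of the skewness changes.
    """
    if sd <= 0:
        raise ValueError(f"sd must be > 0, got {sd}")
    rng = np.random.default_rng() if rng is None else rng
    if distribution == "normal":
        return rng.normal(mean, sd, size)
    if distribution == "uniform":
        half = math.sqrt(3.0) * sd
        return rng.uniform(mean - half, mean + half, size)
    if distribution in ("gamma_right", "gamma_left"):
        scale = sd / math.sqrt(shape)
        base = rng.gamma(shape, scale, size) - shape * scale  # centered at 0
        return mean + base if distribution == "gamma_right" else mean - base
    raise ValueError(f"unknown distribution {distribution!r}")


def _draw_case_matrix(config: SimulationConfig, md_per_gene: np.ndarray,
                      rng) -> np.ndarray:
    G, n1 = config.n_genes, config.n1
    if config.distribution == "mixture":
        spec = config.mixture_spec
        comp = rng.choice(spec.weights.size, size=(G, n1), p=spec.weights)
        z = rng.standard_normal((G, n1))
        return config.mu0 + spec.mean_offsets[comp] + spec.sds[comp] * z
    case_sd = config.r * config.s0
    base = draw_group(config.distribution, (G, n1), 0.0, case_sd,
                      config.gamma_shape, rng)
    return base + config.mu0 + md_per_gene[:, None]


def _planted_count(config: SimulationConfig) -> int:
    if config.nonnull_fraction is None:
        return config.n_genes if config.md != 0 else 0
    return int(round(config.nonnull_fraction * config.n_genes))


def _md_per_gene(config: SimulationConfig) -> np.ndarray:
    md = np.full(config.n_genes, config.md)
    if config.nonnull_fraction is not None:
        md[_planted_count(config):] = 0.0
    return md


def simulate_dataset(config: SimulationConfig,
                     rng: np.random.Generator = None) -> LabeledExpressionMatrix:
    """One gene x sample dataset under the scenario; case columns first."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    case = _draw_case_matrix(config, _md_per_gene(config), rng)
    ctrl = config.mu0 + draw_group(
        config.distribution if config.distribution != "mixture" else "normal",
        (config.n_genes, config.n0), 0.0, config.s0, config.gamma_shape, rng)
    values = np.hstack([case, ctrl])
    labels = np.r_[np.ones(config.n1, dtype=int), np.zeros(config.n0, dtype=int)]
    return LabeledExpressionMatrix(values=values, labels=labels)


# ---------------------------------------------------------------------------
# Monte Carlo null calibration for the score statistics
# ---------------------------------------------------------------------------

@dataclass
class MonteCarloCalibration:
    """Frozen fudge factor and two-sided critical value for one statistic.

    Built in two passes over independent null datasets (md = 0, r = 1):
    first the per-dataset CV-minimizing c0 estimates, whose median is
    frozen; then the (1 - alpha) quantile of |score| computed with that
    frozen c0.
    """

    method: str
    c0: Optional[float]
    critical_value: float
    alpha: float
    n_gene_tests: int

    @classmethod
    def calibrate(cls, config: SimulationConfig, method: str,
                  rng: np.random.Generator) -> "MonteCarloCalibration":
        null_cfg = config.null_config()
        n_data = null_cfg.n_datasets
        c0 = None
        if method in SCORE_STATISTICS:
            c0s = []
            for _ in range(n_data):
                summary = summarize_groups(simulate_dataset(null_cfg, rng))
                c0s.append(fudge_factor_for(summary, method).c0)
            c0 = float(np.median(c0s))
        scores = []
        for _ in range(n_data):
            matrix = simulate_dataset(null_cfg, rng)
            scores.append(np.abs(_observed_scores(matrix, method, c0)))
        pooled = np.concatenate(scores)
        crit = float(np.quantile(pooled[np.isfinite(pooled)],
                                 1.0 - config.alpha))
        return cls(method=method, c0=c0, critical_value=crit,
                   alpha=config.alpha, n_gene_tests=pooled.size)


def _observed_scores(matrix, method, c0):
    from .inference import compute_scores

    return compute_scores(matrix, method, c0=c0).scores


def _t_critical(method: str, config: SimulationConfig) -> float:
    df = (config.n1 + config.n0 - 2) if method == "student_t" else config.n0 - 1
    return float(sps.t.ppf(1.0 - config.alpha / 2.0, df))


def estimate_type1_power(config: SimulationConfig,
                         methods: Sequence[str] = STATISTICS,
                         calibration: str = "auto",
                         calibrations: Optional[dict] = None,
                         null_mode: str = "per_gene",
                         rng: np.random.Generator = None) -> dict:
    """Per-gene rejection rate of each statistic under one scenario.

    With md = 0 the rate is the type I error, otherwise the power.
    ``calibration`` is ``"auto"`` (parametric t rule for the t statistics,
    Monte Carlo null calibration for the scores), ``"parametric"``,
    ``"mc_null"`` or ``"permutation"``.  Pre-built
    :class:`MonteCarloCalibration` objects may be passed per method via
    ``calibrations`` to share a null run across scenarios.
    """
    if config.reps < 1000:
        raise ValueError(f"reps must be >= 1000, got {config.reps}")
    for m in methods:
        if m not in STATISTICS:
            raise ValueError(f"unknown statistic {m!r}")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    modes = {}
    for m in methods:
        if calibration == "auto":
            modes[m] = "parametric" if m not in SCORE_STATISTICS else "mc_null"
        else:
            modes[m] = calibration
        if modes[m] == "parametric" and m in SCORE_STATISTICS:
            raise ValueError(
                f"{m} has no parametric null; use mc_null or permutation")

    calibrations = dict(calibrations or {})
    for m in methods:
        if modes[m] == "mc_null" and m not in calibrations:
            calibrations[m] = MonteCarloCalibration.calibrate(config, m, rng)

    rejected = {m: 0 for m in methods}
    total = {m: 0 for m in methods}
    for _ in range(config.n_datasets):
        matrix = simulate_dataset(config, rng)
        for m in methods:
            if modes[m] == "parametric":
                scores = _observed_scores(matrix, m, None)
                ok = np.isfinite(scores)
                rej = np.abs(scores[ok]) > _t_critical(m, config)
            elif modes[m] == "mc_null":
                cal = calibrations[m]
                scores = _observed_scores(matrix, m, cal.c0)
                ok = np.isfinite(scores)
                rej = np.abs(scores[ok]) > cal.critical_value
            else:
                seed = int(rng.integers(2**31))
                res = permutation_null(matrix, m, B=config.B, seed=seed)
                p = permutation_pvalues(res, mode=null_mode)
                ok = np.isfinite(p)
                rej = p[ok] <= config.alpha
            rejected[m] += int(rej.sum())
            total[m] += int(ok.sum())

    metric = "type_i_error" if config.md == 0 else "power"
    out = {}
    for m in methods:
        rate = rejected[m] / total[m] if total[m] else float("nan")
        out[m] = PowerEstimate(method=m, rejection_rate=rate,
                               mc_se=_mc_se(rate, total[m]), reps=total[m],
                               metric=metric, config=config)
    return out


def fdr_power_comparison(config: SimulationConfig,
                         methods: Sequence[str] = STATISTICS,
                         q: float = 0.05, null_mode: str = "pooled",
                         rng: np.random.Generator = None) -> dict:
    """BH-at-q power (true-positive rate) per method over replicates.

    Permutation p-values per dataset (pooled across genes by default, for
    resolution far below 1/(B+1)), then Benjamini-Hochberg at ``q``.
    With planted non-null genes the estimate is the mean fraction of
    planted genes discovered; under a global null it is the fraction of
    replicate datasets with at least one (false) discovery.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    k = _planted_count(config)
    hits = {m: 0.0 for m in methods}
    n_data = config.n_datasets
    for _ in range(n_data):
        matrix = simulate_dataset(config, rng)
        for m in methods:
            seed = int(rng.integers(2**31))
            res = permutation_null(matrix, m, B=config.B, seed=seed)
            p = permutation_pvalues(res, mode=null_mode)
            _, signif = bh_fdr(p, q=q)
            if k:
                hits[m] += signif[:k].mean()
            else:
                hits[m] += float(signif.any())
    metric = "fdr_power" if k else "any_discovery_rate"
    out = {}
    for m in methods:
        rate = hits[m] / n_data
        n_eff = n_data * k if k else n_data
        out[m] = PowerEstimate(method=m, rejection_rate=rate,
                               mc_se=_mc_se(rate, n_eff), reps=n_eff,
                               metric=metric, config=config)
    return out


# ---------------------------------------------------------------------------
# scenario grids
# ---------------------------------------------------------------------------

def load_scenario_grid(path):
    """Parse a YAML scenario file.

    Layout: optional ``base`` mapping of shared config keys, a
    ``scenarios`` mapping of name -> per-scenario overrides, optional
    ``methods`` list and ``metric`` ("alpha" rejection rates or "fdr"
    BH power).  Returns (scenarios dict, methods, metric).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "scenarios" not in raw:
        raise ValueError("scenario file must define a 'scenarios' mapping")
    base = raw.get("base", {})
    methods = raw.get("methods", list(STATISTICS))
    metric = raw.get("metric", "alpha")
    if metric not in ("alpha", "fdr"):
        raise ValueError(f"metric must be 'alpha' or 'fdr', got {metric!r}")
    scenarios = {}
    for name, overrides in raw["scenarios"].items():
        params = {**base, **(overrides or {})}
        try:
            scenarios[name] = SimulationConfig(**params)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"scenario {name!r}: {exc}") from exc
    return scenarios, methods, metric


def run_scenario_grid(scenarios: dict, methods: Sequence[str],
                      metric: str = "alpha", seed: int = 0) -> pd.DataFrame:
    """Run every scenario and return a tidy results table.

    Columns: scenario, method, metric, estimate, mc_se, reps.  Scenario
    seeds are spawned from ``seed`` so the grid is reproducible as a
    whole.
    """
    seq = np.random.SeedSequence(seed)
    rows = []
    for child, (name, config) in zip(seq.spawn(len(scenarios)),
                                     sorted(scenarios.items())):
        rng = np.random.default_rng(child)
        if metric == "alpha":
            estimates = estimate_type1_power(config, methods, rng=rng)
        else:
            estimates = fdr_power_comparison(config, methods, rng=rng)
        for m in methods:
            est = estimates[m]
            rows.append({"scenario": name, "method": m, "metric": est.metric,
                         "estimate": est.rejection_rate, "mc_se": est.mc_se,
                         "reps": est.reps})
    return pd.DataFrame(rows)
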