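"""Benchmarking harness: scenario grids, replicates, and accuracy metrics.

Three experiment modes mirror the standard validation designs for
pedigree-accumulation estimators:

* ``factorial`` — all combinations of true abundances and offspring sample
  sizes, many replicates per cell;
* ``uniform``  — N_P and N_OBS each drawn integer-uniform (default 25-500)
  per replicate, to probe behaviour as a function of the N_OBS:N_P ratio;
* ``error``    — a factorial grid where each simulated base sample has
  Type I or Type II pedigree errors injected at several rates, every rate
  applied to the *same* base sample for comparability.

Accuracy is summarized by the bias ratio (estimate/truth), the coefficient
of variation (100 * sample SD / mean), RMSE, and the fraction of 95%
confidence/credible intervals containing the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import chao as chao_mod
from .bayes import MCMCSettings, ParentAugmentationModel
from .detect import DetectionVector, build_detection_vector
from .errors import inject_type1, inject_type2
from .simulate import BreedingScenario, sample_offspring, simulate_breeding, split_sex_ratio

__all__ = [
    "GridConfig",
    "compute_bias",
    "compute_cv",
    "compute_rmse",
    "compute_coverage",
    "run_grid",
    "load_config",
]


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def compute_bias(estimates: Sequence[float], truth: float) -> tuple[float, float]:
    """Mean and median of the per-replicate bias ratio estimate/truth."""
    est = np.asarray(estimates, dtype=float)
    if est.size == 0:
        raise ValueError("no estimates")
    if not truth > 0:
        raise ValueError("truth must be > 0")
    ratios = est / truth
    return float(ratios.mean()), float(np.median(ratios))


def compute_cv(estimates: Sequence[float]) -> float:
    """Coefficient of variation, 100 * SD / mean, with sample (n-1) SD."""
    est = np.asarray(estimates, dtype=float)
    if est.size < 2:
        raise ValueError("CV needs >= 2 estimates")
    mean = est.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return float(100.0 * est.std(ddof=1) / mean)


def compute_rmse(estimates: Sequence[float], truth: float) -> float:
    """Root mean squared error of the estimates around the truth."""
    est = np.asarray(estimates, dtype=float)
    if est.size == 0:
        raise ValueError("no estimates")
    return float(np.sqrt(np.mean((est - truth) ** 2)))


def compute_coverage(intervals: Sequence[tuple[float, float]], truth: float | Sequence[float]) -> float:
    """Fraction of closed intervals [low, high] containing the truth.

    ``truth`` may be a scalar or one value per interval (uniform-draw mode).
    """
    iv = np.asarray(intervals, dtype=float)
    if iv.size == 0:
        raise ValueError("no intervals")
    t = np.broadcast_to(np.asarray(truth, dtype=float), (iv.shape[0],))
    hits = (iv[:, 0] <= t) & (t <= iv[:, 1])
    return float(hits.mean())


# ---------------------------------------------------------------------------
# grid configuration and execution
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GridConfig:
    """Configuration for one benchmarking experiment."""

    mode: str = "factorial"  # 'factorial' | 'uniform' | 'error'
    n_p_values: tuple[int, ...] = (25, 50, 100, 200, 500)
    n_obs_values: tuple[int, ...] = (25, 50, 100, 200, 500)
    n_replicates: int = 100
    estimators: tuple[str, ...] = ("chao1", "ichao", "bayes")
    sex_ratio: tuple[float, float] = (1.0, 1.0)  # males : females
    mate_lambda: float = 4.0
    fecundity: tuple[int, int] = (2500, 6500)
    # uniform mode
    uniform_low: int = 25
    uniform_high: int = 500
    # error mode
    error_type: str | None = None  # 'type1' | 'type2'
    error_rates: tuple[float, ...] = (0.0, 0.01, 0.05)
    # bayesian settings
    factor: float = 50.0
    mcmc: MCMCSettings = field(default_factory=MCMCSettings)
    rhat_threshold: float = 1.1
    seed: int = 0
    n_jobs: int = 1

    def __post_init__(self) -> None:
        if self.mode not in ("factorial", "uniform", "error"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "error" and self.error_type not in ("type1", "type2"):
            raise ValueError("error mode requires error_type 'type1' or 'type2'")
        bad = set(self.estimators) - {"chao1", "ichao", "bayes"}
        if bad:
            raise ValueError(f"unknown estimators: {sorted(bad)}")


def load_config(path: str) -> GridConfig:
    """Read a GridConfig from a YAML mapping of field names to values."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    mcmc = MCMCSettings(**raw.pop("mcmc", {}))
    for key in ("n_p_values", "n_obs_values", "estimators", "sex_ratio",
                "fecundity", "error_rates"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return GridConfig(mcmc=mcmc, **raw)


def _estimate_rows(
    d: DetectionVector,
    cfg: GridConfig,
    rng: np.random.Generator,
    base: dict,
) -> list[dict]:
    rows = []
    for method in cfg.estimators:
        row = dict(base)
        row["method"] = method
        row["n_det"] = d.n_det
        try:
            if method == "chao1":
                est = chao_mod.chao1(d)
                row.update(
                    estimate=est.n_p_hat, ci_low=est.ci_low, ci_high=est.ci_high,
                    converged=True, rhat_max=np.nan,
                )
            elif method == "ichao":
                est = chao_mod.ichao(d)
                row.update(
                    estimate=est.n_p_hat, ci_low=est.ci_low, ci_high=est.ci_high,
                    converged=True, rhat_max=np.nan,
                )
            else:
                model = ParentAugmentationModel(d, factor=cfg.factor)
                res = model.fit(
                    chains=cfg.mcmc.chains,
                    burnin=cfg.mcmc.burnin,
                    iterations=cfg.mcmc.iterations,
                    thin=cfg.mcmc.thin,
                    seed=rng,
                    rhat_threshold=cfg.rhat_threshold,
                )
                row.update(
                    estimate=res.stats.n_p_median,
                    ci_low=res.stats.hpd_low,
                    ci_high=res.stats.hpd_high,
                    converged=res.stats.converged,
                    rhat_max=max(res.stats.rhat.values()),
                )
            row["failed"] = False
        except Exception as exc:  # noqa: BLE001 - partial failures are reported, not fatal
            row.update(
                estimate=np.nan, ci_low=np.nan, ci_high=np.nan,
                converged=False, rhat_max=np.nan, failed=True, error=str(exc),
            )
        rows.append(row)
    return rows


def _run_replicate(task: dict, cfg: GridConfig) -> list[dict]:
    """Simulate one replicate and estimate with every configured method."""
    ss = np.random.SeedSequence(entropy=cfg.seed, spawn_key=(task["task_index"],))
    n_rates = len(cfg.error_rates) if cfg.mode == "error" else 0
    children = ss.spawn(2 + 2 * n_rates)
    rng_sim = np.random.default_rng(children[0])

    n_females, n_males = split_sex_ratio(task["n_p_true"], *cfg.sex_ratio)
    scen = BreedingScenario(
        n_females, n_males,
        mate_lambda=cfg.mate_lambda,
        fecundity_min=cfg.fecundity[0],
        fecundity_max=cfg.fecundity[1],
    )
    ped = simulate_breeding(scen, rng_sim)
    sample = sample_offspring(ped, task["n_obs"], rng_sim)

    base = {
        "n_p_true": task["n_p_true"],
        "n_obs": task["n_obs"],
        "sex_ratio": f"{cfg.sex_ratio[0]:g}:{cfg.sex_ratio[1]:g}",
        "replicate": task["replicate"],
        "seed": cfg.seed,
        "error_type": cfg.error_type or "none",
    }
    rows: list[dict] = []
    if cfg.mode == "error":
        injector = inject_type1 if cfg.error_type == "type1" else inject_type2
        for r, rate in enumerate(cfg.error_rates):
            # the same base sample underlies every rate in this replicate
            rng_err = np.random.default_rng(children[2 + 2 * r])
            rng_est = np.random.default_rng(children[3 + 2 * r])
            perturbed = injector(sample, rate, rng_err)
            d = build_detection_vector(perturbed)
            rows += _estimate_rows(d, cfg, rng_est, {**base, "error_rate": rate})
    else:
        rng_est = np.random.default_rng(children[1])
        d = build_detection_vector(sample)
        rows += _estimate_rows(d, cfg, rng_est, {**base, "error_rate": 0.0})
    return rows


def _build_tasks(cfg: GridConfig) -> list[dict]:
    tasks = []
    if cfg.mode == "uniform":
        draw_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=cfg.seed, spawn_key=(0xA11CE,))
        )
        for i in range(cfg.n_replicates):
            n_p = int(draw_rng.integers(cfg.uniform_low, cfg.uniform_high + 1))
            n_obs = int(draw_rng.integers(cfg.uniform_low, cfg.uniform_high + 1))
            tasks.append({"n_p_true": n_p, "n_obs": n_obs, "replicate": i})
    else:
        for n_p in cfg.n_p_values:
            for n_obs in cfg.n_obs_values:
                for i in range(cfg.n_replicates):
                    tasks.append({"n_p_true": n_p, "n_obs": n_obs, "replicate": i})
    for idx, t in enumerate(tasks):
        t["task_index"] = idx
    return tasks


def run_grid(cfg: GridConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Execute an experiment; returns (results, metrics) DataFrames.

    ``results`` has one row per replicate x error-rate x method; ``metrics``
    aggregates each scenario cell. For the Bayesian estimator the metrics
    are restricted to converged fits (raw rows keep everything); failed
    replicates are excluded from metrics with their count reported in
    ``n_failed``, never silently dropped.
    """
    tasks = _build_tasks(cfg)
    if cfg.n_jobs != 1:
        from joblib import Parallel, delayed

        chunks = Parallel(n_jobs=cfg.n_jobs)(
            delayed(_run_replicate)(t, cfg) for t in tasks
        )
    else:
        chunks = [_run_replicate(t, cfg) for t in tasks]
    results = pd.DataFrame([row for chunk in chunks for row in chunk])
    return results, summarize_metrics(results, cfg)


def summarize_metrics(results: pd.DataFrame, cfg: GridConfig) -> pd.DataFrame:
    """Aggregate a results table into per-cell accuracy metrics.

    In uniform mode the truth varies per replicate, so one row per method
    is produced with ratio-based spread metrics (CV and RMSE of the bias
    ratio around 1); in the fixed-truth modes metrics are on the estimate
    scale.
    """
    group_cols = (
        ["method"] if cfg.mode == "uniform"
        else ["n_p_true", "n_obs", "error_rate", "method"]
    )
    out = []
    for key, g in results.groupby(group_cols, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        info = dict(zip(group_cols, key))
        n_total = len(g)
        ok = g[~g["failed"]]
        method = info["method"]
        if method == "bayes":
            ok = ok[ok["converged"]]
        row = {
            **info,
            "n_replicates": n_total,
            "n_converged": int(g["converged"].sum()),
            "n_failed": int(g["failed"].sum()),
        }
        if len(ok) >= 2:
            est = ok["estimate"].to_numpy()
            truth = ok["n_p_true"].to_numpy(dtype=float)
            ratios = est / truth
            row["mean_bias"] = float(ratios.mean())
            row["median_bias"] = float(np.median(ratios))
            row["coverage"] = compute_coverage(
                list(zip(ok["ci_low"], ok["ci_high"])), truth
            )
            if cfg.mode == "uniform":
                row["cv"] = compute_cv(ratios)
                row["rmse"] = compute_rmse(ratios, 1.0)
            else:
                row["cv"] = compute_cv(est)
                row["rmse"] = compute_rmse(est, float(truth[0]))
        out.append(row)
    return pd.DataFrame(out)
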