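import numpy as np
import pytest

from pedaccum.bayes import MCMCSettings
from pedaccum.evaluate import (
    GridConfig,
    compute_bias,
    compute_coverage,
    compute_cv,
    compute_rmse,
    load_config,
    run_grid,
)

FAST_MCMC = MCMCSettings(chains=2, burnin=200, iterations=600, thin=6)


def test_bias_ratios():
    assert compute_bias([110.0], 100.0) == (pytest.approx(1.1), pytest.approx(1.1))
    assert compute_bias([100.0, 100.0], 100.0) == (1.0, 1.0)
    mean, med = compute_bias([50.0, 150.0], 100.0)
    assert mean == pytest.approx(1.0) and med == pytest.approx(1.0)
    with pytest.raises(ValueError):
        compute_bias([], 100.0)


def test_cv_uses_sample_sd():
    assert compute_cv([100.0, 100.0, 100.0]) == 0.0
    assert compute_cv([90.0, 110.0]) == pytest.approx(100.0 * np.sqrt(200.0) / 100.0)
    assert compute_cv([9.0, 11.0]) == pytest.approx(compute_cv([90.0, 110.0]))
    with pytest.raises(ValueError):
        compute_cv([5.0])


def test_rmse():
    assert compute_rmse([100.0, 100.0], 100.0) == 0.0
    assert compute_rmse([90.0, 110.0], 100.0) == pytest.approx(10.0)
    est = [80.0, 95.0, 130.0]
    assert compute_rmse(est, 100.0) >= abs(np.mean(est) - 100.0)


def test_coverage():
    assert compute_coverage([(100.0, 100.0)] * 3, 100.0) == 1.0
    assert compute_coverage([(1.0, 2.0), (3.0, 4.0)], 100.0) == 0.0
    intervals = [(90.0, 110.0)] * 863 + [(1.0, 2.0)] * 137
    assert compute_coverage(intervals, 100.0) == pytest.approx(0.863)
    # per-interval truths (uniform-draw mode)
    assert compute_coverage([(0.0, 10.0), (0.0, 10.0)], [5.0, 50.0]) == 0.5


def test_factorial_grid_bookkeeping():
    cfg = GridConfig(
        mode="factorial", n_p_values=(10, 20), n_obs_values=(15,), n_replicates=2,
        estimators=("chao1", "ichao"), fecundity=(30, 60), seed=1,
    )
    results, metrics = run_grid(cfg)
    assert len(results) == 2 * 1 * 2 * 2  # cells x replicates x methods
    assert set(results["method"]) == {"chao1", "ichao"}
    assert (results["estimate"] >= results["n_det"]).all()
    assert set(metrics.columns) >= {"mean_bias", "median_bias", "cv", "rmse", "coverage"}


def test_uniform_mode_is_deterministic():
    cfg = GridConfig(
        mode="uniform", n_replicates=6, estimators=("chao1",),
        uniform_low=10, uniform_high=40, fecundity=(50, 90), seed=9,
    )
    r1, m1 = run_grid(cfg)
    r2, m2 = run_grid(cfg)
    assert r1.equals(r2) and m1.equals(m2)


def test_parallel_matches_serial():
    base = dict(
        mode="factorial", n_p_values=(8,), n_obs_values=(12,), n_replicates=4,
        estimators=("chao1",), fecundity=(20, 40), seed=3,
    )
    r1, _ = run_grid(GridConfig(**base))
    r2, _ = run_grid(GridConfig(**base, n_jobs=2))
    assert r1.equals(r2)


def test_error_grid_shares_base_samples_across_rates():
    base = dict(
        mode="error", error_type="type2", n_p_values=(10,), n_obs_values=(20,),
        n_replicates=4, estimators=("chao1",), fecundity=(40, 80), seed=6,
    )
    r_both, _ = run_grid(GridConfig(**base, error_rates=(0.0, 0.05)))
    r_zero, _ = run_grid(GridConfig(**base, error_rates=(0.0,)))
    zero_rows = r_both[r_both["error_rate"] == 0.0].reset_index(drop=True)
    assert zero_rows[["n_det", "estimate"]].equals(
        r_zero[["n_det", "estimate"]].reset_index(drop=True)
    )
    # type II errors can only split parents
    by_rep = r_both.pivot_table(index="replicate", columns="error_rate", values="n_det")
    assert (by_rep[0.05] >= by_rep[0.0]).all()


def test_bayes_rows_carry_convergence_diagnostics():
    cfg = GridConfig(
        mode="factorial", n_p_values=(10,), n_obs_values=(30,), n_replicates=2,
        estimators=("bayes",), fecundity=(40, 80), seed=2, mcmc=FAST_MCMC,
    )
    results, metrics = run_grid(cfg)
    assert results["rhat_max"].notna().all()
    assert results["converged"].isin([True, False]).all()
    assert {"n_converged", "n_failed"} <= set(metrics.columns)
    assert (metrics["n_failed"] == 0).all()


def test_load_config_roundtrip(tmp_path):
    cfg_file = tmp_path / "grid.yaml"
    cfg_file.write_text(
        "mode: error\n"
        "error_type: type1\n"
        "n_p_values: [10]\n"
        "n_obs_values: [20]\n"
        "n_replicates: 3\n"
        "estimators: [chao1]\n"
        "error_rates: [0.0, 0.01]\n"
        "fecundity: [30, 50]\n"
        "seed: 4\n"
        "mcmc: {chains: 2, burnin: 100, iterations: 200, thin: 4}\n"
    )
    cfg = load_config(str(cfg_file))
    assert cfg.mode == "error" and cfg.error_type == "type1"
    assert cfg.error_rates == (0.0, 0.01)
    assert cfg.mcmc.chains == 2


def test_config_validation():
    with pytest.raises(ValueError):
        GridConfig(mode="bogus")
    with pytest.raises(ValueError):
        GridConfig(mode="error", error_type=None)
    with pytest.raises(ValueError):
        GridConfig(estimators=("chao1", "jackknife"))
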