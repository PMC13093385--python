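import shutil
import subprocess

import numpy as np
import pytest

from pedaccum.bayes import (
    AugmentedData,
    MCMCSettings,
    ParentAugmentationModel,
    augment,
    exact_posterior,
    fit,
    gelman_rubin,
    hpd_interval,
    presence_probability,
    summarize,
)
from pedaccum.detect import DetectionVector


def small_aug(y, n_obs, L):
    y = np.asarray(y, dtype=int)
    y_aug = np.zeros(L, dtype=int)
    y_aug[: y.size] = y
    return AugmentedData(y_aug, n_obs, int(y.size), L)


# -- augmentation -----------------------------------------------------------

def test_augment_pads_to_fifty_fold():
    d = DetectionVector(np.array([3, 1, 1, 1]), 3)
    aug = augment(d)
    assert aug.L == 200
    assert int((aug.y_aug == 0).sum()) == 196
    assert aug.y_aug[:4].sum() == 6


def test_augment_factor_one_pins_posterior_at_n_det():
    d = DetectionVector(np.array([2, 1, 1]), 2)
    with pytest.warns(UserWarning):
        aug = augment(d, factor=1)
    chains = fit(aug, MCMCSettings(chains=2, burnin=50, iterations=200, thin=2),
                 np.random.default_rng(0))
    assert np.all(chains.n_p == 3)
    vals, probs = exact_posterior(aug)
    assert vals.tolist() == [3] and probs[0] == pytest.approx(1.0)


def test_augment_rejects_factor_below_one():
    d = DetectionVector(np.array([1, 1]), 1)
    with pytest.raises(ValueError):
        augment(d, factor=0.5)


def test_fit_rejects_empty_detection():
    aug = AugmentedData(np.zeros(10, dtype=int), 5, 0, 10)
    with pytest.raises(ValueError):
        fit(aug, MCMCSettings(chains=2, burnin=10, iterations=20, thin=2),
            np.random.default_rng(0))


def test_settings_validation():
    with pytest.raises(ValueError):
        MCMCSettings(chains=1)
    with pytest.raises(ValueError):
        MCMCSettings(iterations=10, thin=50)
    with pytest.raises(ValueError):
        MCMCSettings(alpha_p=0.0)


# -- conditionals and the enumerated posterior ------------------------------

def test_presence_conditional_hand_value():
    assert presence_probability(0.5, 0.5, 1) == pytest.approx(1.0 / 3.0, abs=1e-12)


def test_exact_posterior_normalizes_and_is_stable_at_large_L():
    aug = small_aug([3, 1, 1], 5, 15)
    _, probs = exact_posterior(aug)
    assert probs.sum() == pytest.approx(1.0, abs=1e-12)
    big = small_aug([4, 2, 1, 1], 4, 10_000)
    _, probs_big = exact_posterior(big)
    assert np.all(np.isfinite(probs_big))
    assert probs_big.sum() == pytest.approx(1.0, abs=1e-9)


def test_gibbs_mean_matches_enumerated_posterior():
    aug = small_aug([3, 1, 1], 5, 15)
    vals, probs = exact_posterior(aug)
    exact_mean = float((vals * probs).sum())
    exact_sd = float(np.sqrt(((vals - exact_mean) ** 2 * probs).sum()))
    chains = fit(aug, MCMCSettings(chains=2, burnin=500, iterations=100_000, thin=1),
                 np.random.default_rng(7))
    draws = chains.n_p.ravel()
    # 5 SE guard band, doubled to allow for residual chain autocorrelation
    assert abs(draws.mean() - exact_mean) < 10 * exact_sd / np.sqrt(draws.size)


def test_every_draw_respects_support_bounds():
    aug = small_aug([2, 1, 1], 2, 40)
    chains = fit(aug, MCMCSettings(chains=3, burnin=100, iterations=500, thin=5),
                 np.random.default_rng(3))
    assert chains.n_p.min() >= 3
    assert chains.n_p.max() <= 40
    assert np.all((chains.psi > 0) & (chains.psi < 1))
    assert np.all((chains.p > 0) & (chains.p < 1))


def test_fit_is_deterministic_given_seed():
    d = DetectionVector(np.array([3, 2, 1, 1, 1]), 4)
    r1 = ParentAugmentationModel(d).fit(burnin=100, iterations=300, thin=3, seed=42)
    r2 = ParentAugmentationModel(d).fit(burnin=100, iterations=300, thin=3, seed=42)
    assert np.array_equal(r1.chains.n_p, r2.chains.n_p)
    assert np.array_equal(r1.chains.p, r2.chains.p)


def test_deeper_sampling_with_same_counts_lowers_p_and_raises_n_p():
    """More trials with unchanged counts imply a lower detection probability,
    which (with singletons present) shifts the abundance posterior up."""

    def stats_for(n_obs):
        aug = small_aug([1, 1, 1, 1], n_obs, 80)
        vals, probs = exact_posterior(aug)
        mean_np = float((vals * probs).sum())
        chains = fit(aug, MCMCSettings(chains=2, burnin=300, iterations=4000, thin=2),
                     np.random.default_rng(11))
        return mean_np, float(chains.p.mean())

    np_shallow, p_shallow = stats_for(4)
    np_deep, p_deep = stats_for(40)
    assert p_deep < p_shallow
    assert np_deep >= np_shallow


# -- diagnostics ------------------------------------------------------------

def test_gelman_rubin_identical_chains():
    c = np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
    assert gelman_rubin(c) == pytest.approx(np.sqrt(2.0 / 3.0))


def test_gelman_rubin_divergent_chains_hand_value():
    c = np.array([[1.0, 2.0, 3.0], [101.0, 102.0, 103.0]])
    # W = 1, B/n = 5000, V = 2/3 + (3/2) * 5000 -> R = sqrt(7500.6667)
    assert gelman_rubin(c) == pytest.approx(np.sqrt(2.0 / 3.0 + 1.5 * 5000.0), rel=1e-12)
    assert gelman_rubin(c) > 10


def test_gelman_rubin_constant_chain_sentinels():
    assert gelman_rubin(np.full((3, 10), 7.0)) == 1.0
    diverged = np.vstack([np.full(10, 1.0), np.full(10, 2.0)])
    assert gelman_rubin(diverged) == np.inf


def test_hpd_window_matches_brute_force():
    draws = np.arange(1.0, 101.0)
    lo, hi = hpd_interval(draws, 0.95)
    assert hi - lo == 94.0
    rng = np.random.default_rng(8)
    sample = rng.gamma(3.0, 2.0, size=400)
    lo, hi = hpd_interval(sample, 0.9)
    s = np.sort(sample)
    m = int(np.ceil(0.9 * s.size))
    widths = [s[i + m - 1] - s[i] for i in range(s.size - m + 1)]
    assert hi - lo == pytest.approx(min(widths))
    # shortest window is no wider than the equal-tail interval
    eq = np.quantile(sample, [0.05, 0.95])
    assert hi - lo <= eq[1] - eq[0] + 1e-12


def test_hpd_degenerate_draws():
    lo, hi = hpd_interval(np.full(10, 4.2))
    assert lo == hi == 4.2


def test_summary_median_can_be_half_integer():
    settings = MCMCSettings(chains=2, burnin=10, iterations=20, thin=10)
    from pedaccum.bayes import PosteriorChains

    chains = PosteriorChains(
        n_p=np.array([[4, 5], [5, 6]]),
        psi=np.full((2, 2), 0.5),
        p=np.full((2, 2), 0.5),
        n_det=4, n_obs=3, L=12, settings=settings,
    )
    s = summarize(chains)
    assert s.n_p_median == 5.0
    chains.n_p = np.array([[4, 5], [6, 7]])
    assert summarize(chains).n_p_median == 5.5
    assert s.hpd_low <= s.n_p_median <= s.hpd_high


def test_gibbs_matches_jags_reference():
    """Cross-check the conjugate sampler against the same model declared in
    JAGS (via rjags), on a small instance."""
    if shutil.which("Rscript") is None:
        pytest.fail("Rscript unavailable: JAGS cross-check cannot run")
    script = r"""
suppressMessages(library(rjags))
y <- c(3,1,1, rep(0,12)); Nobs <- 5; L <- length(y)
mod <- "model {
  for (j in 1:L) { z[j] ~ dbern(psi); y[j] ~ dbin(p*z[j], Nobs) }
  psi ~ dbeta(1,1); p ~ dbeta(1,1)
  N <- sum(z)
}"
jm <- jags.model(textConnection(mod), data=list(y=y, Nobs=Nobs, L=L),
                 n.chains=2, n.adapt=500, quiet=TRUE,
                 inits=list(list(z=rep(1,L), .RNG.name="base::Mersenne-Twister", .RNG.seed=1),
                            list(z=rep(1,L), .RNG.name="base::Mersenne-Twister", .RNG.seed=2)))
update(jm, 1000)
s <- coda.samples(jm, c("N"), n.iter=20000)
cat(mean(unlist(lapply(s, function(x) as.numeric(x[,"N"])))))
"""
    out = subprocess.run(
        ["Rscript", "-e", script], capture_output=True, text=True, timeout=300
    )
    assert out.returncode == 0, out.stderr
    jags_mean = float(out.stdout.strip().split()[-1])
    aug = small_aug([3, 1, 1], 5, 15)
    vals, probs = exact_posterior(aug)
    exact_mean = float((vals * probs).sum())
    chains = fit(aug, MCMCSettings(chains=2, burnin=500, iterations=20_000, thin=1),
                 np.random.default_rng(5))
    gibbs_mean = chains.n_p.mean()
    assert jags_mean == pytest.approx(exact_mean, abs=0.1)
    assert gibbs_mean == pytest.approx(exact_mean, abs=0.1)
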