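"""Closed-form nonparametric abundance estimators (Chao1 and iChao1).

Both treat the detection vector like a species-abundance sample: the number
of never-detected parents is extrapolated from the rare-count frequencies.
Chao1 uses singletons and doubletons,

    N̂ = N_DET + [a1(a1-1) / (2(a2+1))] · (N_OBS-1)/N_OBS,

the bias-corrected form that stays finite when a2 = 0. iChao1 adds a
tripleton/quadrupleton correction and is always >= Chao1. 95% confidence
intervals use the log-transform of the excess N̂ - N_DET, which respects
the hard lower bound N̂ >= N_DET and the rightward skew of the sampling
distribution.

Model/results layout: ``Chao1(d)`` / ``IChao1(d)`` are model objects whose
``fit()`` returns a :class:`ChaoEstimate`; the module-level functions
``chao1(d)`` and ``ichao(d)`` are shorthands for ``Model(d).fit()``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .detect import DetectionVector

__all__ = ["ChaoEstimate", "Chao1", "IChao1", "chao1", "ichao", "chao_log_ci"]


@dataclass(frozen=True)
class ChaoEstimate:
    """Point estimate, variance and 95% log-transform CI for one estimator."""

    method: str  # 'chao1' | 'ichao'
    n_det: int
    n_obs: int
    n_p_hat: float
    variance: float
    ci_low: float
    ci_high: float
    degenerate_ci: bool = False  # True when n_p_hat == n_det (zero excess)

    def conf_int(self) -> tuple[float, float]:
        return (self.ci_low, self.ci_high)

    def summary(self) -> str:
        lines = [
            f"{self.method} parental-abundance estimate",
            "-" * 42,
            f"detected parents (N_DET)   {self.n_det:>10d}",
            f"offspring sampled (N_OBS)  {self.n_obs:>10d}",
            f"N_P estimate               {self.n_p_hat:>10.3f}",
            f"variance                   {self.variance:>10.3f}",
            f"95% CI                     [{self.ci_low:.3f}, {self.ci_high:.3f}]",
        ]
        if self.degenerate_ci:
            lines.append("note: zero excess over N_DET; interval is degenerate")
        return "\n".join(lines)


def chao_log_ci(
    n_det: int, n_p_hat: float, variance: float, level: float = 0.95
) -> tuple[float, float, bool]:
    """Log-transform confidence interval around a Chao-type estimate.

    With excess T = N̂ - N_DET and
    R = exp(z * sqrt(ln(1 + var/T²))), the interval is
    [N_DET + T/R, N_DET + T·R]. Returns (low, high, degenerate) where
    degenerate flags the T = 0 collapse to [N_DET, N_DET].
    """
    if variance < 0:
        raise ValueError("variance must be >= 0")
    if n_p_hat < n_det:
        raise ValueError("n_p_hat must be >= n_det")
    excess = n_p_hat - n_det
    if excess == 0.0:
        return (float(n_det), float(n_det), True)
    z = stats.norm.ppf(0.5 + level / 2.0)
    r = np.exp(z * np.sqrt(np.log1p(variance / excess**2)))
    return (n_det + excess / r, n_det + excess * r, False)


def _k(n_obs: int) -> float:
    return (n_obs - 1) / n_obs


def _chao1_point(n_det: int, a1: int, a2: int, n_obs: int) -> float:
    return n_det + (a1 * (a1 - 1)) / (2.0 * (a2 + 1)) * _k(n_obs)


def _chao1_variance(n_det: int, a1: int, a2: int, n_obs: int) -> float:
    """Bias-corrected Chao1 variance.

    Branches (documented, not interchangeable):
      a2 > 0: a2 [ (k²/4)(a1/a2)^4 + k²(a1/a2)^3 + (k/2)(a1/a2)^2 ]
      a2 = 0, a1 > 0: k a1(a1-1)/2 + k² a1(2a1-1)²/4 − k² a1^4/(4 N̂)
      a1 = 0: 0 (estimate collapses to N_DET; CI degenerates)
    with k = (N_OBS−1)/N_OBS.
    """
    k = _k(n_obs)
    if a1 == 0:
        return 0.0
    if a2 > 0:
        r = a1 / a2
        return a2 * ((k**2 / 4.0) * r**4 + k**2 * r**3 + (k / 2.0) * r**2)
    n_hat = _chao1_point(n_det, a1, a2, n_obs)
    return (
        k * a1 * (a1 - 1) / 2.0
        + k**2 * a1 * (2 * a1 - 1) ** 2 / 4.0
        - k**2 * a1**4 / (4.0 * n_hat)
    )


def _ichao_extra(a1: int, a2: int, a3: int, a4: int) -> float:
    """Tripleton/quadrupleton additive correction; a4=0 is handled by the
    same +1-style device as the bias-corrected Chao1 denominator."""
    if a3 == 0:
        return 0.0
    a4_eff = a4 if a4 > 0 else 1
    return (a3 / (4.0 * a4_eff)) * max(a1 - a2 * a3 / (2.0 * a4_eff), 0.0)


def _estimate_from_hist(hist: dict[int, int], n_obs: int, method: str) -> float:
    """Point estimate as a function of the full frequency histogram (used
    both directly and for delta-method differentiation)."""
    n_det = float(sum(hist.values()))
    a = {k: float(hist.get(k, 0)) for k in (1, 2, 3, 4)}
    est = n_det + (a[1] * (a[1] - 1)) / (2.0 * (a[2] + 1)) * _k(n_obs)
    if method == "ichao":
        if a[3] > 0:
            a4_eff = a[4] if a[4] > 0 else 1.0
            est += (a[3] / (4.0 * a4_eff)) * max(a[1] - a[2] * a[3] / (2.0 * a4_eff), 0.0)
    return est


def _delta_variance(d: DetectionVector, method: str) -> float:
    """Delta-method variance over the frequency counts.

    cov(a_i, a_j) ≈ a_i(δ_ij − a_i/N̂) on the diagonal and −a_i a_j/N̂ off
    it; the gradient is taken numerically (central differences) on the
    smooth closed form. Used for iChao, whose printed variance has no
    compact closed form.
    """
    hist = d.histogram()
    n_hat = _estimate_from_hist(hist, d.n_obs, method)
    ks = sorted(set(hist) | {1, 2, 3, 4})
    grad = np.empty(len(ks))
    h = 1e-4
    for i, k in enumerate(ks):
        up, dn = dict(hist), dict(hist)
        up[k] = up.get(k, 0) + h
        dn[k] = dn.get(k, 0) - h
        grad[i] = (
            _estimate_from_hist(up, d.n_obs, method)
            - _estimate_from_hist(dn, d.n_obs, method)
        ) / (2 * h)
    a = np.array([hist.get(k, 0) for k in ks], dtype=float)
    cov = np.diag(a) - np.outer(a, a) / n_hat
    var = float(grad @ cov @ grad)
    return max(var, 0.0)


class Chao1:
    """Chao1 abundance model for a detection vector."""

    method = "chao1"

    def __init__(self, detection: DetectionVector):
        self.detection = detection

    def fit(self) -> ChaoEstimate:
        d = self.detection
        a1, a2 = d.a(1), d.a(2)
        n_hat = _chao1_point(d.n_det, a1, a2, d.n_obs)
        var = _chao1_variance(d.n_det, a1, a2, d.n_obs)
        lo, hi, degen = chao_log_ci(d.n_det, n_hat, var)
        return ChaoEstimate(self.method, d.n_det, d.n_obs, n_hat, var, lo, hi, degen)


class IChao1(Chao1):
    """iChao1 abundance model: Chao1 plus the a3/a4 correction."""

    method = "ichao"

    def fit(self) -> ChaoEstimate:
        d = self.detection
        a1, a2, a3, a4 = (d.a(k) for k in (1, 2, 3, 4))
        n_hat = _chao1_point(d.n_det, a1, a2, d.n_obs) + _ichao_extra(a1, a2, a3, a4)
        if a3 == 0:
            # identical to Chao1, including its variance branch set
            base = Chao1(d).fit()
            return ChaoEstimate(
                self.method, d.n_det, d.n_obs, base.n_p_hat, base.variance,
                base.ci_low, base.ci_high, base.degenerate_ci,
            )
        var = _delta_variance(d, "ichao")
        lo, hi, degen = chao_log_ci(d.n_det, n_hat, var)
        return ChaoEstimate(self.method, d.n_det, d.n_obs, n_hat, var, lo, hi, degen)


def chao1(d: DetectionVector) -> ChaoEstimate:
    """Bias-corrected Chao1 estimate with variance and 95% log-transform CI."""
    return Chao1(d).fit()


def ichao(d: DetectionVector) -> ChaoEstimate:
    """iChao1 estimate (always >= Chao1) with delta-method variance and CI."""
    return IChao1(d).fit()
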