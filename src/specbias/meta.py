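"""Random-effects meta-analysis across embedding models.

Each embedding model contributes one effect estimate per contrast (a Cohen's
d with sampling variance v_i).  Models are treated as a random sample of
"language mediums" with between-model variance tau^2, pooled with weights
w*_i = 1/(v_i + tau^2):

    estimate = sum(w* y) / sum(w*),   se = sqrt(1 / sum(w*)).

tau^2 comes from the DerSimonian-Laird moment estimator by default (REML
optional); heterogeneity is summarised by Cochran's Q and
I^2 = max(0, (Q - df) / Q).  Confidence intervals are normal Wald intervals
and p-values two-sided normal — the convention the audit's reported CIs and
Z statistics follow.

Correlations are pooled on the Fisher-z scale (variance 1/(n-3)) and the
pooled estimate and CI are back-transformed through tanh.

`meta_power` is the design-stage analytic power of the pooled Wald test for
a standardized mean difference d observed in k models with n1/n2 words per
group, treating a target I^2 as a fixed design parameter: the per-model
sampling variance v implies tau^2 = v * I2 / (1 - I2), so each model's
total variance is v/(1 - I2) and SE_meta = sqrt(v / ((1 - I2) k)).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .effects import CorrelationEstimate, GroupContrast

__all__ = [
    "MetaResult",
    "PowerQuery",
    "tau2_dl",
    "tau2_reml",
    "pool",
    "pool_estimates",
    "pool_correlations",
    "meta_power",
]

Z975 = float(stats.norm.ppf(0.975))


@dataclass(frozen=True)
class MetaResult:
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    z: float
    p: float
    tau2: float
    Q: float
    df: int
    I2: float
    k: int
    method: str
    # set for correlation pooling: estimate/CI back-transformed through tanh
    scale: str = "d"


@dataclass(frozen=True)
class PowerQuery:
    """Design for a meta-analytic power calculation.

    d is the true standardized mean difference; n1, n2 the per-group word
    counts; k the number of models; I2 the anticipated heterogeneity as a
    proportion of total variance; alpha the two-sided level.
    """

    d: float
    n1: int
    n2: int
    k: int
    I2: float = 0.0
    alpha: float = 0.05


def tau2_dl(estimates: Sequence[float], variances: Sequence[float]) -> float:
    """DerSimonian-Laird moment estimator of between-study variance.

    With fixed-effect weights w_i = 1/v_i and fixed mean m,
    Q = sum w_i (y_i - m)^2 and
    tau2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w)).
    """
    y = np.asarray(estimates, dtype=np.float64)
    v = np.asarray(variances, dtype=np.float64)
    if y.size < 2:
        raise ValueError("need at least 2 estimates")
    if np.any(v <= 0):
        raise ValueError("variances must be positive")
    w = 1.0 / v
    m = np.sum(w * y) / np.sum(w)
    q = float(np.sum(w * (y - m) ** 2))
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    if denom <= 0:
        return 0.0
    return max(0.0, (q - (y.size - 1)) / float(denom))


def tau2_reml(estimates: Sequence[float], variances: Sequence[float], tol: float = 1e-10) -> float:
    """REML estimate of tau^2 (numerical maximization of the restricted
    log-likelihood profile in tau^2)."""
    y = np.asarray(estimates, dtype=np.float64)
    v = np.asarray(variances, dtype=np.float64)
    if y.size < 2:
        raise ValueError("need at least 2 estimates")

    def nll(t2: float) -> float:
        wi = 1.0 / (v + t2)
        mu = np.sum(wi * y) / np.sum(wi)
        return 0.5 * (
            np.sum(np.log(v + t2)) + np.log(np.sum(wi)) + np.sum(wi * (y - mu) ** 2)
        )

    hi = max(tau2_dl(y, v) * 10 + 1.0, 10.0 * float(np.var(y, ddof=1) + v.max()))
    res = optimize.minimize_scalar(nll, bounds=(0.0, hi), method="bounded",
                                   options={"xatol": tol})
    t2 = float(res.x)
    return t2 if nll(t2) <= nll(0.0) else 0.0


def pool_estimates(
    estimates: Sequence[float],
    variances: Sequence[float],
    method: str = "DL",
) -> MetaResult:
    """Random-effects pool of generic (estimate, variance) pairs."""
    y = np.asarray(estimates, dtype=np.float64)
    v = np.asarray(variances, dtype=np.float64)
    if y.size == 0:
        raise ValueError("nothing to pool")
    if method not in ("DL", "REML"):
        raise ValueError(f"unknown tau2 method {method!r}")
    k = int(y.size)
    if k == 1:
        tau2, q = 0.0, 0.0
    else:
        tau2 = tau2_dl(y, v) if method == "DL" else tau2_reml(y, v)
        w = 1.0 / v
        m = np.sum(w * y) / np.sum(w)
        q = float(np.sum(w * (y - m) ** 2))
    ws = 1.0 / (v + tau2)
    est = float(np.sum(ws * y) / np.sum(ws))
    se = float(np.sqrt(1.0 / np.sum(ws)))
    z = est / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    df = k - 1
    i2 = max(0.0, (q - df) / q) if q > 0 else 0.0
    return MetaResult(
        estimate=est, se=se, ci_low=est - Z975 * se, ci_high=est + Z975 * se,
        z=float(z), p=p, tau2=float(tau2), Q=q, df=df, I2=float(i2), k=k, method=method,
    )


def pool(contrasts: Sequence[GroupContrast], method: str = "DL") -> MetaResult:
    """Pool one contrast's per-model Cohen's d values across models.

    All contrasts must share the attribute and the (group1, group2) pair;
    a single contrast passes through with its own variance and tau2 = 0.
    """
    if not contrasts:
        raise ValueError("no contrasts to pool")
    keys = {(c.attribute, c.group1, c.group2) for c in contrasts}
    if len(keys) > 1:
        raise ValueError(f"mixed contrasts cannot be pooled: {sorted(keys)}")
    return pool_estimates([c.d for c in contrasts], [c.var_d for c in contrasts], method)


def pool_correlations(corrs: Sequence[CorrelationEstimate], method: str = "DL") -> MetaResult:
    """Pool per-model Pearson correlations on the Fisher-z scale.

    z and p are reported on the z-scale; estimate and CI are tanh
    back-transformed to the correlation scale.
    """
    if not corrs:
        raise ValueError("no correlations to pool")
    if any(c.n < 4 for c in corrs):
        raise ValueError("every correlation needs n >= 4")
    res = pool_estimates([c.fisher_z for c in corrs], [c.var_z for c in corrs], method)
    return MetaResult(
        estimate=float(np.tanh(res.estimate)), se=res.se,
        ci_low=float(np.tanh(res.ci_low)), ci_high=float(np.tanh(res.ci_high)),
        z=res.z, p=res.p, tau2=res.tau2, Q=res.Q, df=res.df, I2=res.I2,
        k=res.k, method=res.method, scale="r",
    )


def meta_power(q: PowerQuery) -> float:
    """Analytic power of the two-sided pooled Wald test under the design.

    Per-model sampling variance v = (n1+n2)/(n1 n2) + d^2/(2(n1+n2)); the
    design I2 converts to tau^2 = v I2/(1-I2), so each model's total
    variance is v/(1-I2) and the meta SE is sqrt(v / ((1-I2) k)).  Power is
    P(|Z| > z_{1-a/2}) for Z ~ N(d/SE, 1).
    """
    if q.n1 < 2 or q.n2 < 2:
        raise ValueError("need at least 2 words per group")
    if q.k < 1:
        raise ValueError("need at least one model")
    if not 0.0 <= q.I2 < 1.0:
        raise ValueError("I2 must be in [0, 1)")
    if not 0.0 < q.alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    v = (q.n1 + q.n2) / (q.n1 * q.n2) + q.d**2 / (2.0 * (q.n1 + q.n2))
    se = np.sqrt(v / (1.0 - q.I2) / q.k)
    zc = stats.norm.ppf(1.0 - q.alpha / 2.0)
    lam = q.d / se
    return float(stats.norm.cdf(lam - zc) + stats.norm.cdf(-lam - zc))
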