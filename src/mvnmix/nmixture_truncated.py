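"""The classical N-mixture likelihood with a finite summation bound K.

The per-site likelihood sums the mixing pmf times a product of binomial
detection terms over latent abundance N from max(y) to K.  K replaces an
infinite sum, and a K chosen too small biases the abundance estimate
downward, so besides a fixed-K mode (kept to demonstrate exactly that
pathology) the bound can be chosen automatically as the smallest K whose
upper-tail mixing probability falls below a configurable epsilon, refreshed
from the current abundance estimate during optimization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import gammaln, logsumexp

from .data_model import CountMatrix, ModelParams, validate_counts

#: hard cap on K so a runaway abundance estimate cannot allocate unbounded sums
K_CAP = 10**6


@dataclass(frozen=True)
class TruncationPolicy:
    """How to pick the summation bound.

    mode "fixed" uses K as given; mode "auto" uses the smallest K with
    upper-tail mixing probability below epsilon (floored at the maximum
    observed count).  epsilon defaults to 1e-5, far below optimizer
    tolerance; it is configurable because no single threshold suits every
    use.
    """

    mode: str = "auto"
    K: int | None = None
    epsilon: float = 1e-5

    def __post_init__(self) -> None:
        if self.mode not in ("fixed", "auto"):
            raise ValueError("truncation mode must be 'fixed' or 'auto'")
        if self.mode == "fixed":
            if self.K is None or self.K < 1:
                raise ValueError("fixed mode requires a positive integer K")
        else:
            if not (0.0 < self.epsilon <= 0.1):
                raise ValueError("epsilon must lie in (0, 0.1]")


def mixing_sf(K: int, params: ModelParams, family: str) -> float:
    """P(N > K) under the mixing distribution."""
    if family == "poisson":
        return float(stats.poisson.sf(K, params.lam))
    if family == "negbin":
        b = params.b
        return float(stats.nbinom.sf(K, params.a, b / (1.0 + b)))
    if family == "zip":
        return float((1.0 - (params.psi or 0.0)) * stats.poisson.sf(K, params.lam))
    raise ValueError(f"unknown family {family!r}")


def mixing_logpmf(N: np.ndarray, params: ModelParams, family: str) -> np.ndarray:
    if family == "poisson":
        return stats.poisson.logpmf(N, params.lam)
    if family == "negbin":
        b = params.b
        return stats.nbinom.logpmf(N, params.a, b / (1.0 + b))
    if family == "zip":
        psi = params.psi or 0.0
        out = np.log1p(-psi) + stats.poisson.logpmf(N, params.lam)
        return np.where(N == 0, np.logaddexp(np.log(psi), out) if psi > 0 else out, out)
    raise ValueError(f"unknown family {family!r}")


def choose_K_auto(
    params: ModelParams,
    policy: TruncationPolicy,
    counts: CountMatrix | None = None,
    k_cap: int = K_CAP,
) -> int:
    """Smallest K with P(N > K) < epsilon, floored at the max observed count."""
    if policy.mode != "auto":
        raise ValueError("choose_K_auto requires an auto-mode policy")
    params.validate("poisson" if params.a is None and params.psi is None else
                    "negbin" if params.a is not None else "zip")
    family = "negbin" if params.a is not None else ("zip" if params.psi is not None else "poisson")
    floor = counts.max_count if counts is not None else 0
    eps = policy.epsilon
    # bracket from the family quantile, then exact integer scan
    if family == "negbin":
        b = params.b
        k = int(stats.nbinom.ppf(1.0 - eps, params.a, b / (1.0 + b)))
    else:
        k = int(stats.poisson.ppf(1.0 - eps, params.lam))
    k = max(k, floor)
    while mixing_sf(k, params, family) >= eps:
        k += 1
        if k > k_cap:
            raise ValueError(f"auto-selected K exceeds the cap {k_cap}")
    while k > floor and mixing_sf(k - 1, params, family) < eps:
        k -= 1
    if k > k_cap:
        raise ValueError(f"auto-selected K exceeds the cap {k_cap}")
    return k


def _row_logliks(rows: np.ndarray, params: ModelParams, family: str, K: int) -> np.ndarray:
    """Per-row truncated log pmfs, summing N = 0..K (terms with N < max(y)
    vanish through the binomial coefficient)."""
    if K < rows.max():
        raise ValueError(f"K={K} is below the maximum observed count {rows.max()}")
    if K > K_CAP:
        raise ValueError(f"K={K} exceeds the cap {K_CAP}")
    N = np.arange(K + 1, dtype=np.float64)
    logmix = mixing_logpmf(N, params, family)
    y = rows[:, :, None].astype(np.float64)  # (R, T, 1)
    Nb = N[None, None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        logbin = (
            gammaln(Nb + 1.0)
            - gammaln(Nb - y + 1.0)
            - gammaln(y + 1.0)
            + y * np.log(params.p)
            + (Nb - y) * np.log1p(-params.p)
        )
    logbin = np.where(Nb >= y, logbin, -np.inf)
    return logsumexp(logmix[None, :] + logbin.sum(axis=1), axis=1)


def site_likelihood_truncated(
    y, params: ModelParams, family: str, K: int
) -> float:
    """Truncated per-site likelihood: sum_{N=max(y)}^{K} f(N) prod_t Bin(y_t; N, p).

    Monotonically non-decreasing in K at fixed parameters.
    """
    y = np.asarray(y, dtype=np.int64).reshape(1, -1)
    if (y < 0).any():
        raise ValueError("negative count")
    params.validate(family)
    return float(np.exp(_row_logliks(y, params, family, int(K))[0]))


def dataset_loglik_truncated(
    counts,
    params: ModelParams,
    family: str,
    policy: TruncationPolicy | None = None,
    K: int | None = None,
) -> float:
    """Dataset log-likelihood under the truncated formulation.

    Pass either an explicit K or a TruncationPolicy; auto mode picks K from
    the current parameters and the observed maximum count.
    """
    counts = validate_counts(counts)
    params.validate(family)
    if K is None:
        policy = policy if policy is not None else TruncationPolicy()
        if policy.mode == "fixed":
            K = policy.K
        else:
            K = choose_K_auto(params, policy, counts)
    rows, mult = np.unique(counts.counts, axis=0, return_counts=True)
    row_ll = _row_logliks(rows, params, family, int(K))
    total = float(mult @ row_ll)
    if not np.isfinite(total):
        raise FloatingPointError("truncated site likelihood underflowed to zero")
    return total
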