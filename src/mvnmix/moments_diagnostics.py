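"""Sample moments, infinite-estimate diagnostics, and moment estimators.

Three sample moments summarize an S x T count matrix:

    m1   grand mean of all counts               -> p * mu
    m2   mean of squared counts                 -> p(1-p) mu + p^2 (mu + E[nu^2])
    m11  mean over sites and occasion pairs of
         the cross product y_it * y_iu          -> p^2 (mu + E[nu^2])

where mu is the mean and nu the (possibly random) Poisson mean of the site
abundance.  Two scalar diagnostics follow:

    D1 = m11 - m1^2    the pooled-mean (intraclass) covariance of counts on
                       different occasions; non-positive values predict an
                       infinite abundance MLE in the Poisson model.
    D2 = m1 - m2 + m11 equals m1 times the moment estimate of p; a
                       non-positive value means the moment estimate of
                       abundance is infinite (negative-binomial case).

Solving the three moment equations gives closed-form estimators
p = D2/m1, mu = m1/p, and the gamma-mixing variance; the corresponding
validity conditions are exactly the diagnostics plus positivity of the
implied mixing variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .data_model import CountMatrix, validate_counts


def _require_pairs(counts: CountMatrix) -> None:
    if counts.T < 2:
        raise ValueError("diagnostics and moment estimation require T >= 2 occasions")


@dataclass(frozen=True)
class MomentSet:
    m1: float
    m2: float
    m11: float


def sample_moments(counts) -> MomentSet:
    """m1, m2 and the mean pairwise cross-moment m11 (all T(T-1)/2 unordered
    pairs weighted equally)."""
    counts = validate_counts(counts)
    _require_pairs(counts)
    y = counts.counts.astype(np.float64)
    m1 = float(y.mean())
    m2 = float((y**2).mean())
    iu, ju = np.triu_indices(counts.T, 1)
    m11 = float((y[:, iu] * y[:, ju]).mean())
    return MomentSet(m1=m1, m2=m2, m11=m11)


def diagnostic_signs(counts) -> tuple[int, int]:
    """Exact signs of (D1, D2) via integer arithmetic.

    Both diagnostics are rationals with different denominators, and both
    have genuine point masses at exactly zero (all-zero data for D1; 0/1
    counts with no within-site repeat detection for D2), where the floating
    difference of the sample moments is sign-noise at the 1e-16 level.
    Clearing denominators gives integer numerators whose signs are exact:

        sign(D1) = sign( S11 * S * T^2 - n_pairs * S1^2 )
        sign(D2) = sign( n_pairs * (S1 - S2) + T * S11 )

    with S1 = sum y, S2 = sum y^2, S11 = sum of pairwise products and
    n_pairs = T(T-1)/2.
    """
    counts = validate_counts(counts)
    _require_pairs(counts)
    y = counts.counts
    S, T = counts.S, counts.T
    n_pairs = T * (T - 1) // 2
    S1 = int(y.sum())
    S2 = int((y.astype(np.int64) ** 2).sum())
    iu, ju = np.triu_indices(T, 1)
    S11 = int((y[:, iu] * y[:, ju]).sum())
    d1_num = S11 * S * T * T - n_pairs * S1 * S1
    d2_num = n_pairs * (S1 - S2) + T * S11
    return (d1_num > 0) - (d1_num < 0), (d2_num > 0) - (d2_num < 0)


def cov_diagnostic(counts) -> float:
    """D1 = m11 - m1^2, the intraclass covariance estimate.

    The pooled grand mean is the right centring because every occasion
    shares the same expectation p*mu.  For T = 2 this is the sample
    covariance of the two visit counts about the pooled mean; for T > 2 it
    averages all pairwise cross-moments first.
    """
    m = sample_moments(counts)
    return m.m11 - m.m1**2


def nb_diagnostic2(counts) -> float:
    """D2 = m1 - m2 + m11 = m1 * p_hat.

    Positive iff the moment estimate of detection is positive, hence iff
    the moment estimate of abundance is finite.  The complementary upper
    bound p_hat <= 1 is m11 <= m2, a Cauchy-Schwarz consequence that always
    holds and carries no diagnostic value.
    """
    m = sample_moments(counts)
    return m.m1 - m.m2 + m.m11


@dataclass(frozen=True)
class DiagnosticReport:
    """Signs of the two diagnostics and the infinite-estimate verdicts.

    A diagnostic counts as negative when non-positive: an exact zero arises
    from degenerate data (for D2, a matrix of 0/1 counts with no within-site
    repeat detection) for which the moment estimate of abundance is already
    infinite, so zero triggers the flag.  Quantitative sign-classification
    experiments may instead use strict negativity; see
    simulation_study.run_nb_diag_study.
    """

    D1: float
    D2: float
    d1_negative: bool
    d2_negative: bool
    predicted_infinite_poisson: bool
    predicted_infinite_negbin_moments: bool

    def to_dict(self) -> dict:
        return {
            "D1": self.D1,
            "D2": self.D2,
            "d1_negative": self.d1_negative,
            "d2_negative": self.d2_negative,
            "predicted_infinite_poisson": self.predicted_infinite_poisson,
            "predicted_infinite_negbin_moments": self.predicted_infinite_negbin_moments,
        }


def diagnose(counts) -> DiagnosticReport:
    counts = validate_counts(counts)
    s1, s2 = diagnostic_signs(counts)
    return DiagnosticReport(
        D1=cov_diagnostic(counts),
        D2=nb_diagnostic2(counts),
        d1_negative=s1 <= 0,
        d2_negative=s2 <= 0,
        predicted_infinite_poisson=s1 <= 0,
        predicted_infinite_negbin_moments=s2 <= 0,
    )


@dataclass(frozen=True)
class MomentEstimates:
    p_hat: float
    lambda_hat: float
    a_hat: float | None
    sigma2_hat: float | None
    valid: bool
    infinite_lambda: bool
    method: str
    reasons: tuple[str, ...] = field(default_factory=tuple)


def mom_poisson(counts) -> MomentEstimates:
    """Correlation-based moment estimator for the Poisson model.

    Detection is estimated by the mean sample correlation of counts across
    occasion pairs (for Poisson mixing the population correlation between
    two visits equals p exactly), and abundance by m1 / p_hat.  Correlations
    use the population (denominator-S) form for internal consistency with
    the raw moments; an occasion with zero variance leaves the correlation
    undefined and invalidates the estimate.
    """
    counts = validate_counts(counts)
    _require_pairs(counts)
    y = counts.counts.astype(np.float64)
    m1 = float(y.mean())
    sd = y.std(axis=0)  # population form
    means = y.mean(axis=0)
    reasons: list[str] = []
    corrs = []
    for t, u in combinations(range(counts.T), 2):
        if sd[t] == 0.0 or sd[u] == 0.0:
            reasons.append(
                f"zero variance on occasion {t + 1} or {u + 1}: correlation undefined"
            )
            continue
        cov = float((y[:, t] * y[:, u]).mean() - means[t] * means[u])
        corrs.append(cov / (sd[t] * sd[u]))
    if not corrs:
        return MomentEstimates(
            p_hat=np.nan, lambda_hat=np.nan, a_hat=None, sigma2_hat=None,
            valid=False, infinite_lambda=False, method="correlation",
            reasons=tuple(reasons),
        )
    p_hat = float(np.mean(corrs))
    if p_hat <= 0.0:
        reasons.append("mean correlation non-positive: abundance estimate infinite")
        return MomentEstimates(
            p_hat=p_hat, lambda_hat=np.inf, a_hat=None, sigma2_hat=None,
            valid=False, infinite_lambda=True, method="correlation",
            reasons=tuple(reasons),
        )
    return MomentEstimates(
        p_hat=p_hat, lambda_hat=m1 / p_hat, a_hat=None, sigma2_hat=None,
        valid=True, infinite_lambda=False, method="correlation",
        reasons=tuple(reasons),
    )


def mom_mixed_poisson(counts) -> MomentEstimates:
    """Closed-form moment estimators for the gamma-mixed (NB-2) model.

    p_hat = (m1 - m2 + m11) / m1, mu_hat = m1 / p_hat, and the implied
    mixing variance sigma2_hat = m11 / p_hat^2 - mu_hat - mu_hat^2 with
    gamma shape a_hat = mu_hat^2 / sigma2_hat.  Validity requires D1 > 0,
    D2 > 0 and sigma2_hat > 0; failures are flagged separately, never
    clipped.  sigma2_hat <= 0 with the other two positive is
    Poisson-compatible data (no evidence of overdispersion).
    """
    counts = validate_counts(counts)
    _require_pairs(counts)
    m = sample_moments(counts)
    reasons: list[str] = []
    if m.m1 == 0.0:
        return MomentEstimates(
            p_hat=np.nan, lambda_hat=np.nan, a_hat=None, sigma2_hat=None,
            valid=False, infinite_lambda=False, method="cross-moment",
            reasons=("no detections: moments carry no information",),
        )
    sign1, sign2 = diagnostic_signs(counts)
    d2 = m.m1 - m.m2 + m.m11
    p_hat = d2 / m.m1
    if sign2 <= 0:
        reasons.append("D2 <= 0: moment estimate of abundance is infinite")
        return MomentEstimates(
            p_hat=p_hat, lambda_hat=np.inf, a_hat=None, sigma2_hat=None,
            valid=False, infinite_lambda=True, method="cross-moment",
            reasons=tuple(reasons),
        )
    mu_hat = m.m1 / p_hat
    sigma2_hat = m.m11 / p_hat**2 - mu_hat - mu_hat**2
    if sign1 <= 0:
        reasons.append("D1 <= 0: implied variance of abundance is non-positive")
    a_hat = None
    if sigma2_hat > 0.0:
        a_hat = mu_hat**2 / sigma2_hat
    else:
        reasons.append(
            "implied mixing variance <= 0: no gamma shape (Poisson-compatible data)"
        )
    return MomentEstimates(
        p_hat=p_hat,
        lambda_hat=mu_hat,
        a_hat=a_hat,
        sigma2_hat=float(sigma2_hat),
        valid=sign1 > 0 and sign2 > 0,
        infinite_lambda=False,
        method="cross-moment",
        reasons=tuple(reasons),
    )
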