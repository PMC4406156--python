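"""Exact site pmfs and dataset log-likelihoods without a truncation bound.

The Poisson N-mixture likelihood is identical to a multivariate Poisson
likelihood over the subset decomposition: the per-site pmf is a finite sum
over latent configurations of products of independent Poisson masses with
rates theta_s = lambda * w_s, where w_s = p^|s| (1-p)^(T-|s|).  Gamma mixing
of the site mean gives the multivariate negative-binomial (NB-2) analogue,
and a point mass at zero mixed with Poisson abundance gives the
zero-inflated-Poisson form.  None of them involves the truncation constant K
of the classical formulation.

Everything is computed in log space with log-sum-exp over configurations;
gamma functions of a + M and the factorials overflow quickly otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp

from .data_model import CountMatrix, ModelParams, validate_counts
from .subset_decomposition import (
    SubsetSystem,
    build_subset_system,
    enumerate_configs,
)

_LOGIT_CLIP = 1e-12


def _log_rates(sys: SubsetSystem, lam: float, p: float) -> np.ndarray:
    """log theta_s = log lam + |s| log p + (T - |s|) log(1 - p)."""
    return np.log(lam) + sys.sizes * np.log(p) + (sys.T - sys.sizes) * np.log1p(-p)


def _log_weights(sys: SubsetSystem, p: float) -> np.ndarray:
    return sys.sizes * np.log(p) + (sys.T - sys.sizes) * np.log1p(-p)


def detected_fraction(p: float, T: int) -> float:
    """W = 1 - (1-p)^T, the chance an individual is seen on at least one visit."""
    return -np.expm1(T * np.log1p(-p))


class DatasetCache:
    """Per-dataset enumeration cache for fast repeated likelihood evaluation.

    The latent configuration sets depend only on the observed counts, not on
    the parameters, so they are enumerated once per unique site row and the
    per-parameter work reduces to dense linear algebra plus a segmented
    log-sum-exp.  This is what makes iterative maximization of the exact
    likelihoods cheap even when a boundary search drives lambda very large.
    """

    def __init__(self, counts: CountMatrix, sys: SubsetSystem | None = None):
        counts = validate_counts(counts)
        self.counts = counts
        self.sys = sys if sys is not None else build_subset_system(counts.T)
        rows, inverse, mult = np.unique(
            counts.counts, axis=0, return_inverse=True, return_counts=True
        )
        self.rows = rows
        self.mult = mult.astype(np.float64)
        self.row_is_zero = ~rows.any(axis=1)
        blocks = [enumerate_configs(self.sys, r).configs for r in rows]
        lens = np.array([b.shape[0] for b in blocks], dtype=np.int64)
        if (lens == 0).any():
            raise AssertionError("every count vector admits at least one configuration")
        self.starts = np.concatenate(([0], np.cumsum(lens)[:-1]))
        self.N = np.concatenate(blocks, axis=0).astype(np.float64)
        self.M = self.N.sum(axis=1)
        self.neg_logfact = -gammaln(self.N + 1.0).sum(axis=1)

    def _segment_logsumexp(self, vals: np.ndarray) -> np.ndarray:
        mx = np.maximum.reduceat(vals, self.starts)
        lens = np.diff(np.concatenate((self.starts, [vals.shape[0]])))
        shifted = vals - np.repeat(mx, lens)
        return mx + np.log(np.add.reduceat(np.exp(shifted), self.starts))

    def row_logpmf_poisson(self, lam: float, p: float) -> np.ndarray:
        theta_total = lam * detected_fraction(p, self.sys.T)
        terms = self.N @ _log_rates(self.sys, lam, p) + self.neg_logfact
        return -theta_total + self._segment_logsumexp(terms)

    def row_logpmf_negbin(self, lam: float, a: float, p: float) -> np.ndarray:
        b = a / lam
        W = detected_fraction(p, self.sys.T)
        terms = (
            self.N @ _log_weights(self.sys, p)
            + self.neg_logfact
            + gammaln(a + self.M)
            - gammaln(a)
            + a * np.log(b)
            - (a + self.M) * np.log(b + W)
        )
        return self._segment_logsumexp(terms)

    def row_logpmf_zip(self, lam: float, p: float, psi: float) -> np.ndarray:
        base = self.row_logpmf_poisson(lam, p)
        if psi == 0.0:
            return base
        out = np.log1p(-psi) + base
        if self.row_is_zero.any():
            out = np.where(
                self.row_is_zero,
                np.logaddexp(np.log(psi), np.log1p(-psi) + base),
                out,
            )
        return out

    def loglik(self, params: ModelParams, family: str) -> float:
        params.validate(family)
        if family == "poisson":
            rows = self.row_logpmf_poisson(params.lam, params.p)
        elif family == "negbin":
            rows = self.row_logpmf_negbin(params.lam, params.a, params.p)
        else:
            rows = self.row_logpmf_zip(params.lam, params.p, params.psi or 0.0)
        total = float(self.mult @ rows)
        if not np.isfinite(total):
            raise FloatingPointError(
                "site pmf underflowed to zero despite log-space evaluation"
            )
        return total


def _site_cache(y, sys: SubsetSystem | None) -> DatasetCache:
    y = np.asarray(y, dtype=np.int64).reshape(1, -1)
    return DatasetCache(validate_counts(y), sys)


def mvpois_logpmf(y, lam: float, p: float, sys: SubsetSystem | None = None) -> float:
    """Log pmf of the multivariate Poisson count vector y at (lam, p)."""
    ModelParams(lam=lam, p=p).validate("poisson")
    return float(_site_cache(y, sys).row_logpmf_poisson(lam, p)[0])


def mvpois_pmf(y, lam: float, p: float, sys: SubsetSystem | None = None) -> float:
    return float(np.exp(mvpois_logpmf(y, lam, p, sys)))


def mvnb_logpmf(
    y, lam: float, a: float, p: float, sys: SubsetSystem | None = None
) -> float:
    """Log pmf of the multivariate negative-binomial (NB-2 mixing) vector y.

    Gamma shape a and rate b = a/lam; the Poisson model is the a -> infinity
    limit at fixed lam.
    """
    ModelParams(lam=lam, p=p, a=a).validate("negbin")
    return float(_site_cache(y, sys).row_logpmf_negbin(lam, a, p)[0])


def mvnb_pmf(y, lam: float, a: float, p: float, sys: SubsetSystem | None = None) -> float:
    return float(np.exp(mvnb_logpmf(y, lam, a, p, sys)))


def zip_logpmf(
    y, lam: float, p: float, psi: float, sys: SubsetSystem | None = None
) -> float:
    """Zero-inflated Poisson: point mass psi at N=0 mixed with Poisson(lam).

    Integrates to psi * 1{y == 0} + (1 - psi) * mvpois_pmf(y; lam, p).
    """
    ModelParams(lam=lam, p=p, psi=psi).validate("zip")
    return float(_site_cache(y, sys).row_logpmf_zip(lam, p, psi)[0])


def zip_pmf(y, lam: float, p: float, psi: float, sys: SubsetSystem | None = None) -> float:
    return float(np.exp(zip_logpmf(y, lam, p, psi, sys)))


def bivariate_pois_pmf(y1: int, y2: int, lam: float, p: float) -> float:
    """Closed-form bivariate Poisson pmf for T = 2.

    theta_1 = theta_2 = lam p (1-p), theta_12 = lam p^2; the sum over the
    shared component runs from 0 to min(y1, y2).
    """
    ModelParams(lam=lam, p=p).validate("poisson")
    if y1 < 0 or y2 < 0:
        raise ValueError("negative count")
    th1 = lam * p * (1.0 - p)
    th12 = lam * p * p
    k = np.arange(min(y1, y2) + 1)
    logterms = (
        (y1 - k) * np.log(th1)
        + (y2 - k) * np.log(th1)
        + k * np.log(th12)
        - gammaln(y1 - k + 1)
        - gammaln(y2 - k + 1)
        - gammaln(k + 1)
    )
    return float(np.exp(-(2 * th1 + th12) + logsumexp(logterms)))


def dataset_loglik(
    counts,
    params: ModelParams,
    family: str,
    cache: DatasetCache | None = None,
) -> float:
    """Log-likelihood of an S x T dataset: sites are independent, so the
    dataset log-likelihood is the multiplicity-weighted sum of unique-row
    log pmfs."""
    if cache is None:
        cache = DatasetCache(validate_counts(counts))
    return cache.loglik(params, family)
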