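"""Synthetic count-survey generator and Monte-Carlo experiment runners.

The generator draws site abundances from the mixing distribution (Poisson,
gamma-mixed Poisson, or zero-inflated Poisson) and thins them with
independent per-visit binomial detection — the hierarchical route, exactly
the process the models describe.  The experiment runners reproduce the
sign-diagnostic studies (proportion of datasets whose diagnostics predict an
infinite abundance estimate, and how often the MLE is indeed infinite), the
fixed-K bias experiment, and the design-subsampling workflow.

Randomness is counter-based: one root seed plus (scenario index, replicate
index) spawn keys, so scenarios can run in any order, or in parallel, with
identical results.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import CountMatrix
from .fitting import fit
from .moments_diagnostics import cov_diagnostic, diagnostic_signs, nb_diagnostic2
from .nmixture_truncated import TruncationPolicy


@dataclass(frozen=True)
class ScenarioSpec:
    """One simulation scenario.

    family in {poisson, negbin, zip}; lam is mean abundance, p per-visit
    detection, a the gamma shape (negbin), psi the zero-inflation mass
    (zip); T visits at S sites, n_sim replicates from root seed `seed`.
    """

    family: str = "poisson"
    lam: float = 2.0
    p: float = 0.1
    a: float | None = None
    psi: float | None = None
    T: int = 2
    S: int = 20
    n_sim: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in ("poisson", "negbin", "zip"):
            raise ValueError(f"unknown family {self.family!r}")
        if not (self.lam > 0):
            raise ValueError("lam must be > 0")
        if not (0.0 < self.p <= 1.0):
            raise ValueError("p must lie in (0, 1]")
        if self.family == "negbin" and not (self.a and self.a > 0):
            raise ValueError("negbin scenario requires a > 0")
        if self.family == "zip" and not (self.psi is not None and 0 <= self.psi < 1):
            raise ValueError("zip scenario requires psi in [0, 1)")
        if self.S < 1 or self.T < 1 or self.n_sim < 1:
            raise ValueError("S, T and n_sim must be positive")


def _rng(seed: int, scen_idx: int, rep: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(int(scen_idx), int(rep)))
    )


def simulate_counts(spec: ScenarioSpec, rep: int = 0, scen_idx: int = 0) -> CountMatrix:
    """One S x T count matrix: N_i from the mixing distribution, then
    independent Binomial(N_i, p) counts per visit."""
    rng = _rng(spec.seed, scen_idx, rep)
    if spec.family == "poisson":
        N = rng.poisson(spec.lam, spec.S)
    elif spec.family == "negbin":
        nu = rng.gamma(shape=spec.a, scale=spec.lam / spec.a, size=spec.S)
        N = rng.poisson(nu)
    else:
        N = np.where(rng.random(spec.S) < spec.psi, 0, rng.poisson(spec.lam, spec.S))
    y = rng.binomial(N[:, None], spec.p, size=(spec.S, spec.T))
    return CountMatrix(y)


def poisson_diag_scenarios(S: int = 20, n_sim: int = 1000, seed: int = 0) -> list[ScenarioSpec]:
    """The Poisson diagnostic study grid: lam x p x T at S sites."""
    return [
        ScenarioSpec(family="poisson", lam=lam, p=p, T=T, S=S, n_sim=n_sim, seed=seed)
        for lam in (2, 5, 10)
        for p in (0.10, 0.25)
        for T in (2, 3, 4)
    ]


def negbin_diag_scenarios(S: int = 20, n_sim: int = 1000, seed: int = 0) -> list[ScenarioSpec]:
    """The negative-binomial diagnostic study grid: lam x p x a x T at S sites."""
    return [
        ScenarioSpec(family="negbin", lam=lam, p=p, a=a, T=T, S=S, n_sim=n_sim, seed=seed)
        for lam in (2, 5, 10)
        for p in (0.10, 0.25)
        for a in (1.25, 5.00)
        for T in (2, 3)
    ]


def _mc_se(prop: float, n: int) -> float:
    return float(np.sqrt(max(prop * (1.0 - prop), 0.0) / n)) if n > 0 else np.nan


def run_epn_epd(
    scenarios: list[ScenarioSpec],
    n_sim: int | None = None,
    fit_mle: bool = True,
    maxiter: int = 500,
) -> pd.DataFrame:
    """Poisson diagnostic study: per scenario, EPN = proportion of datasets
    with a non-positive covariance diagnostic, and (optionally) EPD = the
    proportion whose Poisson MLE of abundance is operationally infinite.

    Fit errors are counted in an `n_fit_error` column, never dropped
    silently.
    """
    rows = []
    for idx, spec in enumerate(scenarios):
        if spec.family != "poisson":
            raise ValueError("run_epn_epd expects poisson scenarios")
        nsim = n_sim if n_sim is not None else spec.n_sim
        n_neg = n_inf = n_err = 0
        for rep in range(nsim):
            cm = simulate_counts(spec, rep=rep, scen_idx=idx)
            n_neg += diagnostic_signs(cm)[0] <= 0
            if fit_mle:
                try:
                    fr = fit(cm, family="poisson", formulation="multivariate",
                             maxiter=maxiter, stop="ftol", seed=rep)
                    n_inf += fr.boundary_infinite
                except ValueError:
                    n_err += 1
        epn = n_neg / nsim
        row = {
            "family": spec.family, "lam": spec.lam, "p": spec.p, "T": spec.T,
            "S": spec.S, "n_sim": nsim, "EPN": epn, "EPN_se": _mc_se(epn, nsim),
        }
        if fit_mle:
            n_ok = nsim - n_err
            epd = n_inf / n_ok if n_ok else np.nan
            row.update({"EPD": epd, "EPD_se": _mc_se(epd, n_ok), "n_fit_error": n_err})
        rows.append(row)
    return pd.DataFrame(rows)


def run_nb_diag_study(
    scenarios: list[ScenarioSpec],
    n_sim: int | None = None,
    fit_negative: bool = True,
    max_fits_positive: int | None = 0,
    strict: bool = True,
    maxiter: int = 500,
) -> pd.DataFrame:
    """Negative-binomial diagnostic study.

    Per scenario: the joint sign classification of (D1, D2) and, for the
    both-negative replicates (and an optional random subsample of the
    both-positive ones), the proportion whose negative-binomial MLE of
    abundance is operationally infinite.  `strict` classifies "negative" as
    strictly below zero, which is the convention the sign-classification
    study uses: D2 carries a point mass at exactly zero (0/1 counts with no
    within-site repeat detection) that would otherwise dominate the sparse
    scenarios.  Conditional proportions are NaN when the conditioning event
    has no replicates.
    """
    rows = []
    for idx, spec in enumerate(scenarios):
        if spec.family != "negbin":
            raise ValueError("run_nb_diag_study expects negbin scenarios")
        nsim = n_sim if n_sim is not None else spec.n_sim
        neg_reps, pos_reps = [], []
        datasets = {}
        for rep in range(nsim):
            cm = simulate_counts(spec, rep=rep, scen_idx=idx)
            s1, s2 = diagnostic_signs(cm)
            neg1 = s1 < 0 if strict else s1 <= 0
            neg2 = s2 < 0 if strict else s2 <= 0
            if neg1 and neg2:
                neg_reps.append(rep)
                datasets[rep] = cm
            elif s1 > 0 and s2 > 0:
                # exact zeros are ties, not evidence of positivity: they fall
                # in the mixed category and enter neither conditional study
                pos_reps.append(rep)
                datasets[rep] = cm

        def _inf_prop(reps: list[int]) -> tuple[float, int, int]:
            n_inf = n_err = 0
            for rep in reps:
                try:
                    fr = fit(datasets[rep], family="negbin",
                             formulation="multivariate", maxiter=maxiter,
                             stop="ftol", seed=rep)
                    n_inf += fr.boundary_infinite
                except ValueError:
                    n_err += 1
            n_ok = len(reps) - n_err
            return (n_inf / n_ok if n_ok else np.nan), n_ok, n_err

        p_both_neg = len(neg_reps) / nsim
        p_both_pos = len(pos_reps) / nsim
        row = {
            "family": spec.family, "lam": spec.lam, "p": spec.p, "a": spec.a,
            "T": spec.T, "S": spec.S, "n_sim": nsim,
            "p_both_neg": p_both_neg, "p_both_neg_se": _mc_se(p_both_neg, nsim),
            "p_both_pos": p_both_pos, "p_both_pos_se": _mc_se(p_both_pos, nsim),
            "p_inf_given_both_neg": np.nan, "n_fit_neg": 0,
            "p_inf_given_both_pos": np.nan, "n_fit_pos": 0,
            "n_fit_error": 0,
        }
        if fit_negative and neg_reps:
            prop, n_ok, n_err = _inf_prop(neg_reps)
            row.update({"p_inf_given_both_neg": prop, "n_fit_neg": n_ok,
                        "n_fit_error": row["n_fit_error"] + n_err})
        if max_fits_positive and pos_reps:
            sub_rng = _rng(spec.seed, idx, nsim)  # off the replicate stream
            take = min(max_fits_positive, len(pos_reps))
            chosen = sorted(sub_rng.choice(pos_reps, size=take, replace=False))
            prop, n_ok, n_err = _inf_prop(list(chosen))
            row.update({"p_inf_given_both_pos": prop, "n_fit_pos": n_ok,
                        "n_fit_error": row["n_fit_error"] + n_err})
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_nb_study(df: pd.DataFrame) -> dict:
    """Scenario-averaged conditional infinite-estimate proportions, skipping
    scenarios where the conditioning event never occurred."""
    neg = df["p_inf_given_both_neg"].dropna()
    pos = df["p_inf_given_both_pos"].dropna()
    return {
        "mean_inf_given_both_neg": float(neg.mean()) if len(neg) else np.nan,
        "n_scenarios_both_neg": int(len(neg)),
        "mean_inf_given_both_pos": float(pos.mean()) if len(pos) else np.nan,
        "n_scenarios_both_pos": int(len(pos)),
    }


def run_k_sensitivity(
    scenario: ScenarioSpec,
    K_list: list[int],
    n_sim: int | None = None,
    maxiter: int = 500,
) -> dict[int, np.ndarray]:
    """Fixed-K bias experiment: fit the truncated likelihood with each bound
    K to the same simulated datasets and return the per-K abundance
    estimates.  When the likelihood is flat the estimate piles up near a
    K-dependent ceiling, so the upper mode moves right as K grows."""
    if scenario.family != "poisson":
        raise ValueError("the fixed-K experiment is defined for poisson scenarios")
    nsim = n_sim if n_sim is not None else scenario.n_sim
    out: dict[int, list[float]] = {int(K): [] for K in K_list}
    for rep in range(nsim):
        cm = simulate_counts(scenario, rep=rep, scen_idx=0)
        if not cm.counts.any():
            continue  # no detections: abundance not estimable for any K
        for K in K_list:
            K = int(K)
            fr = fit(cm, family="poisson", formulation="truncated",
                     policy=TruncationPolicy(mode="fixed", K=max(K, cm.max_count)),
                     maxiter=maxiter, seed=rep)
            out[K].append(fr.estimates.lam)
    return {K: np.asarray(v) for K, v in out.items()}


def upper_mode_summary(lam_hats: np.ndarray, lam_true: float) -> dict:
    """Location and mass of the upper mode of a bimodal estimate sample,
    operationally: estimates exceeding 10x the true abundance."""
    lam_hats = np.asarray(lam_hats, dtype=float)
    upper = lam_hats[lam_hats > 10.0 * lam_true]
    return {
        "upper_mass": float(len(upper) / len(lam_hats)) if len(lam_hats) else np.nan,
        "upper_mode_location": float(np.median(upper)) if len(upper) else np.nan,
        "n": int(len(lam_hats)),
    }


def subsample_design(
    counts: CountMatrix,
    S_keep: int,
    T_keep: int,
    n_draws: int = 1000,
    seed: int = 0,
) -> float:
    """Proportion of random site/visit subsamples with a non-positive
    covariance diagnostic — the study-design workflow: fewer sites or
    visits raise the risk of an infinite abundance estimate."""
    if not (1 <= S_keep <= counts.S) or not (2 <= T_keep <= counts.T):
        raise ValueError("infeasible subsample sizes (need S_keep <= S, 2 <= T_keep <= T)")
    rng = np.random.default_rng(seed)
    n_neg = 0
    for _ in range(n_draws):
        sites = rng.choice(counts.S, size=S_keep, replace=False)
        visits = rng.choice(counts.T, size=T_keep, replace=False)
        sub = CountMatrix(counts.counts[np.ix_(np.sort(sites), np.sort(visits))])
        n_neg += diagnostic_signs(sub)[0] <= 0
    return n_neg / n_draws
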