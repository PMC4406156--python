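"""Latent decomposition of repeat counts over non-empty subsets of occasions.

Each individual present at a site is seen on some subset s of the T visits
(possibly none).  Writing n_s for the number of individuals seen exactly on
the occasions in s, the observed count on visit t is the sum of n_s over all
subsets containing t.  Under Poisson abundance the n_s are independent
Poisson variables with rates lambda * p^|s| * (1-p)^(T-|s|), which is what
makes the exact multivariate likelihoods tractable.

This module builds the subset index system and enumerates, for an observed
count vector y, every non-negative integer configuration (n_s) consistent
with the per-occasion sums — the set over which the exact pmfs sum.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

#: enumeration guard: 2^T - 1 latent dimensions beyond this is refused
T_MAX_DEFAULT = 10

#: guard on the size of an enumerated configuration set
MAX_CONFIGS_DEFAULT = 5_000_000


@dataclass(frozen=True)
class SubsetSystem:
    """The 2^T - 1 non-empty subsets of occasions {1..T} in canonical order.

    Canonical order is by subset size ascending, then lexicographically by
    occasion labels, giving a reproducible index for the latent rates across
    modules.  ``membership[t-1]`` lists the indices of the 2^(T-1) subsets
    that contain occasion t.
    """

    T: int
    subsets: tuple[tuple[int, ...], ...]
    sizes: np.ndarray
    membership: tuple[tuple[int, ...], ...]

    @property
    def n_subsets(self) -> int:
        return len(self.subsets)


def build_subset_system(T: int, t_max: int = T_MAX_DEFAULT) -> SubsetSystem:
    """Construct the canonical subset system for T occasions."""
    if not isinstance(T, (int, np.integer)) or T < 1:
        raise ValueError("T must be a positive integer")
    if T > t_max:
        raise ValueError(
            f"T={T} exceeds the enumeration guard t_max={t_max} "
            f"(2^T - 1 = {2**T - 1} latent dimensions)"
        )
    subsets: list[tuple[int, ...]] = []
    for size in range(1, T + 1):
        subsets.extend(combinations(range(1, T + 1), size))
    sizes = np.array([len(s) for s in subsets], dtype=np.int64)
    membership = tuple(
        tuple(i for i, s in enumerate(subsets) if t in s) for t in range(1, T + 1)
    )
    sizes.setflags(write=False)
    return SubsetSystem(T=T, subsets=tuple(subsets), sizes=sizes, membership=membership)


def thinning_weights(sys: SubsetSystem, p: float) -> np.ndarray:
    """Probability that an individual is seen exactly on each subset s.

    w_s = p^|s| (1-p)^(T-|s|); the multivariate Poisson rates are
    theta_s = lambda * w_s.  Sum over all s equals 1 - (1-p)^T, the
    probability of being detected at least once.
    """
    if not (0.0 < p < 1.0):
        raise ValueError("p must lie strictly in (0, 1)")
    return p ** sys.sizes * (1.0 - p) ** (sys.T - sys.sizes)


@dataclass(frozen=True)
class LatentConfigSet:
    """All latent configurations consistent with one observed count vector.

    ``configs`` has one row per configuration and one column per subset in
    canonical order; row i satisfies, for every occasion t,
    sum over subsets s containing t of configs[i, s] == y[t].
    """

    y: tuple[int, ...]
    configs: np.ndarray

    @property
    def n_configs(self) -> int:
        return self.configs.shape[0]


def enumerate_configs(
    sys: SubsetSystem, y, max_configs: int = MAX_CONFIGS_DEFAULT
) -> LatentConfigSet:
    """Enumerate every non-negative integer solution of the occasion sums.

    Depth-first over subsets in canonical order, carrying per-occasion
    remaining budgets; the feasible range for n_s is 0..min of the budgets of
    the occasions in s, and a branch dies as soon as an occasion with a
    positive budget is no longer covered by any remaining subset.
    """
    y = np.asarray(y, dtype=np.int64)
    if y.ndim != 1 or y.shape[0] != sys.T:
        raise ValueError(f"y must have length T={sys.T}")
    if (y < 0).any():
        raise ValueError("negative count in y")

    m = sys.n_subsets
    # occasions (0-based) covered by subsets at position >= i
    coverage: list[set[int]] = [set() for _ in range(m + 1)]
    for i in range(m - 1, -1, -1):
        coverage[i] = coverage[i + 1] | {t - 1 for t in sys.subsets[i]}

    budgets = y.copy()
    current = np.zeros(m, dtype=np.int64)
    out: list[np.ndarray] = []

    def dfs(i: int) -> None:
        if i == m:
            if not budgets.any():
                out.append(current.copy())
            return
        # prune: an occasion still owed counts but not covered downstream
        for t in range(sys.T):
            if budgets[t] > 0 and t not in coverage[i]:
                return
        members = [t - 1 for t in sys.subsets[i]]
        bound = int(min(budgets[t] for t in members))
        for n in range(bound + 1):
            current[i] = n
            for t in members:
                budgets[t] -= n
            dfs(i + 1)
            for t in members:
                budgets[t] += n
            if len(out) > max_configs:
                raise ValueError(
                    f"configuration set exceeds max_configs={max_configs}"
                )
        current[i] = 0

    dfs(0)
    configs = (
        np.array(out, dtype=np.int64) if out else np.empty((0, m), dtype=np.int64)
    )
    configs.setflags(write=False)
    return LatentConfigSet(y=tuple(int(v) for v in y), configs=configs)
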