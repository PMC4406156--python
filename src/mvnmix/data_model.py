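"""Validated data containers shared across the package.

The universal input is an S x T matrix of non-negative integer counts:
S sites surveyed on T occasions under a closed population, every individual
sharing the same per-visit detection probability p.  The design is balanced;
missing visits are rejected rather than imputed.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

FAMILIES = ("poisson", "negbin", "zip")


@dataclass(frozen=True)
class CountMatrix:
    """S x T matrix of non-negative integer survey counts.

    Rows are sites, columns are repeat visits (occasions).  Occasions are
    labelled 1..T on every external surface; storage is 0-based.
    """

    counts: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "counts", np.ascontiguousarray(self.counts, dtype=np.int64))
        self.counts.setflags(write=False)

    @property
    def S(self) -> int:
        return self.counts.shape[0]

    @property
    def T(self) -> int:
        return self.counts.shape[1]

    @property
    def max_count(self) -> int:
        return int(self.counts.max())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return self.counts.shape == other.counts.shape and bool(
            np.array_equal(self.counts, other.counts)
        )

    def __hash__(self) -> int:  # frozen dataclass with array field
        return hash((self.counts.shape, self.counts.tobytes()))


def validate_counts(raw) -> CountMatrix:
    """Validate a rectangular matrix of counts and wrap it in a CountMatrix.

    Raises ValueError for ragged rows, empty input, negative or non-integer
    entries.  Idempotent: validating a CountMatrix's own counts returns an
    equal object.
    """
    if isinstance(raw, CountMatrix):
        raw = raw.counts
    try:
        arr = np.asarray(raw)
    except ValueError as exc:
        raise ValueError("ragged rows: counts must form a rectangular matrix") from exc
    if arr.dtype == object:
        raise ValueError("ragged rows: counts must form a rectangular matrix")
    if arr.ndim == 1:
        raise ValueError("counts must be two-dimensional (sites x occasions)")
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError("empty matrix: need at least one site and one occasion")
    if np.issubdtype(arr.dtype, np.floating):
        if not np.all(np.isfinite(arr)) or not np.all(arr == np.floor(arr)):
            raise ValueError("non-integer count entry")
    elif not np.issubdtype(arr.dtype, np.integer):
        raise ValueError("non-integer count entry")
    if (arr < 0).any():
        raise ValueError("negative count")
    return CountMatrix(arr.astype(np.int64))


def read_counts_csv(path_or_buf) -> CountMatrix:
    """Read counts from plain CSV: one row per site, one column per occasion.

    An optional header row is auto-detected (a first line with any
    non-numeric cell is treated as a header).  Cells must be integers.
    """
    if isinstance(path_or_buf, (str,)):
        with open(path_or_buf, "r", encoding="utf-8") as fh:
            text = fh.read()
    else:
        text = path_or_buf.read()
    first = text.splitlines()[0] if text.strip() else ""
    header = None
    for tok in first.split(","):
        tok = tok.strip()
        if tok == "":
            continue
        try:
            int(tok)
        except ValueError:
            header = 0
            break
    df = pd.read_csv(io.StringIO(text), header=header)
    return validate_counts(df.to_numpy())


def write_counts_csv(cm: CountMatrix, path) -> None:
    df = pd.DataFrame(cm.counts, columns=[f"visit_{t}" for t in range(1, cm.T + 1)])
    df.to_csv(path, index=False)


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the N-mixture model.

    lam    mean site abundance (> 0); the mean of the mixing distribution in
           every family, so abundance estimates are comparable across models.
    p      per-individual, per-visit detection probability, in (0, 1).
    a      gamma shape of the negative-binomial mixing (NB-2), > 0; the gamma
           rate is b = a / lam so the mixing mean stays lam, and the
           coefficient of variation of the Poisson mean is 1/sqrt(a).
    psi    zero-inflation mass in [0, 1) (zip family only).
    """

    lam: float
    p: float
    a: float | None = None
    psi: float | None = None

    def validate(self, family: str) -> "ModelParams":
        if family not in FAMILIES:
            raise ValueError(f"unknown family {family!r}; expected one of {FAMILIES}")
        if not (self.lam > 0 and np.isfinite(self.lam)):
            raise ValueError("lambda must be finite and > 0")
        if not (0.0 < self.p < 1.0):
            raise ValueError("p must lie strictly in (0, 1)")
        if family == "negbin":
            if self.a is None or not (self.a > 0 and np.isfinite(self.a)):
                raise ValueError("negbin family requires gamma shape a > 0")
        if family == "zip":
            if self.psi is None or not (0.0 <= self.psi < 1.0):
                raise ValueError("zip family requires psi in [0, 1)")
        return self

    @property
    def b(self) -> float:
        """Gamma rate implied by (lam, a); mixing mean is a/b = lam."""
        if self.a is None:
            raise ValueError("rate b is defined only for the negbin family")
        return self.a / self.lam


@dataclass(frozen=True)
class MixingSpec:
    """A family name bound to a validated parameter vector."""

    family: str
    params: ModelParams = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.params is not None:
            self.params.validate(self.family)

    @property
    def n_free_params(self) -> int:
        return {"poisson": 2, "negbin": 3, "zip": 3}[self.family]
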