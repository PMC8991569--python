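"""Two-level screening and three-level response-surface designs.

Construction and validation of Plackett-Burman (PB) and Box-Behnken (BB)
design matrices in coded units, plus the coded <-> natural level mapping
for individual factors.

Coded levels are stored as small integers in {-1, 0, +1}; natural levels
are floats in the factor's own units.  All statistics downstream operate
on the coded matrix, so validation here (balance, orthogonality) is what
guarantees the simple contrast formulas used by the screening and
response-surface stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Factor",
    "DesignMatrix",
    "code_levels",
    "decode_levels",
    "make_pb_design",
    "make_bb_design",
    "validate_pb",
    "validate_bb",
]


@dataclass(frozen=True)
class Factor:
    """A controllable culture variable with a coded-level mapping.

    Parameters
    ----------
    name : str
        Short label, e.g. ``"CaCl2"``.
    unit : str
        Natural unit, e.g. ``"g/L"`` or ``"mL/500mL"``.
    low, high : float
        Natural values at coded -1 and +1.
    center : float, optional
        Natural value at coded 0; defaults to the midpoint ``(low+high)/2``.
    """

    name: str
    unit: str
    low: float
    high: float
    center: float | None = None

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"factor {self.name!r}: low ({self.low}) must be < high ({self.high})")
        if self.center is None:
            object.__setattr__(self, "center", (self.low + self.high) / 2)
        elif not (self.low < self.center < self.high):
            raise ValueError(
                f"factor {self.name!r}: center ({self.center}) must lie strictly "
                f"between low ({self.low}) and high ({self.high})"
            )

    @property
    def half_range(self) -> float:
        return (self.high - self.low) / 2


def code_levels(factor: Factor, natural_value):
    """Map natural units onto the coded scale: ``(x - center) / ((high-low)/2)``.

    The three defining levels map exactly to -1, 0 and +1.  Accepts scalars
    or arrays.
    """
    if factor.half_range == 0:
        raise ValueError(f"factor {factor.name!r} has zero range")
    return (np.asarray(natural_value, dtype=float) - factor.center) / factor.half_range


def decode_levels(factor: Factor, coded_value):
    """Inverse of :func:`code_levels`: coded scale back to natural units."""
    return np.asarray(coded_value, dtype=float) * factor.half_range + factor.center


@dataclass
class DesignMatrix:
    """A runs x factors array of coded levels with run identifiers.

    ``coded`` entries are restricted to {-1, 0, +1}.  Center runs (all
    coordinates 0) are flagged by :attr:`is_center` and are excluded from
    screening statistics.
    """

    factors: list[Factor]
    coded: np.ndarray
    runs: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.coded = np.asarray(self.coded)
        if self.coded.ndim != 2 or self.coded.shape[1] != len(self.factors):
            raise ValueError(
                f"coded matrix shape {self.coded.shape} does not match "
                f"{len(self.factors)} factors"
            )
        if not np.isin(self.coded, (-1, 0, 1)).all():
            bad = np.unique(self.coded[~np.isin(self.coded, (-1, 0, 1))])
            raise ValueError(f"coded levels must be in {{-1, 0, +1}}; found {bad}")
        self.coded = self.coded.astype(np.int8)
        if self.runs is None:
            self.runs = np.arange(1, self.n_runs + 1)
        else:
            self.runs = np.asarray(self.runs)
            if len(self.runs) != self.n_runs:
                raise ValueError("run identifiers do not align with rows")

    @property
    def n_runs(self) -> int:
        return self.coded.shape[0]

    @property
    def n_factors(self) -> int:
        return self.coded.shape[1]

    @property
    def is_center(self) -> np.ndarray:
        """Boolean mask, true iff every coded entry in the row is 0."""
        return (self.coded == 0).all(axis=1)

    @property
    def factor_names(self) -> list[str]:
        return [f.name for f in self.factors]

    def natural(self) -> np.ndarray:
        """Design in natural units (float array, runs x factors)."""
        out = np.empty(self.coded.shape, dtype=float)
        for j, f in enumerate(self.factors):
            out[:, j] = decode_levels(f, self.coded[:, j])
        return out

    def to_frame(self, levels: str = "coded") -> pd.DataFrame:
        values = self.coded if levels == "coded" else self.natural()
        df = pd.DataFrame(values, columns=self.factor_names)
        df.insert(0, "run", self.runs)
        return df

    def factorial_mask(self) -> np.ndarray:
        return ~self.is_center


def as_response_vector(values, design: DesignMatrix) -> np.ndarray:
    """Validate a per-run response (yield in g/L) against a design.

    Responses must align one-to-one with design rows, be finite, and be
    nonnegative (they are pigment yields).
    """
    y = np.asarray(values, dtype=float)
    if y.ndim != 1 or len(y) != design.n_runs:
        raise ValueError(
            f"response length {y.shape} does not match {design.n_runs} design runs"
        )
    if not np.isfinite(y).all():
        raise ValueError("responses must all be finite")
    if (y < 0).any():
        raise ValueError("negative responses rejected: yields are nonnegative")
    return y


# ---------------------------------------------------------------------------
# Plackett-Burman construction
# ---------------------------------------------------------------------------

# Standard cyclic first-row generators (Plackett & Burman's construction):
# row i is the (i-1)-fold cyclic shift of the generator, and the final row
# is all -1.  Keys are run counts N; generators have length N-1.
_PB_GENERATORS: dict[int, tuple[int, ...]] = {
    8: (1, 1, 1, -1, 1, -1, -1),
    12: (1, 1, -1, 1, 1, 1, -1, -1, -1, 1, -1),
    16: (1, 1, 1, 1, -1, 1, -1, 1, 1, -1, -1, 1, -1, -1, -1),
    20: (1, 1, -1, -1, 1, 1, 1, 1, -1, 1, -1, 1, -1, -1, -1, -1, 1, 1, -1),
}


def make_pb_design(
    n_factors: int,
    n_runs: int = 12,
    n_center: int = 0,
    factors: Sequence[Factor] | None = None,
) -> DesignMatrix:
    """Build a Plackett-Burman screening design.

    The cyclic generator for ``n_runs`` is rotated to give ``n_runs - 1``
    rows, the all-minus row is appended, and the matrix is truncated to the
    first ``n_factors`` columns.  ``n_center`` all-zero rows are appended
    last (curvature / reference runs).

    Parameters
    ----------
    n_factors : int
        Number of variables to screen, 2..11 and at most ``n_runs - 1``.
    n_runs : int
        Factorial run count; one of 8, 12, 16, 20.
    n_center : int
        Number of all-center runs appended after the factorial block.
    factors : sequence of Factor, optional
        Natural-unit bindings; anonymous unit-range factors are created
        when omitted.
    """
    if n_runs not in _PB_GENERATORS:
        raise ValueError(
            f"no Plackett-Burman generator for n_runs={n_runs}; "
            f"supported sizes: {sorted(_PB_GENERATORS)}"
        )
    if not 2 <= n_factors <= 11:
        raise ValueError(f"n_factors must be in 2..11, got {n_factors}")
    if n_factors > n_runs - 1:
        raise ValueError(f"{n_runs}-run design screens at most {n_runs - 1} factors")
    if n_center < 0:
        raise ValueError("n_center must be >= 0")

    gen = np.array(_PB_GENERATORS[n_runs], dtype=np.int8)
    rows = [np.roll(gen, i) for i in range(n_runs - 1)]
    rows.append(np.full(n_runs - 1, -1, dtype=np.int8))
    coded = np.vstack(rows)[:, :n_factors]
    if n_center:
        coded = np.vstack([coded, np.zeros((n_center, n_factors), dtype=np.int8)])

    if factors is None:
        factors = [Factor(f"X{j + 1}", "coded", -1.0, 1.0) for j in range(n_factors)]
    design = DesignMatrix(list(factors), coded)
    validate_pb(design)
    return design


def validate_pb(design: DesignMatrix) -> None:
    """Check PB balance and orthogonality on the factorial (non-center) rows.

    Each column must split exactly half +1 / half -1, and every pair of
    distinct columns must have inner product zero.
    """
    X = design.coded[design.factorial_mask()].astype(int)
    n = X.shape[0]
    if n == 0 or n % 2:
        raise ValueError(f"PB factorial block must have an even, positive run count (got {n})")
    if np.isin(X, 0).any():
        raise ValueError("PB factorial rows must use only coded levels -1/+1")
    plus = (X == 1).sum(axis=0)
    if not (plus == n // 2).all():
        bad = [design.factor_names[j] for j in np.flatnonzero(plus != n // 2)]
        raise ValueError(f"unbalanced PB columns (not {n // 2}/{n // 2}): {bad}")
    gram = X.T @ X
    off = gram - np.diag(np.diag(gram))
    if off.any():
        i, j = np.argwhere(off)[0]
        raise ValueError(
            f"PB columns not orthogonal: {design.factor_names[i]} . "
            f"{design.factor_names[j]} = {off[i, j]}"
        )


# ---------------------------------------------------------------------------
# Box-Behnken construction
# ---------------------------------------------------------------------------


def make_bb_design(
    n_factors: int,
    n_center: int = 3,
    factors: Sequence[Factor] | None = None,
) -> DesignMatrix:
    """Build a Box-Behnken design: edge midpoints of the factor cube.

    For every pair of factors (in index order) the design takes the four
    +/-1 combinations with all remaining factors at 0, followed by
    ``n_center`` all-center rows.  For 3 factors and 3 center runs this is
    the classical 15-run design supporting a full 10-term quadratic model.
    """
    if not 3 <= n_factors <= 5:
        raise ValueError(f"Box-Behnken supported for 3..5 factors, got {n_factors}")
    if n_center < 1:
        raise ValueError("Box-Behnken requires at least one center run")

    rows = []
    for i in range(n_factors):
        for j in range(i + 1, n_factors):
            for si in (-1, 1):
                for sj in (-1, 1):
                    row = np.zeros(n_factors, dtype=np.int8)
                    row[i], row[j] = si, sj
                    rows.append(row)
    rows.extend(np.zeros(n_factors, dtype=np.int8) for _ in range(n_center))
    coded = np.vstack(rows)

    if factors is None:
        factors = [Factor(f"X{j + 1}", "coded", -1.0, 1.0) for j in range(n_factors)]
    design = DesignMatrix(list(factors), coded)
    validate_bb(design)
    return design


def validate_bb(design: DesignMatrix) -> None:
    """Structural checks for a Box-Behnken design.

    Non-center rows carry exactly two nonzero (+/-1) coordinates; each
    linear column sums to zero and is orthogonal to every other linear
    column and to every pairwise-product column.
    """
    X = design.coded.astype(int)
    center = design.is_center
    if not center.any():
        raise ValueError("Box-Behnken design must include center runs")
    edge = X[~center]
    nonzero = (edge != 0).sum(axis=1)
    if not (nonzero == 2).all():
        raise ValueError("each non-center Box-Behnken row must vary exactly two factors")
    if X.sum(axis=0).any():
        raise ValueError("Box-Behnken linear columns must sum to zero")
    k = design.n_factors
    for i in range(k):
        for j in range(k):
            if i < j and (X[:, i] * X[:, j]).sum() != 0:
                raise ValueError(f"linear columns {i} and {j} not orthogonal")
            for m in range(j + 1, k):
                if (X[:, i] * X[:, j] * X[:, m]).sum() != 0:
                    raise ValueError(
                        f"linear column {i} not orthogonal to product column ({j},{m})"
                    )
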