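"""Plackett-Burman screening statistics.

Main effects, pooled-variance two-sample t statistics, significance
classification against a tabulated critical-value ladder, and ranking of
factors for the follow-up response-surface stage.

The main effect of factor j is the average yield change between its high
and low level,

    E_j = mean(y | x_j = +1) - mean(y | x_j = -1)
        = (sum of high-level y - sum of low-level y) / N,   N = runs / 2,

and its t statistic is the equal-variance unpaired two-sample t between
the same two groups.  Center runs carry no +/- information and are
excluded before grouping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import DesignMatrix, as_response_vector

__all__ = [
    "ThresholdTable",
    "ScreeningResult",
    "main_effects",
    "t_values",
    "classify",
    "screen",
    "select_significant",
    "fold_change",
    "PAPER_THRESHOLDS",
]

NOT_SIGNIFICANT = "n.s."


@dataclass(frozen=True)
class ThresholdTable:
    """Ordered (label, critical t) pairs, most stringent first.

    A |t| is assigned the most stringent label whose critical value it
    reaches (boundary inclusive); below the loosest critical value the
    label is ``"n.s."``.
    """

    levels: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        crit = [c for _, c in self.levels]
        if not all(a > b for a, b in zip(crit, crit[1:])):
            raise ValueError("critical values must be strictly decreasing as levels loosen")
        if any(c <= 0 for c in crit):
            raise ValueError("critical values must be positive")

    def classify_one(self, abs_t: float) -> str:
        for label, crit in self.levels:
            if abs_t >= crit:
                return label
        return NOT_SIGNIFICANT


#: Two-tailed critical values for 10 degrees of freedom (6 vs 6 runs),
#: the ladder used with the 12-run screening design.
PAPER_THRESHOLDS = ThresholdTable(
    (("1%", 3.70), ("5%", 2.446), ("10%", 1.94), ("20%", 1.372))
)


@dataclass
class ScreeningResult:
    """Per-factor screening statistics, aligned with the design's factors."""

    factor_names: list[str]
    main_effect: np.ndarray
    t_value: np.ndarray
    df: int
    significance: list[str]
    thresholds: ThresholdTable = field(default=PAPER_THRESHOLDS, repr=False)

    @property
    def abs_t(self) -> np.ndarray:
        return np.abs(self.t_value)

    @property
    def sign(self) -> list[str]:
        return ["+" if e > 0 else "-" if e < 0 else "0" for e in self.main_effect]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "factor": self.factor_names,
                "main_effect": self.main_effect,
                "t_value": self.t_value,
                "df": self.df,
                "significance": self.significance,
                "sign": self.sign,
            }
        )


def _split_groups(design: DesignMatrix, responses) -> tuple[np.ndarray, np.ndarray]:
    y = as_response_vector(responses, design)
    mask = design.factorial_mask()
    X = design.coded[mask].astype(int)
    y = y[mask]
    if np.isin(X, 0).any():
        raise ValueError("screening requires two-level (+/-1) factorial rows; found 0 levels")
    plus = X == 1
    n = X.shape[0]
    if not ((plus.sum(axis=0) == n // 2).all() and n % 2 == 0):
        raise ValueError("unbalanced design column after excluding center runs")
    return X, y


def main_effects(design: DesignMatrix, responses) -> np.ndarray:
    """Per-factor main effect: difference of high-group and low-group means."""
    X, y = _split_groups(design, responses)
    n_half = X.shape[0] // 2
    return (np.where(X == 1, 1.0, -1.0).T @ y) / n_half


def t_values(design: DesignMatrix, responses) -> tuple[np.ndarray, int]:
    """Pooled-variance two-sample t per factor, plus shared degrees of freedom.

    t_j = (mean+ - mean-) / sqrt(s2_pooled * (1/n+ + 1/n-)) with the usual
    pooled variance; the groups are equal-sized halves so df = n - 2.

    A factor whose two groups have zero pooled variance gets t = +/-inf
    (with a warning) when its effect is nonzero, and t = 0 when the effect
    is zero as well.
    """
    X, y = _split_groups(design, responses)
    n = X.shape[0]
    n_half = n // 2
    if n_half < 2:
        raise ValueError("each level group needs at least 2 runs for a t statistic")
    df = n - 2
    out = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        hi, lo = y[X[:, j] == 1], y[X[:, j] == -1]
        effect = hi.mean() - lo.mean()
        s2 = ((n_half - 1) * hi.var(ddof=1) + (n_half - 1) * lo.var(ddof=1)) / df
        if s2 == 0:
            if effect == 0:
                out[j] = 0.0
            else:
                warnings.warn(
                    f"zero pooled variance with nonzero effect for factor index {j}; "
                    "t reported as infinite"
                )
                out[j] = np.inf * np.sign(effect)
        else:
            out[j] = effect / np.sqrt(s2 * (2 / n_half))
    return out, df


def classify(t_list, thresholds: ThresholdTable = PAPER_THRESHOLDS) -> list[str]:
    """Map each |t| to the most stringent satisfied significance level."""
    return [thresholds.classify_one(abs(t)) for t in np.asarray(t_list, dtype=float)]


def screen(
    design: DesignMatrix,
    responses,
    thresholds: ThresholdTable = PAPER_THRESHOLDS,
) -> ScreeningResult:
    """Run the full screening stage: effects, t statistics, significance."""
    effects = main_effects(design, responses)
    t, df = t_values(design, responses)
    return ScreeningResult(
        factor_names=design.factor_names,
        main_effect=effects,
        t_value=t,
        df=df,
        significance=classify(t, thresholds),
        thresholds=thresholds,
    )


def select_significant(result: ScreeningResult, k: int) -> list[tuple[str, str]]:
    """Top-k factors by |t| (ties by |effect|, then input order), with signs.

    The sign says which direction to carry into the follow-up design:
    a positive effect means the high level favoured yield, so the next
    stage explores upward, and vice versa.
    """
    if k > len(result.factor_names):
        raise ValueError(f"k={k} exceeds the {len(result.factor_names)} screened factors")
    order = sorted(
        range(len(result.factor_names)),
        key=lambda j: (-result.abs_t[j], -abs(result.main_effect[j]), j),
    )
    return [(result.factor_names[j], result.sign[j]) for j in order[:k]]


def fold_change(new_yield: float, reference_yield: float) -> float:
    """Yield ratio new/reference, e.g. optimized medium over basal medium."""
    if reference_yield <= 0:
        raise ValueError("reference yield must be positive")
    return new_yield / reference_yield
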