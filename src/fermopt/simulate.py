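"""Synthetic screening and response-surface datasets with known truth.

Generates responses with the exact statistical structure the analysis
stages assume -- additive two-level factor effects for screening, a known
quadratic surface for the response-surface stage, both with i.i.d.
homoscedastic noise -- so every pipeline stage can be tested against a
planted ground truth without external data.

The default baseline yield (0.36 g/L) and noise level (0.05 g/L) put
synthetic responses on the scale of a real submerged-culture pigment
fermentation; see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .design import DesignMatrix, Factor, make_bb_design, make_pb_design
from .rsm import QuadraticModel, expand_model_matrix, predict

__all__ = ["SyntheticSpec", "simulate_pb", "simulate_bb"]

#: Baseline yield (g/L): grand mean of a typical 12-run screening response.
DEFAULT_BASELINE = 0.36


@dataclass
class SyntheticSpec:
    """Ground-truth description of a synthetic dataset.

    For ``kind="pb"`` supply ``true_main_effects`` (one per factor): the
    response is ``mu + sum_j (E_j / 2) x_j + noise`` so that factor j's
    expected main effect is exactly ``E_j``.  For ``kind="bb"`` supply
    ``true_coefficients`` in model-matrix order (intercept, linear,
    interactions i<j, squared): the response is that quadratic evaluated
    at the coded runs, plus noise.
    """

    kind: Literal["pb", "bb"]
    factors: Sequence[Factor] | int
    true_main_effects: Sequence[float] | None = None
    true_coefficients: Sequence[float] | None = None
    noise_sd: float = 0.05
    seed: int | None = None
    n_replicates: int = 1
    baseline: float = DEFAULT_BASELINE
    n_runs: int = 12  # PB factorial runs
    n_center: int = 0  # PB center runs (BB always uses 3)
    noise: Literal["gaussian", "laplace"] = "gaussian"
    nonnegative: bool = False

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if isinstance(self.factors, int):
            self.factors = [
                Factor(f"X{j + 1}", "coded", -1.0, 1.0) for j in range(self.factors)
            ]
        k = len(self.factors)
        if self.kind == "pb":
            if self.true_main_effects is None or len(self.true_main_effects) != k:
                raise ValueError(f"true_main_effects must have length {k}")
        elif self.kind == "bb":
            p = 1 + 2 * k + k * (k - 1) // 2
            if self.true_coefficients is None or len(self.true_coefficients) != p:
                raise ValueError(f"true_coefficients must have length {p} for k={k}")
        else:
            raise ValueError(f"unknown design kind {self.kind!r}")


def _noise(rng: np.random.Generator, sd: float, shape, kind: str) -> np.ndarray:
    if kind == "gaussian":
        return rng.normal(0.0, sd, shape)
    if kind == "laplace":
        # scale chosen so the standard deviation is still `sd`
        return rng.laplace(0.0, sd / np.sqrt(2.0), shape)
    raise ValueError(f"unknown noise model {kind!r}")


def _finalize(y: np.ndarray, spec: SyntheticSpec) -> np.ndarray:
    if spec.nonnegative:
        y = np.clip(y, 0.0, None)
    return y[0] if spec.n_replicates == 1 else y


def simulate_pb(spec: SyntheticSpec, rng: np.random.Generator | None = None):
    """Simulate a Plackett-Burman screening dataset.

    Returns ``(design, responses)`` where responses has shape ``(n_runs,)``,
    or ``(n_replicates, n_runs)`` when several independent replicates are
    requested.  Reproducible given ``spec.seed``.
    """
    if spec.kind != "pb":
        raise ValueError("spec.kind must be 'pb'")
    rng = rng or np.random.default_rng(spec.seed)
    design = make_pb_design(
        len(spec.factors), spec.n_runs, spec.n_center, factors=spec.factors
    )
    half_effects = np.asarray(spec.true_main_effects, dtype=float) / 2.0
    mean = spec.baseline + design.coded.astype(float) @ half_effects
    y = mean + _noise(rng, spec.noise_sd, (spec.n_replicates, design.n_runs), spec.noise)
    return design, _finalize(y, spec)


def simulate_bb(spec: SyntheticSpec, rng: np.random.Generator | None = None):
    """Simulate a Box-Behnken dataset from a known quadratic surface."""
    if spec.kind != "bb":
        raise ValueError("spec.kind must be 'bb'")
    rng = rng or np.random.default_rng(spec.seed)
    design = make_bb_design(len(spec.factors), n_center=3, factors=spec.factors)
    mean = expand_model_matrix(design.coded) @ np.asarray(spec.true_coefficients, float)
    y = mean + _noise(rng, spec.noise_sd, (spec.n_replicates, design.n_runs), spec.noise)
    return design, _finalize(y, spec)
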