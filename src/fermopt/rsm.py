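"""Response-surface modelling: quadratic fit, prediction, exact maximization.

The response y (melanin yield, g/L) is modelled over coded variables
X1..Xk by the full second-order polynomial

    y = b0 + sum_i bi Xi + sum_{i<j} bij Xi Xj + sum_i bii Xi^2,

fitted by ordinary least squares on the expanded model matrix.  On a
Box-Behnken design the linear and interaction coefficients reduce to
simple contrasts (sum(Xi y)/sum(Xi^2), sum(Xi Xj y)/sum((Xi Xj)^2)),
which the fit verifies internally.

The fitted quadratic is maximized over the coded cube [-1,1]^k exactly,
by enumerating the stationary points of every face restriction together
with all corners -- a quadratic restricted to a face is again a
quadratic, and its maximum over the face is either an interior
stationary point or lies on the face's boundary, which is itself a
lower-dimensional face in the enumeration.  No iterative solver, hence
no tolerance or starting-point questions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import DesignMatrix, Factor, decode_levels, as_response_vector, validate_bb

__all__ = [
    "QuadraticModel",
    "OptimizationResult",
    "fit_quadratic",
    "predict",
    "maximize_over_box",
    "surface_grid",
    "verification_report",
    "expand_model_matrix",
    "term_names",
]


def term_names(factor_names: list[str]) -> list[str]:
    k = len(factor_names)
    names = ["Intercept"] + list(factor_names)
    names += [f"{factor_names[i]}:{factor_names[j]}" for i in range(k) for j in range(i + 1, k)]
    names += [f"{n}^2" for n in factor_names]
    return names


def expand_model_matrix(coded: np.ndarray) -> np.ndarray:
    """Expand coded runs into [1, Xi, XiXj (i<j), Xi^2] columns."""
    X = np.asarray(coded, dtype=float)
    n, k = X.shape
    cols = [np.ones(n)] + [X[:, i] for i in range(k)]
    cols += [X[:, i] * X[:, j] for i in range(k) for j in range(i + 1, k)]
    cols += [X[:, i] ** 2 for i in range(k)]
    return np.column_stack(cols)


@dataclass
class QuadraticModel:
    """Full second-order polynomial over coded variables.

    Coefficients are split into intercept, linear vector, upper-triangular
    interaction matrix (entry [i, j], i<j) and squared-term vector.  The
    quadratic form is ``y(x) = beta0 + b.x + x' A x`` where A has the
    squared coefficients on its diagonal and half of each interaction
    coefficient off-diagonal.
    """

    factors: list[Factor]
    beta0: float
    linear: np.ndarray
    interaction: np.ndarray  # k x k, only i<j entries used
    squared: np.ndarray
    r_squared: float | None = None
    residuals: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        k = len(self.factors)
        self.linear = np.asarray(self.linear, dtype=float).reshape(k)
        self.squared = np.asarray(self.squared, dtype=float).reshape(k)
        self.interaction = np.asarray(self.interaction, dtype=float).reshape(k, k)

    @property
    def k(self) -> int:
        return len(self.factors)

    @property
    def quadratic_form(self) -> np.ndarray:
        """Symmetric matrix A with y = beta0 + b.x + x'Ax."""
        A = np.diag(self.squared).astype(float)
        for i in range(self.k):
            for j in range(i + 1, self.k):
                A[i, j] = A[j, i] = self.interaction[i, j] / 2
        return A

    def coefficients(self) -> dict[str, float]:
        """Flat term-name -> coefficient mapping (reporting order)."""
        names = term_names([f.name for f in self.factors])
        vals = [self.beta0, *self.linear]
        vals += [self.interaction[i, j] for i in range(self.k) for j in range(i + 1, self.k)]
        vals += list(self.squared)
        return dict(zip(names, vals))

    def __call__(self, x) -> np.ndarray | float:
        return predict(self, x)

    @classmethod
    def from_coefficients(
        cls,
        factors: list[Factor],
        beta0: float,
        linear,
        interaction_upper,
        squared,
        r_squared: float | None = None,
    ) -> "QuadraticModel":
        """Build a model from explicit coefficients (e.g. a published fit).

        ``interaction_upper`` lists the i<j interaction coefficients in
        row-major order (X1X2, X1X3, ..., X2X3, ...).
        """
        k = len(factors)
        inter = np.zeros((k, k))
        it = iter(np.asarray(interaction_upper, dtype=float).ravel())
        for i in range(k):
            for j in range(i + 1, k):
                inter[i, j] = next(it)
        return cls(factors, float(beta0), linear, inter, squared, r_squared=r_squared)


@dataclass
class OptimizationResult:
    """Location and value of the model maximum over the coded cube."""

    coded_optimum: np.ndarray
    natural_optimum: np.ndarray
    predicted_response: float
    boundary_flags: np.ndarray  # True where the coordinate is clamped at +/-1

    def to_frame(self, factors: list[Factor]) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "factor": [f.name for f in factors],
                "unit": [f.unit for f in factors],
                "coded": self.coded_optimum,
                "natural": self.natural_optimum,
                "at_boundary": self.boundary_flags,
            }
        )


def fit_quadratic(design: DesignMatrix, responses) -> QuadraticModel:
    """Least-squares fit of the full second-order model to a design.

    Requires at least as many runs as the 1 + 2k + k(k-1)/2 coefficients
    and a full-rank expanded model matrix.  On a valid Box-Behnken design
    the linear and interaction estimates are cross-checked against their
    closed-form contrast values.
    """
    y = as_response_vector(responses, design)
    k = design.n_factors
    M = expand_model_matrix(design.coded)
    p = M.shape[1]
    if design.n_runs < p:
        raise ValueError(f"need >= {p} runs to fit {p} coefficients, have {design.n_runs}")
    rank = np.linalg.matrix_rank(M)
    if rank < p:
        names = term_names(design.factor_names)
        # identify columns whose removal restores full complement
        _, R = np.linalg.qr(M)
        dependent = [names[j] for j in range(p) if abs(R[j, j]) < 1e-9 * abs(R).max()]
        raise ValueError(f"rank-deficient model matrix; collinear columns: {dependent}")

    beta, *_ = np.linalg.lstsq(M, y, rcond=None)
    fitted = M @ beta
    resid = fitted - y
    sst = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 - (resid**2).sum() / sst if sst > 0 else 1.0

    n_int = k * (k - 1) // 2
    inter = np.zeros((k, k))
    idx = 1 + k
    for i in range(k):
        for j in range(i + 1, k):
            inter[i, j] = beta[idx]
            idx += 1
    model = QuadraticModel(
        factors=list(design.factors),
        beta0=float(beta[0]),
        linear=beta[1 : 1 + k],
        interaction=inter,
        squared=beta[1 + k + n_int :],
        r_squared=float(r2),
        residuals=resid,
    )

    try:
        validate_bb(design)
    except ValueError:
        return model
    # Box-Behnken orthogonality: linear/interaction estimates must equal
    # their contrast formulas; a mismatch means the solver went wrong.
    X = design.coded.astype(float)
    for i in range(k):
        contrast = (X[:, i] * y).sum() / (X[:, i] ** 2).sum()
        if abs(contrast - model.linear[i]) > 1e-8:
            raise AssertionError("linear coefficient deviates from its contrast estimate")
        for j in range(i + 1, k):
            prod = X[:, i] * X[:, j]
            contrast = (prod * y).sum() / (prod**2).sum()
            if abs(contrast - inter[i, j]) > 1e-8:
                raise AssertionError("interaction coefficient deviates from its contrast estimate")
    return model


def predict(model: QuadraticModel, coded_point) -> np.ndarray | float:
    """Evaluate the polynomial at one coded point or an array of points."""
    x = np.asarray(coded_point, dtype=float)
    scalar = x.ndim == 1
    pts = np.atleast_2d(x)
    if pts.shape[1] != model.k:
        raise ValueError(f"points have dimension {pts.shape[1]}, model has {model.k}")
    A = model.quadratic_form
    vals = model.beta0 + pts @ model.linear + np.einsum("ni,ij,nj->n", pts, A, pts)
    return float(vals[0]) if scalar else vals


def maximize_over_box(model: QuadraticModel, bound: float = 1.0) -> OptimizationResult:
    """Exact global maximum of the quadratic over the cube [-bound, bound]^k.

    Enumerates every face of the cube: for each subset of coordinates
    fixed at +/-bound, the restricted quadratic's stationary point is
    solved in the free coordinates and kept when it lies inside the face.
    Corners (all coordinates fixed) are always candidates.  Singular
    restricted Hessians simply contribute no interior candidate -- the
    restricted problem's maximum then lies on the face boundary, which a
    smaller face covers.
    """
    k = model.k
    A = model.quadratic_form
    b = model.linear
    best_val, best_x = -np.inf, None

    for fixed in itertools.chain.from_iterable(
        itertools.combinations(range(k), r) for r in range(k + 1)
    ):
        free = [i for i in range(k) if i not in fixed]
        for signs in itertools.product((-bound, bound), repeat=len(fixed)):
            x = np.zeros(k)
            x[list(fixed)] = signs
            if free:
                # stationary point: 2 A_ff x_f = -(b_f + 2 A_fc x_c)
                Aff = A[np.ix_(free, free)]
                rhs = -(b[free] + 2 * A[np.ix_(free, list(fixed))] @ x[list(fixed)])
                try:
                    xf = np.linalg.solve(2 * Aff, rhs)
                except np.linalg.LinAlgError:
                    continue
                if (np.abs(xf) > bound + 1e-12).any():
                    continue
                x[free] = np.clip(xf, -bound, bound)
            val = predict(model, x)
            if val > best_val:
                best_val, best_x = val, x

    flags = np.isclose(np.abs(best_x), bound)
    natural = np.array(
        [decode_levels(f, c) for f, c in zip(model.factors, best_x)], dtype=float
    )
    return OptimizationResult(
        coded_optimum=best_x,
        natural_optimum=natural,
        predicted_response=float(best_val),
        boundary_flags=flags,
    )


def surface_grid(
    model: QuadraticModel,
    factor_a: int | str,
    factor_b: int | str,
    fixed_levels: dict[int | str, float] | None = None,
    n: int = 41,
) -> pd.DataFrame:
    """Prediction grid over two factors for 3-D surface / contour plots.

    The two chosen factors sweep [-1, 1] on an ``n x n`` rectangular grid;
    every other factor sits at the coded level given in ``fixed_levels``
    (default 0, the center).  Returns a long-format frame with coded and
    natural coordinates plus the predicted response.
    """
    names = [f.name for f in model.factors]

    def _index(f):
        return names.index(f) if isinstance(f, str) else int(f)

    ia, ib = _index(factor_a), _index(factor_b)
    if ia == ib:
        raise ValueError("surface factors must differ")
    fixed = np.zeros(model.k)
    for key, val in (fixed_levels or {}).items():
        fixed[_index(key)] = val

    axis = np.linspace(-1.0, 1.0, n)
    ga, gb = np.meshgrid(axis, axis, indexing="ij")
    pts = np.tile(fixed, (n * n, 1))
    pts[:, ia] = ga.ravel()
    pts[:, ib] = gb.ravel()
    pred = predict(model, pts)
    fa, fb = model.factors[ia], model.factors[ib]
    return pd.DataFrame(
        {
            f"{fa.name}_coded": pts[:, ia],
            f"{fb.name}_coded": pts[:, ib],
            f"{fa.name}_{fa.unit}": decode_levels(fa, pts[:, ia]),
            f"{fb.name}_{fb.unit}": decode_levels(fb, pts[:, ib]),
            "predicted": pred,
        }
    )


def verification_report(
    model: QuadraticModel,
    optimum: OptimizationResult,
    observed_yield: float,
    basal_yield: float,
) -> dict[str, float]:
    """Compare the model's predicted optimum against a verification run.

    Tabulates predicted vs observed yield at the optimum, the absolute and
    relative deviation, and the fold-change of the observed yield over the
    basal-medium yield.
    """
    if observed_yield <= 0 or basal_yield <= 0:
        raise ValueError("yields must be positive")
    predicted = optimum.predicted_response
    deviation = predicted - observed_yield
    return {
        "predicted_g_per_L": predicted,
        "observed_g_per_L": observed_yield,
        "absolute_deviation_g_per_L": abs(deviation),
        "relative_deviation_pct": abs(deviation) / predicted * 100.0,
        "fold_change_vs_basal": observed_yield / basal_yield,
        "basal_g_per_L": basal_yield,
    }
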