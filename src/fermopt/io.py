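"""Reading and writing design/response tables and factor configurations.

Design CSVs have a header ``run,<factor1>,...,<factorK>[,response]`` with
one row per run; levels may be coded (-1/0/1) or natural, declared by a
``levels: coded|natural`` key in the YAML factor configuration.  Natural
three-level files must use each factor's exact low/center/high values.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .design import DesignMatrix, Factor, as_response_vector, code_levels

__all__ = [
    "load_factors",
    "read_design",
    "write_design",
    "run_reference_reproduction",
]

log = logging.getLogger("fermopt")

RESPONSE_COLUMN = "response"


def load_factors(path) -> tuple[list[Factor], str]:
    """Load a factor configuration; returns (factors, levels) with
    ``levels`` one of ``"coded"`` / ``"natural"``."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    levels = cfg.get("levels", "coded")
    if levels not in ("coded", "natural"):
        raise ValueError(f"levels must be 'coded' or 'natural', got {levels!r}")
    factors = [
        Factor(
            name=str(f["name"]),
            unit=str(f.get("unit", "")),
            low=float(f["low"]),
            high=float(f["high"]),
            center=float(f["center"]) if "center" in f else None,
        )
        for f in cfg["factors"]
    ]
    return factors, levels


def _code_natural_column(factor: Factor, values: np.ndarray, path) -> np.ndarray:
    """Natural three-level values -> exact coded levels, or error."""
    coded = np.empty(len(values), dtype=np.int8)
    targets = {-1: factor.low, 0: factor.center, 1: factor.high}
    for r, v in enumerate(values):
        for level, nat in targets.items():
            if np.isclose(v, nat, rtol=1e-9, atol=0.0):
                coded[r] = level
                break
        else:
            raise ValueError(
                f"{path}, row {r + 2}: {factor.name} value {v} is not one of "
                f"low/center/high ({factor.low}/{factor.center}/{factor.high})"
            )
    return coded


def read_design(path, factors: list[Factor], levels: str = "coded"):
    """Read a design CSV into a :class:`DesignMatrix` (+ responses if present).

    Returns ``(design, responses)`` with ``responses=None`` when the file
    has no response column.  Malformed rows are reported with their line
    number in the file (header = line 1).
    """
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: no design rows")
    names = [f.name for f in factors]
    expected = ["run", *names]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}; header must be run,<factors>[,response]")
    extra = [c for c in df.columns if c not in expected and c != RESPONSE_COLUMN]
    if extra:
        raise ValueError(f"{path}: unknown factor columns {extra}")

    for col in names:
        bad = df.index[df[col].isna()]
        if len(bad):
            raise ValueError(f"{path}, row {bad[0] + 2}: missing level for {col}")

    if levels == "coded":
        coded = np.empty((len(df), len(names)), dtype=np.int8)
        for j, col in enumerate(names):
            vals = df[col].to_numpy(dtype=float)
            ok = np.isin(vals, (-1.0, 0.0, 1.0))
            if not ok.all():
                r = int(np.flatnonzero(~ok)[0])
                raise ValueError(
                    f"{path}, row {r + 2}: coded level {vals[r]} for {col} not in -1/0/1"
                )
            coded[:, j] = vals
    else:
        coded = np.column_stack(
            [
                _code_natural_column(f, df[c].to_numpy(dtype=float), path)
                for f, c in zip(factors, names)
            ]
        )

    design = DesignMatrix(list(factors), coded, runs=df["run"].to_numpy())
    responses = None
    if RESPONSE_COLUMN in df.columns:
        vals = df[RESPONSE_COLUMN]
        bad = df.index[vals.isna()]
        if len(bad):
            raise ValueError(
                f"{path}, row {bad[0] + 2}: run {df['run'].iloc[bad[0]]} has no response"
            )
        responses = as_response_vector(vals.to_numpy(dtype=float), design)
    log.info("read_design: %s -> %d runs x %d factors (responses: %s)",
             path.name, design.n_runs, design.n_factors, responses is not None)
    return design, responses


def write_design(path, design: DesignMatrix, responses=None, levels: str = "coded") -> None:
    """Write a design (and optional responses) as CSV, coded or natural."""
    df = design.to_frame(levels=levels)
    if responses is not None:
        df[RESPONSE_COLUMN] = as_response_vector(responses, design)
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# End-to-end reproduction of the reference study's statistics
# ---------------------------------------------------------------------------


def run_reference_reproduction() -> tuple[str, dict]:
    """Re-run the whole two-stage analysis on the shipped reference tables.

    Screens the 13-run Plackett-Burman fixture, selects the top three
    factors, fits the quadratic model to the 15-run Box-Behnken fixture,
    maximizes the published polynomial over the coded cube, and compares
    every recomputed statistic side-by-side with its published value.

    Returns ``(text_report, results)`` where ``results`` holds the raw
    numbers.  The report body is deterministic (no timestamps).
    """
    from . import datasets
    from .rsm import fit_quadratic, maximize_over_box, verification_report
    from .screening import fold_change, screen, select_significant

    lines: list[str] = []
    results: dict = {}

    pb_design, pb_y = datasets.load_pb_table1()
    scr = screen(pb_design, pb_y)
    log.info("screening: 12 factorial runs, 11 factors, df=%d", scr.df)
    top3 = select_significant(scr, 3)
    results["screening"] = scr.to_frame()
    results["top3"] = top3

    lines.append("Two-stage medium optimization: reference reproduction")
    lines.append("=" * 56)
    lines.append("")
    lines.append("Stage 1 - Plackett-Burman screening (11 factors, 12 factorial runs)")
    lines.append(f"{'factor':<14}{'effect':>9}{'ref':>8}{'|dev|':>8}"
                 f"{'t':>8}{'ref_t':>7}{'signif':>8}")
    for j, name in enumerate(scr.factor_names):
        ref_e = datasets.REFERENCE_MAIN_EFFECTS[j]
        ref_t = datasets.REFERENCE_T_VALUES[j]
        lines.append(
            f"{name:<14}{scr.main_effect[j]:>9.3f}{ref_e:>8}{abs(scr.main_effect[j] - ref_e):>8.3f}"
            f"{scr.t_value[j]:>8.2f}{ref_t:>7}{scr.significance[j]:>8}"
        )
    lines.append(f"top-3 by |t|: {', '.join(f'{n} ({s})' for n, s in top3)}")
    lines.append("")

    bb_design, bb_y = datasets.load_bb_table2()
    model = fit_quadratic(bb_design, bb_y)
    log.info("quadratic fit: 15 runs, 10 terms, R^2=%.3f", model.r_squared)
    results["model"] = model
    ref_model = datasets.reference_polynomial()
    ref_coef = ref_model.coefficients()

    lines.append("Stage 2 - Box-Behnken quadratic fit (3 factors, 15 runs, coded units)")
    lines.append(f"{'term':<22}{'fitted':>10}{'ref':>10}{'|dev|':>8}  note")
    exact_terms = {"Intercept", "CaCl2:TraceElement"}
    for term, value in model.coefficients().items():
        ref = ref_coef[term]
        note = "exact" if term in exact_terms else "tolerance +/-0.03 (*)"
        lines.append(f"{term:<22}{value:>10.5f}{ref:>10.5f}{abs(value - ref):>8.4f}  {note}")
    lines.append(f"{'R^2':<22}{model.r_squared:>10.3f}{datasets.REFERENCE_R_SQUARED:>10.3f}"
                 f"{abs(model.r_squared - datasets.REFERENCE_R_SQUARED):>8.4f}  tolerance +/-0.03 (*)")
    lines.append("(*) the reference study fitted unrounded responses; the shipped table")
    lines.append("    is printed to 2 decimals, so only the intercept and the CaCl2 x")
    lines.append("    TraceElement interaction are exactly recoverable from it.")
    lines.append("")

    opt = maximize_over_box(ref_model)
    log.info("optimum: coded %s, predicted %.5f g/L", opt.coded_optimum, opt.predicted_response)
    results["optimum"] = opt
    lines.append("Maximum of the published polynomial over the coded cube [-1,1]^3")
    for f, c, nat in zip(ref_model.factors, opt.coded_optimum, opt.natural_optimum):
        lines.append(f"  {f.name:<14} coded {c:+.0f}  ->  {nat:g} {f.unit}")
    lines.append(f"  predicted yield: {opt.predicted_response:.5f} g/L "
                 f"(ref {datasets.REFERENCE_PREDICTED_OPTIMUM} g/L at 3 dp)")
    lines.append("")

    report = verification_report(
        ref_model, opt, datasets.OBSERVED_OPTIMUM_YIELD, datasets.BASAL_YIELD
    )
    results["verification"] = report
    results["fold_change"] = fold_change(
        datasets.OBSERVED_OPTIMUM_YIELD, datasets.BASAL_YIELD
    )
    lines.append("Verification against the wet-lab yields (inputs, not recomputed)")
    lines.append(f"  predicted {report['predicted_g_per_L']:.3f} g/L vs observed "
                 f"{report['observed_g_per_L']:.3f} g/L "
                 f"(deviation {report['absolute_deviation_g_per_L']:.3f} g/L, "
                 f"{report['relative_deviation_pct']:.1f}%)")
    lines.append(f"  fold-change over basal medium ({datasets.BASAL_YIELD} g/L): "
                 f"{results['fold_change']:.2f}")
    return "\n".join(lines) + "\n", results
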