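"""Built-in reference datasets from the original melanin-optimization study.

The two experimental tables of the reference study on *Hortaea werneckii*
AS1 are shipped as plain-CSV package data:

* ``pb_table1`` -- the 12-run (+1 center run) Plackett-Burman screen of
  11 culture variables, with the measured melanin yield (g/L) per run;
* ``bb_table2`` -- the 15-run Box-Behnken design over the three factors
  the screen retained (CaCl2, trace-element solution, culture volume),
  again with measured yields.

Also provided: the study's published second-order polynomial (for use as
a fixed reference model), its significance-threshold ladder, and the
wet-lab yields used in verification.  Responses are stored exactly as
printed (2-3 decimals); statistics recomputed from them can differ
slightly from published values fitted on unrounded data.
"""

from __future__ import annotations

from importlib import resources

import numpy as np

from .design import DesignMatrix
from .io import load_factors, read_design
from .rsm import QuadraticModel

__all__ = [
    "load_pb_table1",
    "load_bb_table2",
    "pb_factors",
    "bb_factors",
    "reference_polynomial",
    "BB_TABLE2_RUN_OF_CANONICAL",
    "REFERENCE_MAIN_EFFECTS",
    "REFERENCE_T_VALUES",
    "REFERENCE_R_SQUARED",
    "REFERENCE_PREDICTED_OPTIMUM",
    "OBSERVED_OPTIMUM_YIELD",
    "BASAL_YIELD",
    "SCREEN_VERIFIED_YIELD",
]

_DATA = resources.files("fermopt") / "data"


def pb_factors():
    """The 11 screened culture variables with their natural levels."""
    factors, _ = load_factors(_DATA / "factors_pb.yml")
    return factors


def bb_factors():
    """The 3 response-surface factors with their natural three-level sets."""
    factors, _ = load_factors(_DATA / "factors_bb.yml")
    return factors


def load_pb_table1() -> tuple[DesignMatrix, np.ndarray]:
    """The screening design and measured yields (12 factorial + 1 center run)."""
    return read_design(_DATA / "pb_table1.csv", pb_factors(), levels="coded")


def load_bb_table2() -> tuple[DesignMatrix, np.ndarray]:
    """The 15-run Box-Behnken design and measured yields, in published run order."""
    return read_design(_DATA / "bb_table2.csv", bb_factors(), levels="coded")


#: Published-table run number for each row of the canonical generated
#: 3-factor Box-Behnken design (pairs in index order, centers last):
#: ``canonical row i`` appears as run ``BB_TABLE2_RUN_OF_CANONICAL[i]``.
BB_TABLE2_RUN_OF_CANONICAL = (7, 2, 6, 14, 12, 13, 4, 9, 3, 11, 5, 8, 1, 10, 15)

#: Published per-factor main effects (g/L) and t statistics, in the
#: table's factor order (glucose ... culture volume).
REFERENCE_MAIN_EFFECTS = (0.11, 0.004, -0.044, 0.31, -0.07, -0.005, -0.15, -0.035, -0.06, 0.11, 0.31)
REFERENCE_T_VALUES = (0.69, 0.02, 0.28, 2.53, 0.46, 0.02, 1.0, 0.22, 0.37, 0.73, 2.47)

REFERENCE_R_SQUARED = 0.853
#: Model prediction at the optimum, as published (3 dp).
REFERENCE_PREDICTED_OPTIMUM = 0.994
#: Wet-lab measurements (inputs to verification, never recomputed).
OBSERVED_OPTIMUM_YIELD = 0.938  # g/L at the model optimum
BASAL_YIELD = 0.646  # g/L in the unoptimized basal medium
SCREEN_VERIFIED_YIELD = 0.509  # g/L after the screening stage alone


def reference_polynomial() -> QuadraticModel:
    """The published second-order model over coded (CaCl2, trace, volume).

    y = 0.64 + 0.13625 X1 + 0.015 X2 + 0.22875 X3
        - 0.045 X1X2 - 0.0825 X1X3 + 0.015 X2X3
        + 0.09125 X1^2 + 0.02375 X2^2 - 0.05875 X3^2
    """
    return QuadraticModel.from_coefficients(
        bb_factors(),
        beta0=0.64,
        linear=(0.13625, 0.015, 0.22875),
        interaction_upper=(-0.045, -0.0825, 0.015),
        squared=(0.09125, 0.02375, -0.05875),
        r_squared=REFERENCE_R_SQUARED,
    )
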