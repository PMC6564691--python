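"""Comparative-Ct relative expression and demethylating-agent reactivation calls.

Expression of a target gene is normalised within-sample to a reference
(housekeeping) gene on the cycle-threshold scale:

    relative expression = 2^−(Ct_target − Ct_reference)

Re-expression after a DNMT-inhibitor treatment (5-aza-2'-deoxycytidine) is
called from the treated/untreated fold change against a configurable
threshold (default 2-fold).  Technical replicates are averaged on the Ct
scale before transformation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_REEXPRESSION_FOLD = 2.0


@dataclass(frozen=True)
class CtRecord:
    sample: str
    target_Ct: float
    reference_Ct: float

    def __post_init__(self):
        if not (math.isfinite(self.target_Ct) and math.isfinite(self.reference_Ct)):
            raise ValueError(f"non-finite Ct for sample {self.sample!r}")


def rel_expr(target_Ct: float, reference_Ct: float) -> float:
    """Relative expression ``2^−(Ct_target − Ct_reference)`` (ΔCt form)."""
    if not (math.isfinite(target_Ct) and math.isfinite(reference_Ct)):
        raise ValueError("Ct values must be finite")
    return 2.0 ** -(target_Ct - reference_Ct)


def rel_expr_ddct(
    target_Ct: float, reference_Ct: float, calibrator_dCt: float
) -> float:
    """ΔΔCt variant: expression relative to a calibrator sample's ΔCt."""
    if not math.isfinite(calibrator_dCt):
        raise ValueError("calibrator ΔCt must be finite")
    return 2.0 ** -((target_Ct - reference_Ct) - calibrator_dCt)


def fold_change(
    expr_treated: float,
    expr_untreated: float,
    threshold: float = DEFAULT_REEXPRESSION_FOLD,
) -> tuple[float, bool]:
    """Treated/untreated expression ratio and a re-expression flag.

    A zero untreated expression (silenced gene) yields infinite fold change,
    flagged re-expressed with a warning rather than an error.
    """
    if expr_treated < 0 or expr_untreated < 0:
        raise ValueError("expression values must be non-negative")
    if expr_untreated == 0:
        warnings.warn(
            "untreated expression is zero: infinite-fold re-expression",
            RuntimeWarning,
            stacklevel=2,
        )
        return math.inf, True
    fold = expr_treated / expr_untreated
    return fold, fold > threshold


def expression_table(ct_table: pd.DataFrame) -> pd.DataFrame:
    """Relative expression per sample from a long Ct table.

    Expects columns sample, target_Ct, reference_Ct; duplicate rows per sample
    (technical replicates) are averaged on the Ct scale first.
    """
    required = {"sample", "target_Ct", "reference_Ct"}
    if not required.issubset(ct_table.columns):
        raise ValueError(f"Ct table needs columns {sorted(required)}")
    if not np.isfinite(ct_table[["target_Ct", "reference_Ct"]].to_numpy()).all():
        raise ValueError("non-finite Ct values in table")
    mean_ct = ct_table.groupby("sample", sort=False)[["target_Ct", "reference_Ct"]].mean()
    expr = 2.0 ** -(mean_ct["target_Ct"] - mean_ct["reference_Ct"])
    return expr.rename("rel_expr").reset_index()


def read_ct_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_expression_table(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", index=False)
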