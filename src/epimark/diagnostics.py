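"""Diagnostic evaluation of binary serum methylation-specific-PCR (MSP) calls.

A serum sample is MSP-positive when the methylated-allele band (M) is
present, regardless of the unmethylated band.  Calls are crossed with the
disease labels into a 2×2 confusion table, and sensitivity, specificity,
positive and negative predictive value are reported as percentages.

Percent formatting matters for matching published tables: ``truncate1``
floors to one decimal (47/53 → 88.6), ``round1`` rounds half-up, ``raw``
keeps full precision.  Metrics are computed with exact rational arithmetic
so that the formatting mode, not float representation, decides the last
digit.  A zero denominator makes the corresponding metric undefined (None),
never 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from typing import Literal, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

FormatMode = Literal["truncate1", "round1", "raw"]

MSP_POSITIVE = "M"
MSP_NEGATIVE = "U"


@dataclass(frozen=True)
class DxTable:
    """2×2 confusion counts for a binary diagnostic call."""

    TP: int
    FP: int
    TN: int
    FN: int
    positive_definition: frozenset[str] = frozenset()

    def __post_init__(self):
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n_positive(self) -> int:
        return self.TP + self.FN

    @property
    def n_negative(self) -> int:
        return self.TN + self.FP


@dataclass(frozen=True)
class DxMetrics:
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    mode: FormatMode


def _format_percent(num: int, den: int, mode: FormatMode) -> float | None:
    """Percentage 100·num/den under a formatting mode, None when den == 0."""
    if den == 0:
        return None
    frac = Fraction(100 * num, den)
    if mode == "raw":
        return float(frac)
    if mode == "truncate1":
        # floor(10·x)/10 in exact arithmetic: float floor would misplace
        # values sitting exactly on a tenth
        return (frac.numerator * 10 // frac.denominator) / 10
    if mode == "round1":
        d = Decimal(frac.numerator) / Decimal(frac.denominator)
        return float(d.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
    raise ValueError(f"unknown formatting mode {mode!r}")


def confusion(
    calls: Mapping[str, str],
    labels: Mapping[str, str],
    positive_groups: set[str] | frozenset[str],
) -> DxTable:
    """Cross binary MSP calls with disease labels into a DxTable.

    ``calls`` maps sample → "M" (methylated band present, positive) or "U";
    ``labels`` maps sample → disease group.  Every called sample must be
    labeled.  Samples labeled but never called (no serum available) are
    simply absent from ``calls``; their count is logged.
    """
    unlabeled = sorted(set(calls) - set(labels))
    if unlabeled:
        raise ValueError(f"called samples without a group label: {unlabeled}")
    uncalled = len(set(labels) - set(calls))
    if uncalled:
        logger.info("%d labeled samples lack a serum call and are excluded", uncalled)
    tp = fp = tn = fn = 0
    for sample, call in calls.items():
        if call not in (MSP_POSITIVE, MSP_NEGATIVE):
            raise ValueError(f"sample {sample}: call must be 'M' or 'U', got {call!r}")
        diseased = labels[sample] in positive_groups
        positive = call == MSP_POSITIVE
        if diseased and positive:
            tp += 1
        elif diseased:
            fn += 1
        elif positive:
            fp += 1
        else:
            tn += 1
    return DxTable(TP=tp, FP=fp, TN=tn, FN=fn, positive_definition=frozenset(positive_groups))


def dx_metrics(t: DxTable, mode: FormatMode = "truncate1") -> DxMetrics:
    """Sensitivity, specificity, PPV and NPV (percent) of a confusion table."""
    return DxMetrics(
        sensitivity=_format_percent(t.TP, t.TP + t.FN, mode),
        specificity=_format_percent(t.TN, t.TN + t.FP, mode),
        ppv=_format_percent(t.TP, t.TP + t.FP, mode),
        npv=_format_percent(t.TN, t.TN + t.FN, mode),
        mode=mode,
    )


@dataclass(frozen=True)
class DxReport:
    """Two-block diagnostic report: cancer-only and cancer-or-IM positives."""

    cancer_table: DxTable
    cancer_metrics: DxMetrics
    cancer_or_im_table: DxTable
    cancer_or_im_metrics: DxMetrics


def table_report(
    cohort: pd.DataFrame,
    cancer_group: str = "cancer",
    im_group: str = "IM",
    mode: FormatMode = "truncate1",
) -> DxReport:
    """Diagnostic metrics of serum MSP calls under two disease definitions.

    Block 1 takes cancer alone as disease-positive; block 2 takes cancer or
    intestinal metaplasia.  Both blocks share the same negative set — serum
    samples from groups in neither definition (the non-cancer controls) — so
    IM serum samples are excluded from block 1 rather than counted negative.

    Expects cohort columns sample_id, group, msp_call, serum_available.
    """
    required = {"sample_id", "group", "msp_call", "serum_available"}
    if not required.issubset(cohort.columns):
        raise ValueError(f"cohort needs columns {sorted(required)}")
    serum = cohort[cohort["serum_available"].astype(int) == 1]
    if serum.empty:
        raise ValueError("cohort has no serum samples")
    labels = dict(zip(serum["sample_id"], serum["group"]))
    calls = dict(zip(serum["sample_id"], serum["msp_call"]))
    negative_groups = set(labels.values()) - {cancer_group, im_group}
    if not any(g in negative_groups for g in labels.values()):
        raise ValueError("no disease-negative serum samples in cohort")

    def block(positive_groups: set[str]) -> tuple[DxTable, DxMetrics]:
        keep = {
            s: c
            for s, c in calls.items()
            if labels[s] in positive_groups or labels[s] in negative_groups
        }
        t = confusion(keep, labels, positive_groups)
        return t, dx_metrics(t, mode)

    t1, m1 = block({cancer_group})
    t2, m2 = block({cancer_group, im_group})
    return DxReport(
        cancer_table=t1, cancer_metrics=m1, cancer_or_im_table=t2, cancer_or_im_metrics=m2
    )


def _fmt(v: float | None) -> str:
    return "undefined" if v is None else f"{v:.1f}%"


def report_text(report: DxReport) -> str:
    """Human-readable two-column block mirroring a published diagnostics table."""
    lines = [
        f"{'':24s}{'Cancer only':>18s}{'Cancer or IM':>18s}",
        f"{'n positive':24s}{report.cancer_table.n_positive:>18d}"
        f"{report.cancer_or_im_table.n_positive:>18d}",
        f"{'n negative (shared)':24s}{report.cancer_table.n_negative:>18d}"
        f"{report.cancer_or_im_table.n_negative:>18d}",
    ]
    for name in ("sensitivity", "specificity", "ppv", "npv"):
        lines.append(
            f"{name:24s}{_fmt(getattr(report.cancer_metrics, name)):>18s}"
            f"{_fmt(getattr(report.cancer_or_im_metrics, name)):>18s}"
        )
    return "\n".join(lines)


def report_frame(report: DxReport) -> pd.DataFrame:
    rows = []
    for block, t, m in (
        ("cancer_only", report.cancer_table, report.cancer_metrics),
        ("cancer_or_im", report.cancer_or_im_table, report.cancer_or_im_metrics),
    ):
        rows.append(
            {
                "block": block,
                "TP": t.TP,
                "FN": t.FN,
                "FP": t.FP,
                "TN": t.TN,
                "sensitivity": m.sensitivity,
                "specificity": m.specificity,
                "ppv": m.ppv,
                "npv": m.npv,
            }
        )
    return pd.DataFrame(rows)
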