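"""β-value computation and differential-probe selection for two-condition Infinium-style arrays.

The methylation level of a probe is summarised as

    β = M / (U + M + 100)

where ``M`` and ``U`` are the fluorescence intensities of the methylated and
unmethylated allele and the +100 offset regularises low-intensity probes
(β is therefore strictly below 1).  Differential probes between a case and a
control condition are selected on Δβ = mean β(case) − mean β(control) with an
inclusive threshold (default 0.25, i.e. a 25-percentage-point methylation
difference).
"""

from __future__ import annotations

from typing import Iterable, Literal

import numpy as np
import pandas as pd

BETA_OFFSET = 100.0

#: columns identifying a probe in an intensity table
PROBE_META_COLUMNS = ["probe_id", "chrom", "pos", "gene"]

Direction = Literal["hypo", "hyper", "both"]


def compute_beta(M, U):
    """β-value of a probe: ``M / (U + M + 100)``.

    Accepts scalars or arrays; intensities must be non-negative.
    """
    M = np.asarray(M, dtype=float)
    U = np.asarray(U, dtype=float)
    if np.any(M < 0) or np.any(U < 0):
        raise ValueError("intensities must be non-negative")
    beta = M / (U + M + BETA_OFFSET)
    return beta.item() if beta.ndim == 0 else beta


def sample_names(table: pd.DataFrame) -> list[str]:
    """Sample names of an intensity table (columns come in ``M_<name>``/``U_<name>`` pairs)."""
    ms = [c[2:] for c in table.columns if c.startswith("M_")]
    us = [c[2:] for c in table.columns if c.startswith("U_")]
    if ms != us:
        raise ValueError(f"unpaired intensity columns: M for {ms}, U for {us}")
    return ms


def beta_matrix(table: pd.DataFrame, min_total_intensity: float = 0.0) -> pd.DataFrame:
    """β-values for every probe × sample of an intensity table.

    Parameters
    ----------
    table
        Intensity table with ``probe_id`` plus paired ``M_<sample>`` /
        ``U_<sample>`` columns (as written by the simulator or read with
        :func:`read_intensity_table`).
    min_total_intensity
        Optional floor on ``M + U``; probes below it in any sample get ``NaN``
        there.  Default 0 disables the filter.

    Returns
    -------
    DataFrame indexed by ``probe_id`` (input order preserved), one column per
    sample, entries equal to the scalar β formula applied cell-wise.
    """
    if "probe_id" not in table.columns:
        raise ValueError("intensity table lacks a probe_id column")
    if table["probe_id"].duplicated().any():
        dups = table.loc[table["probe_id"].duplicated(), "probe_id"].tolist()
        raise ValueError(f"duplicate probe ids: {dups}")
    names = sample_names(table)
    out = {}
    for name in names:
        M = table[f"M_{name}"].to_numpy(dtype=float)
        U = table[f"U_{name}"].to_numpy(dtype=float)
        bad = ~np.isfinite(M) | ~np.isfinite(U)
        if bad.any():
            raise ValueError(f"malformed intensity at row {int(np.flatnonzero(bad)[0])} (sample {name})")
        beta = compute_beta(M, U)
        if min_total_intensity > 0:
            beta = np.where(M + U < min_total_intensity, np.nan, beta)
        out[name] = beta
    return pd.DataFrame(out, index=pd.Index(table["probe_id"], name="probe_id"))


def delta_beta(case: pd.DataFrame, control: pd.DataFrame) -> pd.Series:
    """Δβ per probe: mean β over case samples minus mean β over control samples.

    Both tables must cover the same probe set; replicates are combined by the
    arithmetic mean of β within each condition before differencing.
    """
    missing_in_control = case.index.difference(control.index)
    missing_in_case = control.index.difference(case.index)
    if len(missing_in_control) or len(missing_in_case):
        raise ValueError(
            "probe sets differ: only in case "
            f"{sorted(missing_in_control)}; only in control {sorted(missing_in_case)}"
        )
    control = control.reindex(case.index)
    delta = case.mean(axis=1) - control.mean(axis=1)
    delta.name = "delta_beta"
    return delta


def select_differential(
    deltas: pd.Series, threshold: float = 0.25, direction: Direction = "hypo"
) -> pd.Index:
    """Probes whose Δβ passes an inclusive threshold.

    ``hypo`` keeps Δβ ≤ −threshold, ``hyper`` keeps Δβ ≥ +threshold, ``both``
    keeps |Δβ| ≥ threshold.  The boundary value is included ("at least" a
    25-point difference at the default).
    """
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must be in (0,1), got {threshold}")
    if direction == "hypo":
        mask = deltas <= -threshold
    elif direction == "hyper":
        mask = deltas >= threshold
    elif direction == "both":
        mask = deltas.abs() >= threshold
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return deltas.index[mask]


def read_intensity_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    sample_names(table)  # validates pairing
    return table


def write_intensity_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_delta_table(deltas: pd.Series, path) -> None:
    """Write Δβ sorted ascending (most hypomethylated first) for inspection."""
    deltas.sort_values().to_frame().to_csv(path, sep="\t")


def read_delta_table(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col="probe_id")
    return df["delta_beta"]
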