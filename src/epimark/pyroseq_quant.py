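"""Per-CpG methylation quantification from bisulphite-pyrosequencing signals.

After bisulphite conversion, an unmethylated cytosine reads as T and a
methylated one as C, so per-site methylation % is 100·C/(C+T) from the
fluorescence signals.  An assay covers a handful of CpG sites at fixed
offsets from the TSS (defaults match a promoter assay spanning +1094..+1387
with six CpGs between +1209 and +1229); the per-sample summary is the
unweighted mean over defined sites.  Sites with total signal below a floor
are flagged missing rather than reported as 0 % or 100 %.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_REGION = (1094, 1387)
DEFAULT_SITE_OFFSETS = (1209, 1213, 1217, 1221, 1225, 1229)
DEFAULT_MIN_SIGNAL = 10.0


class UndefinedSiteError(ValueError):
    """Raised when a site (or a whole sample) has no usable signal."""


def site_percent(C_signal: float, T_signal: float, min_signal: float = 0.0) -> float:
    """Methylation % at one CpG: ``100 · C / (C + T)``.

    Raises :class:`UndefinedSiteError` when C + T is zero or below
    ``min_signal`` — a silent 0 % would be indistinguishable from a real
    unmethylated call.
    """
    if C_signal < 0 or T_signal < 0:
        raise ValueError("fluorescence signals must be non-negative")
    total = C_signal + T_signal
    if total == 0 or total < min_signal:
        raise UndefinedSiteError(f"total signal {total} below floor {max(min_signal, 1e-12)}")
    return 100.0 * C_signal / total


@dataclass
class PyroAssay:
    """A pyrosequencing assay: named CpG sites at fixed offsets from the TSS.

    ``signals`` holds per sample a list of (C, T) pairs in site order.
    """

    assay_name: str
    region: tuple[int, int] = DEFAULT_REGION
    site_offsets: tuple[int, ...] = DEFAULT_SITE_OFFSETS
    min_signal: float = DEFAULT_MIN_SIGNAL
    signals: dict[str, list[tuple[float, float]]] = field(default_factory=dict)

    def __post_init__(self):
        if len(self.site_offsets) < 1:
            raise ValueError("assay needs at least one CpG site")
        if list(self.site_offsets) != sorted(set(self.site_offsets)):
            raise ValueError("site offsets must be strictly increasing")

    def add_sample(self, sample_id: str, signals: list[tuple[float, float]]) -> None:
        if len(signals) != len(self.site_offsets):
            raise ValueError(
                f"{sample_id}: {len(signals)} signal pairs for {len(self.site_offsets)} sites"
            )
        self.signals[sample_id] = [(float(c), float(t)) for c, t in signals]


@dataclass
class AssaySummary:
    sample_id: str
    site_percents: list[float]  # NaN where undefined
    mean_percent: float
    n_defined: int
    n_undefined: int


def assay_summary(assay: PyroAssay, sample_id: str) -> AssaySummary:
    """Per-site methylation % and their unweighted mean for one sample.

    Undefined sites (signal below the assay floor) are excluded from the mean
    and counted; if every site is undefined the sample is unquantifiable and
    an :class:`UndefinedSiteError` is raised.
    """
    if sample_id not in assay.signals:
        raise KeyError(f"sample {sample_id!r} not loaded in assay {assay.assay_name}")
    percents: list[float] = []
    defined: list[float] = []
    for c, t in assay.signals[sample_id]:
        try:
            p = site_percent(c, t, min_signal=assay.min_signal)
        except UndefinedSiteError:
            percents.append(float("nan"))
        else:
            percents.append(p)
            defined.append(p)
    if not defined:
        raise UndefinedSiteError(f"sample {sample_id!r}: all {len(percents)} sites undefined")
    return AssaySummary(
        sample_id=sample_id,
        site_percents=percents,
        mean_percent=float(np.mean(defined)),
        n_defined=len(defined),
        n_undefined=len(percents) - len(defined),
    )


def read_signal_table(path, assay_name: str = "assay", **assay_kwargs) -> PyroAssay:
    """Load a per-site signal TSV (sample_id, site_index, C, T) into a PyroAssay."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "site_index", "C", "T"}
    if not required.issubset(df.columns):
        raise ValueError(f"signal table needs columns {sorted(required)}")
    n_sites = int(df["site_index"].max()) + 1
    if "site_offsets" not in assay_kwargs:
        offsets = DEFAULT_SITE_OFFSETS
        if n_sites != len(offsets):
            offsets = tuple(range(n_sites))
        assay_kwargs["site_offsets"] = offsets
    assay = PyroAssay(assay_name=assay_name, **assay_kwargs)
    for sample_id, sub in df.groupby("sample_id", sort=False):
        sub = sub.sort_values("site_index")
        if list(sub["site_index"]) != list(range(n_sites)):
            raise ValueError(f"sample {sample_id}: site indices not 0..{n_sites - 1}")
        assay.add_sample(str(sample_id), list(zip(sub["C"], sub["T"])))
    return assay


def summarize_all(assay: PyroAssay) -> pd.DataFrame:
    """Per-sample summary table over every loaded sample."""
    rows = []
    for sample_id in assay.signals:
        s = assay_summary(assay, sample_id)
        rows.append(
            {
                "sample_id": s.sample_id,
                "mean_percent": s.mean_percent,
                "n_defined": s.n_defined,
                "n_undefined": s.n_undefined,
                **{
                    f"site_{off}": p
                    for off, p in zip(assay.site_offsets, s.site_percents)
                },
            }
        )
    return pd.DataFrame(rows)
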