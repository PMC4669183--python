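"""Cumulative DVH analysis and CT-vs-MR plan comparison.

The cumulative dose-volume histogram of a target VOI gives, for each dose
level D, the fraction of the VOI receiving at least D ("≥-dose"
convention).  D_x is the dose received by the hottest x % of the volume,
read off the curve with linear interpolation; at an exact plateau crossing
the highest dose on the plateau is returned, so a two-voxel VOI with doses
(10, 20) Gy has D50 = 20 Gy.

MR-based plan metrics are normalised to the CT-based reference
(ratio = MR / CT per metric) and group differences are tested with the
Mann-Whitney U test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .volume import ImageVolume


class DvhError(ValueError):
    pass


@dataclass
class DVHCurve:
    """Cumulative DVH: ``volume_fraction[i]`` is the fraction of the VOI
    receiving at least ``dose_bins[i]`` Gy."""

    dose_bins: np.ndarray
    volume_fraction: np.ndarray

    def __post_init__(self) -> None:
        self.dose_bins = np.asarray(self.dose_bins, dtype=float)
        self.volume_fraction = np.asarray(self.volume_fraction, dtype=float)
        if self.dose_bins.shape != self.volume_fraction.shape:
            raise DvhError("dose_bins and volume_fraction must align")
        if np.any(np.diff(self.dose_bins) <= 0):
            raise DvhError("dose_bins must be strictly ascending")


@dataclass
class DoseMetrics:
    d5: float
    d50: float
    d90: float

    def __post_init__(self) -> None:
        if not self.d5 >= self.d50 >= self.d90:
            raise DvhError(f"expected D5 >= D50 >= D90, got {self.d5}, {self.d50}, {self.d90}")

    def as_dict(self) -> dict[str, float]:
        return {"D5": self.d5, "D50": self.d50, "D90": self.d90}


def cumulative_dvh(dose: ImageVolume, voi: np.ndarray, bin_width: float = 0.05) -> DVHCurve:
    """Exact cumulative DVH of the VOI at bin width <= ``bin_width`` Gy.

    The first bin sits at 0 Gy (fraction 1 for non-negative dose) and the
    last one strictly above the maximum dose (fraction 0).
    """
    voi = np.asarray(voi, dtype=bool)
    if not voi.any():
        raise DvhError("empty VOI")
    doses = np.asarray(dose.data, dtype=float)[voi]
    top = float(doses.max())
    n_bins = max(2, int(np.ceil(top / bin_width)) + 2)
    grid = np.linspace(0.0, top + bin_width, n_bins)
    # include the exact voxel dose values so the curve is the exact step
    # function of the data, not a binned approximation
    bins = np.unique(np.concatenate([grid, doses]))
    sorted_doses = np.sort(doses)
    # fraction receiving >= b: count of doses >= b via searchsorted
    idx = np.searchsorted(sorted_doses, bins, side="left")
    frac = (doses.size - idx) / doses.size
    return DVHCurve(bins, frac)


def d_metric(dvh: DVHCurve, x_percent: float) -> float:
    """Dose received by the hottest ``x_percent`` % of the VOI.

    Returns the largest dose bin whose volume fraction is still >= x/100.
    Because the curve carries the exact voxel dose values as bins, this is
    exact for voxel data (a two-voxel VOI at 10/20 Gy has D50 = 20 Gy under
    the >=-dose convention) and within one bin width of the continuous
    crossing otherwise.
    """
    if not 0 < x_percent < 100:
        raise DvhError("x_percent must lie strictly between 0 and 100")
    target = x_percent / 100.0
    vf = dvh.volume_fraction
    bins = dvh.dose_bins
    above = np.flatnonzero(vf >= target)
    if above.size == 0:
        return float(bins[0])
    return float(bins[above[-1]])


def dose_metrics(dose: ImageVolume, voi: np.ndarray, bin_width: float = 0.05) -> DoseMetrics:
    dvh = cumulative_dvh(dose, voi, bin_width=bin_width)
    return DoseMetrics(
        d5=d_metric(dvh, 5), d50=d_metric(dvh, 50), d90=d_metric(dvh, 90)
    )


def compare_to_ct(
    ct_metrics: dict[str, DoseMetrics],
    mr_metrics_by_method: dict[str, dict[str, DoseMetrics]],
) -> pd.DataFrame:
    """Normalise MR-based metrics to the CT-based reference.

    ``ct_metrics`` maps beam-configuration name -> metrics;
    ``mr_metrics_by_method`` maps method name -> {configuration -> metrics}.
    Returns one row per (method, configuration) with D5/D50/D90 ratios.
    """
    rows = []
    for method, per_config in mr_metrics_by_method.items():
        for config, mr in per_config.items():
            if config not in ct_metrics:
                raise DvhError(f"no CT reference for configuration {config!r}")
            ct = ct_metrics[config]
            for name, ct_val in ct.as_dict().items():
                if ct_val == 0:
                    raise DvhError(f"zero CT {name} for configuration {config!r}")
            rows.append(
                {
                    "method": method,
                    "configuration": config,
                    "ratio_D5": mr.d5 / ct.d5,
                    "ratio_D50": mr.d50 / ct.d50,
                    "ratio_D90": mr.d90 / ct.d90,
                }
            )
    return pd.DataFrame(rows)


def aggregate_ratios(frames: list[pd.DataFrame]) -> pd.DataFrame:
    """Mean +/- SD of per-animal normalised metrics, one row per
    (method, configuration)."""
    if not frames:
        raise DvhError("no ratio tables to aggregate")
    allrows = pd.concat(frames, ignore_index=True)
    return (
        allrows.groupby(["method", "configuration"])
        .agg(
            ratio_D5_mean=("ratio_D5", "mean"),
            ratio_D5_sd=("ratio_D5", "std"),
            ratio_D50_mean=("ratio_D50", "mean"),
            ratio_D50_sd=("ratio_D50", "std"),
            ratio_D90_mean=("ratio_D90", "mean"),
            ratio_D90_sd=("ratio_D90", "std"),
            n_animals=("ratio_D50", "size"),
        )
        .reset_index()
    )


def mann_whitney(group_a, group_b) -> tuple[float, float]:
    """Mann-Whitney U test (two-sided).

    Exact null distribution when the combined sample size is <= 20 and no
    ties are present; otherwise the normal approximation with tie and
    continuity correction.  Returns ``(U, p)`` with U counted for the first
    group.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (a.size + b.size <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
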