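"""Dice-coefficient evaluation of segmentations.

Agreement between a reference segmentation and an automatic one is scored
with the 3-D Dice coefficient per tissue class,

    D_t = 2 |R_t ∩ A_t| / (|R_t| + |A_t|),

computed independently for bone and soft tissue; their average is the
final similarity measure (air is reported as a diagnostic only, since the
vast background would dominate it).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fcm_segmentation import AsmrImage, subset_name
from .volume import AIR, BONE, SOFT, LabelVolume


@dataclass
class DiceReport:
    combination: str
    dice_bone: float
    dice_soft: float
    dice_air: float
    dice_mean: float
    n_ref_voxels: dict[int, int]


def dice_class(ref: LabelVolume, test: LabelVolume, tissue: int) -> float:
    """Dice coefficient for one tissue class.

    Returns 1 (with a warning) if the class is absent from both volumes —
    vacuous perfect agreement, kept finite so rankings stay total.
    """
    ref.check_same_grid(test)
    a = ref.class_mask(tissue)
    b = test.class_mask(tissue)
    na = int(a.sum())
    nb = int(b.sum())
    if na == 0 and nb == 0:
        warnings.warn(f"tissue class {tissue} absent from both volumes; Dice set to 1")
        return 1.0
    inter = int(np.count_nonzero(a & b))
    return 2.0 * inter / (na + nb)


def dice_report(ref: LabelVolume, asmr: AsmrImage) -> DiceReport:
    d_bone = dice_class(ref, asmr.labels, BONE)
    d_soft = dice_class(ref, asmr.labels, SOFT)
    d_air = dice_class(ref, asmr.labels, AIR)
    return DiceReport(
        combination=subset_name(asmr.combination),
        dice_bone=d_bone,
        dice_soft=d_soft,
        dice_air=d_air,
        dice_mean=0.5 * (d_bone + d_soft),
        n_ref_voxels=ref.class_counts(),
    )


def evaluate_sweep(ref: LabelVolume, asmr_list: list[AsmrImage]) -> list[DiceReport]:
    """Score every ASMR image against the reference, ranked by mean
    (bone+soft) Dice, descending; the sort is stable."""
    if not asmr_list:
        raise ValueError("empty ASMR list")
    reports = [dice_report(ref, a) for a in asmr_list]
    reports.sort(key=lambda r: -r.dice_mean)
    return reports


def reports_to_frame(reports: list[DiceReport]) -> pd.DataFrame:
    """Tabulate ranked reports (CSV-ready)."""
    rows = [
        {
            "combination": r.combination,
            "dice_bone": r.dice_bone,
            "dice_soft": r.dice_soft,
            "dice_air": r.dice_air,
            "dice_mean": r.dice_mean,
            "rank": i + 1,
        }
        for i, r in enumerate(reports)
    ]
    return pd.DataFrame(rows)


def aggregate_dice(frames: list[pd.DataFrame]) -> pd.DataFrame:
    """Mean +/- SD of per-animal mean Dice for each combination.

    Each input frame is one animal's ranked sweep; the aggregate reports
    the arithmetic mean and SD across animals, re-ranked by mean.
    """
    if not frames:
        raise ValueError("no frames to aggregate")
    allrows = pd.concat(frames, ignore_index=True)
    agg = (
        allrows.groupby("combination")
        .agg(
            dice_mean=("dice_mean", "mean"),
            dice_sd=("dice_mean", "std"),
            dice_bone=("dice_bone", "mean"),
            dice_soft=("dice_soft", "mean"),
            n_animals=("dice_mean", "size"),
        )
        .reset_index()
        .sort_values("dice_mean", ascending=False, kind="stable")
        .reset_index(drop=True)
    )
    agg["rank"] = np.arange(1, len(agg) + 1)
    return agg
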