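"""Weighted cell counting and dual-channel classification.

Touching cells merge into single segmented objects; rather than splitting
them, each object is weighted by its area relative to the median object
area — an object twice the median counts as 2 cells, three times as 3,
and so on, with a minimum weight of 1.  Weights sum to the image's cell
count.

For two-reporter images, each object is classified by the ratio r of the
two channels' mean intensities: r > 2 is positive for channel A only,
r < 0.5 for channel B only, and the closed interval [0.5, 2] is double
positive.  A merged object carries its whole weight into its one class.
"""

from __future__ import annotations

import math
from enum import Enum

import numpy as np

from eecquant.detection import DetectedObject

RATIO_HIGH = 2.0
RATIO_LOW = 0.5


class ClassLabel(str, Enum):
    """Dual-reporter class of an object (A = numerator channel)."""

    A_ONLY = "A_only"
    B_ONLY = "B_only"
    DOUBLE = "double"


def assign_weights(objects: list[DetectedObject]) -> list[DetectedObject]:
    """Assign the touching-cell multiplicity weight to each object.

    weight = max(1, round_half_up(area / median_area)), with the median
    taken as the mean of the middle two areas for an even number of
    objects.  Idempotent: weights are recomputed from areas only.
    """
    if not objects:
        return []
    median = float(np.median([o.area for o in objects]))
    if median <= 0:
        raise ValueError("median object area is zero")
    for obj in objects:
        obj.weight = max(1, _round_half_up(obj.area / median))
    return objects


def _round_half_up(x: float) -> int:
    return math.floor(x + 0.5)


def weighted_total(objects: list[DetectedObject]) -> int:
    """Total cell count for an image: the sum of object weights."""
    return int(sum(o.weight for o in objects))


def classify_dual(
    objects: list[DetectedObject],
    a_channel: int = 0,
    b_channel: int = 1,
    t_high: float = RATIO_HIGH,
    t_low: float = RATIO_LOW,
) -> list[tuple[DetectedObject, ClassLabel]]:
    """Classify objects by the A:B mean-intensity ratio.

    r = mean_A / mean_B (taken as +inf when mean_B is 0 and mean_A > 0).
    r > t_high -> A_only; r < t_low -> B_only; t_low <= r <= t_high ->
    double positive (boundaries inclusive).  Labels are invariant to
    rescaling both channels by the same positive constant.
    """
    out = []
    for obj in objects:
        mean_a = obj.mean_intensity[a_channel]
        mean_b = obj.mean_intensity[b_channel]
        if mean_a == 0 and mean_b == 0:
            raise ValueError(
                f"object {obj.object_id} has zero mean intensity in both channels"
            )
        r = mean_a / mean_b if mean_b > 0 else math.inf
        if r > t_high:
            lab = ClassLabel.A_ONLY
        elif r < t_low:
            lab = ClassLabel.B_ONLY
        else:
            lab = ClassLabel.DOUBLE
        out.append((obj, lab))
    return out


def class_totals(
    classified: list[tuple[DetectedObject, ClassLabel]],
) -> dict[ClassLabel, int]:
    """Weighted cell count per class; sums to :func:`weighted_total`."""
    totals = {lab: 0 for lab in ClassLabel}
    for obj, lab in classified:
        totals[lab] += obj.weight
    return totals
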