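"""Recruitment scoring: the IN/OUT ratio and the clustering index.

The IN/OUT ratio is the mean marker (mTOR) intensity over all object pixels
(IN) divided by the mean over all ring pixels (OUT), one ratio per image
(pooled pixels, not a mean of per-object ratios).  Because it is a ratio of
means of a background-subtracted image, it is invariant to multiplicative
intensity scaling but *not* to additive offsets — which is why background
subtraction must precede it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Channel, InvalidParameterError, Mask
from .puncta import InOutMasks


@dataclass
class RecruitmentResult:
    """Per-image IN/OUT recruitment measurement.

    `valid` is False when the measurement is undefined (no objects, no ring
    pixels, or zero background); the reason is recorded rather than the row
    being dropped, so per-condition n stays auditable.
    """

    image_id: str
    condition: str
    mean_in: float
    mean_out: float
    ratio: float
    n_in_pixels: int
    n_out_pixels: int
    n_objects: int
    valid: bool = True
    reason: str = ""
    per_object: pd.DataFrame | None = field(default=None, repr=False)

    def to_row(self) -> dict:
        return {
            "image_id": self.image_id,
            "condition": self.condition,
            "mean_in": self.mean_in,
            "mean_out": self.mean_out,
            "ratio": self.ratio,
            "n_in_pixels": self.n_in_pixels,
            "n_out_pixels": self.n_out_pixels,
            "n_objects": self.n_objects,
            "valid": self.valid,
            "reason": self.reason,
        }


def _invalid(image_id: str, condition: str, reason: str,
             n_in: int = 0, n_out: int = 0, n_objects: int = 0) -> RecruitmentResult:
    return RecruitmentResult(
        image_id=image_id, condition=condition,
        mean_in=float("nan"), mean_out=float("nan"), ratio=float("nan"),
        n_in_pixels=n_in, n_out_pixels=n_out, n_objects=n_objects,
        valid=False, reason=reason,
    )


def in_out_ratio(
    mtor: Channel,
    masks: InOutMasks,
    image_id: str = "",
    condition: str = "",
    n_objects: int | None = None,
) -> RecruitmentResult:
    """Measure the IN/OUT ratio of a marker channel over prepared masks.

    mean_in is the mean of `mtor` over the IN mask, mean_out over the ring
    OUT mask; ratio = mean_in / mean_out.  When `masks` carries per-object
    footprints, a per-object table (id, mean_in, mean_out, ratio) is
    attached.
    """
    in_vals = masks.in_mask.values
    out_vals = masks.out_mask.values
    if mtor.shape != in_vals.shape:
        raise InvalidParameterError("channel and mask shapes differ")
    n_in = int(in_vals.sum())
    n_out = int(out_vals.sum())
    n_obj = n_objects if n_objects is not None else len(masks.per_object_in)
    if n_in == 0:
        return _invalid(image_id, condition, "no-objects", n_in, n_out, n_obj)
    if n_out == 0:
        return _invalid(image_id, condition, "no-ring", n_in, n_out, n_obj)
    mean_in = float(mtor.values[in_vals].mean())
    mean_out = float(mtor.values[out_vals].mean())
    if mean_out == 0:
        return _invalid(image_id, condition, "zero-background", n_in, n_out, n_obj)

    per_object = None
    if masks.per_object_in:
        rows = []
        for obj_id in sorted(masks.per_object_in):
            oin = masks.per_object_in[obj_id]
            oring = masks.per_object_rings.get(obj_id, np.zeros_like(oin))
            if oin.sum() == 0 or oring.sum() == 0:
                rows.append({"id": obj_id, "mean_in": np.nan, "mean_out": np.nan,
                             "ratio": np.nan})
                continue
            m_in = float(mtor.values[oin].mean())
            m_out = float(mtor.values[oring].mean())
            rows.append({
                "id": obj_id, "mean_in": m_in, "mean_out": m_out,
                "ratio": m_in / m_out if m_out > 0 else np.nan,
            })
        per_object = pd.DataFrame(rows, columns=["id", "mean_in", "mean_out", "ratio"])

    return RecruitmentResult(
        image_id=image_id,
        condition=condition,
        mean_in=mean_in,
        mean_out=mean_out,
        ratio=mean_in / mean_out,
        n_in_pixels=n_in,
        n_out_pixels=n_out,
        n_objects=n_obj,
        per_object=per_object,
    )


def clustering_index(
    ch: Channel, region: Mask, literal: bool = False
) -> tuple[float, str]:
    """Intensity-contrast clustering index over a region.

    Default formula: (max - min) / mean over the region's pixels — a
    dimensionless contrast measure that is 0 for a uniform region and grows
    as intensity concentrates into clusters.  `literal=True` computes the
    variant (max / min) / mean instead (units 1/intensity; requires a
    strictly positive minimum).

    Returns (index, formula_name).
    """
    if region.area == 0:
        raise InvalidParameterError("clustering_index: empty region")
    vals = ch.values[region.values]
    vmax, vmin, vmean = float(vals.max()), float(vals.min()), float(vals.mean())
    if literal:
        if vmin == 0:
            raise InvalidParameterError(
                "clustering_index(literal): division by zero min"
            )
        return (vmax / vmin) / vmean, "(max/min)/mean"
    return (vmax - vmin) / vmean, "(max-min)/mean"
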