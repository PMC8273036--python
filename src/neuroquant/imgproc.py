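"""Background subtraction and thresholding primitives.

The rolling-ball background estimate used throughout the pipeline is the
grayscale morphological opening of the image with a ball-shaped structuring
element whose height profile is the spherical cap

    b(dr, dc) = sqrt(R^2 - dr^2 - dc^2)   for dr^2 + dc^2 <= R^2,

i.e. the classical "roll a ball of radius R under the intensity surface"
definition.  The public parameter is the ball *diameter* in pixels, the unit
in which such diameters are conventionally reported for this analysis
(R = diameter / 2).  Pixels outside the image are ignored (no padding value
ever influences the result).

Thresholding offers the two methods the pipeline needs: the global *mean*
threshold (t = mean of all pixel values, mask = values > t) and *isodata*
(iterative intermeans: t is a fixed point of t = (mean below + mean above)/2),
the classical default auto-threshold of ImageJ-style tools.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi

from .core import Channel, InvalidParameterError, Mask


def ball_element(radius: float) -> tuple[np.ndarray, np.ndarray]:
    """Footprint (bool) and height profile (float) of a spherical-cap element.

    Both arrays are (2r+1, 2r+1) with r = floor(radius); heights are zero
    outside the footprint.
    """
    if radius <= 0:
        raise InvalidParameterError("ball radius must be > 0")
    r = int(np.floor(radius))
    dr, dc = np.mgrid[-r : r + 1, -r : r + 1]
    d2 = dr * dr + dc * dc
    footprint = d2 <= radius * radius
    heights = np.sqrt(np.maximum(radius * radius - d2, 0.0))
    heights[~footprint] = 0.0
    return footprint, heights


def _grey_opening_ball(values: np.ndarray, radius: float) -> np.ndarray:
    """Grayscale opening with the spherical-cap element, ignoring out-of-image
    pixels (erosion pads +inf, dilation pads -inf)."""
    footprint, heights = ball_element(radius)
    r = footprint.shape[0] // 2
    offs = np.argwhere(footprint)
    hs = heights[tuple(offs.T)]
    n_rows, n_cols = values.shape

    padded = np.pad(values, r, mode="constant", constant_values=np.inf)
    eroded = np.full_like(values, np.inf)
    for (orow, ocol), h in zip(offs, hs):
        window = padded[orow : orow + n_rows, ocol : ocol + n_cols]
        np.minimum(eroded, window - h, out=eroded)

    padded = np.pad(eroded, r, mode="constant", constant_values=-np.inf)
    opened = np.full_like(values, -np.inf)
    for (orow, ocol), h in zip(offs, hs):
        # dilation uses the reflected element; the ball is symmetric
        window = padded[orow : orow + n_rows, ocol : ocol + n_cols]
        np.maximum(opened, window + h, out=opened)
    return opened


def rolling_ball_subtract(ch: Channel, ball_diameter: float) -> Channel:
    """Subtract a rolling-ball background estimate from a channel.

    Parameters
    ----------
    ch : channel to correct (any non-negative float image).
    ball_diameter : diameter of the ball in pixels; the ball radius is
        ``ball_diameter / 2``.

    Returns
    -------
    Channel with ``values = ch.values - opening`` where *opening* is the
    grayscale opening by the spherical-cap element.  The output is
    everywhere >= 0 and <= the input, and structures smaller than the ball
    (puncta) pass through unattenuated.
    """
    if ball_diameter < 1:
        raise InvalidParameterError("ball_diameter must be >= 1 pixel")
    background = _grey_opening_ball(ch.values, ball_diameter / 2.0)
    out = ch.values - background
    # opening <= input pointwise, so out >= 0 up to float round-off
    np.clip(out, 0.0, None, out=out)
    return ch.with_values(out, f"rolling_ball_subtract(d={ball_diameter})")


def mean_threshold_value(values: np.ndarray) -> float:
    return float(values.mean())


def isodata_threshold_value(values: np.ndarray, tol: float = 1e-8) -> float:
    """Iterative intermeans threshold on the raw values.

    Iterates t <- (mean of values <= t + mean of values > t) / 2 from the
    grand mean until the change is below `tol`.  Requires at least two
    distinct values.
    """
    vals = np.asarray(values, dtype=float).ravel()
    if vals.min() == vals.max():
        raise InvalidParameterError("isodata threshold undefined for a constant image")
    t = vals.mean()
    for _ in range(500):
        below = vals[vals <= t]
        above = vals[vals > t]
        if above.size == 0:  # t at or above the max: step back
            t_new = (below.mean() + vals.max()) / 2.0
        else:
            t_new = (below.mean() + above.mean()) / 2.0
        if abs(t_new - t) <= tol:
            return float(t_new)
        t = t_new
    return float(t)


def auto_threshold(ch: Channel, method: str = "isodata") -> Mask:
    """Threshold a channel into a boolean mask (values strictly above t).

    method="mean": t is the arithmetic mean of all pixels.  A constant image
    yields an empty mask (documented degenerate case).
    method="isodata": iterative intermeans fixed point; a constant image
    raises because no threshold exists.
    """
    if method == "mean":
        t = mean_threshold_value(ch.values)
    elif method == "isodata":
        t = isodata_threshold_value(ch.values)
    else:
        raise InvalidParameterError(f"unknown threshold method {method!r}")
    return Mask(
        ch.values > t,
        provenance=f"{ch.name}:{ch.provenance} -> threshold({method}, t={t:.6g})",
    )


def mask_from_signal(
    ch: Channel, method: str = "isodata", min_component_area: int = 50
) -> Mask:
    """Cell-surface mask from a fluorescent signal channel.

    Threshold, fill holes, then reject speckle components smaller than
    `min_component_area` pixels.  Used for transfection-marker masks
    (e.g. mCherry-tagged constructs) delimiting a cell's surface.
    """
    m = auto_threshold(ch, method=method)
    filled = ndi.binary_fill_holes(m.values)
    labels, _ = ndi.label(filled, structure=np.ones((3, 3), dtype=int))
    areas = np.bincount(labels.ravel())
    keep = areas >= min_component_area
    keep[0] = False
    cleaned = keep[labels]
    return Mask(
        cleaned,
        provenance=f"{m.provenance} -> fill_holes -> remove_small(<{min_component_area}px)",
    )
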