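"""Core in-memory containers shared by every analysis stage.

A *field* (one multi-channel micrograph) is the unit of analysis.  Channels
are plain 2D float arrays tagged with a name, a physical pixel size and a
free-text provenance string recording what has been done to them; masks and
labelled objects carry the same provenance so that no anonymous region ever
reaches a measurement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np
import pandas as pd
from skimage.measure import regionprops


class InvalidParameterError(ValueError):
    """A parameter violates a documented precondition."""


@dataclass
class Channel:
    """One named 2D intensity image.

    Parameters
    ----------
    values : 2D float array, non-negative finite intensities.
    pixel_size : physical pixel pitch in nm/pixel.
    name : stain name ("MAP2", "LAMP1", "mTOR", "P-pS6", ...).
    provenance : processing history, appended to by each operation.
    """

    values: np.ndarray
    pixel_size: float = 65.0
    name: str = ""
    provenance: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InvalidParameterError(
                f"channel {self.name!r}: expected 2D array, got {self.values.ndim}D"
            )
        if not np.all(np.isfinite(self.values)):
            raise InvalidParameterError(f"channel {self.name!r}: non-finite values")
        if self.pixel_size <= 0:
            raise InvalidParameterError("pixel_size must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def with_values(self, values: np.ndarray, step: str) -> "Channel":
        """Return a copy holding `values`, with `step` appended to provenance."""
        return Channel(
            values=values,
            pixel_size=self.pixel_size,
            name=self.name,
            provenance=f"{self.provenance} -> {step}",
        )


@dataclass
class Mask:
    """Boolean region with provenance (which channel/threshold produced it)."""

    values: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.ndim != 2:
            raise InvalidParameterError("mask must be 2D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def area(self) -> int:
        return int(self.values.sum())

    def __and__(self, other: "Mask") -> "Mask":
        return Mask(self.values & other.values,
                    provenance=f"({self.provenance}) AND ({other.provenance})")

    def __invert__(self) -> "Mask":
        return Mask(~self.values, provenance=f"NOT ({self.provenance})")


@dataclass
class LabeledObjects:
    """Integer-labelled segmented objects (0 = background).

    Object ids are consecutive from 1.  Per-object area, centroid and
    equivalent diameter (in nm, derived from `pixel_size`) are exposed as a
    DataFrame via :meth:`table`.
    """

    labels: np.ndarray
    pixel_size: float = 65.0
    provenance: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise InvalidParameterError("labels must be 2D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            self.labels = self.labels.astype(np.int32)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def n_objects(self) -> int:
        return int(self.labels.max())

    @property
    def ids(self) -> list[int]:
        return list(range(1, self.n_objects + 1))

    def table(self) -> pd.DataFrame:
        """Per-object id, area (px), centroid (row, col), equivalent diameter (nm)."""
        rows = []
        for rp in regionprops(self.labels):
            rows.append(
                {
                    "id": rp.label,
                    "area": int(rp.area),
                    "centroid_row": rp.centroid[0],
                    "centroid_col": rp.centroid[1],
                    "equivalent_diameter_nm": rp.equivalent_diameter_area
                    * self.pixel_size,
                }
            )
        return pd.DataFrame(
            rows,
            columns=["id", "area", "centroid_row", "centroid_col",
                     "equivalent_diameter_nm"],
        )

    def footprint(self) -> Mask:
        return Mask(self.labels > 0, provenance=f"footprint({self.provenance})")

    def mask_of(self, object_id: int) -> np.ndarray:
        return self.labels == object_id


@dataclass
class MultiChannelImage:
    """Named 2D channels sharing shape and pixel size: one field of view."""

    channels: dict[str, Channel] = field(default_factory=dict)
    image_id: str = ""

    def __post_init__(self) -> None:
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) > 1:
            raise InvalidParameterError(f"channel shapes differ: {shapes}")
        sizes = {ch.pixel_size for ch in self.channels.values()}
        if len(sizes) > 1:
            raise InvalidParameterError(f"channel pixel sizes differ: {sizes}")

    @property
    def shape(self) -> tuple[int, int]:
        ch = next(iter(self.channels.values()))
        return ch.shape

    @property
    def pixel_size(self) -> float:
        return next(iter(self.channels.values())).pixel_size

    def __getitem__(self, name: str) -> Channel:
        return self.channels[name]

    def __contains__(self, name: str) -> bool:
        return name in self.channels

    def __iter__(self) -> Iterator[str]:
        return iter(self.channels)

    @classmethod
    def from_arrays(
        cls,
        arrays: Mapping[str, np.ndarray],
        pixel_size: float = 65.0,
        image_id: str = "",
    ) -> "MultiChannelImage":
        return cls(
            channels={
                name: Channel(values=arr, pixel_size=pixel_size, name=name)
                for name, arr in arrays.items()
            },
            image_id=image_id,
        )
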