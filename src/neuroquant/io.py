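"""Reading fixtures and real TIFF data back into analysis containers."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .core import Channel, LabeledObjects, Mask, MultiChannelImage
from .simulate import GroundTruth


def read_channels(
    path: "str | Path",
    channel_names: list[str],
    pixel_size: float = 65.0,
    image_id: str = "",
) -> MultiChannelImage:
    """Read a multi-page TIFF into a MultiChannelImage (page i = name i)."""
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.shape[0] < len(channel_names):
        raise ValueError(
            f"{path}: {arr.shape[0]} pages but {len(channel_names)} channel names"
        )
    return MultiChannelImage.from_arrays(
        {name: arr[i].astype(float) for i, name in enumerate(channel_names)},
        pixel_size=pixel_size,
        image_id=image_id or Path(path).stem,
    )


def read_fixture(
    sidecar_path: "str | Path",
) -> tuple[MultiChannelImage, GroundTruth | None]:
    """Load a simulated fixture (channels + ground truth) from its sidecar.

    Inverse of :func:`neuroquant.simulate.write_fixture`; channel arrays
    round-trip bit-for-bit against the 16-bit quantized values written.
    """
    sidecar_path = Path(sidecar_path)
    with open(sidecar_path) as fh:
        meta = json.load(fh)
    if meta.get("schema_version") != 1:
        raise ValueError(f"{sidecar_path}: unsupported truth schema version")
    directory = sidecar_path.parent
    stem = sidecar_path.name[: -len("_truth.json")]
    names = meta["channel_order"]
    pixel_size = float(meta["pixel_size"])
    if meta.get("multipage", True):
        image = read_channels(
            directory / f"{stem}.tif", names, pixel_size, meta.get("image_id", stem)
        )
    else:
        arrays = {
            n: tifffile.imread(
                directory / f"{stem}_{n.replace('/', '-')}.tif"
            ).astype(float)
            for n in names
        }
        image = MultiChannelImage.from_arrays(
            arrays, pixel_size=pixel_size, image_id=meta.get("image_id", stem)
        )

    truth = None
    if "truth_labels_file" in meta:
        pages = tifffile.imread(directory / meta["truth_labels_file"])
        truth = GroundTruth(
            map2_mask=Mask(pages[0] > 0, provenance="truth map2 (reloaded)"),
            soma_labels=LabeledObjects(
                pages[1].astype(np.int32), pixel_size=pixel_size,
                provenance="truth somata (reloaded)",
            ),
            dendrite_centerlines={
                int(k): np.asarray(v, dtype=float)
                for k, v in meta["dendrite_centerlines"].items()
            },
            le_labels=LabeledObjects(
                pages[2].astype(np.int32), pixel_size=pixel_size,
                provenance="truth LEs (reloaded)",
            ),
            per_le_enrichment={
                int(k): float(v) for k, v in meta["per_le_enrichment"].items()
            },
            dendrite_neuron={
                int(k): int(v)
                for k, v in meta.get("dendrite_neuron", {}).items()
            },
            hotspot_truth=[(int(d), float(s)) for d, s in meta["hotspot_truth"]],
            dendrite_id_map=pages[3].astype(np.int32),
            dendrite_arclength=pages[4].astype(float),
            pixel_size=pixel_size,
        )
    return image, truth
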