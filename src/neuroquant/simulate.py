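"""Synthetic multi-channel neuron fields with full ground truth.

The generator renders the four stains the analysis consumes:

* **MAP2** — somatodendritic marker: disk somata with piecewise-linear
  dendrites radiating outward (no branching; bounded turning angle).
* **LAMP1** — punctate late-endosome (LE) objects: disks (optionally
  annular, emulating the donut-like appearance of larger LEs) centred on
  dendrite centerlines, non-overlapping by default.
* **mTOR** — diffuse cytoplasmic signal over the MAP2 support, multiplied
  by a per-object enrichment factor inside each LE.  An enrichment of 1
  means no recruitment; the enrichment is the ground-truth analogue of the
  measured IN/OUT ratio.
* **P-pS6** — activity proxy: constant in somata, decaying exponentially
  with arclength along each dendrite, with optional Gaussian hot spots at
  chosen arclength positions.

Photophysics is layered on top of the noise-free render: additive
background with a smooth shading gradient, isotropic Gaussian PSF blur,
Poisson shot noise and additive Gaussian read noise.  Everything is
deterministic for a fixed seed, and the noise-free render does not consume
randomness at all.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage as ndi

from .core import (
    Channel,
    InvalidParameterError,
    LabeledObjects,
    Mask,
    MultiChannelImage,
)

logger = logging.getLogger(__name__)

CHANNEL_ORDER = ("MAP2", "LAMP1", "mTOR", "P-pS6")
TRUTH_SCHEMA_VERSION = 1


def _check_range(name: str, rng: tuple[float, float]) -> None:
    lo, hi = rng
    if lo > hi:
        raise InvalidParameterError(f"{name}: low {lo} > high {hi}")
    if lo < 0:
        raise InvalidParameterError(f"{name}: must be non-negative")


@dataclass
class GeometryParams:
    """Geometry of one synthetic field.

    Defaults describe a dendrite-scale field at 65 nm/pixel (100x-objective
    regime), where the 25-px object-size floor corresponds to ~350 nm
    equivalent diameter.
    """

    image_shape: tuple[int, int] = (512, 512)
    pixel_size: float = 65.0
    n_neurons: int = 12
    soma_radius_range: tuple[float, float] = (10.0, 16.0)
    dendrites_per_neuron: int = 4
    dendrite_length_range: tuple[float, float] = (120.0, 220.0)
    dendrite_width_range: tuple[float, float] = (4.0, 7.0)
    n_les_per_100um_dendrite: float = 30.0
    le_radius_range: tuple[float, float] = (3.2, 6.0)
    seed: int = 0
    allow_le_overlap: bool = False
    le_annular_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise InvalidParameterError("pixel_size must be > 0")
        if self.n_neurons < 0 or self.dendrites_per_neuron < 0:
            raise InvalidParameterError("counts must be >= 0")
        if self.n_les_per_100um_dendrite < 0:
            raise InvalidParameterError("LE density must be >= 0")
        for nm in ("soma_radius_range", "dendrite_length_range",
                   "dendrite_width_range", "le_radius_range"):
            _check_range(nm, getattr(self, nm))
        if self.n_neurons > 0 and (
            self.soma_radius_range[1] > min(self.image_shape) / 2
        ):
            raise InvalidParameterError(
                "soma radius does not fit inside image_shape"
            )


@dataclass
class PhotophysicsParams:
    """Intensities, optics and noise for rendering a field.

    `mtor_enrichment` is the ground-truth IN/OUT ratio applied uniformly to
    every LE (1 = no recruitment).  `hotspot_positions` lists
    (dendrite id, arclength fraction in [0, 1]) pairs; bump height is
    `hotspot_amplitude` times the local dendritic P-pS6 baseline.
    `pps6_soma_cv` > 0 draws a log-normal per-neuron activity factor with
    that coefficient of variation (unit mean), applied to each neuron's
    soma and dendrites — emulating the inter-neuronal response variability
    that per-soma percentile analyses quantify; 0 (the default) keeps the
    render fully deterministic.
    """

    background_level: float = 20.0
    shading_amplitude: float = 0.0
    map2_intensity: float = 120.0
    lamp1_intensity: float = 150.0
    mtor_cytoplasm_intensity: float = 100.0
    pps6_soma_intensity: float = 150.0
    mtor_enrichment: float = 1.0
    pps6_dendrite_decay_length: float = 80.0
    pps6_soma_cv: float = 0.0
    hotspot_positions: list[tuple[int, float]] = field(default_factory=list)
    hotspot_amplitude: float = 2.5
    hotspot_sigma: float = 3.0
    psf_sigma: float = 0.0
    poisson_noise: bool = False
    gaussian_read_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mtor_enrichment < 0:
            raise InvalidParameterError("mtor_enrichment must be >= 0")
        if self.pps6_dendrite_decay_length <= 0:
            raise InvalidParameterError("decay length must be > 0")


@dataclass
class GroundTruth:
    """Everything the generator knows about a rendered field."""

    map2_mask: Mask
    soma_labels: LabeledObjects
    dendrite_centerlines: dict[int, np.ndarray]
    le_labels: LabeledObjects
    per_le_enrichment: dict[int, float]
    dendrite_neuron: dict[int, int] = field(default_factory=dict)
    hotspot_truth: list[tuple[int, float]] = field(default_factory=list)
    dendrite_id_map: np.ndarray | None = None
    dendrite_arclength: np.ndarray | None = None
    pixel_size: float = 65.0
    geometry_params: GeometryParams | None = None

    @property
    def dendrite_mask(self) -> Mask:
        vals = self.map2_mask.values & ~(self.soma_labels.labels > 0)
        return Mask(vals, provenance="truth dendrites")


def _stamp_disk(canvas: np.ndarray, center: tuple[float, float], radius: float,
                value: int | bool, inner_radius: float = 0.0) -> None:
    """Paint a (possibly annular) disk into an integer or boolean canvas."""
    r0, c0 = center
    r_lo = max(int(np.floor(r0 - radius)), 0)
    r_hi = min(int(np.ceil(r0 + radius)) + 1, canvas.shape[0])
    c_lo = max(int(np.floor(c0 - radius)), 0)
    c_hi = min(int(np.ceil(c0 + radius)) + 1, canvas.shape[1])
    rr, cc = np.mgrid[r_lo:r_hi, c_lo:c_hi]
    d2 = (rr - r0) ** 2 + (cc - c0) ** 2
    sel = d2 <= radius * radius
    if inner_radius > 0:
        sel &= d2 >= inner_radius * inner_radius
    canvas[r_lo:r_hi, c_lo:c_hi][sel] = value


def _resample(path: np.ndarray, step: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    seg = np.diff(path, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    s = np.arange(0.0, cum[-1] + step / 2, step)
    rows = np.interp(s, cum, path[:, 0])
    cols = np.interp(s, cum, path[:, 1])
    return np.column_stack([rows, cols]), s


def polyline_length(path: np.ndarray) -> float:
    seg = np.diff(np.asarray(path, dtype=float), axis=0)
    return float(np.hypot(seg[:, 0], seg[:, 1]).sum())


def make_geometry(params: GeometryParams) -> GroundTruth:
    """Build the geometric ground truth of one field.

    Somata are disks; each neuron grows `dendrites_per_neuron` unbranched
    piecewise-linear dendrites radiating outward with bounded turning angle
    (segments of ~15 px, heading jitter <= 20 degrees), truncated at the
    image border.  LE disks are placed on dendrite centerlines with a
    density of `n_les_per_100um_dendrite` per 100 um of total dendrite
    length; by default placement rejects overlaps so each object's ring
    background is unambiguous.
    """
    rng = np.random.default_rng(params.seed)
    n_rows, n_cols = params.image_shape
    map2 = np.zeros((n_rows, n_cols), dtype=bool)
    soma_labels = np.zeros((n_rows, n_cols), dtype=np.int32)
    dendrite_id_map = np.zeros((n_rows, n_cols), dtype=np.int32)
    arclength = np.full((n_rows, n_cols), np.nan, dtype=float)
    centerlines: dict[int, np.ndarray] = {}

    # --- somata -----------------------------------------------------------
    soma_centers: list[tuple[float, float]] = []
    soma_radii: list[float] = []
    margin = params.soma_radius_range[1] + 4
    for neuron in range(1, params.n_neurons + 1):
        radius = rng.uniform(*params.soma_radius_range)
        for _ in range(200):
            center = (
                rng.uniform(margin, n_rows - margin),
                rng.uniform(margin, n_cols - margin),
            )
            ok = all(
                np.hypot(center[0] - c0, center[1] - c1) > radius + r0 + 8
                for (c0, c1), r0 in zip(soma_centers, soma_radii)
            )
            if ok:
                break
        soma_centers.append(center)
        soma_radii.append(radius)
        _stamp_disk(soma_labels, center, radius, neuron)
        _stamp_disk(map2, center, radius, True)

    # --- dendrites --------------------------------------------------------
    dend_id = 0
    dendrite_neuron: dict[int, int] = {}
    seg_step = 15.0
    max_turn = np.deg2rad(20.0)
    for neuron_idx, (center, radius) in enumerate(zip(soma_centers, soma_radii)):
        base = rng.uniform(0, 2 * np.pi)
        for k in range(params.dendrites_per_neuron):
            dend_id += 1
            heading = base + 2 * np.pi * k / max(params.dendrites_per_neuron, 1)
            heading += rng.uniform(-0.3, 0.3)
            length = rng.uniform(*params.dendrite_length_range)
            width = rng.uniform(*params.dendrite_width_range)
            start = (
                center[0] + radius * np.sin(heading),
                center[1] + radius * np.cos(heading),
            )
            verts = [start]
            pos = np.array(start)
            travelled = 0.0
            while travelled < length:
                step = min(seg_step, length - travelled)
                pos = pos + step * np.array([np.sin(heading), np.cos(heading)])
                if not (2 <= pos[0] < n_rows - 2 and 2 <= pos[1] < n_cols - 2):
                    break
                verts.append(tuple(pos))
                travelled += step
                heading += rng.uniform(-max_turn, max_turn)
            if len(verts) < 2:
                dend_id -= 1
                continue
            path = np.asarray(verts)
            centerlines[dend_id] = path
            dendrite_neuron[dend_id] = neuron_idx + 1
            pts, s_vals = _resample(path, step=1.0)
            half = width / 2.0
            for (pr, pc), s in zip(pts, s_vals):
                _stamp_disk(map2, (pr, pc), half, True)
                r_lo = max(int(np.floor(pr - half)), 0)
                r_hi = min(int(np.ceil(pr + half)) + 1, n_rows)
                c_lo = max(int(np.floor(pc - half)), 0)
                c_hi = min(int(np.ceil(pc + half)) + 1, n_cols)
                rr, cc = np.mgrid[r_lo:r_hi, c_lo:c_hi]
                sel = (rr - pr) ** 2 + (cc - pc) ** 2 <= half * half
                block_id = dendrite_id_map[r_lo:r_hi, c_lo:c_hi]
                block_s = arclength[r_lo:r_hi, c_lo:c_hi]
                assign = sel & (
                    np.isnan(block_s) | ((block_id == dend_id) & (s < block_s))
                )
                block_id[assign] = dend_id
                block_s[assign] = s
    # soma pixels are somatic, not dendritic
    in_soma = soma_labels > 0
    dendrite_id_map[in_soma] = 0
    arclength[in_soma] = np.nan

    # --- late endosomes ---------------------------------------------------
    le_labels = np.zeros((n_rows, n_cols), dtype=np.int32)
    total_len_px = sum(polyline_length(p) for p in centerlines.values())
    total_len_um = total_len_px * params.pixel_size / 1000.0
    n_les = int(round(params.n_les_per_100um_dendrite * total_len_um / 100.0))
    le_centers: list[tuple[float, float]] = []
    le_radii: list[float] = []
    dend_ids = list(centerlines)
    weights = None
    if dend_ids:
        lengths = np.array([polyline_length(centerlines[d]) for d in dend_ids])
        weights = lengths / lengths.sum()
    le_id = 0
    attempts = 0
    while le_id < n_les and dend_ids and attempts < 50 * max(n_les, 1):
        attempts += 1
        d = rng.choice(len(dend_ids), p=weights)
        pts, _ = _resample(centerlines[dend_ids[d]], step=1.0)
        center = tuple(pts[rng.integers(0, len(pts))])
        radius = rng.uniform(*params.le_radius_range)
        if not (
            radius + 1 <= center[0] < n_rows - radius - 1
            and radius + 1 <= center[1] < n_cols - radius - 1
        ):
            continue
        if not params.allow_le_overlap:
            clash = any(
                np.hypot(center[0] - c0, center[1] - c1) <= radius + r0 + 1.5
                for (c0, c1), r0 in zip(le_centers, le_radii)
            )
            if clash:
                continue
        # keep LEs out of somata so they are dendritic objects
        if any(
            np.hypot(center[0] - c0, center[1] - c1) < radius + r0 + 2
            for (c0, c1), r0 in zip(soma_centers, soma_radii)
        ):
            continue
        le_id += 1
        annular = rng.random() < params.le_annular_fraction
        inner = 0.45 * radius if annular else 0.0
        _stamp_disk(le_labels, center, radius, le_id, inner_radius=inner)
        le_centers.append(center)
        le_radii.append(radius)

    return GroundTruth(
        map2_mask=Mask(map2, provenance="truth map2"),
        soma_labels=LabeledObjects(
            soma_labels, pixel_size=params.pixel_size, provenance="truth somata"
        ),
        dendrite_centerlines=centerlines,
        le_labels=LabeledObjects(
            le_labels, pixel_size=params.pixel_size, provenance="truth LEs"
        ),
        per_le_enrichment={i: 1.0 for i in range(1, le_id + 1)},
        dendrite_neuron=dendrite_neuron,
        dendrite_id_map=dendrite_id_map,
        dendrite_arclength=arclength,
        pixel_size=params.pixel_size,
        geometry_params=params,
    )


def noise_free_render(truth: GroundTruth, phys: PhotophysicsParams) -> dict[str, np.ndarray]:
    """Deterministic signal model before blur and noise, one array per channel."""
    shape = truth.map2_mask.shape
    map2 = truth.map2_mask.values
    les = truth.le_labels.labels
    somata = truth.soma_labels.labels > 0

    map2_ch = phys.map2_intensity * map2.astype(float)
    lamp1_ch = phys.lamp1_intensity * (les > 0).astype(float)

    mtor_ch = phys.mtor_cytoplasm_intensity * map2.astype(float)
    for obj_id, enrich in truth.per_le_enrichment.items():
        sel = (les == obj_id) & map2
        mtor_ch[sel] *= enrich

    pps6_ch = np.zeros(shape, dtype=float)
    pps6_ch[somata] = phys.pps6_soma_intensity
    arclen = truth.dendrite_arclength
    dend_ids = truth.dendrite_id_map
    if arclen is not None:
        on_dend = (dend_ids > 0) & ~somata & ~np.isnan(arclen)
        pps6_ch[on_dend] = phys.pps6_soma_intensity * np.exp(
            -arclen[on_dend] / phys.pps6_dendrite_decay_length
        )
        for dend_id, frac in phys.hotspot_positions:
            if dend_id not in truth.dendrite_centerlines:
                raise InvalidParameterError(f"unknown dendrite id {dend_id}")
            s0 = frac * polyline_length(truth.dendrite_centerlines[dend_id])
            local = on_dend & (dend_ids == dend_id)
            baseline = phys.pps6_soma_intensity * np.exp(
                -s0 / phys.pps6_dendrite_decay_length
            )
            bump = (
                phys.hotspot_amplitude
                * baseline
                * np.exp(
                    -((arclen[local] - s0) ** 2) / (2 * phys.hotspot_sigma**2)
                )
            )
            pps6_ch[local] += bump

    if phys.pps6_soma_cv > 0:
        # unit-mean log-normal per-neuron activity factor, one draw per
        # neuron, shared by its soma and dendrites
        n_neurons = truth.soma_labels.n_objects
        sigma = np.sqrt(np.log(1.0 + phys.pps6_soma_cv**2))
        factor_rng = np.random.default_rng(phys.seed + 424243)
        factors = np.exp(
            factor_rng.normal(-(sigma**2) / 2.0, sigma, size=n_neurons)
        )
        factor_map = np.ones(shape)
        for neuron in range(1, n_neurons + 1):
            factor_map[truth.soma_labels.labels == neuron] = factors[neuron - 1]
        if dend_ids is not None:
            for d, neuron in truth.dendrite_neuron.items():
                factor_map[(dend_ids == d) & ~somata] = factors[neuron - 1]
        pps6_ch *= factor_map

    return {"MAP2": map2_ch, "LAMP1": lamp1_ch, "mTOR": mtor_ch, "P-pS6": pps6_ch}


def _shading_field(shape: tuple[int, int]) -> np.ndarray:
    """Smooth deterministic gradient in [-1, 1] (diagonal ramp)."""
    rr = np.linspace(-0.5, 0.5, shape[0])[:, None]
    cc = np.linspace(-0.5, 0.5, shape[1])[None, :]
    return rr + cc  # range [-1, 1]


def render(truth: GroundTruth, phys: PhotophysicsParams) -> MultiChannelImage:
    """Render the four channels with background, shading, PSF blur and noise.

    Side effects on `truth`: `per_le_enrichment` is set to
    `phys.mtor_enrichment` for every object and `hotspot_truth` is filled
    with (dendrite id, arclength px) pairs, so the returned truth matches
    what was actually rendered.
    """
    truth.per_le_enrichment = {
        i: phys.mtor_enrichment for i in truth.per_le_enrichment
    }
    truth.hotspot_truth = [
        (d, frac * polyline_length(truth.dendrite_centerlines[d]))
        for d, frac in phys.hotspot_positions
        if d in truth.dendrite_centerlines
    ]
    signal = noise_free_render(truth, phys)
    shape = truth.map2_mask.shape
    background = phys.background_level * (
        1.0 + phys.shading_amplitude * _shading_field(shape)
    )
    rng = np.random.default_rng(phys.seed)
    channels = {}
    for name in CHANNEL_ORDER:
        img = signal[name] + background
        if phys.psf_sigma > 0:
            img = ndi.gaussian_filter(img, phys.psf_sigma)
        if phys.poisson_noise:
            img = rng.poisson(np.maximum(img, 0.0)).astype(float)
        if phys.gaussian_read_noise_sd > 0:
            img = img + rng.normal(0.0, phys.gaussian_read_noise_sd, size=shape)
        np.clip(img, 0.0, None, out=img)
        channels[name] = Channel(
            values=img,
            pixel_size=truth.pixel_size,
            name=name,
            provenance="synthetic",
        )
    return MultiChannelImage(channels=channels)


def expected_mtor_total(truth: GroundTruth, phys: PhotophysicsParams) -> float:
    """Closed-form total mTOR intensity of the noise-free, blur-free render
    (flat background): cytoplasm mass + extra enrichment mass + background."""
    map2 = truth.map2_mask.values
    les = truth.le_labels.labels
    total = phys.mtor_cytoplasm_intensity * map2.sum()
    for obj_id, enrich in truth.per_le_enrichment.items():
        inter = ((les == obj_id) & map2).sum()
        total += phys.mtor_cytoplasm_intensity * (enrich - 1.0) * inter
    total += phys.background_level * map2.size
    return float(total)


# ---------------------------------------------------------------------------
# Fixture I/O

def _quantize_u16(values: np.ndarray) -> np.ndarray:
    rounded = np.round(values)
    if rounded.max(initial=0) > 65535:
        warnings.warn("intensities exceed 16-bit range; clipping at 65535")
        logger.warning("clipping %d pixels above 65535", int((rounded > 65535).sum()))
    return np.clip(rounded, 0, 65535).astype(np.uint16)


def write_fixture(
    image: MultiChannelImage,
    truth: GroundTruth | None,
    directory: "str | Path",
    stem: str,
    multipage: bool = True,
) -> dict[str, str]:
    """Write one field to disk: 16-bit TIFF channel(s), a float32 truth-label
    TIFF and a JSON truth sidecar (schema-versioned).  Returns the file map.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}
    names = [n for n in CHANNEL_ORDER if n in image.channels]
    try:
        if multipage:
            path = directory / f"{stem}.tif"
            stack = np.stack([_quantize_u16(image[n].values) for n in names])
            tifffile.imwrite(path, stack, photometric="minisblack")
            files["image"] = str(path)
        else:
            for n in names:
                path = directory / f"{stem}_{n.replace('/', '-')}.tif"
                tifffile.imwrite(path, _quantize_u16(image[n].values))
                files[f"channel:{n}"] = str(path)
    except OSError as exc:
        raise OSError(f"failed writing fixture under {directory}: {exc}") from exc

    sidecar = {
        "schema_version": TRUTH_SCHEMA_VERSION,
        "image_id": image.image_id or stem,
        "pixel_size": image.pixel_size,
        "channel_order": names,
        "multipage": multipage,
    }
    if truth is not None:
        labels_path = directory / f"{stem}_truth_labels.tif"
        pages = np.stack(
            [
                truth.map2_mask.values.astype(np.float32),
                truth.soma_labels.labels.astype(np.float32),
                truth.le_labels.labels.astype(np.float32),
                (truth.dendrite_id_map if truth.dendrite_id_map is not None
                 else np.zeros(truth.map2_mask.shape)).astype(np.float32),
                (truth.dendrite_arclength if truth.dendrite_arclength is not None
                 else np.full(truth.map2_mask.shape, np.nan)).astype(np.float32),
            ]
        )
        tifffile.imwrite(labels_path, pages, photometric="minisblack")
        files["truth_labels"] = str(labels_path)
        sidecar.update(
            {
                "per_le_enrichment": {
                    str(k): v for k, v in truth.per_le_enrichment.items()
                },
                "hotspot_truth": [[int(d), float(s)] for d, s in truth.hotspot_truth],
                "dendrite_centerlines": {
                    str(k): np.asarray(v).tolist()
                    for k, v in truth.dendrite_centerlines.items()
                },
                "dendrite_neuron": {
                    str(k): int(v) for k, v in truth.dendrite_neuron.items()
                },
                "truth_labels_file": labels_path.name,
                "truth_label_pages": [
                    "map2_mask", "soma_labels", "le_labels",
                    "dendrite_id_map", "dendrite_arclength",
                ],
            }
        )
    sidecar_path = directory / f"{stem}_truth.json"
    with open(sidecar_path, "w") as fh:
        json.dump(sidecar, fh, indent=1, sort_keys=True)
    files["sidecar"] = str(sidecar_path)
    return files
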