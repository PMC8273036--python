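"""End-to-end pipelines tying simulation, masks, measurements and statistics.

Each `run_*` function consumes a manifest (one row per field: image_id,
condition, file paths) and writes auditable CSVs: every file begins with a
comment block recording the tool version, the configuration hash and the
seed, and floating-point formatting is pinned, so re-running a completed
analysis on unchanged inputs yields byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .activity import field_activity, per_soma_intensities, percentile_shift, segment_somas
from .core import Mask, MultiChannelImage
from .imgproc import auto_threshold, rolling_ball_subtract
from .io import read_fixture
from .puncta import build_in_out, remove_somas, segment_les, somas_from_map2
from .recruitment import in_out_ratio
from .simulate import (
    GeometryParams,
    PhotophysicsParams,
    make_geometry,
    render,
    write_fixture,
)
from .stats import GroupComparison, compare_many, compare_two

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.9g"


@dataclass
class RunConfig:
    """Analysis parameters; defaults are the pipeline's standard settings
    (rolling-ball diameters 50 px for P-pS6 and 75 px for mTOR, 25-px LE
    size floor, ring 6 px out / 4 px wide, mean auto-threshold for the MAP2
    dendrite mask)."""

    pixel_size: float = 65.0
    rolling_ball_diameter_pps6: float = 50.0
    rolling_ball_diameter_mtor: float = 75.0
    le_min_area: int = 25
    ring_gap: float = 6.0
    ring_width: float = 4.0
    map2_threshold_method: str = "mean"
    pps6_threshold_method: str = "isodata"
    min_soma_area: int = 200
    soma_opening_radius: int = 8
    remove_soma_regions: bool = True
    profile_width: int = 3
    hotspot_min_prominence_factor: float = 0.5
    hotspot_min_separation: float = 10.0
    percentile_q: float = 75.0
    control_condition: str = "control"
    write_qc_overlays: bool = False
    seed: int = 0

    def to_yaml(self, path: "str | Path") -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: "str | Path") -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def write_csv(df: pd.DataFrame, path: "str | Path", config: RunConfig) -> None:
    """Write a CSV with a reproducibility comment header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = (
        f"# neuroquant {__version__}\n"
        f"# config_hash: {config.digest()}\n"
        f"# seed: {config.seed}\n"
    )
    body = df.to_csv(index=False, float_format=FLOAT_FORMAT, lineterminator="\n")
    with open(path, "w", newline="") as fh:
        fh.write(header)
        fh.write(body)


# ---------------------------------------------------------------------------
# simulate

def run_simulate(
    config: RunConfig,
    out_dir: "str | Path",
    n_images: int,
    conditions: dict[str, float],
    geometry: GeometryParams | None = None,
    phys: PhotophysicsParams | None = None,
    hotspot_conditions: dict[str, list[tuple[int, float]]] | None = None,
) -> pd.DataFrame:
    """Write `n_images` fixture fields per condition; `conditions` maps the
    condition name to its ground-truth mTOR enrichment.  Returns (and
    writes) the manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    geometry = geometry or GeometryParams()
    phys = phys or PhotophysicsParams()
    hotspot_conditions = hotspot_conditions or {}
    rows = []
    counter = 0
    for condition, enrichment in conditions.items():
        for i in range(n_images):
            counter += 1
            seed = config.seed * 100003 + counter
            geo = dataclasses.replace(geometry, seed=seed)
            ph = dataclasses.replace(
                phys,
                mtor_enrichment=enrichment,
                seed=seed + 1,
                hotspot_positions=hotspot_conditions.get(
                    condition, phys.hotspot_positions
                ),
            )
            truth = make_geometry(geo)
            image = render(truth, ph)
            image_id = f"{condition}_{i:03d}"
            image.image_id = image_id
            files = write_fixture(image, truth, out_dir, image_id)
            rows.append(
                {
                    "image_id": image_id,
                    "condition": condition,
                    "sidecar": Path(files["sidecar"]).name,
                    "enrichment": enrichment,
                    "seed": seed,
                }
            )
    manifest = pd.DataFrame(rows)
    write_csv(manifest, out_dir / "manifest.csv", config)
    return manifest


def read_manifest(path: "str | Path") -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def _load_rows(
    manifest: pd.DataFrame, base_dir: Path, required: tuple[str, ...]
):
    """Yield (row, image, truth) for readable manifest rows; skip and log
    rows whose files are missing/corrupt or lack a required channel."""
    for _, row in manifest.iterrows():
        sidecar = base_dir / row["sidecar"]
        try:
            image, truth = read_fixture(sidecar)
        except Exception as exc:  # corrupt/missing file: keep going
            logger.warning("skipping %s: %s", row.get("image_id", sidecar), exc)
            continue
        missing = [ch for ch in required if ch not in image]
        if missing:
            logger.warning(
                "skipping %s: missing channel(s) %s", row["image_id"], missing
            )
            continue
        yield row, image, truth


def _compare_conditions(by_condition: dict[str, np.ndarray]) -> GroupComparison | None:
    usable = {k: np.asarray(v) for k, v in by_condition.items() if len(v) >= 3}
    if len(usable) < 2:
        return None
    if len(usable) == 2:
        (n1, a), (n2, b) = usable.items()
        return compare_two(a, b, names=(n1, n2))
    return compare_many(usable)


# ---------------------------------------------------------------------------
# recruitment

def run_recruitment(
    config: RunConfig,
    manifest: pd.DataFrame,
    base_dir: "str | Path",
    out_dir: "str | Path",
) -> tuple[pd.DataFrame, pd.DataFrame, GroupComparison | None]:
    """Full recruitment pipeline on every manifest row.

    Per image: rolling-ball subtract the mTOR channel (75-px ball), segment
    LEs from LAMP1 (isodata, 25-px size floor), build the MAP2 dendrite
    mask (mean auto-threshold, somata removed), construct IN/ring-OUT masks
    (gap 6 px, width 4 px) and measure the IN/OUT ratio.  Writes the
    per-image results CSV, a per-condition summary (mean +/- SEM, n) and a
    comparison report.
    """
    base_dir, out_dir = Path(base_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results = []
    for row, image, _truth in _load_rows(
        manifest, base_dir, required=("MAP2", "LAMP1", "mTOR")
    ):
        mtor = rolling_ball_subtract(
            image["mTOR"], config.rolling_ball_diameter_mtor
        )
        les = segment_les(image["LAMP1"], min_area=config.le_min_area)
        map2_mask = auto_threshold(
            image["MAP2"], method=config.map2_threshold_method
        )
        logger.info(
            "%s: MAP2 %s; LEs: %d objects",
            row["image_id"], map2_mask.provenance, les.n_objects,
        )
        if config.remove_soma_regions:
            somas = somas_from_map2(
                map2_mask,
                opening_radius=config.soma_opening_radius,
                min_soma_area=config.min_soma_area,
                pixel_size=config.pixel_size,
            )
            dendrite_mask = remove_somas(map2_mask, somas)
        else:
            dendrite_mask = map2_mask
        masks = build_in_out(
            les, dendrite_mask, gap=config.ring_gap, width=config.ring_width
        )
        res = in_out_ratio(
            mtor, masks,
            image_id=str(row["image_id"]), condition=str(row["condition"]),
            n_objects=les.n_objects,
        )
        results.append(res)
        if config.write_qc_overlays:
            from .plotting import save_recruitment_overlay

            save_recruitment_overlay(
                mtor, image["LAMP1"], masks.in_mask, masks.out_mask,
                dendrite_mask, out_dir / f"qc_{row['image_id']}.png",
            )

    results_df = pd.DataFrame(
        [r.to_row() for r in results],
        columns=["image_id", "condition", "mean_in", "mean_out", "ratio",
                 "n_in_pixels", "n_out_pixels", "n_objects", "valid", "reason"],
    )
    write_csv(results_df, out_dir / "recruitment.csv", config)

    valid = results_df[results_df["valid"] == True]  # noqa: E712
    summary_rows = []
    by_condition: dict[str, np.ndarray] = {}
    for condition, grp in valid.groupby("condition", sort=True):
        vals = grp["ratio"].to_numpy(dtype=float)
        by_condition[str(condition)] = vals
        summary_rows.append({
            "condition": condition,
            "n": len(vals),
            "mean_ratio": vals.mean() if len(vals) else np.nan,
            "sem_ratio": (vals.std(ddof=1) / np.sqrt(len(vals))
                          if len(vals) > 1 else np.nan),
        })
    summary_df = pd.DataFrame(
        summary_rows, columns=["condition", "n", "mean_ratio", "sem_ratio"]
    )
    write_csv(summary_df, out_dir / "recruitment_summary.csv", config)

    comparison = _compare_conditions(by_condition)
    if comparison is not None:
        with open(out_dir / "recruitment_comparison.txt", "w") as fh:
            fh.write(comparison.summary() + "\n")
        if comparison.posthoc is not None:
            write_csv(
                comparison.posthoc, out_dir / "recruitment_posthoc.csv", config
            )
    return results_df, summary_df, comparison


# ---------------------------------------------------------------------------
# activity

def run_activity(
    config: RunConfig,
    manifest: pd.DataFrame,
    base_dir: "str | Path",
    out_dir: "str | Path",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, GroupComparison | None]:
    """P-pS6 activity pipeline: per-field compartment means, per-soma table,
    percentile-shift summary against the control condition, and a
    whole-field comparison report."""
    base_dir, out_dir = Path(base_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    field_rows, soma_rows = [], []
    for row, image, _truth in _load_rows(
        manifest, base_dir, required=("MAP2", "P-pS6")
    ):
        pps6 = rolling_ball_subtract(
            image["P-pS6"], config.rolling_ball_diameter_pps6
        )
        map2_mask = auto_threshold(image["MAP2"], method="isodata")
        somas = segment_somas(
            pps6, map2_mask, min_soma_area=config.min_soma_area
        )
        fa = field_activity(
            pps6, map2_mask, somas.footprint(),
            image_id=str(row["image_id"]), condition=str(row["condition"]),
        )
        field_rows.append(fa.to_row())
        if config.write_qc_overlays:
            from .plotting import save_activity_overlay

            save_activity_overlay(
                pps6, map2_mask, somas.footprint(),
                out_dir / f"qc_{row['image_id']}.png",
            )
        for rec in per_soma_intensities(
            pps6, somas,
            image_id=str(row["image_id"]), condition=str(row["condition"]),
        ):
            soma_rows.append(rec.to_row())

    field_df = pd.DataFrame(
        field_rows,
        columns=["image_id", "condition", "mean_whole", "mean_soma",
                 "mean_dendrite", "area_whole", "area_soma", "area_dendrite",
                 "valid", "reason"],
    )
    soma_df = pd.DataFrame(
        soma_rows,
        columns=["image_id", "condition", "soma_id", "mean_intensity",
                 "area", "centroid_row", "centroid_col"],
    )
    write_csv(field_df, out_dir / "activity_fields.csv", config)
    write_csv(soma_df, out_dir / "activity_somas.csv", config)

    shift_rows = []
    control = config.control_condition
    ctrl_vals = soma_df.loc[
        soma_df["condition"] == control, "mean_intensity"
    ].to_numpy(dtype=float)
    if ctrl_vals.size:
        for condition, grp in soma_df.groupby("condition", sort=True):
            treated = grp["mean_intensity"].to_numpy(dtype=float)
            threshold, frac = percentile_shift(
                ctrl_vals, treated, q=config.percentile_q
            )
            shift_rows.append({
                "condition": condition,
                "control": control,
                "q": config.percentile_q,
                "threshold": threshold,
                "fraction_above": frac,
                "n_somas": len(treated),
            })
    shift_df = pd.DataFrame(
        shift_rows,
        columns=["condition", "control", "q", "threshold",
                 "fraction_above", "n_somas"],
    )
    write_csv(shift_df, out_dir / "activity_percentile_shift.csv", config)

    valid = field_df[field_df["valid"] == True]  # noqa: E712
    by_condition = {
        str(cond): grp["mean_whole"].to_numpy(dtype=float)
        for cond, grp in valid.groupby("condition", sort=True)
    }
    comparison = _compare_conditions(by_condition)
    if comparison is not None:
        with open(out_dir / "activity_comparison.txt", "w") as fh:
            fh.write(comparison.summary() + "\n")
    return field_df, soma_df, shift_df, comparison


# ---------------------------------------------------------------------------
# profiles

def run_profiles(
    config: RunConfig,
    manifest: pd.DataFrame,
    base_dir: "str | Path",
    out_dir: "str | Path",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample P-pS6 along each field's dendrite centerlines (from the truth
    sidecar) and detect hot spots; writes profile and hot-spot CSVs."""
    from .profiles import detect_hotspots, sample_profile

    base_dir, out_dir = Path(base_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    prof_rows, spot_rows = [], []
    for row, image, truth in _load_rows(manifest, base_dir, required=("P-pS6",)):
        if truth is None:
            logger.warning("skipping %s: no centerlines available", row["image_id"])
            continue
        pps6 = rolling_ball_subtract(
            image["P-pS6"], config.rolling_ball_diameter_pps6
        )
        for dend_id, path in truth.dendrite_centerlines.items():
            profile = sample_profile(
                pps6, path, width=config.profile_width, dendrite_id=dend_id
            )
            for pos, inten in zip(
                profile.arclength_positions, profile.intensities
            ):
                prof_rows.append({
                    "image_id": row["image_id"], "condition": row["condition"],
                    "dendrite_id": dend_id, "arclength": pos, "intensity": inten,
                })
            for spot in detect_hotspots(
                profile,
                min_prominence_factor=config.hotspot_min_prominence_factor,
                min_separation=config.hotspot_min_separation,
            ):
                spot_rows.append({
                    "image_id": row["image_id"], "condition": row["condition"],
                    "dendrite_id": dend_id, "arclength": spot.arclength,
                    "prominence": spot.prominence, "width": spot.width,
                })
    prof_df = pd.DataFrame(
        prof_rows,
        columns=["image_id", "condition", "dendrite_id", "arclength", "intensity"],
    )
    spot_df = pd.DataFrame(
        spot_rows,
        columns=["image_id", "condition", "dendrite_id", "arclength",
                 "prominence", "width"],
    )
    write_csv(prof_df, out_dir / "profiles.csv", config)
    write_csv(spot_df, out_dir / "hotspots.csv", config)
    return prof_df, spot_df
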