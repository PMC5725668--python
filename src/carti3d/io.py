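"""Reading and writing of image stacks, masks, measurement tables and
pipeline configuration.

Stacks and masks use multi-page grayscale TIFF (8/16-bit input accepted;
masks written with foreground = 255). Measurement tables are plain CSV.
Configuration is a YAML file whose missing keys fall back to documented
defaults.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .model import (
    BinaryVolume,
    Calibration,
    Channel,
    ChannelStack,
    Compartment,
    ConfigError,
    FormatError,
    Group,
    InputError,
    MeasurementRecord,
    ThicknessMap,
    VOISpec,
)
from .segmentation import SegmentationParams

log = logging.getLogger(__name__)

MEASUREMENT_COLUMNS = [
    "sample_id",
    "group",
    "compartment",
    "mean_thickness_um",
    "n_voxels",
]


# ---------------------------------------------------------------------------
# Stacks and masks
# ---------------------------------------------------------------------------


def read_channel_stack(
    path: str | Path,
    channel: Channel,
    calibration: Calibration | None = None,
) -> ChannelStack:
    """Read a stack from a multi-page TIFF or a directory of per-slice TIFFs.

    Directory slices are ordered lexicographically by file name; integer
    intensities are preserved losslessly.
    """
    path = Path(path)
    calibration = calibration or Calibration()
    if not path.exists():
        raise InputError(f"stack path does not exist: {path}")
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff")
        )
        if not files:
            raise FormatError(f"no TIFF slices found in directory {path}")
        slices = [tifffile.imread(f) for f in files]
        shapes = {s.shape for s in slices}
        if len(shapes) != 1 or slices[0].ndim != 2:
            raise FormatError(
                f"slices in {path} have unequal or non-2D shapes: {sorted(shapes)}"
            )
        data = np.stack(slices, axis=0)
    else:
        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None]
        if data.ndim != 3:
            raise FormatError(
                f"{path}: expected a grayscale multi-page TIFF, got shape {data.shape}"
            )
    if data.shape[0] == 0:
        raise FormatError(f"{path}: zero slices")
    log.debug("read %s stack %s from %s", channel.value, data.shape, path)
    return ChannelStack(channel, data, calibration)


def write_mask_stack(mask: BinaryVolume, path: str | Path) -> None:
    """Write a binary mask as a multi-page TIFF (foreground = 255)."""
    if mask.voxels.size == 0:
        raise InputError("refusing to write an empty mask")
    path = Path(path)
    try:
        tifffile.imwrite(path, (mask.voxels.astype(np.uint8) * 255))
    except OSError as exc:  # pragma: no cover - depends on filesystem
        raise InputError(f"cannot write mask to {path}: {exc}") from exc


def read_mask_stack(
    path: str | Path, voxel_size: float, label=None
) -> BinaryVolume:
    """Read a mask written by :func:`write_mask_stack` (threshold at 128)."""
    stack = read_channel_stack(path, Channel.UV)
    from .model import TissueLabel

    return BinaryVolume(
        stack.voxels >= 128, voxel_size, label or TissueLabel.OTHER
    )


def write_thickness_map(tmap: ThicknessMap, path: str | Path) -> None:
    """Write a thickness map as a 32-bit float TIFF (µm; 0 = undefined)."""
    tifffile.imwrite(Path(path), tmap.values.astype(np.float32))


# ---------------------------------------------------------------------------
# Measurement tables
# ---------------------------------------------------------------------------


def write_measurements(
    records: list[MeasurementRecord], path: str | Path
) -> None:
    """Write measurement records as CSV, sorted by (sample_id, compartment)."""
    if not records:
        raise InputError("no measurement records to write")
    df = pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "group": r.group.value,
                "compartment": r.compartment.value,
                "mean_thickness_um": r.mean_thickness_um,
                "n_voxels": r.n_voxels,
            }
            for r in records
        ],
        columns=MEASUREMENT_COLUMNS,
    ).sort_values(["sample_id", "compartment"], kind="stable")
    try:
        df.to_csv(path, index=False)
    except OSError as exc:  # pragma: no cover
        raise InputError(f"cannot write measurements to {path}: {exc}") from exc


def read_measurements(path: str | Path) -> list[MeasurementRecord]:
    """Read a measurement CSV back into records (inverse of write)."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"measurement table does not exist: {path}")
    df = pd.read_csv(path)
    missing = set(MEASUREMENT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return [
        MeasurementRecord(
            sample_id=str(row.sample_id),
            group=Group(row.group),
            compartment=Compartment(row.compartment),
            mean_thickness_um=float(row.mean_thickness_um),
            n_voxels=int(row.n_voxels),
        )
        for row in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PipelineConfig:
    """Aggregated pipeline parameters (single source of numeric settings)."""

    calibration: Calibration = field(default_factory=Calibration)
    voi: VOISpec = field(default_factory=VOISpec)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    #: which x side is medial; left and right limbs mirror, so this flag is
    #: flipped per sample when cohorts mix sides.
    medial_side: str = "low_x"
    #: anchor VOIs on the cartilage footprint (default) or the bone surface
    voi_anchor: str = "cartilage"

    def __post_init__(self) -> None:
        if self.medial_side not in ("low_x", "high_x"):
            raise ConfigError("medial_side must be 'low_x' or 'high_x'")
        if self.voi_anchor not in ("cartilage", "bone"):
            raise ConfigError("voi_anchor must be 'cartilage' or 'bone'")


def _build_section(cls, data: dict, section: str, path):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    for key in sorted(unknown):
        log.warning("%s: ignoring unknown key '%s.%s'", path, section, key)
    return cls(**{k: v for k, v in data.items() if k in known})


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a YAML configuration file; missing keys take the defaults.

    Unknown keys produce a warning in the log but are not an error; malformed
    YAML raises a configuration error carrying the offending line number.
    """
    if path is None:
        return PipelineConfig()
    path = Path(path)
    if not path.exists():
        raise InputError(f"config file does not exist: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        line = f" at line {mark.line + 1}" if mark is not None else ""
        raise ConfigError(f"malformed config {path}{line}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config root must be a mapping")

    known_sections = {"calibration", "voi", "segmentation", "medial_side", "voi_anchor"}
    for key in sorted(set(raw) - known_sections):
        log.warning("%s: ignoring unknown key '%s'", path, key)

    cfg = PipelineConfig()
    if isinstance(raw.get("calibration"), dict):
        cfg = replace(
            cfg,
            calibration=_build_section(
                Calibration, raw["calibration"], "calibration", path
            ),
        )
    if isinstance(raw.get("voi"), dict):
        cfg = replace(cfg, voi=_build_section(VOISpec, raw["voi"], "voi", path))
    if isinstance(raw.get("segmentation"), dict):
        seg = dict(raw["segmentation"])
        if seg.get("adjacency_margin") in ("inf", ".inf", "infinity"):
            seg["adjacency_margin"] = float("inf")
        cfg = replace(
            cfg,
            segmentation=_build_section(
                SegmentationParams, seg, "segmentation", path
            ),
        )
    if "medial_side" in raw:
        cfg = replace(cfg, medial_side=str(raw["medial_side"]))
    if "voi_anchor" in raw:
        cfg = replace(cfg, voi_anchor=str(raw["voi_anchor"]))
    log.info("loaded config from %s: %s", path, cfg)
    return cfg
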