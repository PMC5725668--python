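"""End-to-end drivers: single-sample measurement and cohort analysis.

The per-sample chain is: read both channels -> rescale to the isotropic
working grid -> bone mask from UV -> cartilage from Cy5 by mask subtraction
-> automated VOI placement -> local thickness -> mean thickness per
compartment VOI. Cohorts add group statistics (ANOVA + Tukey across groups,
paired t-tests for matched limb pairs) on the pooled measurement table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    PipelineConfig,
    read_channel_stack,
    write_mask_stack,
    write_measurements,
    write_thickness_map,
)
from .model import (
    BinaryVolume,
    Channel,
    ChannelStack,
    Compartment,
    Group,
    InputError,
    MeasurementRecord,
    ThicknessMap,
    TissueLabel,
    VOIBox,
)
from .segmentation import make_bone_mask, rescale_to_isotropic, segment_cartilage
from .stats import AnovaResult, one_way_anova_tukey, paired_ttest
from .thickness import local_thickness, mean_thickness_in_voi
from .voi import map_vois

log = logging.getLogger(__name__)


@dataclass
class SampleResult:
    records: tuple[MeasurementRecord, MeasurementRecord]  # (medial, lateral)
    bone_mask: BinaryVolume
    cartilage_mask: BinaryVolume
    thickness_map: ThicknessMap
    vois: tuple[VOIBox, VOIBox]


def measure_sample(
    uv: ChannelStack,
    cy5: ChannelStack,
    config: PipelineConfig | None = None,
    sample_id: str = "sample",
    group: Group = Group.NAIVE,
    medial_side: str | None = None,
) -> SampleResult:
    """Run the full measurement chain on in-memory channel stacks."""
    config = config or PipelineConfig()
    side = medial_side or config.medial_side
    uv_i = rescale_to_isotropic(uv)
    cy5_i = rescale_to_isotropic(cy5)
    if uv_i.shape != cy5_i.shape:
        raise InputError(
            f"channel grids differ after rescaling: UV {uv_i.shape} vs "
            f"Cy5 {cy5_i.shape}"
        )
    bone = make_bone_mask(uv_i, config.segmentation)
    cart = segment_cartilage(cy5_i, bone, config.segmentation)
    vois = map_vois(cart, config.voi, side)
    tmap = local_thickness(cart)
    records = []
    for box in vois:
        mean, n = mean_thickness_in_voi(tmap, box, cart)
        records.append(
            MeasurementRecord(sample_id, group, box.compartment, mean, n)
        )
        log.info(
            "%s %s: mean thickness %.2f um over %d voxels",
            sample_id,
            box.compartment.value,
            mean,
            n,
        )
    return SampleResult(tuple(records), bone, cart, tmap, tuple(vois))


def _voi_overlay(result: SampleResult) -> BinaryVolume:
    """Mask of cartilage restricted to the two VOI boxes (for QC export)."""
    overlay = np.zeros(result.cartilage_mask.shape, dtype=bool)
    for box in result.vois:
        overlay[box.slices] |= result.cartilage_mask.voxels[box.slices]
    return BinaryVolume(
        overlay, result.cartilage_mask.voxel_size, TissueLabel.CARTILAGE
    )


def run_sample(
    uv_path: str | Path,
    cy5_path: str | Path,
    config: PipelineConfig | None = None,
    out_dir: str | Path = ".",
    sample_id: str = "sample",
    group: Group = Group.NAIVE,
    medial_side: str | None = None,
) -> SampleResult:
    """Measure one sample from channel stack files and write QC artifacts.

    Writes the bone and cartilage masks, the thickness map (32-bit TIFF),
    a VOI overlay mask and a two-row measurement CSV into ``out_dir``.
    Deterministic: re-running on the same input reproduces the CSV
    byte-for-byte.
    """
    config = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    uv = read_channel_stack(uv_path, Channel.UV, config.calibration)
    cy5 = read_channel_stack(cy5_path, Channel.CY5, config.calibration)
    result = measure_sample(uv, cy5, config, sample_id, group, medial_side)
    write_mask_stack(result.bone_mask, out / f"{sample_id}_bone_mask.tif")
    write_mask_stack(result.cartilage_mask, out / f"{sample_id}_cartilage_mask.tif")
    write_thickness_map(result.thickness_map, out / f"{sample_id}_thickness_um.tif")
    write_mask_stack(_voi_overlay(result), out / f"{sample_id}_voi_overlay.tif")
    write_measurements(list(result.records), out / f"{sample_id}_measurements.csv")
    return result


def measure_cohort_samples(
    samples, config: PipelineConfig | None = None
) -> list[MeasurementRecord]:
    """Measure a list of in-memory cohort samples (e.g. generated phantoms).

    Convenience driver for simulation studies: runs :func:`measure_sample`
    on each sample's channel stacks and pools the records.
    """
    config = config or PipelineConfig()
    records: list[MeasurementRecord] = []
    for s in samples:
        result = measure_sample(
            s.uv, s.cy5, config, sample_id=s.sample_id, group=s.group
        )
        records.extend(result.records)
    return records


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------


@dataclass
class CohortStats:
    anova: dict[Compartment, AnovaResult]
    paired: dict[Compartment, tuple[float, float]]  # (t, p) per compartment


def cohort_statistics(
    records: list[MeasurementRecord],
    pairs: dict[str, dict[Group, str]] | None = None,
) -> CohortStats:
    """Group statistics over a measurement table.

    Per compartment: one-way ANOVA + Tukey across all groups with >= 2
    samples; if ``pairs`` declares matched contralateral/operated sample ids
    per animal, a two-tailed paired t-test (contralateral vs operated) is
    added.
    """
    by_comp_group: dict[Compartment, dict[str, list[float]]] = {}
    by_id_comp: dict[tuple[str, Compartment], float] = {}
    for r in records:
        by_comp_group.setdefault(r.compartment, {}).setdefault(
            r.group.value, []
        ).append(r.mean_thickness_um)
        by_id_comp[(r.sample_id, r.compartment)] = r.mean_thickness_um

    anova: dict[Compartment, AnovaResult] = {}
    for comp, groups in by_comp_group.items():
        usable = {g: v for g, v in groups.items() if len(v) >= 2}
        if len(usable) < 2:
            log.warning(
                "%s: fewer than two groups with >= 2 samples; ANOVA skipped",
                comp.value,
            )
            continue
        anova[comp] = one_way_anova_tukey(usable)

    paired: dict[Compartment, tuple[float, float]] = {}
    if pairs:
        for comp in (Compartment.MEDIAL, Compartment.LATERAL):
            a, b = [], []
            for _, mapping in sorted(pairs.items()):
                ia = mapping.get(Group.CONTRALATERAL)
                ib = mapping.get(Group.DMM)
                if ia is None or ib is None:
                    continue
                if (ia, comp) in by_id_comp and (ib, comp) in by_id_comp:
                    a.append(by_id_comp[(ia, comp)])
                    b.append(by_id_comp[(ib, comp)])
            if len(a) >= 2:
                paired[comp] = paired_ttest(a, b)
            else:
                log.warning(
                    "%s: fewer than two matched pairs; paired t-test skipped",
                    comp.value,
                )
    return CohortStats(anova=anova, paired=paired)


def infer_pairs(sample_ids: list[str], groups: list[Group]):
    """Infer matched limb pairs from ids of the form ``<animal>_<suffix>``."""
    pairs: dict[str, dict[Group, str]] = {}
    for sid, grp in zip(sample_ids, groups):
        animal = sid.rsplit("_", 1)[0] if "_" in sid else sid
        pairs.setdefault(animal, {})[grp] = sid
    return {k: v for k, v in pairs.items() if len(v) >= 2}


def run_cohort(
    manifest_path: str | Path,
    config: PipelineConfig | None = None,
    out_dir: str | Path = ".",
) -> tuple[list[MeasurementRecord], CohortStats]:
    """Run every sample of a cohort manifest and compare groups.

    The manifest is a CSV with columns ``sample_id, group, uv_path,
    cy5_path`` and optionally ``medial_side`` (per-sample mirroring) and
    ``pair_id`` (matched-limb declaration; by default pairs are inferred
    from ``<animal>_<suffix>`` ids). Missing stack files are reported
    collectively before aborting.
    """
    config = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = pd.read_csv(manifest_path)
    required = {"sample_id", "group", "uv_path", "cy5_path"}
    if missing := required - set(manifest.columns):
        raise InputError(f"manifest missing columns: {sorted(missing)}")
    base = Path(manifest_path).parent
    missing_files = []
    for _, row in manifest.iterrows():
        for col in ("uv_path", "cy5_path"):
            p = Path(row[col])
            if not p.is_absolute():
                p = base / p
            if not p.exists():
                missing_files.append(str(p))
    if missing_files:
        raise InputError(
            "missing stack files:\n  " + "\n  ".join(missing_files)
        )

    records: list[MeasurementRecord] = []
    for _, row in manifest.iterrows():
        uv_p, cy5_p = Path(row["uv_path"]), Path(row["cy5_path"])
        if not uv_p.is_absolute():
            uv_p, cy5_p = base / uv_p, base / cy5_p
        side = row.get("medial_side") if "medial_side" in manifest.columns else None
        result = run_sample(
            uv_p,
            cy5_p,
            config,
            out / str(row["sample_id"]),
            sample_id=str(row["sample_id"]),
            group=Group(row["group"]),
            medial_side=side,
        )
        records.extend(result.records)
    write_measurements(records, out / "cohort_measurements.csv")

    if "pair_id" in manifest.columns:
        pairs: dict[str, dict[Group, str]] = {}
        for _, row in manifest.iterrows():
            pairs.setdefault(str(row["pair_id"]), {})[Group(row["group"])] = str(
                row["sample_id"]
            )
        pairs = {k: v for k, v in pairs.items() if len(v) >= 2}
    else:
        pairs = infer_pairs(
            [str(r) for r in manifest["sample_id"]],
            [Group(g) for g in manifest["group"]],
        )
    if len(manifest) < 2:
        log.warning("single-sample manifest: statistics skipped")
        return records, CohortStats(anova={}, paired={})
    stats = cohort_statistics(records, pairs or None)
    _write_stats_report(stats, out)
    return records, stats


def _write_stats_report(stats: CohortStats, out: Path) -> None:
    rows = []
    lines = ["Cohort statistics", "================="]
    for comp, res in stats.anova.items():
        lines.append(
            f"{comp.value}: ANOVA F = {res.f_statistic:.4g}, p = {res.p_value:.4g}"
        )
        rows.append(
            {"compartment": comp.value, "test": "anova", "statistic":
             res.f_statistic, "p_value": res.p_value, "pair": ""}
        )
        for (g1, g2), p in res.pairwise_p.items():
            lines.append(f"  Tukey {g1} vs {g2}: p = {p:.4g}")
            rows.append(
                {"compartment": comp.value, "test": "tukey", "statistic":
                 float("nan"), "p_value": p, "pair": f"{g1} vs {g2}"}
            )
    for comp, (t, p) in stats.paired.items():
        lines.append(
            f"{comp.value}: paired t (contralateral vs operated) t = {t:.4g}, "
            f"p = {p:.4g}"
        )
        rows.append(
            {"compartment": comp.value, "test": "paired_t", "statistic": t,
             "p_value": p, "pair": "contralateral vs dmm"}
        )
    (out / "stats_report.txt").write_text("\n".join(lines) + "\n")
    pd.DataFrame(
        rows, columns=["compartment", "test", "statistic", "p_value", "pair"]
    ).to_csv(out / "stats_results.csv", index=False)
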