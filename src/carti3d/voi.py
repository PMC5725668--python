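"""Automated placement of the fixed-size volumes-of-interest (VOIs) on the
medial and lateral tibial plateau.

The cartilage mask is projected along the cutting axis; the projection is
split at its centroid's medial-lateral coordinate, and the largest connected
region of each half defines the compartment footprint. Each VOI is a
fixed-size box (default 500 µm medial-lateral x 800 µm anterior-posterior)
centered on its footprint centroid — anatomy-anchored but identically sized
in every sample, which is what makes thickness averages comparable across
animals.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage

from .model import (
    BinaryVolume,
    Compartment,
    DegenerateDataError,
    VOIBox,
    VOISpec,
)

log = logging.getLogger(__name__)

_CONN4 = ndimage.generate_binary_structure(2, 1)


def _largest_component(mask2d: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(mask2d, structure=_CONN4)
    if n == 0:
        return mask2d
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == int(np.argmax(counts))


def find_compartment_footprints(
    cartilage_mask: BinaryVolume, medial_side: str = "low_x"
) -> tuple[np.ndarray, np.ndarray]:
    """Split the cartilage footprint into medial and lateral compartments.

    Returns two 2D (y, x) boolean masks, ``(medial, lateral)``. The split
    line is the x centroid of the z-projection (robust to off-center
    mounting); each half contributes its largest 4-connected component.
    ``medial_side`` maps the low- or high-x half to the medial compartment
    (left and right limbs mirror).
    """
    if medial_side not in ("low_x", "high_x"):
        raise DegenerateDataError(f"invalid medial_side {medial_side!r}")
    proj = cartilage_mask.voxels.any(axis=0)
    if not proj.any():
        raise DegenerateDataError("empty cartilage mask: no footprint")
    xs = np.nonzero(proj)[1]
    split = xs.mean()
    # a single connected footprint means one plateau only: splitting it at
    # the centroid would fabricate two compartments out of one structure
    _, n_comp = ndimage.label(proj, structure=_CONN4)
    if n_comp == 1:
        low_present = xs.mean() < proj.shape[1] / 2.0
        present = "low_x" if low_present else "high_x"
        missing = (
            "lateral" if present == medial_side else "medial"
        )
        raise DegenerateDataError(
            f"{missing} compartment footprint is empty: the cartilage "
            "projection forms a single plateau"
        )
    cols = np.arange(proj.shape[1])
    low = proj & (cols < split)[None, :]
    high = proj & (cols >= split)[None, :]
    med2d, lat2d = (low, high) if medial_side == "low_x" else (high, low)
    for half, name in ((med2d, "medial"), (lat2d, "lateral")):
        if not half.any():
            raise DegenerateDataError(f"{name} compartment footprint is empty")
    return _largest_component(med2d), _largest_component(lat2d)


def _centered_range(center: float, extent: int, bound: int) -> tuple[int, int]:
    start = int(np.floor(center - extent / 2.0 + 0.5))  # round-half-up
    if extent >= bound:
        log.warning("VOI extent %d exceeds volume bound %d; clipping", extent, bound)
        return 0, bound
    if start < 0 or start + extent > bound:
        clipped = min(max(start, 0), bound - extent)
        log.warning("VOI shifted to fit volume bounds (%d -> %d)", start, clipped)
        start = clipped
    return start, start + extent


def map_vois(
    cartilage_mask: BinaryVolume,
    spec: VOISpec | None = None,
    medial_side: str = "low_x",
) -> tuple[VOIBox, VOIBox]:
    """Place the medial and lateral VOI boxes on the tibial plateau.

    Each box has x extent ``round(width_ml / voxel_size)`` and y extent
    ``round(length_ap / voxel_size)`` voxels, is centered at its compartment
    footprint centroid, clipped to the volume (logged), and spans the full
    stack in z — the cartilage mask itself limits where thickness is
    averaged. Placement is deterministic and translation-equivariant.
    """
    spec = spec or VOISpec()
    vs = cartilage_mask.voxel_size
    wx = int(round(spec.width_ml / vs))
    wy = int(round(spec.length_ap / vs))
    if wx < 1 or wy < 1:
        raise DegenerateDataError("VOI smaller than one voxel")
    med_fp, lat_fp = find_compartment_footprints(cartilage_mask, medial_side)
    nz, ny, nx = cartilage_mask.shape
    boxes = []
    for fp, comp in ((med_fp, Compartment.MEDIAL), (lat_fp, Compartment.LATERAL)):
        ys, xs = np.nonzero(fp)
        cy, cx = ys.mean(), xs.mean()
        x_range = _centered_range(cx, wx, nx)
        y_range = _centered_range(cy, wy, ny)
        box = VOIBox(comp, x_range=x_range, y_range=y_range, z_range=(0, nz))
        log.info(
            "%s VOI centered at (y=%.1f, x=%.1f): x=%s y=%s (%d x %d voxels)",
            comp.value,
            cy,
            cx,
            x_range,
            y_range,
            wx,
            wy,
        )
        boxes.append(box)
    return boxes[0], boxes[1]
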