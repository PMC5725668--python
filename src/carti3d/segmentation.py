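"""Dual-channel segmentation chain: isotropic rescaling, bone masking from
the ultraviolet channel, and cartilage extraction from the Cy5 channel.

The chain mirrors how the tissues are imaged: subchondral bone is the bright
structure under ultraviolet excitation, so a bone mask is obtained by
smoothing, Otsu thresholding, morphological cleaning and cavity filling.
Cartilage is the *darkest* structure in the Cy5 channel; after excluding the
bone mask, smoothing and inverting the Cy5 stack turns cartilage into the
brightest class, which a second Otsu threshold isolates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import ball, closing, opening
from skimage.transform import resize_local_mean

from .model import (
    BinaryVolume,
    Calibration,
    ChannelStack,
    ConfigError,
    DegenerateDataError,
    TissueLabel,
)

log = logging.getLogger(__name__)

#: 6-connectivity structuring element (faces only), used for connected
#: components and cavity filling throughout the package.
CONN6 = ndimage.generate_binary_structure(3, 1)


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable parameters of the segmentation chain (all lengths in µm).

    sigma_bone, sigma_cartilage
        Gaussian pre-smoothing of the UV and Cy5 channels.
    morph_radius
        Ball radius for closing-then-opening of the bone mask.
    min_component
        Foreground components smaller than this voxel count are discarded.
    adjacency_margin
        Maximum distance from the bone surface for a candidate cartilage
        component to be kept (``inf`` disables the filter).
    """

    sigma_bone: float = 5.0
    sigma_cartilage: float = 5.0
    morph_radius: float = 10.0
    min_component: int = 1000
    adjacency_margin: float = 25.0

    def __post_init__(self) -> None:
        for name in (
            "sigma_bone",
            "sigma_cartilage",
            "morph_radius",
            "min_component",
            "adjacency_margin",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"SegmentationParams.{name} must be >= 0")


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------


def rescale_to_isotropic(stack: ChannelStack) -> ChannelStack:
    """Resample a stack to the isotropic working grid.

    In-plane (XY) extents become ``round(extent_um / target_voxel)`` pixels;
    the Z axis is left untouched when the cutting thickness already equals the
    target voxel. Intensities are area-averaged (local-mean) so that constant
    images stay constant and downsampling does not alias.
    """
    cal = stack.calibration
    t = cal.target_voxel
    if cal.xy_resolution > t:
        raise ConfigError(
            "target_voxel smaller than xy_resolution: XY upsampling is not supported"
        )
    nz, ny, nx = stack.shape
    new_ny = int(round(ny * cal.xy_resolution / t))
    new_nx = int(round(nx * cal.xy_resolution / t))
    new_nz = nz if cal.z_step == t else int(round(nz * cal.z_step / t))
    out_cal = Calibration(xy_resolution=t, z_step=t, target_voxel=t)
    if (new_nz, new_ny, new_nx) == (nz, ny, nx):
        if cal.is_isotropic:
            return stack
        return ChannelStack(stack.channel, stack.voxels, out_cal)
    data = resize_local_mean(
        stack.voxels.astype(np.float32), (new_nz, new_ny, new_nx)
    )
    log.info(
        "rescaled %s stack %s -> %s (target voxel %.3g um)",
        stack.channel.value,
        (nz, ny, nx),
        data.shape,
        t,
    )
    return ChannelStack(stack.channel, np.maximum(data, 0.0), out_cal)


def gaussian_smooth(stack: ChannelStack, sigma: float) -> ChannelStack:
    """3D Gaussian smoothing with standard deviation ``sigma`` in µm.

    ``sigma = 0`` is the identity. Boundaries are handled by reflection so
    constant stacks are preserved exactly.
    """
    if sigma < 0:
        raise ConfigError("sigma must be >= 0")
    if sigma == 0:
        return stack
    sv = sigma / stack.calibration.target_voxel
    data = ndimage.gaussian_filter(
        stack.voxels.astype(np.float32), sigma=sv, mode="reflect"
    )
    return ChannelStack(stack.channel, np.maximum(data, 0.0), stack.calibration)


def otsu_threshold(stack, select: np.ndarray | None = None) -> float:
    """Otsu threshold of a stack: 256 bins over the observed intensity range.

    Returns the threshold ``t`` maximizing the between-class variance of the
    intensity histogram; foreground is defined as ``intensity > t``. Ties are
    broken toward the lowest maximizing threshold.

    Parameters
    ----------
    stack : ChannelStack or ndarray
        Intensities to threshold.
    select : bool ndarray, optional
        If given, only voxels where ``select`` is True enter the histogram
        (used to exclude already-masked tissue); the returned threshold still
        applies to the whole stack.
    """
    arr = np.asarray(getattr(stack, "voxels", stack))
    values = arr[select] if select is not None else arr.ravel()
    if values.size == 0:
        raise DegenerateDataError("no voxels selected for thresholding")
    vmin = float(values.min())
    vmax = float(values.max())
    if vmin == vmax:
        raise DegenerateDataError(
            "constant stack: Otsu threshold undefined (needs >= 2 intensity levels)"
        )
    hist, edges = np.histogram(values, bins=256, range=(vmin, vmax))
    w = hist.astype(np.float64) / hist.sum()
    centers = (edges[:-1] + edges[1:]) / 2.0
    omega = np.cumsum(w)  # class-0 weight for split after bin k
    mu = np.cumsum(w * centers)  # class-0 first moment
    mu_t = mu[-1]
    # between-class variance for every candidate split k = 0..254
    omega_k = omega[:-1]
    mu_k = mu[:-1]
    denom = omega_k * (1.0 - omega_k)
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = np.where(denom > 0, (mu_t * omega_k - mu_k) ** 2 / denom, 0.0)
    k = int(np.argmax(sigma_b))  # argmax returns the first (lowest) maximizer
    thr = float(edges[k + 1])
    log.debug("otsu threshold %.4g (range %.4g..%.4g)", thr, vmin, vmax)
    return thr


def morphological_clean(mask: BinaryVolume, radius: float) -> BinaryVolume:
    """Binary closing then opening with a digital ball of ``radius`` µm.

    Removes speckle and bridges small gaps; the closing-opening composition
    is idempotent, so re-applying the same radius is a no-op.
    """
    r = int(round(radius / mask.voxel_size))
    if r == 0:
        return BinaryVolume(mask.voxels.copy(), mask.voxel_size, mask.label)
    # pad so the structuring element never interacts with the array border
    selem = ball(r)
    v = np.pad(mask.voxels, r, mode="constant", constant_values=False)
    v = opening(closing(v, selem), selem)
    v = v[r:-r, r:-r, r:-r]
    return BinaryVolume(v, mask.voxel_size, mask.label)


def fill_cavities(mask: BinaryVolume) -> BinaryVolume:
    """Fill enclosed background cavities (6-connectivity).

    Every background component with no path (through faces) to the volume
    border becomes foreground; border-connected background and existing
    foreground are unchanged, so the result always contains the input.
    """
    v = ndimage.binary_fill_holes(mask.voxels, structure=CONN6)
    return BinaryVolume(v, mask.voxel_size, mask.label)


def drop_small_components(
    mask: BinaryVolume, min_voxels: int
) -> BinaryVolume:
    """Remove 6-connected foreground components below ``min_voxels``."""
    if min_voxels <= 1:
        return mask
    labels, n = ndimage.label(mask.voxels, structure=CONN6)
    if n == 0:
        return mask
    counts = np.bincount(labels.ravel())
    keep = counts >= min_voxels
    keep[0] = False
    return BinaryVolume(keep[labels], mask.voxel_size, mask.label)


# ---------------------------------------------------------------------------
# Channel-specific chains
# ---------------------------------------------------------------------------


def make_bone_mask(
    uv: ChannelStack, params: SegmentationParams | None = None
) -> BinaryVolume:
    """Segment subchondral bone from the (isotropic) ultraviolet stack.

    Chain: Gaussian smoothing -> Otsu threshold (bone is UV-bright, so
    foreground = above threshold) -> closing/opening -> cavity filling ->
    removal of small components. The returned mask encloses all bone tissue
    including internal marrow-like voids.
    """
    params = params or SegmentationParams()
    vs = uv.calibration.target_voxel
    sm = gaussian_smooth(uv, params.sigma_bone)
    thr = otsu_threshold(sm)
    mask = BinaryVolume(sm.voxels > thr, vs, TissueLabel.BONE)
    mask = morphological_clean(mask, params.morph_radius)
    mask = fill_cavities(mask)
    mask = drop_small_components(mask, params.min_component)
    log.info(
        "bone mask: threshold %.4g, %d voxels (%.1f%% of volume)",
        thr,
        mask.count,
        100.0 * mask.count / mask.voxels.size,
    )
    return mask


def segment_cartilage(
    cy5: ChannelStack,
    bone_mask: BinaryVolume,
    params: SegmentationParams | None = None,
) -> BinaryVolume:
    """Segment articular cartilage from the Cy5 stack given the bone mask.

    Steps: (1) bone subtraction — voxels inside the bone mask are saturated
    to the stack maximum so they cannot survive inversion; (2) Gaussian
    smoothing; (3) inversion ``v -> max - v`` (cartilage, darkest in Cy5,
    becomes brightest); (4) Otsu threshold computed from the non-bone voxels,
    foreground = above threshold; (5) keep components that lie within
    ``adjacency_margin`` of the bone surface and have at least
    ``min_component`` voxels. The result is disjoint from the bone mask.
    """
    params = params or SegmentationParams()
    if cy5.shape != bone_mask.shape:
        raise ConfigError(
            f"Cy5 stack {cy5.shape} and bone mask {bone_mask.shape} grids differ"
        )
    if bone_mask.count == 0:
        raise DegenerateDataError(
            "empty bone mask: cartilage adjacency is undefined"
        )
    vs = cy5.calibration.target_voxel
    bone = bone_mask.voxels

    arr = cy5.voxels.astype(np.float32).copy()
    arr[bone] = arr.max()
    sm = gaussian_smooth(ChannelStack(cy5.channel, arr, cy5.calibration),
                         params.sigma_cartilage)
    inv = float(sm.voxels.max()) - sm.voxels
    thr = otsu_threshold(inv, select=~bone)
    fg = (inv > thr) & ~bone

    labels, n = ndimage.label(fg, structure=CONN6)
    if n:
        counts = np.bincount(labels.ravel())
        keep = counts >= params.min_component
        keep[0] = False
        if np.isfinite(params.adjacency_margin):
            dist_to_bone = ndimage.distance_transform_edt(~bone) * vs
            idx = np.flatnonzero(keep)
            if idx.size:
                min_dist = ndimage.minimum(dist_to_bone, labels, index=idx)
                keep[idx] &= np.atleast_1d(min_dist) <= params.adjacency_margin
        fg = keep[labels]
    log.info(
        "cartilage mask: threshold %.4g on inverted Cy5, %d voxels kept "
        "from %d components",
        thr,
        int(fg.sum()),
        n,
    )
    return BinaryVolume(fg, vs, TissueLabel.CARTILAGE)
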