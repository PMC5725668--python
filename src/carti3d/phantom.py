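"""Synthetic dual-channel phantoms of a mouse tibial epiphysis.

The phantom stands in for block-face autofluorescence data: a solid bone
block whose top surface carries two gently domed plateaus (medial at low x,
lateral at high x) separated by a notch groove, with a cartilage layer of
known thickness draped over each plateau. Channel intensities follow the
tissue contrast of the imaging method — bone bright under ultraviolet,
cartilage darkest in Cy5 — with additive Gaussian noise. Optional features
emulate osteoarthritic joints: a full-thickness medial lesion (an ellipse in
which the cartilage is reduced to a residual thickness) and a marginal
medial osteophyte (a bone bump with a cartilage cap).

Ground-truth masks and per-compartment mean thickness inside the nominal
VOI are returned alongside the stacks, so segmentation and thickness
measurements can be scored against a known answer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .model import (
    BinaryVolume,
    Calibration,
    Channel,
    ChannelStack,
    Compartment,
    ConfigError,
    Group,
    MeasurementRecord,
    TissueLabel,
    VOISpec,
)
from . import voi as voi_mapping

log = logging.getLogger(__name__)

#: Default mean intensity (8-bit scale) per channel and tissue. Chosen to
#: respect the qualitative contrast of the imaging method: UV bone >> UV
#: cartilage ~ UV background; Cy5 cartilage < Cy5 background < Cy5 bone.
#: Background keeps a mild level because the opacified embedding reduces but
#: does not null its fluorescence.
DEFAULT_INTENSITIES = {
    "uv": {"bone": 200.0, "cartilage": 30.0, "background": 20.0},
    "cy5": {"bone": 180.0, "cartilage": 25.0, "background": 90.0},
}


@dataclass(frozen=True)
class LesionSpec:
    """Elliptical full-thickness cartilage defect on the medial plateau.

    ``center`` is (x, y) in µm; ``None`` centers the lesion on the medial
    plateau footprint. ``residual_thickness`` is the cartilage left inside
    the lesion (0 = full erosion down to the bone plate).
    """

    radius_x: float
    radius_y: float
    residual_thickness: float = 0.0
    center: tuple[float, float] | None = None


@dataclass(frozen=True)
class OsteophyteSpec:
    """Marginal bone bump (with thin cartilage cap) at the medial joint edge."""

    radius: float = 60.0
    cap_thickness: float = 30.0


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, optics and noise of one synthetic epiphysis.

    Lengths in µm. The default grid (56 x 272 x 360 voxels at 5 µm, i.e.
    1.8 mm medial-lateral) matches the scale of a mouse tibial plateau: each
    compartment comfortably holds the standard 500 x 800 µm VOI *and* a
    cohort lesion covering that VOI, with a cartilage margin ring to spare.
    """

    grid_shape: tuple[int, int, int] = (56, 272, 360)  # (z, y, x)
    voxel_size: float = 5.0
    plateau_height: float = 60.0
    dome_height: float = 20.0
    notch_width: float = 40.0
    cartilage_thickness_medial: float = 60.0
    cartilage_thickness_lateral: float = 80.0
    #: peak-to-peak linear thickness variation along the anterior-posterior
    #: axis *across the nominal VOI length* (real cartilage is not uniformly
    #: thick; this also keeps the VOI average responsive to sub-voxel
    #: thickness differences instead of snapping to whole voxel layers --
    #: 10 µm spans exactly one two-voxel quantization period of the
    #: largest-inscribed-sphere measure at 5 µm voxels)
    thickness_ramp: float = 10.0
    lesion: LesionSpec | None = None
    osteophyte: OsteophyteSpec | None = None
    intensities: dict = field(
        default_factory=lambda: {
            ch: dict(tissues) for ch, tissues in DEFAULT_INTENSITIES.items()
        }
    )
    noise_sd: float = 10.0
    anisotropic_output: bool = False
    #: nominal VOI used for ground-truth means (scaled-down phantoms carry a
    #: proportionally smaller VOI)
    voi: VOISpec = field(default_factory=VOISpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.cartilage_thickness_medial, self.cartilage_thickness_lateral) < 0:
            raise ConfigError("cartilage thickness must be >= 0")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.lesion is not None and (
            self.lesion.residual_thickness > self.cartilage_thickness_medial
        ):
            raise ConfigError(
                "lesion residual_thickness exceeds the cartilage thickness at the site"
            )
        uv, cy5 = self.intensities["uv"], self.intensities["cy5"]
        if not (uv["bone"] > uv["cartilage"] and uv["bone"] > uv["background"]):
            raise ConfigError("UV contrast must satisfy bone >> cartilage ~ background")
        if not (cy5["cartilage"] < cy5["background"] < cy5["bone"]):
            raise ConfigError(
                "Cy5 contrast must satisfy cartilage < background < bone"
            )

    @property
    def top_margin(self) -> float:
        """Background headspace (µm) kept above the tallest cartilage."""
        return 4 * self.voxel_size

    @property
    def block_depth(self) -> float:
        """Depth (µm from the top of the stack) of the flat bone block top."""
        t_max = max(
            self.cartilage_thickness_medial, self.cartilage_thickness_lateral
        )
        return self.top_margin + t_max + 10.0 + self.dome_height + self.plateau_height


def small_spec(**overrides) -> PhantomSpec:
    """A scaled-down phantom for simulation studies (same geometry ratios).

    Grid 40 x 64 x 96 voxels at 5 µm with a 100 x 160 µm nominal VOI; the
    VOI still sits inside each plateau footprint and default cohort lesions
    still cover the VOI.
    """
    base = dict(
        grid_shape=(40, 64, 96),
        plateau_height=40.0,
        dome_height=10.0,
        voi=VOISpec(width_ml=100.0, length_ap=160.0),
    )
    base.update(overrides)
    return PhantomSpec(**base)


@dataclass
class PhantomResult:
    uv: ChannelStack
    cy5: ChannelStack
    bone_truth: BinaryVolume
    cartilage_truth: BinaryVolume
    true_mean_thickness: dict[Compartment, float]


def _plateau_geometry(spec: PhantomSpec):
    """Continuous surface depth S(y, x) and thickness field T(y, x), in µm."""
    nz, ny, nx = spec.grid_shape
    vs = spec.voxel_size
    xu = (np.arange(nx) + 0.5) * vs  # voxel-center physical coordinates
    yu = (np.arange(ny) + 0.5) * vs
    X, Y = np.meshgrid(xu, yu)  # (y, x)

    x_mid = nx * vs / 2.0
    margin = 3 * vs
    half_notch = spec.notch_width / 2.0
    extents = {
        Compartment.MEDIAL: (margin, x_mid - half_notch),
        Compartment.LATERAL: (x_mid + half_notch, nx * vs - margin),
    }
    y0, y1 = margin, ny * vs - margin

    S = np.full((ny, nx), spec.block_depth)
    T = np.zeros((ny, nx))
    footprints: dict[Compartment, np.ndarray] = {}
    thickness = {
        Compartment.MEDIAL: spec.cartilage_thickness_medial,
        Compartment.LATERAL: spec.cartilage_thickness_lateral,
    }
    for comp, (x0, x1) in extents.items():
        fp = (X >= x0) & (X < x1) & (Y >= y0) & (Y < y1)
        footprints[comp] = fp
        # separable cosine dome: gentle, maximal at the footprint center
        xi = np.clip(2.0 * (X - x0) / (x1 - x0) - 1.0, -1.0, 1.0)
        eta = np.clip(2.0 * (Y - y0) / (y1 - y0) - 1.0, -1.0, 1.0)
        dome = spec.dome_height * np.cos(np.pi * xi / 2) * np.cos(np.pi * eta / 2)
        S = np.where(fp, spec.block_depth - spec.plateau_height - dome, S)
        ramp_slope = spec.thickness_ramp / spec.voi.length_ap
        t_field = np.maximum(
            thickness[comp] + ramp_slope * (Y - (y0 + y1) / 2.0), 0.0
        )
        T = np.where(fp, t_field, T)

    if spec.lesion is not None:
        les = spec.lesion
        if les.center is None:
            fp = footprints[Compartment.MEDIAL]
            cx = X[fp].mean()
            cy = Y[fp].mean()
        else:
            cx, cy = les.center
        inside = ((X - cx) / les.radius_x) ** 2 + ((Y - cy) / les.radius_y) ** 2 <= 1.0
        T = np.where(inside & footprints[Compartment.MEDIAL],
                     les.residual_thickness, T)

    if spec.osteophyte is not None:
        ost = spec.osteophyte
        # hemispherical bump straddling the medial outer margin
        bx, by = margin, ny * vs / 2.0
        rho2 = (X - bx) ** 2 + (Y - by) ** 2
        elev = np.sqrt(np.maximum(ost.radius**2 - rho2, 0.0))
        bump = elev > 0
        S_bump = spec.block_depth - elev
        grow = bump & (S_bump < S)
        S = np.where(grow, S_bump, S)
        T = np.where(grow & (T == 0), ost.cap_thickness, T)

    return S, T, footprints


def _voxelize(spec: PhantomSpec, S: np.ndarray, T: np.ndarray):
    nz, ny, nx = spec.grid_shape
    vs = spec.voxel_size
    zc = (np.arange(nz) + 0.5)[:, None, None] * vs
    bone = zc >= S[None, :, :]
    cart = (T[None, :, :] > 0) & (zc >= (S - T)[None, :, :]) & (zc < S[None, :, :])
    if np.any((S - T) < spec.voxel_size):
        raise ConfigError(
            "cartilage layer does not fit above the plateau; enlarge the grid "
            "or reduce thickness"
        )
    return bone, cart


def _render_channel(
    spec: PhantomSpec, channel: Channel, bone: np.ndarray, cart: np.ndarray,
    rng: np.random.Generator,
) -> ChannelStack:
    levels = spec.intensities[channel.value]
    img = np.full(spec.grid_shape, levels["background"], dtype=np.float32)
    img[bone] = levels["bone"]
    img[cart] = levels["cartilage"]
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape).astype(np.float32)
    img = np.maximum(img, 0.0)
    cal = Calibration(
        xy_resolution=spec.voxel_size, z_step=spec.voxel_size,
        target_voxel=spec.voxel_size,
    )
    if spec.anisotropic_output:
        native = Calibration()  # 1.218 µm XY, 5 µm Z
        f = spec.voxel_size / native.xy_resolution
        img = ndimage.zoom(img, (1.0, f, f), order=1, grid_mode=True,
                           mode="nearest")
        img = np.maximum(img, 0.0)
        cal = Calibration(
            xy_resolution=native.xy_resolution, z_step=spec.voxel_size,
            target_voxel=spec.voxel_size,
        )
    return ChannelStack(channel, img.astype(np.float32), cal)


def _truth_means(
    spec: PhantomSpec, cart: BinaryVolume
) -> dict[Compartment, float]:
    """Voxel-weighted mean column thickness inside each nominal VOI.

    Each cartilage voxel in a column of ``n`` cartilage voxels carries a
    thickness of ``n * voxel_size``; averaging over voxels reproduces what a
    local-thickness measurement reports on a draped near-vertical layer.
    """
    means: dict[Compartment, float] = {}
    try:
        boxes = voi_mapping.map_vois(cart, spec.voi, medial_side="low_x")
    except Exception:
        return {Compartment.MEDIAL: 0.0, Compartment.LATERAL: 0.0}
    for box in boxes:
        sub = cart.voxels[box.slices]
        ncol = sub.sum(axis=0).astype(np.float64)
        total = ncol.sum()
        if total == 0:
            means[box.compartment] = 0.0
        else:
            means[box.compartment] = float(
                (ncol**2).sum() / total * spec.voxel_size
            )
    return means


def generate_phantom(spec: PhantomSpec | None = None) -> PhantomResult:
    """Generate one dual-channel phantom with ground truth.

    Identical ``spec.seed`` yields bit-identical output. With ``noise_sd=0``
    and ``dome_height=0`` the cartilage over each plateau is an exact slab of
    the requested thickness and the reported true means are exact.
    """
    spec = spec or PhantomSpec()
    S, T, _ = _plateau_geometry(spec)
    bone, cart = _voxelize(spec, S, T)
    rng = np.random.default_rng(spec.seed)
    uv = _render_channel(spec, Channel.UV, bone, cart, rng)
    cy5 = _render_channel(spec, Channel.CY5, bone, cart, rng)
    bone_truth = BinaryVolume(bone, spec.voxel_size, TissueLabel.BONE)
    cart_truth = BinaryVolume(cart, spec.voxel_size, TissueLabel.CARTILAGE)
    means = _truth_means(spec, cart_truth)
    log.info(
        "phantom: %d bone / %d cartilage voxels, true VOI means %s",
        bone_truth.count,
        cart_truth.count,
        {k.value: round(v, 2) for k, v in means.items()},
    )
    return PhantomResult(uv, cy5, bone_truth, cart_truth, means)


def default_cohort_lesion(spec: PhantomSpec) -> LesionSpec:
    """Full-erosion medial lesion sized to cover the whole VOI (radii = 0.8
    of the VOI extents, centered on the plateau)."""
    return LesionSpec(
        radius_x=0.8 * spec.voi.width_ml,
        radius_y=0.8 * spec.voi.length_ap,
        residual_thickness=0.0,
        center=None,
    )


@dataclass
class CohortSample:
    sample_id: str
    group: Group
    uv: ChannelStack
    cy5: ChannelStack
    bone_truth: BinaryVolume
    cartilage_truth: BinaryVolume


def generate_cohort(
    n_pairs: int,
    base_spec: PhantomSpec | None = None,
    dmm_effect: LesionSpec | None = None,
    thickness_jitter_sd: float = 4.0,
    seed: int = 0,
) -> tuple[list[CohortSample], list[MeasurementRecord]]:
    """Simulate a paired surgical cohort: per animal, one contralateral limb
    (no lesion) and one operated limb carrying ``dmm_effect`` on the medial
    plateau (the lateral compartment is spared).

    Per-limb, per-compartment cartilage thickness is jittered around the
    base values (Gaussian, sd ``thickness_jitter_sd`` µm), emulating
    biological variation. ``dmm_effect=None`` generates a null cohort (both
    limbs lesion-free) for calibration studies. Returns the samples and the
    expected measurement records carrying ground-truth VOI means.
    """
    if n_pairs < 1:
        raise ConfigError("n_pairs must be >= 1")
    base_spec = base_spec or PhantomSpec()
    rng = np.random.default_rng(seed)
    samples: list[CohortSample] = []
    expected: list[MeasurementRecord] = []
    for i in range(1, n_pairs + 1):
        for group, suffix in ((Group.CONTRALATERAL, "ctl"), (Group.DMM, "dmm")):
            jit_m, jit_l = rng.normal(0.0, thickness_jitter_sd, size=2)
            sub_seed = int(rng.integers(0, 2**31 - 1))
            lesion = dmm_effect if group is Group.DMM else None
            spec_i = replace(
                base_spec,
                cartilage_thickness_medial=max(
                    base_spec.cartilage_thickness_medial + jit_m, 0.0
                ),
                cartilage_thickness_lateral=max(
                    base_spec.cartilage_thickness_lateral + jit_l, 0.0
                ),
                lesion=lesion,
                seed=sub_seed,
            )
            result = generate_phantom(spec_i)
            sample_id = f"m{i:02d}_{suffix}"
            samples.append(
                CohortSample(
                    sample_id,
                    group,
                    result.uv,
                    result.cy5,
                    result.bone_truth,
                    result.cartilage_truth,
                )
            )
            for comp in (Compartment.MEDIAL, Compartment.LATERAL):
                mean = result.true_mean_thickness[comp]
                n_proxy = 0 if mean == 0 else 1
                expected.append(
                    MeasurementRecord(sample_id, group, comp, mean, n_proxy)
                )
    return samples, expected
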