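"""Synthetic co-registered T1/T2 brain slice phantoms with known tumor masks.

The phantom emulates the intensity structure the segmentation pipeline
assumes: an 8-bit, geometrically aligned T1/T2 pair showing a well-centered
axial brain slice built from tissue classes with distinct (T1, T2) mean
intensities - background/air, skull, gray matter, white matter, CSF - plus
a tumor that is bright on T2, and optionally a rim of edema (T2-bright, the
pipeline's documented failure mode).  Gaussian noise is added per pixel,
independently per channel.

Geometry is deliberately simple: the brain is an axis-aligned ellipse
centered in the image, wrapped by a skull ring and a gray-matter band, with
two mirror-symmetric ventricles (CSF).  The tumor is an ellipse placed in
the left or right hemisphere or straddling the midline.  The ground-truth
mask is exactly the rasterized tumor ellipse.

Default intensities are typical of non-contrast 1.5 T imaging mapped to
8 bits: white matter bright on T1 / mid on T2, CSF dark on T1 / bright on
T2, tumor moderately hypointense on T1 and hyperintense on T2.  The default
tumor size (~1900 px on a 256x256 grid) matches the ground-truth areas
reported for clinical meningioma slices of that matrix size.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import yaml
from scipy.ndimage import gaussian_filter

from .histogram_fcm import ImagePair

__all__ = ["TissueClass", "TumorSpec", "EdemaSpec", "PhantomSpec", "generate_phantom"]


@dataclass(frozen=True)
class TissueClass:
    """A tissue with mean 8-bit intensities on T1 and T2 and an intra-tissue SD.

    ``sd`` models biological heterogeneity and partial-volume spread within
    the tissue (same on both channels); acquisition noise is added on top
    via :attr:`PhantomSpec.noise_sd`.
    """

    name: str
    t1_mean: float
    t2_mean: float
    sd: float = 0.0

    def __post_init__(self) -> None:
        for v in (self.t1_mean, self.t2_mean):
            if not 0 <= v <= 255:
                raise ValueError(f"{self.name}: mean intensity {v} outside [0, 255]")
        if self.sd < 0:
            raise ValueError(f"{self.name}: sd must be >= 0")


@dataclass(frozen=True)
class TumorSpec:
    """Tumor ellipse: T2-bright lesion with given semi-axes (rows, cols)."""

    t1_mean: float = 90.0
    t2_mean: float = 200.0
    sd: float = 5.0  # meningiomas are characteristically T2-homogeneous
    semi_axes: tuple[int, int] = (22, 28)

    def __post_init__(self) -> None:
        for v in (self.t1_mean, self.t2_mean):
            if not 0 <= v <= 255:
                raise ValueError(f"tumor mean intensity {v} outside [0, 255]")


@dataclass(frozen=True)
class EdemaSpec:
    """Edema ring around the tumor; T2 between tumor and normal tissue."""

    t1_mean: float = 100.0
    t2_mean: float = 165.0
    sd: float = 8.0
    width: int = 8


DEFAULT_TISSUES = (
    TissueClass("background", 0.0, 0.0, 0.0),
    TissueClass("skull", 30.0, 20.0, 5.0),
    TissueClass("gray_matter", 110.0, 115.0, 25.0),
    TissueClass("white_matter", 150.0, 90.0, 25.0),
    TissueClass("csf", 45.0, 230.0, 25.0),
)


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters for one synthetic T1/T2 slice pair.

    ``tumor_position`` is ``"left"``, ``"right"`` or ``"midline"`` (patient
    left appears on the image left here; no radiological flip).  ``noise_sd``
    is the per-pixel, per-channel Gaussian noise in 8-bit intensity units.
    A fixed ``seed`` makes the output byte-identical across runs.
    """

    width: int = 256
    height: int = 256
    tissue_classes: tuple[TissueClass, ...] = DEFAULT_TISSUES
    tumor: Optional[TumorSpec] = field(default_factory=TumorSpec)
    tumor_position: str = "left"
    edema: Optional[EdemaSpec] = None
    noise_sd: float = 5.0
    texture_corr: float = 2.0  # correlation length (px) of intra-tissue heterogeneity
    seed: int = 0

    # geometry, as fractions of the half-extent
    brain_fraction: float = 0.82  # brain semi-axes / image half-extent
    skull_width: int = 6
    gray_band: int = 12

    def __post_init__(self) -> None:
        if self.tumor_position not in ("left", "right", "midline"):
            raise ValueError(f"tumor_position must be left/right/midline, got {self.tumor_position!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def tissue(self, name: str) -> TissueClass:
        for t in self.tissue_classes:
            if t.name == name:
                return t
        raise KeyError(name)

    def to_yaml(self) -> str:
        def plain(obj):
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            return obj

        return yaml.safe_dump(plain(asdict(self)), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "PhantomSpec":
        d = yaml.safe_load(text)
        if "tissue_classes" in d:
            d["tissue_classes"] = tuple(TissueClass(**t) for t in d["tissue_classes"])
        if d.get("tumor") is not None:
            d["tumor"] = TumorSpec(**{**d["tumor"], "semi_axes": tuple(d["tumor"]["semi_axes"])})
        if d.get("edema") is not None:
            d["edema"] = EdemaSpec(**d["edema"])
        return cls(**d)


def _ellipse_mask(shape: tuple[int, int], center: tuple[float, float], semi_axes: tuple[float, float]) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return ((rr - center[0]) / semi_axes[0]) ** 2 + ((cc - center[1]) / semi_axes[1]) ** 2 <= 1.0


def _tumor_center(spec: PhantomSpec, brain_axes: tuple[float, float]) -> tuple[float, float]:
    r0 = (spec.height - 1) / 2.0
    c0 = (spec.width - 1) / 2.0
    if spec.tumor_position == "midline":
        return (r0 - brain_axes[0] * 0.35, c0)
    offset = brain_axes[1] * 0.45
    return (r0, c0 - offset if spec.tumor_position == "left" else c0 + offset)


def generate_phantom(spec: PhantomSpec) -> tuple[ImagePair, np.ndarray]:
    """Render `spec` into an (ImagePair, ground-truth tumor mask) tuple.

    The label geometry is painted back-to-front (background, skull ring,
    gray-matter band, white-matter core, ventricles, edema, tumor), noise is
    added, and intensities are rounded and clipped to [0, 255].  The returned
    mask is exactly the tumor ellipse.

    Raises ``ValueError`` if the tumor (or its edema ring) is not fully
    inside the brain ellipse.
    """
    shape = (spec.height, spec.width)
    # center on the pixel grid's midpoint so even-width phantoms are exactly
    # mirror-symmetric column-for-column
    center = ((spec.height - 1) / 2.0, (spec.width - 1) / 2.0)
    half = (spec.height / 2.0, spec.width / 2.0)
    outer_axes = (half[0] * spec.brain_fraction, half[1] * spec.brain_fraction)
    brain_axes = (outer_axes[0] - spec.skull_width, outer_axes[1] - spec.skull_width)
    wm_axes = (brain_axes[0] - spec.gray_band, brain_axes[1] - spec.gray_band)

    bg = spec.tissue("background")
    t1 = np.full(shape, bg.t1_mean)
    t2 = np.full(shape, bg.t2_mean)
    sd_map = np.full(shape, bg.sd)

    def paint(mask: np.ndarray, t1_mean: float, t2_mean: float, sd: float = 0.0) -> None:
        t1[mask] = t1_mean
        t2[mask] = t2_mean
        sd_map[mask] = sd

    skull = _ellipse_mask(shape, center, outer_axes)
    brain = _ellipse_mask(shape, center, brain_axes)
    wm = _ellipse_mask(shape, center, wm_axes)
    sk = spec.tissue("skull")
    gm = spec.tissue("gray_matter")
    wmt = spec.tissue("white_matter")
    csf = spec.tissue("csf")
    paint(skull, sk.t1_mean, sk.t2_mean, sk.sd)
    paint(brain, gm.t1_mean, gm.t2_mean, gm.sd)
    paint(wm, wmt.t1_mean, wmt.t2_mean, wmt.sd)

    # two mirror-symmetric ventricles near the center
    vent_axes = (spec.height * 0.07, spec.width * 0.035)
    vent_off = spec.width * 0.06
    for sign in (-1, 1):
        paint(
            _ellipse_mask(shape, (center[0], center[1] + sign * vent_off), vent_axes),
            csf.t1_mean,
            csf.t2_mean,
            csf.sd,
        )

    gt_mask = np.zeros(shape, dtype=bool)
    if spec.tumor is not None:
        tc = _tumor_center(spec, brain_axes)
        gt_mask = _ellipse_mask(shape, tc, spec.tumor.semi_axes)
        halo_axes = spec.tumor.semi_axes
        if spec.edema is not None:
            halo_axes = (halo_axes[0] + spec.edema.width, halo_axes[1] + spec.edema.width)
        halo = _ellipse_mask(shape, tc, halo_axes)
        if (halo & ~brain).any():
            raise ValueError("tumor (with edema) extends outside the brain ellipse; shrink or recenter it")
        if spec.edema is not None:
            paint(halo & ~gt_mask, spec.edema.t1_mean, spec.edema.t2_mean, spec.edema.sd)
        paint(gt_mask, spec.tumor.t1_mean, spec.tumor.t2_mean, spec.tumor.sd)

    # intra-tissue heterogeneity is a spatially smooth random field (unit
    # variance after filtering) scaled by the tissue SD; acquisition noise is
    # iid on top.  Fields are drawn independently per channel.
    rng = np.random.default_rng(spec.seed)
    for img in (t1, t2):
        if (sd_map > 0).any():
            field = rng.standard_normal(shape)
            if spec.texture_corr > 0:
                field = gaussian_filter(field, sigma=spec.texture_corr)
                field /= field.std()
            img += field * sd_map
        if spec.noise_sd > 0:
            img += rng.standard_normal(shape) * spec.noise_sd

    t1 = np.clip(np.rint(t1), 0, 255).astype(np.uint8)
    t2 = np.clip(np.rint(t2), 0, 255).astype(np.uint8)
    return ImagePair(t1=t1, t2=t2), gt_mask
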