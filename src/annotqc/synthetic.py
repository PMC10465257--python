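"""OCT-like phantoms and simulated annotators with known ground truth.

The phantom is deliberately schematic, not a simulation of OCT physics: a
dark vitreous above and below a brighter three-band "retina", with dark
elliptical fluid regions embedded in the tissue.  Speckle is modelled as
count noise, pixel ~ Poisson(lambda * clean) / lambda, which preserves the
mean, gives variance clean / lambda, and makes lambda identifiable from the
variance/mean slope — the contract the noise estimator is tested against.

Simulated annotators perturb the true regions through a signed-distance
representation: a positive boundary bias dilates every region (the
oversegmentation habit of junior readers), smooth radial jitter wobbles the
boundary, regions are occasionally missed altogether, and spurious small
regions may be added.  Errors grow with distance from the image centre via
a per-rater zone-decay multiplier.

All randomness descends from one root seed; per-(rater, image, round)
sub-seeds are derived by hashing, so adding a rater never changes another
rater's masks.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage

from .image_properties import ZoneSpec, zone_of
from .io_manifest import AnnotationMask, BScanImage

__all__ = [
    "PhantomSpec",
    "RaterProfile",
    "SyntheticStudy",
    "GenerationError",
    "generate_phantom",
    "simulate_annotator",
    "generate_study",
    "default_phantom_specs",
    "default_profiles",
    "subseed",
]


class GenerationError(RuntimeError):
    """Phantom regions could not be placed within the image bounds."""


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, intensity and noise parameters of one phantom B-scan.

    Defaults mirror a typical clinical B-scan: 732 x 428 px at 10.5 um/px
    laterally and 3.8 um/px axially, mid-grey tissue (~0.5) and minimally
    reflective fluid (~0.05).  ``region_axes_um`` bounds the ellipse
    semi-axes in microns, so regions are roughly round in physical space
    and elongated vertically in (anisotropic) pixel space.
    """

    height_px: int = 428
    width_px: int = 732
    scale_x_um: float = 10.5
    scale_y_um: float = 3.8
    n_regions: int = 12
    region_axes_um: tuple[float, float] = (25.0, 120.0)
    tissue_intensity: float = 0.5
    fluid_intensity: float = 0.05
    noise_lambda: float = 20.0
    edge_blur_px: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.fluid_intensity < self.tissue_intensity <= 1):
            raise ValueError("need 0 <= fluid_intensity < tissue_intensity <= 1")
        if self.noise_lambda <= 0:
            raise ValueError("noise_lambda must be positive")
        if self.n_regions < 0:
            raise ValueError("n_regions must be nonnegative")
        lo, hi = self.region_axes_um
        if not 0 < lo <= hi:
            raise ValueError("region_axes_um must be a positive (lo, hi) range")


@dataclass(frozen=True)
class RaterProfile:
    """Error model of one simulated annotator.

    boundary_bias_px > 0 dilates (oversegments); jitter_sd_px is the s.d.
    of a smooth radial boundary perturbation; miss_rate is the per-region
    omission probability; spurious_rate the expected count of false regions
    per image; zone_decay >= 1 multiplies jitter and miss once per zone
    step away from the centre.
    """

    rater_id: str
    tier: Literal["expert", "junior"]
    boundary_bias_px: float = 0.0
    jitter_sd_px: float = 0.0
    miss_rate: float = 0.0
    spurious_rate: float = 0.0
    zone_decay: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.miss_rate <= 1.0:
            raise ValueError("miss_rate must be a probability")
        if self.jitter_sd_px < 0 or self.spurious_rate < 0 or self.zone_decay < 1:
            raise ValueError("jitter_sd_px, spurious_rate >= 0 and zone_decay >= 1")


# --------------------------------------------------------------------------
# phantom generation
# --------------------------------------------------------------------------

_TISSUE_TOP = 0.22  # tissue band as fractions of image height
_TISSUE_BOTTOM = 0.78
_VITREOUS_INTENSITY = 0.04


def _clean_background(spec: PhantomSpec) -> np.ndarray:
    """Layered tissue: three horizontal bands with smoothed transitions."""
    h, w = spec.height_px, spec.width_px
    profile = np.full(h, _VITREOUS_INTENSITY)
    top = int(_TISSUE_TOP * h)
    bottom = int(_TISSUE_BOTTOM * h)
    band = bottom - top
    t = spec.tissue_intensity
    profile[top:top + band // 3] = 1.15 * t
    profile[top + band // 3:top + 2 * band // 3] = 0.85 * t
    profile[top + 2 * band // 3:bottom] = 1.10 * t
    profile = ndimage.gaussian_filter1d(profile, sigma=4.0, mode="nearest")
    return np.clip(np.tile(profile[:, None], (1, w)), 0.0, 1.0)


def _place_ellipses(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    h, w = spec.height_px, spec.width_px
    truth = np.zeros((h, w), dtype=bool)
    lo, hi = spec.region_axes_um
    row_lo, row_hi = int(0.30 * h), int(0.70 * h)
    rows_idx, cols_idx = np.mgrid[0:h, 0:w]
    for _ in range(spec.n_regions):
        for attempt in range(200):
            a_um = rng.uniform(lo, hi)   # lateral semi-axis, microns
            b_um = rng.uniform(lo, hi)   # axial semi-axis, microns
            ax = max(a_um / spec.scale_x_um, 1.5)  # px
            ay = max(b_um / spec.scale_y_um, 1.5)  # px
            if ax + 2 >= w - ax - 2:
                continue  # region wider than the image
            cy = rng.uniform(row_lo, row_hi)
            cx = rng.uniform(ax + 2, w - ax - 2)
            if cy - ay < 2 or cy + ay > h - 2:
                continue
            ellipse = ((rows_idx - cy) / ay) ** 2 + ((cols_idx - cx) / ax) ** 2 <= 1.0
            truth |= ellipse
            break
        else:
            raise GenerationError(
                f"could not place region within bounds after 200 attempts "
                f"(spec seed {spec.seed})"
            )
    return truth


def generate_phantom(spec: PhantomSpec) -> tuple[BScanImage, AnnotationMask]:
    """Phantom B-scan plus its exact fluid-region truth mask.

    Pure function of ``spec`` (including its seed): same spec, same bits.
    """
    rng = np.random.default_rng(spec.seed)
    clean = _clean_background(spec)
    truth = _place_ellipses(spec, rng)
    clean[truth] = spec.fluid_intensity
    if spec.edge_blur_px > 0:
        clean = ndimage.gaussian_filter(clean, sigma=spec.edge_blur_px)
    lam = spec.noise_lambda
    noisy = rng.poisson(lam * clean).astype(np.float64) / lam
    image = BScanImage(
        image_id=f"phantom-{spec.seed}",
        pixels=np.clip(noisy, 0.0, 1.0),
        scale_x_um=spec.scale_x_um,
        scale_y_um=spec.scale_y_um,
    )
    mask = AnnotationMask(image_id=image.image_id, rater_id="truth",
                          round_id=1, mask=truth)
    return image, mask


# --------------------------------------------------------------------------
# annotator simulation
# --------------------------------------------------------------------------


def _zone_factor(profile: RaterProfile, zone: int | None,
                 n_zones: int) -> float:
    z = zone if zone is not None else n_zones + 1
    return profile.zone_decay ** (z - 1)


def _perturb_region(region: np.ndarray, bias_px: float, jitter_sd_px: float,
                    rng: np.random.Generator,
                    jitter_corr_px: float = 3.0) -> np.ndarray:
    """Deform one region through its signed distance map.

    Output = { d + bias + eta >= 0 } where d is the signed Euclidean
    distance (positive inside) and eta a smooth zero-mean field of s.d.
    jitter_sd_px.  bias alone reproduces morphological dilation/erosion by
    a disc of that radius (up to rasterisation).
    """
    d = ndimage.distance_transform_edt(region) - \
        ndimage.distance_transform_edt(~region)
    if jitter_sd_px > 0:
        noise = ndimage.gaussian_filter(
            rng.standard_normal(region.shape), sigma=jitter_corr_px)
        sd = noise.std()
        eta = noise / sd * jitter_sd_px if sd > 0 else 0.0
    else:
        eta = 0.0
    return d + bias_px + eta >= 0


def simulate_annotator(
    truth: AnnotationMask,
    image: BScanImage,
    profile: RaterProfile,
    seed: int,
    round_id: int = 1,
    zone_spec: ZoneSpec = ZoneSpec(),
) -> AnnotationMask:
    """One rater's imperfect re-annotation of the true regions."""
    truth.check_aligned(image)
    rng = np.random.default_rng(seed)
    h, w = truth.shape
    out = np.zeros((h, w), dtype=bool)
    structure = ndimage.generate_binary_structure(2, 2)
    labels, n = ndimage.label(truth.mask, structure=structure)
    objects = ndimage.find_objects(labels)
    n_zones = len(zone_spec.boundaries_mm)
    for rid in range(1, n + 1):
        sl = objects[rid - 1]
        rows, cols = np.nonzero(labels == rid)
        zone = zone_of((float(rows.mean()), float(cols.mean())), image, zone_spec)
        zf = _zone_factor(profile, zone, n_zones)
        if rng.random() < min(1.0, profile.miss_rate * zf):
            continue
        jitter = profile.jitter_sd_px * zf
        pad = int(np.ceil(abs(profile.boundary_bias_px) + 4 * jitter + 4))
        r0, r1 = max(sl[0].start - pad, 0), min(sl[0].stop + pad, h)
        c0, c1 = max(sl[1].start - pad, 0), min(sl[1].stop + pad, w)
        crop = labels[r0:r1, c0:c1] == rid
        out[r0:r1, c0:c1] |= _perturb_region(
            crop, profile.boundary_bias_px, jitter, rng)
    # spurious annotations: small ellipses dropped into the tissue band
    n_spurious = rng.poisson(profile.spurious_rate) if profile.spurious_rate > 0 else 0
    if n_spurious:
        rows_idx, cols_idx = np.mgrid[0:h, 0:w]
        for _ in range(n_spurious):
            ay = rng.uniform(2.0, 6.0)
            ax = rng.uniform(2.0, 6.0)
            cy = rng.uniform(_TISSUE_TOP * h + ay, _TISSUE_BOTTOM * h - ay)
            cx = rng.uniform(ax, w - ax)
            out |= ((rows_idx - cy) / ay) ** 2 + ((cols_idx - cx) / ax) ** 2 <= 1.0
    return AnnotationMask(image_id=truth.image_id, rater_id=profile.rater_id,
                          round_id=round_id, mask=out)


# --------------------------------------------------------------------------
# whole-study generation
# --------------------------------------------------------------------------


@dataclass
class SyntheticStudy:
    """A full simulated grading study with its truth channel."""

    images: dict[str, BScanImage]
    truth: dict[str, AnnotationMask]
    masks: dict[tuple[str, str, int], AnnotationMask]
    profiles: list[RaterProfile]
    true_lambdas: dict[str, float] = field(default_factory=dict)

    @property
    def image_ids(self) -> list[str]:
        return list(self.images)

    @property
    def rater_tiers(self) -> dict[str, str]:
        return {p.rater_id: p.tier for p in self.profiles}

    @property
    def consensus_raters(self) -> list[str]:
        return [p.rater_id for p in self.profiles if p.tier == "expert"]


def subseed(root: int, *parts: object) -> int:
    """Stable sub-seed below 2**31 derived from a root seed and a key."""
    key = ":".join([str(root), *map(str, parts)]).encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "little") % (2**31)


def generate_study(
    phantom_specs: Sequence[PhantomSpec],
    profiles: Sequence[RaterProfile],
    rounds: int = 2,
    seed: int = 0,
    zone_spec: ZoneSpec = ZoneSpec(),
) -> SyntheticStudy:
    """Generate phantoms and every rater's masks for every round.

    Rounds are i.i.d. draws from the same profiles: the study this emulates
    found little change between rounds, and no quantitative round-effect
    model is available, so none is imposed.
    """
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    if not phantom_specs or not profiles:
        raise ValueError("need at least one phantom spec and one profile")
    images: dict[str, BScanImage] = {}
    truth: dict[str, AnnotationMask] = {}
    masks: dict[tuple[str, str, int], AnnotationMask] = {}
    lambdas: dict[str, float] = {}
    for i, spec in enumerate(phantom_specs):
        spec_i = replace(spec, seed=subseed(seed, "phantom", i))
        image, tmask = generate_phantom(spec_i)
        image_id = f"img{i:02d}"
        image = BScanImage(image_id=image_id, pixels=image.pixels,
                           scale_x_um=image.scale_x_um,
                           scale_y_um=image.scale_y_um)
        tmask = AnnotationMask(image_id=image_id, rater_id="truth",
                               round_id=1, mask=tmask.mask)
        images[image_id] = image
        truth[image_id] = tmask
        lambdas[image_id] = spec.noise_lambda
        for profile in profiles:
            for rnd in range(1, rounds + 1):
                s = subseed(seed, profile.rater_id, image_id, rnd)
                masks[(image_id, profile.rater_id, rnd)] = simulate_annotator(
                    tmask, image, profile, seed=s, round_id=rnd,
                    zone_spec=zone_spec,
                )
    return SyntheticStudy(images=images, truth=truth, masks=masks,
                          profiles=list(profiles), true_lambdas=lambdas)


# study-scale defaults: 10 images whose noise levels span the low/medium/
# high bins (5/3/2), 2 experts + 3 juniors, 2 rounds
_DEFAULT_LAMBDAS = (5.0, 8.0, 12.0, 15.0, 18.0, 25.0, 30.0, 38.0, 45.0, 80.0)


def default_phantom_specs(
    n_images: int = 10, **overrides: object
) -> list[PhantomSpec]:
    """Phantom specs for a default study; noise spans lambda ~ 5 to 80."""
    specs = []
    for i in range(n_images):
        lam = _DEFAULT_LAMBDAS[i % len(_DEFAULT_LAMBDAS)]
        specs.append(PhantomSpec(noise_lambda=lam, **overrides))  # type: ignore[arg-type]
    return specs


def default_profiles() -> list[RaterProfile]:
    """Two careful experts and three juniors with oversegmentation bias,
    boundary jitter, misses and zone-dependent decay; junior severity
    varies to emulate a range of trainee experience."""
    return [
        RaterProfile("Ex1", "expert", boundary_bias_px=0.0, jitter_sd_px=0.4,
                     miss_rate=0.02, spurious_rate=0.05, zone_decay=1.0),
        RaterProfile("Ex2", "expert", boundary_bias_px=0.2, jitter_sd_px=0.5,
                     miss_rate=0.02, spurious_rate=0.05, zone_decay=1.0),
        RaterProfile("Jr1", "junior", boundary_bias_px=1.5, jitter_sd_px=1.2,
                     miss_rate=0.08, spurious_rate=0.3, zone_decay=1.4),
        RaterProfile("Jr2", "junior", boundary_bias_px=3.0, jitter_sd_px=2.2,
                     miss_rate=0.15, spurious_rate=0.6, zone_decay=1.9),
        RaterProfile("Jr3", "junior", boundary_bias_px=2.5, jitter_sd_px=1.8,
                     miss_rate=0.12, spurious_rate=0.5, zone_decay=1.7),
    ]
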