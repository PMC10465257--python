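"""Image, mask and study-manifest IO.

A study is a set of greyscale B-scans, each with its own physical scaling
(microns per pixel, anisotropic), plus one binary annotation mask per
(image, rater, round).  The manifest binds them together and declares which
raters' masks form the consensus ground truth.

Intensities are normalised to [0, 1] by dividing by the container dtype
maximum (255 or 65535), never by the per-image maximum, so that intensity
statistics are comparable across images.  Masks are strict on write
(0/255 single-channel PNG) and tolerant on read (any nonzero pixel is
foreground).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import tifffile
from pydantic import BaseModel, Field, field_validator

__all__ = [
    "BScanImage",
    "AnnotationMask",
    "ImageRecord",
    "MaskRecord",
    "StudyManifest",
    "ManifestError",
    "AlignmentError",
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "load_manifest",
    "save_manifest",
    "write_table",
]


class ManifestError(ValueError):
    """Referential-integrity or schema violation in a study manifest."""


class AlignmentError(ValueError):
    """A mask does not align with the image it claims to annotate."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class BScanImage:
    """A single 2-D greyscale B-scan with physical pixel scaling.

    ``pixels`` holds normalised intensity in [0, 1]; ``scale_x_um`` /
    ``scale_y_um`` are microns per pixel along columns (lateral) and rows
    (axial) respectively.
    """

    image_id: str
    pixels: np.ndarray
    scale_x_um: float
    scale_y_um: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got shape {px.shape}")
        if px.size and (px.min() < 0.0 or px.max() > 1.0):
            raise ValueError("pixel intensities must lie in [0, 1]")
        if not (self.scale_x_um > 0 and self.scale_y_um > 0):
            raise ValueError("physical scales must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def height_px(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width_px(self) -> int:
        return int(self.pixels.shape[1])

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class AnnotationMask:
    """Binary annotation tagged with its (image, rater, round) identity."""

    image_id: str
    rater_id: str
    round_id: int
    mask: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mask)
        if m.ndim != 2:
            raise ValueError(f"mask must be 2-D, got shape {m.shape}")
        if m.dtype != bool:
            m = m != 0
        if not self.rater_id:
            raise ValueError("rater_id must be non-empty")
        if self.round_id not in (1, 2):
            raise ValueError(f"round_id must be 1 or 2, got {self.round_id}")
        object.__setattr__(self, "mask", m)

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape  # type: ignore[return-value]

    def check_aligned(self, image: BScanImage) -> None:
        if self.image_id != image.image_id or self.shape != image.shape:
            raise AlignmentError(
                f"mask ({self.image_id}, {self.rater_id}, r{self.round_id}) "
                f"shape {self.shape} does not align with image "
                f"{image.image_id} shape {image.shape}"
            )


# pydantic models do the schema-level validation of manifest files
class ImageRecord(BaseModel):
    image_id: str = Field(min_length=1)
    path: str
    scale_x_um: float = Field(gt=0)
    scale_y_um: float = Field(gt=0)


class MaskRecord(BaseModel):
    image_id: str = Field(min_length=1)
    rater_id: str = Field(min_length=1)
    round_id: int
    path: str

    @field_validator("round_id")
    @classmethod
    def _round_in_range(cls, v: int) -> int:
        if v not in (1, 2):
            raise ValueError("round_id must be 1 or 2")
        return v


@dataclass
class StudyManifest:
    """The study design as data: images x raters x rounds, plus roles.

    ``rater_tiers`` maps every rater to ``"expert"`` or ``"junior"``;
    ``consensus_raters`` lists the raters whose last-round masks are fused
    into the ground truth.
    """

    images: list[ImageRecord]
    masks: list[MaskRecord]
    rater_tiers: dict[str, str]
    consensus_raters: list[str]
    root: Path = field(default_factory=Path)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        image_ids = [im.image_id for im in self.images]
        if len(set(image_ids)) != len(image_ids):
            raise ManifestError("duplicate image_id in manifest")
        declared = set(image_ids)
        raters = set(self.rater_tiers)
        seen: set[tuple[str, str, int]] = set()
        for mk in self.masks:
            if mk.image_id not in declared:
                raise ManifestError(
                    f"mask references undeclared image {mk.image_id!r}"
                )
            if mk.rater_id not in raters:
                raise ManifestError(
                    f"mask references undeclared rater {mk.rater_id!r}"
                )
            key = (mk.image_id, mk.rater_id, mk.round_id)
            if key in seen:
                raise ManifestError(f"duplicate mask record {key}")
            seen.add(key)
        for tier in self.rater_tiers.values():
            if tier not in ("expert", "junior"):
                raise ManifestError(f"unknown rater tier {tier!r}")
        for r in self.consensus_raters:
            if r not in raters:
                raise ManifestError(f"consensus rater {r!r} not declared")

    @property
    def rater_ids(self) -> list[str]:
        return sorted(self.rater_tiers)

    def rounds_of(self, rater_id: str, image_id: str | None = None) -> list[int]:
        rounds = {
            mk.round_id
            for mk in self.masks
            if mk.rater_id == rater_id
            and (image_id is None or mk.image_id == image_id)
        }
        return sorted(rounds)

    def mask_record(
        self, image_id: str, rater_id: str, round_id: int
    ) -> MaskRecord | None:
        for mk in self.masks:
            if (mk.image_id, mk.rater_id, mk.round_id) == (
                image_id,
                rater_id,
                round_id,
            ):
                return mk
        return None


# --------------------------------------------------------------------------
# raster IO
# --------------------------------------------------------------------------


def _load_raster(path: Path) -> np.ndarray:
    if not path.exists():
        raise IOError(f"no such file: {path}")
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(str(path))
    else:
        arr = iio.imread(str(path))
    return np.asarray(arr)


def _collapse_grey(arr: np.ndarray, path: Path) -> np.ndarray:
    """Accept single-channel rasters, or multi-channel with equal channels."""
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3 and arr.shape[2] in (2, 3, 4):
        rgb = arr[..., : min(arr.shape[2], 3)]
        if not (rgb == rgb[..., :1]).all():
            raise ValueError(
                f"{path}: multi-channel image with unequal channels is not greyscale"
            )
        return rgb[..., 0]
    raise ValueError(f"{path}: unsupported raster shape {arr.shape}")


def _dtype_max(arr: np.ndarray) -> float:
    if np.issubdtype(arr.dtype, np.integer):
        return float(np.iinfo(arr.dtype).max)
    return 1.0  # float rasters are assumed pre-normalised


def read_image(path: str | Path, scale_x_um: float, scale_y_um: float,
               image_id: str | None = None) -> BScanImage:
    """Read a greyscale raster, normalise to [0, 1], attach physical scaling."""
    path = Path(path)
    arr = _collapse_grey(_load_raster(path), path)
    px = arr.astype(np.float64) / _dtype_max(arr)
    return BScanImage(
        image_id=image_id or path.stem,
        pixels=np.clip(px, 0.0, 1.0),
        scale_x_um=scale_x_um,
        scale_y_um=scale_y_um,
    )


def write_image(image: BScanImage, path: str | Path, bit_depth: int = 8) -> None:
    """Write normalised intensities back out as an 8- or 16-bit grey raster."""
    path = Path(path)
    if bit_depth == 8:
        arr = np.round(image.pixels * 255).astype(np.uint8)
    elif bit_depth == 16:
        arr = np.round(image.pixels * 65535).astype(np.uint16)
    else:
        raise ValueError("bit_depth must be 8 or 16")
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(str(path), arr)
    else:
        iio.imwrite(str(path), arr)


def read_mask(path: str | Path, image: BScanImage, rater_id: str = "unknown",
              round_id: int = 1) -> AnnotationMask:
    """Read a binary mask; any nonzero pixel is foreground.

    Raises :class:`AlignmentError` if the raster shape differs from the
    image's — the signature of mis-paired files.
    """
    path = Path(path)
    arr = _collapse_grey(_load_raster(path), path)
    if arr.shape != image.shape:
        raise AlignmentError(
            f"{path}: mask shape {arr.shape} != image shape {image.shape}"
        )
    return AnnotationMask(
        image_id=image.image_id, rater_id=rater_id, round_id=round_id,
        mask=arr != 0,
    )


def write_mask(mask: AnnotationMask, path: str | Path) -> None:
    """Write a mask as single-channel PNG, 0 = background, 255 = foreground."""
    arr = np.where(mask.mask, 255, 0).astype(np.uint8)
    iio.imwrite(str(Path(path)), arr)


# --------------------------------------------------------------------------
# manifest IO
# --------------------------------------------------------------------------

_CSV_COLUMNS = [
    "image_id", "image_path", "scale_x_um", "scale_y_um",
    "rater_id", "tier", "round_id", "mask_path", "is_consensus",
]


def load_manifest(path: str | Path) -> StudyManifest:
    """Load a study manifest from canonical JSON or the flat-CSV dialect."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        return _manifest_from_csv(path)
    with open(path) as fh:
        doc = json.load(fh)
    try:
        images = [ImageRecord(**rec) for rec in doc["images"]]
        masks = [MaskRecord(**rec) for rec in doc["masks"]]
        tiers = dict(doc["rater_tiers"])
        consensus = list(doc["consensus_raters"])
    except (KeyError, TypeError) as exc:
        raise ManifestError(f"malformed manifest {path}: {exc}") from exc
    return StudyManifest(images, masks, tiers, consensus, root=path.parent)


def _manifest_from_csv(path: Path) -> StudyManifest:
    images: dict[str, ImageRecord] = {}
    masks: list[MaskRecord] = []
    tiers: dict[str, str] = {}
    consensus: list[str] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            iid = row["image_id"]
            if iid not in images:
                images[iid] = ImageRecord(
                    image_id=iid, path=row["image_path"],
                    scale_x_um=float(row["scale_x_um"]),
                    scale_y_um=float(row["scale_y_um"]),
                )
            masks.append(MaskRecord(
                image_id=iid, rater_id=row["rater_id"],
                round_id=int(row["round_id"]), path=row["mask_path"],
            ))
            tiers[row["rater_id"]] = row["tier"]
            truthy = str(row.get("is_consensus", "")).strip().lower()
            if truthy in ("1", "true", "yes") and row["rater_id"] not in consensus:
                consensus.append(row["rater_id"])
    return StudyManifest(list(images.values()), masks, tiers, consensus,
                         root=path.parent)


def save_manifest(manifest: StudyManifest, path: str | Path) -> None:
    path = Path(path)
    doc = {
        "images": [im.model_dump() for im in manifest.images],
        "masks": [mk.model_dump() for mk in manifest.masks],
        "rater_tiers": manifest.rater_tiers,
        "consensus_raters": manifest.consensus_raters,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")


# --------------------------------------------------------------------------
# result tables
# --------------------------------------------------------------------------


def _fmt(value: object) -> str:
    if isinstance(value, float):
        if value != value:  # NaN marks an undefined metric
            return ""
        return format(value, ".6g")
    return str(value)


def write_table(rows: Sequence[Mapping[str, object]], path: str | Path,
                columns: Iterable[str] | None = None) -> None:
    """Write records as CSV with stable column order and 6-significant-digit
    float formatting, so re-runs are byte-identical."""
    rows = list(rows)
    if columns is None:
        cols: list[str] = []
        for row in rows:
            for k in row:
                if k not in cols:
                    cols.append(k)
    else:
        cols = list(columns)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(cols)
        for row in rows:
            writer.writerow([_fmt(row.get(c, "")) for c in cols])
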