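"""Acquisition-metadata access for mammograms and reconstructed MRI models.

Mammography units write the per-exposure acquisition parameters into the
DICOM header of each image; the linear %-density model consumes eleven of
them.  Because the tags holding several of these values are vendor private
and differ between scanners, the name-to-tag mapping is configuration, not
code: :data:`DEFAULT_TAG_MAP` ships a GE Senographe-style dialect and every
entry can be overridden from a JSON file via :func:`load_tag_map`.

For synthetic fixtures a plain raster (``.npy``, PNG, TIFF) plus a JSON
sidecar carrying the same eleven fields is accepted everywhere a DICOM is.
Thicknesses are standardized to millimetres on read; a sidecar may declare
``"thickness_unit": "cm"`` and is converted (and logged) on ingestion.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

logger = logging.getLogger(__name__)

#: Allowed X-ray filter / anode target materials and their model coding.
MATERIALS = ("molybdenum", "rhodium")
MATERIAL_CODES = {"molybdenum": 1.0, "rhodium": 0.0}

CONTINUOUS_FIELDS = (
    "preexposure_dose",
    "preexposure_thickness",
    "radiation_dose",
    "preexposure_kvp",
    "anatomical_mean_intensity",
    "thresh",
    "final_exposure_thickness",
    "compression_force",
    "detector_sensitivity",
)
CATEGORICAL_FIELDS = ("filter_material", "anode_material")
#: The eleven acquisition parameters of the linear %-density model.
PARAMETER_FIELDS = CONTINUOUS_FIELDS + CATEGORICAL_FIELDS

#: Default pixel-area x thickness -> mL conversion factor.  This constant is
#: specific to the viewing geometry of the imager that produced the images
#: and absorbs all remaining unit conversion; override it per scanner.
DEFAULT_PIXEL_TO_ML_FACTOR = 9.96

#: Default name -> (group, element) DICOM tag dialect.  Standard tags are
#: used where DICOM defines one; the remainder live in a private group as
#: on the GE Senographe family.  Override any entry via a tag-map file.
DEFAULT_TAG_MAP: dict[str, tuple[int, int]] = {
    "preexposure_kvp": (0x0018, 0x0060),          # KVP
    "final_exposure_thickness": (0x0018, 0x11A0),  # BodyPartThickness (mm)
    "compression_force": (0x0018, 0x11A2),         # CompressionForce (N)
    "detector_sensitivity": (0x0018, 0x6000),      # Sensitivity
    "radiation_dose": (0x0018, 0x1405),            # RelativeXRayExposure
    "filter_material": (0x0018, 0x7050),           # FilterMaterial
    "anode_material": (0x0018, 0x1191),            # AnodeTargetMaterial
    "preexposure_dose": (0x0045, 0x1020),
    "preexposure_thickness": (0x0045, 0x1021),
    "anatomical_mean_intensity": (0x0045, 0x1022),
    "thresh": (0x0045, 0x1023),
    "raddose_pct_g": (0x0045, 0x1024),             # optional
}

_RASTER_SUFFIXES = {".npy", ".png", ".tif", ".tiff"}
_DICOM_SUFFIXES = {".dcm", ".dicom"}


@dataclass(frozen=True)
class ImagingParameters:
    """The eleven mammographic acquisition parameters of the %-G model.

    Continuous fields are raw header values in the unit the scanner records
    (thicknesses in mm, compression force in N, tube voltage in kV; dose,
    mean intensity, ``thresh`` and detector sensitivity are opaque
    detector-scale numbers passed through unchanged).  The filter and anode
    target materials are categorical and coded molybdenum=1, rhodium=0 when
    entering the linear model.
    """

    preexposure_dose: float
    preexposure_thickness: float
    radiation_dose: float
    preexposure_kvp: float
    anatomical_mean_intensity: float
    thresh: float
    final_exposure_thickness: float
    compression_force: float
    detector_sensitivity: float
    filter_material: str
    anode_material: str

    def __post_init__(self) -> None:
        for name in CONTINUOUS_FIELDS:
            v = getattr(self, name)
            if not isinstance(v, (int, float)) or not math.isfinite(v):
                raise ValueError(f"{name} must be a finite number, got {v!r}")
        for name in (
            "preexposure_thickness",
            "final_exposure_thickness",
            "compression_force",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in CATEGORICAL_FIELDS:
            v = getattr(self, name)
            if v not in MATERIALS:
                raise ValueError(
                    f"{name} must be one of {MATERIALS}, got {v!r}"
                )

    def coded(self) -> dict[str, float]:
        """All eleven fields as numbers, categoricals coded 1/0."""
        out = {name: float(getattr(self, name)) for name in CONTINUOUS_FIELDS}
        for name in CATEGORICAL_FIELDS:
            out[name] = MATERIAL_CODES[getattr(self, name)]
        return out

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class VoxelGeometry:
    """Reconstructed voxel geometry of a 3D breast model.

    ``reconstructed_voxel_size`` is the in-plane (x = y) voxel edge in mm;
    ``voxel_ratio`` is the z-to-x edge ratio.  The voxel volume is
    ``voxel_ratio * reconstructed_voxel_size ** 3`` in mm^3.
    """

    reconstructed_voxel_size: float
    voxel_ratio: float

    def __post_init__(self) -> None:
        if not (self.reconstructed_voxel_size > 0):
            raise ValueError(
                f"reconstructed_voxel_size must be > 0, "
                f"got {self.reconstructed_voxel_size!r}"
            )
        if not (self.voxel_ratio > 0):
            raise ValueError(f"voxel_ratio must be > 0, got {self.voxel_ratio!r}")

    @property
    def voxel_volume_mm3(self) -> float:
        return self.voxel_ratio * self.reconstructed_voxel_size**3


@dataclass
class MammogramRecord:
    """A 2D mammogram with its acquisition metadata.

    ``raddose_pct_g`` is the mammography unit's own percent-glandular
    estimate (the header's "Raddose" value); it is optional because not
    every dialect exposes it.
    """

    pixels: np.ndarray
    params: ImagingParameters
    pixel_to_ml_factor: float = DEFAULT_PIXEL_TO_ML_FACTOR
    raddose_pct_g: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2D array")
        if self.pixels.size and self.pixels.min() < 0:
            raise ValueError("pixel intensities must be non-negative")
        if not (self.pixel_to_ml_factor > 0):
            raise ValueError("pixel_to_ml_factor must be > 0")
        if self.raddose_pct_g is not None and not (
            0.0 <= self.raddose_pct_g <= 100.0
        ):
            raise ValueError("raddose_pct_g must lie in [0, 100]")


def load_tag_map(path: str | Path) -> dict[str, tuple[int, int]]:
    """Read a tag-map JSON (name -> "GGGG,EEEE" hex string) over the defaults."""
    with open(path) as fh:
        raw = json.load(fh)
    tag_map = dict(DEFAULT_TAG_MAP)
    for name, spec in raw.items():
        if isinstance(spec, str):
            group, element = (int(part, 16) for part in spec.split(","))
        else:
            group, element = int(spec[0]), int(spec[1])
        tag_map[name] = (group, element)
    return tag_map


def _material_from_header(value: object, field: str) -> str:
    text = str(value).strip().lower()
    aliases = {
        "molybdenum": "molybdenum",
        "mo": "molybdenum",
        "rhodium": "rhodium",
        "rh": "rhodium",
    }
    if text not in aliases:
        raise ValueError(f"unrecognized {field} value {value!r}")
    return aliases[text]


def _params_from_mapping(meta: Mapping, source: str) -> ImagingParameters:
    thickness_scale = 1.0
    unit = str(meta.get("thickness_unit", "mm")).lower()
    if unit == "cm":
        thickness_scale = 10.0
        logger.info("converting thicknesses from cm to mm for %s", source)
    elif unit != "mm":
        raise ValueError(f"unsupported thickness_unit {unit!r} in {source}")

    values: dict[str, object] = {}
    for name in PARAMETER_FIELDS:
        if name not in meta:
            raise KeyError(
                f"missing required metadata field '{name}' in {source}"
            )
        values[name] = meta[name]
    for name in CONTINUOUS_FIELDS:
        values[name] = float(values[name])  # type: ignore[arg-type]
    for name in ("preexposure_thickness", "final_exposure_thickness"):
        values[name] = values[name] * thickness_scale  # type: ignore[operator]
    for name in CATEGORICAL_FIELDS:
        values[name] = _material_from_header(values[name], name)
    return ImagingParameters(**values)  # type: ignore[arg-type]


def _read_raster(path: Path) -> np.ndarray:
    if path.suffix == ".npy":
        return np.load(path)
    import imageio.v3 as iio

    return np.asarray(iio.imread(path))


def sidecar_path(image_path: str | Path) -> Path:
    """JSON sidecar convention: same stem, ``.json`` suffix."""
    return Path(image_path).with_suffix(".json")


def read_mammogram(
    path: str | Path,
    tag_map: Mapping[str, tuple[int, int]] | None = None,
) -> MammogramRecord:
    """Read a mammogram (DICOM, or raster + JSON sidecar) into a record.

    Parameters
    ----------
    path
        A ``.dcm``/``.dicom`` file, or a raster image whose metadata lives
        in a JSON sidecar next to it (same stem, ``.json``).
    tag_map
        Name -> (group, element) overrides for the DICOM dialect; merged
        over :data:`DEFAULT_TAG_MAP`.

    Raises
    ------
    KeyError
        A required acquisition field is absent; the message names it.
    ValueError
        Pixel data cannot be decoded, or a field fails validation.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in _DICOM_SUFFIXES:
        return _read_dicom_mammogram(path, tag_map)

    meta_path = sidecar_path(path)
    if not meta_path.exists():
        raise FileNotFoundError(
            f"metadata sidecar {meta_path} not found for raster {path}"
        )
    with open(meta_path) as fh:
        meta = json.load(fh)
    params = _params_from_mapping(meta, str(meta_path))
    raddose = meta.get("raddose_pct_g")
    return MammogramRecord(
        pixels=_read_raster(path),
        params=params,
        pixel_to_ml_factor=float(
            meta.get("pixel_to_ml_factor", DEFAULT_PIXEL_TO_ML_FACTOR)
        ),
        raddose_pct_g=None if raddose is None else float(raddose),
    )


def _read_dicom_mammogram(
    path: Path, tag_map: Mapping[str, tuple[int, int]] | None
) -> MammogramRecord:
    import pydicom

    tags = dict(DEFAULT_TAG_MAP)
    if tag_map:
        tags.update(tag_map)
    ds = pydicom.dcmread(path, force=True)

    meta: dict[str, object] = {}
    for name in PARAMETER_FIELDS:
        group, element = tags[name]
        if (group, element) not in ds:
            raise KeyError(
                f"missing required DICOM tag ({group:04X},{element:04X}) "
                f"for '{name}' in {path}"
            )
        meta[name] = ds[(group, element)].value
    params = _params_from_mapping(meta, str(path))

    raddose = None
    rd_tag = tags.get("raddose_pct_g")
    if rd_tag is not None and rd_tag in ds:
        raddose = float(ds[rd_tag].value)

    try:
        pixels = np.asarray(ds.pixel_array)
    except Exception as exc:  # pydicom raises several types here
        raise ValueError(f"unparseable pixel data in {path}: {exc}") from exc
    return MammogramRecord(pixels=pixels, params=params, raddose_pct_g=raddose)


def write_mammogram_fixture(
    record: MammogramRecord, out_stem: str | Path
) -> tuple[Path, Path]:
    """Write ``<stem>.npy`` + ``<stem>.json`` so the record round-trips.

    Every metadata field is reproduced bit-exactly by
    :func:`read_mammogram` on the written pair.
    """
    out_stem = Path(out_stem)
    image_path = out_stem.with_suffix(".npy")
    meta_path = out_stem.with_suffix(".json")
    np.save(image_path, record.pixels)
    meta = record.params.to_dict()
    meta["pixel_to_ml_factor"] = record.pixel_to_ml_factor
    if record.raddose_pct_g is not None:
        meta["raddose_pct_g"] = record.raddose_pct_g
    with open(meta_path, "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return image_path, meta_path


def read_mri_geometry(path: str | Path) -> VoxelGeometry:
    """Read reconstructed voxel geometry from a JSON sidecar or DICOM header.

    A JSON sidecar carries ``reconstructed_voxel_size_mm`` and
    ``voxel_ratio`` directly; from a DICOM header the in-plane size is
    ``PixelSpacing[0]`` and the ratio is ``SpacingBetweenSlices`` (or
    ``SliceThickness``) divided by it.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in _DICOM_SUFFIXES:
        import pydicom

        ds = pydicom.dcmread(path, force=True)
        size = float(ds.PixelSpacing[0])
        z = float(getattr(ds, "SpacingBetweenSlices", 0) or ds.SliceThickness)
        if size <= 0:
            raise ValueError(f"non-positive voxel size in {path}")
        return VoxelGeometry(reconstructed_voxel_size=size, voxel_ratio=z / size)
    with open(path) as fh:
        meta = json.load(fh)
    return VoxelGeometry(
        reconstructed_voxel_size=float(meta["reconstructed_voxel_size_mm"]),
        voxel_ratio=float(meta["voxel_ratio"]),
    )
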