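"""Ground-truth phantom and table generators for every pathway.

These generators emulate the statistical structure the estimation methods
assume — two intensity compartments inside a breast-shaped region, and
per-subject measures that are highly correlated across methods with
method-level offsets — with known, exact ground truth:

* class membership is assigned by exact count (not Bernoulli draws), so a
  planted gland fraction of 0.40 in a 10,000-pixel region means exactly
  4,000 gland pixels;
* every generator is a pure function of its seed and spec, so fixtures
  are byte-identical across runs.

Intensity noise is Gaussian per class.  That is a simplification: real
mammograms carry structured texture and scanner processing, and MRI
magnitude noise is Rician, so recovery results on these phantoms bound
algorithmic error only, not real-data error.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dicom_meta import ImagingParameters, MammogramRecord, VoxelGeometry
from .math_density import MathCoefficients
from .mri_density import MriVolume
from .types import METHODS

logger = logging.getLogger(__name__)

#: Default per-outcome means and SDs for measure tables (mL or percent);
#: chosen to resemble premenopausal screening populations: total breast
#: volume ~800 mL, about a third of it glandular.
OUTCOME_SCALES = {
    "pct_g": (35.0, 8.0),
    "gv_ml": (250.0, 60.0),
    "fv_ml": (550.0, 120.0),
    "tv_ml": (800.0, 150.0),
}


#: Total breast volume emulated by mammogram phantoms (mL).  The phantom's
#: pixel-to-mL factor is derived from this so the synthetic imager has a
#: self-consistent viewing geometry and realistic volumes.
MAMMO_TARGET_TV_ML = 800.0


@dataclass(frozen=True)
class PhantomSpec:
    """Specification of a two-compartment phantom.

    ``shape`` is (rows, cols) for mammograms or (z, y, x) for MRI volumes.
    Class means/SDs are raw signal units; ``None`` means use the context
    default (gland bright on raw mammograms; protocol-dependent for MRI).
    The seed is mandatory: all generation is reproducible.
    """

    shape: tuple[int, ...] = (256, 256)
    gland_fraction: float = 0.40
    gland_mean: float | None = None
    gland_sd: float = 40.0
    fat_mean: float | None = None
    fat_sd: float = 40.0
    compression_thickness: float = 52.0
    geometry: VoxelGeometry = field(
        default_factory=lambda: VoxelGeometry(1.0, 1.0)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.gland_fraction <= 1.0:
            raise ValueError("gland_fraction must lie in [0, 1]")
        if self.gland_sd < 0 or self.fat_sd < 0:
            raise ValueError("class SDs must be non-negative")
        if (
            self.gland_mean is not None
            and self.fat_mean is not None
            and self.gland_mean == self.fat_mean
        ):
            raise ValueError("class means must be distinct")
        if not (self.compression_thickness > 0):
            raise ValueError("compression_thickness must be > 0")
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("seed is mandatory and must be an integer")


def _ellipse_mask(shape: tuple[int, int]) -> np.ndarray:
    ny, nx = shape
    y, x = np.ogrid[:ny, :nx]
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    ry, rx = 0.42 * ny, 0.42 * nx
    return ((y - cy) / ry) ** 2 + ((x - cx) / rx) ** 2 <= 1.0


def _ellipsoid_mask(shape: tuple[int, int, int]) -> np.ndarray:
    nz, ny, nx = shape
    z, y, x = np.ogrid[:nz, :ny, :nx]
    cz, cy, cx = (nz - 1) / 2.0, (ny - 1) / 2.0, (nx - 1) / 2.0
    rz, ry, rx = 0.45 * nz, 0.45 * ny, 0.45 * nx
    return (
        ((z - cz) / rz) ** 2 + ((y - cy) / ry) ** 2 + ((x - cx) / rx) ** 2
        <= 1.0
    )


def _exact_count_labels(
    n: int, fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, float]:
    """Boolean gland labels with the planted fraction exact at unit
    resolution; returns (labels, achieved fraction)."""
    n_gland = int(round(fraction * n))
    achieved = n_gland / n
    if not math.isclose(achieved, fraction, abs_tol=1e-12):
        logger.info(
            "requested fraction %.6f not achievable with %d units; "
            "using nearest %.6f",
            fraction,
            n,
            achieved,
        )
    labels = np.zeros(n, dtype=bool)
    labels[:n_gland] = True
    rng.shuffle(labels)
    return labels, achieved


def _plausible_parameters(
    fraction: float, thickness: float, rng: np.random.Generator
) -> ImagingParameters:
    """Acquisition parameters whose linear-model %-G tracks the planted
    fraction.

    All raw header values are drawn near realistic screening settings;
    the anatomical mean intensity is then solved from the default model
    coefficients so that the linear score equals 100*fraction (plus small
    noise), making the MATH pathway a faithful emulation of a unit whose
    exposure settings encode the breast's density.
    """
    c = MathCoefficients()
    base = {
        "preexposure_dose": 5000.0 + rng.normal(0.0, 150.0),
        "preexposure_thickness": thickness,
        "radiation_dose": 100.0 + rng.normal(0.0, 5.0),
        "preexposure_kvp": float(rng.choice([26.0, 27.0, 28.0, 29.0])),
        "thresh": 1500.0 + rng.normal(0.0, 50.0),
        "final_exposure_thickness": thickness * 0.97,
        "compression_force": 120.0 + rng.normal(0.0, 10.0),
        "detector_sensitivity": 0.01,
        "filter_material": "molybdenum",
        "anode_material": "molybdenum",
    }
    score_without_ami = c.intercept + sum(
        getattr(c, name)
        * (1.0 if isinstance(v, str) and v == "molybdenum" else 0.0 if isinstance(v, str) else v)
        for name, v in base.items()
    )
    target = 100.0 * fraction + rng.normal(0.0, 0.5)
    ami = (score_without_ami - target) / (-c.anatomical_mean_intensity)
    return ImagingParameters(anatomical_mean_intensity=float(ami), **base)


def make_mammogram_phantom(
    spec: PhantomSpec,
) -> tuple[MammogramRecord, float, np.ndarray]:
    """Two-class elliptical mammogram phantom on a zero background.

    Returns ``(record, truth_fraction, mask)`` where ``truth_fraction`` is
    the achieved (exact-count) gland pixel fraction and ``mask`` the
    ground-truth breast region.  The record's metadata sidecar fields are
    filled with plausible acquisition parameters (see
    :func:`_plausible_parameters`) and a Raddose estimate near the truth.
    """
    if len(spec.shape) != 2:
        raise ValueError("mammogram phantom needs a 2D shape")
    rng = np.random.default_rng(spec.seed)
    gland_mean = 800.0 if spec.gland_mean is None else spec.gland_mean
    fat_mean = 400.0 if spec.fat_mean is None else spec.fat_mean
    if gland_mean == fat_mean:
        raise ValueError("class means must be distinct")

    mask = _ellipse_mask(spec.shape)  # type: ignore[arg-type]
    n = int(mask.sum())
    labels, achieved = _exact_count_labels(n, spec.gland_fraction, rng)

    intensities = np.where(
        labels,
        gland_mean + spec.gland_sd * rng.standard_normal(n),
        fat_mean + spec.fat_sd * rng.standard_normal(n),
    )
    # keep the ROI strictly above the zero background
    intensities = np.maximum(intensities, 1.0)
    pixels = np.zeros(spec.shape, dtype=float)
    pixels[mask] = intensities

    params = _plausible_parameters(achieved, spec.compression_thickness, rng)
    raddose = float(np.clip(100.0 * achieved + rng.normal(0.0, 1.5), 0.0, 100.0))
    # calibrate the synthetic imager's geometry so the phantom breast has a
    # realistic total volume (area x thickness x factor = target mL)
    factor = MAMMO_TARGET_TV_ML / (n * spec.compression_thickness)
    record = MammogramRecord(
        pixels=pixels,
        params=params,
        pixel_to_ml_factor=factor,
        raddose_pct_g=raddose,
    )
    return record, achieved, mask


def make_mri_phantom(
    spec: PhantomSpec, protocol: str = "3DGRE"
) -> tuple[MriVolume, dict]:
    """Two-class ellipsoidal MRI phantom with protocol-correct polarity.

    Under 3DGRE fat is bright (gland mean < fat mean); under STIR fat is
    suppressed (gland mean > fat mean).  Returns ``(volume, truth)`` where
    ``truth`` holds the achieved gland fraction, the per-voxel gland
    labels, and the ground-truth volumes in mL.
    """
    if len(spec.shape) != 3:
        raise ValueError("MRI phantom needs a 3D shape")
    if protocol not in ("3DGRE", "STIR"):
        raise ValueError("protocol must be '3DGRE' or 'STIR'")
    rng = np.random.default_rng(spec.seed)
    if protocol == "3DGRE":
        gland_mean = 400.0 if spec.gland_mean is None else spec.gland_mean
        fat_mean = 1000.0 if spec.fat_mean is None else spec.fat_mean
    else:
        gland_mean = 900.0 if spec.gland_mean is None else spec.gland_mean
        fat_mean = 200.0 if spec.fat_mean is None else spec.fat_mean
    if gland_mean == fat_mean:
        raise ValueError("class means must be distinct")

    mask = _ellipsoid_mask(spec.shape)  # type: ignore[arg-type]
    n = int(mask.sum())
    labels, achieved = _exact_count_labels(n, spec.gland_fraction, rng)

    intensities = np.where(
        labels,
        gland_mean + spec.gland_sd * rng.standard_normal(n),
        fat_mean + spec.fat_sd * rng.standard_normal(n),
    )
    voxels = np.zeros(spec.shape, dtype=float)
    voxels[mask] = intensities

    label_volume = np.zeros(spec.shape, dtype=bool)
    label_volume[mask] = labels
    tv_ml = n * spec.geometry.voxel_volume_mm3 / 1000.0
    truth = {
        "fraction_gland": achieved,
        "gland_labels": label_volume,
        "tv_ml": tv_ml,
        "gv_ml": tv_ml * achieved,
        "fv_ml": tv_ml * (1.0 - achieved),
    }
    vol = MriVolume(
        voxels=voxels, breast_mask=mask, geometry=spec.geometry,
        protocol=protocol,
    )
    return vol, truth


def make_measure_table(
    n_subjects: int,
    inter_method_rho: float,
    offsets: dict[str, float] | None = None,
    seed: int = 0,
    methods: tuple[str, ...] = METHODS,
) -> pd.DataFrame:
    """Multi-method measure table with known cross-method correlation.

    For each outcome the method columns are drawn from a multivariate
    normal with equicorrelation ``inter_method_rho`` and per-method mean
    offsets (``offsets`` maps method name to a shift added to all of that
    method's columns).  Returns a wide table with a (method, outcome)
    column MultiIndex, as consumed by :mod:`breastdensity.concordance`.
    """
    if not 0.0 <= inter_method_rho <= 1.0:
        raise ValueError("inter_method_rho must lie in [0, 1]")
    if n_subjects < 1:
        raise ValueError("n_subjects must be positive")
    offsets = offsets or {}
    unknown = set(offsets) - set(methods)
    if unknown:
        raise ValueError(f"offsets given for unknown methods: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    m = len(methods)

    data: dict[tuple[str, str], np.ndarray] = {}
    for outcome, (mean, sd) in OUTCOME_SCALES.items():
        if inter_method_rho == 1.0:
            z = rng.standard_normal(n_subjects)
            draws = np.tile(z[:, None], (1, m))
        else:
            cov = np.full((m, m), inter_method_rho)
            np.fill_diagonal(cov, 1.0)
            try:
                chol = np.linalg.cholesky(cov)
            except np.linalg.LinAlgError as exc:
                raise ValueError(
                    "implied cross-method covariance is not positive "
                    "semidefinite"
                ) from exc
            draws = rng.standard_normal((n_subjects, m)) @ chol.T
        for j, method in enumerate(methods):
            data[(method, outcome)] = (
                mean + offsets.get(method, 0.0) + sd * draws[:, j]
            )

    index = pd.Index(
        [f"S{i:04d}" for i in range(1, n_subjects + 1)], name="subject_id"
    )
    table = pd.DataFrame(data, index=index)
    table.columns.names = ["method", "outcome"]
    return table.sort_index(axis=1)
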