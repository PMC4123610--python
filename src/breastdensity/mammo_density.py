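"""Histogram-segmentation (HSM) pathway for 2D mammograms.

The breast region of interest is isolated from the background and chest
wall, an intensity threshold splits its pixels into glandular (dense) and
fat classes, and the resulting areas are lifted to volumes with the
compression thickness and a geometry-dependent mL conversion factor:

    %-G = G_AREA / (G_AREA + F_AREA)
    GV  = factor * G_AREA * thickness
    FV  = factor * F_AREA * thickness
    TV  = GV + FV

The historical workflow selected the threshold interactively from the
histogram; here the selection is programmatic — Otsu's between-class
variance criterion by default, or a fixed value.

Polarity convention: on raw (unprocessed) mammograms dense tissue is the
brighter class, so glandular means intensity >= threshold.  Pixels exactly
at the threshold count as glandular (closed lower bound on the gland
class).  Dialects with inverted polarity are handled with
``glandular_bright=False``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .dicom_meta import MammogramRecord
from .types import BreastComposition

logger = logging.getLogger(__name__)

#: Bin count used when histogramming floating-point images.
FLOAT_HISTOGRAM_BINS = 256


@dataclass(frozen=True)
class SegmentationResult:
    """Threshold and pixel areas from segmenting one mammogram."""

    threshold: float
    g_area_px: int
    f_area_px: int
    t_area_px: int
    breast_mask: np.ndarray

    def __post_init__(self) -> None:
        if min(self.g_area_px, self.f_area_px, self.t_area_px) < 0:
            raise ValueError("pixel areas must be non-negative")
        if self.g_area_px + self.f_area_px != self.t_area_px:
            raise ValueError(
                "t_area_px must equal g_area_px + f_area_px "
                f"({self.g_area_px} + {self.f_area_px} != {self.t_area_px})"
            )

    @property
    def pct_g(self) -> float:
        return 100.0 * self.g_area_px / self.t_area_px


def isolate_breast_roi(
    pixels: np.ndarray,
    background_level: float,
    chest_wall_margin: int = 0,
    chest_side: str = "left",
) -> np.ndarray:
    """Mask the breast: largest connected component above background.

    Parameters
    ----------
    pixels
        2D intensity image.
    background_level
        Pixels at or below this raw intensity are background.
    chest_wall_margin
        Number of image columns on ``chest_side`` excluded before the
        component search, to drop chest wall and pectoral muscle.
    chest_side
        ``"left"`` or ``"right"``.

    Returns
    -------
    2D boolean mask of the retained breast region.

    Raises
    ------
    ValueError
        Empty image, or no foreground component found.
    """
    arr = np.asarray(pixels)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError("pixels must be a non-empty 2D array")
    if chest_side not in ("left", "right"):
        raise ValueError("chest_side must be 'left' or 'right'")
    fg = arr > background_level
    if chest_wall_margin > 0:
        if chest_side == "left":
            fg[:, :chest_wall_margin] = False
        else:
            fg[:, arr.shape[1] - chest_wall_margin:] = False
    labels, n_components = ndimage.label(fg)
    if n_components == 0:
        raise ValueError("no breast region found above background level")
    sizes = ndimage.sum_labels(fg, labels, index=np.arange(1, n_components + 1))
    keep = int(np.argmax(sizes)) + 1
    if n_components > 1:
        logger.info(
            "retained largest of %d foreground components (%d px)",
            n_components,
            int(sizes.max()),
        )
    return labels == keep


def image_histogram(
    pixels: np.ndarray, mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Intensity histogram of the masked pixels as (values, counts).

    Integer images use native integer bins (exact value counts); float
    images use :data:`FLOAT_HISTOGRAM_BINS` uniform bins with bin centers
    as representative values.
    """
    arr = np.asarray(pixels)
    vals = arr[np.asarray(mask, dtype=bool)]
    if vals.size == 0:
        raise ValueError("mask selects no pixels")
    if np.issubdtype(vals.dtype, np.integer):
        values, counts = np.unique(vals, return_counts=True)
        return values.astype(float), counts.astype(np.int64)
    lo, hi = float(vals.min()), float(vals.max())
    if lo == hi:
        return np.array([lo]), np.array([vals.size], dtype=np.int64)
    counts, edges = np.histogram(vals, bins=FLOAT_HISTOGRAM_BINS, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    keep = counts > 0
    return centers[keep], counts[keep].astype(np.int64)


def _as_value_count_arrays(
    histogram: Mapping[float, int] | tuple[Sequence[float], Sequence[int]],
) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(histogram, Mapping):
        values = np.asarray(sorted(histogram), dtype=float)
        counts = np.asarray([histogram[v] for v in values], dtype=float)
    else:
        values = np.asarray(histogram[0], dtype=float)
        counts = np.asarray(histogram[1], dtype=float)
        order = np.argsort(values)
        values, counts = values[order], counts[order]
    keep = counts > 0
    return values[keep], counts[keep]


def otsu_threshold(
    values: np.ndarray | Sequence[float], counts: np.ndarray | Sequence[int]
) -> float:
    """Otsu's threshold on a (values, counts) histogram.

    Evaluates the between-class variance ``w0*w1*(mu0-mu1)^2`` at every cut
    that places intensities ``< t`` in the lower class and ``>= t`` in the
    upper class, and returns the lowest maximizing cut value.  The result
    is one of the observed intensity values, strictly above the minimum.
    """
    values = np.asarray(values, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if values.size < 2:
        raise ValueError(
            "histogram has a single intensity value; no separable classes"
        )
    total = counts.sum()
    # cumulative mass / weighted mean below each candidate cut values[1:]
    w0 = np.cumsum(counts)[:-1] / total
    w1 = 1.0 - w0
    cum_mean = np.cumsum(counts * values)[:-1] / total
    grand_mean = float((counts * values).sum() / total)
    mu0 = cum_mean / w0
    mu1 = (grand_mean - cum_mean) / w1
    between = w0 * w1 * (mu0 - mu1) ** 2
    return float(values[1:][int(np.argmax(between))])


def select_threshold(
    histogram: Mapping[float, int] | tuple[Sequence[float], Sequence[int]],
    strategy: str | tuple[str, float] = "otsu",
) -> float:
    """Select a segmentation threshold from a breast-ROI histogram.

    ``strategy`` is ``"otsu"`` (default), ``"fixed:<value>"``, or the tuple
    ``("fixed", value)``; a fixed value is returned verbatim.
    """
    values, counts = _as_value_count_arrays(histogram)
    if values.size == 0:
        raise ValueError("histogram is empty")
    if isinstance(strategy, tuple):
        name, value = strategy
        if name != "fixed":
            raise ValueError(f"unknown threshold strategy {strategy!r}")
        return float(value)
    if strategy.startswith("fixed:"):
        return float(strategy.split(":", 1)[1])
    if strategy == "otsu":
        return otsu_threshold(values, counts)
    raise ValueError(f"unknown threshold strategy {strategy!r}")


def segment_areas(
    pixels: np.ndarray,
    mask: np.ndarray,
    threshold: float,
    glandular_bright: bool = True,
) -> SegmentationResult:
    """Split masked pixels into glandular and fat areas at ``threshold``.

    Glandular is the bright class (``>= threshold``) on raw mammograms;
    pixels exactly equal to the threshold are glandular.
    """
    arr = np.asarray(pixels)
    mask = np.asarray(mask, dtype=bool)
    if arr.shape != mask.shape:
        raise ValueError("pixels and mask shapes differ")
    if glandular_bright:
        gland = mask & (arr >= threshold)
    else:
        gland = mask & (arr <= threshold)
    g = int(gland.sum())
    t = int(mask.sum())
    return SegmentationResult(
        threshold=float(threshold),
        g_area_px=g,
        f_area_px=t - g,
        t_area_px=t,
        breast_mask=mask,
    )


def areas_to_composition(
    seg: SegmentationResult,
    preexposure_thickness: float,
    factor: float = 9.96,
    method: str = "HSM",
) -> BreastComposition:
    """Lift segmented areas to volumes (mL).

    ``gv = factor * g_area * thickness`` and likewise for fat; the total is
    their sum, and %-G is the glandular area fraction.  ``factor`` is the
    imager-geometry pixel-area-to-mL constant (default 9.96) and absorbs
    all unit conversion; ``preexposure_thickness`` is the compression
    thickness in mm recorded before the exposure.
    """
    if not (preexposure_thickness > 0):
        raise ValueError("preexposure_thickness must be > 0")
    if not (factor > 0):
        raise ValueError("factor must be > 0")
    if seg.t_area_px == 0:
        raise ValueError("segmentation contains no breast pixels")
    gv = factor * seg.g_area_px * preexposure_thickness
    fv = factor * seg.f_area_px * preexposure_thickness
    return BreastComposition(
        method=method,
        pct_g=100.0 * seg.g_area_px / seg.t_area_px,
        gv_ml=gv,
        fv_ml=fv,
        tv_ml=gv + fv,
    )


def hsm_composition(
    record: MammogramRecord,
    background_level: float = 0.0,
    threshold_strategy: str | tuple[str, float] = "otsu",
    chest_wall_margin: int = 0,
    glandular_bright: bool = True,
) -> tuple[BreastComposition, SegmentationResult]:
    """Full HSM pipeline: ROI -> histogram -> threshold -> areas -> volumes."""
    mask = isolate_breast_roi(
        record.pixels, background_level, chest_wall_margin=chest_wall_margin
    )
    hist = image_histogram(record.pixels, mask)
    threshold = select_threshold(hist, threshold_strategy)
    seg = segment_areas(
        record.pixels, mask, threshold, glandular_bright=glandular_bright
    )
    comp = areas_to_composition(
        seg,
        preexposure_thickness=record.params.preexposure_thickness,
        factor=record.pixel_to_ml_factor,
    )
    return comp, seg
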