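"""MRI pathway: two-Gaussian decomposition of a breast voxel histogram.

A segmented 3D breast model is reduced to a histogram of voxel signal
intensities and, under the assumption that the breast contains exactly two
compartments (adipose and fibroglandular tissue), the histogram is fitted
with a sum of two Gaussian peaks by nonlinear least squares:

    y(x) = A1 * exp(-(x - mu1)^2 / (2 s1^2)) + A2 * exp(-(x - mu2)^2 / (2 s2^2))

The glandular fraction is the analytic area of the gland peak,
``A * sigma * sqrt(2 pi)``, over the total peak area.  Which peak is gland
depends on the pulse sequence: without fat suppression (3DGRE) fat is
bright, so gland is the lower-mean peak; with fat suppression (STIR) fat
is dark, so gland is the higher-mean peak.

Volumes come from voxel counting: ``TV = n_masked_voxels * voxel_volume``
with voxel volume = voxel_ratio * (reconstructed voxel size)^3 in mm^3,
then ``GV = TV * fraction_gland`` and ``FV = TV - GV``.

The fit targets the binned histogram (peak/curve fitting), not per-voxel
EM: it is deterministic for fixed bins and mirrors how such histograms are
analysed with peak-fitting software.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .dicom_meta import VoxelGeometry
from .types import BreastComposition

logger = logging.getLogger(__name__)

PROTOCOLS = ("3DGRE", "STIR")
DEFAULT_N_BINS = 256
MAX_RESTARTS = 5
#: Component-area share below which a two-peak fit is flagged degenerate.
DEGENERATE_AREA_SHARE = 0.01

SQRT_2PI = math.sqrt(2.0 * math.pi)


@dataclass
class MriVolume:
    """A 3D breast MRI model: voxels, breast mask, geometry, protocol."""

    voxels: np.ndarray
    breast_mask: np.ndarray
    geometry: VoxelGeometry
    protocol: str

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        self.breast_mask = np.asarray(self.breast_mask, dtype=bool)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D array")
        if self.breast_mask.shape != self.voxels.shape:
            raise ValueError("breast_mask shape must match voxels")
        if not self.breast_mask.any():
            raise ValueError("breast_mask is empty")
        if self.protocol not in PROTOCOLS:
            raise ValueError(f"protocol must be one of {PROTOCOLS}")


@dataclass(frozen=True)
class GaussianComponent:
    """One fitted peak: amplitude, mean and width on the intensity axis."""

    amplitude: float
    mean: float
    sigma: float

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if not (self.sigma > 0):
            raise ValueError("sigma must be > 0")

    @property
    def area(self) -> float:
        """Analytic area under the peak, ``A * sigma * sqrt(2*pi)``."""
        return self.amplitude * self.sigma * SQRT_2PI


@dataclass(frozen=True)
class MixtureFit:
    """Two-Gaussian fit to a voxel-intensity histogram.

    ``adipose`` and ``gland`` are the labeled peaks (labeling follows the
    pulse-sequence polarity; see :func:`assign_gland_component`), ``rss``
    the residual sum of squares against the bin counts, ``converged`` the
    honest optimizer status, and ``degenerate`` whether one peak carries a
    negligible share of the total area (effectively a one-compartment
    histogram).
    """

    adipose: GaussianComponent
    gland: GaussianComponent
    rss: float
    converged: bool
    degenerate: bool = False

    @property
    def fraction_gland(self) -> float:
        total = self.adipose.area + self.gland.area
        if total == 0:
            return 0.0
        return self.gland.area / total

    def summary(self) -> str:
        lines = [
            "Two-Gaussian histogram fit",
            "==========================",
            f"{'component':<10}{'amplitude':>12}{'mean':>12}{'sigma':>12}{'area':>14}",
        ]
        for name in ("adipose", "gland"):
            c: GaussianComponent = getattr(self, name)
            lines.append(
                f"{name:<10}{c.amplitude:>12.4g}{c.mean:>12.4g}"
                f"{c.sigma:>12.4g}{c.area:>14.6g}"
            )
        lines += [
            f"fraction_gland = {self.fraction_gland:.6f}",
            f"rss = {self.rss:.6g}   converged = {self.converged}"
            + ("   DEGENERATE" if self.degenerate else ""),
        ]
        return "\n".join(lines)


def build_histogram(
    vol: MriVolume, n_bins: int = DEFAULT_N_BINS
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of masked voxel intensities as (bin centers, counts).

    Counts sum to the number of masked voxels and the bin edges span the
    masked intensity range exactly.
    """
    vals = np.asarray(vol.voxels)[vol.breast_mask].astype(float)
    if vals.size == 0:
        raise ValueError("breast mask selects no voxels")
    lo, hi = float(vals.min()), float(vals.max())
    if lo == hi:
        return np.array([lo]), np.array([vals.size], dtype=np.int64)
    counts, edges = np.histogram(vals, bins=n_bins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, counts.astype(np.int64)


def two_gaussian_curve(x: np.ndarray, p: Sequence[float]) -> np.ndarray:
    """Evaluate the two-peak model; ``p = (A1, mu1, s1, A2, mu2, s2)``."""
    a1, m1, s1, a2, m2, s2 = p
    x = np.asarray(x, dtype=float)
    return a1 * np.exp(-0.5 * ((x - m1) / s1) ** 2) + a2 * np.exp(
        -0.5 * ((x - m2) / s2) ** 2
    )


def _auto_init(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Means at the weighted 25th/75th percentiles, sigma = range/8."""
    order = np.argsort(x)
    x, y = x[order], y[order]
    cdf = np.cumsum(y) / y.sum()
    m1 = float(np.interp(0.25, cdf, x))
    m2 = float(np.interp(0.75, cdf, x))
    span = float(x.max() - x.min())
    sigma = max(span / 8.0, 1e-6 * max(span, 1.0))
    a1 = max(float(np.interp(m1, x, y)), 1e-12)
    a2 = max(float(np.interp(m2, x, y)), 1e-12)
    return np.array([a1, m1, sigma, a2, m2, sigma])


class TwoGaussianHistogramModel:
    """Two-compartment Gaussian model of a voxel-intensity histogram.

    A thin model/results wrapper: construct from histogram values and
    counts (and the pulse-sequence protocol, which fixes which peak is
    glandular), call :meth:`fit`, and read the labeled :class:`MixtureFit`.

    Examples
    --------
    >>> centers, counts = build_histogram(vol)        # doctest: +SKIP
    >>> fit = TwoGaussianHistogramModel(centers, counts, "STIR").fit(seed=0)
    ... # doctest: +SKIP
    >>> print(fit.summary())                          # doctest: +SKIP
    """

    def __init__(
        self,
        values: Sequence[float],
        counts: Sequence[float],
        protocol: str = "3DGRE",
    ) -> None:
        if protocol not in PROTOCOLS:
            raise ValueError(f"protocol must be one of {PROTOCOLS}")
        values = np.asarray(values, dtype=float)
        counts = np.asarray(counts, dtype=float)
        if values.shape != counts.shape or values.ndim != 1:
            raise ValueError("values and counts must be 1D and equal length")
        keep = counts >= 0
        if not keep.all():
            raise ValueError("counts must be non-negative")
        self.values = values
        self.counts = counts
        self.protocol = protocol

    def fit(
        self,
        init: str | Sequence[float] = "auto",
        seed: int = 0,
        max_restarts: int = MAX_RESTARTS,
    ) -> MixtureFit:
        """Bounded least-squares fit with seeded jittered restarts.

        ``init`` is ``"auto"`` (percentile-based start) or an explicit
        6-vector ``(A1, mu1, s1, A2, mu2, s2)``.  Non-convergence after the
        restart budget is reported honestly via ``converged=False``; it is
        never raised.
        """
        x, y = self.values, self.counts
        nonzero = int((y > 0).sum())
        if nonzero < 6:
            raise ValueError(
                f"histogram has {nonzero} nonzero bins; at least 6 needed "
                "for the 6-parameter two-Gaussian model"
            )
        span = float(x.max() - x.min())
        lo = np.array([0.0, x.min() - span, 1e-9 * max(span, 1.0),
                       0.0, x.min() - span, 1e-9 * max(span, 1.0)])
        hi = np.array([np.inf, x.max() + span, 4.0 * span,
                       np.inf, x.max() + span, 4.0 * span])

        if isinstance(init, str):
            if init != "auto":
                raise ValueError(f"unknown init {init!r}")
            p0 = _auto_init(x, y)
        else:
            p0 = np.asarray(init, dtype=float)
            if p0.shape != (6,):
                raise ValueError("explicit init must have 6 parameters")
        p0 = np.clip(p0, lo, hi)

        def residual(p: np.ndarray) -> np.ndarray:
            return two_gaussian_curve(x, p) - y

        rng = np.random.default_rng(seed)
        best = None
        start = p0
        for attempt in range(max_restarts + 1):
            res = least_squares(
                residual, start, bounds=(lo, hi),
                xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
            rss = float(np.sum(res.fun**2))
            if res.success and (best is None or rss < best[1]):
                best = (res.x, rss)
            # good-enough absolute fit: stop restarting
            if best is not None and best[1] <= 1e-12 * max(float((y**2).sum()), 1.0):
                break
            jitter = 1.0 + 0.2 * rng.standard_normal(6)
            start = np.clip(p0 * jitter, lo, hi)

        if best is None:
            # report the last attempt, flagged unconverged
            params, rss, converged = res.x, rss, False
        else:
            params, rss = best
            converged = True

        c1 = GaussianComponent(*(float(v) for v in params[:3]))
        c2 = GaussianComponent(*(float(v) for v in params[3:]))
        fit = _label_components(c1, c2, self.protocol, rss, converged)
        if fit.degenerate:
            warnings.warn(
                "two-Gaussian fit is degenerate: one component carries "
                f"{min(c1.area, c2.area):.3g} of {c1.area + c2.area:.3g} "
                "total area; histogram may contain a single compartment",
                RuntimeWarning,
                stacklevel=2,
            )
        return fit


def _label_components(
    c1: GaussianComponent,
    c2: GaussianComponent,
    protocol: str,
    rss: float,
    converged: bool,
) -> MixtureFit:
    low, high = sorted((c1, c2), key=lambda c: c.mean)
    if protocol == "3DGRE":  # fat bright -> gland is the dim (low-mean) peak
        gland, adipose = low, high
    else:  # STIR: fat suppressed -> gland is the bright (high-mean) peak
        gland, adipose = high, low
    total = c1.area + c2.area
    # degenerate: one peak carries negligible area, or the two peaks
    # coincide (a single compartment split arbitrarily between them)
    degenerate = (
        total > 0 and min(c1.area, c2.area) / total < DEGENERATE_AREA_SHARE
    ) or abs(c1.mean - c2.mean) < max(c1.sigma, c2.sigma)
    return MixtureFit(
        adipose=adipose, gland=gland, rss=rss,
        converged=converged, degenerate=degenerate,
    )


def fit_two_gaussians(
    histogram: tuple[Sequence[float], Sequence[float]],
    init: str | Sequence[float] = "auto",
    protocol: str = "3DGRE",
    seed: int = 0,
) -> MixtureFit:
    """Functional front end to :class:`TwoGaussianHistogramModel`."""
    values, counts = histogram
    return TwoGaussianHistogramModel(values, counts, protocol).fit(
        init=init, seed=seed
    )


def assign_gland_component(
    fit: MixtureFit, protocol: str, override_gland: str | None = None
) -> MixtureFit:
    """Re-label which peak is glandular for a given pulse sequence.

    Under 3DGRE (no fat suppression, fat bright) gland is the lower-mean
    peak; under STIR (fat suppressed) gland is the higher-mean peak.
    ``override_gland`` (``"low"`` or ``"high"``) forces the assignment and
    logs a warning.
    """
    if fit.adipose.mean == fit.gland.mean:
        raise ValueError("component means are equal; cannot assign gland peak")
    if override_gland is not None:
        if override_gland not in ("low", "high"):
            raise ValueError("override_gland must be 'low' or 'high'")
        logger.warning(
            "gland-component override %r supersedes the %s polarity rule",
            override_gland,
            protocol,
        )
        low, high = sorted(
            (fit.adipose, fit.gland), key=lambda c: c.mean
        )
        gland, adipose = (low, high) if override_gland == "low" else (high, low)
        return replace(fit, adipose=adipose, gland=gland)
    return _label_components(
        fit.adipose, fit.gland, protocol, fit.rss, fit.converged
    )


def mri_composition(vol: MriVolume, fit: MixtureFit) -> BreastComposition:
    """Convert voxel count and fitted gland fraction to volumes in mL."""
    if not fit.converged:
        raise ValueError("mixture fit did not converge; composition undefined")
    n = int(vol.breast_mask.sum())
    tv_ml = n * vol.geometry.voxel_volume_mm3 / 1000.0
    frac = fit.fraction_gland
    gv = tv_ml * frac
    return BreastComposition(
        method=vol.protocol,
        pct_g=100.0 * frac,
        gv_ml=gv,
        fv_ml=tv_ml - gv,
        tv_ml=tv_ml,
    )
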