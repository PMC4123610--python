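"""MATH pathway: %-glandular from acquisition parameters, plus FFDM passthrough.

The mammography unit manipulates its exposure settings per breast, and
those settings carry enough information to predict percent glandular
tissue directly.  The MATH model is a fixed linear combination of the
eleven recorded acquisition parameters:

    %-G = 481.33 - 0.0057*preexposure_dose + 1.2305*preexposure_thickness
          - 0.094*radiation_dose + 5.2056*preexposure_kvp
          - 0.0599*anatomical_mean_intensity - 0.0192*thresh
          - 2.0223*final_exposure_thickness - 0.049*compression_force
          - 37220*detector_sensitivity - 1.9863*filter_material
          + 25.314*anode_material

with filter and anode material coded molybdenum=1, rhodium=0.  The
coefficients were fitted on a GE Senographe-family unit and may require
recalibration for other scanner models, so they are data, not code: any
coefficient set can be loaded from JSON.

Volumes follow from a known total volume: GV = TV * %-G/100 and
FV = TV - GV.  The FFDM pathway is identical except that %-G comes from
the unit's own header estimate ("Raddose").
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .dicom_meta import ImagingParameters, MammogramRecord
from .types import BreastComposition

logger = logging.getLogger(__name__)

COEFFICIENT_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class MathCoefficients:
    """Intercept and eleven slopes of the linear %-G model."""

    intercept: float = 481.33
    preexposure_dose: float = -0.0057
    preexposure_thickness: float = 1.2305
    radiation_dose: float = -0.094
    preexposure_kvp: float = 5.2056
    anatomical_mean_intensity: float = -0.0599
    thresh: float = -0.0192
    final_exposure_thickness: float = -2.0223
    compression_force: float = -0.049
    detector_sensitivity: float = -37220.0
    filter_material: float = -1.9863
    anode_material: float = 25.314

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v):
                raise ValueError(f"coefficient {f.name} must be finite")

    @classmethod
    def from_json(cls, path: str | Path) -> "MathCoefficients":
        with open(path) as fh:
            raw = json.load(fh)
        version = raw.pop("schema_version", COEFFICIENT_SCHEMA_VERSION)
        if version != COEFFICIENT_SCHEMA_VERSION:
            raise ValueError(f"unsupported coefficient schema version {version}")
        return cls(**{k: float(v) for k, v in raw.items()})

    def to_json(self, path: str | Path) -> None:
        payload = {"schema_version": COEFFICIENT_SCHEMA_VERSION}
        payload.update(dataclasses.asdict(self))
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")


def math_pct_g(
    params: ImagingParameters,
    coefficients: MathCoefficients | None = None,
    clamp: bool = True,
) -> float:
    """Evaluate the linear %-G model on one parameter record.

    With ``clamp`` (the default) scores outside [0, 100] are truncated to
    the valid percent range and a warning is logged; with ``clamp=False``
    the raw linear score is returned, which can leave [0, 100].
    """
    c = coefficients or MathCoefficients()
    x = params.coded()
    score = c.intercept
    for name, value in x.items():
        score += getattr(c, name) * value
    if not np.isfinite(score):
        raise ValueError("non-finite score from linear model")
    if clamp and not 0.0 <= score <= 100.0:
        clipped = min(100.0, max(0.0, score))
        logger.warning(
            "linear %%-G score %.3f outside [0, 100]; truncated to %.1f",
            score,
            clipped,
        )
        return clipped
    return score


def compose_from_pct(pct_g: float, tv_ml: float, method: str) -> BreastComposition:
    """Decompose a known total volume by a percent-glandular estimate.

    ``gv = tv * pct_g / 100`` and ``fv = tv - gv`` (conserving the total
    exactly in floating point).  ``pct_g`` must already lie in [0, 100]:
    clamping of out-of-range model scores happens upstream, deliberately,
    so volume decomposition never silently repairs an invalid percent.
    """
    if not 0.0 <= pct_g <= 100.0:
        raise ValueError(f"pct_g must lie in [0, 100], got {pct_g}")
    if tv_ml < 0:
        raise ValueError(f"tv_ml must be non-negative, got {tv_ml}")
    gv = tv_ml * pct_g / 100.0
    return BreastComposition(
        method=method, pct_g=pct_g, gv_ml=gv, fv_ml=tv_ml - gv, tv_ml=tv_ml
    )


def math_composition(
    record: MammogramRecord,
    tv_ml: float,
    coefficients: MathCoefficients | None = None,
    clamp: bool = True,
) -> BreastComposition:
    """MATH pathway composition: linear-model %-G applied to a known TV.

    The total volume is an explicit argument — typically the HSM total
    (total area x compression thickness x factor) for the same mammogram.
    """
    pct = math_pct_g(record.params, coefficients, clamp=clamp)
    return compose_from_pct(pct, tv_ml, method="MATH")


def ffdm_composition(record: MammogramRecord, tv_ml: float) -> BreastComposition:
    """FFDM pathway: the unit's own Raddose %-G applied to a known TV."""
    if record.raddose_pct_g is None:
        raise ValueError(
            "record carries no Raddose %-G estimate; FFDM pathway unavailable"
        )
    return compose_from_pct(record.raddose_pct_g, tv_ml, method="FFDM")
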