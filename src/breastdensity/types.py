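"""Shared result types for the breast-density pathways.

Every estimation pathway (mammographic or MRI) ultimately reports the same
four quantities for one breast: percent glandular tissue (%-G), glandular
volume (GV), fat volume (FV) and total volume (TV), in mL.  They are carried
in a single :class:`BreastComposition` record tagged with the method that
produced it, so downstream concordance analysis can mix pathways freely.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

#: The five estimation pathways.
METHODS = ("HSM", "FFDM", "MATH", "3DGRE", "STIR")

#: Long-format CSV schema shared by all pathway outputs.
CSV_COLUMNS = ("subject_id", "method", "pct_g", "gv_ml", "fv_ml", "tv_ml")

#: Relative tolerance for the GV + FV = TV conservation invariant.
CONSERVATION_RTOL = 1e-9


@dataclass(frozen=True)
class BreastComposition:
    """Breast tissue composition estimated by one method.

    Attributes
    ----------
    method : str
        One of ``HSM``, ``FFDM``, ``MATH``, ``3DGRE``, ``STIR``.
    pct_g : float
        Percent glandular (dense) tissue, in [0, 100].
    gv_ml, fv_ml, tv_ml : float
        Glandular, fat and total breast volume in mL; ``gv + fv == tv``
        up to floating-point tolerance.
    """

    method: str
    pct_g: float
    gv_ml: float
    fv_ml: float
    tv_ml: float

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(
                f"unknown method {self.method!r}; expected one of {METHODS}"
            )
        for name in ("pct_g", "gv_ml", "fv_ml", "tv_ml"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if not 0.0 <= self.pct_g <= 100.0:
            raise ValueError(f"pct_g must lie in [0, 100], got {self.pct_g}")
        if self.gv_ml < 0 or self.fv_ml < 0 or self.tv_ml < 0:
            raise ValueError("volumes must be non-negative")
        scale = max(1.0, abs(self.tv_ml))
        if abs(self.gv_ml + self.fv_ml - self.tv_ml) > CONSERVATION_RTOL * scale:
            raise ValueError(
                f"volume conservation violated: gv={self.gv_ml} + fv={self.fv_ml}"
                f" != tv={self.tv_ml}"
            )

    def as_row(self, subject_id: str) -> dict:
        """Long-format row for the shared measures CSV."""
        return {
            "subject_id": subject_id,
            "method": self.method,
            "pct_g": self.pct_g,
            "gv_ml": self.gv_ml,
            "fv_ml": self.fv_ml,
            "tv_ml": self.tv_ml,
        }


def compositions_to_frame(
    rows: Iterable[tuple[str, BreastComposition]],
) -> pd.DataFrame:
    """Assemble (subject_id, composition) pairs into the long-format table."""
    records = [comp.as_row(sid) for sid, comp in rows]
    return pd.DataFrame.from_records(records, columns=list(CSV_COLUMNS))
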