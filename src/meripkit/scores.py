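"""Small exactly-specified clinical scoring formulas.

The immunohistochemistry immunoreactive score (IRS) multiplies a staining
intensity grade (0 negative .. 3 strong) by a positive-cell extent grade
(1: <=25%, 2: 26-50%, 3: 51-75%, 4: >75%); the subcutaneous xenograft
tumor volume is length x width^2 x 0.5 in mm^3.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import pandas as pd

from .io import atomic_write

INTENSITY_GRADES = (0, 1, 2, 3)
EXTENT_GRADES = (1, 2, 3, 4)


def irs(intensity: int, extent: int) -> int:
    """Immunoreactive score: intensity grade times extent grade."""
    if intensity not in INTENSITY_GRADES:
        raise ValueError(f"intensity must be one of {INTENSITY_GRADES}")
    if extent not in EXTENT_GRADES:
        raise ValueError(f"extent must be one of {EXTENT_GRADES}")
    return intensity * extent


def extent_grade(percent_positive: float) -> int:
    """Map a positive-cell percentage to the extent grade bands."""
    if not 0 <= percent_positive <= 100:
        raise ValueError("percentage must be in [0, 100]")
    if percent_positive <= 25:
        return 1
    if percent_positive <= 50:
        return 2
    if percent_positive <= 75:
        return 3
    return 4


def tumor_volume(length_mm: float, width_mm: float) -> float:
    """Caliper tumor volume in mm^3: length x width^2 x 0.5.

    Length is the longer axis; swapped inputs are corrected with a
    warning, negative inputs are rejected.
    """
    if length_mm < 0 or width_mm < 0:
        raise ValueError("dimensions must be non-negative")
    if width_mm > length_mm:
        warnings.warn("width > length; axes swapped")
        length_mm, width_mm = width_mm, length_mm
    return length_mm * width_mm ** 2 * 0.5


def score_table(table: pd.DataFrame) -> pd.DataFrame:
    """Batch scoring: adds an ``irs`` column from intensity/extent columns
    and/or a ``volume_mm3`` column from length_mm/width_mm columns."""
    out = table.copy()
    if {"intensity", "extent"} <= set(out.columns):
        out["irs"] = [irs(int(i), int(e))
                      for i, e in zip(out.intensity, out.extent)]
    if {"length_mm", "width_mm"} <= set(out.columns):
        out["volume_mm3"] = [tumor_volume(float(l), float(w))
                             for l, w in zip(out.length_mm, out.width_mm)]
    return out


def score_file(in_path: str | Path, out_path: str | Path) -> pd.DataFrame:
    table = score_table(pd.read_csv(in_path, sep="\t"))
    with atomic_write(out_path) as fh:
        table.to_csv(fh, sep="\t", index=False)
    return table
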