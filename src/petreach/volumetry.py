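"""MRI lesion volumetry from traced slice areas.

Volume is the study's planimetric estimate: the sum of the traced
per-slice areas times the (uniform) slice thickness, with no
partial-slice interpolation.  Arms are compared with the unpaired
two-tailed pooled-variance t-test.
"""

from __future__ import annotations

import numpy as np

from .stats import students_t_test
from .synth import LesionTrace

__all__ = ["lesion_volume", "area_from_mask", "compare_lesion_volumes"]


def lesion_volume(trace: LesionTrace) -> float:
    """Summed traced areas times slice thickness, in mm^3."""
    return float(sum(trace.areas_mm2) * trace.thickness_mm)


def area_from_mask(mask: np.ndarray, pixel_size_mm: float) -> float:
    """Traced area of one binary slice mask, in mm^2.

    ``pixel_size_mm`` is the in-plane edge length of a (square) pixel.
    """
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError(f"mask must be 2-D, got {mask.ndim} dimensions")
    if pixel_size_mm <= 0:
        raise ValueError(f"pixel size must be > 0, got {pixel_size_mm}")
    if not np.isin(mask, (0, 1, True, False)).all():
        raise ValueError("mask must be binary")
    return float(mask.astype(bool).sum()) * pixel_size_mm**2


def compare_lesion_volumes(volumes_a, volumes_b) -> dict:
    """Group means +/- sd and the two-tailed pooled t-test."""
    a = np.asarray(volumes_a, dtype=float)
    b = np.asarray(volumes_b, dtype=float)
    t, p, df = students_t_test(a, b)
    return {
        "n_a": int(a.size),
        "n_b": int(b.size),
        "mean_a": float(a.mean()),
        "mean_b": float(b.mean()),
        "sd_a": float(a.std(ddof=1)),
        "sd_b": float(b.std(ddof=1)),
        "t": t,
        "p": p,
        "df": df,
    }
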