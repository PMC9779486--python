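"""Regional PET quantification and stimulated-vs-unstimulated contrast.

Regional mean activities are converted to standardized uptake values
(SUV) only to choose the reference region — the region whose SUV varies
least across scans (lowest coefficient of variation).  Each scan is then
normalized to its own reference-region activity, which cancels the
per-scan global scale (injected dose, uptake efficiency).  The effect
measure per region is the within-animal ratio of normalized uptake,
stimulated over unstimulated; its group mean is expressed as

    delta_ratio_pct = (mean ratio - 1) * 100,

with a percentile bootstrap CI over animals and significance declared
when the CI excludes 1.0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .image_io import ScanRecord
from .stats import (
    BootstrapConfig,
    CiResult,
    bootstrap_mean_ci,
    exact_resample_ci,
)

__all__ = [
    "NormalizedScan",
    "RegionalContrast",
    "suv",
    "infer_hemispheres",
    "select_reference_region",
    "normalize_to_reference",
    "condition_ratios",
    "delta_ratio_percent",
    "contrast_table",
]


@dataclass(frozen=True)
class NormalizedScan:
    """A scan's activities divided by its reference-region activity."""

    scan_id: str
    animal_id: str
    condition: str
    reference_region: str
    values: dict[str, float]


@dataclass(frozen=True)
class RegionalContrast:
    """Per-region condition contrast across animals."""

    region: str
    hemisphere: str
    ratios: tuple[float, ...]
    mean_ratio: float
    delta_pct: float
    ci_low: float
    ci_high: float
    significant: bool
    n: int


def infer_hemispheres(regions) -> dict[str, str]:
    """Hemisphere tags from qualified region names.

    Names ending in ``_ipsi``/``_contra`` carry their tag; anything else
    is treated as midline.
    """
    out = {}
    for r in regions:
        if r.endswith("_ipsi"):
            out[r] = "ipsi"
        elif r.endswith("_contra"):
            out[r] = "contra"
        else:
            out[r] = "midline"
    return out


def suv(mean_activity: float, dose_kbq: float, weight_g: float) -> float:
    """Standardized uptake value: activity over dose per gram body weight.

    Tissue density is taken as 1 g/cm3, so kBq/cm3 divided by kBq/g is
    dimensionless.
    """
    if dose_kbq <= 0:
        raise ValueError(f"injected dose must be > 0, got {dose_kbq}")
    if weight_g <= 0:
        raise ValueError(f"body weight must be > 0, got {weight_g}")
    return mean_activity / (dose_kbq / weight_g)


def _common_regions(scans) -> list[str]:
    scans = list(scans)
    if not scans:
        raise ValueError("no scans supplied")
    regions = set(scans[0].activities)
    for s in scans[1:]:
        if set(s.activities) != regions:
            raise ValueError(
                f"scan {s.scan_id!r} has a different region set than the first scan"
            )
    return sorted(regions)


def select_reference_region(scans) -> str:
    """Region whose SUV has the lowest variability across all scans.

    Variability is the coefficient of variation (sample sd over mean) of
    the region's SUV pooled over every scan; ties break lexicographically
    by region name so selection is deterministic.
    """
    scans = list(scans)
    if len(scans) < 2:
        raise ValueError("reference selection needs at least 2 scans")
    regions = _common_regions(scans)
    best_region = None
    best_cv = np.inf
    for region in regions:  # sorted, so first-wins implements the tie-break
        suvs = np.array(
            [suv(s.activities[region], s.dose_kbq, s.weight_g) for s in scans]
        )
        mean = suvs.mean()
        if mean <= 0:
            continue
        cv = suvs.std(ddof=1) / mean
        if cv < best_cv:
            best_cv = cv
            best_region = region
    if best_region is None:
        raise ValueError("no region with positive mean SUV")
    return best_region


def normalize_to_reference(scan: ScanRecord, reference: str) -> NormalizedScan:
    """Divide every region's activity by the scan's reference activity."""
    if reference not in scan.activities:
        raise KeyError(f"reference region {reference!r} absent from scan")
    ref_val = scan.activities[reference]
    if ref_val <= 0:
        raise ValueError(
            f"reference activity must be > 0, got {ref_val} in scan {scan.scan_id!r}"
        )
    values = {r: v / ref_val for r, v in scan.activities.items()}
    values[reference] = 1.0  # exact by construction
    return NormalizedScan(
        scan_id=scan.scan_id,
        animal_id=scan.animal_id,
        condition=scan.condition,
        reference_region=reference,
        values=values,
    )


def condition_ratios(normalized, region: str) -> dict[str, float]:
    """Within-animal stimulated/unstimulated ratio of normalized uptake.

    Returns a mapping animal_id -> ratio, requiring exactly one scan per
    condition per animal.
    """
    by_animal: dict[str, dict[str, float]] = {}
    for ns in normalized:
        if region not in ns.values:
            raise KeyError(f"region {region!r} absent from scan {ns.scan_id!r}")
        slot = by_animal.setdefault(ns.animal_id, {})
        if ns.condition in slot:
            raise ValueError(
                f"animal {ns.animal_id!r} has multiple {ns.condition} scans"
            )
        slot[ns.condition] = ns.values[region]
    ratios = {}
    for animal, conds in sorted(by_animal.items()):
        if set(conds) != {"stimulated", "unstimulated"}:
            raise ValueError(f"animal {animal!r} lacks one of the two conditions")
        if conds["unstimulated"] <= 0:
            raise ValueError(f"non-positive unstimulated value for {animal!r}")
        ratios[animal] = conds["stimulated"] / conds["unstimulated"]
    return ratios


def delta_ratio_percent(mean_ratio: float) -> float:
    """Percent change implied by a mean condition ratio."""
    if mean_ratio <= 0:
        raise ValueError(f"mean ratio must be > 0, got {mean_ratio}")
    return (mean_ratio - 1.0) * 100.0


def _region_ci(ratios: np.ndarray, config: BootstrapConfig, method: str) -> CiResult:
    if method == "exact" or (method == "auto" and ratios.size <= 6):
        return exact_resample_ci(ratios, alpha=config.alpha)
    return bootstrap_mean_ci(ratios, config)


def contrast_table(
    scans,
    reference: str = "auto",
    hemispheres: dict[str, str] | None = None,
    bootstrap: BootstrapConfig | None = None,
    ci_method: str = "mc",
) -> tuple[pd.DataFrame, str]:
    """Full per-region contrast: mean ratio, delta %, CI, significance.

    Parameters
    ----------
    scans : iterable of ScanRecord
        Two scans (one per condition) per animal.
    reference : str
        A region name, or ``"auto"`` to pick the lowest-SUV-CV region.
    hemispheres : mapping region -> hemisphere tag, optional
    bootstrap : BootstrapConfig, optional
    ci_method : {"mc", "exact", "auto"}
        CI flavor; ``auto`` enumerates exactly for n <= 6 animals.

    Returns
    -------
    (table, reference) : the per-region DataFrame (one row per region,
        sorted by name) and the reference region actually used.
    """
    if ci_method not in ("mc", "exact", "auto"):
        raise ValueError(f"unknown ci_method {ci_method!r}")
    scans = list(scans)
    cfg = bootstrap if bootstrap is not None else BootstrapConfig()
    ref = select_reference_region(scans) if reference == "auto" else reference
    normalized = [normalize_to_reference(s, ref) for s in scans]
    regions = _common_regions(scans)
    if hemispheres is None:
        hemispheres = infer_hemispheres(regions)
    # independent per-region resampling streams derived from the one seed
    seeds = np.random.SeedSequence(cfg.seed).generate_state(len(regions)) % (2**31)
    rows = []
    for region, region_seed in zip(regions, seeds):
        ratios = np.array(list(condition_ratios(normalized, region).values()))
        region_cfg = BootstrapConfig(
            n_resamples=cfg.n_resamples, alpha=cfg.alpha, seed=int(region_seed)
        )
        ci = _region_ci(ratios, region_cfg, ci_method)
        mean_ratio = float(ratios.mean())
        rows.append(
            {
                "region": region,
                "hemisphere": (hemispheres or {}).get(region, ""),
                "n": ratios.size,
                "mean_ratio": mean_ratio,
                "delta_pct": delta_ratio_percent(mean_ratio),
                "ci_low": ci.ci_low,
                "ci_high": ci.ci_high,
                "significant": ci.significant,
            }
        )
    return pd.DataFrame(rows), ref
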