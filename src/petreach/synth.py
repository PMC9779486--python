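"""Synthetic cohort generator.

The animal data behind the analysis (paired FDG-PET scans under
stimulated and unstimulated conditions, single-pellet-reaching sessions,
and MRI lesion traces) are not publicly deposited, so this module
generates cohorts with the statistical structure the pipeline assumes,
with known ground truth, making every downstream stage testable.

PET model
---------
The regional activity of scan ``s`` (animal ``a``, condition stim/unstim)
in region ``r`` is

    A(s, r) = G_s * mu_r * (1 + delta_r * [stim]) * eps,

with ``G_s`` a lognormal per-scan global scale factor (injected-dose and
uptake-efficiency variation), ``mu_r`` the region's baseline uptake,
``delta_r`` the stimulation effect fraction (zero in the reference
region), and ``eps`` lognormal multiplicative region noise with log-sd
``sigma_r``.  Because ``G_s`` multiplies every region of a scan,
reference-region normalization removes it exactly — the premise of
cerebellum normalization.

Behavior model
--------------
Each animal reaches in four sessions (baseline, final pre-intervention,
post-stroke day 2 and day 7); each reach is a Bernoulli success with the
animal's grasp probability, reduced by a stroke deficit factor after the
lesion and partially restored on day 7 in the stimulated arm.

Lesions are ellipsoids cut into parallel slices; the traced per-slice
areas follow the analytic elliptical cross-sections with optional
multiplicative noise.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .image_io import ScanRecord, write_scans_tsv

__all__ = [
    "RegionSpec",
    "SynthConfig",
    "ReachSession",
    "LesionTrace",
    "SynthCohort",
    "default_regions",
    "generate_pet_scans",
    "generate_reach_sessions",
    "generate_lesion_traces",
    "generate_cohort",
    "write_cohort",
    "write_image_cohort",
    "config_with",
    "region_key",
]

DAYS = ("baseline", "final_pre", "day2", "day7")
HEMISPHERES = ("ipsi", "contra", "midline")


@dataclass(frozen=True)
class RegionSpec:
    """One atlas region as the generator sees it.

    ``delta`` is the fractional stimulation effect on uptake (0.15 means
    +15% under stimulation); ``sigma`` the lognormal noise sd of the
    region's multiplicative measurement noise.
    """

    name: str
    hemisphere: str
    baseline: float
    delta: float = 0.0
    sigma: float = 0.05

    def __post_init__(self) -> None:
        if self.hemisphere not in HEMISPHERES:
            raise ValueError(
                f"hemisphere must be one of {HEMISPHERES}, got {self.hemisphere!r}"
            )
        if self.baseline <= 0:
            raise ValueError(f"baseline uptake must be > 0, got {self.baseline}")
        if self.delta <= -1.0:
            raise ValueError(f"delta must be > -1, got {self.delta}")
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")


def default_regions(
    delta_scale: float = 1.0, sigma: float = 0.05, reference_sigma: float = 0.02
) -> tuple[RegionSpec, ...]:
    """Region set emulating a basal-ganglia/brainstem VOI panel.

    Baselines are in kBq/cm3 at a typical rodent FDG dose; the reference
    region (cerebellum) carries zero stimulation effect and the smallest
    noise sd.  ``delta_scale`` scales every non-reference effect, so
    ``delta_scale=0`` gives a null cohort with the same geometry.
    """
    specs = [
        ("cerebellum", "midline", 620.0, 0.0, reference_sigma),
        ("motor_cortex", "ipsi", 700.0, 0.20 * delta_scale, sigma),
        ("motor_cortex", "contra", 700.0, 0.0, sigma),
        ("striatum", "ipsi", 760.0, 0.15 * delta_scale, sigma),
        ("striatum", "contra", 760.0, 0.05 * delta_scale, sigma),
        ("stn", "ipsi", 680.0, 0.25 * delta_scale, sigma),
        ("globus_pallidus", "ipsi", 640.0, 0.18 * delta_scale, sigma),
        ("vmh", "midline", 560.0, -0.12 * delta_scale, sigma),
        ("gigantocellular_nu", "ipsi", 590.0, 0.15 * delta_scale, sigma),
        ("vestibular_nu", "contra", 600.0, 0.10 * delta_scale, sigma),
    ]
    return tuple(
        RegionSpec(name=n, hemisphere=h, baseline=b, delta=d, sigma=s)
        for n, h, b, d, s in specs
    )


@dataclass(frozen=True)
class SynthConfig:
    """All generator knobs.

    PET: ``n_animals_pet`` animals each scanned once per condition;
    ``scan_scale_sd`` is the log-sd of the per-scan global factor;
    dose/weight means follow the study's injected activities (~46-48 MBq
    into ~320 g rats).

    Behavior: ``n_animals_behavior_per_arm`` animals per arm (stim,
    sham); grasp probability drawn per animal from a Beta distribution;
    ``attempts_rate`` is the Poisson mean of reaches per 10-min session;
    ``stroke_deficit`` multiplies the grasp probability after the lesion;
    ``stim_recovery_day7`` additionally multiplies it on day 7 in the
    stimulated arm (``sham_recovery_day7`` likewise for sham).
    ``n_zero_final_pre_per_arm`` animals are forced to zero successes in
    the final pre-intervention session and
    ``n_no_lesion_per_arm`` are flagged lesion-absent, so the exclusion
    rules have material to act on.

    Lesions: per-arm ellipsoid semi-axes in mm, slice thickness in mm,
    and a multiplicative area noise sd.
    """

    n_animals_pet: int = 4
    regions: tuple[RegionSpec, ...] = field(default_factory=default_regions)
    reference_region: str = "cerebellum"
    scan_scale_sd: float = 0.10
    dose_mean_kbq: tuple[float, float] = (46_500.0, 48_000.0)  # (unstim, stim)
    dose_sd_kbq: tuple[float, float] = (17_300.0, 12_600.0)
    weight_mean_g: float = 320.0
    weight_sd_g: float = 25.0

    n_animals_behavior_per_arm: int = 8
    grasp_beta: tuple[float, float] = (24.0, 6.0)  # mean 0.8
    attempts_rate: float = 25.0
    min_attempts: int = 20
    stroke_deficit: float = 0.08
    stim_recovery_day7: float = 3.0
    sham_recovery_day7: float = 1.0
    n_zero_final_pre_per_arm: int = 0
    n_no_lesion_per_arm: int = 0

    lesion_semiaxes_mm: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {"stim": (3.0, 2.2, 2.0), "sham": (3.3, 2.5, 2.2)}
    )
    slice_thickness_mm: float = 1.0
    lesion_area_sd: float = 0.10
    lesion_scale_sd: float = 0.40  # per-animal lognormal volume dispersion

    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_animals_pet < 1 or self.n_animals_behavior_per_arm < 1:
            raise ValueError("animal counts must be >= 1")
        if min(self.scan_scale_sd, self.lesion_area_sd, self.lesion_scale_sd) < 0:
            raise ValueError("dispersion parameters must be >= 0")
        names = [r.name for r in self.regions]
        if len(set(names)) != len(names):
            # same name on two hemispheres is allowed via the qualified key
            qualified = [f"{r.name}_{r.hemisphere}" for r in self.regions]
            if len(set(qualified)) != len(qualified):
                raise ValueError("region (name, hemisphere) pairs must be unique")
        ref = self.reference_region
        refs = [r for r in self.regions if r.name == ref]
        if not refs:
            raise ValueError(f"reference region {ref!r} not among regions")
        if any(r.delta != 0.0 for r in refs):
            raise ValueError("reference region must have delta = 0")
        for axes in self.lesion_semiaxes_mm.values():
            if any(a <= 0 for a in axes):
                raise ValueError("lesion semi-axes must be > 0")
        if self.slice_thickness_mm <= 0:
            raise ValueError("slice thickness must be > 0")
        if not 0.0 <= self.stroke_deficit:
            raise ValueError("stroke_deficit must be >= 0")


@dataclass(frozen=True)
class ReachSession:
    """Ordered per-reach outcomes for one animal on one day."""

    animal_id: str
    arm: str  # "stim" or "sham"
    day: str  # one of DAYS
    outcomes: tuple[int, ...]
    duration_min: float = 10.0

    def __post_init__(self) -> None:
        if self.arm not in ("stim", "sham"):
            raise ValueError(f"arm must be 'stim' or 'sham', got {self.arm!r}")
        if self.day not in DAYS:
            raise ValueError(f"day must be one of {DAYS}, got {self.day!r}")
        if any(o not in (0, 1) for o in self.outcomes):
            raise ValueError("outcomes must be 0 or 1")
        if not 0 < self.duration_min <= 10.0:
            raise ValueError("session duration must be in (0, 10] minutes")


@dataclass(frozen=True)
class LesionTrace:
    """Ordered per-slice traced areas (mm^2) with slice thickness (mm)."""

    animal_id: str
    areas_mm2: tuple[float, ...]
    thickness_mm: float
    arm: str = "stim"

    def __post_init__(self) -> None:
        if self.thickness_mm <= 0:
            raise ValueError("slice thickness must be > 0")
        if any(a < 0 for a in self.areas_mm2):
            raise ValueError("traced areas must be >= 0")


@dataclass(frozen=True)
class SynthCohort:
    scans: tuple[ScanRecord, ...]
    sessions: tuple[ReachSession, ...]
    lesions: tuple[LesionTrace, ...]
    lesion_present: dict[str, bool]
    truth: dict


def _streams(config: SynthConfig, seed: int | None):
    master = config.seed if seed is None else seed
    ss = np.random.SeedSequence(master)
    return [np.random.default_rng(s) for s in ss.spawn(3)]


def region_key(region: RegionSpec) -> str:
    """Qualified column name: ``name`` for midline, ``name_hemi`` otherwise."""
    if region.hemisphere == "midline":
        return region.name
    return f"{region.name}_{region.hemisphere}"


def generate_pet_scans(
    config: SynthConfig, seed: int | None = None
) -> list[ScanRecord]:
    """Paired PET scans: one per condition for each PET animal.

    Returns ``2 * n_animals_pet`` :class:`~petreach.image_io.ScanRecord`
    objects with strictly positive regional activities, injected dose
    and body weight.  Deterministic for a fixed seed.
    """
    rng = _streams(config, seed)[0]
    scans: list[ScanRecord] = []
    for i in range(config.n_animals_pet):
        animal = f"pet{i + 1:02d}"
        weight = max(150.0, rng.normal(config.weight_mean_g, config.weight_sd_g))
        for c, condition in enumerate(("unstimulated", "stimulated")):
            dose = -1.0
            while dose <= 1000.0:  # redraw implausible (<1 MBq) doses
                dose = rng.normal(config.dose_mean_kbq[c], config.dose_sd_kbq[c])
            # activity tracks the injected dose per gram (so SUV removes
            # the dose), times a residual lognormal scan factor
            dose_factor = (dose / weight) / (
                config.dose_mean_kbq[c] / config.weight_mean_g
            )
            g_s = dose_factor * float(np.exp(rng.normal(0.0, config.scan_scale_sd)))
            stim = 1.0 if condition == "stimulated" else 0.0
            activities = {}
            for r in config.regions:
                eps = float(np.exp(rng.normal(0.0, r.sigma))) if r.sigma > 0 else 1.0
                activities[region_key(r)] = (
                    g_s * r.baseline * (1.0 + r.delta * stim) * eps
                )
            scans.append(
                ScanRecord(
                    scan_id=f"{animal}_{condition[:6]}",
                    animal_id=animal,
                    condition=condition,
                    dose_kbq=float(dose),
                    weight_g=float(weight),
                    activities=activities,
                )
            )
    return scans


def generate_reach_sessions(
    config: SynthConfig, seed: int | None = None
) -> list[ReachSession]:
    """Reach sessions for both arms across the four study days.

    Per animal: a baseline and a final pre-intervention session at the
    animal's grasp probability, then day-2 and day-7 sessions at the
    deficit-reduced probability, with the day-7 recovery factor applied
    per arm.  The first ``n_zero_final_pre_per_arm`` animals of each arm
    are forced to zero successes in the final pre-intervention session.
    """
    rng = _streams(config, seed)[1]
    a, b = config.grasp_beta
    sessions: list[ReachSession] = []
    for arm in ("stim", "sham"):
        recovery = (
            config.stim_recovery_day7 if arm == "stim" else config.sham_recovery_day7
        )
        for i in range(config.n_animals_behavior_per_arm):
            animal = f"{arm}{i + 1:02d}"
            p_base = float(rng.beta(a, b))
            p_post = min(1.0, p_base * config.stroke_deficit)
            p_day7 = min(1.0, p_post * recovery)
            force_zero = i < config.n_zero_final_pre_per_arm
            for day, p in (
                ("baseline", p_base),
                ("final_pre", p_base),
                ("day2", p_post),
                ("day7", p_day7),
            ):
                n_attempts = max(config.min_attempts, int(rng.poisson(config.attempts_rate)))
                if day == "final_pre" and force_zero:
                    outcomes = np.zeros(n_attempts, dtype=int)
                else:
                    outcomes = (rng.random(n_attempts) < p).astype(int)
                sessions.append(
                    ReachSession(
                        animal_id=animal,
                        arm=arm,
                        day=day,
                        outcomes=tuple(int(o) for o in outcomes),
                    )
                )
    return sessions


def _ellipse_area(a: float, b: float, c: float, z: float) -> float:
    if abs(z) >= c:
        return 0.0
    return float(np.pi * a * b * (1.0 - (z / c) ** 2))


def generate_lesion_traces(
    config: SynthConfig, seed: int | None = None
) -> list[LesionTrace]:
    """Per-animal lesion traces from elliptical cross sections.

    Slices are taken at midpoints of consecutive thickness-wide slabs
    spanning the lesion extent along its third semi-axis, so the summed
    areas times the thickness converge to the analytic ellipsoid volume
    ``(4/3) * pi * a * b * c`` as the thickness shrinks.
    """
    rng = _streams(config, seed)[2]
    traces: list[LesionTrace] = []
    t = config.slice_thickness_mm
    for arm in ("stim", "sham"):
        a, b, c = config.lesion_semiaxes_mm[arm]
        n_slices = int(np.ceil(2.0 * c / t))
        for i in range(config.n_animals_behavior_per_arm):
            animal = f"{arm}{i + 1:02d}"
            # per-animal size factor, mean-one lognormal on the volume scale
            if config.lesion_scale_sd > 0:
                s = config.lesion_scale_sd
                animal_scale = float(
                    np.exp(rng.normal(-0.5 * s * s, s))
                )
            else:
                animal_scale = 1.0
            areas = []
            for k in range(n_slices):
                z = -c + (k + 0.5) * t
                area = _ellipse_area(a, b, c, z) * animal_scale
                if area > 0 and config.lesion_area_sd > 0:
                    area *= float(np.exp(rng.normal(0.0, config.lesion_area_sd)))
                areas.append(area)
            traces.append(
                LesionTrace(
                    animal_id=animal,
                    areas_mm2=tuple(areas),
                    thickness_mm=t,
                    arm=arm,
                )
            )
    return traces


def generate_cohort(config: SynthConfig, seed: int | None = None) -> SynthCohort:
    """Full cohort: PET scans, reach sessions, lesion traces, ground truth."""
    scans = generate_pet_scans(config, seed)
    sessions = generate_reach_sessions(config, seed)
    lesions = generate_lesion_traces(config, seed)
    # the LAST n_no_lesion_per_arm animals of each arm are lesion-absent
    lesion_present = {}
    for arm in ("stim", "sham"):
        for i in range(config.n_animals_behavior_per_arm):
            animal = f"{arm}{i + 1:02d}"
            lesion_present[animal] = (
                i < config.n_animals_behavior_per_arm - config.n_no_lesion_per_arm
            )
    truth = {
        "delta": {region_key(r): r.delta for r in config.regions},
        "sigma": {region_key(r): r.sigma for r in config.regions},
        "reference_region": config.reference_region,
        "stroke_deficit": config.stroke_deficit,
        "stim_recovery_day7": config.stim_recovery_day7,
        "sham_recovery_day7": config.sham_recovery_day7,
        "lesion_volume_mm3": {
            arm: 4.0 / 3.0 * float(np.pi) * axes[0] * axes[1] * axes[2]
            for arm, axes in config.lesion_semiaxes_mm.items()
        },
        "seed": config.seed if seed is None else seed,
    }
    return SynthCohort(
        scans=tuple(scans),
        sessions=tuple(sessions),
        lesions=tuple(lesions),
        lesion_present=lesion_present,
        truth=truth,
    )


def sessions_to_frame(sessions) -> pd.DataFrame:
    rows = [
        {
            "animal_id": s.animal_id,
            "arm": s.arm,
            "day": s.day,
            "outcomes": "".join(str(o) for o in s.outcomes),
        }
        for s in sessions
    ]
    return pd.DataFrame(rows)


def lesions_to_frame(lesions) -> pd.DataFrame:
    rows = []
    for t in lesions:
        for k, area in enumerate(t.areas_mm2):
            rows.append(
                {
                    "animal_id": t.animal_id,
                    "arm": t.arm,
                    "slice_index": k,
                    "area_mm2": area,
                    "thickness_mm": t.thickness_mm,
                }
            )
    return pd.DataFrame(rows)


def write_cohort(cohort: SynthCohort, outdir: str | Path) -> dict[str, Path]:
    """Write scans.tsv, sessions.tsv, lesions.tsv and truth.json."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "scans": out / "scans.tsv",
        "sessions": out / "sessions.tsv",
        "lesions": out / "lesions.tsv",
        "truth": out / "truth.json",
    }
    write_scans_tsv(cohort.scans, paths["scans"])
    sessions_to_frame(cohort.sessions).to_csv(paths["sessions"], sep="\t", index=False)
    lesions_to_frame(cohort.lesions).to_csv(
        paths["lesions"], sep="\t", index=False, float_format="%.10g"
    )
    truth = dict(cohort.truth)
    truth["lesion_present"] = cohort.lesion_present
    paths["truth"].write_text(json.dumps(truth, indent=2, sort_keys=True))
    return paths


def config_with(config: SynthConfig, **overrides) -> SynthConfig:
    """Functional update of a frozen config."""
    return dataclasses.replace(config, **overrides)


def write_image_cohort(
    cohort: SynthCohort, config: SynthConfig, outdir: str | Path
) -> dict[str, Path]:
    """Write the PET side of a cohort as NIfTI volumes plus metadata.

    Builds a small label volume with one 2x2x2-voxel block per region
    (label ids 1..n in region order, 0 = background) and, per scan, an
    activity volume constant within each block at the scan's tabulated
    regional activity — so VOI reduction of the images reproduces
    scans.tsv exactly.  Intended for exercising the image path
    end-to-end, not for emulating scanner physics.
    """
    from .image_io import (
        RegionTable,
        save_volume,
        write_region_table,
    )

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    keys = [region_key(r) for r in config.regions]
    n = len(keys)
    shape = (2 * n, 4, 4)
    labels = np.zeros(shape, dtype=np.int16)
    for i in range(n):
        labels[2 * i : 2 * i + 2, 1:3, 1:3] = i + 1
    paths: dict[str, Path] = {"labels": out / "labels.nii"}
    save_volume(labels, paths["labels"])
    table = RegionTable(
        entries={
            i + 1: (region_key(r), r.hemisphere)
            for i, r in enumerate(config.regions)
        }
    )
    paths["regions"] = out / "regions.tsv"
    write_region_table(table, paths["regions"])
    meta_rows = []
    for s in cohort.scans:
        vol = np.zeros(shape)
        for i, key in enumerate(keys):
            vol[labels == i + 1] = s.activities[key]
        p = out / f"{s.scan_id}.nii"
        save_volume(vol, p)
        paths[s.scan_id] = p
        meta_rows.append(
            {
                "scan_id": s.scan_id,
                "animal_id": s.animal_id,
                "condition": s.condition,
                "dose_kbq": s.dose_kbq,
                "weight_g": s.weight_g,
            }
        )
    paths["metadata"] = out / "scan_metadata.tsv"
    pd.DataFrame(meta_rows).to_csv(
        paths["metadata"], sep="\t", index=False, float_format="%.12g"
    )
    return paths
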