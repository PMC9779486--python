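"""Volume and table I/O, and reduction of images to regional activities.

The pipeline's native representation is the per-scan per-region mean
activity table; this module produces it either from NIfTI activity
volumes paired with an integer atlas label volume, or directly from a
TSV written by the cohort generator.  Registration between activity and
label volumes is taken as given — only grid congruence is validated.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "ScanRecord",
    "RegionTable",
    "time_average",
    "voi_mean",
    "scans_from_images",
    "read_scans_tsv",
    "write_scans_tsv",
    "read_region_table",
    "write_region_table",
    "load_volume",
    "save_volume",
]

CONDITIONS = ("stimulated", "unstimulated")

_META_COLUMNS = ["scan_id", "animal_id", "condition", "dose_kbq", "weight_g"]


@dataclass(frozen=True)
class ScanRecord:
    """One PET scan: metadata plus per-region mean activities (kBq/cm3)."""

    scan_id: str
    animal_id: str
    condition: str
    dose_kbq: float
    weight_g: float
    activities: dict[str, float]

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )
        if self.dose_kbq <= 0:
            raise ValueError(f"injected dose must be > 0, got {self.dose_kbq}")
        if self.weight_g <= 0:
            raise ValueError(f"body weight must be > 0, got {self.weight_g}")
        if any(v < 0 for v in self.activities.values()):
            raise ValueError("regional activities must be >= 0")

    @property
    def regions(self) -> tuple[str, ...]:
        return tuple(self.activities)


@dataclass(frozen=True)
class RegionTable:
    """Atlas label id -> (region name, hemisphere tag) lookup."""

    entries: dict[int, tuple[str, str]]

    def __post_init__(self) -> None:
        names = [n for n, _ in self.entries.values()]
        if len(set(names)) != len(names):
            raise ValueError("region names must be unique")
        if any(i < 0 for i in self.entries):
            raise ValueError("label ids must be non-negative")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.entries.values())

    def hemisphere(self, name: str) -> str:
        for n, h in self.entries.values():
            if n == name:
                return h
        raise KeyError(name)


def time_average(frames, durations) -> np.ndarray:
    """Duration-weighted voxelwise mean of a dynamic frame stack.

    Parameters
    ----------
    frames : sequence of ndarray
        Activity volumes of identical shape.
    durations : sequence of float
        Frame durations in seconds, all > 0.
    """
    frames = [np.asarray(f, dtype=float) for f in frames]
    durations = np.asarray(durations, dtype=float)
    if len(frames) == 0:
        raise ValueError("need at least one frame")
    if durations.size != len(frames):
        raise ValueError("one duration per frame required")
    if np.any(durations <= 0):
        raise ValueError("frame durations must be > 0")
    shape = frames[0].shape
    if any(f.shape != shape for f in frames):
        raise ValueError("all frames must share one grid shape")
    stack = np.stack(frames, axis=0)
    weights = durations / durations.sum()
    return np.tensordot(weights, stack, axes=1)


def voi_mean(activity: np.ndarray, labels: np.ndarray, region_id: int) -> float:
    """Mean activity over the voxels carrying ``region_id``.

    Raises a ``KeyError`` when the region id is absent (or its VOI is
    empty), so silent zero-size means cannot occur.
    """
    activity = np.asarray(activity, dtype=float)
    labels = np.asarray(labels)
    if activity.shape != labels.shape:
        raise ValueError(
            f"activity grid {activity.shape} and label grid {labels.shape} differ"
        )
    mask = labels == region_id
    if not mask.any():
        raise KeyError(f"region id {region_id} absent from label volume")
    return float(activity[mask].mean())


def scans_from_images(
    volumes: dict[str, np.ndarray],
    labels: np.ndarray,
    regions: RegionTable,
    metadata: pd.DataFrame,
) -> list[ScanRecord]:
    """Build ScanRecords by reducing each activity volume over atlas VOIs.

    Parameters
    ----------
    volumes : mapping scan_id -> activity volume
    labels : integer label volume congruent with every activity volume
    regions : RegionTable mapping label ids to names
    metadata : DataFrame with columns scan_id, animal_id, condition,
        dose_kbq, weight_g — one row per scan.

    Returns one record per metadata row; raises if any row lacks its
    volume or if an (animal, condition) pair repeats.
    """
    missing = [c for c in _META_COLUMNS if c not in metadata.columns]
    if missing:
        raise ValueError(f"metadata lacks columns: {missing}")
    seen: set[tuple[str, str]] = set()
    records = []
    for row in metadata.itertuples(index=False):
        sid = str(row.scan_id)
        if sid not in volumes:
            raise ValueError(f"no activity volume supplied for scan {sid!r}")
        key = (str(row.animal_id), str(row.condition))
        if key in seen:
            raise ValueError(f"duplicate (animal, condition) pair {key}")
        seen.add(key)
        vol = volumes[sid]
        activities = {
            name: voi_mean(vol, labels, rid)
            for rid, (name, _) in regions.entries.items()
        }
        records.append(
            ScanRecord(
                scan_id=sid,
                animal_id=str(row.animal_id),
                condition=str(row.condition),
                dose_kbq=float(row.dose_kbq),
                weight_g=float(row.weight_g),
                activities=activities,
            )
        )
    return records


def write_scans_tsv(scans, path: str | Path) -> None:
    """One row per scan; metadata columns then one column per region."""
    scans = list(scans)
    if not scans:
        raise ValueError("no scans to write")
    region_cols = list(scans[0].activities)
    rows = []
    for s in scans:
        if list(s.activities) != region_cols:
            raise ValueError("region set differs between scans")
        row = {
            "scan_id": s.scan_id,
            "animal_id": s.animal_id,
            "condition": s.condition,
            "dose_kbq": s.dose_kbq,
            "weight_g": s.weight_g,
        }
        row.update(s.activities)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_scans_tsv(path: str | Path) -> list[ScanRecord]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"scan table lacks columns: {missing}")
    region_cols = [c for c in df.columns if c not in _META_COLUMNS]
    return [
        ScanRecord(
            scan_id=str(r.scan_id),
            animal_id=str(r.animal_id),
            condition=str(r.condition),
            dose_kbq=float(r.dose_kbq),
            weight_g=float(r.weight_g),
            activities={c: float(getattr(r, c)) for c in region_cols},
        )
        for r in df.itertuples(index=False)
    ]


def write_region_table(table: RegionTable, path: str | Path) -> None:
    rows = [
        {"region_id": rid, "name": name, "hemisphere": hemi}
        for rid, (name, hemi) in table.entries.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_region_table(path: str | Path) -> RegionTable:
    df = pd.read_csv(path, sep="\t")
    return RegionTable(
        entries={
            int(r.region_id): (str(r.name), str(r.hemisphere))
            for r in df.itertuples(index=False)
        }
    )


def load_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a NIfTI volume; returns (data array, affine)."""
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine


def save_volume(data: np.ndarray, path: str | Path, affine=None) -> None:
    if affine is None:
        affine = np.eye(4)
    nib.save(nib.Nifti1Image(np.asarray(data), affine), str(path))
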