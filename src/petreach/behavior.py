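"""Single-pellet reaching: scoring, success rates, exclusions, arm tests.

Each reach scores 1 only when the pellet is reached, retrieved, brought
to the mouth and eaten; anything else scores 0.  An animal's post-stroke
success rate is its day-2 (or day-7) session score as a percentage of
its last pre-intervention score.  The day-7-vs-day-2 contrast can be
formed as a per-animal ratio, a per-animal difference in percentage
points, or — the default headline — the baseline-normalized day-7 rate
compared between arms, which keeps animals with zero day-2 success in
the comparison.

Cohort exclusions follow two rules, in order: animals without a
macroscopic lesion are removed first, then animals with zero successes
in the final pre-intervention session.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .stats import mann_whitney_u
from .synth import ReachSession

__all__ = [
    "SuccessSummary",
    "score_session",
    "success_rate",
    "day7_vs_day2",
    "paw_preference",
    "apply_exclusions",
    "summarize_animals",
    "compare_arms",
]

METRIC_MODES = ("sr_d7", "d7_vs_d2_ratio", "d7_vs_d2_difference")


@dataclass(frozen=True)
class SuccessSummary:
    """Per-animal scores and normalized success rates (NaN = undefined)."""

    animal_id: str
    arm: str
    score_final_pre: int
    score_d2: int
    score_d7: int
    sr_d2_pct: float
    sr_d7_pct: float
    excluded: bool = False
    exclusion_reason: str = ""


def score_session(session: ReachSession) -> int:
    """Session score: the number of fully successful reaches."""
    return int(sum(session.outcomes))


def success_rate(score_post: int, score_baseline: int) -> float:
    """Post score as a percentage of the last pre-intervention score."""
    if score_baseline <= 0:
        raise ValueError(
            "baseline score must be > 0; zero-baseline animals are excluded "
            "upstream, not rated"
        )
    return 100.0 * score_post / score_baseline


def day7_vs_day2(sr_d7: float, sr_d2: float, mode: str = "ratio") -> float:
    """Day-7 rate normalized to day 2.

    ``ratio`` mode returns ``100 * sr_d7 / sr_d2`` and is NaN when the
    animal had no day-2 success; ``difference`` mode returns
    ``sr_d7 - sr_d2`` in percentage points and is always defined.
    """
    if mode == "ratio":
        if sr_d2 <= 0:
            return math.nan
        return 100.0 * sr_d7 / sr_d2
    if mode == "difference":
        return sr_d7 - sr_d2
    raise ValueError(f"mode must be 'ratio' or 'difference', got {mode!r}")


def paw_preference(attempts_left: int, attempts_right: int) -> str | None:
    """Preferred paw: the side with strictly more grasp attempts.

    Returns ``None`` when tied (preference undetermined; training
    continues).
    """
    if attempts_left < 0 or attempts_right < 0:
        raise ValueError("attempt counts must be >= 0")
    if attempts_left + attempts_right == 0:
        raise ValueError("no attempts recorded")
    if attempts_left > attempts_right:
        return "left"
    if attempts_right > attempts_left:
        return "right"
    return None


def _sessions_by_animal(sessions) -> dict[str, dict[str, ReachSession]]:
    table: dict[str, dict[str, ReachSession]] = {}
    for s in sessions:
        table.setdefault(s.animal_id, {})[s.day] = s
    return table


def apply_exclusions(
    sessions, lesion_present: dict[str, bool]
) -> tuple[list[ReachSession], list[dict]]:
    """Drop animals failing either study exclusion rule.

    Rule 1 (checked first): no macroscopic lesion.  Rule 2: zero
    successes in the final pre-intervention session.  Returns the kept
    sessions and a log with one entry per excluded animal naming the
    first matching rule.  Idempotent.
    """
    by_animal = _sessions_by_animal(sessions)
    log: list[dict] = []
    kept_animals = set()
    for animal in sorted(by_animal):
        days = by_animal[animal]
        if "final_pre" not in days:
            raise ValueError(f"animal {animal!r} lacks a final_pre session")
        if animal not in lesion_present:
            raise ValueError(f"animal {animal!r} lacks a lesion-present flag")
        if not lesion_present[animal]:
            log.append({"animal_id": animal, "rule": "no_macroscopic_lesion"})
        elif score_session(days["final_pre"]) == 0:
            log.append({"animal_id": animal, "rule": "zero_final_pre_score"})
        else:
            kept_animals.add(animal)
    kept = [s for s in sessions if s.animal_id in kept_animals]
    return kept, log


def summarize_animals(sessions) -> list[SuccessSummary]:
    """Per-animal scores and baseline-normalized day-2/day-7 rates.

    Call after :func:`apply_exclusions`; every animal must have a
    positive final pre-intervention score and all three scored days.
    """
    by_animal = _sessions_by_animal(sessions)
    out = []
    for animal in sorted(by_animal):
        days = by_animal[animal]
        for day in ("final_pre", "day2", "day7"):
            if day not in days:
                raise ValueError(f"animal {animal!r} lacks a {day} session")
        base = score_session(days["final_pre"])
        d2 = score_session(days["day2"])
        d7 = score_session(days["day7"])
        out.append(
            SuccessSummary(
                animal_id=animal,
                arm=days["final_pre"].arm,
                score_final_pre=base,
                score_d2=d2,
                score_d7=d7,
                sr_d2_pct=success_rate(d2, base),
                sr_d7_pct=success_rate(d7, base),
            )
        )
    return out


def _metric_values(summaries, mode: str) -> dict[str, list[float]]:
    arms: dict[str, list[float]] = {"stim": [], "sham": []}
    for s in summaries:
        if mode == "sr_d7":
            v = s.sr_d7_pct
        elif mode == "d7_vs_d2_ratio":
            v = day7_vs_day2(s.sr_d7_pct, s.sr_d2_pct, "ratio")
        elif mode == "d7_vs_d2_difference":
            v = day7_vs_day2(s.sr_d7_pct, s.sr_d2_pct, "difference")
        else:
            raise ValueError(f"metric mode must be one of {METRIC_MODES}, got {mode!r}")
        if not math.isnan(v):
            arms[s.arm].append(v)
    return arms


def compare_arms(summaries, metric: str = "sr_d7", seed: int = 0) -> dict:
    """Mann-Whitney comparison of a success metric between arms.

    Animals whose metric is undefined (ratio mode with zero day-2
    success) are dropped from the test and counted in the report.

    Returns a dict with group sizes, means, medians, U and p.
    """
    summaries = list(summaries)
    arms = _metric_values(summaries, metric)
    n_total = {
        a: sum(1 for s in summaries if s.arm == a) for a in ("stim", "sham")
    }
    for arm, vals in arms.items():
        if len(vals) < 2:
            raise ValueError(
                f"arm {arm!r} has fewer than 2 animals with a defined metric"
            )
    u, p = mann_whitney_u(arms["stim"], arms["sham"], seed=seed)
    return {
        "metric": metric,
        "n_stim": len(arms["stim"]),
        "n_sham": len(arms["sham"]),
        "n_undefined_stim": n_total["stim"] - len(arms["stim"]),
        "n_undefined_sham": n_total["sham"] - len(arms["sham"]),
        "mean_stim": float(np.mean(arms["stim"])),
        "mean_sham": float(np.mean(arms["sham"])),
        "median_stim": float(np.median(arms["stim"])),
        "median_sham": float(np.median(arms["sham"])),
        "U": u,
        "p": p,
    }
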