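"""Breeding-bout detection, bout-to-luteal linkage, trial tables, and the
uniform-null chi-square fertility comparison.

A breeding bout is a maximal run of consecutive calendar days each containing
at least one confirmed coital act ("breeding" events; "attempt" events never
enter bout detection). The fertility comparison is a chi-square goodness-of-fit
of per-group counts against a uniform expectation (total/g per group, df =
g - 1, no continuity correction): for three groups this has the convenient
closed form p = exp(-chi2/2), so counts (3, 0, 0) give chi2 = 6 and
p = exp(-3) ~ 0.0498.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_model import (
    ContractError,
    GROUPS,
    StudyDesign,
    UndefinedTestError,
    ValidationError,
)

EVENT_TYPES = ("breeding", "attempt")


@dataclass(frozen=True)
class MatingEvent:
    """A scored male-female interaction: a confirmed intromission
    ("breeding") or a rebuffed/incomplete mount ("attempt")."""

    day: int
    female_id: str
    male_id: str
    event_type: str

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValidationError(f"unknown event_type {self.event_type!r}")


@dataclass(frozen=True)
class BreedingBout:
    """Maximal run of consecutive days with >= 1 breeding event (inclusive)."""

    female_id: str
    start_day: int
    end_day: int
    n_days: int


class ChisqResult(NamedTuple):
    chi2: float
    df: int
    p: float


def detect_bouts(
    events: Sequence[MatingEvent], female_id: str
) -> list[BreedingBout]:
    """Find the female's maximal consecutive-day breeding bouts.

    Attempts are ignored; multiple breedings on one day collapse to one day.
    """
    days = sorted(
        {e.day for e in events if e.female_id == female_id and e.event_type == "breeding"}
    )
    bouts: list[BreedingBout] = []
    i = 0
    while i < len(days):
        j = i
        while j + 1 < len(days) and days[j + 1] == days[j] + 1:
            j += 1
        bouts.append(
            BreedingBout(female_id, days[i], days[j], days[j] - days[i] + 1)
        )
        i = j + 1
    return bouts


def link_luteal(
    bouts: Sequence[BreedingBout],
    luteal_calls: Sequence,
    max_lag_days: int = 21,
) -> int:
    """Number of bouts followed by a luteal phase.

    A bout is "followed" iff some luteal call starts in
    ``(bout.end_day, bout.end_day + max_lag_days]``; each luteal call credits
    at most one bout — the nearest preceding one.
    """
    if max_lag_days <= 0:
        raise ContractError("max_lag_days must be > 0")
    females = {b.female_id for b in bouts}
    for c in luteal_calls:
        if c.phase_type != "luteal":
            raise ContractError("luteal linkage requires luteal-type phase calls")
        if females and c.animal_id not in females:
            raise ContractError(
                f"luteal call for {c.animal_id!r} does not match bout female(s)"
            )
    followed: set[int] = set()
    for c in sorted(luteal_calls, key=lambda c: c.start_day):
        candidates = [
            i
            for i, b in enumerate(bouts)
            if b.end_day < c.start_day <= b.end_day + max_lag_days
        ]
        if candidates:
            nearest = max(candidates, key=lambda i: bouts[i].end_day)
            followed.add(nearest)
    return len(followed)


def chisq_uniform(counts: Sequence[float]) -> ChisqResult:
    """Chi-square goodness-of-fit of per-group counts against a uniform null.

    expected = total/g for every group; chi2 = sum((O-E)^2/E); p is the
    upper tail of the chi-square distribution with g-1 df.
    """
    obs = np.asarray(counts, dtype=float)
    g = obs.size
    if g < 2:
        raise ContractError("need >= 2 groups")
    if np.any(obs < 0):
        raise ValidationError("counts must be non-negative")
    total = obs.sum()
    if total == 0:
        raise UndefinedTestError("chi-square undefined for zero total count")
    expected = total / g
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    df = g - 1
    return ChisqResult(chi2, df, float(stats.chi2.sf(chi2, df)))


@dataclass
class TrialTable:
    """Per-group mating-trial counts."""

    table: pd.DataFrame  # group, n_females_bred, n_bouts, n_luteal_after_bout,
    #                      n_pregnant, n_kittens
    tests: pd.DataFrame  # metric, counts, chi2, df, p, note


_METRICS = (
    "n_females_bred",
    "n_bouts",
    "n_luteal_after_bout",
    "n_pregnant",
    "n_kittens",
)


def build_trial_table(
    events: Sequence[MatingEvent],
    luteal_calls: Mapping[str, Sequence],
    kittens: Mapping[str, int],
    design: StudyDesign,
    trial_window: tuple[int, int],
    max_lag_days: int = 21,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate one mating trial into per-group counts and run the
    uniform-null chi-square on each count row.

    ``events`` must already be restricted to the trial window; ``kittens``
    maps conceiving females to litter size (a female with an entry counts as
    pregnant). Rows whose counts total zero carry NaN statistics and an
    explanatory note rather than aborting the trial.
    """
    w0, w1 = trial_window
    for e in events:
        if e.female_id not in design.groups:
            raise ContractError(f"female {e.female_id!r} absent from study design")
    for female in kittens:
        if female not in design.groups:
            raise ContractError(f"female {female!r} absent from study design")

    per_group = {g: dict.fromkeys(_METRICS, 0) for g in GROUPS}
    group_sizes = {g: sum(1 for a in design.groups.values() if a == g) for g in GROUPS}
    females = sorted({e.female_id for e in events} | set(kittens))
    for female in females:
        group = design.group_of(female)
        bouts = detect_bouts(events, female)
        calls = [
            c
            for c in luteal_calls.get(female, [])
            if w0 < c.start_day <= w1 + max_lag_days
        ]
        row = per_group[group]
        if bouts:
            row["n_females_bred"] += 1
            row["n_bouts"] += len(bouts)
            row["n_luteal_after_bout"] += link_luteal(bouts, calls, max_lag_days)
        n_kit = int(kittens.get(female, 0))
        if female in kittens:
            row["n_pregnant"] += 1
            row["n_kittens"] += n_kit

    for g in GROUPS:
        if per_group[g]["n_females_bred"] > group_sizes[g]:
            raise ContractError(f"more bred females than animals in group {g!r}")

    table = pd.DataFrame(
        [(g, *(per_group[g][m] for m in _METRICS)) for g in GROUPS],
        columns=["group", *_METRICS],
    )
    test_rows = []
    for metric in _METRICS:
        counts = tuple(per_group[g][metric] for g in GROUPS)
        try:
            chi2, df, p = chisq_uniform(counts)
            note = ""
        except UndefinedTestError as exc:
            chi2 = df = p = float("nan")
            note = str(exc)
        test_rows.append((metric, counts, chi2, df, p, note))
    tests = pd.DataFrame(
        test_rows, columns=["metric", "counts", "chi2", "df", "p", "note"]
    )
    return table, tests
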