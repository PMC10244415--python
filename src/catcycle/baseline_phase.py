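"""Iterative hormone-baseline estimation and run-length phase calling.

The baseline of a fecal metabolite series is estimated on the pre-treatment
window by iteratively excluding every retained point strictly greater than
mean + k*SD (sample SD, n-1 denominator) of the currently retained points,
until an iteration excludes nothing. Excluded points never re-enter. The
converged threshold is then applied to the whole series: an estrous phase is a
maximal run of >= 2 consecutive fecal samples with E2 strictly above the
threshold, a luteal phase a maximal run of >= 6 consecutive samples with P4
strictly above it. "Consecutive" means adjacent in collection order (sampling
is thrice weekly), and runs may not span an exclusion interval (pregnancy,
lactation, suspended collection).

Two threshold modes are supported: ``sd_above_mean`` (mean + k*SD) and
``fold_of_mean`` (k * mean); the latter exists because luteal elevation is
sometimes defined as a fold-change over the baseline mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_model import (
    ContractError,
    ExclusionInterval,
    HormoneSeries,
    InsufficientDataError,
    DegenerateWindowError,
    merge_intervals,
    overlap_days,
)

PHASE_TYPES = ("estrous", "luteal")


@dataclass
class BaselineFit:
    """Converged iterative baseline for one animal x analyte.

    ``retained_mask`` is a boolean over the samples of the baseline window in
    collection order; after convergence no retained value strictly exceeds
    ``threshold``.
    """

    animal_id: str
    analyte: str
    baseline_mean: float
    baseline_sd: float
    k: float
    mode: str
    threshold: float
    n_input: int
    n_retained: int
    n_iterations: int
    retained_mask: np.ndarray


@dataclass(frozen=True)
class PhaseCall:
    """A maximal run of consecutive above-threshold samples."""

    animal_id: str
    phase_type: str
    start_day: int
    end_day: int
    n_samples: int
    peak_value: float


@dataclass(frozen=True)
class PhaseFrequency:
    """Phase count in a window, normalized to phases per ``norm_days``."""

    animal_id: str
    phase_type: str
    window_name: str
    n_phases: int
    effective_days: int
    normalized: float


def _threshold(mean: float, sd: float, k: float, mode: str) -> float:
    if mode == "sd_above_mean":
        return mean + k * sd
    if mode == "fold_of_mean":
        return k * mean
    raise ContractError(f"unknown baseline mode {mode!r}")


def fit_baseline(
    series: HormoneSeries,
    window: tuple[int, int],
    k: float = 1.5,
    mode: str = "sd_above_mean",
) -> BaselineFit:
    """Iteratively estimate the non-elevated baseline of ``series`` on ``window``.

    Starting from all window samples, repeatedly compute the mean and sample
    SD of retained points and permanently exclude every retained point
    strictly greater than the threshold; stop when an iteration excludes
    nothing. Requires >= 3 samples in the window.
    """
    if k <= 0:
        raise ContractError("k must be > 0")
    sub = series.in_window(*window)
    values = sub.values
    n = values.size
    if n < 3:
        raise InsufficientDataError(
            f"baseline window [{window[0]}, {window[1]}) holds {n} samples "
            f"for {series.animal_id}/{series.analyte}; need >= 3"
        )
    retained = np.ones(n, dtype=bool)
    n_iter = 0
    while True:
        n_iter += 1
        vals = values[retained]
        if vals.size == 0:  # cannot happen for sd mode with k>0; fold mode guard
            raise InsufficientDataError(
                "iterative exclusion removed every baseline point "
                f"({series.animal_id}/{series.analyte}, mode={mode})"
            )
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        thr = _threshold(mean, sd, k, mode)
        drop = retained & (values > thr)
        if not drop.any():
            break
        retained &= ~drop
    return BaselineFit(
        animal_id=series.animal_id,
        analyte=series.analyte,
        baseline_mean=mean,
        baseline_sd=sd,
        k=float(k),
        mode=mode,
        threshold=thr,
        n_input=n,
        n_retained=int(retained.sum()),
        n_iterations=n_iter,
        retained_mask=retained,
    )


def _segments(
    days: np.ndarray, exclusions: Sequence[ExclusionInterval]
) -> np.ndarray:
    """Segment label per sample: increments whenever an exclusion interval lies
    between two consecutive retained samples (runs may not span it)."""
    seg = np.zeros(days.size, dtype=np.int64)
    if days.size == 0 or not exclusions:
        return seg
    bounds = merge_intervals([(e.start_day, e.end_day) for e in exclusions])
    label = 0
    for i in range(1, days.size):
        d0, d1 = int(days[i - 1]), int(days[i])
        if any(a < d1 and b > d0 for a, b in bounds):
            label += 1
        seg[i] = label
    return seg


def call_phases(
    series: HormoneSeries,
    fit: BaselineFit,
    phase_type: str,
    min_run: int,
    exclusions: Sequence[ExclusionInterval] = (),
) -> list[PhaseCall]:
    """Call maximal runs of consecutive samples strictly above ``fit.threshold``.

    Samples inside exclusion intervals are removed first; the remaining
    samples are segmented at exclusion boundaries and runs are found within
    each segment. Runs shorter than ``min_run`` are discarded; ties with the
    threshold count as baseline.
    """
    if phase_type not in PHASE_TYPES:
        raise ContractError(f"unknown phase type {phase_type!r}")
    if min_run < 1:
        raise ContractError("min_run must be >= 1")
    if (series.animal_id, series.analyte) != (fit.animal_id, fit.analyte):
        raise ContractError(
            f"series {series.animal_id}/{series.analyte} does not match "
            f"fit {fit.animal_id}/{fit.analyte}"
        )
    sub = series.drop_excluded(exclusions)
    if len(sub) == 0:
        return []
    above = sub.values > fit.threshold
    seg = _segments(sub.days, exclusions)
    calls: list[PhaseCall] = []
    i = 0
    n = len(sub)
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and above[j + 1] and seg[j + 1] == seg[i]:
            j += 1
        if j - i + 1 >= min_run:
            calls.append(
                PhaseCall(
                    animal_id=series.animal_id,
                    phase_type=phase_type,
                    start_day=int(sub.days[i]),
                    end_day=int(sub.days[j]),
                    n_samples=j - i + 1,
                    peak_value=float(sub.values[i : j + 1].max()),
                )
            )
        i = j + 1
    return calls


def phase_frequency(
    calls: Sequence[PhaseCall],
    window: tuple[int, int],
    exclusions: Sequence[ExclusionInterval],
    norm_days: int,
    animal_id: str | None = None,
    phase_type: str | None = None,
    window_name: str = "",
) -> PhaseFrequency:
    """Count calls starting in ``window`` and normalize per ``norm_days``.

    ``effective_days`` is the window length minus its overlap with exclusion
    intervals; ``normalized = n_phases / effective_days * norm_days``.
    """
    w0, w1 = int(window[0]), int(window[1])
    if w0 >= w1:
        raise DegenerateWindowError(f"degenerate window [{w0}, {w1})")
    if calls:
        ids = {c.animal_id for c in calls}
        kinds = {c.phase_type for c in calls}
        if len(ids) > 1 or len(kinds) > 1:
            raise ContractError("calls must share one animal and one phase type")
        animal_id = animal_id or next(iter(ids))
        phase_type = phase_type or next(iter(kinds))
    excluded = overlap_days(
        (w0, w1), [(e.start_day, e.end_day) for e in exclusions]
    )
    effective = (w1 - w0) - excluded
    if effective <= 0:
        raise DegenerateWindowError(
            f"window [{w0}, {w1}) has no effective days after exclusions"
        )
    n = sum(1 for c in calls if w0 <= c.start_day < w1)
    return PhaseFrequency(
        animal_id=animal_id or "",
        phase_type=phase_type or "",
        window_name=window_name,
        n_phases=n,
        effective_days=effective,
        normalized=n / effective * norm_days,
    )


def amh_threshold_compliance(
    series: HormoneSeries, target: float, treatment_day: int = 0
) -> tuple[float, bool]:
    """Fraction of post-treatment serum AMH samples >= ``target`` and a flag
    that is true iff every post-treatment sample meets the target."""
    if series.analyte != "AMH_serum":
        raise ContractError(
            f"AMH compliance requires an AMH_serum series, got {series.analyte!r}"
        )
    post = series.values[series.days >= treatment_day]
    if post.size == 0:
        raise InsufficientDataError(
            f"no post-treatment AMH samples for {series.animal_id}"
        )
    ok = post >= target
    return float(ok.mean()), bool(ok.all())


def match_calls_to_windows(
    calls: Sequence[PhaseCall], windows: Sequence[tuple[int, int]]
) -> tuple[int, int]:
    """Match phase calls against ground-truth half-open day windows by overlap.

    Returns (number of truth windows overlapped by at least one call, number
    of calls overlapping at least one truth window). A call spans the closed
    day interval [start_day, end_day].
    """
    def overlaps(c: PhaseCall, w: tuple[int, int]) -> bool:
        return c.start_day < w[1] and c.end_day >= w[0]

    hit_windows = sum(1 for w in windows if any(overlaps(c, w) for c in calls))
    true_calls = sum(1 for c in calls if any(overlaps(c, w) for w in windows))
    return hit_windows, true_calls
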