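"""Stochastic simulator of an induced-ovulator feline cohort.

The domestic cat is an induced ovulator: ovulation is normally triggered by
copulation, though spontaneous ovulation is well documented, particularly in
group-housed females. The simulator runs a per-animal renewal state machine:

    interestrous gap -> estrus (E2 elevated a few days) -> either
      * ovulation (induced by a mating bout, or spontaneous), starting a
        luteal window of sustained P4 elevation lasting several weeks —
        gestation-length if conception occurred, followed by lactation; or
      * no ovulation, and the next estrus follows after an interestrous
        interval draw.

Fecal E2 and P4 are sampled on three fixed weekdays per week as
baseline-times-fold-change levels with multiplicative lognormal noise: E2 is
elevated during estrus windows, P4 during luteal windows (including the
luteal window that spans a gestation). Pregnancy and lactation produce
exclusion intervals exactly covering them, mirroring the suspension of those
periods from analysis. Treatment effects (suppressed ovulation probability,
reduced mating receptivity, damped luteal P4 amplitude) act on the dose
groups from day 0; before treatment every animal behaves like a control.

Mating occurs only during estrus windows that intersect a mating-trial
window, with at most one bout (1-4 consecutive days, >= 1 coital act per day)
per estrus. Per-animal RNG substreams are derived from (master_seed,
animal_index), so growing the cohort does not reshuffle existing animals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .io_model import (
    ExclusionInterval,
    GROUPS,
    HormoneSeries,
    StudyDesign,
    ValidationError,
    write_birth_table,
    write_design,
    write_event_log,
    write_exclusion_table,
    write_hormone_table,
)
from .mating_trial import MatingEvent


def _default_p_ovulation() -> dict[str, float]:
    # treated groups: induced ovulation strongly suppressed post-treatment
    return {"control": 0.9, "low_dose": 0.15, "high_dose": 0.05}


def _default_p_spontaneous() -> dict[str, float]:
    # per-estrus spontaneous ovulation; kept modest so that the 6-month
    # baseline window stays baseline-dominated (the operating assumption of
    # the iterative mean + k*SD threshold)
    return {"control": 0.05, "low_dose": 0.02, "high_dose": 0.01}


def _default_p_mating() -> dict[str, float]:
    # probability a female accepts a bout during an estrus inside a trial
    return {"control": 0.9, "low_dose": 0.3, "high_dose": 0.15}


def _default_p4_scale() -> dict[str, float]:
    # post-treatment damping of luteal P4 amplitude in dose groups
    return {"control": 1.0, "low_dose": 0.7, "high_dose": 0.5}


@dataclass
class SimConfig:
    """Simulation parameters; defaults emulate the 9-cat, 30-month layout:
    180 pre-treatment days, treatment at day 0, and two 4-month mating trials
    beginning 8 and 20 months post-treatment."""

    n_per_group: int = 3
    study_days: int = 900  # covers [-pre_days, study_days - pre_days)
    pre_days: int = 180
    sampling_weekdays: tuple[int, ...] = (0, 2, 4)  # thrice weekly, fixed days
    e2_baseline: float = 50.0  # ng/g dry feces
    e2_sigma: float = 0.25  # lognormal sigma (multiplicative noise)
    e2_estrus_fold: tuple[float, float] = (2.5, 4.0)  # drawn per estrus window
    estrus_duration: tuple[int, int] = (5, 7)  # days, inclusive bounds
    interestrous_interval: tuple[int, int] = (14, 21)
    p4_baseline: float = 500.0  # ng/g dry feces
    p4_sigma: float = 0.25
    p4_luteal_fold: tuple[float, float] = (4.0, 9.0)  # drawn per luteal window
    luteal_duration: tuple[int, int] = (30, 45)  # non-pregnant, days
    gestation_days: int = 65
    lactation_days: int = 56
    p_ovulation_given_mating: dict[str, float] = field(
        default_factory=_default_p_ovulation
    )
    p_spontaneous_ovulation: dict[str, float] = field(
        default_factory=_default_p_spontaneous
    )
    p_conception: float = 0.9
    p_mating_given_estrus: dict[str, float] = field(default_factory=_default_p_mating)
    p_attempt_given_estrus: float = 0.3  # rebuffed approach when no bout occurs
    p4_fold_scale: dict[str, float] = field(default_factory=_default_p4_scale)
    bout_days: tuple[int, int] = (1, 4)
    litter_size: tuple[int, int] = (2, 4)
    trial_windows: tuple[tuple[int, int], ...] = ((240, 360), (600, 720))
    suspend_windows: tuple[tuple[int, int], ...] = ()
    treatment_day: int = 0
    master_seed: int = 0

    def __post_init__(self) -> None:
        for m in (
            self.p_ovulation_given_mating,
            self.p_spontaneous_ovulation,
            self.p_mating_given_estrus,
            self.p4_fold_scale,
        ):
            if set(m) != set(GROUPS):
                raise ValidationError(f"group map must cover {GROUPS}, got {set(m)}")
        probs = (
            list(self.p_ovulation_given_mating.values())
            + list(self.p_spontaneous_ovulation.values())
            + list(self.p_mating_given_estrus.values())
            + [self.p_conception, self.p_attempt_given_estrus]
        )
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValidationError("probabilities must lie in [0, 1]")
        for lo, hi in (
            self.estrus_duration,
            self.interestrous_interval,
            self.luteal_duration,
            self.bout_days,
            self.litter_size,
        ):
            if lo <= 0 or hi < lo:
                raise ValidationError("duration bounds must be positive and ordered")
        for lo, hi in (self.e2_estrus_fold, self.p4_luteal_fold):
            if lo <= 1.0 or hi < lo:
                raise ValidationError("fold-elevation bounds must be > 1 and ordered")
        if self.study_days <= 0 or self.pre_days < 0:
            raise ValidationError("study_days must be positive")

    @property
    def start_day(self) -> int:
        return -self.pre_days

    @property
    def end_day(self) -> int:
        return self.study_days - self.pre_days


@dataclass
class AnimalTruth:
    """Ground-truth event windows for one simulated animal (half-open days)."""

    estrus_windows: list[tuple[int, int]] = field(default_factory=list)
    estrus_folds: list[float] = field(default_factory=list)  # parallel to windows
    ovulations: list[tuple[int, str]] = field(default_factory=list)  # (day, cause)
    luteal_windows: list[tuple[int, int]] = field(default_factory=list)
    luteal_folds: list[float] = field(default_factory=list)  # parallel to windows
    pregnancy_windows: list[tuple[int, int]] = field(default_factory=list)
    lactation_windows: list[tuple[int, int]] = field(default_factory=list)
    mating_days: list[int] = field(default_factory=list)
    attempt_days: list[int] = field(default_factory=list)
    litters: list[tuple[int, int]] = field(default_factory=list)  # (conception, kittens)


@dataclass
class SimTruth:
    """Per-animal ground truth for detector validation."""

    animals: dict[str, AnimalTruth] = field(default_factory=dict)

    def __getitem__(self, animal_id: str) -> AnimalTruth:
        return self.animals[animal_id]


def animal_ids(config: SimConfig) -> list[str]:
    prefix = {"control": "ctl", "low_dose": "low", "high_dose": "high"}
    return [
        f"{prefix[g]}{i + 1}" for g in GROUPS for i in range(config.n_per_group)
    ]


def group_map(config: SimConfig) -> dict[str, str]:
    ids = animal_ids(config)
    return {
        a: g
        for a, g in zip(ids, [g for g in GROUPS for _ in range(config.n_per_group)])
    }


def _rng_for(
    config: SimConfig, group_index: int, within_index: int
) -> np.random.Generator:
    # substream keyed on (master_seed, group, animal-within-group): growing the
    # cohort or adding groups never reshuffles existing animals
    return np.random.default_rng([config.master_seed, group_index, within_index])


def _ranged_int(rng: np.random.Generator, bounds: tuple[int, int]) -> int:
    return int(rng.integers(bounds[0], bounds[1] + 1))


def _simulate_animal(
    config: SimConfig, group: str, rng: np.random.Generator
) -> AnimalTruth:
    truth = AnimalTruth()
    end = config.end_day
    t = config.start_day + _ranged_int(rng, (0, config.interestrous_interval[1]))
    while t < end:
        effective = group if t >= config.treatment_day else "control"
        dur = _ranged_int(rng, config.estrus_duration)
        estrus = (t, min(t + dur, end))
        truth.estrus_windows.append(estrus)
        truth.estrus_folds.append(float(rng.uniform(*config.e2_estrus_fold)))

        # mating: at most one bout per estrus, inside a trial window
        bout_end: int | None = None
        overlap = None
        for w in config.trial_windows:
            a, b = max(estrus[0], w[0]), min(estrus[1], w[1])
            if a < b:
                overlap = (a, b)
                break
        if overlap is not None:
            if rng.random() < config.p_mating_given_estrus[effective]:
                b_start = int(rng.integers(overlap[0], overlap[1]))
                b_len = _ranged_int(rng, config.bout_days)
                days = range(b_start, min(b_start + b_len, overlap[1]))
                truth.mating_days.extend(days)
                bout_end = max(days)
            elif rng.random() < config.p_attempt_given_estrus:
                # rebuffed approach without intromission
                truth.attempt_days.append(int(rng.integers(overlap[0], overlap[1])))

        # ovulation: induced by mating, else possibly spontaneous
        ov_day: int | None = None
        cause = ""
        if bout_end is not None and (
            rng.random() < config.p_ovulation_given_mating[effective]
        ):
            ov_day, cause = bout_end + 1, "induced"
        elif rng.random() < config.p_spontaneous_ovulation[effective]:
            ov_day, cause = t + dur, "spontaneous"

        if ov_day is not None and ov_day < end:
            truth.ovulations.append((ov_day, cause))
            conceive = (
                cause == "induced" and rng.random() < config.p_conception
            )
            fold = float(rng.uniform(*config.p4_luteal_fold))
            if conceive:
                g_end = min(ov_day + config.gestation_days, end)
                l_end = min(ov_day + config.gestation_days + config.lactation_days, end)
                truth.luteal_windows.append((ov_day, g_end))
                truth.luteal_folds.append(fold)
                truth.pregnancy_windows.append((ov_day, g_end))
                if g_end > ov_day + config.gestation_days - 1:
                    truth.litters.append(
                        (ov_day, _ranged_int(rng, config.litter_size))
                    )
                if l_end > g_end:
                    truth.lactation_windows.append((g_end, l_end))
                resume = ov_day + config.gestation_days + config.lactation_days
            else:
                l_dur = _ranged_int(rng, config.luteal_duration)
                truth.luteal_windows.append((ov_day, min(ov_day + l_dur, end)))
                truth.luteal_folds.append(fold)
                resume = ov_day + l_dur
        else:
            resume = t + dur
        t = resume + _ranged_int(rng, config.interestrous_interval)
    return truth


def _scheduled_days(config: SimConfig) -> np.ndarray:
    days = np.arange(config.start_day, config.end_day)
    # weekday anchored so that day 0 is weekday 0
    keep = np.isin(days % 7, np.asarray(config.sampling_weekdays) % 7)
    days = days[keep]
    for a, b in config.suspend_windows:
        days = days[(days < a) | (days >= b)]
    return days


def _in_any(day_arr: np.ndarray, windows: Sequence[tuple[int, int]]) -> np.ndarray:
    hit = np.zeros(day_arr.size, dtype=bool)
    for a, b in windows:
        hit |= (day_arr >= a) & (day_arr < b)
    return hit


def simulate_cohort(
    config: SimConfig,
) -> tuple[
    list[HormoneSeries],
    list[MatingEvent],
    dict[str, list[ExclusionInterval]],
    SimTruth,
]:
    """Simulate hormone series, mating events, exclusion intervals and ground
    truth for a full cohort. Deterministic given ``config.master_seed``."""
    ids = animal_ids(config)
    groups = group_map(config)
    schedule = _scheduled_days(config)
    series: list[HormoneSeries] = []
    events: list[MatingEvent] = []
    exclusions: dict[str, list[ExclusionInterval]] = {}
    truth = SimTruth()

    for idx, animal in enumerate(ids):
        rng = _rng_for(config, idx // config.n_per_group, idx % config.n_per_group)
        at = _simulate_animal(config, groups[animal], rng)
        truth.animals[animal] = at

        # hormone series on the sampling schedule
        e2 = np.full(schedule.size, config.e2_baseline)
        for (a, b), fold in zip(at.estrus_windows, at.estrus_folds):
            e2[(schedule >= a) & (schedule < b)] *= fold
        p4 = np.full(schedule.size, config.p4_baseline)
        for (a, b), fold in zip(at.luteal_windows, at.luteal_folds):
            scale = (
                config.p4_fold_scale[groups[animal]]
                if a >= config.treatment_day
                else 1.0
            )
            p4[(schedule >= a) & (schedule < b)] *= fold * scale
        e2 *= rng.lognormal(0.0, config.e2_sigma, size=schedule.size)
        p4 *= rng.lognormal(0.0, config.p4_sigma, size=schedule.size)
        series.append(
            HormoneSeries(animal, "E2_fecal", schedule.copy(), e2, "ng/g dry feces")
        )
        series.append(
            HormoneSeries(animal, "P4_fecal", schedule.copy(), p4, "ng/g dry feces")
        )

        # exclusions exactly cover pregnancy + lactation
        exs = [
            ExclusionInterval(a, b, "pregnancy") for a, b in at.pregnancy_windows
        ] + [
            ExclusionInterval(a, b, "lactation") for a, b in at.lactation_windows
        ]
        exs += [
            ExclusionInterval(a, b, "collection_suspended")
            for a, b in config.suspend_windows
        ]
        exclusions[animal] = sorted(exs, key=lambda e: e.start_day)

        # mating events: one breeding record per bout day, plus rebuffed attempts
        def _male(d: int) -> str:
            for i, (a, b) in enumerate(config.trial_windows):
                if a <= d < b:
                    return f"male{i + 1}"
            return "male1"

        for d in at.mating_days:
            events.append(MatingEvent(int(d), animal, _male(d), "breeding"))
        for d in at.attempt_days:
            events.append(MatingEvent(int(d), animal, _male(d), "attempt"))

    events.sort(key=lambda e: (e.day, e.female_id, e.event_type))
    return series, events, exclusions, truth


def sim_design(config: SimConfig) -> StudyDesign:
    """Study design matching a simulated cohort (groups, default periods,
    trial windows, and the simulator's exclusion intervals)."""
    _, _, exclusions, _ = simulate_cohort(config)
    return StudyDesign(
        groups=group_map(config),
        treatment_day=config.treatment_day,
        trial_windows=config.trial_windows,
        exclusions=exclusions,
    )


def truth_phase_counts(
    truth: SimTruth, window: tuple[int, int]
) -> dict[str, dict[str, int]]:
    """Per-animal counts of estrus and luteal events whose start day lies in
    the half-open ``window``."""
    w0, w1 = int(window[0]), int(window[1])
    if w0 >= w1:
        raise ValidationError(f"degenerate window [{w0}, {w1})")
    out: dict[str, dict[str, int]] = {}
    for animal, at in truth.animals.items():
        out[animal] = {
            "estrus": sum(1 for a, _ in at.estrus_windows if w0 <= a < w1),
            "luteal": sum(1 for a, _ in at.luteal_windows if w0 <= a < w1),
        }
    return out


def detectable_windows(
    windows: Sequence[tuple[int, int]],
    schedule: np.ndarray,
    exclusions: Sequence[ExclusionInterval],
    min_run: int,
) -> list[tuple[int, int]]:
    """Truth windows containing at least ``min_run`` scheduled, non-excluded
    sampling days — the windows a run-length detector can possibly call."""
    out = []
    for a, b in windows:
        m = (schedule >= a) & (schedule < b)
        days = schedule[m]
        for ex in exclusions:
            days = days[(days < ex.start_day) | (days >= ex.end_day)]
        if days.size >= min_run:
            out.append((a, b))
    return out


def schedule_for(config: SimConfig) -> np.ndarray:
    """The cohort's shared sampling-day schedule."""
    return _scheduled_days(config)


def births_from_truth(truth: SimTruth) -> list[tuple[str, int, int]]:
    """(female, conception_day, kittens) records for every completed litter."""
    return [
        (animal, day, kittens)
        for animal, at in sorted(truth.animals.items())
        for day, kittens in at.litters
    ]


def write_cohort(config: SimConfig, out_dir: str | Path) -> None:
    """Simulate and write hormones.csv, events.csv, exclusions.csv,
    births.csv, truth.csv, and design.yaml to ``out_dir``."""
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    series, events, exclusions, truth = simulate_cohort(config)
    write_hormone_table(series, out_dir / "hormones.csv")
    write_event_log(events, out_dir / "events.csv")
    write_exclusion_table(exclusions, out_dir / "exclusions.csv")
    write_birth_table(births_from_truth(truth), out_dir / "births.csv")
    design = StudyDesign(
        groups=group_map(config),
        treatment_day=config.treatment_day,
        trial_windows=config.trial_windows,
        exclusions=exclusions,
    )
    write_design(design, out_dir / "design.yaml")
    rows = []
    for animal in sorted(truth.animals):
        at = truth.animals[animal]
        for a, b in at.estrus_windows:
            rows.append((animal, "estrus", a, b, ""))
        for a, b in at.luteal_windows:
            rows.append((animal, "luteal", a, b, ""))
        for a, b in at.pregnancy_windows:
            rows.append((animal, "pregnancy", a, b, ""))
        for a, b in at.lactation_windows:
            rows.append((animal, "lactation", a, b, ""))
        for d, cause in at.ovulations:
            rows.append((animal, "ovulation", d, d, cause))
        for d in at.mating_days:
            rows.append((animal, "mating", d, d, ""))
    pd.DataFrame(
        rows, columns=["animal_id", "kind", "start_day", "end_day", "detail"]
    ).to_csv(out_dir / "truth.csv", index=False, lineterminator="\n")


def detector_performance(
    config: SimConfig,
    k: float = 1.5,
    mode: str = "sd_above_mean",
    baseline_window: tuple[int, int] | None = None,
) -> dict[str, dict[str, float]]:
    """Validate the phase caller against simulator ground truth.

    Simulates a cohort, fits per-animal baselines on the pre-treatment window
    and calls phases, then scores them per analyte:

    - ``sensitivity`` / ``specificity``: sample-level true/false positive
      rates (a sample is truth-positive iff it falls inside a truth window,
      predicted-positive iff covered by a call);
    - ``event_sensitivity``: fraction of detectable truth windows (>= min_run
      scheduled non-excluded samples) overlapped by a call;
    - ``event_precision``: fraction of calls overlapping any truth window;
    - ``n_true_events`` / ``n_calls``: event counts.
    """
    from .baseline_phase import call_phases, fit_baseline, match_calls_to_windows

    if baseline_window is None:
        baseline_window = (config.start_day, config.treatment_day)
    series, _, exclusions, truth = simulate_cohort(config)
    schedule = _scheduled_days(config)
    out: dict[str, dict[str, float]] = {}
    for phase, analyte, min_run, attr in (
        ("estrous", "E2_fecal", 2, "estrus_windows"),
        ("luteal", "P4_fecal", 6, "luteal_windows"),
    ):
        tp = fp = tn = fn = 0
        hit_w = n_w = n_c = true_c = 0
        for s in (x for x in series if x.analyte == analyte):
            at = truth[s.animal_id]
            exs = exclusions[s.animal_id]
            fit = fit_baseline(s, baseline_window, k, mode)
            calls = call_phases(s, fit, phase, min_run, exs)
            windows = getattr(at, attr)
            det = detectable_windows(windows, schedule, exs, min_run)
            hw, _ = match_calls_to_windows(calls, det)
            _, tc = match_calls_to_windows(calls, windows)
            hit_w += hw
            n_w += len(det)
            n_c += len(calls)
            true_c += tc
            days = s.drop_excluded(exs).days
            truth_pos = _in_any(days, windows)
            pred_pos = np.zeros(days.size, dtype=bool)
            for c in calls:
                pred_pos |= (days >= c.start_day) & (days <= c.end_day)
            tp += int((truth_pos & pred_pos).sum())
            fp += int((~truth_pos & pred_pos).sum())
            tn += int((~truth_pos & ~pred_pos).sum())
            fn += int((truth_pos & ~pred_pos).sum())
        out[phase] = {
            "sensitivity": tp / (tp + fn) if tp + fn else 1.0,
            "specificity": tn / (tn + fp) if tn + fp else 1.0,
            "event_sensitivity": hit_w / n_w if n_w else 1.0,
            "event_precision": true_c / n_c if n_c else 1.0,
            "n_true_events": n_w,
            "n_calls": n_c,
        }
    return out


def with_noise(config: SimConfig, sigma: float) -> SimConfig:
    """Copy of ``config`` with both analytes' noise set to ``sigma``."""
    return replace(config, e2_sigma=sigma, p4_sigma=sigma)
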