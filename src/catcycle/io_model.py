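"""Data model, file formats, configuration, and the pipeline driver.

Time is expressed as integer day offsets from the treatment day (day 0 =
injection). Hormone concentrations are non-negative reals in the units the
assay reports (ng/g dry feces for fecal metabolites, ug/ml or ng/ml for serum
analytes); units are carried through but never converted. All tabular formats
are comma-separated text with fixed headers, and all period/exclusion windows
are half-open ``[start, end)`` day intervals.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("catcycle")

#: Recognised analyte labels. Fecal metabolites drive phase calling; serum
#: analytes are carried for period comparisons and threshold-compliance checks.
ANALYTES = frozenset(
    {
        "E2_fecal",
        "P4_fecal",
        "AMH_serum",
        "LH_serum",
        "INHA_serum",
        "INHB_serum",
        "FST_serum",
        "T_serum",
        "CNP_serum",
    }
)

#: Treatment group labels, in display order.
GROUPS = ("control", "low_dose", "high_dose")

EXCLUSION_REASONS = frozenset({"pregnancy", "lactation", "collection_suspended"})


# ---------------------------------------------------------------------------
# errors
# ---------------------------------------------------------------------------


class CatcycleError(Exception):
    """Base class for all package errors."""


class ParseError(CatcycleError):
    """A delimited input file could not be parsed (names the offending line)."""


class ValidationError(CatcycleError):
    """Input violated a data-model invariant."""


class ContractError(CatcycleError):
    """An operation was called with mismatched or out-of-contract arguments."""


class InsufficientDataError(CatcycleError):
    """Too few samples to carry out the requested estimate."""


class DegenerateWindowError(CatcycleError):
    """A window had no effective (non-excluded) days."""


class DegenerateVarianceError(CatcycleError):
    """A variance needed by a test statistic is exactly zero."""


class UndefinedTestError(CatcycleError):
    """A test is undefined for the given counts (e.g. zero total)."""


class UnbalancedDesignError(CatcycleError):
    """The block design is incomplete (an animal misses a period)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExclusionInterval:
    """Half-open day interval removed from analysis (pregnancy, lactation,
    or suspended sample collection)."""

    start_day: int
    end_day: int
    reason: str

    def __post_init__(self) -> None:
        if self.start_day >= self.end_day:
            raise ValidationError(
                f"exclusion interval must satisfy start < end, got "
                f"[{self.start_day}, {self.end_day})"
            )
        if self.reason not in EXCLUSION_REASONS:
            raise ValidationError(f"unknown exclusion reason {self.reason!r}")

    def contains(self, day: int) -> bool:
        return self.start_day <= day < self.end_day


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge possibly-overlapping half-open intervals into a disjoint sorted list."""
    ivs = sorted((int(a), int(b)) for a, b in intervals)
    merged: list[tuple[int, int]] = []
    for a, b in ivs:
        if merged and a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return merged


def overlap_days(window: tuple[int, int], intervals: Iterable[tuple[int, int]]) -> int:
    """Total number of days of ``window`` covered by ``intervals`` (merged first)."""
    w0, w1 = window
    total = 0
    for a, b in merge_intervals(intervals):
        total += max(0, min(b, w1) - max(a, w0))
    return total


@dataclass
class HormoneSeries:
    """One animal x one analyte irregularly sampled concentration series.

    ``days`` are integer offsets from treatment day 0 and must be strictly
    increasing; ``values`` are non-negative concentrations. Missing samples are
    simply absent records, never placeholders.
    """

    animal_id: str
    analyte: str
    days: np.ndarray
    values: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.analyte not in ANALYTES:
            raise ValidationError(f"unknown analyte {self.analyte!r}")
        if self.days.shape != self.values.shape or self.days.ndim != 1:
            raise ValidationError("days and values must be 1-d arrays of equal length")
        if self.days.size > 1 and not np.all(np.diff(self.days) > 0):
            raise ValidationError(
                f"collection days must be strictly increasing for "
                f"{self.animal_id}/{self.analyte}"
            )
        if np.any(self.values < 0):
            raise ValidationError(
                f"negative concentration in series {self.animal_id}/{self.analyte}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError(
                f"non-finite concentration in series {self.animal_id}/{self.analyte}"
            )

    def __len__(self) -> int:
        return int(self.days.size)

    def in_window(self, start: int, end: int) -> "HormoneSeries":
        """Sub-series with ``start <= day < end``."""
        m = (self.days >= start) & (self.days < end)
        return HormoneSeries(
            self.animal_id, self.analyte, self.days[m], self.values[m], self.units
        )

    def drop_excluded(self, exclusions: Sequence[ExclusionInterval]) -> "HormoneSeries":
        """Sub-series with samples inside any exclusion interval removed."""
        if not exclusions:
            return self
        keep = np.ones(len(self), dtype=bool)
        for ex in exclusions:
            keep &= ~((self.days >= ex.start_day) & (self.days < ex.end_day))
        return HormoneSeries(
            self.animal_id, self.analyte, self.days[keep], self.values[keep], self.units
        )


def _default_periods() -> dict[str, tuple[int, int]]:
    # 30-day "months": 6-month pre-treatment, 2-month transition, 22-month post
    return {
        "pre_treatment": (-180, 0),
        "transition": (0, 60),
        "post_treatment": (60, 720),
    }


@dataclass
class StudyDesign:
    """Group assignments, treatment day, analysis periods, mating-trial windows
    and per-animal exclusion intervals."""

    groups: dict[str, str]
    treatment_day: int = 0
    periods: dict[str, tuple[int, int]] = field(default_factory=_default_periods)
    trial_windows: tuple[tuple[int, int], ...] = ((240, 360), (600, 720))
    exclusions: dict[str, list[ExclusionInterval]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for animal, group in self.groups.items():
            if group not in GROUPS:
                raise ValidationError(f"unknown group {group!r} for animal {animal!r}")
        spans = sorted(self.periods.values())
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            if a1 > b0:
                raise ValidationError("period windows must be disjoint and ordered")
        for name, (a, b) in self.periods.items():
            if a >= b:
                raise ValidationError(f"degenerate period {name!r}: [{a}, {b})")

    def period(self, name: str) -> tuple[int, int]:
        try:
            return self.periods[name]
        except KeyError:
            raise ContractError(f"unknown period {name!r}") from None

    def exclusions_for(self, animal_id: str) -> list[ExclusionInterval]:
        return self.exclusions.get(animal_id, [])

    def group_of(self, animal_id: str) -> str:
        try:
            return self.groups[animal_id]
        except KeyError:
            raise ContractError(f"animal {animal_id!r} not in study design") from None


@dataclass
class AnalysisConfig:
    """Tunable analysis parameters.

    ``baseline_multiplier`` (k) and ``baseline_mode`` define the elevation
    threshold: mean + k*SD of retained baseline points (``sd_above_mean``) or
    k * mean (``fold_of_mean``). Run lengths and normalization constants follow
    the operational phase definitions: an estrous phase is >=2 consecutive
    elevated fecal E2 samples (reported per 30 days), a luteal phase >=6
    consecutive elevated fecal P4 samples (reported per 180 days).
    """

    baseline_multiplier: float = 1.5
    baseline_mode: str = "sd_above_mean"
    luteal_mode: str = "sd_above_mean"  # Methods wording; fold_of_mean also supported
    estrous_min_run: int = 2
    luteal_min_run: int = 6
    estrous_norm_days: int = 30
    luteal_norm_days: int = 180
    baseline_window: str = "pre_treatment"
    amh_target: float = 0.25  # ug/ml
    max_lag_days: int = 21  # bout -> luteal linkage window
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_multiplier <= 0:
            raise ValidationError("baseline_multiplier must be > 0")
        for mode in (self.baseline_mode, self.luteal_mode):
            if mode not in ("sd_above_mean", "fold_of_mean"):
                raise ValidationError(f"unknown baseline mode {mode!r}")
        if self.estrous_min_run < 1 or self.luteal_min_run < 1:
            raise ValidationError("min_run values must be >= 1")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_HORMONE_COLS = ["animal_id", "analyte", "day", "value", "units"]
_EVENT_COLS = ["day", "female_id", "male_id", "event_type"]
_EXCLUSION_COLS = ["animal_id", "start_day", "end_day", "reason"]
_BIRTH_COLS = ["female_id", "conception_day", "kittens"]


def _read_csv(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.ParserError as exc:  # malformed row: pandas names the line
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    return df


def _numeric(df: pd.DataFrame, col: str, path: Path) -> pd.Series:
    out = pd.to_numeric(df[col], errors="coerce")
    bad = out.isna() & df[col].notna()
    if df[col].isna().any():
        line = int(df.index[df[col].isna()][0]) + 2  # header is line 1
        raise ParseError(f"{path}: empty {col!r} field at line {line}")
    if bad.any():
        line = int(df.index[bad][0]) + 2
        raise ParseError(f"{path}: non-numeric {col!r} at line {line}")
    return out


def read_hormone_table(path: str | Path) -> list[HormoneSeries]:
    """Read a hormone CSV (animal_id, analyte, day, value, units) into one
    :class:`HormoneSeries` per (animal, analyte), rows sorted by day.

    Raises :class:`ParseError` for malformed rows (naming the line number) and
    :class:`ValidationError` for negative values or duplicate sample days.
    """
    path = Path(path)
    df = _read_csv(path, _HORMONE_COLS)
    if df.empty:
        return []
    df["day"] = _numeric(df, "day", path).astype(np.int64)
    df["value"] = _numeric(df, "value", path)
    if (df["value"] < 0).any():
        line = int(df.index[df["value"] < 0][0]) + 2
        raise ValidationError(f"{path}: negative value at line {line}")
    dup = df.duplicated(subset=["animal_id", "analyte", "day"], keep=False)
    if dup.any():
        row = df[dup].iloc[0]
        raise ValidationError(
            f"{path}: duplicate sample day {row['day']} for "
            f"{row['animal_id']}/{row['analyte']}"
        )
    series: list[HormoneSeries] = []
    for (animal, analyte), g in df.groupby(["animal_id", "analyte"], sort=True):
        g = g.sort_values("day")
        units = g["units"].astype(str).unique()
        if len(units) > 1:
            raise ValidationError(
                f"{path}: conflicting units {list(units)} for {animal}/{analyte}"
            )
        series.append(
            HormoneSeries(
                str(animal),
                str(analyte),
                g["day"].to_numpy(),
                g["value"].to_numpy(),
                str(units[0]),
            )
        )
    return series


def write_hormone_table(series: Iterable[HormoneSeries], path: str | Path) -> None:
    rows = []
    for s in series:
        for d, v in zip(s.days, s.values):
            rows.append((s.animal_id, s.analyte, int(d), float(v), s.units))
    df = pd.DataFrame(rows, columns=_HORMONE_COLS)
    df.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")


def read_event_log(path: str | Path) -> list:
    """Read a mating-event CSV (day, female_id, male_id, event_type) into
    :class:`~catcycle.mating_trial.MatingEvent` records sorted by day."""
    from .mating_trial import MatingEvent  # local import avoids a module cycle

    path = Path(path)
    df = _read_csv(path, _EVENT_COLS)
    if df.empty:
        return []
    df["day"] = _numeric(df, "day", path).astype(np.int64)
    bad = ~df["event_type"].isin(["breeding", "attempt"])
    if bad.any():
        row = df[bad].iloc[0]
        raise ValidationError(f"{path}: unknown event_type {row['event_type']!r}")
    df = df.sort_values(["day", "female_id", "male_id"], kind="stable")
    return [
        MatingEvent(int(r.day), str(r.female_id), str(r.male_id), str(r.event_type))
        for r in df.itertuples()
    ]


def write_event_log(events: Iterable, path: str | Path) -> None:
    rows = [(e.day, e.female_id, e.male_id, e.event_type) for e in events]
    pd.DataFrame(rows, columns=_EVENT_COLS).to_csv(
        path, index=False, lineterminator="\n"
    )


def read_exclusion_table(path: str | Path) -> dict[str, list[ExclusionInterval]]:
    path = Path(path)
    df = _read_csv(path, _EXCLUSION_COLS)
    out: dict[str, list[ExclusionInterval]] = {}
    for r in df.itertuples():
        out.setdefault(str(r.animal_id), []).append(
            ExclusionInterval(int(r.start_day), int(r.end_day), str(r.reason))
        )
    return out


def write_exclusion_table(
    exclusions: Mapping[str, Sequence[ExclusionInterval]], path: str | Path
) -> None:
    rows = [
        (animal, ex.start_day, ex.end_day, ex.reason)
        for animal in sorted(exclusions)
        for ex in exclusions[animal]
    ]
    pd.DataFrame(rows, columns=_EXCLUSION_COLS).to_csv(
        path, index=False, lineterminator="\n"
    )


def read_birth_table(path: str | Path) -> list[tuple[str, int, int]]:
    """Read (female_id, conception_day, kittens) records."""
    path = Path(path)
    df = _read_csv(path, _BIRTH_COLS)
    return [
        (str(r.female_id), int(r.conception_day), int(r.kittens))
        for r in df.itertuples()
    ]


def write_birth_table(births: Iterable[tuple[str, int, int]], path: str | Path) -> None:
    pd.DataFrame(list(births), columns=_BIRTH_COLS).to_csv(
        path, index=False, lineterminator="\n"
    )


# ---------------------------------------------------------------------------
# configuration files (flat YAML)
# ---------------------------------------------------------------------------


def write_design(design: StudyDesign, path: str | Path) -> None:
    doc = {
        "groups": dict(sorted(design.groups.items())),
        "treatment_day": design.treatment_day,
        "periods": {k: list(v) for k, v in design.periods.items()},
        "trial_windows": [list(w) for w in design.trial_windows],
        "exclusions": {
            a: [[e.start_day, e.end_day, e.reason] for e in exs]
            for a, exs in sorted(design.exclusions.items())
        },
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_design(path: str | Path) -> StudyDesign:
    doc = yaml.safe_load(Path(path).read_text())
    return StudyDesign(
        groups=dict(doc["groups"]),
        treatment_day=int(doc.get("treatment_day", 0)),
        periods={k: (int(v[0]), int(v[1])) for k, v in doc["periods"].items()},
        trial_windows=tuple(
            (int(a), int(b)) for a, b in doc.get("trial_windows", [])
        ),
        exclusions={
            a: [ExclusionInterval(int(s), int(e), str(r)) for s, e, r in exs]
            for a, exs in doc.get("exclusions", {}).items()
        },
    )


def write_analysis_config(config: AnalysisConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(config), sort_keys=False))


def read_analysis_config(path: str | Path) -> AnalysisConfig:
    doc = yaml.safe_load(Path(path).read_text()) or {}
    return AnalysisConfig(**doc)


# ---------------------------------------------------------------------------
# pipeline driver
# ---------------------------------------------------------------------------

PIPELINE_TABLES = (
    "baselines.csv",
    "phases.csv",
    "frequencies.csv",
    "period_stats.csv",
    "trial_table.csv",
    "trial_tests.csv",
)


def _write_table(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")


def run_pipeline(
    config: AnalysisConfig,
    design: StudyDesign,
    hormones: str | Path,
    events: str | Path,
    out_dir: str | Path,
    births: str | Path | None = None,
) -> dict[str, pd.DataFrame]:
    """Run the full analysis and write the report bundle to ``out_dir``.

    Stages: per-animal iterative baselines on fecal E2 and P4 (pre-treatment
    window), estrous/luteal phase calling, phase-frequency normalization for
    the pre- and post-treatment periods, period comparisons (log-scale t tests
    on metabolite levels, RCB ANOVA + Tukey on phase frequencies), and per
    mating-trial bout/fertility tables with uniform-null chi-square tests.

    Writes six CSV tables plus ``run_log.json``; partial outputs are removed
    if any stage fails. Returns the tables as DataFrames keyed by file name.
    """
    from . import __version__
    from .baseline_phase import call_phases, fit_baseline, phase_frequency
    from .mating_trial import build_trial_table
    from .period_stats import log_t_test, rcb_anova_tukey

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "setup"
    try:
        stage = "read"
        all_series = read_hormone_table(hormones)
        event_list = read_event_log(events)
        birth_list = read_birth_table(births) if births is not None else None
        for s in all_series:
            design.group_of(s.animal_id)  # every animal must be in the design
        logger.info(
            "pipeline: %d series, %d events, seed=%d",
            len(all_series), len(event_list), config.rng_seed,
        )

        base_window = design.period(config.baseline_window)
        fecal = {
            (s.animal_id, s.analyte): s
            for s in all_series
            if s.analyte in ("E2_fecal", "P4_fecal")
        }
        animals = sorted({a for a, _ in fecal})

        stage = "baseline"
        fits = {}
        base_rows = []
        for (animal, analyte), s in sorted(fecal.items()):
            mode = config.baseline_mode if analyte == "E2_fecal" else config.luteal_mode
            fit = fit_baseline(s, base_window, config.baseline_multiplier, mode)
            fits[(animal, analyte)] = fit
            base_rows.append(
                (
                    animal, analyte, mode, config.baseline_multiplier,
                    fit.baseline_mean, fit.baseline_sd, fit.threshold,
                    fit.n_input, fit.n_retained, fit.n_iterations,
                )
            )
        baselines = pd.DataFrame(
            base_rows,
            columns=[
                "animal_id", "analyte", "mode", "k", "baseline_mean",
                "baseline_sd", "threshold", "n_input", "n_retained",
                "n_iterations",
            ],
        )

        stage = "phases"
        calls_by_animal: dict[str, dict[str, list]] = {}
        phase_rows = []
        for animal in animals:
            exclusions = design.exclusions_for(animal)
            calls_by_animal[animal] = {}
            for analyte, phase_type, min_run in (
                ("E2_fecal", "estrous", config.estrous_min_run),
                ("P4_fecal", "luteal", config.luteal_min_run),
            ):
                if (animal, analyte) not in fecal:
                    continue
                calls = call_phases(
                    fecal[(animal, analyte)], fits[(animal, analyte)],
                    phase_type, min_run, exclusions,
                )
                calls_by_animal[animal][phase_type] = calls
                for c in calls:
                    phase_rows.append(
                        (animal, phase_type, c.start_day, c.end_day,
                         c.n_samples, c.peak_value)
                    )
        phases = pd.DataFrame(
            phase_rows,
            columns=["animal_id", "phase_type", "start_day", "end_day",
                     "n_samples", "peak_value"],
        )

        stage = "frequencies"
        freq_rows = []
        for animal in animals:
            exclusions = design.exclusions_for(animal)
            for phase_type, norm in (
                ("estrous", config.estrous_norm_days),
                ("luteal", config.luteal_norm_days),
            ):
                for period_name in ("pre_treatment", "post_treatment"):
                    window = design.period(period_name)
                    pf = phase_frequency(
                        calls_by_animal[animal].get(phase_type, []),
                        window, exclusions, norm,
                        animal_id=animal, phase_type=phase_type,
                        window_name=period_name,
                    )
                    freq_rows.append(
                        (animal, design.group_of(animal), phase_type, period_name,
                         pf.n_phases, pf.effective_days, pf.normalized)
                    )
        frequencies = pd.DataFrame(
            freq_rows,
            columns=["animal_id", "group", "phase_type", "period", "n_phases",
                     "effective_days", "normalized"],
        )

        stage = "period_stats"
        stat_rows = []
        # log-scale t tests: mean metabolite excretion, pre vs post, per group
        for analyte in ("E2_fecal", "P4_fecal"):
            for group in GROUPS:
                gs = [
                    s for (a, an), s in sorted(fecal.items())
                    if an == analyte and design.group_of(a) == group
                ]
                if not gs:
                    continue
                pre, post = [], []
                for s in gs:
                    s2 = s.drop_excluded(design.exclusions_for(s.animal_id))
                    pre.extend(s2.in_window(*design.period("pre_treatment")).values)
                    post.extend(s2.in_window(*design.period("post_treatment")).values)
                try:
                    t, df_, p = log_t_test(pre, post)
                    note = ""
                except CatcycleError as exc:
                    t = df_ = p = float("nan")
                    note = str(exc)
                stat_rows.append(
                    ("log_t_test", analyte, group, "pre_vs_post", t, df_, p, note)
                )
        # RCB ANOVA + Tukey on normalized phase frequencies
        for phase_type in ("estrous", "luteal"):
            sub = frequencies[frequencies.phase_type == phase_type]
            samples = pd.DataFrame(
                {
                    "animal": sub.animal_id,
                    "group": sub.group,
                    "period": sub.period,
                    "value": sub.normalized,
                }
            )
            anova, tukey = rcb_anova_tukey(samples)
            for r in anova.itertuples():
                stat_rows.append(
                    ("rcb_anova", f"{phase_type}_frequency", r.term, "",
                     r.F, r.df, r.p, r.note)
                )
            for r in tukey.itertuples():
                stat_rows.append(
                    ("tukey", f"{phase_type}_frequency",
                     f"{r.cell_a}|{r.cell_b}", "", r.q, r.df, r.p_adj, r.note)
                )
        period_stats = pd.DataFrame(
            stat_rows,
            columns=["analysis", "measure", "term", "contrast",
                     "statistic", "df", "p", "note"],
        )

        stage = "mating_trial"
        # For bout -> luteal linkage the pregnancy exclusion is lifted: the
        # fertile luteal rise (which becomes the pregnancy) is exactly what
        # the trial table counts as a post-bout luteal phase. Frequency and
        # period analyses above keep the full exclusions.
        linkage_calls: dict[str, list] = {}
        for animal in animals:
            if (animal, "P4_fecal") not in fecal:
                linkage_calls[animal] = []
                continue
            non_preg = [
                e for e in design.exclusions_for(animal) if e.reason != "pregnancy"
            ]
            linkage_calls[animal] = call_phases(
                fecal[(animal, "P4_fecal")], fits[(animal, "P4_fecal")],
                "luteal", config.luteal_min_run, non_preg,
            )
        trial_rows, test_rows = [], []
        for i, window in enumerate(design.trial_windows, start=1):
            w_events = [e for e in event_list if window[0] <= e.day < window[1]]
            luteal_by_female = linkage_calls
            if birth_list is not None:
                kittens = {}
                for female, day, n in birth_list:
                    if window[0] <= day < window[1]:
                        kittens[female] = kittens.get(female, 0) + n
            else:
                # fall back on pregnancy exclusions; litter sizes unknown
                kittens = {
                    a: 0
                    for a in animals
                    for ex in design.exclusions_for(a)
                    if ex.reason == "pregnancy"
                    and window[0] <= ex.start_day < window[1]
                }
            table, tests = build_trial_table(
                w_events, luteal_by_female, kittens, design, window,
                max_lag_days=config.max_lag_days,
            )
            for r in table.itertuples():
                trial_rows.append((i, r.group, r.n_females_bred, r.n_bouts,
                                   r.n_luteal_after_bout, r.n_pregnant, r.n_kittens))
            for r in tests.itertuples():
                test_rows.append(
                    (i, r.metric) + tuple(r.counts) + (r.chi2, r.df, r.p, r.note)
                )
        trial_table = pd.DataFrame(
            trial_rows,
            columns=["trial", "group", "n_females_bred", "n_bouts",
                     "n_luteal_after_bout", "n_pregnant", "n_kittens"],
        )
        trial_tests = pd.DataFrame(
            test_rows,
            columns=["trial", "metric", *(f"count_{g}" for g in GROUPS),
                     "chi2", "df", "p", "note"],
        )

        stage = "write"
        tables = {
            "baselines.csv": baselines,
            "phases.csv": phases,
            "frequencies.csv": frequencies,
            "period_stats.csv": period_stats,
            "trial_table.csv": trial_table,
            "trial_tests.csv": trial_tests,
        }
        for name, df in tables.items():
            p = out_dir / name
            _write_table(df, p)
            written.append(p)
        log = {
            "config": dataclasses.asdict(config),
            "seed": config.rng_seed,
            "n_series": len(all_series),
            "n_events": len(event_list),
            "versions": {
                "catcycle": __version__,
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
        }
        log_path = out_dir / "run_log.json"
        log_path.write_text(json.dumps(log, indent=2, sort_keys=True))
        written.append(log_path)
        return tables
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise CatcycleError(f"pipeline stage {stage!r} failed: {exc}") from exc


def remove_output(out_dir: str | Path) -> None:
    """Delete a report bundle directory (helper for CLI --force)."""
    shutil.rmtree(out_dir, ignore_errors=True)
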