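"""Group-level period statistics.

Implements the study's statistical toolkit: unpaired pooled-variance t tests
on natural-log-transformed hormone concentrations; a randomized complete
block (RCB) ANOVA for phase frequencies, with animals as blocks nested in
treatment groups and crossed with period (a split-plot layout — the group
effect is tested against the between-animal mean square, period and the
period x group interaction against the residual), followed by Tukey
studentized-range pairwise comparisons of the period x group cell means;
one-way ANOVA with Dunnett many-to-one contrasts against a control group;
and the stereological follicle-count correction for serial sectioning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_model import (
    ContractError,
    DegenerateVarianceError,
    GROUPS,
    InsufficientDataError,
    UnbalancedDesignError,
    ValidationError,
)


class TTestResult(NamedTuple):
    t: float
    df: int
    p: float


@dataclass(frozen=True)
class PeriodSample:
    """One animal's value (hormone level or phase frequency) in one period."""

    animal_id: str
    group: str
    period: str
    value: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.value):
            raise ValidationError("PeriodSample value must be finite")


@dataclass(frozen=True)
class FollicleCounts:
    """Follicle tally of one stage in one animal, counted on every nth serial
    section; ``corrected_count = raw_count * correction_factor``."""

    animal_id: str
    group: str
    stage: str
    raw_count: int
    correction_factor: int = 5
    corrected_count: int | None = None

    def __post_init__(self) -> None:
        if self.stage not in ("primordial", "primary", "secondary", "antral"):
            raise ValidationError(f"unknown follicle stage {self.stage!r}")
        if self.raw_count < 0 or self.correction_factor < 1:
            raise ValidationError("counts and correction factor must be non-negative")
        if (
            self.corrected_count is not None
            and self.corrected_count % self.correction_factor != 0
        ):
            raise ValidationError("corrected_count must be divisible by the factor")


def correct_counts(raw: FollicleCounts) -> FollicleCounts:
    """Apply the serial-section correction factor to a raw follicle count."""
    return replace(raw, corrected_count=raw.raw_count * raw.correction_factor)


def log_t_test(a: Sequence[float], b: Sequence[float]) -> TTestResult:
    """Pooled-variance two-sample t test on natural-log values.

    Both samples must be strictly positive with size >= 2. Raises
    :class:`DegenerateVarianceError` when the pooled within-group variance is
    exactly zero (the statistic is undefined).
    """
    xa = np.asarray(a, dtype=float)
    xb = np.asarray(b, dtype=float)
    if xa.size < 2 or xb.size < 2:
        raise InsufficientDataError("each sample needs >= 2 observations")
    if np.any(xa <= 0) or np.any(xb <= 0):
        raise ValidationError("log transform requires strictly positive values")
    la, lb = np.log(xa), np.log(xb)
    na, nb = la.size, lb.size
    df = na + nb - 2
    sp2 = ((na - 1) * la.var(ddof=1) + (nb - 1) * lb.var(ddof=1)) / df
    if sp2 == 0.0:
        raise DegenerateVarianceError("zero pooled within-group variance")
    t = (la.mean() - lb.mean()) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    p = 2.0 * stats.t.sf(abs(t), df)
    return TTestResult(float(t), int(df), float(p))


def _as_frame(samples) -> pd.DataFrame:
    if isinstance(samples, pd.DataFrame):
        df = samples.copy()
    else:
        df = pd.DataFrame(
            [(s.animal_id, s.group, s.period, s.value) for s in samples],
            columns=["animal", "group", "period", "value"],
        )
    needed = {"animal", "group", "period", "value"}
    if not needed.issubset(df.columns):
        raise ContractError(f"samples need columns {sorted(needed)}")
    return df


def rcb_anova_tukey(
    samples, tukey: bool = True
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Randomized-complete-block ANOVA with Tukey pairwise cell comparisons.

    ``samples`` is a DataFrame (or sequence of :class:`PeriodSample`) with one
    observation per animal x period. Animals are blocks nested in groups and
    crossed with period. The sequential (orthogonal, balanced) decomposition is

        SS_total = SS_group + SS_block(group) + SS_period
                   + SS_period:group + SS_residual

    The group F uses the block mean square as denominator (animals are the
    experimental units for group); period and interaction use the residual.
    Tukey-adjusted p-values compare the period x group cell means using the
    residual mean square. With all values identical every F is undefined and
    p is reported as 1 with a note (zero-variance convention).
    """
    df = _as_frame(samples)
    periods = sorted(df["period"].unique())
    groups = sorted(df["group"].unique())
    if len(periods) < 2 or len(groups) < 2:
        raise ContractError("need >= 2 periods and >= 2 groups")
    # every animal observed exactly once in every period
    pivot = df.pivot_table(
        index="animal", columns="period", values="value", aggfunc="count"
    )
    if pivot.isna().any().any() or (pivot != 1).any().any():
        raise UnbalancedDesignError(
            "each animal must be observed exactly once in every period"
        )
    animal_group = df.groupby("animal")["group"].agg(lambda g: g.unique())
    if any(len(g) != 1 for g in animal_group):
        raise ContractError("an animal cannot belong to two groups")
    n_per_group = df.groupby("group")["animal"].nunique()
    if (n_per_group < 2).any():
        raise UnbalancedDesignError("need >= 2 animals per group")
    if n_per_group.nunique() != 1:
        raise UnbalancedDesignError("groups must hold equal numbers of animals")

    y = df["value"].to_numpy(float)
    grand = y.mean()
    g_mean = df.groupby("group")["value"].transform("mean").to_numpy(float)
    a_mean = df.groupby("animal")["value"].transform("mean").to_numpy(float)
    p_mean = df.groupby("period")["value"].transform("mean").to_numpy(float)
    c_mean = (
        df.groupby(["group", "period"])["value"].transform("mean").to_numpy(float)
    )

    ss_total = float(((y - grand) ** 2).sum())
    ss_group = float(((g_mean - grand) ** 2).sum())
    ss_block = float(((a_mean - g_mean) ** 2).sum())
    ss_period = float(((p_mean - grand) ** 2).sum())
    ss_inter = float(((c_mean - g_mean - p_mean + grand) ** 2).sum())
    ss_resid = ss_total - ss_group - ss_block - ss_period - ss_inter

    n_animals = df["animal"].nunique()
    g, p_ = len(groups), len(periods)
    df_group = g - 1
    df_block = n_animals - g
    df_period = p_ - 1
    df_inter = (g - 1) * (p_ - 1)
    df_resid = (n_animals - g) * (p_ - 1)

    def _row(term, ss, dfree, denom_ms, denom_df):
        ms = ss / dfree if dfree > 0 else np.nan
        if ss_total == 0.0:
            return (term, ss, dfree, ms, np.nan, 1.0, "zero total variance")
        if denom_ms is None:
            return (term, ss, dfree, ms, np.nan, np.nan, "")
        if denom_ms == 0.0:
            if ms == 0.0:
                return (term, ss, dfree, ms, np.nan, 1.0, "zero variance")
            return (term, ss, dfree, ms, np.inf, 0.0, "zero denominator variance")
        F = ms / denom_ms
        return (term, ss, dfree, ms, F, float(stats.f.sf(F, dfree, denom_df)), "")

    ms_block = ss_block / df_block if df_block > 0 else 0.0
    ms_resid = ss_resid / df_resid if df_resid > 0 else 0.0
    rows = [
        _row("Group", ss_group, df_group, ms_block, df_block),
        _row("Block", ss_block, df_block, ms_resid, df_resid),
        _row("Period", ss_period, df_period, ms_resid, df_resid),
        _row("Period:Group", ss_inter, df_inter, ms_resid, df_resid),
        ("Residual", ss_resid, df_resid, ms_resid, np.nan, np.nan, ""),
    ]
    anova = pd.DataFrame(
        rows, columns=["term", "sum_sq", "df", "mean_sq", "F", "p", "note"]
    )

    tukey_rows = []
    if tukey:
        cells = df.groupby(["group", "period"])["value"].mean()
        n_cell = n_per_group.iloc[0]
        k = len(cells)
        labels = [f"{g_}:{p_lab}" for g_, p_lab in cells.index]
        means = cells.to_numpy(float)
        for i in range(k):
            for j in range(i + 1, k):
                diff = means[i] - means[j]
                if ss_total == 0.0 or ms_resid == 0.0:
                    if diff == 0.0:
                        q, padj, note = np.nan, 1.0, "zero variance"
                    else:
                        q, padj, note = np.inf, 0.0, "zero residual variance"
                else:
                    q = abs(diff) / np.sqrt(ms_resid / n_cell)
                    padj = float(
                        np.clip(stats.studentized_range.sf(q, k, df_resid), 0, 1)
                    )
                    note = ""
                tukey_rows.append(
                    (labels[i], labels[j], diff, q, df_resid, padj, note)
                )
    tukey_df = pd.DataFrame(
        tukey_rows,
        columns=["cell_a", "cell_b", "diff", "q", "df", "p_adj", "note"],
    )
    return anova, tukey_df


class DunnettResult(NamedTuple):
    F: float
    p_overall: float
    contrasts: pd.DataFrame  # group, estimate, t, p_adj


def one_way_anova_dunnett(
    counts_by_group: Mapping[str, Sequence[float]], control: str
) -> DunnettResult:
    """One-way ANOVA with Dunnett-adjusted two-sided comparisons vs control.

    The Dunnett adjustment evaluates the equicorrelated multivariate-t tail
    probability (correlation 1/2 for balanced designs)."""
    if control not in counts_by_group:
        raise ContractError(f"control group {control!r} absent")
    if len(counts_by_group) < 2:
        raise ContractError("need >= 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in counts_by_group.items()}
    if any(a.size < 2 for a in arrays.values()):
        raise InsufficientDataError("each group needs >= 2 observations")
    treated = [k for k in arrays if k != control]
    F, p_overall = stats.f_oneway(*arrays.values())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # tiny p-values can warn about accuracy
        res = stats.dunnett(
            *(arrays[k] for k in treated), control=arrays[control]
        )
    contrasts = pd.DataFrame(
        {
            "group": treated,
            "estimate": [arrays[k].mean() - arrays[control].mean() for k in treated],
            "t": res.statistic,
            "p_adj": res.pvalue,
        }
    )
    return DunnettResult(float(F), float(p_overall), contrasts)
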