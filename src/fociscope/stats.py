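"""Stratified focus-count statistics.

Covers the reporting surface of a repair-kinetics study: per-condition x
phase summaries (mean foci/cell, SEM, n), fold-changes and percent increases
between conditions, Student's t for two groups, one-way ANOVA with Tukey HSD
for multi-group comparisons, and time-course tables expressing residual
damage relative to the 0.5 h post-irradiation peak.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .gating import CellRecord, records_to_frame
from .params import ValidationError

DEFAULT_GROUP_KEYS = ("line_id", "marker", "dose_gy", "time_h", "phase")


@dataclass
class SummaryRow:
    line_id: str
    marker: str
    dose_gy: float
    time_h: float
    phase: str
    mean_foci: float
    sem: float
    n_cells: int


@dataclass
class ComparisonResult:
    kind: str                      # "t_test" or "anova_tukey"
    statistic: float
    p_value: float
    pairwise: List[Tuple[str, str, float, bool]] = field(default_factory=list)


@dataclass
class TimeCourseRow:
    line_id: str
    marker: str
    phase: str
    mean_0h: float
    mean_05h: float
    mean_2h: float
    mean_6h: float
    percent_remaining_2h: float
    percent_remaining_6h: float


class TimeCourseGapError(ValueError):
    """A required time point is missing from the summaries."""


def _mean_sem(values: np.ndarray) -> Tuple[float, float]:
    n = len(values)
    mean = float(np.mean(values))
    if n == 1:
        warnings.warn("group of size 1: SEM reported as 0", stacklevel=3)
        return mean, 0.0
    return mean, float(np.std(values, ddof=1) / np.sqrt(n))


def summarize_foci(records: Sequence[CellRecord],
                   group_keys: Sequence[str] = DEFAULT_GROUP_KEYS
                   ) -> List[SummaryRow]:
    """One row per group: mean foci/cell, SEM (sample SD / sqrt n), n."""
    if len(records) == 0:
        raise ValidationError("no records to summarize")
    frame = records_to_frame(records)
    rows: List[SummaryRow] = []
    for key, grp in frame.groupby(list(group_keys), sort=True):
        info = dict(zip(group_keys, key if isinstance(key, tuple) else (key,)))
        mean, sem = _mean_sem(grp["foci_count"].to_numpy(dtype=float))
        rows.append(SummaryRow(
            line_id=str(info.get("line_id", "")),
            marker=str(info.get("marker", "")),
            dose_gy=float(info.get("dose_gy", 0.0)),
            time_h=float(info.get("time_h", 0.0)),
            phase=str(info.get("phase", "")),
            mean_foci=mean, sem=sem, n_cells=len(grp)))
    return rows


SUMMARY_COLUMNS = ["line_id", "marker", "dose_gy", "time_h", "phase",
                   "mean_foci", "sem", "n_cells"]


def summaries_to_frame(rows: Sequence[SummaryRow]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in rows], columns=SUMMARY_COLUMNS)


def fold_change(mean_num: float, mean_den: float) -> float:
    """Raw ratio of two group means (e.g. irradiated over control)."""
    if mean_den <= 0:
        raise ValidationError("denominator mean must be > 0")
    return mean_num / mean_den


def format_fold(ratio: float) -> float:
    """Reporting convention for fold values: nearest integer for large folds
    (>= 10, e.g. '18-fold'), one decimal otherwise (e.g. '2.1-times')."""
    return float(round(ratio)) if ratio >= 10 else round(ratio, 1)


def percent_increase(ctrl_mean: float, irr_mean: float) -> float:
    """Percent change of the treated mean over the control mean."""
    if ctrl_mean <= 0:
        raise ValidationError("control mean must be > 0")
    return 100.0 * (irr_mean - ctrl_mean) / ctrl_mean


def compare_two_groups(a: Sequence[float], b: Sequence[float],
                       equal_var: bool = True) -> ComparisonResult:
    """Two-sample Student's t test (two-sided); Welch form via equal_var=False."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs n >= 2")
    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    return ComparisonResult(kind="t_test", statistic=float(t), p_value=float(p))


def anova_tukey(groups: Dict[str, Sequence[float]],
                alpha: float = 0.05) -> ComparisonResult:
    """One-way ANOVA plus Tukey HSD pairwise comparisons (Tukey-Kramer for
    unequal group sizes)."""
    if len(groups) < 3:
        raise ValidationError(
            "anova_tukey needs >= 3 groups; use compare_two_groups for two")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if len(v) < 2:
            raise ValidationError(f"group {k!r} needs n >= 2")
    f, p = sps.f_oneway(*arrays.values())
    values = np.concatenate(list(arrays.values()))
    labels = np.concatenate([[k] * len(v) for k, v in arrays.items()])
    if np.ptp(values) == 0:
        # all observations identical: F = 0, nothing can be significant
        pairs = []
        names = list(arrays)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                pairs.append((names[i], names[j], 1.0, False))
        return ComparisonResult(kind="anova_tukey", statistic=0.0,
                                p_value=1.0, pairwise=pairs)
    tk = pairwise_tukeyhsd(values, labels, alpha=alpha)
    from itertools import combinations
    pairs = list(combinations(tk.groupsunique, 2))  # statsmodels pair order
    pairwise = [(str(g1), str(g2), float(adj_p), bool(reject))
                for (g1, g2), adj_p, reject in zip(pairs, tk.pvalues, tk.reject)]
    return ComparisonResult(kind="anova_tukey", statistic=float(f),
                            p_value=float(p), pairwise=pairwise)


TIME_POINTS = (0.0, 0.5, 2.0, 6.0)


def repair_time_course(summaries: Sequence[SummaryRow]) -> List[TimeCourseRow]:
    """Time-course rows per (line, marker, phase): means at 0/0.5/2/6 h and
    the percent of the 0.5 h peak remaining at 2 h and 6 h."""
    frame = summaries_to_frame(list(summaries))
    rows: List[TimeCourseRow] = []
    for (line, marker, phase), grp in frame.groupby(
            ["line_id", "marker", "phase"], sort=True):
        means = {}
        for t in TIME_POINTS:
            sel = grp[np.isclose(grp["time_h"], t)]
            if sel.empty:
                raise TimeCourseGapError(
                    f"missing time point {t} h for ({line}, {marker}, {phase})")
            means[t] = float(sel["mean_foci"].iloc[0])
        if means[0.5] <= 0:
            raise ValidationError(
                "percent_remaining undefined: 0.5 h peak mean is not positive")
        rows.append(TimeCourseRow(
            line_id=line, marker=marker, phase=phase,
            mean_0h=means[0.0], mean_05h=means[0.5],
            mean_2h=means[2.0], mean_6h=means[6.0],
            percent_remaining_2h=100.0 * means[2.0] / means[0.5],
            percent_remaining_6h=100.0 * means[6.0] / means[0.5]))
    return rows


TC_COLUMNS = ["line_id", "marker", "phase", "mean_0h", "mean_05h", "mean_2h",
              "mean_6h", "percent_remaining_2h", "percent_remaining_6h"]


def timecourse_to_frame(rows: Sequence[TimeCourseRow]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in rows], columns=TC_COLUMNS)


def load_reference_summary() -> pd.DataFrame:
    """Packaged per-condition summary table (mean foci/cell, SEM, n) for the
    five cell lines at low/high passage, both markers, control and 1 Gy,
    split by cell-cycle phase.  Used for worked examples and as simulation
    rates."""
    with resources.files("fociscope.data").joinpath("table1.csv").open() as fh:
        return pd.read_csv(fh, comment="#")


def reference_mean(table: pd.DataFrame, line_id: str, passage: str,
                   marker: str, treatment: str, phase: str) -> float:
    sel = table[(table.line_id == line_id) & (table.passage == passage)
                & (table.marker == marker) & (table.treatment == treatment)
                & (table.phase == phase)]
    if len(sel) != 1:
        raise KeyError(f"no unique row for {(line_id, passage, marker, treatment, phase)}")
    return float(sel["mean_foci"].iloc[0])
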