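"""Score dichotomisation and Kaplan-Meier / log-rank survival comparison.

Two cut-point strategies are provided: the cohort median, and the maximally
selected rank statistic (the cut-point maximising the standardized two-group
log-rank statistic over admissible splits). Kaplan-Meier curves are fitted
with lifelines; the log-rank machinery itself is implemented here because the
maxstat scan needs the standardized statistic at every candidate cut-point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats


@dataclass
class SurvivalCurve:
    """Kaplan-Meier estimate for one group."""

    label: str
    times: np.ndarray
    survival: np.ndarray
    median: float | None
    n: int


@dataclass
class KMComparison:
    """Two-group Kaplan-Meier comparison with a log-rank test."""

    curves: dict[str, SurvivalCurve]
    logrank_chi2: float
    logrank_p: float


@dataclass
class CutpointResult:
    """Maximally selected rank statistic scan."""

    cutpoint: float
    standardized_statistic: float
    scan: list[tuple[float, float]] = field(default_factory=list)


def split_by_median(scores: pd.Series) -> pd.Series:
    """Dichotomise scores at the cohort median.

    Scores strictly above the median are "high"; scores at or below it are
    "low" (ties at the median go to "low", keeping "high" strictly above).
    """
    if len(scores) < 2:
        raise ValueError("need at least 2 samples to split")
    med = float(scores.median())
    if float(scores.max()) == float(scores.min()):
        raise ValueError("all scores identical: degenerate split")
    return pd.Series(
        np.where(scores > med, "high", "low"), index=scores.index, name="group"
    )


def logrank_observed_expected(
    time: np.ndarray, event: np.ndarray, in_group: np.ndarray
) -> tuple[float, float, float]:
    """(O, E, V) of events in ``in_group`` under the two-group log-rank model.

    At each distinct event time, the expected event count in the group is
    ``d * n1/n`` and the hypergeometric variance
    ``d (n1/n)(1 - n1/n)(n - d)/(n - 1)``.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    in_group = np.asarray(in_group, dtype=bool)
    uts, d = np.unique(time[event], return_counts=True)
    if len(uts) == 0:
        return 0.0, 0.0, 0.0
    d1 = np.zeros(len(uts))
    np.add.at(d1, np.searchsorted(uts, time[event & in_group]), 1)
    st = np.sort(time)
    sg = np.sort(time[in_group])
    n = len(time) - np.searchsorted(st, uts, side="left")
    n1 = len(sg) - np.searchsorted(sg, uts, side="left")
    frac = n1 / n
    o = float(d1.sum())
    e = float((d * frac).sum())
    ok = n > 1
    v = float(
        (d[ok] * frac[ok] * (1.0 - frac[ok]) * (n[ok] - d[ok]) / (n[ok] - 1)).sum()
    )
    return o, e, v


def standardized_logrank(
    time: np.ndarray, event: np.ndarray, in_group: np.ndarray
) -> float:
    """|O - E| / sqrt(V) for the two-group log-rank statistic."""
    o, e, v = logrank_observed_expected(time, event, in_group)
    if v <= 0:
        return 0.0
    return abs(o - e) / np.sqrt(v)


def maxstat_cutpoint(
    scores: pd.Series,
    time: np.ndarray,
    event: np.ndarray,
    min_prop: float = 0.1,
    max_prop: float = 0.9,
) -> CutpointResult:
    """Cut-point maximising the standardized two-group log-rank statistic.

    Candidates are the observed score values whose split (score <= candidate
    vs above) keeps both groups within ``[min_prop, max_prop]`` of the cohort
    size. The full scan is returned alongside the maximiser; ties on the
    statistic resolve to the smallest cut-point. No selection-adjusted
    p-value is computed — downstream comparisons report the ordinary log-rank
    p of the induced split.
    """
    s = scores.to_numpy(dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    n = len(s)
    if n < 10 or event.sum() < 1:
        raise ValueError("need >= 10 subjects with >= 1 event")
    scan = []
    best: tuple[float, float] | None = None
    for c in np.unique(s):
        low = s <= c
        n_low = int(low.sum())
        if not (min_prop * n <= n_low <= max_prop * n):
            continue
        stat = standardized_logrank(time, event, ~low)
        scan.append((float(c), float(stat)))
        if best is None or stat > best[1]:
            best = (float(c), float(stat))
    if best is None:
        raise ValueError(
            f"no admissible cut-point with both groups in [{min_prop}, {max_prop}] of n"
        )
    return CutpointResult(cutpoint=best[0], standardized_statistic=best[1], scan=scan)


def split_by_maxstat(
    scores: pd.Series, time, event, min_prop: float = 0.1, max_prop: float = 0.9
) -> tuple[pd.Series, CutpointResult]:
    """Dichotomise scores at the maximally selected rank-statistic cut-point."""
    cut = maxstat_cutpoint(scores, time, event, min_prop, max_prop)
    groups = pd.Series(
        np.where(scores > cut.cutpoint, "high", "low"),
        index=scores.index,
        name="group",
    )
    return groups, cut


def km_logrank(
    time, event, groups: pd.Series | np.ndarray
) -> KMComparison:
    """Kaplan-Meier curves per group and the two-group log-rank test.

    The product-limit estimator and median (smallest time with S(t) <= 0.5;
    ``None`` if never reached) come from lifelines; the log-rank chi-square is
    ``(O - E)^2 / V`` with the standard hypergeometric variance, referred to a
    chi-square distribution with 1 df.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    groups = np.asarray(groups)
    if np.any(time <= 0):
        raise ValueError("survival times must be positive")
    labels = sorted(pd.unique(groups))
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {labels}")
    curves = {}
    for lab in labels:
        mask = groups == lab
        if mask.sum() == 0:
            raise ValueError(f"group {lab!r} has no subjects")
        kmf = KaplanMeierFitter()
        kmf.fit(time[mask], event_observed=event[mask], label=str(lab))
        med = kmf.median_survival_time_
        curves[str(lab)] = SurvivalCurve(
            label=str(lab),
            times=kmf.survival_function_.index.to_numpy(dtype=float),
            survival=kmf.survival_function_[str(lab)].to_numpy(dtype=float),
            median=None if np.isinf(med) else float(med),
            n=int(mask.sum()),
        )
    o, e, v = logrank_observed_expected(time, event, groups == labels[1])
    if v > 0:
        chi2 = (o - e) ** 2 / v
        p = float(stats.chi2.sf(chi2, df=1))
    else:
        chi2, p = 0.0, 1.0
    return KMComparison(curves=curves, logrank_chi2=float(chi2), logrank_p=p)
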