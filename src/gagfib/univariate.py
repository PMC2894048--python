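"""Single-parameter analyses of the acceleration statistic G.

Each analysis regresses G on one descriptor at a time: Pearson correlation
with a two-tailed t-test p-value, the ordinary least-squares line and its
x-intercept (the descriptor value at which the GAG has no net effect),
per-level and per-bin mean summaries, and Welch two-group comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import DatasetEntry, entries_to_frame
from .exceptions import InsufficientDataError

__all__ = [
    "CorrelationResult",
    "GroupSummary",
    "TwoGroupResult",
    "correlate",
    "correlate_xy",
    "mean_G_by_level",
    "mean_G_by_bin",
    "compare_two_groups",
]


@dataclass
class CorrelationResult:
    """Pearson correlation plus the OLS line of best fit for G against one descriptor."""

    r: float
    p: float
    n: int
    slope: float
    intercept: float
    x_intercept: float  # abscissa where the fitted line crosses G = 0; nan if flat

    def __str__(self):
        return (
            f"r = {self.r:.3f}, p = {self.p:.2e}, n = {self.n}, "
            f"slope = {self.slope:.4g}, x-intercept = {self.x_intercept:.3g}"
        )


@dataclass
class GroupSummary:
    """Mean and spread of G within one level or bin of a descriptor."""

    label: object
    mean_G: float
    sd_G: float | None  # None when n < 2
    n: int


@dataclass
class TwoGroupResult:
    """Welch comparison of G between two descriptor levels."""

    summary_a: GroupSummary
    summary_b: GroupSummary
    t: float | None
    p: float | None  # None when a group has n < 2 and the test cannot run


def _as_frame(entries) -> pd.DataFrame:
    if isinstance(entries, pd.DataFrame):
        return entries
    return entries_to_frame(entries)


def correlate_xy(x: np.ndarray, y: np.ndarray) -> CorrelationResult:
    """Pearson r with exact two-tailed t-transform p and the OLS line."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    n = len(x)
    if n < 3:
        raise InsufficientDataError(f"need at least 3 paired observations, have {n}")
    if np.ptp(x) == 0:
        raise InsufficientDataError("x is constant; correlation undefined")
    r, p = stats.pearsonr(x, y)
    slope, intercept = np.polyfit(x, y, 1)
    x_int = -intercept / slope if slope != 0 else float("nan")
    return CorrelationResult(float(r), float(p), n, float(slope), float(intercept), float(x_int))


def correlate(
    entries: Sequence[DatasetEntry] | pd.DataFrame,
    x_variable: str,
    filter: Callable[[pd.DataFrame], pd.Series] | pd.Series | None = None,
) -> CorrelationResult:
    """Correlate G with one numeric descriptor, optionally on a filtered subset.

    ``filter`` may be a boolean mask or a callable evaluated on the flattened
    entry table (e.g. ``lambda d: d["protein"] == "alpha-synuclein"``).
    """
    frame = _as_frame(entries)
    if filter is not None:
        mask = filter(frame) if callable(filter) else filter
        frame = frame[np.asarray(mask, bool)]
    return correlate_xy(frame[x_variable].to_numpy(float), frame["G"].to_numpy(float))


def _summaries(values: pd.Series, groups: pd.Series) -> list[GroupSummary]:
    out = []
    for label, sub in values.groupby(groups, observed=True, sort=True):
        n = len(sub)
        out.append(
            GroupSummary(
                label=label,
                mean_G=float(sub.mean()),
                sd_G=float(sub.std(ddof=1)) if n >= 2 else None,
                n=n,
            )
        )
    return out


def mean_G_by_level(
    entries: Sequence[DatasetEntry] | pd.DataFrame,
    x_variable: str,
) -> tuple[list[GroupSummary], CorrelationResult]:
    """Mean G per distinct level of a descriptor, plus the correlation over means.

    Used for plots where each point is the average G of all entries sharing the
    same descriptor value (e.g. the same sulfation state).
    """
    frame = _as_frame(entries)
    x = frame[x_variable]
    if x.nunique() < 3:
        raise InsufficientDataError(
            f"{x_variable!r} takes {x.nunique()} distinct values; need >= 3 levels"
        )
    summaries = _summaries(frame["G"], x)
    levels = np.array([float(s.label) for s in summaries])
    means = np.array([s.mean_G for s in summaries])
    return summaries, correlate_xy(levels, means)


def mean_G_by_bin(
    entries: Sequence[DatasetEntry] | pd.DataFrame,
    x_variable: str,
    bin_edges: Sequence[float] | None = None,
) -> tuple[list[GroupSummary], CorrelationResult, np.ndarray]:
    """Mean G within bins of a continuous descriptor, plus correlation on bin centers.

    When ``bin_edges`` is None, quartile-based edges of the observed values are
    used (and returned, so the binning is reproducible from the output).
    Empty bins are dropped before correlating.
    """
    frame = _as_frame(entries)
    x = frame[x_variable].to_numpy(float)
    g = frame["G"].to_numpy(float)
    mask = np.isfinite(x) & np.isfinite(g)
    x, g = x[mask], g[mask]
    if len(x) == 0:
        raise InsufficientDataError("no finite observations to bin")
    if bin_edges is None:
        bin_edges = np.unique(np.quantile(x, [0.0, 0.25, 0.5, 0.75, 1.0]))
    bin_edges = np.asarray(bin_edges, float)
    if len(bin_edges) < 2 or bin_edges[0] > x.min() or bin_edges[-1] < x.max():
        raise InsufficientDataError("bin edges must cover the observed range")
    idx = np.clip(np.digitize(x, bin_edges, right=False) - 1, 0, len(bin_edges) - 2)
    centers = (bin_edges[:-1] + bin_edges[1:]) / 2.0
    summaries = []
    used_centers = []
    for b in range(len(bin_edges) - 1):
        sel = idx == b
        n = int(sel.sum())
        if n == 0:
            continue
        vals = g[sel]
        summaries.append(
            GroupSummary(
                label=(float(bin_edges[b]), float(bin_edges[b + 1])),
                mean_G=float(vals.mean()),
                sd_G=float(vals.std(ddof=1)) if n >= 2 else None,
                n=n,
            )
        )
        used_centers.append(centers[b])
    if len(summaries) < 3:
        raise InsufficientDataError(
            f"only {len(summaries)} non-empty bins; need >= 3 for a correlation"
        )
    corr = correlate_xy(np.asarray(used_centers), np.array([s.mean_G for s in summaries]))
    return summaries, corr, bin_edges


def compare_two_groups(
    entries: Sequence[DatasetEntry] | pd.DataFrame,
    grouping_variable: str,
    level_a: object,
    level_b: object,
    matching: dict[str, object] | None = None,
) -> TwoGroupResult:
    """Welch two-sided comparison of G between two levels of a descriptor.

    ``matching`` fixes covariates before comparing, e.g.
    ``{"sulfates_per_disaccharide": 2}`` restricts to GAGs with two sulfates
    per disaccharide unit. If either group has fewer than two entries the
    summaries are returned without a test (t and p are None).
    """
    frame = _as_frame(entries)
    if matching:
        for var, value in matching.items():
            frame = frame[frame[var] == value]
    col = frame[grouping_variable].astype(str)
    a = frame.loc[col == str(level_a), "G"].to_numpy(float)
    b = frame.loc[col == str(level_b), "G"].to_numpy(float)
    if len(a) == 0 or len(b) == 0:
        raise InsufficientDataError(
            f"empty group for {grouping_variable!r} in {{{level_a!r}, {level_b!r}}}"
        )

    def summ(label, v):
        return GroupSummary(
            label=label,
            mean_G=float(v.mean()),
            sd_G=float(v.std(ddof=1)) if len(v) >= 2 else None,
            n=len(v),
        )

    sa, sb = summ(level_a, a), summ(level_b, b)
    if len(a) < 2 or len(b) < 2:
        return TwoGroupResult(sa, sb, None, None)
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return TwoGroupResult(sa, sb, float(t), float(p))
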