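"""Single-unit and population tuning statistics.

Modulation-depth (MD) maps — the absolute difference in mean firing rate
between every pair of conditions —, one-way ANOVA with Tukey–Kramer post-hoc
pair separation (studentized-range criterion on unbalanced group sizes), a
sliding one-way ANOVA over doubly aligned, sigma = 50 ms smoothed rates in
1 ms steps (fraction of units tuned per time point, no multiple-comparison
correction), and the population visual-response latency, defined as the time
from cue onset until the population curve reaches 75% of its post-cue peak.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .prep import NSpaceMatrix, RateTensor


@dataclass
class MDMap:
    """Symmetric conditions x conditions map of |mean rate difference| (Hz)."""

    matrix: pd.DataFrame    # indexed/columned by ascending condition id
    unit_id: int
    epoch: str

    @property
    def max_md(self) -> float:
        return float(self.matrix.to_numpy().max())

    @property
    def n_pairs(self) -> int:
        n = self.matrix.shape[0]
        return n * (n - 1) // 2


def _condition_means(values: np.ndarray, condition_ids: np.ndarray):
    order = np.array(sorted(set(condition_ids)))
    means = np.array(
        [values[condition_ids == cid].mean() for cid in order]
    )
    counts = np.array([(condition_ids == cid).sum() for cid in order])
    return order, means, counts


def modulation_depth(nspace: NSpaceMatrix, unit: int) -> MDMap:
    """MD map of one unit: conditions on the axes in ascending id order."""
    col = int(np.flatnonzero(nspace.unit_ids == unit)[0])
    values = nspace.values[:, col]
    order, means, counts = _condition_means(values, nspace.condition_ids)
    if len(order) < 2:
        raise ValueError("modulation depth needs at least two conditions")
    if (counts == 0).any():
        raise ValueError("condition with zero trials")
    md = np.abs(means[:, None] - means[None, :])
    np.fill_diagonal(md, 0.0)
    return MDMap(
        matrix=pd.DataFrame(md, index=order, columns=order),
        unit_id=unit,
        epoch=nspace.epoch,
    )


def oneway_anova(values: np.ndarray, labels: np.ndarray):
    """Vectorized fixed-effects one-way ANOVA.

    ``values`` has samples on axis 0 (any trailing shape); returns (F, p)
    over the trailing axes.  Matches ``scipy.stats.f_oneway``.
    """
    values = np.asarray(values, dtype=np.float64)
    groups = sorted(set(labels))
    k = len(groups)
    n = values.shape[0]
    if k < 2:
        raise ValueError("ANOVA needs at least two groups")
    grand = values.mean(axis=0)
    ss_total = ((values - grand) ** 2).sum(axis=0)
    ss_between = np.zeros_like(grand)
    for g in groups:
        sel = values[np.asarray(labels) == g]
        ss_between += sel.shape[0] * (sel.mean(axis=0) - grand) ** 2
    ss_within = ss_total - ss_between
    df_between, df_within = k - 1, n - k
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_between / df_between) / (ss_within / df_within)
    p = stats.f.sf(f, df_between, df_within)
    return f, p


@lru_cache(maxsize=512)
def _studentized_range_crit(alpha: float, k: int, df: int) -> float:
    """1 - alpha quantile of the studentized range (numerically integrated)."""
    return float(stats.studentized_range.ppf(1.0 - alpha, k, df))


@dataclass
class TukeyResult:
    unit_id: int
    p_anova: float
    separated_pairs: set[tuple[str, str]]
    n_pairs: int
    degenerate: bool = False

    @property
    def fraction_separated(self) -> float:
        return len(self.separated_pairs) / self.n_pairs


def anova_tukey(nspace: NSpaceMatrix, unit: int, alpha: float = 0.01) -> TukeyResult:
    """One-way ANOVA across conditions plus Tukey–Kramer pair separation.

    A pair (c1, c2) is declared separated when its studentized-range
    statistic ``|m1 - m2| / sqrt(MSW/2 * (1/n1 + 1/n2))`` exceeds the
    1 - alpha quantile of the studentized range with (k, N - k) parameters
    (the Tukey–Kramer criterion for unbalanced groups).
    """
    col = int(np.flatnonzero(nspace.unit_ids == unit)[0])
    values = nspace.values[:, col]
    labels = nspace.condition_ids
    order, means, counts = _condition_means(values, labels)
    if (counts < 2).any():
        raise ValueError("Tukey-Kramer requires >= 2 trials per condition")
    k, n = len(order), len(values)

    ss_within = 0.0
    for cid in order:
        sel = values[labels == cid]
        ss_within += ((sel - sel.mean()) ** 2).sum()
    df_within = n - k
    msw = ss_within / df_within

    _, p = oneway_anova(values[:, None], labels)
    p_anova = float(p[0])

    pairs = list(combinations(range(k), 2))
    if msw == 0.0:
        separated = {
            (order[i], order[j]) for i, j in pairs if means[i] != means[j]
        }
        return TukeyResult(unit, p_anova, separated, len(pairs), degenerate=True)

    q_crit = _studentized_range_crit(alpha, k, df_within)
    separated = set()
    for i, j in pairs:
        se = np.sqrt(msw / 2.0 * (1.0 / counts[i] + 1.0 / counts[j]))
        if abs(means[i] - means[j]) / se > q_crit:
            separated.add((order[i], order[j]))
    return TukeyResult(unit, p_anova, separated, len(pairs))


@dataclass
class TunedFractionCurve:
    """Fraction of units significantly tuned per time point."""

    time: np.ndarray
    fraction: np.ndarray
    boundary: int
    alpha: float
    sem: np.ndarray | None = None
    n_units: int = 0


def sliding_anova(
    tensor: RateTensor,
    alpha: float = 0.01,
    *,
    unit_chunk: int = 16,
) -> TunedFractionCurve:
    """Per-time-point one-way ANOVA across conditions for every unit.

    Returns the fraction of units with p < alpha at each point of the doubly
    aligned axis.  Units are processed in chunks to bound memory.
    """
    labels = tensor.condition_ids
    if len(set(labels)) < 2:
        raise ValueError("sliding ANOVA needs at least two conditions")
    n_units = tensor.rates.shape[0]
    tuned = np.zeros(tensor.rates.shape[2])
    for start in range(0, n_units, unit_chunk):
        block = tensor.rates[start : start + unit_chunk]   # u x trials x bins
        values = np.moveaxis(block, 1, 0)                  # trials x u x bins
        _, p = oneway_anova(values, labels)
        tuned += (p < alpha).sum(axis=0)
    return TunedFractionCurve(
        time=tensor.time,
        fraction=tuned / n_units,
        boundary=tensor.boundary,
        alpha=alpha,
        n_units=n_units,
    )


def average_curves(curves: list[TunedFractionCurve]) -> TunedFractionCurve:
    """Average tuned-fraction curves across sessions, with s.e.m."""
    stackable = np.array([c.fraction for c in curves])
    sem = stackable.std(axis=0, ddof=1) / np.sqrt(len(curves)) if len(curves) > 1 else None
    first = curves[0]
    return TunedFractionCurve(
        time=first.time,
        fraction=stackable.mean(axis=0),
        boundary=first.boundary,
        alpha=first.alpha,
        sem=sem,
        n_units=sum(c.n_units for c in curves),
    )


def population_rate_curve(tensor: RateTensor) -> TunedFractionCurve:
    """Mean population rate modulation over time (Hz), an alternative
    "population activity" curve for the latency estimate: per time point,
    the mean over units of |rate - pre-cue mean rate| averaged over trials.
    """
    pre_cue = tensor.time[: tensor.boundary] < 0
    baseline = tensor.rates[:, :, :tensor.boundary][:, :, pre_cue].mean(
        axis=2, keepdims=True
    )
    modulation = np.abs(tensor.rates - baseline).mean(axis=(0, 1))
    return TunedFractionCurve(
        time=tensor.time,
        fraction=modulation,
        boundary=tensor.boundary,
        alpha=float("nan"),
        n_units=tensor.rates.shape[0],
    )


def response_latency(
    curve: TunedFractionCurve,
    cue_time: float = 0.0,
    peak_window: tuple[float, float] | None = None,
) -> float:
    """Latency: first time after cue onset reaching 75% of the post-cue peak.

    The peak is searched on the cue-aligned segment within ``peak_window``
    (default: the 700 ms cue epoch).  Returns NaN with a warning when the
    curve is flat (peak not above the pre-cue baseline).
    """
    time = curve.time[: curve.boundary]
    frac = curve.fraction[: curve.boundary]
    if peak_window is None:
        peak_window = (cue_time, cue_time + 0.7)
    in_window = (time >= peak_window[0]) & (time <= peak_window[1])
    if not in_window.any():
        raise ValueError("peak window outside the cue-aligned segment")
    peak = frac[in_window].max()
    pre_cue = frac[time < cue_time]
    baseline = pre_cue.mean() if pre_cue.size else 0.0
    if peak <= baseline + 1e-9:
        warnings.warn("flat tuning curve: latency undefined", stacklevel=2)
        return float("nan")
    threshold = 0.75 * peak
    after = np.flatnonzero((time >= cue_time) & (frac >= threshold))
    if after.size == 0:
        warnings.warn("tuning curve never reaches 75% of peak after cue", stacklevel=2)
        return float("nan")
    return float(time[after[0]] - cue_time)
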