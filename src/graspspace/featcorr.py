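"""Time-resolved feature-code correlation between areas.

For each area, spiking is binned at 10 ms, smoothed (sigma = 300 ms) and
doubly aligned; at every time bin the Euclidean distance between the rate
vectors of all trial pairs gives an m x m modulation pattern.  Correlating
the patterns of two areas per bin (Spearman's r over the vectorized strict
upper triangles) yields a correlation time course per area pair (AIP-F5,
AIP-M1, F5-M1): a time-resolved representational-similarity measure of how
strongly the two populations share their trial-by-trial feature code.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform

from .prep import RateTensor


@dataclass
class TrialDistanceSeries:
    """Per-bin condensed trial-pair distance vectors for one area.

    ``distances[b]`` is the strict-upper-triangle vector (length
    m * (m - 1) / 2) of the m x m Euclidean trial-distance matrix at bin b.
    """

    distances: np.ndarray      # bins x n_pairs
    time: np.ndarray
    boundary: int
    trial_ids: np.ndarray
    condition_ids: np.ndarray
    area: str | None = None

    @property
    def n_trials(self) -> int:
        return len(self.trial_ids)

    def matrix_at(self, bin_index: int) -> np.ndarray:
        return squareform(self.distances[bin_index])

    def centred_ranks(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-bin mean-centred ordinal ranks of the distance vectors.

        Cached; bins with constant distances are flagged invalid.  Distances
        are continuous, so ordinal ranks coincide with tie-averaged ranks
        almost surely and Pearson on them is Spearman's r.
        """
        cached = getattr(self, "_rank_cache", None)
        if cached is not None:
            return cached
        n_bins, n_pairs = self.distances.shape
        ranks = np.empty((n_bins, n_pairs), dtype=np.float64)
        valid = np.ptp(self.distances, axis=1) > 0
        arange = np.arange(n_pairs, dtype=np.float64)
        mid = (n_pairs - 1) / 2.0
        for b in range(n_bins):
            order = np.argsort(self.distances[b], kind="stable")
            ranks[b, order] = arange
        ranks -= mid
        self._rank_cache = (ranks, valid)
        return self._rank_cache


def trial_distance_series(
    tensor: RateTensor, area: str | None = None, baseline_subtract: bool = False
) -> TrialDistanceSeries:
    """Euclidean distances between all trial pairs at every time bin.

    By default distances are taken on the raw smoothed rates; with
    ``baseline_subtract`` each unit/trial is referenced to its mean pre-cue
    rate first.
    """
    n_units, n_trials, n_bins = tensor.rates.shape
    if n_trials < 2:
        raise ValueError("trial distances need at least two trials")
    rates = tensor.rates
    if baseline_subtract:
        pre_cue = tensor.time[: tensor.boundary] < 0
        baseline = rates[:, :, :tensor.boundary][:, :, pre_cue].mean(
            axis=2, keepdims=True
        )
        rates = rates - baseline
    iu, ju = np.triu_indices(n_trials, k=1)
    distances = np.empty((n_bins, len(iu)), dtype=np.float32)
    for b in range(n_bins):
        x = rates[:, :, b].T.astype(np.float64)   # trials x units
        sq = (x**2).sum(axis=1)
        d2 = sq[:, None] + sq[None, :] - 2.0 * (x @ x.T)
        distances[b] = np.sqrt(np.maximum(d2[iu, ju], 0.0))
    return TrialDistanceSeries(
        distances=distances,
        time=tensor.time,
        boundary=tensor.boundary,
        trial_ids=tensor.trial_ids,
        condition_ids=tensor.condition_ids,
        area=area,
    )


@dataclass
class CorrelationTimecourse:
    """Spearman r per time bin for one area pair; NaN where undefined."""

    time: np.ndarray
    r: np.ndarray
    boundary: int
    pair: tuple[str | None, str | None] = (None, None)


def correlate_areas(
    series_a: TrialDistanceSeries, series_b: TrialDistanceSeries
) -> CorrelationTimecourse:
    """Per-bin Spearman correlation of two areas' trial-pair distances.

    Bins where either distance vector is constant give a missing value
    (NaN), never zero.
    """
    if series_a.distances.shape != series_b.distances.shape:
        raise ValueError("series must share trials and bins")
    if not np.array_equal(series_a.trial_ids, series_b.trial_ids):
        raise ValueError("series must be computed on the same trials")

    ra, valid_a = series_a.centred_ranks()
    rb, valid_b = series_b.centred_ranks()
    ok = valid_a & valid_b
    r = np.full(series_a.distances.shape[0], np.nan)
    if ok.any():
        denom = np.sqrt(
            np.einsum("ij,ij->i", ra[ok], ra[ok])
            * np.einsum("ij,ij->i", rb[ok], rb[ok])
        )
        vals = np.einsum("ij,ij->i", ra[ok], rb[ok])
        with np.errstate(invalid="ignore"):
            r[ok] = np.where(denom > 0, vals / denom, np.nan)
    return CorrelationTimecourse(
        time=series_a.time,
        r=r,
        boundary=series_a.boundary,
        pair=(series_a.area, series_b.area),
    )


def condition_distance_snapshot(
    series: TrialDistanceSeries, t: float, segment: str = "cue"
) -> pd.DataFrame:
    """The trial-distance matrix at time ``t``, rows/columns sorted by
    condition id (ties by trial id) for display or export.

    ``segment`` selects which part of the doubly aligned axis ``t`` refers
    to: 'cue' (relative to cue onset) or 'go' (relative to the go signal).
    """
    if segment == "cue":
        times, offset = series.time[: series.boundary], 0
    elif segment == "go":
        times, offset = series.time[series.boundary :], series.boundary
    else:
        raise ValueError("segment must be 'cue' or 'go'")
    if times.size == 0 or t < times.min() - 1e-9 or t > times.max() + 1e-9:
        raise ValueError(f"time {t} outside the {segment}-aligned axis")
    b = offset + int(np.argmin(np.abs(times - t)))

    full = series.matrix_at(b)
    order = np.lexsort((series.trial_ids, series.condition_ids))
    sorted_ids = [
        f"{series.condition_ids[i]}#{series.trial_ids[i]}" for i in order
    ]
    return pd.DataFrame(full[np.ix_(order, order)], index=sorted_ids, columns=sorted_ids)
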