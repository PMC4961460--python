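"""From raw sessions to aligned rate tensors, N-space and J-space matrices.

Spike trains are smoothed with a Gaussian kernel (default sigma = 50 ms for
sliding statistics, 300 ms for the feature-code correlation), trials are
doubly aligned — a cue-onset-aligned segment concatenated with a go-aligned
segment, absorbing the variable planning-epoch duration — and epoch-mean
matrices are extracted: the N-space (trials x units, baseline-relative mean
rates) and the J-space (trials x 27 mean hold-epoch joint angles after
low-pass filtering).

The kernel is truncated at +/- 5 sigma (< 1e-6 of its mass); no padding is
applied at trial edges, so rates near the edges are computed from observed
spikes only, a small documented downward bias.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal
from scipy.ndimage import gaussian_filter1d

from .synth import N_JOINT_ANGLES, SessionData

_TRUNCATE_SIGMAS = 5.0

#: epoch name -> (start event, end event)
EPOCH_EVENTS = {
    "fixation": ("fixation_on", "cue_on"),
    "cue": ("cue_on", "cue_off"),
    "plan": ("cue_off", "go"),
    "move": ("movement_onset", "hold_on"),
    "grasp": ("movement_onset", "hold_on"),   # alias
    "hold": ("hold_on", "hold_off"),
}


def gaussian_smooth(
    spike_times: np.ndarray, sigma: float, time_grid: np.ndarray
) -> np.ndarray:
    """Gaussian-kernel rate estimate on an arbitrary time grid.

    ``rate(t) = sum_spikes N(t - t_spike; sigma)`` with the kernel normalized
    so that the time integral of the output equals the spike count (for a
    grid covering the kernel support).  The kernel is cut at 5 sigma.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    time_grid = np.asarray(time_grid, dtype=float)
    if time_grid.size == 0:
        raise ValueError("time grid must not be empty")
    spike_times = np.asarray(spike_times, dtype=float)
    rate = np.zeros_like(time_grid)
    if spike_times.size == 0:
        return rate
    norm = 1.0 / (sigma * np.sqrt(2.0 * np.pi))
    cutoff = _TRUNCATE_SIGMAS * sigma
    for t_spike in spike_times:
        d = time_grid - t_spike
        mask = np.abs(d) <= cutoff
        rate[mask] += norm * np.exp(-0.5 * (d[mask] / sigma) ** 2)
    return rate


def binned_rates(
    trial_spikes: Sequence[np.ndarray],
    t_stop: float,
    bin_width: float,
    sigma: float,
    t_start: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Fast binned-and-smoothed rates for all units of one trial.

    Returns ``(rates [units x bins] in Hz, bin-centre times)``.  Spike counts
    are binned at ``bin_width`` and convolved with a discrete Gaussian
    (truncated at 5 sigma, zero-padded edges), which conserves total spike
    mass away from the trial edges.
    """
    n_bins = int(round((t_stop - t_start) / bin_width))
    edges_scale = 1.0 / bin_width
    counts = np.empty((len(trial_spikes), n_bins))
    for u, train in enumerate(trial_spikes):
        idx = np.floor((train - t_start) * edges_scale).astype(int)
        idx = idx[(idx >= 0) & (idx < n_bins)]
        counts[u] = np.bincount(idx, minlength=n_bins)
    sigma_bins = sigma / bin_width
    if sigma_bins <= 10.0:
        rates = gaussian_filter1d(
            counts, sigma_bins, axis=1, mode="constant", truncate=_TRUNCATE_SIGMAS
        ) / bin_width
    else:
        # wide kernels: FFT convolution (zero-padded edges, same normalization)
        half = int(_TRUNCATE_SIGMAS * sigma_bins + 0.5)
        x = np.arange(-half, half + 1)
        kernel = np.exp(-0.5 * (x / sigma_bins) ** 2)
        kernel /= kernel.sum()
        rates = signal.fftconvolve(counts, kernel[None, :], mode="same", axes=1)
        rates /= bin_width
        np.maximum(rates, 0.0, out=rates)   # clip FFT ringing below zero
    times = t_start + (np.arange(n_bins) + 0.5) * bin_width
    return rates, times


@dataclass
class RateTensor:
    """Smoothed rates on a doubly aligned time base.

    ``rates`` is units x trials x bins (Hz).  The output axis concatenates a
    cue-onset-aligned segment (``time`` relative to cue_on) and a go-aligned
    segment (``time`` relative to go); ``boundary`` is the index of the first
    go-aligned bin.
    """

    rates: np.ndarray
    time: np.ndarray
    boundary: int
    bin_width: float
    sigma: float
    trial_ids: np.ndarray
    condition_ids: np.ndarray
    unit_ids: np.ndarray
    window_cue: tuple[float, float]
    window_go: tuple[float, float] | None
    dropped_trials: list[int] = field(default_factory=list)

    @property
    def n_trials(self) -> int:
        return self.rates.shape[1]

    def select_units(self, unit_index: np.ndarray) -> "RateTensor":
        return RateTensor(
            rates=self.rates[unit_index],
            time=self.time,
            boundary=self.boundary,
            bin_width=self.bin_width,
            sigma=self.sigma,
            trial_ids=self.trial_ids,
            condition_ids=self.condition_ids,
            unit_ids=self.unit_ids[unit_index],
            window_cue=self.window_cue,
            window_go=self.window_go,
            dropped_trials=self.dropped_trials,
        )


def double_align(
    trial_rates: Sequence[np.ndarray],
    trial_times: Sequence[np.ndarray],
    trials: pd.DataFrame,
    window_cue: tuple[float, float],
    window_go: tuple[float, float] | None,
    bin_width: float,
    *,
    sigma: float = float("nan"),
    go_event: str = "go",
) -> RateTensor:
    """Concatenate cue-aligned and go-aligned rate segments per trial.

    ``trial_rates[t]`` is a units x bins array on the grid ``trial_times[t]``.
    Trials whose recorded span cannot cover a window are dropped with a
    warning.  ``window_go=None`` produces a cue-aligned-only tensor.
    """
    n_cue = int(round((window_cue[1] - window_cue[0]) / bin_width))
    n_go = (
        0 if window_go is None else int(round((window_go[1] - window_go[0]) / bin_width))
    )

    kept, dropped, segments = [], [], []
    for t, row in enumerate(trials.itertuples(index=False)):
        times = trial_times[t]
        t0, t1 = times[0], times[-1]
        start_cue = row.cue_on + window_cue[0]
        ok = start_cue >= t0 - bin_width and row.cue_on + window_cue[1] <= t1 + bin_width
        if window_go is not None:
            anchor = getattr(row, go_event)
            ok = ok and anchor + window_go[0] >= t0 - bin_width
            ok = ok and anchor + window_go[1] <= t1 + bin_width
        if not ok:
            dropped.append(t)
            continue
        # half-up rounding keeps half-sample offsets consistent across trials
        def _index(start: float) -> int:
            return max(int(np.floor((start - t0) / bin_width + 0.5 + 1e-9)), 0)

        i_cue = _index(start_cue)
        seg = trial_rates[t][:, i_cue : i_cue + n_cue]
        if window_go is not None:
            anchor = getattr(row, go_event)
            i_go = _index(anchor + window_go[0])
            seg = np.concatenate([seg, trial_rates[t][:, i_go : i_go + n_go]], axis=1)
        segments.append(seg)
        kept.append(t)

    if dropped:
        warnings.warn(
            f"double_align dropped {len(dropped)} trial(s) whose span did not "
            f"cover the requested windows: {dropped[:10]}",
            stacklevel=2,
        )
    if not kept:
        raise ValueError("no trial covers the requested alignment windows")

    rates = np.stack(segments, axis=1).astype(np.float32)  # units x trials x bins
    time_cue = window_cue[0] + (np.arange(n_cue) + 0.5) * bin_width
    time_go = (
        np.empty(0)
        if window_go is None
        else window_go[0] + (np.arange(n_go) + 0.5) * bin_width
    )
    return RateTensor(
        rates=rates,
        time=np.concatenate([time_cue, time_go]),
        boundary=n_cue,
        bin_width=bin_width,
        sigma=sigma,
        trial_ids=trials["trial_id"].to_numpy()[kept],
        condition_ids=trials["condition_id"].to_numpy()[kept],
        unit_ids=np.arange(trial_rates[0].shape[0]),
        window_cue=window_cue,
        window_go=window_go,
        dropped_trials=dropped,
    )


def build_rate_tensor(
    session: SessionData,
    *,
    bin_width: float,
    sigma: float,
    window_cue: tuple[float, float],
    window_go: tuple[float, float] | None,
    unit_index: np.ndarray | None = None,
    go_event: str = "go",
) -> RateTensor:
    """Smooth all spike trains of a session and doubly align them."""
    if unit_index is None:
        unit_index = np.arange(session.n_units)
    trial_rates, trial_times = [], []
    for t, row in enumerate(session.trials.itertuples(index=False)):
        trains = [session.spikes[t][u] for u in unit_index]
        rates, times = binned_rates(trains, row.hold_off, bin_width, sigma)
        trial_rates.append(rates)
        trial_times.append(times)
    tensor = double_align(
        trial_rates,
        trial_times,
        session.trials,
        window_cue,
        window_go,
        bin_width,
        sigma=sigma,
        go_event=go_event,
    )
    tensor.unit_ids = np.asarray(unit_index)
    return tensor


def save_rate_tensor(tensor: RateTensor, path) -> None:
    """Write a RateTensor as ``<path>.npz`` plus a ``<path>.json`` sidecar
    describing the axes (bin width, sigma, windows, boundary, ids)."""
    import json
    from pathlib import Path

    path = Path(path)
    np.savez_compressed(
        path.with_suffix(".npz"),
        rates=tensor.rates,
        time=tensor.time,
        trial_ids=tensor.trial_ids,
        condition_ids=np.asarray(tensor.condition_ids, dtype=str),
        unit_ids=tensor.unit_ids,
    )
    sidecar = {
        "axes": ["unit", "trial", "time_bin"],
        "bin_width_s": tensor.bin_width,
        "sigma_s": tensor.sigma,
        "boundary": tensor.boundary,
        "window_cue": list(tensor.window_cue),
        "window_go": list(tensor.window_go) if tensor.window_go else None,
        "dropped_trials": tensor.dropped_trials,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2) + "\n")


def load_rate_tensor(path) -> RateTensor:
    import json
    from pathlib import Path

    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    with np.load(path.with_suffix(".npz")) as data:
        return RateTensor(
            rates=data["rates"],
            time=data["time"],
            boundary=int(sidecar["boundary"]),
            bin_width=float(sidecar["bin_width_s"]),
            sigma=float(sidecar["sigma_s"]),
            trial_ids=data["trial_ids"],
            condition_ids=data["condition_ids"],
            unit_ids=data["unit_ids"],
            window_cue=tuple(sidecar["window_cue"]),
            window_go=tuple(sidecar["window_go"]) if sidecar["window_go"] else None,
            dropped_trials=list(sidecar["dropped_trials"]),
        )


@dataclass
class NSpaceMatrix:
    """Trials x units matrix of epoch-mean rates (Hz), baseline-relative."""

    values: np.ndarray
    trial_ids: np.ndarray
    condition_ids: np.ndarray
    unit_ids: np.ndarray
    epoch: str
    baseline_epoch: str | None


@dataclass
class JSpaceMatrix:
    """Trials x 27 matrix of mean hold-epoch joint angles (degrees)."""

    values: np.ndarray
    trial_ids: np.ndarray
    condition_ids: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape[1] != N_JOINT_ANGLES:
            raise ValueError(
                f"J-space requires exactly {N_JOINT_ANGLES} channels, "
                f"got {self.values.shape[1]}"
            )


def _epoch_bounds(row, epoch: str) -> tuple[float, float]:
    try:
        start_ev, end_ev = EPOCH_EVENTS[epoch]
    except KeyError:
        raise ValueError(f"unknown epoch {epoch!r}") from None
    t0, t1 = getattr(row, start_ev), getattr(row, end_ev)
    if t1 <= t0:
        raise ValueError(f"zero-length epoch {epoch!r} in trial {row.trial_id}")
    return t0, t1


def epoch_means(
    session: SessionData,
    epoch: str,
    baseline_epoch: str | None = "fixation",
    *,
    unit_index: np.ndarray | None = None,
) -> NSpaceMatrix:
    """Mean epoch firing rate per trial and unit, minus the per-trial mean
    rate in ``baseline_epoch`` (pass ``None`` for raw rates)."""
    if unit_index is None:
        unit_index = np.arange(session.n_units)
    n_trials = session.n_trials
    values = np.empty((n_trials, len(unit_index)))
    for t, row in enumerate(session.trials.itertuples(index=False)):
        t0, t1 = _epoch_bounds(row, epoch)
        if baseline_epoch is not None:
            b0, b1 = _epoch_bounds(row, baseline_epoch)
        for j, u in enumerate(unit_index):
            train = session.spikes[t][u]
            rate = np.searchsorted(train, (t0, t1))
            value = (rate[1] - rate[0]) / (t1 - t0)
            if baseline_epoch is not None:
                base = np.searchsorted(train, (b0, b1))
                value -= (base[1] - base[0]) / (b1 - b0)
            values[t, j] = value
    return NSpaceMatrix(
        values=values,
        trial_ids=session.trials["trial_id"].to_numpy(),
        condition_ids=session.trials["condition_id"].to_numpy(),
        unit_ids=np.asarray(unit_index),
        epoch=epoch,
        baseline_epoch=baseline_epoch,
    )


def _lowpass(trajectory: np.ndarray, fs: float, cutoff_hz: float) -> np.ndarray:
    """Zero-phase Kaiser-window FIR low-pass along the time axis."""
    numtaps = 31
    if trajectory.shape[0] <= 3 * numtaps:
        numtaps = max(5, 2 * (trajectory.shape[0] // 6) + 1)
    taps = signal.firwin(numtaps, cutoff_hz, window=("kaiser", 5.0), fs=fs)
    return signal.filtfilt(taps, [1.0], trajectory, axis=0)


def build_jspace(
    session: SessionData, cutoff_hz: float = 10.0
) -> JSpaceMatrix:
    """Low-pass filter the 50 Hz trajectories and average the hold epoch."""
    if not 5.0 <= cutoff_hz <= 20.0:
        raise ValueError("cutoff_hz must lie within the 5-20 Hz passband range")
    fs = session.kin_rate_hz
    dt = 1.0 / fs
    values = np.empty((session.n_trials, N_JOINT_ANGLES))
    for t, row in enumerate(session.trials.itertuples(index=False)):
        traj = session.kinematics[t]
        if traj.shape[1] != N_JOINT_ANGLES:
            raise ValueError(
                f"J-space requires exactly {N_JOINT_ANGLES} channels, "
                f"got {traj.shape[1]}"
            )
        filtered = _lowpass(traj, fs, cutoff_hz)
        i0 = int(np.ceil(row.hold_on / dt))
        i1 = int(np.floor(row.hold_off / dt)) + 1
        values[t] = filtered[i0:i1].mean(axis=0)
    return JSpaceMatrix(
        values=values,
        trial_ids=session.trials["trial_id"].to_numpy(),
        condition_ids=session.trials["condition_id"].to_numpy(),
    )
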