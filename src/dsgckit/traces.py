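"""Preprocessing of raw patch-clamp sweeps into per-direction scalar responses.

A :class:`SweepSet` holds the recorded traces for one cell: for each of the
stimulus directions (canonically 8 at 45° spacing) there are several trial
repetitions of either voltage-clamp current (pA), current-clamp voltage (mV),
or a cell-attached pipette signal.  The operations here reduce those sweeps to
the per-direction numbers the tuning statistics consume: trial-averaged,
baseline-subtracted traces; spike times and maximum firing rates; peak ON/OFF
currents; and peak subthreshold depolarizations.

Responses to a moving bar arrive in two phases — an ON response as the bright
bar enters the receptive field and an OFF response as it leaves — which are
driven by separate circuits and therefore analyzed independently, each inside
its own 1.5 s window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .errors import InvalidArgumentError, InvalidInputError

RecordingMode = Literal["voltage_clamp", "current_clamp", "cell_attached"]
Pathway = Literal["ON", "OFF"]


@dataclass
class SweepSet:
    """Direction-indexed, trial-replicated traces with sampling metadata.

    Parameters
    ----------
    directions
        Stimulus directions in degrees, unique, each in [0, 360).
    traces
        Array of shape ``(n_directions, n_trials, n_samples)``.
    sampling_rate
        Samples per second (Hz).
    recording_mode
        One of ``voltage_clamp``, ``current_clamp``, ``cell_attached``.
    units
        ``pA`` for currents, ``mV`` for membrane potential.
    holding_mv
        Command potential for voltage clamp, else ``None``.
    """

    directions: np.ndarray
    traces: np.ndarray
    sampling_rate: float
    recording_mode: RecordingMode
    units: str = "pA"
    holding_mv: float | None = None

    def __post_init__(self) -> None:
        self.directions = np.asarray(self.directions, dtype=float)
        self.traces = np.asarray(self.traces, dtype=float)
        if self.traces.ndim != 3:
            raise InvalidInputError(
                "traces must be (n_directions, n_trials, n_samples); ragged "
                "trial lengths are not representable"
            )
        if self.traces.shape[0] != self.directions.size:
            raise InvalidInputError("one trace block per direction required")
        if self.sampling_rate <= 0:
            raise InvalidInputError("sampling_rate must be positive")
        if np.unique(self.directions).size != self.directions.size:
            raise InvalidInputError("directions must be unique")

    @property
    def n_trials(self) -> int:
        return self.traces.shape[1]

    @property
    def n_samples(self) -> int:
        return self.traces.shape[2]

    @property
    def time(self) -> np.ndarray:
        """Sample times in seconds."""
        return np.arange(self.n_samples) / self.sampling_rate


@dataclass
class ResponseWindows:
    """ON/OFF analysis windows and the baseline interval, all in seconds.

    ``on_start`` / ``off_start`` mark the beginning of the two disjoint 1.5 s
    windows holding the ON (bar entry) and OFF (bar exit) responses.  The
    baseline is the initial stretch of the sweep before the stimulus reaches
    the receptive field; its mean is subtracted from every sample.
    """

    on_start: float = 0.5
    off_start: float = 2.5
    width: float = 1.5
    baseline_width: float = 0.5

    def __post_init__(self) -> None:
        if self.width <= 0 or self.baseline_width <= 0:
            raise InvalidArgumentError("window widths must be positive")
        on = (self.on_start, self.on_start + self.width)
        off = (self.off_start, self.off_start + self.width)
        if max(on[0], off[0]) < min(on[1], off[1]):
            raise InvalidInputError("ON and OFF windows must be disjoint")

    def start(self, pathway: Pathway) -> float:
        return self.on_start if pathway == "ON" else self.off_start

    def slice(self, pathway: Pathway, sampling_rate: float, n_samples: int) -> slice:
        """Index slice of the given response window on a sample grid."""
        lo = int(round(self.start(pathway) * sampling_rate))
        hi = int(round((self.start(pathway) + self.width) * sampling_rate))
        if lo < 0 or hi > n_samples:
            raise InvalidInputError("response window lies outside the trace")
        return slice(lo, hi)


@dataclass
class PeakTable:
    """Per (direction, pathway) peak responses for one cell.

    ``table`` has columns ``direction_deg``, ``pathway``, ``metric``,
    ``value`` (signed peak), ``magnitude`` (absolute value), ``t_peak_s``,
    ``units``.
    """

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def magnitudes(self, pathway: Pathway) -> tuple[np.ndarray, np.ndarray]:
        """(directions, |peak|) for one pathway, sorted by direction."""
        sub = self.table[self.table["pathway"] == pathway].sort_values("direction_deg")
        return sub["direction_deg"].to_numpy(), sub["magnitude"].to_numpy()


def average_trials(sweeps: SweepSet) -> np.ndarray:
    """Pointwise mean across trials for each direction.

    Returns an array of shape ``(n_directions, n_samples)``.  Raw traces are
    averaged across the trial repetitions of each direction before any peak
    extraction, which suppresses trial noise by ``1/sqrt(n_trials)``.
    """
    if sweeps.n_trials < 1:
        raise InvalidInputError("at least one trial per direction required")
    return sweeps.traces.mean(axis=1)


def baseline_subtract(
    trace: np.ndarray, windows: ResponseWindows, sampling_rate: float
) -> np.ndarray:
    """Subtract the mean of the initial baseline interval from a trace.

    The baseline is the first ``windows.baseline_width`` seconds (default
    500 ms).  Idempotent: the baseline mean of the output is zero.
    """
    trace = np.asarray(trace, dtype=float)
    n_base = int(round(windows.baseline_width * sampling_rate))
    if n_base < 1 or n_base > trace.shape[-1]:
        raise InvalidInputError("baseline window exceeds trace length")
    return trace - trace[..., :n_base].mean(axis=-1, keepdims=True)


def _bandpass(trace: np.ndarray, low: float, high: float, fs: float) -> np.ndarray:
    # zero-phase to keep spike times unshifted
    sos = signal.butter(2, [low, high], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, trace)


def detect_spikes(
    trace: np.ndarray,
    sampling_rate: float,
    band: tuple[float, float] = (80.0, 2000.0),
    threshold: float | None = None,
    polarity: int = 1,
    refractory: float = 0.002,
) -> np.ndarray:
    """Spike times (s) from a cell-attached sweep by band-pass + threshold.

    The trace is band-pass filtered (default 80–2000 Hz, zero-phase) and
    upward crossings of ``threshold`` are reported.  When ``threshold`` is
    ``None`` it is set automatically to 5× the median absolute deviation of
    the filtered trace — an automated stand-in for per-cell manual threshold
    choice.  ``polarity=-1`` detects downward spikes.  Crossings closer than
    ``refractory`` seconds to the previous accepted event are merged into it.
    """
    low, high = band
    if sampling_rate <= 2 * high:
        raise InvalidArgumentError("sampling_rate must exceed twice the upper band edge")
    filt = _bandpass(np.asarray(trace, dtype=float), low, high, sampling_rate)
    if polarity < 0:
        filt = -filt
    if threshold is None:
        mad = np.median(np.abs(filt - np.median(filt)))
        threshold = 5.0 * mad
    above = filt > threshold
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    if crossings.size == 0:
        return np.empty(0)
    times = crossings / sampling_rate
    keep = [times[0]]
    for t in times[1:]:
        if t - keep[-1] >= refractory:
            keep.append(t)
    return np.asarray(keep)


def max_firing_rate(
    spike_times: Sequence[float],
    windows: ResponseWindows,
    pathway: Pathway,
    slide_width: float = 0.1,
) -> float:
    """Maximum firing rate (Hz) in one response window by a sliding count.

    Slides an interval of ``slide_width`` seconds across the 1.5 s response
    window and returns the maximum of (spike count)/(slide width).  The
    search is event-driven — a candidate interval starts at each spike — which
    attains the supremum over all continuous placements.  Counting is
    half-open ``[t, t+slide)``.  No spikes → 0 Hz.
    """
    if slide_width <= 0 or slide_width > windows.width:
        raise InvalidArgumentError("slide_width must be in (0, window width]")
    t0 = windows.start(pathway)
    t1 = t0 + windows.width
    spikes = np.sort(np.asarray(spike_times, dtype=float))
    spikes = spikes[(spikes >= t0) & (spikes < t1)]
    if spikes.size == 0:
        return 0.0
    best = 0
    for start in spikes:
        start = min(start, t1 - slide_width)
        n = np.count_nonzero((spikes >= start) & (spikes < start + slide_width))
        best = max(best, n)
    return best / slide_width


def peak_current(
    mean_trace: np.ndarray,
    windows: ResponseWindows,
    pathway: Pathway,
    mode: Literal["IPSC", "EPSC"],
    sampling_rate: float,
) -> tuple[float, float]:
    """Signed peak current and its time within one response window.

    IPSCs (recorded at the cation reversal, 0 mV) are outward/positive, so
    the peak is the window maximum; EPSCs (recorded at the chloride reversal,
    −60 mV) are inward/negative, so the peak is the window minimum.  Ties go
    to the earliest sample.  The trace must already be baseline-subtracted.
    """
    mean_trace = np.asarray(mean_trace, dtype=float)
    sl = windows.slice(pathway, sampling_rate, mean_trace.size)
    seg = mean_trace[sl]
    idx = int(np.argmax(seg)) if mode == "IPSC" else int(np.argmin(seg))
    t_peak = (sl.start + idx) / sampling_rate
    return float(seg[idx]), float(t_peak)


def remove_spikes_and_peak_vm(
    trace: np.ndarray,
    windows: ResponseWindows,
    pathway: Pathway,
    sampling_rate: float,
    lowpass_cutoff: float = 50.0,
) -> float:
    """Peak subthreshold depolarization (mV) after low-pass spike removal.

    Current-clamp traces contain action potentials riding on the synaptic
    depolarization; a zero-phase low-pass filter (default 50 Hz) removes the
    brief spikes while passing the slow envelope, whose window maximum is the
    peak subthreshold ΔVm.  The trace must be baseline-subtracted so the
    result is a depolarization relative to rest.
    """
    if lowpass_cutoff >= sampling_rate / 2:
        raise InvalidArgumentError("lowpass cutoff must be below Nyquist")
    sos = signal.butter(4, lowpass_cutoff, btype="lowpass", fs=sampling_rate, output="sos")
    filt = signal.sosfiltfilt(sos, np.asarray(trace, dtype=float))
    sl = windows.slice(pathway, sampling_rate, filt.size)
    return float(np.max(filt[sl]))


def build_peak_table(
    sweeps: SweepSet,
    windows: ResponseWindows,
    metric: Literal["IPSC", "EPSC", "spike_rate", "delta_vm"],
    **kwargs,
) -> PeakTable:
    """Reduce a SweepSet to a PeakTable for the requested metric.

    Voltage-clamp sweeps are trial-averaged, baseline-subtracted and peak
    currents extracted per window; cell-attached sweeps are spike-detected per
    trial and the trial-mean maximum firing rate reported; current-clamp
    sweeps are averaged, baseline-subtracted, low-pass filtered and the peak
    ΔVm reported.  Extra keyword arguments pass through to the respective
    extraction operation.
    """
    rows = []
    fs = sweeps.sampling_rate
    if metric in ("IPSC", "EPSC"):
        means = average_trials(sweeps)
        for d, tr in zip(sweeps.directions, means):
            sub = baseline_subtract(tr, windows, fs)
            for pathway in ("ON", "OFF"):
                val, tpk = peak_current(sub, windows, pathway, metric, fs)
                rows.append((d, pathway, metric, val, abs(val), tpk, sweeps.units))
    elif metric == "spike_rate":
        for d, block in zip(sweeps.directions, sweeps.traces):
            for pathway in ("ON", "OFF"):
                rates = [
                    max_firing_rate(
                        detect_spikes(trial, fs, **{k: v for k, v in kwargs.items()
                                                    if k in ("band", "threshold", "polarity", "refractory")}),
                        windows,
                        pathway,
                        slide_width=kwargs.get("slide_width", 0.1),
                    )
                    for trial in block
                ]
                rate = float(np.mean(rates))
                rows.append((d, pathway, metric, rate, rate, np.nan, "Hz"))
    elif metric == "delta_vm":
        means = average_trials(sweeps)
        for d, tr in zip(sweeps.directions, means):
            sub = baseline_subtract(tr, windows, fs)
            for pathway in ("ON", "OFF"):
                val = remove_spikes_and_peak_vm(
                    sub, windows, pathway, fs,
                    lowpass_cutoff=kwargs.get("lowpass_cutoff", 50.0),
                )
                rows.append((d, pathway, metric, val, abs(val), np.nan, "mV"))
    else:
        raise InvalidArgumentError(f"unknown metric {metric!r}")
    table = pd.DataFrame(
        rows,
        columns=["direction_deg", "pathway", "metric", "value", "magnitude", "t_peak_s", "units"],
    )
    return PeakTable(table)
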