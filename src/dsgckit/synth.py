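"""Synthetic recordings with known ground truth for every pipeline stage.

No public dataset accompanies this kind of experiment, so the toolkit ships
generators that emulate each data stream the pipeline consumes — direction-
tuned postsynaptic currents and spike trains, linear IV datasets, dual-camera
pupil-marker streams, and dendritic-field point clouds — each returning the
latent parameters used, so downstream stages can be tested as parameter
recovery.

Tuning is modeled by a von-Mises-shaped kernel rescaled so the preferred
direction responds with f = 1 and the opposite direction with f = 0:

    f(Δ) = (exp(κ·cos Δ) − exp(−κ)) / (exp(κ) − exp(−κ))

with the concentration κ solved from a half-width parameter (the angular
offset at which f drops to 1/2; 90° gives the cosine kernel, κ → 0).
Synaptic transients are alpha functions a(t) = (t/τ)·exp(1 − t/τ); eye
saccades follow a minimum-jerk displacement profile.  All generators are
deterministic given (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import InvalidArgumentError
from .okr import (
    DEFAULT_SACCADE_THRESHOLD,
    DIRECTION_VECTORS,
    PUPIL_MARKERS,
    REFLECTION_MARKERS,
    StimSpec,
)
from .paired import IvCurve
from .traces import ResponseWindows, SweepSet

DEFAULT_SAMPLING_RATE = 10_000.0  # Hz, matching typical patch-clamp acquisition
DEFAULT_SWEEP_DURATION = 4.5  # s, one moving-bar presentation


# --------------------------------------------------------------------------- #
# specs

@dataclass
class TuningSpec:
    """Direction-tuned response parameters for PSC / spike / Vm generators.

    ``peak_pd`` and ``peak_nd`` are the noiseless response amplitudes at the
    preferred direction and 180° opposite (pA for currents, Hz for spike
    rates, mV for voltage); intermediate directions follow the rescaled
    von-Mises kernel with the given half-width.
    """

    preferred_direction: float = 180.0  # degrees
    tuning_width: float = 90.0  # degrees, half-width at half maximum of f
    peak_pd: float = 600.0
    peak_nd: float = 100.0
    on_latency: float = 0.1  # s after ON window start
    off_latency: float = 0.1  # s after OFF window start
    kernel_tau: float = 0.08  # s, alpha-function time constant
    noise_sd: float = 10.0
    n_trials: int = 3

    def __post_init__(self) -> None:
        if not (0 <= self.preferred_direction < 360):
            raise InvalidArgumentError("preferred_direction must be in [0, 360)")
        if not (0 < self.tuning_width < 180):
            raise InvalidArgumentError("tuning_width must be in (0, 180)")
        if not (self.peak_pd >= self.peak_nd >= 0):
            raise InvalidArgumentError("require peak_pd >= peak_nd >= 0")
        if self.noise_sd < 0:
            raise InvalidArgumentError("noise_sd must be non-negative")
        if self.n_trials < 1:
            raise InvalidArgumentError("n_trials must be >= 1")


@dataclass
class EyeSimSpec:
    """Latent eye-movement and rendering parameters for the OKR generator.

    The latent eye tracks the stimulus at ``gain_true`` of its velocity and
    is reset by saccades of ``saccade_amplitude`` opposite the stimulus
    direction, arriving at ``saccade_rate`` per second.  Defaults reflect a
    standard presentation: 2°/s gratings for 45 s filmed at 100 fps, with
    mouse-like resetting saccades (~10°, several hundred °/s).
    """

    gain_true: float = 0.7
    stim_direction: str = "posterior"
    stim_velocity: float = 2.0  # °/s
    duration: float = 45.0  # s
    fps: float = 100.0
    saccade_rate: float = 0.3  # events/s
    saccade_amplitude: float = 10.0  # degrees
    saccade_peak_velocity: float = 700.0  # °/s
    position_noise_sd: float = 0.05  # degrees
    dropout_prob: float = 0.05

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise InvalidArgumentError("fps must be positive")
        if not (0 <= self.dropout_prob < 1):
            raise InvalidArgumentError("dropout_prob must be in [0, 1)")
        if self.stim_direction not in DIRECTION_VECTORS:
            raise InvalidArgumentError(f"unknown stim_direction {self.stim_direction!r}")
        if self.saccade_rate > 0 and self.saccade_peak_velocity <= DEFAULT_SACCADE_THRESHOLD:
            raise InvalidArgumentError(
                "saccade_peak_velocity must exceed the classification threshold"
            )


@dataclass
class IvSimSpec:
    """Linear IV ground truth: I = g_true · (V_hold − e_rev_true) + noise."""

    g_true: float = 2.0  # nS
    e_rev_true: float = -60.0  # mV
    holds: Sequence[float] = (-80.0, -70.0, -60.0, -50.0, -40.0)
    noise_sd: float = 5.0  # pA
    n_trials: int = 3

    def __post_init__(self) -> None:
        if len(set(self.holds)) < 2:
            raise InvalidArgumentError("need >= 2 distinct holding potentials")
        if self.g_true < 0:
            raise InvalidArgumentError("g_true must be non-negative")
        if self.noise_sd < 0:
            raise InvalidArgumentError("noise_sd must be non-negative")


# --------------------------------------------------------------------------- #
# tuning kernel

def _kappa_from_half_width(half_width_deg: float) -> float:
    """Concentration whose rescaled von-Mises kernel halves at half_width."""
    w = np.deg2rad(half_width_deg)

    def f_of_kappa(kappa: float) -> float:
        if abs(kappa) < 1e-8:
            return (1.0 + np.cos(w)) / 2.0  # κ→0 cosine limit
        return (np.exp(kappa * np.cos(w)) - np.exp(-kappa)) / (
            np.exp(kappa) - np.exp(-kappa)
        )

    return brentq(lambda k: f_of_kappa(k) - 0.5, -50.0, 50.0, xtol=1e-10)


def tuning_kernel(delta_deg: np.ndarray, half_width_deg: float) -> np.ndarray:
    """Unimodal kernel with f(0)=1, f(180°)=0, f(half_width)=1/2."""
    kappa = _kappa_from_half_width(half_width_deg)
    d = np.deg2rad(np.asarray(delta_deg, dtype=float))
    if abs(kappa) < 1e-8:
        return (1.0 + np.cos(d)) / 2.0
    return (np.exp(kappa * np.cos(d)) - np.exp(-kappa)) / (np.exp(kappa) - np.exp(-kappa))


def tuned_peak(spec: TuningSpec, directions: np.ndarray) -> np.ndarray:
    """Noiseless response amplitude per direction under the tuning law."""
    f = tuning_kernel(
        np.asarray(directions, dtype=float) - spec.preferred_direction,
        spec.tuning_width,
    )
    return spec.peak_nd + (spec.peak_pd - spec.peak_nd) * f


def alpha_transient(t: np.ndarray, onset: float, tau: float) -> np.ndarray:
    """Alpha function (t/τ)·e^(1−t/τ) starting at ``onset``; unit peak at onset+τ."""
    s = np.maximum(t - onset, 0.0) / tau
    return s * np.exp(1.0 - s)


def _check_directions(directions: Sequence[float]) -> np.ndarray:
    d = np.asarray(directions, dtype=float)
    if d.size == 0:
        raise InvalidArgumentError("directions must be non-empty")
    if np.any((d < 0) | (d >= 360)):
        raise InvalidArgumentError("directions must be in [0, 360)")
    return d


# --------------------------------------------------------------------------- #
# electrophysiology generators

def gen_psc_sweeps(
    spec: TuningSpec,
    directions: Sequence[float],
    seed: int,
    windows: ResponseWindows | None = None,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
    duration: float = DEFAULT_SWEEP_DURATION,
    polarity: int = 1,
    recording_mode: str = "voltage_clamp",
    units: str = "pA",
    holding_mv: float | None = 0.0,
) -> SweepSet:
    """Direction-tuned postsynaptic-current sweeps with trial noise.

    Each sweep holds an ON and an OFF alpha-function transient inside the two
    response windows, with noiseless peak amplitude following the tuning law
    at that direction, plus additive white noise.  ``polarity=+1`` renders
    outward (IPSC-like) deflections, ``-1`` inward (EPSC-like).
    """
    dirs = _check_directions(directions)
    windows = windows or ResponseWindows()
    rng = np.random.default_rng(seed)
    n = int(round(duration * sampling_rate))
    t = np.arange(n) / sampling_rate
    peaks = tuned_peak(spec, dirs)
    shape = (
        alpha_transient(t, windows.on_start + spec.on_latency, spec.kernel_tau)
        + alpha_transient(t, windows.off_start + spec.off_latency, spec.kernel_tau)
    )
    clean = polarity * peaks[:, None] * shape[None, :]  # (n_dir, n_samples)
    noise = rng.normal(0.0, spec.noise_sd, size=(dirs.size, spec.n_trials, n))
    traces = clean[:, None, :] + noise
    return SweepSet(
        directions=dirs,
        traces=traces,
        sampling_rate=sampling_rate,
        recording_mode=recording_mode,  # type: ignore[arg-type]
        units=units,
        holding_mv=holding_mv,
    )


def _spike_template(sampling_rate: float, amplitude: float = 50.0) -> np.ndarray:
    """One-period biphasic waveform (positive lobe first), ~1 ms long."""
    n = max(int(round(1e-3 * sampling_rate)), 4)
    ph = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    return amplitude * np.sin(ph)


def gen_spike_sweeps(
    spec: TuningSpec,
    directions: Sequence[float],
    seed: int,
    windows: ResponseWindows | None = None,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
    duration: float = DEFAULT_SWEEP_DURATION,
    spike_amplitude: float = 50.0,
    min_isi: float = 0.0,
) -> tuple[SweepSet, dict[float, list[np.ndarray]]]:
    """Cell-attached-like sweeps with Poisson spikes following the tuning law.

    Within each response window, spike times are drawn from a homogeneous
    Poisson process whose rate is the tuned amplitude (Hz) at that direction
    (so the window-mean rate follows the tuning law exactly in expectation);
    outside the windows the rate is zero.  Spikes render as 1 ms biphasic
    waveforms on top of white noise.  ``min_isi`` (s) optionally thins the
    train to an absolute refractory period so rendered waveforms never
    overlap; the default 0 keeps the process purely Poisson.  Returns the
    sweeps and the ground-truth spike times, ``{direction: [times per trial]}``.
    """
    dirs = _check_directions(directions)
    windows = windows or ResponseWindows()
    rng = np.random.default_rng(seed)
    n = int(round(duration * sampling_rate))
    rates = tuned_peak(spec, dirs)
    template = _spike_template(sampling_rate, spike_amplitude)
    traces = rng.normal(0.0, spec.noise_sd, size=(dirs.size, spec.n_trials, n))
    ground_truth: dict[float, list[np.ndarray]] = {}
    window_starts = (windows.on_start, windows.off_start)
    for i, (d, rate) in enumerate(zip(dirs, rates)):
        per_trial: list[np.ndarray] = []
        for trial in range(spec.n_trials):
            times: list[float] = []
            for w0 in window_starts:
                count = rng.poisson(rate * windows.width)
                times.extend(np.sort(rng.uniform(w0, w0 + windows.width, count)))
            times_arr = np.asarray(sorted(times))
            if min_isi > 0 and times_arr.size > 1:
                kept = [times_arr[0]]
                for st in times_arr[1:]:
                    if st - kept[-1] >= min_isi:
                        kept.append(st)
                times_arr = np.asarray(kept)
            per_trial.append(times_arr)
            for st in times_arr:
                k = int(round(st * sampling_rate))
                hi = min(k + template.size, n)
                traces[i, trial, k:hi] += template[: hi - k]
        ground_truth[float(d)] = per_trial
    sweeps = SweepSet(
        directions=dirs,
        traces=traces,
        sampling_rate=sampling_rate,
        recording_mode="cell_attached",
        units="pA",
    )
    return sweeps, ground_truth


# --------------------------------------------------------------------------- #
# IV generators

def gen_iv_currents(spec: IvSimSpec, seed: int) -> IvCurve:
    """Trial-replicated peak currents on the line I = g·(V − E_rev) + noise."""
    rng = np.random.default_rng(seed)
    holds = np.asarray(sorted(spec.holds), dtype=float)
    clean = spec.g_true * (holds - spec.e_rev_true)
    trial_peaks = clean[:, None] + rng.normal(
        0.0, spec.noise_sd, size=(holds.size, spec.n_trials)
    )
    return IvCurve(
        holds=holds,
        peaks=trial_peaks.mean(axis=1),
        n_trials=spec.n_trials,
        trial_peaks=trial_peaks,
    )


def render_iv_sweeps(
    spec: IvSimSpec,
    seed: int,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
    duration: float = 1.0,
    epoch: tuple[float, float] = (0.2, 0.6),
    tau: float = 0.02,
) -> tuple[dict[float, np.ndarray], dict]:
    """Full per-hold sweep traces whose evoked peak follows the IV line.

    Each sweep is baseline noise plus an alpha-function evoked current of
    peak g·(V − E_rev) rising at the start of the depolarization ``epoch``.
    Returns ``(sweeps_per_hold, meta)`` where meta carries the sampling rate
    and epoch for :func:`dsgckit.paired.build_iv`.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration * sampling_rate))
    t = np.arange(n) / sampling_rate
    shape = alpha_transient(t, epoch[0] + 0.01, tau)
    sweeps: dict[float, np.ndarray] = {}
    for hold in spec.holds:
        peak = spec.g_true * (hold - spec.e_rev_true)
        block = peak * shape[None, :] + rng.normal(
            0.0, spec.noise_sd, size=(spec.n_trials, n)
        )
        sweeps[float(hold)] = block
    meta = {"sampling_rate": sampling_rate, "epoch": epoch, "duration": duration}
    return sweeps, meta


# --------------------------------------------------------------------------- #
# eye-tracking generator

def _min_jerk_displacement(s: np.ndarray) -> np.ndarray:
    """Normalized minimum-jerk position profile on s in [0, 1]."""
    s = np.clip(s, 0.0, 1.0)
    return 10 * s**3 - 15 * s**4 + 6 * s**5


@dataclass
class EyeGroundTruth:
    """Latent (noise-free) eye trajectory underlying a rendered marker stream."""

    t: np.ndarray  # s
    x_deg: np.ndarray
    y_deg: np.ndarray
    saccade_frames: np.ndarray  # bool, latent speed > classification threshold
    gain_true: float
    scale_deg_per_px: float
    stim: StimSpec
    saccade_onsets_s: np.ndarray = field(default_factory=lambda: np.empty(0))


def _dlc_table(
    pupil_xyl: np.ndarray, refl_xyl: np.ndarray, scorer: str = "synthetic"
) -> pd.DataFrame:
    names = PUPIL_MARKERS + REFLECTION_MARKERS
    data = np.concatenate([pupil_xyl, refl_xyl], axis=1)  # (n, 11, 3)
    cols = pd.MultiIndex.from_product(
        [[scorer], names, ["x", "y", "likelihood"]],
        names=["scorer", "bodyparts", "coords"],
    )
    return pd.DataFrame(data.reshape(data.shape[0], -1), columns=cols)


def gen_eye_markers(
    spec: EyeSimSpec,
    seed: int,
    scale_deg_per_px: float = 0.5,
    separation_deg: float = 12.0,
    pupil_radius_px: float = 40.0,
    dropout_likelihood: float = 0.2,
) -> tuple[pd.DataFrame, pd.DataFrame, EyeGroundTruth]:
    """Render two pose-marker camera streams from a latent eye trajectory.

    The latent angular position is gain_true · stim_velocity · t along the
    stimulus axis, interrupted by minimum-jerk resetting saccades of the
    stated amplitude opposite the stimulus direction.  Both cameras see the
    same trajectory under an orthographic projection at ``scale_deg_per_px``;
    their pupil centers are offset by the fixed pixel distance implied by the
    camera separation (separation_deg / scale).  Each frame carries 8 pupil
    markers placed exactly on a circle around the (noisy) center and 3
    corneal reflections at fixed per-camera positions; dropout frames get
    sub-threshold pupil-marker likelihoods.

    Returns marker tables for cameras A and B (pose-estimation CSV layout)
    and the noise-free ground truth.
    """
    n = int(round(spec.duration * spec.fps))
    if n < 2:
        raise InvalidArgumentError("duration * fps must give at least 2 frames")
    rng = np.random.default_rng(seed)
    t = np.arange(n) / spec.fps
    u = np.asarray(DIRECTION_VECTORS[spec.stim_direction], dtype=float)
    pursuit = spec.gain_true * spec.stim_velocity * t  # deg along u

    sacc_total = np.zeros(n)
    onsets: list[float] = []
    if spec.saccade_rate > 0:
        T = 1.875 * spec.saccade_amplitude / spec.saccade_peak_velocity  # min-jerk
        n_sacc = rng.poisson(spec.saccade_rate * spec.duration)
        candidates = np.sort(rng.uniform(0.5, max(spec.duration - 0.5 - T, 0.5), n_sacc))
        for c in candidates:
            if onsets and c - onsets[-1] < 3 * T + 0.05:
                continue
            onsets.append(float(c))
            sacc_total -= spec.saccade_amplitude * _min_jerk_displacement((t - c) / T)
    latent = (pursuit + sacc_total)[:, None] * u[None, :]  # (n, 2) deg

    latent_v = np.linalg.norm(np.gradient(latent, axis=0) * spec.fps, axis=1)
    saccade_frames = latent_v > DEFAULT_SACCADE_THRESHOLD

    stim = StimSpec(direction=spec.stim_direction,  # type: ignore[arg-type]
                    velocity=spec.stim_velocity, duration=spec.duration)
    truth = EyeGroundTruth(
        t=t, x_deg=latent[:, 0], y_deg=latent[:, 1],
        saccade_frames=saccade_frames, gain_true=spec.gain_true,
        scale_deg_per_px=scale_deg_per_px, stim=stim,
        saccade_onsets_s=np.asarray(onsets),
    )

    base = {"A": np.array([640.0, 480.0]), "B": np.array([640.0, 480.0])}
    offset_px = separation_deg / scale_deg_per_px
    center_shift = {"A": np.zeros(2), "B": np.array([offset_px, 0.0])}
    refl_base = np.array([[600.0, 420.0], [680.0, 420.0], [640.0, 380.0]])
    marker_angles = np.deg2rad(np.arange(8) * 45.0)
    ring = pupil_radius_px * np.column_stack([np.cos(marker_angles), np.sin(marker_angles)])

    tables = {}
    for cam in ("A", "B"):
        noise = rng.normal(0.0, spec.position_noise_sd / scale_deg_per_px, size=(n, 2)) \
            if spec.position_noise_sd > 0 else np.zeros((n, 2))
        centers = base[cam] + center_shift[cam] + latent / scale_deg_per_px + noise
        pupil = centers[:, None, :] + ring[None, :, :]  # (n, 8, 2)
        drop = rng.random(n) < spec.dropout_prob
        lik = np.where(drop[:, None], dropout_likelihood, 1.0)
        pupil_xyl = np.concatenate(
            [pupil, np.broadcast_to(lik[:, :, None] * np.ones((1, 8, 1)), (n, 8, 1))],
            axis=2,
        )
        refl = np.broadcast_to(refl_base[None, :, :], (n, 3, 2))
        refl_xyl = np.concatenate([refl, np.ones((n, 3, 1))], axis=2)
        tables[cam] = _dlc_table(pupil_xyl, refl_xyl)
    return tables["A"], tables["B"], truth


# --------------------------------------------------------------------------- #
# dendritic fields

def gen_dendrite_fields(
    overlap_frac: float,
    seed: int,
    width_um: float = 200.0,
    height_um: float = 150.0,
    n_interior: int = 200,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Two rectangular point clouds with a prescribed convex-hull overlap.

    Both clouds fill axis-aligned rectangles of identical size; cloud B is
    shifted horizontally so the hull intersection is exactly
    ``overlap_frac × area(A)``.  Corner points are included so the hulls are
    the exact rectangles.  Returns ``(points_a, points_b, true_overlap_um2)``.
    """
    if not (0.0 <= overlap_frac <= 1.0):
        raise InvalidArgumentError("overlap_frac must be in [0, 1]")
    rng = np.random.default_rng(seed)
    shift = width_um * (1.0 - overlap_frac)
    if overlap_frac == 0.0:
        shift = width_um + 10.0  # strictly disjoint, not edge-touching

    def cloud(x0: float) -> np.ndarray:
        corners = np.array(
            [[x0, 0.0], [x0 + width_um, 0.0], [x0 + width_um, height_um], [x0, height_um]]
        )
        interior = np.column_stack(
            [rng.uniform(x0, x0 + width_um, n_interior),
             rng.uniform(0.0, height_um, n_interior)]
        )
        return np.vstack([corners, interior])

    true_overlap = overlap_frac * width_um * height_um
    return cloud(0.0), cloud(shift), float(true_overlap)
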