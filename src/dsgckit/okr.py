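"""Optokinetic-reflex gain from dual-camera pupil-marker streams.

The optokinetic reflex (OKR) is quantified from video eye tracking: a pose
network labels 8 pupil-border markers and 3 corneal-reflection markers per
frame on each of two infrared cameras placed 12° apart around the eye.  The
pipeline here turns those markers into a per-presentation gain:

1. fit a circle to the high-confidence pupil markers of each frame (linear
   least-squares, the Coope substitution x² + y² = 2ax + 2by + c); frames
   with fewer than three usable markers carry the last good center forward;
2. reference the pupil center to the corneal-reflection centroid, which
   cancels translation of the eye/camera;
3. convert pixels to degrees with a scale from the known 12° inter-camera
   separation: the same eye viewed from two angles shows pupil centers a
   fixed pixel distance apart;
4. smooth, differentiate, and label frames as slow pursuit vs saccade by a
   30°/s total-velocity threshold;
5. integrate the signed slow-pursuit displacement along the stimulus axis
   and divide by total stimulus displacement — the OKR gain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation, gaussian_filter1d

from .errors import (
    CalibrationError,
    InvalidArgumentError,
    InvalidInputError,
    UnrecoverableTraceError,
)

DEFAULT_LIKELIHOOD_THRESHOLD = 0.9
DEFAULT_SACCADE_THRESHOLD = 30.0  # °/s
DEFAULT_SMOOTHING_SIGMA = 2.0  # frames
DEFAULT_SEPARATION_DEG = 12.0

#: Unit vectors of the four cardinal stimulus directions in eye coordinates
#: (x = horizontal, nasal/anterior positive; y = vertical, superior positive).
DIRECTION_VECTORS: dict[str, tuple[float, float]] = {
    "anterior": (1.0, 0.0),
    "posterior": (-1.0, 0.0),
    "superior": (0.0, 1.0),
    "inferior": (0.0, -1.0),
}

PUPIL_MARKERS = [f"pupil_{i}" for i in range(1, 9)]
REFLECTION_MARKERS = [f"reflection_{i}" for i in range(1, 4)]


@dataclass
class StimSpec:
    """One grating presentation: direction, angular velocity, duration."""

    direction: Literal["anterior", "posterior", "superior", "inferior"]
    velocity: float = 2.0  # °/s
    duration: float = 45.0  # s

    @property
    def axis(self) -> Literal["horizontal", "vertical"]:
        return "horizontal" if self.direction in ("anterior", "posterior") else "vertical"

    @property
    def unit_vector(self) -> np.ndarray:
        return np.asarray(DIRECTION_VECTORS[self.direction])

    @property
    def total_displacement_deg(self) -> float:
        return self.velocity * self.duration


@dataclass
class MarkerFrame:
    """Markers of one frame: 8 pupil rows and 3 reflection rows of (x, y, likelihood)."""

    pupil: np.ndarray  # (8, 3)
    reflections: np.ndarray  # (3, 3)
    frame_index: int = 0
    camera_id: str = "A"

    def __post_init__(self) -> None:
        self.pupil = np.asarray(self.pupil, dtype=float)
        self.reflections = np.asarray(self.reflections, dtype=float)
        if self.pupil.shape != (8, 3) or self.reflections.shape != (3, 3):
            raise InvalidInputError("expected 8 pupil and 3 reflection (x, y, likelihood) rows")


@dataclass
class PupilFit:
    center: tuple[float, float]
    radius: float
    n_markers_used: int
    imputed: bool = False


@dataclass
class EyeTrace:
    """Calibrated angular eye position with per-frame velocity and labels."""

    t: np.ndarray  # s
    x_deg: np.ndarray
    y_deg: np.ndarray
    vx: np.ndarray  # °/s, from smoothed position
    vy: np.ndarray
    v_total: np.ndarray
    labels: np.ndarray  # 'slow' | 'saccade' | 'low_confidence'
    scale: float  # °/px
    fps: float
    x_raw_deg: np.ndarray | None = None  # pre-smoothing, for displacement sums
    y_raw_deg: np.ndarray | None = None
    stim: StimSpec | None = None


@dataclass
class GainResult:
    axis: Literal["horizontal", "vertical"]
    cumulative_slow_deg: float
    stimulus_deg: float
    gain: float
    pct_saccade_frames: float = 0.0
    pct_low_confidence: float = 0.0
    no_slow_frames: bool = False


def coope_circle(points: np.ndarray) -> tuple[tuple[float, float], float]:
    """Least-squares circle through >= 3 planar points (Coope linearization).

    Substituting x² + y² = 2ax + 2by + c turns circle fitting into a linear
    problem solved in one least-squares step; center is (a, b) and radius
    sqrt(c + a² + b²).  Exact for points lying on a circle.
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 3:
        raise InvalidArgumentError("need >= 3 points to determine a circle")
    m = np.column_stack([2 * pts[:, 0], 2 * pts[:, 1], np.ones(len(pts))])
    z = pts[:, 0] ** 2 + pts[:, 1] ** 2
    (a, b, c), *_ = np.linalg.lstsq(m, z, rcond=None)
    return (float(a), float(b)), float(np.sqrt(max(c + a * a + b * b, 0.0)))


def fit_pupil_circle(
    frame: MarkerFrame,
    likelihood_threshold: float = DEFAULT_LIKELIHOOD_THRESHOLD,
    previous: PupilFit | None = None,
) -> PupilFit:
    """Coope circle fit of one frame's high-confidence pupil markers.

    Markers below the likelihood threshold are discarded.  Three markers are
    the minimum that determines a circle, so frames with fewer survivors are
    imputed: the last non-imputed center is carried forward (``previous``),
    marked ``imputed=True``.
    """
    ok = frame.pupil[:, 2] >= likelihood_threshold
    if np.count_nonzero(ok) >= 3:
        center, radius = coope_circle(frame.pupil[ok, :2])
        return PupilFit(center=center, radius=radius, n_markers_used=int(ok.sum()))
    if previous is None:
        raise UnrecoverableTraceError(
            "fewer than 3 high-confidence markers and no prior fit to carry forward"
        )
    return PupilFit(center=previous.center, radius=previous.radius,
                    n_markers_used=int(ok.sum()), imputed=True)


def track_pupil(
    pupil_xyl: np.ndarray,
    likelihood_threshold: float = DEFAULT_LIKELIHOOD_THRESHOLD,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-frame pupil centers for a whole stream, vectorized.

    ``pupil_xyl`` has shape (n_frames, 8, 3).  Frames with >= 3 markers above
    threshold get a weighted Coope fit (solved as a batched 3x3 normal
    system); other frames carry the last good center forward and are flagged
    imputed.  Leading frames before the first good fit are back-filled from
    it.  Returns ``(centers (n, 2), radii (n,), imputed (n,) bool)``.
    """
    xyl = np.asarray(pupil_xyl, dtype=float)
    if xyl.ndim != 3 or xyl.shape[1:] != (8, 3):
        raise InvalidInputError("pupil_xyl must be (n_frames, 8, 3)")
    n = xyl.shape[0]
    w = (xyl[:, :, 2] >= likelihood_threshold).astype(float)
    valid = w.sum(axis=1) >= 3
    if not np.any(valid):
        raise UnrecoverableTraceError("no frame has 3 high-confidence pupil markers")
    x, y = xyl[:, :, 0], xyl[:, :, 1]
    m = np.stack([2 * x, 2 * y, np.ones_like(x)], axis=-1)  # (n, 8, 3)
    z = x**2 + y**2
    mw = m * w[:, :, None]
    ata = np.einsum("nij,nik->njk", mw, m)
    atb = np.einsum("nij,ni->nj", mw, z)
    centers = np.zeros((n, 2))
    radii = np.zeros(n)
    sol = np.linalg.solve(ata[valid], atb[valid][:, :, None])[:, :, 0]
    centers[valid] = sol[:, :2]
    radii[valid] = np.sqrt(np.maximum(sol[:, 2] + np.sum(sol[:, :2] ** 2, axis=1), 0.0))
    # carry-forward imputation (back-fill before the first valid frame)
    imputed = ~valid
    first = int(np.flatnonzero(valid)[0])
    centers[:first] = centers[first]
    radii[:first] = radii[first]
    last = first
    for k in range(first + 1, n):
        if valid[k]:
            last = k
        else:
            centers[k] = centers[last]
            radii[k] = radii[last]
    return centers, radii, imputed


def reference_to_cornea(
    centers: np.ndarray,
    reflections_xyl: np.ndarray,
    likelihood_threshold: float = DEFAULT_LIKELIHOOD_THRESHOLD,
) -> tuple[np.ndarray, np.ndarray]:
    """Pupil centers relative to the corneal-reflection centroid, per frame.

    The three laser reflections define a reference point fixed on the cornea;
    subtracting its centroid makes the pupil coordinate invariant to global
    translation of the image.  Frames with no high-confidence reflection
    carry the last reference forward and are flagged.
    """
    centers = np.asarray(centers, dtype=float)
    refl = np.asarray(reflections_xyl, dtype=float)
    n = centers.shape[0]
    if refl.shape != (n, 3, 3):
        raise InvalidInputError("reflections must be (n_frames, 3, 3)")
    ok = refl[:, :, 2] >= likelihood_threshold
    flagged = np.zeros(n, dtype=bool)
    reference = np.zeros((n, 2))
    have_prev = False
    prev = np.zeros(2)
    for k in range(n):
        if np.any(ok[k]):
            prev = refl[k, ok[k], :2].mean(axis=0)
            have_prev = True
        else:
            flagged[k] = True
            if not have_prev:
                # back-filled once a reference appears; mark and defer
                reference[k] = np.nan
                continue
        reference[k] = prev
    if not have_prev:
        raise UnrecoverableTraceError("no frame has a high-confidence corneal reflection")
    nan_rows = np.isnan(reference[:, 0])
    if np.any(nan_rows):
        first = int(np.flatnonzero(~nan_rows)[0])
        reference[nan_rows] = reference[first]
    return centers - reference, flagged


def calibrate_scale(
    centers_a: np.ndarray,
    centers_b: np.ndarray,
    valid: np.ndarray | None = None,
    separation_deg: float = DEFAULT_SEPARATION_DEG,
) -> float:
    """Degrees-per-pixel scale from the known inter-camera separation.

    The two cameras view the eye from directions ``separation_deg`` apart, so
    the (cornea-referenced) pupil centers they report sit a fixed pixel
    distance apart; scale = separation / mean paired distance.  ``valid``
    selects the frames (high confidence in both cameras) entering the mean.
    Calibration is repeated per presentation to absorb head-position changes.
    """
    a = np.asarray(centers_a, dtype=float)
    b = np.asarray(centers_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2:
        raise InvalidInputError("paired center series must have equal shape (n, 2)")
    if valid is not None:
        a, b = a[valid], b[valid]
    if a.shape[0] == 0:
        raise CalibrationError("no overlapping high-confidence frames")
    mean_dist = float(np.mean(np.linalg.norm(a - b, axis=1)))
    if mean_dist <= 0:
        raise CalibrationError("zero mean inter-camera pupil distance")
    return separation_deg / mean_dist


def build_eye_trace(
    rel_centers_px: np.ndarray,
    imputed: np.ndarray,
    scale: float,
    fps: float,
    gaussian_sigma: float = DEFAULT_SMOOTHING_SIGMA,
    stim: StimSpec | None = None,
) -> EyeTrace:
    """Calibrated, smoothed angular eye trace with per-frame velocity.

    Pixel centers (already imputation-filled and cornea-referenced) are
    scaled to degrees, smoothed with a Gaussian of ``gaussian_sigma`` frames
    along time, and differentiated (central differences in the interior,
    one-sided at the edges) to °/s.  Raw (unsmoothed) positions are kept for
    displacement integration.  Labels start as 'low_confidence' on imputed
    frames and 'slow' elsewhere; :func:`classify_frames` adds saccades.
    """
    pos = np.asarray(rel_centers_px, dtype=float) * scale
    if pos.shape[0] < 2:
        raise InvalidInputError("need at least two frames")
    if gaussian_sigma > 0:
        smooth = gaussian_filter1d(pos, gaussian_sigma, axis=0, mode="nearest")
    else:
        smooth = pos
    vx = np.gradient(smooth[:, 0]) * fps
    vy = np.gradient(smooth[:, 1]) * fps
    labels = np.where(np.asarray(imputed, dtype=bool), "low_confidence", "slow")
    return EyeTrace(
        t=np.arange(pos.shape[0]) / fps,
        x_deg=smooth[:, 0],
        y_deg=smooth[:, 1],
        vx=vx,
        vy=vy,
        v_total=np.hypot(vx, vy),
        labels=labels.astype(object),
        scale=scale,
        fps=fps,
        x_raw_deg=pos[:, 0],
        y_raw_deg=pos[:, 1],
        stim=stim,
    )


def classify_frames(
    trace: EyeTrace, threshold: float = DEFAULT_SACCADE_THRESHOLD
) -> np.ndarray:
    """Label each frame slow / saccade / low_confidence.

    A frame whose total pupil velocity exceeds ``threshold`` (°/s, default
    30) is a saccade or fast movement; imputed frames keep their
    low-confidence label; everything else is slow pursuit.  The labels are
    written back onto the trace and returned.
    """
    labels = np.asarray(trace.labels, dtype=object).copy()
    fast = trace.v_total > threshold
    labels[fast & (labels != "low_confidence")] = "saccade"
    trace.labels = labels
    return labels


def cumulative_slow_pursuit(
    trace: EyeTrace,
    stim: StimSpec | None = None,
    saccade_margin: int = 1,
) -> tuple[float, bool]:
    """Signed slow-pursuit displacement along the stimulus axis, in degrees.

    Per-frame displacements (backward differences of the unsmoothed position)
    are projected onto the stimulus direction unit vector — positive when the
    eye moves with the stimulus — and summed over slow-labeled frames.
    Backward differencing matters for imputed runs: the carried-forward
    position catches up in one jump on the first good frame after a gap, and
    assigning that jump to the good (slow) frame keeps the pursuit that
    happened during the gap in the integral.  Frames within
    ``saccade_margin`` of a saccade-labeled frame are excluded, so saccadic
    displacement smeared into neighbors by the position smoothing does not
    leak in.  Returns ``(degrees, no_slow_frames)``.
    """
    stim = stim or trace.stim
    if stim is None:
        raise InvalidInputError("stimulus specification required")
    labels = np.asarray(trace.labels, dtype=object)
    xs = trace.x_raw_deg if trace.x_raw_deg is not None else trace.x_deg
    ys = trace.y_raw_deg if trace.y_raw_deg is not None else trace.y_deg
    disp = np.zeros((xs.size, 2))
    disp[1:, 0] = np.diff(xs)
    disp[1:, 1] = np.diff(ys)
    along = disp @ stim.unit_vector
    exclude = labels != "slow"
    if saccade_margin > 0:
        sacc = labels == "saccade"
        exclude |= binary_dilation(sacc, iterations=saccade_margin)
    slow = ~exclude
    if not np.any(slow):
        return 0.0, True
    return float(np.sum(along[slow])), False


def okr_gain(cumulative_deg: float, stim: StimSpec, *, no_slow: bool = False,
             pct_saccade: float = 0.0, pct_low_conf: float = 0.0) -> GainResult:
    """OKR gain: cumulative slow-pursuit displacement / stimulus displacement.

    Both are in degrees along the stimulus axis; gain 1 is perfect tracking,
    0 no tracking, and negative values indicate net movement opposite the
    stimulus.  Zero stimulus displacement is invalid.
    """
    total = stim.total_displacement_deg
    if total <= 0:
        raise InvalidInputError("stimulus displacement must be positive")
    return GainResult(
        axis=stim.axis,
        cumulative_slow_deg=cumulative_deg,
        stimulus_deg=total,
        gain=cumulative_deg / total,
        pct_saccade_frames=pct_saccade,
        pct_low_confidence=pct_low_conf,
        no_slow_frames=no_slow,
    )


def markers_from_dataframe(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Split a pose-estimation marker table into pupil and reflection arrays.

    Expects the three-level column layout (scorer / bodyparts / coords) with
    bodyparts ``pupil_1..8`` and ``reflection_1..3``, each carrying x, y,
    likelihood.  Returns ``(pupil (n, 8, 3), reflections (n, 3, 3))``.
    """
    if not isinstance(df.columns, pd.MultiIndex) or df.columns.nlevels != 3:
        raise InvalidInputError("expected 3-level (scorer, bodyparts, coords) columns")
    scorer = df.columns.get_level_values(0)[0]

    def _stack(names: list[str]) -> np.ndarray:
        arrs = [
            df[(scorer, nm)][["x", "y", "likelihood"]].to_numpy(dtype=float)
            for nm in names
        ]
        return np.stack(arrs, axis=1)

    return _stack(PUPIL_MARKERS), _stack(REFLECTION_MARKERS)


def process_presentation(
    markers_a: pd.DataFrame,
    markers_b: pd.DataFrame,
    stim: StimSpec,
    fps: float = 100.0,
    likelihood_threshold: float = DEFAULT_LIKELIHOOD_THRESHOLD,
    gaussian_sigma: float = DEFAULT_SMOOTHING_SIGMA,
    saccade_threshold: float = DEFAULT_SACCADE_THRESHOLD,
    separation_deg: float = DEFAULT_SEPARATION_DEG,
    camera: Literal["auto", "A", "B"] = "auto",
) -> tuple[GainResult, EyeTrace]:
    """Full OKR quantification for one stimulus presentation.

    Tracks the pupil in both camera streams, calibrates the °/px scale from
    the inter-camera pupil-center distance, selects the camera with more
    high-confidence frames (or the one forced by ``camera``), builds the
    angular eye trace, classifies frames, and returns the gain along the
    stimulus axis together with the labeled trace.
    """
    pup_a, refl_a = markers_from_dataframe(markers_a)
    pup_b, refl_b = markers_from_dataframe(markers_b)
    cen_a, _, imp_a = track_pupil(pup_a, likelihood_threshold)
    cen_b, _, imp_b = track_pupil(pup_b, likelihood_threshold)
    rel_a, flag_a = reference_to_cornea(cen_a, refl_a, likelihood_threshold)
    rel_b, flag_b = reference_to_cornea(cen_b, refl_b, likelihood_threshold)
    good_a = ~(imp_a | flag_a)
    good_b = ~(imp_b | flag_b)
    scale = calibrate_scale(rel_a, rel_b, valid=good_a & good_b,
                            separation_deg=separation_deg)
    if camera == "auto":
        camera = "A" if good_a.sum() >= good_b.sum() else "B"
    rel, imp = (rel_a, imp_a | flag_a) if camera == "A" else (rel_b, imp_b | flag_b)
    trace = build_eye_trace(rel, imp, scale, fps, gaussian_sigma, stim=stim)
    labels = classify_frames(trace, saccade_threshold)
    cum, no_slow = cumulative_slow_pursuit(trace, stim)
    n = labels.size
    result = okr_gain(
        cum, stim, no_slow=no_slow,
        pct_saccade=100.0 * np.count_nonzero(labels == "saccade") / n,
        pct_low_conf=100.0 * np.count_nonzero(labels == "low_confidence") / n,
    )
    return result, trace
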