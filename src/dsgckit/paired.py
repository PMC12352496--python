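"""Dual-recording connection strength: IV fits and dendritic-overlap geometry.

In a paired recording a presynaptic starburst amacrine cell (SAC) is
depolarized while the postsynaptic DSGC is voltage-clamped at a series of
holding potentials (−80 to −40 mV, junction-corrected).  The evoked peak
currents form an IV curve; because the GABAergic synapse is Ohmic over this
range, a straight-line fit I = g·V + b yields the connection conductance
(slope, nS) and its reversal potential (x-intercept, mV).  Recordings whose
linear fit has R² ≤ 0.80 are rejected as poor quality.

Connection strength is then related to anatomical opportunity: the convex
hulls of the two cells' traced dendritic arbors are overlaid and the
intersection area (μm²) serves as a wiring-opportunity covariate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import stats
from scipy.spatial import ConvexHull, QhullError
from shapely.geometry import Polygon

from .errors import DegenerateGeometryError, InvalidInputError

QC_R2_THRESHOLD = 0.80  # strict: passes only when R² > 0.80


@dataclass
class IvCurve:
    """Trial-averaged peak current (pA) per junction-corrected hold (mV)."""

    holds: np.ndarray
    peaks: np.ndarray
    n_trials: int = 1
    trial_peaks: np.ndarray | None = None  # (n_holds, n_trials) if retained

    def __post_init__(self) -> None:
        self.holds = np.asarray(self.holds, dtype=float)
        self.peaks = np.asarray(self.peaks, dtype=float)
        if self.holds.size < 2 or np.unique(self.holds).size < 2:
            raise InvalidInputError("an IV curve needs >= 2 distinct holding potentials")
        order = np.argsort(self.holds)
        self.holds = self.holds[order]
        self.peaks = self.peaks[order]
        if self.trial_peaks is not None:
            self.trial_peaks = np.asarray(self.trial_peaks, dtype=float)[order]


@dataclass
class LinearFit:
    """OLS line through the IV points: conductance, reversal, fit quality."""

    slope_ns: float
    intercept_pa: float
    x_intercept_mv: float  # reversal; NaN when slope ~ 0
    r_squared: float
    passes_qc: bool

    @property
    def reversal_defined(self) -> bool:
        return np.isfinite(self.x_intercept_mv)


@dataclass
class HullOverlap:
    area_a: float
    area_b: float
    area_intersection: float


def build_iv(
    sweeps_per_hold: Mapping[float, np.ndarray],
    sampling_rate: float,
    epoch: tuple[float, float],
    baseline: tuple[float, float] = (0.0, 0.1),
    junction_mv: float = -10.0,
) -> IvCurve:
    """Assemble an IV curve from per-hold sweep blocks.

    For each commanded holding potential, the trials (rows of a
    ``(n_trials, n_samples)`` array) are averaged, the pre-stimulation
    baseline mean subtracted, and the evoked peak taken as the maximal
    absolute deflection (sign preserved) within the depolarization ``epoch``
    (seconds).  Commanded holds are shifted by ``junction_mv`` to correct for
    the liquid junction potential (−10 mV for the dual-recording solutions).
    """
    if len(sweeps_per_hold) < 2:
        raise InvalidInputError("need sweeps at >= 2 holding potentials")
    holds, peaks, trial_peaks = [], [], []
    for hold, block in sweeps_per_hold.items():
        block = np.atleast_2d(np.asarray(block, dtype=float))
        b0 = int(round(baseline[0] * sampling_rate))
        b1 = int(round(baseline[1] * sampling_rate))
        e0 = int(round(epoch[0] * sampling_rate))
        e1 = int(round(epoch[1] * sampling_rate))
        if e1 > block.shape[1] or b1 > block.shape[1]:
            raise InvalidInputError("epoch or baseline window outside sweeps")

        def _peak(tr: np.ndarray) -> float:
            seg = tr - tr[b0:b1].mean()
            seg = seg[e0:e1]
            return float(seg[np.argmax(np.abs(seg))])

        mean_trace = block.mean(axis=0)
        holds.append(hold + junction_mv)
        peaks.append(_peak(mean_trace))
        trial_peaks.append([_peak(tr) for tr in block])
    n_trials = len(trial_peaks[0])
    return IvCurve(
        holds=np.asarray(holds),
        peaks=np.asarray(peaks),
        n_trials=n_trials,
        trial_peaks=np.asarray(trial_peaks),
    )


def fit_iv(iv: IvCurve) -> LinearFit:
    """Ordinary least-squares line through the IV points.

    Slope is the synaptic conductance in nS (pA/mV); the x-intercept −b/a is
    the reversal potential.  R² = 1 − SS_res/SS_tot gates recording quality:
    ``passes_qc`` requires R² strictly above 0.80.  With only two points the
    fit is exact (R² = 1).  A slope below numerical epsilon leaves the
    reversal undefined (NaN).
    """
    res = stats.linregress(iv.holds, iv.peaks)
    slope, intercept = float(res.slope), float(res.intercept)
    # linregress rvalue is 0 for zero-variance y; recompute R² directly so a
    # perfectly flat IV (slope 0, residuals 0) still reports its SS ratio.
    pred = slope * iv.holds + intercept
    ss_res = float(np.sum((iv.peaks - pred) ** 2))
    ss_tot = float(np.sum((iv.peaks - iv.peaks.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 and ss_res == 0 else (1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0)
    eps = 1e-12 * max(1.0, float(np.max(np.abs(iv.peaks), initial=0.0)))
    x_int = -intercept / slope if abs(slope) > eps else float("nan")
    return LinearFit(
        slope_ns=slope,
        intercept_pa=intercept,
        x_intercept_mv=x_int,
        r_squared=r2,
        passes_qc=r2 > QC_R2_THRESHOLD,
    )


def convex_hull(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Convex hull of a planar point set: (CCW vertices, area in μm²).

    Wraps the Qhull computation; the area of a 2-D hull is Qhull's "volume".
    Fewer than three points, or all points collinear, is a degenerate
    geometry error.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2 or points.shape[0] < 3:
        raise DegenerateGeometryError("need >= 3 planar points")
    try:
        hull = ConvexHull(points)
    except QhullError as exc:
        raise DegenerateGeometryError(f"degenerate point set: {exc}") from exc
    return points[hull.vertices], float(hull.volume)


def hull_overlap(poly_a: np.ndarray, poly_b: np.ndarray) -> HullOverlap:
    """Intersection area of two convex polygons (vertex lists, μm²).

    Symmetric in its arguments; disjoint polygons give zero.  The overlap can
    never exceed the smaller hull's area.
    """
    pa = Polygon(np.asarray(poly_a, dtype=float))
    pb = Polygon(np.asarray(poly_b, dtype=float))
    if not (pa.is_valid and pb.is_valid):
        raise DegenerateGeometryError("invalid polygon")
    inter = pa.intersection(pb).area
    return HullOverlap(area_a=pa.area, area_b=pb.area, area_intersection=float(inter))


def overlap_conductance_relation(pairs: list[tuple[float, float]]) -> float:
    """Squared Pearson correlation of conductance against overlap area.

    ``pairs`` holds (g_GABA in nS, intersection area in μm²) per recorded
    pair.  Returns NaN (with a warning) when either variable has zero
    variance.
    """
    if len(pairs) < 3:
        raise InvalidInputError("need >= 3 pairs for a correlation")
    g = np.asarray([p[0] for p in pairs], dtype=float)
    a = np.asarray([p[1] for p in pairs], dtype=float)
    if np.ptp(g) == 0 or np.ptp(a) == 0:
        warnings.warn("zero variance: correlation undefined", stacklevel=2)
        return float("nan")
    r = float(np.corrcoef(g, a)[0, 1])
    return r * r
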