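"""Directional statistics on per-direction response magnitudes.

Direction-selective ganglion cells are characterized by a tuning curve
r(θ) — one non-negative response magnitude per stimulus direction.  Two
summaries are standard:

* the **vector sum**: Σ_d r_d · (cos θ_d, sin θ_d), whose angle points at the
  response-weighted mean direction and whose length, normalized by the peak
  response r_max, quantifies tuning strength (VS);
* the **direction selectivity index** DSI = (PD − ND)/(PD + ND), the contrast
  between the preferred- and null-direction responses.

For inhibitory currents the convention inverts: inhibition is strongest in
the *null* direction, so the cell's ND is read off the IPSC tuning curve
(either its argmax or its vector-sum angle) and the PD is 180° opposite.
Spiking and subthreshold-voltage curves give the PD directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .errors import (
    InvalidArgumentError,
    UndefinedDirectionError,
    UndefinedDsiError,
)

_ANGLE_TOL = 1e-9  # relative |Σ| below which the vector-sum angle is undefined


@dataclass
class TuningCurve:
    """Response magnitude per stimulus direction for one pathway/metric."""

    angles: np.ndarray  # degrees
    magnitudes: np.ndarray  # non-negative, |peak| per direction
    pathway: Literal["ON", "OFF"] = "ON"
    metric: Literal["IPSC", "EPSC", "spike_rate", "delta_vm"] = "IPSC"

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        self.magnitudes = np.asarray(self.magnitudes, dtype=float)
        if self.angles.shape != self.magnitudes.shape:
            raise InvalidArgumentError("angles and magnitudes must align")
        if np.any(self.magnitudes < 0):
            raise InvalidArgumentError("magnitudes are |peak| and must be >= 0")


@dataclass
class VectorSumResult:
    angle: float  # degrees in [0, 360); NaN when undefined
    magnitude: float  # |Σ V_D|, response units
    normalized: float  # |Σ V_D| / r_max
    defined: bool = True


@dataclass
class DsiResult:
    pd_angle: float
    nd_angle: float
    pd_resp: float
    nd_resp: float
    dsi: float
    convention: Literal["argmax", "vector"] = "argmax"


def vector_sum(curve: TuningCurve) -> VectorSumResult:
    """Vector sum of direction-weighted responses, normalized by the peak.

    Each direction contributes a vector of length r_d at angle θ_d; the result
    reports the angle of the summed vector (degrees in [0, 360)), its raw
    length, and the length normalized by r_max = max(r).  A symmetric curve
    sums to (numerically) zero, in which case the angle is undefined and the
    result is flagged with ``defined=False``.

    Normalizing by r_max rather than Σr follows the conventional definition
    used for these cells; for broad bimodal curves the normalized value can
    exceed 1, which is a property of the statistic, not an error.
    """
    if np.unique(curve.angles).size < 2:
        raise InvalidArgumentError("need at least two distinct angles")
    rmax = float(np.max(curve.magnitudes))
    if rmax <= 0:
        raise UndefinedDirectionError("all-zero magnitudes: vector-sum angle undefined")
    vec = np.sum(curve.magnitudes * np.exp(1j * np.deg2rad(curve.angles)))
    mag = float(np.abs(vec))
    if mag < _ANGLE_TOL * rmax:
        return VectorSumResult(angle=float("nan"), magnitude=mag,
                               normalized=mag / rmax, defined=False)
    ang = float(np.rad2deg(np.angle(vec)) % 360.0)
    return VectorSumResult(angle=ang, magnitude=mag, normalized=mag / rmax)


def _snap(angle: float, grid: np.ndarray) -> float:
    """Nearest sampled angle by circular distance (responses only exist there)."""
    d = np.abs((grid - angle + 180.0) % 360.0 - 180.0)
    return float(grid[int(np.argmin(d))])


def _lookup(curve: TuningCurve, angle: float) -> float:
    return float(curve.magnitudes[np.flatnonzero(curve.angles == angle)[0]])


def null_and_preferred_from_inhibition(
    curve: TuningCurve, convention: Literal["argmax", "vector"] = "argmax"
) -> DsiResult:
    """Infer ND/PD from an inhibitory tuning curve.

    Inhibition onto a DSGC is maximal for null-direction motion, so the ND is
    taken either as the direction of the maximum IPSC (``argmax``) or as the
    vector-sum angle of the IPSC curve (``vector``); the PD is 180° away.
    Both angles are snapped to the sampled grid for response lookup and the
    DSI of PD vs ND responses is filled in.

    Argmax ties are broken toward the angle nearest the vector-sum angle,
    then toward the smallest angle.  A fully symmetric curve under the
    ``vector`` convention has no defined ND.
    """
    if curve.metric != "IPSC":
        raise InvalidArgumentError("ND-from-inhibition requires an IPSC curve")
    if convention == "vector":
        vs = vector_sum(curve)
        if not vs.defined:
            raise UndefinedDirectionError("symmetric IPSC curve: ND undefined")
        nd = _snap(vs.angle, curve.angles)
    else:
        m = curve.magnitudes
        ties = curve.angles[m == m.max()]
        if ties.size > 1:
            try:
                vs = vector_sum(curve)
                ref = vs.angle if vs.defined else None
            except UndefinedDirectionError:
                ref = None
            if ref is not None:
                d = np.abs((ties - ref + 180.0) % 360.0 - 180.0)
                ties = ties[d == d.min()]
            nd = float(np.min(ties))
        else:
            nd = float(ties[0])
    pd_angle = _snap((nd + 180.0) % 360.0, curve.angles)
    pd_resp = _lookup(curve, pd_angle)
    nd_resp = _lookup(curve, nd)
    return DsiResult(
        pd_angle=pd_angle,
        nd_angle=nd,
        pd_resp=pd_resp,
        nd_resp=nd_resp,
        dsi=dsi(pd_resp, nd_resp),
        convention=convention,
    )


def preferred_from_output(curve: TuningCurve) -> float:
    """PD of a spiking or subthreshold-Vm curve: the vector-sum angle itself."""
    if curve.metric not in ("spike_rate", "delta_vm"):
        raise InvalidArgumentError("use an output (spike_rate or delta_vm) curve")
    vs = vector_sum(curve)
    if not vs.defined:
        raise UndefinedDirectionError("uniform output curve: PD undefined")
    return vs.angle


def dsi(pd_resp: float, nd_resp: float) -> float:
    """Direction selectivity index (PD − ND)/(PD + ND).

    1 for a response confined to the PD, 0 for an untuned cell; bounded in
    [−1, 1] for non-negative responses.
    """
    total = pd_resp + nd_resp
    if total == 0:
        raise UndefinedDsiError("PD + ND responses are zero")
    return (pd_resp - nd_resp) / total


def asymmetric_inhibition(nd_ipsc: float, pd_ipsc: float) -> float:
    """ND minus PD peak IPSC: the directionally tuned inhibitory component.

    Positive when inhibition is appropriately biased to the null direction;
    the sign is preserved so a preferred-direction bias shows as negative.
    """
    return nd_ipsc - pd_ipsc


def alignment_offset(pd_angle: float, nominal_axis: float) -> float:
    """Minimal signed circular difference pd_angle − nominal_axis, in (−180, 180].

    Used to quantify how far a cell's preferred direction deviates from its
    subtype's nominal axis (e.g. nasal = 180°); antipodal angles map to +180.
    """
    d = (pd_angle - nominal_axis) % 360.0
    if d > 180.0:
        d -= 360.0
    return d
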