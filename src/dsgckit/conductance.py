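"""Parallel-conductance membrane model and conductance extraction.

A DSGC's subthreshold membrane potential is modeled as a single RC
compartment with three conductance branches — excitatory, inhibitory and
leak — each pulling the voltage toward its own reversal potential:

    dV/dt = −[ G_exc(t)·(V − E_exc) + G_inh(t)·(V − E_inh)
               + G_leak·(V − E_leak) ] / C_m

integrated by forward Euler, V(t+Δt) = V(t) + (dV/dt)·Δt.  Units are chosen
so the expression is self-consistent without conversion factors: conductance
in nS, voltage in mV, capacitance in pF, time in ms (nS·mV/pF = mV/ms).

The synaptic conductance inputs come from voltage-clamp recordings: holding
the cell at one branch's reversal silences that branch's driving force, so
the recorded current isolates the other branch and divides by its driving
force to give conductance.  Default passive constants (C_m = 80 pF,
G_leak = 3.3 nS, E_leak = −55 mV) are typical empirical values for these
cells; reversals are E_exc = 0 mV (cations) and E_inh = −60 mV (chloride).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Mapping

import numpy as np

from .errors import InstabilityError, InvalidArgumentError, InvalidInputError
from .traces import ResponseWindows
from .tuning import TuningCurve


@dataclass
class ModelParams:
    """RC-circuit constants. cm pF, conductances nS, potentials mV, dt ms."""

    cm: float = 80.0
    g_leak: float = 3.3
    e_leak: float = -55.0
    e_exc: float = 0.0
    e_inh: float = -60.0
    dt: float = 0.1
    v_init: float | None = None  # defaults to e_leak

    def __post_init__(self) -> None:
        if self.cm <= 0:
            raise InvalidArgumentError("cm must be positive")
        if self.g_leak < 0:
            raise InvalidArgumentError("g_leak must be non-negative")
        if self.dt <= 0:
            raise InvalidArgumentError("dt must be positive")
        if self.v_init is None:
            self.v_init = self.e_leak

    def stability_bound(self, g_syn_max: float = 0.0) -> float:
        """Largest Euler step (ms) keeping V inside the reversal envelope."""
        g_tot = self.g_leak + g_syn_max
        return np.inf if g_tot == 0 else self.cm / g_tot


@dataclass
class ConductanceTrace:
    """Rectified synaptic conductance time series on a common ms grid."""

    t: np.ndarray  # ms
    g_exc: np.ndarray  # nS, >= 0
    g_inh: np.ndarray  # nS, >= 0
    direction: float = float("nan")
    pathway: Literal["ON", "OFF"] = "ON"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.g_exc = np.asarray(self.g_exc, dtype=float)
        self.g_inh = np.asarray(self.g_inh, dtype=float)
        if not (self.t.shape == self.g_exc.shape == self.g_inh.shape):
            raise InvalidInputError("t, g_exc, g_inh must share one grid")


@dataclass
class SimResult:
    """Simulated membrane potential and derived peak depolarizations."""

    t: np.ndarray  # ms
    v: np.ndarray  # mV
    direction: float = float("nan")
    peak_dvm: dict = field(default_factory=dict)  # pathway -> mV


def extract_conductance(
    mean_epsc: np.ndarray,
    mean_ipsc: np.ndarray,
    params: ModelParams,
    sampling_rate: float,
    hold_exc: float = -60.0,
    hold_inh: float = 0.0,
    direction: float = float("nan"),
) -> ConductanceTrace:
    """Synaptic conductance from baseline-subtracted, trial-averaged currents.

    Excitation is recorded clamped at the inhibitory reversal (−60 mV) and
    inhibition clamped at the excitatory reversal (0 mV), so each current
    reflects one branch alone:

        g_exc(t) = I_epsc(t) / (V_hold_exc − E_exc)
        g_inh(t) = I_ipsc(t) / (V_hold_inh − E_inh)

    with pA / mV = nS.  Negative conductance values, which arise from noise
    of the wrong sign, are rectified to zero.
    """
    mean_epsc = np.asarray(mean_epsc, dtype=float)
    mean_ipsc = np.asarray(mean_ipsc, dtype=float)
    if mean_epsc.shape != mean_ipsc.shape:
        raise InvalidInputError("EPSC and IPSC traces must share one grid")
    if hold_exc == params.e_exc or hold_inh == params.e_inh:
        raise InvalidArgumentError("holding potential equals reversal: zero driving force")
    g_exc = mean_epsc / (hold_exc - params.e_exc)
    g_inh = mean_ipsc / (hold_inh - params.e_inh)
    t_ms = np.arange(mean_epsc.size) / sampling_rate * 1e3
    return ConductanceTrace(
        t=t_ms,
        g_exc=np.maximum(g_exc, 0.0),
        g_inh=np.maximum(g_inh, 0.0),
        direction=direction,
    )


def _euler(
    g_exc: np.ndarray,
    g_inh: np.ndarray,
    params: ModelParams,
    i_inj_pa: float = 0.0,
) -> np.ndarray:
    n = g_exc.size
    v = np.empty(n)
    v[0] = params.v_init
    dt, cm = params.dt, params.cm
    gl, el, ee, ei = params.g_leak, params.e_leak, params.e_exc, params.e_inh
    vk = float(v[0])
    for k in range(n - 1):
        dv = -(g_exc[k] * (vk - ee) + g_inh[k] * (vk - ei) + gl * (vk - el)) + i_inj_pa
        vk = vk + dt * dv / cm
        if abs(vk) > 200.0:
            bound = params.stability_bound(float(np.max(g_exc + g_inh)))
            raise InstabilityError(
                f"forward Euler diverged (|V| > 200 mV); dt must be < {bound:.6g} ms"
            )
        v[k + 1] = vk
    return v


def simulate_vm(cond: ConductanceTrace, params: ModelParams) -> SimResult:
    """Integrate the parallel-conductance model by forward Euler.

    The conductance traces are resampled onto the Euler grid (step ``params.dt``
    ms) by previous-sample hold, and the update

        V(t+Δt) = V(t) − Δt·[ Σ_i g_i(t)·(V − E_i) ] / C_m

    is iterated from ``params.v_init``.  With zero synaptic input the voltage
    relaxes to E_leak with time constant C_m/G_leak.  Divergence (|V| > 200 mV)
    raises :class:`InstabilityError` naming the required dt bound.
    """
    if cond.t.size < 2:
        raise InvalidInputError("need at least two conductance samples")
    duration = cond.t[-1] - cond.t[0]
    n = int(np.floor(duration / params.dt)) + 1
    t = cond.t[0] + np.arange(n) * params.dt
    idx = np.minimum(np.searchsorted(cond.t, t, side="right") - 1, cond.t.size - 1)
    ge = cond.g_exc[idx]
    gi = cond.g_inh[idx]
    v = _euler(ge, gi, params)
    return SimResult(t=t, v=v, direction=cond.direction)


def simulated_tuning(
    results: Mapping[float, SimResult],
    windows: ResponseWindows,
    params: ModelParams,
) -> dict[str, TuningCurve]:
    """Per-direction peak simulated depolarization, as ΔVm tuning curves.

    For each direction's simulated voltage trace, the peak of V − V_init
    within the ON and OFF windows is taken as the simulated response; the
    resulting curves feed the same vector-sum/DSI statistics as recorded data.
    """
    if not results:
        raise InvalidInputError("no simulation results supplied")
    directions = np.asarray(sorted(results), dtype=float)
    curves: dict[str, TuningCurve] = {}
    for pathway in ("ON", "OFF"):
        mags = []
        for d in directions:
            sim = results[d]
            t_s = sim.t / 1e3
            lo = windows.start(pathway)  # type: ignore[arg-type]
            hi = lo + windows.width
            mask = (t_s >= lo) & (t_s < hi)
            if not np.any(mask):
                raise InvalidInputError("response window outside simulated range")
            peak = float(np.max(sim.v[mask] - params.v_init))
            sim.peak_dvm[pathway] = peak
            mags.append(max(peak, 0.0))
        curves[pathway] = TuningCurve(
            angles=directions, magnitudes=np.asarray(mags),
            pathway=pathway, metric="delta_vm",  # type: ignore[arg-type]
        )
    return curves


def passive_step_response(
    params: ModelParams,
    mode: Literal["voltage_clamp", "current_step"],
    amplitude: float,
    duration_ms: float = 200.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Response of the passive (leak-only) model to a step input.

    ``voltage_clamp``: the command potential is ``amplitude`` (mV) and the
    returned trace is the clamp current in pA, which for a purely passive
    cell settles immediately to the Ohmic leak G_leak·(V_hold − E_leak).

    ``current_step``: ``amplitude`` pA is injected from t=0 and the membrane
    voltage is integrated by forward Euler from rest; it relaxes
    exponentially (τ = C_m/G_leak) to E_leak + I/G_leak.

    Returns ``(t_ms, trace)``.
    """
    n = int(round(duration_ms / params.dt)) + 1
    t = np.arange(n) * params.dt
    if mode == "voltage_clamp":
        i_ss = params.g_leak * (amplitude - params.e_leak)
        return t, np.full(n, i_ss)
    if mode == "current_step":
        p = replace(params, v_init=params.e_leak)
        zeros = np.zeros(n)
        v = _euler(zeros, zeros, p, i_inj_pa=amplitude)
        return t, v
    raise InvalidArgumentError(f"unknown mode {mode!r}")
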