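"""Aerobic power kinetics.

After a change in work rate the aerobic metabolic power Qa does not jump to
its steady state; it relaxes toward the virtual steady-state power Qbar_vir
with a first-order lag,

    dQvir/dt = (Qbar_vir(t) - Qvir(t)) / tau_a,      Qvir(0) = Qr,
    Qa(t)    = min(Qmax, Qvir(t)),

where tau_a is the e-folding time (default 30 s) and Qmax the maximal aerobic
power.  The virtual power Qvir integrates unclamped — it carries the "excess"
memory during supramaximal bouts — and the clamp is applied pointwise to the
output.  For constant Qbar_vir below Qmax the ODE has the mono-exponential
closed form implemented in :func:`aerobic_analytic`.

Integration is fixed-step classical Runge-Kutta (RK4).  The grid is aligned
to the protocol's breakpoints so no step straddles a discontinuity, which
keeps the integrator at its nominal order and makes energy bookkeeping
reproducible bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .parameters import EnergeticsParameters
from .profiles import PowerProfile

__all__ = [
    "AerobicSeries",
    "aerobic_rhs",
    "aerobic_analytic",
    "aerobic_derivative",
    "integrate_aerobic",
    "integrate_aerobic_time_varying",
    "profile_grid",
]


@dataclass(frozen=True)
class AerobicSeries:
    """Time series of the aerobic stage on the simulation grid.

    Arrays are aligned: ``Qbar_vir`` is the protocol input, ``Qvir`` the
    unclamped virtual power, ``Qa = min(Qmax, Qvir)`` the aerobic power.

    At an interior protocol breakpoint ``Qbar_vir`` holds the right (later)
    segment's value while ``Qbar_vir_pre`` holds the left limit; the two
    differ only at jumps.  Quadratures over Qbar_vir use both so that no
    trapezoid straddles a discontinuity.
    """

    t: np.ndarray
    Qbar_vir: np.ndarray
    Qvir: np.ndarray
    Qa: np.ndarray
    params: EnergeticsParameters
    Qbar_vir_pre: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.t)
        if self.Qbar_vir_pre is None:
            object.__setattr__(self, "Qbar_vir_pre", self.Qbar_vir)
        if not (
            len(self.Qbar_vir) == len(self.Qvir) == len(self.Qa)
            == len(self.Qbar_vir_pre) == n
        ):
            raise ValueError("misaligned series")

    def index_of(self, time: float) -> int:
        """Index of the grid point nearest ``time`` (must be within 1e-9 s)."""
        i = int(np.argmin(np.abs(self.t - time)))
        if abs(self.t[i] - time) > 1e-9:
            raise ValueError(f"t={time} is not on the simulation grid")
        return i


def aerobic_rhs(Qvir: float, Qbar_vir: float, tau_a: float) -> float:
    """Right-hand side of the virtual-power ODE, (Qbar_vir - Qvir)/tau_a in J/s^2."""
    if not tau_a > 0:
        raise ValueError("tau_a must be > 0")
    return (Qbar_vir - Qvir) / tau_a


def aerobic_analytic(
    Qbar_vir: float, Qa_t0: float, tau_a: float, t: float, t0: float = 0.0
) -> float:
    """Mono-exponential solution for constant Qbar_vir:

        Qa(t) = Qbar_vir - (Qbar_vir - Qa(t0)) exp(-(t - t0)/tau_a).

    Valid only while Qvir stays below Qmax (the caller's responsibility).
    """
    if t < t0:
        raise ValueError("t must be >= t0")
    return Qbar_vir - (Qbar_vir - Qa_t0) * math.exp(-(t - t0) / tau_a)


def aerobic_derivative(
    Qvir: float, Qbar_vir: float, params: EnergeticsParameters
) -> float:
    """Clamp-aware rate of change of the aerobic power, dQa/dt in J/s^2.

    Below the clamp this is the ODE right-hand side (Qbar_vir - Qvir)/tau_a.
    At or above Qmax with the relaxation target also at or above Qmax, Qa is
    pinned at the clamp and the derivative is 0; once the target drops below
    Qmax (recovery) the relaxation resumes and the derivative is negative.
    This is the dQa/dt fed to the alactic model 2 — taken from the right-hand
    side, never from finite differences of the output series.
    """
    r = (Qbar_vir - Qvir) / params.tau_a
    if Qvir >= params.Qmax and Qbar_vir >= params.Qmax:
        return 0.0
    return r


def profile_grid(profile: PowerProfile, dt: float) -> list[tuple[int, int, float]]:
    """Per-segment grid layout: (n_steps, segment_index, step) for each segment.

    Each segment [a, b] is subdivided into ceil((b-a)/dt) equal steps, so the
    actual step never exceeds dt and every breakpoint is a grid point.
    """
    if not dt > 0:
        raise ValueError("dt must be > 0")
    layout = []
    for k, seg in enumerate(profile.segments):
        length = seg.t_end - seg.t_start
        n = max(1, math.ceil(length / dt - 1e-9))
        layout.append((n, k, length / n))
    return layout


def _integrate(
    profile: PowerProfile,
    rhs: Callable[[float, float], float],
    y0: float,
    dt: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """RK4 of dy/dt = rhs(t, y) over the profile grid.

    Returns (t, Qbar_vir, Qbar_vir_pre, y): Qbar_vir at interior breakpoints
    takes the right (later) segment's value and Qbar_vir_pre the left limit.
    """
    ts = [0.0]
    qbars = [profile.segments[0].func(0.0)]
    qbars_pre = [qbars[0]]
    ys = [y0]
    y = y0
    for n, k, h in profile_grid(profile, dt):
        seg = profile.segments[k]
        f = seg.func
        for i in range(n):
            t = seg.t_start + i * h
            qb1 = f(t)
            if not math.isfinite(qb1):
                raise FloatingPointError(f"non-finite profile value at t={t}")
            qb2 = f(t + 0.5 * h)
            qb3 = f(t + h)
            k1 = rhs(qb1, y)
            k2 = rhs(qb2, y + 0.5 * h * k1)
            k3 = rhs(qb2, y + 0.5 * h * k2)
            k4 = rhs(qb3, y + h * k3)
            y = y + h / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
            ts.append(seg.t_start + (i + 1) * h)
            ys.append(y)
            qbars.append(qb3)
            qbars_pre.append(qb3)
        # at an interior breakpoint the main column takes the next segment's
        # value while the left limit stays with this segment
        if seg.t_end < profile.duration:
            qbars[-1] = profile(seg.t_end)
    return np.asarray(ts), np.asarray(qbars), np.asarray(qbars_pre), np.asarray(ys)


def integrate_aerobic(
    profile: PowerProfile,
    params: EnergeticsParameters,
    dt: float = 0.1,
    Qvir0: float | None = None,
) -> AerobicSeries:
    """Integrate the virtual-power ODE over a protocol and clamp the output.

    ``Qvir0`` defaults to the resting power Qr; pass a previous run's terminal
    Qvir to chain simulations (warm start).
    """
    y0 = params.Qr if Qvir0 is None else float(Qvir0)
    rhs = lambda qbar, y: (qbar - y) / params.tau_a
    t, qbar, qbar_pre, qvir = _integrate(profile, rhs, y0, dt)
    qa = np.minimum(params.Qmax, qvir)
    return AerobicSeries(
        t=t, Qbar_vir=qbar, Qvir=qvir, Qa=qa, params=params, Qbar_vir_pre=qbar_pre
    )


def integrate_aerobic_time_varying(
    profile: PowerProfile,
    params: EnergeticsParameters,
    dt: float = 0.1,
    efficiency_schedule: Callable[[float], float] | None = None,
) -> AerobicSeries:
    """Aerobic kinetics with a time-varying work-efficiency product.

    Integrates the first-order lag in terms of the virtual *work* power
    Pvir = s(t) (Qvir - Qr), where s(t) = eta * eta_a may drift through time
    (e.g. with lactate accumulation):

        dPvir/dt = (s(t) (Qbar_vir(t) - Qr) - Pvir) / tau_a,   Pvir(0) = 0.

    The output is mapped back to metabolic units via Qvir = Qr + Pvir/s(t)
    and clamped as usual; Pvir(0) = 0 then coincides with the resting start
    Qvir(0) = Qr.  For a constant schedule the trajectory equals
    :func:`integrate_aerobic`'s exactly (the constant s cancels from the ODE).
    """
    if efficiency_schedule is None:
        efficiency_schedule = lambda t: params.eta * params.eta_a
    # validate the schedule on the grid before integrating
    for n, k, h in profile_grid(profile, dt):
        seg = profile.segments[k]
        for i in range(n + 1):
            s = efficiency_schedule(seg.t_start + min(i * h, seg.t_end - seg.t_start))
            if not (math.isfinite(s) and s > 0):
                raise ValueError(
                    f"efficiency schedule must be positive and finite, got {s!r}"
                )

    ts = [0.0]
    qbars = [profile.segments[0].func(0.0)]
    qbars_pre = [qbars[0]]
    ps = [0.0]
    p = 0.0
    tau = params.tau_a
    Qr = params.Qr
    for n, k, h in profile_grid(profile, dt):
        seg = profile.segments[k]
        f = seg.func
        for i in range(n):
            t = seg.t_start + i * h

            def rhs(tt: float, y: float) -> float:
                return (efficiency_schedule(tt) * (f(tt) - Qr) - y) / tau

            k1 = rhs(t, p)
            k2 = rhs(t + 0.5 * h, p + 0.5 * h * k1)
            k3 = rhs(t + 0.5 * h, p + 0.5 * h * k2)
            k4 = rhs(t + h, p + h * k3)
            p = p + h / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
            ts.append(seg.t_start + (i + 1) * h)
            ps.append(p)
            qbars.append(f(t + h))
            qbars_pre.append(f(t + h))
        if seg.t_end < profile.duration:
            qbars[-1] = profile(seg.t_end)
    t_arr = np.asarray(ts)
    s_arr = np.asarray([efficiency_schedule(tt) for tt in ts])
    qvir = Qr + np.asarray(ps) / s_arr
    qa = np.minimum(params.Qmax, qvir)
    return AerobicSeries(
        t=t_arr,
        Qbar_vir=np.asarray(qbars),
        Qvir=qvir,
        Qa=qa,
        params=params,
        Qbar_vir_pre=np.asarray(qbars_pre),
    )
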