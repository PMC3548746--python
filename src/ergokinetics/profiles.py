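"""Virtual steady-state power protocols.

Everything downstream of the exercise protocol consumes a single function of
time: the virtual steady-state metabolic power Qbar_vir(t), the metabolic
power that would be attained if the work rate could be sustained under purely
aerobic conditions.  Qbar_vir may exceed the maximal aerobic power Qmax; the
aerobic stage clamps it later.

Two front ends build that function: a piecewise-linear speed -> power curve
through measured steady-state points (with linear extrapolation beyond the
measured range), and closed-form protocol generators (constant bout,
bout + recovery, sinusoidal interval, ramp-then-hold continuous exercise).

Profiles are parameterized by Qbar_vir directly (as fractions of Qmax), not by
treadmill speed; the speed -> power curve is a separate front end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.interpolate import interp1d

__all__ = [
    "SteadyStatePoint",
    "ProfileSegment",
    "PowerProfile",
    "ProfileError",
    "build_virtual_power_curve",
    "skier_fixture_points",
    "constant_bout_profile",
    "bout_with_recovery_profile",
    "interval_profile",
    "continuous_profile",
]


class ProfileError(ValueError):
    """Invalid protocol definition."""


@dataclass(frozen=True)
class SteadyStatePoint:
    """One measured steady-state point anchoring the virtual-power curve.

    ``speed`` is treadmill speed in m/s; ``qvir_fraction`` is the virtual
    steady-state metabolic power as a fraction of Qmax.
    """

    speed: float
    qvir_fraction: float

    def __post_init__(self) -> None:
        if not self.speed > 0:
            raise ProfileError(f"speed must be > 0, got {self.speed!r}")
        if not self.qvir_fraction > 0:
            raise ProfileError(f"qvir_fraction must be > 0, got {self.qvir_fraction!r}")


@dataclass(frozen=True)
class ProfileSegment:
    """One smooth piece of a protocol: Qbar_vir = func(t) on [t_start, t_end]."""

    t_start: float
    t_end: float
    func: Callable[[float], float]


@dataclass(frozen=True)
class PowerProfile:
    """A protocol: Qbar_vir(t) in J/s on [0, duration].

    The profile is a sequence of smooth segments; segment boundaries are the
    protocol breakpoints that the integrator aligns its grid to, so no
    integration step straddles a jump or kink.  Evaluation at a shared
    boundary returns the right (later) segment's value.
    """

    segments: tuple[ProfileSegment, ...]
    label: str = "profile"

    def __post_init__(self) -> None:
        if not self.segments:
            raise ProfileError("profile needs at least one segment")
        t = 0.0
        for seg in self.segments:
            if not math.isclose(seg.t_start, t, abs_tol=1e-12):
                raise ProfileError("segments must be contiguous from t=0")
            if not seg.t_end > seg.t_start:
                raise ProfileError("segment must have positive length")
            t = seg.t_end

    @property
    def duration(self) -> float:
        return self.segments[-1].t_end

    @property
    def breakpoints(self) -> tuple[float, ...]:
        return tuple(s.t_start for s in self.segments) + (self.duration,)

    def __call__(self, t: float) -> float:
        """Qbar_vir(t), right-continuous at interior breakpoints."""
        if t < 0 or t > self.duration:
            raise ProfileError(f"t={t} outside [0, {self.duration}]")
        for seg in self.segments:
            if seg.t_start <= t < seg.t_end:
                return seg.func(t)
        return self.segments[-1].func(t)  # t == duration


def build_virtual_power_curve(
    points: Sequence[SteadyStatePoint], Qmax: float
) -> Callable[[float], float]:
    """Piecewise-linear speed -> Qbar_vir (J/s) curve through measured points.

    Inside the measured speed range the curve linearly interpolates the
    points; outside it, the first/last segment is extended linearly.
    Speeds must be strictly increasing and there must be at least two points.
    """
    if len(points) < 2:
        raise ProfileError("need at least 2 steady-state points")
    speeds = np.array([p.speed for p in points], dtype=float)
    if np.any(np.diff(speeds) <= 0):
        raise ProfileError("speeds must be strictly increasing (no duplicates)")
    powers = np.array([p.qvir_fraction for p in points], dtype=float) * Qmax
    f = interp1d(speeds, powers, kind="linear", fill_value="extrapolate")
    return lambda v: float(f(v))


def skier_fixture_points() -> list[SteadyStatePoint]:
    """The published steady-state points of the reference skier.

    Eight exercise speeds (v1..v8) plus the 1.67 m/s active-recovery point,
    each paired with its measured Qbar_vir/Qmax fraction; sorted by speed.
    """
    pairs = [
        (1.67, 0.47),  # active recovery
        (2.08, 0.59),
        (2.33, 0.66),
        (2.64, 0.74),
        (2.83, 0.80),
        (3.08, 0.87),
        (3.19, 0.90),
        (3.33, 0.94),
        (3.88, 1.09),
    ]
    return [SteadyStatePoint(v, f) for v, f in pairs]


def constant_bout_profile(
    qvir_fraction: float, duration: float, Qmax: float = 1886.0
) -> PowerProfile:
    """Constant work-rate bout: Qbar_vir(t) = qvir_fraction * Qmax on [0, duration]."""
    if not qvir_fraction > 0:
        raise ProfileError(f"qvir_fraction must be > 0, got {qvir_fraction!r}")
    if not duration > 0:
        raise ProfileError(f"duration must be > 0, got {duration!r}")
    q = qvir_fraction * Qmax
    return PowerProfile(
        (ProfileSegment(0.0, float(duration), lambda t, q=q: q),),
        label=f"constant[{qvir_fraction:g}Qmax,{duration:g}s]",
    )


def bout_with_recovery_profile(
    work_fraction: float,
    work_duration: float,
    recovery_fraction: float,
    recovery_duration: float,
    Qmax: float = 1886.0,
) -> PowerProfile:
    """Two-phase piecewise-constant protocol: work bout then active recovery."""
    if not (work_duration > 0 and recovery_duration > 0):
        raise ProfileError("durations must be > 0")
    if not (work_fraction > 0 and recovery_fraction > 0):
        raise ProfileError("fractions must be > 0")
    qw = work_fraction * Qmax
    qr = recovery_fraction * Qmax
    t1 = float(work_duration)
    t2 = t1 + float(recovery_duration)
    return PowerProfile(
        (
            ProfileSegment(0.0, t1, lambda t, q=qw: q),
            ProfileSegment(t1, t2, lambda t, q=qr: q),
        ),
        label=f"bout_recovery[{work_fraction:g},{work_duration:g}s;"
        f"{recovery_fraction:g},{recovery_duration:g}s]",
    )


def interval_profile(Qmax: float, T: float = 360.0, n_periods: int = 5) -> PowerProfile:
    """Sinusoidal interval exercise: Qbar_vir = Qmax/2 + (Qmax/2) sin(2 pi t / T).

    The intensity oscillates between 0 and Qmax with period T (default 360 s),
    spending half of each period above Qmax/2; `n_periods` full periods are
    generated (one segment per period, so period boundaries are grid points).
    """
    if not T > 0:
        raise ProfileError("T must be > 0")
    if n_periods < 1:
        raise ProfileError("n_periods must be >= 1")

    def f(t: float) -> float:
        return Qmax / 2.0 + Qmax / 2.0 * math.sin(2.0 * math.pi * t / T)

    segs = tuple(
        ProfileSegment(k * T, (k + 1) * T, f) for k in range(n_periods)
    )
    return PowerProfile(segs, label=f"interval[T={T:g}s,n={n_periods}]")


def continuous_profile(
    Qmax: float, Q5_fraction: float = 0.87, T: float = 360.0, n_periods: int = 5
) -> PowerProfile:
    """Continuous exercise matched to the interval protocol: sinusoidal ramp
    over the first quarter period up to Q5 = Q5_fraction * Qmax, then a hold.

    Both branches give Q5 at t = T/4, so the profile is continuous; the kink
    at T/4 is a segment boundary.  Total duration is n_periods * T.
    """
    if not T > 0:
        raise ProfileError("T must be > 0")
    if n_periods < 1:
        raise ProfileError("n_periods must be >= 1")
    Q5 = Q5_fraction * Qmax

    def ramp(t: float) -> float:
        return Qmax / 2.0 + (Q5 - Qmax / 2.0) * math.sin(2.0 * math.pi * t / T)

    return PowerProfile(
        (
            ProfileSegment(0.0, T / 4.0, ramp),
            ProfileSegment(T / 4.0, n_periods * T, lambda t, q=Q5: q),
        ),
        label=f"continuous[Q5={Q5_fraction:g}Qmax,T={T:g}s,n={n_periods}]",
    )
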