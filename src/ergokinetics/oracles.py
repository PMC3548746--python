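"""In-model fixtures and independent cross-check oracles.

The reference inputs here are generated from the published values for one
elite cross-country skier (steady-state points, protocol durations); there is
no external data.  The oracles deliberately use different algorithms than the
operations they check: root bracketing instead of the closed-form steady
state, and plain trapezoid quadrature instead of the telescoping energy
closed forms.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import trapezoid
from scipy.optimize import brentq

from .lactate import DIVERGENT, Divergent, lactate_drive, lactate_rhs
from .parameters import EnergeticsParameters, LactateParameters
from .profiles import (
    PowerProfile,
    bout_with_recovery_profile,
    build_virtual_power_curve,
    constant_bout_profile,
    skier_fixture_points,
)

__all__ = [
    "DEGENERATE",
    "oracle_steady_state_lactate",
    "oracle_energy_quadrature",
    "protocol_suite",
]

#: Returned when the lactate drive vanishes (Qa = 0): dC/dt is identically
#: zero, so every concentration is a fixed point.
DEGENERATE = "degenerate"

#: Upper bracket for the steady-state root search, mmol/L; far above any
#: physiological concentration.
_C_BRACKET_MMOL = 50.0


def oracle_steady_state_lactate(
    Qa: float, params: LactateParameters, Qmax: float
) -> float | Divergent | str:
    """Steady-state lactate concentration by root bracketing on the rate law.

    Finds the zero of dC/dt in C over [0, 50] mmol/L with Brent's method
    (tolerance 1e-10 mmol/L), independently of the closed form.  Returns
    :data:`DIVERGENT` when the rate is still positive at the top of the
    bracket (no steady state) and :data:`DEGENERATE` when the drive vanishes
    and the rate is identically zero.
    """
    if abs(lactate_drive(Qa, params, Qmax)) < 1e-300:
        return DEGENERATE
    f = lambda c: lactate_rhs(c, Qa, params, Qmax)
    lo, hi = 1e-12, _C_BRACKET_MMOL
    if f(hi) > 0:
        return DIVERGENT
    return float(brentq(f, lo, hi, xtol=1e-10))


def oracle_energy_quadrature(
    t: np.ndarray, power: np.ndarray, t0: float, t1: float
) -> float:
    """Trapezoid quadrature of a power series over [t0, t1], in J.

    Reference integral for checking the closed-form energy expressions; for
    an independent grid-resolution check, re-simulate at a finer dt and pass
    that series in.
    """
    mask = (t >= t0 - 1e-9) & (t <= t1 + 1e-9)
    if not mask.any():
        raise ValueError("interval outside series")
    return float(trapezoid(np.asarray(power)[mask], np.asarray(t)[mask]))


#: Duration cap, s, for the bouts the protocol list only describes as run
#: "to exhaustion" (no stopping rule is modeled); flagged in the label.
EXHAUSTION_CAP_S = 600.0


def protocol_suite(
    params: EnergeticsParameters | None = None,
) -> dict[str, PowerProfile]:
    """The named treadmill protocols of the reference skier's test battery.

    Speeds are mapped to Qbar_vir fractions through the piecewise-linear
    curve over the published steady-state points.  Includes the six 5-min
    steady-state stages (v1-v6), the longer and recovery variants, and the
    supramaximal v8 stages; "to exhaustion" bouts carry a 600 s cap and a
    ``capped`` marker in their label, since no exhaustion criterion is
    modeled.
    """
    params = params or EnergeticsParameters()
    qmax = params.Qmax
    curve = build_virtual_power_curve(skier_fixture_points(), qmax)
    frac = lambda v: curve(v) / qmax

    def bout(name: str, speed: float, duration: float, capped: bool = False) -> PowerProfile:
        p = constant_bout_profile(frac(speed), duration, Qmax=qmax)
        label = f"{name}[{speed:g}m/s,{duration:g}s" + (",capped]" if capped else "]")
        return PowerProfile(p.segments, label=label)

    suite: dict[str, PowerProfile] = {}
    for i, speed in enumerate([2.08, 2.33, 2.64, 2.83, 3.08, 3.19], start=1):
        suite[f"v{i}"] = bout(f"v{i}", speed, 300.0)
    suite["v4_800s"] = bout("v4_800s", 2.87, 800.0)
    suite["v5_800s"] = bout("v5_800s", 3.08, 800.0)
    rec = bout_with_recovery_profile(frac(3.08), 800.0, frac(1.67), 300.0, Qmax=qmax)
    suite["v5_recovery"] = PowerProfile(
        rec.segments, label="v5_recovery[3.08m/s,800s;1.67m/s,300s]"
    )
    suite["v5_2000s"] = bout("v5_2000s", 3.08, 2000.0)
    suite["v5_exhaustion"] = bout("v5_exhaustion", 3.05, EXHAUSTION_CAP_S, capped=True)
    suite["v6_400s"] = bout("v6_400s", 3.19, 400.0)
    suite["v6_exhaustion"] = bout("v6_exhaustion", 3.19, EXHAUSTION_CAP_S, capped=True)
    suite["v7_400s"] = bout("v7_400s", 3.33, 400.0)
    suite["v8_150s"] = bout("v8_150s", 3.88, 150.0)
    suite["v8_200s"] = bout("v8_200s", 3.88, 200.0)
    suite["v8_exhaustion"] = bout("v8_exhaustion", 3.88, EXHAUSTION_CAP_S, capped=True)
    return suite
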