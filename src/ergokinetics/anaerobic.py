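"""Alactic (phosphocreatine) anaerobic power, O2-deficit and EPOC bookkeeping.

Two competing models close the power balance

    Q(t) - Qr = (Qa(t) - Qr) + Q_G(t) + Q_CK(t)

once the aerobic power Qa and the lactic power Q_G are known.

Model 1 assumes the total work power equals the virtual steady-state work
power at every instant, which yields the alactic power

    Q_CK1 = (eta_a/eta_CK) [ Qbar_vir - Qa - (eta_G/eta_a) Q_G ],

a generalization of the classical O2-deficit method (to which it reduces when
all three chemical coupling efficiencies are equal).  Model 2 instead ties
the alactic power to the rate of change of the aerobic power,

    Q_CK2 = theta * dQa/dt,

so the alactic energy drawn between two times depends only on the aerobic
power at the endpoints, E_CK2 = theta * (Qa(t) - Qa(t0)).

Recovery bookkeeping: the O2-deficit E_DF integrates the gap between the
virtual and the actual aerobic power; during recovery its negative is the
energy depth E_DB; EPOC integrates the excess of Qa over its steady-state
value; and EPOC_Alt = tau_a * (Qa(t1) - Qa(t2)) is the endpoint shortcut.
When the clamp never engages and the virtual power is the steady-state power
throughout, the three recovery measures coincide.

Sign convention: E_DB, EPOC and EPOC_Alt are positive during a recovery from
elevated Qa (they measure the same excess post-exercise oxygen consumption),
consistent with their stated equality.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .aerobic import AerobicSeries, aerobic_derivative
from .lactate import LactateSeries, lactic_energy
from .parameters import EnergeticsParameters

__all__ = [
    "WorkHeatSplit",
    "work_heat_decomposition",
    "alactic_power_model1",
    "metabolic_power_model1",
    "alactic_power_model2",
    "oxygen_deficit",
    "gap_cumtrapz",
    "alactic_energy_model1",
    "alactic_energy_model2",
    "epoc_measures",
    "store_trajectories",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WorkHeatSplit:
    """Work and heat powers of the three ATP pathways, J/s."""

    Pa: float
    PG: float
    PCK: float
    PT: float
    Haw: float
    HG: float
    HCK: float
    H: float


def work_heat_decomposition(
    Qaw: float, QG: float, QCK: float, params: EnergeticsParameters
) -> WorkHeatSplit:
    """Split each pathway's metabolic power into work and heat.

    Work power of a pathway is its metabolic power times the mechanical
    efficiency eta and that pathway's chemical coupling efficiency; the
    remainder is heat.
    """
    Pa = params.eta * params.eta_a * Qaw
    PG = params.eta * params.eta_G * QG
    PCK = params.eta * params.eta_CK * QCK
    return WorkHeatSplit(
        Pa=Pa,
        PG=PG,
        PCK=PCK,
        PT=Pa + PG + PCK,
        Haw=Qaw - Pa,
        HG=QG - PG,
        HCK=QCK - PCK,
        H=(Qaw - Pa) + (QG - PG) + (QCK - PCK),
    )


def alactic_power_model1(
    Qbar_vir: float, Qa: float, QG: float, params: EnergeticsParameters
) -> float:
    """Model-1 alactic power Q_CK1 in J/s (may be negative: store recharging).

    During recovery the lactic power Q_G turns negative, which lets Q_CK1
    exceed (eta_a/eta_CK)(Qbar_vir - Qa): the recharge overshoot seen when
    phosphocreatine is rebuilt partly at glycolytic expense.
    """
    return (
        params.eta_a
        / params.eta_CK
        * (Qbar_vir - Qa - params.eta_G / params.eta_a * QG)
    )


def metabolic_power_model1(
    Qa: float, QG: float, Qbar_vir: float, params: EnergeticsParameters
) -> float:
    """Model-1 total metabolic power Q1 in J/s.

    Algebraically identical to Qr + (Qa - Qr) + Q_G + Q_CK1; at a steady
    state below the lactate threshold it reduces to Qa.
    """
    r_a = params.eta_a / params.eta_CK
    r_G = params.eta_G / params.eta_CK
    return (
        params.Qr
        + (Qa - params.Qr) * (1.0 - r_a)
        + QG * (1.0 - r_G)
        + r_a * (Qbar_vir - params.Qr)
    )


def alactic_power_model2(Qa_dot: float, theta: float) -> float:
    """Model-2 alactic power Q_CK2 = theta * dQa/dt in J/s.

    ``Qa_dot`` must come from the clamp-aware ODE right-hand side
    (:func:`ergokinetics.aerobic.aerobic_derivative`), not from finite
    differences of the output series.  Negative during recovery (store
    rebuilding).
    """
    return theta * Qa_dot


def _slice(series: AerobicSeries, t0: float, t: float) -> slice:
    i0 = series.index_of(t0)
    i1 = series.index_of(t)
    if i1 < i0:
        raise ValueError("t must be >= t0")
    return slice(i0, i1 + 1)


def gap_cumtrapz(
    t: np.ndarray, y_right: np.ndarray, y_left: np.ndarray
) -> np.ndarray:
    """Cumulative trapezoid of a piecewise-smooth function with jumps.

    ``y_right[i]`` is the value just after t[i], ``y_left[i]`` just before;
    each interval [t[i], t[i+1]] is integrated with the one-sided limits that
    belong to it, so no trapezoid straddles a protocol discontinuity.
    """
    dt = np.diff(t)
    inc = 0.5 * dt * (y_right[:-1] + y_left[1:])
    return np.concatenate(([0.0], np.cumsum(inc)))


def oxygen_deficit(
    aerobic: AerobicSeries, t0: float, t: float, reference: str = "Qbar_vir"
) -> float:
    """O2-deficit E_DF(t0, t) = integral of (reference - Qa) dt, in J.

    ``reference`` selects the driving power: the virtual steady-state power
    "Qbar_vir" (the default) or its clamped counterpart "Qbar_a"
    = min(Qmax, Qbar_vir).  The two differ only during supramaximal bouts.
    Trapezoid quadrature on the simulation grid.
    """
    sl = _slice(aerobic, t0, t)
    ref_r = aerobic.Qbar_vir[sl]
    ref_l = aerobic.Qbar_vir_pre[sl]
    if reference == "Qbar_a":
        qmax = aerobic.params.Qmax
        ref_r = np.minimum(qmax, ref_r)
        ref_l = np.minimum(qmax, ref_l)
    elif reference != "Qbar_vir":
        raise ValueError(f"unknown reference {reference!r}")
    qa = aerobic.Qa[sl]
    return float(gap_cumtrapz(aerobic.t[sl], ref_r - qa, ref_l - qa)[-1])


def alactic_energy_model1(
    aerobic: AerobicSeries,
    lactate: LactateSeries,
    t0: float,
    t: float,
    params: EnergeticsParameters,
) -> float:
    """Model-1 alactic energy E_CK1(t0, t) in J.

    E_CK1 = (eta_a/eta_CK) E_DF(t0,t) - (eta_G/eta_CK) E_G(t0,t): the part of
    the O2-deficit not accounted for by lactate accumulation, rescaled by the
    coupling-efficiency ratios.
    """
    edf = oxygen_deficit(aerobic, t0, t)
    eg = lactic_energy(lactate, t0, t, params.m, params.lambda_)
    return params.eta_a / params.eta_CK * edf - params.eta_G / params.eta_CK * eg


def alactic_energy_model2(
    aerobic: AerobicSeries, t0: float, t: float, theta: float
) -> float:
    """Model-2 alactic energy E_CK2(t0, t) = theta * (Qa(t) - Qa(t0)) in J.

    Exact and path-independent: only the endpoint aerobic powers enter, so
    any closed cycle in Qa draws zero net alactic energy.
    """
    i0 = aerobic.index_of(t0)
    i1 = aerobic.index_of(t)
    return theta * float(aerobic.Qa[i1] - aerobic.Qa[i0])


def epoc_measures(
    aerobic: AerobicSeries, t1: float, t2: float
) -> tuple[float, float, float]:
    """Recovery bookkeeping over [t1, t2]: (E_DB, EPOC, EPOC_Alt), each in J.

    E_DB      = integral of (Qa - Qbar_vir) dt   (energy depth, = -E_DF),
    EPOC      = integral of (Qa - Qbar_a) dt     (excess over steady state),
    EPOC_Alt  = tau_a * (Qa(t1) - Qa(t2))        (endpoint form).

    All three are positive while Qa decays from an elevated level, and they
    agree (to quadrature accuracy) whenever the clamp never engaged and
    Qbar_vir = Qbar_a on the interval.
    """
    edb = -oxygen_deficit(aerobic, t1, t2, reference="Qbar_vir")
    epoc = -oxygen_deficit(aerobic, t1, t2, reference="Qbar_a")
    sl = _slice(aerobic, t1, t2)
    qa = aerobic.Qa[sl]
    epoc_alt = aerobic.params.tau_a * float(qa[0] - qa[-1])
    return edb, epoc, epoc_alt


def store_trajectories(
    aerobic: AerobicSeries,
    lactate: LactateSeries,
    params: EnergeticsParameters,
) -> dict[str, np.ndarray]:
    """Fractional energy-store trajectories from the start of the series.

    Returns arrays ``EG_frac``, ``ECK1_frac``, ``ECK2_frac`` on the series
    grid: fraction(t) = 1 - E_used(0, t) / (E0 * m), starting at exactly 1.
    Fractions may rise back toward 1 during recovery (stores recharging);
    values outside [0, 1 + 1e-6] are allowed but logged, since the model has
    no hard store-clamping rule.
    """
    t = aerobic.t
    edf = gap_cumtrapz(
        t, aerobic.Qbar_vir - aerobic.Qa, aerobic.Qbar_vir_pre - aerobic.Qa
    )
    eg = params.m * params.lambda_ * (lactate.C - lactate.C[0])
    eck1 = params.eta_a / params.eta_CK * edf - params.eta_G / params.eta_CK * eg
    eck2 = params.theta * (aerobic.Qa - aerobic.Qa[0])
    out = {
        "EG_frac": 1.0 - eg / (params.E_G0 * params.m),
        "ECK1_frac": 1.0 - eck1 / (params.E_CK0 * params.m),
        "ECK2_frac": 1.0 - eck2 / (params.E_CK0 * params.m),
    }
    for name, frac in out.items():
        if np.any(frac < -1e-9) or np.any(frac > 1.0 + 1e-6):
            logger.warning(
                "store fraction %s left [0, 1] (min %.4f, max %.6f)",
                name,
                float(frac.min()),
                float(frac.max()),
            )
    return out
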