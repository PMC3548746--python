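"""Whole-body blood-lactate kinetics and the lactic anaerobic power.

The lactate concentration C, averaged over the whole lactate space (muscles
plus blood), follows a one-compartment balance between production driven by
the aerobic power Qa and a removal term that saturates at high concentration:

    dC/dt = p0 D(Qa) - d0 * (tanh(chi C)/chi) * D(Qa) * (Qmax - Qa),

with the metabolic drive

    D(Qa) = Qa - alpha0 * s * tanh(Qa / s),        s = 0.6 Qmax,

where s sits around the intensity of peak fat metabolism.  The rate law is
evaluated in its native units (C in kg/m^3, powers in J/s); the public
interface uses mmol/L with a single canonical conversion point.

For constant Qa the balance has a closed-form steady state (the drive
cancels).  Writing x = p0 chi / (d0 (Qmax - Qa)):

    Cs = artanh(x)/chi = ln((1+x)/(1-x)) / (2 chi)      if x < 1,

and no steady state exists for x >= 1: removal saturates and can never match
production, so C grows without bound.  The boundary x = 1 defines the lactate
threshold Q_LT = Qmax - p0 chi / d0, the highest aerobic power with a finite
lactate steady state.

The lactic anaerobic power is proportional to the rate of whole-body lactate
accumulation, Q_G = m * lambda * dC/dt, and the lactic energy over an
interval is therefore an exact function of the concentration endpoints,
E_G = m * lambda * (C(t) - C(t0)).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .aerobic import AerobicSeries
from .parameters import (
    KG_PER_M3_PER_MMOL_PER_L,
    EnergeticsParameters,
    LactateParameters,
)

__all__ = [
    "Divergent",
    "DIVERGENT",
    "LactateSeries",
    "lactate_drive",
    "lactate_rhs",
    "steady_state_concentration",
    "lactate_threshold",
    "integrate_lactate",
    "lactic_power",
    "lactic_energy",
]

logger = logging.getLogger(__name__)


class Divergent:
    """Marker: no finite lactate steady state exists at this intensity."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover
        return "DIVERGENT"


#: Returned by :func:`steady_state_concentration` above the lactate threshold,
#: so downstream code must branch explicitly instead of propagating an inf.
DIVERGENT = Divergent()


@dataclass(frozen=True)
class LactateSeries:
    """Lactate concentration (mmol/L) and its rate on the simulation grid."""

    t: np.ndarray
    C: np.ndarray
    Cdot: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.t) == len(self.C) == len(self.Cdot)):
            raise ValueError("misaligned series")

    def index_of(self, time: float) -> int:
        i = int(np.argmin(np.abs(self.t - time)))
        if abs(self.t[i] - time) > 1e-9:
            raise ValueError(f"t={time} is not on the simulation grid")
        return i


def lactate_drive(Qa: float, params: LactateParameters, Qmax: float) -> float:
    """Metabolic drive D(Qa) = Qa - alpha0 * s * tanh(Qa/s), s = fat_peak_fraction * Qmax.

    D(0) = 0, D is strictly positive for Qa > 0 when alpha0 < 1 (since
    s*tanh(Qa/s) < Qa), and D -> Qa - alpha0*s for large Qa.  Units: J/s.
    """
    if Qa < 0:
        raise ValueError("Qa must be >= 0")
    s = params.fat_peak_fraction * Qmax
    return Qa - params.alpha0 * s * math.tanh(Qa / s)


def _rhs_native(C_kg: float, Qa: float, params: LactateParameters, Qmax: float) -> float:
    """dC/dt in kg/(m^3 s) with C in kg/m^3."""
    D = lactate_drive(Qa, params, Qmax)
    removal = params.d0 * (math.tanh(params.chi * C_kg) / params.chi) * D * (Qmax - Qa)
    return params.p0 * D - removal


def lactate_rhs(
    C: float, Qa: float, params: LactateParameters, Qmax: float
) -> float:
    """dC/dt in mmol/(L s) for C in mmol/L.

    The rate law is computed in its native units (kg/m^3, J/s) and the result
    converted back, keeping a single canonical conversion point.
    """
    if C < 0:
        raise ValueError("C must be >= 0")
    C_kg = C * KG_PER_M3_PER_MMOL_PER_L
    return _rhs_native(C_kg, Qa, params, Qmax) / KG_PER_M3_PER_MMOL_PER_L


def steady_state_concentration(
    Qa: float, params: LactateParameters, Qmax: float
) -> float | Divergent:
    """Closed-form steady-state lactate concentration Cs (mmol/L) at constant Qa.

    Returns :data:`DIVERGENT` when the saturation argument
    x = p0 chi / (d0 (Qmax - Qa)) reaches 1, i.e. at and above the lactate
    threshold.  As chi -> 0 the value converges to
    p0 / (d0 (Qmax - Qa)) (no saturation).
    """
    if Qa >= Qmax:
        raise ValueError("steady state is defined only for Qa < Qmax")
    x = params.p0 * params.chi / (params.d0 * Qmax * (1.0 - Qa / Qmax))
    # 1e-12 slack so that Qa computed as exactly the threshold lands on the
    # divergent branch despite float round-off in (Qmax - Qa)
    if x >= 1.0 - 1e-12:
        return DIVERGENT
    cs_kg = math.atanh(x) / params.chi
    return cs_kg / KG_PER_M3_PER_MMOL_PER_L


def lactate_threshold(
    params: LactateParameters, Qmax: float
) -> tuple[float, float]:
    """Lactate threshold (Q_LT in J/s, Q_LT/Qmax).

    Q_LT = Qmax - p0 chi / d0 is the aerobic power at which the steady-state
    saturation argument reaches 1; above it the modeled concentration grows
    without bound.
    """
    qlt = Qmax - params.p0 * params.chi / params.d0
    if qlt <= 0:
        raise ValueError(
            "parameters place the lactate threshold at or below zero power"
        )
    return qlt, qlt / Qmax


def integrate_lactate(
    aerobic: AerobicSeries,
    params: LactateParameters,
    C0: float | None = None,
) -> LactateSeries:
    """RK4 integration of the lactate balance driven by an aerobic-power series.

    Qa between grid points is taken as the linear interpolant of the series
    (the midpoint stage uses the endpoint average).  C starts at ``C0``
    (default: the parameter record's initial concentration, mmol/L).  Tiny
    negative excursions (< 1e-9 mmol/L, numerical) are clipped to zero;
    anything larger aborts.
    """
    t = aerobic.t
    qa = aerobic.Qa
    qmax = aerobic.params.Qmax
    qr = aerobic.params.Qr
    if np.any(qa < qr - 1e-9):
        logger.warning(
            "aerobic power below resting power: the lactate drive may be "
            "negative in this regime, which the model was never fitted for"
        )
    c = (params.C0 if C0 is None else float(C0)) * KG_PER_M3_PER_MMOL_PER_L
    chi, p0, d0 = params.chi, params.p0, params.d0
    s = params.fat_peak_fraction * qmax
    alpha0 = params.alpha0

    def f(c_kg: float, q: float) -> float:
        D = q - alpha0 * s * math.tanh(q / s)
        return p0 * D - d0 * (math.tanh(chi * c_kg) / chi) * D * (qmax - q)

    n = len(t)
    cs = np.empty(n)
    cdot = np.empty(n)
    cs[0] = c
    cdot[0] = f(c, qa[0])
    for i in range(n - 1):
        h = t[i + 1] - t[i]
        q0, q1 = qa[i], qa[i + 1]
        qm = 0.5 * (q0 + q1)
        k1 = f(c, q0)
        k2 = f(c + 0.5 * h * k1, qm)
        k3 = f(c + 0.5 * h * k2, qm)
        k4 = f(c + h * k3, q1)
        c = c + h / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if c < 0.0:
            if c < -1e-9 * KG_PER_M3_PER_MMOL_PER_L:
                raise FloatingPointError(
                    f"lactate concentration went negative at t={t[i + 1]:.3f}s"
                )
            c = 0.0
        cs[i + 1] = c
        cdot[i + 1] = f(c, q1)
    return LactateSeries(
        t=t,
        C=cs / KG_PER_M3_PER_MMOL_PER_L,
        Cdot=cdot / KG_PER_M3_PER_MMOL_PER_L,
    )


def lactic_power(Cdot: float, m: float, lambda_: float) -> float:
    """Lactic anaerobic power Q_G = m * lambda * dC/dt in J/s.

    Negative during net lactate removal (recovery), when glycolytic stores
    are being rebuilt.
    """
    return m * lambda_ * Cdot


def lactic_energy(
    series: LactateSeries, t0: float, t: float, m: float, lambda_: float
) -> float:
    """Lactic energy E_G(t0, t) = m * lambda * (C(t) - C(t0)) in J.

    Exact — the integral of Q_G telescopes to the concentration endpoints, so
    no quadrature is involved.  Zero over any closed cycle with
    C(t) = C(t0).
    """
    i0 = series.index_of(t0)
    i1 = series.index_of(t)
    return m * lambda_ * (series.C[i1] - series.C[i0])
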