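"""Simulation engine: profile -> aerobic -> lactate -> anaerobic on one grid.

The engine runs the four model stages in order on a single shared grid (no
interpolation between stages; protocol breakpoints are grid points) and
collects everything into a :class:`SimulationResult` whose metadata is
sufficient to reproduce the run bit-for-bit.  The model is fully
deterministic — repeated runs produce byte-identical output.
"""

from __future__ import annotations

import io
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .aerobic import AerobicSeries, aerobic_derivative, integrate_aerobic
from .anaerobic import (
    alactic_power_model1,
    epoc_measures,
    gap_cumtrapz,
    metabolic_power_model1,
    store_trajectories,
)
from .lactate import LactateSeries, integrate_lactate, lactate_threshold
from .parameters import EnergeticsParameters, LactateParameters
from .profiles import PowerProfile

__all__ = ["SimulationResult", "run_simulation", "write_timeseries", "read_timeseries", "summary_report"]

logger = logging.getLogger(__name__)

#: Column order of the time-series table; all powers J/s, energies J,
#: concentration mmol/L, fractions dimensionless.
COLUMNS = [
    "t",
    "Qbar_vir",
    "Qvir",
    "Qa",
    "C",
    "Cdot",
    "QG",
    "QCK1",
    "QCK2",
    "Q1",
    "EDF",
    "EG",
    "ECK1",
    "ECK2",
    "EG_frac",
    "ECK1_frac",
    "ECK2_frac",
]


@dataclass(frozen=True)
class SimulationResult:
    """Aligned time series of a full bioenergetic simulation plus metadata."""

    data: pd.DataFrame
    metadata: dict[str, Any]
    aerobic: AerobicSeries | None = field(default=None, repr=False, compare=False)
    lactate: LactateSeries | None = field(default=None, repr=False, compare=False)

    @property
    def t(self) -> np.ndarray:
        return self.data["t"].to_numpy()


def run_simulation(
    profile: PowerProfile,
    params: EnergeticsParameters | None = None,
    lactate_params: LactateParameters | None = None,
    dt: float = 0.1,
    Qvir0: float | None = None,
    C0: float | None = None,
) -> SimulationResult:
    """Run all model stages over a protocol and assemble the result table.

    Stages: (1) aerobic-power ODE with clamp; (2) lactate balance driven by
    the aerobic series; (3) lactic, alactic (both models) and total powers;
    (4) cumulative energies and store fractions.

    ``Qvir0`` and ``C0`` warm-start the run from a non-resting state (e.g. a
    previous run's terminal values); by default the athlete starts at rest
    (Qvir = Qr, C at the parameter record's initial concentration).
    """
    params = params or EnergeticsParameters()
    lactate_params = lactate_params or LactateParameters()

    try:
        aer = integrate_aerobic(profile, params, dt=dt, Qvir0=Qvir0)
    except Exception as exc:  # pragma: no cover
        raise RuntimeError(f"aerobic stage failed: {exc}") from exc
    try:
        lac = integrate_lactate(aer, lactate_params, C0=C0)
    except Exception as exc:
        raise RuntimeError(f"lactate stage failed: {exc}") from exc

    m, lam = params.m, params.lambda_
    qg = m * lam * lac.Cdot
    qck1 = np.array(
        [
            alactic_power_model1(qb, qa, g, params)
            for qb, qa, g in zip(aer.Qbar_vir, aer.Qa, qg)
        ]
    )
    qa_dot = np.array(
        [aerobic_derivative(qv, qb, params) for qv, qb in zip(aer.Qvir, aer.Qbar_vir)]
    )
    qck2 = params.theta * qa_dot
    q1 = np.array(
        [
            metabolic_power_model1(qa, g, qb, params)
            for qa, g, qb in zip(aer.Qa, qg, aer.Qbar_vir)
        ]
    )

    edf = gap_cumtrapz(
        aer.t, aer.Qbar_vir - aer.Qa, aer.Qbar_vir_pre - aer.Qa
    )
    eg = m * lam * (lac.C - lac.C[0])
    eck1 = params.eta_a / params.eta_CK * edf - params.eta_G / params.eta_CK * eg
    eck2 = params.theta * (aer.Qa - aer.Qa[0])
    fracs = store_trajectories(aer, lac, params)

    data = pd.DataFrame(
        {
            "t": aer.t,
            "Qbar_vir": aer.Qbar_vir,
            "Qvir": aer.Qvir,
            "Qa": aer.Qa,
            "C": lac.C,
            "Cdot": lac.Cdot,
            "QG": qg,
            "QCK1": qck1,
            "QCK2": qck2,
            "Q1": q1,
            "EDF": edf,
            "EG": eg,
            "ECK1": eck1,
            "ECK2": eck2,
            "EG_frac": fracs["EG_frac"],
            "ECK1_frac": fracs["ECK1_frac"],
            "ECK2_frac": fracs["ECK2_frac"],
        },
        columns=COLUMNS,
    )
    metadata = {
        "protocol": profile.label,
        "dt": dt,
        "duration": profile.duration,
        "breakpoints": list(profile.breakpoints),
        "parameters": {
            "energetics": params.__dict__.copy(),
            "lactate": lactate_params.__dict__.copy(),
        },
        "software_version": __version__,
    }
    return SimulationResult(data=data, metadata=metadata, aerobic=aer, lactate=lac)


def write_timeseries(
    result: SimulationResult, path: str | Path, format: str = "csv"
) -> Path:
    """Write the result to disk.

    CSV: a ``#`` comment line with units, a metadata comment line (JSON), one
    header row, full float precision.  JSON: columns plus metadata in one
    document.
    """
    path = Path(path)
    if format == "csv":
        buf = io.StringIO()
        buf.write(
            "# units: t s, powers J/s, C mmol/L, Cdot mmol/(L s), "
            "energies J, *_frac dimensionless\n"
        )
        buf.write("# metadata: " + json.dumps(result.metadata, sort_keys=True) + "\n")
        result.data.to_csv(buf, index=False, float_format="%.17g")
        path.write_text(buf.getvalue())
    elif format == "json":
        doc = {
            "metadata": result.metadata,
            "columns": {c: result.data[c].tolist() for c in result.data.columns},
        }
        path.write_text(json.dumps(doc, sort_keys=True))
    else:
        raise ValueError(f"unknown format {format!r}; expected 'csv' or 'json'")
    return path


def read_timeseries(path: str | Path) -> SimulationResult:
    """Read a result written by :func:`write_timeseries` (either format)."""
    path = Path(path)
    text = path.read_text()
    if text.lstrip().startswith("{"):
        doc = json.loads(text)
        return SimulationResult(
            data=pd.DataFrame(doc["columns"]), metadata=doc["metadata"]
        )
    metadata: dict[str, Any] = {}
    for line in text.splitlines():
        if line.startswith("# metadata: "):
            metadata = json.loads(line[len("# metadata: "):])
    data = pd.read_csv(io.StringIO(text), comment="#", float_precision="round_trip")
    return SimulationResult(data=data, metadata=metadata)


def summary_report(
    result: SimulationResult,
    recovery_start: float | None = None,
) -> dict[str, float]:
    """Deterministic scalar summary of a completed run.

    Threshold quantities come from the closed forms, not from the series.
    If the protocol has more than one segment, recovery measures (E_DB, EPOC,
    EPOC_Alt) are computed from the start of the last segment to the end of
    the run; ``recovery_start`` overrides that choice.
    """
    params = EnergeticsParameters(**result.metadata["parameters"]["energetics"])
    lpar = LactateParameters(**result.metadata["parameters"]["lactate"])
    qlt, qlt_frac = lactate_threshold(lpar, params.Qmax)
    report: dict[str, float] = {
        "QLT_J_per_s": qlt,
        "QLT_over_Qmax": qlt_frac,
        "peak_C_mmol_per_L": float(result.data["C"].max()),
        "terminal_C_mmol_per_L": float(result.data["C"].iloc[-1]),
        "EDF_total_J": float(result.data["EDF"].iloc[-1]),
        "EG_total_J": float(result.data["EG"].iloc[-1]),
        "ECK1_total_J": float(result.data["ECK1"].iloc[-1]),
        "ECK2_total_J": float(result.data["ECK2"].iloc[-1]),
        "terminal_EG_frac": float(result.data["EG_frac"].iloc[-1]),
        "terminal_ECK1_frac": float(result.data["ECK1_frac"].iloc[-1]),
        "terminal_ECK2_frac": float(result.data["ECK2_frac"].iloc[-1]),
    }
    breakpoints = result.metadata.get("breakpoints", [])
    if recovery_start is None and len(breakpoints) > 2:
        recovery_start = breakpoints[-2]
    if recovery_start is not None and result.aerobic is not None:
        edb, epoc, epoc_alt = epoc_measures(
            result.aerobic, recovery_start, result.aerobic.t[-1]
        )
        report["EDB_J"] = edb
        report["EPOC_J"] = epoc
        report["EPOC_Alt_J"] = epoc_alt
    return report
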