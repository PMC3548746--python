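"""Model constants for whole-body exercise bioenergetics.

Two parameter records cover the full model: :class:`EnergeticsParameters`
(athlete mass, metabolic powers, kinetic time constant, efficiencies) and
:class:`LactateParameters` (constants of the whole-body lactate rate law).
Defaults reproduce the published parameter set fitted to one elite
cross-country skier; they are not population values.

All powers are metabolic powers in J/s (1 J/s = 1 W of chemical energy
turnover, not external work). Lactate concentration is handled internally in
mmol/L; kg/m^3 is accepted at the boundary via
:func:`convert_lactate_concentration`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, fields, replace
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = [
    "EnergeticsParameters",
    "LactateParameters",
    "ParameterError",
    "LACTATE_MOLAR_MASS_G_PER_MOL",
    "KG_PER_M3_PER_MMOL_PER_L",
    "convert_lactate_concentration",
    "lambda_from_oxygen_equivalent",
    "gross_efficiency",
    "load_parameters",
]

#: Molar mass of lactate (C3H5O3-), g/mol.  Fixed so that the conversion
#: 0.045 kg/m^3 <-> 0.5 mmol/L used throughout the model is exact at one
#: decimal.
LACTATE_MOLAR_MASS_G_PER_MOL = 90.08

#: 1 mmol/L of lactate expressed in kg/m^3.
KG_PER_M3_PER_MMOL_PER_L = LACTATE_MOLAR_MASS_G_PER_MOL * 1e-3


class ParameterError(ValueError):
    """A parameter value violates a model invariant, or a config is malformed."""


@dataclass(frozen=True)
class EnergeticsParameters:
    """Athlete-level constants of the bioenergetic model.

    Attributes
    ----------
    m : float
        Body mass, kg.
    Qr : float
        Resting metabolic power, J/s.
    Qmax : float
        Maximal aerobic metabolic power, J/s.
    tau_a : float
        e-folding time of the aerobic power response, s.
    eta : float
        Mechanical efficiency (work per unit ATP free energy), dimensionless.
    eta_a, eta_G, eta_CK : float
        Chemical coupling efficiencies of ATP production by oxidative
        phosphorylation, glycolysis/glycogenolysis, and the creatine-kinase
        reaction, dimensionless.
    theta : float
        Proportionality constant of the alactic-power model 2
        (Q_CK2 = theta * dQa/dt), s.  The published value is 20 s; see
        :meth:`derived_theta` for the (eta_a/eta_CK)*tau_a alternative.
    c : float
        Slope of the virtual steady-state metabolic power vs work rate line,
        dimensionless.
    lambda_ : float
        Energy equivalent of lactate accumulation, J per kg body mass per
        (mmol/L).
    E_G0 : float
        Initial lactic (glycolytic) energy store, J per kg body mass.
    E_CK0 : float
        Initial alactic (phosphocreatine) energy store, J per kg body mass.
    """

    m: float = 77.5
    Qr: float = 80.0
    Qmax: float = 1886.0
    tau_a: float = 30.0
    eta: float = 0.5
    eta_a: float = 0.6
    eta_G: float = 0.6
    eta_CK: float = 0.95
    theta: float = 20.0
    c: float = 6.6
    lambda_: float = 60.0
    E_G0: float = 870.0
    E_CK0: float = 830.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not isinstance(v, (int, float)) or not v > 0:
                raise ParameterError(f"{f.name} must be strictly positive, got {v!r}")
        if not self.Qr < self.Qmax:
            raise ParameterError(
                f"Qr must be below Qmax (Qr={self.Qr}, Qmax={self.Qmax})"
            )
        for name in ("eta", "eta_a", "eta_G", "eta_CK"):
            v = getattr(self, name)
            if v > 1:
                raise ParameterError(f"{name} is an efficiency and must be <= 1, got {v}")

    def derived_theta(self) -> float:
        """theta recomputed from the efficiency ratio, (eta_a/eta_CK)*tau_a, s."""
        return self.eta_a / self.eta_CK * self.tau_a

    def with_derived_theta(self) -> "EnergeticsParameters":
        """Copy with theta replaced by (eta_a/eta_CK)*tau_a instead of the printed 20 s."""
        return replace(self, theta=self.derived_theta())


@dataclass(frozen=True)
class LactateParameters:
    """Constants of the one-compartment whole-body lactate rate law.

    The rate law is written in the native units of the published fit:
    concentration in kg/m^3 and powers in J/s.

    Attributes
    ----------
    chi : float
        Saturation parameter of the removal term, m^3/kg.
    p0 : float
        Production scale, kg/(m^3 s) per (J/s).
    d0 : float
        Removal scale, 1/((J/s)^2 s).
    alpha0 : float
        Offset factor of the metabolic drive function, dimensionless.
    fat_peak_fraction : float
        The drive saturation scale expressed as a fraction of Qmax
        (around peak fat metabolism), dimensionless.
    C0 : float
        Initial lactate concentration, mmol/L.
    """

    chi: float = 2.54
    p0: float = 1e-5
    d0: float = 1.1e-7
    alpha0: float = 0.9
    fat_peak_fraction: float = 0.6
    C0: float = 0.5

    def __post_init__(self) -> None:
        for name in ("chi", "p0", "d0", "C0"):
            v = getattr(self, name)
            if not v > 0:
                raise ParameterError(f"{name} must be strictly positive, got {v!r}")
        if not 0 <= self.alpha0 < 1:
            raise ParameterError(f"alpha0 must be in [0, 1), got {self.alpha0!r}")
        if not 0 < self.fat_peak_fraction < 1:
            raise ParameterError(
                f"fat_peak_fraction must be in (0, 1), got {self.fat_peak_fraction!r}"
            )


def convert_lactate_concentration(value: float, from_unit: str) -> float:
    """Convert a lactate concentration between kg/m^3 and mmol/L.

    Uses the lactate molar mass 90.08 g/mol, i.e. 1 mmol/L = 0.09008 kg/m^3.
    The round trip is the identity to better than 1e-12 relative.

    Parameters
    ----------
    value : float
        Concentration, >= 0, in ``from_unit``.
    from_unit : {"kg/m3", "mmol/L"}
        Unit of ``value``; the result is in the other unit.
    """
    if value < 0:
        raise ParameterError(f"concentration must be non-negative, got {value!r}")
    if from_unit == "kg/m3":
        return value / KG_PER_M3_PER_MMOL_PER_L
    if from_unit == "mmol/L":
        return value * KG_PER_M3_PER_MMOL_PER_L
    raise ParameterError(
        f"unknown concentration unit {from_unit!r}; expected 'kg/m3' or 'mmol/L'"
    )


def lambda_from_oxygen_equivalent(
    ml_O2_per_kg_per_mmolL: float, joules_per_ml_O2: float
) -> float:
    """Lactate energy equivalent from its oxygen equivalent.

    The energy freed per unit lactate accumulation is expressed as an O2
    volume per kg body mass per mmol/L times an energy content per ml O2;
    the published values 3 ml/kg/(mmol/L) and 20 J/ml give lambda = 60
    J/(kg mmol/L).
    """
    if ml_O2_per_kg_per_mmolL < 0 or joules_per_ml_O2 <= 0:
        raise ParameterError("oxygen-equivalent factors must be positive")
    return ml_O2_per_kg_per_mmolL * joules_per_ml_O2


def gross_efficiency(c: float, eta: float, eta_a: float) -> float:
    """Gross efficiency eta_r = 1/(c * eta * eta_a) of steady-state locomotion.

    With the skier's c = 6.6, eta = 0.5, eta_a = 0.6 this evaluates to 0.505,
    i.e. 0.51 at two decimals.
    """
    denom = c * eta * eta_a
    if denom <= 0:
        raise ParameterError("c, eta and eta_a must all be strictly positive")
    return 1.0 / denom


_ENERGETICS_FIELDS = {f.name for f in fields(EnergeticsParameters)}
_LACTATE_FIELDS = {f.name for f in fields(LactateParameters)}


def load_parameters(
    config_source: str | Path | Mapping[str, Any] | None = None,
    *,
    overrides: Mapping[str, Any] | None = None,
) -> tuple[EnergeticsParameters, LactateParameters]:
    """Build both parameter records from a flat config mapping.

    ``config_source`` may be ``None`` (all defaults), a mapping, or a path to
    a YAML/JSON file containing one flat key -> number mapping whose keys
    match the dataclass field names exactly.  Unknown keys are rejected so a
    typo cannot silently fall back to a default.  ``overrides`` are applied
    on top (CLI ``--set key=value``).
    """
    data: dict[str, Any] = {}
    if config_source is None:
        pass
    elif isinstance(config_source, Mapping):
        data.update(config_source)
    else:
        path = Path(config_source)
        text = path.read_text()
        loaded = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ParameterError(f"config {path} must contain a flat mapping")
        data.update(loaded)
    if overrides:
        data.update(overrides)

    unknown = set(data) - _ENERGETICS_FIELDS - _LACTATE_FIELDS
    if unknown:
        raise ParameterError(f"unknown parameter name(s): {sorted(unknown)}")
    energetics = EnergeticsParameters(
        **{k: float(v) for k, v in data.items() if k in _ENERGETICS_FIELDS}
    )
    lactate = LactateParameters(
        **{k: float(v) for k, v in data.items() if k in _LACTATE_FIELDS}
    )
    return energetics, lactate
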