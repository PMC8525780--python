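"""Farquhar-von Caemmerer-Berry (FvCB) forward model of C3 leaf photosynthesis.

Net CO2 assimilation is modelled as the minimum of three potentially limiting
gross rates -- Rubisco carboxylation (Ac), RuBP regeneration through electron
transport (Aj) and triose-phosphate utilisation (Ap) -- minus mitochondrial
respiration in the light::

    A_net = min(Ac, Aj, Ap) - Rd

with

    Ac = Vcmax (Ci - GammaStar) / (Ci + Kc (1 + O/Ko))
    Aj = J (Ci - GammaStar) / (4 Ci + 8 GammaStar)
    Ap = 3 Tp

All gas concentrations are mole fractions: Ci, Kc and GammaStar in umol mol-1,
Ko and O in mmol mol-1.  Rates are umol m-2 s-1.  Each parameter is stored at
the 25 degC reference temperature and rescaled to the leaf temperature of each
observation with a (possibly peaked) Arrhenius function, so fitted values are
directly comparable across measurement conditions.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Mapping

import numpy as np
import yaml

__all__ = [
    "R_GAS",
    "ArrheniusParams",
    "TemperatureResponses",
    "KineticConstants",
    "FvCBParams",
    "LimitationState",
    "load_constants",
    "default_temperature_responses",
    "default_kinetics",
    "temp_scaler",
    "kinetics_at_T",
    "electron_transport_rate",
    "fvcb_forward",
]

R_GAS = 8.314  # universal gas constant, J mol-1 K-1

#: parameter tags for which a temperature response must be defined
PARAM_KINDS = ("Vcmax", "Jmax", "Tp", "Rdark", "Kc", "Ko", "GammaStar")


class LimitationState(str, Enum):
    """Which gross rate is the binding minimum at one observation."""

    Ac = "Ac"
    Aj = "Aj"
    Ap = "Ap"


@dataclass(frozen=True)
class ArrheniusParams:
    """Arrhenius parameters for one temperature-dependent quantity.

    Ha is the activation energy (J mol-1).  When the deactivation energy Hd
    (J mol-1) and entropy term dS (J mol-1 K-1) are both given, the peaked
    form with a temperature optimum is used; otherwise the response is the
    pure (monotone) Arrhenius exponential.
    """

    Ha: float
    Hd: float | None = None
    dS: float | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.Ha) or self.Ha <= 0:
            raise ValueError(f"Ha must be positive and finite, got {self.Ha}")
        if (self.Hd is None) != (self.dS is None):
            raise ValueError("Hd and dS must be given together (peaked form)")
        if self.Hd is not None and self.Hd <= self.Ha:
            raise ValueError("peaked form requires Hd > Ha")

    @property
    def peaked(self) -> bool:
        return self.Hd is not None


@dataclass(frozen=True)
class TemperatureResponses:
    """Arrhenius parameters per parameter kind plus the reference temperature."""

    responses: Mapping[str, ArrheniusParams]
    Tref: float = 25.0  # degC
    R: float = R_GAS

    def __getitem__(self, kind: str) -> ArrheniusParams:
        try:
            return self.responses[kind]
        except KeyError:
            raise KeyError(
                f"no temperature response defined for parameter kind {kind!r}; "
                f"known kinds: {sorted(self.responses)}"
            ) from None


@dataclass(frozen=True)
class KineticConstants:
    """Rubisco kinetic constants at 25 degC (mole-fraction basis).

    Kc25 and GammaStar25 are umol mol-1, Ko25 and O are mmol mol-1.
    """

    Kc25: float = 404.9
    Ko25: float = 278.4
    GammaStar25: float = 42.75
    O: float = 210.0

    def __post_init__(self) -> None:
        for name in ("Kc25", "Ko25", "GammaStar25", "O"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.GammaStar25 >= self.Kc25:
            raise ValueError("GammaStar25 must be below Kc25")


@dataclass(frozen=True)
class FvCBParams:
    """FvCB parameters at the 25 degC reference temperature.

    Tp25 is optional: when ``None`` the triose-phosphate-utilisation limb is
    disabled and A_net = min(Ac, Aj) - Rd.
    """

    Vcmax25: float
    Jmax25: float
    Rd25: float
    Tp25: float | None = None
    theta: float = 0.7    # curvature of the light response (dimensionless)
    alpha: float = 0.425  # apparent quantum yield (mol e- mol-1 photons)

    def __post_init__(self) -> None:
        for name in ("Vcmax25", "Jmax25", "Rd25"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if self.Tp25 is not None and (not np.isfinite(self.Tp25) or self.Tp25 < 0):
            raise ValueError(f"Tp25 must be finite and >= 0, got {self.Tp25}")
        if not 0 < self.theta < 1:
            raise ValueError(f"theta must lie in (0, 1), got {self.theta}")
        if self.alpha <= 0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")

    def with_(self, **kwargs) -> "FvCBParams":
        return replace(self, **kwargs)


def load_constants(path=None) -> tuple[TemperatureResponses, KineticConstants]:
    """Load temperature-response and kinetic constants from a YAML file.

    With no argument, the constants file shipped with the package is used.
    The file format is documented in ``leafspec/data/temperature_responses.yaml``.
    """
    if path is None:
        src = importlib.resources.files("leafspec").joinpath(
            "data/temperature_responses.yaml"
        )
        raw = yaml.safe_load(src.read_text())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    responses = {
        kind: ArrheniusParams(**entry) for kind, entry in raw["responses"].items()
    }
    trp = TemperatureResponses(
        responses=responses,
        Tref=float(raw.get("reference_temperature_C", 25.0)),
        R=float(raw.get("gas_constant", R_GAS)),
    )
    kc = KineticConstants(**raw.get("kinetics", {}))
    return trp, kc


_DEFAULTS: list = []


def _defaults() -> tuple[TemperatureResponses, KineticConstants]:
    if not _DEFAULTS:
        _DEFAULTS.append(load_constants())
    return _DEFAULTS[0]


def default_temperature_responses() -> TemperatureResponses:
    """The packaged temperature-response parameterisation."""
    return _defaults()[0]


def default_kinetics() -> KineticConstants:
    """The packaged Rubisco kinetic constants."""
    return _defaults()[1]


def temp_scaler(param_kind: str, Tleaf, trp: TemperatureResponses | None = None):
    """Dimensionless factor scaling a parameter from Tref to the leaf temperature.

    Returns ``f`` such that ``P(Tleaf) = P(Tref) * f``.  The peaked form

        f(T) = exp(Ha (T - Tr) / (Tr R T))
               * (1 + exp((Tr dS - Hd) / (Tr R))) / (1 + exp((T dS - Hd) / (T R)))

    (temperatures in kelvin) is used when Hd/dS are present for the kind,
    and reduces to the pure Arrhenius exponential otherwise.  ``f(Tref) = 1``
    exactly in both forms.

    Parameters
    ----------
    param_kind : str
        One of the kinds defined in the constants file (e.g. ``"Vcmax"``).
    Tleaf : float or array
        Leaf temperature in degC; must lie in the physically plausible
        0-50 degC range.
    trp : TemperatureResponses, optional
        Defaults to the packaged constants.
    """
    if trp is None:
        trp = default_temperature_responses()
    ap = trp[param_kind]
    Tleaf = np.asarray(Tleaf, dtype=float)
    if not np.all(np.isfinite(Tleaf)):
        raise ValueError("Tleaf must be finite")
    if np.any(Tleaf < 0.0) or np.any(Tleaf > 50.0):
        raise ValueError("Tleaf outside the plausible 0-50 degC range")
    Tk = Tleaf + 273.15
    Tr = trp.Tref + 273.15
    R = trp.R
    f = np.exp(ap.Ha * (Tk - Tr) / (Tr * R * Tk))
    if ap.peaked:
        f = f * (1.0 + np.exp((Tr * ap.dS - ap.Hd) / (Tr * R)))
        f = f / (1.0 + np.exp((Tk * ap.dS - ap.Hd) / (Tk * R)))
    return f if f.ndim else float(f)


def kinetics_at_T(
    Tleaf,
    kc: KineticConstants | None = None,
    trp: TemperatureResponses | None = None,
):
    """Rubisco kinetic constants rescaled from 25 degC to the leaf temperature.

    Returns ``(Kc, Ko, GammaStar)`` at ``Tleaf``, each scaled by its own
    Arrhenius factor.
    """
    if kc is None:
        kc = default_kinetics()
    if trp is None:
        trp = default_temperature_responses()
    Kc = kc.Kc25 * temp_scaler("Kc", Tleaf, trp)
    Ko = kc.Ko25 * temp_scaler("Ko", Tleaf, trp)
    GammaStar = kc.GammaStar25 * temp_scaler("GammaStar", Tleaf, trp)
    return Kc, Ko, GammaStar


def electron_transport_rate(Q, Jmax, theta: float = 0.7, alpha: float = 0.425):
    """Electron transport rate J at irradiance Q (non-rectangular hyperbola).

    J is the smaller root of ``theta J^2 - (alpha Q + Jmax) J + alpha Q Jmax = 0``,
    so that J <= min(alpha*Q, Jmax), J(0) = 0 and J saturates at Jmax.
    """
    if not 0 < theta < 1:
        raise ValueError(f"theta must lie in (0, 1), got {theta}")
    Q = np.asarray(Q, dtype=float)
    if np.any(Q < 0):
        raise ValueError("irradiance Q must be >= 0")
    Jmax = np.asarray(Jmax, dtype=float)
    b = alpha * Q + Jmax
    disc = b * b - 4.0 * theta * alpha * Q * Jmax
    J = (b - np.sqrt(np.maximum(disc, 0.0))) / (2.0 * theta)
    return J if J.ndim else float(J)


def fvcb_forward(
    params: FvCBParams,
    Ci,
    Tleaf,
    Q=None,
    kc: KineticConstants | None = None,
    trp: TemperatureResponses | None = None,
    return_components: bool = False,
):
    """Net assimilation rate and limitation state under the FvCB model.

    Each observation's parameters are rescaled from 25 degC to its own leaf
    temperature before the three gross limbs are evaluated; the binding limb
    is the elementwise minimum.  Missing irradiance (``Q=None``) is treated
    as saturating, i.e. J = Jmax(Tleaf).

    Parameters
    ----------
    params : FvCBParams
    Ci : array-like
        Intercellular CO2 mole fraction, umol mol-1; must be >= 0.
    Tleaf : array-like
        Leaf temperature, degC.
    Q : array-like, optional
        Irradiance, umol m-2 s-1.

    Returns
    -------
    A_net : ndarray
        Net assimilation, umol m-2 s-1.
    states : ndarray of LimitationState
        The limb achieving the minimum gross rate at each observation.
    components : dict, only if ``return_components``
        Arrays ``Ac``, ``Aj``, ``Ap``, ``Rd`` at leaf temperature.
    """
    if kc is None:
        kc = default_kinetics()
    if trp is None:
        trp = default_temperature_responses()
    Ci = np.atleast_1d(np.asarray(Ci, dtype=float))
    if np.any(Ci < 0):
        raise ValueError("Ci must be >= 0")
    Tleaf = np.broadcast_to(np.asarray(Tleaf, dtype=float), Ci.shape)

    Kc, Ko, GammaStar = kinetics_at_T(Tleaf, kc, trp)
    Vcmax = params.Vcmax25 * temp_scaler("Vcmax", Tleaf, trp)
    Jmax = params.Jmax25 * temp_scaler("Jmax", Tleaf, trp)
    Rd = params.Rd25 * temp_scaler("Rdark", Tleaf, trp)

    Ac = Vcmax * (Ci - GammaStar) / (Ci + Kc * (1.0 + kc.O / Ko))
    if Q is None:
        J = Jmax
    else:
        Q = np.broadcast_to(np.asarray(Q, dtype=float), Ci.shape)
        J = electron_transport_rate(Q, Jmax, params.theta, params.alpha)
    Aj = J * (Ci - GammaStar) / (4.0 * Ci + 8.0 * GammaStar)

    if params.Tp25 is not None:
        Tp = params.Tp25 * temp_scaler("Tp", Tleaf, trp)
        Ap = np.broadcast_to(3.0 * Tp, Ci.shape)
    else:
        Ap = np.full_like(Ac, np.inf)

    gross = np.stack([Ac, Aj, Ap])
    idx = np.argmin(gross, axis=0)
    A_net = np.min(gross, axis=0) - Rd
    if not np.all(np.isfinite(A_net)):
        raise FloatingPointError("non-finite assimilation prediction")
    states = np.array(
        [(LimitationState.Ac, LimitationState.Aj, LimitationState.Ap)[i] for i in idx],
        dtype=object,
    )

    if return_components:
        return A_net, states, {"Ac": Ac, "Aj": Aj, "Ap": Ap, "Rd": Rd}
    return A_net, states
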