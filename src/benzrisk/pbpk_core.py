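"""Forward PBPK model: inhaled benzene to urinary trans,trans-muconic acid.

A four-compartment steady-state description of benzene disposition in a
child: richly perfused tissue, fat, poorly perfused tissue and liver. Under
a constant inhaled concentration, arterial blood is assumed to equilibrate
instantaneously, tissue levels follow a saturable first-order filling curve

    C_tissue(t) = (Q * P * C_art * t) / (V * P + Q * t),

benzene is metabolized in the liver with Michaelis-Menten kinetics, and a
fixed fraction of the metabolized mass appears in bladder urine as
trans,trans-muconic acid (tt-MA) between successive micturitions. The chain
is monotone in the inhaled concentration, which is what makes the reverse
(exposure-reconstruction) step in :mod:`benzrisk.reverse_translation`
well-posed.

Units are L/min for flows, L for volumes, mg/L for concentrations in blood,
urine and tissue, mg/m^3 for air, and minutes for time.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

from scipy.optimize import brentq

from .errors import ConfigError, DomainError

#: Molar mass of benzene, g/mol.
MW_BENZENE = 78.11
#: Molar mass of trans,trans-muconic acid (C6H6O4), g/mol.
MW_TTMA = 142.11
#: Molar volume of an ideal gas at 25 degC and 1 atm, L/mol.
MOLAR_VOLUME_25C = 24.45


class CompartmentName(str, enum.Enum):
    RICHLY_PERFUSED = "richly_perfused"
    FAT = "fat"
    POORLY_PERFUSED = "poorly_perfused"
    LIVER = "liver"


@dataclass(frozen=True)
class CompartmentParams:
    """One tissue compartment: blood flow Q (L/min), volume V (L), and
    tissue:blood partition coefficient P (dimensionless)."""

    name: CompartmentName
    Q: float
    V: float
    P: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "name", CompartmentName(self.name))
        for attr in ("Q", "V", "P"):
            if not getattr(self, attr) > 0:
                raise ConfigError(
                    f"compartment {self.name.value}: {attr} must be > 0, "
                    f"got {getattr(self, attr)!r}"
                )


@dataclass(frozen=True)
class MetabolismParams:
    """Hepatic Michaelis-Menten metabolism and the urinary metabolite yield.

    Vmax : maximum metabolic capacity, mg/min
    Km : half-saturation concentration, mg/L
    t_half : benzene elimination half-life, min (carried for completeness;
        the steady-state chain does not use it)
    f_ttma : fraction of metabolized benzene excreted in urine as tt-MA,
        on a molar basis, in (0, 1]
    """

    Vmax: float
    Km: float
    t_half: float = 30.0
    f_ttma: float = 0.039

    def __post_init__(self) -> None:
        if not self.Vmax > 0:
            raise ConfigError(f"Vmax must be > 0, got {self.Vmax!r}")
        if not self.Km > 0:
            raise ConfigError(f"Km must be > 0, got {self.Km!r}")
        if not 0 < self.f_ttma <= 1:
            raise ConfigError(f"f_ttma must be in (0, 1], got {self.f_ttma!r}")


@dataclass(frozen=True)
class Physiology:
    """Subject-level physiology entering the forward chain.

    P_blood_air is the blood:air partition coefficient; Q_alv and Q_card the
    alveolar ventilation and cardiac output (L/min); urine_void_volume the
    bladder volume emptied per micturition (L); micturition_interval the
    accumulation window between voids (min, default 180 = three hours);
    urinary_creatinine in g/L for creatinine-normalized reporting.
    """

    age: float
    body_weight: float
    P_blood_air: float = 8.19
    Q_alv: float = 2.0
    Q_card: float = 2.76
    urine_void_volume: float = 0.15
    micturition_interval: float = 180.0
    urinary_creatinine: float = 1.0

    def __post_init__(self) -> None:
        for attr in (
            "age",
            "body_weight",
            "P_blood_air",
            "Q_alv",
            "Q_card",
            "urine_void_volume",
            "micturition_interval",
            "urinary_creatinine",
        ):
            if not getattr(self, attr) > 0:
                raise ConfigError(
                    f"physiology field {attr} must be > 0, got {getattr(self, attr)!r}"
                )


@dataclass(frozen=True)
class PBPKParameters:
    """The full parameter set: exactly one compartment per tissue name plus
    metabolism, with a free-text provenance note per parameter."""

    compartments: tuple[CompartmentParams, ...]
    metabolism: MetabolismParams
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [c.name for c in self.compartments]
        if sorted(n.value for n in names) != sorted(n.value for n in CompartmentName):
            raise ConfigError(
                "compartments must contain exactly one of each of "
                f"{[n.value for n in CompartmentName]}, got {[n.value for n in names]}"
            )

    def compartment(self, name: CompartmentName | str) -> CompartmentParams:
        name = CompartmentName(name)
        for c in self.compartments:
            if c.name is name:
                return c
        raise KeyError(name)  # unreachable given the invariant

    @property
    def liver(self) -> CompartmentParams:
        return self.compartment(CompartmentName.LIVER)


@dataclass(frozen=True)
class UrineOutput:
    """Urinary tt-MA from one micturition interval at steady state."""

    ttma_conc: float  # mg tt-MA per L urine
    ttma_per_creatinine: float  # mg tt-MA per g creatinine
    metabolized_rate: float  # mg benzene metabolized per min


def compartment_concentration(comp: CompartmentParams, c_art: float, t: float) -> float:
    """Tissue benzene concentration (mg/L) after time t at constant arterial level.

    C(t) = (Q*P*C_art*t) / (V*P + Q*t): zero at t = 0, rising monotonically
    to the partition-equilibrium asymptote P*C_art. ``t = math.inf`` returns
    the asymptote exactly.
    """
    if t < 0:
        raise DomainError(f"time must be >= 0, got {t!r}")
    if c_art < 0:
        raise DomainError(f"arterial concentration must be >= 0, got {c_art!r}")
    if math.isinf(t):
        return comp.P * c_art
    return (comp.Q * comp.P * c_art * t) / (comp.V * comp.P + comp.Q * t)


def steady_state_time(comp: CompartmentParams, rtol: float = 1e-6) -> float:
    """Time at which the filling curve is within ``rtol`` (relative) of its
    asymptote: the relative shortfall is (V*P)/(V*P + Q*t) <= rtol."""
    if not 0 < rtol < 1:
        raise DomainError(f"rtol must be in (0, 1), got {rtol!r}")
    return comp.V * comp.P * (1.0 - rtol) / (comp.Q * rtol)


def _liver_venous_steady(c_art: float, liver: CompartmentParams, met: MetabolismParams) -> float:
    """Liver venous concentration solving Q*(C_art - C_v) = Vmax*C_v/(Km + C_v)."""
    if c_art == 0.0:
        return 0.0

    def balance(c_v: float) -> float:
        return liver.Q * (c_art - c_v) - met.Vmax * c_v / (met.Km + c_v)

    return brentq(balance, 0.0, c_art, xtol=1e-15, rtol=8.9e-16)


def arterial_concentration(
    c_inh: float,
    phys: Physiology,
    mode: str = "equilibrium",
    params: PBPKParameters | None = None,
) -> float:
    """Arterial benzene concentration (mg/L) for a constant air level (mg/m^3).

    ``equilibrium`` (default) assumes blood instantaneously equilibrates with
    inhaled air: C_art = P_blood_air * C_inh / 1000 (the factor 1000 converts
    mg/m^3 to mg/L of air). ``mass_balance`` instead solves the standard
    steady-state lung mass balance

        C_art = (Q_alv*C_inh/1000 + Q_card*C_ven) / (Q_card + Q_alv/P_blood_air)

    with the mixed venous return C_ven computed self-consistently from the
    tissue compartments, the liver extracting benzene by Michaelis-Menten
    kinetics; this mode therefore needs the full ``params``. Both modes are
    linear (equilibrium) or sub-linear (mass balance) and monotone in c_inh.
    """
    if c_inh < 0:
        raise DomainError(f"air concentration must be >= 0, got {c_inh!r}")
    c_air_blood_side = c_inh / 1000.0  # mg per L of air
    if mode == "equilibrium":
        return phys.P_blood_air * c_air_blood_side
    if mode != "mass_balance":
        raise ConfigError(f"unknown arterial mode {mode!r}")
    if params is None:
        raise ConfigError("mass_balance arterial mode requires PBPK parameters")
    if c_inh == 0.0:
        return 0.0

    liver = params.liver
    q_total = sum(c.Q for c in params.compartments)

    def mixed_venous(c_art: float) -> float:
        # Non-metabolizing tissues return blood at C_art once equilibrated;
        # the liver returns blood depleted by metabolism.
        c_vl = _liver_venous_steady(c_art, liver, params.metabolism)
        q_rest = q_total - liver.Q
        return (q_rest * c_art + liver.Q * c_vl) / q_total

    def residual(c_art: float) -> float:
        num = phys.Q_alv * c_air_blood_side + phys.Q_card * mixed_venous(c_art)
        den = phys.Q_card + phys.Q_alv / phys.P_blood_air
        return num / den - c_art

    upper = phys.P_blood_air * c_air_blood_side  # equilibrium value bounds it
    return brentq(residual, 0.0, upper * (1 + 1e-12), xtol=1e-18, rtol=8.9e-16)


def metabolic_rate(c_liver_venous: float, met: MetabolismParams) -> float:
    """Hepatic metabolism rate (mg/min), Vmax*C/(Km + C): saturable, < Vmax."""
    if c_liver_venous < 0:
        raise DomainError(
            f"liver venous concentration must be >= 0, got {c_liver_venous!r}"
        )
    return met.Vmax * c_liver_venous / (met.Km + c_liver_venous)


def ttma_saturation_bound(params: PBPKParameters, phys: Physiology) -> float:
    """Supremum of urinary tt-MA (mg/L) the forward chain can produce.

    As c_inh grows the metabolic rate approaches Vmax, so tt-MA per void is
    capped at f_ttma * Vmax * interval * (MW_tt-MA / MW_benzene), diluted in
    one void volume.
    """
    met = params.metabolism
    return (
        met.f_ttma
        * met.Vmax
        * phys.micturition_interval
        * (MW_TTMA / MW_BENZENE)
        / phys.urine_void_volume
    )


def ttma_urine_forward(
    c_inh: float,
    params: PBPKParameters,
    phys: Physiology,
    t_ss: float | None = None,
    arterial_mode: str = "equilibrium",
) -> UrineOutput:
    """Urinary tt-MA a child would present under a constant air level.

    Chain: arterial concentration -> liver tissue level at ``t_ss`` (default:
    long enough for the filling curve to be within 1e-6 of its asymptote) ->
    liver venous level C_liver / P_liver -> Michaelis-Menten metabolism ->
    benzene mass metabolized over one micturition interval -> tt-MA mass via
    the molar yield f_ttma and the molar-mass ratio -> concentration in one
    void volume.
    """
    if phys.urine_void_volume <= 0:  # Physiology validates; guard stays cheap
        raise ConfigError("urine_void_volume must be positive")
    c_art = arterial_concentration(c_inh, phys, mode=arterial_mode, params=params)
    liver = params.liver
    if t_ss is None:
        t_ss = steady_state_time(liver)
    elif t_ss <= 0:
        raise DomainError(f"t_ss must be > 0, got {t_ss!r}")
    c_liver = compartment_concentration(liver, c_art, t_ss)
    c_venous = c_liver / liver.P
    rate = metabolic_rate(c_venous, params.metabolism)
    metabolized_mass = rate * phys.micturition_interval  # mg benzene per void
    ttma_mass = params.metabolism.f_ttma * metabolized_mass * (MW_TTMA / MW_BENZENE)
    ttma_conc = ttma_mass / phys.urine_void_volume
    return UrineOutput(
        ttma_conc=ttma_conc,
        ttma_per_creatinine=ttma_conc / phys.urinary_creatinine,
        metabolized_rate=rate,
    )


def mg_m3_to_ppm(
    x: float, mw: float = MW_BENZENE, molar_volume: float = MOLAR_VOLUME_25C
) -> float:
    """Convert an air concentration in mg/m^3 to ppm (v/v) at 25 degC, 1 atm."""
    if x < 0:
        raise DomainError(f"concentration must be >= 0, got {x!r}")
    if mw <= 0:
        raise DomainError(f"molar mass must be > 0, got {mw!r}")
    return x * molar_volume / mw
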