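"""EPA-style scenario exposure, hazard quotient, cancer risk and burden.

Chronic exposure averages a constant workplace air concentration over the
scenario's time-activity pattern,

    CE = (C * ET * EF * ED) / (1440 * AT),        AT = ED * 365 days,

so with that averaging-time convention CE depends only on the fraction of
time exposed (ET/1440 * EF/365), not on the duration ED. Non-cancer hazard
is the quotient HQ = CE / RfC against the inhalation reference
concentration; excess lifetime leukemia risk is ICR = CE * IUR for the low
and high inhalation-unit-risk bounds. Presentation follows risk-assessment
convention: CE to two decimals (HQ is computed from the rounded CE so
printed tables are self-consistent), cancer risks per 1000 exposed at one
significant figure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ConfigError, DomainError

#: EPA inhalation reference concentration for benzene, mg/m^3
DEFAULT_RFC = 0.03
#: Inhalation unit risk bounds for benzene-induced leukemia, per (ug/m^3)
DEFAULT_IUR_LOW = 2.2e-6
DEFAULT_IUR_HIGH = 7.8e-6

MINUTES_PER_DAY = 1440.0
DAYS_PER_YEAR = 365.0


@dataclass(frozen=True)
class ExposureScenario:
    """One time-activity scenario: air level C (mg/m^3), exposure time ET
    (min/day), frequency EF (days/year), duration ED (years) and averaging
    time AT (days)."""

    label: str
    C: float
    ET: float
    EF: float
    ED: float
    AT: float

    def __post_init__(self) -> None:
        if not 0 < self.ET <= MINUTES_PER_DAY:
            raise ConfigError(f"ET must be in (0, 1440], got {self.ET!r}")
        if not 0 < self.EF <= DAYS_PER_YEAR:
            raise ConfigError(f"EF must be in (0, 365], got {self.EF!r}")
        if not self.ED > 0:
            raise ConfigError(f"ED must be > 0, got {self.ED!r}")
        if self.C < 0:
            raise ConfigError(f"C must be >= 0, got {self.C!r}")


@dataclass(frozen=True)
class ToxicityCriteria:
    """Benzene toxicity reference values.

    rfc: inhalation reference concentration, mg/m^3.
    iur_low / iur_high: inhalation-unit-risk bounds. ``iur_units`` tags the
    concentration basis; 'per_ug_m3' values are numerically 1000x smaller
    than 'per_mg_m3' ones and are normalized internally.
    """

    rfc: float = DEFAULT_RFC
    iur_low: float = DEFAULT_IUR_LOW
    iur_high: float = DEFAULT_IUR_HIGH
    iur_units: str = "per_ug_m3"

    def __post_init__(self) -> None:
        if not self.rfc > 0:
            raise ConfigError(f"rfc must be > 0, got {self.rfc!r}")
        if not 0 < self.iur_low <= self.iur_high:
            raise ConfigError(
                f"need 0 < iur_low <= iur_high, got {self.iur_low!r}, {self.iur_high!r}"
            )
        if self.iur_units not in {"per_ug_m3", "per_mg_m3"}:
            raise ConfigError(f"unknown iur_units {self.iur_units!r}")

    def iur_per_ug_m3(self) -> tuple[float, float]:
        if self.iur_units == "per_ug_m3":
            return self.iur_low, self.iur_high
        return self.iur_low / 1000.0, self.iur_high / 1000.0


@dataclass(frozen=True)
class RiskResult:
    """Exposure and risk for one scenario, raw and at printed precision."""

    scenario_label: str
    ce_raw: float  # mg/m^3, unrounded
    ce: float  # mg/m^3, 2 d.p. presentation value
    hq: float  # computed from the rounded CE
    icr_low: float  # lifetime excess probability
    icr_high: float
    icr_per_1000_low: float  # 1-s.f. presentation, cases per 1000 exposed
    icr_per_1000_high: float


@dataclass(frozen=True)
class PopulationBurden:
    """Exposed head-count and expected case interval for a community."""

    n_units: int
    children_per_unit: int
    n_exposed: int
    pct_of_population: int
    expected_cases_low: int
    expected_cases_high: int


def round_to_sig_figs(x: float, n: int = 1) -> float:
    """Round to ``n`` significant figures (12.48 -> 10 at one figure)."""
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (n - 1))


def chronic_exposure(s: ExposureScenario) -> float:
    """Time-averaged exposure CE = (C*ET*EF*ED)/(1440*AT) in mg/m^3."""
    if s.AT <= 0:
        raise DomainError(f"AT must be > 0, got {s.AT!r}")
    return (s.C * s.ET * s.EF * s.ED) / (MINUTES_PER_DAY * s.AT)


def hazard_quotient(ce: float, rfc: float = DEFAULT_RFC, round_ce: bool = True) -> float:
    """Non-cancer hazard quotient CE/RfC; > 1 flags potential harm.

    By default CE is first rounded to 2 d.p. so the quotient matches what a
    reader recomputes from a printed exposure table.
    """
    if not rfc > 0:
        raise DomainError(f"rfc must be > 0, got {rfc!r}")
    if ce < 0:
        raise DomainError(f"ce must be >= 0, got {ce!r}")
    if round_ce:
        ce = round(ce, 2)
    return ce / rfc


def cancer_risk(ce: float, tox: ToxicityCriteria = ToxicityCriteria()) -> tuple[float, float]:
    """Excess lifetime leukemia risk interval ICR = CE * IUR.

    CE (mg/m^3) is converted to ug/m^3 before applying the unit risks, which
    are normalized to a per-(ug/m^3) basis whatever their configured units.
    """
    if ce < 0:
        raise DomainError(f"ce must be >= 0, got {ce!r}")
    iur_low, iur_high = tox.iur_per_ug_m3()
    ce_ug = ce * 1000.0
    return ce_ug * iur_low, ce_ug * iur_high


def assess_scenario(
    s: ExposureScenario,
    tox: ToxicityCriteria = ToxicityCriteria(),
    ce_override: float | None = None,
) -> RiskResult:
    """Full per-scenario characterization; ``ce_override`` replaces the
    computed CE (used when an external exposure calculator's value is to be
    carried through unchanged)."""
    ce_raw = chronic_exposure(s) if ce_override is None else float(ce_override)
    if ce_raw < 0:
        raise DomainError(f"CE must be >= 0, got {ce_raw!r}")
    ce_2dp = round(ce_raw, 2)
    icr_low, icr_high = cancer_risk(ce_2dp, tox)
    return RiskResult(
        scenario_label=s.label,
        ce_raw=ce_raw,
        ce=ce_2dp,
        hq=hazard_quotient(ce_raw, tox.rfc, round_ce=True),
        icr_low=icr_low,
        icr_high=icr_high,
        icr_per_1000_low=round_to_sig_figs(icr_low * 1000.0),
        icr_per_1000_high=round_to_sig_figs(icr_high * 1000.0),
    )


def build_scenarios(C: float, scenario_c_ed_years: float = 70.0) -> list[ExposureScenario]:
    """The three standard time-activity scenarios at air concentration C.

    (a) para-occupational, 4 h/day, 300 days/year for 6 years;
    (b) occupational, 8 h/day, 300 days/year for 6 years;
    (c) lifetime projection, 8 h/day, 300 days/year from birth to 70 years.
    AT = ED * 365 throughout.
    """
    if not C > 0:
        raise DomainError(f"C must be > 0, got {C!r}")

    def scenario(label: str, et: float, ed: float) -> ExposureScenario:
        return ExposureScenario(label=label, C=C, ET=et, EF=300.0, ED=ed, AT=ed * DAYS_PER_YEAR)

    return [
        scenario("a", 240.0, 6.0),
        scenario("b", 480.0, 6.0),
        scenario("c", 480.0, scenario_c_ed_years),
    ]


def assess_scenarios(
    C: float,
    tox: ToxicityCriteria = ToxicityCriteria(),
    scenario_c_ce_override: float | None = None,
) -> list[RiskResult]:
    """Characterize all three scenarios; the lifetime scenario's CE may be
    overridden (e.g. by an external exposure calculator's output)."""
    results = []
    for s in build_scenarios(C):
        override = scenario_c_ce_override if s.label == "c" else None
        results.append(assess_scenario(s, tox, ce_override=override))
    return results


def population_burden(
    n_units: int,
    children_per_unit: int,
    ref_population: int,
    risk_interval_rounded: tuple[float, float],
) -> PopulationBurden:
    """Expected leukemia case interval for the exposed child population.

    ``risk_interval_rounded`` is the per-capita lifetime risk interval at its
    presented (rounded) precision, e.g. (2e-3, 6e-3); expected cases are the
    nearest integers of head-count times per-capita risk.
    """
    if n_units < 0 or children_per_unit < 0:
        raise DomainError("counts must be >= 0")
    if ref_population <= 0:
        raise DomainError(f"ref_population must be > 0, got {ref_population!r}")
    lo, hi = risk_interval_rounded
    if not 0 <= lo <= hi:
        raise DomainError(f"need 0 <= low <= high risk, got {lo!r}, {hi!r}")
    n_exposed = n_units * children_per_unit
    return PopulationBurden(
        n_units=n_units,
        children_per_unit=children_per_unit,
        n_exposed=n_exposed,
        pct_of_population=round(n_exposed / ref_population * 100.0),
        expected_cases_low=round(n_exposed * lo),
        expected_cases_high=round(n_exposed * hi),
    )
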