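"""Reverse dosimetry: air benzene from urinary tt-MA, with cohort filtering.

The forward chain in :mod:`benzrisk.pbpk_core` maps a constant air benzene
concentration to the urinary tt-MA a child would present. It is strictly
monotone below the metabolic ceiling, so each child's air exposure is
recovered by a bracketing root search on that map. Before inversion the
cohort is filtered the way the source biomonitoring data were: records with
tt-MA below the assay's limit of quantification are censored out (their
tt-MA cannot be attributed to the occupational source), and children with an
abnormal urinary albumin/creatinine ratio are excluded because the model
assumes normal renal function.

Cohort CSV schema (one row per child):

    child_id,age_y,weight_kg,height_cm,ttma_mg_L,below_loq,creatinine_g_L,acr_mg_g,acr_normal

``below_loq`` and ``acr_normal`` are booleans (``true``/``false``); a
missing ``ttma_mg_L`` is permitted when ``below_loq`` is true.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import (
    CohortSchemaError,
    ConfigError,
    DomainError,
    EmptyCohortError,
    SaturationError,
)
from .pbpk_core import (
    PBPKParameters,
    Physiology,
    ttma_saturation_bound,
    ttma_urine_forward,
)

#: Default assay limit of quantification for urinary tt-MA, mg/L.
DEFAULT_LOQ = 0.06
#: Default clinical cutoff for an abnormal albumin/creatinine ratio, mg/g.
DEFAULT_ACR_CUTOFF = 30.0

REASON_BELOW_LOQ = "below_loq"
REASON_ABNORMAL_ACR = "abnormal_acr"

COHORT_COLUMNS = [
    "child_id",
    "age_y",
    "weight_kg",
    "height_cm",
    "ttma_mg_L",
    "below_loq",
    "creatinine_g_L",
    "acr_mg_g",
    "acr_normal",
]


@dataclass(frozen=True)
class ChildRecord:
    """One child's anthropometrics and urine biomarker measurements."""

    child_id: str
    age: float  # years
    weight: float  # kg
    height: float  # cm
    ttma: float  # mg/L urine; 0.0 allowed for censored records
    urinary_creatinine: float  # g/L
    albumin_creatinine_ratio: float  # mg/g
    acr_normal: bool = True
    below_loq: bool = False

    def __post_init__(self) -> None:
        for attr in ("age", "weight", "height", "urinary_creatinine"):
            if not getattr(self, attr) > 0:
                raise ConfigError(
                    f"child {self.child_id}: {attr} must be > 0, got {getattr(self, attr)!r}"
                )
        if self.ttma < 0:
            raise ConfigError(f"child {self.child_id}: ttma must be >= 0")


@dataclass(frozen=True)
class ExclusionReport:
    """Outcome of the cohort exclusion rules; the partition is exhaustive."""

    n_input: int
    n_below_loq: int
    n_abnormal_acr: int
    n_retained: int
    retained: tuple[ChildRecord, ...]
    excluded: tuple[tuple[ChildRecord, str], ...]


@dataclass(frozen=True)
class CohortEstimate:
    """Cohort-level summary: tt-MA moments and per-child inverted air levels."""

    n: int
    ttma_mean: float  # mg/L
    ttma_sd: float  # mg/L, n-1 denominator (0.0 for a single child)
    air_conc_per_child: tuple[float, ...]  # mg/m^3
    air_conc_mean: float  # mg/m^3
    air_conc_sd: float  # mg/m^3


def filter_cohort(
    records: Sequence[ChildRecord],
    loq: float = DEFAULT_LOQ,
    require_normal_acr: bool = True,
) -> ExclusionReport:
    """Apply the exclusion rules, below-LOQ first, then abnormal ACR.

    A record failing both rules counts as below-LOQ (the censoring rule is
    applied first, so the counts partition the input exactly). Duplicate
    child ids are rejected.
    """
    if not loq > 0:
        raise DomainError(f"loq must be > 0, got {loq!r}")
    seen: set[str] = set()
    for rec in records:
        if rec.child_id in seen:
            raise CohortSchemaError(f"duplicate child_id {rec.child_id!r}")
        seen.add(rec.child_id)

    retained: list[ChildRecord] = []
    excluded: list[tuple[ChildRecord, str]] = []
    for rec in records:
        if rec.below_loq or rec.ttma < loq:
            excluded.append((rec, REASON_BELOW_LOQ))
        elif require_normal_acr and not rec.acr_normal:
            excluded.append((rec, REASON_ABNORMAL_ACR))
        else:
            retained.append(rec)
    n_below = sum(1 for _, r in excluded if r == REASON_BELOW_LOQ)
    n_acr = sum(1 for _, r in excluded if r == REASON_ABNORMAL_ACR)
    return ExclusionReport(
        n_input=len(records),
        n_below_loq=n_below,
        n_abnormal_acr=n_acr,
        n_retained=len(retained),
        retained=tuple(retained),
        excluded=tuple(excluded),
    )


def invert_air_concentration(
    ttma_obs: float,
    params: PBPKParameters,
    phys: Physiology,
    arterial_mode: str = "equilibrium",
    rtol: float = 1e-9,
    max_doublings: int = 200,
) -> float:
    """Air benzene concentration (mg/m^3) whose forward image is ``ttma_obs``.

    The forward map is strictly increasing below its metabolic ceiling, so a
    unique root exists for any observation below
    :func:`~benzrisk.pbpk_core.ttma_saturation_bound`. The upper bracket is
    doubled until it straddles the observation, then scipy's ``brentq``
    polishes to relative tolerance ``rtol``.
    """
    if ttma_obs < 0:
        raise DomainError(f"ttma_obs must be >= 0, got {ttma_obs!r}")
    if ttma_obs == 0.0:
        return 0.0
    bound = ttma_saturation_bound(params, phys)
    if ttma_obs >= bound:
        raise SaturationError(
            f"tt-MA {ttma_obs} mg/L is at or above the metabolic ceiling "
            f"{bound:.6g} mg/L; no finite air concentration reproduces it"
        )

    def f(c: float) -> float:
        return ttma_urine_forward(c, params, phys, arterial_mode=arterial_mode).ttma_conc - ttma_obs

    upper = 1.0
    for _ in range(max_doublings):
        if f(upper) > 0.0:
            break
        upper *= 2.0
    else:
        raise RuntimeError("failed to bracket the inversion root")
    return brentq(f, 0.0, upper, rtol=max(rtol, 8.9e-16), maxiter=200)


def physiology_for_child(record: ChildRecord, base: Physiology) -> Physiology:
    """A per-child physiology: the base template with the child's age, weight
    and urinary creatinine substituted in."""
    return dataclasses.replace(
        base,
        age=record.age,
        body_weight=record.weight,
        urinary_creatinine=record.urinary_creatinine,
    )


def cohort_estimate(
    report: ExclusionReport,
    params: PBPKParameters,
    base_physiology: Physiology,
    phys_per_child: Callable[[ChildRecord], Physiology] | None = None,
    arterial_mode: str = "equilibrium",
    mode: str = "per_child",
) -> CohortEstimate:
    """Summarize the retained cohort and estimate air benzene exposure.

    tt-MA mean and SD use the n-1 denominator. In the default ``per_child``
    mode each child's tt-MA is inverted with that child's physiology and the
    air concentrations are then averaged; ``pooled`` instead inverts the
    cohort-mean tt-MA once with the base physiology (every per-child entry
    then equals that pooled value).
    """
    if report.n_retained < 1:
        raise EmptyCohortError("no children retained after exclusions")
    if phys_per_child is None:
        phys_per_child = lambda rec: physiology_for_child(rec, base_physiology)  # noqa: E731

    ttma = np.array([rec.ttma for rec in report.retained], dtype=float)
    ttma_mean = float(ttma.mean())
    ttma_sd = float(ttma.std(ddof=1)) if ttma.size > 1 else 0.0

    if mode == "per_child":
        air = [
            invert_air_concentration(
                rec.ttma, params, phys_per_child(rec), arterial_mode=arterial_mode
            )
            for rec in report.retained
        ]
    elif mode == "pooled":
        pooled = invert_air_concentration(
            ttma_mean, params, base_physiology, arterial_mode=arterial_mode
        )
        air = [pooled] * report.n_retained
    else:
        raise ConfigError(f"unknown estimation mode {mode!r}")

    air_arr = np.array(air, dtype=float)
    return CohortEstimate(
        n=report.n_retained,
        ttma_mean=ttma_mean,
        ttma_sd=ttma_sd,
        air_conc_per_child=tuple(float(a) for a in air_arr),
        air_conc_mean=float(air_arr.mean()),
        air_conc_sd=float(air_arr.std(ddof=1)) if air_arr.size > 1 else 0.0,
    )


def records_to_frame(records: Iterable[ChildRecord]) -> pd.DataFrame:
    rows = [
        {
            "child_id": r.child_id,
            "age_y": r.age,
            "weight_kg": r.weight,
            "height_cm": r.height,
            "ttma_mg_L": r.ttma,
            "below_loq": r.below_loq,
            "creatinine_g_L": r.urinary_creatinine,
            "acr_mg_g": r.albumin_creatinine_ratio,
            "acr_normal": r.acr_normal,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def write_cohort_csv(records: Iterable[ChildRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def _parse_bool(value: object, line: int, column: str) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    text = str(value).strip().lower()
    if text in {"true", "1", "yes"}:
        return True
    if text in {"false", "0", "no"}:
        return False
    raise CohortSchemaError(f"row {line}: column {column!r} is not a boolean: {value!r}")


def read_cohort_csv(path: str | Path) -> list[ChildRecord]:
    """Parse a cohort CSV against the documented schema, with row-numbered errors."""
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise CohortSchemaError(f"{path}: missing columns {missing}")
    records: list[ChildRecord] = []
    for idx, row in df.iterrows():
        line = int(idx) + 2  # header is line 1
        below = _parse_bool(row["below_loq"], line, "below_loq")
        ttma = row["ttma_mg_L"]
        if pd.isna(ttma):
            if not below:
                raise CohortSchemaError(
                    f"row {line}: ttma_mg_L missing but below_loq is false"
                )
            ttma = 0.0
        try:
            records.append(
                ChildRecord(
                    child_id=str(row["child_id"]),
                    age=float(row["age_y"]),
                    weight=float(row["weight_kg"]),
                    height=float(row["height_cm"]),
                    ttma=float(ttma),
                    urinary_creatinine=float(row["creatinine_g_L"]),
                    albumin_creatinine_ratio=float(row["acr_mg_g"]),
                    acr_normal=_parse_bool(row["acr_normal"], line, "acr_normal"),
                    below_loq=below,
                )
            )
        except (ConfigError, ValueError) as exc:
            raise CohortSchemaError(f"row {line}: {exc}") from exc
    if not math.isfinite(sum(r.ttma for r in records)):
        raise CohortSchemaError(f"{path}: non-finite tt-MA values")
    return records
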