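"""Seeded synthetic cohorts with the structure of the motivating biomonitoring sample.

The study sample this emulates: 41 children aged 6-12 from shoemaking
households, of whom 23 had urinary tt-MA below the assay limit of
quantification, 3 had an abnormal albumin/creatinine ratio, and the 15
retained children had tt-MA with sample mean 0.81 mg/L and SD 0.83 mg/L.
Two generators are provided: a stochastic one (:func:`generate_cohort`)
whose retained-subset tt-MA follows a moment-matched lognormal, and a frozen
41-record fixture (:func:`fixture_cohort_41`) that reproduces the published
counts and retained-subset moments exactly at printed precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .errors import ConfigError, DomainError
from .pbpk_core import PBPKParameters, Physiology, ttma_urine_forward
from .reverse_translation import DEFAULT_LOQ, ChildRecord

#: Linear growth references for 6-12-year-olds: value at age 6 plus a
#: per-year slope. Crude, but monotone in age, which is all the pipeline uses.
WEIGHT_AT_6_KG = 21.0
WEIGHT_SLOPE_KG_PER_Y = 3.2
HEIGHT_AT_6_CM = 116.0
HEIGHT_SLOPE_CM_PER_Y = 5.7

#: Frozen retained-subset tt-MA values (mg/L) for the 41-record fixture.
#: Constructed once from moment-matched lognormal quantiles with a power
#: adjustment so the 15 values have sample mean 0.81 and sample SD 0.83
#: (n-1 denominator) at two decimals, all above the 0.06 mg/L LOQ.
_FIXTURE_RETAINED_TTMA = (
    0.086, 0.149, 0.203, 0.257, 0.315, 0.377, 0.447, 0.528,
    0.623, 0.738, 0.885, 1.082, 1.370, 1.868, 3.221,
)


@dataclass(frozen=True)
class CohortGenConfig:
    """Targets and composition for the stochastic cohort generator.

    Fractions mirror the study sample (23/41 censored; 3 of the 18
    quantifiable records with abnormal ACR); tt-MA moment targets are the
    published retained-subset mean and SD.
    """

    n_children: int = 41
    frac_below_loq: float = 23 / 41
    frac_abnormal_acr: float = 3 / 18
    loq: float = DEFAULT_LOQ
    ttma_mean_target: float = 0.81
    ttma_sd_target: float = 0.83
    age_min: float = 6.0
    age_max: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_children < 0:
            raise ConfigError("n_children must be >= 0")
        for frac in (self.frac_below_loq, self.frac_abnormal_acr):
            if not 0 <= frac <= 1:
                raise ConfigError(f"fractions must be in [0, 1], got {frac!r}")
        if not (self.loq > 0 and self.ttma_mean_target > 0 and self.ttma_sd_target > 0):
            raise ConfigError("loq and moment targets must be > 0")
        if not self.age_min < self.age_max:
            raise ConfigError("need age_min < age_max")


def lognormal_moment_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of the lognormal with the given arithmetic mean and SD:
    mu = ln(m^2 / sqrt(m^2 + s^2)), sigma^2 = ln(1 + s^2/m^2)."""
    if mean <= 0 or sd <= 0:
        raise ConfigError(f"moment targets must be > 0, got mean={mean!r}, sd={sd!r}")
    mu = math.log(mean**2 / math.sqrt(mean**2 + sd**2))
    sigma = math.sqrt(math.log(1.0 + sd**2 / mean**2))
    return mu, sigma


def growth_reference(age: float) -> tuple[float, float]:
    """(weight kg, height cm) from the linear age-indexed reference."""
    return (
        WEIGHT_AT_6_KG + WEIGHT_SLOPE_KG_PER_Y * (age - 6.0),
        HEIGHT_AT_6_CM + HEIGHT_SLOPE_CM_PER_Y * (age - 6.0),
    )


def generate_cohort(cfg: CohortGenConfig = CohortGenConfig()) -> list[ChildRecord]:
    """Draw a synthetic cohort; deterministic given ``cfg.seed``.

    Each child is censored below the LOQ with probability ``frac_below_loq``
    (tt-MA then uniform on (0, LOQ)); quantifiable children carry an
    abnormal-ACR flag with probability ``frac_abnormal_acr`` and draw tt-MA
    from the moment-matched lognormal (abnormal-ACR children from the same
    distribution — no difference is modelled). Ages are uniform on the age
    range; weight and height follow the linear growth reference.
    """
    rng = np.random.default_rng(cfg.seed)
    mu, sigma = lognormal_moment_params(cfg.ttma_mean_target, cfg.ttma_sd_target)
    records: list[ChildRecord] = []
    for i in range(cfg.n_children):
        age = float(rng.uniform(cfg.age_min, cfg.age_max))
        weight, height = growth_reference(age)
        creatinine = float(rng.uniform(0.6, 1.4))
        below = bool(rng.random() < cfg.frac_below_loq)
        if below:
            ttma = float(rng.uniform(0.0, cfg.loq))
            acr_normal = True
            acr = float(rng.uniform(5.0, 25.0))
        else:
            ttma = float(rng.lognormal(mu, sigma))
            # resample the rare draw that lands under the LOQ so flags stay
            # consistent with values
            while ttma < cfg.loq:
                ttma = float(rng.lognormal(mu, sigma))
            acr_normal = not bool(rng.random() < cfg.frac_abnormal_acr)
            acr = float(rng.uniform(5.0, 25.0) if acr_normal else rng.uniform(35.0, 100.0))
        records.append(
            ChildRecord(
                child_id=f"S{i + 1:02d}",
                age=age,
                weight=weight,
                height=height,
                ttma=ttma,
                urinary_creatinine=creatinine,
                albumin_creatinine_ratio=acr,
                acr_normal=acr_normal,
                below_loq=below,
            )
        )
    return records


def _fixture_child(
    i: int, ttma: float, below_loq: bool, acr_normal: bool
) -> ChildRecord:
    age = 6.0 + (i % 7)  # cycles 6..12
    weight, height = growth_reference(age)
    acr = 12.0 + (i % 5) * 3.0 if acr_normal else 45.0 + (i % 3) * 15.0
    return ChildRecord(
        child_id=f"C{i + 1:02d}",
        age=age,
        weight=weight,
        height=height,
        ttma=ttma,
        urinary_creatinine=round(0.7 + 0.02 * (i % 20), 2),
        albumin_creatinine_ratio=acr,
        acr_normal=acr_normal,
        below_loq=below_loq,
    )


def build_fixture_records() -> list[ChildRecord]:
    """Construct the frozen 41-record fixture in code (no randomness).

    23 records censored below the 0.06 mg/L LOQ, 3 quantifiable records with
    abnormal ACR, and 15 retained records carrying the frozen tt-MA values.
    """
    records: list[ChildRecord] = []
    i = 0
    for k in range(23):
        ttma = round(DEFAULT_LOQ * (k + 0.5) / 23.0, 4)
        records.append(_fixture_child(i, ttma, below_loq=True, acr_normal=True))
        i += 1
    for ttma in (0.42, 0.95, 1.6):  # quantifiable but renally excluded
        records.append(_fixture_child(i, ttma, below_loq=False, acr_normal=False))
        i += 1
    for ttma in _FIXTURE_RETAINED_TTMA:
        records.append(_fixture_child(i, ttma, below_loq=False, acr_normal=True))
        i += 1
    return records


def fixture_cohort_41() -> list[ChildRecord]:
    """The versioned 41-record fixture, loaded from the packaged CSV."""
    from .reverse_translation import read_cohort_csv

    ref = resources.files("benzrisk").joinpath("data/fixture_cohort_41.csv")
    with resources.as_file(ref) as path:
        return read_cohort_csv(path)


def write_fixture_csv(path: str | Path) -> None:
    """Write the frozen fixture to ``path`` in the cohort CSV schema."""
    from .reverse_translation import write_cohort_csv

    write_cohort_csv(build_fixture_records(), path)


def simulate_biomonitoring(
    true_air_conc: float,
    n: int,
    noise_gsd: float,
    seed: int,
    params: PBPKParameters | None = None,
    phys: Physiology | None = None,
    loq: float = DEFAULT_LOQ,
) -> list[ChildRecord]:
    """Forward-simulate urinary tt-MA for ``n`` children at a known air level.

    Each child's tt-MA is the noiseless forward value multiplied by
    median-one lognormal noise with geometric standard deviation
    ``noise_gsd`` (GSD 1 means no noise). Used for parameter-recovery checks:
    invert each record and compare the recovered median with the truth.
    """
    if true_air_conc < 0:
        raise DomainError(f"true_air_conc must be >= 0, got {true_air_conc!r}")
    if noise_gsd < 1:
        raise DomainError(f"noise_gsd must be >= 1, got {noise_gsd!r}")
    if params is None or phys is None:
        from .config import default_parameters

        d_params, d_phys = default_parameters()
        params = params or d_params
        phys = phys or d_phys
    rng = np.random.default_rng(seed)
    base = ttma_urine_forward(true_air_conc, params, phys).ttma_conc
    records: list[ChildRecord] = []
    for i in range(n):
        noise = 1.0 if noise_gsd == 1.0 else float(rng.lognormal(0.0, math.log(noise_gsd)))
        ttma = base * noise
        records.append(
            ChildRecord(
                child_id=f"M{i + 1:03d}",
                age=phys.age,
                weight=phys.body_weight,
                height=growth_reference(phys.age)[1],
                ttma=ttma,
                urinary_creatinine=phys.urinary_creatinine,
                albumin_creatinine_ratio=10.0,
                acr_normal=True,
                below_loq=ttma < loq,
            )
        )
    return records
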