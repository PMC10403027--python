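"""Synthetic decedent cohorts, care-state sequences and costed claims.

The generator emulates a national claims extract for a decedent cohort:

* **Cohort** — patient demographics, diagnosis flags, Charlson scores,
  deprivation quintiles and palliative-care flags drawn to match the
  published 2015 French decedent-population marginals (50.6% female, mean
  age at death 78.5 +/- 14.9 years, 19% dementia, 27% hospital palliative
  care use, 5% of patients with no medical spending, ...).
* **Pathways** — each patient's 365-day care-state sequence is a noisy
  realization of one of three pathway archetypes: (1) home for most of the
  year with a single short acute stay near death; (2) home until roughly
  the last 3 months, then alternating acute and rehabilitation care; (3)
  early and repeated admissions mixing acute care, rehabilitation and
  hospital-at-home across the whole year.  The archetype drawn for each
  patient is returned as a ground-truth label for validation only; the
  analysis stages never read it.
* **Claims** — hospital-state days generate per-diem claims in the
  matching hospital service category; ambulatory services are drawn as
  time-inhomogeneous Poisson event streams whose rates increase in the
  last 90 days of life, with zero-inflated lognormal event costs.

Noise model: each day's state is independently resampled to one of the
other four states with probability ``per_day_noise``; the final day is
never resampled, since it encodes the (recorded) place of death.

All generation is deterministic given the config seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .costing import CATEGORY_CODES, ServiceCategory
from .states import (
    SEQUENCE_LENGTH,
    CareState,
    SequenceSet,
)

#: Diagnosis categories carried as cohort flags (columns ``dx_<label>``).
DIAGNOSIS_LABELS = (
    "dementia",
    "cold",
    "breast_cancer",
    "lung_cancer",
    "prostate_cancer",
    "acute_stroke",
    "acute_coronary_syndrome",
    "parkinson",
    "esrd_dialysis",
)

#: Published decedent-population diagnosis prevalences used as defaults.
DEFAULT_PREVALENCES = {
    "dementia": 0.190,
    "cold": 0.173,
    "breast_cancer": 0.023,
    "lung_cancer": 0.050,
    "prostate_cancer": 0.023,
    "acute_stroke": 0.043,
    "acute_coronary_syndrome": 0.014,
    "parkinson": 0.035,
    "esrd_dialysis": 0.012,
}

# Deprivation quintile shares conditional on non-missing (published shares
# 16.0/16.3/19.1/20.0/21.9 with 6.7% missing, renormalised).
_RAW_QUINTILES = np.array([0.160, 0.163, 0.191, 0.200, 0.219])
DEFAULT_QUINTILE_WEIGHTS = tuple(_RAW_QUINTILES / _RAW_QUINTILES.sum())


def _check_proportion(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {value}")


@dataclass
class CohortConfig:
    """Parameters of the synthetic decedent cohort."""

    n_patients: int = 1000
    female_fraction: float = 0.506
    age_mean: float = 78.5
    age_sd: float = 14.9
    diagnosis_prevalences: dict = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCES)
    )
    charlson_mean: float = 4.3
    charlson_sd: float = 3.7
    deprivation_quintile_weights: Sequence[float] = DEFAULT_QUINTILE_WEIGHTS
    deprivation_missing_fraction: float = 0.067
    palliative_fraction: float = 0.27
    zero_spend_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be non-negative")
        for name in ("female_fraction", "deprivation_missing_fraction",
                     "palliative_fraction", "zero_spend_fraction"):
            _check_proportion(name, getattr(self, name))
        for label, p in self.diagnosis_prevalences.items():
            _check_proportion(f"prevalence of {label}", p)
        w = np.asarray(self.deprivation_quintile_weights, dtype=float)
        if w.shape != (5,) or np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("deprivation quintile weights must be 5 "
                             "non-negative proportions summing to 1")
        if self.age_sd <= 0 or self.charlson_sd <= 0:
            raise ValueError("age_sd and charlson_sd must be positive")


#: Default archetype templates: (state, duration) runs summing to 365 days.
DEFAULT_TEMPLATES = (
    # 1 — few and late hospitalizations: home, one short acute stay near death
    (("HOME", 348), ("ACUTE", 12), ("HOME", 5)),
    # 2 — acute care in the last 3 months: home 275 days, then alternating
    #     acute / rehabilitation blocks filling the final 90 days
    (("HOME", 275), ("ACUTE", 30), ("REHAB", 25), ("ACUTE", 20),
     ("REHAB", 10), ("ACUTE", 5)),
    # 3 — early and repeated hospitalizations: recurring acute,
    #     rehabilitation and hospital-at-home spells across the year
    (("HOME", 30), ("ACUTE", 20), ("HOME", 40), ("REHAB", 30), ("HOME", 30),
     ("HAH", 45), ("HOME", 30), ("ACUTE", 25), ("REHAB", 35), ("HOME", 20),
     ("ACUTE", 30), ("HAH", 20), ("ACUTE", 10)),
)

#: Published cluster-size proportions (dementia typology) as default weights.
DEFAULT_MIXTURE_WEIGHTS = (0.67, 0.27, 0.06)

# Per-archetype probabilities of dying in hospital, calibrated so the
# mixture-weighted share under the default weights is 0.59 (the published
# share of in-hospital deaths).
DEFAULT_HOSPITAL_DEATH_PROBS = (0.507, 0.75, 0.80)


def expand_template(template) -> np.ndarray:
    """Expand a (state, duration) run list into a 365-day code array."""
    parts = [np.full(int(d), CareState[s].value, dtype=np.uint8)
             for s, d in template]
    out = np.concatenate(parts) if parts else np.empty(0, np.uint8)
    if out.size != SEQUENCE_LENGTH:
        raise ValueError(
            f"template durations must sum to {SEQUENCE_LENGTH}, got {out.size}"
        )
    return out


@dataclass
class ArchetypeConfig:
    """Pathway archetypes and the noise model around them."""

    templates: Sequence = DEFAULT_TEMPLATES
    mixture_weights: Sequence[float] = DEFAULT_MIXTURE_WEIGHTS
    per_day_noise: float = 0.05
    hospital_death_probs: Optional[Sequence[float]] = None
    terminal_days: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        self.expanded = np.vstack([expand_template(t) for t in self.templates])
        w = np.asarray(self.mixture_weights, dtype=float)
        if len(w) != len(self.templates):
            raise ValueError("one mixture weight per template is required")
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("mixture weights must be non-negative and sum to 1")
        _check_proportion("per_day_noise", self.per_day_noise)
        if self.hospital_death_probs is not None:
            p = np.asarray(self.hospital_death_probs, dtype=float)
            if len(p) != len(self.templates):
                raise ValueError("one hospital-death probability per template")
            for v in p:
                _check_proportion("hospital_death_probs", v)
        if not 1 <= self.terminal_days <= SEQUENCE_LENGTH:
            raise ValueError("terminal_days must lie in 1..365")

    @property
    def n_archetypes(self) -> int:
        return len(self.templates)


#: Default per-diem costs by hospital state, EUR/day (invented plumbing:
#: order-of-magnitude realistic for French hospital tariffs).
DEFAULT_PER_DIEM = {"ACUTE": 1300.0, "REHAB": 700.0, "HAH": 250.0, "PSY": 500.0}

#: Hospital state -> claim service category.  Psychiatric per-diems are
#: booked with the "other services" (physio_other) category, which pools
#: psychiatric, biology and related services in the published tables.
STATE_CATEGORY = {
    CareState.ACUTE: ServiceCategory.ACUTE_HOSPITAL.value,
    CareState.REHAB: ServiceCategory.REHABILITATION.value,
    CareState.HAH: ServiceCategory.HOSPITAL_AT_HOME.value,
    CareState.PSY: ServiceCategory.PHYSIO_OTHER.value,
}

#: Default ambulatory event streams: category -> (events per patient-year,
#: lognormal mu, lognormal sigma of the per-event cost in EUR).
DEFAULT_AMBULATORY = {
    "nursing_services": (60.0, 3.0, 0.6),
    "outpatient_visits": (12.0, 3.4, 0.3),
    "physio_other": (20.0, 3.2, 0.5),
    "equipment_devices": (6.0, 5.3, 0.8),
    "pharmacy": (24.0, 4.4, 0.9),
    "expensive_hospital_drugs": (0.5, 7.6, 0.7),
    "transportation": (8.0, 4.8, 0.6),
    "procedures_imaging": (10.0, 4.7, 0.7),
}


@dataclass
class CostConfig:
    """Claim-generation parameters (per-diems, event rates, cost laws)."""

    per_diem: dict = field(default_factory=lambda: dict(DEFAULT_PER_DIEM))
    ambulatory: dict = field(default_factory=lambda: dict(DEFAULT_AMBULATORY))
    last90_multiplier: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        for state, cost in self.per_diem.items():
            CareState[state]
            if cost < 0:
                raise ValueError(f"per-diem cost for {state} must be >= 0")
        for cat, (rate, _, sigma) in self.ambulatory.items():
            if cat not in CATEGORY_CODES:
                raise ValueError(f"unknown ambulatory category {cat!r}")
            if rate < 0 or sigma < 0:
                raise ValueError(f"rate and sigma for {cat} must be >= 0")
        if self.last90_multiplier < 1:
            raise ValueError("last90_multiplier must be >= 1")


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Draw a synthetic decedent cohort.

    Returns a DataFrame with one row per patient: patient_id, sex,
    age_at_death (truncated normal on [1, 110]), dx_* diagnosis flags,
    charlson_score (discretised truncated normal), deprivation_quintile
    (1..5, NA for missing), palliative_flag and the generator-only
    zero_spend_flag.  Breast and prostate cancer are drawn sex-specifically
    so their population prevalences match the configured values.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    ids = [f"P{i:07d}" for i in range(n)]
    female = rng.random(n) < config.female_fraction
    sex = np.where(female, "female", "male")

    a = (1.0 - config.age_mean) / config.age_sd
    b = (110.0 - config.age_mean) / config.age_sd
    age = stats.truncnorm.rvs(a, b, loc=config.age_mean, scale=config.age_sd,
                              size=n, random_state=rng)

    c_a = (0.0 - config.charlson_mean) / config.charlson_sd
    charlson = np.rint(
        stats.truncnorm.rvs(c_a, np.inf, loc=config.charlson_mean,
                            scale=config.charlson_sd, size=n, random_state=rng)
    ).astype(int)

    cohort = pd.DataFrame({"patient_id": ids, "sex": sex, "age_at_death": age,
                           "charlson_score": charlson})

    f = config.female_fraction
    for label in DIAGNOSIS_LABELS:
        p = config.diagnosis_prevalences.get(label, 0.0)
        u = rng.random(n)
        if label == "breast_cancer":
            cond = min(p / f, 1.0) if f > 0 else 0.0
            flag = female & (u < cond)
        elif label == "prostate_cancer":
            cond = min(p / (1 - f), 1.0) if f < 1 else 0.0
            flag = ~female & (u < cond)
        else:
            flag = u < p
        cohort[f"dx_{label}"] = flag

    miss = rng.random(n) < config.deprivation_missing_fraction
    quint = rng.choice(np.arange(1, 6), size=n,
                       p=np.asarray(config.deprivation_quintile_weights))
    cohort["deprivation_quintile"] = pd.array(quint, dtype="Int64")
    cohort.loc[miss, "deprivation_quintile"] = pd.NA

    cohort["palliative_flag"] = rng.random(n) < config.palliative_fraction
    cohort["zero_spend_flag"] = rng.random(n) < config.zero_spend_fraction
    return cohort


def generate_pathways(
    cohort: pd.DataFrame, config: ArchetypeConfig
) -> tuple[SequenceSet, np.ndarray]:
    """Draw each patient's daily state sequence as a noisy archetype copy.

    Returns the sequences and the ground-truth archetype labels (1..K).
    The labels exist only to validate clustering recovery; analysis stages
    must not read them.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    rng = np.random.default_rng(config.seed)
    n = len(cohort)
    K = config.n_archetypes
    labels = rng.choice(K, size=n, p=np.asarray(config.mixture_weights)) + 1
    data = config.expanded[labels - 1].copy()

    if config.hospital_death_probs is not None:
        p = np.asarray(config.hospital_death_probs, dtype=float)
        hosp_death = rng.random(n) < p[labels - 1]
        t = config.terminal_days
        last = data[:, -1]
        home = CareState.HOME.value
        to_hosp = hosp_death & (last == home)
        to_home = ~hosp_death & (last != home)
        data[to_hosp, -t:] = CareState.ACUTE.value
        data[to_home, -t:] = home

    if config.per_day_noise > 0:
        mask = rng.random((n, SEQUENCE_LENGTH)) < config.per_day_noise
        mask[:, -1] = False  # the final day records the place of death
        shift = rng.integers(1, 5, size=(n, SEQUENCE_LENGTH), dtype=np.uint8)
        data = np.where(mask, (data + shift) % 5, data).astype(np.uint8)

    return SequenceSet(list(cohort["patient_id"]), data), labels


def generate_claims(
    cohort: pd.DataFrame, sequences: SequenceSet, config: CostConfig
) -> pd.DataFrame:
    """Draw costed service claims consistent with the state sequences.

    Every hospital-state day of a non-zero-spend patient yields a per-diem
    claim in the matching hospital category.  Ambulatory claims are drawn
    per category as Poisson event counts with the last-90-day rate
    multiplier, with lognormal per-event costs.  Patients flagged zero-
    spend receive no claims at all.
    """
    if list(cohort["patient_id"]) != list(sequences.ids):
        raise ValueError("sequences are not aligned to the cohort")
    rng = np.random.default_rng(config.seed)
    n = len(cohort)
    ids = np.asarray(cohort["patient_id"])
    spender = ~cohort["zero_spend_flag"].to_numpy(dtype=bool)

    frames = []
    # hospital per-diem claims
    for state, category in STATE_CATEGORY.items():
        cost = config.per_diem.get(state.name, 0.0)
        rows, cols = np.nonzero((sequences.data == state.value) & spender[:, None])
        if rows.size == 0:
            continue
        frames.append(pd.DataFrame({
            "patient_id": ids[rows],
            "days_before_death": (SEQUENCE_LENGTH - 1 - cols).astype(int),
            "category": category,
            "cost": float(cost),
        }))

    # ambulatory event streams, inhomogeneous in time
    m = config.last90_multiplier
    for cat, (rate, mu, sigma) in config.ambulatory.items():
        lam_early = rate * (SEQUENCE_LENGTH - 90) / 365.0
        lam_late = rate * m * 90 / 365.0
        for lam, lo, hi in ((lam_early, 90, SEQUENCE_LENGTH - 1), (lam_late, 0, 89)):
            counts = rng.poisson(lam, size=n) * spender
            total = int(counts.sum())
            if total == 0:
                continue
            frames.append(pd.DataFrame({
                "patient_id": np.repeat(ids, counts),
                "days_before_death": rng.integers(lo, hi + 1, size=total),
                "category": cat,
                "cost": rng.lognormal(mu, sigma, size=total),
            }))

    if not frames:
        return pd.DataFrame(columns=["patient_id", "days_before_death",
                                     "category", "cost"])
    claims = pd.concat(frames, ignore_index=True)
    return claims.sort_values(
        ["patient_id", "days_before_death", "category"],
        ascending=[True, False, True], kind="stable",
    ).reset_index(drop=True)
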