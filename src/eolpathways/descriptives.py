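"""Cohort characterization and pathway-membership association.

Descriptive tables for a decedent cohort: sex, age bands at death,
deprivation quintiles, Charlson comorbidity classes and diagnosis
prevalences; place of death read off the final day of each care-state
sequence; hospital palliative-care uptake; and logistic-regression odds
ratios for membership in a designated pathway cluster.

Age bands follow the half-open convention [lower, upper), with open first
("<20") and last (">=90") bands.  The Charlson index is binned into the
classes 0, 1-2, 3-4, >=5, which partition the non-negative integers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .states import CareState, SequenceSet

#: Age-band lower edges; band i is [edge[i], edge[i+1]).
AGE_BAND_EDGES = [0, 20, 30, 40, 50, 60, 70, 80, 90, np.inf]
AGE_BAND_LABELS = ["<20", "20-29", "30-39", "40-49", "50-59",
                   "60-69", "70-79", "80-89", ">=90"]

CHARLSON_CLASSES = ["0", "1-2", "3-4", ">=5"]

#: Final-day state -> place-of-death label.
PLACE_OF_DEATH = {
    CareState.ACUTE: "hospital_acute",
    CareState.REHAB: "rehabilitation",
    CareState.HAH: "hospital_at_home",
    CareState.PSY: "psychiatry",
    CareState.HOME: "home",
}


def charlson_class(score: int) -> str:
    """Charlson comorbidity class containing an integer score."""
    if score < 0 or int(score) != score:
        raise ValueError("Charlson score must be a non-negative integer")
    if score == 0:
        return "0"
    if score <= 2:
        return "1-2"
    if score <= 4:
        return "3-4"
    return ">=5"


def age_band(age: float) -> str:
    """Age band at death for a given age in years."""
    idx = int(np.searchsorted(AGE_BAND_EDGES, age, side="right")) - 1
    return AGE_BAND_LABELS[min(idx, len(AGE_BAND_LABELS) - 1)]


def characteristics_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Cohort characteristics: counts and percentages per category.

    Long format with columns (section, level, count, pct, mean, sd); the
    mean/sd columns are populated only for the continuous summaries (age,
    Charlson score).  Exclusive sections (sex, age bands, deprivation,
    Charlson classes) each sum to the cohort size; diagnosis flags are
    non-exclusive prevalences.
    """
    n = len(cohort)
    if n == 0:
        raise ValueError("cohort is empty")
    rows: list[dict] = []

    def add(section, level, count):
        rows.append({"section": section, "level": level, "count": int(count),
                     "pct": 100.0 * count / n, "mean": np.nan, "sd": np.nan})

    for sex in ("male", "female"):
        add("sex", sex, (cohort["sex"] == sex).sum())

    age = cohort["age_at_death"].to_numpy(dtype=float)
    rows.append({"section": "age", "level": "mean_sd", "count": n,
                 "pct": np.nan, "mean": age.mean(),
                 "sd": np.std(age, ddof=1) if n > 1 else 0.0})
    bands = pd.Categorical(
        [age_band(a) for a in age], categories=AGE_BAND_LABELS
    )
    for label, count in pd.Series(bands).value_counts(sort=False).items():
        add("age_band", label, count)

    if "deprivation_quintile" in cohort.columns:
        q = cohort["deprivation_quintile"]
        for quint in range(1, 6):
            add("deprivation", f"Q{quint}", (q == quint).sum())
        add("deprivation", "missing", q.isna().sum())

    charlson = cohort["charlson_score"].to_numpy(dtype=float)
    rows.append({"section": "charlson", "level": "mean_sd", "count": n,
                 "pct": np.nan, "mean": charlson.mean(),
                 "sd": np.std(charlson, ddof=1) if n > 1 else 0.0})
    classes = pd.Categorical(
        [charlson_class(int(s)) for s in charlson], categories=CHARLSON_CLASSES
    )
    for label, count in pd.Series(classes).value_counts(sort=False).items():
        add("charlson_class", label, count)

    for col in sorted(c for c in cohort.columns if c.startswith("dx_")):
        add("diagnosis", col[3:], cohort[col].astype(bool).sum())

    if "palliative_flag" in cohort.columns:
        add("palliative_care", "used", cohort["palliative_flag"].astype(bool).sum())

    return pd.DataFrame(rows)


def place_of_death_summary(sequences: SequenceSet) -> pd.Series:
    """Distribution of place of death, read from each final-day state."""
    last = sequences.data[:, -1]
    out = {}
    for state, label in PLACE_OF_DEATH.items():
        out[label] = float((last == state.value).mean()) if len(sequences) else 0.0
    return pd.Series(out)


def palliative_summary(cohort: pd.DataFrame) -> pd.DataFrame:
    """Hospital palliative-care uptake, overall and by sex and age band.

    Returns rows (group, level, n, users, proportion).
    """
    flag = cohort["palliative_flag"].astype(bool)
    rows = [{"group": "overall", "level": "all", "n": len(cohort),
             "users": int(flag.sum()),
             "proportion": float(flag.mean()) if len(cohort) else 0.0}]
    for sex in ("male", "female"):
        m = cohort["sex"] == sex
        rows.append({"group": "sex", "level": sex, "n": int(m.sum()),
                     "users": int(flag[m].sum()),
                     "proportion": float(flag[m].mean()) if m.any() else 0.0})
    bands = pd.Series([age_band(a) for a in cohort["age_at_death"]],
                      index=cohort.index)
    for label in AGE_BAND_LABELS:
        m = bands == label
        rows.append({"group": "age_band", "level": label, "n": int(m.sum()),
                     "users": int(flag[m].sum()),
                     "proportion": float(flag[m].mean()) if m.any() else 0.0})
    return pd.DataFrame(rows)


def pathway_association(
    features: pd.DataFrame,
    labels: pd.Series,
    reference_cluster: int,
) -> pd.DataFrame:
    """Odds ratios for membership in one pathway cluster versus the rest.

    Fits a maximum-likelihood logistic regression of the binary outcome
    "patient belongs to ``reference_cluster``" on the given features and
    returns exponentiated coefficients with Wald 95% confidence intervals.

    Parameters
    ----------
    features : DataFrame of numeric patient covariates (age, sex indicator,
        Charlson score, diagnosis flags, ...), indexed by patient id.
    labels : Series mapping patient id -> cluster id.
    reference_cluster : the cluster whose membership is modelled.

    Returns
    -------
    DataFrame indexed by feature with columns odds_ratio, ci_low, ci_high,
    coef, se, n, converged.

    Raises
    ------
    ValueError
        If the outcome has no variation or the fit shows (quasi-)perfect
        separation.
    """
    labels = pd.Series(labels)
    y = (labels.loc[features.index] == reference_cluster).astype(float)
    if y.nunique() < 2:
        raise ValueError("outcome has no variation: cannot fit association model")
    X = features.astype(float)
    X = sm.add_constant(X, has_constant="add")
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except Exception as exc:  # perfect separation raises inside statsmodels
        raise ValueError(f"logistic fit failed (possible separation): {exc}") from exc
    converged = bool(fit.mle_retvals.get("converged", False))
    params = fit.params
    if not np.all(np.isfinite(fit.bse)) or np.any(np.abs(params.drop("const")) > 30):
        raise ValueError("logistic fit indicates perfect separation")
    ci = fit.conf_int(alpha=0.05)
    out = pd.DataFrame(
        {
            "odds_ratio": np.exp(params),
            "ci_low": np.exp(ci[0]),
            "ci_high": np.exp(ci[1]),
            "coef": params,
            "se": fit.bse,
            "n": len(y),
            "converged": converged,
        }
    )
    return out.drop(index="const")
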