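"""Cohort data model, I/O, score standardisation and exposure classification.

The in-memory representation of a cohort is a long-format
:class:`pandas.DataFrame` with one row per participant-wave and a fixed
column contract (:data:`COHORT_COLUMNS`).  Waves are biennial interviews;
cognition is measured by an episodic-memory recall sum (0-20 words) and a
one-minute animal-naming fluency count.  A participant's analytic baseline
is the first wave with complete cognitive and covariate data, and exposure
(continuing education, "CE") is classified from the per-wave CE reports
observed after that baseline.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import CohortFormatError, CohortIntegrityError, DegenerateInputError

#: Columns every cohort CSV must carry, in canonical order.
COHORT_COLUMNS = [
    "participant_id",
    "wave",
    "age",
    "memory_raw",
    "fluency_raw",
    "ce_report",
    "sex",
    "education_level",
    "labour_force",
    "wealth_z",
    "smoker",
    "alcohol",
    "mvpa_weekly",
    "hearing",
    "cesd",
    "hypertension",
    "heart_disease",
    "stroke",
    "cancer",
    "diabetes",
    "psychiatric",
]

SCORE_COLUMNS = ["memory_raw", "fluency_raw"]
Z_COLUMNS = {"memory_raw": "memory_z", "fluency_raw": "fluency_z"}

#: Covariates fixed at baseline vs. allowed to vary over follow-up.
BASELINE_FIXED_COVARIATES = ["sex", "education_level"]
TIME_UPDATING_COVARIATES = [
    "labour_force",
    "wealth_z",
    "smoker",
    "alcohol",
    "mvpa_weekly",
    "hearing",
    "cesd",
    "hypertension",
    "heart_disease",
    "stroke",
    "cancer",
    "diabetes",
    "psychiatric",
]
COVARIATES = BASELINE_FIXED_COVARIATES + TIME_UPDATING_COVARIATES

CONDITION_FLAGS = [
    "hypertension",
    "heart_disease",
    "stroke",
    "cancer",
    "diabetes",
    "psychiatric",
]
BINARY_COVARIATES = ["smoker", "alcohol", "mvpa_weekly"] + CONDITION_FLAGS

SEX_LEVELS = ["male", "female"]
EDUCATION_LEVELS = ["below_hs", "hs", "above_hs"]
LABOUR_FORCE_LEVELS = ["employed", "unemployed_disabled", "retired", "homemaker_other"]
HEARING_LEVELS = ["excellent", "very_good", "good", "fair", "poor"]

_CATEGORICAL_LEVELS = {
    "sex": SEX_LEVELS,
    "education_level": EDUCATION_LEVELS,
    "labour_force": LABOUR_FORCE_LEVELS,
    "hearing": HEARING_LEVELS,
}

_NUMERIC_COLUMNS = ["age", "memory_raw", "fluency_raw", "wealth_z", "cesd"] + BINARY_COVARIATES

_TRUE_TOKENS = {"true", "1", "yes", "t", "y", "1.0"}
_FALSE_TOKENS = {"false", "0", "no", "f", "n", "0.0", ""}


def _parse_bool(series: pd.Series) -> pd.Series:
    s = series.astype(str).str.strip().str.lower()
    out = pd.Series(np.nan, index=series.index, dtype=float)
    out[s.isin(_TRUE_TOKENS)] = 1.0
    out[s.isin(_FALSE_TOKENS)] = 0.0
    return out


def read_cohort(path) -> pd.DataFrame:
    """Read a long-format cohort CSV into a typed DataFrame.

    Parameters
    ----------
    path : str or path-like
        CSV with one row per participant-wave and the columns listed in
        :data:`COHORT_COLUMNS`.  Missing values are empty cells.

    Returns
    -------
    pandas.DataFrame
        Typed records sorted by (participant_id, wave).  Rows whose
        identifier, wave or age could not be parsed are dropped; their
        0-based CSV row indices and offending fields are recorded in
        ``df.attrs["rejected_rows"]``.

    Raises
    ------
    CohortFormatError
        If a mandatory column is missing.
    CohortIntegrityError
        If a (participant, wave) pair is duplicated or age decreases
        within a participant.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in COHORT_COLUMNS if c not in raw.columns]
    if missing:
        raise CohortFormatError(f"cohort file {path} is missing mandatory column(s): {missing}")

    df = pd.DataFrame(index=raw.index)
    df["participant_id"] = raw["participant_id"].str.strip()
    df["wave"] = pd.to_numeric(raw["wave"].replace("", np.nan), errors="coerce")
    for col in _NUMERIC_COLUMNS:
        df[col] = pd.to_numeric(raw[col].replace("", np.nan), errors="coerce")
    df["ce_report"] = _parse_bool(raw["ce_report"]).fillna(0.0).astype(bool)
    for col, levels in _CATEGORICAL_LEVELS.items():
        vals = raw[col].str.strip()
        df[col] = vals.where(vals.isin(levels), np.nan)

    rejected = []
    bad_id = df["participant_id"] == ""
    bad_wave = df["wave"].isna() | (df["wave"] % 1 != 0) | (df["wave"] < 1)
    bad_age = df["age"].isna()
    for idx in df.index[bad_id | bad_wave | bad_age]:
        fields = [
            name
            for name, mask in (("participant_id", bad_id), ("wave", bad_wave), ("age", bad_age))
            if mask[idx]
        ]
        rejected.append({"row": int(idx), "fields": fields})
    df = df[~(bad_id | bad_wave | bad_age)].copy()
    df["wave"] = df["wave"].astype(int)

    dup = df.duplicated(subset=["participant_id", "wave"], keep=False)
    if dup.any():
        pairs = df.loc[dup, ["participant_id", "wave"]].drop_duplicates().values.tolist()
        raise CohortIntegrityError(f"duplicate (participant, wave) pairs: {pairs[:10]}")

    df = df.sort_values(["participant_id", "wave"], kind="mergesort").reset_index(drop=True)
    age_drop = df.groupby("participant_id", sort=False)["age"].diff() < 0
    if age_drop.any():
        bad = df.loc[age_drop, "participant_id"].unique().tolist()
        raise CohortIntegrityError(f"age decreases within participant(s): {bad[:10]}")

    df = df[COHORT_COLUMNS]
    df.attrs["rejected_rows"] = rejected
    return df


def write_cohort(df: pd.DataFrame, path) -> None:
    """Write a cohort table in the canonical CSV dialect (empty cell = missing)."""
    out = df[COHORT_COLUMNS].copy()
    out["ce_report"] = out["ce_report"].astype(bool)
    out.to_csv(path, index=False)


class ScoreStandardizer(TransformerMixin, BaseEstimator):
    """Pooled z-standardisation of the raw cognitive scores.

    For each domain the z-score is ``(raw - pooled mean) / pooled SD`` where
    mean and SD (n-1 denominator) are taken over every non-missing
    person-wave observation in the table the transformer was fitted on, so
    each domain has pooled mean 0 and SD 1.  Missing raw scores give
    missing z-scores.
    """

    def __init__(self, columns=tuple(SCORE_COLUMNS)):
        self.columns = columns

    def fit(self, X: pd.DataFrame, y=None):
        means, sds = {}, {}
        for col in self.columns:
            vals = pd.to_numeric(X[col], errors="coerce").dropna()
            if len(vals) < 2:
                raise DegenerateInputError(f"{col}: need >=2 non-missing values to standardise")
            sd = float(vals.std(ddof=1))
            if sd == 0.0:
                raise DegenerateInputError(f"{col}: zero pooled SD, cannot standardise")
            means[col] = float(vals.mean())
            sds[col] = sd
        self.means_ = means
        self.sds_ = sds
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        out = X.copy()
        for col in self.columns:
            zcol = Z_COLUMNS.get(col, col + "_z")
            out[zcol] = (pd.to_numeric(out[col], errors="coerce") - self.means_[col]) / self.sds_[col]
        return out


def standardise_scores(records: pd.DataFrame) -> pd.DataFrame:
    """Add ``memory_z``/``fluency_z`` standardised over the pooled sample."""
    return ScoreStandardizer().fit_transform(records)


def define_baseline(records: pd.DataFrame) -> pd.Series:
    """Earliest wave per participant with complete cognitive and covariate data.

    Returns a float Series indexed by participant_id; NaN when a participant
    never has a complete wave.
    """
    complete = records[SCORE_COLUMNS + COVARIATES].notna().all(axis=1)
    waves = records["wave"].where(complete, np.nan)
    return waves.groupby(records["participant_id"]).min()


def build_profiles(records: pd.DataFrame) -> pd.DataFrame:
    """Collapse wave records into one profile row per participant.

    Requires standardised scores (``memory_z``/``fluency_z``) to be present.
    The profile carries the analytic baseline, exposure classification,
    time origin (first post-baseline CE wave) and the five matching
    variables, plus baseline covariate values for balance reporting.
    """
    for col in ("memory_z", "fluency_z"):
        if col not in records.columns:
            raise CohortFormatError(f"records lack {col}; run standardise_scores first")

    baseline = define_baseline(records)
    rec = records.merge(
        baseline.rename("baseline_wave"), left_on="participant_id", right_index=True, how="left"
    )
    pid = rec["participant_id"]

    base_rows = rec[rec["wave"] == rec["baseline_wave"]].set_index("participant_id")
    profiles = pd.DataFrame(index=baseline.index)
    profiles["baseline_wave"] = baseline
    profiles["baseline_age"] = base_rows["age"]
    profiles["baseline_ce"] = base_rows["ce_report"].reindex(baseline.index) == True  # noqa: E712
    profiles["pre_baseline_ce"] = (
        rec["ce_report"].where(rec["wave"] < rec["baseline_wave"], False).groupby(pid).any()
    )

    analysed = rec["wave"] >= rec["baseline_wave"]
    n_analysed = analysed.groupby(pid).sum().astype(int)
    profiles["n_analysed_waves"] = n_analysed
    profiles["followup_duration"] = n_analysed

    ce_post = rec["ce_report"] & analysed & (rec["wave"] > rec["baseline_wave"])
    profiles["n_ce_waves"] = ce_post.groupby(pid).sum().astype(int)
    profiles["t0_wave"] = rec["wave"].where(ce_post).groupby(pid).min()
    at_t0 = rec.merge(
        profiles["t0_wave"].rename("_t0"), left_on="participant_id", right_index=True, how="left"
    )
    age_t0 = at_t0[at_t0["wave"] == at_t0["_t0"]].set_index("participant_id")["age"]
    profiles["age_t0"] = age_t0
    n = profiles["n_ce_waves"]
    profiles["exposure_group"] = np.select([n == 0, n == 1], ["control", "single_ce"], "multiple_ce")
    profiles["mean_z_baseline"] = (base_rows["memory_z"] + base_rows["fluency_z"]) / 2.0
    for cov in COVARIATES:
        profiles[cov] = base_rows[cov]
    profiles.index.name = "participant_id"
    return profiles.reset_index()


#: Exclusion reasons in application order.
EXCLUSION_ORDER = ["no_baseline", "baseline_ce", "lt2_waves"]


def apply_exclusions(profiles: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Apply eligibility rules and return (eligible profiles, exclusion ledger).

    Rules, in order: participants with no complete-data baseline; CE
    reported at the baseline wave (no pre-exposure assessment exists);
    fewer than two analysed waves.  CE reported only before the analytic
    baseline does not exclude or reclassify (the ``pre_baseline_ce`` flag
    records it).
    """
    ledger = {"input": int(len(profiles)), "excluded": {}, "output": 0}
    remaining = profiles
    masks = {
        "no_baseline": lambda p: p["baseline_wave"].isna(),
        "baseline_ce": lambda p: p["baseline_ce"].astype(bool),
        "lt2_waves": lambda p: p["n_analysed_waves"] < 2,
    }
    for reason in EXCLUSION_ORDER:
        drop = masks[reason](remaining)
        ledger["excluded"][reason] = int(drop.sum())
        remaining = remaining[~drop.fillna(False).astype(bool)] if reason == "no_baseline" else remaining[~drop]
    ledger["output"] = int(len(remaining))
    return remaining.reset_index(drop=True), ledger


def classify_exposure(profiles: pd.DataFrame) -> pd.DataFrame:
    """Recompute exposure_group from the CE wave count (idempotent).

    ``single_ce`` iff exactly one post-baseline CE wave, ``multiple_ce``
    iff two or more, ``control`` iff none; t0 is the first CE wave.
    """
    out = profiles.copy()
    n = out["n_ce_waves"]
    out["exposure_group"] = np.select([n == 0, n == 1], ["control", "single_ce"], "multiple_ce")
    return out
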