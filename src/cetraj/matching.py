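"""Coarsened exact matching (CEM) with k-to-k pruning and time-origin alignment.

Treated (continuing-education) and control participants are matched by
exact agreement on coarsened versions of five baseline variables: age,
sex, education level, mean standardised cognitive performance and
follow-up duration.  Within each stratum, surplus members are randomly
dropped so treated and control counts are equal (k-to-k), which permits
unweighted downstream analysis.  Each stratum's kept controls receive a
time origin at the median treated age-at-exposure (aget0) in that
stratum, so the two arms are compared over the same span of ages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .errors import CetrajError, OutOfSupportError

#: The five matching variables.
MATCHING_VARIABLES = ["baseline_age", "sex", "education_level", "mean_z_baseline", "followup_duration"]


def _default_rules() -> dict:
    return {
        "baseline_age": {"kind": "bins", "edges": list(np.arange(50.0, 100.0, 5.0))},
        "sex": {"kind": "exact"},
        "education_level": {"kind": "exact"},
        "mean_z_baseline": {"kind": "bins", "edges": list(np.arange(-3.0, 3.5, 0.5))},
        "followup_duration": {"kind": "exact"},
    }


@dataclass
class CoarseningSpec:
    """Per-variable coarsening rules defining the matching strata.

    Each matching variable has exactly one rule: ``{"kind": "exact"}`` for
    categorical/integer variables, or ``{"kind": "bins", "edges": [...]}``
    with strictly increasing edges for continuous ones.  Bins are
    half-open ``[lo, hi)``; values outside the outermost edges are out of
    support.
    """

    rules: dict = field(default_factory=_default_rules)

    def validate(self) -> None:
        for var in MATCHING_VARIABLES:
            if var not in self.rules:
                raise CetrajError(f"coarsening spec lacks a rule for {var}")
            rule = self.rules[var]
            if rule["kind"] == "bins":
                edges = np.asarray(rule["edges"], dtype=float)
                if len(edges) < 2 or not np.all(np.diff(edges) > 0):
                    raise CetrajError(f"{var}: bin edges must be strictly increasing")
            elif rule["kind"] != "exact":
                raise CetrajError(f"{var}: unknown rule kind {rule['kind']!r}")

    def to_dict(self) -> dict:
        return {
            var: ({"kind": "exact"} if r["kind"] == "exact" else {"kind": "bins", "edges": [float(e) for e in r["edges"]]})
            for var, r in self.rules.items()
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CoarseningSpec":
        spec = cls(rules={k: dict(v) for k, v in d.items()})
        spec.validate()
        return spec


def coarsen(profiles: pd.DataFrame, spec: CoarseningSpec) -> pd.Series:
    """Map each profile to its stratum key (tuple of bin indices / labels).

    Half-open ``[lo, hi)`` bins; a continuous value outside the outermost
    edges raises :class:`OutOfSupportError`.
    """
    spec.validate()
    parts = []
    for var in MATCHING_VARIABLES:
        rule = spec.rules[var]
        col = profiles[var]
        if rule["kind"] == "exact":
            parts.append(col.astype(str))
        else:
            edges = np.asarray(rule["edges"], dtype=float)
            vals = col.to_numpy(dtype=float)
            out = (vals < edges[0]) | (vals >= edges[-1]) | ~np.isfinite(vals)
            if out.any():
                bad = profiles.loc[out, ["participant_id", var]].head(5).to_dict("records")
                raise OutOfSupportError(f"{var}: values outside coarsening support, e.g. {bad}")
            parts.append(pd.Series(np.digitize(vals, edges) - 1, index=profiles.index).astype(str))
    keys = parts[0]
    for p in parts[1:]:
        keys = keys + "|" + p
    return keys


def support_mask(profiles: pd.DataFrame, spec: CoarseningSpec) -> pd.Series:
    """True where every binned matching variable lies inside its bin support."""
    spec.validate()
    ok = pd.Series(True, index=profiles.index)
    for var in MATCHING_VARIABLES:
        rule = spec.rules[var]
        if rule["kind"] == "bins":
            edges = np.asarray(rule["edges"], dtype=float)
            vals = profiles[var].to_numpy(dtype=float)
            ok &= np.isfinite(vals) & (vals >= edges[0]) & (vals < edges[-1])
    return ok


@dataclass
class Stratum:
    key: str
    treated_ids: list
    control_ids: list
    t0_age_control: float


@dataclass
class MatchedCohort:
    """Result of a k-to-k coarsened exact matching for one exposure group."""

    group_label: str
    strata: dict  # key -> Stratum
    unmatched_treated: list
    unmatched_controls: list
    dropped_treated: list
    dropped_controls: list
    seed: int
    spec: CoarseningSpec

    @property
    def treated_ids(self) -> list:
        return [i for s in self.strata.values() for i in s.treated_ids]

    @property
    def control_ids(self) -> list:
        return [i for s in self.strata.values() for i in s.control_ids]

    @property
    def n_pairs(self) -> int:
        return sum(len(s.treated_ids) for s in self.strata.values())

    def summary(self) -> dict:
        n_treated_in = self.n_pairs + len(self.unmatched_treated) + len(self.dropped_treated)
        return {
            "group_label": self.group_label,
            "n_strata": len(self.strata),
            "n_pairs": self.n_pairs,
            "n_unmatched_treated": len(self.unmatched_treated),
            "n_dropped_treated": len(self.dropped_treated),
            "n_dropped_controls": len(self.dropped_controls),
            "matched_fraction_treated": self.n_pairs / n_treated_in if n_treated_in else 0.0,
            "seed": self.seed,
        }


class CoarsenedExactMatcher(BaseEstimator):
    """CEM with k-to-k pruning, as a scikit-learn style estimator.

    Parameters
    ----------
    spec : CoarseningSpec, optional
        Coarsening rules (defaults: 5-year age bins, 0.5-SD cognition bins
        over [-3, 3), exact sex/education/follow-up duration).
    treated_group : str
        Which ``exposure_group`` label is treated (``single_ce`` or
        ``multiple_ce``); all ``control`` profiles form the control pool.
    seed : int
        Seed for the uniform random dropping of surplus stratum members.

    After :meth:`fit`, the matching is available as ``cohort_``
    (a :class:`MatchedCohort`) plus the convenience attributes
    ``strata_``, ``unmatched_treated_`` and ``matched_fraction_``.
    """

    def __init__(self, spec: CoarseningSpec | None = None, treated_group: str = "single_ce", seed: int = 0):
        self.spec = spec
        self.treated_group = treated_group
        self.seed = seed

    def fit(self, X: pd.DataFrame, y=None):
        profiles = X
        spec = self.spec if self.spec is not None else CoarseningSpec()
        treated = profiles[profiles["exposure_group"] == self.treated_group]
        controls = profiles[profiles["exposure_group"] == "control"]
        if len(treated) == 0:
            raise CetrajError(f"no treated profiles with exposure_group={self.treated_group!r}")

        # profiles outside the coarsening support cannot be assigned a
        # stratum and are reported unmatched
        t_ok = support_mask(treated, spec)
        c_ok = support_mask(controls, spec)
        oos_treated = treated.loc[~t_ok, "participant_id"].tolist()
        oos_controls = controls.loc[~c_ok, "participant_id"].tolist()
        treated, controls = treated[t_ok], controls[c_ok]
        if len(treated) == 0:
            raise CetrajError("all treated profiles fall outside the coarsening support")

        tkeys = coarsen(treated, spec)
        ckeys = coarsen(controls, spec)
        rng = np.random.default_rng([int(self.seed) % (2**31), 7])

        strata: dict[str, Stratum] = {}
        unmatched_t, unmatched_c, dropped_t, dropped_c = list(oos_treated), list(oos_controls), [], []
        t_by_key = {k: g for k, g in treated.groupby(tkeys)}
        c_by_key = {k: g for k, g in controls.groupby(ckeys)}
        matched_keys = set()
        for key in sorted(t_by_key):
            tg = t_by_key[key]
            cg = c_by_key.get(key)
            if cg is None or len(cg) == 0:
                unmatched_t.extend(tg["participant_id"].tolist())
                continue
            matched_keys.add(key)
            t_ids = tg["participant_id"].tolist()
            c_ids = cg["participant_id"].tolist()
            k = min(len(t_ids), len(c_ids))
            if len(c_ids) > k:
                kept = rng.choice(len(c_ids), size=k, replace=False)
                kept_c = [c_ids[i] for i in sorted(kept)]
                dropped_c.extend(sorted(set(c_ids) - set(kept_c)))
            else:
                kept_c = c_ids
            if len(t_ids) > k:
                kept = rng.choice(len(t_ids), size=k, replace=False)
                kept_t = [t_ids[i] for i in sorted(kept)]
                dropped_t.extend(sorted(set(t_ids) - set(kept_t)))
            else:
                kept_t = t_ids
            t0_ctrl = assign_control_t0(tg.loc[tg["participant_id"].isin(kept_t), "age_t0"])
            strata[key] = Stratum(key, kept_t, kept_c, t0_ctrl)
        for key, cg in c_by_key.items():
            if key not in matched_keys:
                unmatched_c.extend(cg["participant_id"].tolist())

        self.cohort_ = MatchedCohort(
            group_label=self.treated_group,
            strata=strata,
            unmatched_treated=unmatched_t,
            unmatched_controls=unmatched_c,
            dropped_treated=dropped_t,
            dropped_controls=dropped_c,
            seed=int(self.seed),
            spec=spec,
        )
        self.strata_ = strata
        self.unmatched_treated_ = unmatched_t
        self.matched_fraction_ = self.cohort_.summary()["matched_fraction_treated"]
        return self


def assign_control_t0(treated_age_t0: pd.Series | np.ndarray) -> float:
    """Stratum time origin for controls: median treated aget0 (midpoint for even counts)."""
    return float(np.median(np.asarray(treated_age_t0, dtype=float)))


def match_k2k(
    profiles: pd.DataFrame, spec: CoarseningSpec | None = None, treated_group: str = "single_ce", seed: int = 0
) -> MatchedCohort:
    """Functional wrapper over :class:`CoarsenedExactMatcher`."""
    return CoarsenedExactMatcher(spec=spec, treated_group=treated_group, seed=seed).fit(profiles).cohort_


def build_two_control_groups(
    profiles: pd.DataFrame, spec: CoarseningSpec | None = None, seed: int = 0
) -> tuple[MatchedCohort, MatchedCohort, int]:
    """Match the single- and multiple-CE groups against the same control pool.

    Controls may be kept in either or both matchings; the overlap count is
    the number of controls appearing in both.
    """
    spec = spec if spec is not None else CoarseningSpec()

    def _match_or_empty(label: str, s: int) -> MatchedCohort:
        if (profiles["exposure_group"] == label).any():
            return match_k2k(profiles, spec, label, s)
        return MatchedCohort(label, {}, [], [], [], [], s, spec)

    single = _match_or_empty("single_ce", seed)
    multiple = _match_or_empty("multiple_ce", seed + 1)
    overlap = len(set(single.control_ids) & set(multiple.control_ids))
    return single, multiple, overlap


def assign_time_axes(cohort: MatchedCohort, records: pd.DataFrame, profiles: pd.DataFrame) -> pd.DataFrame:
    """Build the matched long table with centred time axes.

    Returns one row per analysed wave (wave >= analytic baseline) of every
    matched participant, with ``t = age - age_t0`` where ``age_t0`` is the
    participant's own age at first CE report (treated) or the stratum
    median treated aget0 (controls), a 0/1 ``group`` indicator, the
    stratum key and a 1-based ``assessment_round`` counter.
    """
    rows = []
    for key, s in cohort.strata.items():
        for pid in s.treated_ids:
            rows.append((pid, key, 1))
        for pid in s.control_ids:
            rows.append((pid, key, 0))
    member = pd.DataFrame(rows, columns=["participant_id", "stratum", "group"])

    prof = profiles.set_index("participant_id")
    member["baseline_wave"] = member["participant_id"].map(prof["baseline_wave"])
    own_t0 = member["participant_id"].map(prof["age_t0"])
    strat_t0 = member["stratum"].map({k: s.t0_age_control for k, s in cohort.strata.items()})
    member["age_t0"] = np.where(member["group"] == 1, own_t0, strat_t0)

    out = records.merge(member, on="participant_id", how="inner")
    out = out[out["wave"] >= out["baseline_wave"]].copy()
    out["t"] = out["age"] - out["age_t0"]
    out = out.sort_values(["participant_id", "wave"], kind="mergesort").reset_index(drop=True)
    out["assessment_round"] = out.groupby("participant_id").cumcount() + 1
    out["group_label"] = cohort.group_label
    return out


#: Baseline variables summarised in the balance report.
_BALANCE_NUMERIC = ["baseline_age", "mean_z_baseline", "followup_duration", "wealth_z", "cesd"]
_BALANCE_BINARY = [
    "smoker",
    "alcohol",
    "mvpa_weekly",
    "hypertension",
    "heart_disease",
    "stroke",
    "cancer",
    "diabetes",
    "psychiatric",
]
_BALANCE_CATEGORICAL = {"sex": None, "education_level": None, "labour_force": None, "hearing": None}


def balance_report(cohort: MatchedCohort, profiles: pd.DataFrame) -> pd.DataFrame:
    """Standardised mean differences (treated - control) at baseline.

    SMD = (mean_T - mean_C) / sqrt((var_T + var_C) / 2); exactly-matched
    categorical variables yield exact zeros.  Categorical covariates are
    expanded into one indicator per level.
    """
    prof = profiles.set_index("participant_id")
    t = prof.loc[cohort.treated_ids]
    c = prof.loc[cohort.control_ids]

    cols = {}
    for var in _BALANCE_NUMERIC + _BALANCE_BINARY:
        cols[var] = (pd.to_numeric(t[var], errors="coerce"), pd.to_numeric(c[var], errors="coerce"))
    for var in _BALANCE_CATEGORICAL:
        levels = sorted(set(t[var].dropna()) | set(c[var].dropna()))
        for lev in levels:
            cols[f"{var}={lev}"] = ((t[var] == lev).astype(float), (c[var] == lev).astype(float))

    out = []
    for name, (tv, cv) in cols.items():
        mt, mc = tv.mean(), cv.mean()
        pooled = np.sqrt((tv.var(ddof=1) + cv.var(ddof=1)) / 2.0)
        diff = mt - mc
        if pooled == 0 or np.isnan(pooled):
            smd = 0.0 if np.isclose(diff, 0.0, atol=1e-12) else np.inf
        else:
            smd = diff / pooled
        out.append({"variable": name, "mean_treated": mt, "mean_control": mc, "smd": smd})
    return pd.DataFrame(out)
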