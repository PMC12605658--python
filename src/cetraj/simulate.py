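"""Synthetic longitudinal cohort generator with selective exposure uptake.

The generator emulates the structure of a biennial ageing cohort (waves
every two years, entry ages 50-75, episodic-memory and verbal-fluency
scores, a per-wave continuing-education report, and the covariate set the
analysis adjusts for), with known ground truth so every downstream stage
is testable without any external data.

Data-generating model (per domain, latent z scale)::

    y_i(age) = m(age) + b0_i + b1_i * min(t, 0) + b2_i * max(t, 0)
               + exposed_i * [step + slope * max(t_true, 0)] + eps

where ``m(age)`` is an age-referenced mean trajectory (linear slope plus a
mild quadratic acceleration of decline), ``t`` is time from the
participant's candidate time origin, ``(b0, b1, b2)`` is a zero-mean
random intercept / pre-slope / post-slope triple with unstructured
covariance, and ``t_true`` is time from the true exposure origin.  The
mean trajectory is deliberately a smooth function of age, not of the
candidate origin: a mean kink at an unobservable candidate age is an
artefact no real cohort exhibits, and the matched analysis would
mis-attribute it.  Person-level heterogeneity in pre/post slopes around
the origin is retained through the random effects.

Reverse-causality selection: each participant receives a candidate origin
wave (uniform over interior waves); the probability of actually taking up
continuing education there is logistic in the person's latent cognitive
level (in SD units) and their employment status, so cognitively healthier
and employed people select into the exposure.  Attrition is a per-wave
logistic hazard in age and latent cognition.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .cohort import COHORT_COLUMNS
from .errors import CohortIntegrityError, ConfigError

_REF_AGE = 65.0  # age at which slope_mean applies


def _default_re_cov() -> np.ndarray:
    # intercept, pre-slope, post-slope (latent SD units; slopes per year)
    return np.array(
        [
            [0.55, -0.0010, -0.0020],
            [-0.0010, 0.0006, 0.0003],
            [-0.0020, 0.0003, 0.0006],
        ]
    )


@dataclass
class TrajectoryParams:
    """Latent trajectory parameters for one cognitive domain.

    ``slope_mean`` is the mean decline per year at age 65; ``curvature``
    bends the mean trajectory quadratically in age so decline accelerates
    with age (slope changes by ``2 * curvature`` per year of age).
    ``re_cov`` is the 3x3 unstructured covariance of the random intercept
    and the random pre/post slope deviations around the candidate origin.
    """

    intercept_mean: float = 0.0
    slope_mean: float = -0.016
    curvature: float = -0.0006
    re_cov: np.ndarray = field(default_factory=_default_re_cov)
    resid_sd: float = 0.55

    def validate(self, name: str) -> None:
        cov = np.asarray(self.re_cov, dtype=float)
        if cov.shape != (3, 3) or not np.allclose(cov, cov.T):
            raise ConfigError(f"{name}.re_cov must be a symmetric 3x3 matrix")
        if np.linalg.eigvalsh(cov).min() < -1e-10:
            raise ConfigError(f"{name}.re_cov is not positive semi-definite")
        if self.resid_sd < 0:
            raise ConfigError(f"{name}.resid_sd must be >= 0")


@dataclass
class SelectionParams:
    """Log-odds of continuing-education uptake at the candidate wave."""

    base: float = -2.5
    per_sd_cognition: float = 2.0
    employed: float = 0.8


@dataclass
class AttritionParams:
    """Per-wave dropout hazard, logistic in age and latent cognition."""

    base: float = -3.0
    per_year_age: float = 0.03
    per_sd_cognition: float = -0.15


@dataclass
class EffectParams:
    """True exposure effect added after the true origin (exposed only)."""

    slope: float = 0.0  # SD per year added to the post-origin slope
    step: float = 0.0  # SD added at and after the origin
    quad: float = 0.0  # SD per year^2, quadratic in post-origin time


@dataclass
class SimulationConfig:
    n_exposed: int = 750
    n_control_pool: int = 2250
    n_waves: int = 10
    wave_gap: float = 2.0
    age_entry_range: tuple = (50.0, 75.0)
    memory: TrajectoryParams = field(default_factory=TrajectoryParams)
    fluency: TrajectoryParams = field(
        default_factory=lambda: TrajectoryParams(slope_mean=-0.010, curvature=-0.0004, resid_sd=0.60)
    )
    selection: SelectionParams = field(default_factory=SelectionParams)
    attrition: AttritionParams = field(default_factory=AttritionParams)
    true_effect: EffectParams = field(default_factory=EffectParams)
    multiple_ce_prob: float = 0.65
    extra_ce_prob: float = 0.4
    fluency_gap_wave: int | None = 6
    missing_covariate_prob: float = 0.01
    round_scores: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_exposed < 1:
            raise ConfigError("n_exposed must be >= 1")
        if self.n_control_pool < 1:
            raise ConfigError("n_control_pool must be >= 1")
        if self.n_waves < 2:
            raise ConfigError("n_waves must be >= 2")
        if self.wave_gap <= 0:
            raise ConfigError("wave_gap must be > 0")
        for p in ("multiple_ce_prob", "extra_ce_prob", "missing_covariate_prob"):
            v = getattr(self, p)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{p} must be in [0, 1]")
        self.memory.validate("memory")
        self.fluency.validate("fluency")


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _mean_trajectory(p: TrajectoryParams, age):
    d = age - _REF_AGE
    return p.intercept_mean + p.slope_mean * d + p.curvature * d * d


def _simulate_batch(cfg: SimulationConfig, rng: np.random.Generator, n: int) -> dict:
    """Simulate n candidate participants; returns per-person arrays."""
    W = cfg.n_waves
    entry_age = rng.uniform(*cfg.age_entry_range, size=n)
    ages = entry_age[:, None] + cfg.wave_gap * np.arange(W)[None, :]

    b_mem = rng.multivariate_normal(np.zeros(3), np.asarray(cfg.memory.re_cov, float), size=n)
    b_flu = rng.multivariate_normal(np.zeros(3), np.asarray(cfg.fluency.re_cov, float), size=n)

    # candidate origin wave: interior waves only, so a pre- and post-origin
    # observation can exist in a complete panel
    if W >= 3:
        cand_wave = rng.integers(2, W, size=n)  # waves 2..W-1 (1-based)
    else:
        cand_wave = np.full(n, 2)
    cand_age = entry_age + cfg.wave_gap * (cand_wave - 1)
    t_rel = ages - cand_age[:, None]

    def latent(bmat, p: TrajectoryParams):
        dev = (
            bmat[:, [0]]
            + bmat[:, [1]] * np.minimum(t_rel, 0.0)
            + bmat[:, [2]] * np.maximum(t_rel, 0.0)
        )
        return _mean_trajectory(p, ages) + dev

    lat_mem = latent(b_mem, cfg.memory)
    lat_flu = latent(b_flu, cfg.fluency)
    lat_mean_dev = (
        (lat_mem - _mean_trajectory(cfg.memory, ages)) + (lat_flu - _mean_trajectory(cfg.fluency, ages))
    ) / 2.0
    sd0 = float(np.sqrt((cfg.memory.re_cov[0][0] + cfg.fluency.re_cov[0][0]) / 4.0))
    z_dev = lat_mean_dev / sd0 if sd0 > 0 else np.zeros_like(lat_mean_dev)

    # attrition: once out, out; wave 1 always observed
    haz = _sigmoid(
        cfg.attrition.base
        + cfg.attrition.per_year_age * (ages - 70.0)
        + cfg.attrition.per_sd_cognition * z_dev
    )
    drop = rng.random((n, W)) < haz
    drop[:, 0] = False
    dropped = np.cumsum(drop, axis=1) > 0
    observed = ~dropped
    last_wave = observed.sum(axis=1)  # waves are observed 1..last_wave

    # employment: employed before an individual retirement age
    retirement_age = rng.normal(64.0, 3.0, size=n)
    lf_type = rng.choice(
        ["employed", "unemployed_disabled", "homemaker_other"], size=n, p=[0.82, 0.08, 0.10]
    )
    employed_at_cand = (cand_age < retirement_age) & (lf_type == "employed")

    z_cog_cand = z_dev[np.arange(n), cand_wave - 1]
    uptake = _sigmoid(
        cfg.selection.base
        + cfg.selection.per_sd_cognition * z_cog_cand
        + cfg.selection.employed * employed_at_cand
    )
    takes = (rng.random(n) < uptake) & (cand_wave <= last_wave)

    return dict(
        entry_age=entry_age,
        ages=ages,
        b_mem=b_mem,
        b_flu=b_flu,
        cand_wave=cand_wave,
        cand_age=cand_age,
        lat_mem=lat_mem,
        lat_flu=lat_flu,
        observed=observed,
        last_wave=last_wave,
        retirement_age=retirement_age,
        lf_type=lf_type,
        uptake=uptake,
        exposed=takes,
        z_cog_cand=z_cog_cand,
    )


def _covariate_panel(cfg: SimulationConfig, rng: np.random.Generator, batch: dict) -> dict:
    """Simulate the covariate process for a batch (arrays of shape (n, W))."""
    n, W = batch["ages"].shape
    ages = batch["ages"]
    cov = {}
    cov["sex"] = np.where(rng.random(n) < 0.554, "female", "male")
    cov["education_level"] = rng.choice(["below_hs", "hs", "above_hs"], size=n, p=[0.245, 0.545, 0.21])

    employed = (ages < batch["retirement_age"][:, None]) & (batch["lf_type"] == "employed")[:, None]
    lf = np.where(
        employed,
        "employed",
        np.where(
            (batch["lf_type"] == "employed")[:, None] | (ages >= batch["retirement_age"][:, None]),
            "retired",
            batch["lf_type"][:, None],
        ),
    )
    cov["labour_force"] = lf

    base_wealth = rng.normal(0.1, 1.1, size=n)
    cov["wealth_z"] = base_wealth[:, None] + np.cumsum(rng.normal(0, 0.08, size=(n, W)), axis=1)

    smoker0 = rng.random(n) < 0.17
    quit = rng.random((n, W)) < 0.04
    quit[:, 0] = False
    cov["smoker"] = (smoker0[:, None] & (np.cumsum(quit, axis=1) == 0)).astype(float)

    alc0 = rng.random(n) < 0.92
    flip = rng.random((n, W)) < 0.02
    flip[:, 0] = False
    cov["alcohol"] = (alc0[:, None] ^ (np.cumsum(flip, axis=1) % 2 == 1)).astype(float)

    mvpa0 = rng.random(n) < 0.84
    flip = rng.random((n, W)) < 0.05
    flip[:, 0] = False
    cov["mvpa_weekly"] = (mvpa0[:, None] ^ (np.cumsum(flip, axis=1) % 2 == 1)).astype(float)

    hear_latent = rng.normal(0, 1, size=n)[:, None] + 0.02 * (ages - 65.0)
    cuts = [-0.8, -0.1, 0.6, 1.4]
    levels = np.array(["excellent", "very_good", "good", "fair", "poor"])
    cov["hearing"] = levels[np.searchsorted(cuts, hear_latent).clip(0, 4)]

    cesd_base = np.abs(rng.normal(1.1, 1.5, size=n))
    cov["cesd"] = np.clip(
        np.round(cesd_base[:, None] + rng.normal(0, 0.7, size=(n, W))), 0, 8
    ).astype(float)

    prevalence = dict(
        hypertension=0.25, heart_disease=0.02, stroke=0.08, cancer=0.04, diabetes=0.04, psychiatric=0.08
    )
    onset = dict(
        hypertension=0.015, heart_disease=0.004, stroke=0.004, cancer=0.004, diabetes=0.004, psychiatric=0.004
    )
    for cond in prevalence:
        has0 = rng.random(n) < prevalence[cond]
        new = rng.random((n, W)) < onset[cond]
        new[:, 0] = False
        cov[cond] = (has0[:, None] | (np.cumsum(new, axis=1) > 0)).astype(float)
    return cov


def simulate_cohort(cfg: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a cohort with known ground truth.

    Returns
    -------
    records : pandas.DataFrame
        Long table in the canonical cohort dialect (plus ``latent_memory``
        and ``latent_fluency`` columns on the latent z scale), one row per
        observed participant-wave.
    truth : pandas.DataFrame
        Ground-truth sidecar, one row per participant: latent random
        effects, true group, candidate/true origin wave and age, uptake
        probability and last observed wave.

    Candidate participants are generated in batches and rejection-sampled
    until the exposed and control quotas are filled; surplus candidates are
    discarded so the configured group sizes are exact.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    need_exp, need_ctl = cfg.n_exposed, cfg.n_control_pool
    kept_records, kept_truth = [], []
    total_candidates = 0
    pid_counter = 0
    limit = 200 * (need_exp + need_ctl)

    while need_exp > 0 or need_ctl > 0:
        n_batch = int(max(1000, 2.5 * (need_exp + need_ctl)))
        total_candidates += n_batch
        if total_candidates > limit:
            raise ConfigError(
                "could not fill exposed/control quotas; selection or attrition settings "
                "leave too few eligible candidates"
            )
        batch = _simulate_batch(cfg, rng, n_batch)
        cov = _covariate_panel(cfg, rng, batch)

        exposed = batch["exposed"]
        keep_exp = np.flatnonzero(exposed)[:need_exp]
        keep_ctl = np.flatnonzero(~exposed)[:need_ctl]
        need_exp -= len(keep_exp)
        need_ctl -= len(keep_ctl)
        keep = np.concatenate([keep_exp, keep_ctl])
        if len(keep) == 0:
            continue

        rec, truth = _materialise(cfg, rng, batch, cov, keep, pid_counter)
        pid_counter += len(keep)
        kept_records.append(rec)
        kept_truth.append(truth)

    records = pd.concat(kept_records, ignore_index=True)
    truth = pd.concat(kept_truth, ignore_index=True)
    records = records.sort_values(["participant_id", "wave"], kind="mergesort").reset_index(drop=True)
    truth = truth.sort_values("participant_id", kind="mergesort").reset_index(drop=True)
    return records, truth


def _materialise(cfg, rng, batch, cov, keep, pid_start) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Turn kept batch candidates into long records + truth rows."""
    W = cfg.n_waves
    n = len(keep)
    ids = np.array([f"P{pid_start + i:06d}" for i in range(n)])
    exposed = batch["exposed"][keep]
    cand_wave = batch["cand_wave"][keep]
    cand_age = batch["cand_age"][keep]
    last_wave = batch["last_wave"][keep]
    ages = batch["ages"][keep]
    lat_mem = batch["lat_mem"][keep].copy()
    lat_flu = batch["lat_flu"][keep].copy()

    # true exposure effect, anchored at the true origin
    t_true = ages - cand_age[:, None]
    post = np.maximum(t_true, 0.0)
    on = (t_true >= 0.0).astype(float)
    eff = exposed[:, None] * (
        cfg.true_effect.step * on + cfg.true_effect.slope * post + cfg.true_effect.quad * post**2
    )
    lat_mem += eff
    lat_flu += eff

    obs_mem = lat_mem + rng.normal(0, cfg.memory.resid_sd, size=(n, W))
    obs_flu = lat_flu + rng.normal(0, cfg.fluency.resid_sd, size=(n, W))
    if cfg.round_scores:
        memory_raw = np.clip(np.round(10.0 + 3.5 * obs_mem), 0, 20)
        fluency_raw = np.clip(np.round(20.0 + 6.0 * obs_flu), 0, 60)
    else:
        memory_raw = 10.0 + 3.5 * obs_mem
        fluency_raw = 20.0 + 6.0 * obs_flu

    # CE reports: first at the origin wave; multiple reporters add later waves
    ce = np.zeros((n, W), dtype=bool)
    if exposed.any():
        rows = np.flatnonzero(exposed)
        ce[rows, cand_wave[rows] - 1] = True
        multi = rng.random(n) < cfg.multiple_ce_prob
        later = (np.arange(W)[None, :] + 1 > cand_wave[:, None]) & (
            np.arange(W)[None, :] + 1 <= last_wave[:, None]
        )
        extra = (rng.random((n, W)) < cfg.extra_ce_prob) & later & multi[:, None] & exposed[:, None]
        # a flagged multiple reporter with later waves available always gets >=1
        forced = multi & exposed & (later.sum(axis=1) > 0) & (extra.sum(axis=1) == 0)
        for i in np.flatnonzero(forced):
            choices = np.flatnonzero(later[i])
            extra[i, choices[rng.integers(0, len(choices))]] = True
        ce |= extra

    observed = np.arange(W)[None, :] + 1 <= last_wave[:, None]

    # long format
    ii, ww = np.nonzero(observed)
    rec = pd.DataFrame(
        {
            "participant_id": ids[ii],
            "wave": ww + 1,
            "age": ages[ii, ww],
            "memory_raw": memory_raw[ii, ww],
            "fluency_raw": fluency_raw[ii, ww],
            "ce_report": ce[ii, ww],
            "latent_memory": lat_mem[ii, ww],
            "latent_fluency": lat_flu[ii, ww],
        }
    )
    for name in ("sex", "education_level"):
        rec[name] = cov[name][keep][ii]
    for name in (
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
    ):
        rec[name] = cov[name][keep][ii, ww]

    if cfg.fluency_gap_wave is not None and W >= cfg.fluency_gap_wave:
        rec.loc[rec["wave"] == cfg.fluency_gap_wave, "fluency_raw"] = np.nan
    if cfg.missing_covariate_prob > 0:
        from .cohort import TIME_UPDATING_COVARIATES

        for col in TIME_UPDATING_COVARIATES:
            miss = rng.random(len(rec)) < cfg.missing_covariate_prob
            rec.loc[miss, col] = np.nan

    rec = rec[COHORT_COLUMNS + ["latent_memory", "latent_fluency"]]

    b_mem = batch["b_mem"][keep]
    b_flu = batch["b_flu"][keep]
    truth = pd.DataFrame(
        {
            "participant_id": ids,
            "true_group": np.where(exposed, "exposed", "control"),
            "candidate_t0_wave": cand_wave,
            "true_t0_wave": np.where(exposed, cand_wave, np.nan),
            "age_t0_true": np.where(exposed, cand_age, np.nan),
            "candidate_age": cand_age,
            "uptake_prob": batch["uptake"][keep],
            "last_wave": last_wave,
            "entry_age": batch["entry_age"][keep],
            "b0_memory": b_mem[:, 0],
            "b_pre_memory": b_mem[:, 1],
            "b_post_memory": b_mem[:, 2],
            "b0_fluency": b_flu[:, 0],
            "b_pre_fluency": b_flu[:, 1],
            "b_post_fluency": b_flu[:, 2],
        }
    )
    return rec, truth


def inject_effect(
    records: pd.DataFrame, truth: pd.DataFrame, delta_slope: float, delta_step: float
) -> pd.DataFrame:
    """Add a post-origin step and/or slope to exposed participants' scores.

    Operates on the standardised/latent score columns present in
    ``records`` (any of ``latent_memory``, ``latent_fluency``,
    ``memory_z``, ``fluency_z``); raw integer scores are left untouched.
    Control rows and pre-origin rows are unchanged, so repeated injections
    are additive.
    """
    unknown = set(records["participant_id"]) - set(truth["participant_id"])
    if unknown:
        raise CohortIntegrityError(f"records contain participants absent from ground truth: {sorted(unknown)[:5]}")
    cols = [c for c in ("latent_memory", "latent_fluency", "memory_z", "fluency_z") if c in records.columns]
    if not cols:
        raise CohortIntegrityError("records carry no latent or standardised score columns to inject into")

    out = records.copy()
    exp = truth[truth["true_group"] == "exposed"].set_index("participant_id")
    t0_age = out["participant_id"].map(exp["age_t0_true"])
    post_time = out["age"] - t0_age
    add = (delta_step + delta_slope * post_time).where(post_time >= 0, 0.0).fillna(0.0)
    for c in cols:
        out[c] = out[c] + add
    return out


def config_to_dict(cfg: SimulationConfig) -> dict:
    """JSON/YAML-serialisable form of a simulation config."""
    d = asdict(cfg)
    d["memory"]["re_cov"] = np.asarray(cfg.memory.re_cov).tolist()
    d["fluency"]["re_cov"] = np.asarray(cfg.fluency.re_cov).tolist()
    d["age_entry_range"] = list(cfg.age_entry_range)
    return d


def config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    kwargs = {}
    for key, cls in (
        ("memory", TrajectoryParams),
        ("fluency", TrajectoryParams),
        ("selection", SelectionParams),
        ("attrition", AttritionParams),
        ("true_effect", EffectParams),
    ):
        if key in d:
            sub = dict(d.pop(key))
            if "re_cov" in sub:
                sub["re_cov"] = np.asarray(sub["re_cov"], dtype=float)
            kwargs[key] = cls(**sub)
    if "age_entry_range" in d:
        d["age_entry_range"] = tuple(d["age_entry_range"])
    cfg = SimulationConfig(**d, **kwargs)
    return cfg
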