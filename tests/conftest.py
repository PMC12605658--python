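"""Shared fixtures: simulated cohorts and handmade matched tables."""

import numpy as np
import pandas as pd
import pytest

from cetraj.cohort import apply_exclusions, build_profiles, standardise_scores
from cetraj.matching import assign_time_axes, match_k2k
from cetraj.model import carry_forward_covariates, fit_piecewise_lmm
from cetraj.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_sim():
    """A small null cohort (no true effect) shared across read-only tests."""
    cfg = SimulationConfig(n_exposed=150, n_control_pool=500, n_waves=6, seed=11, multiple_ce_prob=0.4)
    records, truth = simulate_cohort(cfg)
    return cfg, records, truth


@pytest.fixture(scope="session")
def eligible_profiles(small_sim):
    _, records, _ = small_sim
    records = standardise_scores(records)
    profiles = build_profiles(records)
    eligible, ledger = apply_exclusions(profiles)
    return records, eligible, ledger


@pytest.fixture(scope="session")
def matched_axes(eligible_profiles):
    records, eligible, _ = eligible_profiles
    cohort = match_k2k(eligible, treated_group="single_ce", seed=5)
    axes = assign_time_axes(cohort, records, eligible)
    return carry_forward_covariates(axes, baseline_fallback=True)


@pytest.fixture(scope="session")
def fitted_small(matched_axes):
    return fit_piecewise_lmm(matched_axes, "memory_z")


def make_matched_table(coef=None, aget0_values=(58.0, 60.0, 62.0, 64.0), t_grid=(-4, -2, 0, 2, 4, 6),
                       n_per_cell=1, noise_sd=0.0, seed=0):
    """Handmade matched-format long table with outcome built by explicit arithmetic.

    The outcome is computed directly from the stated column definitions
    (pre = min(t,0), post = max(t,0), aget0 centred at its sample mean,
    covariates as dummy-coded) so it is independent of the package's
    design builder; used as the oracle for exact-recovery tests.
    """
    coef = dict(coef or {})
    rng = np.random.default_rng(seed)
    rows = []
    pid = 0
    labour = ["employed", "unemployed_disabled", "retired", "homemaker_other"]
    hearing = ["excellent", "very_good", "good", "fair", "poor"]
    for group in (1, 0):
        for a0 in aget0_values:
            for rep in range(n_per_cell):
                pid += 1
                a0_eff = a0 + 0.3 * rep
                crng = np.random.default_rng(10_000 + pid)  # person covariates: seeded draws
                sex = "female" if crng.random() < 0.5 else "male"
                edu = ["below_hs", "hs", "above_hs"][crng.integers(0, 3)]
                lf = labour[crng.integers(0, 4)]
                hear = hearing[crng.integers(0, 5)]
                smoker = float(crng.random() < 0.3)
                alcohol = float(crng.random() < 0.6)
                mvpa = float(crng.random() < 0.5)
                conds = {name: float(crng.random() < 0.3) for name in (
                    "hypertension", "heart_disease", "stroke", "cancer", "diabetes", "psychiatric")}
                for k, t in enumerate(t_grid):
                    wave = k + 1 + (pid % 3)  # staggered entry decouples wave from t
                    rows.append(
                        dict(
                            participant_id=f"H{pid:03d}",
                            wave=wave,
                            age=a0_eff + t,
                            t=float(t),
                            group=group,
                            age_t0=a0_eff,
                            assessment_round=wave,
                            sex=sex,
                            education_level=edu,
                            labour_force=lf,
                            hearing=hear,
                            wealth_z=0.1 * ((3 * pid + wave) % 7) - 0.3 + 0.05 * crng.integers(0, 5),
                            smoker=smoker,
                            alcohol=alcohol,
                            mvpa_weekly=mvpa,
                            cesd=float((pid + wave) % 4),
                            **conds,
                        )
                    )
    d = pd.DataFrame(rows)
    a0c = d["age_t0"] - d["age_t0"].mean()
    pre = np.minimum(d["t"], 0.0)
    post = np.maximum(d["t"], 0.0)
    proxy = 2.0 * (d["wave"] - 1) - d["age"]
    cols = {
        "const": 1.0,
        "pre_time": pre,
        "post_time": post,
        "group": d["group"],
        "group_pre": d["group"] * pre,
        "group_post": d["group"] * post,
        "aget0": a0c,
        "aget0_pre": a0c * pre,
        "aget0_post": a0c * post,
        "pre2": pre**2,
        "pre3": pre**3,
        "post2": post**2,
        "post3": post**3,
        "group_post2": d["group"] * post**2,
        "aget0_post2": a0c * post**2,
        "disc": (d["t"] >= 0).astype(float),
        "group_disc": d["group"] * (d["t"] >= 0).astype(float),
        "wealth_z": d["wealth_z"],
        "cesd": d["cesd"],
        "female": (d["sex"] == "female").astype(float),
        "edu_hs": (d["education_level"] == "hs").astype(float),
        "edu_above_hs": (d["education_level"] == "above_hs").astype(float),
        "birth_cohort": proxy - proxy.mean(),
    }
    y = np.zeros(len(d))
    for name, value in coef.items():
        y = y + value * np.asarray(cols[name], dtype=float)
    if noise_sd > 0:
        y = y + rng.normal(0, noise_sd, len(d))
    d["memory_z"] = y
    return d
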