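"""End-to-end orchestration: cohort -> matching -> model -> contrasts.

The full analysis is run separately for the single- and multiple-CE
groups, each against its own k-to-k matched control group drawn from the
shared control pool, and separately per cognitive domain.  Stage counts
(participants in/out) are accumulated so a run is reconstructible from
its report bundle.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import apply_exclusions, build_profiles, standardise_scores
from .contrasts import decline_contrast, marginal_trajectory, step_contrast
from .errors import CetrajError
from .matching import (
    CoarseningSpec,
    assign_time_axes,
    balance_report,
    build_two_control_groups,
)
from .model import backward_select, carry_forward_covariates, fit_discontinuity_variant
from .simulate import SimulationConfig, config_to_dict


@dataclass
class RunConfig:
    """Configuration for a full pipeline run."""

    simulation: SimulationConfig | None = None
    coarsening: CoarseningSpec = field(default_factory=CoarseningSpec)
    outcomes: tuple = ("memory_z", "fluency_z")
    groups: tuple = ("single_ce", "multiple_ce")
    candidate_terms: tuple = ("pre2", "pre3", "post2", "post3")
    discontinuity: bool = False
    practice_effect: bool = False
    pre_window: float = 4.0
    post_window: float = 8.0
    alpha: float = 0.05
    power: float = 0.80
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "simulation": config_to_dict(self.simulation) if self.simulation else None,
            "coarsening": self.coarsening.to_dict(),
            "outcomes": list(self.outcomes),
            "groups": list(self.groups),
            "candidate_terms": list(self.candidate_terms),
            "discontinuity": self.discontinuity,
            "practice_effect": self.practice_effect,
            "pre_window": self.pre_window,
            "post_window": self.post_window,
            "alpha": self.alpha,
            "power": self.power,
            "seed": self.seed,
        }

    def hash(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def prepare_cohort(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Standardise scores, build profiles and apply eligibility rules."""
    records = standardise_scores(records)
    profiles = build_profiles(records)
    eligible, ledger = apply_exclusions(profiles)
    return records, eligible, ledger


def analyse_matched_group(
    records: pd.DataFrame,
    eligible: pd.DataFrame,
    cohort,
    config: RunConfig,
) -> dict:
    """Fit models and contrasts for one matched exposure group."""
    axes = assign_time_axes(cohort, records, eligible)
    axes = carry_forward_covariates(axes, baseline_fallback=True)
    bal = balance_report(cohort, eligible)
    out = {
        "match": cohort.summary(),
        "balance_max_abs_smd": float(bal["smd"].replace([np.inf, -np.inf], np.nan).abs().max()),
        "balance": bal.to_dict("records"),
        "outcomes": {},
    }
    for outcome in config.outcomes:
        model, trail = backward_select(
            axes,
            outcome=outcome,
            candidates=config.candidate_terms,
            alpha=config.alpha,
            practice_effect=config.practice_effect,
        )
        contrast = decline_contrast(
            model,
            pre_window=config.pre_window,
            post_window=config.post_window,
            alpha=config.alpha,
            power=config.power,
        )
        res = {
            "fit": model.fit_.to_dict(),
            "selection_trail": trail,
            "contrast": contrast.to_dict(),
        }
        if config.discontinuity:
            dmodel = fit_discontinuity_variant(
                axes, outcome=outcome, terms=tuple(model.fit_.terms), practice_effect=config.practice_effect
            )
            res["discontinuity_fit"] = dmodel.fit_.to_dict()
            res["step_contrast"] = step_contrast(dmodel, horizon=config.post_window)
        times = np.linspace(-config.pre_window, config.post_window, 25)
        res["trajectory"] = {
            "times": times.tolist(),
            "exposed": marginal_trajectory(model, 1, times).tolist(),
            "control": marginal_trajectory(model, 0, times).tolist(),
        }
        out["outcomes"][outcome] = res
    return out


def run_analysis(records: pd.DataFrame, config: RunConfig) -> dict:
    """Full pipeline on a cohort table; returns the machine-readable summary.

    Analyses are performed separately for each requested exposure group
    against its own matched controls.  A group with no eligible treated
    participants is skipped with an explicit notice rather than an error.
    """
    records, eligible, ledger = prepare_cohort(records)
    single, multiple, overlap = build_two_control_groups(eligible, config.coarsening, config.seed)
    cohorts = {"single_ce": single, "multiple_ce": multiple}

    summary = {
        "config_hash": config.hash(),
        "seed": config.seed,
        "exclusions": ledger,
        "n_eligible": int(len(eligible)),
        "exposure_counts": eligible["exposure_group"].value_counts().to_dict(),
        "control_overlap": overlap,
        "analyses": {},
        "skipped": {},
    }
    for label in config.groups:
        n_treated = int((eligible["exposure_group"] == label).sum())
        if n_treated == 0 or cohorts[label].n_pairs == 0:
            summary["skipped"][label] = f"no matched treated participants (eligible treated: {n_treated})"
            continue
        summary["analyses"][label] = analyse_matched_group(records, eligible, cohorts[label], config)
    if not summary["analyses"]:
        raise CetrajError("no exposure group could be analysed")
    return summary


def summary_to_json(summary: dict) -> str:
    """Deterministic JSON serialisation of a run summary."""

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not serialisable: {type(o)}")

    return json.dumps(summary, sort_keys=True, indent=1, default=_default)
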