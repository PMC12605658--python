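"""Coarsened exact matching: keys, k-to-k pruning, origin assignment, balance."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cetraj.cohort import COVARIATES
from cetraj.errors import CetrajError, OutOfSupportError
from cetraj.matching import (
    CoarseningSpec,
    MATCHING_VARIABLES,
    assign_control_t0,
    balance_report,
    build_two_control_groups,
    coarsen,
    match_k2k,
)


def _profile(pid, group="control", baseline_age=60.0, sex="female", education_level="hs",
             mean_z_baseline=0.2, followup_duration=5, age_t0=np.nan, **kw):
    base = dict(
        participant_id=pid, exposure_group=group, baseline_age=baseline_age, sex=sex,
        education_level=education_level, mean_z_baseline=mean_z_baseline,
        followup_duration=followup_duration, age_t0=age_t0, baseline_wave=1,
        labour_force="employed", wealth_z=0.0, smoker=0.0, alcohol=1.0, mvpa_weekly=1.0,
        hearing="good", cesd=1.0, hypertension=0.0, heart_disease=0.0, stroke=0.0,
        cancer=0.0, diabetes=0.0, psychiatric=0.0,
    )
    base.update(kw)
    return base


def _frame(rows):
    return pd.DataFrame(rows)


class TestCoarsen:
    def test_half_open_age_bin(self):
        spec = CoarseningSpec()
        p = _frame([_profile("a", baseline_age=57.3)])
        key = coarsen(p, spec).iloc[0]
        assert key.split("|")[0] == "1"  # [55, 60)
        p2 = _frame([_profile("b", baseline_age=55.0)])
        assert coarsen(p2, spec).iloc[0].split("|")[0] == "1"  # lower edge inclusive

    def test_identical_profiles_identical_keys(self):
        p = _frame([_profile("a"), _profile("b")])
        keys = coarsen(p, CoarseningSpec())
        assert keys.iloc[0] == keys.iloc[1]

    def test_out_of_support(self):
        p = _frame([_profile("a", mean_z_baseline=3.7)])
        with pytest.raises(OutOfSupportError, match="mean_z_baseline"):
            coarsen(p, CoarseningSpec())

    def test_spec_requires_all_variables(self):
        spec = CoarseningSpec(rules={"sex": {"kind": "exact"}})
        with pytest.raises(CetrajError):
            spec.validate()


class TestK2K:
    def test_surplus_controls_dropped_to_equal_counts(self):
        rows = [_profile(f"t{i}", group="single_ce", age_t0=62.0 + i) for i in range(3)]
        rows += [_profile(f"c{i}") for i in range(5)]
        mc = match_k2k(_frame(rows), seed=0)
        assert mc.n_pairs == 3
        assert len(mc.control_ids) == 3
        assert len(mc.dropped_controls) == 2

    def test_surplus_treated_dropped_to_equal_counts(self):
        rows = [_profile(f"t{i}", group="single_ce", age_t0=62.0) for i in range(4)]
        rows += [_profile("c0"), _profile("c1")]
        mc = match_k2k(_frame(rows), seed=0)
        assert mc.n_pairs == 2
        assert len(mc.dropped_treated) == 2

    def test_unmatched_treated_reported(self):
        rows = [_profile("t0", group="single_ce", age_t0=62.0, baseline_age=57.0)]
        rows += [_profile("c0", baseline_age=72.0)]
        mc = match_k2k(_frame(rows), seed=0)
        assert mc.unmatched_treated == ["t0"]
        assert mc.summary()["matched_fraction_treated"] == 0.0

    def test_empty_treated_is_error(self):
        with pytest.raises(CetrajError, match="no treated"):
            match_k2k(_frame([_profile("c0")]), seed=0)

    def test_counts_balance_and_key_audit(self, eligible_profiles):
        _, eligible, _ = eligible_profiles
        spec = CoarseningSpec()
        mc = match_k2k(eligible, spec, "single_ce", seed=2)
        keys = coarsen(eligible, spec)
        bykey = dict(zip(eligible["participant_id"], keys))
        for key, s in mc.strata.items():
            assert len(s.treated_ids) == len(s.control_ids) >= 1
            for pid in s.treated_ids + s.control_ids:
                assert bykey[pid] == key
        assert sum(len(s.treated_ids) for s in mc.strata.values()) == sum(
            len(s.control_ids) for s in mc.strata.values()
        )

    def test_determinism(self, eligible_profiles):
        _, eligible, _ = eligible_profiles
        a = match_k2k(eligible, treated_group="single_ce", seed=7)
        b = match_k2k(eligible, treated_group="single_ce", seed=7)
        assert a.control_ids == b.control_ids and a.treated_ids == b.treated_ids

    def test_control_dropping_is_uniform(self):
        """Over 200 seeds, each of 1000 eligible controls is kept ~uniformly."""
        n_controls = 1000
        rows = [_profile("t0", group="single_ce", age_t0=62.0)]
        rows += [_profile(f"c{i:04d}") for i in range(n_controls)]
        frame = _frame(rows)
        counts = {}
        n_seeds = 200
        for seed in range(n_seeds):
            mc = match_k2k(frame, seed=seed)
            (kept,) = mc.control_ids
            counts[kept] = counts.get(kept, 0) + 1
        assert sum(counts.values()) == n_seeds
        # Bonferroni-adjusted 99% binomial bound on the per-control keep count
        bound = stats.binom.isf(0.01 / n_controls, n_seeds, 1.0 / n_controls)
        assert max(counts.values()) <= bound


class TestControlT0:
    @pytest.mark.parametrize(
        "ages,expected", [((60.0, 62.0, 65.0), 62.0), ((60.0, 64.0), 62.0), ((63.4,), 63.4)]
    )
    def test_median_conventions(self, ages, expected):
        assert assign_control_t0(np.array(ages)) == expected

    def test_control_time_axis_anchored_at_stratum_origin(self, eligible_profiles):
        from cetraj.matching import assign_time_axes

        records, eligible, _ = eligible_profiles
        mc = match_k2k(eligible, treated_group="single_ce", seed=5)
        axes = assign_time_axes(mc, records, eligible)
        ctl = axes[axes["group"] == 0]
        t0_map = {k: s.t0_age_control for k, s in mc.strata.items()}
        assert np.allclose(ctl["t"], ctl["age"] - ctl["stratum"].map(t0_map))
        trt = axes[axes["group"] == 1]
        own = eligible.set_index("participant_id")["age_t0"]
        assert np.allclose(trt["t"], trt["age"] - trt["participant_id"].map(own))


class TestTwoControlGroups:
    def test_clone_pool_fully_matched_with_audited_overlap(self):
        rows = []
        for i in range(8):
            rows.append(_profile(f"s{i}", group="single_ce", age_t0=61.0, baseline_age=55.0 + (i % 3) * 5))
        for i in range(8):
            rows.append(_profile(f"m{i}", group="multiple_ce", age_t0=63.0, baseline_age=55.0 + (i % 2) * 5))
        # clone controls: one per treated, identical matching variables
        for i in range(8):
            rows.append(_profile(f"cs{i}", baseline_age=55.0 + (i % 3) * 5))
        for i in range(8):
            rows.append(_profile(f"cm{i}", baseline_age=55.0 + (i % 2) * 5))
        frame = _frame(rows)
        single, multiple, overlap = build_two_control_groups(frame, seed=0)
        assert single.n_pairs == 8 and multiple.n_pairs == 8
        assert not single.unmatched_treated and not multiple.unmatched_treated
        # brute-force key audit of the possible overlap
        spec = CoarseningSpec()
        keys = dict(zip(frame["participant_id"], coarsen(frame, spec)))
        both_keys = {keys[p] for p in single.control_ids} & {keys[p] for p in multiple.control_ids}
        observed = set(single.control_ids) & set(multiple.control_ids)
        assert overlap == len(observed)
        assert all(keys[p] in both_keys for p in observed)

    def test_same_seed_reproduces(self, eligible_profiles):
        _, eligible, _ = eligible_profiles
        a = build_two_control_groups(eligible, seed=3)
        b = build_two_control_groups(eligible, seed=3)
        assert a[0].control_ids == b[0].control_ids
        assert a[1].control_ids == b[1].control_ids
        assert a[2] == b[2]


class TestBalance:
    def test_hand_built_smd(self):
        rows = [
            _profile("t0", group="single_ce", age_t0=62.0, wealth_z=1.2),
            _profile("t1", group="single_ce", age_t0=62.0, wealth_z=-0.8),
            _profile("c0", wealth_z=1.0),
            _profile("c1", wealth_z=-1.0),
        ]
        mc = match_k2k(_frame(rows), seed=0)
        bal = balance_report(mc, _frame(rows)).set_index("variable")
        # means 0.2 vs 0.0, pooled SD sqrt((2+2)/2) -> SMD 0.2 / sqrt(2)
        expected = 0.2 / np.sqrt((2.0 + 2.0) / 2.0)
        assert bal.loc["wealth_z", "smd"] == pytest.approx(expected, abs=1e-12)
        assert bal.loc["sex=female", "smd"] == 0.0

    def test_exactly_matched_variables_have_zero_smd(self, eligible_profiles):
        _, eligible, _ = eligible_profiles
        mc = match_k2k(eligible, treated_group="single_ce", seed=5)
        bal = balance_report(mc, eligible).set_index("variable")
        assert bal.loc["followup_duration", "smd"] == pytest.approx(0.0, abs=1e-12)
        for var in ("sex=female", "sex=male", "education_level=hs"):
            assert bal.loc[var, "smd"] == pytest.approx(0.0, abs=1e-12)
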