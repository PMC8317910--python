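"""Generator contracts: determinism, ground-truth oracle, file round trip."""

import math

import numpy as np
import pandas as pd
import pytest

from pehsurv.lifetable import load_standard
from pehsurv.simulate import (
    ConfigError,
    SimulationConfig,
    baseline_segments_from_standard,
    generate_population,
    read_child_recode,
    true_q5,
    write_child_recode,
    WOMEN_SCHEMA,
    CHILDREN_SCHEMA,
)

SINGLE_SEGMENT = ((0.0, 60.0, 0.004),)
ZERO_HAZARD = ((0.0, 60.0, 0.0),)


@pytest.mark.parametrize(
    "override, message",
    [
        ({"education_joint_probs": (0.5, 0.5, 0.1, 0.1)}, "sum to 1"),
        ({"education_joint_probs": (1.5, -0.5, 0.0, 0.0)}, "nonnegative"),
        ({"baseline_hazard_segments": ((0.0, 30.0, 0.001),)}, "60"),
        ({"baseline_hazard_segments": ((0.0, 30.0, 0.001), (35.0, 60.0, 0.001))}, "gap"),
        ({"baseline_hazard_segments": ((0.0, 60.0, -0.001),)}, "nonnegative"),
        ({"fertility_schedule": (0.1,) * 6}, "7"),
        ({"frac_multiple_births": 1.2}, "frac_multiple_births"),
        ({"covariate_effects": {"sex": {"robot": 0.2}}}, "unknown level"),
        ({"covariate_effects": {"shoe_size": {"44": 0.2}}}, "unknown covariate"),
    ],
)
def test_invalid_config_names_violated_invariant(override, message):
    cfg = SimulationConfig(n_women=10, **override)
    with pytest.raises(ConfigError, match=message):
        cfg.validate()


def test_zero_hazard_produces_no_deaths():
    cfg = SimulationConfig(n_women=300, seed=5, baseline_hazard_segments=ZERO_HAZARD)
    _, children = generate_population(cfg)
    assert len(children) > 0
    assert not children["died"].any()
    assert children["aad_months"].isna().all()


def test_same_seed_is_byte_identical_and_seeds_differ():
    cfg = SimulationConfig(n_women=200, seed=42)
    w1, c1 = generate_population(cfg)
    w2, c2 = generate_population(cfg)
    pd.testing.assert_frame_equal(w1, w2)
    pd.testing.assert_frame_equal(c1, c2)
    w3, _ = generate_population(SimulationConfig(n_women=200, seed=43))
    assert not w1["age_group"].equals(w3["age_group"])


def test_true_q5_closed_form_values():
    cfg = SimulationConfig(n_women=10, baseline_hazard_segments=SINGLE_SEGMENT)
    assert true_q5(cfg, peh=4) == pytest.approx(1 - math.exp(-0.24), abs=1e-12)
    cfg2 = SimulationConfig(
        n_women=10,
        baseline_hazard_segments=SINGLE_SEGMENT,
        log_hr_peh=(math.log(1.6), 0.0, 0.0),
    )
    assert true_q5(cfg2, peh=1) == pytest.approx(1 - math.exp(-0.24 * 1.6), abs=1e-12)
    zero = SimulationConfig(n_women=10, baseline_hazard_segments=ZERO_HAZARD)
    assert true_q5(zero, peh=1) == 0.0


def test_true_q5_requires_full_covariate_profile():
    cfg = SimulationConfig(n_women=10, covariate_effects={"toilet": {"unimproved": 0.3}})
    with pytest.raises(ValueError, match="toilet"):
        true_q5(cfg, peh=4)
    with pytest.raises(ValueError, match="unknown level"):
        true_q5(cfg, peh=4, covariate_profile={"toilet": "golden"})
    lo = true_q5(cfg, peh=4, covariate_profile={"toilet": "improved"})
    hi = true_q5(cfg, peh=4, covariate_profile={"toilet": "unimproved"})
    assert hi > lo


def test_empirical_mortality_matches_programmed_ratio():
    """Cohort death fraction by five years tracks the closed-form oracle."""
    cfg = SimulationConfig(
        n_women=6000,
        seed=9,
        baseline_hazard_segments=SINGLE_SEGMENT,
        log_hr_peh=(math.log(1.6), 0.0, 0.0),
        education_joint_probs=(0.5, 0.0, 0.0, 0.5),
    )
    women, children = generate_population(cfg)
    # children with complete five-year exposure before the interview
    full = children.loc[cfg.interview_cmc - children["birth_cmc"] >= 60].copy()
    mother_peh = women.set_index("woman_id")
    wife = mother_peh.reindex(full["woman_id"])["wife_edu"].isin(["none", "primary"])
    husb = mother_peh.reindex(full["woman_id"])["husband_edu"].isin(["none", "primary"])
    died_by_60 = (full["aad_exact"] < 60).fillna(False).to_numpy()
    cat1 = (wife & husb).to_numpy()
    p1, p4 = died_by_60[cat1].mean(), died_by_60[~cat1].mean()
    for p_emp, p_true, n in (
        (p1, true_q5(cfg, 1), cat1.sum()),
        (p4, true_q5(cfg, 4), (~cat1).sum()),
    ):
        se = math.sqrt(p_true * (1 - p_true) / n)
        assert abs(p_emp - p_true) < 3 * se


def test_ceb_counts_consistent_with_children():
    cfg = SimulationConfig(n_women=300, seed=3, frac_multiple_births=0.05)
    women, children = generate_population(cfg)
    counts = children.groupby("woman_id").size()
    deaths = children.groupby("woman_id")["died"].sum()
    for _, w in women.iterrows():
        assert w["ceb"] == counts.get(w["woman_id"], 0)
        assert w["ceb_dead"] == deaths.get(w["woman_id"], 0)
        assert w["ceb_dead"] <= w["ceb"]
    assert (women["weight"] > 0).all()


def test_age_at_death_present_iff_died_and_within_window(small_population):
    _, children = small_population
    assert children["aad_months"].notna().equals(children["died"])
    aad = children["aad_months"].dropna()
    assert ((aad >= 0) & (aad <= 59)).all()


def test_round_trip_is_lossless(tmp_path, small_population):
    women, children = small_population
    write_child_recode(women, children, tmp_path)
    w2, c2 = read_child_recode(tmp_path)
    pd.testing.assert_frame_equal(
        women[WOMEN_SCHEMA].reset_index(drop=True), w2, check_dtype=False
    )
    comparable = children[CHILDREN_SCHEMA].reset_index(drop=True)
    pd.testing.assert_frame_equal(comparable, c2, check_dtype=False)


def test_empty_population_round_trips(tmp_path):
    women = pd.DataFrame(columns=WOMEN_SCHEMA)
    children = pd.DataFrame(columns=CHILDREN_SCHEMA)
    write_child_recode(women, children, tmp_path)
    w2, c2 = read_child_recode(tmp_path)
    assert len(w2) == 0 and len(c2) == 0
    assert list(w2.columns) == WOMEN_SCHEMA
    assert list(c2.columns) == CHILDREN_SCHEMA


def test_invalid_file_rejected_with_named_row(tmp_path, small_population):
    women, children = small_population
    bad = women.copy()
    bad.loc[bad.index[2], "ceb_dead"] = bad.loc[bad.index[2], "ceb"] + 1
    write_child_recode(bad, children, tmp_path)
    with pytest.raises(ValueError, match=str(bad.loc[bad.index[2], "woman_id"])):
        read_child_recode(tmp_path)


def test_hazards_from_standard_reproduce_target_q5():
    std = load_standard("unit_test_exp")
    segs = baseline_segments_from_standard(std, 0.150)
    cfg = SimulationConfig(n_women=10, baseline_hazard_segments=segs)
    assert true_q5(cfg, peh=4) == pytest.approx(0.150, abs=1e-12)
    # and the intermediate survivorships follow the alpha-shifted standard
    total = sum(lam * (e - s) for s, e, lam in segs[:1])
    assert 1 - math.exp(-total) < 0.150
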