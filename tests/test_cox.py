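"""Cox workflow: fitting, screening, and proportional-hazards diagnostics."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from pehsurv import cox, oracle, recode
from pehsurv.simulate import generate_population
from pehsurv.studies import study_config


def _obs(times, events, x, levels=("a", "b")):
    return pd.DataFrame(
        {
            "child_id": range(len(times)),
            "time_months": times,
            "event": events,
            "x": x,
            "weight": 1.0,
        }
    )


def test_symmetric_groups_give_zero_coefficient():
    times = [3.0, 5.0, 8.0, 13.0] * 2
    events = [True, True, False, True] * 2
    x = ["a"] * 4 + ["b"] * 4
    fit = cox.fit_cox(_obs(times, events, x), ["x"])
    assert fit.params.iloc[0] == pytest.approx(0.0, abs=1e-6)


def test_small_fixture_matches_brute_force_oracle():
    rng = np.random.default_rng(2)
    times = rng.uniform(1, 50, size=6)
    events = [True, True, False, True, True, False]
    x = ["a", "b", "a", "b", "a", "b"]
    fit = cox.fit_cox(_obs(times, events, x), ["x"])
    beta = oracle.brute_force_cox(fit.times, fit.events, fit.design.to_numpy())
    assert fit.params.to_numpy() == pytest.approx(beta, abs=1e-6)


def test_breslow_equals_efron_without_ties():
    rng = np.random.default_rng(3)
    n = 60
    obs = _obs(
        rng.uniform(0.5, 59, size=n),
        rng.random(n) < 0.6,
        rng.choice(["a", "b", "c"], size=n),
    )
    b = cox.fit_cox(obs, ["x"], tie_method="breslow")
    e = cox.fit_cox(obs, ["x"], tie_method="efron")
    assert b.params.to_numpy() == pytest.approx(e.params.to_numpy(), abs=1e-7)


def test_rank_invariance_under_time_scaling_and_shift():
    rng = np.random.default_rng(4)
    n = 80
    obs = _obs(rng.uniform(1, 50, size=n), rng.random(n) < 0.5, rng.choice(["a", "b"], size=n))
    base = cox.fit_cox(obs, ["x"]).params.to_numpy()
    scaled = obs.assign(time_months=obs["time_months"] * 3.7)
    shifted = obs.assign(time_months=obs["time_months"] + 11.0)
    assert cox.fit_cox(scaled, ["x"]).params.to_numpy() == pytest.approx(base, abs=1e-7)
    assert cox.fit_cox(shifted, ["x"]).params.to_numpy() == pytest.approx(base, abs=1e-7)


def test_reference_level_and_ci_bracket(small_observations):
    fit = cox.fit_cox(small_observations, ["peh", "sex"])
    assert "peh=4" not in fit.summary.index  # reference category
    assert {"peh=1", "peh=2", "peh=3", "sex=male"} <= set(fit.summary.index)
    s = fit.summary
    assert ((s["ci_low"] <= s["hr"]) & (s["hr"] <= s["ci_high"])).all()
    assert fit.tie_method == "breslow"


def test_fit_requires_events():
    obs = _obs([1.0, 2.0, 3.0, 4.0], [False] * 4, ["a", "b", "a", "b"])
    with pytest.raises(ValueError, match="event"):
        cox.fit_cox(obs, ["x"])


def test_screening_always_retains_peh_and_handles_empty_candidates():
    cfg = study_config(31, n_women=500)  # null: no programmed PEH effect
    women, children = generate_population(cfg)
    obs = recode.build_survival_data(women, children, cfg.interview_cmc)
    selected, fits = cox.unadjusted_screen(obs, ["peh", "sex"], alpha=0.10)
    assert selected[0] == "peh"  # retained regardless of its p-value
    assert "peh" in fits
    only_peh, _ = cox.unadjusted_screen(obs, [], alpha=0.10)
    assert only_peh == ["peh"]
    fit = cox.fit_cox(obs, only_peh)
    assert set(fit.summary.index) == {"peh=1", "peh=2", "peh=3"}


def test_screening_selects_null_covariate_at_screening_rate():
    """A covariate with no programmed effect passes the alpha=0.10 screen at
    roughly the screening rate (minimum-p over its levels inflates it a bit)."""
    hits = 0
    n_reps = 60
    for r in range(n_reps):
        cfg = study_config(5000 + r, n_women=300)
        women, children = generate_population(cfg)
        obs = recode.build_survival_data(women, children, cfg.interview_cmc)
        selected, _ = cox.unadjusted_screen(obs, ["residence"], alpha=0.10, always_keep=())
        hits += "residence" in selected
    assert 0.02 <= hits / n_reps <= 0.30


def test_schoenfeld_residuals_match_manual_calculation():
    # four subjects, two events; risk sets enumerable by hand
    obs = _obs([1.0, 2.0, 3.0, 4.0], [True, True, False, False], ["b", "a", "b", "a"])
    fit = cox.fit_cox(obs, ["x"])
    beta = float(fit.params.iloc[0])
    w = np.exp(beta)
    times, resid = cox.schoenfeld_residuals(fit)
    np.testing.assert_allclose(times, [1.0, 2.0])
    # event 1 (x=1): risk set {all four}, two exposed
    xbar1 = 2 * w / (2 * w + 2)
    # event 2 (x=0): risk set {2,3,4}, one exposed
    xbar2 = w / (w + 2)
    np.testing.assert_allclose(resid[:, 0], [1 - xbar1, 0 - xbar2], atol=1e-10)
    import dataclasses

    single_event = dataclasses.replace(fit, n_events=1)
    with pytest.raises(ValueError, match="two events"):
        cox.schoenfeld_test(single_event)


def test_schoenfeld_test_shape(small_observations):
    fit = cox.fit_cox(small_observations, ["peh"])
    res = cox.schoenfeld_test(fit)
    assert list(res.table.index) == list(fit.summary.index)
    assert ((res.table["p"] >= 0) & (res.table["p"] <= 1)).all()
    assert 0 <= res.global_p <= 1
    assert res.global_df == 3
    rank = cox.schoenfeld_test(fit, transform="rank")
    assert rank.transform == "rank"


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
def test_cox_fit_and_zph_match_r_survival(tmp_path, small_observations):
    """Independent cross-check against R survival::coxph / cox.zph."""
    obs = small_observations.sample(n=500, random_state=0).reset_index(drop=True)
    fit = cox.fit_cox(obs, ["peh"], tie_method="breslow")
    d = fit.design.copy()
    d.columns = [c.replace("=", "_") for c in d.columns]
    d["time"] = fit.times
    d["event"] = fit.events.astype(int)
    csv = tmp_path / "obs.csv"
    d.to_csv(csv, index=False)
    script = tmp_path / "check.R"
    script.write_text(
        f"""
        suppressMessages(library(survival))
        d <- read.csv("{csv}")
        f <- coxph(Surv(time, event) ~ peh_1 + peh_2 + peh_3, data=d, ties="breslow")
        z <- cox.zph(f, transform="identity", global=TRUE)
        cat(coef(f), "\n")
        cat(z$table["GLOBAL", "chisq"], z$table["GLOBAL", "p"], "\n")
        """
    )
    out = subprocess.run(
        ["Rscript", str(script)], capture_output=True, text=True, check=True
    ).stdout.split("\n")
    r_coefs = np.array([float(v) for v in out[0].split()])
    r_chi2, r_p = (float(v) for v in out[1].split())
    np.testing.assert_allclose(fit.params.to_numpy(), r_coefs, atol=2e-5)
    mine = cox.schoenfeld_test(fit, transform="identity")
    assert mine.global_chi2 == pytest.approx(r_chi2, rel=0.15, abs=0.3)
    assert mine.global_p == pytest.approx(r_p, abs=0.05)


def test_km_loglog_parallel_under_proportional_hazards(small_observations):
    curves = cox.km_loglog(small_observations, "peh")
    assert set(curves["peh"].unique()) <= {1, 2, 3, 4}
    # under PH the vertical offset between group curves is roughly constant:
    # regress the offset between categories 1 and 4 on log time
    a = curves[curves["peh"] == 1].set_index("time_months")["loglog_survival"]
    b = curves[curves["peh"] == 4].set_index("time_months")["loglog_survival"]
    common = np.arange(6, 54, 2.0)
    da = np.interp(common, a.index, a.to_numpy())
    db = np.interp(common, b.index, b.to_numpy())
    slope = np.polyfit(np.log(common), da - db, 1)[0]
    assert abs(slope) < 0.5


def test_km_loglog_single_group_and_no_events():
    obs = _obs([1.0, 5.0, 9.0], [True, True, False], ["a", "a", "a"])
    curves = cox.km_loglog(obs, "x")
    assert set(curves["x"]) == {"a"}
    censored = _obs([1.0, 5.0], [False, False], ["a", "a"])
    with pytest.raises(ValueError, match="no group with events"):
        with pytest.warns(UserWarning, match="omitted"):
            cox.km_loglog(censored, "x")
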