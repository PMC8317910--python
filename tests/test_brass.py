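"""Indirect child-mortality estimation from CEB/CD summaries."""

import numpy as np
import pandas as pd
import pytest

from pehsurv import brass
from pehsurv.brass import (
    fit_alpha_and_q5,
    load_trussell_coefficients,
    qx_from_summaries,
    summarize_by_age_group,
    trussell_k,
)
from pehsurv.lifetable import exponential_standard

#: synthetic multipliers: k == 1 everywhere, so q(x) == D(i) exactly and the
#: code path is exercised independently of the shipped reference constants
UNIT_COEFFS = pd.DataFrame(
    {
        "i": range(1, 8),
        "age_x": [1, 2, 3, 5, 10, 15, 20],
        "a": 1.0,
        "b": 0.0,
        "c": 0.0,
    }
).set_index("i")


def _women(rows):
    return pd.DataFrame(rows, columns=["age_group", "ceb", "ceb_dead"])


def test_summary_single_woman():
    s = summarize_by_age_group(_women([("20-24", 2, 1)]))
    assert s.loc[2, "P"] == 2.0
    assert s.loc[2, "D"] == 0.5
    assert not s.loc[1, "usable"]


def test_summary_hand_tally():
    rows = (
        [("15-19", 1, 0)] * 4
        + [("20-24", 2, 1), ("20-24", 2, 0), ("20-24", 0, 0)]
        + [("25-29", 3, 1), ("25-29", 5, 2)]
        + [("30-34", 4, 0), ("30-34", 6, 3), ("45-49", 7, 2)]
    )
    s = summarize_by_age_group(_women(rows))
    assert s.loc[1, "total_ceb"] == 4 and s.loc[1, "total_dead"] == 0
    assert s.loc[2, "P"] == pytest.approx(4 / 3)
    assert s.loc[2, "D"] == pytest.approx(1 / 4)
    assert s.loc[3, "P"] == 4.0 and s.loc[3, "D"] == pytest.approx(3 / 8)
    assert s.loc[4, "D"] == pytest.approx(3 / 10)
    assert s.loc[7, "D"] == pytest.approx(2 / 7)
    with pytest.raises(ValueError):
        summarize_by_age_group(_women([]))


def test_trussell_k_arithmetic():
    coeffs = pd.DataFrame(
        {"i": [1], "age_x": [1], "a": [1.0], "b": [0.1], "c": [-0.2]}
    ).set_index("i")
    assert trussell_k(1, 0.2, 0.5, coeffs) == pytest.approx(0.92, abs=1e-12)
    assert trussell_k(1, 0.2, 0.5, UNIT_COEFFS) == 1.0  # b=c=0 -> a
    # linear in each ratio holding the other fixed
    k1 = trussell_k(1, 0.2, 0.5, coeffs)
    k2 = trussell_k(1, 0.4, 0.5, coeffs)
    k3 = trussell_k(1, 0.6, 0.5, coeffs)
    assert k3 - k2 == pytest.approx(k2 - k1, abs=1e-12)
    with pytest.raises(ValueError, match="positive"):
        trussell_k(1, -0.1, 0.5, coeffs)


def test_qx_from_summaries():
    rows = [("15-19", 1, 0)] * 2 + [("20-24", 2, 0)] * 3 + [("25-29", 4, 1)] * 3
    s = summarize_by_age_group(_women(rows))
    q = qx_from_summaries(s, UNIT_COEFFS)
    assert q[1] == 0.0 and q[2] == 0.0
    assert q[3] == pytest.approx(3 / 12)  # three women with ceb=4, one death each
    assert 5 not in q  # group 30-34 empty -> omitted
    # q(2) = k * D with a hand multiplier
    coeffs = UNIT_COEFFS.copy()
    coeffs.loc[2, "a"] = 1.05
    rows = [("15-19", 1, 0)] * 2 + [("20-24", 25, 2)] + [("25-29", 4, 1)] * 3
    s = summarize_by_age_group(_women(rows))
    q = qx_from_summaries(s, coeffs)
    assert q[2] == pytest.approx(1.05 * 0.08, abs=1e-12)


def test_qx_requires_positive_parities():
    s = summarize_by_age_group(_women([("25-29", 4, 1)]))
    with pytest.raises(ValueError, match="P1, P2, P3"):
        qx_from_summaries(s, UNIT_COEFFS)


def test_alpha_combination_self_consistency():
    std = exponential_standard(0.03)
    qx = {2: std.q(2), 3: std.q(3), 5: std.q(5)}
    est = fit_alpha_and_q5(qx, std, indices_used=(2, 3, 4))
    assert est.alpha == pytest.approx(0.0, abs=1e-12)
    assert est.q5_per_1000 == pytest.approx(1000 * std.q(5), abs=1e-9)
    single = fit_alpha_and_q5({5: 0.2}, std, indices_used=(4,))
    from pehsurv.lifetable import alpha_from_q, q5_from_alpha

    assert single.q5_per_1000 == pytest.approx(
        1000 * q5_from_alpha(alpha_from_q(0.2, 5, std), std), abs=1e-9
    )
    with pytest.raises(ValueError, match="no usable index"):
        fit_alpha_and_q5({2: 0.0}, std, indices_used=(2,))


def test_moving_a_survivor_to_dead_increases_q5():
    rng = np.random.default_rng(7)
    rows = []
    for grp, n in (("15-19", 30), ("20-24", 60), ("25-29", 60), ("30-34", 50)):
        for _ in range(n):
            ceb = int(rng.integers(1, 6))
            rows.append((grp, ceb, int(rng.binomial(ceb, 0.12))))
    women = _women(rows)
    std = exponential_standard(0.03)
    base = fit_alpha_and_q5(
        qx_from_summaries(summarize_by_age_group(women), UNIT_COEFFS), std
    ).q5_per_1000
    bumped = women.copy()
    idx = bumped.index[(bumped["age_group"] == "25-29") & (bumped["ceb_dead"] < bumped["ceb"])][0]
    bumped.loc[idx, "ceb_dead"] += 1
    worse = fit_alpha_and_q5(
        qx_from_summaries(summarize_by_age_group(bumped), UNIT_COEFFS), std
    ).q5_per_1000
    assert worse > base


def test_stratified_estimates_and_empty_stratum_warning():
    rng = np.random.default_rng(11)
    rows = []
    for grp in ("15-19", "20-24", "25-29", "30-34"):
        for _ in range(600):
            ceb = int(rng.integers(1, 5))
            rows.append(
                {
                    "age_group": grp,
                    "ceb": ceb,
                    "ceb_dead": int(rng.binomial(ceb, 0.1)),
                    "peh": int(rng.integers(1, 4)),  # stratum 4 never occurs...
                }
            )
    rows.append({"age_group": "45-49", "ceb": 3, "ceb_dead": 1, "peh": 4})  # ...except here
    women = pd.DataFrame(rows)
    std = exponential_standard(0.03)
    with pytest.warns(UserWarning, match="omitted"):
        ests = brass.estimate_u5m_by_stratum(women, std, stratifier="peh", coeffs=UNIT_COEFFS)
    labels = {e.stratum for e in ests}
    assert labels == {"1", "2", "3"}  # stratum 4 lacks the parity ratios
    # identical generation process -> estimates within coarse agreement
    q5s = [e.q5_per_1000 for e in ests]
    assert max(q5s) - min(q5s) < 80


def test_shipped_coefficients_shape():
    coeffs = load_trussell_coefficients()
    assert list(coeffs.index) == list(range(1, 8))
    assert list(coeffs["age_x"]) == [1, 2, 3, 5, 10, 15, 20]
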