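import dataclasses

import numpy as np
import pandas as pd
import pytest

from correctmem.generate import default_config, simulate_dataset
from correctmem.glmm import (
    SeparationError,
    conditional_models,
    fit_binomial_mixed,
    fit_gaussian_mixed,
    pairwise_contrasts,
)


def _two_level_table(p_by_level, n_participants=50, n_items=50, seed=0, gaussian=False):
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_participants):
        for i in range(n_items):
            level = "A" if i < n_items // 2 else "B"
            mu = p_by_level[level]
            y = rng.normal(mu, 1.0) if gaussian else rng.binomial(1, mu)
            rows.append(
                {"participant_id": p, "topic_id": i, "condition": level, "y": y}
            )
    return pd.DataFrame(rows)


@pytest.fixture(scope="module")
def e1_overall_fit(e1_trials):
    return fit_binomial_mixed(e1_trials, "real_recalled", "condition")


@pytest.fixture(scope="module")
def e1_conditional_fit(e1_trials):
    return conditional_models(e1_trials, "real_recalled")


def test_zero_variance_recovers_pooled_probabilities():
    table = _two_level_table({"A": 0.2, "B": 0.8})
    fit = fit_binomial_mixed(table, "y", "condition")
    assert abs(fit.estimate_for("A") - 0.2) <= 0.03
    assert abs(fit.estimate_for("B") - 0.8) <= 0.03


def test_separation_raises():
    table = _two_level_table({"A": 0.5, "B": 0.5})
    table.loc[table["condition"] == "A", "y"] = 1
    with pytest.raises(SeparationError):
        fit_binomial_mixed(table, "y", "condition")


def test_constant_outcome_raises():
    table = _two_level_table({"A": 0.5, "B": 0.5})
    table["y"] = 0
    with pytest.raises(SeparationError):
        fit_binomial_mixed(table, "y", "condition")


def test_estimates_contract(e1_overall_fit):
    est = e1_overall_fit.estimates
    assert est["estimate"].between(0, 1).all()
    assert (est["ci_low"] <= est["estimate"]).all()
    assert (est["estimate"] <= est["ci_high"]).all()
    assert len(e1_overall_fit.contrasts) == 6  # all pairs of 4 levels
    assert e1_overall_fit.convergence["converged"]


def test_contrast_adjustment_monotone(e1_overall_fit):
    for method in ("tukey", "holm"):
        table = pairwise_contrasts(e1_overall_fit, adjust=method)
        assert (table["p_adj"] >= table["p_raw"] - 1e-15).all()
    none = pairwise_contrasts(e1_overall_fit, adjust="none")
    assert np.allclose(none["p_adj"], none["p_raw"])


def test_identical_levels_give_null_contrast():
    rng = np.random.default_rng(4)
    base = _two_level_table({"A": 0.5, "B": 0.5}, seed=4)
    fit = fit_binomial_mixed(base, "y", "condition")
    row = fit.contrasts.iloc[0]
    assert abs(row["statistic"]) < 2.0
    assert row["p_raw"] > 0.05


def test_reminder_vs_unlabeled_contrast_significant(e1_overall_fit):
    contrasts = e1_overall_fit.contrasts.set_index(["level_a", "level_b"])
    key = ("FRLC", "UC") if ("FRLC", "UC") in contrasts.index else ("UC", "FRLC")
    assert contrasts.loc[key, "p_adj"] < 0.001


def test_gaussian_zero_variance_equals_level_means():
    table = _two_level_table({"A": 3.0, "B": 4.5}, gaussian=True, seed=5)
    fit = fit_gaussian_mixed(table, "y", "condition")
    means = table.groupby("condition")["y"].mean()
    for level in ("A", "B"):
        assert abs(fit.estimate_for(level) - means[level]) < 0.05
    assert fit.convergence["dof_method"].startswith("Satterthwaite")
    assert np.isfinite(fit.contrasts["df"]).all()


def test_gaussian_belief_gap_matches_threshold_expectation():
    cfg = default_config(1)
    means = {
        "REAL_RECALL": {k: 4.8 for k in ["REP", "UC", "LC", "FRLC"]},
        "INTRUSION": {k: 3.0 for k in ["UC", "LC", "FRLC"]},
        "OTHER": dict(cfg.belief_means["OTHER"]),
    }
    cfg = dataclasses.replace(
        cfg, belief_means=means, belief_sd=0.5, belief_sd_participant=0.0, n_participants=64
    )
    trials = simulate_dataset(cfg, design_seed=5)
    from correctmem.coding import code_trials

    coded = code_trials(trials)
    sub = coded[
        (coded["condition"] != "REP")
        & (coded["response_category"].isin(["REAL_RECALL", "INTRUSION"]))
    ]
    fit = fit_gaussian_mixed(sub, "belief_rating", ["condition", "response_category"])
    gaps = []
    for cond in ["UC", "LC", "FRLC"]:
        gaps.append(
            fit.estimate_for(f"{cond}:REAL_RECALL") - fit.estimate_for(f"{cond}:INTRUSION")
        )
    assert abs(np.mean(gaps) - 1.8) <= 0.15


def test_belief_accuracy_direction(e1_coded):
    sub = e1_coded[
        (e1_coded["condition"] != "REP")
        & (e1_coded["response_category"].isin(["REAL_RECALL", "INTRUSION"]))
    ]
    fit = fit_gaussian_mixed(sub, "belief_rating", ["condition", "response_category"])
    for cond in ["UC", "LC", "FRLC"]:
        assert fit.estimate_for(f"{cond}:REAL_RECALL") > fit.estimate_for(f"{cond}:INTRUSION")


def test_conditional_model_structure(e1_conditional_fit):
    levels = set(e1_conditional_fit.estimates["level"])
    assert len(levels) == 9  # 3 conditions x 3 classes at default calibration
    effects = set(e1_conditional_fit.term_tests["effect"])
    assert effects == {"condition", "conditional_class", "condition x conditional_class"}


def test_conditional_recall_ordering(e1_conditional_fit):
    est = e1_conditional_fit.estimates.set_index("level")["estimate"]
    for cond in ["UC", "LC", "FRLC"]:
        assert est[f"{cond}:CORR_FN_RECALLED"] > est[f"{cond}:NOTCORR_FN_NOT_RECALLED"]


def test_conditional_intrusions_exclude_fake_recalled_class(e1_trials):
    fit = conditional_models(e1_trials, "intrusion")
    assert not any("CORR_FN_RECALLED" == lv.split(":")[1] for lv in fit.estimates["level"])


def test_sparse_cells_dropped(e1_trials):
    fit = conditional_models(e1_trials, "real_recalled", min_cell=250)
    assert fit.dropped_cells
    assert len(fit.estimates) < 9


def test_row_order_invariance(e1_trials):
    shuffled = e1_trials.sample(frac=1.0, random_state=11).reset_index(drop=True)
    a = fit_binomial_mixed(e1_trials, "real_recalled", "condition")
    b = fit_binomial_mixed(shuffled, "real_recalled", "condition")
    np.testing.assert_allclose(
        a.estimates["estimate"].to_numpy(), b.estimates["estimate"].to_numpy(), atol=1e-5
    )
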