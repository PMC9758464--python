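import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from correctmem.mpt import (
    SamplerSettings,
    category_probs,
    credible_difference,
    familiarity_vs_others,
    fit_hierarchical,
    loglik,
    moment_estimates,
    recover,
)


def test_category_probs_examples():
    assert category_probs(0.5, 0.4) == (0.5, 0.2, 0.3)
    assert category_probs(1.0, 0.7) == (1.0, 0.0, 0.0)
    assert category_probs(0.0, 1.0) == (0.0, 1.0, 0.0)


def test_category_probs_grid_sums_to_one():
    grid = np.linspace(0, 1, 101)
    for r in grid:
        for f in grid:
            assert abs(sum(category_probs(r, f)) - 1.0) < 1e-12


def test_category_probs_monotonicity():
    grid = np.linspace(0, 1, 101)
    for f in (0.0, 0.3, 0.9):
        p_real = [category_probs(r, f)[0] for r in grid]
        assert all(b >= a for a, b in zip(p_real, p_real[1:]))
    for r in (0.0, 0.4, 0.9):
        p_intr = [category_probs(r, f)[1] for f in grid]
        assert all(b >= a for a, b in zip(p_intr, p_intr[1:]))


def test_category_probs_rejects_out_of_range():
    with pytest.raises(ValueError):
        category_probs(1.2, 0.5)


def test_loglik_examples():
    assert loglik((1, 0, 0), r=1.0, f=0.0) == 0.0
    assert loglik((0, 1, 0), r=1.0, f=0.5) == -math.inf
    expected = 30 * math.log(0.5) + 12 * math.log(0.2) + 18 * math.log(0.3)
    assert abs(loglik((30, 12, 18), r=0.5, f=0.4) - expected) < 1e-12


def test_moment_estimates_examples():
    est = moment_estimates(30, 12, 18)
    assert (est.r, est.f) == (0.5, 0.4)
    est = moment_estimates(0, 0, 60)
    assert (est.r, est.f) == (0.0, 0.0)
    est = moment_estimates(15, 0, 0)
    assert est.r == 1.0 and not est.f_defined


def test_moment_inversion_exhaustive_small_n():
    """category_probs(moment_estimates(c)) * n reproduces every triple, n <= 30."""
    for n in range(1, 31):
        for a in range(n + 1):
            for b in range(n - a + 1):
                c = n - a - b
                est = moment_estimates(a, b, c)
                probs = category_probs(est.r, est.f)
                for count, p in zip((a, b, c), probs):
                    assert abs(p * n - count) < 1e-9


@settings(max_examples=50, deadline=None)
@given(
    r=st.floats(min_value=0, max_value=1, allow_nan=False),
    f=st.floats(min_value=0, max_value=1, allow_nan=False),
)
def test_property_probs_sum_to_one(r, f):
    assert abs(sum(category_probs(r, f)) - 1.0) < 1e-12


def _toy_counts(n_participants=12, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_participants):
        for cond, (r, f) in {"UC": (0.3, 0.3), "LC": (0.45, 0.15), "FRLC": (0.55, 0.15)}.items():
            cats = rng.multinomial(15, category_probs(r, f))
            rows.append(
                {
                    "participant_id": p,
                    "condition": cond,
                    "n_real": cats[0],
                    "n_intrusion": cats[1],
                    "n_other": cats[2],
                }
            )
    return pd.DataFrame(rows)


_FAST = SamplerSettings(chains=2, walkers=16, steps=300, burn=150, seed=9)


def test_fit_deterministic_and_relabel_invariant():
    counts = _toy_counts()
    a = fit_hierarchical(counts, settings=_FAST, check_diagnostics=False)
    b = fit_hierarchical(counts, settings=_FAST, check_diagnostics=False)
    np.testing.assert_array_equal(a.draws_mu_r, b.draws_mu_r)
    shuffled = counts.sample(frac=1.0, random_state=1).reset_index(drop=True)
    c = fit_hierarchical(shuffled, settings=_FAST, check_diagnostics=False)
    np.testing.assert_allclose(a.summary()["mean"], c.summary()["mean"], atol=1e-12)


def test_posterior_contract_single_condition():
    counts = _toy_counts()[lambda d: d["condition"] == "UC"]
    post = fit_hierarchical(counts, settings=_FAST, check_diagnostics=False)
    summ = post.summary()
    assert summ["mean"].between(0, 1).all()
    assert (summ["ci_low"] <= summ["mean"]).all() and (summ["mean"] <= summ["ci_high"]).all()
    assert set(post.diagnostics) >= {"max_rhat", "min_ess"}


def test_credible_difference_contract(e1_posterior):
    mean, (lo, hi), flag = credible_difference(e1_posterior, "r", "UC", "UC")
    assert mean == 0.0 and not flag
    with pytest.raises(ValueError):
        credible_difference(e1_posterior, "r", "UC", "NOPE")
    with pytest.raises(ValueError):
        credible_difference(e1_posterior, "q", "UC", "LC")


def test_recollection_ordering(e1_posterior):
    summ = e1_posterior.summary().set_index(["parameter", "condition"])
    r = summ.loc["r"]["mean"]
    assert r["FRLC"] > r["LC"] > r["UC"]


def test_familiarity_vs_others_matches_draws(e1_posterior):
    mean, (lo, hi), _ = familiarity_vs_others(e1_posterior, "UC")
    assert lo <= mean <= hi
    conds = list(e1_posterior.conditions)
    i = conds.index("UC")
    draws = e1_posterior.draws_f
    manual = draws[:, i] - np.delete(draws, i, axis=1).mean(axis=1)
    assert abs(mean - manual.mean()) < 1e-12


def test_participant_effects_table(e1_posterior, e1_counts):
    eff = e1_posterior.participant_effects
    assert set(["participant_id", "condition", "delta_r", "delta_f"]) <= set(eff.columns)
    assert len(eff) == len(e1_counts)


def test_diagnostics_gate_on_convergent_fit(e1_posterior):
    assert e1_posterior.diagnostics["max_rhat"] <= 1.05


def test_recover_zero_replicates(e1_config):
    report = recover(e1_config, n_replicates=0, seed=1)
    assert report["parameters"] == {}
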