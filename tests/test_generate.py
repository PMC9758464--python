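import dataclasses

import numpy as np
import pandas as pd
import pytest

from correctmem.coding import INTRUSION, code_trials
from correctmem.generate import (
    REQUIRED_COLUMNS,
    GeneratorConfig,
    SchemaError,
    default_config,
    read_trials,
    simulate_dataset,
    write_trials,
)
from correctmem.mpt import category_probs


def test_default_config_exp1_calibration():
    cfg = default_config(1)
    r, f = cfg.r_by_condition, cfg.f_by_condition
    assert r == {"UC": 0.25, "LC": 0.40, "FRLC": 0.51}
    assert abs((r["LC"] - r["UC"]) - 0.15) < 1e-12
    assert abs((r["FRLC"] - r["LC"]) - 0.11) < 1e-12
    assert abs(f["UC"] - (f["LC"] + f["FRLC"]) / 2 - 0.18) < 1e-12
    assert cfg.p_repetition_recall == 0.76


def test_default_config_exp2_calibration():
    cfg = default_config(2)
    r = cfg.r_by_condition
    assert abs((r["LFN"] - r["UC"]) - 0.05) < 1e-12
    # the minimum reminder advantage across both experiments is 0.11
    advantages = [r["FRLC"] - r["UC"], r["FRLC"] - r["LFN"]]
    r1 = default_config(1).r_by_condition
    advantages += [r1["FRLC"] - r1["UC"], r1["FRLC"] - r1["LC"]]
    assert abs(min(advantages) - 0.11) < 1e-12
    assert cfg.p_repetition_recall == 0.70


def test_validate_rejects_bad_configs():
    cfg = default_config(1)
    with pytest.raises(ValueError):
        dataclasses.replace(cfg, p_repetition_recall=1.2).validate()
    with pytest.raises(ValueError):
        dataclasses.replace(cfg, sd_participant=-0.1).validate()
    with pytest.raises(ValueError):
        dataclasses.replace(cfg, belief_cutpoints=(5.5, 4.5, 3.5, 2.5, 1.5)).validate()
    with pytest.raises(ValueError):
        dataclasses.replace(cfg, r_by_condition={"UC": 0.2}).validate()


def test_yaml_round_trip():
    cfg = default_config(2)
    assert GeneratorConfig.from_yaml(cfg.to_yaml()) == cfg


def test_dataset_shape_and_schema(e1_trials, e1_config):
    assert len(e1_trials) == e1_config.n_participants * 60
    assert set(REQUIRED_COLUMNS) <= set(e1_trials.columns)
    per = e1_trials.groupby("participant_id")["condition"].value_counts()
    assert (per == 15).all()


def test_trial_invariants(e1_trials, e2_trials):
    for df in (e1_trials, e2_trials):
        assert ((df["fake_recalled"] == 0) | (df["classified_correction"] == 1)).all()
        rep = df[df["condition"] == "REP"]
        assert (rep["fake_recalled"] == 0).all()
        for col in ["phase1_familiarity", "phase1_belief", "belief_rating"]:
            assert df[col].between(1, 6).all()


def test_degenerate_r_one_all_recalled():
    cfg = default_config(1)
    cfg = dataclasses.replace(
        cfg,
        n_participants=8,
        sd_participant=0.0,
        sd_item=0.0,
        r_by_condition={k: 1.0 for k in cfg.r_by_condition},
    )
    df = simulate_dataset(cfg, design_seed=1)
    corr = df[df["condition"] != "REP"]
    assert (corr["real_recalled"] == 1).all()


def test_degenerate_pure_familiarity_all_intrusions():
    cfg = default_config(1)
    cfg = dataclasses.replace(
        cfg,
        n_participants=8,
        sd_participant=0.0,
        sd_item=0.0,
        r_by_condition={k: 0.0 for k in cfg.r_by_condition},
        f_by_condition={k: 1.0 for k in cfg.f_by_condition},
    )
    df = code_trials(simulate_dataset(cfg, design_seed=1))
    corr = df[df["condition"] != "REP"]
    assert (corr["response_category"] == INTRUSION).all()


def test_zero_variance_frequencies_match_tree():
    """With no random effects, category frequencies converge to the tree."""
    cfg = default_config(1)
    cfg = dataclasses.replace(cfg, n_participants=2000, sd_participant=0.0, sd_item=0.0)
    df = code_trials(simulate_dataset(cfg, design_seed=2))
    corr = df[df["condition"] != "REP"]
    for cond in ["UC", "LC", "FRLC"]:
        sub = corr[corr["condition"] == cond]
        freq = sub["response_category"].value_counts(normalize=True)
        probs = category_probs(cfg.r_by_condition[cond], cfg.f_by_condition[cond])
        for cat, p in zip(["REAL_RECALL", "INTRUSION", "OTHER"], probs):
            assert abs(freq.get(cat, 0.0) - p) <= 0.01


def test_seeded_determinism(e1_config, e1_trials):
    again = simulate_dataset(e1_config, design_seed=7)
    pd.testing.assert_frame_equal(again, e1_trials)


def test_belief_rating_monotone_in_mean():
    cfg = default_config(1)
    means = {k: dict(v) for k, v in cfg.belief_means.items()}
    means["REAL_RECALL"] = {k: v + 1.0 for k, v in means["REAL_RECALL"].items()}
    higher = dataclasses.replace(cfg, belief_means=means, n_participants=48)
    base = simulate_dataset(dataclasses.replace(cfg, n_participants=48), design_seed=3)
    bumped = simulate_dataset(higher, design_seed=3)
    mask = base["real_recalled"] == 1
    assert bumped[mask]["belief_rating"].mean() >= base[mask]["belief_rating"].mean()


def test_csv_round_trip(tmp_path, e1_trials):
    path = tmp_path / "trials.csv"
    write_trials(e1_trials, path)
    back = read_trials(path)
    pd.testing.assert_frame_equal(
        back[e1_trials.columns].reset_index(drop=True), e1_trials.reset_index(drop=True)
    )


def test_schema_rejects_out_of_range_rating(tmp_path, e1_trials):
    bad = e1_trials.copy()
    bad.loc[bad.index[3], "belief_rating"] = 7
    path = tmp_path / "bad.csv"
    bad.to_csv(path, index=False)
    with pytest.raises(SchemaError):
        read_trials(path)


def test_schema_rejects_fake_recall_without_classification(tmp_path, e1_trials):
    bad = e1_trials.copy()
    ix = bad[bad["condition"] != "REP"].index[0]
    bad.loc[ix, "fake_recalled"] = 1
    bad.loc[ix, "classified_correction"] = 0
    path = tmp_path / "bad.csv"
    bad.to_csv(path, index=False)
    with pytest.raises(SchemaError):
        read_trials(path)


def test_schema_rejects_missing_column(tmp_path, e1_trials):
    path = tmp_path / "bad.csv"
    e1_trials.drop(columns=["belief_rating"]).to_csv(path, index=False)
    with pytest.raises(SchemaError):
        read_trials(path)


def test_exp2_labeled_fake_lowers_phase1_belief(e2_trials):
    lfn = e2_trials[e2_trials["condition"] == "LFN"]["phase1_belief"].mean()
    uc = e2_trials[e2_trials["condition"] == "UC"]["phase1_belief"].mean()
    assert lfn < uc - 0.5
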