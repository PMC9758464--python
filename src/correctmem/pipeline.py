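"""End-to-end pipeline: simulate, code, fit, and emit tables and summaries.

``run_pipeline`` executes the analysis stages in the order of the result
narrative — overall recall, intrusions, fake-news recall, conditional models,
the hierarchical MPT, belief models, conditional belief models — writing one
CSV/JSON artifact per stage plus a manifest that links them and records
provenance (config hash, seeds, library versions). Stage failures are
recorded in the manifest and do not stop later, independent stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .coding import INTRUSION, REAL_RECALL, code_trials, tabulate_mpt
from .design import Condition, correction_conditions
from .generate import GeneratorConfig, default_config, simulate_dataset
from .glmm import ModelEstimates, conditional_models, fit_binomial_mixed, fit_gaussian_mixed
from .mpt import SamplerSettings, credible_difference, familiarity_vs_others, fit_hierarchical

logger = logging.getLogger(__name__)

STAGES = [
    "overall_recall",
    "intrusions",
    "fake_recall",
    "conditional",
    "mpt",
    "beliefs",
    "conditional_beliefs",
]


@dataclass
class PipelineResult:
    """Everything one pipeline run produced, in memory."""

    experiment: int
    design_summary: dict
    dataset_digest: dict
    trials: pd.DataFrame
    models: dict = field(default_factory=dict)  # stage -> ModelEstimates (or dict for conditional)
    mpt_summary: pd.DataFrame | None = None
    mpt_differences: pd.DataFrame | None = None
    recovery: dict | None = None
    provenance: dict = field(default_factory=dict)
    errors: dict = field(default_factory=dict)  # stage -> message


def _config_hash(config: GeneratorConfig) -> str:
    return hashlib.sha256(config.to_yaml().encode()).hexdigest()[:16]


def _frame_digest(df: pd.DataFrame) -> str:
    return hashlib.sha256(df.to_csv(index=False).encode()).hexdigest()


def derive_seeds(seed: int) -> dict:
    """Deterministic per-stage seeds (< 2^31) from one master seed."""
    children = np.random.SeedSequence(entropy=seed).spawn(3)
    names = ["data", "design", "sampler"]
    return {
        name: int(child.generate_state(1, dtype=np.uint64)[0] % (2**31))
        for name, child in zip(names, children)
    }


def _dataset_digest(trials: pd.DataFrame) -> dict:
    return {
        "n_rows": int(len(trials)),
        "n_participants": int(trials["participant_id"].nunique()),
        "condition_counts": {
            str(k): int(v) for k, v in trials["condition"].value_counts().sort_index().items()
        },
        "sha256": _frame_digest(trials),
    }


def _estimates_artifact(fit: ModelEstimates) -> dict:
    return {
        "outcome": fit.outcome,
        "scale": fit.scale,
        "adjustment": fit.adjustment,
        "estimates": fit.estimates.to_dict("records"),
        "contrasts": fit.contrasts.to_dict("records"),
        "term_tests": fit.term_tests.to_dict("records") if fit.term_tests is not None else [],
        "dropped_cells": fit.dropped_cells,
        "convergence": fit.convergence,
    }


def _mpt_differences(post, experiment: int) -> pd.DataFrame:
    """Headline posterior differences: all-pairs recollection + familiarity-vs-others."""
    rows = []
    conds = post.conditions
    for i in range(len(conds)):
        for j in range(len(conds)):
            if i == j:
                continue
            a, b = conds[i], conds[j]
            mean, (lo, hi), cred = credible_difference(post, "r", a, b)
            rows.append(
                {
                    "parameter": "r",
                    "contrast": f"{a} - {b}",
                    "mean": mean,
                    "ci_low": lo,
                    "ci_high": hi,
                    "credible": cred,
                }
            )
    for cond in conds:
        mean, (lo, hi), cred = familiarity_vs_others(post, cond)
        rows.append(
            {
                "parameter": "f",
                "contrast": f"{cond} - mean(others)",
                "mean": mean,
                "ci_low": lo,
                "ci_high": hi,
                "credible": cred,
            }
        )
    out = pd.DataFrame(rows)
    out.insert(0, "experiment", experiment)
    return out


def run_pipeline(
    experiment: int,
    config: GeneratorConfig | str | Path | None = None,
    seed: int = 0,
    out_dir: str | Path = "pipeline_out",
    sampler_settings: SamplerSettings | None = None,
) -> PipelineResult:
    """Run every stage for one experiment and write artifacts plus a manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if config is None:
        config = default_config(experiment)
    elif not isinstance(config, GeneratorConfig):
        config = GeneratorConfig.from_yaml(Path(config).read_text())
    seeds = derive_seeds(seed)
    config = dataclasses.replace(config, seed=seeds["data"])
    settings = sampler_settings or SamplerSettings(seed=seeds["sampler"])

    t0 = time.time()
    trials = simulate_dataset(config, design_seed=seeds["design"])
    trials = code_trials(trials)
    logger.info(
        "simulated experiment %d: %d trials in %.1fs (seed=%d)",
        experiment,
        len(trials),
        time.time() - t0,
        seed,
    )
    corr = trials[trials["condition"] != Condition.REPETITION.value].copy()
    corr["intrusion"] = (corr["response_category"] == INTRUSION).astype(int)
    corr["fake_recalled_bin"] = corr["fake_recalled"].astype(int)

    result = PipelineResult(
        experiment=experiment,
        design_summary={
            "n_topics": 60,
            "n_conditions": 4,
            "conditions": [c.value for c in Condition if c.value in set(trials["condition"])],
            "counterbalance_lists": 4,
        },
        dataset_digest=_dataset_digest(trials),
        trials=trials,
        provenance={
            "package_version": __version__,
            "experiment": experiment,
            "seed": seed,
            "derived_seeds": seeds,
            "config_hash": _config_hash(config),
            "sampler": dataclasses.asdict(settings),
            "versions": {
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
        },
    )

    manifest = {"stages": {}, "provenance": result.provenance}
    trials_path = out_dir / "trials.csv"
    trials.to_csv(trials_path, index=False)
    manifest["dataset"] = {"path": trials_path.name, **result.dataset_digest}

    def stage(name, fn):
        t = time.time()
        try:
            path = fn()
            manifest["stages"][name] = {
                "status": "ok",
                "path": path.name,
                "seconds": round(time.time() - t, 2),
            }
            logger.info("stage %s ok in %.1fs", name, time.time() - t)
        except Exception as exc:  # noqa: BLE001 - stage isolation is the contract
            result.errors[name] = f"{type(exc).__name__}: {exc}"
            manifest["stages"][name] = {"status": "error", "message": result.errors[name]}
            logger.warning("stage %s failed: %s", name, result.errors[name])

    def _write_model(name, fit):
        result.models[name] = fit
        path = out_dir / f"{name}.json"
        path.write_text(json.dumps(_estimates_artifact(fit), indent=1, default=str))
        return path

    stage(
        "overall_recall",
        lambda: _write_model(
            "overall_recall", fit_binomial_mixed(trials, "real_recalled", "condition")
        ),
    )
    stage(
        "intrusions",
        lambda: _write_model("intrusions", fit_binomial_mixed(corr, "intrusion", "condition")),
    )
    stage(
        "fake_recall",
        lambda: _write_model(
            "fake_recall", fit_binomial_mixed(corr, "fake_recalled_bin", "condition")
        ),
    )

    def _conditional():
        result.models["conditional_recall"] = conditional_models(trials, "real_recalled")
        result.models["conditional_intrusions"] = conditional_models(trials, "intrusion")
        path = out_dir / "conditional.json"
        path.write_text(
            json.dumps(
                {
                    "real_recalled": _estimates_artifact(result.models["conditional_recall"]),
                    "intrusion": _estimates_artifact(result.models["conditional_intrusions"]),
                },
                indent=1,
                default=str,
            )
        )
        return path

    stage("conditional", _conditional)

    def _mpt():
        counts = tabulate_mpt(trials)
        post = fit_hierarchical(counts, correction_conditions(experiment), settings)
        result.models["mpt_posterior"] = post
        result.mpt_summary = post.summary()
        result.mpt_differences = _mpt_differences(post, experiment)
        result.mpt_summary.to_csv(out_dir / "mpt_summary.csv", index=False)
        result.mpt_differences.to_csv(out_dir / "mpt_differences.csv", index=False)
        path = out_dir / "mpt.json"
        path.write_text(
            json.dumps(
                {
                    "summary": result.mpt_summary.to_dict("records"),
                    "differences": result.mpt_differences.to_dict("records"),
                    "diagnostics": post.diagnostics,
                },
                indent=1,
                default=str,
            )
        )
        return path

    stage("mpt", _mpt)

    def _beliefs():
        sub = corr[corr["response_category"].isin([REAL_RECALL, INTRUSION])]
        fit = fit_gaussian_mixed(sub, "belief_rating", ["condition", "response_category"])
        return _write_model("beliefs", fit)

    stage("beliefs", _beliefs)

    def _conditional_beliefs():
        sub = corr[corr["response_category"].isin([REAL_RECALL, INTRUSION])].copy()
        sizes = sub.groupby(
            ["condition", "response_category", "conditional_class"], observed=True
        ).size()
        keep = sizes[sizes >= 5].index
        sub = sub[
            sub.set_index(["condition", "response_category", "conditional_class"]).index.isin(keep)
        ]
        sub["class_by_response"] = (
            sub["response_category"].astype(str) + "|" + sub["conditional_class"].astype(str)
        )
        fit = fit_gaussian_mixed(sub, "belief_rating", ["condition", "class_by_response"])
        fit.dropped_cells = [
            ":".join(map(str, ix)) for ix in sizes[sizes < 5].index
        ]
        return _write_model("conditional_beliefs", fit)

    stage("conditional_beliefs", _conditional_beliefs)

    manifest_path = out_dir / "manifest.json"
    manifest["errors"] = result.errors
    manifest_path.write_text(json.dumps(manifest, indent=1, default=str))
    return result


# ---------------------------------------------------------------------------
# Tables and figure summaries

_TABLE1_STAGES = [
    ("Overall real news recall", "overall_recall"),
    ("Intrusions of fake news", "intrusions"),
    ("Fake news recall", "fake_recall"),
    ("Conditional real news recall", "conditional_recall"),
    ("Conditional intrusions", "conditional_intrusions"),
]
_TABLE2_STAGES = [
    ("Beliefs by response", "beliefs"),
    ("Beliefs by response and classification", "conditional_beliefs"),
]
_TABLE_COLUMNS = ["analysis", "effect", "statistic", "df", "p"]


def _table_rows(result: PipelineResult | None, stages) -> pd.DataFrame:
    rows = []
    for label, key in stages:
        fit = result.models.get(key) if result is not None else None
        if fit is None or fit.term_tests is None or fit.term_tests.empty:
            rows.append(
                {"analysis": label, "effect": None, "statistic": None, "df": None, "p": None}
            )
            continue
        for rec in fit.term_tests.to_dict("records"):
            rows.append({"analysis": label, **{k: rec[k] for k in ["effect", "statistic", "df", "p"]}})
    return pd.DataFrame(rows, columns=_TABLE_COLUMNS)


def make_tables(result: PipelineResult | None) -> dict[str, pd.DataFrame]:
    """Model-results tables: recall/intrusion/fake-recall and belief analyses.

    Rows are (analysis, effect, statistic, df, p); analyses whose model is
    missing yield a single all-NA row so the table structure is stable.
    """
    return {
        "table1": _table_rows(result, _TABLE1_STAGES),
        "table2": _table_rows(result, _TABLE2_STAGES),
    }


def _figure_frame(fit: ModelEstimates, family: str, exclude=None) -> pd.DataFrame:
    est = fit.estimates.copy()
    if exclude is not None:
        est = est[~est["level"].map(exclude)]
    total = est["n_obs"].sum()
    out = est.rename(columns={"n_obs": "cell_n"})[
        ["level", "estimate", "ci_low", "ci_high", "cell_n"]
    ].copy()
    out["cell_prop"] = out["cell_n"] / total if total else 0.0
    out["sparse"] = out["cell_n"] < 20
    out.insert(0, "family", family)
    return out


def summarize_figures(result: PipelineResult) -> dict[str, pd.DataFrame]:
    """Tidy per-figure CSDataFrames: level, estimate, interval, cell sizes.

    Within each conditioning family the cell proportions sum to 1; the
    conditional-intrusion family omits accurately-classified-with-fake-recall
    cells, where intrusions are not defined.
    """
    figs: dict[str, pd.DataFrame] = {}

    def get(key):
        return result.models.get(key)

    fig2_parts = []
    for key, family in [
        ("overall_recall", "real_recall"),
        ("intrusions", "intrusion"),
        ("fake_recall", "fake_recall"),
    ]:
        fit = get(key)
        if fit is not None:
            est = fit
            if key == "overall_recall":
                # figure family covers the correction conditions
                est = ModelEstimates(
                    outcome=fit.outcome,
                    scale=fit.scale,
                    estimates=fit.estimates[
                        fit.estimates["level"] != Condition.REPETITION.value
                    ].reset_index(drop=True),
                    contrasts=fit.contrasts,
                    adjustment=fit.adjustment,
                )
            fig2_parts.append(_figure_frame(est, family))
    if fig2_parts:
        figs["fig2"] = pd.concat(fig2_parts, ignore_index=True)

    fig3_parts = []
    if get("conditional_recall") is not None:
        fig3_parts.append(_figure_frame(get("conditional_recall"), "conditional_recall"))
    if get("conditional_intrusions") is not None:
        fig3_parts.append(
            _figure_frame(
                get("conditional_intrusions"),
                "conditional_intrusion",
                exclude=lambda lv: "CORR_FN_RECALLED" in lv and "NOTCORR" not in lv,
            )
        )
    if fig3_parts:
        figs["fig3"] = pd.concat(fig3_parts, ignore_index=True)

    if result.mpt_summary is not None:
        counts = tabulate_mpt(result.trials)
        n_by_cond = counts.groupby("condition")[["n_real", "n_intrusion", "n_other"]].sum().sum(
            axis=1
        )
        mp = result.mpt_summary.copy()
        mp["level"] = mp["condition"]
        mp["estimate"] = mp["mean"]
        mp["cell_n"] = mp["condition"].map(n_by_cond).astype(int)
        parts = []
        for param in ["r", "f"]:
            sub = mp[mp["parameter"] == param][
                ["level", "estimate", "ci_low", "ci_high", "cell_n"]
            ].copy()
            sub["cell_prop"] = sub["cell_n"] / sub["cell_n"].sum()
            sub["sparse"] = sub["cell_n"] < 20
            sub.insert(0, "family", f"mpt_{param}")
            parts.append(sub)
        figs["fig4"] = pd.concat(parts, ignore_index=True)

    if get("beliefs") is not None:
        figs["fig5"] = _figure_frame(get("beliefs"), "beliefs")
    if get("conditional_beliefs") is not None:
        figs["fig6"] = _figure_frame(get("conditional_beliefs"), "conditional_beliefs")
    return figs


def write_report(result: PipelineResult, out_dir: str | Path) -> list[Path]:
    """Write the tables and figure summaries of a pipeline result as CSVs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in make_tables(result).items():
        path = out_dir / f"{name}.csv"
        df.to_csv(path, index=False)
        written.append(path)
    for name, df in summarize_figures(result).items():
        path = out_dir / f"{name}.csv"
        df.to_csv(path, index=False)
        written.append(path)
    return written
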