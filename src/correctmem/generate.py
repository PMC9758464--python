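"""Generative model of trial-level data for the three-phase headline paradigm.

The generator is the study's dual-process assumption run forward. On each
correction trial a recollection indicator fires with probability
``invlogit(logit(r_c) + u_p + w_i)`` — ``r_c`` the condition's latent
recollection probability for a typical participant and item, ``u_p`` and
``w_i`` participant and item intercepts on the logit scale. Recollection
yields correct real-news recall; absent recollection, a familiarity indicator
(condition parameter ``f_c``) yields an intrusion of the fake detail;
otherwise the response is coded OTHER. Correction classification and fake-news
recall follow as Bernoulli stages conditioned on that path, and belief ratings
come from a latent Gaussian thresholded onto the 1-6 scale.

Calibration targets the conditional (random-effects-at-zero) probability so
that a mixed model's inverse-link fixed-effect estimate, and the hierarchical
tree model's group-level location, recover the generating value directly.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .design import (
    Condition,
    DesignList,
    build_design,
    correction_conditions,
)

RATING_MIN, RATING_MAX = 1, 6

#: CSV columns in canonical order. ``fake_produced`` and ``response_category``
#: are generator-side extras (intrusions require knowing whether the fake
#: detail was produced; on scored real data the category column is precoded).
REQUIRED_COLUMNS = [
    "participant_id",
    "topic_id",
    "experiment",
    "condition",
    "phase1_familiarity",
    "phase1_belief",
    "real_recalled",
    "belief_rating",
    "classified_correction",
    "fake_recalled",
]
OPTIONAL_COLUMNS = ["fake_produced", "response_category"]


class SchemaError(ValueError):
    """Raised when a trial table violates the trial-record schema."""


@dataclass
class GeneratorConfig:
    """Calibration of the generative model for one experiment.

    Probabilities are conditional values at participant/item effects of zero;
    ``sd_participant`` and ``sd_item`` are logit-scale random-intercept SDs.
    Belief parameters live on the latent rating scale cut at
    ``belief_cutpoints`` to produce 1-6 ratings.
    """

    experiment: int
    n_participants: int = 96
    r_by_condition: dict[str, float] = field(default_factory=dict)
    f_by_condition: dict[str, float] = field(default_factory=dict)
    p_repetition_recall: float = 0.76
    sd_participant: float = 0.8
    sd_item: float = 0.5
    p_classify_given_recollect: float = 0.9
    p_classify_given_no_recollect: float = 0.2
    p_fakerecall_given_classified: dict[str, float] = field(default_factory=dict)
    belief_means: dict[str, dict[str, float]] = field(default_factory=dict)
    belief_sd: float = 1.0
    belief_sd_participant: float = 0.3
    belief_cutpoints: tuple[float, ...] = (1.5, 2.5, 3.5, 4.5, 5.5)
    phase1_belief_means: dict[str, float] = field(default_factory=dict)
    phase1_familiarity_means: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        probs = [
            self.p_repetition_recall,
            self.p_classify_given_recollect,
            self.p_classify_given_no_recollect,
            *self.r_by_condition.values(),
            *self.f_by_condition.values(),
            *self.p_fakerecall_given_classified.values(),
        ]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if self.sd_participant < 0 or self.sd_item < 0 or self.belief_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        cuts = np.asarray(self.belief_cutpoints, dtype=float)
        if len(cuts) != RATING_MAX - 1 or not np.all(np.diff(cuts) > 0):
            raise ValueError("belief_cutpoints must be 5 strictly increasing thresholds")
        expected = {c.value for c in correction_conditions(self.experiment)}
        for name, d in (("r_by_condition", self.r_by_condition),
                        ("f_by_condition", self.f_by_condition)):
            if set(d) != expected:
                raise ValueError(
                    f"{name} must have entries for exactly {sorted(expected)}, got {sorted(d)}"
                )

    def to_yaml(self) -> str:
        d = asdict(self)
        d["belief_cutpoints"] = list(self.belief_cutpoints)
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "GeneratorConfig":
        d = yaml.safe_load(text)
        d["belief_cutpoints"] = tuple(d["belief_cutpoints"])
        return cls(**d)


def default_config(experiment: int) -> GeneratorConfig:
    """Documented default calibration for either experiment.

    Condition differences in the latent recollection and familiarity
    parameters equal the published difference estimates; the absolute anchors
    (e.g. unlabeled-correction recollection 0.25 in Experiment 1) are design
    choices respecting the qualitative ordering of recall and intrusion rates.
    """
    if experiment == 1:
        r = {"UC": 0.25, "LC": 0.40, "FRLC": 0.51}
        f = {"UC": 0.30, "LC": 0.12, "FRLC": 0.12}
        p_rep = 0.76
        p_fr = {"UC": 0.35, "LC": 0.50, "FRLC": 0.75}
        belief = {
            "REAL_RECALL": {"REP": 4.8, "UC": 4.4, "LC": 4.6, "FRLC": 4.8},
            "INTRUSION": {"UC": 3.4, "LC": 2.9, "FRLC": 2.8},
            "OTHER": {"REP": 3.5, "UC": 3.5, "LC": 3.5, "FRLC": 3.5},
        }
        phase1_belief = {"real": 4.2, "fake_unlabeled": 3.4, "fake_labeled": 3.4}
    elif experiment == 2:
        r = {"UC": 0.28, "LFN": 0.33, "FRLC": 0.51}
        f = {"UC": 0.15, "LFN": 0.12, "FRLC": 0.12}
        p_rep = 0.70
        p_fr = {"UC": 0.35, "LFN": 0.50, "FRLC": 0.75}
        belief = {
            "REAL_RECALL": {"REP": 4.7, "UC": 4.6, "LFN": 4.6, "FRLC": 4.7},
            "INTRUSION": {"UC": 3.4, "LFN": 2.6, "FRLC": 2.9},
            "OTHER": {"REP": 3.5, "UC": 3.5, "LFN": 3.5, "FRLC": 3.5},
        }
        phase1_belief = {"real": 4.2, "fake_unlabeled": 3.4, "fake_labeled": 2.0}
    else:
        raise ValueError(f"experiment must be 1 or 2, got {experiment!r}")
    return GeneratorConfig(
        experiment=experiment,
        r_by_condition=r,
        f_by_condition=f,
        p_repetition_recall=p_rep,
        p_fakerecall_given_classified=p_fr,
        belief_means=belief,
        phase1_belief_means=phase1_belief,
        phase1_familiarity_means={"real": 3.8, "fake_unlabeled": 3.2, "fake_labeled": 3.2},
    )


def _invlogit(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def _logit(p: float) -> float:
    if p <= 0.0:
        return -np.inf
    if p >= 1.0:
        return np.inf
    return float(np.log(p / (1.0 - p)))


def _threshold(latent: np.ndarray, cutpoints) -> np.ndarray:
    return 1 + np.searchsorted(np.asarray(cutpoints, dtype=float), latent)


def simulate_dataset(config: GeneratorConfig, design_seed: int) -> pd.DataFrame:
    """Simulate one experiment: n_participants x 60 long-format trial rows.

    Participants rotate through the four counterbalance lists
    (participant p gets list p mod 4). Deterministic given config.seed and
    design_seed.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed))
    designs = [build_design(config.experiment, cb, design_seed) for cb in range(4)]

    n_topics = len(designs[0].topic_ids)
    w_item = rng.normal(0.0, config.sd_item, size=n_topics)  # indexed topic_id-1
    u_part = rng.normal(0.0, config.sd_participant, size=config.n_participants)
    u_belief = rng.normal(0.0, config.belief_sd_participant, size=config.n_participants)

    rows: list[dict] = []
    for p in range(config.n_participants):
        design: DesignList = designs[p % 4]
        for t in design.topic_ids:
            cond = design.condition_of[t]
            eta = u_part[p] + w_item[t - 1]
            rec = intr = 0
            classified = fake_rec = 0
            if cond is Condition.REPETITION:
                real = int(rng.random() < _invlogit(_logit(config.p_repetition_recall) + eta))
                category = "REAL_RECALL" if real else "OTHER"
            else:
                c = cond.value
                rec = int(rng.random() < _invlogit(_logit(config.r_by_condition[c]) + eta))
                if rec:
                    real = 1
                    category = "REAL_RECALL"
                    classified = int(rng.random() < config.p_classify_given_recollect)
                else:
                    real = 0
                    fam = int(rng.random() < _invlogit(_logit(config.f_by_condition[c]) + eta))
                    intr = fam
                    category = "INTRUSION" if fam else "OTHER"
                    classified = int(rng.random() < config.p_classify_given_no_recollect)
                if classified:
                    fake_rec = int(rng.random() < config.p_fakerecall_given_classified[c])

            mu = config.belief_means[category][cond.value]
            latent = rng.normal(mu + u_belief[p], config.belief_sd)
            belief = int(_threshold(latent, config.belief_cutpoints))

            veracity = design.phase1_veracity[t]
            if veracity == "real":
                key = "real"
            elif cond is Condition.LABELED_FAKE:
                key = "fake_labeled"
            else:
                key = "fake_unlabeled"
            p1_belief = int(_threshold(
                rng.normal(config.phase1_belief_means[key] + u_belief[p], config.belief_sd),
                config.belief_cutpoints,
            ))
            p1_fam = int(_threshold(
                rng.normal(config.phase1_familiarity_means[key] + u_belief[p], config.belief_sd),
                config.belief_cutpoints,
            ))

            rows.append(
                {
                    "participant_id": p + 1,
                    "topic_id": t,
                    "experiment": config.experiment,
                    "condition": cond.value,
                    "phase1_familiarity": p1_fam,
                    "phase1_belief": p1_belief,
                    "real_recalled": real,
                    "belief_rating": belief,
                    "classified_correction": classified,
                    "fake_recalled": fake_rec,
                    "fake_produced": intr,
                    "response_category": category,
                }
            )
    return pd.DataFrame(rows)


def _check_schema(df: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing columns: {missing}")
    for col in ("phase1_familiarity", "phase1_belief", "belief_rating"):
        bad = df.index[(df[col] < RATING_MIN) | (df[col] > RATING_MAX)]
        if len(bad):
            raise SchemaError(f"{col} out of range 1-6 at row {bad[0]}")
    bad = df.index[(df["fake_recalled"] == 1) & (df["classified_correction"] == 0)]
    if len(bad):
        raise SchemaError(
            f"fake_recalled=1 without classified_correction=1 at row {bad[0]}"
        )
    bad = df.index[(df["condition"] == Condition.REPETITION.value) & (df["fake_recalled"] == 1)]
    if len(bad):
        raise SchemaError(f"fake_recalled=1 on a repetition trial at row {bad[0]}")
    valid_conditions = {c.value for c in Condition}
    bad_cond = set(df["condition"]) - valid_conditions
    if bad_cond:
        raise SchemaError(f"unknown condition codes: {sorted(bad_cond)}")


def write_trials(df: pd.DataFrame, path) -> None:
    """Write a trial table to CSV after validating the schema."""
    _check_schema(df)
    cols = REQUIRED_COLUMNS + [c for c in OPTIONAL_COLUMNS if c in df.columns]
    df[cols].to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    """Read and validate a trial-table CSV.

    Accepts the optional precoded ``response_category`` column so that scored
    exports of real data (where intrusion status comes from human scoring of
    recall text) can enter the pipeline.
    """
    if isinstance(path, (str, bytes)) or hasattr(path, "__fspath__") or isinstance(path, io.IOBase):
        df = pd.read_csv(path)
    else:
        df = pd.read_csv(path)
    _check_schema(df)
    int_cols = [
        "participant_id", "topic_id", "experiment", "phase1_familiarity",
        "phase1_belief", "real_recalled", "belief_rating",
        "classified_correction", "fake_recalled",
    ] + [c for c in ("fake_produced",) if c in df.columns]
    df[int_cols] = df[int_cols].astype(int)
    return df
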