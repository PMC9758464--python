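"""Counterbalanced list construction for the three-phase headline paradigm.

Each experiment presents 60 news topics to every participant. The topics are
split into four fixed sets of 15 and rotated through the four within-participant
headline-type conditions by a Latin square over the counterbalance index, so
that across the four lists every topic serves every condition exactly once.
Presentation orders for the three phases are random permutations subject to two
constraints used to neutralize serial-position confounds:

* no more than three consecutive topics from the same condition, and
* each condition's mean list position within two positions of the grand mean.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

N_TOPICS = 60
SET_SIZE = 15
N_SETS = 4
MAX_RUN = 3
POSITION_TOL = 2.0
MAX_RESTARTS = 10_000


class Condition(str, Enum):
    """Headline-type condition of a topic within one counterbalance list."""

    REPETITION = "REP"
    UNLABELED_CORRECTION = "UC"
    LABELED_CORRECTION = "LC"
    LABELED_FAKE = "LFN"
    REMINDER_LABELED_CORRECTION = "FRLC"

    @property
    def is_correction(self) -> bool:
        return self is not Condition.REPETITION


def conditions_for_experiment(experiment: int) -> list[Condition]:
    """The four headline types of an experiment, in canonical order.

    Experiment 1 contrasts labeled vs unlabeled corrections; Experiment 2
    replaces the labeled-correction condition with fake news labeled on its
    debut.
    """
    if experiment == 1:
        return [
            Condition.REPETITION,
            Condition.UNLABELED_CORRECTION,
            Condition.LABELED_CORRECTION,
            Condition.REMINDER_LABELED_CORRECTION,
        ]
    if experiment == 2:
        return [
            Condition.REPETITION,
            Condition.UNLABELED_CORRECTION,
            Condition.LABELED_FAKE,
            Condition.REMINDER_LABELED_CORRECTION,
        ]
    raise ValueError(f"experiment must be 1 or 2, got {experiment!r}")


def correction_conditions(experiment: int) -> list[Condition]:
    """The three non-repetition conditions of an experiment."""
    return [c for c in conditions_for_experiment(experiment) if c.is_correction]


@dataclass
class DesignList:
    """One counterbalance list: topic-condition assignment plus phase orders.

    ``phaseN_order`` holds topic ids in presentation order; position ``k``
    (1-based) of a topic is ``order.index(topic) + 1``. Phase-1 veracity is
    ``real`` for repetition topics (true headlines repeated verbatim in
    Phase 2) and ``fake`` for all correction topics.
    """

    experiment: int
    counterbalance_index: int
    topic_ids: list[int]
    condition_of: dict[int, Condition]
    phase1_order: list[int]
    phase2_order: list[int]
    phase3_order: list[int]
    phase1_veracity: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.phase1_veracity:
            self.phase1_veracity = {
                t: "real" if self.condition_of[t] is Condition.REPETITION else "fake"
                for t in self.topic_ids
            }

    def orders(self) -> dict[int, list[int]]:
        return {1: self.phase1_order, 2: self.phase2_order, 3: self.phase3_order}

    def to_json(self) -> str:
        payload = {
            "experiment": self.experiment,
            "counterbalance_index": self.counterbalance_index,
            "topics": self.topic_ids,
            "conditions": {str(t): c.value for t, c in self.condition_of.items()},
            "orders": {str(k): v for k, v in self.orders().items()},
            "phase1_veracity": {str(t): v for t, v in self.phase1_veracity.items()},
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "DesignList":
        d = json.loads(text)
        return cls(
            experiment=d["experiment"],
            counterbalance_index=d["counterbalance_index"],
            topic_ids=list(d["topics"]),
            condition_of={int(t): Condition(c) for t, c in d["conditions"].items()},
            phase1_order=list(d["orders"]["1"]),
            phase2_order=list(d["orders"]["2"]),
            phase3_order=list(d["orders"]["3"]),
            phase1_veracity={int(t): v for t, v in d["phase1_veracity"].items()},
        )

    def to_frame(self) -> pd.DataFrame:
        """Tidy one-row-per-topic view (positions are 1-based)."""
        pos = {
            phase: {t: i + 1 for i, t in enumerate(order)}
            for phase, order in self.orders().items()
        }
        return pd.DataFrame(
            {
                "topic_id": self.topic_ids,
                "condition": [self.condition_of[t].value for t in self.topic_ids],
                "phase1_pos": [pos[1][t] for t in self.topic_ids],
                "phase2_pos": [pos[2][t] for t in self.topic_ids],
                "phase3_pos": [pos[3][t] for t in self.topic_ids],
                "phase1_veracity": [self.phase1_veracity[t] for t in self.topic_ids],
            }
        )


class DesignConstraintError(RuntimeError):
    """Raised when no order satisfying the constraints is found."""


def _latin_square_assignment(experiment: int, cb: int) -> dict[int, Condition]:
    # Fixed partition: topics 1-15, 16-30, 31-45, 46-60; rotate sets through
    # conditions by the counterbalance index.
    conds = conditions_for_experiment(experiment)
    assignment: dict[int, Condition] = {}
    for s in range(N_SETS):
        cond = conds[(s + cb) % N_SETS]
        for t in range(s * SET_SIZE + 1, (s + 1) * SET_SIZE + 1):
            assignment[t] = cond
    return assignment


def _max_run_length(labels: list[Condition]) -> int:
    best = run = 1
    for a, b in zip(labels, labels[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def _repair_runs(order: list[int], cond_of: dict[int, Condition], rng: np.random.Generator,
                 max_passes: int = 200) -> bool:
    """Break runs longer than MAX_RUN by swapping an offender elsewhere."""
    for _ in range(max_passes):
        labels = [cond_of[t] for t in order]
        bad = None
        run = 1
        for i in range(1, len(labels)):
            run = run + 1 if labels[i] == labels[i - 1] else 1
            if run > MAX_RUN:
                bad = i
                break
        if bad is None:
            return True
        candidates = [j for j in range(len(order)) if cond_of[order[j]] != labels[bad]]
        j = int(rng.choice(candidates))
        order[bad], order[j] = order[j], order[bad]
    return False


def _order_ok(order: list[int], cond_of: dict[int, Condition]) -> bool:
    labels = [cond_of[t] for t in order]
    if _max_run_length(labels) > MAX_RUN:
        return False
    grand = (len(order) + 1) / 2
    means = _condition_means(order, cond_of)
    return all(abs(m - grand) <= POSITION_TOL for m in means.values())


def _condition_means(order: list[int], cond_of: dict[int, Condition]) -> dict[Condition, float]:
    sums: dict[Condition, list[int]] = {}
    for i, t in enumerate(order, start=1):
        sums.setdefault(cond_of[t], []).append(i)
    return {c: float(np.mean(p)) for c, p in sums.items()}


def _constrained_order(topics: list[int], cond_of: dict[int, Condition],
                       rng: np.random.Generator) -> list[int]:
    for _ in range(MAX_RESTARTS):
        order = list(rng.permutation(topics))
        order = [int(t) for t in order]
        if not _repair_runs(order, cond_of, rng):
            continue
        if _order_ok(order, cond_of):
            return order
    raise DesignConstraintError(
        f"no order satisfying run<= {MAX_RUN} and position balance "
        f"<= {POSITION_TOL} found in {MAX_RESTARTS} restarts"
    )


def build_design(experiment: int, counterbalance_index: int, seed: int) -> DesignList:
    """Build one counterbalance list with constrained phase orders.

    Deterministic given ``seed``: the same arguments always yield a
    byte-identical design.
    """
    if counterbalance_index not in range(N_SETS):
        raise ValueError(f"counterbalance_index must be 0-3, got {counterbalance_index!r}")
    cond_of = _latin_square_assignment(experiment, counterbalance_index)
    topics = sorted(cond_of)
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(experiment, counterbalance_index))
    )
    orders = [_constrained_order(topics, cond_of, rng) for _ in range(3)]
    return DesignList(
        experiment=experiment,
        counterbalance_index=counterbalance_index,
        topic_ids=topics,
        condition_of=cond_of,
        phase1_order=orders[0],
        phase2_order=orders[1],
        phase3_order=orders[2],
    )


def mean_positions(d: DesignList, phase: int) -> dict[Condition, float]:
    """Mean 1-based list position of each condition in one phase order."""
    order = d.orders()[phase]
    return _condition_means(order, d.condition_of)


def validate_design(d: DesignList) -> list[str]:
    """Check every design invariant; return the violated ones (empty = valid)."""
    report: list[str] = []
    conds = conditions_for_experiment(d.experiment)
    if sorted(d.topic_ids) != list(range(1, N_TOPICS + 1)):
        report.append(f"topic set is not 1..{N_TOPICS}")
    counts = pd.Series([d.condition_of[t] for t in d.topic_ids]).value_counts()
    if set(counts.index) != set(conds) or not (counts == SET_SIZE).all():
        report.append(f"conditions do not each contain exactly {SET_SIZE} topics")
    n_fake = sum(1 for t in d.topic_ids if d.phase1_veracity.get(t) == "fake")
    if n_fake != N_TOPICS - SET_SIZE:
        report.append(f"Phase 1 does not contain {N_TOPICS - SET_SIZE} fake-news topics")
    for t in d.topic_ids:
        expected = "real" if d.condition_of[t] is Condition.REPETITION else "fake"
        if d.phase1_veracity.get(t) != expected:
            report.append("Phase-1 veracity inconsistent with condition assignment")
            break
    for phase, order in d.orders().items():
        if sorted(order) != sorted(d.topic_ids):
            report.append(f"phase {phase} order is not a permutation of the topics")
            continue
        labels = [d.condition_of[t] for t in order]
        if _max_run_length(labels) > MAX_RUN:
            report.append(f"phase {phase} order has a run of >{MAX_RUN} same-condition topics")
        grand = (len(order) + 1) / 2
        offenders = {
            c.value: m
            for c, m in _condition_means(order, d.condition_of).items()
            if abs(m - grand) > POSITION_TOL
        }
        if offenders:
            report.append(
                f"phase {phase} mean positions off grand mean by >{POSITION_TOL}: {offenders}"
            )
    return report
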