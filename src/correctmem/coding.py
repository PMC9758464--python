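"""Response-category and conditional-classification coding, plus tree counts.

Every cued-recall trial is coded into one of three response categories —
correct real-news recall, an intrusion of the fake detail, or anything else —
and every correction trial additionally into one of three classification
classes combining the yes/no correction judgment with whether the fake detail
was subsequently recalled. Per-participant, per-condition category counts feed
the multinomial processing tree.
"""

from __future__ import annotations

from enum import Enum

import pandas as pd

from .design import Condition

REAL_RECALL = "REAL_RECALL"
INTRUSION = "INTRUSION"
OTHER = "OTHER"
RESPONSE_CATEGORIES = [REAL_RECALL, INTRUSION, OTHER]


class ConditionalClass(str, Enum):
    """Correction-classification class of a correction trial."""

    CORR_FN_RECALLED = "CORR_FN_RECALLED"
    CORR_FN_NOT_RECALLED = "CORR_FN_NOT_RECALLED"
    NOTCORR_FN_NOT_RECALLED = "NOTCORR_FN_NOT_RECALLED"


def code_category(row) -> str:
    """Response category of one trial.

    Uses the precoded ``response_category`` when present (scored real data);
    otherwise derives it from ``real_recalled`` and the generator's
    ``fake_produced`` flag. Repetition trials have no fake counterpart and can
    never yield an intrusion.
    """
    if row.get("real_recalled"):
        return REAL_RECALL
    if row.get("condition") == Condition.REPETITION.value:
        return OTHER
    pre = row.get("response_category")
    if isinstance(pre, str) and pre in RESPONSE_CATEGORIES:
        return pre
    return INTRUSION if row.get("fake_produced") else OTHER


def conditional_class(row) -> ConditionalClass:
    """Classification class of a correction trial; rejects repetition trials."""
    if row.get("condition") == Condition.REPETITION.value:
        raise ValueError("conditional classes are defined only for correction trials")
    if row.get("classified_correction"):
        if row.get("fake_recalled"):
            return ConditionalClass.CORR_FN_RECALLED
        return ConditionalClass.CORR_FN_NOT_RECALLED
    return ConditionalClass.NOTCORR_FN_NOT_RECALLED


def code_trials(df: pd.DataFrame) -> pd.DataFrame:
    """Add response_category and conditional_class columns to a trial table."""
    out = df.copy()
    out["response_category"] = [code_category(r) for r in df.to_dict("records")]
    cls = []
    for r in out.to_dict("records"):
        if r["condition"] == Condition.REPETITION.value:
            cls.append(None)
        else:
            cls.append(conditional_class(r).value)
    out["conditional_class"] = cls
    return out


def tabulate_mpt(df: pd.DataFrame) -> pd.DataFrame:
    """Per-participant, per-correction-condition 3-category count table.

    Columns: participant_id, condition, n_real, n_intrusion, n_other;
    the three counts sum to that participant's number of trials in the
    condition (15 at the full design).
    """
    coded = df if "response_category" in df.columns else code_trials(df)
    corr = coded[coded["condition"] != Condition.REPETITION.value]
    tab = (
        corr.groupby(["participant_id", "condition"])["response_category"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=RESPONSE_CATEGORIES, fill_value=0)
        .reset_index()
    )
    tab.columns.name = None
    return tab.rename(
        columns={REAL_RECALL: "n_real", INTRUSION: "n_intrusion", OTHER: "n_other"}
    )
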