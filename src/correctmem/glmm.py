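"""Mixed-effects estimation of condition-level probabilities and ratings.

Binary outcomes (real-news recall, intrusions, fake-news recall) are analyzed
with logistic mixed models with crossed participant and item (topic) random
intercepts; belief ratings with Gaussian linear mixed models. Models are fit
with lme4 (glmer: Laplace approximation to the marginal likelihood; lmer:
REML) driven through an Rscript subprocess, the standard estimation route for
crossed-random-effects designs. Reported per-level estimates are conditional
(random-effects-at-zero): the inverse link of the fixed-effect predictor for
a typical participant and item. All-pairs contrasts are Wald z statistics for
logistic models and t statistics with Satterthwaite degrees of freedom
(lmerTest) for Gaussian models, with a configurable multiplicity adjustment
(Tukey by default). Factor-level chi-square tests are Wald tests built from
contrast matrices over the cell means.
"""

from __future__ import annotations

import json
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .coding import INTRUSION, code_trials
from .design import Condition


class SeparationError(RuntimeError):
    """Outcome is constant within a fixed-effect cell (complete separation)."""


class ConvergenceWarningError(RuntimeError):
    """The mixed-model optimizer reported non-convergence."""

    def __init__(self, message: str, diagnostics: dict):
        super().__init__(message)
        self.diagnostics = diagnostics


class RBackendError(RuntimeError):
    """Rscript/lme4 invocation failed."""


@dataclass
class ModelEstimates:
    """Per-level estimates with 95% intervals, all-pairs contrasts, diagnostics."""

    outcome: str
    scale: str  # "probability" or "rating"
    estimates: pd.DataFrame  # level, estimate, ci_low, ci_high, n_obs
    contrasts: pd.DataFrame  # level_a, level_b, estimate, statistic, df, p_raw, p_adj
    adjustment: str
    convergence: dict = field(default_factory=dict)
    term_tests: pd.DataFrame | None = None  # effect, statistic, df, p
    dropped_cells: list = field(default_factory=list)

    def estimate_for(self, level: str) -> float:
        return float(self.estimates.set_index("level").loc[level, "estimate"])


# ---------------------------------------------------------------------------
# R backend

_BINOMIAL_TEMPLATE = """
suppressMessages({{library(lme4); library(jsonlite)}})
d <- read.csv("{csv}")
d$cell <- factor(d$cell, levels=fromJSON('{levels}'))
fit <- glmer(y ~ 0 + cell + (1|pid) + (1|item), data=d, family=binomial,
             control=glmerControl(optimizer="bobyqa"))
vc <- as.data.frame(VarCorr(fit))
out <- list(beta=as.numeric(fixef(fit)), names=names(fixef(fit)),
            vcov=as.matrix(vcov(fit)), vc_sd=as.list(setNames(vc$sdcor, vc$grp)),
            singular=isSingular(fit),
            messages=as.list(unlist(fit@optinfo$conv$lme4$messages)))
writeLines(toJSON(out, digits=12, auto_unbox=TRUE), "{out}")
"""

_GAUSSIAN_TEMPLATE = """
suppressMessages({{library(lmerTest); library(jsonlite)}})
d <- read.csv("{csv}")
d$cell <- factor(d$cell, levels=fromJSON('{levels}'))
fit <- lmer(y ~ 0 + cell + (1|pid) + (1|item), data=d, REML=TRUE,
            control=lmerControl(optimizer="bobyqa"))
k <- length(fixef(fit))
pairs <- list()
idx <- 1
for (i in seq_len(k-1)) for (j in seq((i+1), k)) {{
  L <- rep(0, k); L[i] <- 1; L[j] <- -1
  ct <- lmerTest::contest1D(fit, L)
  pairs[[idx]] <- list(i=i, j=j, est=ct$Estimate, se=ct$`Std. Error`,
                       df=ct$df, t=ct$`t value`)
  idx <- idx + 1
}}
vc <- as.data.frame(VarCorr(fit))
out <- list(beta=as.numeric(fixef(fit)), names=names(fixef(fit)),
            vcov=as.matrix(vcov(fit)), vc_sd=as.list(setNames(vc$sdcor, vc$grp)),
            singular=isSingular(fit), pairs=pairs,
            messages=as.list(unlist(fit@optinfo$conv$lme4$messages)))
writeLines(toJSON(out, digits=12, auto_unbox=TRUE), "{out}")
"""


def _run_lme4(df: pd.DataFrame, outcome: str, levels: list[str], family: str) -> dict:
    """Fit ``y ~ 0 + cell + (1|pid) + (1|item)`` in lme4 and return the pieces."""
    if shutil.which("Rscript") is None:
        raise RBackendError("Rscript not found on PATH; lme4 backend unavailable")
    with tempfile.TemporaryDirectory(prefix="correctmem_glmm_") as tmp:
        tmp = Path(tmp)
        data = pd.DataFrame(
            {
                "y": df[outcome].values,
                "cell": df["_cell"].astype(str).values,
                "pid": df["participant_id"].values,
                "item": df["topic_id"].values,
            }
        )
        data.to_csv(tmp / "data.csv", index=False)
        template = _BINOMIAL_TEMPLATE if family == "binomial" else _GAUSSIAN_TEMPLATE
        script = template.format(
            csv=tmp / "data.csv", levels=json.dumps(levels), out=tmp / "out.json"
        )
        (tmp / "fit.R").write_text(script)
        proc = subprocess.run(
            ["Rscript", "--vanilla", str(tmp / "fit.R")],
            capture_output=True,
            text=True,
            timeout=600,
        )
        if proc.returncode != 0 or not (tmp / "out.json").exists():
            raise RBackendError(f"lme4 fit failed:\n{proc.stderr[-2000:]}")
        out = json.loads((tmp / "out.json").read_text())
    out["vcov"] = np.atleast_2d(np.asarray(out["vcov"], dtype=float))
    out["beta"] = np.asarray(out["beta"], dtype=float)
    messages = out.get("messages") or []
    if isinstance(messages, str):
        messages = [messages]
    out["messages"] = messages
    return out


# ---------------------------------------------------------------------------
# Contrast and term-test machinery (link scale)


def _combined_factor(df: pd.DataFrame, fixed) -> tuple[pd.Series, list[str]]:
    fixed = [fixed] if isinstance(fixed, str) else list(fixed)
    if not fixed:
        raise ValueError("at least one fixed factor is required")
    col = df[fixed[0]].astype(str)
    for f in fixed[1:]:
        col = col + ":" + df[f].astype(str)
    return col, fixed


def _check_separation(y: pd.Series, cells: pd.Series) -> None:
    means = y.groupby(cells).mean()
    degenerate = means[(means == 0.0) | (means == 1.0)]
    if len(degenerate):
        raise SeparationError(
            "outcome is constant within cell(s) "
            f"{list(degenerate.index)}; logistic fixed effects are unbounded"
        )


def _adjust_p(out: pd.DataFrame, k: int, adjust: str) -> pd.DataFrame:
    if out.empty:
        out["p_adj"] = []
        return out
    if adjust == "none":
        out["p_adj"] = out["p_raw"]
    elif adjust == "tukey":
        out["p_adj"] = [
            min(
                1.0,
                float(
                    stats.studentized_range.sf(
                        abs(s) * np.sqrt(2), k, d if np.isfinite(d) else 1e7
                    )
                ),
            )
            for s, d in zip(out["statistic"], out["df"])
        ]
    elif adjust == "holm":
        from statsmodels.stats.multitest import multipletests

        out["p_adj"] = multipletests(out["p_raw"], method="holm")[1]
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    out["p_adj"] = np.maximum(out["p_adj"], out["p_raw"])
    return out


def _pairwise_wald(levels, beta, cov, adjust) -> pd.DataFrame:
    """All-pairs Wald z contrasts on the link scale."""
    rows = []
    for i in range(len(levels)):
        for j in range(i + 1, len(levels)):
            d = beta[i] - beta[j]
            se = np.sqrt(max(cov[i, i] + cov[j, j] - 2 * cov[i, j], 0.0))
            stat = d / se if se > 0 else 0.0
            rows.append(
                {
                    "level_a": levels[i],
                    "level_b": levels[j],
                    "estimate": d,
                    "statistic": stat,
                    "df": np.inf,
                    "p_raw": min(1.0, 2 * stats.norm.sf(abs(stat))),
                }
            )
    return _adjust_p(pd.DataFrame(rows), len(levels), adjust)


def _pairwise_satterthwaite(levels, pairs, adjust) -> pd.DataFrame:
    """All-pairs t contrasts with per-contrast Satterthwaite df from lmerTest."""
    rows = []
    for p in pairs:
        i, j = int(p["i"]) - 1, int(p["j"]) - 1
        stat, dof = float(p["t"]), float(p["df"])
        rows.append(
            {
                "level_a": levels[i],
                "level_b": levels[j],
                "estimate": float(p["est"]),
                "statistic": stat,
                "df": dof,
                "p_raw": min(1.0, 2 * stats.t.sf(abs(stat), dof)),
            }
        )
    return _adjust_p(pd.DataFrame(rows), len(levels), adjust)


def _term_tests(levels, beta, cov, fixed_cols) -> pd.DataFrame:
    """Wald chi-square tests of main effects and interaction from cell means.

    Contrast matrices weight observed cells equally, which reduces to the
    usual factorial (type III) tests when the design is complete.
    """
    parts = [lv.split(":") for lv in levels]
    rows = []

    def wald(C):
        C = np.atleast_2d(C)
        Cb = C @ beta
        V = C @ cov @ C.T
        try:
            chi2 = float(Cb @ np.linalg.solve(V, Cb))
        except np.linalg.LinAlgError:
            return None
        q = int(np.linalg.matrix_rank(C))
        return chi2, q, float(stats.chi2.sf(chi2, q))

    for fi, fname in enumerate(fixed_cols):
        fac_levels = sorted({p[fi] for p in parts})
        C = []
        for a, b in zip(fac_levels, fac_levels[1:]):
            row = np.zeros(len(levels))
            in_a = [i for i, p in enumerate(parts) if p[fi] == a]
            in_b = [i for i, p in enumerate(parts) if p[fi] == b]
            row[in_a] = 1.0 / len(in_a)
            row[in_b] = -1.0 / len(in_b)
            C.append(row)
        res = wald(np.array(C))
        if res:
            rows.append({"effect": fname, "statistic": res[0], "df": res[1], "p": res[2]})
    if len(fixed_cols) == 2:
        fa = sorted({p[0] for p in parts})
        fb = sorted({p[1] for p in parts})
        cell_ix = {tuple(p): i for i, p in enumerate(parts)}
        C = []
        for a0, a1 in zip(fa, fa[1:]):
            for b0, b1 in zip(fb, fb[1:]):
                need = [(a0, b0), (a0, b1), (a1, b0), (a1, b1)]
                if not all(c in cell_ix for c in need):
                    continue  # incomplete cell: interaction contrast undefined
                row = np.zeros(len(levels))
                row[cell_ix[need[0]]] = 1
                row[cell_ix[need[1]]] = -1
                row[cell_ix[need[2]]] = -1
                row[cell_ix[need[3]]] = 1
                C.append(row)
        if C:
            res = wald(np.array(C))
            if res:
                rows.append(
                    {
                        "effect": " x ".join(fixed_cols),
                        "statistic": res[0],
                        "df": res[1],
                        "p": res[2],
                    }
                )
    return pd.DataFrame(rows)


def _prepare(table, outcome, fixed):
    df = table.copy()
    cells, fixed_cols = _combined_factor(df, fixed)
    df["_cell"] = cells
    observed = sorted(df["_cell"].unique())
    if len(observed) < 2:
        raise ValueError("need at least two fixed-effect cells")
    return df, observed, fixed_cols


def _diagnostics(out: dict, method: str, n_obs: int, extra: dict | None = None) -> dict:
    diag = {
        "method": method,
        "converged": not any("failed to converge" in m.lower() for m in out["messages"]),
        "singular": bool(out.get("singular", False)),
        "messages": out["messages"],
        "random_effect_sd": {k: float(v) for k, v in out.get("vc_sd", {}).items()},
        "n_obs": n_obs,
    }
    if extra:
        diag.update(extra)
    return diag


def fit_binomial_mixed(
    table: pd.DataFrame,
    outcome: str,
    fixed,
    adjust: str = "tukey",
) -> ModelEstimates:
    """Logistic mixed model with crossed participant and item intercepts.

    Cell-means parameterization of the (possibly crossed) fixed factors, fit
    by glmer (Laplace). Raises :class:`SeparationError` when any cell's
    outcome is constant and :class:`ConvergenceWarningError` when lme4
    reports convergence failure.
    """
    df, observed, fixed_cols = _prepare(table, outcome, fixed)
    y = df[outcome].astype(float)
    if y.nunique() < 2:
        raise SeparationError(f"outcome {outcome!r} is constant in the table")
    _check_separation(y, df["_cell"])

    out = _run_lme4(df, outcome, observed, "binomial")
    diagnostics = _diagnostics(out, "glmer (Laplace)", len(df))
    if not diagnostics["converged"]:
        raise ConvergenceWarningError("glmer did not converge", diagnostics)

    beta, cov = out["beta"], out["vcov"]
    se = np.sqrt(np.diag(cov))
    counts = df.groupby("_cell", observed=True)[outcome].count().reindex(observed)
    est = pd.DataFrame(
        {
            "level": observed,
            "estimate": expit(beta),
            "ci_low": expit(beta - 1.96 * se),
            "ci_high": expit(beta + 1.96 * se),
            "n_obs": counts.values,
        }
    )
    return ModelEstimates(
        outcome=outcome,
        scale="probability",
        estimates=est,
        contrasts=_pairwise_wald(observed, beta, cov, adjust),
        adjustment=adjust,
        convergence=diagnostics,
        term_tests=_term_tests(observed, beta, cov, fixed_cols),
    )


def fit_gaussian_mixed(
    table: pd.DataFrame,
    outcome: str,
    fixed,
    adjust: str = "tukey",
) -> ModelEstimates:
    """Linear mixed model for ratings with crossed random intercepts.

    REML fit; estimates on the rating scale; contrasts are t statistics with
    Satterthwaite degrees of freedom.
    """
    df, observed, fixed_cols = _prepare(table, outcome, fixed)
    out = _run_lme4(df, outcome, observed, "gaussian")
    diagnostics = _diagnostics(
        out, "lmer (REML)", len(df), {"dof_method": "Satterthwaite (lmerTest)"}
    )
    if not diagnostics["converged"]:
        raise ConvergenceWarningError("lmer did not converge", diagnostics)

    beta, cov = out["beta"], out["vcov"]
    se = np.sqrt(np.diag(cov))
    counts = df.groupby("_cell", observed=True)[outcome].count().reindex(observed)
    est = pd.DataFrame(
        {
            "level": observed,
            "estimate": beta,
            "ci_low": beta - 1.96 * se,
            "ci_high": beta + 1.96 * se,
            "n_obs": counts.values,
        }
    )
    return ModelEstimates(
        outcome=outcome,
        scale="rating",
        estimates=est,
        contrasts=_pairwise_satterthwaite(observed, out.get("pairs", []), adjust),
        adjustment=adjust,
        convergence=diagnostics,
        term_tests=_term_tests(observed, beta, cov, fixed_cols),
    )


def _correction_trials(table: pd.DataFrame) -> pd.DataFrame:
    coded = table if "conditional_class" in table.columns else code_trials(table)
    return coded[coded["condition"] != Condition.REPETITION.value].copy()


def conditional_models(
    table: pd.DataFrame,
    outcome: str = "real_recalled",
    adjust: str = "tukey",
    min_cell: int = 5,
) -> ModelEstimates:
    """Headline type x classification-class interaction model.

    For the intrusion outcome the accurately-classified-with-fake-recall class
    is excluded (intrusions there are redundant and sparse). Cells with fewer
    than ``min_cell`` observations are flagged and omitted from the fit.
    """
    df = _correction_trials(table)
    if outcome == "intrusion":
        df["intrusion"] = (df["response_category"] == INTRUSION).astype(int)
        df = df[df["conditional_class"] != "CORR_FN_RECALLED"]
    sizes = df.groupby(["condition", "conditional_class"], observed=True).size()
    sparse = sizes[sizes < min_cell]
    dropped = [f"{c}:{k}" for (c, k) in sparse.index]
    if dropped:
        keep = df.set_index(["condition", "conditional_class"]).index.isin(
            sizes[sizes >= min_cell].index
        )
        df = df[keep]
    est = fit_binomial_mixed(df, outcome, ["condition", "conditional_class"], adjust=adjust)
    est.dropped_cells = dropped
    return est


def pairwise_contrasts(fit: ModelEstimates, adjust: str = "tukey") -> pd.DataFrame:
    """Re-adjust the all-pairs contrast table of a fitted model."""
    out = fit.contrasts[["level_a", "level_b", "estimate", "statistic", "df", "p_raw"]].copy()
    return _adjust_p(out, len(fit.estimates), adjust)
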