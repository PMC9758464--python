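"""Dual-process multinomial processing tree for correction recall.

The tree has two latent parameters per correction condition: recollection
``r`` (contextual retrieval of the correction and its veracity) and
familiarity ``f`` (acontextual fluency of the topic that, absent
recollection, drives misattribution of the fake detail). Category
probabilities are

    P(real recall) = r
    P(intrusion)   = (1 - r) * f
    P(other)       = (1 - r) * (1 - f)

which is saturated (just-identified) per condition, so the closed-form moment
estimator inverts the tree exactly at the empirical frequencies and serves as
an independent oracle for the hierarchical fit.

The hierarchical model places the tree at the participant level. Each
participant x condition cell carries one standard-normal latent ability
x_pc ~ Normal(0, 1) entering both branches with parameter-specific loadings:

    r_pc = invlogit(mu_r[c] + sigma_r * x_pc)
    f_pc = invlogit(mu_f[c] + sigma_f * x_pc)

A single shared ability per cell captures the selection dependence between
the branches — the familiarity branch is only reached on trials where
recollection failed, so low-ability cells contribute disproportionately many
familiarity observations, and ignoring that dependence biases the group-level
familiarity location downward in high-recollection conditions. Abilities are
independent across conditions, so condition contrasts carry
participant-sampling uncertainty, matching the magnitude of published
credible intervals for such designs. Priors are weakly informative:
mu ~ Normal(0, 1.5^2) on the logit scale (near-uniform on the probability
scale), sigma ~ Half-Normal(1).

The cell abilities are marginalized by one-dimensional Gauss-Hermite
quadrature, leaving a low-dimensional group-level posterior that is sampled
with an affine-invariant ensemble sampler (independent ensembles serve as
chains for split-R-hat diagnostics). Population estimates are reported as
invlogit(mu): the probability for a typical (zero-ability) participant,
matching the conditional convention of the mixed models elsewhere in the
pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import arviz as az
import emcee
import numpy as np
import pandas as pd
from scipy.special import expit, gammaln, logit

from .design import correction_conditions

PRIOR_MU_SD = 1.5
PRIOR_SIGMA_SD = 1.0
GH_NODES = 31
RHAT_LIMIT = 1.05

# hermegauss weights integrate against exp(-x^2/2); dividing by sqrt(2*pi)
# turns them into expectation weights against the standard normal density.
_gh_nodes, _gh_weights = np.polynomial.hermite_e.hermegauss(GH_NODES)
_gh_logw = np.log(_gh_weights) - 0.5 * np.log(2 * np.pi)
_gh_logw -= np.log(np.sum(np.exp(_gh_logw)))  # exact renormalization


# ---------------------------------------------------------------------------
# Tree algebra


def category_probs(r: float, f: float) -> tuple[float, float, float]:
    """(P_real, P_intrusion, P_other) under the dual-process tree."""
    r = float(r)
    f = float(f)
    if not (0.0 <= r <= 1.0 and 0.0 <= f <= 1.0):
        raise ValueError("r and f must lie in [0, 1]")
    return r, (1.0 - r) * f, (1.0 - r) * (1.0 - f)


def loglik(counts, r: float, f: float) -> float:
    """Multinomial log-likelihood kernel of one (real, intrusion, other) triple.

    Returns -inf when a zero-probability category has a positive count.
    """
    n = np.asarray(counts, dtype=float)
    p = np.asarray(category_probs(r, f), dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.log(p)
        terms = np.where(n > 0, n * logp, 0.0)
    if np.any(np.isneginf(terms)):
        return -np.inf
    return float(np.sum(terms))


@dataclass
class MomentEstimate:
    r: float
    f: float
    f_defined: bool = True


def moment_estimates(n_real: int, n_intrusion: int, n_other: int) -> MomentEstimate:
    """Closed-form inversion of the tree at the empirical frequencies.

    r_hat = n_real / n and f_hat = n_intrusion / (n - n_real); when every
    trial was a real recall the familiarity frequency is undefined and
    flagged (f is reported as 0).
    """
    n = n_real + n_intrusion + n_other
    if n <= 0:
        raise ValueError("empty count triple")
    r_hat = n_real / n
    rem = n - n_real
    if rem == 0:
        return MomentEstimate(r=1.0, f=0.0, f_defined=False)
    return MomentEstimate(r=r_hat, f=n_intrusion / rem)


# ---------------------------------------------------------------------------
# Hierarchical model


class MPTConvergenceError(RuntimeError):
    """Raised when sampler diagnostics exceed their thresholds."""

    def __init__(self, message: str, diagnostics: dict):
        super().__init__(message)
        self.diagnostics = diagnostics


@dataclass
class MPTPosterior:
    """Posterior draws and summaries of the hierarchical tree fit.

    ``draws_r``/``draws_f`` are probability-scale draws of invlogit(mu),
    shaped (n_draws, n_conditions); ``participant_effects`` holds
    empirical-Bayes logit-scale cell effects (conditional posterior means of
    sigma * x_pc at the posterior mean of the group-level parameters), one
    row per participant x condition.
    """

    conditions: list[str]
    draws_mu_r: np.ndarray
    draws_mu_f: np.ndarray
    draws_sigma_r: np.ndarray
    draws_sigma_f: np.ndarray
    chain_ids: np.ndarray
    participant_ids: list
    participant_effects: pd.DataFrame
    diagnostics: dict = field(default_factory=dict)

    @property
    def draws_r(self) -> np.ndarray:
        return expit(self.draws_mu_r)

    @property
    def draws_f(self) -> np.ndarray:
        return expit(self.draws_mu_f)

    def _draws(self, param: str) -> np.ndarray:
        if param == "r":
            return self.draws_r
        if param == "f":
            return self.draws_f
        raise ValueError(f"param must be 'r' or 'f', got {param!r}")

    def summary(self) -> pd.DataFrame:
        """Posterior mean and central 95% interval per condition and parameter."""
        rows = []
        for param in ("r", "f"):
            draws = self._draws(param)
            for j, cond in enumerate(self.conditions):
                lo, hi = np.percentile(draws[:, j], [2.5, 97.5])
                rows.append(
                    {
                        "condition": cond,
                        "parameter": param,
                        "mean": float(draws[:, j].mean()),
                        "ci_low": float(lo),
                        "ci_high": float(hi),
                    }
                )
        return pd.DataFrame(rows)


def _split_counts(counts: pd.DataFrame, conditions: list[str]):
    """Pivot the long count table into (participants, conditions) arrays."""
    required = {"participant_id", "condition", "n_real", "n_intrusion", "n_other"}
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"count table missing columns: {sorted(missing)}")
    pids = sorted(counts["participant_id"].unique())
    shape = (len(pids), len(conditions))
    n_real = np.zeros(shape)
    n_intr = np.zeros(shape)
    n_other = np.zeros(shape)
    pid_ix = {p: i for i, p in enumerate(pids)}
    cond_ix = {c: j for j, c in enumerate(conditions)}
    for row in counts.itertuples(index=False):
        i = pid_ix[row.participant_id]
        j = cond_ix.get(row.condition)
        if j is None:
            raise ValueError(f"unknown condition {row.condition!r} in count table")
        n_real[i, j] += row.n_real
        n_intr[i, j] += row.n_intrusion
        n_other[i, j] += row.n_other
    return pids, n_real, n_intr, n_other


def _binom_ll(eta, successes, failures):
    """Binomial log-likelihood kernel at logit eta, softplus-stabilized."""
    return successes * -np.logaddexp(0.0, -eta) + failures * -np.logaddexp(0.0, eta)


def _marginal_loglik(mu_r, mu_f, log_sigma_r, log_sigma_f, n_real, n_intr, n_other):
    """Cell-wise marginal tree log-likelihood, vectorized over walkers.

    mu_*: (W, C); log_sigma_*: (W,); counts: (P, C). The shared cell ability
    x ~ Normal(0, 1) enters both branches and is marginalized by
    Gauss-Hermite quadrature. Returns (W,) log-likelihood sums over cells.
    """
    s_r = np.exp(log_sigma_r)
    s_f = np.exp(log_sigma_f)
    # eta: (W, Q, P, C)
    eta_r = mu_r[:, None, None, :] + (s_r[:, None] * _gh_nodes[None, :])[:, :, None, None]
    eta_f = mu_f[:, None, None, :] + (s_f[:, None] * _gh_nodes[None, :])[:, :, None, None]
    rem = n_intr + n_other  # non-recollected trials: binomial denominator for f
    ll = _binom_ll(eta_r, n_real[None, None], rem[None, None])
    ll += _binom_ll(eta_f, n_intr[None, None], n_other[None, None])
    ll += _gh_logw[None, :, None, None]
    # logsumexp over quadrature nodes per cell, then sum over cells
    m = ll.max(axis=1, keepdims=True)
    out = m[:, 0] + np.log(np.exp(ll - m).sum(axis=1))  # (W, P, C)
    return out.sum(axis=(1, 2))


def _log_multinom_const(n_real, n_intr, n_other) -> float:
    n = n_real + n_intr + n_other
    return float(
        np.sum(gammaln(n + 1) - gammaln(n_real + 1) - gammaln(n_intr + 1) - gammaln(n_other + 1))
    )


def _make_log_post(n_real, n_intr, n_other, n_cond):
    def log_post(theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        mu_r = theta[:, :n_cond]
        mu_f = theta[:, n_cond : 2 * n_cond]
        ls_r = theta[:, 2 * n_cond]
        ls_f = theta[:, 2 * n_cond + 1]
        lp = np.zeros(theta.shape[0])
        # priors: mu ~ N(0, 1.5^2); sigma ~ Half-Normal(1) with log-jacobian
        lp -= 0.5 * ((mu_r**2).sum(axis=1) + (mu_f**2).sum(axis=1)) / PRIOR_MU_SD**2
        for ls in (ls_r, ls_f):
            sigma = np.exp(ls)
            lp += -0.5 * (sigma / PRIOR_SIGMA_SD) ** 2 + ls
        lp = np.where(np.abs(theta).max(axis=1) > 30, -np.inf, lp)
        ok = np.isfinite(lp)
        if ok.any():
            lp[ok] += _marginal_loglik(
                mu_r[ok], mu_f[ok], ls_r[ok], ls_f[ok], n_real, n_intr, n_other
            )
        return lp

    return log_post


@dataclass
class SamplerSettings:
    """Ensemble-sampler configuration; defaults give 4 chains x 1000 draws."""

    chains: int = 4
    walkers: int = 16
    steps: int = 1000
    burn: int = 500
    seed: int = 3

    @property
    def draws_per_chain(self) -> int:
        return (self.steps - self.burn) * self.walkers


def fit_hierarchical(
    counts: pd.DataFrame,
    conditions: list[str] | None = None,
    settings: SamplerSettings | None = None,
    check_diagnostics: bool = True,
) -> MPTPosterior:
    """Fit the hierarchical tree to a per-participant count table.

    ``counts`` has one row per participant x condition with columns
    participant_id, condition, n_real, n_intrusion, n_other. Each of
    ``settings.chains`` independent ensembles contributes one chain of pooled
    walker draws; split-R-hat is computed across chains per group-level
    parameter and the fit raises when it exceeds 1.05.
    """
    settings = settings or SamplerSettings()
    if conditions is None:
        conditions = sorted(counts["condition"].unique())
    pids, n_real, n_intr, n_other = _split_counts(counts, conditions)
    if len(pids) < 2:
        raise ValueError("hierarchical fit needs at least 2 participants")
    n_cond = len(conditions)
    ndim = 2 * n_cond + 2
    log_post = _make_log_post(n_real, n_intr, n_other, n_cond)

    # crude data-driven center for initialization: pooled moment estimates
    pooled_r = n_real.sum(axis=0) / np.maximum((n_real + n_intr + n_other).sum(axis=0), 1)
    pooled_f = n_intr.sum(axis=0) / np.maximum((n_intr + n_other).sum(axis=0), 1)
    center = np.concatenate(
        [
            logit(np.clip(pooled_r, 0.02, 0.98)),
            logit(np.clip(pooled_f, 0.02, 0.98)),
            [np.log(0.5), np.log(0.5)],
        ]
    )

    chain_draws = []
    chain_ids = []
    seed_seq = np.random.SeedSequence(entropy=settings.seed)
    for chain, child in enumerate(seed_seq.spawn(settings.chains)):
        rng = np.random.default_rng(child)
        p0 = center[None, :] + 0.1 * rng.standard_normal((settings.walkers, ndim))
        sampler = emcee.EnsembleSampler(settings.walkers, ndim, log_post, vectorize=True)
        # emcee's random_state setter silently ignores anything that is not a
        # RandomState.get_state() tuple, falling back to the *global* numpy
        # RNG state -- pass the tuple so the ensemble is genuinely seeded.
        rstate = np.random.RandomState(rng.integers(2**31 - 1)).get_state()
        state = emcee.State(p0, random_state=rstate)
        sampler.run_mcmc(state, settings.steps, progress=False)
        chain_draws.append(sampler.get_chain(discard=settings.burn))  # (steps-burn, W, ndim)
        chain_ids.append(np.full(settings.draws_per_chain, chain))

    # arviz layout: (chain, draw, ...) with walkers folded into the draw axis
    arr = np.stack([c.reshape(-1, ndim) for c in chain_draws])  # (chains, draws, ndim)
    names = (
        [f"mu_r[{c}]" for c in conditions]
        + [f"mu_f[{c}]" for c in conditions]
        + ["log_sigma_r", "log_sigma_f"]
    )
    idata = az.from_dict({name: arr[:, :, k] for k, name in enumerate(names)})
    rhat = az.rhat(idata)
    ess = az.ess(idata)
    max_rhat = float(max(rhat[name].values for name in names))
    min_ess = float(min(ess[name].values for name in names))
    diagnostics = {
        "max_rhat": max_rhat,
        "min_ess": min_ess,
        "divergences": 0,
        "chains": settings.chains,
        "draws_per_chain": settings.draws_per_chain,
        "rhat": {name: float(rhat[name].values) for name in names},
    }
    if check_diagnostics and max_rhat > RHAT_LIMIT:
        raise MPTConvergenceError(
            f"split-R-hat {max_rhat:.3f} exceeds {RHAT_LIMIT}", diagnostics
        )

    flat = arr.reshape(-1, ndim)
    post = MPTPosterior(
        conditions=list(conditions),
        draws_mu_r=flat[:, :n_cond],
        draws_mu_f=flat[:, n_cond : 2 * n_cond],
        draws_sigma_r=np.exp(flat[:, 2 * n_cond]),
        draws_sigma_f=np.exp(flat[:, 2 * n_cond + 1]),
        chain_ids=np.concatenate(chain_ids),
        participant_ids=list(pids),
        participant_effects=pd.DataFrame(),
        diagnostics=diagnostics,
    )
    post.participant_effects = _eb_participant_effects(
        post, n_real, n_intr, n_other
    )
    return post


def _eb_participant_effects(post: MPTPosterior, n_real, n_intr, n_other) -> pd.DataFrame:
    """Conditional posterior means of the cell effects at the group-level mean.

    One row per participant x condition with columns delta_r, delta_f
    (logit-scale, empirical-Bayes shrunk toward zero).
    """
    mu_r = post.draws_mu_r.mean(axis=0)
    mu_f = post.draws_mu_f.mean(axis=0)
    s_r = float(post.draws_sigma_r.mean())
    s_f = float(post.draws_sigma_f.mean())
    grid = np.linspace(-4, 4, 161)

    # joint cell posterior over the shared ability, using both branches
    eta_r = mu_r[None, None, :] + s_r * grid[:, None, None]  # (G, P, C)
    eta_f = mu_f[None, None, :] + s_f * grid[:, None, None]
    ll = _binom_ll(eta_r, n_real[None], (n_intr + n_other)[None])
    ll += _binom_ll(eta_f, n_intr[None], n_other[None])
    ll -= 0.5 * grid[:, None, None] ** 2
    w = np.exp(ll - ll.max(axis=0, keepdims=True))
    x_mean = (grid[:, None, None] * w).sum(axis=0) / w.sum(axis=0)  # (P, C)
    dr = s_r * x_mean
    df_ = s_f * x_mean
    rows = []
    for i, pid in enumerate(post.participant_ids):
        for j, cond in enumerate(post.conditions):
            rows.append(
                {
                    "participant_id": pid,
                    "condition": cond,
                    "delta_r": float(dr[i, j]),
                    "delta_f": float(df_[i, j]),
                }
            )
    return pd.DataFrame(rows)


def credible_difference(
    post: MPTPosterior, param: str, cond_a: str, cond_b: str
) -> tuple[float, tuple[float, float], bool]:
    """Probability-scale posterior difference cond_a - cond_b.

    Returns (posterior mean, central 95% interval, credible flag); the flag is
    true iff the interval excludes zero.
    """
    draws = post._draws(param)
    for c in (cond_a, cond_b):
        if c not in post.conditions:
            raise ValueError(f"condition {c!r} not in posterior ({post.conditions})")
    ia, ib = post.conditions.index(cond_a), post.conditions.index(cond_b)
    diff = draws[:, ia] - draws[:, ib]
    lo, hi = np.percentile(diff, [2.5, 97.5])
    credible = bool(lo > 0.0 or hi < 0.0)
    return float(diff.mean()), (float(lo), float(hi)), credible


def familiarity_vs_others(post: MPTPosterior, cond: str) -> tuple[float, tuple[float, float], bool]:
    """Draw-wise f(cond) minus the mean of f over the other conditions."""
    others = [c for c in post.conditions if c != cond]
    draws = post.draws_f
    i = post.conditions.index(cond)
    js = [post.conditions.index(c) for c in others]
    diff = draws[:, i] - draws[:, js].mean(axis=1)
    lo, hi = np.percentile(diff, [2.5, 97.5])
    return float(diff.mean()), (float(lo), float(hi)), bool(lo > 0.0 or hi < 0.0)


# ---------------------------------------------------------------------------
# Parameter recovery harness


def recover(
    config,
    n_replicates: int,
    seed: int,
    settings: SamplerSettings | None = None,
) -> dict:
    """Simulate-and-refit recovery study at a generator calibration.

    For each replicate a fresh dataset is simulated at ``config`` (with a
    replicate-specific generator seed derived from ``seed``), the hierarchical
    tree is fit, and per-parameter error and interval coverage of the
    generating conditional probabilities are recorded. Returns a JSON-ready
    report with bias, RMSE and coverage per condition and parameter.
    """
    from .coding import tabulate_mpt
    from .generate import simulate_dataset

    conds = [c.value for c in correction_conditions(config.experiment)]
    truth = {("r", c): config.r_by_condition[c] for c in conds}
    truth.update({("f", c): config.f_by_condition[c] for c in conds})
    errors: dict[tuple[str, str], list[float]] = {k: [] for k in truth}
    covered: dict[tuple[str, str], list[bool]] = {k: [] for k in truth}

    ss = np.random.SeedSequence(entropy=seed)
    children = ss.spawn(n_replicates)
    for rep, child in enumerate(children):
        rep_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        cfg = type(config)(**{**config.__dict__, "seed": rep_seed})
        try:
            trials = simulate_dataset(cfg, design_seed=rep_seed)
            counts = tabulate_mpt(trials)
            fit_settings = settings or SamplerSettings()
            fit_settings = SamplerSettings(**{**fit_settings.__dict__, "seed": rep_seed + 1})
            post = fit_hierarchical(counts, conditions=conds, settings=fit_settings)
        except Exception as exc:  # noqa: BLE001 - replicate index must surface
            raise RuntimeError(f"recovery replicate {rep} failed: {exc}") from exc
        summ = post.summary().set_index(["parameter", "condition"])
        for (param, cond), true_val in truth.items():
            row = summ.loc[(param, cond)]
            errors[(param, cond)].append(float(row["mean"]) - true_val)
            covered[(param, cond)].append(bool(row["ci_low"] <= true_val <= row["ci_high"]))

    report = {"experiment": config.experiment, "n_replicates": n_replicates, "parameters": {}}
    for (param, cond), errs in errors.items():
        key = f"{param}[{cond}]"
        if n_replicates == 0:
            continue
        e = np.asarray(errs)
        report["parameters"][key] = {
            "truth": truth[(param, cond)],
            "bias": float(e.mean()),
            "rmse": float(np.sqrt((e**2).mean())),
            "coverage": float(np.mean(covered[(param, cond)])),
        }
    return report


def write_recovery_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
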