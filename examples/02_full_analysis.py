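"""Code responses, fit the mixed models and the hierarchical MPT.

Reproduces the package's analysis narrative on one synthetic Experiment-1
dataset: overall recall GLMM, conditional models, and the dual-process tree
with its headline recollection/familiarity contrasts.
"""

import correctmem as cm

config = cm.default_config(1)
trials = cm.code_trials(cm.simulate_dataset(config, design_seed=7))

# --- Overall recall (logistic mixed model, crossed random intercepts) --------
fit = cm.fit_binomial_mixed(trials, "real_recalled", "condition")
print("conditional recall probabilities:")
print(fit.estimates.round(3).to_string(index=False))
print("\nall-pairs contrasts (Tukey-adjusted):")
print(fit.contrasts.round(4).to_string(index=False))

# --- Conditional models (headline type x classification class) ---------------
cond = cm.conditional_models(trials, "real_recalled")
print("\nconditional recall by classification class:")
print(cond.estimates.round(3).to_string(index=False))

# --- Hierarchical MPT ---------------------------------------------------------
counts = cm.tabulate_mpt(trials)
post = cm.fit_hierarchical(counts)
print("\nposterior summaries (probability scale):")
print(post.summary().round(3).to_string(index=False))

for a, b in [("LC", "UC"), ("FRLC", "LC"), ("FRLC", "UC")]:
    mean, (lo, hi), credible = cm.credible_difference(post, "r", a, b)
    print(f"r({a}) - r({b}) = {mean:.3f} [{lo:.3f}, {hi:.3f}] credible={credible}")
mean, (lo, hi), credible = cm.familiarity_vs_others(post, "UC")
print(f"f(UC) - mean(others) = {mean:.3f} [{lo:.3f}, {hi:.3f}] credible={credible}")
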