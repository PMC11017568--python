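"""AIC model selection over candidate predictor sets.

For each call parameter the candidate models are body mass alone, mass plus
an additive emission-type effect, and mass crossed with emission type.  The
table mirrors the usual best-models report: ML log-likelihood, AIC, ΔAIC
and Akaike weights; the winner is refit by REML for reported estimates.
"""

import echoscale as es

dataset, truth = es.simulate_study_dataset(es.SimulationConfig(seed=11))

candidates = [
    "log_mass",
    "log_mass + emission",
    "log_mass + emission + log_mass:emission",
]

for response in ("log_peak", "log_bandwidth", "log_duration"):
    table, best = es.model_selection(dataset, response, candidates)
    print(f"\n=== {response} ===")
    print(table[["formula", "k", "logL_ML", "AIC", "dAIC", "weight"]].round(3))
    slope = best.coef["log_mass"]
    ci = es.slope_ci(best, 0.95).loc["log_mass"]
    print(
        f"best: {best.formula}\n"
        f"slope {slope:.3f} (95% CI {ci['low']:.3f}, {ci['high']:.3f}), "
        f"lambda {best.lambda_reml:.2f}, R2_lik {es.r2_lik(best):.2f}"
    )

# An Akaike weight is the probability-like share of evidence for a model
# within this candidate set; slopes are allometric exponents on log10 scales.
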