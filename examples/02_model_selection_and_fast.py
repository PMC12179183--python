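"""Choose the FA order and rank genotypes with the FAST statistics.

Fits FA(1)-FA(3) to a simulated two-factor MET, builds the
model-comparison table (log-likelihood, deviance, parameter count,
explained variance, ASVR), selects the most parsimonious adequate order,
and computes overall performance (OP), stability (RMSD), reliability and
the combined FAST index per genotype.
"""

import fastmet as fm

# two latent factors with small environment-specific (lack-of-fit) variance,
# so a two-factor model should satisfy the 80% adequacy thresholds
truth = fm.simulate_fa_truth(n_env=10, n_gen=100, k=2, seed=7,
                             ranges={"specific_variance": (5e3, 2e4)})
table = fm.simulate_met_phenotypes(truth, n_blocks=3, missing_rate=0.05, seed=8)

fits = {k: fm.fit_fa_model(table, k) for k in (1, 2, 3)}
summary = fm.summarize_models(fits)
print("model comparison:")
print(summary.round(2).to_string())

choice = fm.select_model(summary, var_threshold=80, asvr_threshold=80)
k = choice.selected_k
print(f"\nselected k = {k} (smallest k with var% and ASVR% >= 80)")

fast = fm.fast_summary(fits[k])
print("\ntop 5 genotypes by FAST index:")
print(fast.top(5).round(3).to_string())
print("\nOP is the genotype main effect on the first (performance) factor;")
print("RMSD measures deviations from that factor (lower = more stable);")
print("the index weights performance twice as much as stability and")
print("discounts genotypes whose predictions are unreliable.")
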