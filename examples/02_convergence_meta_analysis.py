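"""Stouffer's-Z convergence meta-analysis across the four conditions.

Runs DE for every (cell line, drug) condition, combines the per-gene Z-scores
over the five condition sets (prop, prim, daoy, npc, all), and prints the
convergent gene list plus the weighted/unweighted cross-condition
correlations.
"""

import convergex as cx

cfg = cx.SimulationConfig(n_genes=1500, frac_convergent=0.03, effect_size_log2=2.0, seed=11)
matrix, truth = cx.generate_experiment(cfg)

results = {
    f"{ct}_{drug[:4]}": cx.run_de(matrix, ct, drug)
    for ct in ("daoy", "npc")
    for drug in ("propranolol", "primidone")
}
panel = cx.zpanel_from_de(results)
conv = cx.run_convergence(panel)

hits = cx.convergent_genes(conv, "all")
true = set(truth.index[truth.is_convergent])
print(f"panel: {len(panel)} genes present in all four conditions")
print(f"'all'-set convergent DEGs at q<0.05: {len(hits)} "
      f"({len(set(hits) & true)} of {len(true)} truth genes recovered)")
print("\nstrongest convergent genes:")
print(conv.sort_values('q_all').head(5)[['z_prop', 'z_prim', 'z_all', 'q_all']].to_string())

print("\nunweighted cross-condition Pearson r (z-scores):")
print(cx.condition_correlation_matrix(panel).round(3).to_string())
print("\nweighted (z*|z|) correlations emphasize the most significant genes:")
print(cx.condition_correlation_matrix(panel, weighted=True).round(3).to_string())
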