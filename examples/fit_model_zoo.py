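"""Fit all twelve candidate endothermy path models to a synthetic
17-species trait table and rank them.

The table is drawn from the thermogenic-capacity model (zoo id VI), so with
luck — at n = 17 the information is limited — that model should top the
BIC ranking.  Columns: chi2 and its P (the model survives if P > 0.05),
BIC (lower is better), RMSEA (< 0.05 is adequate fit) and the share of
R_max variance explained.
"""

import endopath as ep

model = ep.model_zoo("VI", b3="covariance")
traits = ep.simulate_traits(model, dict(ep.DEFAULT_THETA), 17, seed=3)

fits = [
    ep.fit_ml(ep.model_zoo(mid), traits, ep.FitOptions(n_restarts=5, seed=0))
    for mid in ep.ZOO_IDS
]
table = ep.model_selection_table(fits)
print(table.round(3).to_string(index=False))

best = table.iloc[0]["model_id"]
print(f"\nBest model by BIC: {best}")
print("\nFitted structural equations of the best model:")
best_fit = next(f for f in fits if f.model_id == best)
print(ep.equations_report([best_fit], {best: ep.model_zoo(best)}))
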