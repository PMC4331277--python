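"""Fit the tuned, covariate-pruned density forest on zonal training data.

Aggregates the fine census one admin level up, summarises each covariate
zonally per coarse unit, builds the log-density response, and runs the
multi-stage estimation: mtry tuning, forest growing, and iterative
elimination of zero-importance covariates.
"""

from popforest import (
    ForestParams,
    LandscapeSpec,
    build_training_table,
    generate_landscape,
    rasterize_units,
    select_covariates,
    zonal_aggregate,
)

land = generate_landscape(LandscapeSpec(seed=42))
coarse = land.fine.aggregate(1)
labels = rasterize_units(coarse, land.template)
table = build_training_table(coarse, zonal_aggregate(land.stack, labels, coarse))
print(f"training table: {table.n_units} units, "
      f"{len(table.covariate_names)} covariates, response = {table.density_unit}")

reduced, model, history = select_covariates(table, ForestParams(seed=42))
for step in history:
    print(f"iteration {step['iteration']}: mtry={step['mtry']}, "
          f"OOB MSE={step['oob_mse']:.3f}, dropped {step['dropped'] or 'nothing'}")

print(f"\nfinal model: mtry={model.params.mtry}, "
      f"OOB variance explained {model.oob_var_explained:.1%}")
print("permutation importance (mean increase in OOB MSE):")
imp = model.importance["permutation"].sort_values(ascending=False)
for name, val in imp.items():
    print(f"  {name:12s} {val:8.4f}")

# Covariates that the density model actually uses (distance to built
# fabric, the built-class mask, distance to settlements) survive the
# elimination; the pure-noise layers are dropped with the message above.
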