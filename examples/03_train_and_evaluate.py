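"""Train the two-step purity forest and evaluate it on held-out samples.

Runs the full pipeline (stratified split -> dip screen -> importance
ranking -> OOB candidate sweep -> final forest) against the synthetic
truth, then reports held-out agreement and the per-entity purity quantiles
used to derive low-purity cut-offs.
"""

import purityforest as pf

cfg_sim = pf.SimulationConfig(
    n_probes=2000, n_informative=120, n_entity_probes=60, lump_panel_size=20,
    samples_per_entity=30, seed=1,
)
cohort = pf.simulate_cohort(cfg_sim)

config = pf.TrainConfig(seed=1)  # dip screen at 20%, 500 trees, 70/30 split
model = pf.train_purity_model(cohort.betas, cohort.truth, config)

print("candidate sweep (probe count -> OOB MSE):")
for i, (count, err) in enumerate(model.candidate_record):
    marker = " <- chosen" if i == model.selected_candidate else ""
    print(f"  {count:>5} probes: {err:.5f}{marker}")

test = cohort.betas.restrict_samples(model.test_ids)
pred, imputed = pf.predict_purity(model, test)
report = pf.evaluate_predictions(pred, cohort.truth.restrict(model.test_ids))
print(f"\nheld-out samples: n={report.n}")
print(f"Pearson r vs truth:      {report.pearson_r:.3f}")
print(f"MSE:                     {report.mse:.5f}")
print(f"median |pred - truth|:   {report.median_abs_diff:.4f}")

# per-entity quantiles of the predictions, the basis for entity-specific
# low-purity exclusion thresholds
grouped = pf.PurityTable(purity=pred.purity, source="RF_PREDICTED",
                         group=cohort.entity.loc[pred.sample_ids])
quant = pf.purity_quantiles_by_group(grouped)
print("\npredicted purity quantiles per entity:")
print(quant.to_frame().round(3).to_string(index=False))
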