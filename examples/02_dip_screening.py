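"""Screen probes for multimodality with the dip statistic.

Ranks every probe of a simulated cohort by Hartigan's dip, keeps the top
20%, and reports how many of the planted informative probes the screen
recovered versus a standard-deviation screen at the same fraction.
"""

import purityforest as pf

cfg = pf.SimulationConfig(
    n_probes=2000, n_informative=120, n_entity_probes=60, lump_panel_size=0,
    samples_per_entity=30, seed=7,
)
cohort = pf.simulate_cohort(cfg)
planted = set(cohort.informative_probes)

dip_rank = pf.rank_probes_by_dip(cohort.betas, min_samples=10)
sd_rank = pf.rank_probes_by_sd(cohort.betas, min_samples=10)

for name, ranking in (("dip", dip_rank), ("sd", sd_rank)):
    top = set(pf.select_top_fraction(ranking, 0.20))
    recovered = len(top & planted)
    print(f"{name:>3} screen, top 20% ({len(top)} probes): "
          f"recovered {recovered}/{len(planted)} planted informative probes")

# the dip values themselves: planted probes sit far above the unimodal bulk
stats = dip_rank.statistic
planted_mean = stats[stats.index.isin(planted)].mean()
rest_mean = stats[~stats.index.isin(planted)].mean()
print(f"mean dip: planted {planted_mean:.3f} vs all other probes {rest_mean:.3f}")
print("(the dip of an n-sample probe lives in [1/(2n), 0.25];"
      " multimodality pushes it up)")
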