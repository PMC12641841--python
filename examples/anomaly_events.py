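"""Flag person-specific exposure anomalies from the sparse component.

Each column of S is rescaled by its residual standard deviation so that
deviations are comparable across chemicals; cells beyond the pooled
95th/5th percentiles become High/Low exposure events.
"""

import numpy as np

import expomix as em

cfg = em.MixtureSimConfig(n_participants=200, n_analytes=20, true_rank=3,
                          spike_fraction=0.02, spike_scale=3.0,
                          lod_quantiles=0.1, noise_sd=0.3, seed=13)
study = em.generate_exposure_matrix(cfg)
panel = em.substitute_lod(study.panel)
scaled, factors, lod_scaled = em.scale_columns(panel)

res = em.decompose(scaled.values, lod_scaled.values, panel.detect_flag.values,
                   panel.missing_mask.values,
                   em.PCPParams(lam=em.default_lambda(*scaled.shape),
                                mu=em.default_mu(*scaled.shape), rank=3))

residuals = em.residual_matrix(scaled.values, res.L)
rescaled = em.rescale_sparse(res.S, residuals)
grid = em.classify_events(rescaled)

counts = grid.counts()
print("event labels across all person x chemical cells:", counts)
spikes = study.true_S != 0
high = grid.labels == "High"
print(f"true spike cells flagged High: {high[spikes].mean():.1%} "
      f"(background High rate {high.mean():.1%})")
print("a spike-cell High rate far above the background rate shows the "
      "sparse layer isolates genuine individual exposure episodes.")

tiers = em.tier_by_lod_median(panel)
vals, cnts = np.unique(tiers, return_counts=True)
print("\ncensoring-aware three-tier labels (below-LOD=Sparse, <=median=Low):",
      dict(zip(vals.tolist(), cnts.tolist())))
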