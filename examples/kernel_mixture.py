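"""Estimate joint mixture effects on a liver marker with kernel regression.

The model Y = h(X) + Z*beta + eps places a Gaussian-process prior on the
exposure-response surface h; binary inclusion indicators in the kernel
yield posterior inclusion probabilities (PIPs) that rank mixture members.
Here two of eight exposures truly drive the outcome through a sigmoidal
dose-response.
"""

import numpy as np

import expomix as em

cfg = em.MixtureSimConfig(n_participants=200, n_analytes=8, true_rank=3,
                          lod_quantiles=0.0, noise_sd=1.0,
                          h_form="sigmoidal", active_exposures=(1, 4), seed=3)
study = em.generate_outcomes(em.generate_exposure_matrix(cfg), cfg)

model = em.KMRModel(exposures=study.true_X, covariates=study.covariates.values,
                    outcome=study.outcomes["alt"].values)
post = em.fit(model, n_iter=800, n_burn=400, seed=3)

pips = em.pip(post)
print("posterior inclusion probabilities (truth: exposures 1 and 4 active):")
for m, p in enumerate(pips):
    marker = " <-- active" if m in (1, 4) else ""
    print(f"  exposure {m}: {p:.2f}{marker}")

eff = em.univariate_effect(post, 1)
print(f"\neffect of moving exposure 1 from its 25th to 75th percentile "
      f"(others at medians): {eff.estimate:+.2f} "
      f"[{eff.lower95:+.2f}, {eff.upper95:+.2f}]")

overall = em.overall_mixture_effect(post, grid=(0.25, 0.5, 0.75))
print("\noverall mixture effect vs the all-median profile:")
for e in overall:
    print(f"  {e.context}: {e.estimate:+.2f} [{e.lower95:+.2f}, {e.upper95:+.2f}]")
print("a rising overall curve means jointly higher exposure shifts the "
      "liver marker upward; intervals are 95% credible intervals.")
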