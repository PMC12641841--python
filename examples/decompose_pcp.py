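"""Split a censored exposure matrix into shared patterns plus spikes.

The decomposition X = L + S separates population-level co-exposure
structure (non-negative low-rank L) from person-specific exposure spikes
(sparse S), treating below-LOD cells as interval constraints [0, LOD]
rather than imputing them.  With stored ground truth we can measure how
well each part is recovered.
"""

import numpy as np
import numpy.linalg as la

import expomix as em

cfg = em.MixtureSimConfig(n_participants=200, n_analytes=30, true_rank=3,
                          spike_fraction=0.02, lod_quantiles=0.3,
                          noise_sd=0.0, seed=7)
study = em.generate_exposure_matrix(cfg)
panel = study.panel
scaled, factors, lod_scaled = em.scale_columns(panel)

params = em.PCPParams(lam=em.default_lambda(*scaled.shape),
                      mu=em.default_mu(*scaled.shape), rank=3)
res = em.decompose(scaled.values, lod_scaled.values, panel.detect_flag.values,
                   panel.missing_mask.values, params)

L_true = study.true_L / factors.values[None, :]
err = la.norm(res.L - L_true) / la.norm(L_true)
spikes = study.true_S != 0
print(f"30% of cells are left-censored; fit converged = {res.converged}")
print(f"relative error of recovered co-exposure structure L: {err:.3f}")
print(f"sparse part S: {np.count_nonzero(res.S)} non-zero cells "
      f"({spikes.sum()} true spikes)")
print("a small relative error means the shared exposure patterns were "
      "reconstructed despite one third of the data being below detection limits.")
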