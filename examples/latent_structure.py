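"""Latent co-exposure axes and correlation denoising.

After the decomposition, an SVD of the denoised matrix L gives the
dominant co-exposure axes; comparing Spearman correlations of raw vs
denoised data shows how the low-rank step sharpens chemical-class blocks.
"""

import expomix as em

cfg = em.MixtureSimConfig(n_participants=300, n_analytes=16, n_classes=4,
                          true_rank=4, spike_fraction=0.02, lod_quantiles=0.1,
                          noise_sd=1.0, seed=5)
study = em.generate_exposure_matrix(cfg)
panel = em.substitute_lod(study.panel)
scaled, factors, lod_scaled = em.scale_columns(panel)

res = em.decompose(scaled.values, lod_scaled.values, panel.detect_flag.values,
                   panel.missing_mask.values,
                   em.PCPParams(lam=em.default_lambda(*scaled.shape),
                                mu=em.default_mu(*scaled.shape), rank=4))

lat = em.svd_loadings(res.L, k=3, analytes=panel.analytes)
print("variance explained by the first three co-exposure axes:",
      [f"{v:.1%}" for v in lat.variance_explained])

table = em.component_loadings(lat, [1, 2, 3], panel.analyte_class)
lead = table[table.component == 1].nlargest(3, "loading")
print("\nstrongest loadings on component 1 (a shared exposure profile):")
print(lead[["analyte", "class", "loading"]].to_string(index=False))

comp = em.compare_raw_denoised(scaled.values, res.L,
                               classes=panel.analyte_class, columns=panel.analytes)
print("\nmean |Spearman rho| within chemical-class blocks:")
print(f"  raw matrix:      {comp.raw_blocks.within_mean_abs.mean():.3f}")
print(f"  denoised matrix: {comp.denoised_blocks.within_mean_abs.mean():.3f}")
print("higher within-block coherence after denoising means clearer "
      "chemical groupings once measurement noise and spikes are removed.")
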