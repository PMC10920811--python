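"""The two covariance feature pipelines on one cohort.

Band-pass filter into the seven analysis bands, estimate one SPD spatial
covariance per epoch and band, then either (a) fit CSP filters and take
log-variance features referenced to the first class, or (b) project with
PCA and map into the tangent space of the SPD manifold at the Karcher
mean. Both yield a plain epochs-x-features matrix for a linear model.
"""

from eegdecode import (
    CohortConfig,
    apply_filter_bank,
    csp_fit,
    csp_log_features,
    epoch_covariance,
    fit_riemann_references,
    generate_cohort,
    pca_fit,
    project_covariances,
    tangent_features,
)

epochs, _ = generate_cohort(
    CohortConfig(n_subjects_per_group=4, n_channels=12,
                 n_epochs_per_subject_per_task=10, tasks=("verb",), seed=1)
)
cov = epoch_covariance(apply_filter_bank(epochs), shrinkage=0.05)
print(f"covariance tensor: {cov.matrices.shape}  (epochs x bands x N x N)")

# supervised: CSP log-variance, J components per band
filt = csp_fit(cov, epochs.group, J=3)
f_csp = csp_log_features(cov, filt)
print(f"CSP features: {f_csp.values.shape}  e.g. {f_csp.feature_names[:3]}")
print(f"alpha1 eigenvalues (class-M variance ratios): {filt.eigenvalues[2].round(3)}")

# unsupervised: PCA projection + Riemannian tangent space
pca = pca_fit(cov, J=3)
proj = project_covariances(cov, pca)
refs = fit_riemann_references(proj)
f_ts = tangent_features(proj, refs)
print(f"tangent features: {f_ts.values.shape}  (K * J(J+1)/2 = 7*6 per epoch)")
# eigenvalues near 0.5 mean a band carries no class contrast; values far
# from 0.5 mark discriminative spatial directions
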