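"""Band-wise spatial covariance features: CSP log-variance and Riemannian
tangent-space vectorization.

Both covariance pipelines start from the same object: one symmetric
positive-definite (SPD) spatial covariance per epoch and per frequency
band, ``X in R^{K x N x N}``. The supervised route learns Common Spatial
Pattern (CSP) filters ``W`` from the class-mean covariances and uses
log-variance features referenced to the first class,

    F_i[j] = log((W^T S_i W)[j,j]) - log((W^T S_1 W)[j,j]),

while the unsupervised route projects with PCA filters and maps the
projected covariance into the tangent space of the SPD manifold at its
Karcher mean under the affine-invariant metric,

    F_i = Upper(logm(G^{-1/2} S_i G^{-1/2})),  G = Karcher mean,

with sqrt(2)-weighted off-diagonals so Euclidean length in the tangent
space equals Riemannian distance on the manifold. Filters and features
are computed per band and concatenated across the seven bands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sp_linalg

from .containers import BandEpochs, FeatureMatrix

_EIG_FLOOR = 1e-12


@dataclass
class BandCovarianceSet:
    """Per-epoch, per-band SPD spatial covariances (epochs x bands x N x N)."""

    matrices: np.ndarray
    bands: list[str]
    ch_names: list[str]
    labels: np.ndarray | None = None  # per-epoch group labels, if known

    def __post_init__(self) -> None:
        m = np.asarray(self.matrices, float)
        if m.ndim != 4 or m.shape[1] != len(self.bands) or m.shape[2] != m.shape[3]:
            raise ValueError("matrices must be (epochs, bands, N, N)")
        self.matrices = m

    @property
    def n_epochs(self) -> int:
        return self.matrices.shape[0]

    @property
    def n_channels(self) -> int:
        return self.matrices.shape[2]

    def select(self, mask) -> "BandCovarianceSet":
        labels = None if self.labels is None else np.asarray(self.labels, object)[mask]
        return BandCovarianceSet(self.matrices[mask], self.bands, self.ch_names, labels)


@dataclass
class SpatialFilters:
    """Fitted spatial projections, one N x J filter matrix per band.

    ``mode`` is ``"supervised-CSP"`` or ``"unsupervised-PCA"``;
    eigenvalues are sorted decreasing; for CSP, ``ref_logvar`` stores the
    log-diagonal of ``W^T S_1 W`` (first-class mean), the reference the
    log-variance features subtract.
    """

    mode: str
    bands: list[str]
    filters: list[np.ndarray]
    eigenvalues: list[np.ndarray]
    ch_names: list[str]
    ref_logvar: list[np.ndarray] | None = None
    first_class: str | None = None

    @property
    def n_components(self) -> int:
        return self.filters[0].shape[1]


@dataclass
class RiemannReference:
    """Karcher mean of a set of SPD matrices and its inverse square root."""

    mean: np.ndarray
    invsqrt: np.ndarray


# --------------------------------------------------------------- SPD helpers
def _check_spd(mat: np.ndarray, what: str = "matrix") -> None:
    if not np.allclose(mat, mat.T if mat.ndim == 2 else np.swapaxes(mat, -1, -2), atol=1e-10):
        raise ValueError(f"{what} is not symmetric")
    w = np.linalg.eigvalsh(mat)
    if np.any(w <= 0):
        raise ValueError(f"{what} is not positive-definite (min eigenvalue {w.min():.3e})")


def _sym_func(mats: np.ndarray, func) -> np.ndarray:
    """Apply a scalar function to the eigenvalues of stacked symmetric matrices."""
    w, v = np.linalg.eigh(mats)
    w = np.maximum(w, _EIG_FLOOR * np.max(w, axis=-1, keepdims=True))
    fw = func(w)
    return (v * fw[..., None, :]) @ np.swapaxes(v, -1, -2)


def sym_logm(mats: np.ndarray) -> np.ndarray:
    return _sym_func(mats, np.log)


def sym_expm(mats: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(mats)
    return (v * np.exp(w)[..., None, :]) @ np.swapaxes(v, -1, -2)


def sym_powm(mats: np.ndarray, p: float) -> np.ndarray:
    return _sym_func(mats, lambda w: w**p)


# ------------------------------------------------------------- covariances
def epoch_covariance(band_epochs: BandEpochs, shrinkage: float = 0.05) -> BandCovarianceSet:
    """Per-epoch sample covariance over time, shrunk toward scaled identity.

    ``S_hat = (1-g) S + g (tr S / N) I`` keeps the trace and guarantees
    positive-definiteness even for rank-deficient epochs; g=0.05 is a
    light conditioning default for a few hundred samples per epoch.
    """
    if not 0.0 <= shrinkage <= 1.0:
        raise ValueError("shrinkage must be in [0, 1]")
    x = band_epochs.data  # (bands, epochs, channels, samples)
    if x.shape[-1] < 2:
        raise ValueError("need more than one sample per epoch")
    if not np.all(np.isfinite(x)):
        bad = np.argwhere(~np.isfinite(x).all(axis=(0, 2, 3)))
        raise ValueError(f"non-finite input in epoch(s) {bad.ravel().tolist()}")
    xc = x - x.mean(axis=-1, keepdims=True)
    T = x.shape[-1]
    S = np.einsum("bect,bedt->becd", xc, xc) / (T - 1)
    if shrinkage > 0:
        N = S.shape[-1]
        tr = np.trace(S, axis1=-2, axis2=-1)[..., None, None]
        S = (1.0 - shrinkage) * S + shrinkage * (tr / N) * np.eye(N)
    src = band_epochs.source
    return BandCovarianceSet(
        matrices=np.swapaxes(S, 0, 1),
        bands=[b.name for b in band_epochs.bands],
        ch_names=list(src.ch_names),
        labels=np.asarray(src.group, object),
    )


def class_mean_covariances(
    covset: BandCovarianceSet, labels, classes: tuple[str, str]
) -> tuple[np.ndarray, np.ndarray]:
    """Arithmetic per-band mean covariance of each class (bands x N x N)."""
    labels = np.asarray(labels, object)
    masks = [labels == c for c in classes]
    if not (masks[0].any() and masks[1].any()):
        raise ValueError(f"both classes {classes} must be present")
    m1 = covset.matrices[masks[0]].mean(axis=0)
    m2 = covset.matrices[masks[1]].mean(axis=0)
    return m1, m2


# ---------------------------------------------------------------------- CSP
def csp_fit(
    covset: BandCovarianceSet,
    labels=None,
    J: int = 4,
    classes: tuple[str, str] = ("M", "H"),
) -> SpatialFilters:
    """Fit per-band CSP filters from class-mean covariances.

    Solves the generalized eigenproblem ``S1 w = lam (S1 + S2) w`` per
    band and keeps the J eigenvectors of largest eigenvalue (variance
    ratio of class 1 in the composite), normalized so
    ``w^T (S1+S2) w = 1``. ``classes[0]`` is the "first class" whose mean
    filtered log-variance becomes the feature reference.
    """
    if labels is None:
        labels = covset.labels
    if labels is None:
        raise ValueError("labels required")
    N = covset.n_channels
    if not 1 <= J <= N:
        raise ValueError(f"J must be in [1, {N}]")
    S1b, S2b = class_mean_covariances(covset, labels, classes)
    filters, eigvals, ref = [], [], []
    for S1, S2 in zip(S1b, S2b):
        lam, V = sp_linalg.eigh(S1, S1 + S2)  # ascending, V^T (S1+S2) V = I
        order = np.argsort(lam)[::-1][:J]
        W = V[:, order]
        filters.append(W)
        eigvals.append(lam[order])
        d = np.diag(W.T @ S1 @ W)
        ref.append(np.log(np.maximum(d, _EIG_FLOOR)))
    return SpatialFilters(
        mode="supervised-CSP",
        bands=list(covset.bands),
        filters=filters,
        eigenvalues=eigvals,
        ch_names=list(covset.ch_names),
        ref_logvar=ref,
        first_class=classes[0],
    )


def csp_log_features(covset: BandCovarianceSet, filters: SpatialFilters) -> FeatureMatrix:
    """Log-variance CSP features referenced to the first-class mean.

    Per band and component, ``log((W^T S_i W)[j,j]) - log((W^T S1 W)[j,j])``;
    bands concatenated, giving K*J features per epoch.
    """
    if filters.mode != "supervised-CSP" or filters.ref_logvar is None:
        raise ValueError("filters must be fitted in supervised-CSP mode")
    feats, names = [], []
    for b, (band, W, ref) in enumerate(zip(filters.bands, filters.filters, filters.ref_logvar)):
        # diag(W^T S W) for all epochs at once
        d = np.einsum("nj,enk,kj->ej", W, covset.matrices[:, b], W)
        if np.any(d <= 0):
            warnings.warn("nonpositive filtered variance floored")
            d = np.maximum(d, _EIG_FLOOR)
        feats.append(np.log(d) - ref)
        names.extend(f"{band}_csp{j + 1}" for j in range(W.shape[1]))
    return FeatureMatrix(np.hstack(feats), names, pipeline="supervised")


# ---------------------------------------------------------------------- PCA
def pca_fit(covset: BandCovarianceSet, J: int) -> SpatialFilters:
    """Per-band PCA filters: top-J eigenvectors of the mean covariance.

    The mean is taken over all training epochs with classes pooled. (For
    equal-length, per-epoch-demeaned data this equals the covariance of
    the concatenated signal, so the two common readings coincide.)
    """
    N = covset.n_channels
    if not 1 <= J <= N:
        raise ValueError(f"J must be in [1, {N}]")
    filters, eigvals = [], []
    for b in range(len(covset.bands)):
        S = covset.matrices[:, b].mean(axis=0)
        w, V = np.linalg.eigh(S)
        order = np.argsort(w)[::-1][:J]
        filters.append(V[:, order])
        eigvals.append(w[order])
    return SpatialFilters(
        mode="unsupervised-PCA",
        bands=list(covset.bands),
        filters=filters,
        eigenvalues=eigvals,
        ch_names=list(covset.ch_names),
    )


def project_covariances(covset: BandCovarianceSet, filters: SpatialFilters) -> BandCovarianceSet:
    """Congruence-project each covariance: ``S -> W^T S W`` per band."""
    mats = np.stack(
        [
            np.einsum("nj,enk,kl->ejl", W, covset.matrices[:, b], W)
            for b, W in enumerate(filters.filters)
        ],
        axis=1,
    )
    comp_names = [f"c{j + 1}" for j in range(filters.n_components)]
    return BandCovarianceSet(mats, list(covset.bands), comp_names, covset.labels)


# ------------------------------------------------------------ Riemannian ops
def riemannian_mean(mats: np.ndarray, tol: float = 1e-8, max_iter: int = 50) -> RiemannReference:
    """Karcher (Frechet) mean under the affine-invariant metric.

    Fixed-point iteration: whiten by the current mean, average the matrix
    logs, and move the mean along that tangent direction until the mean
    log-gradient's Frobenius norm falls below ``tol``.
    """
    mats = np.asarray(mats, float)
    if mats.ndim != 3 or mats.shape[1] != mats.shape[2]:
        raise ValueError("mats must be (n, J, J)")
    _check_spd(mats, "input")
    G = mats.mean(axis=0)
    for _ in range(max_iter):
        G_isq = sym_powm(G, -0.5)
        G_sq = sym_powm(G, 0.5)
        logs = sym_logm(G_isq @ mats @ G_isq)
        grad = logs.mean(axis=0)
        if np.linalg.norm(grad, "fro") <= tol:
            return RiemannReference(mean=G, invsqrt=G_isq)
        G = G_sq @ sym_expm(grad) @ G_sq
        G = 0.5 * (G + G.T)
    raise RuntimeError(
        f"Karcher mean did not converge in {max_iter} iterations "
        f"(gradient norm {np.linalg.norm(grad, 'fro'):.3e})"
    )


def geodesic_midpoint(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Closed-form affine-invariant geodesic midpoint of two SPD matrices."""
    A_sq, A_isq = sym_powm(A, 0.5), sym_powm(A, -0.5)
    return A_sq @ sym_powm(A_isq @ B @ A_isq, 0.5) @ A_sq


def airm_distance(A: np.ndarray, B: np.ndarray) -> float:
    """Affine-invariant Riemannian distance sqrt(sum log^2 eig(A^-1 B))."""
    lam = sp_linalg.eigh(B, A, eigvals_only=True)
    return float(np.sqrt(np.sum(np.log(lam) ** 2)))


def tangent_vectorize(
    covs: np.ndarray, ref: RiemannReference, weight_offdiag: bool = True
) -> np.ndarray:
    """Map SPD matrices to tangent-space vectors at the reference mean.

    Each matrix becomes the upper triangle of
    ``logm(G^{-1/2} S G^{-1/2})``; with ``weight_offdiag`` the
    off-diagonal entries are scaled by sqrt(2) so the vector's Euclidean
    norm equals the affine-invariant distance to the mean, giving
    J(J+1)/2 components per matrix.
    """
    covs = np.asarray(covs, float)
    single = covs.ndim == 2
    if single:
        covs = covs[None]
    _check_spd(covs, "input")
    _check_spd(ref.mean, "reference")
    L = sym_logm(ref.invsqrt @ covs @ ref.invsqrt)
    J = L.shape[-1]
    iu, ju = np.triu_indices(J)
    vecs = L[:, iu, ju]
    if weight_offdiag:
        vecs = vecs * np.where(iu == ju, 1.0, np.sqrt(2.0))
    return vecs[0] if single else vecs


def fit_riemann_references(proj: BandCovarianceSet, **kwargs) -> list[RiemannReference]:
    """Karcher mean of the projected covariances, per band."""
    return [riemannian_mean(proj.matrices[:, b], **kwargs) for b in range(len(proj.bands))]


def tangent_features(
    proj: BandCovarianceSet, refs: list[RiemannReference], weight_offdiag: bool = True
) -> FeatureMatrix:
    """Concatenated per-band tangent-space features (K * J(J+1)/2 per epoch)."""
    feats, names = [], []
    J = proj.n_channels
    iu, ju = np.triu_indices(J)
    for b, (band, ref) in enumerate(zip(proj.bands, refs)):
        feats.append(tangent_vectorize(proj.matrices[:, b], ref, weight_offdiag))
        names.extend(f"{band}_ts_{i + 1}_{j + 1}" for i, j in zip(iu, ju))
    return FeatureMatrix(np.hstack(feats), names, pipeline="riemann")
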