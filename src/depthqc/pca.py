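"""Covariance-based principal component analysis for sample QC.

The n x d data matrix X (samples x features) is column-centered and
decomposed so that the scores Z = X_c A are the coordinates of the samples in
the orthonormal eigenbasis A of the sample covariance matrix S.  The
eigenvalue lambda_j equals the variance of the j-th score column, and
V_j = lambda_j / sum(lambda) is the proportion of variance explained.

For d >> n (the usual genomics regime) the decomposition runs through the
thin SVD of the centered matrix, which is the n-dominant dual route to the
eigendecomposition of S.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, InvalidInputError

__all__ = ["PCAResult", "fit_pca", "scree"]


@dataclass
class PCAResult:
    """Loadings A (d x r), scores Z = X_c A (n x r), eigenvalues and variance
    proportions of the retained components, plus the column means used for
    centering."""

    loadings: np.ndarray
    scores: np.ndarray
    eigenvalues: np.ndarray
    var_prop: np.ndarray
    center: np.ndarray

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def fit_pca(X, r: int | None = None, scale: bool = False) -> PCAResult:
    """Fit covariance PCA on all samples jointly.

    Parameters
    ----------
    X : (n, d) array, samples x features, no non-finite entries.
    r : number of components to retain (default: full rank, min(n-1, d)).
    scale : divide columns by their standard deviation before decomposition
        (correlation PCA).  Off by default: the method operates on the sample
        covariance matrix.

    The sign of each loading column is fixed so that its largest-magnitude
    entry is positive, making results reproducible across platforms.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, d = X.shape
    if n < 2:
        raise InvalidInputError("PCA needs at least 2 samples")
    if not np.all(np.isfinite(X)):
        raise InvalidInputError("data matrix contains non-finite entries")
    rmax = min(n - 1, d)
    if r is None:
        r = rmax
    if not 1 <= r <= rmax:
        raise InvalidInputError(f"r must be in [1, {rmax}], got {r}")

    center = X.mean(axis=0)
    Xc = X - center
    if scale:
        sd = Xc.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Xc = Xc / sd
    total_var = float(np.sum(Xc.var(axis=0, ddof=1)))
    if total_var == 0.0:
        raise DegenerateInputError("constant data matrix: zero total variance")

    # thin SVD: X_c = U S Vt; columns of V are the eigenvectors of S with
    # eigenvalues S^2 / (n - 1)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigvals = S**2 / (n - 1)
    loadings = Vt[:r].T
    scores = U[:, :r] * S[:r]

    # deterministic sign convention
    for j in range(r):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] = -loadings[:, j]
            scores[:, j] = -scores[:, j]

    var_prop = eigvals[:r] / total_var
    return PCAResult(loadings=loadings, scores=scores,
                     eigenvalues=eigvals[:r], var_prop=var_prop,
                     center=center)


def scree(result: PCAResult) -> list[tuple[int, float]]:
    """(component, variance proportion) pairs for elbow inspection.

    The sequence is non-increasing and sums to at most 1 (exactly 1 when all
    non-null components are retained).
    """
    return [(j + 1, float(v)) for j, v in enumerate(result.var_prop)]
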