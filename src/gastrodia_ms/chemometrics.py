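"""Correlation PCA, varimax rotation and the KMO sampling-adequacy statistic.

The chemometric stage asks whether cultivars cluster by geography when
described by their five class-level concentration vectors.  Because class
concentrations span orders of magnitude, PCA runs on the correlation matrix
(columns standardized to mean 0, SD 1).  Components are ordered by
decreasing eigenvalue with a deterministic sign convention: the largest-
magnitude loading of each component is made positive.

Varimax rotates a loading subset toward simple structure by maximizing the
variance of squared loadings; the rotation is orthogonal, so communalities
(row sums of squared loadings) are preserved.  KMO compares simple to
anti-image partial correlations: values near 1 mean the correlation
structure is dominated by shared factors, 0.5 is the no-structure baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PCAResult", "pca", "varimax", "kmo"]


@dataclass(frozen=True)
class PCAResult:
    loadings: np.ndarray  # variables x components (unrotated)
    scores: np.ndarray  # samples x components
    explained_variance_pct: np.ndarray  # over ALL variables, sums to 100
    eigenvalues: np.ndarray
    rotation: np.ndarray | None  # orthonormal, applied to the retained block
    rotated_loadings: np.ndarray | None
    kmo: float | None
    n_components: int
    variables: tuple[str, ...] = ()
    samples: tuple[str, ...] = ()


def _standardize(x: np.ndarray, names: tuple[str, ...]) -> np.ndarray:
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    flat = np.where(sd == 0)[0]
    if flat.size:
        bad = [names[i] if names else str(i) for i in flat]
        raise ValueError(f"constant column(s) after standardization: {bad}")
    return (x - mean) / sd


def pca(
    matrix,
    n_components: int = 2,
    rotate: bool = True,
    compute_kmo: bool = True,
) -> PCAResult:
    """Correlation-matrix PCA with optional varimax rotation and KMO.

    ``matrix`` is samples × variables (ndarray or DataFrame).  Loadings are
    eigenvectors scaled by sqrt(eigenvalue), i.e. variable–component
    correlations; scores are the standardized data projected onto the
    eigenvectors.
    """
    variables: tuple[str, ...] = ()
    samples: tuple[str, ...] = ()
    if hasattr(matrix, "columns"):  # DataFrame
        variables = tuple(map(str, matrix.columns))
        samples = tuple(map(str, matrix.index))
        matrix = matrix.to_numpy(dtype=float)
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need at least 2 samples and 2 variables")
    n, p = x.shape
    if not 1 <= n_components <= p:
        raise ValueError("n_components must be in [1, n_variables]")

    z = _standardize(x, variables)
    corr = np.corrcoef(z, rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]

    # sign convention: largest-|loading| entry of each component positive
    for j in range(p):
        k = np.argmax(np.abs(eigvec[:, j]))
        if eigvec[k, j] < 0:
            eigvec[:, j] = -eigvec[:, j]

    loadings = eigvec * np.sqrt(eigval)
    scores = z @ eigvec
    explained = 100.0 * eigval / p

    rotation = rotated = None
    if rotate and n_components >= 2:
        rotated, rotation = varimax(loadings[:, :n_components])
    kmo_val = kmo(x) if compute_kmo else None

    return PCAResult(
        loadings=loadings,
        scores=scores,
        explained_variance_pct=explained,
        eigenvalues=eigval,
        rotation=rotation,
        rotated_loadings=rotated,
        kmo=kmo_val,
        n_components=n_components,
        variables=variables,
        samples=samples,
    )


def varimax_criterion(loadings: np.ndarray) -> float:
    """Raw varimax objective: sum over components of var of squared loadings."""
    sq = np.asarray(loadings) ** 2
    return float(np.sum(sq.var(axis=0)))


def varimax(
    loadings, tol: float = 1e-10, max_iter: int = 500
) -> tuple[np.ndarray, np.ndarray]:
    """Varimax rotation (Kaiser's SVD iteration, raw criterion).

    Returns (rotated loadings, rotation matrix R) with rotated = loadings @ R
    and RᵀR = I.  The criterion is non-decreasing across iterations; raises
    on non-convergence, carrying the last iterate in the exception args.
    """
    a = np.asarray(loadings, dtype=float)
    if a.ndim != 2 or a.shape[1] < 2:
        raise ValueError("varimax needs at least 2 components")
    p, k = a.shape
    r = np.eye(k)
    d_old = 0.0
    for _ in range(max_iter):
        lam = a @ r
        u, s, vt = np.linalg.svd(
            a.T @ (lam**3 - lam @ np.diag(np.sum(lam**2, axis=0)) / p)
        )
        r = u @ vt
        d = float(np.sum(s))
        if d_old != 0 and (d - d_old) < tol * d_old:
            break
        d_old = d
    else:
        raise RuntimeError("varimax failed to converge", a @ r, r)
    rotated = a @ r
    # deterministic sign convention on the rotated block as well
    for j in range(k):
        i = np.argmax(np.abs(rotated[:, j]))
        if rotated[i, j] < 0:
            rotated[:, j] = -rotated[:, j]
            r[:, j] = -r[:, j]
    return rotated, r


def kmo(matrix) -> float:
    """Kaiser–Meyer–Olkin measure of sampling adequacy.

    KMO = Σr²ᵢⱼ / (Σr²ᵢⱼ + Σq²ᵢⱼ) over i≠j, where q are the anti-image
    partial correlations obtained from the inverse correlation matrix.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[1] < 3:
        raise ValueError("KMO needs at least 3 variables")
    corr = np.corrcoef(x, rowvar=False)
    try:
        inv = np.linalg.inv(corr)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular correlation matrix") from exc
    if np.linalg.cond(corr) > 1e12:
        raise ValueError("singular correlation matrix")
    d = np.sqrt(np.outer(np.diag(inv), np.diag(inv)))
    partial = -inv / d
    off = ~np.eye(corr.shape[0], dtype=bool)
    r2 = np.sum(corr[off] ** 2)
    q2 = np.sum(partial[off] ** 2)
    return float(r2 / (r2 + q2))
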