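"""Dimension reduction of variable blocks: parallel analysis + varimax PCA.

Each block (climate, soil, log10 traits) is reduced to the components
retained by Horn's parallel analysis, then varimax-rotated for simple
structure.  Rotated scores are the model predictors downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class RotatedSpace:
    """Varimax-rotated retained components of one variable block."""

    block: str
    variables: list[str]
    loadings: np.ndarray  # (p, k) rotated loadings
    scores: np.ndarray  # (n, k), column mean 0
    variance_explained: np.ndarray  # (k,) fraction of total variance
    k: int
    rotation: np.ndarray = field(repr=False, default=None)  # (k, k) orthonormal

    @property
    def component_names(self) -> list[str]:
        return [f"{self.block}.PC{j + 1}" for j in range(self.k)]

    def scores_frame(self, index=None) -> pd.DataFrame:
        return pd.DataFrame(self.scores, columns=self.component_names, index=index)

    def loadings_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.loadings, index=self.variables, columns=self.component_names
        )


def _standardize(X: np.ndarray, variables: list[str] | None = None) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        idx = np.nonzero(sd == 0)[0]
        bad = [variables[i] for i in idx] if variables else [int(i) for i in idx]
        raise ValueError(f"zero-variance column(s): {bad}")
    return (X - X.mean(axis=0)) / sd


def _corr_eigvals(X: np.ndarray) -> np.ndarray:
    """Eigenvalues of the correlation matrix, descending."""
    Z = _standardize(X)
    n = Z.shape[0]
    s = np.linalg.svd(Z / np.sqrt(n - 1), compute_uv=False)
    ev = np.zeros(X.shape[1])
    ev[: len(s)] = s**2
    return ev


def parallel_analysis(
    X: np.ndarray, n_iter: int = 1000, seed: int = 0
) -> tuple[int, dict]:
    """Horn's parallel analysis on the correlation matrix of ``X``.

    Compares observed eigenvalues with the mean eigenvalues of ``n_iter``
    standard-normal matrices of the same shape; components are retained
    sequentially while the observed eigenvalue exceeds the random mean
    (equivalently, while the bias-adjusted eigenvalue exceeds 1).

    Returns ``(k, details)`` with the observed and mean random spectra.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if p < 2:
        raise ValueError("parallel analysis needs at least 2 columns")
    if n <= p:
        raise ValueError("parallel analysis needs more rows than columns")
    observed = _corr_eigvals(X)
    rng = np.random.default_rng(seed)
    rand_sum = np.zeros(p)
    for _ in range(n_iter):
        R = rng.standard_normal((n, p))
        rand_sum += _corr_eigvals(R)
    rand_mean = rand_sum / n_iter
    keep = observed > rand_mean
    k = 0
    for flag in keep:
        if not flag:
            break
        k += 1
    return k, {"observed": observed, "random_mean": rand_mean, "adjusted": observed - (rand_mean - 1.0)}


def varimax(
    loadings: np.ndarray,
    kaiser_normalize: bool = True,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> tuple[np.ndarray, np.ndarray]:
    """Varimax rotation of a loading matrix.

    Maximizes the sum over components of the variance of squared loadings,
    with Kaiser row-normalization on by default (rows scaled to unit
    communality before rotation, restored after).  Returns
    ``(rotated_loadings, rotation)`` with ``rotation`` orthonormal.
    """
    L = np.asarray(loadings, dtype=float).copy()
    p, k = L.shape
    if k < 2:
        return L, np.eye(k)
    h = np.sqrt((L**2).sum(axis=1))
    if kaiser_normalize:
        if np.any(h == 0):
            raise ValueError("zero-communality row; cannot Kaiser-normalize")
        L = L / h[:, None]
    R = np.eye(k)
    d = 0.0
    for _ in range(max_iter):
        LR = L @ R
        # gradient of the varimax criterion (gamma = 1)
        B = L.T @ (LR**3 - LR @ np.diag((LR**2).sum(axis=0)) / p)
        u, s, vt = np.linalg.svd(B)
        R = u @ vt
        d_new = s.sum()
        if d_new < d * (1 + tol):
            break
        d = d_new
    rotated = L @ R
    if kaiser_normalize:
        rotated = rotated * h[:, None]
    return rotated, R


def pca_varimax(
    X: np.ndarray, k: int, variables: list[str] | None = None, block: str = "block"
) -> RotatedSpace:
    """Correlation-matrix PCA with varimax rotation of the first k components.

    Loadings are eigenvectors scaled by the square roots of eigenvalues
    (variable-component correlations); rotated scores are the regression
    scores ``Z L (L'L)^{-1}``, which have column mean 0.  Component signs
    are fixed so each column's largest-|loading| entry is positive.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if not (1 <= k <= p):
        raise ValueError(f"k={k} must be in [1, {p}]")
    if variables is None:
        variables = [f"v{j + 1}" for j in range(p)]
    Z = _standardize(X, variables)
    U, s, Vt = np.linalg.svd(Z / np.sqrt(n - 1), full_matrices=False)
    eigvals = s**2
    loadings = Vt.T[:, :k] * s[:k]

    rotated, R = varimax(loadings)

    # sign convention: largest-|loading| entry of each column positive
    signs = np.sign(rotated[np.abs(rotated).argmax(axis=0), np.arange(k)])
    signs[signs == 0] = 1.0
    rotated = rotated * signs

    scores = Z @ rotated @ np.linalg.inv(rotated.T @ rotated)
    var_expl = (rotated**2).sum(axis=0) / p
    return RotatedSpace(
        block=block,
        variables=list(variables),
        loadings=rotated,
        scores=scores,
        variance_explained=var_expl,
        k=k,
        rotation=R,
    )


def communalities(loadings: np.ndarray) -> np.ndarray:
    """Row sums of squared loadings (invariant under orthogonal rotation)."""
    return (np.asarray(loadings) ** 2).sum(axis=1)


def cross_block_correlation(
    spaces: list[RotatedSpace],
    extra_columns: pd.DataFrame | None = None,
    threshold: float = 0.54,
) -> tuple[pd.DataFrame, float]:
    """Pearson correlations among all retained components (+ extra columns).

    Returns the full correlation matrix and the maximum absolute
    off-diagonal value; warns when that maximum exceeds ``threshold``.
    """
    frames = [sp.scores_frame().reset_index(drop=True) for sp in spaces]
    n_rows = {len(f) for f in frames}
    if extra_columns is not None:
        frames.append(extra_columns.reset_index(drop=True))
        n_rows.add(len(extra_columns))
    if len(n_rows) != 1:
        raise ValueError(f"score matrices are not row-aligned: lengths {sorted(n_rows)}")
    all_scores = pd.concat(frames, axis=1)
    corr = all_scores.corr()
    off = corr.to_numpy().copy()
    np.fill_diagonal(off, 0.0)
    max_abs = float(np.abs(off).max()) if off.size > 1 else 0.0
    if max_abs > threshold:
        warnings.warn(
            f"max |r| between retained components is {max_abs:.3f} > {threshold}",
            stacklevel=2,
        )
    return corr, max_abs
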