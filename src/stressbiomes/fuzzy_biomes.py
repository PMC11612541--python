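"""Fuzzy c-means biomes: clustering, model selection, ternary classification.

The forest-predicted axis pairs are clustered with fuzzy c-means; the
number of clusters is selected by the fuzzy silhouette index over
repeated restarts.  With K = 4, the cluster nearest each triangle vertex
is labelled with that vertex strategy (drought, shade, waterlogging/cold)
and the leftover cluster is the low-intermediate group.  Dropping the
low-intermediate membership column and renormalizing rows gives a ternary
membership scheme; hexagons whose two largest ternary memberships both
fall in the split band (0.4-0.6 by default) are polytolerant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.metrics import silhouette_samples

from stressbiomes.config import STRATEGIES

LOW_INTERMEDIATE = "low_intermediate"


@dataclass
class FuzzyPartition:
    """Result of one fuzzy c-means run."""

    U: np.ndarray  # (n, K) memberships, rows sum to 1
    centroids: np.ndarray  # (K, 2)
    m: float
    objective: float
    iterations: int
    converged: bool
    labels: dict[int, str] | None = None  # cluster index -> strategy name

    @property
    def K(self) -> int:
        return self.U.shape[1]

    def hard_labels(self) -> np.ndarray:
        return self.U.argmax(axis=1)


def _memberships(X: np.ndarray, C: np.ndarray, m: float) -> tuple[np.ndarray, np.ndarray]:
    """Membership update; returns (U, squared distances)."""
    D2 = cdist(X, C, metric="sqeuclidean")
    U = np.zeros_like(D2)
    zero = D2 <= 1e-300
    any_zero = zero.any(axis=1)
    with np.errstate(divide="ignore"):
        W = D2 ** (-1.0 / (m - 1.0))
    ok = ~any_zero
    U[ok] = W[ok] / W[ok].sum(axis=1, keepdims=True)
    # a point sitting on a centroid belongs fully to (the first of) them
    if any_zero.any():
        rows = np.nonzero(any_zero)[0]
        cols = zero[rows].argmax(axis=1)
        U[rows, cols] = 1.0
    return U, D2


def fuzzy_kmeans(
    X: np.ndarray,
    K: int,
    m: float = 2.0,
    max_iter: int = 300,
    tol: float = 1e-5,
    seed: int = 0,
    debug: bool = False,
) -> FuzzyPartition:
    """Fuzzy c-means with Euclidean distance.

    Alternates the centroid update ``c_k = sum u_ik^m x_i / sum u_ik^m``
    with the membership update ``u_ik = 1 / sum_j (d_ik/d_ij)^(2/(m-1))``
    until ``max |dU| < tol`` or ``max_iter``.  The objective
    ``J = sum u^m d^2`` is non-increasing across iterations (asserted per
    iteration when ``debug``).
    """
    X = np.asarray(X, dtype=float)
    n = len(X)
    if K >= n:
        raise ValueError(f"K={K} must be smaller than n={n}")
    if K < 2:
        raise ValueError("K must be >= 2")
    if m <= 1:
        raise ValueError("fuzziness m must be > 1")
    rng = np.random.default_rng(seed)
    C = X[rng.choice(n, size=K, replace=False)]
    U, D2 = _memberships(X, C, m)
    prev_J = float((U**m * D2).sum())
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        Um = U**m
        C = (Um.T @ X) / Um.sum(axis=0)[:, None]
        U_new, D2 = _memberships(X, C, m)
        J = float((U_new**m * D2).sum())
        if debug and J > prev_J + 1e-9 * max(1.0, abs(prev_J)):
            raise AssertionError(f"objective increased: {prev_J} -> {J}")
        delta = float(np.abs(U_new - U).max())
        U = U_new
        prev_J = J
        if delta < tol:
            converged = True
            break
    return FuzzyPartition(
        U=U, centroids=C, m=m, objective=prev_J, iterations=it, converged=converged
    )


def fuzzy_silhouette(
    X: np.ndarray, partition: FuzzyPartition, alpha: float = 1.0
) -> float:
    """Fuzzy silhouette: crisp silhouettes weighted by the membership gap.

    ``FS = sum_i (u_ip - u_iq)^alpha s_i / sum_i (u_ip - u_iq)^alpha``
    where p and q index each row's largest and second-largest memberships
    and s_i is the crisp silhouette under hard assignment.
    """
    hard = partition.hard_labels()
    if len(np.unique(hard)) < 2:
        raise ValueError("degenerate partition: fewer than 2 non-empty hard clusters")
    s = silhouette_samples(X, hard)
    U_sorted = np.sort(partition.U, axis=1)
    w = (U_sorted[:, -1] - U_sorted[:, -2]) ** alpha
    total = w.sum()
    if total == 0:
        return 0.0
    return float((w * s).sum() / total)


def select_k_fuzzy_silhouette(
    X: np.ndarray,
    k_range: tuple[int, ...] = (2, 3, 4, 5, 6, 7, 8),
    n_rep: int = 99,
    m: float = 2.0,
    alpha: float = 1.0,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-5,
) -> tuple[int, dict[int, float], dict[int, FuzzyPartition]]:
    """Select the number of clusters by the fuzzy silhouette index.

    For each K, runs ``n_rep`` restarts with distinct seeds, keeps the
    lowest-objective partition, and scores it; restarts whose hard
    partition leaves a cluster empty are discarded with a warning.
    Returns ``(best_K, {K: FS}, {K: best partition})``.
    """
    X = np.asarray(X, dtype=float)
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    ss = np.random.SeedSequence(seed)
    scores: dict[int, float] = {}
    best_parts: dict[int, FuzzyPartition] = {}
    for K in k_range:
        if not (2 <= K < len(X)):
            raise ValueError(f"K={K} outside valid range [2, n-1]")
        child_seeds = ss.spawn(1)[0].generate_state(n_rep) % (2**31)
        best: FuzzyPartition | None = None
        n_degenerate = 0
        for s_run in child_seeds:
            part = fuzzy_kmeans(X, K, m=m, max_iter=max_iter, tol=tol, seed=int(s_run))
            if len(np.unique(part.hard_labels())) < K:
                n_degenerate += 1
                continue
            if best is None or part.objective < best.objective:
                best = part
        if n_degenerate:
            warnings.warn(
                f"K={K}: discarded {n_degenerate}/{n_rep} degenerate restarts",
                stacklevel=2,
            )
        if best is None:
            raise RuntimeError(f"K={K}: all {n_rep} restarts were degenerate")
        scores[K] = fuzzy_silhouette(X, best, alpha=alpha)
        best_parts[K] = best
    best_K = max(scores, key=lambda k: scores[k])
    return best_K, scores, best_parts


def label_clusters_and_rescale(
    partition: FuzzyPartition,
    triangle: dict[str, tuple[float, float]],
    index=None,
) -> tuple[pd.DataFrame, dict[int, str]]:
    """Label the K=4 clusters and rescale memberships to the ternary scheme.

    Each triangle vertex claims its nearest centroid; the three claimed
    centroids must be distinct (otherwise the labelling is ambiguous and
    an error is raised).  The leftover centroid is the low-intermediate
    group; its membership column is dropped and the remaining three are
    renormalized row-wise.  The hard biome label is the argmax of the
    ternary row, with ties broken in the fixed order drought < shade <
    waterlogging/cold.
    """
    if partition.K != 4:
        raise ValueError(f"ternary labelling requires K=4, got K={partition.K}")
    verts = np.array([triangle[s] for s in STRATEGIES], dtype=float)
    d = cdist(verts, partition.centroids)  # (3, 4)
    claimed = d.argmin(axis=1)
    if len(set(claimed)) != 3:
        raise ValueError(
            "ambiguous cluster labelling: two vertices claim the same centroid "
            f"(claims: {dict(zip(STRATEGIES, claimed.tolist()))})"
        )
    labels = {int(c): s for s, c in zip(STRATEGIES, claimed)}
    leftover = (set(range(4)) - set(labels)).pop()
    labels[leftover] = LOW_INTERMEDIATE
    partition.labels = labels

    keep = [int(c) for c in claimed]  # column order: drought, shade, wc
    U3 = partition.U[:, keep]
    row_sums = U3.sum(axis=1)
    assert np.all(row_sums > 0), "zero ternary row-sum is impossible for m > 1"
    T = U3 / row_sums[:, None]

    # argmax with canonical tie-break: first (drought) wins ties by order
    hard = T.argmax(axis=1)
    out = pd.DataFrame(
        {
            "t_drought": T[:, 0],
            "t_shade": T[:, 1],
            "t_waterlogging_cold": T[:, 2],
            "stb": np.asarray(STRATEGIES)[hard],
        },
        index=index,
    )
    return out, labels


_PAIR_CLASS = {
    frozenset(["t_drought", "t_shade"]): "shade_drought",
    frozenset(["t_shade", "t_waterlogging_cold"]): "shade_wc",
    frozenset(["t_drought", "t_waterlogging_cold"]): "excluded_pair",
}

_T_COLS = ["t_drought", "t_shade", "t_waterlogging_cold"]


def detect_polytolerance(
    ternary: pd.DataFrame, band_lo: float = 0.4, band_hi: float = 0.6
) -> pd.Series:
    """Classify each row's polytolerance from its ternary memberships.

    A hexagon is polytolerant iff its two largest ternary memberships both
    lie inside ``[band_lo, band_hi]`` (endpoints inclusive).  The class is
    ``shade_drought`` or ``shade_wc`` by the identity of the pair; a
    drought-waterlogging/cold split is geometrically possible but is not a
    hotspot class and is flagged ``excluded_pair``; everything else is
    ``none``.
    """
    if not (0 <= band_lo < band_hi <= 1):
        raise ValueError("band must satisfy 0 <= lo < hi <= 1")
    T = ternary[_T_COLS].to_numpy()
    order = np.argsort(T, axis=1)
    top, second = order[:, -1], order[:, -2]
    t_top = T[np.arange(len(T)), top]
    t_second = T[np.arange(len(T)), second]
    in_band = (
        (t_top >= band_lo) & (t_top <= band_hi)
        & (t_second >= band_lo) & (t_second <= band_hi)
    )
    classes = np.full(len(T), "none", dtype=object)
    for i in np.nonzero(in_band)[0]:
        pair = frozenset([_T_COLS[top[i]], _T_COLS[second[i]]])
        classes[i] = _PAIR_CLASS[pair]
    return pd.Series(classes, index=ternary.index, name="polytolerance")


def polytolerance_summary(poly: pd.Series) -> pd.DataFrame:
    """Counts and percentages of each polytolerance class among all rows."""
    total = len(poly)
    counts = poly.value_counts()
    rows = []
    for cls in ("shade_drought", "shade_wc", "excluded_pair"):
        n = int(counts.get(cls, 0))
        rows.append(
            {"class": cls, "n": n, "total": total, "pct": 100.0 * n / total if total else 0.0}
        )
    return pd.DataFrame(rows)
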