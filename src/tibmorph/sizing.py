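"""Tibial-component sizing: K-means on (ML, AP), WSS curve, elbow selection.

The cluster count is chosen on the pooled (both-gender) data by the elbow
rule — the point of the min–max-normalized WSS curve farthest from the chord
joining its endpoints — and K-means is then re-run per gender with that k to
obtain gender-specific component dimensions.  Points are clustered in raw
millimetres (ML and AP share units; no standardization).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["WssCurve", "kmeans", "wss_curve", "elbow_k", "size_table"]


@dataclass
class WssCurve:
    """Total within-cluster sum of squares as a function of cluster count."""

    k_values: np.ndarray
    wss_values: np.ndarray

    def __post_init__(self) -> None:
        self.k_values = np.asarray(self.k_values, dtype=int)
        self.wss_values = np.asarray(self.wss_values, dtype=float)
        if len(self.k_values) != len(self.wss_values):
            raise ValueError("k and wss lists must have equal length")
        if np.any(self.k_values < 1) or np.any(np.diff(self.k_values) <= 0):
            raise ValueError("k values must be ascending and >= 1")
        if np.any(self.wss_values < -1e-9):
            raise ValueError("WSS must be non-negative")


def _assign(points: np.ndarray, centroids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d2 = ((points[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    labels = d2.argmin(axis=1)
    return labels, d2[np.arange(len(points)), labels]


def _kmeans_pp(points: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    centroids = np.empty((k, points.shape[1]))
    centroids[0] = points[rng.integers(len(points))]
    d2 = ((points - centroids[0]) ** 2).sum(axis=1)
    for i in range(1, k):
        total = d2.sum()
        if total <= 0:
            centroids[i] = points[rng.integers(len(points))]
        else:
            centroids[i] = points[rng.choice(len(points), p=d2 / total)]
        d2 = np.minimum(d2, ((points - centroids[i]) ** 2).sum(axis=1))
    return centroids


def _lloyd(
    points: np.ndarray, centroids: np.ndarray, max_iter: int = 300,
    tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray, float]:
    k = len(centroids)
    for _ in range(max_iter):
        labels, d2 = _assign(points, centroids)
        new = centroids.copy()
        for c in range(k):
            members = labels == c
            if np.any(members):
                new[c] = points[members].mean(axis=0)
            else:  # reseed an empty cluster to the farthest point
                new[c] = points[d2.argmax()]
                _, d2 = _assign(points, new)
        shift = np.linalg.norm(new - centroids, axis=1).max()
        centroids = new
        if shift < tol:
            break
    labels, d2 = _assign(points, centroids)
    return centroids, labels, float(d2.sum())


def kmeans(
    points, k: int, seed: int = 0, n_init: int = 10
) -> tuple[np.ndarray, np.ndarray, float]:
    """Lloyd's algorithm from k-means++ seeding, best of ``n_init`` restarts.

    Returns ``(centroids, labels, wss)`` with WSS the total squared Euclidean
    distance of every point to its assigned centroid, in raw mm^2.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2:
        raise ValueError("points must be a 2D array")
    n_distinct = len(np.unique(pts, axis=0))
    if k < 1 or k > n_distinct:
        raise ValueError(f"k={k} exceeds the {n_distinct} distinct points")
    best: tuple[np.ndarray, np.ndarray, float] | None = None
    seeds = np.random.SeedSequence(seed).spawn(n_init)
    for ss in seeds:
        rng = np.random.default_rng(ss)
        cent, labels, wss = _lloyd(pts, _kmeans_pp(pts, k, rng))
        if best is None or wss < best[2]:
            best = (cent, labels, wss)
    assert best is not None
    return best


def wss_curve(points, k_min: int = 2, k_max: int = 12, seed: int = 0) -> WssCurve:
    """WSS per cluster count over ``k_min..k_max`` with a shared base seed."""
    pts = np.asarray(points, dtype=float)
    ks = np.arange(k_min, k_max + 1)
    wss = np.array([kmeans(pts, int(k), seed=seed)[2] for k in ks])
    return WssCurve(k_values=ks, wss_values=wss)


def elbow_k(curve: WssCurve) -> int:
    """Elbow rule: the k whose normalized (k, WSS) point is farthest from the
    chord joining the first and last points of the curve; ties (including a
    perfectly linear curve) resolve to the smallest k."""
    k = curve.k_values.astype(float)
    w = curve.wss_values
    if len(k) < 3:
        raise ValueError("elbow selection needs at least 3 curve points")
    kn = (k - k[0]) / (k[-1] - k[0])
    w_span = w.max() - w.min()
    wn = (w - w.min()) / w_span if w_span > 0 else np.zeros_like(w)
    p0 = np.array([kn[0], wn[0]])
    p1 = np.array([kn[-1], wn[-1]])
    chord = p1 - p0
    norm = np.linalg.norm(chord)
    if norm == 0:
        return int(curve.k_values[0])
    rel = np.column_stack([kn, wn]) - p0
    dist = np.abs(rel[:, 0] * chord[1] - rel[:, 1] * chord[0]) / norm
    best = np.flatnonzero(dist >= dist.max() - 1e-12)[0]
    return int(curve.k_values[best])


def size_table(
    points_by_gender: dict[str, np.ndarray], k: int, seed: int = 0
) -> pd.DataFrame:
    """Per-gender component sizes: K-means centroids rounded to integer mm.

    ``points_by_gender`` maps gender to an (n, 2) array of (ml, ap) points.
    Rows are sorted by AP within gender and numbered 1..k.
    Columns: ``size, gender, ap_mm, ml_mm``.
    """
    rows = []
    for gender, pts in points_by_gender.items():
        pts = np.asarray(pts, dtype=float)
        cent, _, _ = kmeans(pts, k, seed=seed)
        cent = np.round(cent)
        order = np.argsort(cent[:, 1], kind="stable")
        for i, c in enumerate(cent[order], start=1):
            rows.append(
                dict(size=i, gender=gender, ap_mm=float(c[1]), ml_mm=float(c[0]))
            )
    return pd.DataFrame(rows, columns=["size", "gender", "ap_mm", "ml_mm"])
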