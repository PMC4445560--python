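"""Isolation by distance and ordination of genetic distance matrices.

Great-circle distances between group centroids feed a Mantel permutation
test against the pairwise F_ST matrix; non-metric MDS (Kruskal stress-1)
embeds the genetic distances in two dimensions.  Group centroids are a
planar mean of site coordinates, which matches the precision of
"centre of the sites" style placements.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.manifold import MDS

logger = logging.getLogger("dloopabc")

EARTH_RADIUS_KM = 6_371.0


def great_circle_km(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Haversine great-circle distance in km between (lat, lon) points."""
    for lat, lon in (a, b):
        if abs(lat) > 90 or abs(lon) > 180:
            raise ValueError(f"invalid coordinates ({lat}, {lon})")
    lat1, lon1, lat2, lon2 = map(math.radians, (*a, *b))
    s = (
        math.sin((lat2 - lat1) / 2) ** 2
        + math.cos(lat1) * math.cos(lat2) * math.sin((lon2 - lon1) / 2) ** 2
    )
    return 2 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(s)))


def group_centroid(points: Sequence[tuple[float, float]]) -> tuple[float, float]:
    """Arithmetic mean of (lat, lon) coordinates (planar approximation)."""
    if len(points) == 0:
        raise ValueError("no points")
    arr = np.asarray(points, dtype=float)
    return float(arr[:, 0].mean()), float(arr[:, 1].mean())


def geo_distance_matrix(
    centroids: dict[str, tuple[float, float]]
) -> pd.DataFrame:
    """Labeled symmetric matrix of great-circle distances (km)."""
    labels = list(centroids)
    k = len(labels)
    mat = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            d = great_circle_km(centroids[labels[i]], centroids[labels[j]])
            mat[i, j] = mat[j, i] = d
    return pd.DataFrame(mat, index=labels, columns=labels)


def _check_square(m: np.ndarray, name: str) -> None:
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(m, m.T):
        raise ValueError(f"{name} must be symmetric")
    if not np.allclose(np.diag(m), 0.0):
        raise ValueError(f"{name} must have a zero diagonal")


def mantel_test(
    m1: np.ndarray | pd.DataFrame,
    m2: np.ndarray | pd.DataFrame,
    n_perm: int = 9_999,
    seed: int | None = None,
) -> tuple[float, float, float]:
    """Mantel test of matrix correlation.

    r is the Pearson correlation over upper-triangle entries; p is
    one-sided, (1 + #{r_perm >= r_obs}) / (1 + n_perm), permuting the
    rows/columns of one matrix jointly.  Returns (r, p, r^2).
    """
    a = np.asarray(m1, dtype=float)
    b = np.asarray(m2, dtype=float)
    if a.shape != b.shape:
        raise ValueError("matrix dimensions differ")
    if (
        isinstance(m1, pd.DataFrame)
        and isinstance(m2, pd.DataFrame)
        and list(m1.index) != list(m2.index)
    ):
        raise ValueError("matrix labels differ")
    _check_square(a, "m1")
    _check_square(b, "m2")
    n = a.shape[0]
    iu = np.triu_indices(n, k=1)
    r_obs = float(np.corrcoef(a[iu], b[iu])[0, 1])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        bp = b[np.ix_(perm, perm)]
        if np.corrcoef(a[iu], bp[iu])[0, 1] >= r_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return r_obs, p, r_obs**2


@dataclass
class MDSResult:
    coords: pd.DataFrame        # index = group labels, columns x, y
    stress: float               # Kruskal stress-1
    n_iter: int
    seed: int | None
    n_clamped: int = 0          # negative input distances clamped to eps


def nmds_embed(
    d: np.ndarray | pd.DataFrame,
    dims: int = 2,
    seed: int | None = None,
    n_init: int = 20,
    eps_clamp: float = 1e-6,
    eps: float = 1e-12,
    max_iter: int = 5_000,
) -> MDSResult:
    """Kruskal non-metric MDS of a (genetic) distance matrix.

    Negative entries (possible for F_ST estimates) are clamped to a small
    epsilon for the ordination only; the clamp count is reported.  The
    best of ``n_init`` restarts by stress-1 is kept.
    """
    labels = list(d.index) if isinstance(d, pd.DataFrame) else [
        f"g{i}" for i in range(np.asarray(d).shape[0])
    ]
    mat = np.asarray(d, dtype=float).copy()
    _check_square(mat, "distance matrix")
    off = ~np.eye(mat.shape[0], dtype=bool)
    if not mat[off].any():
        raise ValueError("all off-diagonal distances are zero")
    n_clamped = int((mat[off] < 0).sum())
    if n_clamped:
        logger.info("nmds_embed: clamping %d negative distances to %g",
                    n_clamped, eps_clamp)
        mat[off & (mat < 0)] = eps_clamp
    mds = MDS(
        n_components=dims,
        metric="precomputed",
        metric_mds=False,
        init="random",
        n_init=n_init,
        max_iter=max_iter,
        eps=eps,
        normalized_stress=True,
        random_state=seed,
    )
    coords = mds.fit_transform(mat)
    return MDSResult(
        coords=pd.DataFrame(coords, index=labels, columns=["x", "y"][:dims]),
        stress=float(mds.stress_),
        n_iter=int(mds.n_iter_),
        seed=seed,
        n_clamped=n_clamped,
    )
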