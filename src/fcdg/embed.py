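"""Bound smoothing, randomized metrization and metric-matrix embedding.

The geometric core of distance geometry: triangle-inequality smoothing
tightens the raw holonomic/experimental bounds, metrization draws a random
but mutually consistent full distance matrix inside the smoothed windows,
and the classical metric-matrix (Gram) embedding turns that matrix into
Cartesian coordinates -- here in 4D, where configurational inversions cost
nothing, before the dynamics stage brings structures down to 3D.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .moltop import BoundsMatrix

__all__ = [
    "SmoothedBounds",
    "EmbeddedStructure",
    "smooth_bounds",
    "metrize",
    "embed_metric",
    "superpose",
    "kabsch_rmsd",
]


@dataclass
class SmoothedBounds:
    """Triangle-smoothed bounds; ``consistent`` is False if any window collapsed."""

    lower: np.ndarray
    upper: np.ndarray
    consistent: bool = True
    violation: tuple[int, int] | None = None

    @property
    def n(self) -> int:
        return self.lower.shape[0]

    def copy(self) -> "SmoothedBounds":
        return SmoothedBounds(self.lower.copy(), self.upper.copy(), self.consistent, self.violation)


@dataclass
class EmbeddedStructure:
    coords4d: np.ndarray  # n x dim
    embed_error: float


def _triangle_pass(lower: np.ndarray, upper: np.ndarray) -> None:
    """One Floyd-Warshall sweep: shortest-path uppers, inverse-triangle lowers."""
    n = lower.shape[0]
    for k in range(n):
        # upper(i,j) <= upper(i,k) + upper(k,j)
        via = upper[:, k, None] + upper[None, k, :]
        np.minimum(upper, via, out=upper)
        # lower(i,j) >= lower(i,k) - upper(k,j)  (and symmetrically)
        raise_ = np.maximum(lower[:, k, None] - upper[None, k, :], lower[None, k, :] - upper[:, k, None])
        np.maximum(lower, raise_, out=lower)


def smooth_bounds(bounds: BoundsMatrix | SmoothedBounds) -> SmoothedBounds:
    """Triangle/inverse-triangle smoothing of a bounds matrix.

    Upper bounds become all-pairs shortest paths over the upper matrix;
    lower bounds are raised via the inverse triangle inequality.  Windows
    only ever shrink.  If some lower ends above its upper, the result is
    flagged inconsistent with one violating pair reported (nothing is
    thrown: callers decide).
    """
    lower = bounds.lower.copy()
    upper = bounds.upper.copy()
    _triangle_pass(lower, upper)
    # lower updates can enable further raises; iterate to a fixed point
    for _ in range(3):
        before = (lower.sum(), upper.sum())
        _triangle_pass(lower, upper)
        if (lower.sum(), upper.sum()) == before:
            break
    np.fill_diagonal(lower, 0.0)
    np.fill_diagonal(upper, 0.0)
    bad = np.argwhere(lower > upper + 1e-9)
    if bad.size:
        i, j = map(int, bad[0])
        return SmoothedBounds(lower, upper, consistent=False, violation=(i + 1, j + 1))
    return SmoothedBounds(lower, upper)


def _local_resmooth(lower: np.ndarray, upper: np.ndarray, i: int, j: int) -> None:
    """Re-tighten all windows using triangles through atoms i and j only."""
    for k in (i, j):
        via = upper[:, k, None] + upper[None, k, :]
        np.minimum(upper, via, out=upper)
        raise_ = np.maximum(lower[:, k, None] - upper[None, k, :], lower[None, k, :] - upper[:, k, None])
        np.maximum(lower, raise_, out=lower)
    np.fill_diagonal(lower, 0.0)
    np.fill_diagonal(upper, 0.0)


def metrize(
    smoothed: SmoothedBounds,
    rng: np.random.Generator,
    max_restarts: int = 10,
    full_resmooth: bool = False,
) -> np.ndarray:
    """Draw a full, triangle-consistent distance matrix within the bounds.

    Pairs are visited in a random order; each distance is drawn uniformly in
    its *current* window and the affected windows are re-smoothed (locally
    through the fixed pair, or globally when ``full_resmooth``).  An
    inconsistency encountered mid-draw triggers a restart with a fresh
    order; after ``max_restarts`` failures an error names the offending
    window.
    """
    if not smoothed.consistent:
        raise ValueError(f"inconsistent bounds at pair {smoothed.violation}")
    n = smoothed.n
    iu, ju = np.triu_indices(n, 1)
    last_bad = None
    for _ in range(max_restarts):
        lower = smoothed.lower.copy()
        upper = smoothed.upper.copy()
        order = rng.permutation(len(iu))
        ok = True
        for p in order:
            i, j = int(iu[p]), int(ju[p])
            lo, up = lower[i, j], upper[i, j]
            if lo > up + 1e-9:
                last_bad = (i + 1, j + 1)
                ok = False
                break
            d = rng.uniform(lo, up) if up > lo else lo
            lower[i, j] = lower[j, i] = d
            upper[i, j] = upper[j, i] = d
            if full_resmooth:
                _triangle_pass(lower, upper)
                np.fill_diagonal(lower, 0.0)
                np.fill_diagonal(upper, 0.0)
            else:
                _local_resmooth(lower, upper, i, j)
            if np.any(lower > upper + 1e-9):
                last_bad = (i + 1, j + 1)
                ok = False
                break
        if ok:
            return upper
    raise RuntimeError(f"metrization failed after {max_restarts} restarts; offending window near pair {last_bad}")


def embed_metric(distances: np.ndarray, dim: int = 4) -> EmbeddedStructure:
    """Classical metric-matrix embedding of a full distance matrix.

    Distances to the centroid come from the standard identity, the Gram
    matrix is eigendecomposed, and coordinates are built from the ``dim``
    largest non-negative eigenvalues.  Negative-eigenvalue mass (non-
    Euclidean input) is truncated and folded into ``embed_error`` together
    with the RMS deviation between input and realized distances.
    """
    d = np.asarray(distances, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n) or not np.allclose(d, d.T) or np.any(np.abs(np.diag(d)) > 1e-9):
        raise ValueError("need a symmetric distance matrix with zero diagonal")
    d2 = d * d
    # squared distances to the centroid
    d0 = d2.mean(axis=1) - d2.sum() / (2.0 * n * n)
    g = 0.5 * (d0[:, None] + d0[None, :] - d2)
    w, v = np.linalg.eigh(g)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    if np.all(w <= 0):
        raise ValueError("metric matrix has no positive eigenvalue; cannot embed")
    wk = np.clip(w[:dim], 0.0, None)
    coords = v[:, :dim] * np.sqrt(wk)[None, :]
    coords -= coords.mean(axis=0)
    realized = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    iu = np.triu_indices(n, 1)
    rms = float(np.sqrt(np.mean((realized[iu] - d[iu]) ** 2)))
    neg = float(np.sqrt(np.sum(np.clip(w, None, 0.0) ** 2)) / n)
    return EmbeddedStructure(coords4d=coords, embed_error=rms + neg)


# ---------------------------------------------------------------------------
# rigid-body superposition helpers (used by clustering and tests)


def superpose(mobile: np.ndarray, target: np.ndarray, allow_reflection: bool = False) -> np.ndarray:
    """Least-squares (Kabsch) superposition of ``mobile`` onto ``target``.

    With ``allow_reflection`` the optimal improper rotation is permitted,
    which is appropriate whenever only relative configuration matters (the
    embedding itself fixes chirality arbitrarily).
    """
    p = mobile - mobile.mean(axis=0)
    q = target - target.mean(axis=0)
    h = p.T @ q
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    if not allow_reflection:
        corr = np.ones(h.shape[0])
        corr[-1] = d
        rot = u @ np.diag(corr) @ vt
    else:
        rot = u @ vt
    return p @ rot + target.mean(axis=0)


def kabsch_rmsd(a: np.ndarray, b: np.ndarray, allow_reflection: bool = False) -> float:
    """RMSD after optimal rigid superposition."""
    moved = superpose(a, b, allow_reflection=allow_reflection)
    return float(np.sqrt(np.mean(np.sum((moved - b) ** 2, axis=1))))
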