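"""Generalized Procrustes analysis and the associated shape geometry.

Shapes are 2D landmark configurations.  Superimposition removes position
(centering), scale (each configuration fixed at unit centroid size — full
Procrustes scaling) and orientation (proper rotation onto the running
consensus; reflections are never allowed, because an improper fit would
silently absorb the left/right asymmetry signal that the downstream
symmetry analysis measures).

For two centered configurations A and B the least-squares rotation taking
A onto B has the closed form

    theta = atan2(sum(A x B), sum(A . B))

where the sums run over landmarks and `x`/`.` are the 2D cross and dot
products of matching landmark vectors.  This is the 2D specialization of
the orthogonal Procrustes problem and is exact, so no SVD is needed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .morphio import LandmarkSet

logger = logging.getLogger(__name__)

__all__ = [
    "AlignedSample",
    "centroid_size",
    "optimal_rotation",
    "gpa",
    "procrustes_distance",
]


@dataclass
class AlignedSample:
    """GPA output: Procrustes coordinates, consensus shape and sizes.

    Attributes
    ----------
    aligned : ndarray, shape (n, k, 2)
        Superimposed configurations: centered, unit centroid size, rotated
        to the consensus.  Dimensionless Procrustes coordinates.
    consensus : ndarray, shape (k, 2)
        Mean shape (arithmetic mean of aligned configurations).
    centroid_sizes : ndarray, shape (n,)
        Centroid sizes of the input configurations, in their original units.
    specimen_ids, population_ids, replicate_ids
        Copied through from the input LandmarkSet.
    iterations : int
    converged : bool
    """

    aligned: np.ndarray
    consensus: np.ndarray
    centroid_sizes: np.ndarray
    specimen_ids: list[str]
    population_ids: list[str]
    replicate_ids: list[int]
    iterations: int
    converged: bool

    @property
    def n(self) -> int:
        return self.aligned.shape[0]

    @property
    def k(self) -> int:
        return self.aligned.shape[1]


def centroid_size(config: np.ndarray) -> float:
    """Centroid size: sqrt of summed squared landmark distances to the centroid.

    Invariant to translation and rotation; scales linearly under isotropic
    scaling.  A fully degenerate configuration (all landmarks coincident)
    returns 0 with a warning — it cannot be scale-normalized.
    """
    config = np.asarray(config, dtype=float)
    centered = config - config.mean(axis=0)
    cs = float(np.sqrt((centered**2).sum()))
    if cs == 0.0:
        warnings.warn("degenerate configuration: all landmarks coincident", stacklevel=2)
    return cs


def _rotation_angles(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Optimal rotation angles taking each centered config in `a` onto `b`.

    `a` has shape (..., k, 2); `b` broadcasts against it.  Vectorized over
    leading axes.
    """
    dot = (a * b).sum(axis=(-2, -1))
    cross = (a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]).sum(axis=-1)
    return np.arctan2(cross, dot)


def _rotate(configs: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Rotate configs (..., k, 2) counterclockwise by per-config angles theta."""
    c, s = np.cos(theta), np.sin(theta)
    x, y = configs[..., 0], configs[..., 1]
    out = np.empty_like(configs)
    out[..., 0] = c[..., None] * x - s[..., None] * y
    out[..., 1] = s[..., None] * x + c[..., None] * y
    return out


def optimal_rotation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Proper rotation matrix R (det = +1) minimizing ||a @ R.T - b||^2.

    Both configurations must be centered.  Returned so that rotating `a` by
    R (row vectors: ``a @ R.T``) best matches `b`.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("configurations must have the same shape")
    if not (np.any(a) and np.any(b)):
        raise ValueError("degenerate (zero) configuration")
    theta = float(_rotation_angles(a, b))
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


def gpa(lm_set: LandmarkSet, tol: float = 1e-10, max_iter: int = 100) -> AlignedSample:
    """Generalized Procrustes analysis of a landmark set.

    Iteratively: center all configurations, scale each to unit centroid
    size, rotate each onto the current consensus, recompute the consensus
    (renormalized to unit size), until the consensus moves by less than
    ``tol`` (Procrustes distance) or ``max_iter`` is reached.
    """
    if lm_set.n < 2:
        raise ValueError("GPA needs at least 2 configurations")
    configs = lm_set.coords - lm_set.coords.mean(axis=1, keepdims=True)
    sizes = np.sqrt((configs**2).sum(axis=(1, 2)))
    if np.any(sizes == 0):
        raise ValueError("fully degenerate configuration (zero centroid size)")
    configs = configs / sizes[:, None, None]

    consensus = configs[0].copy()
    iterations = 0
    converged = False
    for iterations in range(1, max_iter + 1):
        theta = _rotation_angles(configs, consensus)
        configs = _rotate(configs, theta)
        new_consensus = configs.mean(axis=0)
        norm = np.sqrt((new_consensus**2).sum())
        if norm == 0:
            raise ValueError("consensus collapsed to zero")
        new_consensus /= norm
        # align the new consensus with the old so the movement criterion is
        # rotation-free
        new_consensus = _rotate(new_consensus, _rotation_angles(new_consensus, consensus))
        movement = np.sqrt(((new_consensus - consensus) ** 2).sum())
        consensus = new_consensus
        if movement < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"GPA did not converge in {max_iter} iterations", stacklevel=2)
    # final rotation pass onto the converged consensus
    configs = _rotate(configs, _rotation_angles(configs, consensus))
    return AlignedSample(
        aligned=configs,
        consensus=configs.mean(axis=0),
        centroid_sizes=sizes,
        specimen_ids=list(lm_set.specimen_ids),
        population_ids=list(lm_set.population_ids),
        replicate_ids=list(lm_set.replicate_ids),
        iterations=iterations,
        converged=converged,
    )


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Partial Procrustes distance between two unit-size centered configs.

    The square root of the minimized sum of squared coordinate differences
    after the optimal proper rotation of `a` onto `b`.  Symmetric; zero iff
    the two configurations have the same shape.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("configurations must have the same landmark count")
    theta = _rotation_angles(a, b)
    return float(np.sqrt(((_rotate(a, theta) - b) ** 2).sum()))
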