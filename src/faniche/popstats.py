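"""Population-level shape summaries: disparity, mean size, allometry.

Morphological disparity is the within-population Procrustes variance —
the summed squared distances of each specimen's Procrustes coordinates
from the within-group mean shape, divided by (n - 1) by default (the
divisor is an argument because both conventions circulate).

The allometry check regresses every Procrustes coordinate on centroid
size (multivariate shape-on-size regression); the percentage of shape
variance explained is 100 * SS(fitted)/SS(total) and significance comes
from a permutation test of sizes against shapes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .procrustes import AlignedSample

__all__ = [
    "AllometryResult",
    "morphological_disparity",
    "allometry_regression",
    "mean_size_by_population",
]


@dataclass
class AllometryResult:
    percent_explained: float
    p_value: float
    slope_vector: np.ndarray  # (k, 2) change in shape per unit centroid size
    n_permutations: int


def _grouped(aligned: AlignedSample, populations: list[str] | None) -> list[str]:
    pops = aligned.population_ids
    if populations is None:
        populations = list(dict.fromkeys(pops))
    return populations


def morphological_disparity(
    aligned: AlignedSample,
    populations: list[str] | None = None,
    divisor: str = "n-1",
) -> pd.Series:
    """Within-population Procrustes variance.

    Singleton groups have no within-group variance at the (n-1) divisor and
    are reported as NaN.
    """
    if divisor not in ("n-1", "n"):
        raise ValueError("divisor must be 'n-1' or 'n'")
    populations = _grouped(aligned, populations)
    pops = np.asarray(aligned.population_ids)
    out = {}
    for pop in populations:
        members = aligned.aligned[pops == pop]
        n_g = members.shape[0]
        if n_g == 0:
            raise ValueError(f"population {pop!r} has no specimens")
        if n_g == 1 and divisor == "n-1":
            out[pop] = np.nan
            continue
        mean = members.mean(axis=0)
        ss = float(((members - mean) ** 2).sum())
        out[pop] = ss / (n_g - 1 if divisor == "n-1" else n_g)
    return pd.Series(out, name="disparity").reindex(populations)


def mean_size_by_population(
    aligned: AlignedSample, populations: list[str] | None = None
) -> pd.Series:
    """Arithmetic mean centroid size per population, in original units."""
    populations = _grouped(aligned, populations)
    pops = np.asarray(aligned.population_ids)
    out = {}
    for pop in populations:
        sizes = aligned.centroid_sizes[pops == pop]
        if sizes.size == 0:
            raise ValueError(f"population {pop!r} has no specimens")
        out[pop] = float(sizes.mean())
    return pd.Series(out, name="mean_cs").reindex(populations)


def allometry_regression(
    aligned: AlignedSample,
    n_permutations: int = 999,
    log_size: bool = False,
    rng: np.random.Generator | None = None,
) -> AllometryResult:
    """Multivariate regression of Procrustes coordinates on centroid size.

    percent_explained is the share of total (mean-centered) shape variance
    carried by the fitted values; the p-value is the permutation tail
    probability of an equal or larger share when sizes are shuffled
    (with the +1/+1 correction).
    """
    if aligned.n < 3:
        raise ValueError("allometry regression needs at least 3 specimens")
    size = np.log(aligned.centroid_sizes) if log_size else aligned.centroid_sizes.astype(float)
    if np.ptp(size) == 0:
        raise ValueError("size is constant: allometry regression undefined")
    shapes = aligned.aligned.reshape(aligned.n, -1)
    y = shapes - shapes.mean(axis=0)
    x = size - size.mean()
    sxx = float(x @ x)
    ss_total = float((y**2).sum())

    def explained(xc: np.ndarray) -> float:
        beta = (xc @ y) / sxx
        return float((np.outer(xc, beta) ** 2).sum())

    ss_model = explained(x)
    if rng is None:
        rng = np.random.default_rng(0)
    hits = 0
    for _ in range(n_permutations):
        if explained(rng.permutation(x)) >= ss_model:
            hits += 1
    p = (hits + 1) / (n_permutations + 1)
    slope = ((x @ y) / sxx).reshape(aligned.k, 2)
    return AllometryResult(
        percent_explained=100.0 * ss_model / ss_total,
        p_value=p,
        slope_vector=slope,
        n_permutations=n_permutations,
    )
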