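"""Geography: suitability extraction, spatial weights, Moran's I, layer PCA.

Suitability is read off a habitat-suitability raster at two scales: the
*local* value is the single cell containing a population's coordinates,
the *regional* value averages the 3x3 block of cells centered on that
focal cell (truncated at raster edges, missing cells dropped).

Global Moran's I screens the per-population response vectors for spatial
autocorrelation before ordinary regressions are trusted.  Weights default
to inverse great-circle distance (haversine, mean Earth radius 6371 km).
The analytic p-value uses the closed-form variance of I under the
normality assumption; a permutation p-value is also available.

The environmental-layer selection performs a PCA on the correlation
matrix of co-registered layers, keeps the leading axes reaching a target
share of variance, and picks the layer with the largest absolute loading
on each kept axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .morphio import SuitabilityRaster

EARTH_RADIUS_KM = 6371.0

__all__ = [
    "MoranResult",
    "LayerSelection",
    "extract_local_suitability",
    "extract_regional_suitability",
    "inverse_distance_weights",
    "haversine_km",
    "morans_i",
    "pca_layer_selection",
]


@dataclass
class MoranResult:
    observed: float
    expected: float
    sd: float
    p_value: float
    p_permutation: float | None = None


@dataclass
class LayerSelection:
    selected_layer_ids: list[str]
    axes_kept: int
    cumulative_variance: float
    loadings: np.ndarray  # (axes_kept, n_layers)


def _cell_index(raster: SuitabilityRaster, lon: float, lat: float) -> tuple[int, int]:
    """Row/col of the cell containing a point, half-open [west, east) x [south, north).

    Rows are stored north-first, so row 0 is the northernmost.
    """
    x0, y0 = raster.origin
    col = int(np.floor((lon - x0) / raster.cell_size))
    row_from_south = int(np.floor((lat - y0) / raster.cell_size))
    row = raster.nrows - 1 - row_from_south
    if not (0 <= col < raster.ncols and 0 <= row < raster.nrows):
        raise ValueError(
            f"point (lon={lon}, lat={lat}) outside raster extent "
            f"({x0}..{x0 + raster.ncols * raster.cell_size}, "
            f"{y0}..{y0 + raster.nrows * raster.cell_size})"
        )
    return row, col


def extract_local_suitability(raster: SuitabilityRaster, lat: float, lon: float) -> float:
    """Suitability of the single cell containing the point; NaN if NODATA."""
    row, col = _cell_index(raster, lon, lat)
    value = raster.values[row, col]
    if np.isclose(value, raster.nodata):
        return float("nan")
    return float(value)


def extract_regional_suitability(
    raster: SuitabilityRaster, lat: float, lon: float, exclude_focal: bool = False
) -> float:
    """Mean suitability of the 3x3 cell block centered on the focal cell.

    Blocks are truncated at raster edges; NODATA cells are dropped from the
    average.  NaN if no valid cell remains.
    """
    row, col = _cell_index(raster, lon, lat)
    values = []
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if exclude_focal and dr == 0 and dc == 0:
                continue
            rr, cc = row + dr, col + dc
            if 0 <= rr < raster.nrows and 0 <= cc < raster.ncols:
                v = raster.values[rr, cc]
                if not np.isclose(v, raster.nodata):
                    values.append(v)
    if not values:
        return float("nan")
    return float(np.mean(values))


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in km (mean Earth radius 6371 km); vectorized."""
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return EARTH_RADIUS_KM * 2 * np.arcsin(np.clip(np.sqrt(a), 0, 1))


def inverse_distance_weights(
    localities: pd.DataFrame, row_standardize: bool = False
) -> np.ndarray:
    """Inverse great-circle-distance spatial weight matrix, zero diagonal.

    ``localities`` needs latitude/longitude columns; coincident localities
    make the weight infinite and are rejected.  ``row_standardize``
    normalizes each row to sum to one (the convention several R packages
    apply internally); Moran's I itself is unchanged by a global rescale
    but does change under row standardization.
    """
    lat = localities["latitude"].to_numpy(float)
    lon = localities["longitude"].to_numpy(float)
    n = len(lat)
    if n < 3:
        raise ValueError("need at least 3 localities")
    d = haversine_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
    off = ~np.eye(n, dtype=bool)
    if np.any(d[off] == 0):
        i, j = np.argwhere((d == 0) & off)[0]
        ids = localities.get("population_id")
        pair = (ids.iloc[i], ids.iloc[j]) if ids is not None else (i, j)
        raise ValueError(f"coincident localities {pair[0]!r} and {pair[1]!r}")
    w = np.zeros_like(d)
    w[off] = 1.0 / d[off]
    if row_standardize:
        w = w / w.sum(axis=1, keepdims=True)
    return w


def morans_i(
    values: np.ndarray,
    weights: np.ndarray,
    n_permutations: int = 0,
    rng: np.random.Generator | None = None,
) -> MoranResult:
    """Global Moran's I with the normality-assumption z-test.

    I = (n/S0) * sum_ij w_ij z_i z_j / sum_i z_i^2 with z the centered
    values and S0 the total weight.  The expectation under no
    autocorrelation is -1/(n-1); the variance is the closed form under the
    normality assumption and the p-value is two-sided.  With
    ``n_permutations`` > 0 a permutation p-value is added.
    """
    z = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    n = z.size
    if n < 3:
        raise ValueError("need at least 3 values")
    if w.shape != (n, n):
        raise ValueError("weight matrix shape does not match values")
    if np.ptp(z) == 0:
        raise ValueError("zero variance in values: Moran's I undefined")
    z = z - z.mean()
    s0 = w.sum()
    if s0 <= 0:
        raise ValueError("weights must have positive total")

    def stat(zv: np.ndarray) -> float:
        return float((n / s0) * (zv @ w @ zv) / (zv @ zv))

    observed = stat(z)
    expected = -1.0 / (n - 1)
    s1 = 0.5 * ((w + w.T) ** 2).sum()
    s2 = ((w.sum(axis=1) + w.sum(axis=0)) ** 2).sum()
    kurt = n * (z**4).sum() / (z**2).sum() ** 2
    var = (
        n * ((n**2 - 3 * n + 3) * s1 - n * s2 + 3 * s0**2)
        - kurt * (n * (n - 1) * s1 - 2 * n * s2 + 6 * s0**2)
    ) / ((n - 1) * (n - 2) * (n - 3) * s0**2) - expected**2
    sd = float(np.sqrt(var))
    p = float(2 * stats.norm.sf(abs(observed - expected) / sd))

    p_perm = None
    if n_permutations > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        hits = sum(
            abs(stat(rng.permutation(z)) - expected) >= abs(observed - expected)
            for _ in range(n_permutations)
        )
        p_perm = (hits + 1) / (n_permutations + 1)
    return MoranResult(observed=observed, expected=expected, sd=sd, p_value=p, p_permutation=p_perm)


def pca_layer_selection(
    layers: dict[str, SuitabilityRaster] | dict[str, np.ndarray],
    threshold: float = 0.95,
) -> LayerSelection:
    """Pick one representative layer per leading correlation-PCA axis.

    All layers must be co-registered; cells with NODATA in any layer are
    dropped listwise.  The smallest set of leading axes whose cumulative
    explained variance reaches ``threshold`` is kept, and for each kept
    axis the layer with the largest absolute loading is selected
    (deduplicated, axis order preserved).
    """
    if len(layers) < 2:
        raise ValueError("need at least 2 layers")
    names = list(layers)
    cols = []
    mask = None
    shape = None
    for name in names:
        layer = layers[name]
        if isinstance(layer, SuitabilityRaster):
            vals, valid = layer.values, layer.mask()
        else:
            vals = np.asarray(layer, dtype=float)
            valid = np.isfinite(vals)
        if shape is None:
            shape = vals.shape
        elif vals.shape != shape:
            raise ValueError("layers are not co-registered (shape mismatch)")
        mask = valid if mask is None else (mask & valid)
        cols.append(vals)
    matrix = np.column_stack([c[mask] for c in cols])
    sd = matrix.std(axis=0, ddof=1)
    tiny = sd <= 1e-12 * np.maximum(1.0, np.abs(matrix).max(axis=0))
    if np.any(tiny):
        bad = names[int(np.argmax(tiny))]
        raise ValueError(f"layer {bad!r} is constant: correlation undefined")
    standardized = (matrix - matrix.mean(axis=0)) / sd

    pca = PCA()
    pca.fit(standardized)
    cumvar = np.cumsum(pca.explained_variance_ratio_)
    axes_kept = int(np.searchsorted(cumvar, threshold - 1e-12) + 1)
    loadings = pca.components_[:axes_kept]
    selected: list[str] = []
    for axis in range(axes_kept):
        best = names[int(np.argmax(np.abs(loadings[axis])))]
        if best not in selected:
            selected.append(best)
    return LayerSelection(
        selected_layer_ids=selected,
        axes_kept=axes_kept,
        cumulative_variance=float(cumvar[axes_kept - 1]),
        loadings=loadings,
    )
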