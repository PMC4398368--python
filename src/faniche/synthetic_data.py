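"""Synthetic study generator with known FA-suitability coupling.

Everything the pipeline consumes can be simulated here: a symmetric
skull-like mean shape with a left/right landmark pairing, per-population
landmark samples whose fluctuating asymmetry tracks habitat suitability,
replicate digitizations with independent measurement error, a locality
table, and a smooth suitability raster.  Because the latent parameters
are recorded, every downstream stage can be checked by parameter
recovery.

Noise architecture per specimen (all deviations in the tangent space of
the unit-centroid-size mean shape, i.e. in Procrustes units):

* an individual symmetric deviation, sd ``sigma_ind`` per coordinate in
  an orthonormal basis of the *symmetric* shape subspace (dimension
  2l + m - 2);
* a fluctuating-asymmetry deviation, sd ``fa_sd(suitability)`` per
  coordinate in an orthonormal basis of the *asymmetry* subspace (same
  dimension) — drawn there, not landmark-wise, so the injected sd has a
  clean meaning in Procrustes units;
* an optional directional-asymmetry offset shared by all specimens;
* per-digitization isotropic measurement error, sd ``sigma_err``.

The suitability link is linear with a floor: fa_sd = a - b * s, s the
suitability of the population's raster cell.  Because the FA score of a
specimen with per-coordinate asymmetric sd sigma is sigma times a
chi-distributed factor with d = 2l + m - 2 degrees of freedom, the
*expected FA score* is c_d * sigma with c_d = E[chi_d]; the generator
reports the implied FA-score-scale intercept/slope (c_d*a, c_d*b) in its
truth record so fitted regression slopes can be compared with truth.

Digitized coordinates are produced by scaling each specimen to its
centroid size and applying a random rotation and translation per
digitization (removed again by GPA, as for real image coordinates).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.special import gammaln

from .morphio import (
    LandmarkSet,
    SuitabilityRaster,
    SymmetryMap,
    write_ascii_grid,
    write_symmetry_map,
    write_tps,
)

__all__ = [
    "RasterSpec",
    "SyntheticScenario",
    "make_mean_shape",
    "asymmetry_basis",
    "symmetric_basis",
    "chi_mean",
    "simulate_raster",
    "simulate_study",
    "write_study",
    "replicated_subset",
]


@dataclass
class RasterSpec:
    nrows: int = 60
    ncols: int = 60
    cell_size: float = 0.05
    origin: tuple[float, float] = (-45.0, -25.0)
    n_bumps: int = 8
    bump_width: float = 8.0  # in cells
    trend_scale: float = 1.0
    logistic_gain: float = 2.0  # sd of the latent field before squashing


@dataclass
class SyntheticScenario:
    """Study design for the generator; defaults mirror the emulated survey:
    22 populations, 380 specimens, 40 landmarks (17 pairs + 6 midline),
    error test on 50 specimens digitized twice."""

    l: int = 17
    m: int = 6
    n_pops: int = 22
    n_per_pop: tuple[int, ...] | int = ()
    fa_link: tuple[float, float] = ()  # (a, b): fa displacement sd = a - b*s
    fa_floor: float = 1e-5
    sigma_ind: float = 0.01
    sigma_err: float = 0.0026
    da_offset_scale: float = 0.0
    r: int = 2
    n_replicated: int = 50
    size_mean: float = 30.0  # centroid size, arbitrary length units (e.g. mm)
    size_sd: float = 1.5
    raster_spec: RasterSpec = field(default_factory=RasterSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        d = 2 * self.l + self.m - 2
        if not self.fa_link:
            # FA-score scale targets: mean FA 0.020 at s=0, slope -0.004 per
            # unit suitability; converted to per-coordinate displacement sd.
            c = chi_mean(d)
            self.fa_link = (0.020 / c, 0.004 / c)
        if not self.n_per_pop:
            base, extra = divmod(380, self.n_pops)
            self.n_per_pop = tuple(base + (1 if i < extra else 0) for i in range(self.n_pops))
        elif isinstance(self.n_per_pop, int):
            self.n_per_pop = (self.n_per_pop,) * self.n_pops
        if len(self.n_per_pop) != self.n_pops:
            raise ValueError("n_per_pop length must equal n_pops")
        a, b = self.fa_link
        if a - b * 1.0 < self.fa_floor:
            raise ValueError("fa_link must keep the displacement sd above the floor at s=1")

    @property
    def k(self) -> int:
        return 2 * self.l + self.m


def chi_mean(d: int) -> float:
    """E[chi_d] = sqrt(2) * Gamma((d+1)/2) / Gamma(d/2)."""
    return float(np.sqrt(2.0) * np.exp(gammaln((d + 1) / 2) - gammaln(d / 2)))


def make_mean_shape(l: int, m: int) -> tuple[np.ndarray, SymmetryMap]:
    """Deterministic symmetric skull-like outline with its SymmetryMap.

    Midline landmarks sit on the y-axis, pairs are mirrored across it; the
    configuration is centered and scaled to unit centroid size, so tangent
    deviations are directly in Procrustes units.  Landmarks are ordered
    left_1..left_l, right_1..right_l, midline_1..midline_m.
    """
    if l < 2 or m < 1:
        raise ValueError("need at least 2 pairs and 1 midline landmark")
    phi = np.linspace(0.25, np.pi - 0.25, l)
    # ovoid outline with a waist, loosely cranium-like
    width = 0.75 + 0.2 * np.sin(2 * phi) - 0.15 * np.cos(phi)
    left = np.column_stack([-width * np.sin(phi), np.cos(phi)])
    right = left * np.array([-1.0, 1.0])
    midline = np.column_stack([np.zeros(m), np.linspace(0.9, -0.9, m)])
    coords = np.vstack([left, right, midline])
    coords = coords - coords.mean(axis=0)
    coords /= np.sqrt((coords**2).sum())
    sym = SymmetryMap(tuple((i, l + i) for i in range(l)), tuple(2 * l + j for j in range(m)))
    return coords, sym


def _reflect_operator(sym: SymmetryMap) -> np.ndarray:
    """The linear reflect-relabel map on flattened (2k,) centered configs."""
    k = sym.k
    op = np.zeros((2 * k, 2 * k))
    perm = sym.permutation()
    for i in range(k):
        op[2 * perm[i], 2 * i] = -1.0  # x negated
        op[2 * perm[i] + 1, 2 * i + 1] = 1.0
    return op


def _subspace_basis(projector_sign: float, sym: SymmetryMap, mean: np.ndarray) -> np.ndarray:
    """Orthonormal basis (2k, d) of the symmetric (+1) or asymmetric (-1)
    shape subspace at a symmetric mean: the eigenspace of the reflection
    operator, with the non-shape directions (translation and, respectively,
    scale or rotation) projected out."""
    k = sym.k
    op = _reflect_operator(sym)
    proj = (np.eye(2 * k) + projector_sign * op) / 2.0
    if projector_sign > 0:
        # symmetric subspace: remove y-translation and the scaling direction
        t = np.zeros(2 * k)
        t[1::2] = 1.0
        nuisance = [t / np.linalg.norm(t), mean.ravel() / np.linalg.norm(mean)]
    else:
        # asymmetric subspace: remove x-translation and infinitesimal rotation
        t = np.zeros(2 * k)
        t[0::2] = 1.0
        rot = np.column_stack([-mean[:, 1], mean[:, 0]]).ravel()
        nuisance = [t / np.linalg.norm(t), rot / np.linalg.norm(rot)]
    for v in nuisance:
        proj = proj - np.outer(proj @ v, v)
    u, s, _ = np.linalg.svd(proj)
    d = 2 * sym.n_pairs + sym.n_midline - 2
    basis = u[:, :d]
    if s[d - 1] < 0.5 or (len(s) > d and s[d] > 0.5):  # pragma: no cover - sanity
        raise RuntimeError("unexpected symmetry-subspace rank")
    return basis


def asymmetry_basis(sym: SymmetryMap, mean: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the asymmetry shape subspace, shape (2k, 2l+m-2)."""
    return _subspace_basis(-1.0, sym, mean)


def symmetric_basis(sym: SymmetryMap, mean: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the symmetric shape subspace, shape (2k, 2l+m-2)."""
    return _subspace_basis(+1.0, sym, mean)


def simulate_raster(spec: RasterSpec, rng: np.random.Generator) -> SuitabilityRaster:
    """Smooth suitability field: low-order trend plus squared-exponential
    bumps, squashed into [0, 1] by a logistic transform."""
    rows, cols = np.mgrid[0 : spec.nrows, 0 : spec.ncols].astype(float)
    rows /= spec.nrows
    cols /= spec.ncols
    coef = rng.normal(scale=spec.trend_scale, size=3)
    fld = coef[0] + coef[1] * rows + coef[2] * cols
    for _ in range(spec.n_bumps):
        cr, cc = rng.uniform(0, 1, 2)
        amp = rng.normal(scale=1.5)
        w = spec.bump_width / max(spec.nrows, spec.ncols)
        fld += amp * np.exp(-(((rows - cr) ** 2 + (cols - cc) ** 2)) / (2 * w**2))
    # standardize so the logistic output spans most of [0, 1] across the
    # grid, as a suitability surface over a species' full range does
    fld = (fld - fld.mean()) / fld.std() * spec.logistic_gain
    values = 1.0 / (1.0 + np.exp(-fld))
    return SuitabilityRaster(
        values, cell_size=spec.cell_size, origin=spec.origin, nodata=-9999.0
    )


def _place_localities(
    raster: SuitabilityRaster, n_pops: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Locality table at cell centers, stratified across the suitability
    gradient so populations span the field's range (as a survey covering a
    species' distribution would)."""
    valid = np.argwhere(raster.mask())
    if len(valid) < n_pops:
        raise ValueError("raster has fewer valid cells than populations")
    vals = raster.values[valid[:, 0], valid[:, 1]]
    order = np.argsort(vals)
    # one cell from each of n_pops suitability strata
    strata = np.array_split(order, n_pops)
    chosen = [stratum[rng.integers(len(stratum))] for stratum in strata]
    rows = []
    for i, c in enumerate(chosen):
        row, col = valid[c]
        lon = raster.origin[0] + (col + 0.5) * raster.cell_size
        lat = raster.origin[1] + (raster.nrows - row - 0.5) * raster.cell_size
        rows.append(
            {
                "population_id": f"pop{i + 1:02d}",
                "latitude": lat,
                "longitude": lon,
                "suitability": float(raster.values[row, col]),
            }
        )
    out = pd.DataFrame(rows).sample(frac=1.0, random_state=int(rng.integers(2**31)))
    return out.reset_index(drop=True)


def simulate_study(scenario: SyntheticScenario) -> dict:
    """Generate a complete synthetic study.

    Returns a dict with ``landmarks`` (LandmarkSet: one record per
    digitization), ``symmetry_map``, ``localities`` (DataFrame), ``raster``,
    ``truth`` (per-population latent parameters) and ``scenario``.
    """
    rng = np.random.default_rng(scenario.seed)
    mean, sym = make_mean_shape(scenario.l, scenario.m)
    k = scenario.k
    b_sym = symmetric_basis(sym, mean)
    b_asym = asymmetry_basis(sym, mean)
    d = b_asym.shape[1]

    raster = simulate_raster(scenario.raster_spec, rng)
    localities = _place_localities(raster, scenario.n_pops, rng)

    da = np.zeros((k, 2))
    if scenario.da_offset_scale > 0:
        z = rng.normal(size=d)
        da = (b_asym @ (z / np.linalg.norm(z) * scenario.da_offset_scale)).reshape(k, 2)

    a, b = scenario.fa_link
    coords, spec_ids, pop_ids, rep_ids = [], [], [], []
    truth_rows = []
    specimen_counter = 0
    all_specimens: list[tuple[np.ndarray, str, str]] = []  # (true config, id, pop)
    for p in range(scenario.n_pops):
        pop = localities.loc[p, "population_id"]
        s = float(localities.loc[p, "suitability"])
        fa_sd = max(a - b * s, scenario.fa_floor)
        for _ in range(scenario.n_per_pop[p]):
            specimen_counter += 1
            sid = f"sp{specimen_counter:04d}"
            dev = b_sym @ rng.normal(scale=scenario.sigma_ind, size=d)
            asym = b_asym @ rng.normal(scale=fa_sd, size=d)
            shape = mean + dev.reshape(k, 2) + asym.reshape(k, 2) + da
            all_specimens.append((shape, sid, pop))
        truth_rows.append(
            {
                "population_id": pop,
                "latitude": localities.loc[p, "latitude"],
                "longitude": localities.loc[p, "longitude"],
                "suitability": s,
                "n": scenario.n_per_pop[p],
                "fa_sd": fa_sd,
                "expected_mean_fa": chi_mean(d) * fa_sd,
            }
        )

    n_rep = min(scenario.n_replicated, len(all_specimens))
    replicated = set(rng.choice(len(all_specimens), size=n_rep, replace=False))
    for idx, (shape, sid, pop) in enumerate(all_specimens):
        size = scenario.size_mean + scenario.size_sd * rng.standard_normal()
        size = max(size, 0.1 * scenario.size_mean)
        n_digitizations = scenario.r if idx in replicated else 1
        for rep in range(1, n_digitizations + 1):
            noisy = shape + rng.normal(scale=scenario.sigma_err, size=(k, 2))
            config = size * noisy
            theta = rng.uniform(0, 2 * np.pi)
            c, s_ = np.cos(theta), np.sin(theta)
            rot = np.array([[c, -s_], [s_, c]])
            config = config @ rot.T + rng.uniform(-100, 100, size=2)
            coords.append(config)
            spec_ids.append(sid)
            pop_ids.append(pop)
            rep_ids.append(rep)

    landmarks = LandmarkSet(np.stack(coords), spec_ids, pop_ids, rep_ids)
    truth = pd.DataFrame(truth_rows)
    truth.attrs["fa_score_intercept"] = chi_mean(d) * a
    truth.attrs["fa_score_slope"] = chi_mean(d) * b
    return {
        "landmarks": landmarks,
        "symmetry_map": sym,
        "localities": localities[["population_id", "latitude", "longitude"]].copy(),
        "raster": raster,
        "truth": truth,
        "scenario": scenario,
    }


def replicated_subset(lm_set: LandmarkSet, r: int = 2) -> LandmarkSet:
    """Subset to the specimens digitized at least r times (first r replicates),
    the balanced design the measurement-error ANOVA requires."""
    counts = pd.Series(lm_set.specimen_ids).value_counts()
    keep_ids = set(counts[counts >= r].index)
    idx = [
        i
        for i, (sid, rep) in enumerate(zip(lm_set.specimen_ids, lm_set.replicate_ids))
        if sid in keep_ids and rep <= r
    ]
    if not idx:
        raise ValueError("no replicated specimens in the set")
    return lm_set.subset(idx)


def write_study(study: dict, outdir: str | Path) -> dict[str, Path]:
    """Write a ready-to-run study directory (TPS, CSVs, .asc, scenario.yaml)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "tps": outdir / "landmarks.tps",
        "symmetry_map": outdir / "symmetry_map.csv",
        "localities": outdir / "localities.csv",
        "raster": outdir / "suitability.asc",
        "truth": outdir / "truth.csv",
        "scenario": outdir / "scenario.yaml",
    }
    lm = study["landmarks"]
    # TPS has no replicate column; encode replicate in the record id
    tagged = LandmarkSet(
        lm.coords,
        [f"{s}_r{r}" for s, r in zip(lm.specimen_ids, lm.replicate_ids)],
        lm.population_ids,
        [1] * lm.n,
    )
    write_tps(tagged, paths["tps"])
    write_symmetry_map(study["symmetry_map"], paths["symmetry_map"])
    study["localities"].to_csv(paths["localities"], index=False)
    write_ascii_grid(study["raster"], paths["raster"])
    study["truth"].to_csv(paths["truth"], index=False)
    membership = pd.DataFrame(
        {
            "specimen_id": lm.specimen_ids,
            "population_id": lm.population_ids,
            "replicate_id": lm.replicate_ids,
        }
    )
    membership.to_csv(outdir / "specimens.csv", index=False)
    paths["specimens"] = outdir / "specimens.csv"
    sc = study["scenario"]
    scenario_doc = {
        "l": sc.l,
        "m": sc.m,
        "n_pops": sc.n_pops,
        "n_per_pop": list(sc.n_per_pop),
        "fa_link": [float(x) for x in sc.fa_link],
        "sigma_ind": sc.sigma_ind,
        "sigma_err": sc.sigma_err,
        "r": sc.r,
        "n_replicated": sc.n_replicated,
        "seed": sc.seed,
    }
    paths["scenario"].write_text(yaml.safe_dump(scenario_doc, sort_keys=False))
    return paths
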