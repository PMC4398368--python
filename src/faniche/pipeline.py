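"""End-to-end orchestration: from files on disk to the report bundle.

Stages run in order: landmark/raster/locality I/O, generalized Procrustes
analysis, FA scoring, the measurement-error ANOVA (when replicated
digitizations are present), per-population summaries, suitability
extraction at both scales, the Moran's I screen, and the eight-regression
association battery.  Outputs are CSVs plus scatter plots; every file
carries the seed and option set in a run log so a rerun with the same
config is byte-identical (plots aside).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._version import __version__ as _version
from .inference import run_association_suite
from .morphio import LandmarkSet, read_ascii_grid, read_localities, read_symmetry_map, read_tps
from .popstats import mean_size_by_population, morphological_disparity
from .procrustes import gpa
from .spatial import (
    extract_local_suitability,
    extract_regional_suitability,
    inverse_distance_weights,
    morans_i,
)
from .symmetry import fa_scores, mean_fa_by_population, procrustes_anova
from .synthetic_data import replicated_subset

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}/{code}] {message}")
        self.stage = stage
        self.code = code


@dataclass
class PipelineConfig:
    tps: str
    symmetry_map: str
    localities: str
    raster: str | None = None
    specimens: str | None = None  # CSV mapping specimen_id -> population_id[, replicate_id]
    out_dir: str = "fa_niche_out"
    da_correct: bool = False
    disparity_divisor: str = "n-1"
    exclude_focal: bool = False
    moran_permutations: int = 10000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text())
        return cls(**doc)


@dataclass
class PipelineReport:
    summaries: pd.DataFrame
    regressions: pd.DataFrame
    moran: pd.DataFrame
    anova: pd.DataFrame | None
    out_dir: Path
    log: dict = field(default_factory=dict)


def _load_landmarks(cfg: PipelineConfig) -> LandmarkSet:
    lm = read_tps(cfg.tps)
    specimen_ids = list(lm.specimen_ids)
    replicate_ids = list(lm.replicate_ids)
    # ids of the form <specimen>_r<replicate> carry the digitization replicate
    if all("_r" in s for s in specimen_ids):
        parts = [s.rsplit("_r", 1) for s in specimen_ids]
        try:
            replicate_ids = [int(p[1]) for p in parts]
            specimen_ids = [p[0] for p in parts]
        except ValueError:
            replicate_ids = list(lm.replicate_ids)
            specimen_ids = list(lm.specimen_ids)
    population_ids = list(lm.population_ids)
    if cfg.specimens:
        members = pd.read_csv(cfg.specimens, dtype=str)
        pop_of = dict(zip(members["specimen_id"], members["population_id"]))
        population_ids = [pop_of.get(s, "") for s in specimen_ids]
        missing = sorted({s for s, p in zip(specimen_ids, population_ids) if not p})
        if missing:
            raise PipelineError(
                "morphio", "unassigned", f"specimens without population: {missing[:5]}..."
            )
    return LandmarkSet(lm.coords, specimen_ids, population_ids, replicate_ids)


def run_pipeline(cfg: PipelineConfig) -> PipelineReport:
    """Run the full analysis and write the report bundle to cfg.out_dir."""
    t0 = time.time()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"version": _version, "seed": cfg.seed, "stages": {}, "options": vars(cfg).copy()}
    rng = np.random.default_rng(cfg.seed)

    def stage(name):
        logger.info("stage %s", name)
        log["stages"][name] = {"t": round(time.time() - t0, 3)}

    try:
        stage("morphio")
        lm = _load_landmarks(cfg)
        sym = read_symmetry_map(cfg.symmetry_map)
        localities = read_localities(cfg.localities)
        raster = read_ascii_grid(cfg.raster) if cfg.raster else None
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("morphio", "io", str(exc)) from exc

    populations = list(localities["population_id"])

    try:
        stage("symmetry")
        decomps = fa_scores(lm, sym)
        mean_fa = mean_fa_by_population(decomps, populations, da_corrected=cfg.da_correct)
        fa_table = pd.DataFrame(
            {
                "specimen_id": [d.specimen_id for d in decomps],
                "population_id": [d.population_id for d in decomps],
                "fa_score": [d.fa_score for d in decomps],
                "da_corrected_score": [d.da_corrected_score for d in decomps],
                "centroid_size": [d.centroid_size for d in decomps],
            }
        )
        anova_table = None
        if max(lm.replicate_ids) >= 2:
            anova = procrustes_anova(replicated_subset(lm), sym)
            anova_table = anova.to_frame()
            anova_table.attrs["ms_ratio_fa_error"] = anova.ms_ratio_fa_error
            log["ms_ratio_fa_error"] = anova.ms_ratio_fa_error
    except Exception as exc:
        raise PipelineError("symmetry", "fa", str(exc)) from exc

    try:
        stage("popstats")
        # single digitization per specimen for the population summaries
        first = [i for i, r in enumerate(lm.replicate_ids) if r == 1]
        aligned = gpa(lm.subset(first))
        disparity = morphological_disparity(aligned, populations, divisor=cfg.disparity_divisor)
        mean_cs = mean_size_by_population(aligned, populations)
        n_per_pop = pd.Series(aligned.population_ids).value_counts().reindex(populations)
    except Exception as exc:
        raise PipelineError("popstats", "disparity", str(exc)) from exc

    summaries = pd.DataFrame(
        {
            "population_id": populations,
            "n": n_per_pop.to_numpy(),
            "mean_fa": mean_fa.to_numpy(),
            "disparity": disparity.to_numpy(),
            "mean_cs": mean_cs.to_numpy(),
            "latitude": localities["latitude"].to_numpy(),
            "longitude": localities["longitude"].to_numpy(),
        }
    )

    if raster is not None:
        try:
            stage("spatial")
            summaries["suitability_local"] = [
                extract_local_suitability(raster, lat, lon)
                for lat, lon in zip(summaries["latitude"], summaries["longitude"])
            ]
            summaries["suitability_regional"] = [
                extract_regional_suitability(raster, lat, lon, exclude_focal=cfg.exclude_focal)
                for lat, lon in zip(summaries["latitude"], summaries["longitude"])
            ]
        except Exception as exc:
            raise PipelineError("spatial", "extract", str(exc)) from exc
    else:
        logger.warning("no raster given: suitability columns and regressions skipped")

    try:
        stage("moran")
        weights = inverse_distance_weights(localities)
        moran_rows = []
        for var in ("mean_fa", "disparity"):
            res = morans_i(
                summaries[var].to_numpy(),
                weights,
                n_permutations=cfg.moran_permutations,
                rng=np.random.default_rng(rng.integers(2**31)),
            )
            moran_rows.append(
                {
                    "variable": var,
                    "observed": res.observed,
                    "expected": res.expected,
                    "sd": res.sd,
                    "p_normal": res.p_value,
                    "p_permutation": res.p_permutation,
                }
            )
        moran = pd.DataFrame(moran_rows)
    except Exception as exc:
        raise PipelineError("spatial", "moran", str(exc)) from exc

    try:
        stage("inference")
        regressions = run_association_suite(summaries)
    except Exception as exc:
        raise PipelineError("inference", "regression", str(exc)) from exc

    stage("write")
    fa_table.to_csv(out / "fa_scores.csv", index=False)
    summaries.to_csv(out / "population_summary.csv", index=False)
    moran.to_csv(out / "moran.csv", index=False)
    regressions.to_csv(out / "regressions.csv", index=False)
    if anova_table is not None:
        anova_table.to_csv(out / "procrustes_anova.csv", index=False)
    _plots(summaries, out)
    log["cardinalities"] = {
        "specimens": len(fa_table),
        "populations": len(summaries),
        "regressions": len(regressions),
        "moran_tests": len(moran),
    }
    log["elapsed_s"] = round(time.time() - t0, 3)
    (out / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
    return PipelineReport(
        summaries=summaries,
        regressions=regressions,
        moran=moran,
        anova=anova_table,
        out_dir=out,
        log=log,
    )


def _plots(summaries: pd.DataFrame, out: Path) -> None:
    if "suitability_local" not in summaries.columns:
        return
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 2, figsize=(9, 7))
    panels = [
        ("suitability_local", "mean_fa"),
        ("suitability_regional", "mean_fa"),
        ("suitability_local", "disparity"),
        ("suitability_regional", "disparity"),
    ]
    for ax, (xcol, ycol) in zip(axes.ravel(), panels):
        ax.scatter(summaries[xcol], summaries[ycol], s=25, color="k")
        ax.set_xlabel(xcol)
        ax.set_ylabel(ycol)
    fig.tight_layout()
    fig.savefig(out / "associations.png", dpi=120)
    plt.close(fig)
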