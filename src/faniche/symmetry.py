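"""Object-symmetry analysis: FA scores and the Procrustes ANOVA error test.

A bilaterally symmetric structure such as a skull is analyzed by comparing
each landmark configuration with its reflected and relabeled copy: the
configuration is mirrored across the vertical axis and the left/right
landmark labels are swapped, so that a perfectly symmetric shape maps to
itself.  One joint Procrustes superimposition of all originals and all
reflected copies puts both on a common coordinate system.  For each
specimen:

* the *symmetric component* is the average of its aligned original and
  aligned reflected copy — a perfectly symmetric shape;
* the *asymmetry vector* is the deviation of the aligned original from the
  symmetric component;
* the *FA score* is the norm of that deviation, in Procrustes-distance
  units;
* the *DA-corrected score* measures the deviation from the sample-mean
  asymmetry, removing any directional (population-level) asymmetry.

The measurement-error test is a two-factor Procrustes ANOVA (individuals x
sides, with digitization replicates): the individual-by-side interaction
mean square is the fluctuating-asymmetry signal and the replicate error
mean square is digitizing noise; their ratio tells whether FA stands clear
of measurement error.  Degrees of freedom follow the object-symmetry
shape-space dimensions: with l landmark pairs and m midline landmarks in
2D, both the symmetric and the asymmetric subspace of shape variation have
dimension 2l + m - 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .morphio import LandmarkSet, SymmetryMap
from .procrustes import AlignedSample, gpa

__all__ = [
    "SymmetryDecomposition",
    "ProcrustesAnovaTable",
    "reflect_relabel",
    "fa_scores",
    "procrustes_anova",
    "mean_fa_by_population",
]


@dataclass
class SymmetryDecomposition:
    """Per-specimen symmetric/asymmetric split and scalar asymmetry scores."""

    specimen_id: str
    population_id: str
    symmetric_component: np.ndarray  # (k, 2)
    asymmetry_vector: np.ndarray  # (k, 2)
    fa_score: float
    da_corrected_score: float
    centroid_size: float


@dataclass
class ProcrustesAnovaTable:
    """Procrustes ANOVA for object symmetry with replicated digitizations.

    Effects: individual (symmetric shape variation), side (directional
    asymmetry), individual x side (fluctuating asymmetry), error
    (digitizing noise).  ``ms_ratio_fa_error`` = MS(ind x side)/MS(error).
    """

    ss: dict[str, float]
    df: dict[str, int]
    ms: dict[str, float]
    ms_ratio_fa_error: float
    f_p_value: float

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"effect": e, "ss": self.ss[e], "df": self.df[e], "ms": self.ms[e]}
            for e in ("individual", "side", "individual_x_side", "error")
        ]
        return pd.DataFrame(rows)


def reflect_relabel(config: np.ndarray, sym: SymmetryMap) -> np.ndarray:
    """Mirror a configuration and swap the left/right landmark labels.

    The configuration is centered, its x-coordinates are negated, and each
    paired row is swapped with its partner; midline rows keep their index.
    The operation is an involution.
    """
    config = np.asarray(config, dtype=float)
    if config.shape[0] != sym.k:
        raise ValueError(f"symmetry map is for k={sym.k}, configuration has {config.shape[0]}")
    out = config - config.mean(axis=0)
    out = out * np.array([-1.0, 1.0])
    return out[sym.permutation()]


def _reflected_set(lm_set: LandmarkSet, sym: SymmetryMap) -> np.ndarray:
    coords = lm_set.coords - lm_set.coords.mean(axis=1, keepdims=True)
    coords = coords * np.array([-1.0, 1.0])
    return coords[:, sym.permutation(), :]


def _joint_alignment(lm_set: LandmarkSet, sym: SymmetryMap) -> AlignedSample:
    """Joint GPA over all originals followed by all reflected copies (2n)."""
    if lm_set.k != sym.k:
        raise ValueError(f"symmetry map is for k={sym.k}, landmark set has k={lm_set.k}")
    reflected = _reflected_set(lm_set, sym)
    doubled = LandmarkSet(
        np.concatenate([lm_set.coords, reflected]),
        specimen_ids=[f"{s}|orig" for s in lm_set.specimen_ids]
        + [f"{s}|refl" for s in lm_set.specimen_ids],
        population_ids=list(lm_set.population_ids) * 2,
        replicate_ids=list(lm_set.replicate_ids) * 2,
    )
    return gpa(doubled)


def fa_scores(
    lm_set: LandmarkSet,
    sym: SymmetryMap,
    average_replicates: bool = True,
) -> list[SymmetryDecomposition]:
    """Per-specimen FA scores from one joint original+reflected Procrustes fit.

    All originals and all reflected-relabeled copies enter a single GPA; each
    specimen's symmetric component is the mean of its two aligned copies and
    its FA score is the Procrustes-coordinate distance from the aligned
    original to that symmetric component.  ``da_corrected_score`` instead
    measures the deviation from the sample-mean asymmetry, the convention
    that removes directional asymmetry.

    With replicated digitizations and ``average_replicates`` (default), the
    aligned copies of a specimen's replicates are averaged before scoring so
    each specimen yields one decomposition; otherwise every replicate is
    scored separately.
    """
    if lm_set.n < 2:
        raise ValueError("fa_scores needs at least 2 specimens")
    aligned = _joint_alignment(lm_set, sym)
    n = lm_set.n
    orig = aligned.aligned[:n]
    refl = aligned.aligned[n:]

    if average_replicates and max(lm_set.replicate_ids) > 1:
        keys: list[str] = []
        seen: dict[str, int] = {}
        for sid in lm_set.specimen_ids:
            if sid not in seen:
                seen[sid] = len(seen)
            keys.append(sid)
        order = sorted(seen, key=seen.get)
        idx_of = {sid: [i for i, s in enumerate(keys) if s == sid] for sid in order}
        orig = np.stack([orig[idx_of[sid]].mean(axis=0) for sid in order])
        refl = np.stack([refl[idx_of[sid]].mean(axis=0) for sid in order])
        ids = order
        pops = [lm_set.population_ids[idx_of[sid][0]] for sid in order]
        sizes = [float(np.mean(aligned.centroid_sizes[idx_of[sid]])) for sid in order]
    else:
        ids = list(lm_set.specimen_ids)
        pops = list(lm_set.population_ids)
        sizes = [float(s) for s in aligned.centroid_sizes[:n]]

    symmetric = (orig + refl) / 2.0
    asym = orig - symmetric
    mean_asym = asym.mean(axis=0)
    out = []
    for i, sid in enumerate(ids):
        out.append(
            SymmetryDecomposition(
                specimen_id=sid,
                population_id=pops[i],
                symmetric_component=symmetric[i],
                asymmetry_vector=asym[i],
                fa_score=float(np.sqrt((asym[i] ** 2).sum())),
                da_corrected_score=float(np.sqrt(((asym[i] - mean_asym) ** 2).sum())),
                centroid_size=sizes[i],
            )
        )
    return out


def symmetry_subspace_dims(sym: SymmetryMap) -> tuple[int, int]:
    """Shape-space dimensions (d_s, d_a) of the symmetric and asymmetric
    components for 2D object symmetry: both equal 2l + m - 2."""
    d = 2 * sym.n_pairs + sym.n_midline - 2
    return d, d


def procrustes_anova(lm_set: LandmarkSet, sym: SymmetryMap) -> ProcrustesAnovaTable:
    """Measurement-error Procrustes ANOVA on a balanced replicated design.

    Every specimen must carry the same number r >= 2 of digitization
    replicates.  All 2*n*r configurations (originals and reflected copies of
    every replicate) are jointly superimposed, and sums of squares are
    accumulated over all landmark coordinates for the balanced two-factor
    decomposition individuals x sides with replication:

    * individual — specimen means of the symmetric component around the
      grand consensus;
    * side — the mean asymmetry (directional asymmetry);
    * individual x side — specimen-specific asymmetry around the side mean
      (the fluctuating-asymmetry line);
    * error — replicate deviations within specimen/side cells.

    SS are exactly additive.  The FA/error mean-square ratio is returned
    with its F-test p-value at the object-symmetry degrees of freedom.
    """
    reps = pd.Series(lm_set.replicate_ids).groupby(pd.Series(lm_set.specimen_ids)).count()
    r = int(reps.iloc[0])
    if not (reps == r).all():
        raise ValueError("unbalanced replication: subset to a common replicate count first")
    if r < 2:
        raise ValueError("no error term estimable: every specimen needs >= 2 replicates")

    aligned = _joint_alignment(lm_set, sym)
    n_conf = lm_set.n  # n * r
    n = n_conf // r
    grand = aligned.aligned.mean(axis=0)

    # organize as (specimen, side, replicate, k, 2); sides: 0 original, 1 reflected
    specimens = sorted(set(lm_set.specimen_ids), key=lm_set.specimen_ids.index)
    index = {s: i for i, s in enumerate(specimens)}
    cells = np.zeros((n, 2, r, sym.k, 2))
    counts = np.zeros((n, 2), dtype=int)
    for j, sid in enumerate(lm_set.specimen_ids):
        i = index[sid]
        cells[i, 0, counts[i, 0]] = aligned.aligned[j]
        cells[i, 1, counts[i, 1]] = aligned.aligned[n_conf + j]
        counts[i, 0] += 1
        counts[i, 1] += 1

    cell_means = cells.mean(axis=2)  # (n, 2, k, 2)
    ind_means = cell_means.mean(axis=1)  # (n, k, 2)
    side_means = cell_means.mean(axis=0)  # (2, k, 2)

    ss_ind = 2 * r * float(((ind_means - grand) ** 2).sum())
    ss_side = n * r * float(((side_means - grand) ** 2).sum())
    interaction = cell_means - ind_means[:, None] - side_means[None, :] + grand
    ss_int = r * float((interaction**2).sum())
    ss_err = float(((cells - cell_means[:, :, None]) ** 2).sum())

    d_s, d_a = symmetry_subspace_dims(sym)
    df = {
        "individual": (n - 1) * d_s,
        "side": d_a,
        "individual_x_side": (n - 1) * d_a,
        "error": n * (r - 1) * (d_s + d_a),
    }
    ss = {
        "individual": ss_ind,
        "side": ss_side,
        "individual_x_side": ss_int,
        "error": ss_err,
    }
    ms = {e: ss[e] / df[e] for e in ss}
    ratio = ms["individual_x_side"] / ms["error"] if ms["error"] > 0 else np.inf
    p = float(stats.f.sf(ratio, df["individual_x_side"], df["error"]))
    return ProcrustesAnovaTable(ss=ss, df=df, ms=ms, ms_ratio_fa_error=float(ratio), f_p_value=p)


def mean_fa_by_population(
    decomps: list[SymmetryDecomposition],
    populations: list[str] | None = None,
    da_corrected: bool = False,
) -> pd.Series:
    """Average FA score per population.

    ``populations`` fixes the output order (e.g. locality-table order);
    every listed population must contain at least one specimen.
    """
    scores = pd.DataFrame(
        {
            "population_id": [d.population_id for d in decomps],
            "fa": [d.da_corrected_score if da_corrected else d.fa_score for d in decomps],
        }
    )
    means = scores.groupby("population_id")["fa"].mean()
    if populations is not None:
        missing = [p for p in populations if p not in means.index]
        if missing:
            raise ValueError(f"populations with no specimens: {missing}")
        means = means.reindex(populations)
    means.name = "mean_fa"
    return means
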