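"""Trajectory roll statistics.

Turns a snapshot ensemble into the observables used to compare wildtype
and mutant complexes: the snapshots x steps roll matrix (time course),
the per-step average roll profile, Gaussian fits to per-step roll
histograms, and a three-way stability classification of the kink site --
stable with a large kink, stable with a reduced kink, or conformationally
unstable (the kink hops to a neighboring step).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .duplex_builder import BasePair, Duplex
from .helix_geometry import RollProfile, roll_profile
from .structure_io import StructureEnsemble, StructureModel

__all__ = [
    "RollTimeSeriesMatrix",
    "RollHistogramFit",
    "StabilityAssessment",
    "sample_snapshots",
    "roll_time_course",
    "fit_roll_histogram",
    "classify_stability",
]

HISTOGRAM_RANGE = (-20.0, 80.0)   # degrees, covers observed roll ranges
HISTOGRAM_BIN_WIDTH = 2.0         # degrees
NEIGHBOR_OCCUPANCY_UNSTABLE = 0.30
LARGE_KINK_MEAN = 35.0            # degrees


@dataclass
class RollTimeSeriesMatrix:
    values: np.ndarray            # (n_snapshots, n_steps); NaN = missing
    snapshot_indices: list[int]
    step_labels: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)

    @property
    def n_snapshots(self) -> int:
        return self.values.shape[0]

    @property
    def n_steps(self) -> int:
        return self.values.shape[1]

    def column_means(self) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.values, axis=0)

    def missing_counts(self) -> np.ndarray:
        return np.isnan(self.values).sum(axis=0)

    def to_tsv(self) -> str:
        header = "snapshot\t" + "\t".join(self.step_labels)
        rows = [header]
        for idx, row in zip(self.snapshot_indices, self.values):
            rows.append(str(idx) + "\t" + "\t".join(f"{v:.3f}" for v in row))
        return "\n".join(rows) + "\n"


@dataclass
class RollHistogramFit:
    a: float      # amplitude (counts at the center)
    b: float      # curvature, negative; sigma^2 = -1/(2 b)
    c: float      # center, degrees
    rss: float    # residual sum of squares

    @property
    def sigma(self) -> float:
        return math.sqrt(-1.0 / (2.0 * self.b))


@dataclass
class StabilityAssessment:
    reference_step: int
    occupancy: float
    neighbor_occupancy: float
    mean_kink: float
    stability_class: str


def sample_snapshots(ensemble: StructureEnsemble, n: int = 2000) -> list[StructureModel]:
    """Pick n equidistant snapshots: indices floor(k*M/n) for k=0..n-1.

    The first model is always included and the selection is
    deterministic.  If the ensemble holds fewer than n models, all of
    them are returned with a warning.
    """
    m = len(ensemble.models)
    if m == 0:
        raise ValueError("empty ensemble")
    if m < n:
        warnings.warn(f"ensemble has only {m} models; using all of them (requested {n})")
        return list(ensemble.models)
    indices = [(k * m) // n for k in range(n)]
    return [ensemble.models[i] for i in indices]


def _duplex_in_model(duplex: Duplex, model: StructureModel) -> Duplex:
    """Re-anchor a duplex's residue references in another snapshot of
    the same topology (matched by chain id / residue number)."""
    pairs = []
    for p in duplex.pairs:
        r1 = model.find_residue(*p.res_I.id)
        r2 = model.find_residue(*p.res_II.id)
        if r1 is None or r2 is None:
            raise ValueError(
                f"snapshot {model.model_index}: residue "
                f"{p.res_I.id if r1 is None else p.res_II.id} missing "
                "(topology mismatch)"
            )
        pairs.append(BasePair(res_I=r1, res_II=r2, n_hbonds=p.n_hbonds,
                              c1c1_distance=p.c1c1_distance,
                              is_watson_crick=p.is_watson_crick))
    return Duplex(pairs=pairs, sequence_I=duplex.sequence_I,
                  trimmed_5p=duplex.trimmed_5p, trimmed_3p=duplex.trimmed_3p,
                  flipped_positions=set(duplex.flipped_positions))


def roll_time_course(models: list[StructureModel], duplex: Duplex
                     ) -> tuple[RollTimeSeriesMatrix, RollProfile]:
    """Roll matrix (one row per snapshot) plus the average profile.

    Steps that fail frame fitting in a snapshot are stored as NaN and
    excluded from that column's mean; missing counts are available on
    the matrix.
    """
    rows = []
    labels = None
    for model in models:
        local = _duplex_in_model(duplex, model)
        profile, _ = roll_profile(local, model)
        rows.append(profile.rolls)
        if labels is None:
            labels = [f"{i + 1}:{d}" for i, d in enumerate(profile.dinucleotides)]
            dinucs = profile.dinucleotides
    matrix = RollTimeSeriesMatrix(values=np.vstack(rows),
                                  snapshot_indices=[m.model_index for m in models],
                                  step_labels=labels)
    average = RollProfile(rolls=matrix.column_means(), dinucleotides=dinucs)
    return matrix, average


def fit_roll_histogram(values, n_bins: int | None = None) -> RollHistogramFit:
    """Nonlinear least-squares Gaussian fit a*exp(b*(x-c)^2) to a roll
    histogram (counts vs bin centers), b constrained negative.

    Initialized from sample moments: c0 = mean, b0 = -1/(2*variance),
    a0 = max count.  Degenerate (near-constant) data is refused.
    """
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if len(values) < 50:
        raise ValueError(f"need at least 50 values, got {len(values)}")
    var = float(np.var(values))
    if var < 1e-12:
        raise ValueError("degenerate data: variance ~ 0, histogram fit undefined")
    if n_bins is None:
        lo = min(HISTOGRAM_RANGE[0], values.min())
        hi = max(HISTOGRAM_RANGE[1], values.max())
        n_bins = int(round((hi - lo) / HISTOGRAM_BIN_WIDTH))
        edges = np.linspace(lo, hi, n_bins + 1)
    else:
        edges = np.linspace(values.min(), values.max(), n_bins + 1)
    counts, edges = np.histogram(values, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2.0

    def gauss(x, a, b, c):
        return a * np.exp(b * (x - c) ** 2)

    p0 = (float(counts.max()), -1.0 / (2.0 * var), float(values.mean()))
    popt, _ = curve_fit(
        gauss, centers, counts, p0=p0,
        bounds=([0.0, -np.inf, centers.min()], [np.inf, -1e-12, centers.max()]),
        maxfev=10000,
    )
    rss = float(np.sum((gauss(centers, *popt) - counts) ** 2))
    return RollHistogramFit(a=float(popt[0]), b=float(popt[1]), c=float(popt[2]), rss=rss)


def classify_stability(matrix: RollTimeSeriesMatrix, reference_step: int,
                       window: int = 1,
                       neighbor_threshold: float = NEIGHBOR_OCCUPANCY_UNSTABLE,
                       large_kink_mean: float = LARGE_KINK_MEAN) -> StabilityAssessment:
    """Three-way stability classification of a kink site.

    Per snapshot, the step carrying the maximum roll within +-window of
    the reference step is found.  If neighbors win in at least 30% of
    snapshots the site is conformationally unstable (the kink shifts);
    otherwise the site is stable, with a large kink when the reference
    step's mean roll is >= 35 degrees and a reduced kink below that.
    Invariant to snapshot order.
    """
    n_steps = matrix.n_steps
    ref = reference_step - 1
    if not (0 <= ref < n_steps):
        raise IndexError(f"reference step {reference_step} outside matrix")
    lo = max(0, ref - window)
    hi = min(n_steps, ref + window + 1)
    sub = matrix.values[:, lo:hi]
    valid = ~np.all(np.isnan(sub), axis=1)
    argmax = np.full(len(sub), -1)
    argmax[valid] = np.nanargmax(sub[valid], axis=1) + lo
    occupancy = float(np.mean(argmax[valid] == ref)) if valid.any() else 0.0
    neighbor = float(np.mean((argmax[valid] != ref))) if valid.any() else 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_kink = float(np.nanmean(matrix.values[:, ref]))
    if neighbor >= neighbor_threshold:
        cls = "unstable"
    elif mean_kink >= large_kink_mean:
        cls = "stable_large_kink"
    else:
        cls = "stable_reduced_kink"
    return StabilityAssessment(reference_step=reference_step,
                               occupancy=occupancy,
                               neighbor_occupancy=neighbor,
                               mean_kink=mean_kink,
                               stability_class=cls)
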