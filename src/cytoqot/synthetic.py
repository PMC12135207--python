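"""Synthetic trajectory cohorts for benchmarking sample-level distances.

The built-in benchmark emulates a cohort of three subjects observed at
three timepoints.  Each subject's cells are Gaussian blobs (one per cell
type) whose means move over time along a subject-specific trajectory:

* ``branched`` — populations diverge from T1 to T2 and again from T2 to T3;
* ``curved`` — cell-type means advance along a smooth arc;
* ``y_shaped`` — all types leave a common lineage point and then split.

Subjects carry 2, 3 and 2 cell types at the three timepoints.  Two subjects
use 1,000 cells per type; one uses disproportionately sized types — every
subject totals 7,000 cells.  Trajectory geometry lives in the first two
marker dimensions, subject identity in the next two; remaining markers are
pure within-blob spread.  Subject separation is large relative to the
temporal drift, so the expected sample-level structure is block-diagonal by
subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import CytometrySample, StudyCollection, ValidationError, harmonize

__all__ = ["TrajectoryConfig", "generate_subject", "generate_benchmark_study"]

TOPOLOGIES = ("branched", "curved", "y_shaped")


@dataclass
class TrajectoryConfig:
    """Settings for one simulated subject.

    cells_per_celltype is either a single count applied to every type or an
    explicit per-timepoint list of per-type counts.  drift_magnitude scales
    the temporal movement of blob means (same units as marker intensities);
    cluster_spread is the within-blob standard deviation.
    """

    topology: str = "branched"
    n_timepoints: int = 3
    celltype_counts_per_timepoint: list[int] = field(
        default_factory=lambda: [2, 3, 2])
    cells_per_celltype: int | list[list[int]] = 1000
    n_markers: int = 10
    cluster_spread: float = 1.0
    drift_magnitude: float = 1.5
    origin: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self):
        if self.topology not in TOPOLOGIES:
            raise ValidationError(f"unknown topology {self.topology!r}")
        if len(self.celltype_counts_per_timepoint) != self.n_timepoints:
            raise ValidationError(
                "celltype_counts_per_timepoint length must equal n_timepoints")
        if self.n_markers < 4:
            raise ValidationError("need at least 4 markers (2 trajectory + "
                                  "2 subject-identity dimensions)")
        if isinstance(self.cells_per_celltype, (list, tuple)):
            counts = [list(c) for c in self.cells_per_celltype]
            if len(counts) != self.n_timepoints or any(
                    len(c) != k for c, k in
                    zip(counts, self.celltype_counts_per_timepoint)):
                raise ValidationError(
                    "explicit cell counts must give one list per timepoint "
                    "with one entry per cell type")
            self.cells_per_celltype = counts

    def counts_at(self, t: int) -> list[int]:
        k = self.celltype_counts_per_timepoint[t]
        if isinstance(self.cells_per_celltype, list):
            return self.cells_per_celltype[t]
        return [int(self.cells_per_celltype)] * k

    @property
    def total_cells(self) -> int:
        return sum(sum(self.counts_at(t)) for t in range(self.n_timepoints))


def _type_means_2d(topology: str, t: int, n_timepoints: int, n_types: int,
                   drift: float) -> np.ndarray:
    """Blob means in the 2-D trajectory plane for one timepoint."""
    out = np.zeros((n_types, 2))
    if topology == "branched":
        # types fan out progressively: wider spread at every timepoint
        ys = np.linspace(-1.0, 1.0, n_types) if n_types > 1 else np.zeros(1)
        out[:, 0] = t * drift
        out[:, 1] = ys * (0.5 + t) * drift
    elif topology == "curved":
        theta = 0.5 * np.pi * (t / max(n_timepoints - 1, 1))
        center = 2.0 * drift * np.array([np.cos(theta), np.sin(theta)])
        tangent = np.array([-np.sin(theta), np.cos(theta)])
        offs = (np.linspace(-0.4, 0.4, n_types)
                if n_types > 1 else np.zeros(1))
        out = center[None, :] + offs[:, None] * drift * tangent[None, :]
    elif topology == "y_shaped":
        if t == 0:
            # common lineage point: types huddle near the origin
            ys = (np.linspace(-0.15, 0.15, n_types)
                  if n_types > 1 else np.zeros(1))
            out[:, 1] = ys * drift
        else:
            angles = (np.linspace(-np.pi / 4, np.pi / 4, n_types)
                      if n_types > 1 else np.zeros(1))
            out[:, 0] = t * drift * np.cos(angles)
            out[:, 1] = t * drift * np.sin(angles)
    return out


def generate_subject(config: TrajectoryConfig,
                     subject_id: str = "S1") -> list[CytometrySample]:
    """Simulate one subject: one sample per timepoint, seeded and exact.

    Each cell type is a spherical Gaussian blob; the topology is encoded
    entirely in how blob means move across timepoints.
    """
    rng = np.random.default_rng(config.seed)
    m = config.n_markers
    origin = (np.zeros(m) if config.origin is None
              else np.asarray(config.origin, dtype=float))
    if origin.shape != (m,):
        raise ValidationError("origin must have n_markers entries")
    markers = tuple(f"M{i + 1:02d}" for i in range(m))
    samples = []
    for t in range(config.n_timepoints):
        counts = config.counts_at(t)
        means2d = _type_means_2d(config.topology, t, config.n_timepoints,
                                 len(counts), config.drift_magnitude)
        blocks = []
        for k, n_cells in enumerate(counts):
            mean = origin.copy()
            mean[:2] += means2d[k]
            blocks.append(rng.normal(loc=mean, scale=config.cluster_spread,
                                     size=(int(n_cells), m)))
        label = f"T{t + 1}"
        samples.append(CytometrySample(
            sample_id=f"{subject_id}_{label}", subject_id=subject_id,
            timepoint=label, matrix=np.vstack(blocks), marker_names=markers))
    return samples


# Disproportionate cell-type sizes for the first subject: 60/40 of 2,000 at
# T1, 40/35/25 of 3,000 at T2, 55/45 of 2,000 at T3 (7,000 cells in total,
# per-timepoint totals proportional to the 2:3:2 type counts).
SUBJECT1_CELL_COUNTS = [[1200, 800], [1200, 1050, 750], [1100, 900]]


def generate_benchmark_study(seed: int = 0, *,
                             n_markers: int = 10,
                             cluster_spread: float = 1.0,
                             drift_magnitude: float = 1.5,
                             subject_separation: float = 12.0,
                             cells_per_celltype: int = 1000,
                             subject1_counts=None) -> StudyCollection:
    """The three-subject, three-timepoint benchmark cohort (9 samples).

    Subject 1 follows a branched trajectory with disproportionately sized
    cell types, subject 2 a smooth curve, subject 3 a Y-shaped split; every
    subject totals 7,000 cells under the defaults.  Subjects sit at the
    corners of an equilateral triangle (side ``subject_separation``) in two
    identity dimensions, well separated relative to within-subject drift.
    """
    if subject1_counts is None:
        subject1_counts = [list(c) for c in SUBJECT1_CELL_COUNTS]
    child_seeds = (np.random.SeedSequence(seed).generate_state(3)
                   & 0x7FFFFFFF)
    s = float(subject_separation)
    corners = np.array([[0.0, 0.0], [s, 0.0], [0.5 * s, 0.5 * np.sqrt(3) * s]])
    specs = [("S1", "branched", subject1_counts),
             ("S2", "curved", cells_per_celltype),
             ("S3", "y_shaped", cells_per_celltype)]
    samples = []
    for i, (sid, topology, counts) in enumerate(specs):
        origin = np.zeros(n_markers)
        origin[2:4] = corners[i]
        cfg = TrajectoryConfig(topology=topology,
                               cells_per_celltype=counts,
                               n_markers=n_markers,
                               cluster_spread=cluster_spread,
                               drift_magnitude=drift_magnitude,
                               origin=origin,
                               seed=int(child_seeds[i]))
        samples.extend(generate_subject(cfg, subject_id=sid))
    return harmonize(samples)
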