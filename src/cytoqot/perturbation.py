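"""Leave-one-out protein instability analysis.

For each subject, the QOT distance from the baseline draw (earliest
timepoint) to every later draw is computed once with the full marker panel
(``D_t_full``) and once per excluded marker (``D_t_excl``).  The
perturbation a marker causes is ``delta_t = |D_t_full - D_t_excl|`` per
timepoint and ``delta_total = sum_t delta_t`` overall: markers whose
exclusion moves the temporal distances the most are the least stable over
time.  Per-subject rankings (least to most perturbing) are aggregated into
a cohort rank-frequency table read from the most-perturbing end (Rank 1 =
most perturbing).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CytometrySample, ValidationError, timepoint_key
from .qot import GmmCache, QotConfig, qot_distance

__all__ = ["PerturbationRecord", "RankSummary", "baseline_distances",
           "loo_perturbation", "rank_subject", "aggregate_cohort",
           "records_to_frame"]


@dataclass
class PerturbationRecord:
    """Distances and perturbation scores for one (subject, excluded marker)."""

    subject_id: str
    excluded_marker: str | None  # None = full panel
    distances: dict[str, float]  # timepoint -> D_t
    delta_t: dict[str, float] = field(default_factory=dict)
    delta_total: float = 0.0

    def __post_init__(self):
        if self.delta_t:
            total = float(sum(self.delta_t.values()))
            if abs(total - self.delta_total) > 1e-9:
                raise ValidationError(
                    "delta_total inconsistent with per-timepoint deltas")


def _ordered(subject_samples: list[CytometrySample]) -> list[CytometrySample]:
    if not subject_samples:
        raise ValidationError("no samples for subject")
    subs = {s.subject_id for s in subject_samples}
    if len(subs) != 1:
        raise ValidationError(f"samples span multiple subjects: {sorted(subs)}")
    return sorted(subject_samples, key=lambda s: timepoint_key(s.timepoint))


def baseline_distances(subject_samples: list[CytometrySample],
                       markers=None,
                       config: QotConfig = QotConfig(),
                       cache: GmmCache | None = None) -> dict[str, float]:
    """QOT distance from the baseline draw to every later draw.

    The baseline is the subject's earliest observed timepoint; all later
    draws (including extra intermediate ones) contribute.
    """
    ordered = _ordered(subject_samples)
    if len(ordered) < 2:
        raise ValidationError(
            f"{ordered[0].subject_id}: need a baseline and >=1 later draw")
    if markers is not None:
        ordered = [s.select_markers(tuple(markers)) for s in ordered]
    base = ordered[0]
    return {s.timepoint: qot_distance(base, s, config, cache)
            for s in ordered[1:]}


def loo_perturbation(subject_samples: list[CytometrySample],
                     full_markers=None,
                     config: QotConfig = QotConfig(),
                     cache: GmmCache | None = None
                     ) -> list[PerturbationRecord]:
    """One record per marker: how its exclusion perturbs baseline distances.

    Marker-subset refits reuse the same seed as the full-panel fit so the
    exclusion effect is isolated from fit stochasticity.  The full-panel
    record (excluded_marker=None) is returned first.
    """
    ordered = _ordered(subject_samples)
    if full_markers is None:
        full_markers = ordered[0].marker_names
    full_markers = tuple(full_markers)
    if len(full_markers) < 2:
        raise ValidationError("need at least 2 markers for leave-one-out")
    subject_id = ordered[0].subject_id
    d_full = baseline_distances(ordered, full_markers, config, cache)
    records = [PerturbationRecord(subject_id=subject_id, excluded_marker=None,
                                  distances=d_full)]
    for marker in full_markers:
        kept = tuple(m for m in full_markers if m != marker)
        d_excl = baseline_distances(ordered, kept, config, cache)
        delta_t = {t: abs(d_full[t] - d_excl[t]) for t in d_full}
        records.append(PerturbationRecord(
            subject_id=subject_id, excluded_marker=marker,
            distances=d_excl, delta_t=delta_t,
            delta_total=float(sum(delta_t.values()))))
    return records


def rank_subject(records: list[PerturbationRecord]) -> list[str]:
    """Markers ordered least to most perturbing (ties lexicographic)."""
    scored = [(r.excluded_marker, r.delta_total) for r in records
              if r.excluded_marker is not None]
    names = [m for m, _ in scored]
    if len(set(names)) != len(names):
        raise ValidationError("duplicate markers among perturbation records")
    return [m for m, _ in sorted(scored, key=lambda x: (x[1], x[0]))]


@dataclass
class RankSummary:
    """Cohort aggregation of per-subject marker rankings.

    ``rank_frequency`` rows are markers, columns ranks 1..M counted from
    the most-perturbing end (Rank 1 = most perturbing); each entry is the
    fraction of subjects placing that marker at that rank, so every column
    sums to 1.
    """

    rankings: dict[str, list[str]]
    rank_frequency: pd.DataFrame

    def top_marker(self, rank: int = 1) -> str:
        col = self.rank_frequency[rank]
        return col.idxmax()


def aggregate_cohort(rankings: dict[str, list[str]] | list[list[str]]
                     ) -> RankSummary:
    """Build the cohort rank-frequency table from per-subject rankings."""
    if isinstance(rankings, dict):
        named = dict(rankings)
    else:
        named = {f"subject{i + 1}": r for i, r in enumerate(rankings)}
    if not named:
        raise ValidationError("no rankings to aggregate")
    marker_set = None
    for sid, order in named.items():
        ms = frozenset(order)
        if len(order) != len(ms):
            raise ValidationError(f"{sid}: ranking repeats a marker")
        if marker_set is None:
            marker_set = ms
        elif ms != marker_set:
            raise ValidationError("rankings cover inconsistent marker sets")
    markers = sorted(marker_set)
    n_ranks = len(markers)
    counts = pd.DataFrame(0.0, index=markers,
                          columns=range(1, n_ranks + 1))
    for order in named.values():
        # order is least -> most perturbing; Rank 1 = most perturbing
        for pos, marker in enumerate(order):
            rank = n_ranks - pos
            counts.loc[marker, rank] += 1.0
    freq = counts / len(named)
    return RankSummary(rankings=named, rank_frequency=freq)


def records_to_frame(records: list[PerturbationRecord]) -> pd.DataFrame:
    """Tidy table: one row per (subject, excluded marker, timepoint)."""
    full = {r.subject_id: r.distances for r in records
            if r.excluded_marker is None}
    rows = []
    for r in records:
        if r.excluded_marker is None:
            continue
        for t, d_excl in sorted(r.distances.items(),
                                key=lambda kv: timepoint_key(kv[0])):
            rows.append({
                "subject_id": r.subject_id,
                "excluded_marker": r.excluded_marker,
                "timepoint": t,
                "d_full": full.get(r.subject_id, {}).get(t, np.nan),
                "d_excl": d_excl,
                "delta": r.delta_t.get(t, np.nan),
            })
    return pd.DataFrame(rows)
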