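"""Binned lick-rate time courses and cumulative two-bottle trajectories.

The time course bins licks into uniform windows (default 1 min — the
finest scale at which hour-long session curves stay interpretable) and
summarizes across rats as mean +/- SEM per bin.  The cumulative path plots
each rat's running casein count against its running maltodextrin count
after every lick: a rat with no preference tracks the unity diagonal;
casein preference bends the path rightward.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io import LickTrain, SessionRecord

logger = logging.getLogger("lickmicro")

#: Fixed epoch boundary (s): early = first 20 min, late = final 40 min.
EPOCH_SPLIT = 1200.0


@dataclass(frozen=True)
class BinnedTimecourse:
    """Lick counts per uniform time bin, one row per rat.

    ``mean``/``sem`` are across-rat statistics per bin; SEM is NaN for a
    single rat (undefined, reported missing rather than 0).
    """

    bin_edges: np.ndarray          # length n_bins + 1
    counts: np.ndarray             # (n_rats, n_bins)
    rat_ids: tuple[str, ...]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]

    @property
    def mean(self) -> np.ndarray:
        return self.counts.mean(axis=0)

    @property
    def sem(self) -> np.ndarray:
        n = self.counts.shape[0]
        if n < 2:
            return np.full(self.n_bins, math.nan)
        return self.counts.std(axis=0, ddof=1) / math.sqrt(n)


@dataclass(frozen=True)
class CumulativePath:
    """Running (casein, maltodextrin) lick counts after each lick event."""

    points: np.ndarray             # (n_events, 2), non-decreasing columns

    @property
    def final_point(self) -> tuple[int, int]:
        if self.points.shape[0] == 0:
            return (0, 0)
        return (int(self.points[-1, 0]), int(self.points[-1, 1]))

    @property
    def max_diagonal_deviation(self) -> float:
        """Largest |casein - malto| along the path (0 = perfect alternation band)."""
        if self.points.shape[0] == 0:
            return 0.0
        return float(np.max(np.abs(self.points[:, 0] - self.points[:, 1])))


def bin_licks(train: LickTrain, width: float = 60.0, duration: float = 3600.0) -> np.ndarray:
    """Counts of licks in half-open bins [k*w, (k+1)*w) over the session.

    A lick at exactly ``duration`` falls in the final bin; licks beyond the
    session window are clipped into the final bin with a warning.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    n_bins = math.ceil(duration / width)
    edges = np.arange(n_bins + 1, dtype=float) * width
    edges[-1] = max(edges[-1], duration)
    ts = train.timestamps
    n_over = int(np.sum(ts > duration))
    if n_over:
        logger.warning("%d licks beyond session duration clipped to final bin", n_over)
        ts = np.minimum(ts, duration)
    counts, _ = np.histogram(ts, bins=edges)  # last bin closed on the right
    return counts.astype(int)


def group_timecourse(sessions: Iterable[SessionRecord], *,
                     diet_group: str | None = None,
                     solution: str | None = None,
                     session_type: str | None = None,
                     day_index: int | None = None,
                     width: float = 60.0) -> BinnedTimecourse:
    """Across-rat binned time course for the selected (group, solution).

    Selects every (session, bottle) pair matching the non-None filters;
    raises if nothing matches.
    """
    rows: list[np.ndarray] = []
    rats: list[str] = []
    edges: np.ndarray | None = None
    for s in sessions:
        if diet_group is not None and s.diet_group != diet_group:
            continue
        if session_type is not None and s.session_type != session_type:
            continue
        if day_index is not None and s.day_index != day_index:
            continue
        for train in s.bottles:
            if solution is not None and s.solution_map[train.bottle_label] != solution:
                continue
            rows.append(bin_licks(train, width=width, duration=s.duration))
            rats.append(s.rat_id)
            if edges is None:
                n_bins = rows[-1].size
                edges = np.arange(n_bins + 1, dtype=float) * width
                edges[-1] = max(edges[-1], s.duration)
    if not rows:
        raise ValueError("no sessions match the selection")
    return BinnedTimecourse(bin_edges=edges, counts=np.vstack(rows), rat_ids=tuple(rats))


def cumulative_path(casein: LickTrain, malto: LickTrain) -> CumulativePath:
    """Time-ordered cumulative two-bottle trajectory.

    Simultaneous cross-bottle timestamps are ordered casein-first (logged);
    the final point always equals the raw train lengths.
    """
    tc, tm = casein.timestamps, malto.timestamps
    n_ties = int(np.intersect1d(tc, tm).size)
    if n_ties:
        logger.warning("%d simultaneous cross-bottle timestamps; casein ordered first", n_ties)
    # label 0 = casein, 1 = malto; stable mergesort on time keeps casein
    # (listed first) ahead on ties
    times = np.concatenate([tc, tm])
    labels = np.concatenate([np.zeros(tc.size, dtype=int), np.ones(tm.size, dtype=int)])
    order = np.argsort(times, kind="mergesort")
    labels = labels[order]
    points = np.empty((labels.size, 2), dtype=int)
    points[:, 0] = np.cumsum(labels == 0)
    points[:, 1] = np.cumsum(labels == 1)
    return CumulativePath(points=points)


def epoch_counts(train: LickTrain, split: float = EPOCH_SPLIT,
                 duration: float = 3600.0) -> tuple[int, int]:
    """Lick counts in the early [0, split) and late [split, duration] epochs."""
    ts = train.timestamps
    early = int(np.sum(ts < split))
    late = int(np.sum((ts >= split) & (ts <= duration)))
    return early, late


def plot_group_timecourse(tc: BinnedTimecourse, ax=None, label: str | None = None,
                          color=None):
    """Mean line with SEM band; returns the matplotlib axis."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    centers = 0.5 * (tc.bin_edges[:-1] + tc.bin_edges[1:])
    ax.plot(centers, tc.mean, label=label, color=color)
    sem = tc.sem
    if not np.all(np.isnan(sem)):
        ax.fill_between(centers, tc.mean - sem, tc.mean + sem, alpha=0.3, color=color)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("licks per bin")
    return ax
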