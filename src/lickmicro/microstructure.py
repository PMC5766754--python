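"""Cluster segmentation of lick trains and palatability/preference metrics.

Rodents lick rhythmically at ~6-7 Hz within sustained runs and pause
between runs.  A *cluster* is a maximal run of licks in which no interlick
interval (ILI) exceeds a threshold; 0.5 s is the conventional cluster
threshold, with bursts (~0.25 s) and bouts (~1 s) as the analogous
constructs at other thresholds.  Mean cluster size indexes palatability
(orosensory evaluation); cluster count indexes motivation/satiation.

The split rule is strict: an ILI of exactly the threshold stays *within*
a cluster; only ILIs strictly greater start a new one.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import LickTrain

logger = logging.getLogger("lickmicro")

#: Conventional cluster threshold in seconds.
DEFAULT_THRESHOLD = 0.5


@dataclass(frozen=True)
class Cluster:
    """A maximal run of licks with no internal ILI above threshold.

    Indices are 0-based inclusive positions into the source train.
    """

    start_index: int
    end_index: int
    start_time: float
    end_time: float
    within_ilis: np.ndarray

    @property
    def n_licks(self) -> int:
        return self.end_index - self.start_index + 1

    @property
    def duration(self) -> float:
        return self.end_time - self.start_time


@dataclass(frozen=True)
class MicrostructureSummary:
    """Per-train cluster statistics.

    ``mean_licks_per_cluster`` and ``mean_within_cluster_ili`` are NaN when
    undefined (empty train; no within-cluster ILI), never silently 0.
    """

    total_licks: int
    n_clusters: int
    mean_licks_per_cluster: float
    mean_within_cluster_ili: float
    threshold: float


def interlick_intervals(train: LickTrain) -> np.ndarray:
    """Successive lick-to-lick intervals in seconds (length n_licks - 1)."""
    ts = train.timestamps
    if ts.size and np.any(np.diff(ts) <= 0):  # defensive; LickTrain validates
        raise ValueError("timestamps must be strictly increasing")
    return np.diff(ts)


def _apply_ili_floor(train: LickTrain, min_ili: float) -> LickTrain:
    """Drop licks closer than ``min_ili`` to their predecessor (artifacts)."""
    ts = train.timestamps
    if ts.size < 2:
        return train
    keep = [0]
    last = ts[0]
    for i in range(1, ts.size):
        if ts[i] - last >= min_ili:
            keep.append(i)
            last = ts[i]
    dropped = ts.size - len(keep)
    if dropped:
        logger.warning("dropped %d licks with ILI < %.3f s (artifact floor)", dropped, min_ili)
    return LickTrain(train.bottle_label, ts[keep])


def segment_clusters(train: LickTrain, threshold: float = DEFAULT_THRESHOLD,
                     min_cluster_size: int = 1,
                     min_ili: float | None = None) -> list[Cluster]:
    """Greedy left-to-right segmentation of a train into clusters.

    A new cluster begins at lick *i* iff *i* = 0 or the gap from the
    previous lick exceeds ``threshold`` (strictly).  The result is an
    exhaustive, non-overlapping partition of the train.

    ``min_cluster_size`` optionally drops short runs from the returned
    list; ``min_ili`` optionally removes physiologically implausible
    near-coincident licks before segmenting.  Both are off by default.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if min_ili is not None:
        train = _apply_ili_floor(train, min_ili)
    ts = train.timestamps
    if ts.size == 0:
        return []
    ilis = np.diff(ts)
    breaks = np.flatnonzero(ilis > threshold)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [ts.size - 1]))
    clusters = [
        Cluster(int(s), int(e), float(ts[s]), float(ts[e]), ilis[s:e])
        for s, e in zip(starts, ends)
    ]
    if min_cluster_size > 1:
        clusters = [c for c in clusters if c.n_licks >= min_cluster_size]
    return clusters


def summarize(train: LickTrain, threshold: float = DEFAULT_THRESHOLD) -> MicrostructureSummary:
    """Aggregate cluster statistics for one train.

    Single licks count as clusters of size 1; an empty train yields zero
    counts with NaN means.
    """
    clusters = segment_clusters(train, threshold=threshold)
    total = len(train)
    n = len(clusters)
    if n:
        mean_size = total / n
        all_ilis = np.concatenate([c.within_ilis for c in clusters]) if total > n else np.array([])
        mean_ili = float(np.mean(all_ilis)) if all_ilis.size else math.nan
    else:
        mean_size = math.nan
        mean_ili = math.nan
    return MicrostructureSummary(
        total_licks=total, n_clusters=n,
        mean_licks_per_cluster=mean_size,
        mean_within_cluster_ili=mean_ili,
        threshold=threshold,
    )


def preference_score(casein_licks: int, malto_licks: int) -> float:
    """Protein preference: casein licks / total licks, in [0, 1].

    NaN (with a logged warning) when the rat produced no licks at all —
    a missing value, never a number.
    """
    if casein_licks < 0 or malto_licks < 0:
        raise ValueError("lick counts must be >= 0")
    total = casein_licks + malto_licks
    if total == 0:
        logger.warning("preference undefined: zero total licks")
        return math.nan
    return casein_licks / total
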