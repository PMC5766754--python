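"""Session data containers, CSV/operant-file readers, and diet energetics.

The canonical exchange format is a long-form CSV with one row per lick and
columns ``rat, group, session_type, day, bottle, solution, flavor,
timestamp_s``.  Timestamps are seconds from session start, written with
fixed decimal precision well below lickometer resolution so that a
write -> read round trip is lossless.  A bottle that registered no licks is
declared by a single row with an empty ``timestamp_s`` field.

Diet energetics use standard Atwater metabolizable-energy factors
(4 / 4 / 9 kcal per g for protein, carbohydrate, fat).
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("lickmicro")

DIET_GROUPS = ("NR", "PR")
SESSION_TYPES = ("familiarization", "conditioning", "preference")
SOLUTIONS = ("casein", "maltodextrin", "saccharin")

#: Atwater metabolizable-energy factors, kcal per gram.
ATWATER = {"protein": 4.0, "carb": 4.0, "fat": 9.0}

CSV_COLUMNS = [
    "rat", "group", "session_type", "day",
    "bottle", "solution", "flavor", "timestamp_s",
]

#: Decimal places used when writing timestamps (0.1 ms, below lickometer
#: resolution, so round trips are exact at this precision).
TIMESTAMP_DECIMALS = 4


class LickDataFormatError(ValueError):
    """Raised when an input file does not match the expected layout."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LickTrain:
    """Ordered lick timestamps for one bottle in one session.

    Timestamps are seconds from session start, strictly increasing, and may
    be empty.  This is the atomic input of every downstream analysis.
    """

    bottle_label: str
    timestamps: np.ndarray

    def __post_init__(self) -> None:
        ts = np.asarray(self.timestamps, dtype=float)
        if ts.ndim != 1:
            raise ValueError("timestamps must be a 1-D sequence")
        if ts.size:
            if ts[0] < 0:
                raise ValueError("timestamps must be non-negative")
            if np.any(np.diff(ts) <= 0):
                raise ValueError("timestamps must be strictly increasing")
        ts.setflags(write=False)
        object.__setattr__(self, "timestamps", ts)

    def __len__(self) -> int:
        return int(self.timestamps.size)

    @property
    def n_licks(self) -> int:
        return len(self)

    @property
    def span(self) -> float:
        """Time from first to last lick, 0 for trains with < 2 licks."""
        if len(self) < 2:
            return 0.0
        return float(self.timestamps[-1] - self.timestamps[0])

    def shifted(self, offset: float) -> "LickTrain":
        return LickTrain(self.bottle_label, self.timestamps + offset)


@dataclass(frozen=True)
class SessionRecord:
    """Lick trains plus metadata for one rat in one session.

    ``solution_map`` and ``flavor_map`` key on bottle label.  Conditioning
    sessions expose exactly one bottle (single-solution access); preference
    sessions expose two.
    """

    rat_id: str
    diet_group: str
    session_type: str
    day_index: int
    bottles: tuple[LickTrain, ...]
    solution_map: Mapping[str, str]
    flavor_map: Mapping[str, str] = field(default_factory=dict)
    duration: float = 3600.0

    def __post_init__(self) -> None:
        if self.diet_group not in DIET_GROUPS:
            raise ValueError(f"diet_group must be one of {DIET_GROUPS}, got {self.diet_group!r}")
        if self.session_type not in SESSION_TYPES:
            raise ValueError(f"session_type must be one of {SESSION_TYPES}, got {self.session_type!r}")
        if self.day_index < 1:
            raise ValueError("day_index must be >= 1")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        n = len(self.bottles)
        if self.session_type == "conditioning" and n != 1:
            raise ValueError(f"conditioning sessions have exactly 1 bottle, got {n}")
        if self.session_type == "preference" and n != 2:
            raise ValueError(f"preference sessions have exactly 2 bottles, got {n}")
        if not 1 <= n <= 2:
            raise ValueError("sessions carry 1-2 bottles")
        for train in self.bottles:
            if train.bottle_label not in self.solution_map:
                raise ValueError(f"bottle {train.bottle_label!r} missing from solution_map")
            if len(train) and train.timestamps[-1] > self.duration:
                raise ValueError("lick timestamps exceed session duration")

    def train(self, bottle_label: str) -> LickTrain:
        for t in self.bottles:
            if t.bottle_label == bottle_label:
                return t
        raise KeyError(bottle_label)

    def train_for_solution(self, solution: str) -> LickTrain:
        """Return the train of the bottle holding ``solution``."""
        for t in self.bottles:
            if self.solution_map[t.bottle_label] == solution:
                return t
        raise KeyError(f"no bottle holds {solution!r}")

    @property
    def solutions(self) -> tuple[str, ...]:
        return tuple(self.solution_map[t.bottle_label] for t in self.bottles)


@dataclass(frozen=True)
class CageIntakeRecord:
    """Daily chow intake for one group-housed cage (grams/day, cage total)."""

    cage_id: str
    diet_group: str
    n_rats: int
    daily_intake: float

    def __post_init__(self) -> None:
        if self.diet_group not in DIET_GROUPS:
            raise ValueError(f"diet_group must be one of {DIET_GROUPS}")
        if self.n_rats < 1:
            raise ValueError("n_rats must be >= 1")
        if self.daily_intake < 0:
            raise ValueError("daily_intake must be >= 0")


@dataclass(frozen=True)
class DietComposition:
    """Macronutrient composition of a chow, grams per 100 g."""

    name: str
    protein_gpct: float
    carb_gpct: float
    fat_gpct: float

    def __post_init__(self) -> None:
        for v in (self.protein_gpct, self.carb_gpct, self.fat_gpct):
            if v < 0:
                raise ValueError("macronutrient fractions must be >= 0")
        if self.protein_gpct + self.carb_gpct + self.fat_gpct > 100 + 1e-9:
            raise ValueError("macronutrient fractions sum above 100 g per 100 g")


#: The two AIN-93G-based experimental chows (macronutrient g per 100 g).
#: The control chow has a standard 20%-casein protein level; the restricted
#: chow replaces most casein with corn starch at matched energy density.
CONTROL_DIET = DietComposition("D11051801 (control, 20% casein)", 18.0, 62.0, 10.0)
RESTRICTED_DIET = DietComposition("D11092301 (protein-restricted, 5% casein)", 5.0, 76.0, 10.0)


# ---------------------------------------------------------------------------
# Diet energetics
# ---------------------------------------------------------------------------

def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def per_rat_intake(record: CageIntakeRecord) -> float:
    """Average daily intake per animal: cage total / number of rats."""
    if record.n_rats < 1:
        raise ValueError("n_rats must be >= 1")
    return record.daily_intake / record.n_rats


def diet_energy_density(diet: DietComposition) -> float:
    """Metabolizable energy density in kcal/g via Atwater factors.

    Returned at full precision; round to 1 decimal for comparison with
    vendor sheets.
    """
    kcal_per_100g = (
        ATWATER["protein"] * diet.protein_gpct
        + ATWATER["carb"] * diet.carb_gpct
        + ATWATER["fat"] * diet.fat_gpct
    )
    return kcal_per_100g / 100.0


def diet_kcal_percent(diet: DietComposition, macro: str) -> int:
    """Percent of metabolizable energy contributed by ``macro``.

    ``macro`` is one of ``protein``, ``carb``, ``fat``.  Rounded half-up to
    an integer to match how vendor composition tables are printed.
    """
    if macro not in ATWATER:
        raise ValueError(f"macro must be one of {tuple(ATWATER)}")
    total = diet_energy_density(diet) * 100.0
    if total <= 0:
        raise ValueError("zero-energy diet has no defined energy shares")
    grams = {"protein": diet.protein_gpct, "carb": diet.carb_gpct, "fat": diet.fat_gpct}[macro]
    return _round_half_up(100.0 * ATWATER[macro] * grams / total)


# ---------------------------------------------------------------------------
# CSV reader / writer
# ---------------------------------------------------------------------------

def _build_session(rat: str, group: str, session_type: str, day: int,
                   bottle_frames: "dict[str, pd.DataFrame]",
                   duration: float) -> SessionRecord:
    trains = []
    solution_map: dict[str, str] = {}
    flavor_map: dict[str, str] = {}
    for bottle in sorted(bottle_frames):
        sub = bottle_frames[bottle]
        ts = sub["timestamp_s"].dropna().to_numpy(dtype=float)
        ts.sort()
        uniq = np.unique(ts)
        if uniq.size < ts.size:
            logger.warning(
                "rat %s day %s bottle %s: collapsed %d duplicate timestamps",
                rat, day, bottle, ts.size - uniq.size,
            )
        trains.append(LickTrain(bottle, uniq))
        solution_map[bottle] = str(sub["solution"].iloc[0])
        flavor = sub["flavor"].iloc[0]
        flavor_map[bottle] = "" if pd.isna(flavor) else str(flavor)
    return SessionRecord(
        rat_id=rat, diet_group=group, session_type=session_type,
        day_index=day, bottles=tuple(trains),
        solution_map=solution_map, flavor_map=flavor_map, duration=duration,
    )


def read_lick_csv(path: str | Path, duration: float = 3600.0) -> list[SessionRecord]:
    """Read the canonical long-form lick CSV into SessionRecords.

    Rows are grouped by (rat, session_type, day, bottle) and timestamps
    sorted ascending, so the result is invariant to input row order.
    Duplicate timestamps within a bottle are collapsed with a logged
    warning.  Missing required columns raise :class:`LickDataFormatError`
    naming the column.
    """
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise LickDataFormatError(f"missing required column(s): {', '.join(missing)}")
    sessions: list[SessionRecord] = []
    keys = ["rat", "group", "session_type", "day"]
    for (rat, group, stype, day), g in df.groupby(keys, sort=True):
        bottle_frames = {str(b): sub for b, sub in g.groupby("bottle", sort=True)}
        sessions.append(_build_session(str(rat), str(group), str(stype),
                                       int(day), bottle_frames, duration))
    return sessions


def write_session_csv(sessions: Iterable[SessionRecord], path: str | Path) -> None:
    """Write SessionRecords back to the canonical long-form CSV.

    Deterministic row order (sorted by rat, day, bottle, time) and fixed
    timestamp precision make re-writes byte-identical.
    """
    rows = []
    ordered = sorted(sessions, key=lambda s: (s.rat_id, s.session_type, s.day_index))
    for s in ordered:
        for train in sorted(s.bottles, key=lambda t: t.bottle_label):
            base = dict(
                rat=s.rat_id, group=s.diet_group, session_type=s.session_type,
                day=s.day_index, bottle=train.bottle_label,
                solution=s.solution_map[train.bottle_label],
                flavor=s.flavor_map.get(train.bottle_label, ""),
            )
            if len(train) == 0:
                rows.append({**base, "timestamp_s": ""})
            else:
                for t in train.timestamps:
                    rows.append({**base, "timestamp_s": f"{t:.{TIMESTAMP_DECIMALS}f}"})
    out = pd.DataFrame(rows, columns=CSV_COLUMNS)
    out.to_csv(path, index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# Operant-box text reader
# ---------------------------------------------------------------------------

_ARRAY_HEADER = re.compile(r"^([A-Za-z]\w*):\s*$")
_DATA_ROW = re.compile(r"^\s+\d+:\s*(.*)$")


def read_operant_text(path: str | Path, event_map: Mapping[str, object],
                      duration: float = 3600.0) -> list[SessionRecord]:
    """Read an operant-box text dump of named timestamp arrays.

    The dialect is the common behavioral-chamber export: a line ``X:``
    starts array ``X``; indented ``n:  v1  v2 ...`` rows carry its values.
    ``event_map`` supplies everything the file does not: session metadata
    and an ``arrays`` mapping from array name to bottle, e.g.::

        {"rat_id": "r1", "diet_group": "PR", "session_type": "preference",
         "day_index": 5,
         "arrays": {"A": {"bottle": "left", "solution": "casein",
                          "flavor": "cherry"},
                    "B": {"bottle": "right", "solution": "maltodextrin",
                          "flavor": "grape"}}}

    Arrays absent from the mapping are skipped with a warning; a mapped
    array absent from the file yields an empty train.  Malformed data rows
    raise :class:`LickDataFormatError` with the line number.
    """
    arrays: dict[str, list[float]] = {}
    current: str | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                current = None
                continue
            m = _ARRAY_HEADER.match(line)
            if m:
                current = m.group(1)
                arrays.setdefault(current, [])
                continue
            m = _DATA_ROW.match(line)
            if m:
                if current is None:
                    raise LickDataFormatError(f"line {lineno}: data row outside any array block")
                try:
                    arrays[current].extend(float(v) for v in m.group(1).split())
                except ValueError as exc:
                    raise LickDataFormatError(f"line {lineno}: malformed value ({exc})") from None
                continue
            # scalar metadata lines ("Start Date: ...") are ignored
            current = None

    mapping = dict(event_map.get("arrays", {}))  # type: ignore[union-attr]
    for name in arrays:
        if name not in mapping:
            logger.warning("array %r not in event map; skipped", name)

    trains = []
    solution_map: dict[str, str] = {}
    flavor_map: dict[str, str] = {}
    for name, spec in mapping.items():
        values = np.unique(np.asarray(arrays.get(name, []), dtype=float))
        bottle = str(spec["bottle"])  # type: ignore[index]
        trains.append(LickTrain(bottle, values))
        solution_map[bottle] = str(spec["solution"])  # type: ignore[index]
        flavor_map[bottle] = str(spec.get("flavor", ""))  # type: ignore[union-attr]

    record = SessionRecord(
        rat_id=str(event_map["rat_id"]),
        diet_group=str(event_map["diet_group"]),
        session_type=str(event_map["session_type"]),
        day_index=int(event_map["day_index"]),  # type: ignore[arg-type]
        bottles=tuple(trains),
        solution_map=solution_map,
        flavor_map=flavor_map,
        duration=float(event_map.get("duration", duration)),  # type: ignore[arg-type]
    )
    return [record]
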