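"""Valence-arousal emotion semantics and transition analysis.

A vocabulary of 20 emotions is anchored in the valence-arousal plane
(1-9 rating scale). Ratings are annotated with the nearest anchor,
mapped to HVHA/HVLA/LVHA/LVLA quadrants, and before/music/after
transition records are aggregated into conditional probability tables
P(after | before, music type) at either emotion or quadrant
granularity — the machinery behind "which music moves which emotional
state where".
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from emomap.types import InvalidInputError, TransitionRecord, TransitionTable, VARating


@dataclass(frozen=True)
class EmotionAnchor:
    """One named emotion with its valence-arousal coordinates."""

    name: str
    valence: float
    arousal: float


#: Number of emotions in the default vocabulary.
N_EMOTIONS = 20

#: Valence/arousal split between "high" and "low"; the boundary counts as high.
QUADRANT_THRESHOLD = 5.0


def load_anchors(path: str | Path | None = None) -> list[EmotionAnchor]:
    """Load the emotion anchor table (default: the packaged 20-emotion set).

    The packaged coordinates are approximate, documented defaults;
    pass ``path`` to use a custom JSON file of the same shape.
    """
    if path is None:
        text = (
            resources.files("emomap").joinpath("data/emotion_anchors.json").read_text()
        )
    else:
        text = Path(path).read_text()
    raw = json.loads(text)["anchors"]
    anchors = [
        EmotionAnchor(name=name, valence=coord["valence"], arousal=coord["arousal"])
        for name, coord in raw.items()
    ]
    names = [a.name for a in anchors]
    if len(set(names)) != len(names):
        raise InvalidInputError("duplicate anchor names")
    for a in anchors:
        if not (1 <= a.valence <= 9 and 1 <= a.arousal <= 9):
            raise InvalidInputError(f"anchor {a.name} outside the 1-9 scale")
    return anchors


def annotate_emotion(rating: VARating, anchors: list[EmotionAnchor] | None = None) -> str:
    """Name of the nearest anchor (Euclidean; ties broken lexicographically)."""
    anchors = anchors if anchors is not None else load_anchors()
    if not anchors:
        raise InvalidInputError("anchor list is empty")
    best = min(
        anchors,
        key=lambda a: (
            (a.valence - rating.valence) ** 2 + (a.arousal - rating.arousal) ** 2,
            a.name,
        ),
    )
    return best.name


def quadrant(rating: VARating, threshold: float = QUADRANT_THRESHOLD) -> str:
    """Quadrant label; values at the threshold count as High."""
    v = "HV" if rating.valence >= threshold else "LV"
    a = "HA" if rating.arousal >= threshold else "LA"
    return v + a


def emotion_quadrant(name: str, anchors: list[EmotionAnchor] | None = None) -> str:
    """Quadrant of a named emotion via its anchor coordinates."""
    anchors = anchors if anchors is not None else load_anchors()
    for a in anchors:
        if a.name == name:
            return quadrant(VARating(valence=a.valence, arousal=a.arousal))
    raise InvalidInputError(f"unknown emotion name: {name!r}")


def transition_probabilities(
    records: list[TransitionRecord],
    granularity: str = "emotion",
    anchors: list[EmotionAnchor] | None = None,
) -> TransitionTable:
    """Estimate P(after | before, music_type) from observed records.

    With ``granularity="quadrant"`` the before/after emotions are
    first mapped to their valence-arousal quadrants. Probabilities are
    reported with raw counts so low-support cells stay interpretable.
    """
    if not records:
        raise InvalidInputError("no transition records given")
    if granularity not in ("emotion", "quadrant"):
        raise InvalidInputError(f"unknown granularity {granularity!r}")
    if granularity == "quadrant":
        anchors = anchors if anchors is not None else load_anchors()
        records = [
            TransitionRecord(
                before=emotion_quadrant(r.before, anchors),
                music_type=r.music_type,
                after=emotion_quadrant(r.after, anchors),
            )
            for r in records
        ]
    counts: dict[tuple[str, str], dict[str, int]] = {}
    for r in records:
        key = (r.before, r.music_type)
        counts.setdefault(key, {}).setdefault(r.after, 0)
        counts[key][r.after] += 1
    cells: dict[tuple[str, str], dict[str, tuple[int, float]]] = {}
    for key, after_counts in counts.items():
        total = sum(after_counts.values())
        cells[key] = {
            after: (c, c / total) for after, c in sorted(after_counts.items())
        }
    return TransitionTable(cells=cells, granularity=granularity)


def export_parallel_coordinates(
    table: TransitionTable, after_filter: set[str] | None = None
) -> pd.DataFrame:
    """Long-format export for parallel-coordinate plots.

    One row per nonzero (before, music_type, after) cell with its
    count and conditional probability; ``after_filter`` restricts the
    output to chosen after-labels.
    """
    known_after = {a for cell in table.cells.values() for a in cell}
    if after_filter is not None:
        unknown = after_filter - known_after
        if unknown:
            raise InvalidInputError(f"unknown after-labels: {sorted(unknown)}")
    rows = []
    for (before, music_type), cell in sorted(table.cells.items()):
        for after, (count, prob) in cell.items():
            if after_filter is not None and after not in after_filter:
                continue
            rows.append(
                {
                    "before": before,
                    "music_type": music_type,
                    "after": after,
                    "count": count,
                    "probability": prob,
                }
            )
    return pd.DataFrame(rows, columns=["before", "music_type", "after", "count", "probability"])


def table_from_long(df: pd.DataFrame, granularity: str = "emotion") -> TransitionTable:
    """Rebuild a :class:`TransitionTable` from its long-format export."""
    cells: dict[tuple[str, str], dict[str, tuple[int, float]]] = {}
    for _, row in df.iterrows():
        key = (row["before"], row["music_type"])
        cells.setdefault(key, {})[row["after"]] = (int(row["count"]), float(row["probability"]))
    return TransitionTable(cells=cells, granularity=granularity)
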