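"""Stimulus condition sets and event-related presentation sequences.

A :class:`ConditionSet` is the shared index of every matrix in the
pipeline: ``n_conditions`` stimuli, each assigned exactly one category
from a fixed five-label vocabulary (faces, animal bodies, people,
objects, scenes).  An :class:`EventSequence` is the trial order of one
rapid event-related run: image trials interleaved with null (fixation)
trials at a requested proportion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Fixed category vocabulary, in canonical order.
CATEGORIES: tuple[str, ...] = ("face", "animal_body", "person", "object", "scene")

#: Sentinel condition id used for null (fixation) trials in event sequences.
NULL_ID: int = -1


@dataclass(frozen=True)
class ConditionSet:
    """Stimulus conditions with 0-based contiguous ids and category labels."""

    categories: tuple[str, ...]

    def __post_init__(self) -> None:
        unknown = set(self.categories) - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown categories: {sorted(unknown)}")
        if len(self.categories) == 0:
            raise ValueError("a ConditionSet needs at least one condition")

    @property
    def n_conditions(self) -> int:
        return len(self.categories)

    @property
    def ids(self) -> np.ndarray:
        return np.arange(self.n_conditions)

    def category_indices(self) -> np.ndarray:
        """Per-condition index into :data:`CATEGORIES`."""
        lookup = {c: i for i, c in enumerate(CATEGORIES)}
        return np.array([lookup[c] for c in self.categories])

    def members(self, category: str) -> np.ndarray:
        """Condition ids belonging to ``category``."""
        return np.array([i for i, c in enumerate(self.categories) if c == category])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"condition_id": self.ids, "category": list(self.categories)}
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ConditionSet":
        frame = frame.sort_values("condition_id")
        ids = frame["condition_id"].to_numpy()
        if not np.array_equal(ids, np.arange(len(ids))):
            raise ValueError("condition ids must be unique, contiguous and 0-based")
        return cls(tuple(frame["category"]))

    @classmethod
    def read_tsv(cls, path) -> "ConditionSet":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


@dataclass(frozen=True)
class EventSequence:
    """One run of image and null trials with strictly increasing onsets.

    ``condition_ids`` uses :data:`NULL_ID` for null trials.  Trials are
    spaced ``trial_duration + isi`` seconds apart.
    """

    onsets: np.ndarray
    condition_ids: np.ndarray
    trial_duration: float
    isi: float
    null_fraction: float = field(default=0.0)

    def __post_init__(self) -> None:
        onsets = np.asarray(self.onsets, dtype=float)
        ids = np.asarray(self.condition_ids, dtype=int)
        object.__setattr__(self, "onsets", onsets)
        object.__setattr__(self, "condition_ids", ids)
        if onsets.shape != ids.shape:
            raise ValueError("onsets and condition_ids must have matching length")
        if onsets.size and np.any(np.diff(onsets) <= 0):
            raise ValueError("onsets must be strictly increasing")

    @property
    def n_trials(self) -> int:
        return self.onsets.size

    @property
    def n_null(self) -> int:
        return int(np.sum(self.condition_ids == NULL_ID))

    @property
    def n_image(self) -> int:
        return self.n_trials - self.n_null

    @property
    def image_condition_ids(self) -> np.ndarray:
        """The distinct image condition ids, sorted."""
        ids = self.condition_ids[self.condition_ids != NULL_ID]
        return np.unique(ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "onset": self.onsets,
                "condition_id": self.condition_ids,
                "trial_duration": self.trial_duration,
                "isi": self.isi,
            }
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "EventSequence":
        frame = pd.read_csv(path)
        n = frame["condition_id"].ne(NULL_ID).sum()
        n_null = frame["condition_id"].eq(NULL_ID).sum()
        return cls(
            onsets=frame["onset"].to_numpy(),
            condition_ids=frame["condition_id"].to_numpy(),
            trial_duration=float(frame["trial_duration"].iloc[0]),
            isi=float(frame["isi"].iloc[0]),
            null_fraction=float(n_null / max(n + n_null, 1)),
        )
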