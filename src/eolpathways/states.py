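"""Daily care-state sequences over the last year of life.

The unit of analysis is the *care state* occupied by a decedent on each of
the 365 days preceding death: acute hospitalization, rehabilitation,
hospital-at-home, psychiatry, or home (which pools community care and
nursing homes).  A patient's *sequence* is the succession of daily states;
index 0 is the day 365 days before death and the final index is the day of
death itself (day offsets count backwards: ``days_before_death = 0`` is the
day of death).

States carry a fixed priority for resolving same-day overlaps between care
episodes: ACUTE > REHAB > HAH > PSY > HOME, i.e. the more intensive setting
wins the day.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Number of daily states in the observation window before death.
SEQUENCE_LENGTH = 365


class CareState(IntEnum):
    """The five places of care.

    Integer values encode the same-day priority order (lower = higher
    priority); they are also the codes used in the dense sequence arrays.
    """

    ACUTE = 0  #: acute hospitalization
    REHAB = 1  #: rehabilitation / post-acute care
    HAH = 2    #: hospital at home
    PSY = 3    #: psychiatric hospitalization
    HOME = 4   #: home, community care or nursing home (background state)

    @property
    def char(self) -> str:
        return STATE_CHARS[self.value]


#: One-character codes used in the flat text serialization, in CareState order.
STATE_CHARS = "ARDPH"
_CHAR_TO_CODE = {c: i for i, c in enumerate(STATE_CHARS)}

#: States billed as hospital care (per-diem settings).
HOSPITAL_STATES = (CareState.ACUTE, CareState.REHAB, CareState.HAH, CareState.PSY)

N_STATES = len(CareState)


def _coerce_states(states: Sequence[int] | np.ndarray) -> np.ndarray:
    arr = np.asarray(
        [s.value if isinstance(s, CareState) else s for s in states]
        if not isinstance(states, np.ndarray)
        else states
    )
    arr = arr.astype(np.uint8, casting="unsafe")
    if arr.ndim != 1:
        raise ValueError("a state sequence must be one-dimensional")
    if arr.size and arr.max() >= N_STATES:
        raise ValueError("invalid care-state code in sequence")
    return arr


@dataclass(frozen=True)
class StateSequence:
    """One patient's daily care states over the 365 days before death.

    Parameters
    ----------
    patient_id : str
        Opaque patient identifier.
    states : array-like of int or CareState
        Exactly 365 state codes; ``states[-1]`` is the day of death.
    """

    patient_id: str
    states: np.ndarray

    def __post_init__(self) -> None:
        arr = _coerce_states(self.states)
        if arr.size != SEQUENCE_LENGTH:
            raise ValueError(
                f"a StateSequence must have exactly {SEQUENCE_LENGTH} daily "
                f"states, got {arr.size}"
            )
        arr.flags.writeable = False
        object.__setattr__(self, "states", arr)

    def __len__(self) -> int:
        return len(self.states)

    def to_string(self) -> str:
        """Serialize as 365 single-character state codes."""
        return "".join(STATE_CHARS[s] for s in self.states)

    def to_rle(self) -> str:
        """Run-length-encoded form, ``state:length;state:length;...``."""
        return rle_encode(self.states)

    @classmethod
    def from_string(cls, patient_id: str, text: str) -> "StateSequence":
        return cls(patient_id, string_to_codes(text))

    @classmethod
    def from_rle(cls, patient_id: str, text: str) -> "StateSequence":
        return cls(patient_id, rle_decode(text))


def string_to_codes(text: str) -> np.ndarray:
    try:
        return np.fromiter((_CHAR_TO_CODE[c] for c in text), dtype=np.uint8,
                           count=len(text))
    except KeyError as exc:  # invalid character
        raise ValueError(f"invalid state character {exc.args[0]!r}") from None


def rle_encode(codes: np.ndarray) -> str:
    codes = _coerce_states(codes)
    if codes.size == 0:
        return ""
    change = np.flatnonzero(np.diff(codes)) + 1
    starts = np.concatenate(([0], change))
    lengths = np.diff(np.concatenate((starts, [codes.size])))
    return ";".join(f"{STATE_CHARS[codes[s]]}:{l}" for s, l in zip(starts, lengths))


def rle_decode(text: str) -> np.ndarray:
    if not text:
        return np.empty(0, dtype=np.uint8)
    parts = []
    for token in text.split(";"):
        char, _, length = token.partition(":")
        parts.append(np.full(int(length), _CHAR_TO_CODE[char], dtype=np.uint8))
    return np.concatenate(parts)


@dataclass(frozen=True)
class CareEpisode:
    """A contiguous spell in one care state, in days before death.

    ``start_days_before_death >= end_days_before_death`` (time runs
    backwards); both endpoints are included and lie in [0, 364], day 0
    being the day of death.
    """

    patient_id: str
    state: CareState
    start_days_before_death: int
    end_days_before_death: int

    def __post_init__(self) -> None:
        s, e = self.start_days_before_death, self.end_days_before_death
        if not (0 <= e <= s <= SEQUENCE_LENGTH - 1):
            raise ValueError(
                f"episode day offsets must satisfy 0 <= end <= start <= "
                f"{SEQUENCE_LENGTH - 1}, got start={s}, end={e}"
            )
        object.__setattr__(self, "state", CareState(self.state))


def encode_daily_states(
    episodes: Iterable[CareEpisode],
    patient_id: str | None = None,
    include_death_day: bool = True,
) -> StateSequence:
    """Collapse a patient's care episodes into one daily state per day.

    Days covered by no episode are HOME.  When several episodes cover the
    same day, the highest-priority state wins (ACUTE > REHAB > HAH > PSY >
    HOME).  With ``include_death_day`` (the default) the final sequence
    element is the day of death (offset 0); otherwise the window ends the
    day before death (offset 1) and offset-0 episodes fall outside it.

    Parameters
    ----------
    episodes : iterable of CareEpisode
        All episodes of a single patient.
    patient_id : str, optional
        Required when ``episodes`` is empty.

    Returns
    -------
    StateSequence
    """
    episodes = list(episodes)
    if patient_id is None:
        if not episodes:
            raise ValueError("patient_id is required when there are no episodes")
        patient_id = episodes[0].patient_id
    if any(e.patient_id != patient_id for e in episodes):
        raise ValueError("all episodes must belong to a single patient")

    shift = 0 if include_death_day else 1
    codes = np.full(SEQUENCE_LENGTH, CareState.HOME.value, dtype=np.uint8)
    # Sort so higher-priority (lower-code) states are written last.
    for ep in sorted(episodes, key=lambda e: -e.state.value):
        lo = ep.end_days_before_death - shift   # most recent day of the spell
        hi = ep.start_days_before_death - shift
        # day offset d maps to index L-1-d
        i0 = max(SEQUENCE_LENGTH - 1 - hi, 0)
        i1 = SEQUENCE_LENGTH - 1 - lo
        if i1 < 0:
            continue
        codes[i0 : i1 + 1] = np.minimum(codes[i0 : i1 + 1], ep.state.value)
    return StateSequence(patient_id, codes)


@dataclass
class SequenceSet:
    """A collection of aligned daily state sequences.

    Stores the cohort's sequences as an ``(n, n_days)`` uint8 matrix for
    the vectorised operations (dissimilarities, chronograms, place of
    death).  The reference window is 365 days; shorter aligned sets are
    accepted for testing.
    """

    ids: list = field(default_factory=list)
    data: np.ndarray = field(default_factory=lambda: np.empty((0, SEQUENCE_LENGTH), np.uint8))

    def __post_init__(self) -> None:
        self.ids = list(self.ids)
        self.data = np.asarray(self.data, dtype=np.uint8)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D (n, n_days) array")
        if len(self.ids) != self.data.shape[0]:
            raise ValueError("ids and data rows do not match")
        if self.data.size and self.data.max() >= N_STATES:
            raise ValueError("invalid care-state code in sequence data")

    @property
    def n_days(self) -> int:
        return self.data.shape[1]

    def __len__(self) -> int:
        return len(self.ids)

    def __getitem__(self, patient_id) -> StateSequence:
        i = self.ids.index(patient_id)
        return StateSequence(patient_id, self.data[i].copy())

    def subset(self, ids: Sequence) -> "SequenceSet":
        pos = {p: i for i, p in enumerate(self.ids)}
        idx = [pos[p] for p in ids]
        return SequenceSet(list(ids), self.data[idx].copy())

    @classmethod
    def from_sequences(cls, sequences: Iterable[StateSequence]) -> "SequenceSet":
        seqs = list(sequences)
        if not seqs:
            return cls()
        return cls([s.patient_id for s in seqs], np.vstack([s.states for s in seqs]))

    def to_frame(self, rle: bool = False) -> pd.DataFrame:
        """One row per patient; states as a 365-char string or RLE."""
        if rle:
            col = [rle_encode(row) for row in self.data]
        else:
            col = ["".join(STATE_CHARS[s] for s in row) for row in self.data]
        return pd.DataFrame({"patient_id": self.ids, "states": col})

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SequenceSet":
        ids = list(frame["patient_id"])
        rows = []
        for text in frame["states"]:
            codes = rle_decode(text) if ":" in text else string_to_codes(text)
            if rows and codes.size != rows[0].size:
                raise ValueError("serialized sequences have unequal lengths")
            rows.append(codes)
        data = np.vstack(rows) if rows else np.empty((0, SEQUENCE_LENGTH), np.uint8)
        return cls(ids, data)
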