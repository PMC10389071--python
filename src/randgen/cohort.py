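"""Participant digit sequences and cohort I/O.

A cohort is one row per participant: identity, group label, demographics
(age, gender, IQ) and the produced digit sequence (digits 1-10, space
separated inside one CSV cell). This mirrors the shape of the study's
deposited "demographics and produced sequences" table while staying plain
RFC-4180 CSV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical group labels. Unknown labels are an error, never a third group.
GROUPS = ("ASD", "CTRL")

#: Aliases normalised (case-insensitively) onto the canonical labels.
_GROUP_ALIASES = {
    "asd": "ASD",
    "autism": "ASD",
    "autistic": "ASD",
    "ctrl": "CTRL",
    "control": "CTRL",
    "comparison": "CTRL",
    "nt": "CTRL",
}

#: Default column names written by :func:`write_cohort` and expected by
#: :func:`read_cohort` when no mapping is given.
DEFAULT_COLUMNS = {
    "participant_id": "participant_id",
    "group": "group",
    "age": "age",
    "gender": "gender",
    "iq": "iq",
    "sequence": "sequence",
}


class CohortValidationError(ValueError):
    """Raised when a cohort file or object violates an invariant."""


def normalize_group(label: str) -> str:
    """Map a raw group label onto {ASD, CTRL}; unknown labels raise."""
    key = str(label).strip().lower()
    if key in _GROUP_ALIASES:
        return _GROUP_ALIASES[key]
    raise CohortValidationError(
        f"unknown group label {label!r}; expected one of {sorted(set(_GROUP_ALIASES))}"
    )


@dataclass(frozen=True)
class ResponseSequence:
    """One participant's ordered digit sequence (the atomic analysis unit).

    Parameters
    ----------
    participant_id
        Opaque identifier, unique within a cohort.
    group
        Group label in {ASD, CTRL}.
    responses
        Ordered digits, each in [1, 10], at least two of them (digram-based
        indices are undefined below length 2).
    """

    participant_id: str
    group: str
    responses: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "responses", tuple(int(r) for r in self.responses))
        object.__setattr__(self, "group", normalize_group(self.group))
        if len(self.responses) < 2:
            raise CohortValidationError(
                f"participant {self.participant_id!r}: sequence has "
                f"{len(self.responses)} responses; at least 2 are required"
            )
        for pos, r in enumerate(self.responses):
            if not 1 <= r <= 10:
                raise CohortValidationError(
                    f"participant {self.participant_id!r}: response {r} at "
                    f"position {pos} outside the valid range [1,10]"
                )

    def __len__(self) -> int:
        return len(self.responses)


@dataclass(frozen=True)
class ParticipantMeta:
    """Demographics attached to one participant."""

    participant_id: str
    group: str
    age: float
    gender: str
    iq: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "group", normalize_group(self.group))
        gender = str(self.gender).strip().upper()[:1]
        if gender not in ("M", "F"):
            raise CohortValidationError(
                f"participant {self.participant_id!r}: gender must be M or F, "
                f"got {self.gender!r}"
            )
        object.__setattr__(self, "gender", gender)
        if not self.age > 0:
            raise CohortValidationError(
                f"participant {self.participant_id!r}: age must be positive"
            )
        if not self.iq > 0:
            raise CohortValidationError(
                f"participant {self.participant_id!r}: iq must be positive"
            )


@dataclass
class Cohort:
    """A set of participants: sequences plus matching demographics."""

    sequences: list[ResponseSequence] = field(default_factory=list)
    meta: dict[str, ParticipantMeta] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen: set[str] = set()
        for seq in self.sequences:
            if seq.participant_id in seen:
                raise CohortValidationError(
                    f"duplicate participant_id {seq.participant_id!r}"
                )
            seen.add(seq.participant_id)
            if seq.participant_id not in self.meta:
                raise CohortValidationError(
                    f"participant {seq.participant_id!r} has no meta record"
                )
        extra = set(self.meta) - seen
        if extra:
            raise CohortValidationError(
                f"meta records without sequences: {sorted(extra)}"
            )

    def __len__(self) -> int:
        return len(self.sequences)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Cohort):
            return NotImplemented
        return self.sequences == other.sequences and self.meta == other.meta

    def group_sizes(self) -> dict[str, int]:
        sizes = {g: 0 for g in GROUPS}
        for seq in self.sequences:
            sizes[seq.group] += 1
        return sizes

    def subset(self, group: str) -> list[ResponseSequence]:
        group = normalize_group(group)
        return [s for s in self.sequences if s.group == group]


def _parse_sequence_cell(cell: str, participant_id: str, row: int) -> tuple[int, ...]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)) or pd.isna(cell):
        raise CohortValidationError(
            f"row {row}: participant {participant_id!r} has an empty sequence"
        )
    tokens = str(cell).replace(",", " ").split()
    if not tokens:
        raise CohortValidationError(
            f"row {row}: participant {participant_id!r} has an empty sequence"
        )
    responses = []
    for pos, tok in enumerate(tokens):
        try:
            value = int(tok)
        except ValueError:
            raise CohortValidationError(
                f"row {row}: participant {participant_id!r} has non-integer "
                f"token {tok!r} at position {pos}"
            ) from None
        if not 1 <= value <= 10:
            raise CohortValidationError(
                f"row {row}: participant {participant_id!r} response {value} at "
                f"position {pos} outside the valid range [1,10]"
            )
        responses.append(value)
    return tuple(responses)


def read_cohort(path, format_spec: dict[str, str] | None = None) -> Cohort:
    """Read a cohort from a delimited text file.

    Parameters
    ----------
    path
        CSV file with one row per participant.
    format_spec
        Optional mapping from the canonical field names
        (``participant_id``, ``group``, ``age``, ``gender``, ``iq``,
        ``sequence``) to the column names actually present in the file, so
        arbitrarily-headed files can be ingested without editing them.
        Unmapped extra columns are ignored with a logged warning.

    Returns
    -------
    Cohort
        Fully validated; malformed rows raise :class:`CohortValidationError`
        naming the row and participant.
    """
    mapping = dict(DEFAULT_COLUMNS)
    if format_spec:
        unknown = set(format_spec) - set(DEFAULT_COLUMNS)
        if unknown:
            raise CohortValidationError(
                f"format_spec maps unknown fields: {sorted(unknown)}"
            )
        mapping.update(format_spec)

    frame = pd.read_csv(path, dtype=str)
    missing = [col for col in mapping.values() if col not in frame.columns]
    if missing:
        raise CohortValidationError(
            f"{path}: missing required columns {missing}; "
            f"present: {list(frame.columns)}"
        )
    extra = set(frame.columns) - set(mapping.values())
    if extra:
        logger.warning("%s: ignoring unmapped columns %s", path, sorted(extra))

    sequences: list[ResponseSequence] = []
    meta: dict[str, ParticipantMeta] = {}
    for idx, record in frame.iterrows():
        row = int(idx) + 2  # 1-based, counting the header line
        pid = str(record[mapping["participant_id"]]).strip()
        try:
            responses = _parse_sequence_cell(record[mapping["sequence"]], pid, row)
            seq = ResponseSequence(pid, record[mapping["group"]], responses)
            m = ParticipantMeta(
                pid,
                record[mapping["group"]],
                float(record[mapping["age"]]),
                str(record[mapping["gender"]]),
                float(record[mapping["iq"]]),
            )
        except CohortValidationError:
            raise
        except (TypeError, ValueError) as err:
            raise CohortValidationError(f"row {row}: {err}") from err
        if pid in meta:
            raise CohortValidationError(
                f"row {row}: duplicate participant_id {pid!r}"
            )
        sequences.append(seq)
        meta[pid] = m
    return Cohort(sequences, meta)


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort as CSV, re-readable bit-identically by :func:`read_cohort`."""
    records = []
    for seq in cohort.sequences:
        m = cohort.meta[seq.participant_id]
        records.append(
            {
                "participant_id": seq.participant_id,
                "group": seq.group,
                "age": m.age,
                "gender": m.gender,
                "iq": m.iq,
                "sequence": " ".join(str(r) for r in seq.responses),
            }
        )
    frame = pd.DataFrame(records, columns=list(DEFAULT_COLUMNS))
    frame.to_csv(path, index=False)
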