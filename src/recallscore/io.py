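"""Delimited-text readers and writers for study tables.

All interchange files are UTF-8 CSV with a header row: prompts
(``prompt_id, passage_type, text``), responses (``response_id,
participant_id, group, prompt_id, recall_position, source, text``) and
ratings (``response_id, rater_id, rating``).  Readers validate
referential integrity and report malformed rows with their line numbers;
duplicate response ids are rejected rather than silently merged.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .reliability import RatingSet

__all__ = [
    "StudyTableError",
    "Prompt",
    "Response",
    "StudyTable",
    "read_prompts",
    "write_prompts",
    "read_responses",
    "write_responses",
    "read_ratings",
    "write_ratings",
    "read_study",
]

GROUPS = ("patient", "healthy")
SOURCES = ("human", "generic_asr", "custom_asr", "clean")
RECALL_POSITIONS = ("immediate", "delayed")
PASSAGE_TYPES = ("narrative", "instruction")


class StudyTableError(ValueError):
    """A study table file is malformed or referentially inconsistent."""


@dataclass(frozen=True)
class Prompt:
    prompt_id: str
    passage_type: str
    text: str


@dataclass(frozen=True)
class Response:
    response_id: str
    participant_id: str
    group: str
    prompt_id: str
    recall_position: str
    source: str
    text: str


@dataclass
class StudyTable:
    """Prompts, responses and ratings of one study, cross-validated."""

    prompts: dict[str, Prompt]
    responses: list[Response]
    ratings: RatingSet = field(default_factory=RatingSet)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for resp in self.responses:
            if resp.response_id in seen:
                raise StudyTableError(f"duplicate response_id {resp.response_id!r}")
            seen.add(resp.response_id)
            if resp.prompt_id not in self.prompts:
                raise StudyTableError(
                    f"response {resp.response_id!r} references unknown "
                    f"prompt_id {resp.prompt_id!r}"
                )


def _reader(path: str | os.PathLike[str], expected: Sequence[str]):
    fh = open(path, newline="", encoding="utf-8")
    reader = csv.DictReader(fh)
    if reader.fieldnames is None:
        fh.close()
        raise StudyTableError(f"{path}: empty file, expected header {expected}")
    if list(reader.fieldnames) != list(expected):
        fh.close()
        raise StudyTableError(
            f"{path}: header {reader.fieldnames} != expected {list(expected)}"
        )
    return fh, reader


def _check_enum(path, lineno, name, value, allowed):
    if value not in allowed:
        raise StudyTableError(
            f"{path}: line {lineno}: {name} {value!r} not one of {allowed}"
        )


def read_prompts(path: str | os.PathLike[str]) -> dict[str, Prompt]:
    fh, reader = _reader(path, ["prompt_id", "passage_type", "text"])
    prompts: dict[str, Prompt] = {}
    with fh:
        for row in reader:
            lineno = reader.line_num
            pid = row["prompt_id"]
            if not pid:
                raise StudyTableError(f"{path}: line {lineno}: empty prompt_id")
            if pid in prompts:
                raise StudyTableError(
                    f"{path}: line {lineno}: duplicate prompt_id {pid!r}"
                )
            _check_enum(path, lineno, "passage_type", row["passage_type"], PASSAGE_TYPES)
            prompts[pid] = Prompt(pid, row["passage_type"], row["text"])
    return prompts


def write_prompts(prompts: Iterable[Prompt], path: str | os.PathLike[str]) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["prompt_id", "passage_type", "text"])
        for p in prompts:
            writer.writerow([p.prompt_id, p.passage_type, p.text])


_RESPONSE_COLUMNS = [
    "response_id",
    "participant_id",
    "group",
    "prompt_id",
    "recall_position",
    "source",
    "text",
]


def read_responses(path: str | os.PathLike[str]) -> list[Response]:
    fh, reader = _reader(path, _RESPONSE_COLUMNS)
    responses: list[Response] = []
    seen: set[str] = set()
    with fh:
        for row in reader:
            lineno = reader.line_num
            rid = row["response_id"]
            if not rid:
                raise StudyTableError(f"{path}: line {lineno}: empty response_id")
            if rid in seen:
                raise StudyTableError(
                    f"{path}: line {lineno}: duplicate response_id {rid!r}"
                )
            seen.add(rid)
            _check_enum(path, lineno, "group", row["group"], GROUPS)
            _check_enum(path, lineno, "source", row["source"], SOURCES)
            _check_enum(
                path, lineno, "recall_position", row["recall_position"],
                RECALL_POSITIONS,
            )
            responses.append(Response(**{k: row[k] for k in _RESPONSE_COLUMNS}))
    return responses


def write_responses(
    responses: Iterable[Response], path: str | os.PathLike[str]
) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_RESPONSE_COLUMNS)
        for r in responses:
            writer.writerow([getattr(r, col) for col in _RESPONSE_COLUMNS])


def read_ratings(path: str | os.PathLike[str]) -> RatingSet:
    fh, reader = _reader(path, ["response_id", "rater_id", "rating"])
    ratings = RatingSet()
    with fh:
        for row in reader:
            lineno = reader.line_num
            try:
                value = float(row["rating"])
            except ValueError:
                raise StudyTableError(
                    f"{path}: line {lineno}: non-numeric rating {row['rating']!r}"
                ) from None
            try:
                ratings.add(row["response_id"], row["rater_id"], value)
            except ValueError as exc:
                raise StudyTableError(f"{path}: line {lineno}: {exc}") from None
    return ratings


def write_ratings(ratings: RatingSet, path: str | os.PathLike[str]) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["response_id", "rater_id", "rating"])
        for (rid, rater), value in ratings.ratings.items():
            writer.writerow([rid, rater, value])


def read_study(
    prompts_path: str | os.PathLike[str],
    responses_path: str | os.PathLike[str],
    ratings_path: str | os.PathLike[str] | None = None,
) -> StudyTable:
    """Read and cross-validate a full study table."""
    prompts = read_prompts(prompts_path)
    responses = read_responses(responses_path)
    ratings = read_ratings(ratings_path) if ratings_path else RatingSet()
    return StudyTable(prompts=prompts, responses=responses, ratings=ratings)
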