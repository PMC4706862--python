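"""Coding of ranked free-list responses into biological group codes.

Respondents write an ordered list of up to ten living-thing names ("the
first 10 living things coming to your mind").  Each name is mapped to one
of ten biological groups (prokaryotes/protists/funguses, plants,
invertebrates, fishes, amphibians, reptiles, birds, wild mammals, domestic
mammals and pets, human), preserving the rank at which it was written.
The codebook itself is a flat name -> code lookup plus a code -> label
table; person names (respondents sometimes list people they know) map to
the human group via an explicit list rather than any heuristic.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

N_GROUPS = 10

#: Variable labels in group-code order, as used for dataset columns.
GROUP_LABELS: tuple[str, ...] = (
    "prokaryotes_protists_funguses",
    "plants",
    "invertebrates",
    "fishes",
    "amphibians",
    "reptiles",
    "birds",
    "wild_mammals",
    "domestic_mammals",
    "human",
)

_PACKAGED_CODEBOOK = Path(__file__).parent / "data" / "codebook.json"
_PACKAGED_EXAMPLES = Path(__file__).parent / "data" / "example_responses.tsv"


class CodebookError(ValueError):
    """Raised for malformed codebook documents or uncodeable names."""


def normalize_name(name: str) -> str:
    """Normalize a living-thing name for lookup: casefold + trim."""
    return " ".join(name.split()).casefold()


def _expand_entry(raw_name: str) -> list[str]:
    """Expand one raw codebook entry into its lookup keys.

    Handles two conventions common in survey codebooks:

    * a trailing ``(s)``/``(es)`` plural marker yields both the singular
      and the plural form (``Fish(es)`` -> ``fish``, ``fishes``);
    * comma-joined synonyms are separate names (``Cock, Rooster``).
    """
    keys: list[str] = []
    for part in raw_name.split(","):
        part = normalize_name(part)
        if not part:
            continue
        for marker in ("(es)", "(s)"):
            if part.endswith(marker):
                stem = part[: -len(marker)].strip()
                suffix = marker[1:-1]
                keys.extend([stem, stem + suffix])
                break
        else:
            keys.append(part)
    return keys


@dataclass(frozen=True)
class GroupCodebook:
    """Lookup from normalized living-thing names to group codes 1..10."""

    entries: Mapping[str, int]
    labels: Mapping[int, str]
    person_names: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for code in range(1, N_GROUPS + 1):
            if code not in self.labels:
                raise CodebookError(f"group code {code} has no label")
        for name, code in self.entries.items():
            if not 1 <= code <= N_GROUPS:
                raise CodebookError(
                    f"entry {name!r} has code {code} outside 1..{N_GROUPS}"
                )

    def lookup(self, name: str) -> int | None:
        """Group code for *name*, or None if the name is unknown."""
        key = normalize_name(name)
        code = self.entries.get(key)
        if code is None and key in self.person_names:
            return N_GROUPS  # human
        return code

    def __contains__(self, name: str) -> bool:
        return self.lookup(name) is not None

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class RankedResponse:
    """One respondent's ordered list of living-thing names (ranks 1..10)."""

    student_id: str
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.names) > 10:
            raise ValueError(
                f"{self.student_id}: more than 10 names ({len(self.names)})"
            )
        if any(not n.strip() for n in self.names):
            raise ValueError(f"{self.student_id}: empty name in list")


@dataclass(frozen=True)
class CodedResponse:
    """Group codes aligned with the ranks of a :class:`RankedResponse`."""

    student_id: str
    codes: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(not 1 <= c <= N_GROUPS for c in self.codes):
            raise ValueError(f"{self.student_id}: code outside 1..{N_GROUPS}")


def _build(
    pairs: Iterable[tuple[str, int]],
    labels: Mapping[int, str],
    person_names: Iterable[str] = (),
) -> GroupCodebook:
    entries: dict[str, int] = {}
    for raw, code in pairs:
        for key in _expand_entry(raw):
            if key in entries and entries[key] != code:
                raise CodebookError(
                    f"name {key!r} maps to both code {entries[key]} and {code}"
                )
            entries[key] = code
    if not entries:
        raise CodebookError("codebook document defines no entries")
    return GroupCodebook(
        entries=entries,
        labels=dict(labels),
        person_names=frozenset(normalize_name(n) for n in person_names),
    )


def load_codebook(source: str | Path | None = None) -> GroupCodebook:
    """Load a codebook from JSON or TSV; default is the packaged codebook.

    JSON layout: ``{"entries": {name: code}, "labels": {code: label},
    "person_names": [name, ...]}``.  TSV layout: header ``name  code
    label`` with one row per entry (labels read from the first row seen
    for each code).
    """
    path = Path(source) if source is not None else _PACKAGED_CODEBOOK
    if path.suffix.lower() == ".json":
        doc = json.loads(path.read_text())
        pairs = [(name, int(code)) for name, code in doc.get("entries", {}).items()]
        labels = {int(c): lab for c, lab in doc.get("labels", {}).items()}
        persons = doc.get("person_names", [])
    else:
        pairs, labels, persons = [], {}, []
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            for row in reader:
                code = int(row["code"])
                pairs.append((row["name"], code))
                labels.setdefault(code, row.get("label", str(code)))
    return _build(pairs, labels, persons)


def code_response(
    r: RankedResponse, cb: GroupCodebook, policy: str = "error"
) -> CodedResponse:
    """Convert a ranked name list to group codes, preserving order.

    *policy* controls unknown names: ``error`` raises; ``drop`` removes
    them, remaining ranks close up, and each drop is logged; ``report``
    drops like ``drop`` but emits one summary warning per response.
    """
    if policy not in ("error", "drop", "report"):
        raise ValueError(f"unknown-name policy {policy!r}")
    codes: list[int] = []
    unknown: list[str] = []
    for name in r.names:
        code = cb.lookup(name)
        if code is None:
            unknown.append(name)
            if policy == "drop":
                logger.warning("%s: dropping unknown name %r", r.student_id, name)
        else:
            codes.append(code)
    if unknown:
        if policy == "error":
            raise CodebookError(
                f"student {r.student_id}: unknown name(s) "
                f"{', '.join(map(repr, unknown))}"
            )
        if policy == "report":
            logger.warning(
                "%s: dropped %d unknown name(s): %s",
                r.student_id, len(unknown), ", ".join(unknown),
            )
    return CodedResponse(student_id=r.student_id, codes=tuple(codes))


def read_responses(path: str | Path) -> list[RankedResponse]:
    """Read ranked responses from TSV (columns student_id, rank, name)."""
    per_student: dict[str, list[tuple[int, str]]] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None:
            return []
        if [h.strip().lower() for h in header[:3]] != ["student_id", "rank", "name"]:
            raise ValueError(f"{path}: expected header student_id/rank/name")
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(row)}")
            sid, rank_s, name = row[0], row[1], row[2]
            try:
                rank = int(rank_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad rank {rank_s!r}") from exc
            per_student.setdefault(sid, []).append((rank, name))
    out = []
    for sid, items in per_student.items():
        items.sort(key=lambda t: t[0])
        ranks = [r for r, _ in items]
        if ranks != list(range(1, len(ranks) + 1)):
            raise ValueError(f"student {sid}: ranks {ranks} are not 1..{len(ranks)}")
        out.append(RankedResponse(student_id=sid, names=tuple(n for _, n in items)))
    return out


def write_responses(responses: Sequence[RankedResponse], path: str | Path) -> None:
    """Write ranked responses to the TSV dialect read_responses accepts."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["student_id", "rank", "name"])
        for r in responses:
            for rank, name in enumerate(r.names, start=1):
                writer.writerow([r.student_id, rank, name])


def load_example_responses() -> list[RankedResponse]:
    """The five worked-example responses shipped with the package."""
    return read_responses(_PACKAGED_EXAMPLES)
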