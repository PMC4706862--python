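"""Rank-to-aliveness transform.

A coded response holds the group codes a student listed, in listing order.
Two steps turn it into the model input vector:

1. *average rank* — for each group g, the mean of the 1-based ranks at
   which g was listed (0 if never listed);
2. *reflection* — aliveness x_g = 11 - r_g for listed groups, 0 for
   absent ones, so a group listed only first scores 10, only last scores
   1, and absence scores 0.  Without reflection "never listed" (0) would
   sit next to "listed first" (1) in Euclidean distance, which is the
   opposite of what the scale means.

All arithmetic is done at full float precision; 2-decimal half-up
rounding is applied only at serialization.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .codebook import GROUP_LABELS, N_GROUPS, CodedResponse, GroupCodebook, \
    RankedResponse, code_response

_PACKAGED_DATASET = Path(__file__).parent / "data" / "aliveness_100x10.csv"


@dataclass(frozen=True)
class AverageRankVector:
    """Per-group mean listing rank; 0 marks an unlisted group."""

    student_id: str
    r: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.r) != N_GROUPS:
            raise ValueError(f"{self.student_id}: expected {N_GROUPS} values")
        for g, v in enumerate(self.r, start=1):
            if v != 0.0 and not 1.0 <= v <= 10.0:
                raise ValueError(
                    f"{self.student_id}: average rank {v} for group {g} "
                    "outside {0} ∪ [1, 10]"
                )


@dataclass(frozen=True)
class AlivenessVector:
    """Reflected scores in [0, 10]; higher = more prototypically alive."""

    student_id: str
    x: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.x) != N_GROUPS:
            raise ValueError(f"{self.student_id}: expected {N_GROUPS} values")
        if any(not 0.0 <= v <= 10.0 for v in self.x):
            raise ValueError(f"{self.student_id}: aliveness outside [0, 10]")


def average_ranks(c: CodedResponse) -> AverageRankVector:
    """Mean 1-based listing rank per group (0 where the group is absent)."""
    if not c.codes:
        raise ValueError(f"{c.student_id}: empty coded response")
    sums = np.zeros(N_GROUPS)
    counts = np.zeros(N_GROUPS)
    for rank, code in enumerate(c.codes, start=1):
        sums[code - 1] += rank
        counts[code - 1] += 1
    r = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    return AverageRankVector(student_id=c.student_id, r=tuple(r))


def reflect(a: AverageRankVector) -> AlivenessVector:
    """Reflect average ranks: x_g = 11 - r_g if listed, else 0."""
    x = tuple(11.0 - v if v > 0 else 0.0 for v in a.r)
    return AlivenessVector(student_id=a.student_id, x=x)


def round2(value: float) -> float:
    """Half-up rounding to 2 decimals, as used in serialized output."""
    return float(Decimal(repr(float(value))).quantize(Decimal("0.01"), ROUND_HALF_UP))


class Dataset:
    """n_students x 10 aliveness matrix with ordered ids and labels."""

    def __init__(
        self,
        student_ids: Sequence[str],
        values: np.ndarray,
        labels: Sequence[str] = GROUP_LABELS,
    ):
        values = np.asarray(values, dtype=float)
        if values.ndim != 2 or values.shape != (len(student_ids), len(labels)):
            raise ValueError(
                f"matrix shape {values.shape} does not match "
                f"{len(student_ids)} ids x {len(labels)} labels"
            )
        if len(set(student_ids)) != len(student_ids):
            dupes = {s for s in student_ids if list(student_ids).count(s) > 1}
            raise ValueError(f"duplicate student_id(s): {sorted(dupes)}")
        if values.size and (values.min() < 0 or values.max() > 10):
            raise ValueError("aliveness values must lie in [0, 10]")
        self.student_ids = list(student_ids)
        self.values = values
        self.labels = list(labels)

    @property
    def n_students(self) -> int:
        return len(self.student_ids)

    @property
    def n_variables(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.student_ids, name="student_id"),
            columns=self.labels,
        )

    def write_csv(self, path: str | Path) -> None:
        """Serialize with 2-decimal half-up rounding, trailing zeros trimmed."""
        with open(path, "w", newline="") as fh:
            fh.write("student_id," + ",".join(self.labels) + "\n")
            for sid, row in zip(self.student_ids, self.values):
                cells = [f"{round2(v):g}" for v in row]
                fh.write(sid + "," + ",".join(cells) + "\n")

    @classmethod
    def read_csv(cls, path: str | Path) -> "Dataset":
        df = pd.read_csv(path, index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy(float), list(df.columns))

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, Dataset)
            and self.student_ids == other.student_ids
            and self.labels == other.labels
            and np.array_equal(self.values, other.values)
        )


def build_dataset(
    responses: Iterable[RankedResponse],
    cb: GroupCodebook,
    policy: str = "error",
) -> Dataset:
    """Full chain code -> average rank -> reflect over many responses."""
    ids: list[str] = []
    rows: list[tuple[float, ...]] = []
    for resp in responses:
        coded = code_response(resp, cb, policy=policy)
        ids.append(resp.student_id)
        rows.append(reflect(average_ranks(coded)).x)
    values = np.array(rows, dtype=float) if rows else np.empty((0, N_GROUPS))
    return Dataset(ids, values)


def load_packaged_dataset() -> Dataset:
    """The packaged 100-student x 10-variable aliveness dataset."""
    return Dataset.read_csv(_PACKAGED_DATASET)
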