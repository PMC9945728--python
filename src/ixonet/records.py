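"""Literature-derived association records: one row per tick(stage)-host(family) link.

The record table is the primary input of the pipeline: each row states that a
tick species, at a given life stage, has been reported on a vertebrate family
(belonging to a vertebrate order) within a biogeographic realm, with a weight
counting the number of citation events behind the report.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Stage",
    "Realm",
    "AssociationRecord",
    "RecordSchemaError",
    "RecordValidationError",
    "read_records",
    "write_records",
    "merge_duplicates",
    "records_to_frame",
]


class Stage(str, enum.Enum):
    """Tick life stage. ``UNKNOWN`` rows carry stage-unresolved literature records."""

    LARVA = "larva"
    NYMPH = "nymph"
    ADULT = "adult"
    UNKNOWN = "unknown"


#: The three feeding stages in ontogenetic order (unknown excluded).
FEEDING_STAGES: tuple[Stage, Stage, Stage] = (Stage.LARVA, Stage.NYMPH, Stage.ADULT)


class Realm(str, enum.Enum):
    """Biogeographic realm of the record; ``WORLDWIDE`` marks cosmopolitan species."""

    AFROTROPICAL = "Afrotropical"
    ORIENTAL = "Oriental"
    AUSTRALASIAN = "Australasian"
    NEARCTIC = "Nearctic"
    NEOTROPICAL = "Neotropical"
    PALEARCTIC = "Palearctic"
    WORLDWIDE = "worldwide"


class RecordSchemaError(ValueError):
    """A mandatory column is missing from the record table."""


class RecordValidationError(ValueError):
    """A row violates the record invariants (enum tokens, positive weight)."""


@dataclass(frozen=True, slots=True)
class AssociationRecord:
    """One tick(stage)-host(family) association with realm and citation count.

    ``weight`` is the number of independent citation events supporting the
    association; it becomes the edge weight of the bipartite network.
    """

    tick_species: str
    stage: Stage
    host_family: str
    host_order: str
    realm: Realm
    weight: int = 1

    def __post_init__(self) -> None:
        if not isinstance(self.weight, int) or self.weight < 1:
            raise RecordValidationError(
                f"weight must be a positive integer, got {self.weight!r}"
            )
        for field in ("tick_species", "host_family", "host_order"):
            if not getattr(self, field).strip():
                raise RecordValidationError(f"{field} must be non-empty")
        # identifiers are opaque case-sensitive strings after whitespace trimming
        object.__setattr__(self, "tick_species", self.tick_species.strip())
        object.__setattr__(self, "host_family", self.host_family.strip())
        object.__setattr__(self, "host_order", self.host_order.strip())

    @property
    def key(self) -> tuple[str, Stage, str, Realm]:
        """Merge key: records sharing it are duplicate reports."""
        return (self.tick_species, self.stage, self.host_family, self.realm)


REQUIRED_COLUMNS = (
    "tick_species",
    "stage",
    "host_family",
    "host_order",
    "realm",
    "weight",
)

_STAGE_TOKENS = {s.value: s for s in Stage}
_REALM_TOKENS = {r.value: r for r in Realm}
# tolerate case variation on the realm token only ("worldwide" vs "Worldwide")
_REALM_TOKENS.update({r.value.lower(): r for r in Realm})


def _parse_row(row: pd.Series, line_no: int) -> AssociationRecord:
    stage_token = str(row["stage"]).strip().lower()
    if stage_token not in _STAGE_TOKENS:
        raise RecordValidationError(
            f"row {line_no}: unknown stage {row['stage']!r} "
            f"(expected one of {sorted(_STAGE_TOKENS)})"
        )
    realm_token = str(row["realm"]).strip()
    realm = _REALM_TOKENS.get(realm_token) or _REALM_TOKENS.get(realm_token.lower())
    if realm is None:
        raise RecordValidationError(
            f"row {line_no}: unknown realm {row['realm']!r} "
            f"(expected one of {sorted(set(r.value for r in Realm))})"
        )
    try:
        weight = int(row["weight"])
    except (TypeError, ValueError) as exc:
        raise RecordValidationError(
            f"row {line_no}: weight {row['weight']!r} is not an integer"
        ) from exc
    if weight < 1:
        raise RecordValidationError(f"row {line_no}: non-positive weight {weight}")
    return AssociationRecord(
        tick_species=str(row["tick_species"]),
        stage=_STAGE_TOKENS[stage_token],
        host_family=str(row["host_family"]),
        host_order=str(row["host_order"]),
        realm=realm,
        weight=weight,
    )


def merge_duplicates(records: Iterable[AssociationRecord]) -> list[AssociationRecord]:
    """Merge records sharing (species, stage, family, realm) by summing weights.

    Host order must agree within a merge group; a conflict raises, because a
    family cannot belong to two vertebrate orders.  The merged list is sorted
    by key so the result is independent of input order.
    """
    merged: dict[tuple, AssociationRecord] = {}
    n_dup = 0
    for rec in records:
        prev = merged.get(rec.key)
        if prev is None:
            merged[rec.key] = rec
        else:
            if prev.host_order != rec.host_order:
                raise RecordValidationError(
                    f"family {rec.host_family!r} assigned to two orders: "
                    f"{prev.host_order!r} and {rec.host_order!r}"
                )
            merged[rec.key] = replace(prev, weight=prev.weight + rec.weight)
            n_dup += 1
    if n_dup:
        logger.info("merged %d duplicate record rows by summing weights", n_dup)
    return sorted(
        merged.values(),
        key=lambda r: (r.tick_species, r.stage.value, r.host_family, r.realm.value),
    )


def read_records(path: str | Path, sep: str | None = None) -> list[AssociationRecord]:
    """Read a delimited record table (CSV by default, TSV for ``.tsv`` files).

    The header must contain :data:`REQUIRED_COLUMNS`.  Duplicate
    (species, stage, family, realm) rows are merged by summing their weights.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    frame = pd.read_csv(path, sep=sep, dtype=str)
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise RecordSchemaError(
            f"{path}: missing mandatory column(s): {', '.join(missing)}"
        )
    records = [
        _parse_row(row, line_no)
        for line_no, (_, row) in enumerate(frame.iterrows(), start=2)
    ]
    return merge_duplicates(records)


def records_to_frame(records: Sequence[AssociationRecord]) -> pd.DataFrame:
    """Record list as a DataFrame with the canonical column layout."""
    return pd.DataFrame(
        {
            "tick_species": [r.tick_species for r in records],
            "stage": [r.stage.value for r in records],
            "host_family": [r.host_family for r in records],
            "host_order": [r.host_order for r in records],
            "realm": [r.realm.value for r in records],
            "weight": [r.weight for r in records],
        }
    )


def write_records(records: Sequence[AssociationRecord], path: str | Path) -> None:
    """Write records as a CSV table readable by :func:`read_records`."""
    records_to_frame(records).to_csv(path, index=False)
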