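"""Typed registry of the biological entities appearing in a study.

Four entity types participate in the disease hypergraph: metabolites,
proteins, and GO terms become vertices, while diseases become hyperedges.
The catalog owns the id -> type mapping and is the single source of truth
for membership checks when association tables are ingested.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

ENTITY_TYPES = ("metabolite", "protein", "go_term", "disease")
VERTEX_TYPES = ("metabolite", "protein", "go_term")


@dataclass
class EntityCatalog:
    """Registry mapping entity id -> (entity_type, display_label).

    Every id has exactly one type; re-registering an id with a different
    type is an error.
    """

    entries: dict[str, tuple[str, str]] = field(default_factory=dict)

    def add(self, entity_id: str, entity_type: str, label: str | None = None) -> None:
        if entity_type not in ENTITY_TYPES:
            raise ValueError(f"unknown entity type {entity_type!r} for id {entity_id!r}")
        existing = self.entries.get(entity_id)
        if existing is not None and existing[0] != entity_type:
            raise ValueError(
                f"entity {entity_id!r} already registered as {existing[0]!r}, "
                f"cannot re-register as {entity_type!r}"
            )
        self.entries[entity_id] = (entity_type, label if label is not None else entity_id)

    def add_all(self, ids: Iterable[str], entity_type: str) -> None:
        for entity_id in ids:
            self.add(entity_id, entity_type)

    def type_of(self, entity_id: str) -> str:
        try:
            return self.entries[entity_id][0]
        except KeyError:
            raise KeyError(f"entity {entity_id!r} not in catalog") from None

    def __contains__(self, entity_id: str) -> bool:
        return entity_id in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def ids_of_type(self, entity_type: str) -> list[str]:
        """Ids of one type, in insertion order (stable across runs)."""
        if entity_type not in ENTITY_TYPES:
            raise ValueError(f"unknown entity type {entity_type!r}")
        return [i for i, (t, _) in self.entries.items() if t == entity_type]

    def iter_typed(self) -> Iterator[tuple[str, str]]:
        for entity_id, (entity_type, _) in self.entries.items():
            yield entity_id, entity_type

    def counts(self) -> dict[str, int]:
        out = {t: 0 for t in ENTITY_TYPES}
        for _, (t, _) in self.entries.items():
            out[t] += 1
        return out
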