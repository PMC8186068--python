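"""Gene set collections and GMT input/output."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

from .errors import FormatError, ValidationError


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    name: str
    genes: tuple

    def __len__(self) -> int:
        return len(self.genes)


class GeneSetCollection(Mapping):
    """An ordered mapping ``set_id -> GeneSet`` with unique ids and, within
    each set, unique genes."""

    def __init__(self, sets: Iterable[GeneSet]):
        self._sets: dict[str, GeneSet] = {}
        for s in sets:
            if s.set_id in self._sets:
                raise ValidationError(f"duplicate set id {s.set_id!r}")
            if len(set(s.genes)) != len(s.genes):
                raise ValidationError(f"set {s.set_id!r} contains duplicate genes")
            self._sets[s.set_id] = s

    @classmethod
    def from_dict(cls, d: Mapping[str, Iterable[str]]) -> "GeneSetCollection":
        """Build from ``{set_id: genes}``; the id doubles as the name."""
        return cls(GeneSet(k, k, tuple(dict.fromkeys(v))) for k, v in d.items())

    def __getitem__(self, set_id: str) -> GeneSet:
        return self._sets[set_id]

    def __iter__(self) -> Iterator[str]:
        return iter(self._sets)

    def __len__(self) -> int:
        return len(self._sets)

    def sets(self) -> list:
        return list(self._sets.values())


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: tab-separated ``id, description, gene, gene, ...``.

    Duplicate genes within a line are collapsed with a warning; a line with
    fewer than three fields is a format error reported with its line number.
    """
    sets = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            set_id, name, *genes = fields
            genes = [g for g in genes if g]
            unique = tuple(dict.fromkeys(genes))
            if len(unique) != len(genes):
                warnings.warn(
                    f"{path}:{lineno}: duplicate genes in set {set_id!r} collapsed",
                    stacklevel=2,
                )
            sets.append(GeneSet(set_id, name, unique))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for s in collection.sets():
            fh.write("\t".join([s.set_id, s.name, *s.genes]) + "\n")


def filter_by_size(
    collection: GeneSetCollection,
    min_size: int = 5,
    max_size: int = 5000,
    universe: Iterable[str] | None = None,
) -> GeneSetCollection:
    """Drop sets outside ``[min_size, max_size]`` genes (bounds inclusive).

    When ``universe`` is given, size is measured after intersecting each set
    with it.  Size filtering is *not* required by the bias-corrected tests;
    it exists to mirror protocols that need it for other methods.
    """
    if min_size > max_size:
        raise ValueError("min_size must not exceed max_size")
    uni = set(universe) if universe is not None else None
    kept = []
    for s in collection.sets():
        size = len(uni.intersection(s.genes)) if uni is not None else len(s.genes)
        if min_size <= size <= max_size:
            kept.append(s)
    dropped = len(collection) - len(kept)
    if dropped:
        warnings.warn(f"filter_by_size dropped {dropped} gene sets", stacklevel=2)
    return GeneSetCollection(kept)
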