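"""Domain content of a protein: distinct Pfam-A units after overlap grouping.

The *domain content* abstraction deliberately ignores domain order and copy
number: two architectures D1-D2-D2 and D2-D1-D2 have the same content
{D1, D2}.  Annotations that overlap each other over at least half of the
shorter hit are merged into a single :class:`ContentUnit`, so that a
fragmented or doubly-annotated region counts as one domain.  Unit identity
across proteins is by family-set intersection: if any member family of a
unit is annotated in the ortholog, the unit is considered shared.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

PFAM_ACC_RE = re.compile(r"^PF\d{5}$")
CLAN_ACC_RE = re.compile(r"^CL\d{4}$")

GA_YES = "yes"
GA_NO = "no"
GA_UNKNOWN = "unknown"


@dataclass(frozen=True)
class DomainHit:
    """One Pfam-A match on a protein, 1-based closed coordinates."""

    family: str
    start: int
    end: int
    evalue: float = 0.0
    clan: Optional[str] = None
    ga_pass: str = GA_UNKNOWN
    source: str = "synthetic"  # interpro | hmm_scan | synthetic
    protein_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"hit {self.family}: start {self.start} > end {self.end}"
            )
        if self.start < 1:
            raise ValueError(f"hit {self.family}: start {self.start} < 1")
        if self.evalue < 0:
            raise ValueError(f"hit {self.family}: negative E-value")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def with_clan(self, clan: Optional[str]) -> "DomainHit":
        return replace(self, clan=clan)


@dataclass(frozen=True)
class ContentUnit:
    """A distinct-domain unit: one or more families merged by overlap."""

    member_families: frozenset[str]

    def __post_init__(self) -> None:
        if not self.member_families:
            raise ValueError("empty content unit")

    @property
    def representative(self) -> str:
        return min(self.member_families)

    def intersects(self, other: "ContentUnit") -> bool:
        return bool(self.member_families & other.member_families)

    def __str__(self) -> str:  # stable, used in reports
        return "+".join(sorted(self.member_families))


@dataclass
class DomainContent:
    """All distinct units of one protein plus the position-ordered hits."""

    units: dict[str, ContentUnit] = field(default_factory=dict)
    ordered_hits: list[DomainHit] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.units)

    def __iter__(self):
        return iter(self.units.values())

    def matching_unit(self, unit: ContentUnit) -> Optional[ContentUnit]:
        """Unit of this content sharing at least one family with `unit`."""
        for u in self.units.values():
            if u.intersects(unit):
                return u
        return None

    def hits_of(self, unit: ContentUnit) -> list[DomainHit]:
        return [h for h in self.ordered_hits if h.family in unit.member_families]

    def ordered_units(self) -> list[ContentUnit]:
        """Units ordered N→C by the start of their first hit."""
        first: dict[str, int] = {}
        for h in self.ordered_hits:
            for rep, u in self.units.items():
                if h.family in u.member_families and rep not in first:
                    first[rep] = h.start
        return [
            self.units[rep]
            for rep in sorted(self.units, key=lambda r: (first.get(r, 0), r))
        ]


def _overlap_len(a: DomainHit, b: DomainHit) -> int:
    return min(a.end, b.end) - max(a.start, b.start) + 1


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def group_overlapping(
    hits: Sequence[DomainHit], overlap_ratio: float = 0.5
) -> list[ContentUnit]:
    """Merge hits into units by the half-overlap rule.

    Two hits are linked when their interval overlap is at least
    ``overlap_ratio`` of the shorter hit's length, or when they belong to
    the same family (repeats collapse).  Linking is transitive
    (single-linkage), so the result does not depend on input order.
    """
    hits = list(hits)
    if not hits:
        return []
    uf = _UnionFind(len(hits))
    for i in range(len(hits)):
        for j in range(i + 1, len(hits)):
            a, b = hits[i], hits[j]
            if a.family == b.family:
                uf.union(i, j)
                continue
            ov = _overlap_len(a, b)
            if ov <= 0:
                continue
            if ov >= overlap_ratio * min(a.length, b.length):
                uf.union(i, j)
    groups: dict[int, set[str]] = {}
    for i, h in enumerate(hits):
        groups.setdefault(uf.find(i), set()).add(h.family)
    units = [ContentUnit(frozenset(fams)) for fams in groups.values()]
    units.sort(key=lambda u: u.representative)
    # same family appearing in two spatially separate groups still collapses
    # to one unit (repeat rule) -- handled above by family-union, so groups
    # are already disjoint in families.
    return units


def content_of(
    ann,  # AnnotationSet (duck-typed: .hits)
    clans: Optional[Mapping[str, str]] = None,
    overlap_ratio: float = 0.5,
) -> DomainContent:
    """Domain content of an annotated protein.

    Repeats collapse (a family present k>=1 times contributes one unit) and
    overlapping families merge.  Clan accessions are attached to the hits
    when a clan map is supplied.  Deterministic for a given input,
    regardless of the order of ``ann.hits``.
    """
    hits = list(ann.hits)
    if clans is not None:
        hits = [h.with_clan(clans.get(h.family)) for h in hits]
    hits.sort(key=lambda h: (h.start, h.end, h.family))
    units = group_overlapping(hits, overlap_ratio=overlap_ratio)
    return DomainContent(
        units={u.representative: u for u in units}, ordered_hits=hits
    )


def same_clan(
    u1: ContentUnit, u2: ContentUnit, clans: Mapping[str, str]
) -> bool:
    """True iff some family of u1 and some family of u2 share a clan."""
    c1 = {clans[f] for f in u1.member_families if f in clans}
    c2 = {clans[f] for f in u2.member_families if f in clans}
    return bool(c1 & c2)


def unit_clans(unit: ContentUnit, clans: Mapping[str, str]) -> set[str]:
    return {clans[f] for f in unit.member_families if f in clans}
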