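"""Detection of potential missing-domain (MD) and additional-domain (AD) events.

An ortholog pair is a reference protein and its one-to-one ortholog in a
non-reference species.  A unit of the reference content with no
family-intersecting unit in the ortholog content is a potential MD; the
converse is a potential AD.  These are *potential* events: downstream
fact-checking decides whether they are real or artefacts of annotation,
gene prediction or genome assembly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .content import ContentUnit, DomainContent, DomainHit, content_of
from .formats import AnnotationSet

MD = "MD"
AD = "AD"

DEFAULT_MAX_PROTEIN_LEN = 5000


@dataclass
class OrthologPair:
    ref_ann: AnnotationSet
    ortho_ann: AnnotationSet
    species: str
    ref_seq: str = ""
    ortho_seq: str = ""

    def __post_init__(self) -> None:
        if self.ref_ann.protein_id == self.ortho_ann.protein_id:
            raise ValueError("reference and ortholog ids must differ")

    @property
    def ref_id(self) -> str:
        return self.ref_ann.protein_id

    @property
    def ortho_id(self) -> str:
        return self.ortho_ann.protein_id


@dataclass
class PotentialEvent:
    """One MD or AD candidate for one ortholog pair and one content unit."""

    pair: OrthologPair
    direction: str  # MD | AD
    unit: ContentUnit
    ref_hits: list[DomainHit] = field(default_factory=list)
    ortho_hits: list[DomainHit] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.direction not in (MD, AD):
            raise ValueError(f"bad direction {self.direction!r}")

    @property
    def key(self) -> tuple[str, str, str, str]:
        return (self.pair.species, self.pair.ref_id, self.direction, str(self.unit))


def filter_proteins(
    pairs: Sequence[OrthologPair], max_len: int = DEFAULT_MAX_PROTEIN_LEN
) -> tuple[list[OrthologPair], int]:
    """Drop pairs where either sequence exceeds ``max_len`` residues.

    Very long proteins (default cut-off 5,000 aa) are excluded for
    convenience; returns (kept pairs, number removed).
    """
    if max_len <= 0:
        raise ValueError("max_len must be positive")
    kept = [
        p
        for p in pairs
        if len(p.ref_seq or "") <= max_len and len(p.ortho_seq or "") <= max_len
    ]
    return kept, len(pairs) - len(kept)


def detect_events(
    pair: OrthologPair,
    clans: Optional[Mapping[str, str]] = None,
    overlap_ratio: float = 0.5,
    group_ortholog_hits: bool = True,
) -> list[PotentialEvent]:
    """Compare the two domain contents of a pair and emit potential events.

    Unit identity across the pair is family-set intersection: if any member
    family of a reference unit is annotated (in any merged unit) on the
    ortholog, that unit is shared.  ``group_ortholog_hits=False`` restricts
    the overlap-merging step to the reference protein only, leaving each
    ortholog family as its own unit.
    """
    ref_content = content_of(pair.ref_ann, clans, overlap_ratio)
    # with grouping disabled on the ortholog side, only same-family
    # collapsing applies (an overlap ratio no hit pair can reach)
    ortho_ratio = overlap_ratio if group_ortholog_hits else 1.01
    ortho_content = content_of(pair.ortho_ann, clans, ortho_ratio)

    events: list[PotentialEvent] = []
    for unit in ref_content.ordered_units():
        if ortho_content.matching_unit(unit) is None:
            events.append(
                PotentialEvent(
                    pair=pair,
                    direction=MD,
                    unit=unit,
                    ref_hits=ref_content.hits_of(unit),
                    ortho_hits=[],
                )
            )
    for unit in ortho_content.ordered_units():
        if ref_content.matching_unit(unit) is None:
            events.append(
                PotentialEvent(
                    pair=pair,
                    direction=AD,
                    unit=unit,
                    ref_hits=[],
                    ortho_hits=ortho_content.hits_of(unit),
                )
            )
    return events


@dataclass
class PotentialSummary:
    """Ortholog-level tallies of potential events for one species."""

    species: str
    n_orthologs: int = 0
    potential_md: int = 0  # orthologs with >= 1 MD
    potential_ad: int = 0  # orthologs with >= 1 AD
    n_events_md: int = 0  # event-level counts
    n_events_ad: int = 0

    @property
    def total_with_events(self) -> int:
        # an ortholog with both an MD and an AD counts once
        return self._n_any

    _n_any: int = 0

    @property
    def ratio_md_ad(self) -> Optional[float]:
        from .stats import round_half_away

        if self.potential_ad == 0:
            return None
        return round_half_away(self.potential_md / self.potential_ad, 1)

    @property
    def pct_with_events(self) -> Optional[float]:
        from .stats import round_half_away

        if self.n_orthologs == 0:
            return None
        return round_half_away(100.0 * self._n_any / self.n_orthologs, 1)


def tabulate_potential(
    events: Iterable[PotentialEvent], pairs: Sequence[OrthologPair]
) -> dict[str, PotentialSummary]:
    """Per-species summary of potential events at ortholog granularity.

    An ortholog missing two units contributes two events but one MD
    ortholog; an ortholog with both an MD and an AD counts once in the
    total-with-events column.
    """
    summaries: dict[str, PotentialSummary] = {}
    for p in pairs:
        s = summaries.setdefault(p.species, PotentialSummary(p.species))
        s.n_orthologs += 1
    md_orthos: dict[str, set[str]] = {}
    ad_orthos: dict[str, set[str]] = {}
    any_orthos: dict[str, set[str]] = {}
    for ev in events:
        sp = ev.pair.species
        s = summaries.setdefault(sp, PotentialSummary(sp))
        if ev.direction == MD:
            s.n_events_md += 1
            md_orthos.setdefault(sp, set()).add(ev.pair.ortho_id)
        else:
            s.n_events_ad += 1
            ad_orthos.setdefault(sp, set()).add(ev.pair.ortho_id)
        any_orthos.setdefault(sp, set()).add(ev.pair.ortho_id)
    for sp, s in summaries.items():
        s.potential_md = len(md_orthos.get(sp, ()))
        s.potential_ad = len(ad_orthos.get(sp, ()))
        s._n_any = len(any_orthos.get(sp, ()))
    return summaries
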