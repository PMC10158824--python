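"""Fact-checking of potential domain events.

Each potential MD/AD event is passed through a short-circuiting decision
tree; the first decisive stage wins and every verdict records which stages
ran.

For a missing domain (MD) the stages are:

1. *Annotation reconciliation* — re-scan results (HMMER domtblout) are
   consulted.  If the ortholog does carry the domain at E <= 0.01 the event
   is an annotation inconsistency on the ortholog side; if the reference's
   own annotation is not supported at E <= 0.01 it is an inconsistency on
   the reference side.
2. *Gene/isoform prediction check* — the reference domain segment is
   searched against the ortholog's genomic region (six-frame translated
   local alignment, or re-annotation of an externally corrected protein);
   a hit means the gene model, not the genome, lost the domain.
3. *Genome completeness check* — a run of undetermined nucleotides (N) in
   the region means presence/absence cannot be decided.
4. Otherwise the event is true: *domain switching* when the ortholog holds
   a different family of the same Pfam clan, else a true MD.

For an additional domain (AD) the genome-side checks are replaced by a
search of the reference's alternative isoforms (the reference genome and
gene models are axiomatically trusted), then the same final
classification.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .content import ContentUnit, DomainHit, content_of, same_clan, unit_clans
from .events import AD, MD, PotentialEvent
from .formats import AnnotationSet, GenomicRegion
from .translated_search import search_domain_in_region

# verdict classes
ANN_ORTHO = "annotation_inconsistent_ortho"
ANN_REF = "annotation_inconsistent_ref"
GENE_PRED = "gene_prediction_error"
ISOFORM = "isoform_inconsistency"
UNDET_GENOME = "undetermined_genome"
SWITCHING = "domain_switching"
TRUE_MD = "true_MD"
TRUE_AD = "true_AD"

ALL_CLASSES = (
    ANN_ORTHO,
    ANN_REF,
    GENE_PRED,
    ISOFORM,
    UNDET_GENOME,
    SWITCHING,
    TRUE_MD,
    TRUE_AD,
)

# classes grouped as "domain annotation" errors in per-species reports
ANNOTATION_CLASSES = (ANN_ORTHO, ANN_REF)


class ResourceError(RuntimeError):
    """A required check resource is missing (distinct from 'no hits')."""


@dataclass
class Verdict:
    event: PotentialEvent
    klass: str
    evidence: dict = field(default_factory=dict)
    stages_run: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.klass not in ALL_CLASSES:
            raise ValueError(f"unknown verdict class {self.klass!r}")
        if self.klass == TRUE_MD and self.event.direction != MD:
            raise ValueError("true_MD verdict on a non-MD event")
        if self.klass == TRUE_AD and self.event.direction != AD:
            raise ValueError("true_AD verdict on a non-AD event")


@dataclass
class CheckResources:
    """Everything the decision tree consults, keyed by protein/gene id."""

    scan_hits: Mapping[str, Sequence[DomainHit]]
    regions: Mapping[str, GenomicRegion] = field(default_factory=dict)
    ref_isoforms: Mapping[str, Sequence[AnnotationSet]] = field(default_factory=dict)
    clans: Mapping[str, str] = field(default_factory=dict)
    evalue_max: float = 0.01
    min_run: int = 1  # minimum N-run length that counts as undetermined
    min_cov: float = 0.5  # translated-search acceptance thresholds
    min_id: float = 0.4
    search_evalue_max: float = 1e-3  # chance-alignment bound for the search
    # Residues of flanking context added around the domain segment for the
    # translated search.  Default 0: flanks upstream/downstream of a missing
    # domain are typically still encoded by the gene region, so padding lets
    # exact flank matches masquerade as evidence for the domain itself.
    segment_pad: int = 0
    switch_mode: str = "presence"  # presence | reciprocal
    # plug-in hook: ortho_id -> re-annotation (domtblout hits) of an
    # externally corrected protein; used by stage 2 when available
    corrected_scan_hits: Mapping[str, Sequence[DomainHit]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.evalue_max <= 0:
            raise ValueError("evalue_max must be positive")
        if self.switch_mode not in ("presence", "reciprocal"):
            raise ValueError(f"unknown switch mode {self.switch_mode!r}")


def _qualifying_hits(
    res: CheckResources, protein_id: str, unit: ContentUnit
) -> list[DomainHit]:
    if protein_id not in res.scan_hits:
        raise ResourceError(f"no re-scan results for protein {protein_id}")
    return [
        h
        for h in res.scan_hits[protein_id]
        if h.family in unit.member_families and h.evalue <= res.evalue_max
    ]


def reconcile_annotation(
    ev: PotentialEvent, res: CheckResources
) -> Optional[Verdict]:
    """Stage 1: compare the event against standardized re-scan results.

    MD: a qualifying hit of the unit on the *ortholog* means the domain is
    really there (ortholog-side annotation inconsistency); failing that, the
    absence of any qualifying hit on the *reference* means the reference
    annotation itself is unsupported.  AD is the mirror image.
    """
    ortho_q = _qualifying_hits(res, ev.pair.ortho_id, ev.unit)
    ref_q = _qualifying_hits(res, ev.pair.ref_id, ev.unit)
    if ev.direction == MD:
        if ortho_q:
            best = min(ortho_q, key=lambda h: h.evalue)
            return Verdict(
                ev,
                ANN_ORTHO,
                evidence={
                    "matched_hit": best.family,
                    "evalue": best.evalue,
                    "interval": [best.start, best.end],
                },
            )
        if not ref_q:
            return Verdict(
                ev,
                ANN_REF,
                evidence={"note": "reference annotation unsupported by re-scan"},
            )
        return None
    # AD: the gained domain must be confirmed on the ortholog ...
    if not ortho_q:
        return Verdict(
            ev,
            ANN_ORTHO,
            evidence={"note": "ortholog annotation unsupported by re-scan"},
        )
    # ... and must be genuinely absent from the reference
    if ref_q:
        best = min(ref_q, key=lambda h: h.evalue)
        return Verdict(
            ev,
            ANN_REF,
            evidence={
                "matched_hit": best.family,
                "evalue": best.evalue,
                "interval": [best.start, best.end],
            },
        )
    return None


def _domain_segment(ev: PotentialEvent, pad: int) -> Optional[str]:
    if not ev.ref_hits or not ev.pair.ref_seq:
        return None
    start = min(h.start for h in ev.ref_hits)
    end = max(h.end for h in ev.ref_hits)
    seq = ev.pair.ref_seq
    return seq[max(0, start - 1 - pad) : min(len(seq), end + pad)]


def check_gene_prediction(
    ev: PotentialEvent, res: CheckResources
) -> Optional[Verdict]:
    """Stage 2 (MD only): could the genome still code for the domain?

    When a corrected protein re-annotation is registered for the ortholog,
    the criterion is a qualifying hit of the unit at E <= evalue_max in that
    re-annotation.  Otherwise the reference domain segment (+-pad residues)
    is searched against the ortholog's genomic region in six frames.
    """
    if ev.direction != MD:
        return None
    if ev.pair.ortho_id in res.corrected_scan_hits:
        q = [
            h
            for h in res.corrected_scan_hits[ev.pair.ortho_id]
            if h.family in ev.unit.member_families and h.evalue <= res.evalue_max
        ]
        if q:
            best = min(q, key=lambda h: h.evalue)
            return Verdict(
                ev,
                GENE_PRED,
                evidence={
                    "corrected_protein_hit": best.family,
                    "evalue": best.evalue,
                },
            )
        return None
    region = res.regions.get(ev.pair.ortho_id)
    if region is None:
        return None  # logged gap; genome check may still apply
    segment = _domain_segment(ev, res.segment_pad)
    if segment is None or len(segment) < 10:
        return None
    if len(region.sequence) < 3:
        raise ValueError(f"region {region.gene_id} shorter than one codon")
    aln = search_domain_in_region(
        segment, region, min_cov=res.min_cov, min_id=res.min_id,
        max_evalue=res.search_evalue_max,
    )
    if aln is None:
        return None
    return Verdict(
        ev,
        GENE_PRED,
        evidence={
            "identity": round(aln.identity, 4),
            "coverage": round(aln.query_coverage, 4),
            "evalue": aln.evalue,
            "frame": aln.frame,
            "target_span": list(aln.target_span),
            "n_stops": aln.n_stops,
            "min_cov": res.min_cov,
            "min_id": res.min_id,
            "max_evalue": res.search_evalue_max,
        },
    )


def check_isoforms(ev: PotentialEvent, res: CheckResources) -> Optional[Verdict]:
    """Stage 2 (AD only): does a reference alternative isoform carry the unit?

    Matching is at family level (clan relatives are reserved for the
    domain-switching classification).  No isoforms on record -> no verdict.
    """
    if ev.direction != AD:
        return None
    for iso in res.ref_isoforms.get(ev.pair.ref_id, ()):
        iso_content = content_of(iso, res.clans)
        if iso_content.matching_unit(ev.unit) is not None:
            return Verdict(
                ev, ISOFORM, evidence={"isoform_id": iso.protein_id}
            )
    return None


_N_RUN_RE = re.compile(r"N+")


def find_n_runs(sequence: str, min_run: int = 1) -> list[tuple[int, int]]:
    """1-based closed intervals of N-runs of length >= min_run."""
    return [
        (m.start() + 1, m.end())
        for m in _N_RUN_RE.finditer(sequence)
        if m.end() - m.start() >= min_run
    ]


def check_genome_Ns(ev: PotentialEvent, res: CheckResources) -> Optional[Verdict]:
    """Stage 3 (MD only): undetermined nucleotides in the genomic region."""
    if ev.direction != MD:
        return None
    region = res.regions.get(ev.pair.ortho_id)
    if region is None:
        return None
    runs = find_n_runs(region.sequence, res.min_run)
    if not runs:
        return None
    return Verdict(
        ev,
        UNDET_GENOME,
        evidence={"n_runs": [list(r) for r in runs], "min_run": res.min_run},
    )


def classify_final(ev: PotentialEvent, res: CheckResources) -> Verdict:
    """Final stage: domain switching (same-clan relative) or a true event.

    In ``presence`` mode any unit of the counterpart content from the same
    clan (sharing no family with the event unit) triggers switching; in
    ``reciprocal`` mode that clan-mate must itself be unmatched in the
    event protein's content, i.e. part of a complementary event.
    """
    counterpart_ann = (
        ev.pair.ortho_ann if ev.direction == MD else ev.pair.ref_ann
    )
    own_ann = ev.pair.ref_ann if ev.direction == MD else ev.pair.ortho_ann
    counterpart = content_of(counterpart_ann, res.clans)
    own = content_of(own_ann, res.clans)
    for unit in counterpart.ordered_units():
        if unit.intersects(ev.unit):
            continue
        if not same_clan(unit, ev.unit, res.clans):
            continue
        if res.switch_mode == "reciprocal" and own.matching_unit(unit) is not None:
            continue
        return Verdict(
            ev,
            SWITCHING,
            evidence={
                "clan": sorted(unit_clans(unit, res.clans) & unit_clans(ev.unit, res.clans))[0],
                "clan_mate": str(unit),
            },
        )
    klass = TRUE_MD if ev.direction == MD else TRUE_AD
    return Verdict(ev, klass)


_MD_STAGES = (
    ("annotation", reconcile_annotation),
    ("gene_prediction", check_gene_prediction),
    ("genome_n", check_genome_Ns),
)
_AD_STAGES = (
    ("annotation", reconcile_annotation),
    ("isoform", check_isoforms),
)


def fact_check_one(ev: PotentialEvent, res: CheckResources) -> Verdict:
    stages = _MD_STAGES if ev.direction == MD else _AD_STAGES
    ran: list[str] = []
    for name, stage in stages:
        ran.append(name)
        # dual-evidence flag: gene-prediction verdicts also note N-runs
        verdict = stage(ev, res)
        if verdict is not None:
            verdict.stages_run = ran
            if verdict.klass == GENE_PRED:
                region = res.regions.get(ev.pair.ortho_id)
                if region is not None and find_n_runs(region.sequence, res.min_run):
                    verdict.evidence["also_has_n_runs"] = True
            return verdict
    ran.append("final")
    verdict = classify_final(ev, res)
    verdict.stages_run = ran
    return verdict


def fact_check_all(
    events: Iterable[PotentialEvent], res: CheckResources
) -> list[Verdict]:
    """Classify every potential event; exactly one verdict per event.

    Events are processed in a canonical order (species, reference id,
    direction, unit) so the output is deterministic, and each event's
    verdict is independent of the others, so shuffling the input never
    changes any verdict.
    """
    ordered = sorted(events, key=lambda e: e.key)
    return [fact_check_one(ev, res) for ev in ordered]
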