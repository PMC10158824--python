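"""Seeded generator of miniature ortholog datasets with planted ground truth.

The generator emits every input format the pipeline consumes — Interpro-style
JSON annotations, protein and genomic FASTA, HMMER domtblout re-scan results,
a Pfam clans TSV, a pair table, species metadata and a species tree — for a
configurable number of species and ortholog pairs, and plants one event of a
chosen class per selected pair:

* ``true_md`` / ``true_ad`` — the domain is genuinely absent/extra, with a
  clean genomic region.
* ``ann_ortho_md`` — the ortholog protein carries the domain but its
  annotation omits it; the re-scan finds it at E <= 0.01.
* ``ann_ref_md`` — the reference annotation claims a domain the re-scan
  does not support on the reference.
* ``ann_ortho_ad`` — the ortholog annotation claims a domain its sequence
  does not support.
* ``ann_ref_ad`` — the gained domain is, per re-scan, present in the
  reference as well, only unannotated there.
* ``gene_pred`` — the domain is missing from the predicted protein but a
  back-translated copy sits in the gene region (a mis-predicted exon).
* ``n_region`` — the domain locus in the gene region is a run of N's.
* ``isoform`` — the gained domain exists in a reference alternative isoform.
* ``clan_switch`` — the ortholog carries a different family from the same
  clan (yields one MD and one AD, both domain switching).

Fixtures test classification logic, not homology detection power: sequences
are random, orthologs are identical to the reference outside planted edits,
and no phylogenetic sequence evolution is modelled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from Bio.Data import CodonTable

from .content import DomainHit
from .events import OrthologPair
from .factcheck import (
    ANN_ORTHO,
    ANN_REF,
    GENE_PRED,
    ISOFORM,
    SWITCHING,
    TRUE_AD,
    TRUE_MD,
    UNDET_GENOME,
    CheckResources,
)
from .formats import (
    AnnotationSet,
    GenomicRegion,
    PairRow,
    PairTable,
    SpeciesMetadata,
    write_fasta,
    write_pairs_tsv,
    write_species_metadata_tsv,
)

AA20 = "ACDEFGHIKLMNPQRSTVWY"

PLANT_CLASSES = (
    "true_md",
    "true_ad",
    "ann_ortho_md",
    "ann_ref_md",
    "ann_ortho_ad",
    "ann_ref_ad",
    "gene_pred",
    "n_region",
    "isoform",
    "clan_switch",
)

# planted class -> expected (direction, verdict class) rows
PLANT_TRUTH = {
    "true_md": [("MD", TRUE_MD)],
    "true_ad": [("AD", TRUE_AD)],
    "ann_ortho_md": [("MD", ANN_ORTHO)],
    "ann_ref_md": [("MD", ANN_REF)],
    "ann_ortho_ad": [("AD", ANN_ORTHO)],
    "ann_ref_ad": [("AD", ANN_REF)],
    "gene_pred": [("MD", GENE_PRED)],
    "n_region": [("MD", UNDET_GENOME)],
    "isoform": [("AD", ISOFORM)],
    "clan_switch": [("MD", SWITCHING), ("AD", SWITCHING)],
}


@dataclass
class FixtureConfig:
    seed: int = 0
    n_species: int = 3
    n_pairs_per_species: int = 8
    n_families: int = 30
    n_clan_pairs: int = 4  # clans of two families each, used for switching
    domain_len_range: tuple[int, int] = (40, 200)
    linker_len_range: tuple[int, int] = (5, 20)
    flank_nt: int = 1000
    n_run_len: int = 30
    events_per_class: dict = field(
        default_factory=lambda: {c: 1 for c in PLANT_CLASSES}
    )

    def __post_init__(self) -> None:
        unknown = set(self.events_per_class) - set(PLANT_CLASSES)
        if unknown:
            raise ValueError(f"unknown plant classes {sorted(unknown)}")
        if any(v < 0 for v in self.events_per_class.values()):
            raise ValueError("negative plant count")
        if self.events_per_class.get("clan_switch", 0) > 0 and self.n_clan_pairs == 0:
            raise ValueError("clan_switch planting requires a clan pool")
        n_plants = sum(self.events_per_class.values())
        if n_plants > self.n_species * self.n_pairs_per_species:
            raise ValueError(
                f"{n_plants} plants but only "
                f"{self.n_species * self.n_pairs_per_species} pairs"
            )


@dataclass(frozen=True)
class TruthRow:
    ref_id: str
    ortho_id: str
    species: str
    direction: str
    unit: str  # family accession
    planted_class: str


@dataclass
class _Family:
    accession: str
    sequence: str
    clan: Optional[str] = None

    @property
    def length(self) -> int:
        return len(self.sequence)


def _codons_by_aa() -> dict[str, list[str]]:
    table = CodonTable.unambiguous_dna_by_id[1].forward_table
    out: dict[str, list[str]] = {}
    for codon, aa in table.items():
        out.setdefault(aa, []).append(codon)
    for aa in out:
        out[aa].sort()
    return out


_BACK = _codons_by_aa()


def back_translate(protein: str, rng: np.random.Generator) -> str:
    """Uniform synonymous codon choice per residue, seeded."""
    return "".join(
        _BACK[aa][rng.integers(len(_BACK[aa]))] for aa in protein
    )


def _random_dna(n: int, rng: np.random.Generator) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def _random_protein(n: int, rng: np.random.Generator) -> str:
    return "".join(np.array(list(AA20))[rng.integers(0, 20, n)])


def plant_gene_error(
    region_seq: str,
    domain_aa: str,
    insert_at: int,
    rng: np.random.Generator,
    mutation_rate: float = 0.0,
    intron_len: int = 0,
) -> str:
    """Splice a back-translated copy of a domain segment into a region.

    The copy may carry random codon-level substitutions (``mutation_rate``
    per codon) and may be split in half by an intron-like random spacer.
    """
    if len(region_seq) < 3:
        raise ValueError("region too short")
    exon = back_translate(domain_aa, rng)
    if mutation_rate > 0:
        codons = [exon[i : i + 3] for i in range(0, len(exon), 3)]
        for i in range(len(codons)):
            if rng.random() < mutation_rate:
                codons[i] = _random_dna(3, rng)
        exon = "".join(codons)
    if intron_len > 0:
        half = 3 * (len(exon) // 6)
        exon = exon[:half] + _random_dna(intron_len, rng) + exon[half:]
    return region_seq[:insert_at] + exon + region_seq[insert_at:]


@dataclass
class Dataset:
    """In-memory fixture dataset plus its ground-truth table."""

    config: FixtureConfig
    clans: dict[str, str]
    annotations: dict[str, AnnotationSet]
    proteins: dict[str, str]
    isoform_annotations: dict[str, list[AnnotationSet]]
    isoform_proteins: dict[str, str]
    regions: dict[str, GenomicRegion]
    scan_hits: dict[str, list[DomainHit]]
    pairs: PairTable
    metadata: list[SpeciesMetadata]
    tree_newick: str
    truth: list[TruthRow]

    def build_pairs(self) -> list[OrthologPair]:
        return [
            OrthologPair(
                ref_ann=self.annotations[row.ref_id],
                ortho_ann=self.annotations[row.ortho_id],
                species=row.species,
                ref_seq=self.proteins[row.ref_id],
                ortho_seq=self.proteins[row.ortho_id],
            )
            for row in self.pairs
        ]

    def check_resources(self, **overrides) -> CheckResources:
        kwargs = dict(
            scan_hits=self.scan_hits,
            regions=self.regions,
            ref_isoforms=self.isoform_annotations,
            clans=self.clans,
        )
        kwargs.update(overrides)
        return CheckResources(**kwargs)

    def to_dir(self, path) -> None:
        """Write every format to a directory (all plain text)."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        write_fasta(self.proteins, path / "proteins.fasta")
        if self.isoform_proteins:
            write_fasta(self.isoform_proteins, path / "isoforms.fasta")
        write_fasta(
            {r.gene_id: r.sequence for r in self.regions.values()},
            path / "regions.fasta",
        )
        with open(path / "annotations.json", "w") as fh:
            json.dump(
                [_ann_to_json(a, self.proteins) for a in self.annotations.values()],
                fh,
                indent=1,
            )
        iso_entries = [
            _ann_to_json(a, self.isoform_proteins)
            for sets in self.isoform_annotations.values()
            for a in sets
        ]
        with open(path / "isoform_annotations.json", "w") as fh:
            json.dump(iso_entries, fh, indent=1)
        _write_domtblout(self.scan_hits, self.proteins, path / "rescan.domtblout")
        with open(path / "clans.tsv", "w") as fh:
            for fam in sorted(self.clans):
                fh.write(f"{fam}\t{self.clans[fam]}\tclan\tfam\tdesc\n")
        write_pairs_tsv(self.pairs, path / "pairs.tsv")
        write_species_metadata_tsv(self.metadata, path / "species.tsv")
        with open(path / "tree.nwk", "w") as fh:
            fh.write(self.tree_newick + "\n")
        with open(path / "truth.tsv", "w") as fh:
            fh.write("ref_id\tortho_id\tspecies\tdirection\tunit\tplanted_class\n")
            for t in self.truth:
                fh.write(
                    f"{t.ref_id}\t{t.ortho_id}\t{t.species}\t{t.direction}"
                    f"\t{t.unit}\t{t.planted_class}\n"
                )


def _ann_to_json(ann: AnnotationSet, seqs: dict[str, str]) -> dict:
    matches: dict[str, list[dict]] = {}
    for h in ann.hits:
        matches.setdefault(h.family, []).append(
            {"start": h.start, "end": h.end, "evalue": h.evalue}
        )
    return {
        "protein_id": ann.protein_id,
        "species": ann.species,
        "length": ann.length or len(seqs.get(ann.protein_id, "")),
        "source_db": ann.source_db,
        "matches": [
            {"accession": fam, "member_db": "pfam", "locations": locs}
            for fam, locs in sorted(matches.items())
        ],
    }


def _write_domtblout(
    scan_hits: dict[str, list[DomainHit]],
    proteins: dict[str, str],
    path,
) -> None:
    with open(path, "w") as fh:
        fh.write("# target name        accession   tlen query name"
                 "           accession   qlen   E-value  score  bias"
                 "   #  of  c-Evalue  i-Evalue  score  bias  from    to"
                 "  ali_from ali_to  env_from env_to  acc description\n")
        for pid in sorted(scan_hits):
            for k, h in enumerate(scan_hits[pid], start=1):
                tlen = len(proteins.get(pid, "")) or h.end
                qlen = h.end - h.start + 1
                fh.write(
                    f"{pid} - {tlen} {h.family}_name {h.family}.1 {qlen} "
                    f"{h.evalue:.2g} 120.0 0.1 {k} {len(scan_hits[pid])} "
                    f"{h.evalue:.2g} {h.evalue:.2g} 118.0 0.1 1 {qlen} "
                    f"{h.start} {h.end} {max(1, h.start - 3)} "
                    f"{h.end + 3} 0.98 -\n"
                )


# ---------------------------------------------------------------------------
# generation


def _make_tree(species: list[str], rng: np.random.Generator, ref: str) -> str:
    """Caterpillar tree with the reference as the outermost sister."""
    bl = lambda: round(float(rng.uniform(0.02, 0.4)), 4)
    node = f"{species[0]}:{bl()}"
    for sp in species[1:]:
        node = f"({node},{sp}:{bl()}):{bl()}"
    return f"({ref}:{bl()},{node});"


class _PairBuilder:
    """Segment-level construction of one ortholog pair."""

    def __init__(self, ref_id, ortho_id, species, families, rng, cfg):
        self.ref_id, self.ortho_id, self.species = ref_id, ortho_id, species
        self.rng, self.cfg = rng, cfg
        lo, hi = cfg.linker_len_range
        self.linkers = [
            _random_protein(int(rng.integers(lo, hi + 1)), rng)
            for _ in range(len(families) + 1)
        ]
        self.ref_doms: list[_Family] = list(families)
        self.ortho_doms: list[_Family] = list(families)
        # annotation omissions / fabrications, scan manipulations
        self.ref_json_skip: set[str] = set()
        self.ortho_json_skip: set[str] = set()
        self.ortho_json_fake: list[_Family] = []
        self.ref_scan_skip: set[str] = set()
        self.ref_scan_extra: list[_Family] = []
        self.extra_evalue: dict[str, float] = {}
        self.region_domain_insert: Optional[str] = None  # domain aa to plant
        self.region_n_at_removal = False
        self.removed: Optional[_Family] = None

    def remove_from_ortho(self, fam: _Family) -> None:
        self.ortho_doms = [f for f in self.ortho_doms if f is not fam]
        self.removed = fam

    # -- assembly -----------------------------------------------------

    @staticmethod
    def _assemble(doms: list[_Family], linkers: list[str]):
        seq_parts, hits = [], []
        pos = 0
        for i, fam in enumerate(doms):
            seq_parts.append(linkers[i])
            pos += len(linkers[i])
            hits.append((fam, pos + 1, pos + fam.length))
            seq_parts.append(fam.sequence)
            pos += fam.length
        seq_parts.append(linkers[len(doms)])
        return "".join(seq_parts), hits

    def build(self):
        ref_seq, ref_hits = self._assemble(self.ref_doms, self.linkers)
        ortho_seq, ortho_hits = self._assemble(self.ortho_doms, self.linkers)
        # fabricated annotations get a random-residue tail to point at
        fake_hits = []
        for fam in self.ortho_json_fake:
            tail = _random_protein(fam.length, self.rng)
            fake_hits.append((fam, len(ortho_seq) + 1, len(ortho_seq) + fam.length))
            ortho_seq += tail

        def hit(fam, start, end, pid, evalue, source):
            return DomainHit(
                family=fam.accession, start=start, end=end,
                evalue=evalue, source=source, protein_id=pid,
            )

        ref_ann = AnnotationSet(
            protein_id=self.ref_id, species="reference", length=len(ref_seq),
            hits=[
                hit(f, s, e, self.ref_id, 1e-12, "interpro")
                for f, s, e in ref_hits
                if f.accession not in self.ref_json_skip
            ],
        )
        ortho_ann = AnnotationSet(
            protein_id=self.ortho_id, species=self.species, length=len(ortho_seq),
            hits=[
                hit(f, s, e, self.ortho_id, 1e-12, "interpro")
                for f, s, e in ortho_hits
                if f.accession not in self.ortho_json_skip
            ]
            + [hit(f, s, e, self.ortho_id, 1e-12, "interpro") for f, s, e in fake_hits],
        )
        ref_scan = [
            hit(f, s, e, self.ref_id, self.extra_evalue.get(f.accession, 1e-10), "hmm_scan")
            for f, s, e in ref_hits
            if f.accession not in self.ref_scan_skip
        ]
        for fam in self.ref_scan_extra:
            ref_scan.append(
                hit(fam, 1, fam.length, self.ref_id,
                    self.extra_evalue.get(fam.accession, 1e-9), "hmm_scan")
            )
        ortho_scan = [
            hit(f, s, e, self.ortho_id, self.extra_evalue.get(f.accession, 1e-10), "hmm_scan")
            for f, s, e in ortho_hits
        ]
        # genomic region: back-translated CDS of the ortholog protein
        cds = back_translate(ortho_seq, self.rng)
        if self.region_n_at_removal:
            mid = 3 * (len(ortho_seq) // 2)
            cds = cds[:mid] + "N" * self.cfg.n_run_len + cds[mid:]
        if self.region_domain_insert is not None:
            cds = plant_gene_error(cds, self.region_domain_insert, len(cds), self.rng)
        flank = self.cfg.flank_nt
        region = GenomicRegion(
            gene_id=self.ortho_id,
            species=self.species,
            sequence=_random_dna(flank, self.rng) + cds + _random_dna(flank, self.rng),
            flank_nt=flank,
        )
        return ref_seq, ortho_seq, ref_ann, ortho_ann, ref_scan, ortho_scan, region


def generate(config: FixtureConfig) -> Dataset:
    """Generate a full dataset with planted events; bit-reproducible by seed."""
    rng = np.random.default_rng(config.seed)
    lo, hi = config.domain_len_range

    clans: dict[str, str] = {}
    families: list[_Family] = []
    for i in range(config.n_families):
        fam = _Family(
            accession=f"PF9{i:04d}",
            sequence=_random_protein(int(rng.integers(lo, hi + 1)), rng),
        )
        families.append(fam)
    clan_pairs: list[tuple[_Family, _Family]] = []
    for j in range(config.n_clan_pairs):
        a, b = families[2 * j], families[2 * j + 1]
        clan = f"CL9{j:03d}"
        a.clan = b.clan = clan
        clans[a.accession] = clan
        clans[b.accession] = clan
        clan_pairs.append((a, b))
    free_pool = [f for f in families if f.clan is None]
    if len(free_pool) < 5:
        raise ValueError("family pool too small for the requested clan pairs")

    species = [f"SP{k + 1:02d}" for k in range(config.n_species)]
    plants: list[str] = []
    for cls in PLANT_CLASSES:
        plants.extend([cls] * config.events_per_class.get(cls, 0))

    annotations: dict[str, AnnotationSet] = {}
    proteins: dict[str, str] = {}
    iso_ann: dict[str, list[AnnotationSet]] = {}
    iso_seq: dict[str, str] = {}
    regions: dict[str, GenomicRegion] = {}
    scan_hits: dict[str, list[DomainHit]] = {}
    pair_rows: list[PairRow] = []
    truth: list[TruthRow] = []

    n_total = config.n_species * config.n_pairs_per_species
    clan_cycle = 0
    for idx in range(n_total):
        sp = species[idx % config.n_species]
        ref_id = f"R{idx:04d}"
        ortho_id = f"O{idx:04d}_{sp}"
        planted = plants[idx] if idx < len(plants) else None

        n_dom = int(rng.integers(2, 4))
        picks = list(rng.choice(len(free_pool), size=n_dom, replace=False))
        archi = [free_pool[int(p)] for p in picks]
        if planted == "clan_switch":
            d2, d2p = clan_pairs[clan_cycle % len(clan_pairs)]
            clan_cycle += 1
            archi[-1] = d2

        b = _PairBuilder(ref_id, ortho_id, sp, archi, rng, config)
        target = archi[-1]

        if planted == "true_md":
            b.remove_from_ortho(target)
        elif planted == "ann_ortho_md":
            b.ortho_json_skip.add(target.accession)
            b.extra_evalue[target.accession] = 1.6e-8
        elif planted == "ann_ref_md":
            b.remove_from_ortho(target)
            b.ref_scan_skip.add(target.accession)
        elif planted == "gene_pred":
            b.remove_from_ortho(target)
            b.region_domain_insert = target.sequence
        elif planted == "n_region":
            b.remove_from_ortho(target)
            b.region_n_at_removal = True
        elif planted == "true_ad":
            extra = _pick_unused(free_pool, archi, rng)
            b.ortho_doms = b.ortho_doms + [extra]
            b.linkers.append(_random_protein(8, rng))
        elif planted == "ann_ortho_ad":
            extra = _pick_unused(free_pool, archi, rng)
            b.ortho_json_fake.append(extra)
        elif planted == "ann_ref_ad":
            extra = _pick_unused(free_pool, archi, rng)
            b.ortho_doms = b.ortho_doms + [extra]
            b.linkers.append(_random_protein(8, rng))
            b.ref_scan_extra.append(extra)
            b.extra_evalue[extra.accession] = 3.2e-8
        elif planted == "isoform":
            extra = _pick_unused(free_pool, archi, rng)
            b.ortho_doms = b.ortho_doms + [extra]
            b.linkers.append(_random_protein(8, rng))
        elif planted == "clan_switch":
            d2 = archi[-1]
            d2p = [f for f in clan_pairs[(clan_cycle - 1) % len(clan_pairs)] if f is not d2][0]
            b.ortho_doms = b.ortho_doms[:-1] + [d2p]

        ref_seq, ortho_seq, ref_ann, ortho_ann, ref_scan, ortho_scan, region = b.build()

        if planted == "isoform":
            iso_id = f"{ref_id}-iso2"
            iso_seq[iso_id] = ref_seq + "GS" + extra.sequence
            iso_hits = list(ref_ann.hits) + [
                DomainHit(
                    family=extra.accession,
                    start=len(ref_seq) + 3,
                    end=len(ref_seq) + 2 + extra.length,
                    evalue=1e-12,
                    source="interpro",
                    protein_id=iso_id,
                )
            ]
            iso_ann[ref_id] = [
                AnnotationSet(
                    protein_id=iso_id, species="reference",
                    hits=iso_hits, length=len(iso_seq[iso_id]),
                )
            ]

        annotations[ref_id] = ref_ann
        annotations[ortho_id] = ortho_ann
        proteins[ref_id] = ref_seq
        proteins[ortho_id] = ortho_seq
        scan_hits[ref_id] = ref_scan
        scan_hits[ortho_id] = ortho_scan
        regions[ortho_id] = region
        pair_rows.append(PairRow(ref_id, ortho_id, sp))

        if planted is not None:
            for direction, _klass in PLANT_TRUTH[planted]:
                if planted == "clan_switch":
                    unit = target.accession if direction == "MD" else d2p.accession
                elif direction == "MD":
                    unit = target.accession
                else:
                    unit = extra.accession
                truth.append(
                    TruthRow(ref_id, ortho_id, sp, direction, unit, planted)
                )

    metadata = [
        SpeciesMetadata(
            species=sp,
            contig_n50=int(rng.integers(20_000, 50_000_000)),
            busco_complete=round(float(rng.uniform(75, 100)), 1),
            n_coding_genes=int(rng.integers(5_000, 25_000)),
            n_orthologs=config.n_pairs_per_species,
            mean_pct_identity=round(float(rng.uniform(30, 99)), 1),
        )
        for sp in species
    ]
    tree = _make_tree(species, rng, ref="REF")

    return Dataset(
        config=config,
        clans=clans,
        annotations=annotations,
        proteins=proteins,
        isoform_annotations=iso_ann,
        isoform_proteins=iso_seq,
        regions=regions,
        scan_hits=scan_hits,
        pairs=PairTable(pair_rows),
        metadata=metadata,
        tree_newick=tree,
        truth=truth,
    )


def _pick_unused(pool, used, rng: np.random.Generator) -> _Family:
    candidates = [f for f in pool if f not in used]
    return candidates[int(rng.integers(len(candidates)))]
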