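"""End-to-end wiring: dataset directory -> potential events -> verdicts.

The on-disk contract is the file layout written by
:meth:`domfact.synthetic.Dataset.to_dir` (and mirrored by real exports):
``annotations.json``, ``proteins.fasta``, ``regions.fasta``,
``rescan.domtblout``, ``clans.tsv``, ``pairs.tsv``, ``species.tsv``,
``tree.nwk`` and optionally ``isoform_annotations.json``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import formats
from .events import (
    DEFAULT_MAX_PROTEIN_LEN,
    OrthologPair,
    PotentialEvent,
    detect_events,
    filter_proteins,
    tabulate_potential,
)
from .factcheck import CheckResources, Verdict, fact_check_all
from .formats import AnnotationSet, GenomicRegion


@dataclass
class RunConfig:
    evalue_max: float = 0.01
    overlap_ratio: float = 0.5
    min_cov: float = 0.5
    min_id: float = 0.4
    search_evalue_max: float = 1e-3
    min_run: int = 1
    max_protein_len: int = DEFAULT_MAX_PROTEIN_LEN
    switch_mode: str = "presence"
    species_blacklist: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "evalue_max": self.evalue_max,
            "overlap_ratio": self.overlap_ratio,
            "min_cov": self.min_cov,
            "min_id": self.min_id,
            "search_evalue_max": self.search_evalue_max,
            "min_run": self.min_run,
            "max_protein_len": self.max_protein_len,
            "switch_mode": self.switch_mode,
            "species_blacklist": list(self.species_blacklist),
        }


@dataclass
class LoadedDataset:
    pairs: list[OrthologPair]
    n_filtered: int
    resources: CheckResources
    clans: dict
    metadata: list = field(default_factory=list)
    tree_newick: Optional[str] = None
    parse_reports: dict = field(default_factory=dict)


def load_dataset(data_dir, config: Optional[RunConfig] = None) -> LoadedDataset:
    config = config or RunConfig()
    d = Path(data_dir)
    anns, ann_report = formats.read_interpro_json(d / "annotations.json")
    ann_by_id = {a.protein_id: a for a in anns}
    proteins = formats.read_fasta(d / "proteins.fasta", "protein")
    clans = formats.read_clans_tsv(d / "clans.tsv") if (d / "clans.tsv").exists() else {}
    scan, scan_report = formats.read_domtblout(d / "rescan.domtblout")
    scan_by_protein = formats.scan_hits_by_protein(scan)
    # every scanned protein is present in the map, even with zero hits
    for pid in proteins:
        scan_by_protein.setdefault(pid, [])

    regions: dict[str, GenomicRegion] = {}
    if (d / "regions.fasta").exists():
        species_of = {}
        pair_table = formats.read_pairs_tsv(d / "pairs.tsv")
        for row in pair_table:
            species_of[row.ortho_id] = row.species
        for gid, seq in formats.read_fasta(d / "regions.fasta", "dna").items():
            regions[gid] = GenomicRegion(
                gene_id=gid, species=species_of.get(gid, ""), sequence=seq
            )
    else:
        pair_table = formats.read_pairs_tsv(d / "pairs.tsv")

    isoforms: dict[str, list[AnnotationSet]] = {}
    iso_path = d / "isoform_annotations.json"
    if iso_path.exists():
        iso_sets, _ = formats.read_interpro_json(iso_path)
        for iso in iso_sets:
            ref_id = iso.protein_id.split("-iso")[0]
            isoforms.setdefault(ref_id, []).append(iso)

    pairs = []
    for row in pair_table:
        if row.species in config.species_blacklist:
            continue
        pairs.append(
            OrthologPair(
                ref_ann=ann_by_id[row.ref_id],
                ortho_ann=ann_by_id[row.ortho_id],
                species=row.species,
                ref_seq=proteins.get(row.ref_id, ""),
                ortho_seq=proteins.get(row.ortho_id, ""),
            )
        )
    pairs, n_filtered = filter_proteins(pairs, config.max_protein_len)

    resources = CheckResources(
        scan_hits=scan_by_protein,
        regions=regions,
        ref_isoforms=isoforms,
        clans=clans,
        evalue_max=config.evalue_max,
        min_run=config.min_run,
        min_cov=config.min_cov,
        min_id=config.min_id,
        search_evalue_max=config.search_evalue_max,
        switch_mode=config.switch_mode,
    )
    metadata = (
        formats.read_species_metadata_tsv(d / "species.tsv")
        if (d / "species.tsv").exists()
        else []
    )
    tree = (d / "tree.nwk").read_text().strip() if (d / "tree.nwk").exists() else None
    return LoadedDataset(
        pairs=pairs,
        n_filtered=n_filtered,
        resources=resources,
        clans=clans,
        metadata=metadata,
        tree_newick=tree,
        parse_reports={"annotations": ann_report, "rescan": scan_report},
    )


def detect_all(
    loaded: LoadedDataset, config: Optional[RunConfig] = None
) -> list[PotentialEvent]:
    config = config or RunConfig()
    events: list[PotentialEvent] = []
    for pair in loaded.pairs:
        events.extend(
            detect_events(pair, loaded.clans, overlap_ratio=config.overlap_ratio)
        )
    return events


def run_factcheck(
    data_dir, config: Optional[RunConfig] = None
) -> tuple[list[Verdict], LoadedDataset, list[PotentialEvent]]:
    """Load a dataset, detect potential events, and fact-check them all."""
    config = config or RunConfig()
    loaded = load_dataset(data_dir, config)
    events = detect_all(loaded, config)
    verdicts = fact_check_all(events, loaded.resources)
    return verdicts, loaded, events


def write_manifest(path, config: RunConfig, seed: Optional[int] = None) -> None:
    from . import __version__

    manifest = {
        "tool": "domfact",
        "version": __version__,
        "config": config.to_dict(),
        "seed": seed,
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
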