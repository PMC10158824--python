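"""Readers and writers for the external formats the pipeline touches.

All coordinates are normalised to a single internal convention: 1-based,
closed intervals on the protein.  This matches both Interpro JSON location
fragments and HMMER alignment coordinates, so no parser shifts anything.

Parsers never silently drop records: every dropped signature or skipped
entry is counted in a :class:`ParseReport` carried alongside the results.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

from Bio import SeqIO

from .content import CLAN_ACC_RE, PFAM_ACC_RE, GA_NO, GA_UNKNOWN, GA_YES, DomainHit

PathLike = Union[str, Path]

PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYXBZU")
DNA_ALPHABET = set("ACGTN")


class ParseError(ValueError):
    """Malformed input file."""


@dataclass
class ParseReport:
    """What a parser kept and what it dropped, with reasons."""

    n_records: int = 0
    n_hits: int = 0
    dropped: dict[str, int] = field(default_factory=dict)
    skipped_entries: list[str] = field(default_factory=list)

    def drop(self, reason: str, n: int = 1) -> None:
        self.dropped[reason] = self.dropped.get(reason, 0) + n


@dataclass
class AnnotationSet:
    """Pfam-A domain annotation of one protein."""

    protein_id: str
    species: str = ""
    hits: list[DomainHit] = field(default_factory=list)
    source_db: str = "synthetic"  # swissprot | trembl | synthetic
    length: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.protein_id:
            raise ValueError("empty protein_id")
        if self.length is not None:
            for h in self.hits:
                if h.end > self.length:
                    raise ValueError(
                        f"{self.protein_id}: hit {h.family} ends at {h.end} "
                        f"beyond protein length {self.length}"
                    )


class ClanMap(dict):
    """Pfam family accession -> clan accession; unmapped families absent."""

    def __setitem__(self, family: str, clan: str) -> None:
        if not PFAM_ACC_RE.match(family):
            raise ValueError(f"bad Pfam accession {family!r}")
        if not CLAN_ACC_RE.match(clan):
            raise ValueError(f"bad clan accession {clan!r}")
        if family in self and self[family] != clan:
            raise ParseError(
                f"family {family} mapped to both {self[family]} and {clan}"
            )
        super().__setitem__(family, clan)


@dataclass
class GenomicRegion:
    """Genomic DNA of one ortholog gene, with flanks added on each side."""

    gene_id: str
    species: str
    sequence: str
    flank_nt: int = 0

    def __post_init__(self) -> None:
        if self.flank_nt < 0:
            raise ValueError("negative flank")
        if len(self.sequence) <= 2 * self.flank_nt:
            raise ValueError(
                f"{self.gene_id}: region length {len(self.sequence)} "
                f"not greater than twice the flank {self.flank_nt}"
            )
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise ValueError(f"{self.gene_id}: non-DNA characters {sorted(bad)}")


@dataclass
class SpeciesMetadata:
    species: str
    contig_n50: int = 0
    busco_complete: float = 0.0
    n_coding_genes: int = 0
    n_orthologs: int = 0
    mean_pct_identity: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.busco_complete <= 100:
            raise ValueError("BUSCO complete outside [0, 100]")
        if min(self.contig_n50, self.n_coding_genes, self.n_orthologs) < 0:
            raise ValueError("negative count")


@dataclass(frozen=True)
class PairRow:
    ref_id: str
    ortho_id: str
    species: str


class PairTable(list):
    """Rows of (reference protein, ortholog protein, species).

    One-to-one orthology within a species: a (ref, species) combination may
    appear at most once.
    """

    def __init__(self, rows: Iterable[PairRow] = ()) -> None:
        super().__init__()
        seen: set[tuple[str, str]] = set()
        for row in rows:
            key = (row.ref_id, row.species)
            if key in seen:
                raise ParseError(
                    f"reference {row.ref_id} listed twice for {row.species}"
                )
            seen.add(key)
            self.append(row)


# ---------------------------------------------------------------------------
# Interpro-style JSON


def _hits_from_flat_entry(entry: dict, report: ParseReport) -> list[DomainHit]:
    hits: list[DomainHit] = []
    for match in entry.get("matches", []):
        acc = str(match.get("accession", "")).split(".")[0]
        if not PFAM_ACC_RE.match(acc):
            report.drop("non_pfam_signature")
            continue
        for loc in match.get("locations", []):
            start, end = int(loc["start"]), int(loc["end"])
            if start > end:
                raise ParseError(
                    f"{entry.get('protein_id')}: fragment {acc} start {start} > end {end}"
                )
            hits.append(
                DomainHit(
                    family=acc,
                    start=start,
                    end=end,
                    evalue=float(loc.get("evalue", 0.0)),
                    source="interpro",
                    protein_id=entry.get("protein_id"),
                )
            )
    return hits


def _hits_from_api_result(result: dict, report: ParseReport) -> list[DomainHit]:
    pid = result.get("metadata", {}).get("accession")
    hits: list[DomainHit] = []
    for entry in result.get("entry_subset", []):
        db = str(entry.get("source_database", "")).lower()
        acc = str(entry.get("accession", "")).split(".")[0]
        if db != "pfam" or not PFAM_ACC_RE.match(acc):
            report.drop("non_pfam_signature")
            continue
        for loc in entry.get("entry_protein_locations", []):
            score = loc.get("score", 0.0)
            for frag in loc.get("fragments", []):
                start, end = int(frag["start"]), int(frag["end"])
                if start > end:
                    raise ParseError(
                        f"{pid}: fragment {acc} start {start} > end {end}"
                    )
                hits.append(
                    DomainHit(
                        family=acc,
                        start=start,
                        end=end,
                        evalue=float(score or 0.0),
                        source="interpro",
                        protein_id=pid,
                    )
                )
    return hits


def read_interpro_json(
    path: PathLike,
) -> tuple[list[AnnotationSet], ParseReport]:
    """Read Pfam-A annotations from an Interpro-style JSON file.

    Two dialects are accepted: the flat per-protein style emitted by the
    fixture generator (list of ``{"protein_id", "species", "length",
    "source_db", "matches": [...]}``) and the API style
    (``{"results": [{"metadata": ..., "entry_subset": [...]}]}``).
    Non-Pfam member-database signatures are dropped but counted.  An entry
    whose fragment has start > end is skipped and logged, not fatal.
    """
    report = ParseReport()
    try:
        with open(path) as fh:
            data = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: malformed JSON near byte {exc.pos}") from exc

    entries = data["results"] if isinstance(data, dict) and "results" in data else data
    if not isinstance(entries, list):
        raise ParseError(f"{path}: expected a JSON array of protein entries")

    out: list[AnnotationSet] = []
    for entry in entries:
        api_style = "metadata" in entry
        pid = (
            entry.get("metadata", {}).get("accession")
            if api_style
            else entry.get("protein_id")
        )
        try:
            hits = (
                _hits_from_api_result(entry, report)
                if api_style
                else _hits_from_flat_entry(entry, report)
            )
            meta = entry.get("metadata", {}) if api_style else entry
            out.append(
                AnnotationSet(
                    protein_id=pid,
                    species=meta.get("species", ""),
                    hits=hits,
                    source_db=meta.get("source_db", meta.get("source_database", "synthetic")),
                    length=meta.get("length"),
                )
            )
            report.n_records += 1
            report.n_hits += len(hits)
        except (ParseError, ValueError) as exc:
            report.drop("malformed_entry")
            report.skipped_entries.append(f"{pid}: {exc}")
    return out, report


# ---------------------------------------------------------------------------
# HMMER3 domtblout

_DOMTBL_MIN_COLS = 23


def read_domtblout(
    path: PathLike,
    ga_thresholds: Optional[Mapping[str, float]] = None,
) -> tuple[list[DomainHit], ParseReport]:
    """Parse HMMER3 per-domain tabular output.

    One :class:`DomainHit` per row, using the per-domain *independent*
    E-value (column 13) and the alignment coordinates on the target
    sequence (columns 18-19) — the protocol reasons about individual
    domain hits, not whole-sequence E-values.  The hit's ``protein_id`` is
    the target sequence name.  When a gathering-threshold table is given,
    ``ga_pass`` compares the per-domain bit score against it; otherwise it
    is left unknown.
    """
    report = ParseReport()
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) < _DOMTBL_MIN_COLS:
                raise ParseError(
                    f"{path}:{lineno}: expected >= {_DOMTBL_MIN_COLS} columns, "
                    f"got {len(cols)}"
                )
            target = cols[0]
            query_acc = cols[4] if cols[4] != "-" else cols[3]
            family = query_acc.split(".")[0]
            ievalue = float(cols[12])
            score = float(cols[13])
            ali_from, ali_to = int(cols[17]), int(cols[18])
            ga = GA_UNKNOWN
            if ga_thresholds is not None and family in ga_thresholds:
                ga = GA_YES if score >= ga_thresholds[family] else GA_NO
            hits.append(
                DomainHit(
                    family=family,
                    start=ali_from,
                    end=ali_to,
                    evalue=ievalue,
                    ga_pass=ga,
                    source="hmm_scan",
                    protein_id=target,
                )
            )
            report.n_hits += 1
    report.n_records = len({h.protein_id for h in hits})
    return hits, report


def scan_hits_by_protein(hits: Iterable[DomainHit]) -> dict[str, list[DomainHit]]:
    out: dict[str, list[DomainHit]] = {}
    for h in hits:
        out.setdefault(h.protein_id, []).append(h)
    return out


# ---------------------------------------------------------------------------
# Pfam clans TSV


def read_clans_tsv(path: PathLike) -> ClanMap:
    """Read a Pfam-A.clans.tsv-style file (family, clan, ...).

    Families with an empty clan column are left out of the map.  A family
    mapped to two different clans is an error; duplicate consistent rows
    are idempotent.
    """
    cmap = ClanMap()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            family = cols[0].strip()
            clan = cols[1].strip() if len(cols) > 1 else ""
            if not clan:
                continue
            try:
                cmap[family] = clan
            except ParseError:
                raise
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return cmap


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: PathLike, alphabet: str = "protein") -> dict[str, str]:
    """Read FASTA into {id: sequence}.

    Ids are the first whitespace-delimited token; sequences are upper-cased.
    For protein records a trailing/internal ``*`` (stop) is stripped.
    Duplicate ids and characters outside the alphabet are errors.
    """
    if alphabet not in ("protein", "dna"):
        raise ValueError(f"unknown alphabet {alphabet!r}")
    allowed = PROTEIN_ALPHABET if alphabet == "protein" else DNA_ALPHABET
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if alphabet == "protein":
            seq = seq.replace("*", "")
        if rec.id in out:
            raise ParseError(f"{path}: duplicate sequence id {rec.id!r}")
        for i, ch in enumerate(seq):
            if ch not in allowed:
                raise ParseError(
                    f"{path}: record {rec.id}: illegal character {ch!r} "
                    f"at position {i + 1}"
                )
        if not seq:
            raise ParseError(f"{path}: record {rec.id} is empty")
        out[rec.id] = seq
    return out


def write_fasta(seqs: Mapping[str, str], path: PathLike, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Pair table / species metadata / verdicts TSV


def read_pairs_tsv(path: PathLike) -> PairTable:
    rows = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            rows.append(
                PairRow(row["ref_id"], row["ortho_id"], row["species"])
            )
    return PairTable(rows)


def write_pairs_tsv(pairs: PairTable, path: PathLike) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["ref_id", "ortho_id", "species"])
        for row in pairs:
            w.writerow([row.ref_id, row.ortho_id, row.species])


_META_COLS = [
    "species",
    "contig_n50",
    "busco_complete",
    "n_coding_genes",
    "n_orthologs",
    "mean_pct_identity",
]


def read_species_metadata_tsv(path: PathLike) -> list[SpeciesMetadata]:
    out = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            out.append(
                SpeciesMetadata(
                    species=row["species"],
                    contig_n50=int(row["contig_n50"]),
                    busco_complete=float(row["busco_complete"]),
                    n_coding_genes=int(row["n_coding_genes"]),
                    n_orthologs=int(row["n_orthologs"]),
                    mean_pct_identity=float(row["mean_pct_identity"]),
                )
            )
    return out


def write_species_metadata_tsv(
    meta: Sequence[SpeciesMetadata], path: PathLike
) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_META_COLS)
        for m in meta:
            w.writerow([getattr(m, c) for c in _META_COLS])


_VERDICT_COLS = [
    "ref_id",
    "ortho_id",
    "species",
    "direction",
    "unit",
    "verdict",
    "stages",
    "evidence",
]


def write_verdicts_tsv(verdicts: Sequence, path: PathLike) -> None:
    """One row per fact-checked event, stably sorted by (species, ref, unit)."""
    rows = []
    for v in verdicts:
        ev = v.event
        rows.append(
            [
                ev.pair.ref_id,
                ev.pair.ortho_id,
                ev.pair.species,
                ev.direction,
                str(ev.unit),
                v.klass,
                ",".join(v.stages_run),
                json.dumps(v.evidence, sort_keys=True, separators=(",", ":")),
            ]
        )
    rows.sort(key=lambda r: (r[2], r[0], r[4]))
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_VERDICT_COLS)
        w.writerows(rows)


def read_verdicts_tsv(path: PathLike) -> list[dict]:
    """Read back a verdict table as plain dicts (evidence re-parsed)."""
    out = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            row["evidence"] = json.loads(row["evidence"])
            row["stages"] = row["stages"].split(",") if row["stages"] else []
            out.append(row)
    return out
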