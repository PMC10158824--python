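"""Six-frame translated search of a protein segment against genomic DNA.

This is the built-in evidence engine used to decide whether a genome region
could still code for a domain that is absent from the predicted protein: the
region is translated in all six frames and the domain segment is aligned
locally (Smith-Waterman with affine gaps) against each frame's peptide.
There is no splice-site model — an intron-split domain is only recovered
through its largest exon — and no frameshift-aware alignment.  Default
scoring is BLOSUM62 with gap open 11 / extend 1, the classic TBLASTN
parameterisation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable
from numba import njit

from .formats import GenomicRegion

FRAMES = (1, 2, 3, -1, -2, -3)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@lru_cache(maxsize=1)
def _codon_table() -> dict[str, str]:
    table = dict(CodonTable.unambiguous_dna_by_id[1].forward_table)
    for stop in CodonTable.unambiguous_dna_by_id[1].stop_codons:
        table[stop] = "*"
    return table


@dataclass
class FrameTranslation:
    """Peptide of one reading frame plus its codon-start coordinates.

    ``nt_starts[i]`` is the 1-based coordinate, on the forward strand of the
    original region, of the first base read for peptide position ``i``
    (strictly increasing for forward frames, strictly decreasing for
    reverse frames).
    """

    frame: int
    peptide: str
    nt_starts: list[int]


def six_frame_translate(region: GenomicRegion) -> list[FrameTranslation]:
    """Translate a region in all six frames; any codon containing N -> X."""
    seq = region.sequence.upper()
    n = len(seq)
    if n < 3:
        raise ValueError(f"{region.gene_id}: region shorter than one codon")
    table = _codon_table()
    out: list[FrameTranslation] = []
    for frame in FRAMES:
        if frame > 0:
            strand_seq, off = seq, frame - 1
        else:
            strand_seq, off = reverse_complement(seq), -frame - 1
        aas: list[str] = []
        starts: list[int] = []
        for i in range(off, n - 2, 3):
            codon = strand_seq[i : i + 3]
            aas.append("X" if "N" in codon else table[codon])
            # map back to forward-strand coordinates (1-based)
            starts.append(i + 1 if frame > 0 else n - i)
        out.append(FrameTranslation(frame, "".join(aas), starts))
    return out


@dataclass
class LocalAlignment:
    score: float
    identity: float
    query_span: tuple[int, int]  # 1-based closed, on the query protein
    target_span: tuple[int, int]  # 1-based closed, on the frame peptide
    frame: int = 0
    n_stops: int = 0  # stop codons inside the aligned target segment
    query_coverage: float = 0.0
    evalue: float = float("inf")


# Karlin-Altschul parameters for gapped BLOSUM62 with open 11 / extend 1
# (the BLAST defaults matching this scoring scheme)
_KA_LAMBDA = 0.267
_KA_K = 0.041


def karlin_altschul_evalue(score: float, m: int, n: int) -> float:
    """Expected number of chance alignments of this score in an m x n search."""
    return _KA_K * m * n * math.exp(-_KA_LAMBDA * score)


@lru_cache(maxsize=1)
def _blosum62() -> tuple[np.ndarray, dict[str, int]]:
    mat = substitution_matrices.load("BLOSUM62")
    alphabet = str(mat.alphabet)
    sub = np.asarray(mat, dtype=np.int32)
    return sub, {ch: i for i, ch in enumerate(alphabet)}


def _encode(seq: str, index: dict[str, int]) -> np.ndarray:
    x_idx = index["X"]
    enc = np.empty(len(seq), dtype=np.int64)
    for i, ch in enumerate(seq):
        if ch == "U":
            ch = "C"  # selenocysteine scored as cysteine
        enc[i] = index.get(ch, x_idx)
    return enc


@njit(cache=True)
def _gotoh_fill(q, t, sub, gap_open, gap_ext):  # pragma: no cover - jit
    m, n = q.shape[0], t.shape[0]
    NEG = -10_000_000
    H = np.zeros((m + 1, n + 1), dtype=np.int32)
    E = np.full((m + 1, n + 1), NEG, dtype=np.int32)
    F = np.full((m + 1, n + 1), NEG, dtype=np.int32)
    first = gap_open + gap_ext
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            e = E[i, j - 1] - gap_ext
            ho = H[i, j - 1] - first
            E[i, j] = e if e > ho else ho
            f = F[i - 1, j] - gap_ext
            hv = H[i - 1, j] - first
            F[i, j] = f if f > hv else hv
            d = H[i - 1, j - 1] + sub[q[i - 1], t[j - 1]]
            best = 0
            if d > best:
                best = d
            if E[i, j] > best:
                best = E[i, j]
            if F[i, j] > best:
                best = F[i, j]
            H[i, j] = best
    return H, E, F


def local_align(
    query: str,
    target: str,
    gap_open: int = 11,
    gap_extend: int = 1,
) -> LocalAlignment:
    """Optimal local alignment (Smith-Waterman-Gotoh, affine gaps).

    A gap of length k costs ``gap_open + k * gap_extend``.  The traceback is
    deterministic: ties are broken preferring diagonal, then up (gap in the
    target), then left (gap in the query); the end cell is the first maximum
    of the score matrix in row-major order.
    """
    if not query or not target:
        raise ValueError("empty sequence")
    sub, index = _blosum62()
    q = _encode(query, index)
    t = _encode(target, index)
    H, E, F = _gotoh_fill(q, t, sub, np.int32(gap_open), np.int32(gap_extend))

    flat = int(np.argmax(H))
    i, j = divmod(flat, H.shape[1])
    score = int(H[i, j])
    if score <= 0:
        return LocalAlignment(0.0, 0.0, (0, 0), (0, 0))

    first = gap_open + gap_extend
    qi, tj = i, j
    matches = cols = stops = 0
    state = "H"
    while qi > 0 and tj > 0:
        if state == "H":
            if H[qi, tj] == 0:
                break
            diag = H[qi - 1, tj - 1] + sub[q[qi - 1], t[tj - 1]]
            if H[qi, tj] == diag:
                cols += 1
                if q[qi - 1] == t[tj - 1]:
                    matches += 1
                if target[tj - 1] == "*":
                    stops += 1
                qi -= 1
                tj -= 1
            elif H[qi, tj] == F[qi, tj]:
                state = "F"
            else:
                state = "E"
        elif state == "F":  # gap in target: consume query
            cols += 1
            if F[qi, tj] == H[qi - 1, tj] - first:
                state = "H"
            qi -= 1
        else:  # gap in query: consume target
            cols += 1
            if target[tj - 1] == "*":
                stops += 1
            if E[qi, tj] == H[qi, tj - 1] - first:
                state = "H"
            tj -= 1
    q_span = (qi + 1, i)
    t_span = (tj + 1, j)
    identity = matches / cols if cols else 0.0
    coverage = (q_span[1] - q_span[0] + 1) / len(query)
    return LocalAlignment(
        score=float(score),
        identity=identity,
        query_span=q_span,
        target_span=t_span,
        n_stops=stops,
        query_coverage=coverage,
    )


def search_domain_in_region(
    domain_seq: str,
    region: GenomicRegion,
    min_cov: float = 0.5,
    min_id: float = 0.4,
    max_evalue: float = 1e-3,
    gap_open: int = 11,
    gap_extend: int = 1,
) -> Optional[LocalAlignment]:
    """Best six-frame hit of a domain segment in a genomic region.

    Returns the highest-scoring frame alignment, but only when it covers at
    least ``min_cov`` of the domain segment at identity >= ``min_id`` AND
    its Karlin-Altschul E-value over the six-frame search space is at most
    ``max_evalue`` — identity and coverage alone admit chance matches over
    short spans, so significance is gated the way a translated BLAST search
    would gate it.  Stop codons inside the alignment are allowed (they
    score -4) and are counted in ``n_stops`` as a possible intron/
    frameshift signal.
    """
    if len(domain_seq) < 10:
        raise ValueError("domain segment shorter than 10 residues")
    best: Optional[LocalAlignment] = None
    search_space = 0
    for ft in six_frame_translate(region):
        if not ft.peptide:
            continue
        search_space += len(ft.peptide)
        aln = local_align(domain_seq, ft.peptide, gap_open, gap_extend)
        aln.frame = ft.frame
        if best is None or aln.score > best.score:
            best = aln
    if best is None or best.score <= 0:
        return None
    best.evalue = karlin_altschul_evalue(
        best.score, len(domain_seq), search_space)
    if (best.query_coverage >= min_cov and best.identity >= min_id
            and best.evalue <= max_evalue):
        return best
    return None
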