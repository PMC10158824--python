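"""Bundled per-species counts from a genome-scale domain gain/loss survey.

Two published ortholog sets are shipped as plain data: 9 non-human primate
(NHP) proteomes compared to the human reference, and 20 non-*S. cerevisiae*
fungal (NSF) proteomes compared to *S. cerevisiae*.  For each species the
tables carry assembly/annotation quality metrics (contig N50, BUSCO
complete, coding genes, one-to-one ortholog count, mean % identity to the
reference) and the ortholog-level outcome counts of the fact-checking
protocol: potential MD/AD events and their attribution to domain-annotation
inconsistencies, gene/isoform prediction errors, undetermined genome
regions, or true events.

These counts serve as ready-made inputs for the summary arithmetic and the
quality-metric correlation analyses; they are not recomputed here (doing so
would require the source protein and genome databases).
"""

from __future__ import annotations

import pandas as pd

from .stats import SpeciesSummary

# species, contig_n50, busco_complete, n_coding_genes, n_orthologs,
# mean_pct_identity, potential_md, potential_ad,
# md_annotation, md_gene_prediction, md_undetermined, true_md,
# ad_annotation, ad_isoform, true_ad
_NHP_ROWS = [
    ("Chimpanzee", 384816, 96.0, 23534, 17944, 98.5, 237, 92, 107, 63, 57, 10, 42, 18, 32),
    ("Gorilla", 52934, 97.2, 21794, 17670, 98.2, 480, 102, 180, 81, 180, 39, 60, 16, 26),
    ("Orangutan", 11074009, 99.3, 20211, 16490, 97.3, 400, 121, 103, 246, 11, 40, 53, 13, 55),
    ("Gibbon", 35148, 99.7, 20794, 16797, 96.5, 763, 131, 337, 116, 293, 17, 90, 13, 28),
    ("Baboon", 1465768, 98.6, 21882, 17107, 96.1, 422, 154, 160, 181, 15, 66, 79, 15, 60),
    ("Vervet", 90449, 99.0, 19165, 17192, 96.2, 746, 122, 208, 253, 164, 121, 86, 8, 28),
    ("Macaque", 46608966, 98.8, 21761, 16255, 95.9, 388, 199, 155, 182, 0, 51, 77, 20, 102),
    ("Marmoset", 13222669, 99.9, 22078, 16714, 94.0, 349, 139, 178, 139, 2, 30, 90, 12, 37),
    ("Bushbaby", 27100, 97.4, 19506, 16071, 89.4, 677, 173, 285, 107, 248, 37, 139, 5, 29),
]

_NSF_ROWS = [
    ("Yarrowia lipolytica", 182835, 95.7, 6448, 2889, 36.1, 186, 163, 114, 9, 0, 63, 97, 0, 66),
    ("Schizosaccharomyces pombe", 2923134, 79.9, 5145, 2340, 32.9, 130, 174, 72, 3, 0, 55, 94, 0, 80),
    ("Arthrobotrys oligospora", 5390931, 95.4, 11479, 2641, 32.1, 193, 207, 109, 27, 3, 54, 113, 0, 94),
    ("Tuber melanosporum", 63046, 92.8, 7496, 2537, 31.9, 236, 192, 116, 58, 6, 56, 98, 0, 94),
    ("Aspergillus fumigatus", 556577, 96.6, 9623, 2561, 31.7, 164, 199, 95, 13, 1, 55, 100, 0, 99),
    ("Neurospora crassa", 102005, 97.9, 9758, 2615, 31.5, 156, 195, 97, 9, 0, 50, 102, 0, 93),
    ("Eutypa lata", 190808, 97.0, 11685, 2350, 31.0, 294, 183, 124, 90, 33, 47, 96, 0, 87),
    ("Phaeosphaeria nodorum", 16751, 93.2, 12391, 2502, 30.3, 245, 237, 118, 51, 7, 69, 98, 0, 139),
    ("Cryptococcus neoformans", 1423448, 98.7, 6632, 2177, 29.7, 181, 174, 97, 4, 2, 78, 72, 0, 104),
    ("Coprinopsis cinerea", 3468139, 98.8, 13355, 2161, 29.6, 210, 212, 111, 28, 1, 70, 87, 0, 125),
    ("Wallemia ichthyophaga", 436658, 87.0, 4865, 1997, 29.5, 211, 277, 117, 14, 3, 77, 77, 0, 200),
    ("Ustilago maydis", 111545, 99.1, 6765, 2199, 29.0, 180, 221, 86, 3, 9, 82, 83, 0, 138),
    ("Microbotryum violaceum", 1329596, 94.4, 7364, 2202, 28.8, 195, 211, 109, 15, 9, 62, 80, 0, 131),
    ("Puccinia graminis", 53646, 88.8, 15800, 1849, 28.5, 232, 159, 116, 27, 30, 59, 73, 0, 86),
    ("Mixia osmundae", 426173, 88.4, 6726, 2111, 28.1, 181, 316, 101, 7, 3, 70, 86, 0, 228),
    ("Allomyces macrogynus", 35497, 83.9, 18774, 402, 28.2, 273, 173, 122, 44, 63, 44, 67, 0, 106),
    ("Spizellomyces punctatus", 155888, 90.9, 8950, 2100, 29.8, 144, 302, 72, 9, 12, 51, 116, 0, 186),
    ("Gonapodya prolifera", 63757, 74.8, 13827, 1819, 29.1, 207, 161, 97, 33, 6, 71, 66, 0, 95),
    ("Nosema ceranae", 42592, 93.5, 2060, 467, 25.2, 178, 15, 63, 17, 56, 42, 9, 0, 6),
    ("Vavraia culicis", 94471, 95.5, 2773, 491, 24.5, 191, 14, 72, 3, 28, 88, 8, 0, 6),
]

_COLS = [
    "species",
    "contig_n50",
    "busco_complete",
    "n_coding_genes",
    "n_orthologs",
    "mean_pct_identity",
    "potential_md",
    "potential_ad",
    "md_annotation",
    "md_gene_prediction",
    "md_undetermined",
    "true_md",
    "ad_annotation",
    "ad_isoform",
    "true_ad",
]

# parasitic microsporidia with strongly biased MD/AD ratios; excluded from
# the quality-metric correlation analyses by default
MICROSPORIDIA = ("Nosema ceranae", "Vavraia culicis")


def nhp_counts() -> pd.DataFrame:
    """Primate survey counts (9 species vs the human reference)."""
    return pd.DataFrame(_NHP_ROWS, columns=_COLS)


def nsf_counts() -> pd.DataFrame:
    """Fungal survey counts (20 species vs the *S. cerevisiae* reference)."""
    return pd.DataFrame(_NSF_ROWS, columns=_COLS)


def summaries_from_counts(df: pd.DataFrame) -> dict[str, SpeciesSummary]:
    """Build :class:`SpeciesSummary` objects (plus a Total row) from counts.

    This is the entry point for validating the summary arithmetic (ratios,
    percentages, row identities) on externally tabulated ortholog counts.
    """
    out: dict[str, SpeciesSummary] = {}
    total = SpeciesSummary("Total")
    for row in df.itertuples(index=False):
        s = SpeciesSummary(
            species=row.species,
            n_orthologs=int(row.n_orthologs),
            potential_md=int(row.potential_md),
            potential_ad=int(row.potential_ad),
            md_annotation=int(row.md_annotation),
            md_gene_prediction=int(row.md_gene_prediction),
            md_undetermined=int(row.md_undetermined),
            true_md=int(row.true_md),
            ad_annotation=int(row.ad_annotation),
            ad_isoform=int(row.ad_isoform),
            true_ad=int(row.true_ad),
        )
        out[s.species] = s
        for f in (
            "n_orthologs",
            "potential_md",
            "potential_ad",
            "md_annotation",
            "md_gene_prediction",
            "md_undetermined",
            "true_md",
            "ad_annotation",
            "ad_isoform",
            "true_ad",
        ):
            setattr(total, f, getattr(total, f) + getattr(s, f))
    out["Total"] = total
    return out
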