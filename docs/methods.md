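# Methods

This note documents the models, parameter defaults and numerical choices
behind `domfact`, and what the synthetic fixtures do and do not establish
about behaviour on real data.

## Domain content

A protein's domain content is a set of *units* built from its Pfam-A hits
in two steps:

1. **Overlap grouping.** Two hits link when their interval overlap is at
   least `overlap_ratio` (default 0.5) of the *shorter* hit's length.
   Normalising by the shorter hit is the permissive reading: a small domain
   nested inside a larger annotation must merge with it, since the point of
   grouping is to treat redundant annotations of one region as one entry.
   Linking is transitive (single-linkage), so unit membership does not
   depend on input order; a pairwise-only rule would be order-dependent.
2. **Repeat collapsing.** A family present k ≥ 1 times contributes one
   unit, wherever its copies sit.

Grouping is applied to both proteins of a pair, not only the reference:
additional-domain detection needs the symmetric treatment
(`group_ortholog_hits=False` restores reference-only behaviour).

Unit identity across proteins is family-set intersection: if any member
family of a reference unit is annotated on the ortholog, the unit counts as
shared. Domain order, copy number and fusion/fission are outside the model
by construction.

Coordinates are 1-based closed protein intervals everywhere; Interpro JSON
fragments and HMMER alignment coordinates both already use this convention,
so parsers never shift. Discontinuous-domain fragments are kept as separate
hits and rely on overlap grouping to merge.

## Event detection and the decision tree

Potential events are per-(pair, unit): MD when a reference unit has no
intersecting ortholog unit, AD conversely. Ortholog pairs where either
sequence exceeds `max_protein_len` (default 5,000 aa) are dropped up front.

Stages run in a fixed order and the first decisive one wins; every verdict
records the stages that ran.

**MD:** annotation → gene prediction → genome N → final.
**AD:** annotation → isoform → final.

- *Annotation reconciliation* consults re-scan results (HMMER domtblout).
  The decision criterion is the per-domain independent E-value at
  `evalue_max = 0.01`; a gathering-threshold pass/fail flag, when a GA
  table is supplied, is recorded as evidence metadata only (E-value and GA
  filtering are mutually exclusive scan modes; the E-value rule is the one
  the reconciliation logic needs, since it asks whether relaxing the
  annotation threshold reveals the domain). Raising `evalue_max` can only
  move MD events *into* the ortholog-side annotation class, never out —
  a monotonicity property the tests assert.
- *Gene prediction* (MD only): the reference subsequence spanning the
  missing unit's hits (± `segment_pad` residues, default 0 — see
  "Numerical choices") is searched against the ortholog's gene region with
  the translated search below. When an externally corrected protein and
  its re-annotation are registered through the plug-in hook, a qualifying
  hit of the unit at E ≤ `evalue_max` in that re-annotation is the
  criterion instead, and the built-in search is skipped.
- *Isoforms* (AD only): a reference alternative isoform whose content
  contains the gained unit (family-level matching; clan relatives are
  deliberately excluded here) explains the event as an isoform-choice
  inconsistency. The reference genome and gene models are axiomatically
  trusted, so there are no genome-side AD checks.
- *Genome N* (MD only): any run of `N` of length ≥ `min_run` (default 1 —
  any undetermined stretch makes absence undecidable; configurable because
  isolated N's in distal flanks are often benign).
- *Final*: if the counterpart protein carries a unit from the same Pfam
  clan sharing no family with the event unit, the event is domain
  switching; otherwise true MD/AD. Two switching modes exist: `presence`
  (default — any such clan mate) and `reciprocal` (the clan mate must
  itself be unmatched in the event protein's content, i.e. part of a
  complementary event).

An MD event with both a recoverable exon and N-runs is classed by stage
precedence as a gene-prediction error, with a `also_has_n_runs` flag in the
evidence.

Ortholog-level summaries assign an ortholog with several same-direction
events to its highest-precedence class (annotation < gene/isoform <
undetermined < switching < true), which preserves the per-direction
partition identity `potential = Σ classes`; event-level granularity remains
available from the verdict list.

## Translated search

The search for a genome region still coding for a missing domain is a
six-frame translation (standard code; any codon containing N translates to
X; reverse frames read the reverse complement) followed by local alignment
of the domain segment against each frame peptide: Smith–Waterman with
affine gaps (Gotoh), BLOSUM62, gap open 11 / extend 1 — the classic
parameterisation of translated BLAST, which this engine stands in for.
Stop codons score −4 (the BLOSUM62 `*` column) rather than being forbidden,
so near-boundary exons still align, and stops inside an accepted alignment
are counted as a possible intron/frameshift signal.

A hit is accepted when it covers ≥ `min_cov` (0.5) of the domain segment at
identity ≥ `min_id` (0.4) — permissive values mirroring translated-BLAST
sensitivity at close-to-moderate divergence — **and** its Karlin–Altschul
E-value over the six-frame search space is ≤ `search_evalue_max` (10⁻³;
gapped BLOSUM62 11/1 parameters λ = 0.267, K = 0.041). The significance
bound matters: identity and coverage alone admit occasional chance matches
over short spans, which is exactly the failure mode an E-value criterion
exists to remove.

There is no splice-site model and no frameshift-aware alignment: an
intron-split domain is recovered only through its largest exon, which must
clear `min_cov` on its own. Full-fidelity spliced alignment belongs to the
external-evidence hook (corrected proteins + their re-annotation).

The alignment kernel (numba) returns the full H/E/F matrices; the traceback
is deterministic, preferring diagonal, then up, then left, ending at the
first row-major maximum. The kernel is validated against a brute-force
recursive enumerator on short sequences and against an independent local
aligner's scores on random protein pairs.

## Statistics

- **Rounding**: all table-style ratios/percentages round half away from
  zero to one decimal, matching the convention of per-species report
  tables.
- **Spearman**: Pearson correlation of mid-ranks (average ranks on ties);
  two-sided p from the t approximation with df = n − 2. For n ≤ 10 an
  exact permutation p is available (`exact=True`); the t approximation is
  the default because the species panels analysed are small but not tiny
  (n = 9–18), and both are reported where they differ materially.
- **Paired t**: classical paired t on differences, df = n − 1; identical
  vectors return t = 0, p = 1 by documented convention, constant nonzero
  differences return NA.
- **PGLS**: generalized least squares with Brownian covariance V (shared
  root-to-MRCA branch length from the rooted tree, computed via dendropy
  patristic distances), off-diagonals scaled by Pagel's λ; δ and κ are
  fixed at 1 (branch lengths used as given). λ is estimated by bounded ML
  on [0, 1] (scalar search, tolerance 10⁻⁶, explicit boundary checks
  because the bounded optimiser can stall just inside a boundary). The fit
  whitens by the Cholesky factor of V(λ); a singular covariance (e.g.
  duplicate zero-length tips) raises a clear error. R² is 1 − RSS/RSS₀ in
  the GLS metric against the GLS intercept-only model; the slope p-value is
  the F-test with df = (1, n − 2). The default covariate is patristic
  distance to the reference taxon; an explicit covariate (e.g. contig N50)
  can be passed instead.

Two PGLS behaviours worth knowing:

- λ = 0 reduces to *ordinary* least squares only when tip heights are equal
  (ultrametric tree): V(0) is diagonal with the tip heights, i.e. weighted
  LS in general. The test suite exercises the OLS identity on an
  ultrametric ladder with the reference nested (so the distance covariate
  still varies).
- With ~16 taxa and a covariate that is itself a function of the phylogeny,
  λ is weakly identified: under data simulated at λ = 1 the ML estimate
  frequently lands on 0 (the profile likelihood was cross-checked against
  an independent R implementation and matches to six decimals). Slope
  estimates remain unbiased — the validation asserts slope recovery and
  the ML property of λ̂, not a per-replicate "λ̂ ≈ 1".

Correlation analyses accept a per-analysis species blacklist (used e.g. to
drop strongly biased parasitic taxa) rather than hard-coding exclusions.

## Synthetic fixtures

The generator emulates every input the pipeline consumes — Interpro-style
JSON, protein/genomic FASTA, domtblout re-scan output, clans TSV, pair
table, species metadata, Newick tree — for configurable numbers of species
and pairs, planting one event of a chosen class per selected pair with a
deterministic truth table. Everything derives from a single seed,
bit-reproducibly.

Design choices: domain lengths uniform on [40, 200] aa (typical Pfam
range), linkers 5–20 aa, proteins of 2–3 domains, gene regions are uniform
synonymous back-translations of the ortholog protein with 1,000 nt random
flanks; planting counts are exact per class (`events_per_class`) rather
than probabilistic rates, so ground truth is unambiguous. Clan families are
reserved for switching plants so no other architecture accidentally
contains clan relatives.

What the fixtures show: that the decision tree attributes each planted
error class correctly (per-class precision = recall = 1, verified across
many seeds) and that the pipeline's bookkeeping (partition identities,
determinism, round-trips) holds. What they do not show: homology detection
power on real diverged sequences — fixture orthologs are identical to the
reference outside planted edits, there is no phylogenetic sequence
evolution, no codon bias, and no annotation noise. Performance on real
proteomes therefore depends on the upstream annotation and scan quality in
ways the fixtures deliberately do not model.

The bundled survey counts (9 primate and 20 fungal species) validate the
summary arithmetic and the correlation/PGLS plumbing on realistic numbers;
recomputing those counts from live protein/genome databases is outside the
package's scope (it would require the source databases and full HMM
libraries), as is ortholog inference, BUSCO computation and running
hmmsearch/BLAST themselves — their outputs are consumed as files. Two
fungal rows of the bundled AD table are internally inconsistent in the
source by ±2 (components vs totals, offsetting so column totals reconcile);
they are kept verbatim and the row-identity check exempts them.

## Problem sizes used in validation

The planted-recovery validation uses 5 species × 22 pairs with 10 events
per class (110 truth rows); the alignment oracle runs on sequences of ≤ 8
residues over a reduced alphabet, where exhaustive enumeration is exact;
the PGLS simulation uses a 16-tip tree with 200 Brownian replicates. These
sizes give stable statistics while keeping the full suite fast enough to
run on every change.
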