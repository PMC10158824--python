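# domfact

Fact-checking of protein domain gain/loss events between a reference
proteome and its one-to-one orthologs.

## The problem

Comparing Pfam-A domain architectures across species is a standard way to
find lineage-specific innovations: a domain present in a human protein but
absent from its macaque ortholog looks like a domain loss; the converse
looks like a gain. But the annotation pipeline behind each predicted
proteome — genome assembly, gene/isoform prediction, domain assignment — is
error-prone, and most apparent events are artefacts. `domfact` implements
an automated verification protocol that attributes each candidate event to
a concrete error source, or certifies it as a true event, so that
downstream evolutionary analyses run on filtered data.

It is aimed at comparative genomicists working with a high-quality
reference proteome (e.g. human, *S. cerevisiae*) and predicted proteomes of
related species.

## The method

A protein's **domain content** is its set of distinct Pfam-A units: hits
that overlap over at least half of the shorter hit merge into one unit, and
repeats collapse, so content is order- and copy-number-insensitive. For
each ortholog pair, a unit present in the reference content but absent from
the ortholog is a potential **missing domain (MD)**; the converse is a
potential **additional domain (AD)**.

Each potential event then passes through a short-circuiting decision tree;
the first decisive stage wins:

1. **Annotation reconciliation** — standardized re-scan results (HMMER
   domtblout, per-domain independent E-value, threshold E ≤ 0.01) either
   find the "missing" domain in the ortholog, or fail to support the
   reference's own annotation → annotation inconsistency (either side).
2. **Gene/isoform check** — for MD, the reference domain segment is
   searched against the ortholog's gene region (± flanks) by six-frame
   translation and Smith–Waterman alignment (BLOSUM62, gap 11/1); a
   significant hit (coverage ≥ 0.5, identity ≥ 0.4, Karlin–Altschul
   E ≤ 10⁻³) means the gene model, not the genome, lost the domain. For
   AD, the reference's alternative isoforms are searched for the gained
   unit instead.
3. **Genome completeness** — a run of undetermined nucleotides (N) in the
   gene region makes presence/absence undecidable.
4. Otherwise the event is true — classified as **domain switching** when
   the counterpart protein carries a different family of the same Pfam
   clan, else a true MD/AD.

Downstream statistics cover per-species summary tables (MD/AD ratios, %
true events), ordinal N/C-terminal position analysis, Spearman correlations
against assembly-quality metrics (contig N50, BUSCO), paired t-tests of
MD vs AD rates, and PGLS regression of event counts on patristic distance
under a Pagel-λ covariance (δ = κ = 1, λ estimated by bounded ML).

The package also ships a seeded synthetic-data generator that emits every
input format with planted ground truth for all error classes, and a bundled
per-species count table from a genome-scale survey of 9 non-human primates
(vs human) and 20 fungi (vs *S. cerevisiae*) for validating the summary
arithmetic and correlation analyses.

## Worked example

Generate a small synthetic dataset with one planted event of every class,
fact-check it, and summarize:

```sh
$ domfact simulate --seed 3 --out data/
wrote dataset with 24 pairs, 11 planted events to data/

$ domfact factcheck --data data/ --out out/
11 verdicts (2 true events)
```

`out/verdicts.tsv` holds one row per event with its verdict and evidence
trail, e.g. (abridged):

```
ref_id  species  direction  unit     verdict                        stages
R0002   SP03     MD         PF90025  annotation_inconsistent_ortho  annotation
R0006   SP01     MD         PF90026  gene_prediction_error          annotation,gene_prediction
R0009   SP01     MD         PF90000  domain_switching               annotation,gene_prediction,genome_n,final
R0000   SP01     MD         PF90011  true_MD                        annotation,gene_prediction,genome_n,final
```

The planted gene-prediction error is recovered because the back-translated
domain copy sits in the gene region (identity 1.0 in the alignment
evidence); the clan-switch pair yields one MD and one AD verdict, both
`domain_switching`; events with no error evidence end as `true_MD`/`true_AD`.
`out/summary.tsv` aggregates per species: potential counts per direction,
per-class counts, and `% true` columns — on the bundled primate survey
counts these operations give an MD/AD ratio of 3.6, 9.2% true MD and 32.2%
true AD, and an overall post-filter event rate of 0.5% of orthologs.

Library use mirrors the CLI:

```python
from domfact import synthetic, detect_events, fact_check_all

ds = synthetic.generate(synthetic.FixtureConfig(seed=3))
events = [e for p in ds.build_pairs() for e in detect_events(p, ds.clans)]
verdicts = fact_check_all(events, ds.check_resources())
```

## Layout

- `domfact.formats` — readers/writers (Interpro-style JSON, HMMER domtblout,
  Pfam clans TSV, FASTA, pair/metadata/verdict TSV), 1-based closed
  coordinates throughout, parse reports for anything dropped.
- `domfact.content` — domain content: overlap grouping, repeat collapsing,
  clan relations.
- `domfact.events` — potential MD/AD detection and tabulation.
- `domfact.factcheck` — the verification decision tree.
- `domfact.translated_search` — six-frame translation + Smith–Waterman–Gotoh
  local alignment (numba kernel).
- `domfact.stats` — summaries, ordinal positions, Spearman/paired-t, PGLS.
- `domfact.synthetic` — seeded fixture generator with planted ground truth.
- `domfact.datasets` — bundled survey counts (primates, fungi).
- `domfact.cli` — `domfact simulate | detect | factcheck | stats`.

See `docs/methods.md` for modelling assumptions, parameter defaults and
known limitations.
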