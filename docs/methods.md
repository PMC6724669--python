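# Methods

## Variant model and normalization

A variant is a substitution of `alt` for `ref` at a 1-based position on a
canonicalized chromosome (no `chr` prefix; `X`/`Y`/`MT` uppercased;
`M` → `MT`). The variant type is a pure function of the two allele lengths
and the shared anchor base: 1/1 → SNV; 1/k with the anchor shared → INS;
k/1 with the anchor shared → DEL; equal lengths > 1 → MNV; everything else
COMPLEX (including unanchored length changes).

Normalization is **anchor-trim only**: shared trailing bases are removed
first, then shared leading bases, always leaving at least one base on each
allele so indels keep their VCF anchor. No reference FASTA is consulted, so
no left-alignment across repeat tracts is performed; a knowledgebase whose
indels were normalized differently can therefore miss a genomic-key match
(the protein-level match grades partially compensate). Normalization is
idempotent and never changes the edit implied by `(pos, ref, alt)` when
re-applied to a reference sequence — both are property-tested.

GRCh38 input is accepted only as a labeled pass-through with a warning;
coordinates must already be GRCh37-equivalent. Multi-allelic records are
decomposed before any downstream step, because every rule is per-allele.
Symbolic ALTs (`<DEL>`, breakends, `*`) are skipped with a counted log.

## Panel filtering

Panel files are tab-delimited `chrom  start  end  gene_symbol` with
half-open `[start, end)` intervals. A variant is retained iff some position
of its full REF span satisfies `start <= p < end` — positions are compared
on the same axis, so a variant exactly at `end` is outside. (The dialect's
boundary behavior is fixed by this rule rather than by a 0-/1-based
conversion; the distinction only matters in the single base at each
interval edge.) Intersecting by the REF span, not just `pos`, keeps
deletions that cross a panel boundary. Whole-gene intervals are used
rather than exonic footprints: the later functional filter removes
non-coding hits anyway, and whole-gene intervals are robust to transcript
updates. A variant inside two genes' intervals is panel-tagged once per
gene; the result row's gene comes from the selected annotation.

Genotype columns are carried through opaquely for reporting (relevant to
autosomal-recessive sign-out, which happens at the patient level, outside
this per-variant engine) and are never interpreted by any rule.

## Nomenclature standardization

Protein changes parse from one- or three-letter codes with an optional
`p.` prefix and parentheses; the stop codon may be spelled `Ter`, `Term`,
`Stop`, `*`, or `X` — `X` counts as a stop only in the alternate position,
since an unknown reference residue is not salvageable. `=` denotes a
synonymous change. The internal form is one-letter (`R359*`, `L294=`) with
both canonical renderings derivable; parse → render → parse is a tested
fixed point. Parsing never raises: on failure a codon number is extracted
when present (`codon_only`), except from nucleotide-grammar strings
(`c.`/`g.`/... prefixes or `>`), whose numbers are positions, not codons.

Pathogenicity labels map case-insensitively onto B/LB/VUS/LP/P through an
editable data file (`data/pathogenicity_map.tsv`); anything unlisted is
`unmapped`, never silently pathogenic, and the table is constrained (and
tested) so that no label maps to P or LP without containing the substring
"pathogenic".

## Knowledgebase snapshots and match grades

Curated calls, hotspot counts, population frequencies and prediction
scores load from tab-delimited snapshot files with a label recorded in
every output row — classifications drift with database versions, so
provenance is part of the result. Unknown columns are load errors; ClinVar
review stars outside 0–4 are load errors; duplicate
`(source, genomic_key)` curated rows resolve last-wins with a counted
warning.

Matches are graded: `EXACT_GENOMIC` > `EXACT_PROTEIN` >
`SAME_POSITION_DIFF_ALLELE` > `SAME_CODON_DIFF_AA`; each record receives
its best applicable grade. Protein-level matching requires the same gene
and codon number but deliberately **not** the same transcript — locus
databases rarely state transcripts, and requiring them would cost recall
that the grade system already prices in; codon-numbering drift across
transcripts is an accepted, logged risk.

Frequency semantics: an absent frequency and 0.0 differ only in
provenance; both satisfy every absent-or-rare predicate, and only a present
value above a threshold fails one.

Hotspots: COSMIC codons qualify at `tumor_count >= 10` (configurable;
counts are pre-aggregated with hypermutators already removed). The
pediatric-cohort (PCGP) table has no published count threshold, so those
records carry an explicit curated-hotspot flag in the snapshot instead of
a guessed cutoff — the decision is externalized to the data.

## Splice enhancement and transcript selection

Silent or missense calls within a small exonic window of an exon edge are
promoted to `splice_region`, preserving the original class in an audit
field. The window defaults to 3 exonic bases at the donor (3') edge and 1
at the acceptor (5') edge, strand-aware: donor-site consensus extends
further into the exon than acceptor consensus, and the known pathogenic
silent examples sit at exon 3' ends. The window is configuration-exposed
because it is a judgement call, not a published constant. Promotion never
demotes and never touches other classes.

Retained classes are silent, missense, nonsense, frameshift, splice,
splice_region, inframe_indel, stoploss; UTR, intronic, intergenic and
unclassified annotations drop. A variant survives if *any* of its
annotations survives (monotone in added annotations). The medal engine
sees the most severe annotation (frameshift > nonsense > splice >
splice_region > inframe_indel > stoploss > missense > silent), ties broken
by lexicographic transcript accession for determinism.

Promoted `splice_region` calls are *not* treated as truncating by default
(`Config.splice_region_is_truncating` toggles this): promotion exists to
force scrutiny, and auto-gold from a heuristic window would overstate the
evidence. Canonical splice-site calls always count as truncating.

## Medal rules

Evaluation order: blacklist (always unknown), whitelist (always gold —
whitelists encode committee knowledge, the highest-trust source), the
frequency gate, then the rule tiers with the highest granted medal
winning; every fired rule is recorded as `(rule_id, evidence)`.

The gate consults only the ExAC non-TCGA frequency (the non-TCGA subset
avoids enrichment from cancer cohorts); other sources are reported but
never gate. The boundary is inclusive: frequency equal to the cutoff
passes, anything strictly greater fails. A gate-failed variant can be
rescued by an exact match to IARC TP53, or to ClinVar P/LP with at least
the star minimum; once rescued, **all** rules apply (not only the rescuing
match) — the rescue asserts the variant is review-worthy, after which the
usual evidence calculus should run unrestricted. Imperfect matches medal
exactly one tier below exact matches; the downgrade is deterministic
rather than "typical". A variant whose gene has no metadata record is
treated as non-loss-of-function with a logged warning — never silently
gold.

The somatic medal is separate logic over somatic resources only (hotspot
tables plus loss-of-function reasoning): gold for a direct hotspot match
(the variant's amino-acid change observed at a qualifying codon) or a
truncation in a loss-of-function gene; silver for a qualifying codon with
a different change, or an in-silico damaging call; bronze for tolerated;
germline databases are never consulted, so the two medals can differ — a
curated germline match can yield silver germline next to bronze somatic.

### Prediction aggregation

`damaging` if REVEL ≥ 0.5 or a strict majority of non-unknown categorical
calls say damaging (`min_damaging_calls` overrides the majority);
`tolerated` if at least one categorical call is present, all non-unknown
calls agree on tolerated, and REVEL (if present) is below the threshold;
`unknown` otherwise. The REVEL cutoff and majority rule are configuration
defaults, not published constants. One consequence of this definition is
that the aggregate is not monotone in single added categorical calls: one
dissenting damaging call dissolves a tolerated consensus into `unknown`,
which can turn a bronze medal into no medal. The medal-monotonicity
guarantee therefore covers added database matches, hotspot records,
whitelist entries, and REVEL increases — evidence kinds for which it holds
unconditionally — and the aggregation itself is verified against an
exhaustive enumeration of call vectors.

## ACMG tags and classification

Automated tags, per their published definitions restricted to evidence
this pipeline holds: PVS1 (truncating in a loss-of-function gene), PM1
(COSMIC hotspot only — the pediatric flag is not a PM1 source), PM2
(absent or ≤ 0.0001 in the reference population), BA1 (> 5 %; mutually
exclusive with PM2 by construction since the ceiling cannot exceed the
floor), PM4 (in-frame indel), PS1 (exact genomic match, or identical
amino-acid change, to a P/LP record in ClinVar or committee review), PM5
(different amino-acid change at the same codon as such a record). The
PS1/PM5 split follows the guideline: identical change → PS1, same codon
different change → PM5. All other criteria are manual-entry only; auto
tags are removable, and the classification is recomputed on every edit.

The evidence-combining disjuncts ship as a data table
(`data/acmg_combining_rules.tsv`) so the transcription is auditable, and
an independent hard-coded evaluator cross-checks it over all ≤ 6-tag
subsets of an 11-code alphabet. Conflict handling takes the strictest
reading: any fired pathogenic-side rule together with any fired
benign-side rule yields VUS. Tag strength is fixed by the code prefix;
analyst strength-modulation (e.g. PVS1 applied at moderate) is out of
scope.

## Synthetic data generator

`fixtures.generate_suite(seed, out_dir)` emits a complete input set — VCF
(41 decomposed variants over 9 synthetic genes on one sample, including a
multi-allelic record and one symbolic ALT), panels for the five disease
categories, gene metadata, exon models, annotation table, knowledgebase
snapshot, whitelist and blacklist — plus a JSON manifest of expected
medal, gate status, tags and classification per variant. Expectations are
computed exclusively by the independent rule oracles
(`medaltriage.oracles`), which operate on abstract declared feature
vectors and share no code with the engines; the master regression test
runs the real pipeline over the generated files and demands exact
agreement. Five archetype variants are fixed (not randomized) so the
literature-anchored outcomes are stable test anchors; a seeded filler set
adds evidence-free variants. Identical seeds give byte-identical output,
and generation self-checks that every germline medal tier and every gate
status occurs at least three times.

What the generator does **not** emulate: realistic allele-frequency
spectra, mutational signatures, genome-scale variant counts, real gene
coordinates, or dirty real-world database rows beyond the specific
dialects handled by the parsers. Passing the suite demonstrates the rule
logic, the file dialects and the funnel arithmetic; it does not validate
recall against real ClinVar/COSMIC content or VEP output quirks.

## Problem sizes and numerical choices

The randomized rule battery used for engine-vs-oracle equivalence runs 500
cases in the acceptance test (200 in the unit test), a size at which every
rule path is hit many times over while the whole suite stays in seconds.
Frequency sweeps use grids of 1e-5 (gate, PM2) and 0.01 % (BA1) steps,
with grid values rounded to 8–10 decimals so that floating-point grid
construction lands exactly on the configured thresholds. Threshold
comparisons are `<=`/`>` exactly as the rule definitions state; no epsilon
is applied. Output row order is (chromosome in karyotype order, position,
ref, alt, gene), and all generated files are written in sorted order, so
identical inputs give byte-identical outputs.

## Known limitations

- Anchor-trim normalization can disagree with left-aligned databases in
  repeat regions (see above).
- Codon-level protein matching across transcripts can mis-pair records
  whose codon numbering differs between isoforms.
- Prediction scores are only available for the variants present in the
  prediction snapshot (real precomputed-score databases cover nonsilent
  SNVs only; indels rely on their protein-class rules instead).
- Patient-level reasoning (compound heterozygosity, de novo status,
  segregation) is out of scope by design: those ACMG criteria are
  manual-entry, and zygosity is reported only as opaque genotype columns.
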