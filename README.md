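# medaltriage

Rule-based triage and semi-automated ACMG/AMP classification of germline
variants in disease genes.

Exome or genome sequencing of a single individual yields millions of
variants, of which at most a handful are plausibly disease-causing in a
known predisposition gene. `medaltriage` implements the prioritization
funnel a clinical-genomics review committee applies before expert sign-out:

1. **Decompose and normalize** — VCF records (SNVs, indels, MNVs, complex
   substitutions) are split per ALT allele, anchor-trimmed, and keyed as
   `chrom:pos:ref>alt`; symbolic alleles are skipped and counted.
2. **Gene-panel filter** — only variants inside a disease-gene panel
   (cancer, cardiovascular, hematological, immunodeficiency, ALS, or
   custom) proceed.
3. **Functional filter with splice enhancement** — transcript consequences
   are consumed from an effect-predictor–style annotation table; silent and
   missense calls within a few bases of an exon edge are promoted to
   `splice_region` (such changes can disrupt splicing despite a benign
   protein-level annotation), then only coding and splice-related classes
   are retained. Silent variants are deliberately kept: in rare cases they
   are pathogenic splice variants.
4. **Frequency gate** — variants with ExAC non-TCGA allele frequency
   > 0.001 are set aside, unless rescued by an exact match to the IARC TP53
   database or to a ClinVar pathogenic/likely-pathogenic record with ≥ 2
   review stars (founder effects and reduced penetrance can push true
   pathogenic alleles above the cutoff). The gate is adjustable or can be
   disabled.
5. **Medal assignment** — each variant gets a germline medal
   (gold > silver > bronze > unknown) with a full audit trail of fired
   rules, and a separate somatic-context medal computed from somatic
   resources only:
   - *Gold*: truncating (nonsense/frameshift/splice) variant in a
     loss-of-function disease gene; exact match to a highly curated
     database (IARC TP53, ClinVar P/LP with ≥ 2 stars, TERT, MEN2, BIC,
     committee-reviewed P/LP); somatic hotspot codon (COSMIC ≥ 10 tumors,
     or curated pediatric-cohort hotspots); whitelisted keys.
   - *Silver*: in-frame indels; truncations in non-loss-of-function genes;
     predicted damaging in silico (REVEL ≥ 0.5 or a majority of
     algorithms); matches to lower-confidence databases; *imperfect*
     matches (same position different allele, or same codon different
     amino-acid change) to gold-tier databases.
   - *Bronze*: predicted tolerated (unless otherwise medaled); imperfect
     matches to silver-tier databases.
   - Blacklisted keys never medal; the highest granted medal wins.
6. **ACMG evidence tags and five-tier classification** — seven criteria are
   auto-tagged per their published definitions (PVS1, PM1, PM2 ≤ 0.0001,
   BA1 > 5 %, PM4, PS1, PM5); analysts may add or remove any of the 28
   codes, and the P / LP / VUS / LB / B call is recomputed from the
   standard evidence-combining rules, which ship as a reviewable data table
   (`src/medaltriage/data/acmg_combining_rules.tsv`).

All curated resources are consumed as versioned tab-delimited snapshot
files (curated calls, hotspot counts, population frequencies, prediction
scores); heterogeneous protein notations ("Ter", "Term", "*", "X", "Stop",
one- or three-letter codes, "=") and pathogenicity vocabularies are
standardized before comparison. A deterministic synthetic-data generator
(`medaltriage.fixtures`) produces a complete input suite plus a
ground-truth manifest computed by independently written rule oracles.

## Worked example

Generate the synthetic suite and run the pipeline:

```bash
medaltriage fixtures --seed 7 --out demo/suite
medaltriage run \
  --vcf demo/suite/suite.vcf --panel demo/suite/panel.tsv \
  --annotations demo/suite/annotations.tsv --exons demo/suite/exons.tsv \
  --kb demo/suite/kb --genes demo/suite/genes.tsv \
  --whitelist demo/suite/whitelist.txt --blacklist demo/suite/blacklist.txt \
  --out demo/out
```

The funnel summary (stderr) shows each processing step:

```
vcf_records         41
decomposed_variants 41
skipped_symbolic    1
panel_filtered      40
functional_retained 38
gate_passed         32
medaled             23
```

41 decomposed variants enter; one symbolic ALT is skipped; 40 fall in
panel genes, 38 survive the functional filter, 32 pass the frequency gate
(including whitelist and rescue exceptions), and 23 receive a medal.

The single-variant audit for the suite's nonsense truncation in the ETV6
tumor-suppressor gene:

```bash
medaltriage variant --vcf demo/suite/suite.vcf ... "12:41250:C>T"
```

```
gene              ETV6
consequence       nonsense
protein_change    R359*
germline_medal    GOLD
gate_status       passed
germline_reasons  truncating_in_lof_gene[nonsense in loss-of-function gene ETV6]
acmg_tags         PM2,PVS1
classification    LP
```

Read: a nonsense variant in a gene whose disease mechanism is loss of
function medals gold; it is absent from the reference population (PM2) and
truncating in a loss-of-function gene (PVS1), and one very-strong plus one
moderate criterion combine to *likely pathogenic*.

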