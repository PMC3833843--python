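# noveltx

Discovery and classification of **unknown transcripts** (UTs) from an
assembled RNA-seq transcriptome — the transfrags a merge of per-sample
assemblies produces that overlap no annotated or computationally predicted
gene. `noveltx` takes a merged assembly GTF, a reference annotation, an
ab-initio predicted-gene track, the genome FASTA, a per-transcript FPKM
table with 95% confidence bounds, and (optionally) tabular homology hits,
and assigns each unknown transcript one final category:

`novel_coding · amended_gene · utr_of_known_gene · potential_novel_gene ·
pseudogene · potential_pseudogene · lncRNA_conserved · lncRNA_candidate ·
lincRNA_candidate · short_ncRNA_candidate · ambiguous · inconsistent`

It is aimed at annotation and noncoding-RNA researchers working in species
with incomplete genome annotation (the motivating system is bovine skin),
where most long noncoding RNAs are still uncatalogued and a conservative,
fully accountable triage of novel transfrags is needed before laboratory
follow-up.

## The workflow

1. **Expression filter** — transcripts whose FPKM 95% CI lower bound is 0 in
   both conditions are dropped.
2. **Class codes** — each transcript gets a cuffcompare-style code versus
   the reference: `=` (identical intron chain), `j` (same-strand exonic
   overlap, potential novel isoform), `i` (fully intronic), `o` (antisense
   exonic overlap), `u` (unknown intergenic). Only class `u` continues.
3. **Predicted-locus subtraction** — any `u` transcript with ≥ 1 bp of
   exonic overlap with an ab-initio gene model is removed (conservative);
   the survivors are the UT set.
4. **Coding potential, two scorers intersected** — a CPAT-style logistic
   scorer over four alignment-free features (ORF length, ORF coverage,
   Fickett TESTCODE score, in-frame hexamer log-likelihood ratio) giving a
   probability *p*, and a CPC-like score *S* (externally supplied, or the
   built-in log-odds proxy). Categories use the published cuts —
   *S* ≥ 1 coding, *S* ≤ −0.5 noncoding; *p* ≥ 0.5 coding, *p* < 0.02
   noncoding — and agree (`coding`/`noncoding`/`ambiguous`) or are
   `inconsistent`.
5. **Homology screening and curation** — BLAST-outfmt-6-like hits are
   screened (interspecies: mapping identity ≥ 75%, total identity ≥ 90%,
   covered region ≥ 100 nt; intraspecies: both identities ≥ 90%), then
   curated (covered ≥ 150 nt at identity ≥ 75%, or the rescue rule:
   identity ≥ 90% over a shorter region) with a synteny check on shared
   flanking-gene symbols. Discordant flanking context plus coding-gene
   similarity triggers the pseudogene inference.
6. **Position and integration** — nearest annotated gene distance
   (span-to-span); lncRNA = noncoding consensus and length > 200 nt;
   UTR-associated = within 1 kb of a gene; lincRNA = lncRNA further than
   1 kb. Homology categories override the coding consensus; everything is
   logged in a per-transcript evidence trail and a run manifest whose
   category counts always partition the UT set.

A fully deterministic synthetic-data generator (`noveltx simulate`) builds a
toy genome with planted transcripts of every category — including
threshold-straddling decoy hits and zero-CI expression records — so the
entire pipeline is testable offline with known truth.

## Worked example

```bash
noveltx simulate --seed 4 --noiseless --outdir demo
noveltx classify \
    --assembly demo/assembly.gtf --reference demo/reference.gtf \
    --predicted demo/predicted.gtf --genome demo/genome.fa \
    --expression demo/expression.tsv \
    --inter-hits demo/hits_interspecies.tsv \
    --intra-hits demo/hits_intraspecies.tsv \
    --contexts demo/contexts.tsv \
    --seed 4 --outdir demo_out
```

prints

```
classified 150 unknown transcripts
  novel_coding: 25
  utr_of_known_gene: 25
  potential_pseudogene: 25
  lncRNA_conserved: 25
  lincRNA_candidate: 25
  short_ncRNA_candidate: 25
```

The simulation planted 200 transcripts, 25 per category. The 25 known
isoforms (class `j`) and 25 intronic transcripts (class `i`) are correctly
excluded before classification; the remaining 150 class-`u` transcripts
each recover their planted category: the codon-biased plants as novel
coding genes, the transcripts placed within 1 kb of a gene with a syntenic
coding-gene hit as UTR extensions, the gene copies with discordant flanking
context as potential pseudogenes, the plants with syntenic hits to lncRNA
database records as conserved lncRNAs, and the unconserved intergenic
noncoding plants as lincRNA (> 200 nt) or short-ncRNA candidates.
`demo_out/` contains the classified GTF, a per-transcript evidence table,
summary histograms (length, per-chromosome counts, nearest-gene distance),
Table-style accounting TSVs and the run manifest.

Every threshold is a flag (`--cpc-coding`, `--cpat-noncoding`,
`--lnc-min-len`, `--utr-dist`, `--min-covered`, …) or a key in a plain
`key = value` config file; the manifest records the set in force.

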