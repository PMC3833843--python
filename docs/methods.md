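# Methods

## Scope and model of the problem

`noveltx` classifies assembled transcripts that fall outside annotated and
predicted gene models. The procedure assumes: (i) transcript models and
their FPKM estimates (with 95% confidence bounds) come from an upstream
assembler/quantifier and are taken at face value; (ii) homology evidence
arrives as tabular pairwise-alignment hits produced by an external aligner
against curated RNA databases, with a companion table giving each subject's
flanking-gene context; (iii) coding potential can be assessed from sequence
alone. Read alignment, assembly, and running the aligner itself are out of
scope.

Coordinates are 0-based half-open internally and converted at the GTF
boundary (1-based inclusive). Transcripts on unplaced scaffolds are
classified normally and reported under their scaffold name. Strand-unknown
(`.`) single-exon transcripts — the common case for assembled monoexonic
transfrags — are extracted as plus-strand sequence and scored in both
orientations, keeping the more coding-like one; the evidence trail records
that the strand was unknown.

## Unknown-transcript isolation

The expression filter drops transcripts whose FPKM confidence interval has
a zero lower bound in *both* conditions; it is monotone in an optional
threshold parameter. Class codes reduce the full cuffcompare taxonomy to
the five codes the downstream workflow distinguishes (`=`, `j`, `i`, `o`,
`u`). For single-exon transcripts, `=` requires reciprocal exonic overlap
of at least 0.5 (parameter `single_exon_min_overlap`) on the same strand.
`u` requires no exonic overlap with any reference exon on either strand and
no containment in a reference intron. Subtraction of the predicted track
removes any transcript with ≥ 1 bp exonic overlap with a predicted exon,
strand-agnostic — deliberately the most conservative reading, so nothing
attributable to an ab-initio model survives.

## Coding potential

The CPAT-style scorer is a logistic regression over four features:

* longest ATG-anchored ORF length (nt, stop codon included);
* ORF coverage (ORF length / transcript length);
* Fickett TESTCODE score, computed from the published position-asymmetry
  and content lookup tables; the position parameter is the published
  max/(min+1) over the three codon positions (equal counts therefore give
  0.8, not 1.0);
* mean in-frame hexamer log-likelihood ratio log(f_coding/f_noncoding),
  counted with step 3 from the ORF start when an ORF exists and step 1 over
  the whole sequence otherwise; hexamer tables use a pseudocount of 1 so no
  ratio is undefined.

Features are standardised and the logistic fit uses weak regularisation
(C = 1000), matching the near-unregularised fits such scorers use in
practice; training is deterministic given the seed. The second scorer is
either an externally supplied CPC-S column (a real CPC run) or the built-in
proxy: the same four features, independently trained with a different
derived seed and stronger regularisation (C = 1), reported on the log-odds
scale so the published CPC cuts apply. The proxy is a designed component of
the offline pipeline, not a reimplementation of CPC's alignment-based SVM;
when real CPC scores exist they take precedence.

Thresholds are applied exactly as printed, including the inequality
directions: CPC coding iff S ≥ 1, noncoding iff S ≤ −0.5; CPAT coding iff
p ≥ 0.5, noncoding iff p < 0.02 (p = 0.02 is therefore ambiguous). A score
of S = −0.15 falls in the ambiguous band by these cuts even though one
published worked example labels such a transcript concordantly noncoding;
the package follows the printed thresholds and surfaces the case in its
test suite rather than special-casing it.

## Homology

Operational definitions (the source texts use the terms without defining
them): *mapping identity* = percent identity within the aligned region;
*total sequence identity* = mapping identity × covered region / query
length. Screening and curation use the published cut pairs; because total
identity ≥ 90% already forces mapping identity ≥ 90% and ≥ 90% query
coverage, every screened interspecies hit also satisfies the curation
similarity cuts when both stages are applied to the same hit table — in
the original procedure curation was a fresh reverse search, so the
redundancy is a property of the single-table setting, not of the rules.
The rescue rule (identity ≥ 90% over a region shorter than 150 nt) is
evaluated on mapping identity by default and is switchable to total
identity (`CurateThresholds.rescue_on`), since the source is ambiguous; the
screening floor of 100 nt is retained as the minimum covered region.

Synteny is ≥ 1 shared flanking-gene symbol between the query's and
subject's contexts (up to two genes per side); intraspecies hits require
identical adjacent loci on both sides. Hits without subject context are
marked uncurated, never silently passed. Crucially, similarity-passing hits
with *discordant* context are retained with a negative synteny verdict:
they are the evidence for the potential-pseudogene inference, which would
otherwise be unreachable.

Category assignment follows a fixed decision order per hit (known-lncRNA or
intergenic subject → conserved lncRNA; coding subject, syntenic, within
1 kb of an annotated gene → UTR of known gene; coding subject whose gene is
among the transcript's flanking genes → amended gene; coding subject,
syntenic, otherwise → potential novel gene; annotated-pseudogene subject →
pseudogene; coding subject, non-syntenic → potential pseudogene). When
curated hits disagree, the highest-total-identity hit decides (ties: longer
covered region, then subject id). The 1-kb UTR rule needs the
nearest-gene distance, which the positional module supplies explicitly.

## Position and integration

Nearest-neighbour distance is measured between locus-span boundaries
(gene-level, strand-agnostic), not exon boundaries; ties go to the upstream
(left) locus. lncRNA requires a noncoding consensus and length strictly
greater than 200 nt; UTR association means distance ≤ 1 kb; lincRNA is the
lncRNA set minus the UTR-associated set, exactly. During integration the
five curation-weighted homology categories override the coding consensus
(mirroring the manual reassignment of coding-predicted transcripts to
pseudogenes); conserved-lncRNA homology refines, but does not override, a
noncoding consensus. Ambiguous and inconsistent consensus pass through.
Summary outputs: length histogram (configurable bins), per-chromosome
counts, per-chromosome mean FPKM per condition restricted to transcripts
longer than 105 nt, nearest-gene distance histogram at 1-kb resolution
(configurable; the original figure's binning is not specified numerically),
and accounting tables whose marginals all equal the UT total.

## Synthetic data

The generator emulates the statistical structure the classifier assumes on
a two-chromosome, 500-kb-per-chromosome toy genome (GC 0.42): 30 reference
genes (three exons, 150–350 nt, introns 600–900 nt, codon-structured
coding sequence), 6 predicted two-exon genes placed disjoint from the
reference, and 25 plants in each of eight categories (200 total): known
isoform, intronic, intergenic noncoding, novel coding, UTR extension,
pseudogene copy, conserved lncRNA, short ncRNA. Features are laid out on a
least-filled-chromosome schedule with 2.5–4 kb gaps, so intergenic plants
are always > 1 kb from annotated genes while UTR-extension plants sit
300–800 nt downstream of their host gene. Noncoding plant lengths are
log-uniform on 300–2,000 nt (the dominant size range of such transcripts),
short ncRNAs 80–180 nt, coding plants 450–1,500 nt; 91% of plants are
single-exon and 30% of single-exon plants are strand-unknown, matching the
strong monoexonic bias of assembled transfrags.

Coding sequences are ATG-anchored, stop-terminated ORFs drawn from a biased
codon distribution (bias 1.0 ⇒ ~90% preferred codons) with short flanking
UTRs that scale with length. Noncoding sequences are i.i.d. draws
rejection-sampled until, in both orientations, no chance ORF exceeds 12% of
the length (floor 24 nt), the TESTCODE score stays ≤ 0.95 and there is no
in-frame hexamer enrichment against a fixed internal reference model —
planted noncoding transcripts are thereby clearly noncoding by design while
remaining compositionally random. The scorers are trained on unfiltered
corpora from the same designers, so the decision boundary is learned from
the full distribution and the certification never touches the fitted model.

Hit tables place identities and coverages around the decision cuts:
conserved-lncRNA plants get syntenic noncoding-database hits (identity
≥ 90%, full coverage), UTR plants syntenic coding-gene hits naming the host
gene, pseudogene copies coding-gene hits whose subject context is the
*source* gene's neighbourhood (hence discordant). Decoy hits straddle each
cut (total identity 89.9%, covered region 99 nt, and a similarity-passing
hit with discordant context); an intraspecies decoy sits below the 90%
screen. Expression is log-normal (μ=1.5, σ=1 on the log scale) with CI
bounds at 0.4×/1.8× FPKM; a configurable fraction of records (default 0.10)
gets a zero CI lower bound to exercise the expression filter. The
`noiseless` preset zeroes the noise knobs for exact truth-recovery
fixtures. Identical config and seed give byte-identical output files.

What passing on synthetic data does *not* show: performance on real
transcriptomes with positionally overlapping noise transfrags, fragmented
assemblies, expression-dependent assembly artefacts, or genuinely
borderline coding potential — the generator certifies its plants to be
separable, so end-to-end recovery measures the correctness of the decision
logic, not the discriminative power of the features on hard cases.

## Numerical and size choices

Test-suite and acceptance runs use the 200-plant fixture (~1 Mb genome);
a full simulation plus pipeline run takes a few seconds on one core, and
the whole suite runs in about a minute. Floating-point comparisons in
tests use relative tolerances via `pytest.approx`; the accounting layer is
integer-exact. Degenerate inputs are defined rather than accidental:
empty hit files parse to empty lists, an empty UT set yields all-zero
accounting tables, a chromosome without annotated genes yields an infinite
nearest-gene distance (binned into the histogram overflow), and sequences
shorter than one codon have no ORFs.

## Known limitations

* The CPC proxy shares its feature set with the CPAT-style scorer; on real
  data the two are therefore less independent than CPC and CPAT proper.
  Supplying a real CPC column restores full independence.
* Synteny uses flanking-gene *symbols*; it requires consistent symbol
  spaces between query and subject contexts, which the generator guarantees
  but real annotation pairs may not.
* Class codes are the five-code reduction; users needing the full
  cuffcompare taxonomy should run cuffcompare upstream and filter on `u`
  themselves.
* The amended-gene rule keys on the subject gene appearing among the
  transcript's flanking genes; a UT extending a gene whose ortholog is
  named differently in the two annotations will fall through to
  potential-novel-gene.
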