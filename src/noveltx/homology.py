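"""Homology-hit screening, curation and category assignment.

Consumes BLAST-outfmt-6-like tabular hits (12 standard columns plus
``subject_db`` and ``subject_species``) and a flanking-gene context table,
applies the two-stage threshold scheme (screening then curation with a
short-coverage rescue), checks synteny by shared flanking gene symbols, and
assigns each query a Table-3-style homology category.

Definitions: *mapping identity* is the percent identity within the aligned
region (``pident``); *total sequence identity* is mapping identity scaled by
query coverage, ``pident * covered_region / query_length``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

INTERSPECIES = "interspecies"
INTRASPECIES = "intraspecies"

#: Databases whose entries are treated as known lncRNA records.
LNC_DATABASES = frozenset(
    {"noncode", "lncipedia", "lincRNA-set", "rnadb", "lncrnadb"}
)

LNC_CONSERVED = "lncRNA_conserved"
AMENDED_GENE = "amended_gene"
UTR_OF_KNOWN = "utr_of_known_gene"
POTENTIAL_NOVEL = "potential_novel_gene"
PSEUDOGENE = "pseudogene"
POTENTIAL_PSEUDOGENE = "potential_pseudogene"
NO_HOMOLOGY = "none"

HOMOLOGY_CATEGORIES = (
    LNC_CONSERVED, AMENDED_GENE, UTR_OF_KNOWN, POTENTIAL_NOVEL,
    PSEUDOGENE, POTENTIAL_PSEUDOGENE, NO_HOMOLOGY,
)

_HIT_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen qstart qend sstart send "
    "evalue bitscore subject_db subject_species"
).split()

LOCUS_KINDS = ("coding_gene", "noncoding_gene", "intergenic", "pseudogene", "unknown")


@dataclass(frozen=True)
class HomologyHit:
    """One pairwise-alignment hit with subject annotation."""

    query_id: str
    subject_id: str
    subject_db: str
    subject_species: str
    percent_identity: float
    aligned_length: int
    query_length: int
    covered_region: int
    evalue: float = 0.0
    bitscore: float = 0.0
    subject_locus_kind: str = "unknown"
    subject_gene: str = ""

    def __post_init__(self):
        if not (0 < self.percent_identity <= 100):
            raise ValueError(
                f"{self.query_id}->{self.subject_id}: percent identity out of (0, 100]"
            )
        if self.covered_region > self.query_length:
            raise ValueError(
                f"{self.query_id}->{self.subject_id}: covered region "
                f"{self.covered_region} exceeds query length {self.query_length}"
            )
        if self.subject_locus_kind not in LOCUS_KINDS:
            raise ValueError(f"unknown subject_locus_kind {self.subject_locus_kind!r}")

    @property
    def mapping_identity(self) -> float:
        return self.percent_identity

    @property
    def total_identity(self) -> float:
        return self.percent_identity * self.covered_region / self.query_length

    @property
    def mode(self) -> str:
        return INTRASPECIES if self.subject_species == "bovine" else INTERSPECIES

    @property
    def is_lnc_subject(self) -> bool:
        return (
            self.subject_db in LNC_DATABASES
            or self.subject_locus_kind in ("noncoding_gene", "intergenic")
        )


@dataclass(frozen=True)
class LocusContext:
    """Flanking gene symbols around an entity's mapping position."""

    entity_id: str
    chrom: str
    upstream_genes: tuple = ()
    downstream_genes: tuple = ()
    locus_kind: str = "unknown"
    gene_symbol: str = ""

    @property
    def flanking(self) -> frozenset:
        return frozenset(self.upstream_genes) | frozenset(self.downstream_genes)


def read_hit_table(
    path,
    query_lengths: Mapping[str, int],
    contexts: Mapping[str, LocusContext] | None = None,
    max_evalue: float | None = 1e-11,
) -> list[HomologyHit]:
    """Parse a 14-column tab-separated hit file.

    Columns: the 12 BLAST outfmt-6 fields plus subject_db and
    subject_species. Covered region is the aligned span on the query
    (qend - qstart + 1, 1-based inclusive). Subject locus kind and gene
    symbol are joined in from ``contexts`` by subject_id when available.
    The aligner's e-value screen is re-checked when ``max_evalue`` is set.
    """
    contexts = contexts or {}
    hits: list[HomologyHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != len(_HIT_COLUMNS):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(_HIT_COLUMNS)} columns, "
                    f"got {len(fields)}"
                )
            row = dict(zip(_HIT_COLUMNS, fields))
            qid = row["qseqid"]
            if qid not in query_lengths:
                # query not in the analysis set (e.g. removed upstream)
                continue
            qstart, qend = int(row["qstart"]), int(row["qend"])
            covered = abs(qend - qstart) + 1
            evalue = float(row["evalue"])
            if max_evalue is not None and evalue > max_evalue:
                continue
            ctx = contexts.get(row["sseqid"])
            try:
                hits.append(
                    HomologyHit(
                        query_id=qid,
                        subject_id=row["sseqid"],
                        subject_db=row["subject_db"],
                        subject_species=row["subject_species"],
                        percent_identity=float(row["pident"]),
                        aligned_length=int(row["length"]),
                        query_length=int(query_lengths[qid]),
                        covered_region=covered,
                        evalue=evalue,
                        bitscore=float(row["bitscore"]),
                        subject_locus_kind=(
                            ctx.locus_kind if ctx is not None else "unknown"
                        ),
                        subject_gene=(
                            ctx.gene_symbol if ctx is not None else row["sseqid"]
                        ),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return hits


def read_context_table(path) -> dict[str, LocusContext]:
    """Read the flanking-gene context TSV: entity_id, chrom, upstream_gene,
    downstream_gene[, locus_kind, gene_symbol]; multiple symbols per side are
    comma-separated, '-' meaning explicitly none."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("-")
    required = {"entity_id", "chrom", "upstream_gene", "downstream_gene"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing context columns {sorted(missing)}")

    def _split(v: str) -> tuple:
        return tuple(s for s in v.split(",") if s and s != "-")

    out = {}
    for row in df.itertuples(index=False):
        out[row.entity_id] = LocusContext(
            entity_id=row.entity_id,
            chrom=row.chrom,
            upstream_genes=_split(row.upstream_gene),
            downstream_genes=_split(row.downstream_gene),
            locus_kind=getattr(row, "locus_kind", "unknown"),
            gene_symbol=getattr(row, "gene_symbol", "") or "",
        )
    return out


@dataclass(frozen=True)
class ScreenThresholds:
    inter_mapping: float = 75.0
    inter_total: float = 90.0
    intra_mapping: float = 90.0
    intra_total: float = 90.0
    min_covered: int = 100


def screen_hits(
    hits: Iterable[HomologyHit],
    thresholds: ScreenThresholds = ScreenThresholds(),
) -> list[HomologyHit]:
    """First-stage screen.

    Interspecies: mapping identity >= 75, total identity >= 90, covered
    region >= 100 nt. Intraspecies (bovine subjects): mapping and total
    identity both >= 90, covered >= 100 nt.
    """
    passing = []
    for h in hits:
        if h.covered_region < thresholds.min_covered:
            continue
        if h.mode == INTERSPECIES:
            ok = (
                h.mapping_identity >= thresholds.inter_mapping
                and h.total_identity >= thresholds.inter_total
            )
        else:
            ok = (
                h.mapping_identity >= thresholds.intra_mapping
                and h.total_identity >= thresholds.intra_total
            )
        if ok:
            passing.append(h)
    return passing


@dataclass(frozen=True)
class CurateThresholds:
    inter_min_covered: int = 150
    inter_identity: float = 75.0
    rescue_identity: float = 90.0
    intra_identity: float = 95.0
    #: rescue rule applies to "mapping" or "total" identity
    rescue_on: str = "mapping"


@dataclass(frozen=True)
class CurationResult:
    """Curation verdict for one hit: similarity thresholds and synteny are
    recorded separately, because a similarity-passing hit with discordant
    flanking context is the evidence for the pseudogene inference."""

    hit: HomologyHit
    similarity_pass: bool
    syntenic: bool
    has_context: bool
    rescued: bool = False

    @property
    def accepted(self) -> bool:
        """Accepted as conserved homology (similarity + synteny)."""
        return self.similarity_pass and self.syntenic and self.has_context


def _syntenic(query_ctx: LocusContext | None,
              subject_ctx: LocusContext | None,
              mode: str) -> tuple[bool, bool]:
    """(has_context, syntenic). Interspecies synteny: >= 1 shared flanking
    symbol; intraspecies: identical adjacent loci on both sides."""
    if query_ctx is None or subject_ctx is None:
        return False, False
    if not query_ctx.flanking or not subject_ctx.flanking:
        return False, False
    if mode == INTRASPECIES:
        same = (
            frozenset(query_ctx.upstream_genes) == frozenset(subject_ctx.upstream_genes)
            and frozenset(query_ctx.downstream_genes)
            == frozenset(subject_ctx.downstream_genes)
        )
        return True, same
    return True, bool(query_ctx.flanking & subject_ctx.flanking)


def curate_hits(
    hits: Iterable[HomologyHit],
    query_ctx: LocusContext | None,
    subject_contexts: Mapping[str, LocusContext],
    thresholds: CurateThresholds = CurateThresholds(),
) -> list[CurationResult]:
    """Second-stage curation of screened hits.

    Interspecies: covered >= 150 nt with identity >= 75, or the rescue rule
    (identity >= 90 over a shorter covered region). Intraspecies: identity
    >= 95 with identical adjacent loci. Hits without subject context are
    marked uncurated, never silently passed.
    """
    results = []
    for h in hits:
        sctx = subject_contexts.get(h.subject_id)
        has_ctx, syntenic = _syntenic(query_ctx, sctx, h.mode)
        rescued = False
        if h.mode == INTERSPECIES:
            rescue_metric = (
                h.mapping_identity if thresholds.rescue_on == "mapping"
                else h.total_identity
            )
            primary = (
                h.covered_region >= thresholds.inter_min_covered
                and h.mapping_identity >= thresholds.inter_identity
            )
            rescued = (
                not primary
                and rescue_metric >= thresholds.rescue_identity
                and h.covered_region < thresholds.inter_min_covered
            )
            sim = primary or rescued
        else:
            sim = h.mapping_identity >= thresholds.intra_identity
        results.append(
            CurationResult(
                hit=h, similarity_pass=sim, syntenic=syntenic,
                has_context=has_ctx, rescued=rescued,
            )
        )
    return results


def _hit_rank(c: CurationResult):
    h = c.hit
    return (-h.total_identity, -h.covered_region, h.subject_id)


def assign_homology_category(
    ut_id: str,
    curation: Iterable[CurationResult],
    query_ctx: LocusContext | None,
    neighbour_distance: float | None = None,
    utr_dist: float = 1000.0,
) -> str:
    """Table-3-style homology category for one unknown transcript.

    Decision order per hit: (1) lncRNA or intergenic subject, syntenic ->
    conserved lncRNA; (2) coding subject, syntenic, transcript within
    ``utr_dist`` of an annotated gene -> UTR of known gene; (3) coding
    subject, syntenic, subject gene among the transcript's flanking genes ->
    amended gene; (4) coding subject, syntenic otherwise -> potential novel
    gene; (5) annotated-pseudogene subject -> pseudogene; (6) coding
    subject with discordant adjacent gene context -> potential pseudogene;
    (7) otherwise none. When hits disagree the highest-total-identity hit
    wins (ties: longer covered region, then subject id).
    """
    flanking = query_ctx.flanking if query_ctx is not None else frozenset()
    candidates = sorted(
        (c for c in curation if c.similarity_pass), key=_hit_rank
    )
    for c in candidates:
        h = c.hit
        if h.is_lnc_subject and h.subject_locus_kind != "pseudogene":
            if c.syntenic:
                return LNC_CONSERVED
            continue
        if h.subject_locus_kind == "pseudogene":
            return PSEUDOGENE
        if h.subject_locus_kind == "coding_gene":
            if c.syntenic:
                if neighbour_distance is not None and neighbour_distance <= utr_dist:
                    return UTR_OF_KNOWN
                if h.subject_gene and h.subject_gene in flanking:
                    return AMENDED_GENE
                return POTENTIAL_NOVEL
            if c.has_context:
                return POTENTIAL_PSEUDOGENE
    return NO_HOMOLOGY
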