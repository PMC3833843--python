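"""Positional annotation and final category integration.

Each unknown transcript is annotated with its nearest annotated locus
(gene-span distance, strand-agnostic), flagged as lncRNA (>200 nt,
noncoding consensus), UTR-associated (within 1 kb of a gene) or lincRNA
(lncRNA further than 1 kb from any gene), and then integrated with the
coding consensus and homology category into one final class. Summary
tabulations mirror the descriptive reporting: length histogram,
per-chromosome counts and mean FPKM (restricted to transcripts > 105 nt),
nearest-gene distance histogram and category accounting tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import homology as hm
from .coding import AMBIGUOUS, CODING, INCONSISTENT, NONCODING, CodingAssessment
from .model import AnnotationIndex, ExpressionRecord, TranscriptModel

FINAL_CATEGORIES = (
    "novel_coding",
    "amended_gene",
    "utr_of_known_gene",
    "potential_novel_gene",
    "pseudogene",
    "potential_pseudogene",
    "lncRNA_conserved",
    "lncRNA_candidate",
    "lincRNA_candidate",
    "short_ncRNA_candidate",
    "ambiguous",
    "inconsistent",
)

#: Homology categories that override the coding consensus during integration
#: (mirrors the manual curation that reassigned coding-predicted transcripts
#: to pseudogenes).
OVERRIDING_HOMOLOGY = (
    hm.AMENDED_GENE, hm.UTR_OF_KNOWN, hm.POTENTIAL_NOVEL,
    hm.PSEUDOGENE, hm.POTENTIAL_PSEUDOGENE,
)


@dataclass(frozen=True)
class NeighbourAnnotation:
    """Nearest annotated locus: gap between closest span boundaries
    (0 if touching), direction relative to the transcript."""

    transcript_id: str
    nearest_locus_id: str | None
    distance_nt: float
    direction: str  # "upstream" (locus left of transcript) or "downstream"


def nearest_neighbour(
    ut: TranscriptModel, reference: AnnotationIndex
) -> NeighbourAnnotation:
    """Closest reference locus by span-boundary gap, strand-agnostic.

    Ties are broken toward the upstream (left) locus. With no reference
    locus on the transcript's chromosome the distance is infinite.
    """
    best = None  # (distance, prefer_downstream, locus_id, direction)
    for locus_id, span in reference.locus_spans().items():
        if span.chrom != ut.chrom:
            continue
        d = ut.span.gap_to(span)
        direction = "upstream" if span.start <= ut.start else "downstream"
        key = (d, direction == "downstream", locus_id)
        if best is None or key < best[0]:
            best = (key, locus_id, direction)
    if best is None:
        return NeighbourAnnotation(ut.transcript_id, None, math.inf, "upstream")
    (d, _, _), locus_id, direction = best
    return NeighbourAnnotation(ut.transcript_id, locus_id, float(d), direction)


@dataclass(frozen=True)
class LncFlags:
    is_lncRNA: bool
    is_lincRNA: bool
    is_utr_associated: bool


def call_lnc(
    consensus: str,
    spliced_length: int,
    neighbour: NeighbourAnnotation,
    min_len: int = 200,
    utr_dist: float = 1000.0,
) -> LncFlags:
    """lncRNA / lincRNA / UTR-association flags.

    lncRNA: noncoding consensus and length strictly > ``min_len`` (200 nt);
    UTR-associated: nearest-gene distance <= ``utr_dist`` (1 kb); lincRNA:
    lncRNA lying further than ``utr_dist`` from any annotated gene.
    """
    is_utr = neighbour.distance_nt <= utr_dist
    is_lnc = consensus == NONCODING and spliced_length > min_len
    return LncFlags(
        is_lncRNA=is_lnc,
        is_lincRNA=is_lnc and not is_utr,
        is_utr_associated=is_utr,
    )


@dataclass
class ClassifiedTranscript:
    """Final per-transcript classification with its full evidence trail."""

    transcript: TranscriptModel
    assessment: CodingAssessment
    homology_category: str
    neighbour: NeighbourAnnotation
    flags: LncFlags
    final_category: str = ""
    evidence: list = field(default_factory=list)

    @property
    def transcript_id(self) -> str:
        return self.transcript.transcript_id


def integrate(
    consensus: str,
    homology_category: str,
    flags: LncFlags,
) -> tuple[str, list[str]]:
    """Resolve the final category; returns (category, fired rules).

    Homology categories carry manual-curation weight and override the coding
    consensus; otherwise a coding consensus yields a novel coding candidate
    and a noncoding consensus is refined by conservation and position into
    conserved lncRNA / lincRNA / lncRNA / short ncRNA candidates. Ambiguous
    and inconsistent consensus pass through.
    """
    trail: list[str] = []
    if homology_category in OVERRIDING_HOMOLOGY:
        trail.append(f"homology_override:{homology_category}")
        return homology_category, trail
    if consensus == CODING:
        trail.append("consensus_coding->novel_coding")
        return "novel_coding", trail
    if consensus == NONCODING:
        if homology_category == hm.LNC_CONSERVED:
            trail.append("noncoding+conserved_lnc_hit->lncRNA_conserved")
            return "lncRNA_conserved", trail
        if flags.is_lincRNA:
            trail.append("noncoding+intergenic(>utr_dist)->lincRNA_candidate")
            return "lincRNA_candidate", trail
        if flags.is_lncRNA:
            trail.append("noncoding+len>200+near_gene->lncRNA_candidate")
            return "lncRNA_candidate", trail
        trail.append("noncoding+len<=200->short_ncRNA_candidate")
        return "short_ncRNA_candidate", trail
    if consensus in (AMBIGUOUS, INCONSISTENT):
        trail.append(f"consensus_passthrough:{consensus}")
        return consensus, trail
    raise ValueError(f"unknown consensus {consensus!r}")


def classify_transcript(
    transcript: TranscriptModel,
    assessment: CodingAssessment,
    homology_category: str,
    neighbour: NeighbourAnnotation,
    min_len: int = 200,
    utr_dist: float = 1000.0,
) -> ClassifiedTranscript:
    flags = call_lnc(
        assessment.consensus, transcript.spliced_length, neighbour,
        min_len=min_len, utr_dist=utr_dist,
    )
    final, trail = integrate(assessment.consensus, homology_category, flags)
    if transcript.strand == ".":
        trail.append("strand_unknown:plus_strand_sequence_used")
    return ClassifiedTranscript(
        transcript=transcript,
        assessment=assessment,
        homology_category=homology_category,
        neighbour=neighbour,
        flags=flags,
        final_category=final,
        evidence=trail,
    )


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

#: Transcripts at or below this length are excluded from the per-chromosome
#: mean-expression summary (descriptive "size > 105 bp" filter).
MIN_LEN_FOR_EXPRESSION_SUMMARY = 105


def length_histogram(
    lengths: Iterable[int], bin_edges: Iterable[float] | None = None
) -> pd.DataFrame:
    lengths = np.asarray(list(lengths), dtype=float)
    if bin_edges is None:
        bin_edges = [0, 200, 500, 1000, 2000, 5000, np.inf]
    edges = np.asarray(list(bin_edges), dtype=float)
    counts, _ = np.histogram(lengths, bins=edges)
    return pd.DataFrame(
        {"bin_low": edges[:-1], "bin_high": edges[1:], "count": counts}
    )


def distance_histogram(
    distances: Iterable[float], bin_width: float = 1000.0, max_dist: float = 20000.0
) -> pd.DataFrame:
    """Nearest-gene distance histogram at 1-kb resolution; the last bin
    collects everything beyond ``max_dist`` (including chromosomes with no
    annotated gene)."""
    d = np.asarray(list(distances), dtype=float)
    edges = np.arange(0.0, max_dist + bin_width, bin_width)
    counts, _ = np.histogram(np.clip(d, 0, max_dist - 1e-9), bins=edges)
    df = pd.DataFrame(
        {"bin_low": edges[:-1], "bin_high": edges[1:], "count": counts}
    )
    overflow = int((d >= max_dist).sum())
    df.loc[len(df)] = [max_dist, np.inf, overflow]
    return df


def summarize(
    classified: Iterable[ClassifiedTranscript],
    expression: Mapping[str, ExpressionRecord] | None = None,
    length_bins: Iterable[float] | None = None,
    dist_bin: float = 1000.0,
) -> dict[str, pd.DataFrame]:
    """Descriptive report bundle.

    Returns length histogram, per-chromosome counts, per-chromosome mean
    FPKM per condition over transcripts longer than 105 nt, nearest-gene
    distance histogram, and the final-category count table (marginal equals
    the input size).
    """
    classified = list(classified)
    if not classified:
        raise ValueError("cannot summarize an empty classified set")
    lengths = [c.transcript.spliced_length for c in classified]
    chroms = [c.transcript.chrom for c in classified]
    out: dict[str, pd.DataFrame] = {}
    out["length_hist"] = length_histogram(lengths, length_bins)
    out["per_chrom_counts"] = (
        pd.Series(chroms).value_counts().sort_index().rename("count")
        .rename_axis("chrom").reset_index()
    )
    out["distance_hist"] = distance_histogram(
        [c.neighbour.distance_nt for c in classified], bin_width=dist_bin
    )
    cat_counts = pd.Series(
        [c.final_category for c in classified]
    ).value_counts()
    out["category_counts"] = (
        cat_counts.reindex(FINAL_CATEGORIES, fill_value=0)
        .rename("count").rename_axis("final_category").reset_index()
    )
    if expression is not None:
        rows = []
        for c in classified:
            if c.transcript.spliced_length <= MIN_LEN_FOR_EXPRESSION_SUMMARY:
                continue
            rec = expression.get(c.transcript_id)
            if rec is None:
                continue
            rows.append(
                {
                    "chrom": c.transcript.chrom,
                    "fpkm_pigmented": rec.fpkm["pigmented"],
                    "fpkm_nonpigmented": rec.fpkm["nonpigmented"],
                }
            )
        if rows:
            out["per_chrom_mean_fpkm"] = (
                pd.DataFrame(rows).groupby("chrom").mean().reset_index()
            )
        else:
            out["per_chrom_mean_fpkm"] = pd.DataFrame(
                columns=["chrom", "fpkm_pigmented", "fpkm_nonpigmented"]
            )
    return out


def classification_table(
    classified: Iterable[ClassifiedTranscript],
) -> pd.DataFrame:
    """One row per transcript with every evidence column."""
    rows = []
    for c in sorted(classified, key=lambda c: c.transcript_id):
        rows.append(
            {
                "transcript_id": c.transcript_id,
                "chrom": c.transcript.chrom,
                "start": c.transcript.start,
                "end": c.transcript.end,
                "strand": c.transcript.strand,
                "n_exons": c.transcript.n_exons,
                "length": c.transcript.spliced_length,
                "cpc_s": c.assessment.cpc_s,
                "cpat_p": c.assessment.cpat_p,
                "cat_cpc": c.assessment.cat_cpc,
                "cat_cpat": c.assessment.cat_cpat,
                "consensus": c.assessment.consensus,
                "homology_category": c.homology_category,
                "nearest_locus": c.neighbour.nearest_locus_id or "-",
                "distance_nt": c.neighbour.distance_nt,
                "direction": c.neighbour.direction,
                "is_lncRNA": c.flags.is_lncRNA,
                "is_lincRNA": c.flags.is_lincRNA,
                "is_utr_associated": c.flags.is_utr_associated,
                "final_category": c.final_category,
                "evidence": ";".join(c.evidence),
            }
        )
    return pd.DataFrame(rows)
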