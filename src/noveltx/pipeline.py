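"""End-to-end orchestration: unknown-transcript isolation, coding-potential
consensus, homology curation, positional integration, and the bookkeeping
tables (per-tool / intersection coding counts, homology category counts).

Every run records a :class:`RunManifest` with the counts at each stage and
the threshold set in force, so results are fully accountable: stage counts
are non-increasing through the filtering chain and the final categories
partition the unknown-transcript set.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import pyfaidx

from . import __version__
from .coding import (
    AMBIGUOUS, CODING, INCONSISTENT, NONCODING,
    CodingThresholds, assess_transcripts, train_coding_model, train_cpc_proxy,
)
from .homology import (
    HOMOLOGY_CATEGORIES, NO_HOMOLOGY, CurateThresholds, LocusContext,
    ScreenThresholds, assign_homology_category, curate_hits,
    read_context_table, read_hit_table, screen_hits,
)
from .model import (
    AnnotationIndex, TranscriptModel, read_expression_table, read_gtf,
    spliced_sequence, write_gtf,
)
from .novelty import assign_class_codes, filter_low_expression, subtract_predicted
from .positional import (
    FINAL_CATEGORIES, classification_table, classify_transcript,
    nearest_neighbour, summarize,
)
from .simulate import training_corpus

logger = logging.getLogger("noveltx")

PER_TOOL_CATEGORIES = (CODING, NONCODING, AMBIGUOUS)
INTERSECTION_CATEGORIES = (CODING, NONCODING, AMBIGUOUS, INCONSISTENT)


@dataclass
class PipelineInputs:
    assembly_gtf: str
    reference_gtf: str
    predicted_gtf: str
    genome_fasta: str
    expression_tsv: str
    inter_hits_tsv: str | None = None
    intra_hits_tsv: str | None = None
    contexts_tsv: str | None = None
    external_scores_tsv: str | None = None

    def required_paths(self) -> dict[str, str]:
        return {
            "assembly_gtf": self.assembly_gtf,
            "reference_gtf": self.reference_gtf,
            "predicted_gtf": self.predicted_gtf,
            "genome_fasta": self.genome_fasta,
            "expression_tsv": self.expression_tsv,
        }


@dataclass
class PipelineOptions:
    thresholds: CodingThresholds = field(default_factory=CodingThresholds)
    screen: ScreenThresholds = field(default_factory=ScreenThresholds)
    curate: CurateThresholds = field(default_factory=CurateThresholds)
    lnc_min_len: int = 200
    utr_dist: float = 1000.0
    single_exon_min_overlap: float = 0.5
    seed: int = 0


@dataclass
class RunManifest:
    """Bookkeeping record of one classification run."""

    inputs: dict
    thresholds: dict
    seed: int
    version: str
    counts: dict = field(default_factory=dict)
    per_tool_counts: dict = field(default_factory=dict)
    intersection_counts: dict = field(default_factory=dict)
    homology_counts: dict = field(default_factory=dict)
    final_counts: dict = field(default_factory=dict)

    def validate(self) -> None:
        c = self.counts
        chain = [c["input"], c["post_expression_filter"], c["class_u"],
                 c["post_subtraction"]]
        if any(a < b for a, b in zip(chain, chain[1:])):
            raise ValueError("stage counts must be non-increasing")
        if sum(self.final_counts.values()) != c["post_subtraction"]:
            raise ValueError("final categories must partition the UT set")

    def to_text(self) -> str:
        lines = [f"noveltx_version = {self.version}", f"seed = {self.seed}"]
        for k, v in self.inputs.items():
            lines.append(f"input.{k} = {v}")
        for k, v in self.thresholds.items():
            lines.append(f"threshold.{k} = {v}")
        for section, d in (
            ("count", self.counts),
            ("per_tool", {f"{t}.{c}": n for t, cc in self.per_tool_counts.items()
                          for c, n in cc.items()}),
            ("intersection", self.intersection_counts),
            ("homology", self.homology_counts),
            ("final", self.final_counts),
        ):
            for k, v in d.items():
                lines.append(f"{section}.{k} = {v}")
        return "\n".join(lines) + "\n"


def flanking_context(
    ut: TranscriptModel, reference: AnnotationIndex, n_flank: int = 2
) -> LocusContext:
    """Query-side adjacent-gene context: up to ``n_flank`` nearest annotated
    loci on each side of the transcript, by locus-span position."""
    left, right = [], []
    for locus_id, span in reference.locus_spans().items():
        if span.chrom != ut.chrom:
            continue
        if span.start <= ut.start:
            left.append((span.end, locus_id))
        else:
            right.append((span.start, locus_id))
    left.sort(reverse=True)
    right.sort()
    return LocusContext(
        entity_id=ut.transcript_id,
        chrom=ut.chrom,
        upstream_genes=tuple(l for _, l in left[:n_flank]),
        downstream_genes=tuple(l for _, l in right[:n_flank]),
    )


def _read_external_scores(path) -> tuple[dict, dict]:
    df = pd.read_csv(path, sep="\t")
    if "transcript_id" not in df.columns or "cpc_s" not in df.columns:
        raise ValueError(f"{path}: needs transcript_id and cpc_s columns")
    cpc = dict(zip(df["transcript_id"], df["cpc_s"].astype(float)))
    cpat = (
        dict(zip(df["transcript_id"], df["cpat_p"].astype(float)))
        if "cpat_p" in df.columns else {}
    )
    return cpc, cpat


def run_classify(
    inputs: PipelineInputs,
    options: PipelineOptions = PipelineOptions(),
    outdir=None,
):
    """Run the full classification workflow.

    Returns (manifest, classified transcripts, summary tables). With
    ``outdir`` set, also writes the classified GTF, the per-transcript
    evidence TSV, summary/accounting TSVs and the manifest.
    """
    for name, path in inputs.required_paths().items():
        if not Path(path).exists():
            raise FileNotFoundError(f"{name}: {path} does not exist")

    logger.info("reading annotation and assembly")
    assembly = read_gtf(inputs.assembly_gtf, "assembly")
    reference = AnnotationIndex(read_gtf(inputs.reference_gtf, "reference"))
    predicted = AnnotationIndex(read_gtf(inputs.predicted_gtf, "predicted"))
    expression = read_expression_table(inputs.expression_tsv)
    genome = pyfaidx.Fasta(inputs.genome_fasta)

    # stage 1: expression-CI filter
    expressed = filter_low_expression(assembly, expression)
    logger.info("expression filter: %d -> %d", len(assembly), len(expressed))

    # stage 2: class codes vs reference; keep unknown-intergenic ("u")
    codes = assign_class_codes(
        expressed, reference, options.single_exon_min_overlap
    )
    code_counts: dict[str, int] = {}
    for c in codes.values():
        code_counts[c] = code_counts.get(c, 0) + 1
    uts = [t for t in expressed if codes[t.transcript_id] == "u"]

    # stage 3: predicted-locus subtraction
    retained, removed = subtract_predicted(uts, predicted)
    logger.info("class u: %d; predicted-matching removed: %d; UTs: %d",
                len(uts), len(removed), len(retained))

    # stage 4: coding potential
    sequences = {t.transcript_id: spliced_sequence(t, genome) for t in retained}
    strands_of = {
        t.transcript_id: "both" for t in retained if t.strand == "."
    }
    external_cpc = external_cpat = None
    if inputs.external_scores_tsv:
        external_cpc, external_cpat = _read_external_scores(
            inputs.external_scores_tsv
        )
    coding_seqs, noncoding_seqs = training_corpus(options.seed)
    cpat_scorer = train_coding_model(coding_seqs, noncoding_seqs, seed=options.seed)
    cpc_scorer = (
        None if external_cpc is not None
        else train_cpc_proxy(coding_seqs, noncoding_seqs, seed=options.seed)
    )
    assessments = assess_transcripts(
        sequences,
        cpat_scorer=cpat_scorer,
        cpc_scorer=cpc_scorer,
        external_cpc=external_cpc,
        thresholds=options.thresholds,
        strands_of=strands_of,
    )
    if external_cpat:
        # re-derive assessments with externally supplied CPAT probabilities
        from .coding import CodingAssessment
        for tx_id, a in list(assessments.items()):
            if tx_id in external_cpat:
                assessments[tx_id] = CodingAssessment.from_scores(
                    tx_id, a.cpc_s, external_cpat[tx_id], options.thresholds
                )

    # stage 5: homology screening / curation
    contexts = (
        read_context_table(inputs.contexts_tsv) if inputs.contexts_tsv else {}
    )
    query_lengths = {tid: len(s) for tid, s in sequences.items()}
    hits = []
    for path in (inputs.inter_hits_tsv, inputs.intra_hits_tsv):
        if path:
            hits.extend(read_hit_table(path, query_lengths, contexts))
    screened = screen_hits(hits, options.screen)
    hits_by_query: dict[str, list] = {}
    for h in screened:
        hits_by_query.setdefault(h.query_id, []).append(h)

    # stage 6: positional annotation and integration
    classified = []
    for t in retained:
        neighbour = nearest_neighbour(t, reference)
        qctx = flanking_context(t, reference)
        curation = curate_hits(
            hits_by_query.get(t.transcript_id, []), qctx, contexts,
            options.curate,
        )
        hom_cat = assign_homology_category(
            t.transcript_id, curation, qctx,
            neighbour_distance=neighbour.distance_nt,
            utr_dist=options.utr_dist,
        )
        c = classify_transcript(
            t, assessments[t.transcript_id], hom_cat, neighbour,
            min_len=options.lnc_min_len, utr_dist=options.utr_dist,
        )
        for rule in c.evidence:
            logger.debug("%s: %s", t.transcript_id, rule)
        classified.append(c)

    # bookkeeping
    per_tool = {
        "cpc": {c: 0 for c in PER_TOOL_CATEGORIES},
        "cpat": {c: 0 for c in PER_TOOL_CATEGORIES},
    }
    intersection = {c: 0 for c in INTERSECTION_CATEGORIES}
    for a in assessments.values():
        per_tool["cpc"][a.cat_cpc] += 1
        per_tool["cpat"][a.cat_cpat] += 1
        intersection[a.consensus] += 1
    homology_counts = {c: 0 for c in HOMOLOGY_CATEGORIES}
    final_counts = {c: 0 for c in FINAL_CATEGORIES}
    for c in classified:
        homology_counts[c.homology_category] += 1
        final_counts[c.final_category] += 1

    manifest = RunManifest(
        inputs={k: str(v) for k, v in asdict(inputs).items() if v},
        thresholds={
            **{f"coding.{k}": v for k, v in asdict(options.thresholds).items()},
            **{f"screen.{k}": v for k, v in asdict(options.screen).items()},
            **{f"curate.{k}": v for k, v in asdict(options.curate).items()},
            "lnc_min_len": options.lnc_min_len,
            "utr_dist": options.utr_dist,
            "single_exon_min_overlap": options.single_exon_min_overlap,
        },
        seed=options.seed,
        version=__version__,
        counts={
            "input": len(assembly),
            "post_expression_filter": len(expressed),
            **{f"class_{c}": code_counts.get(c, 0) for c in "=jiou" if c != "u"},
            "class_u": len(uts),
            "predicted_matching": len(removed),
            "post_subtraction": len(retained),
        },
        per_tool_counts=per_tool,
        intersection_counts=intersection,
        homology_counts=homology_counts,
        final_counts=final_counts,
    )
    manifest.validate()

    summaries = (
        summarize(classified, expression) if classified else {}
    )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        extra = {
            c.transcript_id: {
                "final_category": c.final_category,
                "cpc_s": f"{c.assessment.cpc_s:.3f}",
                "cpat_p": f"{c.assessment.cpat_p:.4f}",
            }
            for c in classified
        }
        write_gtf([c.transcript for c in classified],
                  outdir / "classified.gtf", extra)
        classification_table(classified).to_csv(
            outdir / "classification.tsv", sep="\t", index=False
        )
        for name, df in summaries.items():
            df.to_csv(outdir / f"summary_{name}.tsv", sep="\t", index=False)
        for name, df in tabulate_accounting(manifest).items():
            df.to_csv(outdir / f"table_{name}.tsv", sep="\t", index=False)
        (outdir / "manifest.txt").write_text(manifest.to_text())

    return manifest, classified, summaries


# ---------------------------------------------------------------------------
# accounting
# ---------------------------------------------------------------------------

def intersection_summary(intersection_counts: dict) -> dict:
    """Identities over the two-tool intersection counts.

    Concordant = identically categorised by both tools (coding + noncoding +
    ambiguous); together with the inconsistent count this partitions the
    unknown-transcript total.
    """
    coding = intersection_counts[CODING]
    noncoding = intersection_counts[NONCODING]
    ambiguous = intersection_counts[AMBIGUOUS]
    inconsistent = intersection_counts[INCONSISTENT]
    concordant = coding + noncoding + ambiguous
    total = concordant + inconsistent
    return {
        "total": total,
        "concordant": concordant,
        "inconsistent": inconsistent,
        "concordant_pct": 100.0 * concordant / total if total else 0.0,
    }


def percentage(part: float, whole: float) -> float:
    return 100.0 * part / whole if whole else 0.0


def tabulate_accounting(manifest: RunManifest) -> dict[str, pd.DataFrame]:
    """Table-2/Table-3-style accounting from a run manifest.

    Coding table: one row per tool plus the intersection row; each row's
    marginal sums to the UT total. Homology table: curated category counts;
    'none' completes the partition.
    """
    total = manifest.counts["post_subtraction"]
    rows = []
    for tool in ("cpc", "cpat"):
        cc = manifest.per_tool_counts[tool]
        rows.append(
            {"predictor": tool, CODING: cc[CODING], NONCODING: cc[NONCODING],
             AMBIGUOUS: cc[AMBIGUOUS], INCONSISTENT: 0,
             "total": sum(cc.values())}
        )
    ic = manifest.intersection_counts
    rows.append(
        {"predictor": "intersection", CODING: ic[CODING],
         NONCODING: ic[NONCODING], AMBIGUOUS: ic[AMBIGUOUS],
         INCONSISTENT: ic[INCONSISTENT], "total": sum(ic.values())}
    )
    coding_df = pd.DataFrame(rows)
    if not (coding_df["total"] == total).all():
        raise ValueError("coding-table marginals must sum to the UT total")
    hom_rows = [
        {"category": cat, "count": manifest.homology_counts.get(cat, 0)}
        for cat in HOMOLOGY_CATEGORIES
    ]
    hom_df = pd.DataFrame(hom_rows)
    if hom_df["count"].sum() != total:
        raise ValueError("homology-table marginal must sum to the UT total")
    conserved = total - manifest.homology_counts.get(NO_HOMOLOGY, 0)
    hom_df.attrs["conserved_total"] = conserved
    hom_df.attrs["conserved_pct"] = percentage(conserved, total)
    final_df = pd.DataFrame(
        [{"category": c, "count": n} for c, n in manifest.final_counts.items()]
    )
    return {"coding_potential": coding_df, "homology": hom_df,
            "final_categories": final_df}
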