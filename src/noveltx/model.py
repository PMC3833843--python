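"""Core genomic data types and GTF/FASTA input-output.

Coordinates are 0-based half-open internally; GTF I/O converts to and from
the standard 1-based inclusive dialect. A :class:`TranscriptModel` is a
stranded chain of exons on a single chromosome; an :class:`AnnotationIndex`
provides interval lookups over exons and over locus spans, backed by
interval trees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd
from Bio.Seq import Seq
from gffutils.feature import feature_from_line
from intervaltree import IntervalTree

VALID_STRANDS = ("+", "-", ".")

#: Expression-table conditions, in column order (pigmented vs nonpigmented skin).
CONDITIONS = ("pigmented", "nonpigmented")


class GtfParseError(ValueError):
    """Raised for a malformed GTF line; message names the line number."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not self.start < self.end:
            raise ValueError(f"start must be < end, got [{self.start}, {self.end})")
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be one of {VALID_STRANDS}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and max(self.start, other.start) < min(self.end, other.end)
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def gap_to(self, other: "GenomicInterval") -> int:
        """Gap in nt between closest boundaries; 0 if touching or overlapping."""
        if self.chrom != other.chrom:
            raise ValueError("gap undefined across chromosomes")
        if self.overlaps(other):
            return 0
        return max(self.start, other.start) - min(self.end, other.end)


@dataclass(frozen=True)
class TranscriptModel:
    """A stranded multi-exon transcript.

    Exons are sorted by start, non-overlapping, and share one chromosome and
    strand. ``source`` tags the annotation track of origin (``assembly``,
    ``reference`` or ``predicted``).
    """

    transcript_id: str
    locus_id: str
    exons: tuple
    source: str = "assembly"

    def __post_init__(self):
        exons = tuple(sorted(self.exons, key=lambda e: (e.start, e.end)))
        object.__setattr__(self, "exons", exons)
        if len(exons) < 1:
            raise ValueError(f"{self.transcript_id}: transcript needs >= 1 exon")
        chroms = {e.chrom for e in exons}
        strands = {e.strand for e in exons}
        if len(chroms) > 1:
            raise ValueError(f"{self.transcript_id}: exons on multiple chromosomes")
        if len(strands) > 1:
            raise ValueError(f"{self.transcript_id}: exons on mixed strands")
        for a, b in zip(exons, exons[1:]):
            if b.start < a.end:
                raise ValueError(f"{self.transcript_id}: overlapping exons")

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    @property
    def spliced_length(self) -> int:
        return sum(e.length for e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def introns(self) -> tuple:
        return tuple(
            GenomicInterval(self.chrom, a.end, b.start, self.strand)
            for a, b in zip(self.exons, self.exons[1:])
            if b.start > a.end
        )

    @property
    def intron_chain(self) -> tuple:
        """Ordered (donor, acceptor) coordinate pairs; empty for single-exon."""
        return tuple((a.end, b.start) for a, b in zip(self.exons, self.exons[1:]))


class AnnotationIndex:
    """Interval index over a transcript set: per-chromosome trees over exons
    and over locus spans, plus locus grouping."""

    def __init__(self, transcripts: Iterable[TranscriptModel]):
        self.transcripts: dict[str, TranscriptModel] = {}
        self.loci: dict[str, list[TranscriptModel]] = {}
        self._exon_trees: dict[str, IntervalTree] = {}
        self._locus_trees: dict[str, IntervalTree] = {}
        for t in sorted(transcripts, key=lambda t: t.transcript_id):
            if t.transcript_id in self.transcripts:
                raise ValueError(f"duplicate transcript_id {t.transcript_id}")
            self.transcripts[t.transcript_id] = t
            self.loci.setdefault(t.locus_id, []).append(t)
            tree = self._exon_trees.setdefault(t.chrom, IntervalTree())
            for e in t.exons:
                tree.addi(e.start, e.end, t.transcript_id)
        self._locus_spans: dict[str, GenomicInterval] = {}
        for locus_id, ts in self.loci.items():
            chrom = ts[0].chrom
            span = GenomicInterval(
                chrom, min(t.start for t in ts), max(t.end for t in ts)
            )
            self._locus_spans[locus_id] = span
            self._locus_trees.setdefault(chrom, IntervalTree()).addi(
                span.start, span.end, locus_id
            )

    def __len__(self) -> int:
        return len(self.transcripts)

    def locus_span(self, locus_id: str) -> GenomicInterval:
        return self._locus_spans[locus_id]

    def locus_spans(self) -> dict[str, GenomicInterval]:
        return dict(self._locus_spans)

    def overlapping_exons(
        self, chrom: str, start: int, end: int
    ) -> set[str]:
        """Transcript ids with >= 1 bp of exonic overlap with [start, end)."""
        tree = self._exon_trees.get(chrom)
        if tree is None:
            return set()
        return {iv.data for iv in tree.overlap(start, end)}

    def overlapping_loci(self, interval: GenomicInterval) -> set[str]:
        """Locus ids whose span intersects the query interval."""
        tree = self._locus_trees.get(interval.chrom)
        if tree is None:
            return set()
        return {iv.data for iv in tree.overlap(interval.start, interval.end)}

    def exonic_overlap_transcripts(self, t: TranscriptModel) -> set[str]:
        """Indexed transcripts sharing >= 1 bp of exonic sequence with ``t``."""
        hits: set[str] = set()
        for e in t.exons:
            hits |= self.overlapping_exons(t.chrom, e.start, e.end)
        return hits


@dataclass(frozen=True)
class ExpressionRecord:
    """FPKM with 95% confidence bounds in the two skin conditions."""

    transcript_id: str
    fpkm: Mapping[str, float] = field(default_factory=dict)
    ci_low: Mapping[str, float] = field(default_factory=dict)
    ci_high: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for cond in self.fpkm:
            f, lo, hi = self.fpkm[cond], self.ci_low[cond], self.ci_high[cond]
            if not (0 <= lo <= f <= hi):
                raise ValueError(
                    f"{self.transcript_id}/{cond}: need 0 <= ci_low <= fpkm <= ci_high,"
                    f" got ({lo}, {f}, {hi})"
                )

    def max_ci_low(self) -> float:
        return max(self.ci_low.values()) if self.ci_low else 0.0


def read_gtf(path, source_label: str = "assembly") -> list[TranscriptModel]:
    """Read exon features from a GTF file into transcript models.

    Only ``exon`` rows are used; exons are grouped by the mandatory
    ``transcript_id`` attribute, ``gene_id`` (falling back to transcript_id)
    names the locus. Output is sorted by transcript_id.
    """
    exons_by_tx: dict[str, list[GenomicInterval]] = {}
    locus_of: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.count("\t") != 8:
                raise GtfParseError(f"{path}:{lineno}: expected 9 tab-separated columns")
            try:
                feat = feature_from_line(line)
            except Exception as exc:  # gffutils raises assorted types
                raise GtfParseError(f"{path}:{lineno}: {exc}") from exc
            if feat.featuretype != "exon":
                continue
            try:
                tx_id = feat.attributes["transcript_id"][0]
            except KeyError:
                raise GtfParseError(
                    f"{path}:{lineno}: exon line lacks transcript_id attribute"
                )
            gene_id = feat.attributes.get("gene_id", [tx_id])[0]
            strand = feat.strand if feat.strand in VALID_STRANDS else "."
            try:
                iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end, strand)
            except ValueError as exc:
                raise GtfParseError(f"{path}:{lineno}: {exc}") from exc
            exons_by_tx.setdefault(tx_id, []).append(iv)
            locus_of[tx_id] = gene_id
    out = []
    for tx_id in sorted(exons_by_tx):
        out.append(
            TranscriptModel(
                transcript_id=tx_id,
                locus_id=locus_of[tx_id],
                exons=tuple(exons_by_tx[tx_id]),
                source=source_label,
            )
        )
    return out


def _fmt_attributes(attrs: Mapping[str, object]) -> str:
    return " ".join(f'{k} "{v}";' for k, v in attrs.items())


def write_gtf(
    transcripts: Iterable[TranscriptModel],
    path,
    extra_attributes: Mapping[str, Mapping[str, object]] | None = None,
) -> None:
    """Write exon rows in 1-based inclusive GTF.

    ``extra_attributes`` maps transcript_id to additional attribute key/value
    pairs (e.g. the final classification category and scores), emitted on
    every exon line of that transcript.
    """
    extra_attributes = extra_attributes or {}
    with open(path, "w") as fh:
        for t in sorted(transcripts, key=lambda t: (t.chrom, t.start, t.transcript_id)):
            attrs = {"gene_id": t.locus_id, "transcript_id": t.transcript_id}
            attrs.update(extra_attributes.get(t.transcript_id, {}))
            for e in t.exons:
                fh.write(
                    "\t".join(
                        [
                            t.chrom,
                            t.source,
                            "exon",
                            str(e.start + 1),
                            str(e.end),
                            ".",
                            t.strand,
                            ".",
                            _fmt_attributes(attrs),
                        ]
                    )
                    + "\n"
                )


def _fetch(genome, chrom: str, start: int, end: int) -> str:
    """Slice [start, end) from a pyfaidx.Fasta or a plain mapping of strings."""
    try:
        rec = genome[chrom]
    except KeyError:
        raise KeyError(f"chromosome {chrom!r} not in genome")
    seq = rec[start:end]
    seq = getattr(seq, "seq", seq)  # pyfaidx Sequence -> str
    if len(seq) != end - start:
        raise ValueError(
            f"exon [{start}, {end}) out of bounds for chromosome {chrom!r}"
        )
    return str(seq)


def spliced_sequence(transcript: TranscriptModel, genome) -> str:
    """Spliced transcript sequence, 5'->3' in transcript orientation.

    Minus-strand transcripts are reverse-complemented; strand-unknown (".")
    transcripts yield the plus-strand sequence (Cufflinks single-exon
    convention), which downstream coding analysis handles by scanning both
    strands.
    """
    parts = [_fetch(genome, transcript.chrom, e.start, e.end) for e in transcript.exons]
    seq = "".join(parts).upper()
    if transcript.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq


def read_expression_table(path) -> dict[str, ExpressionRecord]:
    """Read the per-transcript FPKM table.

    Columns: transcript_id, fpkm_pig, ci_low_pig, ci_high_pig, fpkm_nonpig,
    ci_low_nonpig, ci_high_nonpig.
    """
    df = pd.read_csv(path, sep="\t")
    required = {
        "transcript_id",
        "fpkm_pig", "ci_low_pig", "ci_high_pig",
        "fpkm_nonpig", "ci_low_nonpig", "ci_high_nonpig",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing expression columns {sorted(missing)}")
    out = {}
    for row in df.itertuples(index=False):
        rec = ExpressionRecord(
            transcript_id=row.transcript_id,
            fpkm={"pigmented": row.fpkm_pig, "nonpigmented": row.fpkm_nonpig},
            ci_low={"pigmented": row.ci_low_pig, "nonpigmented": row.ci_low_nonpig},
            ci_high={"pigmented": row.ci_high_pig, "nonpigmented": row.ci_high_nonpig},
        )
        out[rec.transcript_id] = rec
    return out


def write_expression_table(records: Iterable[ExpressionRecord], path) -> None:
    rows = []
    for r in sorted(records, key=lambda r: r.transcript_id):
        rows.append(
            {
                "transcript_id": r.transcript_id,
                "fpkm_pig": r.fpkm["pigmented"],
                "ci_low_pig": r.ci_low["pigmented"],
                "ci_high_pig": r.ci_high["pigmented"],
                "fpkm_nonpig": r.fpkm["nonpigmented"],
                "ci_low_nonpig": r.ci_low["nonpigmented"],
                "ci_high_nonpig": r.ci_high["nonpigmented"],
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")


INF_DISTANCE = math.inf
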