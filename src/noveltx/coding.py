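"""Coding-potential assessment.

Two independent scorers are thresholded and intersected: a CPAT-style
logistic-regression scorer over four alignment-free sequence features (ORF
length, ORF coverage, Fickett TESTCODE score, in-frame hexamer usage
log-likelihood ratio) yielding a coding probability in [0, 1], and a
CPC-like score on an unbounded log-odds scale (either supplied externally
from a run of the real tool, or produced by the internal proxy scorer).

Thresholds follow the published choices: CPC-S >= 1 coding, <= -0.5
noncoding, ambiguous between; CPAT probability >= 0.5 coding, < 0.02
noncoding, ambiguous between. Equal per-tool categories give the consensus;
unequal give "inconsistent".
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio.Seq import Seq
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler

STOP_CODONS = ("TAA", "TAG", "TGA")

CODING = "coding"
NONCODING = "noncoding"
AMBIGUOUS = "ambiguous"
INCONSISTENT = "inconsistent"

CONSENSUS_CATEGORIES = (CODING, NONCODING, AMBIGUOUS, INCONSISTENT)


# ---------------------------------------------------------------------------
# ORF scanning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OrfResult:
    """An open reading frame in transcript coordinates.

    Offsets refer to the scanned strand's sequence (for the antisense strand,
    the reverse complement). ``length_nt`` includes the stop codon when one
    terminates the ORF.
    """

    strand: str            # "+" sense, "-" antisense
    frame: int             # 0..2
    start_offset: int
    end_offset: int
    has_start: bool        # begins with ATG
    has_stop: bool         # ends with an in-frame stop codon

    def __post_init__(self):
        if self.end_offset - self.start_offset < 3:
            raise ValueError("ORF shorter than one codon")
        if (self.end_offset - self.start_offset) % 3:
            raise ValueError("ORF length not a multiple of 3")

    @property
    def length_nt(self) -> int:
        return self.end_offset - self.start_offset


def _scan_frame(seq: str, frame: int, strand: str, mode: str) -> list[OrfResult]:
    n = len(seq)
    out: list[OrfResult] = []
    if mode == "atg_anchored":
        start = None
        for pos in range(frame, n - 2, 3):
            codon = seq[pos : pos + 3]
            if codon in STOP_CODONS:
                if start is not None:
                    out.append(
                        OrfResult(strand, frame, start, pos + 3, True, True)
                    )
                    start = None
            elif codon == "ATG" and start is None:
                start = pos
        if start is not None and n - start >= 3:
            end = start + 3 * ((n - start) // 3)
            out.append(OrfResult(strand, frame, start, end, True, False))
    elif mode == "stop_to_stop":
        start = frame
        for pos in range(frame, n - 2, 3):
            codon = seq[pos : pos + 3]
            if codon in STOP_CODONS:
                if pos + 3 - start >= 3:
                    out.append(
                        OrfResult(
                            strand, frame, start, pos + 3,
                            seq[start : start + 3] == "ATG", True,
                        )
                    )
                start = pos + 3
        if n - start >= 3:
            end = start + 3 * ((n - start) // 3)
            out.append(
                OrfResult(strand, frame, start, end,
                          seq[start : start + 3] == "ATG", False)
            )
    else:
        raise ValueError(f"unknown ORF mode {mode!r}")
    return out


def find_orfs(
    sequence: str,
    mode: str = "atg_anchored",
    strands: str = "sense",
) -> list[OrfResult]:
    """Enumerate ORFs in all frames, longest first.

    ``mode``: ``atg_anchored`` reports maximal ATG -> stop spans per frame
    (trailing ATG-opened spans without a stop are reported with
    ``has_stop=False``); ``stop_to_stop`` reports maximal stop-free spans.
    ``strands``: ``sense`` scans the given sequence only, ``both`` also scans
    its reverse complement (for strand-unknown transcripts). Ties in length
    are broken by leftmost start, then sense strand first.
    """
    seq = sequence.upper()
    if len(seq) < 3:
        return []
    results: list[OrfResult] = []
    strand_seqs = [("+", seq)]
    if strands == "both":
        strand_seqs.append(("-", str(Seq(seq).reverse_complement())))
    elif strands != "sense":
        raise ValueError(f"unknown strands option {strands!r}")
    for strand, s in strand_seqs:
        for frame in range(3):
            results.extend(_scan_frame(s, frame, strand, mode))
    results.sort(key=lambda o: (-o.length_nt, o.start_offset, o.strand != "+"))
    return results


def longest_orf(sequence: str, mode: str = "atg_anchored",
                strands: str = "sense") -> OrfResult | None:
    orfs = find_orfs(sequence, mode=mode, strands=strands)
    return orfs[0] if orfs else None


# ---------------------------------------------------------------------------
# Fickett TESTCODE
# ---------------------------------------------------------------------------
# Published TESTCODE lookup tables: probability that a fragment with the
# given position/content parameter is coding, and the per-base weights.

_POSITION_PROB = {
    "A": (0.94, 0.68, 0.84, 0.93, 0.58, 0.68, 0.45, 0.34, 0.20, 0.22),
    "C": (0.80, 0.70, 0.70, 0.81, 0.66, 0.48, 0.51, 0.33, 0.30, 0.23),
    "G": (0.90, 0.88, 0.74, 0.64, 0.53, 0.48, 0.27, 0.16, 0.08, 0.08),
    "T": (0.97, 0.97, 0.91, 0.68, 0.69, 0.44, 0.54, 0.20, 0.09, 0.09),
}
_POSITION_WEIGHT = {"A": 0.26, "C": 0.18, "G": 0.31, "T": 0.33}
_POSITION_CUTS = (1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1, 0.0)

_CONTENT_PROB = {
    "A": (0.28, 0.49, 0.44, 0.55, 0.62, 0.49, 0.67, 0.65, 0.81, 0.21),
    "C": (0.82, 0.64, 0.51, 0.64, 0.59, 0.59, 0.43, 0.44, 0.39, 0.31),
    "G": (0.40, 0.54, 0.47, 0.64, 0.64, 0.73, 0.41, 0.41, 0.33, 0.29),
    "T": (0.28, 0.24, 0.39, 0.40, 0.55, 0.75, 0.56, 0.69, 0.51, 0.58),
}
_CONTENT_WEIGHT = {"A": 0.11, "C": 0.12, "G": 0.15, "T": 0.14}
_CONTENT_CUTS = (0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.19, 0.17, 0.0)


def _lookup(value: float, cuts: Sequence[float], probs: Sequence[float]) -> float:
    for cut, prob in zip(cuts, probs):
        if value >= cut:
            return prob
    return probs[-1]


def fickett_position_value(sequence: str, base: str) -> float:
    """max/(min+1) over the base's counts at the three codon positions."""
    counts = [0, 0, 0]
    for i, b in enumerate(sequence):
        if b == base:
            counts[i % 3] += 1
    return max(counts) / (min(counts) + 1.0)


def fickett_score(sequence: str) -> float:
    """Fickett TESTCODE score from the published lookup tables.

    Sum over the four bases of the weighted position-asymmetry and content
    probabilities; roughly in [0, 1.9], larger meaning more coding-like.
    N characters are ignored in the content denominator.
    """
    seq = sequence.upper()
    if not seq:
        raise ValueError("cannot score an empty sequence")
    acgt_total = sum(seq.count(b) for b in "ACGT")
    score = 0.0
    for base in "ACGT":
        pos_value = fickett_position_value(seq, base)
        content = seq.count(base) / acgt_total if acgt_total else 0.0
        score += _lookup(pos_value, _POSITION_CUTS, _POSITION_PROB[base]) \
            * _POSITION_WEIGHT[base]
        score += _lookup(content, _CONTENT_CUTS, _CONTENT_PROB[base]) \
            * _CONTENT_WEIGHT[base]
    return score


# ---------------------------------------------------------------------------
# Hexamer usage
# ---------------------------------------------------------------------------

ALL_HEXAMERS = tuple(
    "".join(p) for p in itertools.product("ACGT", repeat=6)
)


@dataclass
class HexamerModel:
    """Log-frequency tables over all 4^6 hexamers for a coding corpus
    (counted in codon frame, step 3) and a noncoding corpus (step 1)."""

    log_ratio: dict = field(default_factory=dict)
    pseudocount: float = 1.0
    trained: bool = False

    @staticmethod
    def _count(seqs: Iterable[str], step: int, pseudocount: float) -> dict:
        counts = dict.fromkeys(ALL_HEXAMERS, pseudocount)
        total = pseudocount * len(ALL_HEXAMERS)
        for s in seqs:
            s = s.upper()
            for i in range(0, len(s) - 5, step):
                h = s[i : i + 6]
                if h in counts:
                    counts[h] += 1
                    total += 1
        return {h: c / total for h, c in counts.items()}

    @classmethod
    def train(
        cls,
        coding_seqs: Iterable[str],
        noncoding_seqs: Iterable[str],
        pseudocount: float = 1.0,
        coding_step: int = 3,
        noncoding_step: int = 1,
    ) -> "HexamerModel":
        fc = cls._count(coding_seqs, coding_step, pseudocount)
        fn = cls._count(noncoding_seqs, noncoding_step, pseudocount)
        ratio = {h: math.log(fc[h] / fn[h]) for h in ALL_HEXAMERS}
        return cls(log_ratio=ratio, pseudocount=pseudocount, trained=True)


def hexamer_llr(sequence: str, model: HexamerModel,
                frame_start: int | None = None) -> float:
    """Mean hexamer log-likelihood ratio log(f_coding / f_noncoding).

    With ``frame_start`` given (an ORF start offset), hexamers are read in
    codon frame from there with step 3; otherwise with step 1 over the whole
    sequence. Returns 0.0 when no scorable hexamer exists.
    """
    if not model.trained:
        raise ValueError("hexamer model is not trained")
    seq = sequence.upper()
    start = frame_start if frame_start is not None else 0
    step = 3 if frame_start is not None else 1
    values = []
    for i in range(start, len(seq) - 5, step):
        h = seq[i : i + 6]
        ratio = model.log_ratio.get(h)
        if ratio is not None:
            values.append(ratio)
    return float(np.mean(values)) if values else 0.0


# ---------------------------------------------------------------------------
# Feature extraction and logistic scorers
# ---------------------------------------------------------------------------

FEATURE_NAMES = ("orf_length", "orf_coverage", "fickett", "hexamer_llr")


def sequence_features(sequence: str, model: HexamerModel,
                      strands: str = "sense") -> np.ndarray:
    """The four scorer features of one transcript sequence."""
    seq = sequence.upper()
    orf = longest_orf(seq, mode="atg_anchored", strands=strands)
    if orf is not None:
        orf_len = orf.length_nt
        scan_seq = seq if orf.strand == "+" else str(Seq(seq).reverse_complement())
        hx = hexamer_llr(scan_seq, model, frame_start=orf.start_offset)
    else:
        orf_len = 0
        hx = hexamer_llr(seq, model, frame_start=None)
    cov = orf_len / len(seq) if seq else 0.0
    return np.array([orf_len, cov, fickett_score(seq), hx], dtype=float)


@dataclass
class CodingScorer:
    """A fitted logistic scorer over the four sequence features.

    ``predict_proba`` returns the CPAT-style coding probability in [0, 1];
    ``log_odds`` the unbounded decision-function value used by the CPC-like
    proxy.
    """

    hexamer_model: HexamerModel
    scaler: StandardScaler | None
    clf: LogisticRegression
    strands: str = "sense"

    def _variants(self, sequence: str, strands: str | None) -> list[str]:
        # strand-unknown transcripts: score each orientation sense-only and
        # keep the more coding-like one
        if (strands or self.strands) == "both":
            return [sequence, str(Seq(sequence).reverse_complement())]
        return [sequence]

    def _X(self, sequences: Sequence[str]) -> np.ndarray:
        X = np.vstack(
            [sequence_features(s, self.hexamer_model, "sense") for s in sequences]
        )
        return self.scaler.transform(X) if self.scaler is not None else X

    def predict_proba(self, sequence: str, strands: str | None = None) -> float:
        X = self._X(self._variants(sequence, strands))
        return float(self.clf.predict_proba(X)[:, 1].max())

    def log_odds(self, sequence: str, strands: str | None = None) -> float:
        X = self._X(self._variants(sequence, strands))
        return float(self.clf.decision_function(X).max())


def train_coding_model(
    coding_seqs: Sequence[str],
    noncoding_seqs: Sequence[str],
    seed: int = 0,
    hexamer_model: HexamerModel | None = None,
    standardize: bool = True,
    C: float = 1000.0,
    strands: str = "sense",
) -> CodingScorer:
    """Fit the logistic coding-probability scorer.

    The hexamer model is trained on the same corpora unless supplied.
    Deterministic given ``seed`` (lbfgs solver; the seed fixes any sampling
    done by callers and the sklearn random_state).
    """
    if not coding_seqs or not noncoding_seqs:
        raise ValueError("need non-empty coding and noncoding training sets")
    hm = hexamer_model or HexamerModel.train(coding_seqs, noncoding_seqs)
    X = np.vstack(
        [sequence_features(s, hm, strands) for s in coding_seqs]
        + [sequence_features(s, hm, strands) for s in noncoding_seqs]
    )
    y = np.array([1] * len(coding_seqs) + [0] * len(noncoding_seqs))
    if len(set(y)) < 2:
        raise ValueError("training set contains a single class")
    scaler = None
    if standardize:
        scaler = StandardScaler().fit(X)
        X = scaler.transform(X)
    clf = LogisticRegression(C=C, max_iter=2000, random_state=seed)
    clf.fit(X, y)
    return CodingScorer(hexamer_model=hm, scaler=scaler, clf=clf, strands=strands)


def train_cpc_proxy(
    coding_seqs: Sequence[str],
    noncoding_seqs: Sequence[str],
    seed: int = 0,
    strands: str = "sense",
) -> CodingScorer:
    """Internal stand-in for an external CPC run: same four features but
    standardised and more strongly regularised, scored on the log-odds
    scale (positive coding, negative noncoding)."""
    return train_coding_model(
        coding_seqs,
        noncoding_seqs,
        seed=seed + 104729,  # decouple from the CPAT-style scorer's seed
        standardize=True,
        C=1.0,
        strands=strands,
    )


# ---------------------------------------------------------------------------
# Thresholding and consensus
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CodingThresholds:
    """Published decision cuts for the two scorers."""

    cpc_coding: float = 1.0
    cpc_noncoding: float = -0.5
    cpat_coding: float = 0.5
    cpat_noncoding: float = 0.02

    def __post_init__(self):
        if not (self.cpc_noncoding < self.cpc_coding
                and self.cpat_noncoding < self.cpat_coding):
            raise ValueError("noncoding cut must lie below coding cut")


def classify_tool_score(
    score: float, tool: str, thresholds: CodingThresholds = CodingThresholds()
) -> str:
    """Per-tool category with the printed inequality directions:
    CPC coding iff >= 1, noncoding iff <= -0.5; CPAT coding iff >= 0.5,
    noncoding iff < 0.02; ambiguous between."""
    if tool == "cpc":
        if score >= thresholds.cpc_coding:
            return CODING
        if score <= thresholds.cpc_noncoding:
            return NONCODING
        return AMBIGUOUS
    if tool == "cpat":
        if score >= thresholds.cpat_coding:
            return CODING
        if score < thresholds.cpat_noncoding:
            return NONCODING
        return AMBIGUOUS
    raise ValueError(f"unknown tool {tool!r}")


def consensus_category(cat_cpc: str, cat_cpat: str) -> str:
    """Intersection of the two per-tool categories; disagreement is
    'inconsistent'. Symmetric."""
    for c in (cat_cpc, cat_cpat):
        if c not in (CODING, NONCODING, AMBIGUOUS):
            raise ValueError(f"unknown per-tool category {c!r}")
    return cat_cpc if cat_cpc == cat_cpat else INCONSISTENT


@dataclass(frozen=True)
class CodingAssessment:
    """Both tool scores, per-tool categories and their intersection."""

    transcript_id: str
    cpc_s: float
    cpat_p: float
    cat_cpc: str
    cat_cpat: str
    consensus: str

    @classmethod
    def from_scores(
        cls, transcript_id: str, cpc_s: float, cpat_p: float,
        thresholds: CodingThresholds = CodingThresholds(),
    ) -> "CodingAssessment":
        cat_cpc = classify_tool_score(cpc_s, "cpc", thresholds)
        cat_cpat = classify_tool_score(cpat_p, "cpat", thresholds)
        return cls(
            transcript_id=transcript_id,
            cpc_s=cpc_s,
            cpat_p=cpat_p,
            cat_cpc=cat_cpc,
            cat_cpat=cat_cpat,
            consensus=consensus_category(cat_cpc, cat_cpat),
        )


def assess_transcripts(
    sequences: dict[str, str],
    cpat_scorer: CodingScorer,
    cpc_scorer: CodingScorer | None = None,
    external_cpc: dict[str, float] | None = None,
    thresholds: CodingThresholds = CodingThresholds(),
    strands_of: dict[str, str] | None = None,
) -> dict[str, CodingAssessment]:
    """Score every transcript with both tools and intersect the categories.

    CPC-S comes from ``external_cpc`` when given (a real CPC run), otherwise
    from the internal proxy scorer. ``strands_of`` may map a transcript id to
    "both" to scan both strands (strand-unknown single-exon transcripts).
    """
    if external_cpc is None and cpc_scorer is None:
        raise ValueError("need either an external CPC table or a proxy scorer")
    strands_of = strands_of or {}
    out = {}
    for tx_id in sorted(sequences):
        seq = sequences[tx_id]
        strands = strands_of.get(tx_id)
        cpat_p = cpat_scorer.predict_proba(seq, strands)
        if external_cpc is not None:
            if tx_id not in external_cpc:
                raise KeyError(f"no external CPC score for {tx_id}")
            cpc_s = external_cpc[tx_id]
        else:
            cpc_s = cpc_scorer.log_odds(seq, strands)
        out[tx_id] = CodingAssessment.from_scores(tx_id, cpc_s, cpat_p, thresholds)
    return out
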