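"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the package's interval indexes and scanning code:
plain nested loops, exhaustive enumeration, and a second literal
transcription of the published TESTCODE tables.
"""

import numpy as np

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
STOPS = {"TAA", "TAG", "TGA"}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# --- class codes ------------------------------------------------------------

def _strand_ok(a, b):
    return a == "." or b == "." or a == b


def _exonic_overlap(t, r):
    return any(
        e.chrom == f.chrom and max(e.start, f.start) < min(e.end, f.end)
        for e in t.exons for f in r.exons
    )


def classcode_oracle(t, reference_transcripts, min_frac=0.5):
    """Exhaustive pairwise class-code assignment (no interval index)."""
    overlapping = [r for r in reference_transcripts if _exonic_overlap(t, r)]
    for r in overlapping:
        if t.n_exons > 1 and r.n_exons > 1:
            if _strand_ok(t.strand, r.strand) and t.intron_chain == r.intron_chain:
                return "="
        elif t.n_exons == 1 and r.n_exons == 1 and _strand_ok(t.strand, r.strand):
            ov = max(
                0,
                min(t.exons[0].end, r.exons[0].end)
                - max(t.exons[0].start, r.exons[0].start),
            )
            if (ov >= min_frac * t.spliced_length
                    and ov >= min_frac * r.spliced_length):
                return "="
    if overlapping:
        if any(_strand_ok(t.strand, r.strand) for r in overlapping):
            return "j"
        return "o"
    for r in reference_transcripts:
        if r.chrom != t.chrom:
            continue
        for a, b in zip(r.exons, r.exons[1:]):
            if a.end <= t.start and t.end <= b.start:
                return "i"
    return "u"


# --- ORFs -------------------------------------------------------------------

def longest_orf_oracle(seq: str, strands: str = "sense") -> int:
    """Length of the longest maximal ATG->stop ORF by exhaustive scan of
    every ATG position on the requested strands (0 when none)."""
    best = 0
    variants = [seq.upper()]
    if strands == "both":
        variants.append(revcomp(seq.upper()))
    for s in variants:
        n = len(s)
        for i in range(n - 2):
            if s[i : i + 3] != "ATG":
                continue
            # skip non-maximal ATGs: an upstream in-frame ATG in the same
            # stop-free stretch starts the maximal span
            j = i - 3
            maximal = True
            while j >= 0:
                codon = s[j : j + 3]
                if codon in STOPS:
                    break
                if codon == "ATG":
                    maximal = False
                    break
                j -= 3
            if not maximal:
                continue
            k = i
            length = None
            while k + 3 <= n:
                if s[k : k + 3] in STOPS:
                    length = k + 3 - i
                    break
                k += 3
            if length is None:
                length = 3 * ((n - i) // 3)
            best = max(best, length)
    return best


# --- Fickett TESTCODE (second literal transcription, array-based) -----------

_POS_PROB = np.array([
    [0.94, 0.68, 0.84, 0.93, 0.58, 0.68, 0.45, 0.34, 0.20, 0.22],  # A
    [0.80, 0.70, 0.70, 0.81, 0.66, 0.48, 0.51, 0.33, 0.30, 0.23],  # C
    [0.90, 0.88, 0.74, 0.64, 0.53, 0.48, 0.27, 0.16, 0.08, 0.08],  # G
    [0.97, 0.97, 0.91, 0.68, 0.69, 0.44, 0.54, 0.20, 0.09, 0.09],  # T
])
_POS_W = np.array([0.26, 0.18, 0.31, 0.33])
_POS_CUT = np.array([1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1, 0.0])
_CON_PROB = np.array([
    [0.28, 0.49, 0.44, 0.55, 0.62, 0.49, 0.67, 0.65, 0.81, 0.21],
    [0.82, 0.64, 0.51, 0.64, 0.59, 0.59, 0.43, 0.44, 0.39, 0.31],
    [0.40, 0.54, 0.47, 0.64, 0.64, 0.73, 0.41, 0.41, 0.33, 0.29],
    [0.28, 0.24, 0.39, 0.40, 0.55, 0.75, 0.56, 0.69, 0.51, 0.58],
])
_CON_W = np.array([0.11, 0.12, 0.15, 0.14])
_CON_CUT = np.array([0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.19, 0.17, 0.0])


def fickett_oracle(seq: str) -> float:
    seq = seq.upper()
    arr = np.frombuffer(seq.encode(), dtype="S1")
    total = 0.0
    acgt = sum((arr == b).sum() for b in [b"A", b"C", b"G", b"T"])
    for bi, base in enumerate([b"A", b"C", b"G", b"T"]):
        hits = arr == base
        counts = np.array([hits[k::3].sum() for k in range(3)], dtype=float)
        pos_val = counts.max() / (counts.min() + 1.0)
        idx = int(np.argmax(pos_val >= _POS_CUT))
        total += _POS_PROB[bi, idx] * _POS_W[bi]
        content = hits.sum() / acgt if acgt else 0.0
        idx = int(np.argmax(content >= _CON_CUT))
        total += _CON_PROB[bi, idx] * _CON_W[bi]
    return float(total)


# --- hexamer LLR ------------------------------------------------------------

def hexamer_oracle(seq: str, log_ratio: dict, start: int | None) -> float:
    """Plain running-sum version of the mean in-frame hexamer log ratio."""
    seq = seq.upper()
    step = 3 if start is not None else 1
    i = start if start is not None else 0
    total, n = 0.0, 0
    while i + 6 <= len(seq):
        h = seq[i : i + 6]
        if h in log_ratio:
            total += log_ratio[h]
            n += 1
        i += step
    return total / n if n else 0.0


# --- nearest neighbour ------------------------------------------------------

def nearest_oracle(ut, locus_spans: dict):
    """Linear scan over all locus spans; returns (locus_id, distance)."""
    best_id, best_d, best_left = None, None, None
    for locus_id in sorted(locus_spans):
        span = locus_spans[locus_id]
        if span.chrom != ut.chrom:
            continue
        if max(span.start, ut.start) < min(span.end, ut.end):
            d = 0
        else:
            d = max(span.start, ut.start) - min(span.end, ut.end)
        left = span.start <= ut.start
        if (best_d is None or d < best_d
                or (d == best_d and left and not best_left)):
            best_id, best_d, best_left = locus_id, d, left
    return best_id, (float("inf") if best_d is None else float(best_d))
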