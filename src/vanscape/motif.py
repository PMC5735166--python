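"""Degenerate DNA motif scanning, typing, arrays, discovery and distances.

The VANC21 target consensus is the 9-mer YAGTATTAY (Y = C or T); instances
ending in C are "C-type", instances ending in T are "T-type".  The VANC6
targets are the 8-mers AGTTGTCC ("CC-type") and AGTTGTAC ("AC-type").
Functional target regions carry many motif copies arrayed in the same
orientation at high density, which is what :func:`find_arrays` detects.

Discovery (:func:`discover`) is a discriminative k-mer enumeration in the
DREME style: every exact word of width ``min_w..max_w`` present in the
positive set is scored with a one-sided Fisher exact test on the number of
positive vs negative sequences containing it, greedy single-position IUPAC
generalisation is applied when it improves the p-value, and significance is
reported as a Bonferroni-style E-value (p times the number of exact words
tested).
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_SET_TO_CODE = {v: k for k, v in IUPAC.items()}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

VANC21_CONSENSUS = "YAGTATTAY"
VANC6_CC = "AGTTGTCC"
VANC6_AC = "AGTTGTAC"


def revcomp(seq: str) -> str:
    """Reverse complement of a (possibly degenerate) DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class IUPACPattern:
    """A degenerate DNA pattern over the 15 IUPAC nucleotide codes."""

    pattern: str

    def __post_init__(self):
        bad = set(self.pattern.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"illegal IUPAC symbol(s): {sorted(bad)}")
        object.__setattr__(self, "pattern", self.pattern.upper())

    @property
    def width(self) -> int:
        return len(self.pattern)

    def sets(self) -> list[frozenset[str]]:
        return [IUPAC[c] for c in self.pattern]

    def instances(self) -> Iterable[str]:
        """Enumerate every concrete ACGT instance of the pattern."""
        for combo in itertools.product(*(sorted(IUPAC[c]) for c in self.pattern)):
            yield "".join(combo)

    def n_instances(self) -> int:
        out = 1
        for c in self.pattern:
            out *= len(IUPAC[c])
        return out

    def regex(self) -> re.Pattern:
        # N in the *sequence* never matches: character classes list ACGT only
        return re.compile("".join("[" + "".join(sorted(IUPAC[c])) + "]" for c in self.pattern))

    def matches(self, word: str) -> bool:
        word = word.upper()
        return len(word) == self.width and all(
            b in IUPAC[c] for b, c in zip(word, self.pattern)
        )


@dataclass(frozen=True)
class MotifHit:
    """One located occurrence of a degenerate motif (0-based half-open)."""

    seq_id: str
    start: int
    end: int
    strand: str
    matched: str  # motif-oriented concrete string
    motif_type: str = "other"


@dataclass
class MotifArray:
    """A maximal same-orientation run of motif hits at high local density."""

    seq_id: str
    start: int
    end: int
    strand: str
    n_hits: int

    @property
    def density(self) -> float:
        """Hits per kb of array span."""
        return self.n_hits / ((self.end - self.start) / 1000.0)


@dataclass
class MotifCandidate:
    """A discovered pattern with its discriminative contingency counts."""

    pattern: IUPACPattern
    pos_with: int
    pos_total: int
    neg_with: int
    neg_total: int
    p: float
    e: float


# ---------------------------------------------------------------------------
# Scanning and typing
# ---------------------------------------------------------------------------

def scan(sequence: str, pattern: IUPACPattern | str, seq_id: str = "seq",
         both_strands: bool = True) -> list[MotifHit]:
    """Find all (overlapping) occurrences of ``pattern`` in ``sequence``.

    Minus-strand hits are occurrences of the pattern's reverse complement in
    the forward sequence; their coordinates refer to the forward strand and
    ``matched`` is reported motif-oriented (reverse-complemented back).
    """
    if isinstance(pattern, str):
        pattern = IUPACPattern(pattern)
    sequence = sequence.upper()
    w = pattern.width
    hits = []
    rx = re.compile("(?=(" + pattern.regex().pattern + "))")
    for m in rx.finditer(sequence):
        s = m.start()
        hits.append(MotifHit(seq_id, s, s + w, "+", m.group(1)))
    if both_strands:
        rc_rx = re.compile("(?=(" + IUPACPattern(revcomp(pattern.pattern)).regex().pattern + "))")
        for m in rc_rx.finditer(sequence):
            s = m.start()
            hits.append(MotifHit(seq_id, s, s + w, "-", revcomp(m.group(1))))
    hits.sort(key=lambda h: (h.start, h.strand))
    return [classify(h) for h in hits]


def classify(hit: MotifHit) -> MotifHit:
    """Assign the motif type from the motif-oriented matched string.

    YAGTATTAY instances are typed C or T by their terminal base; the VANC6
    words AGTTGTCC / AGTTGTAC are typed CC / AC; anything else is "other".
    """
    m = hit.matched.upper()
    if IUPACPattern(VANC21_CONSENSUS).matches(m):
        mtype = "C" if m.endswith("C") else "T"
    elif m == VANC6_CC:
        mtype = "CC"
    elif m == VANC6_AC:
        mtype = "AC"
    else:
        mtype = "other"
    return MotifHit(hit.seq_id, hit.start, hit.end, hit.strand, hit.matched, mtype)


def count_per_te(hits: Sequence[MotifHit], annotation: pd.DataFrame) -> pd.DataFrame:
    """Count hits per (TE, motif type); hits outside all TEs go to 'background'.

    A hit is assigned to the TE interval (half-open) containing its start.
    Both strands are counted and overlapping hits each count once.
    """
    tes = (
        annotation.groupby("te_id", sort=False)
        .agg(chrom=("chrom", "first"), start=("start", "min"), end=("end", "max"))
        .reset_index()
    )
    types = sorted({h.motif_type for h in hits} | {"C", "T"})
    counts: dict[str, dict[str, int]] = {te: dict.fromkeys(types, 0) for te in tes["te_id"]}
    counts["background"] = dict.fromkeys(types, 0)
    for h in hits:
        row = tes[(tes["chrom"] == h.seq_id) & (tes["start"] <= h.start) & (h.start < tes["end"])]
        key = str(row["te_id"].iloc[0]) if len(row) else "background"
        counts[key][h.motif_type] = counts[key].get(h.motif_type, 0) + 1
    out = pd.DataFrame.from_dict(counts, orient="index").fillna(0).astype(int)
    out.index.name = "te_id"
    return out


def find_arrays(hits: Sequence[MotifHit], min_run: int = 3,
                max_gap_bp: int = 200) -> list[MotifArray]:
    """Segment hits into maximal same-strand runs with small inter-hit gaps.

    Consecutive hits (by start, within one sequence) belong to the same run
    when they share a strand and their starts differ by at most
    ``max_gap_bp``; runs of fewer than ``min_run`` hits are discarded.
    """
    arrays: list[MotifArray] = []
    ordered = sorted(hits, key=lambda h: (h.seq_id, h.start))
    run: list[MotifHit] = []

    def flush():
        if len(run) >= min_run:
            arrays.append(MotifArray(run[0].seq_id, run[0].start, max(h.end for h in run),
                                     run[0].strand, len(run)))

    for h in ordered:
        if run and (h.seq_id != run[-1].seq_id or h.strand != run[-1].strand
                    or h.start - run[-1].start > max_gap_bp):
            flush()
            run = []
        run.append(h)
    flush()
    return arrays


# ---------------------------------------------------------------------------
# Discriminative discovery
# ---------------------------------------------------------------------------

def _present_words(seq: str, widths: range) -> set[str]:
    """All exact words of the given widths present on either strand."""
    seq = seq.upper()
    rc = revcomp(seq)
    out: set[str] = set()
    for s in (seq, rc):
        for w in widths:
            for i in range(len(s) - w + 1):
                word = s[i:i + w]
                if "N" not in word:
                    out.add(word)
    return out


def _count_with_pattern(pattern: IUPACPattern, seqs: Sequence[str]) -> int:
    """Number of sequences with >= 1 match of ``pattern`` on either strand."""
    fwd = pattern.regex()
    rev = IUPACPattern(revcomp(pattern.pattern)).regex()
    n = 0
    for s in seqs:
        s = s.upper()
        if fwd.search(s) or rev.search(s):
            n += 1
    return n


def _fisher_greater(pos_with: int, pos_total: int, neg_with: int, neg_total: int) -> float:
    """One-sided (enrichment in positives) Fisher exact p = hypergeometric tail."""
    return float(hypergeom.sf(pos_with - 1, pos_total + neg_total,
                              pos_with + neg_with, pos_total))


_GENERALISATIONS = {
    "A": "RWMDHVN", "C": "YSMBHVN", "G": "RSKBDVN", "T": "YWKBDHN",
}


def _word_table(pos_seqs: Sequence[str], neg_seqs: Sequence[str],
                widths: range) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Per canonical word (lexicographic min of word/revcomp, so each
    double-stranded motif is tested once): sequence-presence counts."""
    pos_with: dict[str, int] = {}
    for s in pos_seqs:
        for w in {min(w, revcomp(w)) for w in _present_words(s, widths)}:
            pos_with[w] = pos_with.get(w, 0) + 1
    neg_with = dict.fromkeys(pos_with, 0)
    for s in neg_seqs:
        for w in {min(w, revcomp(w)) for w in _present_words(s, widths)}:
            if w in neg_with:
                neg_with[w] += 1
    words = list(pos_with)
    return (words, np.array([pos_with[w] for w in words]),
            np.array([neg_with[w] for w in words]))


def discover(pos_seqs: Sequence[str], neg_seqs: Sequence[str], min_w: int = 6,
             max_w: int = 9, e_threshold: float = 0.05,
             generalise: bool = True, max_motifs: int = 10) -> list[MotifCandidate]:
    """Sequentially extract patterns over-represented in the positive set.

    Each round scores every exact word (width ``min_w..max_w``, either
    strand, present in >= 1 remaining positive sequence) by the one-sided
    Fisher test, takes the best word (ties: wider, then lexicographically
    smaller pattern), refines it by greedy generalisation, and — if its
    E-value passes — reports it and erases the sequences it matches before
    the next round.  Contingency counts refer to the sequences remaining
    when the candidate was found; the Bonferroni factor is the number of
    words tested in the first round.  The returned list is sorted by
    (E-value, descending width, pattern).
    """
    if not pos_seqs or not neg_seqs:
        raise ValueError("both sequence sets must be non-empty")
    widths = range(min_w, max_w + 1)
    pos_rem, neg_rem = list(pos_seqs), list(neg_seqs)
    n_words: int | None = None
    candidates: list[MotifCandidate] = []
    while len(candidates) < max_motifs and pos_rem and neg_rem:
        words, pw, nw = _word_table(pos_rem, neg_rem, widths)
        if not words:
            break
        if n_words is None:
            n_words = len(words)
        pos_total, neg_total = len(pos_rem), len(neg_rem)
        p = hypergeom.sf(pw - 1, pos_total + neg_total, pw + nw, pos_total)
        i = min(range(len(words)),
                key=lambda k: (p[k], -len(words[k]), words[k]))
        pat = IUPACPattern(words[i])
        best = (float(p[i]), pat, int(pw[i]), int(nw[i]))
        if generalise:
            word_p, pat, word_pw, word_nw = best
            pat, word_pw, word_nw, word_p = _generalise(
                pat, word_pw, word_nw, word_p, pos_rem, neg_rem)
            best = (word_p, pat, word_pw, word_nw)
        word_p, pat, word_pw, word_nw = best
        e = word_p * n_words
        if e > e_threshold:
            break
        candidates.append(MotifCandidate(pat, word_pw, pos_total, word_nw,
                                         neg_total, word_p, e))
        fwd, rev = pat.regex(), IUPACPattern(revcomp(pat.pattern)).regex()

        def unmatched(s):
            return not (fwd.search(s.upper()) or rev.search(s.upper()))

        pos_rem = [s for s in pos_rem if unmatched(s)]
        neg_rem = [s for s in neg_rem if unmatched(s)]
    candidates.sort(key=lambda c: (c.e, -c.pattern.width, c.pattern.pattern))
    return candidates


def _generalise(pat: IUPACPattern, pw: int, nw: int, p: float,
                pos_seqs: Sequence[str], neg_seqs: Sequence[str]):
    """Greedy single-position IUPAC widening, accepted while it lowers p."""
    pos_total, neg_total = len(pos_seqs), len(neg_seqs)
    improved = True
    while improved:
        improved = False
        best = (p, pat, pw, nw)
        for i, base in enumerate(pat.pattern):
            for code in _GENERALISATIONS.get(base, ""):
                trial = IUPACPattern(pat.pattern[:i] + code + pat.pattern[i + 1:])
                t_pw = _count_with_pattern(trial, pos_seqs)
                t_nw = _count_with_pattern(trial, neg_seqs)
                t_p = _fisher_greater(t_pw, pos_total, t_nw, neg_total)
                if t_p < best[0]:
                    best = (t_p, trial, t_pw, t_nw)
        if best[0] < p:
            p, pat, pw, nw = best
            improved = True
    return pat, pw, nw, p


# ---------------------------------------------------------------------------
# Inter-motif distance
# ---------------------------------------------------------------------------

def min_mismatch(query: IUPACPattern | str, target: IUPACPattern | str) -> int:
    """Minimum Hamming distance between two degenerate patterns.

    The minimum is taken over all concrete instance pairs and all ungapped
    offsets of the shorter pattern within the longer, forward orientation
    only.  Two aligned positions contribute a mismatch iff their IUPAC sets
    are disjoint.
    """
    q = IUPACPattern(query) if isinstance(query, str) else query
    t = IUPACPattern(target) if isinstance(target, str) else target
    if not q.pattern or not t.pattern:
        raise ValueError("empty pattern")
    short, long_ = sorted((q, t), key=lambda x: x.width)
    s_sets, l_sets = short.sets(), long_.sets()
    best = short.width
    for off in range(long_.width - short.width + 1):
        mm = sum(1 for a, b in zip(s_sets, l_sets[off:]) if not (a & b))
        best = min(best, mm)
    return best
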