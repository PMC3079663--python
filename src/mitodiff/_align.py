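"""Seed–chain–extend local similarity core.

Both repeat discovery (genome vs itself) and cross-genome homology mapping
reduce to the same primitive: find all local similarity segments between two
DNA strings, on both strands. The approach is the classical one used by
k-mer based aligners:

1. exact k-mer seeds are collected and merged along diagonals into maximal
   exact runs;
2. runs on nearby diagonals separated by short gaps are chained;
3. each chain's bounding region is re-aligned end-to-end (edlib, unit-cost
   Needleman-Wunsch) to obtain mismatch/indel counts and identity;
4. ends are extended by direct character comparison.

Coordinates throughout are 0-based half-open. For minus-strand matches the
subject interval is reported on the subject's forward strand; the query
segment aligns to the reverse complement of that subject segment.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import edlib

from .model import revcomp

# ungapped blastn-like Karlin-Altschul parameters for +1/-2 scoring
_KA_LAMBDA = 1.28
_KA_K = 0.46


@dataclass
class Match:
    """One local similarity segment between query and subject."""

    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str  # '+': subject forward; '-': subject reverse complement
    columns: int = 0  # alignment columns incl. gaps
    matches: int = 0
    mismatches: int = 0
    indels: int = 0
    cigar: str = ""

    @property
    def identity(self) -> float:
        return 100.0 * self.matches / self.columns if self.columns else 0.0

    @property
    def q_span(self) -> int:
        return self.q_end - self.q_start

    @property
    def s_span(self) -> int:
        return self.s_end - self.s_start

    def score(self) -> int:
        return self.matches - 2 * self.mismatches - 2 * self.indels

    def evalue(self, m: int, n: int) -> float:
        """Karlin-Altschul style expectation for a search space of m x n."""
        s = max(self.score(), 0)
        return _KA_K * m * n * math.exp(-_KA_LAMBDA * s)


def _exact_runs(query: str, subject: str, k: int, skip_diag0: bool) -> list[tuple[int, int, int]]:
    """Maximal exact common runs >= k as (q_start, s_start, length)."""
    index: dict[str, list[int]] = {}
    for j in range(len(subject) - k + 1):
        index.setdefault(subject[j : j + k], []).append(j)
    by_diag: dict[int, list[int]] = {}
    for i in range(len(query) - k + 1):
        for j in index.get(query[i : i + k], ()):
            d = i - j
            if skip_diag0 and d == 0:
                continue
            by_diag.setdefault(d, []).append(i)
    runs: list[tuple[int, int, int]] = []
    for d, starts in by_diag.items():
        starts.sort()
        run_start = prev = starts[0]
        for i in starts[1:]:
            if i <= prev + 1:
                prev = i
            else:
                runs.append((run_start, run_start - d, prev + k - run_start))
                run_start = prev = i
        runs.append((run_start, run_start - d, prev + k - run_start))
    return runs


def _chain_runs(
    runs: list[tuple[int, int, int]], max_gap: int, band: int
) -> list[tuple[int, int, int, int]]:
    """Greedy single-linkage chaining of co-linear runs.

    Returns bounding boxes (q_start, q_end, s_start, s_end). Runs are chained
    when the next run starts within ``max_gap`` of the previous end on both
    sequences and the diagonal shift is at most ``band``.
    """
    runs = sorted(runs, key=lambda r: (r[0], r[1]))
    chains: list[list[int]] = []  # [qs, qe, ss, se, diag_last]
    out: list[tuple[int, int, int, int]] = []
    for qs, ss, ln in runs:
        qe, se = qs + ln, ss + ln
        d = qs - ss
        placed = False
        for ch in chains:
            if (
                abs(d - ch[4]) <= band
                and -band <= qs - ch[1] <= max_gap
                and -band <= ss - ch[3] <= max_gap
            ):
                ch[1] = max(ch[1], qe)
                ch[3] = max(ch[3], se)
                ch[4] = d
                placed = True
                break
        if not placed:
            chains.append([qs, qe, ss, se, d])
    for qs, qe, ss, se, _ in chains:
        out.append((qs, qe, ss, se))
    return out


def _refine(query: str, subject_oriented: str, qs: int, qe: int, ss: int, se: int) -> Match:
    """End-to-end alignment of a chained region; fills diff statistics.

    ``subject_oriented`` is the subject already in match orientation;
    coordinates are in that oriented frame (mapped back by the caller for
    minus-strand matches).
    """
    # ungapped end extension while characters agree
    while qs > 0 and ss > 0 and query[qs - 1] == subject_oriented[ss - 1]:
        qs -= 1
        ss -= 1
    n_q, n_s = len(query), len(subject_oriented)
    while qe < n_q and se < n_s and query[qe] == subject_oriented[se]:
        qe += 1
        se += 1
    qseq = query[qs:qe]
    sseq = subject_oriented[ss:se]
    res = edlib.align(qseq, sseq, mode="NW", task="path")
    cigar = res["cigar"] or ""
    cols = ins = dele = 0
    num = ""
    for c in cigar:
        if c.isdigit():
            num += c
        else:
            n = int(num)
            num = ""
            cols += n
            if c == "I":
                ins += n
            elif c == "D":
                dele += n
    indels = ins + dele
    mismatches = res["editDistance"] - indels
    matches = cols - mismatches - indels
    return Match(qs, qe, ss, se, "+", cols, matches, mismatches, indels, cigar)


def find_local_matches(
    query: str,
    subject: str,
    k: int = 31,
    min_len: int = 100,
    max_gap: int = 100,
    band: int = 50,
    self_mode: bool = False,
    chain: bool = True,
) -> list[Match]:
    """All local similarity segments between two linear strings, both strands.

    In ``self_mode`` (query is subject) the trivial identity diagonal is
    suppressed and each repeat pair is reported once, with the lower-
    coordinate copy as the query side. With ``chain=False`` no gapped
    chaining is done and only maximal exact runs are reported.
    """
    out: list[Match] = []
    n_s = len(subject)

    def _boxes(runs):
        if chain:
            return _chain_runs(runs, max_gap, band)
        return [(qs, qs + ln, ss, ss + ln) for qs, ss, ln in runs]

    # forward strand
    runs = _exact_runs(query, subject, k, skip_diag0=self_mode)
    for qs, qe, ss, se in _boxes(runs):
        m = _refine(query, subject, qs, qe, ss, se)
        if m.columns >= min_len:
            out.append(m)
    # reverse strand: match query against reverse-complemented subject
    rc = revcomp(subject)
    runs = _exact_runs(query, rc, k, skip_diag0=False)
    for qs, qe, ss, se in _boxes(runs):
        m = _refine(query, rc, qs, qe, ss, se)
        if m.columns < min_len:
            continue
        # map oriented-subject coords back to subject forward strand
        m.s_start, m.s_end = n_s - m.s_end, n_s - m.s_start
        m.strand = "-"
        out.append(m)
    if self_mode:
        out = _dedup_self(out)
    return _merge_duplicates(out)


def _dedup_self(matches: list[Match]) -> list[Match]:
    seen = set()
    kept: list[Match] = []
    for m in matches:
        a = (m.q_start, m.q_end)
        b = (m.s_start, m.s_end)
        if a == b:  # a palindrome matching itself
            continue
        key = (min(a, b), max(a, b), m.strand)
        if key in seen:
            continue
        seen.add(key)
        if a > b:  # canonical order: query side has the lower coordinate
            m.q_start, m.q_end, m.s_start, m.s_end = b[0], b[1], a[0], a[1]
        kept.append(m)
    return kept


def _overlap_frac(a0: int, a1: int, b0: int, b1: int) -> float:
    inter = max(0, min(a1, b1) - max(a0, b0))
    shorter = min(a1 - a0, b1 - b0)
    return inter / shorter if shorter else 0.0


def _merge_duplicates(matches: list[Match]) -> list[Match]:
    """Drop matches nearly contained in a longer match of the same strand."""
    matches = sorted(matches, key=lambda m: -m.columns)
    kept: list[Match] = []
    for m in matches:
        dup = False
        for other in kept:
            if (
                other.strand == m.strand
                and _overlap_frac(m.q_start, m.q_end, other.q_start, other.q_end) >= 0.9
                and _overlap_frac(m.s_start, m.s_end, other.s_start, other.s_end) >= 0.9
            ):
                dup = True
                break
        if not dup:
            kept.append(m)
    return kept
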