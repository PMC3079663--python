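"""Cross-genome homology mapping and line-specific (unique) regions.

Given two circular genomes — typically a CMS line and its maintainer, or a
mitochondrial genome and a chloroplast genome — this module finds their
shared local similarity segments, computes coverage statistics, extracts
the regions of one genome with no counterpart in the other (the U-regions
of the wheat Ks3/Km3 comparison), groups near-identical region copies, and
annotates regions against user-supplied reference sequence sets.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import edlib

from ._align import Match, find_local_matches
from ._util import round_half_up
from .model import CircularGenome, FORWARD, OrientedInterval, REVERSE, revcomp
from .repeats import _canonical_interval, _cover_frac, _to_interval


@dataclass
class HomologySegment:
    """One shared segment, reported on both coordinate systems."""

    query_iv: OrientedInterval
    subject_iv: OrientedInterval
    identity: float
    length: int  # alignment columns
    evalue: float = 0.0

    def to_dict(self) -> dict:
        return {
            "query": self.query_iv.to_dict(),
            "subject": self.subject_iv.to_dict(),
            "identity": round_half_up(self.identity, 2),
            "length": self.length,
            "evalue": self.evalue,
        }


@dataclass
class UniqueRegion:
    """A run of one genome with no homologous counterpart in the comparator."""

    id: str
    iv: OrientedInterval
    length: int
    copy_group: str = ""
    group_size: int = 1
    source_class: str = "novel"
    hits: list = field(default_factory=list)  # (set_name, sub_start, sub_end, identity)

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "start": self.iv.printed()[0],
            "end": self.iv.printed()[1],
            "length": self.length,
            "copy_group": self.copy_group,
            "group_size": self.group_size,
            "source_class": self.source_class,
            "hits": list(self.hits),
        }


def find_shared_segments(
    A: CircularGenome,
    B: CircularGenome,
    min_len: int = 100,
    min_identity: float | None = None,
    evalue_cutoff: float = 0.001,
    seed_k: int = 31,
    max_gap: int = 100,
) -> list[HomologySegment]:
    """Non-redundant local similarity segments between two genomes.

    Reverse-orientation hits are allowed; circular genomes are searched via
    the doubling trick with coordinates canonicalized modulo each length.
    ``min_identity`` (percent) is optional; the E-value gate at
    ``evalue_cutoff`` always applies.
    """
    if min_identity is not None and not (0 < min_identity <= 100):
        raise ValueError("min_identity must be in (0, 100]")
    La, Lb = A.length, B.length
    qseq = A.sequence + A.sequence if A.circular else A.sequence
    sseq = B.sequence + B.sequence if B.circular else B.sequence
    raw = find_local_matches(qseq, sseq, k=seed_k, min_len=min_len, max_gap=max_gap)
    # a match longer than a full circle (possible only through the doubling,
    # e.g. comparing a genome with itself or a rotation of itself) is trimmed
    # to one full turn and re-aligned
    raw = [
        _trim_match(m, qseq, sseq, min(La, Lb)) if (m.q_span > La or m.s_span > Lb) else m
        for m in raw
    ]
    # canonical dedup + fragment removal across the doubling seams
    seen: set[tuple] = set()
    matches: list[Match] = []
    for m in sorted(raw, key=lambda m: -(m.q_span + m.s_span)):
        if m.q_span > La or m.s_span > Lb:
            continue
        qa = _canonical_interval(m.q_start, m.q_span, La, A.circular)[:2]
        sa = _canonical_interval(m.s_start, m.s_span, Lb, B.circular)[:2]
        key = (qa, sa, m.strand)
        if key in seen:
            continue
        seen.add(key)
        redundant = False
        for other in matches:
            oq = (other.q_start % La if A.circular else other.q_start, other.q_span)
            os_ = (other.s_start % Lb if B.circular else other.s_start, other.s_span)
            if (
                other.strand == m.strand
                and _cover_frac(qa, oq, La, A.circular) >= 0.9
                and _cover_frac(sa, os_, Lb, B.circular) >= 0.9
            ):
                redundant = True
                break
        if not redundant:
            matches.append(m)
    segments: list[HomologySegment] = []
    for m in matches:
        ev = m.evalue(La, Lb)
        if ev > evalue_cutoff:
            continue
        if min_identity is not None and m.identity < min_identity:
            continue
        q_iv = _to_interval(m.q_start, m.q_span, FORWARD, La, A.circular)
        s_strand = FORWARD if m.strand == "+" else REVERSE
        s_iv = _to_interval(m.s_start, m.s_span, s_strand, Lb, B.circular)
        segments.append(HomologySegment(q_iv, s_iv, m.identity, m.columns, ev))
    segments.sort(key=lambda s: (s.query_iv.start if s.query_iv.wraps_origin else s.query_iv.lo))
    return segments


def _trim_match(m: Match, qseq: str, sseq: str, turn: int) -> Match:
    """Clip an over-long (doubling-seam) match to one full circle."""
    t = min(turn, m.q_span, m.s_span)
    qs, qe = m.q_start, m.q_start + t
    if m.strand == "+":
        ss, se = m.s_start, m.s_start + t
        sub = sseq[ss:se]
    else:  # query prefix pairs with subject suffix in forward coordinates
        ss, se = m.s_end - t, m.s_end
        sub = revcomp(sseq[ss:se])
    res = edlib.align(qseq[qs:qe], sub, mode="NW", task="path")
    cols = ins = dele = 0
    num = ""
    for c in res["cigar"] or "":
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
    mism = res["editDistance"] - indels
    return Match(qs, qe, ss, se, m.strand, cols, cols - mism - indels, mism, indels)


def _side_footprints(
    segments: list[HomologySegment], L: int, side: str
) -> list[tuple[int, int]]:
    pieces: list[tuple[int, int]] = []
    for seg in segments:
        iv = seg.query_iv if side == "query" else seg.subject_iv
        pieces.extend(iv.slices(L))
    return pieces


def _merge_intervals(pieces: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not pieces:
        return []
    pieces = sorted(pieces)
    out = [list(pieces[0])]
    for s, e in pieces[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def coverage_stats(
    segments: list[HomologySegment], genome: CircularGenome, side: str = "query"
) -> tuple[int, float]:
    """(covered_bp, percent of genome length), percent half-up to 1 decimal."""
    if side not in ("query", "subject"):
        raise ValueError("side must be 'query' or 'subject'")
    merged = _merge_intervals(_side_footprints(segments, genome.length, side))
    covered = sum(e - s for s, e in merged)
    return covered, round_half_up(100.0 * covered / genome.length, 1)


def unique_regions(
    A: CircularGenome,
    segments: list[HomologySegment],
    min_len: int = 100,
    side: str = "query",
) -> list[UniqueRegion]:
    """Maximal uncovered runs of ``A`` longer than ``min_len``, labelled U1...

    On a circular genome the run spanning the origin is a single region.
    Runs separated by zero covered bases merge by construction; there is no
    gap tolerance.
    """
    L = A.length
    covered = _merge_intervals(_side_footprints(segments, L, side))
    gaps: list[tuple[int, int]] = []  # 0-based half-open
    if not covered:
        gaps = [(0, L)]
    else:
        for (s1, e1), (s2, e2) in zip(covered, covered[1:]):
            if s2 > e1:
                gaps.append((e1, s2))
        head = covered[0][0]
        tail = L - covered[-1][1]
        if A.circular:
            if head + tail > 0:
                if tail and head:
                    gaps.append((covered[-1][1], L + head))  # wraps origin
                elif tail:
                    gaps.append((covered[-1][1], L))
                elif head:
                    gaps.append((0, head))
        else:
            if head:
                gaps.insert(0, (0, head))
            if tail:
                gaps.append((covered[-1][1], L))
    regions: list[UniqueRegion] = []
    for s, e in sorted(gaps):
        span = e - s
        if span <= min_len:
            continue
        if e > L:  # origin-wrapping run
            iv = OrientedInterval(s + 1, e - L, FORWARD, wraps_origin=True)
        else:
            iv = OrientedInterval(s + 1, e, FORWARD)
        regions.append(UniqueRegion(id="", iv=iv, length=span))
    for i, r in enumerate(regions, start=1):
        r.id = f"U{i}"
    return regions


def unique_total(regions: list[UniqueRegion], L: int) -> tuple[int, float]:
    """Summed unique bp over every copy, and percent of genome length."""
    total = sum(r.length for r in regions)
    return total, round_half_up(100.0 * total / L, 2)


def group_region_copies(
    regions: list[UniqueRegion],
    genome: CircularGenome,
    min_group_identity: float = 97.0,
) -> dict[str, list[str]]:
    """Single-linkage grouping of regions with near-identical sequence.

    Two regions link when either orientation matches at >=
    ``min_group_identity`` percent over >= 90% of the shorter length.
    Group labels and sizes are written back onto the regions; the mapping
    group label -> region ids is returned.
    """
    seqs = [r.iv.extract(genome.sequence) for r in regions]
    n = len(regions)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if _region_pair_matches(seqs[i], seqs[j], min_group_identity):
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    out: dict[str, list[str]] = {}
    for members in groups.values():
        label = regions[min(members)].id
        for i in members:
            regions[i].copy_group = label
            regions[i].group_size = len(members)
        out[label] = [regions[i].id for i in sorted(members)]
    return out


def _region_pair_matches(a: str, b: str, min_identity: float) -> bool:
    if len(a) > len(b):
        a, b = b, a
    window = int(len(a) * 0.9)
    if window == 0:
        return False
    for query in (a, revcomp(a)):
        res = edlib.align(query, b, mode="HW", task="distance")
        if res["editDistance"] < 0:
            continue
        ident = 100.0 * (len(a) - res["editDistance"]) / len(a)
        if ident >= min_identity:
            return True
    return False


_SOURCE_CLASS = {
    "mt_relatives": "mt-homolog",
    "ct_genome": "ct-derived",
    "nuclear": "nuclear-homolog",
    "elements": "element",
}


def annotate_regions(
    regions: list[UniqueRegion],
    genome: CircularGenome,
    reference_sets: dict[str, CircularGenome | list[CircularGenome]],
    min_len: int = 60,
    min_identity: float = 81.0,
    seed_k: int = 21,
) -> list[UniqueRegion]:
    """Classify each region by homology to named local reference sets.

    A region with no hits is ``novel``; one reference class covering >= 90%
    of the region gives that class; anything partial or conflicting is
    ``mixed`` with per-hit sub-intervals recorded.
    """
    if not reference_sets or all(not v for v in reference_sets.values()):
        warnings.warn("empty reference collection: all regions classified novel")
        for r in regions:
            r.source_class = "novel"
        return regions
    for region in regions:
        seq = region.iv.extract(genome.sequence)
        cover_by_class: dict[str, list[tuple[int, int]]] = {}
        hits = []
        for set_name, refs in reference_sets.items():
            if refs is None:
                continue
            if isinstance(refs, CircularGenome):
                refs = [refs]
            cls = _SOURCE_CLASS.get(set_name, set_name)
            for ref in refs:
                target = ref.sequence + ref.sequence if ref.circular else ref.sequence
                seen_hits: set[tuple] = set()
                for m in find_local_matches(seq, target, k=seed_k, min_len=min_len):
                    if m.identity < min_identity:
                        continue
                    key = (cls, m.q_start, m.q_end)  # doubling gives mirror hits
                    if key in seen_hits:
                        continue
                    seen_hits.add(key)
                    cover_by_class.setdefault(cls, []).append((m.q_start, m.q_end))
                    hits.append((cls, m.q_start + 1, m.q_end, round_half_up(m.identity, 2)))
        region.hits = sorted(hits, key=lambda h: h[1])
        if not hits:
            region.source_class = "novel"
            continue
        fracs = {
            cls: sum(e - s for s, e in _merge_intervals(piv)) / region.length
            for cls, piv in cover_by_class.items()
        }
        dominant = [cls for cls, f in fracs.items() if f >= 0.9]
        if len(dominant) == 1 and len(fracs) == 1:
            region.source_class = dominant[0]
        else:
            region.source_class = "mixed"
    return regions
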