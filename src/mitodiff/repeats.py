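"""Direct/inverted repeat family discovery on circular genomes.

A repeat family is a set of two or more near-identical copies of a segment,
each copy in either orientation. Families drive the multipartite structure
of plant mitochondrial genomes: recombination between direct-repeat (DR)
copies splits the master circle into subgenomic circles, recombination
between inverted-repeat (IR) copies produces isomers.

Detection is k-mer seeded (both strands), chained, and refined with an
end-to-end alignment per copy pair; pairwise matches are then clustered
into families by reciprocal interval overlap. Circularity is handled by
the doubling trick: the genome is conceptually concatenated to itself, and
match coordinates are canonicalized modulo the genome length, so repeats
spanning the origin need no special casing.
"""
from __future__ import annotations

from dataclasses import dataclass

import edlib

from ._align import Match, find_local_matches
from ._util import round_half_up
from .model import CircularGenome, FORWARD, OrientedInterval, REVERSE


@dataclass
class RepeatFamily:
    """A family of oriented repeat copies with per-family diff statistics."""

    id: str
    aligned_length: int
    copies: list[OrientedInterval]
    orientation_class: str  # DR, IR, DR/IR, IR/DR
    mismatch_bp: int = 0
    indel_bp: int = 0
    diff_summary: str = "identical"
    identity: float = 100.0

    @property
    def n_copies(self) -> int:
        return len(self.copies)

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "type": self.orientation_class,
            "size": self.aligned_length,
            "copies": [c.to_dict() for c in self.copies],
            "mismatch_bp": self.mismatch_bp,
            "indel_bp": self.indel_bp,
            "difference": self.diff_summary,
            "identity": self.identity,
        }


def copy_identity(aligned_length: int, mismatch_bp: int, indel_bp: int) -> float:
    """Percent identity of repeat copies from gap-inclusive alignment length.

    identity = 100 * (aligned_length - mismatch - indel) / aligned_length,
    rounded half-up to two decimals; this reproduces the printed %IDY of
    the wheat Ks3 repeat table for its two-copy rows.
    """
    if mismatch_bp < 0 or indel_bp < 0:
        raise ValueError("difference counts must be non-negative")
    if aligned_length <= 0:
        raise ValueError("aligned_length must be positive")
    if mismatch_bp + indel_bp > aligned_length:
        raise ValueError("differences exceed aligned length")
    return round_half_up(
        100.0 * (aligned_length - mismatch_bp - indel_bp) / aligned_length, 2
    )


def classify_orientation(copies: list[OrientedInterval]) -> str:
    """DR/IR label of a family, relative to copy-1.

    All copies on one strand -> DR; exactly two copies on opposite strands
    -> IR; three or more copies of mixed orientation -> composite label led
    by copy-2's orientation relative to copy-1 ("IR/DR" if copy-2 is
    opposite, "DR/IR" if copy-2 matches).
    """
    if len(copies) < 2:
        raise ValueError("a repeat family needs at least two copies")
    rel = [c.strand == copies[0].strand for c in copies[1:]]
    if all(rel):
        return "DR"
    if len(copies) == 2:
        return "IR"
    if not any(rel):
        return "IR" if len(copies) == 2 else "IR/DR"
    return "DR/IR" if rel[0] else "IR/DR"


def _canonical_interval(start0: int, span: int, L: int, circular: bool) -> tuple[int, int, bool]:
    """Map a 0-based doubled-coordinate interval onto the circle.

    Returns (canonical_start0, span, wraps).
    """
    if not circular:
        return start0, span, False
    c = start0 % L
    return c, span, c + span > L


def _to_interval(start0: int, span: int, strand: str, L: int, circular: bool) -> OrientedInterval:
    c, span, wraps = _canonical_interval(start0, span, L, circular)
    if wraps:
        return OrientedInterval(c + 1, c + span - L, strand, wraps_origin=True)
    lo, hi = c + 1, c + span
    return OrientedInterval(lo, hi, strand) if strand == FORWARD else OrientedInterval(hi, lo, REVERSE)


def _footprint(c: int, span: int, L: int, circular: bool) -> list[tuple[int, int]]:
    if circular and c + span > L:
        return [(c, L), (0, c + span - L)]
    return [(c, c + span)]


def _cover_frac(a: tuple[int, int], b: tuple[int, int], L: int, circular: bool) -> float:
    """Fraction of circular interval ``a`` covered by ``b`` ((start0, span))."""
    inter = 0
    for s1, e1 in _footprint(a[0], a[1], L, circular):
        for s2, e2 in _footprint(b[0], b[1], L, circular):
            inter += max(0, min(e1, e2) - max(s1, s2))
    return inter / a[1] if a[1] else 0.0


def _self_matches(
    genome: CircularGenome, min_len: int, seed_k: int, max_gap: int, chain: bool = True
) -> list[Match]:
    """Deduplicated self-similarity matches on the (possibly doubled) genome."""
    L = genome.length
    seq = genome.sequence + genome.sequence if genome.circular else genome.sequence
    raw = find_local_matches(
        seq, seq, k=seed_k, min_len=min_len, max_gap=max_gap, self_mode=True,
        chain=chain,
    )
    seen: set[tuple] = set()
    out: list[Match] = []
    for m in raw:
        if m.q_span > L or m.s_span > L:
            continue  # artifact of doubling (e.g. the shift-by-L diagonal)
        qa = _canonical_interval(m.q_start, m.q_span, L, genome.circular)[:2]
        sa = _canonical_interval(m.s_start, m.s_span, L, genome.circular)[:2]
        if qa == sa and m.strand == "+":
            continue  # the same locus seen through the doubling
        key = (min(qa, sa), max(qa, sa), m.strand)
        if key in seen:
            continue
        seen.add(key)
        out.append(m)
    # drop fragment matches: a shorter match whose two sides both lie inside
    # the two sides of a longer match is the same alignment seen piecewise
    # through the doubling (e.g. an origin-wrapping copy split at the seam)
    out.sort(key=lambda m: -(m.q_span + m.s_span))
    kept: list[Match] = []
    kept_keys: list[tuple[tuple[int, int], tuple[int, int]]] = []
    circ = genome.circular
    for m in out:
        qa = (m.q_start % L if circ else m.q_start, m.q_span)
        sa = (m.s_start % L if circ else m.s_start, m.s_span)
        redundant = any(
            (
                _cover_frac(qa, kq, L, circ) >= 0.9
                and _cover_frac(sa, ks, L, circ) >= 0.9
            )
            or (
                _cover_frac(qa, ks, L, circ) >= 0.9
                and _cover_frac(sa, kq, L, circ) >= 0.9
            )
            for kq, ks in kept_keys
        )
        if redundant:
            continue
        kept.append(m)
        kept_keys.append((qa, sa))
    return kept


class _CopyClusters:
    """Groups near-coincident intervals (>= 90% reciprocal overlap)."""

    def __init__(self, L: int, circular: bool):
        self.L = L
        self.circular = circular
        self.reps: list[tuple[int, int]] = []  # (canonical_start0, span)

    def assign(self, start0: int, span: int) -> int:
        c, span, _ = _canonical_interval(start0, span, self.L, self.circular)
        for idx, (rs, rspan) in enumerate(self.reps):
            if self._mutual(c, span, rs, rspan) >= 0.9:
                if span > rspan:
                    self.reps[idx] = (c, span)
                return idx
        self.reps.append((c, span))
        return len(self.reps) - 1

    def _mutual(self, a0: int, alen: int, b0: int, blen: int) -> float:
        # overlap on the circle: compare on canonical coordinates, allowing
        # the wrap by testing both the plain and the +L shifted placement
        best = 0
        for shift_a in (0, self.L if self.circular else 0):
            for shift_b in (0, self.L if self.circular else 0):
                s, e = max(a0 + shift_a, b0 + shift_b), min(
                    a0 + shift_a + alen, b0 + shift_b + blen
                )
                best = max(best, e - s)
        return best / max(alen, blen) if max(alen, blen) else 0.0


def find_repeat_families(
    genome: CircularGenome,
    min_len: int = 100,
    seed_k: int = 31,
    max_diff_rate: float = 0.1,
    max_gap: int = 100,
) -> list[RepeatFamily]:
    """Detect all repeat families of aligned length >= ``min_len``.

    Families are sorted by aligned length descending (ties by smallest
    start coordinate) and labelled R1, R2, ... Copies are listed in
    ascending start order; copy-1 defines the forward orientation.
    """
    if min_len < seed_k:
        raise ValueError(f"min_len ({min_len}) must be >= seed_k ({seed_k})")
    if genome.length < min_len:
        return []
    L = genome.length
    min_identity = 100.0 * (1.0 - max_diff_rate)
    # with a zero difference budget only maximal exact runs qualify, so skip
    # gapped chaining entirely (it would merge neighbouring exact repeats
    # into a gapped — hence non-exact — candidate)
    matches = [
        m
        for m in _self_matches(genome, min_len, seed_k, max_gap, chain=max_diff_rate > 0)
        if m.identity >= min_identity
    ]
    # cluster match endpoints into copies
    clusters = _CopyClusters(L, genome.circular)
    edges: list[tuple[int, int, str]] = []
    for m in matches:
        a = clusters.assign(m.q_start, m.q_span)
        b = clusters.assign(m.s_start, m.s_span)
        if a != b:
            edges.append((a, b, m.strand))
    # connected components over copies = families
    parent = list(range(len(clusters.reps)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b, _ in edges:
        parent[find(a)] = find(b)
    comps: dict[int, list[int]] = {}
    for idx in range(len(clusters.reps)):
        comps.setdefault(find(idx), []).append(idx)

    families: list[RepeatFamily] = []
    for members in comps.values():
        if len(members) < 2:
            continue
        members.sort(key=lambda i: clusters.reps[i][0])
        strands = _propagate_strands(members, edges)
        copies = [
            _to_interval(
                clusters.reps[i][0], clusters.reps[i][1], strands[i], L, genome.circular
            )
            for i in members
        ]
        fam = _family_stats(genome, copies)
        if fam.aligned_length >= min_len:
            families.append(fam)
    families.sort(key=lambda f: (-f.aligned_length, _first_start(f)))
    for rank, fam in enumerate(families, start=1):
        fam.id = f"R{rank}"
    return families


def _first_start(fam: RepeatFamily) -> int:
    c = fam.copies[0]
    return c.start if c.wraps_origin else c.lo


def _propagate_strands(members: list[int], edges: list[tuple[int, int, str]]) -> dict[int, str]:
    """Orient copies relative to copy-1 by walking match edges."""
    mset = set(members)
    adj: dict[int, list[tuple[int, str]]] = {i: [] for i in members}
    for a, b, strand in edges:
        if a in mset and b in mset:
            adj[a].append((b, strand))
            adj[b].append((a, strand))
    strands = {members[0]: FORWARD}
    stack = [members[0]]
    while stack:
        cur = stack.pop()
        for nxt, strand in adj[cur]:
            if nxt in strands:
                continue
            same = strand == "+"
            strands[nxt] = strands[cur] if same else (
                REVERSE if strands[cur] == FORWARD else FORWARD
            )
            stack.append(nxt)
    for i in members:  # isolated copies default forward (shouldn't happen)
        strands.setdefault(i, FORWARD)
    return strands


def _family_stats(genome: CircularGenome, copies: list[OrientedInterval]) -> RepeatFamily:
    """Diff counts and gap-inclusive aligned length, copy-1 as reference."""
    ref = copies[0].extract(genome.sequence)
    mismatch_total = 0
    indel_total = 0
    insert_cols: dict[int, int] = {}  # ref position -> max inserted length
    for cp in copies[1:]:
        seq = cp.extract(genome.sequence)
        res = edlib.align(seq, ref, mode="NW", task="path")
        ins = dele = 0
        ref_pos = 0
        num = ""
        for ch in res["cigar"] or "":
            if ch.isdigit():
                num += ch
                continue
            n = int(num)
            num = ""
            if ch == "I":  # present in copy, absent in ref
                ins += n
                insert_cols[ref_pos] = max(insert_cols.get(ref_pos, 0), n)
            elif ch == "D":
                dele += n
                ref_pos += n
            else:
                ref_pos += n
        indels = ins + dele
        mismatch_total += res["editDistance"] - indels
        indel_total += indels
    aligned_length = len(ref) + sum(insert_cols.values())
    parts = []
    if indel_total:
        parts.append(f"{indel_total} bp indel")
    if mismatch_total:
        parts.append(f"{mismatch_total} bp mismatch")
    summary = "; ".join(parts) if parts else "identical"
    ident = copy_identity(aligned_length, mismatch_total, indel_total)
    return RepeatFamily(
        id="",
        aligned_length=aligned_length,
        copies=copies,
        orientation_class=classify_orientation(copies),
        mismatch_bp=mismatch_total,
        indel_bp=indel_total,
        diff_summary=summary,
        identity=ident,
    )


def repeat_dotplot(
    genome: CircularGenome,
    min_len: int = 100,
    seed_k: int = 31,
    max_gap: int = 100,
    exact_only: bool = False,
) -> list[tuple[int, int, int, str]]:
    """Self-similarity matches as (x, y, length, orientation) for plotting.

    Coordinates are 1-based canonical starts; the trivial identity diagonal
    is included, and every off-diagonal match appears mirrored about it.
    """
    L = genome.length
    pts = [(1, 1, L, "+")]
    for m in _self_matches(genome, min_len, seed_k, max_gap, chain=not exact_only):
        qc = m.q_start % L + 1 if genome.circular else m.q_start + 1
        sc = m.s_start % L + 1 if genome.circular else m.s_start + 1
        pts.append((qc, sc, m.columns, m.strand))
        pts.append((sc, qc, m.columns, m.strand))
    return pts
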