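"""Six-frame ORF discovery on circular genomes and CMS-candidate screening.

Chimeric open reading frames — ORFs stitched together by recombination from
fragments of distinct genomic segments, often sitting next to or on top of
known genes — are the classic molecular candidates for cytoplasmic male
sterility (orf256 in wheat T-CMS, urf13 in maize, orf107 in sorghum). This
module finds all ATG-initiated, stop-terminated ORFs (stop codon included
in the reported interval), classifies ORFs of one genome by their homology
to the comparator and to a chloroplast genome, and flags candidates by
their position relative to known genes.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from ._align import find_local_matches
from .homology import UniqueRegion, _merge_intervals
from .model import CircularGenome, FORWARD, FeatureAnnotation, OrientedInterval, REVERSE, revcomp

_STOPS = ("TAA", "TAG", "TGA")


@dataclass
class OrfRecord:
    """An ORF, possibly present as several identical copies."""

    id: str
    copies: list[OrientedInterval]
    length: int  # bp, stop codon included; multiple of 3
    frame: int  # 1..3 forward, 4..6 reverse
    uniqueness_class: str = "not-unique"
    cms_flags: set = field(default_factory=set)
    evidence: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "copies": [c.to_dict() for c in self.copies],
            "size": self.length,
            "frame": self.frame,
            "uniqueness_class": self.uniqueness_class,
            "cms_flags": sorted(self.cms_flags),
        }


def _scan_strand(seq: str, L: int, circular: bool, min_len: int):
    """Yield (start0, length, frame0) ORFs on one oriented sequence.

    ``seq`` is the forward-reading sequence of that strand; for circular
    genomes it is the doubled sequence and ORFs are canonicalized to start
    in the first copy. Within a frame only the longest ORF per stop is
    produced (first ATG after the previous stop).
    """
    n = len(seq)
    for f in range(3):
        pending: int | None = None
        i = f
        while i + 3 <= n:
            codon = seq[i : i + 3]
            if codon in _STOPS:
                if pending is not None:
                    length = i + 3 - pending
                    if length >= min_len and length <= L and pending < L:
                        yield pending, length, f
                    pending = None
            elif codon == "ATG" and pending is None:
                pending = i
            i += 3


def find_orfs(genome: CircularGenome, min_len: int = 300) -> list[OrfRecord]:
    """All ORFs of length >= ``min_len`` bp in the six reading frames.

    An ORF runs ATG..stop with the stop codon included in its interval and
    length; nested sub-ORFs sharing a stop are not reported. On circular
    genomes ORFs may span the origin. Identical-sequence ORFs at several
    loci merge into one multi-copy record.
    """
    L = genome.length
    fwd = genome.sequence + genome.sequence if genome.circular else genome.sequence
    rc_single = revcomp(genome.sequence)
    rev = rc_single + rc_single if genome.circular else rc_single
    found: dict[tuple, tuple[OrientedInterval, int]] = {}
    for start0, length, _f in _scan_strand(fwd, L, genome.circular, min_len):
        c = start0 % L if genome.circular else start0
        key = (c, length, FORWARD)
        if key in found:
            continue
        if genome.circular and c + length > L:
            iv = OrientedInterval(c + 1, c + length - L, FORWARD, wraps_origin=True)
        else:
            iv = OrientedInterval(c + 1, c + length, FORWARD)
        found[key] = (iv, c % 3 + 1)
    for start0, length, _f in _scan_strand(rev, L, genome.circular, min_len):
        c = start0 % L if genome.circular else start0
        f0 = (L - c - length) % L if genome.circular else L - c - length
        key = (f0, length, REVERSE)
        if key in found:
            continue
        if genome.circular and f0 + length > L:
            iv = OrientedInterval(f0 + 1, f0 + length - L, REVERSE, wraps_origin=True)
        else:
            iv = OrientedInterval(f0 + length, f0 + 1, REVERSE)
        found[key] = (iv, c % 3 + 4)
    # merge identical-sequence ORFs into multi-copy records
    by_seq: dict[str, list[tuple[OrientedInterval, int]]] = {}
    for iv, frame in found.values():
        by_seq.setdefault(iv.extract(genome.sequence), []).append((iv, frame))
    records: list[OrfRecord] = []
    for seq, hits in by_seq.items():
        hits.sort(key=lambda h: h[0].start if h[0].wraps_origin else h[0].lo)
        copies = [iv for iv, _ in hits]
        records.append(OrfRecord("", copies, len(seq), hits[0][1]))
    records.sort(key=lambda r: (r.copies[0].start if r.copies[0].wraps_origin else r.copies[0].lo))
    for i, r in enumerate(records, start=1):
        r.id = f"orf{i}"
    return records


def _orf_hits(seq: str, target: CircularGenome, seed_k: int, min_len: int):
    """Deduplicated local matches of an ORF sequence against a genome."""
    t = target.sequence + target.sequence if target.circular else target.sequence
    Lt = target.length
    hits = []
    seen = set()
    for m in find_local_matches(seq, t, k=seed_k, min_len=min_len):
        key = (m.q_start, m.q_end, m.s_start % Lt, m.strand)
        if key in seen:
            continue
        seen.add(key)
        hits.append(m)
    return hits


def classify_unique_orfs(
    orfs: list[OrfRecord],
    genome: CircularGenome,
    comparator: CircularGenome,
    ct_genome: CircularGenome | None = None,
    unique_regions: list[UniqueRegion] | None = None,
    not_unique_coverage: float = 0.95,
    discrete_separation: int = 1000,
    seed_k: int = 21,
    hit_min_len: int = 60,
) -> list[OrfRecord]:
    """Assign each ORF a uniqueness class by homology evidence.

    * ``not-unique``: one comparator segment covers >= 95% of the ORF;
    * ``ct-derived``: chloroplast homology dominates;
    * ``two-discrete-segments``: >= 2 comparator loci, > 1 kb apart in the
      comparator (or discordant in order/orientation), covering distinct
      parts of the ORF — the chimeric-ORF signature;
    * ``partial-unique``: part matches the comparator, the rest lies in a
      line-specific region;
    * ``novel``: no hits anywhere.
    """
    if ct_genome is None:
        warnings.warn("no chloroplast genome supplied: ct-derived class unavailable")
    Lb = comparator.length
    for orf in orfs:
        seq = orf.copies[0].extract(genome.sequence)
        n = len(seq)
        b_hits = _orf_hits(seq, comparator, seed_k, hit_min_len)
        ct_hits = (
            _orf_hits(seq, ct_genome, seed_k, hit_min_len) if ct_genome is not None else []
        )
        b_cov_iv = _merge_intervals([(m.q_start, m.q_end) for m in b_hits])
        b_cov = sum(e - s for s, e in b_cov_iv) / n
        ct_cov_iv = _merge_intervals([(m.q_start, m.q_end) for m in ct_hits])
        ct_cov = sum(e - s for s, e in ct_cov_iv) / n
        orf.evidence = [
            ("comparator", m.q_start + 1, m.q_end, m.s_start % Lb + 1, m.strand)
            for m in b_hits
        ] + [("ct", m.q_start + 1, m.q_end) for m in ct_hits]
        single_full = any((e - s) / n >= not_unique_coverage for s, e in b_cov_iv)
        if single_full and any(
            (m.q_end - m.q_start) / n >= not_unique_coverage for m in b_hits
        ):
            orf.uniqueness_class = "not-unique"
            continue
        if ct_hits and ct_cov >= 0.8 and ct_cov > b_cov:
            orf.uniqueness_class = "ct-derived"
            continue
        if _is_two_discrete(b_hits, n, Lb, comparator.circular, discrete_separation):
            orf.uniqueness_class = "two-discrete-segments"
            continue
        if not b_hits and not ct_hits:
            orf.uniqueness_class = "novel"
            continue
        orf.uniqueness_class = "partial-unique"
    return orfs


def _is_two_discrete(b_hits, n: int, Lb: int, circular: bool, separation: int) -> bool:
    """Two+ comparator loci covering distinct ORF parts, far apart or discordant."""
    strong = [m for m in b_hits if (m.q_end - m.q_start) / n >= 0.2]
    if len(strong) < 2:
        return False
    total = sum(e - s for s, e in _merge_intervals([(m.q_start, m.q_end) for m in strong]))
    if total / n < 0.8:
        return False
    for i in range(len(strong)):
        for j in range(i + 1, len(strong)):
            a, b = strong[i], strong[j]
            # distinct ORF parts
            qov = min(a.q_end, b.q_end) - max(a.q_start, b.q_start)
            if qov > 0.5 * min(a.q_span, b.q_span):
                continue
            if a.strand != b.strand:
                return True
            d = abs((a.s_start % Lb) - (b.s_start % Lb))
            if circular:
                d = min(d, Lb - d)
            if d > separation:
                return True
            # order discordance: query order opposite subject order
            q_first_a = a.q_start < b.q_start
            s_first_a = (a.s_start % Lb) < (b.s_start % Lb)
            if q_first_a != s_first_a:
                return True
    return False


def flag_cms_candidates(
    orfs: list[OrfRecord],
    features: list[FeatureAnnotation],
    L: int,
    upstream_window: int = 2000,
    unique_regions: list[UniqueRegion] | None = None,
) -> list[OrfRecord]:
    """Positional CMS-candidate flags, following the known-gene geometry of
    characterized CMS loci.

    * ``vicinity-of-gene``: the ORF ends within ``upstream_window`` bp
      upstream of a same-strand gene start (the orf256/cox1 arrangement);
    * ``overlaps-gene``: the ORF shares at least one bp with a gene segment
      (the orf107/atp9 arrangement);
    * ``in-unique-region``: the ORF intersects a line-specific region.
    """
    genes = [f for f in features if f.kind != "ORF"]
    region_ivs = [r.iv for r in unique_regions or []]
    for orf in orfs:
        flags: set[str] = set()
        for copy in orf.copies:
            for gene in genes:
                for seg in gene.segments:
                    if copy.overlaps(seg, L):
                        flags.add("overlaps-gene")
            for gene in genes:
                seg = gene.segments[0]
                if seg.strand != copy.strand or seg.wraps_origin or copy.wraps_origin:
                    continue
                if copy.strand == FORWARD:
                    dist = seg.lo - copy.hi  # gene start downstream of ORF end
                else:
                    dist = copy.lo - seg.hi
                if 0 < dist <= upstream_window:
                    flags.add("vicinity-of-gene")
            for riv in region_ivs:
                if copy.overlaps(riv, L):
                    flags.add("in-unique-region")
        orf.cms_flags = flags
    return orfs
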