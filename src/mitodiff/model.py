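"""Core data types and circular-coordinate arithmetic.

Plant mitochondrial genomes assemble into a single circular "master circle"
(MC) molecule; every downstream analysis here (repeat discovery, homology
mapping, ORF screening, recombination enumeration) works on that circle.
Coordinates follow the conventions of organelle-genome literature:

* externally everything is 1-based and end-inclusive;
* a reverse-oriented interval is printed with descending coordinates
  (start > end), e.g. ``303665-302904`` is a 762 bp reverse feature;
* an interval may wrap the arbitrary origin of the circle, in which case
  its footprint runs ``start..L`` then ``1..end``.

Internally, algorithms convert to 0-based half-open slices on the forward
strand via :meth:`OrientedInterval.slices`.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from ._util import round_half_up

FORWARD = "+"
REVERSE = "-"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_VALID = frozenset("ACGTN")


class AlphabetError(ValueError):
    """Sequence contains characters outside {A, C, G, T, N}."""


class CoordinateError(ValueError):
    """Interval coordinates fall outside the host genome."""


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N is self-complementary)."""
    bad = set(seq.upper()) - _VALID
    if bad:
        raise AlphabetError(f"invalid DNA characters: {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class OrientedInterval:
    """A 1-based inclusive interval on a (possibly circular) genome.

    ``start > end`` with ``wraps_origin=False`` denotes reverse orientation,
    matching the descending-coordinate convention of printed repeat and ORF
    tables. With ``wraps_origin=True`` the footprint crosses the origin:
    it covers ``start..L`` followed by ``1..end`` (orientation given by
    ``strand``).
    """

    start: int
    end: int
    strand: str = FORWARD
    wraps_origin: bool = False

    def __post_init__(self) -> None:
        if self.strand not in (FORWARD, REVERSE):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if min(self.start, self.end) < 1:
            raise CoordinateError(f"coordinates must be >= 1: {self}")
        if not self.wraps_origin:
            # normalize orientation from coordinate order
            if self.start > self.end and self.strand == FORWARD:
                object.__setattr__(self, "strand", REVERSE)

    @classmethod
    def from_printed(cls, start: int, end: int, wraps_origin: bool = False) -> "OrientedInterval":
        """Build from table-style coordinates (descending = reverse)."""
        strand = REVERSE if (start > end and not wraps_origin) else FORWARD
        return cls(start, end, strand, wraps_origin)

    @property
    def lo(self) -> int:
        if self.wraps_origin:
            raise CoordinateError("lo/hi undefined for origin-wrapping interval")
        return min(self.start, self.end)

    @property
    def hi(self) -> int:
        if self.wraps_origin:
            raise CoordinateError("lo/hi undefined for origin-wrapping interval")
        return max(self.start, self.end)

    def length(self, L: int) -> int:
        return interval_length(self, L)

    def validate(self, L: int) -> None:
        if not (1 <= self.start <= L and 1 <= self.end <= L):
            raise CoordinateError(
                f"interval {self.start}-{self.end} outside genome of length {L}"
            )

    def slices(self, L: int) -> list[tuple[int, int]]:
        """0-based half-open slices covering the forward-strand footprint."""
        self.validate(L)
        if self.wraps_origin:
            return [(self.start - 1, L), (0, self.end)]
        return [(self.lo - 1, self.hi)]

    def printed(self) -> tuple[int, int]:
        """(start, end) as rendered in reports: descending iff reverse."""
        if self.wraps_origin:
            return (self.start, self.end)
        if self.strand == REVERSE:
            return (self.hi, self.lo)
        return (self.lo, self.hi)

    def extract(self, sequence: str) -> str:
        """Oriented subsequence from a forward-strand genome string."""
        L = len(sequence)
        s = "".join(sequence[a:b] for a, b in self.slices(L))
        return revcomp(s) if self.strand == REVERSE else s

    def overlaps(self, other: "OrientedInterval", L: int) -> bool:
        mine = set()
        for a, b in self.slices(L):
            mine.update(range(a, b))
        return any(
            any(p in mine for p in range(a, b)) for a, b in other.slices(L)
        )

    def to_dict(self) -> dict:
        return {
            "start": self.start,
            "end": self.end,
            "strand": self.strand,
            "wraps_origin": self.wraps_origin,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "OrientedInterval":
        return cls(d["start"], d["end"], d.get("strand", FORWARD), d.get("wraps_origin", False))


def interval_length(iv: OrientedInterval, L: int, circular: bool = True) -> int:
    """Inclusive span of an interval on a genome of length ``L``.

    Descending coordinates count the same span as their ascending mirror
    (``|start - end| + 1``); an origin-wrapping interval counts
    ``L - start + 1 + end``.
    """
    iv.validate(L)
    if iv.wraps_origin:
        if not circular:
            raise CoordinateError("origin-wrapping interval on a linear genome")
        return L - iv.start + 1 + iv.end
    return abs(iv.start - iv.end) + 1


@dataclass
class CircularGenome:
    """A circular (or optionally linear) DNA molecule."""

    id: str
    sequence: str
    circular: bool = True

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError("empty genome sequence")
        bad = set(self.sequence) - _VALID
        if bad:
            raise AlphabetError(f"genome {self.id}: invalid characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def fetch(self, iv: OrientedInterval) -> str:
        return iv.extract(self.sequence)

    def rotated(self, offset: int) -> "CircularGenome":
        """Genome re-linearized at a new origin (circular genomes only)."""
        if not self.circular:
            raise ValueError("cannot rotate a linear genome")
        k = offset % self.length
        return CircularGenome(self.id, self.sequence[k:] + self.sequence[:k], True)


def gc_content(genome: CircularGenome | str) -> float:
    """G+C percentage of the non-N bases, rounded half-up to one decimal."""
    seq = genome.sequence if isinstance(genome, CircularGenome) else genome.upper()
    denom = len(seq) - seq.count("N")
    if denom == 0:
        raise ValueError("GC content undefined: sequence is all N")
    gc = seq.count("G") + seq.count("C")
    return round_half_up(100.0 * gc / denom, 1)


@dataclass
class FeatureAnnotation:
    """A named genome feature, possibly multi-segment (cis-spliced exons)."""

    name: str
    kind: str  # CDS, rRNA, tRNA, ORF, other
    segments: list[OrientedInterval] = field(default_factory=list)
    genome_id: str = ""

    KINDS = ("CDS", "rRNA", "tRNA", "ORF", "other")

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError(f"feature {self.name}: no segments")
        if self.kind not in self.KINDS:
            self.kind = "other"

    @property
    def strand(self) -> str:
        return self.segments[0].strand

    def span_start(self) -> int:
        seg = self.segments[0]
        return seg.start if seg.wraps_origin else seg.lo

    def total_length(self, L: int) -> int:
        return sum(interval_length(s, L) for s in self.segments)

    def extract(self, genome: CircularGenome) -> str:
        """Spliced, oriented feature sequence."""
        parts = [genome.fetch(s) for s in self.segments]
        return "".join(parts)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "kind": self.kind,
            "segments": [s.to_dict() for s in self.segments],
            "genome_id": self.genome_id,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureAnnotation":
        return cls(
            d["name"],
            d["kind"],
            [OrientedInterval.from_dict(s) for s in d["segments"]],
            d.get("genome_id", ""),
        )


def shift_interval(iv: OrientedInterval, offset: int, L: int) -> OrientedInterval:
    """Rotate an interval's coordinates by ``-offset`` (new origin at offset).

    Used to express rotation invariance: features on ``genome.rotated(k)``
    are the features of ``genome`` shifted by ``-k``.
    """
    def mv(p: int) -> int:
        return (p - 1 - offset) % L + 1

    if iv.wraps_origin:
        s, e = mv(iv.start), mv(iv.end)
        return OrientedInterval(s, e, iv.strand, wraps_origin=s > e)
    lo, hi = mv(iv.lo), mv(iv.hi)
    if lo <= hi:
        return OrientedInterval(lo if iv.strand == FORWARD else hi,
                                hi if iv.strand == FORWARD else lo,
                                iv.strand)
    # footprint now crosses the origin
    start, end = lo, hi
    return OrientedInterval(start, end, iv.strand, wraps_origin=True)
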