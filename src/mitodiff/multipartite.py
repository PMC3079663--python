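"""Recombination products implied by repeat families.

Intra-molecular homologous recombination between two copies of a repeat
reshapes the master circle (MC): a direct-repeat (same-strand) pair splits
it into two subgenomic circles whose lengths sum to the parent, while an
inverted-repeat (opposite-strand) pair inverts the intervening segment and
yields an isomer of unchanged length. Enumerating these events over the
large repeat families predicts the multipartite structure of the genome;
removing one copy of each large repeat estimates the non-redundant
("actual") genome size.
"""
from __future__ import annotations

from dataclasses import dataclass

import edlib

from .model import CircularGenome, CoordinateError, OrientedInterval, revcomp
from .repeats import RepeatFamily, _cover_frac


@dataclass
class RecombinationProduct:
    """Molecules from one recombination event between two repeat copies.

    ``segment_order`` describes each product as a signed list over the
    parent partition {C1 (copy-1), M (between the copies), C2 (copy-2),
    R (the rest)}; a leading '-' marks an inverted segment.
    """

    kind: str  # 'subgenomic-pair' or 'isomer'
    family_id: str
    copy_pair: tuple[int, int]  # 1-based copy indices
    product_lengths: list[int]
    segment_order: list[list[str]]

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "family": self.family_id,
            "copies": list(self.copy_pair),
            "lengths": self.product_lengths,
            "segment_order": self.segment_order,
        }


def _copy_start0(iv: OrientedInterval, L: int) -> int:
    """0-based forward-footprint start of a copy (its 'equivalent' position)."""
    iv.validate(L)
    if iv.wraps_origin:
        return iv.start - 1
    return iv.lo - 1


def enumerate_products(
    L: int, families: list[RepeatFamily], min_len: int = 500
) -> list[RecombinationProduct]:
    """All single recombination events over families >= ``min_len``.

    Every unordered pair of same-strand copies gives one subgenomic pair
    (lengths ``d`` and ``L - d`` with ``d`` the circular distance between
    the copies' start positions); every opposite-strand pair gives one
    isomer of length ``L``. Multicopy families contribute all pairs.
    """
    out: list[RecombinationProduct] = []
    for fam in families:
        if fam.aligned_length < min_len:
            continue
        n = len(fam.copies)
        for i in range(n):
            for j in range(i + 1, n):
                a, b = fam.copies[i], fam.copies[j]
                sa, sb = _copy_start0(a, L), _copy_start0(b, L)
                if a.strand == b.strand:
                    d = (sb - sa) % L
                    out.append(
                        RecombinationProduct(
                            "subgenomic-pair",
                            fam.id,
                            (i + 1, j + 1),
                            [d, L - d],
                            [["C1", "M"], ["C2", "R"]],
                        )
                    )
                else:
                    out.append(
                        RecombinationProduct(
                            "isomer",
                            fam.id,
                            (i + 1, j + 1),
                            [L],
                            [["C1", "-M", "C2", "R"]],
                        )
                    )
    return out


def apply_recombination(
    genome: CircularGenome,
    family: RepeatFamily,
    copy_pair: tuple[int, int] = (1, 2),
    min_identity: float = 99.0,
    force: bool = False,
) -> list[CircularGenome]:
    """Realize one recombination event at the sequence level.

    The crossover is placed at the repeat midpoint; for identical copies
    the resulting circles do not depend on that choice (circles compare
    equal up to rotation). Copies below ``min_identity`` percent identity
    are refused unless ``force`` — a crossover between diverged copies is
    biologically dubious.
    """
    i, j = copy_pair
    a, b = family.copies[i - 1], family.copies[j - 1]
    if a.wraps_origin or b.wraps_origin:
        raise CoordinateError(
            "rotate the genome so neither recombining copy spans the origin"
        )
    seq = genome.sequence
    # identity of the two copies (oriented alike)
    a_seq = a.extract(seq)
    b_seq = b.extract(seq)
    dist = edlib.align(a_seq, b_seq, mode="NW", task="distance")["editDistance"]
    ident = 100.0 * (max(len(a_seq), len(b_seq)) - dist) / max(len(a_seq), len(b_seq))
    if ident < min_identity and not force:
        raise ValueError(
            f"copy identity {ident:.2f}% below {min_identity}%: refusing crossover"
        )
    first, second = (a, b) if a.lo <= b.lo else (b, a)
    span = min(first.hi - first.lo, second.hi - second.lo) + 1
    x = span // 2
    if a.strand == b.strand:
        # direct pair: two subgenomic circles, crossover at copy offset x
        p1 = seq[first.lo - 1 + x : second.lo - 1 + x]
        p2 = seq[second.lo - 1 + x :] + seq[: first.lo - 1 + x]
        return [
            CircularGenome(f"{genome.id}|{family.id}:{i}-{j}|a", p1),
            CircularGenome(f"{genome.id}|{family.id}:{i}-{j}|b", p2),
        ]
    # inverted pair: invert between the aligned crossover points
    lo = first.lo - 1 + x
    hi = second.hi - x
    iso = seq[:lo] + revcomp(seq[lo:hi]) + seq[hi:]
    return [CircularGenome(f"{genome.id}|{family.id}:{i}-{j}|iso", iso)]


def reduced_genome_size(L: int, families: list[RepeatFamily], min_len: int = 500) -> int:
    """Genome size after removing one copy of each large repeat family.

    Families whose copies all lie within copies of a larger retained family
    are dropped first (their removal would otherwise be double-counted),
    then ``L - sum (copies - 1) * aligned_length`` over the rest.
    """
    big = sorted(
        (f for f in families if f.aligned_length >= min_len),
        key=lambda f: -f.aligned_length,
    )
    retained: list[RepeatFamily] = []
    for fam in big:
        nested = all(
            any(
                _cover_frac(_foot(c, L), _foot(rc, L), L, True) >= 0.99
                for r in retained
                for rc in r.copies
            )
            for c in fam.copies
        )
        if not (nested and retained):
            retained.append(fam)
    removed = sum((len(f.copies) - 1) * f.aligned_length for f in retained)
    result = L - removed
    if result <= 0:
        raise ValueError(
            f"inconsistent repeat families: removal ({removed}) exceeds genome ({L})"
        )
    return result


def _foot(iv: OrientedInterval, L: int) -> tuple[int, int]:
    if iv.wraps_origin:
        return (iv.start - 1, L - iv.start + 1 + iv.end)
    return (iv.lo - 1, iv.hi - iv.lo + 1)
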