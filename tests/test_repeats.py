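"""Repeat family discovery, identity arithmetic, orientation labels."""
import numpy as np
import pytest

from mitodiff.model import CircularGenome, OrientedInterval, revcomp
from mitodiff.repeats import (
    classify_orientation,
    copy_identity,
    find_repeat_families,
    repeat_dotplot,
)

from conftest import random_dna


def _runs_of_true(eq):
    if eq.size == 0:
        return
    d = np.diff(eq.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if eq[0]:
        starts = np.r_[0, starts]
    if eq[-1]:
        ends = np.r_[ends, eq.size]
    yield from zip(starts.tolist(), ends.tolist())


def brute_force_exact_pairs(seq: str, min_len: int) -> set[tuple]:
    """All maximal exact repeated-substring pairs of a linear sequence.

    Independent oracle: per-diagonal vectorized character comparison with
    run-length extraction, forward and reverse-complement frames.
    Returns canonical tuples (start1_a, start1_b, length, strand), a <= b.
    """
    a = np.frombuffer(seq.encode(), dtype=np.uint8)
    n = len(a)
    out: set[tuple] = set()
    for d in range(1, n):  # forward pairs, offset d
        eq = a[: n - d] == a[d:]
        for s, e in _runs_of_true(eq):
            if e - s >= min_len:
                out.add((s + 1, s + d + 1, e - s, "+"))
    rc = np.frombuffer(revcomp(seq).encode(), dtype=np.uint8)
    for off in range(-(n - 1), n):  # seq vs revcomp(seq), all alignments
        if off >= 0:
            eq = a[off:] == rc[: n - off]
            base_i = off
            base_x = 0
        else:
            eq = a[: n + off] == rc[-off:]
            base_i = 0
            base_x = -off
        for s, e in _runs_of_true(eq):
            ln = e - s
            if ln < min_len:
                continue
            i = base_i + s
            x = base_x + s
            j = n - x - ln  # map revcomp frame back to forward coordinates
            lo, hi = min(i, j), max(i, j)
            if i == j:
                continue  # a palindrome matching itself
            out.add((lo + 1, hi + 1, ln, "-"))
    return out


class TestCopyIdentity:
    @pytest.mark.parametrize(
        "aligned,mm,ind,expected",
        [(442, 7, 1, 98.19), (145, 2, 12, 90.34), (197, 1, 0, 99.49), (500, 0, 0, 100.0)],
    )
    def test_published_rows(self, aligned, mm, ind, expected):
        assert copy_identity(aligned, mm, ind) == expected

    def test_monotone_and_100_iff_clean(self):
        base = copy_identity(400, 0, 0)
        assert base == 100.0
        prev = base
        for mm in range(1, 6):
            cur = copy_identity(400, mm, 0)
            assert cur < prev
            prev = cur
        assert copy_identity(400, 0, 1) < 100.0

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            copy_identity(100, -1, 0)
        with pytest.raises(ValueError):
            copy_identity(100, 60, 50)


class TestClassifyOrientation:
    def test_two_copy_labels(self):
        fwd = OrientedInterval(1, 100, "+")
        rev = OrientedInterval(300, 201, "-")
        assert classify_orientation([fwd, OrientedInterval(501, 600, "+")]) == "DR"
        assert classify_orientation([fwd, rev]) == "IR"

    def test_composite_labels_follow_copy2(self):
        fwd1 = OrientedInterval(1, 100, "+")
        rev = OrientedInterval(300, 201, "-")
        fwd2 = OrientedInterval(501, 600, "+")
        assert classify_orientation([fwd1, rev, fwd2]) == "IR/DR"
        assert classify_orientation([fwd1, fwd2, rev]) == "DR/IR"

    def test_single_copy_rejected(self):
        with pytest.raises(ValueError):
            classify_orientation([OrientedInterval(1, 100)])


class TestFindRepeatFamilies:
    def test_planted_direct_repeat(self):
        base = random_dna(21, 20_000)
        rep = random_dna(22, 1000)
        g = CircularGenome("g", base[:3000] + rep + base[3000:12000] + rep + base[12000:])
        fams = find_repeat_families(g, min_len=100)
        assert len(fams) == 1
        fam = fams[0]
        assert fam.orientation_class == "DR"
        assert fam.n_copies == 2
        assert fam.identity == 100.0
        starts = sorted(c.lo for c in fam.copies)
        assert abs(starts[0] - 3001) <= 2 and abs(starts[1] - 13001) <= 2

    def test_planted_inverted_repeat(self):
        base = random_dna(21, 20_000)
        rep = random_dna(22, 1000)
        g = CircularGenome(
            "g", base[:3000] + rep + base[3000:12000] + revcomp(rep) + base[12000:]
        )
        (fam,) = find_repeat_families(g, min_len=100)
        assert fam.orientation_class == "IR"
        assert {c.strand for c in fam.copies} == {"+", "-"}

    def test_repeat_free_circle_is_empty(self):
        g = CircularGenome("g", random_dna(23, 5000))
        assert find_repeat_families(g, min_len=100) == []

    def test_min_len_below_seed_k_rejected(self):
        g = CircularGenome("g", random_dna(23, 5000))
        with pytest.raises(ValueError):
            find_repeat_families(g, min_len=20, seed_k=31)

    def test_mutated_copy_statistics(self):
        base = random_dna(24, 15_000)
        rep = list(random_dna(25, 800))
        mut = rep.copy()
        for p in (120, 300, 555):
            mut[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mut[p]]
        del mut[400:402]
        g = CircularGenome(
            "g", base[:2000] + "".join(rep) + base[2000:9000] + "".join(mut) + base[9000:]
        )
        (fam,) = find_repeat_families(g, min_len=100)
        assert fam.mismatch_bp == 3
        assert fam.indel_bp == 2
        assert fam.aligned_length == 800  # gaps counted against copy-1
        assert fam.identity == copy_identity(800, 3, 2)

    def test_rotation_invariance(self):
        base = random_dna(26, 18_000)
        rep = random_dna(27, 700)
        g = CircularGenome("g", base[:4000] + rep + base[4000:11000] + rep + base[11000:])
        ref = find_repeat_families(g)
        assert len(ref) == 1
        for k in (1, 4200, 9000, g.length - 1):  # cuts inside and outside copies
            fams = find_repeat_families(g.rotated(k))
            assert len(fams) == 1
            assert fams[0].orientation_class == "DR"
            assert fams[0].aligned_length == ref[0].aligned_length
            assert fams[0].n_copies == 2

    def test_planted_copy_number(self):
        base = random_dna(28, 20_000)
        rep = random_dna(29, 500)
        seq = (
            base[:2000] + rep + base[2000:8000] + rep
            + base[8000:14000] + rep + base[14000:]
        )
        (fam,) = find_repeat_families(CircularGenome("g", seq))
        assert fam.n_copies == 3
        assert fam.orientation_class == "DR"


class TestBruteForceEquivalence:
    @pytest.mark.parametrize("min_len", [20, 40])
    def test_exact_repeats_match_oracle(self, min_len):
        base = random_dna(31, 4000)
        r1 = random_dna(32, 120)
        r2 = random_dna(33, 60)
        seq = (
            base[:500] + r1 + base[500:1500] + revcomp(r1)
            + base[1500:2500] + r2 + base[2500:3200] + r2 + base[3200:]
        )
        g = CircularGenome("g", seq, circular=False)
        oracle = brute_force_exact_pairs(seq, min_len)
        pts = repeat_dotplot(g, min_len=min_len, seed_k=min(min_len, 31), exact_only=True)
        found = {
            (x, y, ln, o) for x, y, ln, o in pts if (x, y) != (1, 1) and x < y
        }
        assert found == oracle

    def test_oracle_confirms_absence(self):
        seq = random_dna(34, 3000)
        assert brute_force_exact_pairs(seq, 100) == set()
        g = CircularGenome("g", seq, circular=False)
        assert find_repeat_families(g, min_len=100) == []


def test_dotplot_mirrors_and_diagonal():
    base = random_dna(35, 8000)
    rep = random_dna(36, 300)
    g = CircularGenome("g", base[:1000] + rep + base[1000:5000] + rep + base[5000:])
    pts = repeat_dotplot(g, min_len=100)
    assert (1, 1, g.length, "+") in pts
    off = [(x, y) for x, y, _, _ in pts if (x, y) != (1, 1)]
    assert all((y, x) in off for x, y in off)
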