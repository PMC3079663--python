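"""Six-frame ORF discovery, uniqueness classes, CMS-candidate geometry."""
import pytest
from Bio.Seq import Seq

from mitodiff.model import CircularGenome, FeatureAnnotation, OrientedInterval, revcomp
from mitodiff.orfs import classify_unique_orfs, find_orfs, flag_cms_candidates

from conftest import random_codons, random_dna

_STOPS = ("TAA", "TAG", "TGA")


def orf_scan_oracle(seq: str, circular: bool, min_len: int) -> set[tuple]:
    """Independent per-ATG six-frame scan.

    For every ATG, extend codon-wise to the first stop; keep the ORF iff no
    in-frame ATG without an intervening stop precedes it (the longest-per-
    stop rule). Returns canonical (forward_start0, length, strand) tuples.
    """
    L = len(seq)
    out: set[tuple] = set()
    for strand in "+-":
        s = seq if strand == "+" else revcomp(seq)
        work = s + s if circular else s
        n = len(work)
        for p in range(min(L, n - 2)):
            if work[p : p + 3] != "ATG":
                continue
            # superseded by an earlier ATG sharing the stop?
            q = p - 3
            superseded = False
            while q >= 0:
                c = work[q : q + 3]
                if c in _STOPS:
                    break
                if c == "ATG":
                    superseded = True
                    break
                q -= 3
            if superseded:
                continue
            e = p + 3
            while e + 3 <= n and work[e : e + 3] not in _STOPS:
                e += 3
            if e + 3 > n:
                continue  # no stop before running out of sequence
            length = e + 3 - p
            if length < min_len or length > L:
                continue
            if strand == "+":
                start0 = p % L if circular else p
            else:
                start0 = (L - (p % L) - length) % L if circular else L - p - length
            out.add((start0, length, strand))
    return out


def _found_set(genome: CircularGenome, min_len: int) -> set[tuple]:
    out = set()
    for rec in find_orfs(genome, min_len):
        for c in rec.copies:
            if c.wraps_origin:
                start0 = c.start - 1
            else:
                start0 = c.lo - 1 if c.strand == "+" else c.lo - 1
            out.add((start0, rec.length, c.strand))
    return out


class TestFindOrfs:
    def test_no_atg_no_orfs(self):
        g = CircularGenome("g", "CCTTCCTTGG" * 60, circular=False)
        assert find_orfs(g, min_len=30) == []

    def test_planted_reverse_orf_exact(self):
        bg = random_dna(71, 9000)
        orf = "ATG" + random_codons(72, 98) + "TAA"  # 300 bp
        g = CircularGenome("g", bg[:4000] + revcomp(orf) + bg[4000:])
        hits = [o for o in find_orfs(g, 300) if o.length == 300]
        assert len(hits) == 1
        (c,) = hits[0].copies
        assert c.printed() == (4300, 4001)
        assert hits[0].frame >= 4

    def test_origin_spanning_orf_circular_only(self):
        bg = random_dna(73, 5000)
        orf = "ATG" + random_codons(74, 98) + "TAG"
        base = CircularGenome("c", bg[:1000] + orf + bg[1000:])
        cut_mid_orf = base.rotated(1150)
        circ = [o for o in find_orfs(cut_mid_orf, 300) if o.length == 300]
        assert len(circ) == 1
        assert circ[0].copies[0].wraps_origin
        linear = CircularGenome("l", cut_mid_orf.sequence, circular=False)
        assert [o for o in find_orfs(linear, 300) if o.copies[0].wraps_origin] == []

    @pytest.mark.parametrize("min_len", [150, 300, 600])
    def test_equivalence_with_six_frame_oracle(self, min_len):
        bg = random_dna(75, 8000)
        big = "ATG" + random_codons(76, 250) + "TAA"  # 756 bp, both thresholds
        g = CircularGenome("g", bg[:2000] + big + bg[2000:6000] + revcomp(big) + bg[6000:])
        assert _found_set(g, min_len) == orf_scan_oracle(g.sequence, True, min_len)
        lin = CircularGenome("l", g.sequence, circular=False)
        assert _found_set(lin, min_len) == orf_scan_oracle(g.sequence, False, min_len)

    def test_every_orf_translates_cleanly(self):
        g = CircularGenome("g", random_dna(77, 10_000))
        for rec in find_orfs(g, 150):
            prot = str(Seq(rec.copies[0].extract(g.sequence)).translate())
            assert prot.endswith("*")
            assert "*" not in prot[:-1]
            assert rec.length % 3 == 0

    def test_rotation_invariance(self):
        g = CircularGenome("g", random_dna(78, 6000))
        ref = {(rec.length, c.strand) for rec in find_orfs(g, 150) for c in rec.copies}
        for k in (17, 2500, 5999):
            rot = {(rec.length, c.strand) for rec in find_orfs(g.rotated(k), 150) for c in rec.copies}
            assert rot == ref

    def test_identical_copies_merge(self):
        bg = random_dna(79, 9000)
        orf = "ATG" + random_codons(80, 120) + "TGA"
        g = CircularGenome("g", bg[:2000] + orf + bg[2000:6000] + orf + bg[6000:])
        hits = [o for o in find_orfs(g, 300) if o.length == len(orf)]
        assert len(hits) == 1
        assert len(hits[0].copies) == 2


@pytest.fixture(scope="module")
def comparator():
    return CircularGenome("B", random_dna(81, 30_000))


@pytest.fixture(scope="module")
def toy_ct():
    return CircularGenome("ct", random_dna(82, 10_000))


class TestClassifyUniqueOrfs:
    def test_chimera_from_distant_fragments(self, comparator, toy_ct):
        b = comparator.sequence
        f1, f2 = b[2000:2250], revcomp(b[20000:20200])
        fused = list(("ATG" + f1[3:] + f2)[:450])
        for i in range(3, 444, 3):
            if "".join(fused[i : i + 3]) in _STOPS:
                fused[i] = "C"
        fused[447:450] = list("TAA")
        a = CircularGenome("A", b[:9000] + "TAA" + "".join(fused) + b[9000:])
        orfs = [o for o in find_orfs(a, 300) if o.copies[0].lo == 9004]
        assert len(orfs) == 1
        classify_unique_orfs(orfs, a, comparator, ct_genome=toy_ct)
        assert orfs[0].uniqueness_class == "two-discrete-segments"

    def test_ct_derived_orf(self, comparator, toy_ct):
        ct = toy_ct
        frag = list(ct.sequence[1000:1450])
        frag[0:3] = list("ATG")
        for i in range(3, 444, 3):
            if "".join(frag[i : i + 3]) in _STOPS:
                frag[i] = "C"
        frag[447:450] = list("TAA")
        a = CircularGenome(
            "A", comparator.sequence[:5000] + "TAA" + "".join(frag) + comparator.sequence[5000:]
        )
        orfs = [o for o in find_orfs(a, 300) if o.copies[0].lo == 5004]
        classify_unique_orfs(orfs, a, comparator, ct_genome=ct)
        assert orfs[0].uniqueness_class == "ct-derived"

    def test_shared_orf_not_unique(self, comparator, toy_ct):
        orf = "ATG" + random_codons(83, 150) + "TAA"
        b2 = CircularGenome("B2", comparator.sequence[:8000] + orf + comparator.sequence[8000:])
        a = CircularGenome("A", b2.sequence)  # identical genomes
        orfs = [o for o in find_orfs(a, 300) if o.length == len(orf)]
        classify_unique_orfs(orfs, a, b2, ct_genome=toy_ct)
        assert all(o.uniqueness_class == "not-unique" for o in orfs)

    def test_novel_orf_and_missing_ct_warns(self, comparator):
        orf = "ATG" + random_codons(84, 150) + "TAA"
        a = CircularGenome("A", comparator.sequence[:5000] + "TAA" + orf + comparator.sequence[5000:])
        orfs = [o for o in find_orfs(a, 300) if o.copies[0].lo == 5004]
        with pytest.warns(UserWarning):
            classify_unique_orfs(orfs, a, comparator, ct_genome=None)
        assert orfs[0].uniqueness_class == "novel"


class TestCmsFlags:
    def _mk(self, orf_iv, gene_iv, L=20_000):
        orf_rec = find_orfs  # unused; records built directly
        from mitodiff.orfs import OrfRecord

        rec = OrfRecord("orf1", [orf_iv], 300, 1)
        gene = FeatureAnnotation("cox1", "CDS", [gene_iv], "A")
        return rec, gene, L

    def test_vicinity_of_gene_upstream_same_strand(self):
        rec, gene, L = self._mk(
            OrientedInterval(4201, 4500, "+"), OrientedInterval(5001, 6200, "+")
        )
        flag_cms_candidates([rec], [gene], L, upstream_window=2000)
        assert rec.cms_flags == {"vicinity-of-gene"}

    def test_vicinity_respects_strand_and_window(self):
        rec, gene, L = self._mk(
            OrientedInterval(4500, 4201, "-"), OrientedInterval(5001, 6200, "+")
        )
        flag_cms_candidates([rec], [gene], L)
        assert "vicinity-of-gene" not in rec.cms_flags
        rec2, gene2, _ = self._mk(
            OrientedInterval(1201, 1500, "+"), OrientedInterval(5001, 6200, "+")
        )
        flag_cms_candidates([rec2], [gene2], L, upstream_window=2000)
        assert rec2.cms_flags == set()

    def test_overlaps_gene_five_prime(self):
        rec, gene, L = self._mk(
            OrientedInterval(4801, 5100, "+"), OrientedInterval(5001, 5230, "+")
        )
        flag_cms_candidates([rec], [gene], L)
        assert "overlaps-gene" in rec.cms_flags

    def test_isolated_orf_unflagged(self):
        rec, gene, L = self._mk(
            OrientedInterval(12001, 12300, "+"), OrientedInterval(5001, 6200, "+")
        )
        flag_cms_candidates([rec], [gene], L)
        assert rec.cms_flags == set()
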