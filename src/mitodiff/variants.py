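"""CDS substitution calling and classification.

Orthologous protein-coding genes of a CMS line and its maintainer are
aligned end to end; substitution columns become SNP records carrying the
codon index, the encoded amino acids (standard genetic code, three-letter
names), the synonymous/non-synonymous effect and the transition/
transversion class — the layout of published mitochondrial gene-difference
tables. The first (maintainer) sequence provides coordinates and reference
bases.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

from Bio.Align import PairwiseAligner
from Bio.Seq import Seq
from Bio.SeqUtils import seq3

from .model import CircularGenome, FeatureAnnotation

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")
_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class SnpRecord:
    """One substitution between orthologous CDS, reference coordinates."""

    gene: str
    cds_pos: int  # 1-based in reference CDS
    ref_base: str
    alt_base: str
    codon_index: int
    ref_aa: str  # 3-letter
    alt_aa: str
    effect: str  # 'S' or 'N'
    substitution_class: str  # transition / transversion
    low_confidence: bool = False  # within 2 bp of an alignment gap

    @property
    def label(self) -> str:
        """Table-style shorthand, e.g. '204T-G'."""
        return f"{self.cds_pos}{self.ref_base}-{self.alt_base}"

    def to_dict(self) -> dict:
        return {
            "gene": self.gene,
            "nucleic_acid": self.label,
            "amino_acid": ""
            if self.effect == "S"
            else f"{self.codon_index}{self.ref_aa}-{self.alt_aa}",
            "mutation_type": self.effect,
            "snp_type": self.substitution_class,
            "low_confidence": self.low_confidence,
        }


def codon_index(cds_pos: int) -> int:
    """1-based codon number holding CDS nucleotide position ``cds_pos``."""
    if cds_pos < 1:
        raise ValueError("cds_pos must be >= 1")
    return math.ceil(cds_pos / 3)


def substitution_class(ref_base: str, alt_base: str) -> str:
    """'transition' for purine<->purine or pyrimidine<->pyrimidine."""
    ref_base, alt_base = ref_base.upper(), alt_base.upper()
    if ref_base not in _BASES or alt_base not in _BASES:
        raise ValueError(f"invalid bases {ref_base!r}/{alt_base!r}")
    if ref_base == alt_base:
        raise ValueError("not a substitution: bases identical")
    pair = {ref_base, alt_base}
    if pair <= _PURINES or pair <= _PYRIMIDINES:
        return "transition"
    return "transversion"


def effect_class(
    ref_codon: str, alt_codon: str, code_table: int = 1
) -> tuple[str, str, str]:
    """(effect, ref_aa, alt_aa) for a codon pair under a genetic code.

    Effect is 'S' iff both codons encode the same amino acid. Amino acids
    are 3-letter names ('Ter' for a stop).
    """
    ref_codon, alt_codon = ref_codon.upper(), alt_codon.upper()
    if len(ref_codon) != 3 or len(alt_codon) != 3:
        raise ValueError("codons must be length 3")
    ref_aa1 = str(Seq(ref_codon).translate(table=code_table))
    alt_aa1 = str(Seq(alt_codon).translate(table=code_table))
    effect = "S" if ref_aa1 == alt_aa1 else "N"
    return effect, seq3(ref_aa1), seq3(alt_aa1)


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -8
    aligner.extend_gap_score = -1
    return aligner


def align_cds_pair(cds_ref: str, cds_alt: str) -> list[tuple[int | None, int | None]]:
    """Global alignment with affine gaps, as a per-column coordinate map.

    Each element is (ref_pos0, alt_pos0); a ``None`` marks a gap on that
    side. Lengths need not be multiples of three (truncated pseudogenes
    are allowed).
    """
    if not cds_ref or not cds_alt:
        raise ValueError("empty CDS sequence")
    aln = _make_aligner().align(cds_ref.upper(), cds_alt.upper())[0]
    cols: list[tuple[int | None, int | None]] = []
    rpos = apos = 0
    blocks_r, blocks_a = aln.aligned
    for (rs, re), (as_, ae) in zip(blocks_r, blocks_a):
        while rpos < rs:
            cols.append((rpos, None))
            rpos += 1
        while apos < as_:
            cols.append((None, apos))
            apos += 1
        for off in range(re - rs):
            cols.append((rpos + off, apos + off))
        rpos, apos = re, ae
    while rpos < len(cds_ref):
        cols.append((rpos, None))
        rpos += 1
    while apos < len(cds_alt):
        cols.append((None, apos))
        apos += 1
    return cols


def call_snps(gene: str, cds_ref: str, cds_alt: str, code_table: int = 1) -> list[SnpRecord]:
    """SNP records for every substitution column of the aligned CDS pair.

    Gap columns are excluded from calling but substitutions within 2 bp of
    one are flagged low-confidence. Amino-acid changes account for all
    substitutions within the same reference codon (multi-hit codons report
    the same codon-level change on each row, as printed tables do).
    """
    cds_ref, cds_alt = cds_ref.upper(), cds_alt.upper()
    cols = align_cds_pair(cds_ref, cds_alt)
    gap_cols = {i for i, (r, a) in enumerate(cols) if r is None or a is None}
    subs: list[tuple[int, int, int]] = []  # (col, ref_pos0, alt_pos0)
    for i, (r, a) in enumerate(cols):
        if r is None or a is None:
            continue
        if cds_ref[r] != cds_alt[a]:
            subs.append((i, r, a))
    # alternate base per reference codon, applying all its substitutions
    alt_by_refpos = {r: cds_alt[a] for _, r, a in subs}
    records: list[SnpRecord] = []
    for col, r, a in subs:
        pos1 = r + 1
        ci = codon_index(pos1)
        codon_start = 3 * (ci - 1)
        ref_codon = cds_ref[codon_start : codon_start + 3]
        if len(ref_codon) < 3:  # trailing partial codon of a pseudogene
            effect, ref_aa, alt_aa = "N", "---", "---"
        else:
            alt_codon = "".join(
                alt_by_refpos.get(codon_start + k, ref_codon[k]) for k in range(3)
            )
            effect, ref_aa, alt_aa = effect_class(ref_codon, alt_codon, code_table)
        low_conf = any(abs(col - g) <= 2 for g in gap_cols)
        records.append(
            SnpRecord(
                gene=gene,
                cds_pos=pos1,
                ref_base=cds_ref[r],
                alt_base=cds_alt[a],
                codon_index=ci,
                ref_aa=ref_aa,
                alt_aa=alt_aa,
                effect=effect,
                substitution_class=substitution_class(cds_ref[r], cds_alt[a]),
                low_confidence=low_conf,
            )
        )
    return records


def summarize_snps(records: list[SnpRecord]) -> dict[str, int]:
    """Tallies: total, S, N, transitions, transversions, genes."""
    return {
        "total": len(records),
        "S": sum(1 for r in records if r.effect == "S"),
        "N": sum(1 for r in records if r.effect == "N"),
        "transitions": sum(1 for r in records if r.substitution_class == "transition"),
        "transversions": sum(
            1 for r in records if r.substitution_class == "transversion"
        ),
        "genes": len({r.gene for r in records}),
    }


def cds_sequence(genome: CircularGenome, features: list[FeatureAnnotation], name: str) -> str:
    """Spliced CDS of a named gene."""
    for f in features:
        if f.name == name:
            return f.extract(genome)
    raise KeyError(f"gene {name!r} not annotated on {genome.id}")


def compare_gene_sets(
    ref_genome: CircularGenome,
    ref_features: list[FeatureAnnotation],
    alt_genome: CircularGenome,
    alt_features: list[FeatureAnnotation],
    code_table: int = 1,
) -> list[SnpRecord]:
    """SNPs across every protein-coding gene annotated in both genomes."""
    alt_by_name = {f.name: f for f in alt_features if f.kind == "CDS"}
    records: list[SnpRecord] = []
    for f in ref_features:
        if f.kind != "CDS" or f.name not in alt_by_name:
            continue
        records.extend(
            call_snps(
                f.name,
                f.extract(ref_genome),
                alt_by_name[f.name].extract(alt_genome),
                code_table,
            )
        )
    return records
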