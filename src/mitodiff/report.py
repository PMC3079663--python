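"""Genome summaries, percentage conventions and table rendering.

Census percentages follow the conventions of the printed comparison:
half-up rounding, two decimals for genome-fraction censuses, one decimal
for coverage percentages, two decimals for repeat identity (with an
integral 100 printed bare).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from ._util import round_half_up
from .homology import HomologySegment, UniqueRegion, _merge_intervals
from .model import CircularGenome, FeatureAnnotation, gc_content
from .orfs import OrfRecord
from .repeats import RepeatFamily
from .variants import SnpRecord


def pct(part: int, whole: int, decimals: int = 2) -> float:
    """100 * part / whole, rounded half-up."""
    if whole <= 0:
        raise ValueError("whole must be positive")
    if not 0 <= part <= whole:
        raise ValueError("part must lie in [0, whole]")
    return round_half_up(100.0 * part / whole, decimals)


@dataclass
class GenomeSummary:
    length: int
    gc: float
    gene_bp: int = 0
    gene_pct: float = 0.0
    orf_count: int = 0
    orf_bp: int = 0
    orf_pct: float = 0.0
    unique_bp: int = 0
    unique_pct: float = 0.0
    ct_homology_bp: int = 0
    ct_homology_pct: float = 0.0
    element_bp: int = 0
    element_pct: float = 0.0

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _union_bp(pieces: list[tuple[int, int]]) -> int:
    return sum(e - s for s, e in _merge_intervals(pieces))


def summarize(
    genome: CircularGenome,
    features: list[FeatureAnnotation] | None = None,
    orfs: list[OrfRecord] | None = None,
    unique: list[UniqueRegion] | None = None,
    ct_segments: list[HomologySegment] | None = None,
    element_hits: list[tuple[int, int]] | None = None,
) -> GenomeSummary:
    """Census of one genome; bp fields are interval-union sizes.

    Unique regions are the exception: every copy counts, matching the
    published convention for line-specific totals.
    """
    L = genome.length
    s = GenomeSummary(length=L, gc=gc_content(genome))
    if features:
        for f in features:
            if f.genome_id and f.genome_id != genome.id:
                raise ValueError(
                    f"feature {f.name} belongs to {f.genome_id!r}, not {genome.id!r}"
                )
        pieces = [p for f in features for seg in f.segments for p in seg.slices(L)]
        s.gene_bp = _union_bp(pieces)
        s.gene_pct = pct(s.gene_bp, L, 2)
    if orfs:
        pieces = [p for o in orfs for c in o.copies for p in c.slices(L)]
        s.orf_count = len(orfs)
        s.orf_bp = _union_bp(pieces)
        s.orf_pct = pct(s.orf_bp, L, 2)
    if unique:
        s.unique_bp = sum(r.length for r in unique)
        s.unique_pct = pct(s.unique_bp, L, 2)
    if ct_segments:
        pieces = [p for seg in ct_segments for p in seg.query_iv.slices(L)]
        s.ct_homology_bp = _union_bp(pieces)
        s.ct_homology_pct = pct(s.ct_homology_bp, L, 2)
    if element_hits:
        s.element_bp = _union_bp(list(element_hits))
        s.element_pct = pct(s.element_bp, L, 2)
    return s


# ---------------------------------------------------------------------------
# table rendering (TSV, layouts matching the printed tables)


def _fmt_identity(x: float) -> str:
    r = round_half_up(x, 2)
    return "100" if r == 100.0 else f"{r:.2f}"


def render_repeat_table(families: list[RepeatFamily]) -> str:
    lines = ["id\ttype\tsize\tcopies\tdifference\tidentity"]
    for f in families:
        copies = ";".join("{}-{}".format(*c.printed()) for c in f.copies)
        lines.append(
            f"{f.id}\t{f.orientation_class}\t{f.aligned_length}\t{copies}"
            f"\t{f.diff_summary}\t{_fmt_identity(f.identity)}"
        )
    return "\n".join(lines) + "\n"


def render_snp_table(records: list[SnpRecord]) -> str:
    lines = ["gene\tnucleic_acid\tamino_acid\tmutation_type\tsnp_type"]
    for r in records:
        aa = "" if r.effect == "S" else f"{r.codon_index}{r.ref_aa}-{r.alt_aa}"
        lines.append(
            f"{r.gene}\t{r.label}\t{aa}\t{r.effect}\t{r.substitution_class}"
        )
    return "\n".join(lines) + "\n"


def parse_snp_table(text: str) -> list[SnpRecord]:
    """Inverse of :func:`render_snp_table` (modulo recomputed fields)."""
    from .datasets import _AA_LABEL, _SNP_LABEL
    from .variants import codon_index

    records = []
    lines = [ln for ln in text.splitlines() if ln.strip()]
    for ln in lines[1:]:
        gene, nuc, aa_s, eff, cls = ln.split("\t")
        m = _SNP_LABEL.match(nuc)
        aa = _AA_LABEL.match(aa_s) if aa_s else None
        records.append(
            SnpRecord(
                gene=gene,
                cds_pos=int(m.group(1)),
                ref_base=m.group(2),
                alt_base=m.group(3),
                codon_index=int(aa.group(1)) if aa else codon_index(int(m.group(1))),
                ref_aa=aa.group(2) if aa else "",
                alt_aa=aa.group(3) if aa else "",
                effect=eff,
                substitution_class=cls,
            )
        )
    return records


def render_orf_table(orfs: list[OrfRecord]) -> str:
    lines = ["id\tcopies\tsize\thomology_class\tcms_flags"]
    for o in orfs:
        copies = ";".join("{}-{}".format(*c.printed()) for c in o.copies)
        lines.append(
            f"{o.id}\t{copies}\t{o.length}\t{o.uniqueness_class}\t"
            + ",".join(sorted(o.cms_flags))
        )
    return "\n".join(lines) + "\n"


def render_unique_region_table(regions: list[UniqueRegion]) -> str:
    lines = ["id\tstart\tend\tlength\tgroup\tgroup_size\tsource_class"]
    for r in regions:
        s, e = r.iv.printed()
        lines.append(
            f"{r.id}\t{s}\t{e}\t{r.length}\t{r.copy_group}\t{r.group_size}\t{r.source_class}"
        )
    return "\n".join(lines) + "\n"


def write_tables(results: dict[str, str], out_dir: str | Path) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, text in results.items():
        p = out_dir / name
        p.write_text(text)
        written.append(p)
    return written
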