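"""Readers and writers: FASTA sequences, GFF3 / 5-column TSV feature tables.

GFF3 is the primary annotation format. A minimal tab-separated dialect
(name, kind, start, end, strand) is also accepted for hand-written
fixtures; in that dialect descending coordinates denote the reverse
strand, mirroring how organelle repeat/ORF tables are printed.
"""
from __future__ import annotations

import json
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    CircularGenome,
    FeatureAnnotation,
    FORWARD,
    OrientedInterval,
    REVERSE,
)


class ParseError(ValueError):
    """Malformed input record; message carries the offending line number."""


_GFF_KIND = {
    "CDS": "CDS",
    "gene": "CDS",
    "rRNA": "rRNA",
    "tRNA": "tRNA",
    "ORF": "ORF",
}
_KIND_GFF = {"CDS": "CDS", "rRNA": "rRNA", "tRNA": "tRNA", "ORF": "ORF", "other": "region"}


def read_genome(path: str | Path, circular: bool = True) -> CircularGenome:
    """Load the first FASTA record as a genome."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ParseError(f"{path}: no FASTA records")
    rec = records[0]
    return CircularGenome(rec.id, str(rec.seq), circular)


def read_genomes(path: str | Path, circular: bool = True) -> list[CircularGenome]:
    return [
        CircularGenome(rec.id, str(rec.seq), circular)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_genome(genomes: CircularGenome | list[CircularGenome], path: str | Path) -> None:
    if isinstance(genomes, CircularGenome):
        genomes = [genomes]
    records = [
        SeqRecord(Seq(g.sequence), id=g.id, description="") for g in genomes
    ]
    SeqIO.write(records, str(path), "fasta")


def read_features(path: str | Path) -> list[FeatureAnnotation]:
    """Load feature annotations from GFF3 or the 5-column TSV dialect.

    Rows sharing a name are merged into one multi-segment feature (cis-spliced
    exons), segments kept in file order.
    """
    path = Path(path)
    text = path.read_text()
    is_gff = path.suffix.lower() in (".gff", ".gff3") or text.startswith("##gff")
    rows: list[tuple[str, str, OrientedInterval, str]] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.rstrip("\n").split("\t")
        if is_gff:
            rows.append(_parse_gff_row(cols, lineno, path.name))
        else:
            rows.append(_parse_tsv_row(cols, lineno, path.name))
    feats: dict[str, FeatureAnnotation] = {}
    for name, kind, iv, genome_id in rows:
        if name in feats:
            feats[name].segments.append(iv)
        else:
            feats[name] = FeatureAnnotation(name, kind, [iv], genome_id)
    return list(feats.values())


def _parse_gff_row(cols: list[str], lineno: int, fname: str):
    if len(cols) != 9:
        raise ParseError(f"{fname}:{lineno}: expected 9 GFF3 columns, got {len(cols)}")
    seqid, _source, ftype, start_s, end_s, _score, strand, _phase, attrs = cols
    try:
        start, end = int(start_s), int(end_s)
    except ValueError:
        raise ParseError(f"{fname}:{lineno}: non-integer coordinates") from None
    if start > end:
        raise ParseError(f"{fname}:{lineno}: GFF3 requires start <= end")
    if strand not in (FORWARD, REVERSE):
        raise ParseError(f"{fname}:{lineno}: bad strand {strand!r}")
    name = seqid
    for kv in attrs.split(";"):
        if kv.startswith("Name="):
            name = kv[5:]
        elif kv.startswith("ID=") and name == seqid:
            name = kv[3:]
    kind = _GFF_KIND.get(ftype, "other")
    return name, kind, OrientedInterval(start, end, strand), seqid


def _parse_tsv_row(cols: list[str], lineno: int, fname: str):
    if len(cols) < 4:
        raise ParseError(f"{fname}:{lineno}: expected >= 4 TSV columns")
    name, kind = cols[0], cols[1]
    try:
        start, end = int(cols[2]), int(cols[3])
    except ValueError:
        raise ParseError(f"{fname}:{lineno}: non-integer coordinates") from None
    strand = cols[4] if len(cols) > 4 and cols[4] in (FORWARD, REVERSE) else FORWARD
    if start > end:  # descending coordinates mean reverse strand
        strand = REVERSE
    return name, kind, OrientedInterval.from_printed(start, end), ""


def write_features(features: list[FeatureAnnotation], path: str | Path, fmt: str = "gff3") -> None:
    path = Path(path)
    lines: list[str] = []
    if fmt == "gff3":
        lines.append("##gff-version 3")
        for f in features:
            for seg in f.segments:
                lines.append(
                    "\t".join(
                        [
                            f.genome_id or f.name,
                            "mitodiff",
                            _KIND_GFF.get(f.kind, "region"),
                            str(seg.lo),
                            str(seg.hi),
                            ".",
                            seg.strand,
                            ".",
                            f"Name={f.name}",
                        ]
                    )
                )
    elif fmt == "tsv":
        for f in features:
            for seg in f.segments:
                s, e = seg.printed()
                lines.append("\t".join([f.name, f.kind, str(s), str(e), seg.strand]))
    else:
        raise ValueError(f"unknown feature format {fmt!r}")
    path.write_text("\n".join(lines) + "\n")


def dump_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonable) + "\n")


def _jsonable(o):
    if hasattr(o, "to_dict"):
        return o.to_dict()
    raise TypeError(f"not JSON-serializable: {type(o)}")
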