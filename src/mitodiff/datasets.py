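"""Bundled reference tables of the wheat Ks3/Km3 mitochondrial comparison.

Machine-readable copies of the published repeat, SNP and unique-ORF tables
for the K-type CMS line Ks3 (master circle 647,559 bp) versus its
maintainer Km3 (452,526 bp). They serve as worked-example inputs: the
repeat table feeds the reduced-genome-size estimate, the SNP table the
summary tallies, the ORF table the interval-arithmetic conventions.
"""
from __future__ import annotations

import re
from importlib import resources

import pandas as pd

from .model import OrientedInterval
from .repeats import RepeatFamily
from .variants import SnpRecord, codon_index, substitution_class

KS3_LENGTH = 647_559
KM3_LENGTH = 452_526

_SNP_LABEL = re.compile(r"^(\d+)([ACGT])-([ACGT])$")
_AA_LABEL = re.compile(r"^(\d+)([A-Za-z]{3})-([A-Za-z]{3})$")


def _read(name: str) -> pd.DataFrame:
    with resources.files("mitodiff.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", keep_default_na=False)


def ks3_repeat_table() -> pd.DataFrame:
    """The 29 repeat families (> 100 bp) of the Ks3 master circle."""
    return _read("ks3_repeats.tsv")


def ks3_repeat_families() -> list[RepeatFamily]:
    """The repeat table as :class:`RepeatFamily` objects."""
    fams = []
    for _, row in ks3_repeat_table().iterrows():
        copies = [
            OrientedInterval.from_printed(*map(int, c.split("-")))
            for c in row["copies"].split(";")
        ]
        fams.append(
            RepeatFamily(
                id=row["id"],
                aligned_length=int(row["size"]),
                copies=copies,
                orientation_class=row["type"],
                diff_summary=row["difference"],
                identity=float(row["identity"]),
            )
        )
    return fams


def ks3_km3_snp_table() -> pd.DataFrame:
    """The 32 CDS substitutions between Km3 and Ks3 (Km3 as reference)."""
    return _read("ks3_km3_snps.tsv")


def ks3_km3_snp_records() -> list[SnpRecord]:
    records = []
    for _, row in ks3_km3_snp_table().iterrows():
        m = _SNP_LABEL.match(row["nucleic_acid"])
        pos, ref, alt = int(m.group(1)), m.group(2), m.group(3)
        aa = _AA_LABEL.match(row["amino_acid"]) if row["amino_acid"] else None
        records.append(
            SnpRecord(
                gene=row["gene"],
                cds_pos=pos,
                ref_base=ref,
                alt_base=alt,
                codon_index=int(aa.group(1)) if aa else codon_index(pos),
                ref_aa=aa.group(2) if aa else "",
                alt_aa=aa.group(3) if aa else "",
                effect=row["mutation_type"],
                substitution_class=row["snp_type"],
            )
        )
    return records


def ks3_unique_orf_table() -> pd.DataFrame:
    """The 22 ORFs unique to Ks3, with per-copy coordinates."""
    return _read("ks3_unique_orfs.tsv")
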