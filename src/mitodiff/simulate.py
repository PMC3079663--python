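"""Synthetic circular genome pairs with a known edit plan.

A "maintainer-like" ancestor genome (gene backbone plus intergenic
sequence at a target GC) is derived into a "CMS-like" variant by a
declarative :class:`EditPlan`: gene deletions, CDS substitutions with an
intended synonymous/non-synonymous effect, inversions, insertions sourced
from fresh random sequence, from a toy chloroplast genome, or from the
genome itself (planted repeat families), and chimeric ORFs fused from two
distant donor fragments. Every planted feature is reported back in final
variant coordinates as a :class:`TruthSet`, so each pipeline stage can be
checked against ground truth at desk scale.

All randomness flows from one explicit seed through spawned NumPy
generator streams; identical seeds give byte-identical output.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from Bio.Seq import Seq

from .model import CircularGenome, FORWARD, FeatureAnnotation, OrientedInterval, REVERSE, revcomp

_STOPS = ("TAA", "TAG", "TGA")
_BASES = np.array(list("ACGT"))
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

# gene backbone drawn from the standard plant mitochondrial complement;
# cox1/atp9 lead so CMS-geometry fixtures have their classic partners,
# rpl5 is present so the classic maintainer-only gene can be deleted
_CDS_NAMES = [
    "cox1", "atp9", "rpl5", "atp1", "atp4", "atp6", "atp8", "cob", "cox2",
    "cox3", "nad1", "nad2", "nad3", "nad4", "nad5", "nad6", "nad9", "rps1",
    "rps2", "rps3", "rps4", "rps12", "rps13", "rpl2", "rpl16", "matR",
    "mttB", "ccmFN",
]
_RNA_FEATURES = [("rrn18", "rRNA", 501), ("rrn26", "rRNA", 801), ("rrn5", "rRNA", 120),
                 ("trnM", "tRNA", 75), ("trnH", "tRNA", 75)]


@dataclass
class AncestorConfig:
    length: int = 50_000
    gc: float = 44.3  # percent, the wheat mitochondrial value
    gene_count: int = 20
    gene_length_range: tuple[int, int] = (300, 1500)


@dataclass
class Insertion:
    position: int  # 0-based ancestor coordinate (insertion point)
    length: int
    source: str  # 'random' | 'ct' | 'self-copy'
    label: str = ""
    ct_start: int | None = None
    group: str = ""  # insertions sharing a group get identical sequence


@dataclass
class RepeatPlant:
    source_start: int  # 0-based ancestor coordinate of copy-1
    length: int
    insert_positions: list[int] = field(default_factory=list)
    orientations: list[str] = field(default_factory=list)  # per inserted copy
    mismatches: int = 0
    indel_bp: int = 0
    label: str = ""


@dataclass
class CdsSubstitution:
    gene: str
    cds_pos: int  # 1-based in the gene CDS
    alt_base: str
    effect: str  # intended 'S' or 'N'


@dataclass
class ChimeraPlant:
    donors: list[tuple[int, int, str]]  # (0-based start, length, strand) in ancestor
    position: int  # 0-based ancestor insertion point
    label: str = ""


@dataclass
class EditPlan:
    seed: int
    insertions: list[Insertion] = field(default_factory=list)
    repeat_plants: list[RepeatPlant] = field(default_factory=list)
    cds_substitutions: list[CdsSubstitution] = field(default_factory=list)
    gene_deletions: list[str] = field(default_factory=list)
    chimera_plants: list[ChimeraPlant] = field(default_factory=list)
    inversions: list[tuple[int, int]] = field(default_factory=list)  # 0-based half-open

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TruthSet:
    """Planted features in final variant coordinates (1-based)."""

    unique_regions: list[dict] = field(default_factory=list)
    repeat_families: list[dict] = field(default_factory=list)
    snps: list[dict] = field(default_factory=list)
    chimeric_orfs: list[dict] = field(default_factory=list)
    deleted_genes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


class PlanError(ValueError):
    """The edit plan contains conflicting (overlapping) edits."""


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    g = gc / 200.0
    a = (100.0 - gc) / 200.0
    return "".join(rng.choice(_BASES, size=n, p=[a, g, g, a]))


def _random_codons(rng: np.random.Generator, n: int, gc: float) -> str:
    out: list[str] = []
    while len(out) < n:
        c = _random_dna(rng, 3, gc)
        if c not in _STOPS:
            out.append(c)
    return "".join(out)


def _orf_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    assert length % 3 == 0 and length >= 9
    stop = _STOPS[rng.integers(0, 3)]
    return "ATG" + _random_codons(rng, length // 3 - 2, gc) + stop


def generate_ancestor(
    config: AncestorConfig = AncestorConfig(), seed: int = 0
) -> tuple[CircularGenome, list[FeatureAnnotation]]:
    """A circular genome with a clean gene backbone.

    CDS features are valid ORFs (ATG..stop, no internal stops); rRNA/tRNA
    features are plain intervals; intergenic sequence is random at the
    target GC. Deterministic in ``seed``.
    """
    rng = np.random.default_rng(seed)
    gc = config.gc
    lo, hi = config.gene_length_range
    specs: list[tuple[str, str, int]] = []
    for name in _CDS_NAMES[: config.gene_count]:
        n = int(rng.integers(lo // 3, hi // 3 + 1)) * 3
        specs.append((name, "CDS", max(n, 300)))
    specs.extend(_RNA_FEATURES)
    total_genic = sum(s[2] for s in specs)
    n_f = len(specs)
    spare = config.length - total_genic
    if spare < n_f * 50:
        raise ValueError("config error: genome too short for the gene complement")
    # random intergenic gaps (each >= 50 bp) summing to the spare length
    weights = rng.random(n_f)
    gaps = (weights / weights.sum() * (spare - n_f * 50)).astype(int) + 50
    gaps[-1] += spare - int(gaps.sum())
    seq = list(_random_dna(rng, config.length, gc))
    features: list[FeatureAnnotation] = []
    pos = 0
    order = rng.permutation(n_f)
    for idx in order:
        name, kind, length = specs[idx]
        pos += int(gaps[idx])
        strand = FORWARD if rng.random() < 0.5 else REVERSE
        if kind == "CDS":
            orf = _orf_sequence(rng, length, gc)
            insert = orf if strand == FORWARD else revcomp(orf)
            seq[pos : pos + length] = list(insert)
        iv = (
            OrientedInterval(pos + 1, pos + length, FORWARD)
            if strand == FORWARD
            else OrientedInterval(pos + length, pos + 1, REVERSE)
        )
        features.append(FeatureAnnotation(name, kind, [iv], "ancestor"))
        pos += length
    genome = CircularGenome("ancestor", "".join(seq), True)
    features.sort(key=lambda f: f.span_start())
    return genome, features


def generate_chloroplast(length: int = 10_000, seed: int = 0) -> CircularGenome:
    """Toy chloroplast genome: a random circle used as the ct source pool."""
    rng = np.random.default_rng(seed)
    return CircularGenome("ct", _random_dna(rng, length, 38.0), True)


# ---------------------------------------------------------------------------
# plan application


def _check_overlaps(spans: list[tuple[int, int, str]]) -> None:
    spans = sorted(spans)
    conflicts = [
        f"{d1} ({s1}-{e1}) overlaps {d2} ({s2}-{e2})"
        for (s1, e1, d1), (s2, e2, d2) in zip(spans, spans[1:])
        if s2 < e1
    ]
    if conflicts:
        raise PlanError("conflicting edits: " + "; ".join(conflicts))


def derive_variant(
    ancestor: CircularGenome,
    features: list[FeatureAnnotation],
    plan: EditPlan,
    ct: CircularGenome | None = None,
) -> tuple[CircularGenome, list[FeatureAnnotation], TruthSet]:
    """Apply an edit plan; return the variant genome, features and truth.

    Edits apply in a fixed canonical order — deletions, substitutions,
    inversions, insertions (plain, repeat copies, chimeras) — and all
    truth coordinates are lifted through every length-changing edit.
    """
    rng = np.random.default_rng(np.random.SeedSequence(plan.seed).spawn(1)[0])
    feat_by_name = {f.name: f for f in features}
    truth = TruthSet(deleted_genes=list(plan.gene_deletions))

    # --- validation ------------------------------------------------------
    spans: list[tuple[int, int, str]] = []
    for g in plan.gene_deletions:
        f = feat_by_name.get(g)
        if f is None:
            raise PlanError(f"deletion of unknown gene {g!r}")
        seg = f.segments[0]
        spans.append((seg.lo - 1, seg.hi, f"delete:{g}"))
    for s, e in plan.inversions:
        spans.append((s, e, f"invert:{s}-{e}"))
    points = (
        [(ins.position, f"insert:{ins.label or ins.source}") for ins in plan.insertions]
        + [(p, f"repeat:{rp.label}") for rp in plan.repeat_plants for p in rp.insert_positions]
        + [(ch.position, f"chimera:{ch.label}") for ch in plan.chimera_plants]
    )
    for p, desc in points:
        spans.append((p, p + 1, desc))
    _check_overlaps(spans)
    for sub in plan.cds_substitutions:
        f = feat_by_name.get(sub.gene)
        if f is None or f.name in plan.gene_deletions:
            raise PlanError(f"substitution in missing gene {sub.gene!r}")
        seg = f.segments[0]
        for s, e in plan.inversions:
            if seg.lo - 1 < e and s < seg.hi:
                raise PlanError(f"substitution gene {sub.gene} inside an inversion")

    # --- 1. deletions ----------------------------------------------------
    seq = ancestor.sequence
    deletions = sorted(
        (feat_by_name[g].segments[0].lo - 1, feat_by_name[g].segments[0].hi)
        for g in plan.gene_deletions
    )
    for s, e in reversed(deletions):
        seq = seq[:s] + seq[e:]

    def shift_del(p: int) -> int:
        return p - sum(e - s for s, e in deletions if e <= p)

    var_features: list[FeatureAnnotation] = []
    for f in features:
        if f.name in plan.gene_deletions:
            continue
        segs = []
        for seg in f.segments:
            lo0, hi0 = shift_del(seg.lo - 1), shift_del(seg.hi)
            segs.append(
                OrientedInterval(lo0 + 1, hi0, FORWARD)
                if seg.strand == FORWARD
                else OrientedInterval(hi0, lo0 + 1, REVERSE)
            )
        var_features.append(FeatureAnnotation(f.name, f.kind, segs, "variant"))
    vf_by_name = {f.name: f for f in var_features}

    # --- 2. CDS substitutions -------------------------------------------
    seq_l = list(seq)
    for sub in plan.cds_substitutions:
        f = vf_by_name[sub.gene]
        seg = f.segments[0]
        ref_cds = f.extract(CircularGenome("tmp", seq))
        ref_base = ref_cds[sub.cds_pos - 1]
        if ref_base == sub.alt_base:
            raise PlanError(f"{sub.gene}:{sub.cds_pos}: alt equals reference base")
        if seg.strand == FORWARD:
            gpos = seg.lo - 1 + (sub.cds_pos - 1)
            seq_l[gpos] = sub.alt_base
        else:
            gpos = seg.hi - 1 - (sub.cds_pos - 1)
            seq_l[gpos] = _COMP[sub.alt_base]
        ci = (sub.cds_pos + 2) // 3
        cstart = 3 * (ci - 1)
        ref_codon = ref_cds[cstart : cstart + 3]
        alt_codon = (
            ref_codon[: (sub.cds_pos - 1) % 3]
            + sub.alt_base
            + ref_codon[(sub.cds_pos - 1) % 3 + 1 :]
        )
        ref_aa = str(Seq(ref_codon).translate())
        alt_aa = str(Seq(alt_codon).translate())
        pair = {ref_base, sub.alt_base}
        truth.snps.append(
            {
                "gene": sub.gene,
                "cds_pos": sub.cds_pos,
                "ref_base": ref_base,
                "alt_base": sub.alt_base,
                "effect": "S" if ref_aa == alt_aa else "N",
                "substitution_class": "transition"
                if pair in ({"A", "G"}, {"C", "T"})
                else "transversion",
            }
        )
        if truth.snps[-1]["effect"] != sub.effect:
            raise PlanError(
                f"{sub.gene}:{sub.cds_pos}: intended effect {sub.effect} not achievable"
            )
    seq = "".join(seq_l)

    # --- 3. inversions ---------------------------------------------------
    for s, e in sorted(plan.inversions):
        s2, e2 = shift_del(s), shift_del(e)
        seq = seq[:s2] + revcomp(seq[s2:e2]) + seq[e2:]
        for f in var_features:
            segs = []
            for seg in f.segments:
                a, b = seg.lo - 1, seg.hi
                if b <= s2 or a >= e2:
                    segs.append(seg)
                    continue
                if not (s2 <= a and b <= e2):
                    raise PlanError(f"feature {f.name} straddles inversion {s}-{e}")
                na, nb = s2 + e2 - b, s2 + e2 - a
                flipped = REVERSE if seg.strand == FORWARD else FORWARD
                segs.append(
                    OrientedInterval(na + 1, nb, FORWARD)
                    if flipped == FORWARD
                    else OrientedInterval(nb, na + 1, REVERSE)
                )
            f.segments = segs

    # --- 4. insertions (plain, repeat copies, chimeras) ------------------
    inserts: list[tuple[int, str, dict]] = []  # (pos after del-shift, seq, meta)
    group_seqs: dict[str, str] = {}
    for ins in plan.insertions:
        if ins.source == "random":
            if ins.group:
                if ins.group not in group_seqs:
                    group_seqs[ins.group] = _random_dna(rng, ins.length, 44.0)
                s_ins = group_seqs[ins.group]
            else:
                s_ins = _random_dna(rng, ins.length, 44.0)
            cls = "novel"
        elif ins.source == "ct":
            if ct is None:
                raise PlanError("ct-sourced insertion without a chloroplast genome")
            start = ins.ct_start if ins.ct_start is not None else int(
                rng.integers(0, ct.length - ins.length)
            )
            s_ins = ct.sequence[start : start + ins.length]
            cls = "ct-derived"
        else:
            raise PlanError(f"unknown insertion source {ins.source!r}")
        inserts.append(
            (
                shift_del(ins.position),
                s_ins,
                {
                    "type": "unique",
                    "label": ins.label,
                    "source_class": cls,
                    "group": ins.group,
                },
            )
        )
    for rp in plan.repeat_plants:
        src0 = shift_del(rp.source_start)
        source_seq = seq[src0 : src0 + rp.length]
        copy_meta = {
            "type": "repeat-source",
            "label": rp.label,
            "start0": src0,
            "length": rp.length,
        }
        copies_payload = [copy_meta]
        for pos, orient in zip(rp.insert_positions, rp.orientations):
            cp = source_seq if orient == FORWARD else revcomp(source_seq)
            cp = _mutate(rng, cp, rp.mismatches, rp.indel_bp)
            inserts.append(
                (
                    shift_del(pos),
                    cp,
                    {"type": "repeat-copy", "label": rp.label, "strand": orient},
                )
            )
        truth.repeat_families.append(
            {
                "label": rp.label,
                "length": rp.length,
                "mismatches": rp.mismatches,
                "indel_bp": rp.indel_bp,
                "copies": copies_payload,  # completed below
                "orientation_class": "",
            }
        )
    for ch in plan.chimera_plants:
        frags = []
        for start, length, strand in ch.donors:
            d0 = shift_del(start)
            frag = seq[d0 : d0 + length]
            if strand == REVERSE:
                frag = revcomp(frag)
            frags.append(frag)
        orf = _orfify(rng, "".join(frags))
        # an in-frame stop just ahead of the ATG pins the ORF start exactly
        inserts.append(
            (
                shift_del(ch.position),
                "TAA" + orf,
                {"type": "chimera", "label": ch.label, "donors": ch.donors},
            )
        )
    inserts.sort(key=lambda t: t[0])
    positions = [p for p, _, _ in inserts]
    if len(set(positions)) != len(positions):
        raise PlanError("two insertions at the same point")

    # assemble the variant sequence
    out_parts: list[str] = []
    cursor = 0
    for p, s_ins, _ in inserts:
        out_parts.append(seq[cursor:p])
        out_parts.append(s_ins)
        cursor = p
    out_parts.append(seq[cursor:])
    var_seq = "".join(out_parts)

    # lift features
    for f in var_features:
        segs = []
        for seg in f.segments:
            lo0 = seg.lo - 1 + sum(len(s) for q, s, _ in inserts if q <= seg.lo - 1)
            hi0 = lo0 + (seg.hi - seg.lo + 1)
            segs.append(
                OrientedInterval(lo0 + 1, hi0, FORWARD)
                if seg.strand == FORWARD
                else OrientedInterval(hi0, lo0 + 1, REVERSE)
            )
        f.segments = segs

    # truth coordinates
    offset = 0
    fam_truth = {t["label"]: t for t in truth.repeat_families}
    for p, s_ins, meta in inserts:
        start1 = p + offset + 1  # 1-based final start of the inserted block
        if meta["type"] == "unique":
            truth.unique_regions.append(
                {
                    "label": meta["label"],
                    "start": start1,
                    "length": len(s_ins),
                    "source_class": meta["source_class"],
                    "group": meta["group"],
                }
            )
        elif meta["type"] == "repeat-copy":
            fam_truth[meta["label"]]["copies"].append(
                {"start": start1, "length": len(s_ins), "strand": meta["strand"]}
            )
        elif meta["type"] == "chimera":
            orf_start = start1 + 3  # skip the pinned in-frame stop
            orf_len = len(s_ins) - 3
            truth.chimeric_orfs.append(
                {
                    "label": meta["label"],
                    "start": orf_start,
                    "length": orf_len,
                    "donors_ancestor": [list(d) for d in meta["donors"]],
                }
            )
            var_features.append(
                FeatureAnnotation(
                    meta["label"],
                    "ORF",
                    [OrientedInterval(orf_start, orf_start + orf_len - 1, FORWARD)],
                    "variant",
                )
            )
        offset += len(s_ins)
    # finish repeat-family truth: lift the source interval, order copies by
    # start, and express orientations relative to the first copy (matching
    # how detected families are reported)
    for t in truth.repeat_families:
        src = t["copies"][0]
        s1 = src["start0"] + sum(len(s) for q, s, _ in inserts if q <= src["start0"]) + 1
        t["copies"][0] = {"start": s1, "length": src["length"], "strand": FORWARD}
        t["copies"].sort(key=lambda c: c["start"])
        if t["copies"][0]["strand"] == REVERSE:
            for c in t["copies"]:
                c["strand"] = FORWARD if c["strand"] == REVERSE else REVERSE
        strands = [c["strand"] for c in t["copies"]]
        rel = [x == strands[0] for x in strands[1:]]
        if all(rel):
            t["orientation_class"] = "DR"
        elif len(strands) == 2:
            t["orientation_class"] = "IR"
        else:
            t["orientation_class"] = "DR/IR" if rel[0] else "IR/DR"

    variant = CircularGenome("variant", var_seq, True)
    var_features.sort(key=lambda f: f.span_start())
    return variant, var_features, truth


# ---------------------------------------------------------------------------
# the reduced-scale study profile


def _reserve(reserved: list[tuple[int, int]], s: int, e: int) -> bool:
    for rs, re_ in reserved:
        if s < re_ and rs < e:
            return False
    reserved.append((s, e))
    return True


def _sample_interval(
    rng: np.random.Generator, L: int, length: int, reserved: list[tuple[int, int]]
) -> int:
    for _ in range(2000):
        s = int(rng.integers(0, L - length))
        if _reserve(reserved, s, s + length):
            return s
    raise RuntimeError("could not place an interval; genome too crowded")


def _fits(reserved: list[tuple[int, int]], s: int, e: int) -> bool:
    return all(not (s < re_ and rs < e) for rs, re_ in reserved)


def _donor_edits_sparse(frags: list[str], min_space: int = 40) -> bool:
    """True if ORF-ifying the fused fragments needs only well-spaced edits.

    Each in-frame stop codon inside a donor fragment costs one base edit;
    edits (or fragment boundaries) closer than ``min_space`` would leave no
    clean seed window, making the donor undetectable by homology search.
    """
    fused = "".join(frags)
    fused = fused[: len(fused) - len(fused) % 3]
    edits = [i for i in range(3, len(fused) - 3, 3) if fused[i : i + 3] in _STOPS]
    bounds = [0]
    acc = 0
    for f in frags:
        acc += len(f)
        bounds.append(min(acc, len(fused)))
    pts = sorted(set(bounds + edits))
    return all(b - a >= min_space for a, b in zip(pts, pts[1:]))


def _sample_point(
    rng: np.random.Generator,
    gaps: list[tuple[int, int]],
    reserved: list[tuple[int, int]],
    points: list[int],
    min_sep: int = 300,
    margin: int = 60,
) -> int:
    widths = np.array([max(0, e - s - 2 * margin) for s, e in gaps], dtype=float)
    for _ in range(4000):
        gi = int(rng.choice(len(gaps), p=widths / widths.sum()))
        s, e = gaps[gi]
        p = int(rng.integers(s + margin, e - margin))
        if any(abs(p - q) < min_sep for q in points):
            continue
        if any(rs <= p < re_ for rs, re_ in reserved):
            continue
        points.append(p)
        return p
    raise RuntimeError("could not place an insertion point")


def _intergenic_gaps(features: list[FeatureAnnotation], L: int) -> list[tuple[int, int]]:
    spans = sorted((f.segments[0].lo - 1, f.segments[0].hi) for f in features)
    gaps = []
    for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
        if s2 - e1 > 150:
            gaps.append((e1, s2))
    if spans and L - spans[-1][1] + spans[0][0] > 150:
        gaps.append((spans[-1][1], L))  # tail gap (origin margin kept simple)
    return gaps


def _pick_snp(
    rng: np.random.Generator, cds: str, effect: str, used_codons: set[int]
) -> tuple[int, str] | None:
    """(cds_pos, alt_base) giving the intended S/N effect, or None."""
    n_codons = len(cds) // 3
    for _ in range(200):
        ci = int(rng.integers(2, n_codons - 1))  # skip start and stop codons
        if ci in used_codons:
            continue
        codon = cds[3 * (ci - 1) : 3 * ci]
        offsets = [2] if effect == "S" else [0, 1]
        rng.shuffle(offsets)
        for off in offsets:
            for alt in "ACGT":
                if alt == codon[off]:
                    continue
                alt_codon = codon[:off] + alt + codon[off + 1 :]
                if alt_codon in _STOPS:
                    continue
                same = str(Seq(codon).translate()) == str(Seq(alt_codon).translate())
                if (effect == "S") == same:
                    used_codons.add(ci)
                    return 3 * (ci - 1) + off + 1, alt
    return None


def plan_from_paper_profile(
    seed: int, config: AncestorConfig = AncestorConfig()
) -> EditPlan:
    """An edit plan with the study's category structure at reduced scale.

    Eight line-specific regions (two chloroplast-sourced, one sequence
    planted at three loci), five repeat families (a 5 kb direct repeat,
    a 2 kb inverted repeat, a three-copy 600 bp direct repeat with
    mismatches, a 300 bp inverted repeat, a 150 bp direct repeat), twelve
    CDS substitutions (four synonymous), one deleted gene (rpl5), one
    two-gene inversion, and three chimeric ORFs fused from donor fragments
    more than 5 kb apart.
    """
    ancestor, features = generate_ancestor(config, seed)
    ct = generate_chloroplast(10_000, _child_seed(seed, 1))
    rng = np.random.default_rng(_child_seed(seed, 2))
    L = ancestor.length
    feat_by_name = {f.name: f for f in features}
    plan = EditPlan(seed=seed, gene_deletions=["rpl5"])
    reserved: list[tuple[int, int]] = []
    rp = feat_by_name["rpl5"].segments[0]
    reserved.append((rp.lo - 1, rp.hi))

    # inversion spanning two adjacent CDS genes (gene-order signal)
    cds_feats = sorted(
        (f for f in features if f.kind == "CDS" and f.name != "rpl5"),
        key=lambda f: f.span_start(),
    )
    inv_genes: list[str] = []
    for f1, f2 in zip(cds_feats, cds_feats[1:]):
        gap = f2.segments[0].lo - f1.segments[0].hi
        if 0 < gap and _reserve(reserved, f1.segments[0].lo - 1 - 60, f2.segments[0].hi + 60):
            plan.inversions.append((f1.segments[0].lo - 1 - 60, f2.segments[0].hi + 60))
            inv_genes = [f1.name, f2.name]
            break

    # repeat families: (label, source length, copies spec)
    fam_specs = [
        ("F1", 5000, [FORWARD], 0, 0),
        ("F2", 2000, [REVERSE], 0, 0),
        ("F3", 600, [FORWARD, FORWARD], 4, 0),
        ("F4", 300, [REVERSE], 2, 0),
        ("F5", 150, [FORWARD], 0, 0),
    ]
    for label, length, orients, mm, ind in fam_specs:
        src = _sample_interval(rng, L, length, reserved)
        plan.repeat_plants.append(
            RepeatPlant(src, length, [], list(orients), mm, ind, label)
        )

    # chimeric ORF donors: two fragments per chimera, > 5 kb apart, whose
    # fused frame needs only sparse stop-removal edits (keeps each donor
    # detectable by homology search)
    for idx in range(3):
        for _ in range(3000):
            d1 = int(rng.integers(0, L - 250))
            d2 = int(rng.integers(0, L - 200))
            sep = abs(d1 - d2)
            if min(sep, L - sep) <= 5000:
                continue
            if not (_fits(reserved, d1, d1 + 250) and _fits(reserved, d2, d2 + 200)):
                continue
            frags = [
                ancestor.sequence[d1 : d1 + 250],
                revcomp(ancestor.sequence[d2 : d2 + 200]),
            ]
            if not _donor_edits_sparse(frags):
                continue
            reserved.append((d1, d1 + 250))
            reserved.append((d2, d2 + 200))
            plan.chimera_plants.append(
                ChimeraPlant(
                    [(d1, 250, FORWARD), (d2, 200, REVERSE)], 0, f"chim{idx + 1}"
                )
            )
            break
        else:
            raise RuntimeError("no clean chimera donors found")

    # SNPs: 12 over 5 genes, 4 synonymous
    snp_genes = [
        f.name
        for f in cds_feats
        if f.name not in inv_genes and f.segments[0].hi - f.segments[0].lo >= 450
    ][:5]
    effects = ["S", "S", "S", "S", "N", "N", "N", "N", "N", "N", "N", "N"]
    gi = 0
    used: dict[str, set[int]] = {g: set() for g in snp_genes}
    for eff in effects:
        for _ in range(len(snp_genes)):
            gene = snp_genes[gi % len(snp_genes)]
            gi += 1
            cds = feat_by_name[gene].extract(ancestor)
            hit = _pick_snp(rng, cds, eff, used[gene])
            if hit:
                plan.cds_substitutions.append(CdsSubstitution(gene, hit[0], hit[1], eff))
                break
        else:
            raise RuntimeError(f"no {eff} site available in profile genes")

    # insertion points: unique regions, repeat copies, chimera targets
    gaps = _intergenic_gaps(features, L)
    points: list[int] = []
    unique_specs = [
        ("Uq1", 2500, "random", ""),
        ("Uq2", 1200, "random", ""),
        ("Uq3", 800, "ct", ""),
        ("Uq4", 600, "random", ""),
        ("Uq5", 400, "ct", ""),
        ("Uq6", 300, "random", "G1"),
        ("Uq7", 300, "random", "G1"),
        ("Uq8", 300, "random", "G1"),
    ]
    for label, length, source, group in unique_specs:
        p = _sample_point(rng, gaps, reserved, points)
        ct_start = int(rng.integers(0, ct.length - length)) if source == "ct" else None
        plan.insertions.append(Insertion(p, length, source, label, ct_start, group))
    for rplant in plan.repeat_plants:
        for _ in rplant.orientations:
            rplant.insert_positions.append(_sample_point(rng, gaps, reserved, points))
    for ch in plan.chimera_plants:
        ch.position = _sample_point(rng, gaps, reserved, points)
    return plan


def _child_seed(seed: int, stream: int) -> int:
    """A derived 31-bit seed for an auxiliary generator stream."""
    return int(np.random.SeedSequence([seed, stream]).generate_state(1)[0] % (2**31))


def simulate_pair(seed: int, config: AncestorConfig = AncestorConfig()):
    """Generate the full study-shaped desk-scale dataset.

    Returns (ancestor, ancestor_features, variant, variant_features,
    ct_genome, truth, plan).
    """
    ancestor, features = generate_ancestor(config, seed)
    ct = generate_chloroplast(10_000, _child_seed(seed, 1))
    plan = plan_from_paper_profile(seed, config)
    variant, var_features, truth = derive_variant(ancestor, features, plan, ct)
    return ancestor, features, variant, var_features, ct, truth, plan


def _mutate(rng: np.random.Generator, seq: str, mismatches: int, indel_bp: int) -> str:
    """Plant substitutions and one deletion run in a repeat copy interior."""
    s = list(seq)
    n = len(s)
    if mismatches:
        lo, hi = min(40, n // 4), max(n - min(40, n // 4), min(40, n // 4) + 1)
        pos = rng.choice(np.arange(lo, hi), size=mismatches, replace=False)
        for p in pos:
            choices = [b for b in "ACGT" if b != s[p]]
            s[p] = choices[rng.integers(0, 3)]
    if indel_bp:
        p = int(rng.integers(n // 3, 2 * n // 3))
        del s[p : p + indel_bp]
    return "".join(s)


def _orfify(rng: np.random.Generator, seq: str) -> str:
    """Minimal edits making a fused fragment a clean ATG..stop ORF."""
    s = list(seq[: len(seq) - len(seq) % 3])
    s[0:3] = list("ATG")
    for i in range(3, len(s) - 3, 3):
        if "".join(s[i : i + 3]) in _STOPS:
            s[i] = "C"  # breaks every stop codon (TAA/TAG/TGA -> CAx/CGA)
    if "".join(s[-3:]) not in _STOPS:
        s[-3:] = list("TAA")
    return "".join(s)


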