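"""Gene-order extraction and shared-cluster (synteny) detection.

Plant mitochondrial gene content is conserved while gene order is shuffled
by recombination; comparing circular gene orders as circular words (tRNA
genes excluded, as customary) and extracting maximal runs of genes that
stay contiguous — in either orientation — measures how much order survives
between two genomes.
"""
from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd

from .model import FeatureAnnotation

_COPY_SUFFIX = re.compile(r"[-#]\d+$")


def base_symbol(name: str) -> str:
    """Gene symbol with any copy suffix removed (rrn18-2 -> rrn18)."""
    return _COPY_SUFFIX.sub("", name)


@dataclass
class SyntenyCluster:
    """A maximal run of genes contiguous in both circular orders."""

    genes: list[str]
    orientation: str  # 'same' or 'reversed'
    a_index: int  # start index in order A
    b_index: int  # start index in order B (of the first gene, walking B
    # forward for 'same', backward for 'reversed')

    def __len__(self) -> int:
        return len(self.genes)

    def to_dict(self) -> dict:
        return {
            "genes": list(self.genes),
            "orientation": self.orientation,
            "a_index": self.a_index,
            "b_index": self.b_index,
        }


def gene_order(
    features: list[FeatureAnnotation], exclude_kinds: set[str] = frozenset({"tRNA"})
) -> list[str]:
    """Symbols ordered by start coordinate around the circle.

    Multi-segment genes sit at their first segment; duplicate symbols get
    copy suffixes (-2, -3, ...) in coordinate order.
    """
    kept = [f for f in features if f.kind not in exclude_kinds]
    kept.sort(key=lambda f: f.span_start())
    seen: dict[str, int] = {}
    out: list[str] = []
    for f in kept:
        sym = base_symbol(f.name)
        seen[sym] = seen.get(sym, 0) + 1
        out.append(sym if seen[sym] == 1 else f"{sym}-{seen[sym]}")
    return out


def _maximal_common_runs(
    A: list[str], B: list[str], circular: bool = True
) -> list[tuple[int, int, int, int]]:
    """All maximal common runs as (a_start, b_start, direction, length).

    Runs are over base symbols; direction +1 walks B forward, -1 backward
    (a reversed block). Circular orders wrap. Sub-runs and rotations of a
    run are not repeated.
    """
    a = [base_symbol(x) for x in A]
    b = [base_symbol(x) for x in B]
    n, m = len(a), len(b)
    if n == 0 or m == 0:
        return []
    cap = min(n, m)
    runs: set[tuple[int, int, int, int]] = set()
    covered: set[tuple[int, int, int]] = set()  # (a_pos, b_pos, dir) inside a found run
    for i in range(n):
        for j in range(m):
            for d in (1, -1):
                if (i, j, d) in covered:
                    continue
                if a[i] != b[j]:
                    continue
                # maximality: extendable backwards?
                pi = (i - 1) % n if circular else i - 1
                pj = (j - d) % m if circular else j - d
                if (
                    (circular or (pi >= 0 and 0 <= pj < m))
                    and a[pi % n] == b[pj % m]
                    and not (n == 1 or m == 1)
                ):
                    # will be found from the earlier start (unless full circle)
                    ext_back = True
                else:
                    ext_back = False
                t = 1
                while t < cap:
                    ai = (i + t) % n if circular else i + t
                    bj = (j + d * t) % m if circular else j + d * t
                    if not circular and (ai >= n or bj < 0 or bj >= m):
                        break
                    if a[ai % n] != b[bj % m]:
                        break
                    t += 1
                if ext_back and t < cap:
                    continue  # proper sub-run of a longer one
                for s in range(t):
                    covered.add(((i + s) % n, (j + d * s) % m, d))
                runs.add((i, j, d, t))
    # drop runs contained in longer runs sharing positions (rotation dupes)
    out = sorted(runs, key=lambda r: (-r[3], r[0], r[1], -r[2]))
    final: list[tuple[int, int, int, int]] = []
    used: set[tuple[int, int, int]] = set()
    for i, j, d, t in out:
        cells = {((i + s) % n, (j + d * s) % m, d) for s in range(t)}
        if cells <= used:
            continue
        if any(c in used for c in cells) and any(c not in used for c in cells):
            # partially overlapping a longer run: keep (distinct maximal run)
            pass
        final.append((i, j, d, t))
        used |= cells
    return final


def shared_clusters(order_A: list[str], order_B: list[str], circular: bool = True) -> list[SyntenyCluster]:
    """Maximal shared gene clusters between two circular gene orders.

    Reversed blocks are reported with orientation 'reversed'. Each gene
    copy is assignable to one cluster only (greedy, longest cluster first,
    ties by coordinate); singleton matches are excluded.
    """
    a = [base_symbol(x) for x in order_A]
    n, m = len(order_A), len(order_B)
    runs = _maximal_common_runs(order_A, order_B, circular)
    runs.sort(key=lambda r: (-r[3], r[0], r[1]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    clusters: list[SyntenyCluster] = []
    for i, j, d, t in runs:
        if t < 2:
            continue
        apos = [(i + s) % n for s in range(t)]
        bpos = [(j + d * s) % m for s in range(t)]
        if any(p in used_a for p in apos) or any(p in used_b for p in bpos):
            continue
        used_a.update(apos)
        used_b.update(bpos)
        clusters.append(
            SyntenyCluster(
                genes=[a[p] for p in apos],
                orientation="same" if d == 1 else "reversed",
                a_index=i,
                b_index=j,
            )
        )
    return clusters


def gene_copy_table(
    annotated: dict[str, list[FeatureAnnotation]],
    exclude_kinds: set[str] = frozenset(),
) -> pd.DataFrame:
    """Gene x genome matrix of copy counts.

    ``annotated`` maps genome id to its feature list; copies are counted
    per base symbol (segments of one multi-segment gene count once).
    """
    counts: dict[str, dict[str, int]] = {}
    for gid, features in annotated.items():
        for f in features:
            if f.kind in exclude_kinds:
                continue
            sym = base_symbol(f.name)
            counts.setdefault(sym, {}).setdefault(gid, 0)
            counts[sym][gid] += 1
    df = pd.DataFrame.from_dict(counts, orient="index").fillna(0).astype(int)
    df = df.reindex(sorted(df.index))
    df = df[sorted(df.columns)] if len(df.columns) else df
    df.index.name = "gene"
    return df
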