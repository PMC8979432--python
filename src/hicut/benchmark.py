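"""Comparison of interaction sets against reference loop sets.

A reference loop counts as captured when a single query interaction spans
both of its anchors (one paired-end tag through both anchor intervals),
not when two independent single-anchor hits exist.  Reported fractions
are always over the reference set, matching how capture percentages are
quoted in the field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .io import GenomicInterval, LoopRecord, ValidPair, chrom_sort_key
from .pairs import Interaction, PeakIndex

__all__ = [
    "OverlapReport",
    "CoverageVector",
    "match_loops",
    "match_loops_to_loops",
    "colocalization",
    "coverage_vector",
    "spearman_correlation",
]


@dataclass(frozen=True)
class OverlapReport:
    n_reference: int
    n_matched: int
    fraction_matched: float
    n_query: int
    matcher_slack: int = 0

    def as_rows(self) -> list[tuple[str, float]]:
        return [
            ("n_reference", self.n_reference),
            ("n_matched", self.n_matched),
            ("fraction_matched", self.fraction_matched),
            ("n_query", self.n_query),
            ("matcher_slack", self.matcher_slack),
        ]


def match_loops(
    reference: Sequence[LoopRecord],
    query_interactions: Sequence[Interaction],
    slack: int = 0,
) -> OverlapReport:
    """Fraction of reference loops spanned by at least one interaction.

    A loop matches when some interaction has anchor1 inside anchorA and
    anchor2 inside anchorB, each widened by ``slack`` bp on both sides.
    """
    if not reference:
        raise ValueError("reference loop set is empty; fraction undefined")
    if slack < 0:
        raise ValueError("slack must be >= 0")
    # group query anchors per chromosome, sorted by anchor1
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    grouped: dict[str, list[tuple[int, int]]] = {}
    for it in query_interactions:
        grouped.setdefault(it.chrom, []).append((it.anchor1, it.anchor2))
    for chrom, pts in grouped.items():
        pts.sort()
        a1 = np.array([p[0] for p in pts], dtype=np.int64)
        a2 = np.array([p[1] for p in pts], dtype=np.int64)
        by_chrom[chrom] = (a1, a2)

    n_matched = 0
    for loop in reference:
        lp = loop.canonical()
        if lp.is_trans:
            continue
        arrs = by_chrom.get(lp.anchorA.chrom)
        if arrs is None:
            continue
        a1, a2 = arrs
        # 1-based point p inside [start - slack, end + slack) 0-based
        loA = lp.anchorA.start - slack + 1  # min 1-based pos
        hiA = lp.anchorA.end + slack       # max 1-based pos (inclusive)
        i0 = np.searchsorted(a1, loA, side="left")
        i1 = np.searchsorted(a1, hiA, side="right")
        if i0 >= i1:
            continue
        loB = lp.anchorB.start - slack + 1
        hiB = lp.anchorB.end + slack
        sub = a2[i0:i1]
        if np.any((sub >= loB) & (sub <= hiB)):
            n_matched += 1
    return OverlapReport(
        n_reference=len(reference),
        n_matched=n_matched,
        fraction_matched=n_matched / len(reference),
        n_query=len(query_interactions),
        matcher_slack=slack,
    )


def match_loops_to_loops(
    reference: Sequence[LoopRecord],
    query: Sequence[LoopRecord],
) -> OverlapReport:
    """Fraction of reference loops with a query loop overlapping both anchors.

    Anchor agreement is >= 1 bp interval overlap on each side after
    canonical ordering.
    """
    if not reference:
        raise ValueError("reference loop set is empty; fraction undefined")
    by_chrom: dict[str, list[LoopRecord]] = {}
    for q in query:
        qc = q.canonical()
        if not qc.is_trans:
            by_chrom.setdefault(qc.anchorA.chrom, []).append(qc)
    n_matched = 0
    for loop in reference:
        lp = loop.canonical()
        if lp.is_trans:
            continue
        cands = by_chrom.get(lp.anchorA.chrom, ())
        for q in cands:
            if (
                q.anchorA.start < lp.anchorA.end
                and lp.anchorA.start < q.anchorA.end
                and q.anchorB.start < lp.anchorB.end
                and lp.anchorB.start < q.anchorB.end
            ):
                n_matched += 1
                break
    return OverlapReport(
        n_reference=len(reference),
        n_matched=n_matched,
        fraction_matched=n_matched / len(reference),
        n_query=len(query),
        matcher_slack=0,
    )


def colocalization(
    interactions: Sequence[Interaction],
    peaks: Sequence[GenomicInterval],
    mode: str = "any_anchor",
) -> float:
    """Fraction of interactions with anchors inside peaks.

    ``any_anchor``: at least one anchor in a peak; ``both_anchors``: both.
    """
    if not interactions:
        raise ValueError("empty interaction set; colocalization undefined")
    if mode not in ("any_anchor", "both_anchors"):
        raise ValueError(f"unknown mode: {mode}")
    index = PeakIndex(peaks)
    n_hit = 0
    for it in interactions:
        h1 = index.contains(it.chrom, it.anchor1)
        h2 = index.contains(it.chrom, it.anchor2)
        hit = (h1 or h2) if mode == "any_anchor" else (h1 and h2)
        n_hit += hit
    return n_hit / len(interactions)


@dataclass
class CoverageVector:
    """Binned anchor-point coverage: counts of cis pair ends per bin."""

    bin_size: int
    counts: dict[str, np.ndarray]

    @property
    def total(self) -> int:
        return int(sum(c.sum() for c in self.counts.values()))


def coverage_vector(pairs: Iterable[ValidPair], bin_size: int) -> CoverageVector:
    """Bin both anchor points of every cis pair: bin = floor((pos-1)/bin_size)."""
    if bin_size <= 0:
        raise ValueError("bin_size must be > 0")
    points: dict[str, list[int]] = {}
    for p in pairs:
        if not p.is_cis:
            continue
        points.setdefault(p.chrom1, []).append((p.pos1 - 1) // bin_size)
        points.setdefault(p.chrom2, []).append((p.pos2 - 1) // bin_size)
    counts = {}
    for chrom, bins in points.items():
        arr = np.asarray(bins, dtype=np.int64)
        counts[chrom] = np.bincount(arr)
    return CoverageVector(bin_size=bin_size, counts=counts)


def spearman_correlation(a: CoverageVector, b: CoverageVector, drop_zero_bins: bool = False) -> float:
    """Genome-wide Spearman rank correlation between two coverage vectors.

    Vectors are aligned per chromosome (zero-padded to a common length)
    and concatenated in natural chromosome order.  Bins that are zero in
    both vectors are retained by default; ``drop_zero_bins=True`` removes
    them, which materially changes the coefficient on sparse data.
    Returns ``nan`` when either concatenated vector is constant.
    """
    if a.bin_size != b.bin_size:
        raise ValueError("coverage vectors have different bin sizes")
    chroms = sorted(set(a.counts) | set(b.counts), key=chrom_sort_key)
    xs, ys = [], []
    for chrom in chroms:
        ca = a.counts.get(chrom, np.zeros(0, dtype=np.int64))
        cb = b.counts.get(chrom, np.zeros(0, dtype=np.int64))
        n = max(len(ca), len(cb))
        xs.append(np.pad(ca, (0, n - len(ca))))
        ys.append(np.pad(cb, (0, n - len(cb))))
    x = np.concatenate(xs) if xs else np.zeros(0)
    y = np.concatenate(ys) if ys else np.zeros(0)
    if drop_zero_bins:
        keep = (x != 0) | (y != 0)
        x, y = x[keep], y[keep]
    if len(x) < 2 or np.all(x == x[0]) or np.all(y == y[0]):
        return math.nan
    rho, _ = stats.spearmanr(x, y)
    return float(rho)
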