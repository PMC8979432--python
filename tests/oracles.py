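"""Brute-force reference implementations used to cross-check the package.

Everything here is deliberately naive — O(n*m) double loops over records,
dense python arithmetic — and shares no code path with the package
internals (no PeakIndex, no searchsorted, no sparse slicing).
"""

from __future__ import annotations

import numpy as np

from hicut.io import GenomicInterval, LoopRecord, SNPRecord, ValidPair
from hicut.pairs import AnalysisParams, Interaction


def point_in(iv: GenomicInterval, pos_1based: int, slack: int = 0) -> bool:
    return iv.start - slack <= pos_1based - 1 < iv.end + slack


def oracle_call_interactions(pairs, peaks, params: AnalysisParams):
    """Scan every pair against every peak."""
    out = []
    for p in pairs:
        if p.chrom1 != p.chrom2:
            continue
        d = abs(p.pos2 - p.pos1)
        if not (params.long_min <= d <= params.long_max):
            continue
        hit = False
        for pk in peaks:
            if pk.chrom == p.chrom1 and (point_in(pk, p.pos1) or point_in(pk, p.pos2)):
                hit = True
                break
        if hit:
            a1, a2 = sorted((p.pos1, p.pos2))
            out.append(Interaction(chrom=p.chrom1, anchor1=a1, anchor2=a2,
                                   source_id=p.read_id))
    return out


def oracle_match_loops(reference, interactions, slack: int = 0) -> int:
    """Count reference loops spanned by >= 1 interaction, by double loop."""
    n = 0
    for loop in reference:
        lp = loop.canonical()
        if lp.is_trans:
            continue
        for it in interactions:
            if (
                it.chrom == lp.anchorA.chrom
                and point_in(lp.anchorA, it.anchor1, slack)
                and point_in(lp.anchorB, it.anchor2, slack)
            ):
                n += 1
                break
    return n


def oracle_colocalization(interactions, peaks, mode: str) -> float:
    n_hit = 0
    for it in interactions:
        h1 = any(pk.chrom == it.chrom and point_in(pk, it.anchor1) for pk in peaks)
        h2 = any(pk.chrom == it.chrom and point_in(pk, it.anchor2) for pk in peaks)
        n_hit += (h1 or h2) if mode == "any_anchor" else (h1 and h2)
    return n_hit / len(interactions)


def oracle_link_snps(interactions, snps, window: int):
    """Every qualifying (interaction index, snp index) pair."""
    out = []
    for i, it in enumerate(interactions):
        for j, s in enumerate(snps):
            if s.chrom != it.chrom:
                continue
            if abs(s.pos - it.anchor1) <= window or abs(s.pos - it.anchor2) <= window:
                out.append((i, j))
    return out


def oracle_aggregate(dense_by_chrom, n_bins_by_chrom, loci, w, corner, near_diag_ok=False):
    """Naive per-locus slice-and-average over pre-built dense matrices.

    ``dense_by_chrom`` maps chrom -> full dense matrix (possibly with NaN
    rows for unbalanceable bins).  Returns (mean matrix, score, n_used).
    """
    size = 2 * w + 1
    acc = np.zeros((size, size))
    cnt = np.zeros((size, size))
    n_used = 0
    for lp in loci:
        if lp.chrom not in dense_by_chrom:
            continue
        nb = n_bins_by_chrom[lp.chrom]
        if min(lp.bin_i, lp.bin_j) - w < 0 or max(lp.bin_i, lp.bin_j) + w >= nb:
            continue
        if not near_diag_ok and lp.bin_j - lp.bin_i <= 2 * w:
            continue
        D = dense_by_chrom[lp.chrom]
        for r in range(size):
            for c in range(size):
                v = D[lp.bin_i - w + r, lp.bin_j - w + c]
                if np.isfinite(v):
                    acc[r, c] += v
                    cnt[r, c] += 1
        n_used += 1
    mean = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
    center = mean[w, w]
    block = mean[size - corner:, :corner]
    cm = np.nanmean(block)
    score = center / cm if cm > 0 else np.nan
    return mean, score, n_used


# ---------------------------------------------------------------------------
# randomized small instances for oracle-equivalence sweeps
# ---------------------------------------------------------------------------


def random_instance(seed: int):
    """A small random scenario: pairs, peaks, loops, snps + relaxed params."""
    rng = np.random.default_rng(seed)
    params = AnalysisParams(
        min_pair_dist=int(rng.integers(200, 1_500)),
        long_min=int(rng.integers(2_000, 8_000)),
        long_max=int(rng.integers(40_000, 120_000)),
        snp_window=int(rng.integers(500, 6_000)),
    )
    chroms = ["chr1", "chr2"]
    L = 200_000
    pairs = []
    for k in range(int(rng.integers(20, 80))):
        c1 = chroms[int(rng.integers(2))]
        c2 = c1 if rng.random() < 0.85 else chroms[int(rng.integers(2))]
        p1 = int(rng.integers(1, L))
        if c1 == c2:
            p2 = int(np.clip(p1 + rng.integers(-params.long_max * 2, params.long_max * 2), 1, L))
        else:
            p2 = int(rng.integers(1, L))
        lo, hi = sorted((p1, p2)) if c1 == c2 else (p1, p2)
        pairs.append(ValidPair(f"R{k}", c1, lo, "+", c2, hi, "-"))
    peaks = []
    for k in range(int(rng.integers(3, 15))):
        c = chroms[int(rng.integers(2))]
        s = int(rng.integers(0, L - 2_000))
        peaks.append(GenomicInterval(c, s, s + int(rng.integers(200, 2_000))))
    loops = []
    for k in range(int(rng.integers(2, 10))):
        c = chroms[int(rng.integers(2))]
        sA = int(rng.integers(0, L - 60_000))
        wA = int(rng.integers(500, 5_000))
        gap = int(rng.integers(5_000, 50_000))
        sB = sA + wA + gap
        wB = int(rng.integers(500, 5_000))
        loops.append(LoopRecord(GenomicInterval(c, sA, sA + wA),
                                GenomicInterval(c, sB, sB + wB)))
    snps = [
        SNPRecord(chroms[int(rng.integers(2))], int(rng.integers(1, L)), f"rs{k}")
        for k in range(int(rng.integers(3, 12)))
    ]
    return pairs, peaks, loops, snps, params
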