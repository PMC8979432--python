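"""Valid-pair canonicalization, filtering, interaction calling and QC.

The calling rule is deliberately minimal: after removing trans pairs and
cis pairs closer than 1 kb, every deduplicated cis pair whose separation
lies in the long-range window (20 kb – 2 Mb, inclusive) and that has at
least one 1-bp anchor inside a ChIP/CUT&RUN peak becomes one interaction.
Pairs are never merged: two surviving pairs with identical coordinates are
two interactions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .io import GenomicInterval, ValidPair, chrom_sort_key

__all__ = [
    "AnalysisParams",
    "Interaction",
    "QCMetrics",
    "PeakIndex",
    "canonicalize",
    "canonicalize_all",
    "deduplicate",
    "filter_pairs",
    "call_interactions",
    "qc_metrics",
    "classify_pairs",
]


@dataclass(frozen=True)
class AnalysisParams:
    """All thresholds of the analysis in one place (units: bp unless noted).

    Defaults are the published procedure's values: drop cis pairs under
    1 kb, call interactions in the 20 kb – 2 Mb window, link SNPs within
    5 kb of an anchor, promoters are TSS ± 2,500 bp, motif anchors are
    extended ± 100 bp, and APA uses 5 kb bins over peak pairs separated
    by 5 kb – 1 Mb with 200,000 sampled loci.
    """

    min_pair_dist: int = 1_000
    long_min: int = 20_000
    long_max: int = 2_000_000
    snp_window: int = 5_000
    promoter_flank: int = 2_500
    anchor_extension: int = 100
    apa_min_sep: int = 5_000
    apa_max_sep: int = 1_000_000
    apa_sample_n: int = 200_000
    apa_resolution: int = 5_000
    corr_bin: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.min_pair_dist < self.long_min < self.long_max):
            raise ValueError("need 0 < min_pair_dist < long_min < long_max")
        if not (0 < self.apa_min_sep < self.apa_max_sep):
            raise ValueError("need 0 < apa_min_sep < apa_max_sep")
        for name in ("snp_window", "promoter_flank", "anchor_extension",
                     "apa_resolution", "corr_bin"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class Interaction:
    """A called long-range contact: two 1-bp anchors on one chromosome."""

    chrom: str
    anchor1: int
    anchor2: int
    source_id: str = ""

    def __post_init__(self) -> None:
        if self.anchor1 > self.anchor2:
            raise ValueError("anchor1 must be <= anchor2")

    @property
    def distance(self) -> int:
        return self.anchor2 - self.anchor1


@dataclass(frozen=True)
class QCMetrics:
    """Summary counts over a deduplicated valid-pair set.

    ``cis_trans_ratio`` is ``inf`` when there are cis pairs but no trans
    pairs and ``nan`` on empty input.  ``peak_anchored_fraction`` is
    computed over long-range cis pairs (distance >= long_min) and is
    ``nan`` when no peaks were supplied or no long-range pairs exist.
    """

    total_pairs: int
    unique_pairs: int
    cis_pairs: int
    trans_pairs: int
    cis_trans_ratio: float
    long_range_pairs: int
    long_range_fraction: float
    peak_anchored_fraction: float

    def as_rows(self) -> list[tuple[str, float]]:
        return [
            ("total_pairs", self.total_pairs),
            ("unique_pairs", self.unique_pairs),
            ("cis_pairs", self.cis_pairs),
            ("trans_pairs", self.trans_pairs),
            ("cis_trans_ratio", self.cis_trans_ratio),
            ("long_range_pairs", self.long_range_pairs),
            ("long_range_fraction", self.long_range_fraction),
            ("peak_anchored_fraction", self.peak_anchored_fraction),
        ]


# ---------------------------------------------------------------------------
# Peak membership index
# ---------------------------------------------------------------------------


class PeakIndex:
    """Fast point-in-any-peak membership over merged intervals.

    Intervals are merged per chromosome, so only boolean membership is
    answered; use intervaltree-based lookups when interval identity
    matters (see :mod:`hicut.annotate`).
    """

    def __init__(self, peaks: Iterable[GenomicInterval], slack: int = 0):
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for p in peaks:
            by_chrom.setdefault(p.chrom, []).append(
                (p.start - slack, p.end + slack)
            )
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self.n_peaks = 0
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            merged: list[list[int]] = []
            for s, e in ivs:
                self.n_peaks += 1
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            self._starts[chrom] = np.array([m[0] for m in merged], dtype=np.int64)
            self._ends[chrom] = np.array([m[1] for m in merged], dtype=np.int64)

    def contains(self, chrom: str, pos_1based: int) -> bool:
        starts = self._starts.get(chrom)
        if starts is None or len(starts) == 0:
            return False
        p0 = pos_1based - 1
        i = int(np.searchsorted(starts, p0, side="right")) - 1
        return i >= 0 and p0 < self._ends[chrom][i]

    def contains_many(self, chrom: str, pos_1based: np.ndarray) -> np.ndarray:
        starts = self._starts.get(chrom)
        if starts is None or len(starts) == 0:
            return np.zeros(len(pos_1based), dtype=bool)
        p0 = np.asarray(pos_1based, dtype=np.int64) - 1
        idx = np.searchsorted(starts, p0, side="right") - 1
        ok = idx >= 0
        res = np.zeros(len(p0), dtype=bool)
        res[ok] = p0[ok] < self._ends[chrom][idx[ok]]
        return res


# ---------------------------------------------------------------------------
# Pair-level operations
# ---------------------------------------------------------------------------


def canonicalize(pair: ValidPair) -> ValidPair:
    """Order the two ends by (chromosome order, position); idempotent."""
    k1 = (chrom_sort_key(pair.chrom1), pair.pos1)
    k2 = (chrom_sort_key(pair.chrom2), pair.pos2)
    if k2 < k1:
        return ValidPair(
            read_id=pair.read_id,
            chrom1=pair.chrom2,
            pos1=pair.pos2,
            strand1=pair.strand2,
            chrom2=pair.chrom1,
            pos2=pair.pos1,
            strand2=pair.strand1,
        )
    return pair


def canonicalize_all(pairs: Iterable[ValidPair]) -> list[ValidPair]:
    return [canonicalize(p) for p in pairs]


_DEDUP_KEY = ("chrom1", "pos1", "strand1", "chrom2", "pos2", "strand2")


def deduplicate(pairs: Iterable[ValidPair]) -> list[ValidPair]:
    """Collapse exact coordinate+strand duplicates, keeping first occurrence.

    read_id is deliberately not part of the key: PCR duplicates carry
    fresh read names but identical coordinates.
    """
    seen: set[tuple] = set()
    out: list[ValidPair] = []
    for p in pairs:
        key = (p.chrom1, p.pos1, p.strand1, p.chrom2, p.pos2, p.strand2)
        if key not in seen:
            seen.add(key)
            out.append(p)
    return out


def filter_pairs(pairs: Iterable[ValidPair], params: AnalysisParams) -> list[ValidPair]:
    """Drop trans pairs and cis pairs with separation < min_pair_dist.

    Separation exactly at the threshold is retained ("< 1 kb" removed).
    """
    out = []
    for p in pairs:
        if not p.is_cis:
            continue
        if p.distance < params.min_pair_dist:
            continue
        out.append(p)
    return out


def call_interactions(
    pairs: Sequence[ValidPair],
    peaks: Optional[Sequence[GenomicInterval]],
    params: AnalysisParams,
    peak_slack: int = 0,
    allow_no_peaks: bool = False,
) -> list[Interaction]:
    """Call interactions from filtered pairs.

    A pair is called when ``long_min <= distance <= long_max`` (inclusive
    window) and at least one anchor point falls inside a peak (± peak_slack).
    Each surviving pair becomes exactly one interaction; nothing is merged.

    With ``allow_no_peaks=True`` the peak-anchor requirement is waived
    (distance window only); otherwise an empty/missing peak set is an error.
    """
    index: Optional[PeakIndex] = None
    if peaks:
        index = PeakIndex(peaks, slack=peak_slack)
    elif not allow_no_peaks:
        raise ValueError(
            "call_interactions requires a non-empty peak set "
            "(pass allow_no_peaks=True for a distance-only call)"
        )
    out: list[Interaction] = []
    for p in pairs:
        if not p.is_cis:
            continue
        d = p.distance
        if d < params.long_min or d > params.long_max:
            continue
        if index is not None:
            if not (
                index.contains(p.chrom1, p.pos1)
                or index.contains(p.chrom2, p.pos2)
            ):
                continue
        a1, a2 = sorted((p.pos1, p.pos2))
        out.append(Interaction(chrom=p.chrom1, anchor1=a1, anchor2=a2, source_id=p.read_id))
    return out


def qc_metrics(
    raw_pairs: Sequence[ValidPair],
    params: AnalysisParams,
    peaks: Optional[Sequence[GenomicInterval]] = None,
) -> QCMetrics:
    """Compute summary QC over a raw pair set.

    Raw pairs are canonicalized and deduplicated internally;
    ``peak_anchored_fraction`` is the fraction of long-range cis pairs
    (pre peak-filter) with at least one anchor in a peak.
    """
    total = len(raw_pairs)
    uniq = deduplicate(canonicalize_all(raw_pairs))
    cis = [p for p in uniq if p.is_cis]
    n_trans = len(uniq) - len(cis)
    if len(uniq) == 0:
        ratio = math.nan
    elif n_trans == 0:
        ratio = math.inf
    else:
        ratio = len(cis) / n_trans
    long_range = [p for p in cis if p.distance >= params.long_min]
    long_frac = len(long_range) / len(uniq) if uniq else 0.0
    peak_frac = math.nan
    if peaks and long_range:
        index = PeakIndex(peaks)
        n_hit = sum(
            1
            for p in long_range
            if index.contains(p.chrom1, p.pos1) or index.contains(p.chrom2, p.pos2)
        )
        peak_frac = n_hit / len(long_range)
    return QCMetrics(
        total_pairs=total,
        unique_pairs=len(uniq),
        cis_pairs=len(cis),
        trans_pairs=n_trans,
        cis_trans_ratio=ratio,
        long_range_pairs=len(long_range),
        long_range_fraction=long_frac,
        peak_anchored_fraction=peak_frac,
    )


def classify_pairs(
    raw_pairs: Sequence[ValidPair],
    peaks: Sequence[GenomicInterval],
    params: AnalysisParams,
) -> dict[str, int]:
    """Assign every raw pair to exactly one disposition category.

    Categories: duplicate, trans, short (< min_pair_dist), out_of_window
    (outside [long_min, long_max]), no_peak_anchor, called.  Counts sum
    to the input size by construction.
    """
    counts = dict.fromkeys(
        ("duplicate", "trans", "short", "out_of_window", "no_peak_anchor", "called"), 0
    )
    index = PeakIndex(peaks)
    seen: set[tuple] = set()
    for raw in raw_pairs:
        p = canonicalize(raw)
        key = (p.chrom1, p.pos1, p.strand1, p.chrom2, p.pos2, p.strand2)
        if key in seen:
            counts["duplicate"] += 1
            continue
        seen.add(key)
        if not p.is_cis:
            counts["trans"] += 1
        elif p.distance < params.min_pair_dist:
            counts["short"] += 1
        elif p.distance < params.long_min or p.distance > params.long_max:
            counts["out_of_window"] += 1
        elif not (index.contains(p.chrom1, p.pos1) or index.contains(p.chrom2, p.pos2)):
            counts["no_peak_anchor"] += 1
        else:
            counts["called"] += 1
    return counts
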