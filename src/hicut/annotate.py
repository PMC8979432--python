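"""Linking interactions to GWAS SNPs and gene promoters.

The join is two-step, mirroring the window-style joins done with
bedtools: an interaction is linked to a SNP when either 1-bp anchor lies
within ``snp_window`` (5 kb, inclusive) of the SNP position; the linked
interactions are then mapped to promoters, defined as the strand-aware
TSS +/- 2,500 bp.  A separate anchor-preparation step builds the
non-promoter anchor BED used for external motif discovery.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

from intervaltree import IntervalTree

from .io import GenomicInterval, GeneRecord, SNPRecord, chrom_sort_key
from .pairs import AnalysisParams, Interaction

__all__ = [
    "SNPLinkage",
    "promoters",
    "link_snps",
    "map_to_promoters",
    "unique_linked_interactions",
    "unique_promoter_genes",
    "prepare_motif_anchors",
]


@dataclass(frozen=True)
class SNPLinkage:
    """One (interaction, SNP) association within the linking window."""

    interaction: Interaction
    snp: SNPRecord
    matched_anchor: str  # "1", "2" or "both"
    promoter_genes: frozenset[str] = frozenset()


def promoters(genes: Sequence[GeneRecord], flank: int) -> list[GenomicInterval]:
    """Promoter intervals: strand-aware TSS +/- flank, clipped at zero.

    The TSS is tx_start for + genes and the last transcribed base for -
    genes (both as 0-based points); the interval spans ``2*flank + 1`` bp
    centered on it, truncated at the chromosome start.
    """
    if flank <= 0:
        raise ValueError("flank must be > 0")
    out = []
    for g in genes:
        t = g.tss
        out.append(
            GenomicInterval(
                chrom=g.chrom,
                start=max(0, t - flank),
                end=t + flank + 1,
                name=g.name,
            )
        )
    return out


def link_snps(
    interactions: Sequence[Interaction],
    snps: Sequence[SNPRecord],
    params: AnalysisParams,
) -> list[SNPLinkage]:
    """All (interaction, SNP) pairs within ``snp_window`` bp, same chromosome.

    The window is inclusive: an anchor exactly ``snp_window`` bp from the
    SNP links; one bp farther does not.  Every qualifying pair is emitted,
    so one interaction near two SNPs yields two linkages.
    """
    by_chrom: dict[str, list[SNPRecord]] = {}
    for s in snps:
        by_chrom.setdefault(s.chrom, []).append(s)
    wnd = params.snp_window
    out: list[SNPLinkage] = []
    for it in interactions:
        for s in by_chrom.get(it.chrom, ()):
            h1 = abs(s.pos - it.anchor1) <= wnd
            h2 = abs(s.pos - it.anchor2) <= wnd
            if h1 or h2:
                anchor = "both" if (h1 and h2) else ("1" if h1 else "2")
                out.append(SNPLinkage(interaction=it, snp=s, matched_anchor=anchor))
    return out


def unique_linked_interactions(linkages: Iterable[SNPLinkage]) -> int:
    """Count distinct interactions across linkage rows."""
    return len({(l.interaction.chrom, l.interaction.anchor1, l.interaction.anchor2, l.interaction.source_id) for l in linkages})


def _promoter_trees(promoter_intervals: Sequence[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in promoter_intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv.name)
    return trees


def map_to_promoters(
    linkages: Sequence[SNPLinkage],
    promoter_intervals: Sequence[GenomicInterval],
    params: Optional[AnalysisParams] = None,
) -> list[SNPLinkage]:
    """Attach the names of genes whose promoter contains either anchor point.

    Anchor membership is plain point-in-interval containment (no extra
    window).  Returns new linkage records with ``promoter_genes`` filled.
    """
    trees = _promoter_trees(promoter_intervals)
    out = []
    for lk in linkages:
        it = lk.interaction
        tree = trees.get(it.chrom)
        genes: set[str] = set()
        if tree is not None:
            for anchor in (it.anchor1, it.anchor2):
                for hit in tree.at(anchor - 1):  # 1-based point -> 0-based
                    if hit.data is not None:
                        genes.add(hit.data)
        out.append(replace(lk, promoter_genes=frozenset(genes)))
    return out


def unique_promoter_genes(linkages: Iterable[SNPLinkage]) -> set[str]:
    """Union of gene names across promoter-positive linkages."""
    genes: set[str] = set()
    for lk in linkages:
        genes |= lk.promoter_genes
    return genes


def prepare_motif_anchors(
    interactions: Sequence[Interaction],
    genes: Sequence[GeneRecord],
    params: AnalysisParams,
) -> list[GenomicInterval]:
    """Non-promoter anchors extended for motif discovery.

    Collects all 1-bp anchor points, drops those within
    ``promoter_flank`` bp of any TSS, and extends the survivors by
    ``anchor_extension`` bp on each side (201-bp intervals at the
    defaults).  Output is sorted and deduplicated, ready to write as BED.
    """
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        t = g.tss
        trees.setdefault(g.chrom, IntervalTree()).addi(
            max(0, t - params.promoter_flank), t + params.promoter_flank + 1
        )
    seen: set[tuple[str, int]] = set()
    out: list[GenomicInterval] = []
    ext = params.anchor_extension
    for it in interactions:
        for pos in (it.anchor1, it.anchor2):
            key = (it.chrom, pos)
            if key in seen:
                continue
            seen.add(key)
            tree = trees.get(it.chrom)
            if tree is not None and tree.overlaps_point(pos - 1):
                continue
            out.append(
                GenomicInterval(
                    chrom=it.chrom, start=max(0, pos - 1 - ext), end=pos + ext
                )
            )
    out.sort(key=lambda iv: (chrom_sort_key(iv.chrom), iv.start, iv.end))
    return out
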