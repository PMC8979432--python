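"""Readers and writers for the external formats the pipeline touches.

Coordinate conventions, centralized here and used everywhere else:

* interval files (BED, narrowPeak, BEDPE, promoter/anchor outputs) are
  0-based half-open ``[start, end)``;
* pair and SNP positions are 1-based points;
* a 1-based point ``p`` maps to the 0-based half-open interval
  ``[p - 1, p)`` and back.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "ValidPair",
    "GenomicInterval",
    "LoopRecord",
    "SNPRecord",
    "GeneRecord",
    "ParseError",
    "chrom_sort_key",
    "normalize_chrom",
    "point_to_interval",
    "interval_midpoint",
    "read_valid_pairs",
    "write_valid_pairs",
    "read_bed",
    "write_bed",
    "read_bedpe",
    "write_bedpe",
    "read_gwas_catalog",
    "read_gene_table",
    "write_interactions_bedpe",
    "read_interactions_bedpe",
]


class ParseError(ValueError):
    """A malformed record in an input file; the message names the line."""


# ---------------------------------------------------------------------------
# Domain record types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ValidPair:
    """One proximity-ligated read pair (HiC-Pro allValidPairs record).

    Positions are 1-based points; strands travel with their end.
    """

    read_id: str
    chrom1: str
    pos1: int
    strand1: str
    chrom2: str
    pos2: int
    strand2: str

    @property
    def is_cis(self) -> bool:
        return self.chrom1 == self.chrom2

    @property
    def distance(self) -> Optional[int]:
        """Separation ``pos2 - pos1`` for cis pairs, ``None`` for trans."""
        if not self.is_cis:
            return None
        return abs(self.pos2 - self.pos1)


@dataclass(frozen=True)
class GenomicInterval:
    """A BED-convention interval: 0-based half-open ``[start, end)``."""

    chrom: str
    start: int
    end: int
    name: Optional[str] = None
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"empty interval {self.chrom}:{self.start}-{self.end}"
            )

    def contains_point(self, pos_1based: int, slack: int = 0) -> bool:
        """Whether a 1-based point falls inside the interval (± slack bp)."""
        p0 = pos_1based - 1
        return self.start - slack <= p0 < self.end + slack

    @property
    def midpoint(self) -> int:
        """0-based midpoint of the interval."""
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class LoopRecord:
    """A paired-anchor loop (BEDPE record), anchors in canonical order."""

    anchorA: GenomicInterval
    anchorB: GenomicInterval
    score: Optional[float] = None

    @property
    def is_trans(self) -> bool:
        return self.anchorA.chrom != self.anchorB.chrom

    def canonical(self) -> "LoopRecord":
        a, b = self.anchorA, self.anchorB
        ka = (chrom_sort_key(a.chrom), a.start, a.end)
        kb = (chrom_sort_key(b.chrom), b.start, b.end)
        if kb < ka:
            return LoopRecord(anchorA=b, anchorB=a, score=self.score)
        return self


@dataclass(frozen=True)
class SNPRecord:
    """A trait-associated variant from a GWAS catalog export (1-based)."""

    chrom: str
    pos: int
    rsid: str
    trait: str = ""


@dataclass(frozen=True)
class GeneRecord:
    """A gene model row (RefSeq/UCSC style): 0-based half-open tx span."""

    name: str
    chrom: str
    tx_start: int
    tx_end: int
    strand: str

    def __post_init__(self) -> None:
        if self.tx_start >= self.tx_end:
            raise ValueError(f"gene {self.name}: tx_start >= tx_end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.name}: bad strand {self.strand!r}")

    @property
    def tss(self) -> int:
        """Strand-aware transcription start site as a 0-based point."""
        return self.tx_start if self.strand == "+" else self.tx_end - 1


# ---------------------------------------------------------------------------
# Chromosome naming and ordering
# ---------------------------------------------------------------------------

_NAT_SPLIT = re.compile(r"(\d+)")


def chrom_sort_key(chrom: str):
    """Natural-order sort key: chr2 before chr10, chrX after chr22."""
    return tuple(
        int(tok) if tok.isdigit() else tok
        for tok in _NAT_SPLIT.split(chrom)
        if tok != ""
    )


def normalize_chrom(name: str, style: str = "chr") -> str:
    """Normalize '1' <-> 'chr1' to the requested style. Idempotent."""
    name = str(name).strip()
    bare = name[3:] if name.lower().startswith("chr") else name
    if style == "chr":
        return "chr" + bare
    return bare


def point_to_interval(chrom: str, pos_1based: int, name: Optional[str] = None) -> GenomicInterval:
    """1-based point -> 0-based half-open 1-bp interval ``[p-1, p)``."""
    return GenomicInterval(chrom=chrom, start=pos_1based - 1, end=pos_1based, name=name)


def interval_midpoint(iv: GenomicInterval) -> int:
    return iv.midpoint


# ---------------------------------------------------------------------------
# Valid pairs (HiC-Pro allValidPairs dialect)
# ---------------------------------------------------------------------------

#: column indices of the default HiC-Pro allValidPairs layout
DEFAULT_PAIR_DIALECT = {
    "read_id": 0,
    "chrom1": 1,
    "pos1": 2,
    "strand1": 3,
    "chrom2": 4,
    "pos2": 5,
    "strand2": 6,
}


def read_valid_pairs(
    path,
    dialect: Optional[dict] = None,
    strict: bool = True,
) -> list[ValidPair]:
    """Read a HiC-Pro-style allValidPairs TSV.

    Columns 1-7 are read_id, chrom1, pos1, strand1, chrom2, pos2, strand2;
    trailing columns (fragment ids, sizes...) are ignored.  With
    ``strict=False`` malformed lines are skipped with a logged count
    instead of raising.
    """
    cols = dialect or DEFAULT_PAIR_DIALECT
    need = max(cols.values()) + 1
    out: list[ValidPair] = []
    n_skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if len(fields) < need:
                    raise ParseError(
                        f"{path}:{lineno}: expected >= {need} columns, got {len(fields)}"
                    )
                try:
                    pos1 = int(fields[cols["pos1"]])
                    pos2 = int(fields[cols["pos2"]])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: non-integer position") from exc
                if pos1 < 1 or pos2 < 1:
                    raise ParseError(f"{path}:{lineno}: position < 1")
                out.append(
                    ValidPair(
                        read_id=fields[cols["read_id"]],
                        chrom1=fields[cols["chrom1"]],
                        pos1=pos1,
                        strand1=fields[cols["strand1"]],
                        chrom2=fields[cols["chrom2"]],
                        pos2=pos2,
                        strand2=fields[cols["strand2"]],
                    )
                )
            except ParseError:
                if strict:
                    raise
                n_skipped += 1
    if n_skipped:
        log.warning("read_valid_pairs: skipped %d malformed line(s) in %s", n_skipped, path)
    return out


def write_valid_pairs(pairs: Iterable[ValidPair], path) -> None:
    with open(path, "w") as fh:
        for p in pairs:
            fh.write(
                f"{p.read_id}\t{p.chrom1}\t{p.pos1}\t{p.strand1}"
                f"\t{p.chrom2}\t{p.pos2}\t{p.strand2}\n"
            )


# ---------------------------------------------------------------------------
# BED / narrowPeak
# ---------------------------------------------------------------------------


def read_bed(path) -> list[GenomicInterval]:
    """Read BED3/BED6/narrowPeak; columns 4-5 become name/score if present."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 BED columns")
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            name = f[3] if len(f) > 3 else None
            score: Optional[float] = None
            if len(f) > 4 and f[4] not in (".", ""):
                try:
                    score = float(f[4])
                except ValueError:
                    score = None
            try:
                out.append(GenomicInterval(f[0], start, end, name=name, score=score))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed(intervals: Iterable[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None:
                cols.append(iv.name if iv.name is not None else ".")
            if iv.score is not None:
                cols.append(repr(iv.score))
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# BEDPE loops
# ---------------------------------------------------------------------------

_BEDPE_HEADER = re.compile(r"^(#|chrom|track)", re.IGNORECASE)


def _is_bedpe_header(line: str, fields: list[str]) -> bool:
    # a 'chrom1  start1 ...' label row has a non-numeric second column
    if _BEDPE_HEADER.match(line):
        return True
    return len(fields) >= 2 and not fields[1].lstrip("-").isdigit()


def read_bedpe(path) -> list[LoopRecord]:
    """Read a BEDPE loop file; anchors are returned canonically ordered.

    Header lines (leading '#', 'track', or a column-label row) are
    skipped.  Trans records are retained (``LoopRecord.is_trans`` flags
    them).
    """
    out: list[LoopRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if _is_bedpe_header(line, f):
                continue
            if len(f) < 6:
                raise ParseError(f"{path}:{lineno}: expected >= 6 BEDPE columns")
            try:
                a = GenomicInterval(f[0], int(f[1]), int(f[2]))
                b = GenomicInterval(f[3], int(f[4]), int(f[5]))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            score: Optional[float] = None
            if len(f) > 7 and f[7] not in (".", ""):
                try:
                    score = float(f[7])
                except ValueError:
                    score = None
            out.append(LoopRecord(anchorA=a, anchorB=b, score=score).canonical())
    return out


def write_bedpe(loops: Iterable[LoopRecord], path) -> None:
    with open(path, "w") as fh:
        for lp in loops:
            a, b = lp.anchorA, lp.anchorB
            cols = [a.chrom, str(a.start), str(a.end), b.chrom, str(b.start), str(b.end)]
            if lp.score is not None:
                cols += [".", repr(lp.score)]
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# GWAS catalog export
# ---------------------------------------------------------------------------


def read_gwas_catalog(
    path,
    trait_filter: Optional[str] = None,
    chrom_style: str = "chr",
) -> list[SNPRecord]:
    """Read an NHGRI-EBI GWAS catalog TSV export.

    Requires CHR_ID, CHR_POS and SNPS columns; the trait column is
    ``DISEASE/TRAIT`` when present.  Rows with missing or non-numeric
    CHR_POS (interaction entries, unmapped variants) are skipped with a
    logged count — these exports are messy by nature.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["CHR_ID", "CHR_POS", "SNPS"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s): {', '.join(missing)}")
    trait_col = next((c for c in ("DISEASE/TRAIT", "TRAIT", "MAPPED_TRAIT") if c in df.columns), None)
    out: list[SNPRecord] = []
    n_skipped = 0
    # positional access: itertuples() mangles names like 'DISEASE/TRAIT'
    cols = {c: i for i, c in enumerate(df.columns)}
    for raw in df.itertuples(index=False, name=None):
        pos_s = raw[cols["CHR_POS"]].strip()
        chrom_s = raw[cols["CHR_ID"]].strip()
        if not pos_s or not pos_s.isdigit() or not chrom_s:
            n_skipped += 1
            continue
        trait = raw[cols[trait_col]].strip() if trait_col else ""
        if trait_filter is not None and trait_filter.lower() not in trait.lower():
            continue
        out.append(
            SNPRecord(
                chrom=normalize_chrom(chrom_s, style=chrom_style),
                pos=int(pos_s),
                rsid=raw[cols["SNPS"]].strip(),
                trait=trait,
            )
        )
    if n_skipped:
        log.warning("read_gwas_catalog: skipped %d row(s) without usable coordinates", n_skipped)
    return out


# ---------------------------------------------------------------------------
# Gene table (RefSeq / UCSC table-browser style)
# ---------------------------------------------------------------------------


def read_gene_table(path, chrom_style: str = "chr") -> list[GeneRecord]:
    """Read a gene table TSV with chrom, txStart, txEnd, strand, name2 columns.

    Column-name matching is case-insensitive; ``name2`` (gene symbol) is
    preferred over ``name`` (transcript accession) when both exist.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    lower = {c.lower().lstrip("#"): c for c in df.columns}

    def col(*cands):
        for c in cands:
            if c in lower:
                return lower[c]
        raise ParseError(f"{path}: missing required column (one of {cands})")

    c_chrom = col("chrom", "chr")
    c_start = col("txstart", "tx_start", "start")
    c_end = col("txend", "tx_end", "end")
    c_strand = col("strand")
    c_name = col("name2", "gene", "name")
    out = []
    for _, row in df.iterrows():
        out.append(
            GeneRecord(
                name=row[c_name],
                chrom=normalize_chrom(row[c_chrom], style=chrom_style),
                tx_start=int(row[c_start]),
                tx_end=int(row[c_end]),
                strand=row[c_strand],
            )
        )
    return out


def write_gene_table(genes: Iterable[GeneRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\ttxStart\ttxEnd\tstrand\tname2\n")
        for g in genes:
            fh.write(f"{g.chrom}\t{g.tx_start}\t{g.tx_end}\t{g.strand}\t{g.name}\n")


# ---------------------------------------------------------------------------
# Interactions <-> BEDPE (1-bp anchors)
# ---------------------------------------------------------------------------


def write_interactions_bedpe(interactions, path) -> None:
    """Write called interactions as BEDPE with 1-bp anchors ``[pos-1, pos)``."""
    with open(path, "w") as fh:
        for it in interactions:
            fh.write(
                f"{it.chrom}\t{it.anchor1 - 1}\t{it.anchor1}"
                f"\t{it.chrom}\t{it.anchor2 - 1}\t{it.anchor2}"
                f"\t{it.source_id}\n"
            )


def read_interactions_bedpe(path):
    """Read a 1-bp-anchor BEDPE written by :func:`write_interactions_bedpe`."""
    from .pairs import Interaction  # local import to avoid a cycle

    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if _is_bedpe_header(line, f):
                continue
            if len(f) < 6:
                raise ParseError(f"{path}:{lineno}: expected >= 6 BEDPE columns")
            if f[0] != f[3]:
                raise ParseError(f"{path}:{lineno}: trans record in interaction file")
            a1, a2 = int(f[2]), int(f[5])
            source = f[6] if len(f) > 6 else f"L{lineno}"
            out.append(
                Interaction(chrom=f[0], anchor1=min(a1, a2), anchor2=max(a1, a2), source_id=source)
            )
    return out
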