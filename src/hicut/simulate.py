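"""Synthetic valid-pair datasets with known planted ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: cis contact frequency decaying as a power law of separation, a
trans background, protein-occupancy peaks, loops whose anchors coincide
with a subset of peaks, PCR duplicates replaying exact coordinates under
fresh read names, plus SNP positions and a gene/TSS table.  It does not
model sequence, restriction fragments, TADs or compartments.

Defaults are the package's study conditions: two 10 Mb chromosomes, 200
peaks of 500 bp, 50 loops spanning 20 kb - 2 Mb with 40 supporting pairs
each, 50,000 background cis pairs with decay exponent 1.0, 5% trans and
5% duplicates.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .io import (
    GenomicInterval,
    GeneRecord,
    LoopRecord,
    SNPRecord,
    ValidPair,
    chrom_sort_key,
    write_bed,
    write_bedpe,
    write_gene_table,
    write_valid_pairs,
)

__all__ = ["SimulationConfig", "SimBundle", "simulate", "simulate_replicates"]


def _default_chrom_sizes() -> dict[str, int]:
    return {"chr1": 10_000_000, "chr2": 10_000_000}


@dataclass(frozen=True)
class SimulationConfig:
    chrom_sizes: dict[str, int] = field(default_factory=_default_chrom_sizes)
    n_peaks: int = 200
    peak_width: int = 500
    n_loops: int = 50
    loop_distance_range: tuple[int, int] = (20_000, 2_000_000)
    n_background_pairs: int = 50_000
    n_loop_pairs_per_loop: int = 40
    decay_exponent: float = 1.0
    trans_fraction: float = 0.05
    duplicate_fraction: float = 0.05
    background_peak_fraction: float = 0.7
    coverage_field_tile: int = 25_000
    coverage_field_sigma: float = 1.0
    n_snps: int = 100
    n_genes: int = 300
    seed: int = 7

    def __post_init__(self) -> None:
        for name in ("n_peaks", "peak_width", "n_loops", "n_background_pairs",
                     "n_loop_pairs_per_loop", "n_snps", "n_genes"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("trans_fraction", "duplicate_fraction", "background_peak_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.coverage_field_tile <= 0 or self.coverage_field_sigma < 0:
            raise ValueError("coverage field parameters out of range")
        lo, hi = self.loop_distance_range
        if not (0 < lo < hi <= min(self.chrom_sizes.values())):
            raise ValueError("loop_distance_range must lie within (0, min chrom length)")


@dataclass
class _Structure:
    """Planted objects shared across replicate draws."""

    peaks: list[GenomicInterval]
    loops: list[LoopRecord]
    loop_anchor_mids: list[tuple[str, int, int]]  # chrom, midA (1-based), midB
    snps: list[SNPRecord]
    genes: list[GeneRecord]
    # per-chromosome lognormal tile weights: the shared "chromatin state"
    # field that makes replicate coverage correlated, as in real assays
    field_weights: dict[str, np.ndarray] = field(default_factory=dict)


@dataclass
class SimBundle:
    """One simulated dataset plus its truth report."""

    config: SimulationConfig
    pairs: list[ValidPair]
    peaks: list[GenomicInterval]
    loops: list[LoopRecord]
    snps: list[SNPRecord]
    genes: list[GeneRecord]
    truth: dict

    def planted_loci(self, resolution: int) -> list:
        """Planted loop anchors as bin-level loci pairs (for APA)."""
        from .apa import LociPair

        out = []
        seen = set()
        for chrom, midA, midB in self.truth["loop_anchor_midpoints"]:
            bi = (midA - 1) // resolution
            bj = (midB - 1) // resolution
            if bi == bj:
                continue
            key = (chrom, min(bi, bj), max(bi, bj))
            if key in seen:
                continue
            seen.add(key)
            out.append(LociPair(chrom=chrom, bin_i=min(bi, bj), bin_j=max(bi, bj)))
        return out

    def write(self, out_dir) -> dict[str, Path]:
        """Write the bundle in the pipeline's standard on-disk dialects."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "pairs": out / "sim.allValidPairs",
            "peaks": out / "peaks.bed",
            "loops": out / "loops_truth.bedpe",
            "snps": out / "snps.tsv",
            "genes": out / "genes.tsv",
            "truth": out / "truth.json",
        }
        write_valid_pairs(self.pairs, paths["pairs"])
        write_bed(self.peaks, paths["peaks"])
        write_bedpe(self.loops, paths["loops"])
        with open(paths["snps"], "w") as fh:
            fh.write("CHR_ID\tCHR_POS\tSNPS\tDISEASE/TRAIT\n")
            for s in self.snps:
                bare = s.chrom[3:] if s.chrom.startswith("chr") else s.chrom
                fh.write(f"{bare}\t{s.pos}\t{s.rsid}\t{s.trait}\n")
        write_gene_table(self.genes, paths["genes"])
        with open(paths["truth"], "w") as fh:
            json.dump(self.truth, fh, indent=1, sort_keys=True)
        return paths


# ---------------------------------------------------------------------------
# structure planting
# ---------------------------------------------------------------------------


def _allocate(total: int, weights: Sequence[float]) -> list[int]:
    """Largest-remainder allocation of ``total`` across weights."""
    w = np.asarray(weights, dtype=float)
    if w.sum() == 0:
        return [0] * len(w)
    exact = total * w / w.sum()
    base = np.floor(exact).astype(int)
    rem = total - int(base.sum())
    order = np.argsort(-(exact - base), kind="stable")
    for i in range(rem):
        base[order[i]] += 1
    return base.tolist()


def _plant_structure(config: SimulationConfig, rng: np.random.Generator) -> _Structure:
    chroms = sorted(config.chrom_sizes, key=chrom_sort_key)
    sizes = [config.chrom_sizes[c] for c in chroms]
    pw = config.peak_width

    # peaks: non-overlapping slot placement per chromosome
    peaks: list[GenomicInterval] = []
    per_chrom = _allocate(config.n_peaks, sizes)
    for chrom, L, n in zip(chroms, sizes, per_chrom):
        slot = 2 * pw
        n_slots = L // slot
        if n > n_slots:
            raise ValueError(
                f"cannot place {n} non-overlapping peaks of {pw} bp on {chrom} ({L} bp)"
            )
        chosen = np.sort(rng.choice(n_slots, size=n, replace=False))
        for s in chosen:
            start = int(s) * slot + pw // 2
            peaks.append(GenomicInterval(chrom=chrom, start=start, end=start + pw,
                                         name=f"peak_{chrom}_{start}"))

    # loops: ordered peak pairs with midpoint separation in range
    lo, hi = config.loop_distance_range
    candidates: list[tuple[int, int]] = []
    idx_by_chrom: dict[str, list[int]] = {}
    for i, p in enumerate(peaks):
        idx_by_chrom.setdefault(p.chrom, []).append(i)
    for chrom, idxs in idx_by_chrom.items():
        mids = np.array([peaks[i].midpoint for i in idxs])
        for a in range(len(idxs)):
            for b in range(a + 1, len(idxs)):
                d = int(mids[b] - mids[a])
                if lo <= d <= hi:
                    candidates.append((idxs[a], idxs[b]))
    if config.n_loops > len(candidates):
        raise ValueError(
            f"cannot plant {config.n_loops} loops: only {len(candidates)} peak pairs in range"
        )
    loops: list[LoopRecord] = []
    anchor_mids: list[tuple[str, int, int]] = []
    if config.n_loops:
        pick = rng.choice(len(candidates), size=config.n_loops, replace=False)
        for k in np.sort(pick):
            ia, ib = candidates[int(k)]
            pa, pb = peaks[ia], peaks[ib]
            loops.append(LoopRecord(anchorA=pa, anchorB=pb).canonical())
            anchor_mids.append((pa.chrom, pa.midpoint + 1, pb.midpoint + 1))

    # SNPs: half placed near loop anchors (when loops exist), rest uniform
    snps: list[SNPRecord] = []
    n_near = config.n_snps // 2 if anchor_mids else 0
    for k in range(n_near):
        chrom, midA, midB = anchor_mids[k % len(anchor_mids)]
        mid = midA if k % 2 == 0 else midB
        off = int(rng.integers(-4_000, 4_001))
        pos = max(1, mid + off)
        snps.append(SNPRecord(chrom=chrom, pos=pos, rsid=f"rs{900000 + k}",
                              trait="synthetic trait"))
    for k in range(config.n_snps - n_near):
        ci = int(rng.integers(len(chroms)))
        pos = int(rng.integers(1, sizes[ci] + 1))
        snps.append(SNPRecord(chrom=chroms[ci], pos=pos, rsid=f"rs{100000 + k}",
                              trait="synthetic trait"))

    # genes: ~30% with TSS on loop anchors so promoter mapping has signal
    genes: list[GeneRecord] = []
    n_anchor_genes = int(0.3 * config.n_genes) if anchor_mids else 0
    for k in range(config.n_genes):
        strand = "+" if rng.random() < 0.5 else "-"
        length = int(rng.integers(5_000, 50_001))
        if k < n_anchor_genes:
            chrom, midA, midB = anchor_mids[k % len(anchor_mids)]
            tss0 = (midA if k % 2 == 0 else midB) - 1
        else:
            ci = int(rng.integers(len(chroms)))
            chrom = chroms[ci]
            tss0 = int(rng.integers(0, sizes[ci] - length))
        L = config.chrom_sizes[chrom]
        if strand == "+":
            start = min(tss0, L - 2)
            end = min(start + length, L)
        else:
            end = max(2, min(tss0 + 1, L))
            start = max(0, end - length)
        genes.append(GeneRecord(name=f"GENE{k:04d}", chrom=chrom,
                                tx_start=start, tx_end=max(end, start + 1),
                                strand=strand))

    # regional coverage field: lognormal tile intensities shared by replicates
    fields: dict[str, np.ndarray] = {}
    for chrom, L in zip(chroms, sizes):
        n_tiles = int(np.ceil(L / config.coverage_field_tile))
        fields[chrom] = rng.lognormal(0.0, config.coverage_field_sigma, n_tiles)

    return _Structure(peaks=peaks, loops=loops, loop_anchor_mids=anchor_mids,
                      snps=snps, genes=genes, field_weights=fields)


# ---------------------------------------------------------------------------
# pair drawing
# ---------------------------------------------------------------------------


def _powerlaw_distances(
    rng: np.random.Generator, n: int, alpha: float, d_min: float, d_max: float
) -> np.ndarray:
    """Sample separations with density proportional to d^(-alpha) on [d_min, d_max]."""
    u = rng.random(n)
    if abs(alpha - 1.0) < 1e-12:
        d = d_min * np.exp(u * np.log(d_max / d_min))
    else:
        a1 = 1.0 - alpha
        d = (d_min**a1 + u * (d_max**a1 - d_min**a1)) ** (1.0 / a1)
    return np.maximum(np.round(d).astype(np.int64), int(d_min))


def _draw_pairs(
    config: SimulationConfig, structure: _Structure, rng: np.random.Generator
) -> tuple[list[ValidPair], dict]:
    chroms = sorted(config.chrom_sizes, key=chrom_sort_key)
    sizes = [config.chrom_sizes[c] for c in chroms]
    pairs: list[ValidPair] = []
    serial = 0

    def strand() -> str:
        return "+" if rng.random() < 0.5 else "-"

    def emit(c1: str, p1: int, c2: str, p2: int) -> None:
        nonlocal serial
        serial += 1
        pairs.append(ValidPair(read_id=f"SIM{serial:07d}", chrom1=c1, pos1=int(p1),
                               strand1=strand(), chrom2=c2, pos2=int(p2),
                               strand2=strand()))

    # loop-supporting pairs: jitter within the anchor peak (<= peak_width/2)
    jit = config.peak_width // 2
    n_loop_pairs = 0
    for chrom, midA, midB in structure.loop_anchor_mids:
        for _ in range(config.n_loop_pairs_per_loop):
            p1 = max(1, midA + int(rng.integers(-jit, jit + 1)))
            p2 = max(1, midB + int(rng.integers(-jit, jit + 1)))
            emit(chrom, min(p1, p2), chrom, max(p1, p2))
            n_loop_pairs += 1

    # Background cis pairs follow the canonical factorized contact model:
    # intensity(x, y) ~ bias(x) * decay(|x-y|) * bias(y), where bias is a
    # per-bp end propensity — elevated by a factor mu inside planted peaks
    # (protein-directed assays concentrate pair ends at binding sites) and
    # given by the shared lognormal tile field elsewhere.  Sampling is by
    # rejection: propose end1 from bias, the separation from the decay
    # law, and accept with probability bias(end2)/max(bias), which yields
    # the product intensity exactly.  mu is set so a single end falls in
    # a peak with probability q, 1-(1-q)^2 = background_peak_fraction.
    peaks_by_chrom: dict[str, list[GenomicInterval]] = {}
    for p in structure.peaks:
        peaks_by_chrom.setdefault(p.chrom, []).append(p)
    q_end = 1.0 - float(np.sqrt(1.0 - config.background_peak_fraction))
    per_chrom = _allocate(config.n_background_pairs, sizes)
    tile = config.coverage_field_tile

    for chrom, L, n in zip(chroms, sizes, per_chrom):
        if n == 0:
            continue
        w_tiles = structure.field_weights[chrom]
        chrom_peaks = peaks_by_chrom.get(chrom, [])
        pk_starts = np.array([p.start for p in chrom_peaks], dtype=np.int64)
        pk_ends = np.array([p.end for p in chrom_peaks], dtype=np.int64)
        peak_bp = int((pk_ends - pk_starts).sum())
        field_mass = float(w_tiles.sum()) * tile
        if peak_bp and 0 < q_end < 1:
            mu = q_end / (1.0 - q_end) * field_mass / peak_bp
        else:
            mu = 0.0
        m_cap = max(mu, float(w_tiles.max()), 1e-12)
        tile_p = w_tiles / w_tiles.sum()

        def bias_at(pos: np.ndarray) -> np.ndarray:
            """Per-bp end propensity at 1-based positions."""
            out = w_tiles[np.minimum((pos - 1) // tile, len(w_tiles) - 1)]
            if peak_bp:
                k = np.searchsorted(pk_starts, pos - 1, side="right") - 1
                in_pk = (k >= 0) & ((pos - 1) < pk_ends[np.maximum(k, 0)])
                out = np.where(in_pk, mu, out)
            return out

        collected: list[np.ndarray] = []
        n_have = 0
        # acceptance is ~ mean(bias)/max(bias); batch accordingly
        exp_rate = max(float(np.mean(bias_at(np.linspace(1, L, 4_096, dtype=np.int64)))) / m_cap, 1e-4)
        while n_have < n:
            batch = int(min(4_000_000, max(100_000, 1.5 * (n - n_have) / exp_rate)))
            from_peak = rng.random(batch) < (
                mu * peak_bp / (mu * peak_bp + field_mass) if peak_bp else 0.0
            )
            p1 = np.empty(batch, dtype=np.int64)
            n_pk = int(from_peak.sum())
            if n_pk:
                k = rng.integers(0, len(chrom_peaks), size=n_pk)
                widths = pk_ends[k] - pk_starts[k]
                p1[from_peak] = pk_starts[k] + rng.integers(0, widths) + 1
            n_fld = batch - n_pk
            if n_fld:
                t = rng.choice(len(w_tiles), size=n_fld, p=tile_p)
                p1[~from_peak] = np.minimum(
                    t.astype(np.int64) * tile + rng.integers(0, tile, size=n_fld) + 1, L
                )
            d = _powerlaw_distances(rng, batch, config.decay_exponent, 1_000, L - 1)
            up_ok = p1 + d <= L
            down_ok = p1 - d >= 1
            feasible = up_ok | down_ok
            go_up = np.where(up_ok & down_ok, rng.random(batch) < 0.5, up_ok)
            p2 = np.where(go_up, p1 + d, p1 - d)
            accept = feasible & (rng.random(batch) * m_cap < bias_at(np.abs(p2)))
            lo = np.minimum(p1[accept], p2[accept])
            hi = np.maximum(p1[accept], p2[accept])
            take = min(n - n_have, len(lo))
            collected.append(np.stack([lo[:take], hi[:take]], axis=1))
            n_have += take
        for a, b in np.concatenate(collected):
            emit(chrom, int(a), chrom, int(b))

    # trans pairs as a fraction of all emitted pairs
    n_cis = len(pairs)
    tf = config.trans_fraction
    n_trans = int(round(tf / (1 - tf) * n_cis)) if tf < 1 else 0
    if n_trans and len(chroms) < 2:
        raise ValueError("trans_fraction > 0 requires at least two chromosomes")
    for _ in range(n_trans):
        ci, cj = rng.choice(len(chroms), size=2, replace=False)
        emit(chroms[int(ci)], int(rng.integers(1, sizes[int(ci)] + 1)),
             chroms[int(cj)], int(rng.integers(1, sizes[int(cj)] + 1)))

    # duplicates: replay coordinates and strands under fresh read ids
    n_emitted = len(pairs)
    n_dup = int(np.floor(config.duplicate_fraction * n_emitted))
    if n_dup:
        dup_idx = rng.choice(n_emitted, size=n_dup, replace=False)
        for i in np.sort(dup_idx):
            src = pairs[int(i)]
            serial += 1
            pairs.append(dataclasses.replace(src, read_id=f"SIM{serial:07d}"))

    truth_counts = {
        "n_loop_pairs": n_loop_pairs,
        "n_background_pairs": int(sum(per_chrom)),
        "n_trans_pairs": n_trans,
        "n_duplicate_pairs": n_dup,
        "n_total_pairs": len(pairs),
    }
    return pairs, truth_counts


def _truth_report(config: SimulationConfig, structure: _Structure, counts: dict) -> dict:
    return {
        "counts": counts,
        "peaks": [[p.chrom, p.start, p.end] for p in structure.peaks],
        "loops": [
            [l.anchorA.chrom, l.anchorA.start, l.anchorA.end,
             l.anchorB.chrom, l.anchorB.start, l.anchorB.end]
            for l in structure.loops
        ],
        "loop_anchor_midpoints": [list(t) for t in structure.loop_anchor_mids],
        "snps": [[s.chrom, s.pos, s.rsid] for s in structure.snps],
        "n_genes": len(structure.genes),
        "config": {
            **{k: v for k, v in dataclasses.asdict(config).items()
               if k not in ("chrom_sizes", "loop_distance_range")},
            "chrom_sizes": dict(config.chrom_sizes),
            "loop_distance_range": list(config.loop_distance_range),
        },
    }


def simulate(config: SimulationConfig = SimulationConfig(), out_dir=None) -> SimBundle:
    """Generate one dataset; identical config (incl. seed) -> identical bundle."""
    rng = np.random.default_rng(config.seed)
    structure = _plant_structure(config, rng)
    pairs, counts = _draw_pairs(config, structure, rng)
    bundle = SimBundle(
        config=config,
        pairs=pairs,
        peaks=structure.peaks,
        loops=structure.loops,
        snps=structure.snps,
        genes=structure.genes,
        truth=_truth_report(config, structure, counts),
    )
    if out_dir is not None:
        bundle.write(out_dir)
    return bundle


def simulate_replicates(config: SimulationConfig, n_replicates: int) -> list[SimBundle]:
    """Replicate draws over one shared planted structure.

    The structure (peaks, loops, SNPs, genes) is generated once from the
    config seed; each replicate then draws its pairs independently from a
    per-replicate child seed, emulating biological replicates of the same
    underlying chromatin state.
    """
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    structure_rng = np.random.default_rng(config.seed)
    structure = _plant_structure(config, structure_rng)
    bundles = []
    for rep in range(n_replicates):
        rng = np.random.default_rng([config.seed, 1_000 + rep])
        pairs, counts = _draw_pairs(config, structure, rng)
        bundles.append(
            SimBundle(
                config=config,
                pairs=pairs,
                peaks=structure.peaks,
                loops=structure.loops,
                snps=structure.snps,
                genes=structure.genes,
                truth=_truth_report(config, structure, counts),
            )
        )
    return bundles
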