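"""Runs of homozygosity, genomic inbreeding (F_ROH), and consensus ROH maps.

An ROH is a maximal stretch of consecutive SNPs on one chromosome with no
heterozygous call and at most ``max_missing`` missing calls, whose first and
last SNPs are homozygous.  Maximality is under interval inclusion: every
qualifying stretch not contained in a longer qualifying stretch is emitted
(with a positive missing budget two maximal stretches may overlap).  The
standard threshold tiers are at least 5, 30 or 60 SNPs per stretch, with
missing budgets 0, 3 and 5 respectively.

F_ROH is the summed ROH length divided by the autosomal length covered by
SNPs, L_AUTO = sum over chromosomes of (last SNP pos - first SNP pos + 1);
segment lengths are likewise end - start + 1 (1-based inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, PopulationPanel

#: (min_snps, max_missing) per named tier
THRESHOLDS: dict[str, tuple[int, int]] = {
    "ROH5": (5, 0),
    "ROH30": (30, 3),
    "ROH60": (60, 5),
}

CONSENSUS_LEVELS = (0.10, 0.20, 0.25, 0.30, 0.50, 0.75, 0.90, 1.00)


@dataclass
class ROHSegment:
    sample: str
    chrom: str
    start_bp: int
    end_bp: int
    n_snps: int
    n_missing_inside: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return self.chrom == chrom and self.start_bp <= end and start <= self.end_bp


@dataclass
class FrohRecord:
    sample: str
    threshold: str
    froh_all: float
    froh_gt1mb: float
    froh_gt4mb: float
    per_chrom: dict[str, float]


@dataclass
class ConsensusROH:
    chrom: str
    start_bp: int
    end_bp: int
    consensus_level: float     # threshold the run satisfies
    consensus_fraction: float  # maximum carrier fraction inside the run
    n_carriers: int            # individuals with an ROH overlapping the run
    population: str
    subpop_carriers: dict[str, tuple[int, int]] = field(default_factory=dict)
    # subpop -> (n_r carriers, n_t total)

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


# ---------------------------------------------------------------------------


def _maximal_runs(is_hom: np.ndarray, is_miss: np.ndarray, max_missing: int):
    """Maximal (start, end) index runs with no het, <= max_missing missing,
    hom endpoints; contained runs dropped.  Input arrays cover one
    chromosome; positions that are neither hom nor missing are hets."""
    n = len(is_hom)
    is_het = ~is_hom & ~is_miss
    runs: list[tuple[int, int]] = []
    block_start = 0
    for block_end in list(np.flatnonzero(is_het)) + [n]:
        runs.extend(
            _runs_in_block(is_hom, is_miss, block_start, block_end - 1, max_missing)
        )
        block_start = block_end + 1
    return runs


def _runs_in_block(is_hom, is_miss, lo, hi, budget):
    """Maximal runs inside a het-free index block [lo, hi]."""
    if hi < lo:
        return []
    hom_idx = np.flatnonzero(is_hom[lo : hi + 1]) + lo
    if len(hom_idx) == 0:
        return []
    miss_prefix = np.concatenate([[0], np.cumsum(is_miss[lo : hi + 1])])  # local

    def n_miss(i, j):  # inclusive global indices
        return int(miss_prefix[j - lo + 1] - miss_prefix[i - lo])

    runs = []
    best_end = -1
    right = 0  # index into hom_idx for the trimmed right endpoint
    for left in hom_idx:
        right = max(right, int(np.searchsorted(hom_idx, left)))
        # furthest hom endpoint with budget respected
        while right + 1 < len(hom_idx) and n_miss(left, hom_idx[right + 1]) <= budget:
            right += 1
        end = hom_idx[right]
        if end > best_end:
            runs.append((int(left), int(end)))
            best_end = end
    return runs


def call_roh(
    gm: GenotypeMatrix,
    sample: str,
    min_snps: int = 5,
    max_missing: int = 0,
) -> list[ROHSegment]:
    """Homozygous stretches of one individual meeting the SNP-count threshold."""
    if min_snps < 2:
        raise ValueError("min_snps must be >= 2")
    if max_missing < 0:
        raise ValueError("max_missing must be >= 0")
    row = gm.calls[gm.sample_index(sample)]
    segments: list[ROHSegment] = []
    for chrom in gm.chroms:
        idx = gm.chrom_slice(chrom)
        calls = row[idx]
        pos = gm.variants["pos"].to_numpy()[idx]
        is_hom = (calls == 0) | (calls == 2)
        is_miss = calls == MISSING
        for i, j in _maximal_runs(is_hom, is_miss, max_missing):
            if j - i + 1 >= min_snps:
                segments.append(
                    ROHSegment(
                        sample=sample,
                        chrom=chrom,
                        start_bp=int(pos[i]),
                        end_bp=int(pos[j]),
                        n_snps=j - i + 1,
                        n_missing_inside=int(is_miss[i : j + 1].sum()),
                    )
                )
    return segments


def call_roh_all(
    gm: GenotypeMatrix, min_snps: int = 5, max_missing: int = 0
) -> dict[str, list[ROHSegment]]:
    return {s: call_roh(gm, s, min_snps, max_missing) for s in gm.samples}


# ---------------------------------------------------------------------------


def covered_autosome_length(gm: GenotypeMatrix) -> int:
    """L_AUTO: summed per-chromosome span from first to last SNP, inclusive."""
    if gm.n_variants == 0:
        raise ValueError("empty map: L_AUTO undefined")
    total = 0
    pos = gm.variants["pos"].to_numpy()
    for chrom in gm.chroms:
        idx = gm.chrom_slice(chrom)
        total += int(pos[idx].max() - pos[idx].min() + 1)
    return total


def froh(
    segments: list[ROHSegment],
    gm: GenotypeMatrix,
    sample: str,
    threshold_label: str = "ROH5",
) -> FrohRecord:
    """Genomic inbreeding of one individual at the all / >1 Mb / >4 Mb cutoffs."""
    l_auto = covered_autosome_length(gm)
    lengths = np.array([s.length_bp for s in segments if s.sample == sample], dtype=float)
    pos = gm.variants["pos"].to_numpy()
    per_chrom: dict[str, float] = {}
    for chrom in gm.chroms:
        idx = gm.chrom_slice(chrom)
        span = float(pos[idx].max() - pos[idx].min() + 1)
        csum = sum(
            s.length_bp for s in segments if s.sample == sample and s.chrom == chrom
        )
        per_chrom[chrom] = csum / span
    return FrohRecord(
        sample=sample,
        threshold=threshold_label,
        froh_all=float(lengths.sum()) / l_auto,
        froh_gt1mb=float(lengths[lengths > 1_000_000].sum()) / l_auto,
        froh_gt4mb=float(lengths[lengths > 4_000_000].sum()) / l_auto,
        per_chrom=per_chrom,
    )


def mean_froh_from_totals(cumulative_roh_bp: float, n_individuals: int, l_auto_bp: float) -> float:
    """Population mean F_ROH from a cumulative ROH length: sum(L_ROH)/(n * L_AUTO)."""
    return cumulative_roh_bp / (n_individuals * l_auto_bp)


# ---------------------------------------------------------------------------


def consensus_roh(
    segments_by_sample: dict[str, list[ROHSegment]],
    gm: GenotypeMatrix,
    panel: PopulationPanel,
    population: str,
    thresholds: tuple[float, ...] = CONSENSUS_LEVELS,
) -> list[ConsensusROH]:
    """Partially fixed ROH regions of one population.

    The per-SNP carrier fraction is the share of the population's individuals
    whose ROH covers the SNP position; for each consensus level, regions are
    maximal runs of consecutive SNPs at or above that fraction, spanning the
    first to last SNP of the run.
    """
    samples = [s for s in panel.samples_in(population) if s in segments_by_sample]
    if not samples:
        raise ValueError(f"population {population!r} has no called samples")
    n_t = len(samples)
    pos_all = gm.variants["pos"].to_numpy()
    out: list[ConsensusROH] = []
    for chrom in gm.chroms:
        idx = gm.chrom_slice(chrom)
        pos = pos_all[idx]
        cover = np.zeros((n_t, len(idx)), dtype=bool)
        for i, s in enumerate(samples):
            for seg in segments_by_sample[s]:
                if seg.chrom == chrom:
                    cover[i] |= (pos >= seg.start_bp) & (pos <= seg.end_bp)
        frac = cover.mean(axis=0)
        for level in thresholds:
            ok = frac >= level
            if not ok.any():
                continue
            boundaries = np.flatnonzero(np.diff(ok.astype(int)))
            starts = [0] if ok[0] else []
            starts += [b + 1 for b in boundaries if ok[b + 1]]
            ends = [b for b in boundaries if ok[b]]
            ends += [len(ok) - 1] if ok[-1] else []
            for i, j in zip(starts, ends):
                carriers = int(cover[:, i : j + 1].any(axis=1).sum())
                out.append(
                    ConsensusROH(
                        chrom=chrom,
                        start_bp=int(pos[i]),
                        end_bp=int(pos[j]),
                        consensus_level=float(level),
                        consensus_fraction=float(frac[i : j + 1].max()),
                        n_carriers=carriers,
                        population=population,
                    )
                )
    return out


def consensus_summary(regions: list[ConsensusROH]) -> pd.DataFrame:
    """Count, mean length (Mb) and cumulative length (Mb) per consensus level."""
    rows = []
    for level in sorted({r.consensus_level for r in regions}):
        sel = [r for r in regions if r.consensus_level == level]
        lengths = np.array([r.length_bp for r in sel], dtype=float)
        rows.append(
            {
                "consensus_level": level,
                "n_regions": len(sel),
                "mean_length_mb": lengths.mean() / 1e6 if len(sel) else 0.0,
                "cumulative_length_mb": lengths.sum() / 1e6,
            }
        )
    return pd.DataFrame(rows)


def partial_consensus_sharing(
    regions: list[ConsensusROH],
    segments_by_sample: dict[str, list[ROHSegment]],
    panel: PopulationPanel,
) -> pd.DataFrame:
    """Per-region subpopulation carrier counts (n_r/n_t) and pool assignment.

    A region belongs to pool_i when carriers come from exactly i
    subpopulations.  Mutates each region's ``subpop_carriers`` in place and
    returns a table with one row per region.
    """
    rows = []
    for region in regions:
        pop_subs = panel.subpopulations_of(region.population)
        n_regions_with = 0
        for sub in pop_subs:
            members = [
                s for s in panel.samples_in_subpop(sub) if s in segments_by_sample
            ]
            n_r = sum(
                any(
                    seg.overlaps(region.chrom, region.start_bp, region.end_bp)
                    for seg in segments_by_sample[s]
                )
                for s in members
            )
            region.subpop_carriers[sub] = (n_r, len(members))
            n_regions_with += n_r > 0
        rows.append(
            {
                "chrom": region.chrom,
                "start_bp": region.start_bp,
                "end_bp": region.end_bp,
                "consensus_level": region.consensus_level,
                "n_carriers": region.n_carriers,
                "pool": n_regions_with,
                **{
                    f"n_r[{sub}]": region.subpop_carriers[sub][0]
                    for sub in pop_subs
                },
            }
        )
    return pd.DataFrame(rows)


def subpop_sharing_matrix(
    regions: list[ConsensusROH], pool: int = 2
) -> pd.DataFrame:
    """Subpop x subpop count of regions carried in exactly ``pool`` subpops.

    For pool=2 the cell (a, b) counts regions whose carriers come from
    exactly the pair {a, b} — the two-region sharing overview.
    """
    subs = sorted({s for r in regions for s in r.subpop_carriers})
    mat = pd.DataFrame(0, index=subs, columns=subs)
    for r in regions:
        carriers = sorted(s for s, (n_r, _) in r.subpop_carriers.items() if n_r > 0)
        if len(carriers) != pool:
            continue
        for a in carriers:
            for b in carriers:
                if a != b:
                    mat.loc[a, b] += 1
    return mat


def segments_table(segments_by_sample: dict[str, list[ROHSegment]]) -> pd.DataFrame:
    rows = [
        {
            "sample": seg.sample,
            "chrom": seg.chrom,
            "start_bp": seg.start_bp,
            "end_bp": seg.end_bp,
            "n_snps": seg.n_snps,
            "length_bp": seg.length_bp,
        }
        for segs in segments_by_sample.values()
        for seg in segs
    ]
    return pd.DataFrame(
        rows, columns=["sample", "chrom", "start_bp", "end_bp", "n_snps", "length_bp"]
    )


def segments_to_bed(segments_by_sample: dict[str, list[ROHSegment]], sink) -> None:
    """BED export: 0-based half-open, name = sample id."""
    close = isinstance(sink, (str,)) or hasattr(sink, "__fspath__")
    fh = open(sink, "w") if close else sink
    try:
        for segs in segments_by_sample.values():
            for seg in segs:
                fh.write(f"{seg.chrom}\t{seg.start_bp - 1}\t{seg.end_bp}\t{seg.sample}\n")
    finally:
        if close:
            fh.close()
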