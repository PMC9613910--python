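"""Weir–Cockerham F_ST, the d_i divergence statistic, and selective-event calling.

Per SNP and population pair the Weir & Cockerham (1984) variance components
a (among populations), b (among individuals within populations) and c
(within individuals) give theta = a / (a + b + c) for two populations of
unequal size with observed heterozygosity.  Negative estimates are kept —
clipping them would bias the downstream standardisation.

For a focal population i, the locus-specific divergence is the z-score sum

    d_i = sum over j != i of (F_ST^ij - M(F_ST^ij)) / sd(F_ST^ij)

with M and sd taken over all SNPs scored in that pairwise track.  Windowed
means of d_i in non-overlapping 1-Mb tiles (>= 4 SNPs) are called outliers
at or above the 99th percentile of the genome-wide empirical distribution;
outlier windows present in required comparisons and absent from excluded
ones merge into candidate selective events.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, PopulationPanel


@dataclass
class FstTrack:
    pop_pair: tuple[str, str]
    values: np.ndarray  # per-variant theta, NaN where unscored
    mean: float
    sd: float


@dataclass
class DiTrack:
    focal: str
    comparisons: list[tuple[str, str]]
    values: np.ndarray  # NaN at SNPs missing from any comparison track
    n_excluded: int


@dataclass
class SelectiveEvent:
    category: str  # "focal-unique" | "subpopulation-specific"
    label: str
    chrom: str
    start_bp: int
    end_bp: int
    windows: list[tuple[str, int]]  # (chrom, window index)
    genes: list[str] = field(default_factory=list)
    consensus_overlaps: list[tuple[float, str, int, int]] = field(default_factory=list)

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return self.chrom == chrom and self.start_bp <= end and start <= self.end_bp


# ---------------------------------------------------------------------------


def _pop_calls(gm: GenotypeMatrix, panel: PopulationPanel, samples: list[str]):
    rows = [gm.sample_index(s) for s in samples if s in gm.samples]
    return gm.calls[rows, :]


def weir_cockerham_components(
    callsA: np.ndarray, callsB: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP Weir & Cockerham variance components (a, b, c) for two
    populations; NaN where either population has < 2 non-missing genotypes."""
    comps = []
    for calls in (callsA, callsB):
        present = calls != MISSING
        n = present.sum(axis=0).astype(float)
        alt = np.where(present, calls, 0).sum(axis=0)
        het = np.where(present, calls == 1, False).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = alt / (2.0 * n)
            h = het / n
        comps.append((n, p, h))
    (n1, p1, h1), (n2, p2, h2) = comps

    r = 2.0
    nbar = (n1 + n2) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n1 * n1 + n2 * n2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)

        a = (nbar / nc) * (
            s2
            - (1.0 / (nbar - 1.0))
            * (pbar * (1.0 - pbar) - s2 * (r - 1.0) / r - hbar / 4.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1.0 - pbar)
            - s2 * (r - 1.0) / r
            - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar)
        )
        c = hbar / 2.0
    scored = (n1 >= 2) & (n2 >= 2)
    nan = np.where(scored, 0.0, np.nan)
    return a + nan, b + nan, c + nan


def weir_cockerham_theta(callsA: np.ndarray, callsB: np.ndarray) -> np.ndarray:
    """Per-SNP two-population Weir & Cockerham theta from dosage matrices.

    SNPs where either population has fewer than two non-missing genotypes,
    or where a + b + c = 0 (both populations fixed for the same allele),
    are NaN.
    """
    a, b, c = weir_cockerham_components(callsA, callsB)
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = a + b + c
        return np.where(denom != 0, a / denom, np.nan)


def genome_fst(
    gm: GenotypeMatrix, panel: PopulationPanel, popA: str, popB: str
) -> float:
    """Multi-locus weighted theta, sum(a) / sum(a+b+c) over scored SNPs —
    the standard genome-wide Weir-Cockerham estimate (vcftools' weighted
    Fst), unbiased where the per-SNP average of ratios is not."""
    callsA = _pop_calls(gm, panel, panel.samples_in(popA))
    callsB = _pop_calls(gm, panel, panel.samples_in(popB))
    a, b, c = weir_cockerham_components(callsA, callsB)
    return float(np.nansum(a) / np.nansum(a + b + c))


def weir_cockerham_fst(
    gm: GenotypeMatrix, panel: PopulationPanel, popA: str, popB: str,
    samplesA: list[str] | None = None, samplesB: list[str] | None = None,
) -> FstTrack:
    """Pairwise per-SNP theta track with its genome-wide mean and SD.

    ``samplesA``/``samplesB`` override the panel lookup so the same routine
    serves subpopulation contrasts.
    """
    callsA = _pop_calls(gm, panel, samplesA if samplesA is not None else panel.samples_in(popA))
    callsB = _pop_calls(gm, panel, samplesB if samplesB is not None else panel.samples_in(popB))
    if callsA.shape[0] < 2 or callsB.shape[0] < 2:
        raise ValueError(f"both populations need >= 2 samples ({popA!r} vs {popB!r})")
    theta = weir_cockerham_theta(callsA, callsB)
    scored = ~np.isnan(theta)
    if not scored.any():
        raise ValueError(f"no scored SNPs for {popA!r} vs {popB!r}")
    return FstTrack(
        pop_pair=(popA, popB),
        values=theta,
        mean=float(theta[scored].mean()),
        sd=float(theta[scored].std(ddof=1)),
    )


def z_track(track: FstTrack, focal: str | None = None) -> DiTrack:
    """Standardised single-comparison track, for scanning one population pair
    on its own (the building block the cross-comparison event rule works on)."""
    if not (track.sd > 0):
        raise ValueError(f"degenerate track {track.pop_pair}: sd = {track.sd}")
    return DiTrack(
        focal=focal or track.pop_pair[0],
        comparisons=[track.pop_pair],
        values=(track.values - track.mean) / track.sd,
        n_excluded=int(np.isnan(track.values).sum()),
    )


def di_track(tracks: list[FstTrack], focal: str) -> DiTrack:
    """Sum of per-track z-scores at SNPs scored in every comparison."""
    if len(tracks) < 2:
        raise ValueError("d_i needs >= 2 comparison tracks")
    for t in tracks:
        if not (t.sd > 0):
            raise ValueError(f"degenerate track {t.pop_pair}: sd = {t.sd}")
        if focal not in t.pop_pair:
            raise ValueError(f"track {t.pop_pair} does not involve focal {focal!r}")
    z = np.array([(t.values - t.mean) / t.sd for t in tracks])
    values = z.sum(axis=0)  # NaN propagates where any track is unscored
    return DiTrack(
        focal=focal,
        comparisons=[t.pop_pair for t in tracks],
        values=values,
        n_excluded=int(np.isnan(values).sum()),
    )


# ---------------------------------------------------------------------------


def window_scan(
    di: DiTrack,
    gm: GenotypeMatrix,
    window_bp: int = 1_000_000,
    min_snps: int = 4,
    pct: float = 99.0,
) -> pd.DataFrame:
    """Window means of d_i on a fixed 1-Mb tiling anchored at bp 1.

    Windows with fewer than ``min_snps`` scored SNPs are discarded before
    the percentile; a window is an outlier when its mean is at or above the
    linear-interpolation ``pct``-th percentile of all retained windows.
    Columns: chrom, window (index), start_bp, end_bp, n_snps, mean_di,
    outlier; the cut-off is in ``attrs["threshold"]``.
    """
    if not 0 < pct <= 100:
        raise ValueError("pct must be in (0, 100]")
    pos = gm.variants["pos"].to_numpy()
    chroms = gm.variants["chrom"].to_numpy()
    widx = (pos - 1) // window_bp
    rows = []
    scored = ~np.isnan(di.values)
    for chrom in gm.chroms:
        sel = chroms == chrom
        for w in np.unique(widx[sel]):
            in_w = sel & (widx == w) & scored
            n = int(in_w.sum())
            if n < min_snps:
                continue
            rows.append(
                {
                    "chrom": chrom,
                    "window": int(w),
                    "start_bp": int(w * window_bp + 1),
                    "end_bp": int((w + 1) * window_bp),
                    "n_snps": n,
                    "mean_di": float(di.values[in_w].mean()),
                }
            )
    if len(rows) < 2:
        raise ValueError("fewer than 2 retained windows")
    windows = pd.DataFrame(rows)
    threshold = float(np.percentile(windows["mean_di"], pct, method="linear"))
    windows["outlier"] = windows["mean_di"] >= threshold
    windows.attrs["threshold"] = threshold
    windows.attrs["focal"] = di.focal
    return windows


def _merge_windows(
    kept: pd.DataFrame, gm: GenotypeMatrix, category: str, label: str
) -> list[SelectiveEvent]:
    """Merge chromosome-adjacent windows; snap events to first/last SNP."""
    events: list[SelectiveEvent] = []
    pos = gm.variants["pos"].to_numpy()
    chroms = gm.variants["chrom"].to_numpy()
    for chrom, grp in kept.groupby("chrom", sort=False):
        grp = grp.sort_values("window")
        run: list[pd.Series] = []
        for _, row in grp.iterrows():
            if run and row["window"] != run[-1]["window"] + 1:
                events.append(_snap_event(run, chrom, pos, chroms, category, label))
                run = []
            run.append(row)
        if run:
            events.append(_snap_event(run, chrom, pos, chroms, category, label))
    return events


def _snap_event(run, chrom, pos, chroms, category, label) -> SelectiveEvent:
    lo, hi = run[0]["start_bp"], run[-1]["end_bp"]
    inside = (chroms == chrom) & (pos >= lo) & (pos <= hi)
    return SelectiveEvent(
        category=category,
        label=label,
        chrom=str(chrom),
        start_bp=int(pos[inside].min()),
        end_bp=int(pos[inside].max()),
        windows=[(str(chrom), int(r["window"])) for r in run],
    )


def unique_events(
    windows_by_comparison: dict[str, pd.DataFrame],
    required_in: list[str],
    required_out: list[str],
    gm: GenotypeMatrix,
    label: str = "",
) -> list[SelectiveEvent]:
    """Windows that are outliers in every required-in scan and in no
    required-out scan, merged into events."""
    for name in list(required_in) + list(required_out):
        if name not in windows_by_comparison:
            raise KeyError(f"comparison {name!r} not supplied")

    def outlier_keys(name: str) -> set[tuple[str, int]]:
        w = windows_by_comparison[name]
        return set(map(tuple, w.loc[w["outlier"], ["chrom", "window"]].to_numpy()))

    keep = set.intersection(*(outlier_keys(n) for n in required_in))
    for name in required_out:
        keep -= outlier_keys(name)
    base = windows_by_comparison[required_in[0]]
    kept = base[
        base.apply(lambda r: (r["chrom"], r["window"]) in keep, axis=1)
    ]
    if kept.empty:
        return []
    return _merge_windows(kept, gm, "focal-unique", label)


def subpop_specific_events(
    gm: GenotypeMatrix,
    panel: PopulationPanel,
    population: str,
    subpop: str,
    window_bp: int = 1_000_000,
    min_snps: int = 4,
    pct: float = 99.0,
) -> list[SelectiveEvent]:
    """d_i of one subpopulation against each remaining subpopulation of the
    same population, windowed and thresholded, merged into events."""
    subs = panel.subpopulations_of(population)
    if len(subs) < 3:
        raise ValueError("need >= 3 subpopulations for a subpopulation scan")
    if subpop not in subs:
        raise KeyError(f"{subpop!r} is not a subpopulation of {population!r}")
    focal_samples = panel.samples_in_subpop(subpop)
    if len(focal_samples) < 2:
        raise ValueError(f"subpopulation {subpop!r} has < 2 samples")
    tracks = []
    for other in subs:
        if other == subpop:
            continue
        tracks.append(
            weir_cockerham_fst(
                gm, panel, subpop, other,
                samplesA=focal_samples,
                samplesB=panel.samples_in_subpop(other),
            )
        )
    di = di_track(tracks, subpop)
    windows = window_scan(di, gm, window_bp=window_bp, min_snps=min_snps, pct=pct)
    kept = windows[windows["outlier"]]
    return _merge_windows(kept, gm, "subpopulation-specific", subpop)


def event_sharing_matrix(
    events_by_label: dict[str, list[SelectiveEvent]],
) -> pd.DataFrame:
    """Pairwise counts of overlapping events between scans; the diagonal
    counts events specific to that scan alone."""
    labels = list(events_by_label)
    mat = pd.DataFrame(0, index=labels, columns=labels)
    for a in labels:
        for ev in events_by_label[a]:
            sharers = [
                b
                for b in labels
                if b != a
                and any(
                    ev.overlaps(o.chrom, o.start_bp, o.end_bp)
                    for o in events_by_label[b]
                )
            ]
            if not sharers:
                mat.loc[a, a] += 1
            for b in sharers:
                mat.loc[a, b] += 1
    return mat


# ---------------------------------------------------------------------------


def read_bed_intervals(source) -> pd.DataFrame:
    """BED3+ (0-based half-open) -> DataFrame with 1-based inclusive coords."""
    rows = []
    fh = open(source) if isinstance(source, (str,)) or hasattr(source, "__fspath__") else source
    try:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"BED line {lineno}: expected >= 3 fields")
            start0, end0 = int(parts[1]), int(parts[2])
            if end0 <= start0:
                raise ValueError(f"BED line {lineno}: empty or inverted interval")
            rows.append(
                {
                    "chrom": parts[0],
                    "start_bp": start0 + 1,
                    "end_bp": end0,
                    "name": parts[3] if len(parts) > 3 else f"feature_{lineno}",
                }
            )
    finally:
        if fh is not source:
            fh.close()
    return pd.DataFrame(rows, columns=["chrom", "start_bp", "end_bp", "name"])


def annotate_events(
    events: list[SelectiveEvent],
    gene_intervals: pd.DataFrame | None = None,
    consensus_regions: list | None = None,
) -> list[SelectiveEvent]:
    """Attach overlapping genes and consensus-ROH regions (any-bp overlap,
    1-based inclusive coordinates) to each event, in place."""
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    if gene_intervals is not None:
        for _, g in gene_intervals.iterrows():
            trees.setdefault(g["chrom"], IntervalTree()).addi(
                g["start_bp"], g["end_bp"] + 1, g["name"]
            )
    for ev in events:
        if gene_intervals is not None:
            hits = trees.get(ev.chrom, IntervalTree()).overlap(
                ev.start_bp, ev.end_bp + 1
            )
            ev.genes = sorted({h.data for h in hits})
        if consensus_regions is not None:
            ev.consensus_overlaps = [
                (r.consensus_level, r.chrom, r.start_bp, r.end_bp)
                for r in consensus_regions
                if ev.overlaps(r.chrom, r.start_bp, r.end_bp)
            ]
    return events


def events_table(events: list[SelectiveEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "category": e.category,
                "label": e.label,
                "chrom": e.chrom,
                "start_bp": e.start_bp,
                "end_bp": e.end_bp,
                "length_bp": e.end_bp - e.start_bp + 1,
                "n_windows": len(e.windows),
                "genes": ",".join(e.genes),
                "n_consensus_overlaps": len(e.consensus_overlaps),
            }
            for e in events
        ],
        columns=[
            "category", "label", "chrom", "start_bp", "end_bp",
            "length_bp", "n_windows", "genes", "n_consensus_overlaps",
        ],
    )
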