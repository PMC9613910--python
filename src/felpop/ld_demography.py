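"""Linkage-disequilibrium decay and LD-based demographic inference.

r² is the squared Pearson correlation of genotype dosages (0/1/2) between
SNP pairs on the same chromosome — the composite-LD estimator PLINK reports
for unphased data — computed over pairwise-complete samples.  Binned mean
r² as a function of inter-SNP distance gives a decay profile; each bin maps
to a past generation via the Sved (1971) relation

    Ne = (1 - r²) / (4 c r²),   t = 1 / (2 c),   dF = 1 / (2 Ne),

with c the inter-SNP distance in Morgans (by default 100 Mb ~ 1 Morgan).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, PopulationPanel


@dataclass
class DecayProfile:
    population: str
    bins: pd.DataFrame  # dist_lo, dist_hi, n_pairs, mean_r2, mean_dist_bp
    max_mean_r2: float
    half_decay: tuple[float, float] | None  # (mean_r2, mean_dist_bp) or None


def _pairwise_r2_chrom(
    dose: np.ndarray, pos: np.ndarray, min_dist: int, max_dist: int
) -> tuple[np.ndarray, np.ndarray, int]:
    """All within-range pairs on one chromosome.

    Returns (dist_bp, r2, n_skipped_zero_variance).  Missing calls are
    handled by pairwise deletion via indicator-matrix algebra, so each pair's
    correlation uses exactly the samples genotyped at both SNPs.
    """
    m = dose.shape[1]
    if m < 2:
        return np.empty(0), np.empty(0), 0
    present = dose != MISSING
    x = np.where(present, dose, 0).astype(np.float64)
    p = present.astype(np.float64)
    n = p.T @ p          # pairwise-complete counts
    sx = x.T @ p         # sum of x over samples where partner present
    sxx = (x * x).T @ p
    sxy = x.T @ x
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxy - sx * sx.T
        varx = n * sxx - sx * sx
        denom = varx * varx.T
        r2 = np.where(denom > 0, (cov * cov) / denom, np.nan)

    dist = np.abs(pos[:, None] - pos[None, :])
    iu = np.triu_indices(m, k=1)
    dist = dist[iu]
    r2 = r2[iu]
    in_range = (dist >= min_dist) & (dist <= max_dist)
    dist, r2 = dist[in_range], r2[in_range]
    bad = np.isnan(r2)
    return dist[~bad], r2[~bad], int(bad.sum())


def pairwise_r2(
    gm: GenotypeMatrix,
    panel: PopulationPanel,
    population: str,
    min_dist_bp: int = 1_000,
    max_dist_bp: int = 33_300_000,
) -> pd.DataFrame:
    """Within-chromosome dosage r² for all SNP pairs in a distance range.

    SNPs monomorphic within the population are skipped; pairs left with zero
    variance after pairwise deletion are dropped (their count is in the
    ``n_skipped`` DataFrame attribute).
    """
    if min_dist_bp >= max_dist_bp:
        raise ValueError("min_dist_bp must be < max_dist_bp")
    samples = [s for s in panel.samples_in(population) if s in gm.samples]
    if len(samples) < 2:
        raise ValueError(f"population {population!r} needs >= 2 samples")
    rows = [gm.sample_index(s) for s in samples]
    calls = gm.calls[rows, :]

    present = calls != MISSING
    alt = np.where(present, calls, 0).sum(axis=0)
    n2 = 2.0 * present.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n2 > 0, alt / n2, np.nan)
    polymorphic = (freq > 0) & (freq < 1)

    chunks = []
    n_skipped = 0
    for chrom in gm.chroms:
        idx = gm.chrom_slice(chrom)
        idx = idx[polymorphic[idx]]
        pos = gm.variants["pos"].to_numpy()[idx]
        dist, r2, skipped = _pairwise_r2_chrom(
            calls[:, idx], pos, min_dist_bp, max_dist_bp
        )
        n_skipped += skipped
        if len(dist):
            chunks.append(pd.DataFrame({"chrom": chrom, "dist_bp": dist, "r2": r2}))
    out = (
        pd.concat(chunks, ignore_index=True)
        if chunks
        else pd.DataFrame(columns=["chrom", "dist_bp", "r2"])
    )
    out.attrs["n_skipped"] = n_skipped
    out.attrs["population"] = population
    return out


def bin_decay(
    pairs: pd.DataFrame,
    bin_width_bp: int = 100_000,
    population: str | None = None,
) -> DecayProfile:
    """Sort pairs into fixed-width distance bins and locate the 50%-decay bin.

    The half-decay point is the first bin, in ascending distance, whose mean
    r² falls to half the maximum bin mean or below; ``None`` when no bin
    reaches it (flat profile).
    """
    if len(pairs) == 0:
        raise ValueError("no SNP pairs to bin")
    population = population or pairs.attrs.get("population", "")
    dist = pairs["dist_bp"].to_numpy()
    r2 = pairs["r2"].to_numpy()
    lo = (int(dist.min()) // bin_width_bp) * bin_width_bp
    edges = np.arange(lo, int(dist.max()) + bin_width_bp + 1, bin_width_bp)
    which = np.digitize(dist, edges) - 1
    rows = []
    for b in range(len(edges) - 1):
        sel = which == b
        if not sel.any():
            continue
        rows.append(
            {
                "dist_lo_bp": int(edges[b]),
                "dist_hi_bp": int(edges[b + 1]),
                "n_pairs": int(sel.sum()),
                "mean_r2": float(r2[sel].mean()),
                "mean_dist_bp": float(dist[sel].mean()),
            }
        )
    bins = pd.DataFrame(rows)
    max_r2 = float(bins["mean_r2"].max())
    half = None
    for _, row in bins.iterrows():
        if row["mean_r2"] <= max_r2 / 2.0:
            half = (float(row["mean_r2"]), float(row["mean_dist_bp"]))
            break
    return DecayProfile(population, bins, max_r2, half)


def ne_trajectory(
    profile: DecayProfile,
    mb_per_morgan: float = 100.0,
    max_generations: float | None = None,
) -> pd.DataFrame:
    """Sved-relation Ne/ΔF per distance bin, sorted by generations-ago.

    Columns: t (generations in the past), c (Morgans), ne, dF, flagged.
    Bins with mean r² = 0 map to infinite Ne; they are flagged, and excluded
    whenever ``max_generations`` truncation is requested.
    """
    bins = profile.bins
    if len(bins) == 0:
        raise ValueError("decay profile has no bins")
    c = bins["mean_dist_bp"].to_numpy() / (mb_per_morgan * 1e6)
    r2 = bins["mean_r2"].to_numpy()
    with np.errstate(divide="ignore"):
        ne = (1.0 - r2) / (4.0 * c * r2)
        t = 1.0 / (2.0 * c)
        dF = 1.0 / (2.0 * ne)
    out = pd.DataFrame(
        {"t": t, "c": c, "ne": ne, "dF": dF, "flagged": ~np.isfinite(ne)}
    ).sort_values("t", ignore_index=True)
    if max_generations is not None:
        out = out[(out["t"] <= max_generations) & ~out["flagged"]].reset_index(drop=True)
    return out
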