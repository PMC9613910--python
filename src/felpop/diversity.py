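"""Per-population diversity summaries and per-individual F_IS.

Expected heterozygosity uses the small-sample-corrected form
``He = 2pq * 2n/(2n-1)`` by default (the PLINK ``--hardy``/``--het``
convention); pass ``correct_he=False`` for plain ``2pq``.

F_IS for individual *i* is the excess of observed over expected homozygous
genotype counts, ``(O_i - E_i) / (nSNP_i - E_i)``, where ``E_i`` sums
``1 - He`` over the SNPs genotyped in that individual, with allele
frequencies taken from the individual's own population (subpopulations
reuse their parent population's frequencies).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, PopulationPanel


@dataclass
class IndividualFis:
    sample: str
    o_hom: float
    e_hom: float
    n_snp: int
    fis: float  # NaN when undefined (n_snp == e_hom)


def _pop_rows(gm: GenotypeMatrix, panel: PopulationPanel, population: str) -> list[int]:
    samples = panel.samples_in(population)
    if not samples:
        raise KeyError(f"population {population!r} not in panel")
    return [gm.sample_index(s) for s in samples if s in gm.samples]


def per_snp_population_stats(
    gm: GenotypeMatrix,
    panel: PopulationPanel,
    population: str,
    correct_he: bool = True,
) -> pd.DataFrame:
    """Per-variant allele frequency, MAF, Ho, He and monomorphic flag for one
    population; variants with zero non-missing calls get NaN statistics."""
    rows = _pop_rows(gm, panel, population)
    calls = gm.calls[rows, :]
    present = calls != MISSING
    n = present.sum(axis=0).astype(float)
    alt = np.where(present, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / (2.0 * n), np.nan)
        ho = np.where(n > 0, np.where(present, calls == 1, False).sum(axis=0) / n, np.nan)
    maf = np.minimum(p, 1.0 - p)
    he = 2.0 * p * (1.0 - p)
    if correct_he:
        with np.errstate(invalid="ignore", divide="ignore"):
            he = he * np.where(n > 0.5, 2.0 * n / (2.0 * n - 1.0), np.nan)
    mono = maf == 0.0
    return pd.DataFrame(
        {
            "id": gm.variants["id"],
            "chrom": gm.variants["chrom"],
            "pos": gm.variants["pos"],
            "n": n.astype(int),
            "freq": p,
            "maf": maf,
            "ho": ho,
            "he": he,
            "monomorphic": mono,
        }
    )


def fis_per_individual(
    gm: GenotypeMatrix,
    panel: PopulationPanel,
    correct_he: bool = True,
) -> list[IndividualFis]:
    """O/E homozygote counts and F_IS per individual.

    SNPs monomorphic within the population contribute 1 to both the observed
    homozygote count and E_i, so they cancel in the numerator and inflate
    neither side of the ratio.
    """
    panel.validate_against(gm)
    out: list[IndividualFis] = []
    e_hom_by_pop: dict[str, np.ndarray] = {}
    for pop in panel.populations:
        rows = _pop_rows(gm, panel, pop)
        if len(rows) < 2:
            raise ValueError(f"population {pop!r} needs >= 2 samples for F_IS")
        stats = per_snp_population_stats(gm, panel, pop, correct_he=correct_he)
        e_hom_by_pop[pop] = 1.0 - stats["he"].to_numpy()
    for sample in gm.samples:
        pop = panel.population[sample]
        e_hom_snp = e_hom_by_pop[pop]
        row = gm.calls[gm.sample_index(sample)]
        genotyped = (row != MISSING) & ~np.isnan(e_hom_snp)
        n_snp = int(genotyped.sum())
        o_hom = float(((row == 0) | (row == 2))[genotyped].sum())
        e_hom = float(e_hom_snp[genotyped].sum())
        denom = n_snp - e_hom
        fis = (o_hom - e_hom) / denom if denom != 0 else float("nan")
        out.append(IndividualFis(sample, o_hom, e_hom, n_snp, fis))
    return out


def _sd(values: np.ndarray) -> float:
    values = values[~np.isnan(values)]
    return float(np.std(values, ddof=1)) if len(values) > 1 else float("nan")


def summarize(
    gm: GenotypeMatrix,
    panel: PopulationPanel,
    correct_he: bool = True,
    include_monomorphic_in_maf: bool = True,
) -> pd.DataFrame:
    """One summary row per population and per subpopulation.

    MAF/Ho/He means and SDs are over SNPs, F_IS over individuals.  A
    subpopulation row reports Ho over its own samples but He (and the F_IS
    expectations) from its parent population's allele frequencies, the
    convention under which He is constant across subpopulations.
    """
    panel.validate_against(gm)
    fis = {r.sample: r.fis for r in fis_per_individual(gm, panel, correct_he=correct_he)}
    rows = []

    def _row(label: str, parent: str | None, samples: list[str], stats: pd.DataFrame):
        maf = stats["maf"].to_numpy(dtype=float)
        if not include_monomorphic_in_maf:
            maf = maf[maf > 0]
        if parent is None:
            ho = stats["ho"].to_numpy(dtype=float)
        else:  # subpopulation: own samples, parent-population frequencies
            rows_idx = [gm.sample_index(s) for s in samples]
            calls = gm.calls[rows_idx, :]
            present = calls != MISSING
            with np.errstate(invalid="ignore", divide="ignore"):
                ho = np.where(
                    present.sum(axis=0) > 0,
                    (calls == 1).sum(axis=0) / present.sum(axis=0),
                    np.nan,
                )
        fvals = np.array([fis[s] for s in samples], dtype=float)
        mono = stats["monomorphic"].to_numpy()
        scored = ~np.isnan(stats["maf"].to_numpy(dtype=float))
        rows.append(
            {
                "population": label,
                "parent": parent or "",
                "n_samples": len(samples),
                "pct_monomorphic": 100.0 * mono[scored].mean() if scored.any() else np.nan,
                "maf_mean": np.nanmean(maf) if len(maf) else np.nan,
                "maf_sd": _sd(maf),
                "ho_mean": np.nanmean(ho),
                "ho_sd": _sd(np.asarray(ho, dtype=float)),
                "he_mean": np.nanmean(stats["he"].to_numpy(dtype=float)),
                "he_sd": _sd(stats["he"].to_numpy(dtype=float)),
                "fis_mean": np.nanmean(fvals) if len(fvals) else np.nan,
                "fis_sd": _sd(fvals),
            }
        )

    for pop in panel.populations:
        samples = [s for s in panel.samples_in(pop) if s in gm.samples]
        stats = per_snp_population_stats(gm, panel, pop, correct_he=correct_he)
        _row(pop, None, samples, stats)
        for sub in panel.subpopulations_of(pop):
            sub_samples = [s for s in panel.samples_in_subpop(sub) if s in gm.samples]
            if sub_samples:
                _row(sub, pop, sub_samples, stats)
    return pd.DataFrame(rows)


def fis_table(records: list[IndividualFis]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"sample": r.sample, "o_hom": r.o_hom, "e_hom": r.e_hom,
             "n_snp": r.n_snp, "fis": r.fis}
            for r in records
        ]
    )
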