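"""Synthetic genotype datasets with known ground truth.

Three generators cover the test surface of the analysis stages:

* a Balding–Nichols (F-model) generator giving populations with a chosen
  differentiation parameter F and within-individual inbreeding f, so the
  Weir–Cockerham F_ST and F_IS estimators have closed-form targets;
* interval planters that force homozygous stretches (for the ROH caller)
  or near-fixed allele-frequency windows (for the d_i selection scan);
* a forward Wright–Fisher simulator with recombination whose linkage
  disequilibrium encodes a known effective population size.

All draws come from one ``numpy`` Generator seeded from the config, in a
fixed order, so composite datasets are bit-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .genotype_io import MISSING, GenotypeMatrix, PopulationPanel

MB = 1_000_000


class ConfigError(ValueError):
    pass


@dataclass
class PopulationSpec:
    label: str
    n_samples: int
    fst: float = 0.0          # Balding-Nichols F parameter, in [0, 1)
    f_within: float = 0.0     # within-individual inbreeding, in (-1, 1)
    subpop_sizes: dict[str, int] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.fst < 1.0:
            raise ConfigError(f"fst must be in [0, 1), got {self.fst}")
        if not -1.0 < self.f_within < 1.0:
            raise ConfigError(f"f_within must be in (-1, 1), got {self.f_within}")
        if self.subpop_sizes is not None and sum(self.subpop_sizes.values()) != self.n_samples:
            raise ConfigError(f"subpop sizes of {self.label!r} do not sum to n_samples")


@dataclass
class SimConfig:
    """Study-design parameters for a synthetic dataset.

    Defaults mimic a feline-style SNP array: 18 autosomes, array density
    0.02241 SNPs/kb, ancestral allele frequencies uniform on (0.05, 0.95).
    """

    seed: int = 0
    chrom_lengths_bp: dict[str, int] = field(
        default_factory=lambda: {"1": 50 * MB, "2": 50 * MB}
    )
    snp_density_per_kb: float = 0.02241
    populations: list[PopulationSpec] = field(
        default_factory=lambda: [PopulationSpec("pop1", 50)]
    )
    planted_roh: list[tuple] = field(default_factory=list)
    # (target sample-or-population, chrom, start_bp, end_bp)
    planted_sweeps: list[tuple] = field(default_factory=list)
    # (population, chrom, start_bp, end_bp, target_freq)
    wf_ne: int | None = None
    wf_generations: int = 50

    def __post_init__(self) -> None:
        if self.snp_density_per_kb <= 0:
            raise ConfigError("snp_density_per_kb must be > 0")
        for req in self.planted_roh:
            _, chrom, start, end = req
            self._check_interval(chrom, start, end)
        for req in self.planted_sweeps:
            _, chrom, start, end, _ = req
            self._check_interval(chrom, start, end)

    def _check_interval(self, chrom, start, end) -> None:
        if chrom not in self.chrom_lengths_bp:
            raise ConfigError(f"planted interval on unknown chromosome {chrom!r}")
        if not 1 <= start <= end <= self.chrom_lengths_bp[chrom]:
            raise ConfigError(f"planted interval {chrom}:{start}-{end} outside chromosome")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    @classmethod
    def from_yaml(cls, source) -> "SimConfig":
        if hasattr(source, "read"):
            raw = yaml.safe_load(source.read())
        else:
            with open(source) as fh:
                raw = yaml.safe_load(fh)
        pops = [PopulationSpec(**p) for p in raw.pop("populations", [])]
        raw["planted_roh"] = [tuple(r) for r in raw.get("planted_roh", [])]
        raw["planted_sweeps"] = [tuple(r) for r in raw.get("planted_sweeps", [])]
        return cls(populations=pops, **raw)


@dataclass
class TruthSet:
    """Ground truth recorded while generating: frequencies and planted intervals."""

    ancestral_freq: np.ndarray | None = None
    pop_freqs: dict[str, np.ndarray] = field(default_factory=dict)
    roh_intervals: dict[str, list[tuple[str, int, int]]] = field(default_factory=dict)
    sweep_windows: list[tuple[str, str, int, int, float]] = field(default_factory=list)

    def write(self, sink) -> None:
        with open(sink, "w") as fh:
            for sample, ivals in self.roh_intervals.items():
                for chrom, start, end in ivals:
                    fh.write(f"ROH\t{sample}\t{chrom}\t{start}\t{end}\n")
            for pop, chrom, start, end, freq in self.sweep_windows:
                fh.write(f"SWEEP\t{pop}\t{chrom}\t{start}\t{end}\t{freq}\n")


# ---------------------------------------------------------------------------


def make_map(cfg: SimConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Uniform SNP positions per chromosome at the configured density."""
    rng = cfg.rng() if rng is None else rng
    rows = []
    for chrom, length in cfg.chrom_lengths_bp.items():
        n = int(round(length / 1000.0 * cfg.snp_density_per_kb))
        if n > length:
            raise ConfigError(f"density too high for chromosome {chrom}")
        pos = np.unique(rng.integers(1, length + 1, size=n))
        while len(pos) < n:  # replace collisions
            extra = rng.integers(1, length + 1, size=n - len(pos))
            pos = np.unique(np.concatenate([pos, extra]))
        for k, p in enumerate(pos):
            rows.append((f"snp_{chrom}_{k}", str(chrom), int(p), "A", "G"))
    return pd.DataFrame(rows, columns=["id", "chrom", "pos", "ref", "alt"])


def _sample_names(cfg: SimConfig) -> tuple[list[str], PopulationPanel]:
    samples: list[str] = []
    population: dict[str, str] = {}
    subpopulation: dict[str, str] = {}
    for spec in cfg.populations:
        names = [f"{spec.label}_{i}" for i in range(spec.n_samples)]
        samples.extend(names)
        for s in names:
            population[s] = spec.label
        if spec.subpop_sizes:
            it = iter(names)
            for sub, n in spec.subpop_sizes.items():
                for _ in range(n):
                    subpopulation[next(it)] = sub
    return samples, PopulationPanel(population, subpopulation)


def _genotypes_from_freq(
    q: np.ndarray, n: int, f: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw n diploid genotypes per SNP with inbreeding coefficient f.

    P(hom-alt) = q^2 + f q(1-q); P(het) = 2q(1-q)(1-f).  For f < 0 the
    genotype probabilities are clipped at zero and renormalised.
    """
    pq = q * (1.0 - q)
    p_hom_alt = np.clip(q * q + f * pq, 0.0, 1.0)
    p_het = np.clip(2.0 * pq * (1.0 - f), 0.0, 1.0)
    total = np.clip(p_hom_alt + p_het, None, 1.0)
    u = rng.random((n, len(q)))
    return np.where(u < p_hom_alt, 2, np.where(u < total, 1, 0)).astype(np.int8)


def simulate_balding_nichols(
    cfg: SimConfig,
) -> tuple[GenotypeMatrix, PopulationPanel, TruthSet]:
    """F-model genotypes: per-population allele frequencies are Beta-distributed
    around a shared ancestral frequency with variance F·p(1−p)."""
    rng = cfg.rng()
    variants = make_map(cfg, rng)
    m = len(variants)
    p_anc = rng.uniform(0.05, 0.95, size=m)
    truth = TruthSet(ancestral_freq=p_anc)
    samples, panel = _sample_names(cfg)

    blocks = []
    for spec in cfg.populations:
        if spec.fst > 0:
            a = p_anc * (1.0 - spec.fst) / spec.fst
            b = (1.0 - p_anc) * (1.0 - spec.fst) / spec.fst
            q = rng.beta(a, b)
        else:
            q = p_anc.copy()
        truth.pop_freqs[spec.label] = q
        blocks.append(_genotypes_from_freq(q, spec.n_samples, spec.f_within, rng))
    calls = np.vstack(blocks)
    gm = GenotypeMatrix(variants, samples, calls)

    if cfg.planted_roh:
        gm, truth = plant_roh(gm, truth, cfg.planted_roh, panel=panel, rng=rng)
    if cfg.planted_sweeps:
        gm, truth = plant_sweep(gm, truth, cfg.planted_sweeps, panel=panel, rng=rng)
    return gm, panel, truth


def _snap(gm: GenotypeMatrix, chrom: str, start: int, end: int) -> np.ndarray:
    idx = gm.chrom_slice(chrom)
    pos = gm.variants["pos"].to_numpy()[idx]
    return idx[(pos >= start) & (pos <= end)]


def _merge_intervals(ivals: list[tuple[str, int, int]]) -> list[tuple[str, int, int]]:
    out: list[tuple[str, int, int]] = []
    for chrom, s, e in sorted(ivals):
        if out and out[-1][0] == chrom and s <= out[-1][2] + 1:
            out[-1] = (chrom, out[-1][1], max(out[-1][2], e))
        else:
            out.append((chrom, s, e))
    return out


def plant_roh(
    gm: GenotypeMatrix,
    truth: TruthSet,
    requests: list[tuple],
    panel: PopulationPanel | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[GenotypeMatrix, TruthSet]:
    """Force homozygosity (no hets, no missing) in the requested intervals.

    Each request is ``(target, chrom, start_bp, end_bp)`` where target is a
    sample id or, with a panel supplied, a population label.  The recorded
    truth interval is snapped to the first/last SNP inside the request;
    overlapping requests for one sample merge into their union.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    gm = gm.copy()
    for target, chrom, start, end in requests:
        if panel is not None and target in panel.population.values():
            targets = panel.samples_in(target)
        else:
            targets = [target]
        cols = _snap(gm, str(chrom), start, end)
        if len(cols) < 2:
            warnings.warn(
                f"planted ROH {chrom}:{start}-{end} covers {len(cols)} SNP(s)",
                stacklevel=2,
            )
        if len(cols) == 0:
            continue
        # one shared allele per SNP so the interval is also a consensus region
        allele = rng.integers(0, 2, size=len(cols)) * 2
        pos = gm.variants["pos"].to_numpy()[cols]
        snapped = (str(chrom), int(pos[0]), int(pos[-1]))
        for s in targets:
            gm.calls[gm.sample_index(s), cols] = allele
            truth.roh_intervals[s] = _merge_intervals(
                truth.roh_intervals.get(s, []) + [snapped]
            )
    return gm, truth


def plant_sweep(
    gm: GenotypeMatrix,
    truth: TruthSet,
    requests: list[tuple],
    panel: PopulationPanel,
    rng: np.random.Generator | None = None,
) -> tuple[GenotypeMatrix, TruthSet]:
    """Redraw one population's genotypes at ``target_freq`` inside each window,
    leaving every other population untouched."""
    rng = np.random.default_rng(0) if rng is None else rng
    gm = gm.copy()
    for pop, chrom, start, end, target_freq in requests:
        rows = [gm.sample_index(s) for s in panel.samples_in(pop)]
        if not rows:
            raise ConfigError(f"sweep target population {pop!r} has no samples")
        cols = _snap(gm, str(chrom), start, end)
        if len(cols) == 0:
            warnings.warn(f"sweep window {chrom}:{start}-{end} has no SNPs", stacklevel=2)
            continue
        q = np.full(len(cols), float(target_freq))
        gm.calls[np.ix_(rows, cols)] = _genotypes_from_freq(q, len(rows), 0.0, rng)
        truth.sweep_windows.append((pop, str(chrom), int(start), int(end), float(target_freq)))
    return gm, truth


# ---------------------------------------------------------------------------
# Forward Wright-Fisher with recombination


def _crossover_probs(variants: pd.DataFrame, mb_per_morgan: float = 100.0) -> np.ndarray:
    """Haldane inter-SNP crossover probabilities; 0.5 across chromosome breaks."""
    pos = variants["pos"].to_numpy(dtype=float)
    chrom = variants["chrom"].to_numpy()
    d_morgan = np.diff(pos) / (mb_per_morgan * 1e6)
    c = 0.5 * (1.0 - np.exp(-2.0 * d_morgan))
    c[chrom[1:] != chrom[:-1]] = 0.5
    return c


def simulate_wright_fisher_ld(
    cfg: SimConfig,
    sample_generation_zero: bool = False,
) -> tuple[GenotypeMatrix, PopulationPanel, TruthSet]:
    """Discrete-generation forward simulation of ``wf_ne`` diploids.

    Initial haplotypes carry mutually independent alleles at ancestral
    frequencies, so generation 0 has no LD; drift plus Haldane-map
    recombination (100 Mb = 1 Morgan) then builds LD whose decay with
    distance reflects ``wf_ne``.  Samples are drawn without replacement from
    the final generation; the first configured population supplies the label
    and sample count.
    """
    if cfg.wf_ne is None:
        raise ConfigError("wf_ne must be set for the Wright-Fisher simulator")
    spec = cfg.populations[0]
    if spec.n_samples > cfg.wf_ne:
        raise ConfigError("sample size exceeds the simulated population")
    rng = cfg.rng()
    variants = make_map(cfg, rng)
    m = len(variants)
    ne = cfg.wf_ne
    p_anc = rng.uniform(0.05, 0.95, size=m)
    truth = TruthSet(ancestral_freq=p_anc)

    hap = (rng.random((2 * ne, m)) < p_anc).astype(np.int8)
    c = _crossover_probs(variants)
    cols = np.arange(m)
    generations = 0 if sample_generation_zero else cfg.wf_generations
    for _ in range(generations):
        new_hap = np.empty_like(hap)
        for which in (0, 1):
            parents = rng.integers(ne, size=ne)
            start = rng.integers(2, size=(ne, 1))
            co = rng.random((ne, m - 1)) < c
            state = (start + np.concatenate(
                [np.zeros((ne, 1), dtype=np.int64), np.cumsum(co, axis=1)], axis=1
            )) % 2
            new_hap[which::2] = hap[2 * parents[:, None] + state, cols]
        hap = new_hap

    chosen = rng.choice(ne, size=spec.n_samples, replace=False)
    calls = (hap[2 * chosen] + hap[2 * chosen + 1]).astype(np.int8)
    samples = [f"{spec.label}_{i}" for i in range(spec.n_samples)]
    panel = PopulationPanel({s: spec.label for s in samples})
    gm = GenotypeMatrix(variants, samples, calls)
    return gm, panel, truth


def scan_planted_roh(gm: GenotypeMatrix, truth: TruthSet) -> bool:
    """True iff no planted interval contains a het or missing call."""
    for sample, ivals in truth.roh_intervals.items():
        row = gm.calls[gm.sample_index(sample)]
        for chrom, start, end in ivals:
            seg = row[_snap(gm, chrom, start, end)]
            if np.any(seg == 1) or np.any(seg == MISSING):
                return False
    return True
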