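"""Genotype container, PLINK PED/MAP and VCF readers/writers, and QC filtering.

Genotype calls are stored as an ``int8`` matrix of alternate-allele dosages
(0 = hom-ref, 1 = het, 2 = hom-alt, -1 = missing).  For array data without a
reference strand the "alt" allele is the pooled minor allele (ties broken
lexicographically: the smaller symbol becomes ref), so outputs are
reproducible even though every downstream statistic is orientation-invariant.

Coordinates are 1-based inclusive throughout; BED export converts to 0-based
half-open.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

#: chromosome labels never treated as autosomal
NON_AUTOSOMAL = {"0", "X", "Y", "XY", "MT", "M", "x", "y"}

#: felCat-style autosome names in karyotype order, for sorting
FELID_AUTOSOMES = [
    "A1", "A2", "A3", "B1", "B2", "B3", "B4", "C1", "C2",
    "D1", "D2", "D3", "D4", "E1", "E2", "E3", "F1", "F2",
]
_FELID_ORDER = {name: i for i, name in enumerate(FELID_AUTOSOMES)}


class FormatError(ValueError):
    """Malformed input file."""


class DataError(ValueError):
    """Well-formed input with inadmissible content (e.g. >2 alleles)."""


def chrom_sort_key(label: str):
    """Sort key for chromosome labels: felid names, then integers, then text."""
    if label in _FELID_ORDER:
        return (0, _FELID_ORDER[label], "")
    try:
        return (1, int(label), "")
    except ValueError:
        return (2, 0, label)


@dataclass
class GenotypeMatrix:
    """Samples x variants diploid genotype table.

    variants : DataFrame with columns id, chrom, pos (1-based bp), ref, alt,
        sorted by (chrom, pos) with strictly increasing pos per chromosome.
    samples : ordered sample identifiers.
    calls : int8 array (n_samples, n_variants) of alt dosages, -1 missing.
    """

    variants: pd.DataFrame
    samples: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def chroms(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.variants["chrom"]:
            seen.setdefault(c, None)
        return sorted(seen, key=chrom_sort_key)

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise KeyError(f"unknown sample {sample!r}") from None

    def variant_mask(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask, dtype=bool)
        return GenotypeMatrix(
            self.variants.loc[mask].reset_index(drop=True),
            list(self.samples),
            self.calls[:, mask],
        )

    def sample_subset(self, keep: list[str]) -> "GenotypeMatrix":
        idx = [self.sample_index(s) for s in keep]
        return GenotypeMatrix(
            self.variants.copy(), list(keep), self.calls[idx, :]
        )

    def chrom_slice(self, chrom: str) -> np.ndarray:
        """Column indices of one chromosome (contiguous by sort order)."""
        return np.flatnonzero((self.variants["chrom"] == chrom).to_numpy())

    def missing_fraction_per_sample(self) -> np.ndarray:
        if self.n_variants == 0:
            return np.zeros(self.n_samples)
        return (self.calls == MISSING).mean(axis=1)

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.variants.copy(), list(self.samples), self.calls.copy()
        )


@dataclass
class PopulationPanel:
    """sample -> population (and optional subpopulation) mapping."""

    population: dict[str, str]
    subpopulation: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        # a subpopulation label must nest inside exactly one population
        owner: dict[str, str] = {}
        for s, sub in self.subpopulation.items():
            pop = self.population.get(s)
            if pop is None:
                raise ValueError(f"sample {s!r} has a subpopulation but no population")
            if owner.setdefault(sub, pop) != pop:
                raise ValueError(f"subpopulation {sub!r} spans multiple populations")

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.population.values():
            seen.setdefault(p, None)
        return list(seen)

    def samples_in(self, population: str) -> list[str]:
        return [s for s, p in self.population.items() if p == population]

    def subpopulations_of(self, population: str) -> list[str]:
        seen: dict[str, None] = {}
        for s, sub in self.subpopulation.items():
            if self.population[s] == population:
                seen.setdefault(sub, None)
        return list(seen)

    def samples_in_subpop(self, subpop: str) -> list[str]:
        return [s for s, x in self.subpopulation.items() if x == subpop]

    def validate_against(self, gm: GenotypeMatrix) -> None:
        missing = [s for s in gm.samples if s not in self.population]
        if missing:
            raise ValueError(f"samples without population label: {missing[:5]}")

    def restrict(self, samples: list[str]) -> "PopulationPanel":
        keep = set(samples)
        return PopulationPanel(
            {s: p for s, p in self.population.items() if s in keep},
            {s: x for s, x in self.subpopulation.items() if s in keep},
        )


@dataclass
class QCReport:
    """Accounting of one QC pass; ``in - removed = out`` on both axes."""

    n_samples_in: int
    n_variants_in: int
    n_removed_non_autosomal: int
    n_removed_unplaced: int
    n_samples_removed_missing: int
    n_removed_maf: int
    n_removed_variant_missing: int
    sample_missing_max: float
    maf_min: float
    variant_missing_max: float
    autosomes_only: bool

    @property
    def n_samples_out(self) -> int:
        return self.n_samples_in - self.n_samples_removed_missing

    @property
    def n_variants_out(self) -> int:
        return self.n_variants_in - (
            self.n_removed_non_autosomal
            + self.n_removed_unplaced
            + self.n_removed_maf
            + self.n_removed_variant_missing
        )


# ---------------------------------------------------------------------------
# PED/MAP


def _open(source, mode="r"):
    if isinstance(source, (str, os.PathLike)):
        return open(source, mode)
    return source


def _read_lines(source) -> list[str]:
    handle = _open(source)
    try:
        return handle.read().splitlines()
    finally:
        if not isinstance(source, io.IOBase):
            try:
                handle.close()
            except AttributeError:
                pass


def read_map(map_source) -> pd.DataFrame:
    rows = []
    for lineno, line in enumerate(_read_lines(map_source), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) == 4:
            chrom, vid, _cm, pos = parts
        elif len(parts) == 3:
            chrom, vid, pos = parts
        else:
            raise FormatError(f"MAP line {lineno}: expected 3 or 4 fields, got {len(parts)}")
        rows.append((vid, chrom, int(pos)))
    return pd.DataFrame(rows, columns=["id", "chrom", "pos"])


def read_ped_map(ped_source, map_source) -> GenotypeMatrix:
    """Parse whitespace-delimited PLINK text PED + MAP into a GenotypeMatrix.

    ``0 0`` encodes a missing genotype.  Raises :class:`FormatError` on a
    PED/MAP dimension mismatch and :class:`DataError` when a marker shows more
    than two distinct alleles.
    """
    vmap = read_map(map_source)
    n_var = len(vmap)
    samples: list[str] = []
    allele_rows: list[list[str]] = []
    for lineno, line in enumerate(_read_lines(ped_source), 1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6 + 2 * n_var:
            raise FormatError(
                f"PED line {lineno}: expected {6 + 2 * n_var} fields for "
                f"{n_var} markers, got {len(parts)}"
            )
        samples.append(parts[1])
        allele_rows.append(parts[6:])

    n_samp = len(samples)
    a1 = np.empty((n_samp, n_var), dtype="U8")
    a2 = np.empty((n_samp, n_var), dtype="U8")
    for i, row in enumerate(allele_rows):
        a1[i] = row[0::2]
        a2[i] = row[1::2]

    calls = np.full((n_samp, n_var), MISSING, dtype=np.int8)
    refs: list[str] = []
    alts: list[str] = []
    for j in range(n_var):
        c1, c2 = a1[:, j], a2[:, j]
        present = (c1 != "0") & (c2 != "0")
        observed = sorted(set(c1[present]) | set(c2[present]))
        if len(observed) > 2:
            raise DataError(
                f"marker {vmap['id'][j]!r}: more than two alleles observed: {observed}"
            )
        if not observed:
            ref, alt = "A", "B"  # no data at all; placeholder pair
        elif len(observed) == 1:
            ref = observed[0]
            alt = _placeholder_alt(ref)
        else:
            x, y = observed
            nx = int((c1[present] == x).sum() + (c2[present] == x).sum())
            ny = int((c1[present] == y).sum() + (c2[present] == y).sum())
            # minor allele becomes alt; lexicographic tie-break (x < y)
            ref, alt = (x, y) if nx >= ny else (y, x)
        refs.append(ref)
        alts.append(alt)
        dose = (c1 == alt).astype(np.int8) + (c2 == alt).astype(np.int8)
        calls[present, j] = dose[present]

    variants = vmap.assign(ref=refs, alt=alts)
    variants, calls = _sort_variants(variants, calls)
    return GenotypeMatrix(variants, samples, calls)


def _placeholder_alt(ref: str) -> str:
    for base in "ACGT":
        if base != ref:
            return base
    return "B"


def _sort_variants(variants: pd.DataFrame, calls: np.ndarray):
    order = sorted(
        range(len(variants)),
        key=lambda i: (chrom_sort_key(variants["chrom"].iat[i]), variants["pos"].iat[i]),
    )
    variants = variants.iloc[order].reset_index(drop=True)
    return variants, calls[:, order]


def write_ped_map(gm: GenotypeMatrix, ped_sink, map_sink) -> None:
    mh = _open(map_sink, "w")
    for _, v in gm.variants.iterrows():
        mh.write(f"{v['chrom']}\t{v['id']}\t0\t{v['pos']}\n")
    if isinstance(map_sink, (str, os.PathLike)):
        mh.close()
    ph = _open(ped_sink, "w")
    refs = gm.variants["ref"].to_numpy()
    alts = gm.variants["alt"].to_numpy()
    for i, s in enumerate(gm.samples):
        fields = [s, s, "0", "0", "0", "-9"]
        for j, call in enumerate(gm.calls[i]):
            if call == MISSING:
                fields += ["0", "0"]
            elif call == 0:
                fields += [refs[j], refs[j]]
            elif call == 1:
                fields += [refs[j], alts[j]]
            else:
                fields += [alts[j], alts[j]]
        ph.write(" ".join(fields) + "\n")
    if isinstance(ped_sink, (str, os.PathLike)):
        ph.close()


# ---------------------------------------------------------------------------
# VCF

_GT_STRINGS = {MISSING: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(gm: GenotypeMatrix, sink) -> None:
    """Emit a minimal VCF 4.2 (GT only); round-trips through read_vcf."""
    handle = _open(sink, "w")
    close = isinstance(sink, (str, os.PathLike))
    try:
        handle.write("##fileformat=VCFv4.2\n")
        for chrom in gm.chroms:
            idx = gm.chrom_slice(chrom)
            length = int(gm.variants["pos"].iloc[idx].max()) + 1 if len(idx) else 1
            handle.write(f"##contig=<ID={chrom},length={length}>\n")
        handle.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        handle.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        variants = gm.variants
        for j in range(gm.n_variants):
            gts = "\t".join(_GT_STRINGS[int(c)] for c in gm.calls[:, j])
            handle.write(
                f"{variants['chrom'].iat[j]}\t{variants['pos'].iat[j]}\t"
                f"{variants['id'].iat[j]}\t{variants['ref'].iat[j]}\t"
                f"{variants['alt'].iat[j]}\t.\t.\t.\tGT\t{gts}\n"
            )
    finally:
        if close:
            handle.close()


def read_vcf(vcf_source) -> tuple[GenotypeMatrix, int]:
    """Read a VCF (path) keeping biallelic SNPs; returns (matrix, n_skipped).

    ``./.`` becomes missing; phase is ignored; multiallelic and non-SNP
    records are skipped and counted.  REF/ALT orientation is taken from the
    file as-is.
    """
    import cyvcf2

    reader = cyvcf2.VCF(str(vcf_source))
    if "##FORMAT=<ID=GT" not in reader.raw_header and len(reader.samples) > 0:
        raise FormatError("VCF has samples but no GT FORMAT definition")
    samples = list(reader.samples)
    rows = []
    cols = []
    skipped = 0
    for rec in reader:
        if not rec.is_snp or len(rec.ALT) != 1:
            skipped += 1
            continue
        rows.append((rec.ID or f"{rec.CHROM}:{rec.POS}", rec.CHROM, rec.POS,
                     rec.REF, rec.ALT[0]))
        gt = rec.gt_types  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        col = np.where(gt == 2, MISSING, np.where(gt == 3, 2, gt)).astype(np.int8)
        cols.append(col)
    reader.close()
    variants = pd.DataFrame(rows, columns=["id", "chrom", "pos", "ref", "alt"])
    calls = (
        np.array(cols, dtype=np.int8).T
        if cols
        else np.zeros((len(samples), 0), dtype=np.int8)
    )
    variants, calls = _sort_variants(variants, calls)
    return GenotypeMatrix(variants, samples, calls), skipped


# ---------------------------------------------------------------------------
# Panel IO


def read_panel(source) -> PopulationPanel:
    """Tab-delimited ``sample<TAB>population[<TAB>subpopulation]``, '#' comments."""
    population: dict[str, str] = {}
    subpopulation: dict[str, str] = {}
    for lineno, line in enumerate(_read_lines(source), 1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise FormatError(f"panel line {lineno}: expected >= 2 tab-separated fields")
        population[parts[0]] = parts[1]
        if len(parts) >= 3 and parts[2]:
            subpopulation[parts[0]] = parts[2]
    return PopulationPanel(population, subpopulation)


def write_panel(panel: PopulationPanel, sink) -> None:
    handle = _open(sink, "w")
    close = isinstance(sink, (str, os.PathLike))
    try:
        for s, p in panel.population.items():
            sub = panel.subpopulation.get(s, "")
            handle.write(f"{s}\t{p}\t{sub}\n" if sub else f"{s}\t{p}\n")
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# QC


def pooled_maf(calls: np.ndarray) -> np.ndarray:
    """Minor-allele frequency per variant over all samples pooled."""
    present = calls != MISSING
    n = present.sum(axis=0)
    alt = np.where(present, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / (2.0 * n), np.nan)
    return np.where(np.isnan(p), np.nan, np.minimum(p, 1.0 - p))


def apply_qc(
    gm: GenotypeMatrix,
    panel: PopulationPanel | None = None,
    sample_missing_max: float = 0.30,
    maf_min: float = 0.01,
    variant_missing_max: float = 1.0,
    autosomes_only: bool = True,
) -> tuple[GenotypeMatrix, PopulationPanel | None, QCReport]:
    """Standard array-QC in fixed order.

    1. drop non-autosomal and unplaced (chrom "0") variants,
    2. drop samples whose missing fraction exceeds ``sample_missing_max``,
    3. drop variants with pooled MAF < ``maf_min``,
    4. drop variants whose missing fraction exceeds ``variant_missing_max``.

    The defaults (0.30, 0.01, 1.0, autosomes only) are the conventional
    PLINK-style settings for array studies of this kind.
    """
    for name, value in [
        ("sample_missing_max", sample_missing_max),
        ("maf_min", maf_min),
        ("variant_missing_max", variant_missing_max),
    ]:
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {value}")

    n_samples_in, n_variants_in = gm.n_samples, gm.n_variants
    chroms = gm.variants["chrom"].to_numpy()
    unplaced = chroms == "0"
    non_auto = np.isin(chroms, sorted(NON_AUTOSOMAL - {"0"}))
    if autosomes_only:
        keep_v = ~(unplaced | non_auto)
        n_unplaced = int(unplaced.sum())
        n_non_auto = int(non_auto.sum())
    else:
        keep_v = np.ones(len(chroms), dtype=bool)
        n_unplaced = n_non_auto = 0
    gm2 = gm.variant_mask(keep_v)

    miss = gm2.missing_fraction_per_sample()
    keep_s = [s for s, m in zip(gm2.samples, miss) if m <= sample_missing_max]
    n_removed_samples = gm2.n_samples - len(keep_s)
    if not keep_s:
        raise DataError("QC removed every sample")
    gm3 = gm2.sample_subset(keep_s)

    maf = pooled_maf(gm3.calls)
    keep_maf = ~(maf < maf_min)  # NaN (all-missing) falls through to step 4
    n_removed_maf = int((~keep_maf).sum())
    gm4 = gm3.variant_mask(keep_maf)

    vmiss = (gm4.calls == MISSING).mean(axis=0) if gm4.n_samples else np.zeros(0)
    keep_vm = vmiss <= variant_missing_max
    n_removed_vm = int((~keep_vm).sum())
    gm5 = gm4.variant_mask(keep_vm)

    report = QCReport(
        n_samples_in=n_samples_in,
        n_variants_in=n_variants_in,
        n_removed_non_autosomal=n_non_auto,
        n_removed_unplaced=n_unplaced,
        n_samples_removed_missing=n_removed_samples,
        n_removed_maf=n_removed_maf,
        n_removed_variant_missing=n_removed_vm,
        sample_missing_max=sample_missing_max,
        maf_min=maf_min,
        variant_missing_max=variant_missing_max,
        autosomes_only=autosomes_only,
    )
    panel_out = panel.restrict(keep_s) if panel is not None else None
    return gm5, panel_out, report
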