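"""Seeded synthetic cohorts with the statistical structure the scans assume.

Genotypes follow the Balding-Nichols model: each site draws an ancestral
frequency p0 ~ Uniform(bounds) and each population a frequency from
Beta(p0*(1-F)/F, (1-p0)*(1-F)/F), so the expected genome-wide F_ST equals F.
Sweeps are injected by pushing the target population's frequencies at in-
interval sites toward near-fixation of one consistent allele per site, which
produces both the excess differentiation and the heterozygosity loss the scan
looks for.  Phenotype and Ct generators mirror the field-cohort design:
182 animals, an additive 11.75 cm/allele effect on horn length with age and
sex covariates, a recessive effect on SHE-vs-TCF horn shape, and grouped
qPCR Ct tables (4 SHE / 4 TCF / 5 scurred samples, technical triplicates).

Every generator is a pure function of the configuration seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datatypes import GeneAnnotation, GeneRecord, PopulationMap, VariantTable

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SweepSpec:
    pop: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    target_freq: float = 0.98


@dataclass(frozen=True)
class PhenotypeSpec:
    """Horn phenotype generator: length (cm) is additive in the causal
    genotype with age/sex terms and Gaussian noise; shape (SHE vs TCF) is
    Bernoulli under a logistic model on the recessive code; lengths <= 0
    become polled (0 cm) and lengths in (0, 12] scurred."""

    n_animals: int = 182
    beta: float = 11.75          # cm per major-allele copy
    noise_sd: float = 8.0
    intercept: float = 18.0
    age_beta: float = 1.2        # cm per year
    age_range: tuple[float, float] = (1.0, 8.0)
    sex_beta: float = 6.0        # males larger
    male_fraction: float = 0.5
    shape_intercept: float = -1.5   # log-odds of SHE for non-TT animals
    shape_log_odds: float = 4.0     # added log-odds for major-homozygotes
    causal_maf: float = 0.2


@dataclass(frozen=True)
class ExpressionSpec:
    """Group-structured Ct tables: control Ct ~ N(20, 0.2); target Ct adds
    the group's true dCt plus biological noise; technical triplicates add
    replicate noise."""

    group_sizes: dict = field(default_factory=lambda: {"SHE": 4, "TCF": 4, "scurred": 5})
    group_delta_ct: dict = field(default_factory=lambda: {"SHE": 4.0, "TCF": 2.0, "scurred": 2.5})
    biological_sd: float = 0.4
    replicate_sd: float = 0.1
    n_replicates: int = 3
    control_mean: float = 20.0
    control_sd: float = 0.2


@dataclass(frozen=True)
class SimConfig:
    seed: int
    pop_names: tuple[str, ...] = ("PT", "WZ", "T", "STH", "H", "CB")
    groups: dict = field(default_factory=lambda: {
        "WZ": "MGS", "T": "MGS", "STH": "MGS", "H": "MGS", "CB": "MGS"})
    samples_per_pop: int = 10
    chrom_lengths: dict = field(default_factory=lambda: {"chr1": 3_000_000})
    n_sites: int = 6000
    F: float = 0.05
    freq_bounds: tuple[float, float] = (0.05, 0.95)
    #: "uniform" or "neutral" (density proportional to 1/p, the standing
    #: neutral spectrum) for the ancestral-frequency draw
    freq_spectrum: str = "uniform"
    sweeps: tuple[SweepSpec, ...] = ()
    phenotype: PhenotypeSpec = field(default_factory=PhenotypeSpec)
    expression: ExpressionSpec = field(default_factory=ExpressionSpec)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not 0.0 <= self.F < 1.0:
            raise ValueError(f"F must be in [0, 1), got {self.F}")
        lo, hi = self.freq_bounds
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("freq_bounds must satisfy 0 <= lo <= hi <= 1")
        if self.freq_spectrum not in ("uniform", "neutral"):
            raise ValueError(f"unknown freq_spectrum {self.freq_spectrum!r}")
        if self.freq_spectrum == "neutral" and lo <= 0.0:
            raise ValueError("neutral spectrum needs a positive lower bound")


def simulate_genotypes(cfg: SimConfig) -> tuple[VariantTable, PopulationMap]:
    """Balding-Nichols genotypes for every population, plus the sample map.

    Sites are uniformly placed (unique, sorted) across the configured
    chromosomes proportional to length; genotypes are Binomial(2, freq).
    Sweeps listed in ``cfg.sweeps`` are injected before returning.
    """
    rng = np.random.default_rng(cfg.seed)
    chroms, positions = _place_sites(cfg, rng)
    n_sites = len(positions)
    refs = BASES[rng.integers(0, 4, n_sites)]
    alts = np.array([BASES[(np.flatnonzero(BASES == r)[0] + rng.integers(1, 4)) % 4]
                     for r in refs], dtype=object)

    lo, hi = cfg.freq_bounds
    if cfg.freq_spectrum == "neutral":
        # inverse-CDF draw from density proportional to 1/p on (lo, hi)
        p0 = lo * (hi / lo) ** rng.random(n_sites)
    else:
        p0 = rng.uniform(lo, hi, n_sites)
    sample_ids, breeds = [], {}
    cols = []
    for pop in cfg.pop_names:
        if cfg.F == 0.0:
            freq = p0
        else:
            ratio = (1.0 - cfg.F) / cfg.F
            freq = rng.beta(np.maximum(p0 * ratio, 1e-9),
                            np.maximum((1.0 - p0) * ratio, 1e-9))
        geno = rng.binomial(2, freq[:, None], size=(n_sites, cfg.samples_per_pop))
        cols.append(geno)
        for k in range(cfg.samples_per_pop):
            sid = f"{pop}_{k + 1:03d}"
            sample_ids.append(sid)
            breeds[sid] = pop
    vt = VariantTable(chroms, positions, refs, alts,
                      np.concatenate(cols, axis=1).astype(np.int8), sample_ids)
    pmap = PopulationMap(breeds, dict(cfg.groups))
    for i, sw in enumerate(cfg.sweeps):
        vt = inject_sweep(vt, pmap.group_samples(sw.pop), sw,
                          seed=_subseed(cfg.seed, 1000 + i))
    return vt, pmap


def _place_sites(cfg: SimConfig, rng) -> tuple[np.ndarray, np.ndarray]:
    total = sum(cfg.chrom_lengths.values())
    chroms, positions = [], []
    for c, ln in cfg.chrom_lengths.items():
        n = int(round(cfg.n_sites * ln / total))
        pos = np.sort(rng.choice(ln, size=min(n, ln), replace=False))
        chroms.extend([c] * len(pos))
        positions.extend(pos.tolist())
    return np.array(chroms, dtype=object), np.array(positions, dtype=np.int64)


def _subseed(seed: int, offset: int) -> int:
    return int((seed * 100_003 + offset) % (2 ** 31 - 1))


def inject_sweep(vt: VariantTable, pop_samples: list[str], spec: SweepSpec,
                 seed: int) -> VariantTable:
    """Redraw the target population's genotypes inside the sweep interval.

    Per site the allele that is currently minor cohort-wide is driven to
    ``target_freq`` in the target population (one consistent 'haplotype'
    direction), so the swept population both diverges from the others and
    loses heterozygosity.  Other populations' dosages are untouched.
    """
    in_iv = np.flatnonzero((vt.chrom == spec.chrom)
                           & (vt.pos >= spec.start) & (vt.pos < spec.end))
    if in_iv.size == 0:
        raise ValueError(f"sweep interval {spec.chrom}:{spec.start}-{spec.end} "
                         "contains no sites")
    rng = np.random.default_rng(seed)
    cols = vt.sample_indices(pop_samples)
    dos = vt.dosages.copy()
    from .windows import allele_counts
    alt, nchrom = allele_counts(vt.dosages[in_iv])
    alt_freq = np.where(nchrom > 0, alt / np.maximum(nchrom, 1), 0.5)
    swept_alt_freq = np.where(alt_freq < 0.5, spec.target_freq, 1.0 - spec.target_freq)
    new = rng.binomial(2, swept_alt_freq[:, None], size=(in_iv.size, cols.size))
    dos[np.ix_(in_iv, cols)] = new.astype(np.int8)
    return VariantTable(vt.chrom, vt.pos, vt.ref, vt.alt, dos, list(vt.samples))


def simulate_gene_annotation(cfg: SimConfig, gene_length: int = 5000) -> GeneAnnotation:
    """Deterministic gene tiling with, per sweep: one gene inside the
    interval, one inside the 15-kb flank, and one far beyond it."""
    genes: list[GeneRecord] = []
    i = 0
    for c, ln in cfg.chrom_lengths.items():
        for start in range(10_000, ln - gene_length, 120_000):
            genes.append(GeneRecord(f"gene{i:04d}", c, start, start + gene_length))
            i += 1
    for j, sw in enumerate(cfg.sweeps):
        mid = (sw.start + sw.end) // 2
        limit = cfg.chrom_lengths[sw.chrom]
        trio = [
            (f"sweep{j}_inside", mid, mid + gene_length),
            (f"sweep{j}_flank", sw.end + 10_000, sw.end + 12_000),
            (f"sweep{j}_far", sw.end + 60_000, sw.end + 62_000),
        ]
        for name, s, e in trio:
            if e < limit:
                genes.append(GeneRecord(name, sw.chrom, s, e))
    return GeneAnnotation(genes)


def simulate_phenotypes(cfg: SimConfig, causal_snp: str = "OAR10_29461968"
                        ) -> pd.DataFrame:
    """Field-cohort genotype/phenotype table for the association stage.

    The causal SNP's major allele T adds ``beta`` cm per copy (additive) to
    horn length and its homozygote raises the SHE log-odds by
    ``shape_log_odds`` (recessive).  Categories follow the length bands:
    0 cm -> polled, (0, 12] -> scurred, > 12 -> SHE or TCF per the shape
    draw.
    """
    ps = cfg.phenotype
    rng = np.random.default_rng(_subseed(cfg.seed, 77))
    n = ps.n_animals
    p_major = 1.0 - ps.causal_maf
    if not 0.0 < p_major < 1.0:
        raise ValueError("causal SNP would be monomorphic")
    n_major = rng.binomial(2, p_major, n)  # copies of major allele T
    gts = np.array(["CC", "TC", "TT"])[n_major]
    age = rng.uniform(*ps.age_range, n).round(1)
    sex = np.where(rng.random(n) < ps.male_fraction, "M", "F")
    noise = rng.normal(0.0, ps.noise_sd, n) if ps.noise_sd > 0 else np.zeros(n)
    length = (ps.intercept + ps.beta * n_major + ps.age_beta * age
              + ps.sex_beta * (sex == "M") + noise)
    length = np.maximum(length, 0.0).round(1)

    logit = ps.shape_intercept + ps.shape_log_odds * (n_major == 2)
    she = rng.random(n) < 1.0 / (1.0 + np.exp(-logit))
    shape = np.where(length == 0, "polled",
                     np.where(length <= 12, "scurred",
                              np.where(she, "SHE", "TCF")))
    return pd.DataFrame({
        "animal_id": [f"A{i + 1:04d}" for i in range(n)],
        causal_snp: gts,
        "horn_length": length,
        "horn_shape": shape,
        "age": age,
        "sex": sex,
    })


def simulate_ct_table(cfg: SimConfig, target_gene: str = "RXFP2",
                      control_gene: str = "ACTB") -> pd.DataFrame:
    """Grouped qPCR Ct table with technical replicates (long format:
    sample_id, group, gene, replicate, ct)."""
    es = cfg.expression
    rng = np.random.default_rng(_subseed(cfg.seed, 99))
    rows = []
    for group, size in es.group_sizes.items():
        dct = es.group_delta_ct[group]
        for k in range(size):
            sid = f"{group}_{k + 1}"
            control = rng.normal(es.control_mean, es.control_sd)
            target = control + dct + (rng.normal(0.0, es.biological_sd)
                                      if es.biological_sd > 0 else 0.0)
            for rep in range(1, es.n_replicates + 1):
                for gene, base in ((target_gene, target), (control_gene, control)):
                    ct = base + (rng.normal(0.0, es.replicate_sd)
                                 if es.replicate_sd > 0 else 0.0)
                    rows.append({"sample_id": sid, "group": group, "gene": gene,
                                 "replicate": rep, "ct": round(float(ct), 4)})
    return pd.DataFrame(rows)


def sweep_preset(seed: int, n_sweeps: int = 3) -> SimConfig:
    """Strong-sweep scan preset: one 3-Mb-per-chromosome genome dense enough
    that every 30-kb window clears the 50-variant exclusion, with
    ``n_sweeps`` 60-kb injected sweeps in the target population PT."""
    chrom_lengths = {"chr1": 5_100_000, "chr2": 5_100_000, "chr3": 5_100_000}
    sweep_sites = [("chr1", 1_200_000), ("chr2", 2_400_000), ("chr3", 3_600_000)]
    sweeps = tuple(
        SweepSpec("PT", c, s, s + 60_000) for c, s in sweep_sites[:n_sweeps]
    )
    return SimConfig(
        seed=seed,
        chrom_lengths=chrom_lengths,
        n_sites=36_000,
        sweeps=sweeps,
    )


def neutral_preset(seed: int) -> SimConfig:
    return replace(sweep_preset(seed), sweeps=())
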