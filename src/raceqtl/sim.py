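"""Synthetic race-structured cohorts with planted expression-driver SNPs.

The generator emulates the statistical structure the downstream analysis
assumes: population-specific Hardy-Weinberg genotypes, additive cis-eQTL
effects on negative-binomial RNA-seq counts, race effects on expression that
are either mediated by genotype (planted drivers) or not (plain log2 shifts),
expression-linked proportional-hazard survival, and ratio-matched cohort
assembly.  All randomness flows through explicit per-operation seeds; the
same seed and configuration give byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from raceqtl.errors import ConfigError

DEFAULT_POPULATIONS = ("AS", "AA", "CA")


@dataclass(frozen=True)
class PlantedDriver:
    """A SNP whose alt-allele dosage additively shifts one gene's log2 mean.

    ``freqs`` maps population label to the alt-allele frequency; the eQTL
    effect is the log2 change in expected count per alt-allele copy, so the
    group-mean expression ordering across populations mechanically equals the
    frequency ordering times the sign of the effect.
    """

    snp_id: str
    gene_id: str
    freqs: dict[str, float]
    eqtl_log2_effect_per_allele: float


@dataclass(frozen=True)
class PlantedShift:
    """A gene differentially expressed by race with no genotype mediation."""

    gene_id: str
    race_log2_shifts: dict[str, float]


@dataclass(frozen=True)
class SurvivalGene:
    """A gene whose standardized log2 expression enters the log hazard."""

    gene_id: str
    log_hazard_per_sd: float


@dataclass
class SimConfig:
    """Parameters of one synthetic cohort.

    Counts are negative binomial with a shared dispersion ``nb_dispersion``
    (variance mu + alpha*mu^2) and lognormal library-size factors
    (sigma = ``library_sigma``, mean one).  Survival times are exponential
    with a log-linear hazard in standardized log2 expression; censoring is
    independent with probability ``censor_rate`` per sample.
    """

    n_per_population: dict[str, int]
    populations: tuple[str, ...] = DEFAULT_POPULATIONS
    n_genes: int = 300
    n_snps: int = 20
    planted_drivers: list[PlantedDriver] = field(default_factory=list)
    planted_de_only: list[PlantedShift] = field(default_factory=list)
    nb_dispersion: float = 0.2
    baseline_mean: float = 500.0
    library_sigma: float = 0.3
    survival_genes: list[SurvivalGene] = field(default_factory=list)
    baseline_hazard: float = 0.05
    censor_rate: float = 0.3
    cancer_types: tuple[str, ...] = ("PANCAN",)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be > 0")
        if self.baseline_mean <= 0:
            raise ConfigError("baseline_mean must be > 0")
        if self.baseline_hazard <= 0:
            raise ConfigError("baseline_hazard must be > 0")
        if not 0.0 <= self.censor_rate <= 1.0:
            raise ConfigError("censor_rate must be in [0, 1]")
        for pop in self.n_per_population:
            if pop not in self.populations:
                raise ConfigError(f"unknown population label {pop!r}")
        planted_genes = [d.gene_id for d in self.planted_drivers] + [
            s.gene_id for s in self.planted_de_only
        ]
        if len(set(planted_genes)) != len(planted_genes):
            raise ConfigError("planted gene ids must be distinct")
        snp_ids = [d.snp_id for d in self.planted_drivers]
        if len(set(snp_ids)) != len(snp_ids):
            raise ConfigError("planted snp ids must be distinct")
        for d in self.planted_drivers:
            for pop, f in d.freqs.items():
                if pop not in self.populations:
                    raise ConfigError(f"driver {d.snp_id}: unknown population {pop!r}")
                if not 0.0 <= f <= 1.0:
                    raise ConfigError(f"driver {d.snp_id}: frequency {f} outside [0, 1]")

    @property
    def sampled_populations(self) -> tuple[str, ...]:
        """Configured population labels that actually receive samples."""
        return tuple(p for p in self.populations if p in self.n_per_population)

    @property
    def gene_ids(self) -> list[str]:
        planted = [d.gene_id for d in self.planted_drivers] + [
            s.gene_id for s in self.planted_de_only
        ]
        background = [f"G{i:04d}" for i in range(self.n_genes - len(planted))]
        return planted + background

    @property
    def snp_ids(self) -> list[str]:
        planted = [d.snp_id for d in self.planted_drivers]
        background = [f"rsS{i:04d}" for i in range(self.n_snps - len(planted))]
        return planted + background


@dataclass
class GenotypeMatrix:
    """SNP-by-sample alt-allele dosages with VCF-convention metadata.

    ``dosages`` holds integers in {0, 1, 2} with pandas NA for missing
    genotypes; positions are 1-based per the VCF convention.
    """

    dosages: pd.DataFrame  # snp x sample, Int64 with NA for missing
    ref: pd.Series  # snp -> ref allele
    alt: pd.Series  # snp -> alt allele
    chrom: pd.Series  # snp -> chromosome label
    pos: pd.Series  # snp -> 1-based position
    sample_population: pd.Series  # sample -> population label

    @property
    def snp_ids(self) -> list[str]:
        return list(self.dosages.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.dosages.columns)


@dataclass
class CountMatrix:
    """Integer gene-by-sample read counts plus per-sample metadata."""

    counts: pd.DataFrame  # gene x sample, int64
    sample_meta: pd.DataFrame  # index sample_id, columns race, cancer_type

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def samples_of(self, race: str) -> list[str]:
        mask = self.sample_meta["race"] == race
        return list(self.sample_meta.index[mask])


def _sample_ids(n_per_population: dict[str, int]) -> dict[str, list[str]]:
    return {
        pop: [f"{pop}{i:05d}" for i in range(n)] for pop, n in n_per_population.items()
    }


def make_freq_table(config: SimConfig, seed: int | None = None) -> pd.DataFrame:
    """Allele-frequency table for every configured SNP in every population.

    Driver SNPs take their planted per-population frequencies; background
    SNPs get a single frequency drawn uniformly on [0.05, 0.95] shared by
    all populations (no planted frequency differentiation).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    pops = config.sampled_populations
    driver_freqs = {d.snp_id: d.freqs for d in config.planted_drivers}
    rows = []
    for snp in config.snp_ids:
        if snp in driver_freqs:
            for pop in pops:
                if pop not in driver_freqs[snp]:
                    raise ConfigError(f"driver {snp} missing frequency for {pop}")
                rows.append((snp, pop, float(driver_freqs[snp][pop])))
        else:
            f = float(rng.uniform(0.05, 0.95))
            for pop in pops:
                rows.append((snp, pop, f))
    return pd.DataFrame(rows, columns=["snp_id", "population", "alt_freq"])


def simulate_genotypes(
    freqs: pd.DataFrame, n_per_population: dict[str, int], seed: int
) -> GenotypeMatrix:
    """Draw Hardy-Weinberg genotypes: dosage ~ Binomial(2, f_pop) per SNP.

    ``freqs`` is a tidy table with columns snp_id, population, alt_freq;
    every SNP must be present for every requested population.
    """
    rng = np.random.default_rng(seed)
    table = freqs.pivot(index="snp_id", columns="population", values="alt_freq")
    # preserve first-appearance SNP order from the tidy table
    table = table.loc[freqs["snp_id"].drop_duplicates()]
    if table.isna().any().any():
        raise ConfigError("every SNP must have a frequency in every population")
    bad = table[(table < 0).any(axis=1) | (table > 1).any(axis=1)]
    if len(bad):
        raise ConfigError(f"allele frequencies outside [0, 1] for {list(bad.index)}")
    ids = _sample_ids(n_per_population)
    blocks, pops = [], []
    for pop, n in n_per_population.items():
        if pop not in table.columns:
            raise ConfigError(f"population {pop!r} absent from frequency table")
        if n < 1:
            raise ConfigError("sample counts must be >= 1")
        f = table[pop].to_numpy()[:, None]  # snp x 1
        blocks.append(rng.binomial(2, np.broadcast_to(f, (len(table), n))))
        pops.extend([pop] * n)
    all_ids = [s for pop in n_per_population for s in ids[pop]]
    dosages = pd.DataFrame(
        np.hstack(blocks), index=table.index, columns=all_ids, dtype="int64"
    ).astype("Int64")
    n_snps = len(table)
    return GenotypeMatrix(
        dosages=dosages,
        ref=pd.Series("A", index=table.index),
        alt=pd.Series("G", index=table.index),
        chrom=pd.Series("1", index=table.index),
        pos=pd.Series(np.arange(1, n_snps + 1) * 1000, index=table.index),
        sample_population=pd.Series(pops, index=all_ids),
    )


def simulate_expression(
    genotypes: GenotypeMatrix, config: SimConfig, seed: int
) -> CountMatrix:
    """Negative-binomial counts with additive cis-eQTL and race shifts.

    Count for gene g in sample i is NB with mean
    ``baseline_mean * s_i * 2**(beta_g * dosage_i + shift_{g, race(i)})``
    where s_i is a lognormal library-size factor, beta_g the planted eQTL
    log2 effect for driver genes (0 otherwise), and shift the planted
    race-specific log2 offset.
    """
    if config.nb_dispersion <= 0:
        raise ConfigError("nb_dispersion must be > 0")
    rng = np.random.default_rng(seed)
    samples = genotypes.sample_ids
    race = genotypes.sample_population.loc[samples]
    genes = config.gene_ids
    for d in config.planted_drivers:
        if d.snp_id not in genotypes.dosages.index:
            raise ConfigError(f"driver SNP {d.snp_id} absent from genotypes")
    n_g, n_s = len(genes), len(samples)

    log2_mu = np.zeros((n_g, n_s))
    gene_pos = {g: i for i, g in enumerate(genes)}
    for d in config.planted_drivers:
        dos = genotypes.dosages.loc[d.snp_id, samples].to_numpy(dtype=float, na_value=0.0)
        log2_mu[gene_pos[d.gene_id]] += d.eqtl_log2_effect_per_allele * dos
    for s in config.planted_de_only:
        shifts = race.map(lambda r: s.race_log2_shifts.get(r, 0.0)).to_numpy(dtype=float)
        log2_mu[gene_pos[s.gene_id]] += shifts

    sigma = config.library_sigma
    lib = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=n_s)
    mu = config.baseline_mean * lib[None, :] * np.exp2(log2_mu)

    # NB with var = mu + alpha*mu^2  <=>  n = 1/alpha, p = n/(n+mu)
    inv_alpha = 1.0 / config.nb_dispersion
    counts = rng.negative_binomial(inv_alpha, inv_alpha / (inv_alpha + mu))

    n_types = len(config.cancer_types)
    cancer = (
        rng.choice(config.cancer_types, size=n_s)
        if n_types > 1
        else np.repeat(config.cancer_types[0], n_s)
    )
    meta = pd.DataFrame(
        {"race": race.to_numpy(), "cancer_type": cancer}, index=pd.Index(samples, name="sample_id")
    )
    return CountMatrix(
        counts=pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"), columns=samples),
        sample_meta=meta,
    )


def simulate_survival(expr: CountMatrix, config: SimConfig, seed: int) -> pd.DataFrame:
    """Exponential survival with log-linear hazard in standardized expression.

    Hazard for sample i is ``baseline_hazard * exp(sum_g theta_g * z_g(i))``
    with z the per-gene standardized log2(count+1).  Each sample is censored
    independently with probability ``censor_rate``; a censored sample's
    recorded time is uniform on (0, t) so censoring precedes the latent event.

    Returns the clinical table (sample_id, race, cancer_type, time, event).
    """
    if config.baseline_hazard <= 0:
        raise ConfigError("baseline_hazard must be > 0")
    rng = np.random.default_rng(seed)
    samples = expr.sample_ids
    log_hr = np.zeros(len(samples))
    for sg in config.survival_genes:
        if sg.gene_id not in expr.counts.index:
            raise ConfigError(f"survival gene {sg.gene_id} absent from expression")
        x = np.log2(expr.counts.loc[sg.gene_id].to_numpy(dtype=float) + 1.0)
        sd = x.std()
        z = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
        log_hr += sg.log_hazard_per_sd * z
    rate = config.baseline_hazard * np.exp(log_hr)
    t = rng.exponential(1.0 / rate)
    censored = rng.random(len(samples)) < config.censor_rate
    u = rng.random(len(samples))
    time = np.where(censored, u * t, t)
    event = (~censored).astype(int)
    return pd.DataFrame(
        {
            "sample_id": samples,
            "race": expr.sample_meta.loc[samples, "race"].to_numpy(),
            "cancer_type": expr.sample_meta.loc[samples, "cancer_type"].to_numpy(),
            "time": time,
            "event": event,
        }
    )


def assemble_matched_cohort(
    clinical: pd.DataFrame, ratio: dict[str, int], seed: int
) -> pd.DataFrame:
    """Downsample to exact ratio-matched group sizes (k * ratio, k maximal).

    Surplus groups are downsampled without replacement, deterministically for
    a given seed; the returned table keeps the original row order of the
    retained samples.
    """
    rng = np.random.default_rng(seed)
    counts = clinical["race"].value_counts()
    for pop, r in ratio.items():
        if r < 1:
            raise ConfigError("ratio values must be >= 1")
        if pop not in counts.index:
            raise ConfigError(f"population {pop!r} absent from clinical table")
    k = min(counts[pop] // r for pop, r in ratio.items())
    if k < 1:
        raise ConfigError("not enough samples to honour the matching ratio")
    keep_idx: list[int] = []
    for pop, r in ratio.items():
        pos = np.flatnonzero((clinical["race"] == pop).to_numpy())
        chosen = rng.choice(pos, size=k * r, replace=False)
        keep_idx.extend(chosen.tolist())
    keep_idx.sort()
    return clinical.iloc[keep_idx].reset_index(drop=True)


def simulate_dataset(config: SimConfig) -> dict:
    """Run the full generator: frequencies, genotypes, expression, survival.

    Sub-seeds for each stage are derived from ``config.seed`` so that the
    single seed fully determines the dataset.  Returns a dict with keys
    freqs, genotypes, counts, clinical, truth (planted-driver table).
    """
    freqs = make_freq_table(config, seed=config.seed)
    genotypes = simulate_genotypes(freqs, config.n_per_population, seed=config.seed + 1)
    counts = simulate_expression(genotypes, config, seed=config.seed + 2)
    clinical = simulate_survival(counts, config, seed=config.seed + 3)
    truth = pd.DataFrame(
        [
            {
                "snp_id": d.snp_id,
                "gene_id": d.gene_id,
                "eqtl_log2_effect_per_allele": d.eqtl_log2_effect_per_allele,
                **{f"freq_{p}": f for p, f in sorted(d.freqs.items())},
            }
            for d in config.planted_drivers
        ]
    )
    return {
        "freqs": freqs,
        "genotypes": genotypes,
        "counts": counts,
        "clinical": clinical,
        "truth": truth,
    }
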