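"""Synthetic heat-gradient data with planted ground truth.

The generators reproduce the statistical structure the analysis assumes,
at the scale of the motivating experimental design: 8 genotypes x 3 heat
levels (25/32/38 C day temperature) x 10 phenotype replications x 6
traits, and 2 pooled RNA samples per genotype-level combination (47 when
one sample is dropped), with negative-binomial counts at a biological
coefficient of variation around 0.26.

Every downstream stage has a planted truth to recover:

* phenotypes carry per-genotype susceptibilities ``s_i`` that scale the
  linear heat-damage trend of every trait (the target of the HSI);
* counts carry a configurable fraction of dose-responsive genes with
  common log2 slope ``beta`` and a fraction of tolerance genes whose
  per-genotype slope is ``mu + h_i * delta`` for planted index values
  ``h_i``;
* FASTQ reads carry planted low-quality and adapter-bearing subsets for
  the QC filter.

Fixed seeds give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sequtil import ReadRecord

#: per-trait mean profiles over (25, 32, 38) C used by the default
#: phenotype configuration; values emulate a temperate-maize seedling
#: heat-stress trial (monotone damage except the growth-rate optimum
#: at the mild level).
TRAIT_PROFILES = {
    "growth_rate_cm_h": (0.24, 0.29, 0.19),
    "dry_weight_g": (2.02, 1.55, 0.62),
    "plant_height_cm": (21.9, 20.6, 12.5),
    "leaf_count": (3.5, 4.4, 4.6),
    "leaf_temp_c": (24.7, 31.8, 36.4),
    "leaf_greenness_spad": (47.1, 34.2, 29.4),
}


@dataclass
class PhenoSimConfig:
    """Effect-table parameterization of the phenotype simulator.

    ``value[i,j,k,t] = mu[t] + genotype_effects[i,t] + heat_effects[j,t]
    + interaction_effects[i,j,t] + R[j,k,t] + e``, with the block effect
    ``R ~ N(0, sigma_rep[t]^2)`` drawn once per (level, replication) and
    ``e ~ N(0, sigma_resid[t]^2)`` per observation.
    """

    genotypes: tuple
    heat_levels: tuple
    n_reps: int
    traits: tuple
    mu: np.ndarray  # (T,)
    genotype_effects: np.ndarray  # (G, T)
    heat_effects: np.ndarray  # (L, T)
    interaction_effects: np.ndarray  # (G, L, T)
    sigma_rep: np.ndarray  # (T,)
    sigma_resid: np.ndarray  # (T,)
    seed: int = 0

    def __post_init__(self):
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        levels = tuple(float(t) for t in self.heat_levels)
        if any(b <= a for a, b in zip(levels, levels[1:])):
            raise ValueError("heat_levels must be strictly increasing")
        for name in ("sigma_rep", "sigma_resid"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if (arr < 0).any():
                raise ValueError(f"{name} must be >= 0")
            setattr(self, name, arr)
        self.mu = np.asarray(self.mu, dtype=float)
        self.genotype_effects = np.asarray(self.genotype_effects, dtype=float)
        self.heat_effects = np.asarray(self.heat_effects, dtype=float)
        self.interaction_effects = np.asarray(self.interaction_effects, dtype=float)
        G, L, T = len(self.genotypes), len(self.heat_levels), len(self.traits)
        if self.genotype_effects.shape != (G, T):
            raise ValueError("genotype_effects must have shape (G, T)")
        if self.heat_effects.shape != (L, T):
            raise ValueError("heat_effects must have shape (L, T)")
        if self.interaction_effects.shape != (G, L, T):
            raise ValueError("interaction_effects must have shape (G, L, T)")

    def cell_mean(self, i: int, j: int, t: int) -> float:
        """Noise-free mean for genotype i, level j, trait t."""
        return float(
            self.mu[t]
            + self.genotype_effects[i, t]
            + self.heat_effects[j, t]
            + self.interaction_effects[i, j, t]
        )


def make_heat_stress_pheno_config(
    seed: int = 0,
    n_genotypes: int = 8,
    heat_levels: tuple = (25.0, 32.0, 38.0),
    n_reps: int = 10,
    susceptibility: np.ndarray | None = None,
    susceptibility_range: tuple = (0.9, 1.9),
    noise_scale: float = 1.0,
) -> tuple[PhenoSimConfig, np.ndarray]:
    """Default phenotype configuration with planted susceptibilities.

    Each trait follows its :data:`TRAIT_PROFILES` trend; the *linear*
    component of the trend is scaled per genotype by a susceptibility
    ``s_i`` (drawn uniform over ``susceptibility_range`` unless given), so
    genotype-by-level interaction encodes heat tolerance.  Noise levels
    are proportional to each trait's dynamic range (sd: genotype 0.12,
    block 0.06, residual 0.22 of range, times ``noise_scale``), tuned to
    give per-level repeatabilities in the realistic 0.6-0.9 band at 10
    replications.  Returns (config, planted susceptibilities).
    """
    rng = np.random.default_rng(seed)
    traits = tuple(TRAIT_PROFILES)
    levels = tuple(float(t) for t in heat_levels)
    x = (np.asarray(levels) - levels[0]) / (levels[-1] - levels[0])
    if susceptibility is None:
        susceptibility = rng.uniform(*susceptibility_range, size=n_genotypes)
    s = np.asarray(susceptibility, dtype=float)
    if len(s) != n_genotypes:
        raise ValueError("susceptibility length must equal n_genotypes")

    T = len(traits)
    prof = np.array([TRAIT_PROFILES[t] for t in traits]).T  # (L=3, T) base table
    if len(levels) != prof.shape[0]:
        raise ValueError("default profiles are defined for exactly 3 heat levels")
    base = prof[0]  # control-level mean per trait
    damage = prof[-1] - prof[0]  # signed linear span per trait
    nonlinear = prof - (base[None, :] + x[:, None] * damage[None, :])
    rng_span = np.ptp(prof, axis=0)
    rng_span = np.where(rng_span == 0, np.abs(base) + 1.0, rng_span)

    geno_eff = rng.normal(0.0, 0.12 * rng_span * noise_scale, size=(n_genotypes, T))
    heat_eff = nonlinear + x[:, None] * damage[None, :]
    inter = (s[:, None, None] - 1.0) * x[None, :, None] * damage[None, None, :]
    cfg = PhenoSimConfig(
        genotypes=tuple(f"G{i + 1}" for i in range(n_genotypes)),
        heat_levels=levels,
        n_reps=n_reps,
        traits=traits,
        mu=base,
        genotype_effects=geno_eff,
        heat_effects=heat_eff,
        interaction_effects=inter,
        sigma_rep=0.06 * rng_span * noise_scale,
        sigma_resid=0.22 * rng_span * noise_scale,
        seed=seed,
    )
    return cfg, s


def simulate_phenotypes(cfg: PhenoSimConfig) -> pd.DataFrame:
    """Draw the long-format phenotype table for a configuration."""
    rng = np.random.default_rng(cfg.seed)
    G, L, T = len(cfg.genotypes), len(cfg.heat_levels), len(cfg.traits)
    R = cfg.n_reps
    # block effects per (level, rep, trait)
    block = rng.normal(0.0, 1.0, size=(L, R, T)) * cfg.sigma_rep[None, None, :]
    resid = rng.normal(0.0, 1.0, size=(G, L, R, T)) * cfg.sigma_resid[None, None, None, :]
    cell = (
        cfg.mu[None, None, :]
        + cfg.genotype_effects[:, None, :]
        + cfg.heat_effects[None, :, :]
        + cfg.interaction_effects
    )  # (G, L, T)
    values = cell[:, :, None, :] + block[None, :, :, :] + resid

    gi, li, ri, ti = np.meshgrid(
        np.arange(G), np.arange(L), np.arange(R), np.arange(T), indexing="ij"
    )
    return pd.DataFrame(
        {
            "genotype": np.asarray(cfg.genotypes)[gi.ravel()],
            "heat_c": np.asarray(cfg.heat_levels)[li.ravel()],
            "rep": ri.ravel() + 1,
            "trait": np.asarray(cfg.traits)[ti.ravel()],
            "value": values.ravel(),
        }
    )


@dataclass
class CountsSimConfig:
    """Negative-binomial count simulator configuration.

    Counts for gene g in sample s (genotype i, level j) are drawn
    ``NB(mean = L_s * q_g * 2^(gamma_ig * x_j), dispersion phi = bcv^2)``
    where ``q_g`` is the gene's relative abundance (``2^baseline / 1e6``,
    i.e. the baseline parameter is the expected count in a 1M-read
    library at the control level) and ``x_j`` the metric heat code.
    Responsive genes share ``gamma_ig = beta`` across genotypes; tolerance
    genes have ``gamma_ig = mu_slope + h_i * delta``.
    """

    genotypes: tuple = tuple(f"G{i + 1}" for i in range(8))
    hsi: np.ndarray | None = None  # planted h_i; default U(0.9, 1.9)
    heat_levels: tuple = (25.0, 32.0, 38.0)
    n_reps: int = 2
    n_genes: int = 2000
    lib_size_range: tuple = (5e5, 2e6)
    library_sizes: np.ndarray | None = None  # explicit per-sample targets
    bcv: float = 0.26
    frac_responsive: float = 0.10
    frac_tolerance: float = 0.02
    slope_magnitude: float = 4.0
    delta_magnitude: float = 4.0
    tolerance_mu_slope: float | None = None  # None -> -mean(h)*delta (centered)
    baseline_log2_mean: float = 5.0
    baseline_log2_sd: float = 1.5
    baseline_log2_min: float | None = None
    drop_one_sample: bool = False
    seed: int = 0

    def __post_init__(self):
        if len(self.genotypes) == 0:
            raise ValueError("genotype list must not be empty")
        if self.bcv < 0:
            raise ValueError("bcv must be >= 0")
        for f in (self.frac_responsive, self.frac_tolerance):
            if not 0.0 <= f <= 1.0:
                raise ValueError("gene fractions must lie in [0, 1]")
        if self.frac_responsive + self.frac_tolerance > 1.0:
            raise ValueError("frac_responsive + frac_tolerance must be <= 1")
        levels = tuple(float(t) for t in self.heat_levels)
        if any(b <= a for a, b in zip(levels, levels[1:])):
            raise ValueError("heat_levels must be strictly increasing")
        self.heat_levels = levels


@dataclass
class SimTruth:
    """Planted per-gene truth plus the planted susceptibility index."""

    genes: pd.DataFrame  # gene, status, beta, delta, baseline_log2, gamma_<g>...
    hsi: pd.Series  # genotype -> planted h_i


def simulate_counts(
    cfg: CountsSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Draw (count matrix, sample metadata, truth) for a configuration."""
    rng = np.random.default_rng(cfg.seed)
    genos = tuple(cfg.genotypes)
    levels = np.asarray(cfg.heat_levels, dtype=float)
    x = (levels - levels[0]) / (levels[-1] - levels[0])

    h = cfg.hsi
    if h is None:
        h = rng.uniform(0.9, 1.9, size=len(genos))
    h = np.asarray(h, dtype=float)
    if len(h) != len(genos):
        raise ValueError("hsi length must equal the number of genotypes")

    n = cfg.n_genes
    n_resp = int(round(cfg.frac_responsive * n))
    n_tol = int(round(cfg.frac_tolerance * n))
    status = np.array(["null"] * n, dtype=object)
    status[:n_resp] = "responsive"
    status[n_resp : n_resp + n_tol] = "tolerance"
    rng.shuffle(status)

    beta = np.zeros(n)
    delta = np.zeros(n)
    sign = rng.choice([-1.0, 1.0], size=n)
    resp = status == "responsive"
    tol = status == "tolerance"
    beta[resp] = sign[resp] * cfg.slope_magnitude
    delta[tol] = sign[tol] * cfg.delta_magnitude

    baseline = rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, size=n)
    if cfg.baseline_log2_min is not None:
        # reflect draws below the floor back above it
        low = baseline < cfg.baseline_log2_min
        baseline[low] = 2.0 * cfg.baseline_log2_min - baseline[low]
    q = 2.0**baseline / 1e6

    # per-gene, per-genotype slope; tolerance genes center their slope
    # profile at zero by default so planted fold changes stay bounded
    if cfg.tolerance_mu_slope is None:
        mu_slope = -h.mean() * delta
    else:
        mu_slope = np.full(n, float(cfg.tolerance_mu_slope))
    gamma = np.where(resp[:, None], beta[:, None], 0.0) + np.where(
        tol[:, None],
        mu_slope[:, None] + h[None, :] * delta[:, None],
        0.0,
    )  # (n, G)

    samples, meta_rows, mean_cols = [], [], []
    if cfg.library_sizes is not None:
        target_lib = np.asarray(cfg.library_sizes, dtype=float)
        if len(target_lib) != len(genos) * len(levels) * cfg.n_reps:
            raise ValueError("library_sizes must have one entry per sample")
    else:
        target_lib = rng.uniform(
            cfg.lib_size_range[0],
            cfg.lib_size_range[1],
            size=len(genos) * len(levels) * cfg.n_reps,
        )
    si = 0
    for gi, geno in enumerate(genos):
        for lj, level in enumerate(levels):
            for rep in range(1, cfg.n_reps + 1):
                L = target_lib[si]
                si += 1
                samples.append(f"{geno}_T{level:g}_r{rep}")
                meta_rows.append(
                    {"sample": samples[-1], "genotype": geno, "heat_c": level,
                     "rep": rep, "target_lib_size": L}
                )
                mean_cols.append(L * q * 2.0 ** (gamma[:, gi] * x[lj]))
    means = np.column_stack(mean_cols)

    phi = cfg.bcv**2
    if phi == 0.0:
        Y = rng.poisson(means)
    else:
        r = 1.0 / phi
        Y = rng.negative_binomial(r, r / (r + means))

    counts = pd.DataFrame(Y, index=[f"gene{i + 1:05d}" for i in range(n)],
                          columns=samples)
    counts.index.name = "gene"
    meta = pd.DataFrame(meta_rows)

    if cfg.drop_one_sample:
        # emulate the missing pooled replicate: drop the last genotype's
        # second replicate at the middle level
        drop_geno = genos[-1]
        drop_level = levels[len(levels) // 2]
        victim = f"{drop_geno}_T{drop_level:g}_r{cfg.n_reps}"
        counts = counts.drop(columns=[victim])
        meta = meta[meta["sample"] != victim]

    meta = meta.copy()
    meta["lib_size"] = counts.sum(axis=0).to_numpy()
    meta = meta[["sample", "genotype", "heat_c", "rep", "lib_size",
                 "target_lib_size"]].set_index("sample", drop=False)

    genes = pd.DataFrame(
        {
            "gene": counts.index,
            "status": status,
            "beta": beta,
            "delta": delta,
            "mu_slope": mu_slope,
            "baseline_log2": baseline,
        }
    )
    for gi, geno in enumerate(genos):
        genes[f"gamma_{geno}"] = gamma[:, gi]
    truth = SimTruth(genes=genes.set_index("gene"),
                     hsi=pd.Series(h, index=list(genos), name="hsi"))
    return counts, meta, truth


BASES = np.array(list("ACGT"))


def simulate_fastq(
    n_reads: int,
    read_len: int = 100,
    frac_lowq: float = 0.0,
    adapters: tuple = (),
    frac_adapter: float = 0.0,
    seed: int = 0,
) -> tuple[list[ReadRecord], pd.DataFrame]:
    """Reads with planted low-quality and adapter-bearing subsets.

    ``round(frac_lowq * n)`` reads get more than 30% of bases at quality
    <= 20; ``round(frac_adapter * n)`` others contain one of ``adapters``
    as an exact substring; the remainder are clean (qualities 28-40 and
    verified free of the adapter sequences).  Returns (reads, truth table
    with the planted class of every read).
    """
    for f in (frac_lowq, frac_adapter):
        if not 0.0 <= f <= 1.0:
            raise ValueError("fractions must lie in [0, 1]")
    adapters = tuple(adapters)
    if frac_adapter > 0.0:
        if not adapters:
            raise ValueError("frac_adapter > 0 requires adapter sequences")
        if read_len < max(len(a) for a in adapters):
            raise ValueError("read_len shorter than an adapter sequence")
    rng = np.random.default_rng(seed)
    n_lowq = int(round(frac_lowq * n_reads))
    n_adapt = int(round(frac_adapter * n_reads))
    if n_lowq + n_adapt > n_reads:
        raise ValueError("frac_lowq + frac_adapter exceed the read budget")
    perm = rng.permutation(n_reads)
    lowq_idx = set(perm[:n_lowq].tolist())
    adapt_idx = set(perm[n_lowq : n_lowq + n_adapt].tolist())

    def random_seq(k):
        return "".join(BASES[rng.integers(0, 4, size=k)])

    def clean_seq(k):
        seq = random_seq(k)
        while any(a in seq for a in adapters):
            seq = random_seq(k)
        return seq

    reads, rows = [], []
    n_bad_min = int(np.floor(0.30 * read_len)) + 1
    for i in range(n_reads):
        qual = rng.integers(28, 41, size=read_len)
        if i in adapt_idx:
            ad = adapters[int(rng.integers(0, len(adapters)))]
            start = int(rng.integers(0, read_len - len(ad) + 1))
            seq = clean_seq(read_len)
            seq = seq[:start] + ad + seq[start + len(ad):]
            planted = "adapter"
        elif i in lowq_idx:
            seq = clean_seq(read_len)
            n_bad = int(rng.integers(n_bad_min, read_len + 1))
            bad = rng.choice(read_len, size=n_bad, replace=False)
            qual[bad] = rng.integers(2, 21, size=n_bad)
            planted = "low_quality"
        else:
            seq = clean_seq(read_len)
            planted = "clean"
        reads.append(ReadRecord(f"read{i + 1:06d}", seq, qual))
        rows.append({"read_id": reads[-1].read_id, "planted": planted})
    return reads, pd.DataFrame(rows)


def simulate_annotation(
    genes,
    truth: SimTruth | None = None,
    n_terms: int = 20,
    terms_per_gene: float = 2.0,
    enriched_term: str = "TERM_RESPONSIVE",
    enrich_frac: float = 0.6,
    seed: int = 0,
) -> pd.DataFrame:
    """Random gene -> term map with one term planted in responsive genes.

    Background terms are assigned independently (on average
    ``terms_per_gene`` per gene); when a truth table is given,
    ``enrich_frac`` of the responsive genes additionally carry
    ``enriched_term`` (against a 5% background rate), giving the
    enrichment stage a positive control.
    """
    rng = np.random.default_rng(seed)
    genes = list(genes)
    rows = []
    p_bg = min(terms_per_gene / n_terms, 1.0)
    for g in genes:
        for t in range(n_terms):
            if rng.random() < p_bg:
                rows.append({"gene": g, "term": f"TERM{t + 1:03d}"})
    if truth is not None:
        resp = set(truth.genes.index[truth.genes["status"] == "responsive"])
        for g in genes:
            p = enrich_frac if g in resp else 0.05
            if rng.random() < p:
                rows.append({"gene": g, "term": enriched_term})
    return pd.DataFrame(rows, columns=["gene", "term"])
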