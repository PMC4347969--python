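"""Mixed-model analysis of multi-trait phenotype tables from a heat-gradient trial.

The experimental layout is a randomized complete block design repeated at
several day/night temperature regimes ("heat levels"): each genotype is
observed in ``n`` replications (blocks) at each level for each trait.

Three analyses are provided, all REML-based:

* :func:`adjusted_entry_means` -- per-level best linear unbiased estimates
  (BLUEs) of genotype means, with replication as a random block effect;
* :func:`variance_components` / :func:`repeatability` -- genotype and
  residual variances with genotype treated as random, and the entry-mean
  repeatability ``H2 = s2_G / (s2_G + s2_e / n)``;
* :func:`combined_model_tests` -- the across-level model with genotype,
  level and genotype-by-level interaction as fixed effects and replication
  nested in level as random, tested by Wald F with containment
  denominator degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._reml import REMLResult, indicator, reml_fit

REQUIRED_COLUMNS = ("genotype", "heat_c", "rep", "trait", "value")


def load_phenotypes(path) -> pd.DataFrame:
    """Read a long-format phenotype TSV (genotype, heat_c, rep, trait, value)."""
    df = pd.read_csv(path, sep="\t")
    return validate_phenotypes(df)


def validate_phenotypes(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype table lacks columns: {missing}")
    keys = ["genotype", "heat_c", "rep", "trait"]
    dup = df.duplicated(subset=keys)
    if dup.any():
        raise ValueError(
            f"duplicate (genotype, heat_c, rep, trait) keys: "
            f"{df.loc[dup, keys].head().to_dict('records')}"
        )
    if df["value"].isna().any():
        raise ValueError("phenotype values contain NaN")
    return df


def write_phenotypes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


@dataclass
class VarianceDecomposition:
    """Genotype/residual variance split at one heat level for one trait."""

    trait: str
    heat_c: float
    sigma2_genotype: float
    sigma2_resid: float
    n_reps: float
    H2: float = np.nan


@dataclass
class PhenoModelFit:
    """Fixed-effect estimates and Wald F tests from the combined model."""

    trait: str
    mean: float
    genotype_effects: pd.Series
    heat_effects: pd.Series
    interaction_effects: pd.DataFrame
    sigma2_rep: float
    sigma2_resid: float
    tests: pd.DataFrame  # term, F, df1, df2, p
    degenerate: bool = False


def _subset(records: pd.DataFrame, heat_c, trait) -> pd.DataFrame:
    sub = records[(records["heat_c"] == heat_c) & (records["trait"] == trait)]
    if sub.empty:
        raise ValueError(f"no observations for trait {trait!r} at {heat_c} C")
    return sub


def adjusted_entry_means(records: pd.DataFrame, heat_c, trait) -> pd.Series:
    """BLUEs of genotype means at one heat level for one trait.

    Model: value = mu + genotype (fixed) + replication (random) + error,
    fitted by REML.  Cell-means coding makes the coefficient vector the
    genotype BLUEs directly.  For balanced complete data these equal the
    per-genotype arithmetic means; genotypes absent at this level are
    reported missing, never imputed.
    """
    sub = _subset(records, heat_c, trait)
    genos = np.sort(sub["genotype"].unique())
    n_reps = sub["rep"].nunique()
    if n_reps == 1:
        vals = sub.set_index("genotype")["value"]
        return vals.reindex(genos).rename("mean")
    X = indicator(sub["genotype"].to_numpy())
    Z = indicator(sub["rep"].to_numpy())
    fit = reml_fit(sub["value"].to_numpy(), X, [Z], ["rep"])
    return pd.Series(fit.beta, index=genos, name="mean")


def adjusted_means_table(records: pd.DataFrame) -> pd.DataFrame:
    """Long table of BLUEs for every (genotype, heat level, trait) cell."""
    rows = []
    for (heat_c, trait), _ in records.groupby(["heat_c", "trait"]):
        means = adjusted_entry_means(records, heat_c, trait)
        for geno, m in means.items():
            rows.append({"genotype": geno, "heat_c": heat_c, "trait": trait, "mean": m})
    return pd.DataFrame(rows)


def variance_components(
    records: pd.DataFrame, heat_c, trait, rep_random: bool = True
) -> VarianceDecomposition:
    """REML genotype/residual variances at one level (genotype random).

    Replication is kept as a second random effect by default
    (``rep_random=False`` drops it, e.g. when blocks carry no variance by
    construction).  Negative component estimates are truncated at zero
    (REML boundary).  ``n_reps`` is the mean number of observations per
    genotype, which is the replication count for balanced data.
    """
    sub = _subset(records, heat_c, trait)
    if sub["genotype"].nunique() < 2:
        raise ValueError("variance_components needs >= 2 genotypes")
    if rep_random and sub["rep"].nunique() < 2:
        raise ValueError("variance_components needs >= 2 replications")
    y = sub["value"].to_numpy()
    n_reps = len(sub) / sub["genotype"].nunique()
    if np.ptp(y) == 0.0:
        warnings.warn("all phenotype values identical; variances set to 0")
        return VarianceDecomposition(trait, heat_c, 0.0, 0.0, n_reps, H2=0.0)
    X = np.ones((len(sub), 1))
    Zs = [indicator(sub["genotype"].to_numpy())]
    names = ["genotype"]
    if rep_random:
        Zs.append(indicator(sub["rep"].to_numpy()))
        names.append("rep")
    fit = reml_fit(y, X, Zs, names)
    vc = VarianceDecomposition(
        trait=trait,
        heat_c=heat_c,
        sigma2_genotype=fit.sigma2_random["genotype"],
        sigma2_resid=fit.sigma2_resid,
        n_reps=n_reps,
    )
    vc.H2 = repeatability(vc)
    return vc


def repeatability(vc: VarianceDecomposition) -> float:
    """Entry-mean repeatability ``H2 = s2_G / (s2_G + s2_e / n)``."""
    if vc.n_reps < 1:
        raise ValueError("repeatability needs n_reps >= 1")
    denom = vc.sigma2_genotype + vc.sigma2_resid / vc.n_reps
    if denom == 0.0:
        warnings.warn("both variance components are zero; H2 defined as 0")
        return 0.0
    return vc.sigma2_genotype / denom


def repeatability_table(records: pd.DataFrame) -> pd.DataFrame:
    """Repeatability and variance components for every trait x heat level."""
    rows = []
    for (heat_c, trait), _ in records.groupby(["heat_c", "trait"]):
        vc = variance_components(records, heat_c, trait)
        rows.append(
            {
                "trait": trait,
                "heat_c": heat_c,
                "sigma2_genotype": vc.sigma2_genotype,
                "sigma2_resid": vc.sigma2_resid,
                "n_reps": vc.n_reps,
                "H2": vc.H2,
            }
        )
    return pd.DataFrame(rows)


def _sum_to_zero(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sum-to-zero (effect) coding: k-1 columns, last level = -sum of others."""
    cats = np.unique(labels)
    k = len(cats)
    C = np.zeros((len(labels), k - 1))
    for j in range(k - 1):
        C[labels == cats[j], j] = 1.0
    C[labels == cats[-1], :] = -1.0
    return C, cats


def combined_model_tests(records: pd.DataFrame, trait) -> PhenoModelFit:
    """Across-level fixed-effect tests for one trait.

    Model: value = mu + genotype + level + genotype:level (all fixed, sum-to-
    zero coded) + replication-within-level (random) + error.  Wald F uses
    containment denominator df: the residual df for genotype and the
    interaction, and the replication-within-level df for the heat level.
    On balanced data these reproduce the classical split-in-blocks ANOVA
    F statistics.
    """
    sub = records[records["trait"] == trait]
    if sub.empty:
        raise ValueError(f"no observations for trait {trait!r}")
    g_lab = sub["genotype"].to_numpy()
    h_lab = sub["heat_c"].to_numpy()
    if len(np.unique(g_lab)) < 2 or len(np.unique(h_lab)) < 2:
        raise ValueError("combined model needs >= 2 genotypes and >= 2 levels")
    y = sub["value"].to_numpy(dtype=float)

    G, genos = _sum_to_zero(g_lab)
    H, levels = _sum_to_zero(h_lab)
    GH = np.concatenate(
        [G[:, [i]] * H[:, [j]] for i in range(G.shape[1]) for j in range(H.shape[1])],
        axis=1,
    )
    X = np.column_stack([np.ones(len(sub)), G, H, GH])
    rep_in_level = np.array([f"{h}|{r}" for h, r in zip(h_lab, sub["rep"])])
    Z = indicator(rep_in_level)

    if np.ptp(y) == 0.0:
        warnings.warn("all responses equal; combined-model tests degenerate")
        empty = pd.DataFrame(
            {
                "term": ["genotype", "heat", "genotype:heat"],
                "F": np.nan,
                "df1": 0,
                "df2": 0,
                "p": np.nan,
            }
        )
        k_g, k_h = len(genos), len(levels)
        return PhenoModelFit(
            trait=trait,
            mean=float(y[0]),
            genotype_effects=pd.Series(0.0, index=genos),
            heat_effects=pd.Series(0.0, index=levels),
            interaction_effects=pd.DataFrame(
                np.zeros((k_g, k_h)), index=genos, columns=levels
            ),
            sigma2_rep=0.0,
            sigma2_resid=0.0,
            tests=empty,
            degenerate=True,
        )

    fit = reml_fit(y, X, [Z], ["rep"])

    # containment denominator df
    n = len(y)
    n_levels = len(levels)
    rank_XZ = np.linalg.matrix_rank(np.column_stack([X, Z]))
    df_resid = n - rank_XZ
    df_rep = Z.shape[1] - n_levels  # rep-within-level stratum

    p_g = G.shape[1]
    p_h = H.shape[1]
    slices = {
        "genotype": (slice(1, 1 + p_g), df_resid),
        "heat": (slice(1 + p_g, 1 + p_g + p_h), df_rep),
        "genotype:heat": (slice(1 + p_g + p_h, X.shape[1]), df_resid),
    }
    rows = []
    for term, (sl, df2) in slices.items():
        b = fit.beta[sl]
        C = fit.cov_beta[sl, sl]
        df1 = len(b)
        if df2 <= 0 or fit.sigma2_resid <= 0:
            rows.append({"term": term, "F": np.nan, "df1": df1, "df2": df2, "p": np.nan})
            continue
        F = float(b @ np.linalg.solve(C, b)) / df1
        p = float(stats.f.sf(F, df1, df2))
        rows.append({"term": term, "F": F, "df1": df1, "df2": df2, "p": p})

    # reassemble full sum-to-zero effect vectors (last level = -sum)
    bg = fit.beta[1 : 1 + p_g]
    bh = fit.beta[1 + p_g : 1 + p_g + p_h]
    bi = fit.beta[1 + p_g + p_h :].reshape(p_g, p_h)
    g_eff = np.append(bg, -bg.sum())
    h_eff = np.append(bh, -bh.sum())
    ih = np.zeros((p_g + 1, p_h + 1))
    ih[:p_g, :p_h] = bi
    ih[:p_g, p_h] = -bi.sum(axis=1)
    ih[p_g, :] = -ih[:p_g, :].sum(axis=0)

    return PhenoModelFit(
        trait=trait,
        mean=float(fit.beta[0]),
        genotype_effects=pd.Series(g_eff, index=genos),
        heat_effects=pd.Series(h_eff, index=levels),
        interaction_effects=pd.DataFrame(ih, index=genos, columns=levels),
        sigma2_rep=fit.sigma2_random["rep"],
        sigma2_resid=fit.sigma2_resid,
        tests=pd.DataFrame(rows),
        degenerate=False,
    )
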