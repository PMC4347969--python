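"""Dose-response differential expression over a metric-coded heat gradient.

Expression counts are modelled gene-by-gene with a negative-binomial
log-linear GLM on the metric heat code ``x`` (0 at the control level, 1 at
the strongest level), with log effective library size as offset and a
fixed common dispersion:

* overall response: one slope ``beta`` per gene, all genotypes treated as
  replications of one average genotype;
* per-genotype response: one slope ``gamma_i`` per gene and genotype
  (genotype-specific intercepts by default; a strict shared-intercept mode
  is available);
* heat tolerance: per gene, the per-genotype slopes ``gamma_i`` are
  regressed on the phenotypic heat susceptibility index ``h_i`` by OLS,
  ``gamma_i = mu + h_i * delta + e_i``; the per-gene p is deliberately not
  adjusted for multiple testing.

Slopes are reported in log2 units of fold change across the full gradient.
Significance: likelihood-ratio chi-square (1 df) per slope with
Benjamini-Hochberg FDR across genes; a gene is called responsive at
``fdr < 0.05`` and ``|log2 FC| > 2`` (both strict).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

from ._nbglm import nb_irls
from .counts import _lib_sizes
from .heat_index import HeatLevelCoding

LN2 = np.log(2.0)


def _offsets(counts: pd.DataFrame, meta: pd.DataFrame, norm_factors) -> np.ndarray:
    lib = meta.loc[counts.columns, "lib_size"].astype(float)
    lib = _lib_sizes(counts, lib)
    if norm_factors is not None:
        lib = lib * pd.Series(norm_factors, index=counts.columns).astype(float)
    return np.log(lib.to_numpy())


def _codes(counts: pd.DataFrame, meta: pd.DataFrame, coding: HeatLevelCoding):
    heat = meta.loc[counts.columns, "heat_c"].to_numpy(dtype=float)
    return coding.code(heat)


def fit_dose_response_overall(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    coding: HeatLevelCoding,
    phi: float,
    norm_factors=None,
) -> pd.DataFrame:
    """Per-gene NB regression of expression on the metric heat code.

    Returns a frame indexed by gene with ``beta_log2`` (slope in log2
    fold-change units across the full gradient), ``intercept_log2``,
    ``p_value`` (LRT of slope = 0), ``fdr`` (BH across genes) and a
    ``converged`` flag.  All-zero genes get beta 0 and p 1; genes whose
    IRLS did not converge keep their estimates but are flagged and should
    be excluded from calling.
    """
    x = _codes(counts, meta, coding)
    offset = _offsets(counts, meta, norm_factors)
    Y = counts.to_numpy(dtype=float)
    G = Y.shape[0]

    nz = Y.sum(axis=1) > 0
    beta = np.zeros(G)
    intercept = np.full(G, -np.inf)
    p_value = np.ones(G)
    converged = np.ones(G, dtype=bool)

    if nz.any():
        X_full = np.column_stack([np.ones_like(x), x])
        X_null = np.ones((len(x), 1))
        full = nb_irls(Y[nz], X_full, offset, phi)
        null = nb_irls(Y[nz], X_null, offset, phi)
        lrt = np.clip(2.0 * (full.loglik - null.loglik), 0.0, None)
        beta[nz] = full.beta[:, 1] / LN2
        intercept[nz] = full.beta[:, 0] / LN2
        p_value[nz] = stats.chi2.sf(lrt, df=1)
        converged[nz] = full.converged & null.converged

    fdr = multipletests(p_value, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "beta_log2": beta,
            "intercept_log2": intercept,
            "p_value": p_value,
            "fdr": fdr,
            "converged": converged,
        },
        index=pd.Index(counts.index, name="gene"),
    )


def call_significant(
    fits: pd.DataFrame,
    fdr_max: float = 0.05,
    lfc_min: float = 2.0,
    slope_col: str = "beta_log2",
) -> tuple[list, list]:
    """Split fitted genes into up/down calls at strict thresholds.

    A gene is called iff ``fdr < fdr_max`` and ``|slope| > lfc_min`` (both
    strict) and its fit converged.  Returns (up gene list, down gene list).
    """
    ok = fits["converged"] if "converged" in fits else pd.Series(True, fits.index)
    sig = (fits["fdr"] < fdr_max) & ok
    up = list(fits.index[sig & (fits[slope_col] > lfc_min)])
    down = list(fits.index[sig & (fits[slope_col] < -lfc_min)])
    return up, down


@dataclass
class GenotypeSlopes:
    """Per-gene, per-genotype dose-response slopes with LRT significance."""

    gamma_log2: pd.DataFrame  # genes x genotypes
    p_value: pd.DataFrame
    fdr: pd.DataFrame  # BH within genotype, across genes
    converged: pd.DataFrame


def fit_dose_response_per_genotype(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    coding: HeatLevelCoding,
    phi: float,
    norm_factors=None,
    intercepts: str = "per_genotype",
) -> GenotypeSlopes:
    """Genotype-specific dose-response slopes from one joint NB GLM per gene.

    ``intercepts="per_genotype"`` (default) gives every genotype its own
    baseline, reflecting baseline expression differences between inbred
    lines; ``"shared"`` is the strict literal one-intercept form.  Each
    slope's p comes from an LRT dropping that genotype's slope column.
    Genotypes observed at fewer than two heat levels get NaN slopes.
    """
    if intercepts not in ("per_genotype", "shared"):
        raise ValueError("intercepts must be 'per_genotype' or 'shared'")
    x = _codes(counts, meta, coding)
    offset = _offsets(counts, meta, norm_factors)
    genos = np.sort(meta.loc[counts.columns, "genotype"].unique())
    glab = meta.loc[counts.columns, "genotype"].to_numpy()
    Y = counts.to_numpy(dtype=float)
    G = Y.shape[0]

    ind = (glab[:, None] == genos[None, :]).astype(float)
    slope_cols = ind * x[:, None]
    if intercepts == "per_genotype":
        X_full = np.concatenate([ind, slope_cols], axis=1)
        n_int = len(genos)
    else:
        X_full = np.column_stack([np.ones_like(x), slope_cols])
        n_int = 1

    estimable = np.array(
        [len(np.unique(x[glab == g])) >= 2 for g in genos]
    )

    full = nb_irls(Y, X_full, offset, phi)
    gamma = pd.DataFrame(
        full.beta[:, n_int:] / LN2, index=counts.index, columns=genos
    )
    pv = pd.DataFrame(1.0, index=counts.index, columns=genos)
    conv = pd.DataFrame(True, index=counts.index, columns=genos)
    for j, g in enumerate(genos):
        if not estimable[j]:
            gamma[g] = np.nan
            pv[g] = np.nan
            continue
        X_red = np.delete(X_full, n_int + j, axis=1)
        red = nb_irls(Y, X_red, offset, phi)
        lrt = np.clip(2.0 * (full.loglik - red.loglik), 0.0, None)
        pv[g] = stats.chi2.sf(lrt, df=1)
        conv[g] = full.converged & red.converged

    zero = Y.sum(axis=1) == 0
    gamma.loc[zero] = 0.0
    pv.loc[zero] = 1.0

    fdr = pv.copy()
    for g in genos:
        col = pv[g].to_numpy()
        mask = np.isfinite(col)
        if mask.any():
            fdr.loc[mask, g] = multipletests(col[mask], method="fdr_bh")[1]
    gamma.index.name = pv.index.name = fdr.index.name = conv.index.name = "gene"
    return GenotypeSlopes(gamma_log2=gamma, p_value=pv, fdr=fdr, converged=conv)


def per_genotype_calls(
    slopes: GenotypeSlopes, fdr_max: float = 0.05, lfc_min: float = 2.0
) -> dict:
    """Per-genotype (up, down) gene sets at the strict thresholds."""
    out = {}
    for g in slopes.gamma_log2.columns:
        fits = pd.DataFrame(
            {
                "beta_log2": slopes.gamma_log2[g],
                "fdr": slopes.fdr[g],
                "converged": slopes.converged[g],
            }
        ).dropna()
        out[g] = call_significant(fits, fdr_max, lfc_min)
    return out


def overlap_sets(calls: dict, groups: dict) -> pd.DataFrame:
    """Intersections of per-genotype up/down sets over genotype groups.

    ``calls`` maps genotype -> (up list, down list); ``groups`` maps a
    group label (e.g. "all", "flint", "dent", "tolerant", "susceptible")
    to its genotype members.  Returns one row per group with intersection
    sizes and the sorted intersected gene lists.
    """
    rows = []
    for name, members in groups.items():
        unknown = [m for m in members if m not in calls]
        if unknown:
            raise ValueError(f"group {name!r} has unknown genotypes: {unknown}")
        ups = [set(calls[m][0]) for m in members]
        downs = [set(calls[m][1]) for m in members]
        up = set.intersection(*ups) if ups else set()
        down = set.intersection(*downs) if downs else set()
        rows.append(
            {
                "group": name,
                "n_genotypes": len(members),
                "n_up_common": len(up),
                "n_down_common": len(down),
                "up_genes": ",".join(sorted(map(str, up))),
                "down_genes": ",".join(sorted(map(str, down))),
            }
        )
    return pd.DataFrame(rows)


def tolerance_regression(
    gamma: pd.DataFrame,
    hsi: pd.DataFrame,
    p_max: float = 0.05,
    delta_min: float = 2.0,
) -> pd.DataFrame:
    """Per-gene OLS of per-genotype slopes on the susceptibility index.

    ``gamma`` is genes x genotypes (log2 slope units); ``hsi`` is the
    frame from :func:`heatgrad.heat_index.hsi_compute` (or any frame with
    ``genotype`` and ``hsi`` columns).  Per gene: slope ``delta``,
    intercept ``mu``, two-sided t-test p with ``n - 2`` df, *unadjusted*
    for multiple testing; called iff ``p < p_max`` and ``|delta| >
    delta_min`` (strict).  Genotypes with missing slopes are dropped
    gene-wise.
    """
    h = hsi.set_index("genotype")["hsi"]
    common = [g for g in gamma.columns if g in h.index]
    if len(common) < 3:
        raise ValueError("tolerance regression needs >= 3 genotypes with HSI")
    Gm = gamma[common].to_numpy(dtype=float)
    hv = h.loc[common].to_numpy(dtype=float)
    if np.ptp(hv) == 0.0:
        raise ValueError("HSI values are constant; tolerance slope undefined")

    mask = np.isfinite(Gm)
    n = mask.sum(axis=1)
    H = np.where(mask, hv[None, :], 0.0)
    Gz = np.where(mask, Gm, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        hbar = H.sum(axis=1) / n
        gbar = Gz.sum(axis=1) / n
        hc = np.where(mask, hv[None, :] - hbar[:, None], 0.0)
        gc = np.where(mask, Gm - gbar[:, None], 0.0)
        sxx = (hc**2).sum(axis=1)
        sxy = (hc * gc).sum(axis=1)
        delta = sxy / sxx
        mu = gbar - delta * hbar
        resid = np.where(mask, gc - delta[:, None] * hc, 0.0)
        df = n - 2
        s2 = (resid**2).sum(axis=1) / np.where(df > 0, df, np.nan)
        se = np.sqrt(s2 / sxx)
        t = delta / se
        p = 2.0 * stats.t.sf(np.abs(t), df)
    # zero-residual exact fits: se 0 -> t inf -> p 0
    p = np.where(np.isfinite(t) | (se == 0), np.nan_to_num(p, nan=0.0), np.nan)
    p = np.where(df > 0, p, np.nan)
    out = pd.DataFrame(
        {
            "delta": delta,
            "mu": mu,
            "t": t,
            "p_value": p,
            "n_genotypes": n,
        },
        index=pd.Index(gamma.index, name="gene"),
    )
    out["called"] = (out["p_value"] < p_max) & (np.abs(out["delta"]) > delta_min)
    out["called"] = out["called"].fillna(False)
    return out


def cluster_tolerance_genes(
    gamma_called: pd.DataFrame, k: int = 2
) -> tuple[pd.Series, list]:
    """Hierarchically cluster called genes by their per-genotype slope rows.

    Euclidean distance, complete linkage, tree cut at ``k`` clusters.
    Returns (cluster labels 1..k per gene, leaf order for heatmap export).
    Cluster ids are relabelled in order of first appearance along the
    dendrogram leaves, so they are deterministic.
    """
    genes = list(gamma_called.index)
    if len(genes) == 0:
        return pd.Series(dtype=int, name="cluster"), []
    if len(genes) == 1 or k <= 1:
        return (
            pd.Series(1, index=gamma_called.index, name="cluster"),
            genes,
        )
    M = gamma_called.to_numpy(dtype=float)
    Z = hierarchy.linkage(M, method="complete", metric="euclidean")
    raw = hierarchy.fcluster(Z, t=min(k, len(genes)), criterion="maxclust")
    order = list(hierarchy.leaves_list(Z))
    relabel = {}
    for leaf in order:
        relabel.setdefault(raw[leaf], len(relabel) + 1)
    labels = pd.Series(
        [relabel[c] for c in raw], index=gamma_called.index, name="cluster"
    )
    leaf_genes = [genes[i] for i in order]
    return labels, leaf_genes
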