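"""Metric heat-level coding, phenotype PCA and the Heat Susceptibility Index.

The temperature gradient is mapped affinely onto [0, 1] (the *metric
coding*): the lowest level becomes 0, the highest 1, intermediate levels
fall proportionally in between (25/32/38 C -> 0, 7/13, 1).  A PCA of the
genotype-by-level adjusted trait means condenses the multi-trait stress
reaction into PC scores; the Heat Susceptibility Index (HSI) of a genotype
is the OLS slope of its PC1 scores over the metric-coded levels.  High HSI
means heat susceptible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA


@dataclass
class HeatLevelCoding:
    """Affine temperature -> [0, 1] coding used as the dose regressor."""

    levels: tuple
    codes: dict  # heat_c -> x

    def __getitem__(self, heat_c) -> float:
        return self.codes[heat_c]

    def code(self, heat_c) -> np.ndarray:
        """Vectorized lookup (array of temperatures -> array of codes)."""
        arr = np.asarray(heat_c, dtype=float)
        lo, hi = min(self.levels), max(self.levels)
        return (arr - lo) / (hi - lo)


@dataclass
class PCAResult:
    scores: pd.DataFrame  # rows = observations, columns PC1..PCk
    loadings: pd.DataFrame  # rows = variables (traits/genes), columns PC1..PCk
    explained_frac: pd.Series


@dataclass
class HSIProfile:
    genotype: str
    pc1_scores: pd.Series  # indexed by heat_c
    hsi: float
    intercept: float


def metric_heat_coding(levels) -> HeatLevelCoding:
    """Map heat levels (deg C) affinely to [0, 1]; min -> 0, max -> 1."""
    levels = tuple(sorted(float(t) for t in levels))
    if len(set(levels)) < 2:
        raise ValueError("metric coding needs >= 2 distinct heat levels")
    lo, hi = levels[0], levels[-1]
    codes = {t: (t - lo) / (hi - lo) for t in levels}
    return HeatLevelCoding(levels=levels, codes=codes)


def _pivot_means(means: pd.DataFrame) -> pd.DataFrame:
    wide = means.pivot_table(
        index=["genotype", "heat_c"], columns="trait", values="mean", aggfunc="first"
    )
    if wide.isna().any().any():
        holes = [
            (idx, col)
            for col in wide.columns
            for idx in wide.index[wide[col].isna()]
        ]
        raise ValueError(f"missing genotype x level x trait cells: {holes}")
    return wide


def pca_means(means: pd.DataFrame, standardize: bool = True) -> PCAResult:
    """PCA of the (genotype x heat level) by trait adjusted-means matrix.

    Columns (traits) are centered, and scaled to unit variance when
    ``standardize`` (the default: traits carry incommensurable units).
    PC1's sign is oriented so that the mean score increases from the lowest
    to the highest heat level, making "susceptible = high" deterministic.
    """
    wide = _pivot_means(means)
    M = wide.to_numpy(dtype=float)
    if M.shape[0] < 2 or M.shape[1] < 2:
        raise ValueError("PCA needs >= 2 observations and >= 2 traits")
    center = M.mean(axis=0)
    Mc = M - center
    if standardize:
        sd = M.std(axis=0, ddof=1)
        zero = sd == 0.0
        if zero.any():
            raise ValueError(
                f"zero-variance traits cannot be standardized: "
                f"{list(wide.columns[zero])}"
            )
        Mc = Mc / sd
    k = min(Mc.shape)
    pca = PCA(n_components=k)
    scores = pca.fit_transform(Mc)
    loadings = pca.components_.T
    explained = pca.explained_variance_ratio_

    pcs = [f"PC{i + 1}" for i in range(k)]
    scores_df = pd.DataFrame(scores, index=wide.index, columns=pcs)
    heat = wide.index.get_level_values("heat_c").to_numpy(dtype=float)
    lo_mean = scores_df.loc[heat == heat.min(), "PC1"].mean()
    hi_mean = scores_df.loc[heat == heat.max(), "PC1"].mean()
    if hi_mean < lo_mean:
        scores_df["PC1"] *= -1.0
        loadings[:, 0] *= -1.0
    return PCAResult(
        scores=scores_df,
        loadings=pd.DataFrame(loadings, index=wide.columns, columns=pcs),
        explained_frac=pd.Series(explained, index=pcs),
    )


def correlate_traits_pc1(means: pd.DataFrame, pca: PCAResult) -> pd.DataFrame:
    """Pearson r (and two-sided p) between each trait's means and PC1 scores."""
    wide = _pivot_means(means).loc[pca.scores.index]
    pc1 = pca.scores["PC1"].to_numpy()
    rows = []
    for trait in wide.columns:
        v = wide[trait].to_numpy(dtype=float)
        if np.ptp(v) == 0.0:
            warnings.warn(f"trait {trait!r} is constant; correlation undefined")
            rows.append({"trait": trait, "r": np.nan, "p": np.nan})
            continue
        r, p = stats.pearsonr(v, pc1)
        rows.append({"trait": trait, "r": r, "p": p})
    return pd.DataFrame(rows)


def hsi_compute(
    pca: PCAResult, coding: HeatLevelCoding, axis: str = "coding"
) -> pd.DataFrame:
    """Heat Susceptibility Index: per-genotype slope of PC1 score on heat.

    ``axis`` selects the regressor: ``"coding"`` (metric codes in [0,1],
    the default, consistent with the dose-response models) or
    ``"celsius"`` (raw temperature).  Genotypes observed at a single level
    are excluded with a warning.  The result is sorted by descending HSI
    (rank 1 = most susceptible).
    """
    if axis not in ("coding", "celsius"):
        raise ValueError("axis must be 'coding' or 'celsius'")
    rows = []
    for geno, sub in pca.scores.groupby(level="genotype", sort=True):
        heat = sub.index.get_level_values("heat_c").to_numpy(dtype=float)
        if len(np.unique(heat)) < 2:
            warnings.warn(f"genotype {geno!r} observed at a single level; excluded")
            continue
        x = coding.code(heat) if axis == "coding" else heat
        slope, intercept = np.polyfit(x, sub["PC1"].to_numpy(), 1)
        rows.append({"genotype": geno, "hsi": slope, "intercept": intercept})
    out = pd.DataFrame(rows).sort_values("hsi", ascending=False, kind="stable")
    out["rank"] = np.arange(1, len(out) + 1)
    return out.reset_index(drop=True)


def hsi_profiles(pca: PCAResult, coding: HeatLevelCoding) -> list[HSIProfile]:
    """HSI results as per-genotype profiles carrying the PC1 score path."""
    table = hsi_compute(pca, coding)
    out = []
    for _, row in table.iterrows():
        sub = pca.scores.xs(row["genotype"], level="genotype")["PC1"]
        out.append(
            HSIProfile(
                genotype=row["genotype"],
                pc1_scores=sub,
                hsi=float(row["hsi"]),
                intercept=float(row["intercept"]),
            )
        )
    return out
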