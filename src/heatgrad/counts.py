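"""Count-matrix handling: I/O, CPM filtering, TMM normalization, dispersion.

The count matrix is a genes x samples table of non-negative integers with
a sample-metadata table (genotype, heat level, replication, library size).
Poorly expressed genes are removed with the standard CPM rule (at least
``min_cpm`` counts per million in at least ``min_samples`` samples, both
inclusive).  Library composition is normalized with trimmed-mean-of-M-
values (TMM) factors.  Biological variability between replicates is
summarized by a single common negative-binomial dispersion ``phi``; the
biological coefficient of variation is ``BCV = sqrt(phi)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._nbglm import nb_irls, nb_loglik
from .heat_index import PCAResult

META_COLUMNS = ("sample", "genotype", "heat_c", "rep", "lib_size")


def read_counts(path) -> pd.DataFrame:
    """Read a gene x sample count TSV (first column = gene IDs)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    validate_counts(df)
    return df


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene")


def validate_counts(counts: pd.DataFrame) -> None:
    if counts.index.duplicated().any():
        raise ValueError("duplicate gene IDs in count matrix")
    if counts.columns.duplicated().any():
        raise ValueError("duplicate sample IDs in count matrix")
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative entries in count matrix")


def read_sample_meta(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t")
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"sample metadata lacks columns: {missing}")
    return meta.set_index("sample", drop=False)


def write_sample_meta(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def check_meta_covers(counts: pd.DataFrame, meta: pd.DataFrame) -> None:
    missing = [s for s in counts.columns if s not in meta.index]
    if missing:
        raise ValueError(f"samples without metadata: {missing}")


def _lib_sizes(counts: pd.DataFrame, lib_sizes=None) -> pd.Series:
    if lib_sizes is None:
        lib_sizes = counts.sum(axis=0)
    lib_sizes = pd.Series(lib_sizes, index=counts.columns).astype(float)
    if (lib_sizes <= 0).any():
        bad = list(lib_sizes.index[lib_sizes <= 0])
        raise ValueError(f"zero/negative library sizes for samples: {bad}")
    return lib_sizes


def cpm(
    counts: pd.DataFrame, lib_sizes=None, norm_factors=None
) -> pd.DataFrame:
    """Counts per million of effective library size (lib_size x factor)."""
    lib = _lib_sizes(counts, lib_sizes)
    if norm_factors is not None:
        lib = lib * pd.Series(norm_factors, index=counts.columns).astype(float)
    return counts / lib * 1e6


def cpm_filter(
    counts: pd.DataFrame,
    lib_sizes=None,
    norm_factors=None,
    min_cpm: float = 2.0,
    min_samples: int = 2,
) -> tuple[pd.DataFrame, list]:
    """Keep genes with >= ``min_cpm`` CPM in >= ``min_samples`` samples.

    Both bounds are inclusive ("at least").  Returns (kept matrix, list of
    dropped gene IDs).
    """
    if min_cpm <= 0 or min_samples <= 0:
        raise ValueError("cpm_filter thresholds must be positive")
    C = cpm(counts, lib_sizes, norm_factors)
    keep = (C >= min_cpm).sum(axis=1) >= min_samples
    return counts.loc[keep], list(counts.index[~keep])


def tmm_factors(
    counts: pd.DataFrame,
    lib_sizes=None,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors.

    The reference sample is the one whose upper-quartile count proportion
    is closest to the mean upper quartile.  For each sample, gene-wise
    log2 ratios (M) against the reference are trimmed by ``trim_m`` on M
    and ``trim_a`` on average log intensity (A), then averaged with
    inverse asymptotic-variance weights.  Factors are rescaled so their
    geometric mean is 1.
    """
    lib = _lib_sizes(counts, lib_sizes)
    if counts.shape[1] < 2:
        raise ValueError("TMM needs >= 2 samples")
    Y = counts.to_numpy(dtype=float)
    L = lib.to_numpy()
    P = Y / L[None, :]
    f75 = np.quantile(P, 0.75, axis=0)
    if f75.max() < 1e-20:
        ref = int(np.argmax(Y.sum(axis=0)))
    else:
        ref = int(np.argmin(np.abs(f75 - f75.mean())))

    log_factors = np.zeros(counts.shape[1])
    for s in range(counts.shape[1]):
        if s == ref:
            continue
        log_factors[s] = _tmm_pair(
            Y[:, s], Y[:, ref], L[s], L[ref], trim_m, trim_a, counts.columns[s]
        )
    factors = 2.0 ** log_factors
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="norm_factor")


def _tmm_pair(obs, ref, lib_obs, lib_ref, trim_m, trim_a, label) -> float:
    mask = (obs > 0) & (ref > 0)
    if not mask.any():
        warnings.warn(f"sample {label!r} shares no expressed genes with the "
                      "reference; TMM factor set to 1")
        return 0.0
    o, r = obs[mask], ref[mask]
    po, pr = o / lib_obs, r / lib_ref
    M = np.log2(po / pr)
    A = 0.5 * np.log2(po * pr)
    # delta-method precision weights for the log ratio
    v = (lib_obs - o) / (lib_obs * o) + (lib_ref - r) / (lib_ref * r)

    n = len(M)
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rm = stats.rankdata(M)
    ra = stats.rankdata(A)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep.any() or np.sum(1.0 / v[keep]) == 0.0:
        return 0.0
    f = np.sum(M[keep] / v[keep]) / np.sum(1.0 / v[keep])
    if not np.isfinite(f):
        return 0.0
    return f


@dataclass
class DispersionEstimate:
    phi_common: float
    bcv: float


def common_dispersion(
    counts: pd.DataFrame,
    groups=None,
    lib_sizes=None,
    norm_factors=None,
    design: np.ndarray | None = None,
    bounds: tuple = (1e-6, 10.0),
) -> DispersionEstimate:
    """Single NB dispersion shared by all genes, by adjusted profile likelihood.

    For a candidate ``phi`` the per-gene means are profiled by refitting
    each gene's GLM at the supplied design (default: one parameter per
    experimental group, e.g. genotype x heat level cell), and the summed
    Cox-Reid adjusted log-likelihood is evaluated.  ``phi`` maximizes this
    criterion by a bounded 1-D search on ``log phi`` over ``bounds``.

    ``groups`` is a per-sample label sequence (ignored when an explicit
    ``design`` matrix is given).  BCV = sqrt(phi).
    """
    Y = counts.to_numpy(dtype=float)
    lib = _lib_sizes(counts, lib_sizes)
    eff = lib.to_numpy().copy()
    if norm_factors is not None:
        eff = eff * pd.Series(norm_factors, index=counts.columns).to_numpy()
    offset = np.log(eff)

    if design is None:
        if groups is None:
            raise ValueError("common_dispersion needs groups or a design matrix")
        labels = np.asarray(list(groups))
        cats = np.unique(labels)
        design = (labels[:, None] == cats[None, :]).astype(float)
    design = np.asarray(design, dtype=float)
    n, p = design.shape
    if n - np.linalg.matrix_rank(design) <= 0:
        raise ValueError("no residual degrees of freedom under this design")

    # drop all-zero genes: their profiled likelihood is flat in phi
    nz = Y.sum(axis=1) > 0
    Ynz = Y[nz]
    state = {"beta": None}

    def neg_apl(log_phi: float) -> float:
        phi = float(np.exp(log_phi))
        fit = nb_irls(Ynz, design, offset, phi, beta0=state["beta"])
        state["beta"] = fit.beta
        apl = fit.loglik - 0.5 * fit.xtwx_logdet
        return -float(apl.sum())

    res = optimize.minimize_scalar(
        neg_apl,
        bounds=(np.log(bounds[0]), np.log(bounds[1])),
        method="bounded",
        options={"xatol": 1e-4},
    )
    phi = float(np.exp(res.x))
    return DispersionEstimate(phi_common=phi, bcv=float(np.sqrt(phi)))


def expression_pca(
    counts: pd.DataFrame,
    lib_sizes=None,
    norm_factors=None,
    pseudo: float = 1.0,
    n_top: int | None = None,
) -> PCAResult:
    """Sample-level PCA of log2(normalized CPM + pseudo).

    Genes (features) are centered; samples are the observations being
    scored.  ``n_top`` optionally restricts to the N most variable genes.
    """
    if counts.shape[1] < 2:
        raise ValueError("expression PCA needs >= 2 samples")
    logcpm = np.log2(cpm(counts, lib_sizes, norm_factors) + pseudo)
    if n_top is not None:
        var = logcpm.var(axis=1)
        logcpm = logcpm.loc[var.sort_values(ascending=False).index[:n_top]]
    M = logcpm.to_numpy().T  # samples x genes
    from sklearn.decomposition import PCA

    k = min(M.shape[0] - 1, M.shape[1])
    k = max(k, 1)
    pca = PCA(n_components=k)
    scores = pca.fit_transform(M - M.mean(axis=0))
    pcs = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return PCAResult(
        scores=pd.DataFrame(scores, index=counts.columns, columns=pcs),
        loadings=pd.DataFrame(pca.components_.T, index=logcpm.index, columns=pcs),
        explained_frac=pd.Series(pca.explained_variance_ratio_, index=pcs),
    )
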