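"""End-to-end synthetic pipeline runner and plain-text reporting.

``run_pipeline`` chains every stage on simulated inputs: phenotype
simulation -> adjusted means -> repeatability -> combined-model tests ->
phenotype PCA / HSI -> (optional FASTQ QC exercise) -> count simulation
-> CPM filter -> TMM -> common dispersion -> expression PCA -> overall
and per-genotype dose-response fits -> overlaps -> tolerance regression
-> clustering -> enrichment.  Every stage writes a TSV artifact; a run
manifest (config hash, seed, package version) and a summary close the
run.  All randomness derives from the single config seed.

Count simulation plants its tolerance-gene slopes against the HSI values
*estimated* in the phenotype stage, so the planted ``delta`` and the
calling threshold live on the same scale.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, counts as counts_mod, dge, enrichment, heat_index, phenotype, sequtil, synthetic


@dataclass
class PipelineConfig:
    """Thresholds, sizes and switches for a full synthetic run."""

    seed: int = 0
    n_genotypes: int = 8
    heat_levels: tuple = (25.0, 32.0, 38.0)
    n_pheno_reps: int = 10
    n_genes: int = 2000
    n_count_reps: int = 2
    drop_one_sample: bool = True
    bcv: float = 0.26
    frac_responsive: float = 0.10
    frac_tolerance: float = 0.02
    slope_magnitude: float = 4.0
    delta_magnitude: float = 4.0
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 1.0
    baseline_log2_min: float | None = None
    # analysis thresholds
    fdr_max: float = 0.05
    lfc_min: float = 2.0
    p_max: float = 0.05
    delta_min: float = 2.0
    min_cpm: float = 2.0
    min_samples: int = 2
    q_threshold: int = 20
    max_lowq_frac: float = 0.30
    # modes
    coding_axis: str = "coding"
    pca_standardize: bool = True
    eq5_intercepts: str = "per_genotype"
    # QC exercise
    n_qc_reads: int = 500
    qc_frac_lowq: float = 0.1
    qc_frac_adapter: float = 0.1
    qc_adapter: str = "AGATCGGAAGAGC"

    def __post_init__(self):
        for name in ("fdr_max", "lfc_min", "p_max", "delta_min", "min_cpm",
                     "min_samples", "q_threshold", "max_lowq_frac"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")
        self.heat_levels = tuple(float(t) for t in self.heat_levels)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _seeds(seed: int) -> dict:
    """Deterministic per-stage seed fan-out from the master seed."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(4)
    names = ["pheno", "counts", "fastq", "annotation"]
    return {n: int(c.generate_state(1)[0] % (2**31)) for n, c in zip(names, children)}


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute every stage; returns a summary dict (also written to disk)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _seeds(config.seed)
    summary: dict = {"seed": config.seed}

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:  # pragma: no cover - abort path
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return wrap

    # --- phenotype stage -------------------------------------------------
    pheno_cfg, planted_s = synthetic.make_heat_stress_pheno_config(
        seed=seeds["pheno"],
        n_genotypes=config.n_genotypes,
        heat_levels=config.heat_levels,
        n_reps=config.n_pheno_reps,
    )
    pheno = stage("simulate-pheno")(lambda: synthetic.simulate_phenotypes(pheno_cfg))
    phenotype.write_phenotypes(pheno, out / "phenotypes.tsv")
    pd.DataFrame({"genotype": pheno_cfg.genotypes, "planted_susceptibility": planted_s}).to_csv(
        out / "planted_susceptibility.tsv", sep="\t", index=False
    )

    means = stage("pheno-means")(lambda: phenotype.adjusted_means_table(pheno))
    means.to_csv(out / "adjusted_means.tsv", sep="\t", index=False)

    rep_table = stage("repeatability")(lambda: phenotype.repeatability_table(pheno))
    rep_table.to_csv(out / "repeatability.tsv", sep="\t", index=False)

    tests = []
    for trait in pheno_cfg.traits:
        fit = phenotype.combined_model_tests(pheno, trait)
        t = fit.tests.copy()
        t.insert(0, "trait", trait)
        tests.append(t)
    pd.concat(tests).to_csv(out / "combined_model_tests.tsv", sep="\t", index=False)

    # --- HSI stage -------------------------------------------------------
    coding = heat_index.metric_heat_coding(config.heat_levels)
    pca = stage("hsi")(lambda: heat_index.pca_means(means, standardize=config.pca_standardize))
    pca.scores.reset_index().to_csv(out / "pheno_pca_scores.tsv", sep="\t", index=False)
    pca.loadings.reset_index(names="trait").to_csv(out / "pheno_pca_loadings.tsv", sep="\t", index=False)
    pca.explained_frac.rename("explained_frac").to_csv(out / "pheno_pca_explained.tsv", sep="\t")
    trait_corr = heat_index.correlate_traits_pc1(means, pca)
    trait_corr.to_csv(out / "trait_pc1_correlations.tsv", sep="\t", index=False)
    hsi = heat_index.hsi_compute(pca, coding, axis=config.coding_axis)
    hsi.to_csv(out / "hsi.tsv", sep="\t", index=False)
    summary["hsi_range"] = [float(hsi["hsi"].min()), float(hsi["hsi"].max())]
    summary["pheno_pc1_explained_pct"] = float(pca.explained_frac["PC1"] * 100)

    # --- FASTQ QC exercise ----------------------------------------------
    if config.n_qc_reads > 0:
        reads, read_truth = synthetic.simulate_fastq(
            config.n_qc_reads,
            frac_lowq=config.qc_frac_lowq,
            adapters=(config.qc_adapter,),
            frac_adapter=config.qc_frac_adapter,
            seed=seeds["fastq"],
        )
        sequtil.write_fastq(reads, out / "reads.fastq")
        kept, qc_report = sequtil.filter_reads(
            reads,
            q_threshold=config.q_threshold,
            max_lowq_frac=config.max_lowq_frac,
            adapters=(config.qc_adapter,),
        )
        sequtil.write_fastq(kept, out / "reads.kept.fastq")
        qc_report.to_frame().to_csv(out / "qc_report.tsv", sep="\t", index=False)
        summary["reads_kept"] = qc_report.kept
        summary["reads_total"] = qc_report.total

    # --- counts stage ----------------------------------------------------
    hsi_by_geno = hsi.set_index("genotype")["hsi"].reindex(list(pheno_cfg.genotypes))
    counts_cfg = synthetic.CountsSimConfig(
        genotypes=tuple(pheno_cfg.genotypes),
        hsi=hsi_by_geno.to_numpy(),
        heat_levels=config.heat_levels,
        n_reps=config.n_count_reps,
        n_genes=config.n_genes,
        bcv=config.bcv,
        frac_responsive=config.frac_responsive,
        frac_tolerance=config.frac_tolerance,
        slope_magnitude=config.slope_magnitude,
        delta_magnitude=config.delta_magnitude,
        baseline_log2_mean=config.baseline_log2_mean,
        baseline_log2_sd=config.baseline_log2_sd,
        baseline_log2_min=config.baseline_log2_min,
        drop_one_sample=config.drop_one_sample,
        seed=seeds["counts"],
    )
    counts, meta, truth = stage("simulate-counts")(lambda: synthetic.simulate_counts(counts_cfg))
    counts_mod.write_counts(counts, out / "counts.tsv")
    counts_mod.write_sample_meta(meta, out / "sample_meta.tsv")
    truth.genes.reset_index().to_csv(out / "truth_genes.tsv", sep="\t", index=False)
    summary["n_samples"] = counts.shape[1]

    kept_counts, dropped = stage("filter-counts")(
        lambda: counts_mod.cpm_filter(counts, min_cpm=config.min_cpm, min_samples=config.min_samples)
    )
    counts_mod.write_counts(kept_counts, out / "counts.filtered.tsv")
    summary["n_genes_input"] = int(counts.shape[0])
    summary["n_genes_kept"] = int(kept_counts.shape[0])

    factors = stage("normalize")(lambda: counts_mod.tmm_factors(kept_counts))
    factors.rename_axis("sample").reset_index().to_csv(out / "norm_factors.tsv", sep="\t", index=False)

    groups = meta.loc[kept_counts.columns].apply(
        lambda r: f"{r['genotype']}@{r['heat_c']:g}", axis=1
    )
    disp = stage("dispersion")(
        lambda: counts_mod.common_dispersion(kept_counts, groups=groups, norm_factors=factors)
    )
    summary["bcv_estimate"] = float(disp.bcv)
    pd.DataFrame([{"phi_common": disp.phi_common, "bcv": disp.bcv}]).to_csv(
        out / "dispersion.tsv", sep="\t", index=False
    )

    expr_pca = counts_mod.expression_pca(kept_counts, norm_factors=factors)
    expr_pca.scores.reset_index(names="sample").to_csv(out / "expression_pca_scores.tsv", sep="\t", index=False)
    summary["expr_pc1_explained_pct"] = float(expr_pca.explained_frac["PC1"] * 100)

    # --- differential expression -----------------------------------------
    fits = stage("dge-overall")(
        lambda: dge.fit_dose_response_overall(kept_counts, meta, coding, disp.phi_common, norm_factors=factors)
    )
    up, down = dge.call_significant(fits, config.fdr_max, config.lfc_min)
    fits_out = fits.copy()
    fits_out["call"] = "none"
    fits_out.loc[up, "call"] = "up"
    fits_out.loc[down, "call"] = "down"
    fits_out.reset_index().to_csv(out / "dge_overall.tsv", sep="\t", index=False)
    summary["n_up"] = len(up)
    summary["n_down"] = len(down)
    summary["n_responsive_called"] = len(up) + len(down)

    slopes = stage("dge-per-genotype")(
        lambda: dge.fit_dose_response_per_genotype(
            kept_counts, meta, coding, disp.phi_common,
            norm_factors=factors, intercepts=config.eq5_intercepts,
        )
    )
    slopes.gamma_log2.reset_index().to_csv(out / "gamma_matrix.tsv", sep="\t", index=False)
    slopes.fdr.reset_index().to_csv(out / "gamma_fdr.tsv", sep="\t", index=False)

    calls = dge.per_genotype_calls(slopes, config.fdr_max, config.lfc_min)
    per_geno = pd.DataFrame(
        {
            "genotype": list(calls),
            "n_up": [len(u) for u, _ in calls.values()],
            "n_down": [len(d) for _, d in calls.values()],
        }
    )
    per_geno.to_csv(out / "per_genotype_calls.tsv", sep="\t", index=False)

    ranked = hsi.sort_values("hsi")["genotype"].tolist()
    half = len(ranked) // 2
    group_map = {
        "all": list(calls),
        "tolerant": ranked[:half],
        "susceptible": ranked[-half:] if half else [],
    }
    group_map = {k: v for k, v in group_map.items() if v}
    overlaps = stage("overlaps")(lambda: dge.overlap_sets(calls, group_map))
    overlaps.to_csv(out / "overlaps.tsv", sep="\t", index=False)
    all_row = overlaps[overlaps["group"] == "all"].iloc[0]
    summary["n_common_up"] = int(all_row["n_up_common"])
    summary["n_common_down"] = int(all_row["n_down_common"])

    tol = stage("tolerance")(
        lambda: dge.tolerance_regression(slopes.gamma_log2, hsi, config.p_max, config.delta_min)
    )
    called = tol.index[tol["called"]]
    clusters, leaf_order = dge.cluster_tolerance_genes(slopes.gamma_log2.loc[called])
    tol_out = tol.copy()
    tol_out["cluster"] = clusters.reindex(tol_out.index).astype("Int64")
    tol_out.reset_index().to_csv(out / "tolerance.tsv", sep="\t", index=False)
    if len(leaf_order):
        slopes.gamma_log2.loc[leaf_order].reset_index().to_csv(
            out / "tolerance_heatmap_matrix.tsv", sep="\t", index=False
        )
    summary["n_tolerance_called"] = int(tol["called"].sum())
    summary["tolerance_cluster_sizes"] = (
        clusters.value_counts().sort_index().tolist() if len(clusters) else []
    )

    # --- enrichment -------------------------------------------------------
    ann = synthetic.simulate_annotation(
        kept_counts.index, truth=truth, seed=seeds["annotation"]
    )
    enrichment.write_annotation(ann, out / "annotation.tsv")
    universe = list(kept_counts.index)
    enr_up = stage("enrich")(
        lambda: enrichment.hypergeom_enrich(up, ann, universe, config.fdr_max)
    )
    enr_down = enrichment.hypergeom_enrich(down, ann, universe, config.fdr_max)
    enr_up.to_csv(out / "enrichment_up.tsv", sep="\t", index=False)
    enr_down.to_csv(out / "enrichment_down.tsv", sep="\t", index=False)
    summary["n_terms_enriched_up"] = int(enr_up["enriched"].sum()) if len(enr_up) else 0
    summary["n_terms_enriched_down"] = int(enr_down["enriched"].sum()) if len(enr_down) else 0

    # --- recovery vs planted truth ---------------------------------------
    truth_kept = truth.genes.loc[kept_counts.index]
    resp = truth_kept.index[truth_kept["status"] == "responsive"]
    called_set = set(up) | set(down)
    if len(resp):
        summary["responsive_sensitivity"] = float(
            len(called_set & set(resp)) / len(resp)
        )
    nulls = set(truth_kept.index[truth_kept["status"] == "null"])
    if called_set:
        summary["responsive_fdp"] = float(
            len(called_set & nulls) / len(called_set)
        )
    tol_true = set(truth_kept.index[truth_kept["status"] == "tolerance"])
    if tol_true:
        summary["tolerance_sensitivity"] = float(
            len(set(called) & tol_true) / len(tol_true)
        )
    s_series = pd.Series(planted_s, index=list(pheno_cfg.genotypes))
    merged = hsi.set_index("genotype").join(s_series.rename("s"))
    summary["hsi_spearman_vs_planted"] = float(
        merged["hsi"].rank().corr(merged["s"].rank())
    )

    # --- manifest + summary ----------------------------------------------
    manifest = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stage_seeds": seeds,
        "config": asdict(config),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    with open(out / "summary.txt", "w") as fh:
        for k, v in summary.items():
            fh.write(f"{k}\t{v}\n")
    return summary


def write_report(artifact_dir, report_path=None) -> str:
    """Assemble a plain-text report from a completed run's artifacts.

    Mirrors the study's reporting surfaces: repeatability per trait and
    level, HSI ranking, per-genotype up/down counts with overlaps, the
    tolerance-gene table, and enrichment.  Missing stage outputs are
    listed as absent rather than fatal.
    """
    art = Path(artifact_dir)
    lines = ["# heatgrad run report", ""]

    def section(title, fname, formatter):
        lines.append(f"## {title}")
        path = art / fname
        if not path.exists():
            lines.append(f"[absent: {fname}]")
        else:
            formatter(pd.read_csv(path, sep="\t"))
        lines.append("")

    section(
        "Repeatability (trait x heat level)",
        "repeatability.tsv",
        lambda df: lines.extend(
            df.pivot_table(index="trait", columns="heat_c", values="H2")
            .round(3)
            .to_string()
            .splitlines()
        ),
    )
    section(
        "Heat susceptibility index ranking (most susceptible first)",
        "hsi.tsv",
        lambda df: lines.extend(
            df.sort_values("rank")[["rank", "genotype", "hsi"]]
            .round({"hsi": 3})
            .to_string(index=False)
            .splitlines()
        ),
    )
    section(
        "Per-genotype responsive gene counts",
        "per_genotype_calls.tsv",
        lambda df: lines.extend(df.to_string(index=False).splitlines()),
    )
    section(
        "Overlaps (common responsive genes)",
        "overlaps.tsv",
        lambda df: lines.extend(
            df[["group", "n_genotypes", "n_up_common", "n_down_common"]]
            .to_string(index=False)
            .splitlines()
        ),
    )

    def tol_fmt(df):
        called = df[df["called"] == True]  # noqa: E712 - TSV bools
        lines.append(f"called tolerance genes: {len(called)}")
        if len(called):
            lines.extend(
                called[["gene", "delta", "p_value", "cluster"]]
                .round({"delta": 2, "p_value": 4})
                .to_string(index=False)
                .splitlines()
            )

    section("Heat tolerance genes", "tolerance.tsv", tol_fmt)

    def enr_fmt(df):
        hits = df[df["enriched"] == True]  # noqa: E712
        lines.append(f"enriched terms: {len(hits)}")
        if len(hits):
            lines.extend(
                hits[["term", "k", "n", "fold", "fdr"]]
                .round({"fold": 2, "fdr": 4})
                .to_string(index=False)
                .splitlines()
            )

    section("Enrichment (upregulated set)", "enrichment_up.tsv", enr_fmt)
    section("Enrichment (downregulated set)", "enrichment_down.tsv", enr_fmt)

    text = "\n".join(lines)
    report_path = Path(report_path) if report_path else art / "report.txt"
    report_path.write_text(text)
    return text
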