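import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def balanced_pheno():
    """Small balanced phenotype table with known structure (2 traits)."""
    rng = np.random.default_rng(42)
    rows = []
    genos = [f"g{i}" for i in range(4)]
    for trait, scale in (("ta", 1.0), ("tb", 3.0)):
        for j, heat in enumerate((25.0, 32.0, 38.0)):
            for k in range(1, 5):
                block = rng.normal(0, 0.5)
                for i, g in enumerate(genos):
                    rows.append(
                        {
                            "genotype": g,
                            "heat_c": heat,
                            "rep": k,
                            "trait": trait,
                            "value": scale * (10 + i - 0.8 * j * i)
                            + block
                            + rng.normal(0, 1.0),
                        }
                    )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def sim_counts_default():
    """A moderately sized simulated count experiment shared across tests."""
    from heatgrad import synthetic

    cfg = synthetic.CountsSimConfig(
        seed=11,
        n_genes=1200,
        drop_one_sample=True,
        baseline_log2_mean=8.0,
        baseline_log2_sd=1.0,
        baseline_log2_min=float(np.log2(50)),
    )
    counts, meta, truth = synthetic.simulate_counts(cfg)
    return cfg, counts, meta, truth


@pytest.fixture(scope="session")
def fitted_default(sim_counts_default):
    """Filter + TMM + dispersion + overall fit on the shared simulation."""
    from heatgrad import counts as cmod, dge, heat_index

    cfg, counts, meta, truth = sim_counts_default
    kept, _ = cmod.cpm_filter(counts)
    factors = cmod.tmm_factors(kept)
    groups = meta.loc[kept.columns].apply(
        lambda r: f"{r['genotype']}@{r['heat_c']:g}", axis=1
    )
    disp = cmod.common_dispersion(kept, groups=groups, norm_factors=factors)
    coding = heat_index.metric_heat_coding(cfg.heat_levels)
    fits = dge.fit_dose_response_overall(
        kept, meta, coding, disp.phi_common, norm_factors=factors
    )
    return dict(
        cfg=cfg,
        counts=kept,
        meta=meta,
        truth=truth,
        factors=factors,
        disp=disp,
        coding=coding,
        fits=fits,
    )
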