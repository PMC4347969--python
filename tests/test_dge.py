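"""Dose-response GLM, calling, overlaps, tolerance regression, clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from heatgrad import counts as cmod, dge, heat_index, synthetic
from heatgrad._nbglm import nb_irls

CODING = heat_index.metric_heat_coding([25, 32, 38])


def _meta(samples, genotypes, heats, lib):
    return pd.DataFrame(
        {
            "sample": samples,
            "genotype": genotypes,
            "heat_c": heats,
            "rep": 1,
            "lib_size": lib,
        }
    ).set_index("sample", drop=False)


class TestOverallFit:
    def test_two_level_poisson_closed_form(self):
        """phi=0, x in {0,1}, equal libraries: slope = log2 of group-mean ratio."""
        rng = np.random.default_rng(0)
        coding = heat_index.metric_heat_coding([25, 38])
        n_per = 6
        samples = [f"s{i}" for i in range(2 * n_per)]
        heats = [25.0] * n_per + [38.0] * n_per
        meta = _meta(samples, ["g1"] * 2 * n_per, heats, 1e6)
        mu0, fold = 200.0, 5.0
        Y = np.concatenate(
            [rng.poisson(mu0, (40, n_per)), rng.poisson(mu0 * fold, (40, n_per))],
            axis=1,
        )
        C = pd.DataFrame(Y, index=[f"g{i}" for i in range(40)], columns=samples)
        fits = dge.fit_dose_response_overall(C, meta, coding, phi=0.0)
        expect = np.log2(Y[:, n_per:].mean(axis=1) / Y[:, :n_per].mean(axis=1))
        np.testing.assert_allclose(fits["beta_log2"].to_numpy(), expect, atol=1e-6)

    def test_flat_gene_zero_slope(self):
        samples = [f"s{i}" for i in range(6)]
        meta = _meta(samples, ["g1"] * 6, [25.0, 25.0, 32.0, 32.0, 38.0, 38.0], 1e6)
        C = pd.DataFrame([[100] * 6], index=["flat"], columns=samples)
        fits = dge.fit_dose_response_overall(C, meta, CODING, phi=0.05)
        assert fits.loc["flat", "beta_log2"] == pytest.approx(0.0, abs=1e-6)

    def test_all_zero_gene_gets_null_result(self):
        samples = [f"s{i}" for i in range(6)]
        meta = _meta(samples, ["g1"] * 6, [25.0, 25.0, 32.0, 32.0, 38.0, 38.0], 1e6)
        C = pd.DataFrame([[0] * 6, [5, 6, 7, 9, 12, 15]], index=["z", "nz"], columns=samples)
        fits = dge.fit_dose_response_overall(C, meta, CODING, phi=0.05)
        assert fits.loc["z", "beta_log2"] == 0.0 and fits.loc["z", "p_value"] == 1.0

    def test_null_pvalues_uniform(self):
        """1,000 null genes at bcv 0.26: LRT p uniform, few BH calls."""
        cfg = synthetic.CountsSimConfig(
            seed=21,
            n_genes=1000,
            frac_responsive=0.0,
            frac_tolerance=0.0,
            baseline_log2_mean=7.0,
            baseline_log2_sd=1.0,
        )
        C, meta, _ = synthetic.simulate_counts(cfg)
        groups = meta.loc[C.columns].apply(
            lambda r: f"{r['genotype']}@{r['heat_c']:g}", axis=1
        )
        disp = cmod.common_dispersion(C, groups=groups)
        fits = dge.fit_dose_response_overall(C, meta, CODING, disp.phi_common)
        ks = stats.kstest(fits["p_value"].to_numpy(), "uniform")
        assert ks.pvalue > 0.01
        up, down = dge.call_significant(fits)
        assert (len(up) + len(down)) <= 0.01 * len(fits)

    def test_poisson_limit_equals_poisson_glm(self):
        """NB IRLS at phi=0 against statsmodels Poisson GLM, 50-gene toy."""
        import statsmodels.api as sm

        rng = np.random.default_rng(1)
        x = np.tile([0.0, 7.0 / 13.0, 1.0], 8)
        X = np.column_stack([np.ones_like(x), x])
        off = np.log(rng.uniform(0.8e6, 1.2e6, len(x)))
        mu = np.exp(off[None, :] - 10 + rng.normal(0, 1, (50, 1)) * x[None, :])
        Y = rng.poisson(mu).astype(float)
        fit = nb_irls(Y, X, off, 0.0)
        for g in range(50):
            ref = sm.GLM(Y[g], X, family=sm.families.Poisson(), offset=off).fit()
            np.testing.assert_allclose(fit.beta[g], ref.params, atol=1e-6)

    def test_sample_order_invariance(self, fitted_default):
        d = fitted_default
        perm = np.random.default_rng(0).permutation(d["counts"].columns)
        fits2 = dge.fit_dose_response_overall(
            d["counts"][perm], d["meta"], d["coding"], d["disp"].phi_common,
            norm_factors=d["factors"][perm],
        )
        np.testing.assert_allclose(
            d["fits"]["beta_log2"].to_numpy(), fits2["beta_log2"].to_numpy(), atol=1e-7
        )


class TestCallSignificant:
    def test_boundary_slope_exactly_two_not_called(self):
        fits = pd.DataFrame(
            {"beta_log2": [2.0, 2.1], "fdr": [0.01, 0.01], "converged": True},
            index=["at", "above"],
        )
        up, down = dge.call_significant(fits)
        assert up == ["above"] and down == []

    def test_empty_input_empty_output(self):
        fits = pd.DataFrame(columns=["beta_log2", "fdr", "converged"])
        assert dge.call_significant(fits) == ([], [])

    def test_bh_matches_brute_force_enumeration(self):
        """BH ranks/calls identical to a directly coded step-up on <=10 genes."""
        rng = np.random.default_rng(2)
        for _ in range(20):
            m = int(rng.integers(3, 11))
            p = np.round(rng.uniform(0, 0.3, m), 4)
            from statsmodels.stats.multitest import multipletests

            ours = multipletests(p, method="fdr_bh")[1]
            order = np.argsort(p, kind="stable")
            adj = np.empty(m)
            running = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                running = min(running, p[i] * m / rank)
                adj[i] = running
            np.testing.assert_allclose(ours, adj, atol=1e-12)


class TestPerGenotypeFit:
    def test_recovers_planted_contrasting_slopes(self):
        """gamma=+3 for one genotype, 0 for the other, high depth."""
        rng = np.random.default_rng(3)
        coding = heat_index.metric_heat_coding([25, 32, 38])
        samples, genos, heats = [], [], []
        for g in ("A", "B"):
            for h in (25.0, 32.0, 38.0):
                for r in range(4):
                    samples.append(f"{g}{h:g}r{r}")
                    genos.append(g)
                    heats.append(h)
        meta = _meta(samples, genos, heats, 1e6)
        x = coding.code(np.array(heats))
        gam = {"A": 3.0, "B": 0.0}
        mu = np.array(
            [500.0 * 2 ** (gam[g] * xi) for g, xi in zip(genos, x)]
        )
        Y = rng.negative_binomial(1 / 0.04, (1 / 0.04) / (1 / 0.04 + mu), (60, len(x)))
        C = pd.DataFrame(Y, index=[f"gene{i}" for i in range(60)], columns=samples)
        slopes = dge.fit_dose_response_per_genotype(C, meta, coding, phi=0.04)
        assert slopes.gamma_log2["A"].mean() == pytest.approx(3.0, abs=0.3)
        assert abs(slopes.gamma_log2["B"].mean()) <= 0.3

    def test_single_genotype_reduces_to_overall_fit(self, fitted_default):
        d = fitted_default
        geno = d["meta"]["genotype"].iloc[0]
        keep = d["meta"].index[d["meta"]["genotype"] == geno]
        sub = d["counts"][list(keep)].head(120)
        slopes = dge.fit_dose_response_per_genotype(
            sub, d["meta"], d["coding"], d["disp"].phi_common,
            norm_factors=d["factors"][list(keep)],
        )
        overall = dge.fit_dose_response_overall(
            sub, d["meta"], d["coding"], d["disp"].phi_common,
            norm_factors=d["factors"][list(keep)],
        )
        np.testing.assert_allclose(
            slopes.gamma_log2[geno].to_numpy(),
            overall["beta_log2"].to_numpy(),
            atol=1e-6,
        )
        np.testing.assert_allclose(
            slopes.p_value[geno].to_numpy(), overall["p_value"].to_numpy(), atol=1e-6
        )

    def test_level_independent_genotype_has_zero_slope(self):
        samples = [f"s{i}" for i in range(6)]
        meta = _meta(samples, ["A"] * 6, [25.0, 25.0, 32.0, 32.0, 38.0, 38.0], 1e6)
        C = pd.DataFrame([[80] * 6], index=["flat"], columns=samples)
        slopes = dge.fit_dose_response_per_genotype(C, meta, CODING, phi=0.05)
        assert slopes.gamma_log2.loc["flat", "A"] == pytest.approx(0.0, abs=1e-6)


class TestOverlaps:
    CALLS = {
        "A": (["g1", "g2", "g3"], ["d1"]),
        "B": (["g2", "g3"], ["d1", "d2"]),
        "C": (["g3"], []),
    }

    def test_manual_set_algebra(self):
        out = dge.overlap_sets(self.CALLS, {"all": list("ABC"), "pair": list("AB")})
        all_row = out.set_index("group").loc["all"]
        assert all_row["n_up_common"] == 1 and all_row["up_genes"] == "g3"
        assert all_row["n_down_common"] == 0
        pair = out.set_index("group").loc["pair"]
        assert pair["n_up_common"] == 2 and pair["n_down_common"] == 1

    def test_disjoint_and_identical_sets(self):
        calls = {"A": (["x"], []), "B": (["y"], [])}
        out = dge.overlap_sets(calls, {"all": ["A", "B"]})
        assert out.loc[0, "n_up_common"] == 0
        calls = {"A": (["x", "y"], ["z"]), "B": (["x", "y"], ["z"])}
        out = dge.overlap_sets(calls, {"all": ["A", "B"]})
        assert out.loc[0, "n_up_common"] == 2 and out.loc[0, "n_down_common"] == 1

    def test_unknown_genotype_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            dge.overlap_sets(self.CALLS, {"bad": ["A", "Z"]})


class TestToleranceRegression:
    @staticmethod
    def _hsi(h):
        return pd.DataFrame({"genotype": [f"G{i}" for i in range(len(h))], "hsi": h})

    def test_identical_gammas_give_zero_delta(self):
        gamma = pd.DataFrame(
            [[1.5] * 4], index=["g"], columns=[f"G{i}" for i in range(4)]
        )
        out = dge.tolerance_regression(gamma, self._hsi([1.0, 1.2, 1.5, 1.9]))
        assert out.loc["g", "delta"] == pytest.approx(0.0, abs=1e-12)
        assert not out.loc["g", "called"]

    def test_collinear_slope_exactly_two_not_called(self):
        gamma = pd.DataFrame(
            [[1.0, 3.0, 5.0, 7.0]], index=["g"], columns=[f"G{i}" for i in range(4)]
        )
        out = dge.tolerance_regression(gamma, self._hsi([1.0, 2.0, 3.0, 4.0]))
        assert out.loc["g", "delta"] == pytest.approx(2.0, abs=1e-12)
        assert not out.loc["g", "called"]  # strict |delta| > 2

    def test_matches_simple_regression_oracle(self):
        """Random 8-genotype rows against the textbook OLS/t formulas."""
        rng = np.random.default_rng(5)
        h = rng.uniform(0.9, 1.9, 8)
        G = rng.normal(0, 2, (25, 8))
        gamma = pd.DataFrame(G, index=[f"g{i}" for i in range(25)],
                             columns=[f"G{i}" for i in range(8)])
        out = dge.tolerance_regression(gamma, self._hsi(h))
        for i in range(25):
            res = stats.linregress(h, G[i])
            assert out.iloc[i]["delta"] == pytest.approx(res.slope, rel=1e-10)
            assert out.iloc[i]["mu"] == pytest.approx(res.intercept, rel=1e-10)
            assert out.iloc[i]["p_value"] == pytest.approx(res.pvalue, rel=1e-8)

    def test_type_one_error_on_null_genes(self):
        """5,000 null genes through the NB fit + regression: rejection rate
        at alpha=0.05 stays within [0.035, 0.065]."""
        cfg = synthetic.CountsSimConfig(
            seed=22,
            n_genes=5000,
            frac_responsive=0.0,
            frac_tolerance=0.0,
            baseline_log2_mean=7.0,
            baseline_log2_sd=1.0,
        )
        C, meta, truth = synthetic.simulate_counts(cfg)
        groups = meta.loc[C.columns].apply(
            lambda r: f"{r['genotype']}@{r['heat_c']:g}", axis=1
        )
        disp = cmod.common_dispersion(C, groups=groups)
        slopes = dge.fit_dose_response_per_genotype(C, meta, CODING, disp.phi_common)
        hsi = pd.DataFrame({"genotype": truth.hsi.index, "hsi": truth.hsi.to_numpy()})
        out = dge.tolerance_regression(slopes.gamma_log2, hsi)
        rate = (out["p_value"] < 0.05).mean()
        assert 0.035 <= rate <= 0.065

    def test_constant_hsi_rejected(self):
        gamma = pd.DataFrame(
            [[1.0, 2.0, 3.0]], index=["g"], columns=["G0", "G1", "G2"]
        )
        with pytest.raises(ValueError, match="constant"):
            dge.tolerance_regression(gamma, self._hsi([1.0, 1.0, 1.0]))


class TestClustering:
    def test_planted_two_pattern_recovery(self):
        """Up-in-susceptible vs up-in-tolerant patterns: perfect k=2 split."""
        rng = np.random.default_rng(6)
        cols = [f"G{i}" for i in range(8)]
        pattern_a = np.array([4.0] * 4 + [0.0] * 4)
        pattern_b = np.array([0.0] * 4 + [4.0] * 4)
        rows, names = [], []
        for i in range(12):
            rows.append(pattern_a + rng.normal(0, 0.3, 8))
            names.append(f"a{i}")
        for i in range(7):
            rows.append(pattern_b + rng.normal(0, 0.3, 8))
            names.append(f"b{i}")
        gamma = pd.DataFrame(rows, index=names, columns=cols)
        labels, order = dge.cluster_tolerance_genes(gamma, k=2)
        a_labels = set(labels[[n for n in names if n.startswith("a")]])
        b_labels = set(labels[[n for n in names if n.startswith("b")]])
        assert len(a_labels) == 1 and len(b_labels) == 1 and a_labels != b_labels
        assert sorted(order) == sorted(names)

    def test_duplicated_rows_same_cluster(self):
        gamma = pd.DataFrame(
            [[1, 2, 3], [1, 2, 3], [9, 9, 9]],
            index=["a", "a2", "far"],
            columns=["G0", "G1", "G2"],
        )
        labels, _ = dge.cluster_tolerance_genes(gamma, k=2)
        assert labels["a"] == labels["a2"] != labels["far"]

    def test_k_one_single_cluster(self):
        gamma = pd.DataFrame(
            np.random.default_rng(0).normal(size=(5, 3)),
            index=list("abcde"),
            columns=["G0", "G1", "G2"],
        )
        labels, _ = dge.cluster_tolerance_genes(gamma, k=1)
        assert set(labels) == {1}

    def test_single_gene_trivial(self):
        gamma = pd.DataFrame([[1.0, 2.0]], index=["only"], columns=["G0", "G1"])
        labels, order = dge.cluster_tolerance_genes(gamma)
        assert labels["only"] == 1 and order == ["only"]
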