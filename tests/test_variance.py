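"""Variance components: ANOVA oracles, heritability, covariance recovery."""

import numpy as np
import pytest
from scipy import stats as sps

from coldscreen import (
    PanelConfig,
    anova_one_way,
    build_index_matrices,
    descriptive_stats,
    generate_panel,
    genetic_advance,
    genotypic_covariance,
    heritability,
    trait_stats,
    trait_stats_table,
)
from conftest import make_panel


class TestDescriptiveStats:
    def test_constant_panel(self):
        panel = make_panel({"A": {"Y": [3, 3]}, "B": {"Y": [3, 3]}})
        d = descriptive_stats(panel, "Y", "cold")
        assert d == {"min": 3.0, "max": 3.0, "mean": 3.0, "sd": 0.0}

    def test_hand_arithmetic_entry_means(self):
        # entry means {1, 3}: mean 2, sample sd sqrt(2)
        panel = make_panel({"A": {"Y": [0, 2]}, "B": {"Y": [2, 4]}})
        d = descriptive_stats(panel, "Y", "cold")
        assert d["mean"] == pytest.approx(2.0)
        assert d["sd"] == pytest.approx(np.sqrt(2.0))

    def test_absent_trait_raises(self):
        panel = make_panel({"A": {"Y": [1, 2]}})
        with pytest.raises(KeyError):
            descriptive_stats(panel, "Z", "cold")


class TestAnova:
    def test_hand_anova(self):
        # A=(1,2), B=(3,4): grand mean 2.5, SSB = 2*(1.5^2+... ) -> MSG=4, MSE=0.5
        panel = make_panel({"A": {"Y": [1, 2]}, "B": {"Y": [3, 4]}})
        res = anova_one_way(panel, "Y", "cold")
        assert res["MSG"] == pytest.approx(4.0)
        assert res["MSE"] == pytest.approx(0.5)
        assert res["F"] == pytest.approx(8.0)

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(3)
        data = {f"G{i}": {"Y": rng.normal(i * 0.2, 1.0, size=4).tolist()}
                for i in range(6)}
        panel = make_panel(data)
        res = anova_one_way(panel, "Y", "cold")
        groups = [np.array(v["Y"]) for v in data.values()]
        f_ref, p_ref = sps.f_oneway(*groups)
        assert res["F"] == pytest.approx(f_ref)
        assert res["p_value"] == pytest.approx(p_ref)

    def test_identical_observations_warn_nan(self):
        panel = make_panel({"A": {"Y": [2, 2]}, "B": {"Y": [2, 2]}})
        with pytest.warns(UserWarning, match="identical"):
            res = anova_one_way(panel, "Y", "cold")
        assert np.isnan(res["F"])

    def test_single_replicate_rejected(self):
        panel = make_panel({"A": {"Y": [1]}, "B": {"Y": [2]}})
        with pytest.raises(ValueError, match="replicate"):
            anova_one_way(panel, "Y", "cold")

    def test_ss_decomposition(self):
        rng = np.random.default_rng(11)
        data = {f"G{i}": {"Y": rng.normal(size=3).tolist()} for i in range(8)}
        panel = make_panel(data)
        res = anova_one_way(panel, "Y", "cold")
        y = np.array([v["Y"] for v in data.values()])
        ss_total = ((y - y.mean()) ** 2).sum()
        g, r = y.shape
        assert res["MSG"] * (g - 1) + res["MSE"] * (g * (r - 1)) == pytest.approx(ss_total)

    def test_expected_mean_squares(self, single_trait_config):
        # E[MSG] = r*sigma2_g + sigma2_e = 16, E[MSE] = 1 for g=100, r=3
        msgs, mses = [], []
        for seed in range(200):
            panel = generate_panel(single_trait_config(seed=seed))
            res = anova_one_way(panel, "Y", "cold")
            msgs.append(res["MSG"])
            mses.append(res["MSE"])
        assert np.mean(msgs) == pytest.approx(16.0, rel=0.05)
        assert np.mean(mses) == pytest.approx(1.0, rel=0.05)


class TestHeritability:
    @pytest.mark.parametrize("msg,mse,r,expected", [
        (4.0, 0.0, 2, 100.0),       # no error variance
        (4.0, 0.5, 2, 87.5),        # hand arithmetic: sigma2_g=1.75
        (0.5, 4.0, 2, 0.0),         # MSG <= MSE floors to zero
        (1.0, 1.0, 3, 0.0),
    ])
    def test_known_values(self, msg, mse, r, expected):
        assert heritability(msg, mse, r) == pytest.approx(expected)

    def test_plot_basis_lower(self):
        assert heritability(4.0, 0.5, 2, basis="plot") < heritability(4.0, 0.5, 2)

    def test_r_below_two_rejected(self):
        with pytest.raises(ValueError):
            heritability(4.0, 0.5, 1)

    def test_monotone_in_msg_and_r(self):
        h = [heritability(m, 1.0, 3) for m in (1.5, 2.0, 4.0, 8.0)]
        assert h == sorted(h)
        # fixed components sigma2_g=1, sigma2_e=1: H2 rises with replication
        h_r = [100 * 1 / (1 + 1 / r) for r in (2, 3, 5)]
        assert h_r == sorted(h_r)


class TestGeneticAdvance:
    def test_hand_value(self):
        assert genetic_advance(87.5, np.sqrt(2.0), k=2.06) == pytest.approx(2.549, abs=1e-3)

    def test_limits(self):
        assert genetic_advance(0.0, 3.0) == 0.0
        # H2=100%: GA = k * sigma_g (sigma_p equals sigma_g)
        assert genetic_advance(100.0, 2.0, k=2.06) == pytest.approx(4.12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            genetic_advance(50.0, 1.0, k=0.0)
        with pytest.raises(ValueError):
            genetic_advance(50.0, -1.0)


class TestGenotypicCovariance:
    def _panel(self, seed=0):
        rng = np.random.default_rng(seed)
        data = {}
        for i in range(10):
            x = rng.normal(i, 1.0, size=3)
            data[f"G{i}"] = {"X": x.tolist(), "Y": (-x + rng.normal(0, 0.1, 3)).tolist(),
                             "X2": (2 * x).tolist()}
        return make_panel(data), data

    def test_self_covariance_equals_sigma2g(self):
        panel, _ = self._panel()
        cov = genotypic_covariance(panel, "X", "X", "cold")
        st = trait_stats(panel, "X", "cold")
        assert cov == pytest.approx(st.sigma2_g)

    def test_sign_flip(self):
        panel, data = self._panel()
        neg = make_panel({g: {"X": v["X"], "negX": [-x for x in v["X"]]}
                          for g, v in data.items()})
        cov = genotypic_covariance(neg, "X", "negX", "cold")
        # unfloored mirror of sigma2_g
        res = anova_one_way(neg, "X", "cold")
        sigma2_g_raw = (res["MSG"] - res["MSE"]) / 3
        assert cov == pytest.approx(-sigma2_g_raw)

    def test_bilinearity(self):
        panel, _ = self._panel()
        c1 = genotypic_covariance(panel, "X", "Y", "cold")
        c2 = genotypic_covariance(panel, "X2", "Y", "cold")
        assert c2 == pytest.approx(2 * c1)

    def test_bivariate_recovery(self):
        # configured G = [[5,-2],[-2,3]]: cov_g recovered across seeds
        covs = []
        for seed in range(40):
            cfg = PanelConfig(n_genotypes=500, n_replicates=3, traits=("A", "B"),
                              control_means={"A": 0.0, "B": 0.0},
                              G_cov=[[5.0, -2.0], [-2.0, 3.0]], E_cov=np.eye(2),
                              seed=seed)
            covs.append(genotypic_covariance(generate_panel(cfg), "A", "B", "cold"))
        assert np.median(covs) == pytest.approx(-2.0, rel=0.15)


class TestIndexMatrices:
    def test_scalar_case(self):
        panel = make_panel({"A": {"Y": [1, 2]}, "B": {"Y": [3, 4]}})
        M = build_index_matrices(panel, ["Y"])
        res = anova_one_way(panel, "Y", "cold")
        sigma2_g = (res["MSG"] - res["MSE"]) / 2
        assert M.G[0, 0] == pytest.approx(sigma2_g)
        assert M.P[0, 0] == pytest.approx(sigma2_g + res["MSE"] / 2)

    def test_duplicated_trait_flags_singular(self):
        rng = np.random.default_rng(0)
        data = {f"G{i}": {"X": (v := rng.normal(i, 1, 3)).tolist(), "Xdup": v.tolist()}
                for i in range(8)}
        with pytest.warns(UserWarning, match="singular"):
            M = build_index_matrices(make_panel(data), ["X", "Xdup"])
        assert M.ill_conditioned

    def test_p_equals_g_plus_e_over_r(self, preset_panel):
        M = build_index_matrices(preset_panel, ["LI", "qL", "FvFm"])
        stats_tbl = trait_stats_table(preset_panel, "cold", ["LI", "qL", "FvFm"])
        mse = stats_tbl.set_index("trait")["MSE"]
        for i, t in enumerate(M.traits):
            assert M.P[i, i] - M.G[i, i] == pytest.approx(mse[t] / M.r, rel=1e-9)

    def test_diag_matches_sigma2g(self, preset_panel):
        M = build_index_matrices(preset_panel, ["LI", "qL", "FvFm"])
        stats_tbl = trait_stats_table(preset_panel, "cold", ["LI", "qL", "FvFm"])
        s2g = stats_tbl.set_index("trait")["sigma2_g"]
        for i, t in enumerate(M.traits):
            assert M.G[i, i] == pytest.approx(s2g[t])

    def test_three_trait_recovery(self):
        # median entrywise recovery of a known 3-trait G
        G_true = np.array([[5.0, -2.0, 1.0], [-2.0, 3.0, -0.5], [1.0, -0.5, 2.0]])
        ests = []
        for seed in range(30):
            cfg = PanelConfig(n_genotypes=500, n_replicates=3, traits=("A", "B", "C"),
                              control_means=dict.fromkeys("ABC", 0.0),
                              G_cov=G_true, E_cov=np.eye(3), seed=seed)
            ests.append(build_index_matrices(generate_panel(cfg), ["A", "B", "C"]).G)
        med = np.median(ests, axis=0)
        assert np.abs(med - G_true).max() <= 0.15 * np.abs(G_true).max()


class TestTraitStatsTable:
    def test_full_table_structure(self, preset_panel):
        tbl = trait_stats_table(preset_panel, "cold")
        assert set(tbl["trait"]) == {"LI", "qL", "FvFm", "NPQt", "PhiNO",
                                     "SPAD", "LT", "LeafArea"}
        assert tbl["H2_percent"].between(0, 100).all()
        assert (tbl["sigma2_g"] >= 0).all()
        assert (tbl["min"] <= tbl["mean"]).all() and (tbl["mean"] <= tbl["max"]).all()
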