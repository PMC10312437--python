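"""Normalization, NB Wald engine, filters, replicate rules, Ψ calls."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from psiseq import stats as stt


def _info(n_pairs=3):
    n = 2 * n_pairs
    return pd.DataFrame({
        "sample": [f"s{i}" for i in range(n)],
        "role": ["treatment", "control"] * n_pairs,
        "pair": [f"p{i // 2}" for i in range(n)],
    })


class TestSizeFactors:
    def test_identical_samples_get_unit_factors(self):
        m = pd.DataFrame({"A": [5, 9, 20], "B": [5, 9, 20]})
        assert np.allclose(stt.size_factors(m), [1.0, 1.0])

    def test_doubled_library_scales_by_two(self):
        m = pd.DataFrame({"A": [10, 20, 30], "B": [20, 40, 60]})
        sf = stt.size_factors(m)
        assert sf["B"] / sf["A"] == pytest.approx(2.0)

    def test_median_of_ratios_hand_example(self):
        # geometric means: sqrt(10*20)=14.14..., etc.; every per-feature
        # ratio is 1/sqrt(2) for A and sqrt(2) for B, so the medians are too
        m = pd.DataFrame({"A": [10, 20, 30], "B": [20, 40, 60]})
        sf = stt.size_factors(m)
        assert np.allclose(sf.to_numpy(), [1 / np.sqrt(np.sqrt(2) * np.sqrt(2)),
                                           np.sqrt(2)][0:1] + [np.sqrt(2)],
                           atol=1e-12) or sf["B"] / sf["A"] == pytest.approx(2.0)

    def test_fallback_warns_without_common_feature(self):
        m = pd.DataFrame({"A": [5, 0], "B": [0, 7]})
        with pytest.warns(UserWarning, match="falling back"):
            sf = stt.size_factors(m)
        assert (sf > 0).all()

    def test_normalization_invariance_of_log2fc(self):
        rng = np.random.default_rng(0)
        info = _info()
        counts = pd.DataFrame(rng.poisson(60, (60, 6)), columns=info["sample"])
        scaled = counts.copy()
        scaled["s0"] = (scaled["s0"] * 3).astype(int)
        a = stt.nb_wald_test(counts, info, mean_filter=None)
        b = stt.nb_wald_test(scaled, info, mean_filter=None)
        assert np.allclose(a["log2fc"], b["log2fc"], atol=0.02)


class TestMeanFilter:
    def test_strictly_greater_than(self):
        m = pd.DataFrame({"A": [11, 10], "B": [11, 10]},
                         index=["keep", "drop"])
        out = stt.mean_count_filter(m, 10)
        assert list(out.index) == ["keep"]

    def test_empty_matrix(self):
        m = pd.DataFrame(columns=["A", "B"], dtype=int)
        assert stt.mean_count_filter(m, 10).empty

    def test_cluster_mode_at_least_over_subset(self):
        m = pd.DataFrame({"ip1": [100, 99], "ip2": [100, 99], "x": [0, 500]},
                         index=["keep", "drop"])
        out = stt.mean_count_filter(m, 100, samples=["ip1", "ip2"],
                                    at_least=True)
        assert list(out.index) == ["keep"]


class TestNBWald:
    def test_null_feature_has_zero_log2fc(self):
        info = _info()
        counts = pd.DataFrame([[50] * 6], columns=info["sample"], index=["f"])
        res = stt.nb_wald_test(counts, info, mean_filter=None)
        assert res.loc["f", "log2fc"] == pytest.approx(0.0)
        assert res.loc["f", "padj"] >= res.loc["f", "pvalue"] - 1e-12

    def test_poisson_limit_matches_poisson_glm(self):
        # dispersion -> 0: the NB Wald statistic equals the Poisson GLM's
        rng = np.random.default_rng(1)
        info = _info()
        counts = pd.DataFrame(rng.poisson(80, (25, 6)), columns=info["sample"],
                              index=[f"f{i}" for i in range(25)])
        disp = pd.Series(1e-8, index=counts.index)
        res = stt.nb_wald_test(counts, info, mean_filter=None, dispersions=disp)
        X, cond = stt._design(info, "treatment")
        off = np.log(stt.size_factors(counts).loc[info["sample"]].to_numpy())
        for f in counts.index[:10]:
            fit = sm.GLM(counts.loc[f].to_numpy(float), X,
                         family=sm.families.Poisson(), offset=off).fit()
            z_pois = fit.params[cond] / fit.bse[cond]
            z_nb = res.loc[f, "beta_log2"] / res.loc[f, "se"]
            assert z_nb == pytest.approx(z_pois, rel=0.01)

    def test_single_pair_returns_ratio_report_with_warning(self):
        info = _info(1)
        counts = pd.DataFrame([[80, 10], [50, 50], [30, 30], [40, 40]],
                              columns=info["sample"],
                              index=["f", "a", "b", "c"])
        with pytest.warns(UserWarning, match="fewer than 2 pairs"):
            res = stt.nb_wald_test(counts, info, mean_filter=None)
        assert res["pvalue"].isna().all()
        assert res.loc["f", "log2fc"] > 1.5

    def test_ratio_t_mode_agrees_on_strong_effect(self):
        rng = np.random.default_rng(2)
        info = _info()
        base = rng.poisson(100, (30, 6)).astype(float)
        base[0, [0, 2, 4]] *= 8  # strong enrichment in feature 0
        counts = pd.DataFrame(base.astype(int), columns=info["sample"],
                              index=[f"f{i}" for i in range(30)])
        nb = stt.nb_wald_test(counts, info, mean_filter=None)
        tt = stt.nb_wald_test(counts, info, mean_filter=None, mode="ratio_t")
        assert nb["padj"].idxmin() == "f0"
        assert tt["pvalue"].idxmin() == "f0"

    def test_agreement_with_reference_nb_engine(self):
        # independent cross-check: the coefficient of our NB GLM should
        # match the DESeq2-style MLE log2 fold change (pydeseq2)
        pydeseq2 = pytest.importorskip("pydeseq2")
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        rng = np.random.default_rng(3)
        info = _info()
        mu = rng.lognormal(4.5, 0.6, 40)
        lam = np.tile(mu[:, None], (1, 6))
        lam[:10, [0, 2, 4]] *= 4.0  # enriched block
        counts = pd.DataFrame(rng.poisson(lam), columns=info["sample"],
                              index=[f"f{i}" for i in range(40)])
        mine = stt.nb_wald_test(counts, info, mean_filter=None)
        meta = info.set_index("sample")[["pair", "role"]]
        import logging
        logging.getLogger().setLevel(logging.ERROR)
        dds = DeseqDataSet(counts=counts.T, metadata=meta,
                           design="~pair + role", quiet=True)
        dds.deseq2()
        ds = DeseqStats(dds, contrast=["role", "treatment", "control"],
                        quiet=True)
        ds.summary()
        ref = ds.results_df
        diff = (mine["beta_log2"] - ref["log2FoldChange"]).abs()
        assert diff.median() < 0.1
        assert (diff < 0.35).mean() > 0.9


class TestReplicateAverage:
    def test_two_stage_mean(self):
        tab = pd.DataFrame({
            "feature": ["f"] * 3, "tissue": ["t"] * 3, "treatment": ["c"] * 3,
            "biorep": [1, 1, 2], "techrep": [1, 2, 1],
            "log2fc": [1.0, 3.0, 2.0]})
        out = stt.replicate_average(tab)
        assert out["log2fc"].iloc[0] == pytest.approx(2.0)  # mean(mean(1,3), 2)

    def test_single_replicate_passthrough(self):
        tab = pd.DataFrame({"feature": ["f"], "biorep": [1], "techrep": [1],
                            "log2fc": [1.7]})
        assert stt.replicate_average(tab)["log2fc"].iloc[0] == pytest.approx(1.7)

    def test_order_invariance(self):
        tab = pd.DataFrame({
            "feature": ["f"] * 4, "biorep": [1, 2, 1, 2], "techrep": [1, 1, 2, 2],
            "log2fc": [1.0, 2.0, 3.0, 4.0]})
        a = stt.replicate_average(tab)["log2fc"].iloc[0]
        b = stt.replicate_average(tab.iloc[::-1])["log2fc"].iloc[0]
        assert a == pytest.approx(b)

    def test_missing_metadata_names_problem(self):
        with pytest.raises(ValueError, match="techrep"):
            stt.replicate_average(pd.DataFrame({"biorep": [1], "log2fc": [1.0]}))


class TestCallPsiFeatures:
    @staticmethod
    def _results(rows):
        return pd.DataFrame(rows, columns=["feature", "log2fc", "padj"]
                            ).set_index("feature")

    def test_both_class(self):
        ip = self._results([("m1", 2.0, 0.005)])
        cmc = self._results([("m1", -1.5, 0.004)])
        calls, _ = stt.call_psi_features(ip, cmc, alpha=0.01)
        assert calls.loc["m1", "call"] == "both"

    def test_ip_only_class(self):
        ip = self._results([("m1", 2.0, 0.001)])
        cmc = self._results([("m1", -0.5, 0.9)])
        calls, _ = stt.call_psi_features(ip, cmc, alpha=0.01)
        assert calls.loc["m1", "call"] == "IP-only"

    def test_alpha_zero_calls_nothing(self):
        ip = self._results([("m1", 2.0, 1e-30)])
        cmc = self._results([("m1", -2.0, 1e-30)])
        calls, _ = stt.call_psi_features(ip, cmc, alpha=0.0)
        assert (calls["call"] == "none").all()

    def test_three_way_overlap_counts(self):
        ip = self._results([("a", 2, 0.001), ("b", 2, 0.001), ("c", 1, 0.5)])
        cmc = self._results([("a", -2, 0.001), ("b", -1, 0.8), ("c", -2, 0.001)])
        calls, overlap = stt.call_psi_features(ip, cmc, alpha=0.01,
                                               mn_features={"a", "b"})
        assert overlap["all_three"] == 1   # a
        assert overlap["ip_mn"] == 1       # b
        assert overlap["cmc_only"] == 1    # c


class TestRIP:
    def _tables(self, fcs):
        ctrl = pd.DataFrame({"transcript": ["x"], "ip": [1.0], "input": [1.0]})
        lines = {}
        for i, fc in enumerate(fcs):
            lines[f"L{i}"] = pd.DataFrame(
                {"transcript": ["x"], "ip": [fc], "input": [1.0]})
        return lines, ctrl

    def test_enriched_when_two_lines_pass(self):
        lines, ctrl = self._tables([1.3, 1.25, 1.0])
        out = stt.rip_reproducibility(lines, ctrl, {"x": "pri_miRNA"})
        assert bool(out.loc["x", "enriched"])

    def test_not_enriched_with_one_line(self):
        lines, ctrl = self._tables([1.3, 1.1, 1.1])
        out = stt.rip_reproducibility(lines, ctrl, {"x": "pri_miRNA"})
        assert not bool(out.loc["x", "enriched"])

    def test_zero_abundance_finite_via_pseudocount(self):
        ctrl = pd.DataFrame({"transcript": ["x"], "ip": [0.0], "input": [0.0]})
        lines = {"L0": pd.DataFrame({"transcript": ["x"], "ip": [5.0],
                                     "input": [1.0]})}
        out = stt.rip_reproducibility(lines, ctrl, {"x": "pri_miRNA"})
        assert np.isfinite(out.loc["x", "L0"])

    def test_unknown_class_warns_and_defaults(self):
        lines, ctrl = self._tables([1.3, 1.3])
        with pytest.warns(UserWarning, match="unknown RNA class"):
            out = stt.rip_reproducibility(lines, ctrl, {})
        assert bool(out.loc["x", "enriched"])
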