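"""Moderated t, BH, stage ANOVA, early/late tests, hypergeometric enrichment."""

import math
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from lncpeptidome.stats import (
    bh_adjust,
    early_late_test,
    fit_variance_prior,
    hypergeom_enrichment,
    moderated_t_test,
    one_way_anova,
    paired_t_test,
    stage_anova,
    stage_filter,
)
from lncpeptidome.synthetic import simulate_de_matrix, simulate_stage_matrix


class TestModeratedT:
    def test_d0_zero_reduces_to_pooled_t(self):
        matrix, labels, _ = simulate_de_matrix(200, 6, 8, seed=5)
        res = moderated_t_test(matrix, labels, "g1", "g2", d0_override=0.0)
        for gid in matrix.index[:50]:
            a = matrix.loc[gid, labels[labels == "g1"].index]
            b = matrix.loc[gid, labels[labels == "g2"].index]
            t, p = sps.ttest_ind(b, a, equal_var=True)
            assert abs(res.loc[gid, "t_mod"] - t) < 1e-10
            assert abs(res.loc[gid, "p"] - p) < 1e-10

    def test_d0_infinite_shares_one_variance(self):
        matrix, labels, _ = simulate_de_matrix(100, 5, 5, seed=6)
        res = moderated_t_test(matrix, labels, "g1", "g2", d0_override=math.inf)
        # identical fold change implies identical t when variance is shared
        implied_se = res["log2fc"] / res["t_mod"]
        assert np.allclose(implied_se, implied_se.iloc[0])

    def test_null_type_one_error_calibrated(self):
        matrix, labels, _ = simulate_de_matrix(3000, 10, 10, seed=7)
        res = moderated_t_test(matrix, labels, "g1", "g2")
        frac = float((res["p"] < 0.05).mean())
        ci = 1.96 * math.sqrt(0.05 * 0.95 / 3000)
        assert abs(frac - 0.05) < ci + 0.005

    def test_power_and_fdr_with_planted_effects(self):
        matrix, labels, flags = simulate_de_matrix(
            2000, 10, 10, de_fraction=0.1, log2fc=2.0, sd=0.5, seed=8
        )
        res = moderated_t_test(matrix, labels, "g1", "g2")
        called = (res["adj_p"] < 0.05).to_numpy()
        power = called[flags].mean()
        fdr = (called & ~flags).sum() / max(called.sum(), 1)
        assert power >= 0.9
        assert fdr <= 0.07

    def test_missing_rows_flagged_not_dropped(self):
        matrix, labels, _ = simulate_de_matrix(10, 4, 4, seed=9)
        matrix.iloc[0, :3] = np.nan  # one non-missing value in group 1
        res = moderated_t_test(matrix, labels, "g1", "g2")
        assert res["excluded"].iloc[0] != ""
        assert math.isnan(res["p"].iloc[0])
        assert len(res) == 10

    def test_one_level_factor_errors(self):
        matrix, labels, _ = simulate_de_matrix(5, 3, 3, seed=1)
        with pytest.raises(ValueError):
            moderated_t_test(matrix, labels, "g1", "nope")

    def test_matches_limma_oracle(self, tmp_path):
        """Independent cross-check of the empirical-Bayes machinery against
        the reference R implementation on a small fixture."""
        matrix, labels, _ = simulate_de_matrix(
            30, 5, 5, de_fraction=0.2, log2fc=1.5, sd=0.8, seed=12
        )
        res = moderated_t_test(matrix, labels, "g1", "g2")
        in_tsv = tmp_path / "m.tsv"
        matrix.to_csv(in_tsv, sep="\t")
        out_tsv = tmp_path / "limma.tsv"
        script = tmp_path / "oracle.R"
        script.write_text(
            f"""
suppressMessages(library(limma))
m <- as.matrix(read.table("{in_tsv}", header=TRUE, row.names=1, sep="\\t"))
grp <- factor(c(rep("g1", 5), rep("g2", 5)), levels=c("g1", "g2"))
fit <- eBayes(lmFit(m, model.matrix(~grp)))
out <- data.frame(t=fit$t[,2], p=fit$p.value[,2], fc=fit$coefficients[,2])
out$d0 <- fit$df.prior
write.table(out, "{out_tsv}", sep="\\t", quote=FALSE)
"""
        )
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        limma = pd.read_csv(out_tsv, sep="\t")
        assert np.allclose(res["log2fc"], limma["fc"], atol=1e-8)
        assert np.allclose(res["t_mod"], limma["t"], rtol=1e-5)
        assert np.allclose(res["p"], limma["p"], rtol=1e-4)
        assert res.attrs["d0"] == pytest.approx(limma["d0"].iloc[0], rel=1e-3)


class TestVariancePrior:
    def test_recovers_known_prior_roughly(self, rng):
        d0_true, s0_true = 8.0, 0.25
        s2_prior = s0_true * d0_true / rng.chisquare(d0_true, size=4000)
        dg = 10
        s2 = s2_prior * rng.chisquare(dg, size=4000) / dg
        d0, s0 = fit_variance_prior(s2, np.full(4000, dg))
        assert d0 == pytest.approx(d0_true, rel=0.25)
        assert s0 == pytest.approx(s0_true, rel=0.1)

    def test_degenerate_spread_gives_infinite_prior(self):
        s2 = np.full(100, 0.5)
        d0, s0 = fit_variance_prior(s2, np.full(100, 10.0))
        assert math.isinf(d0)


class TestBhAdjust:
    def test_step_up_by_hand(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_identity(self):
        assert bh_adjust([0.5]) == pytest.approx([0.5])

    def test_bounds_and_monotonicity(self, rng):
        p = rng.uniform(size=50)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-12).all() and (adj <= 1).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_invariant_under_permutation(self, rng):
        p = rng.uniform(size=30)
        perm = rng.permutation(30)
        assert np.allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestStageFilter:
    def _matrix(self, counts):
        """One row; stage s gets counts[s] non-missing of 5 samples."""
        cols, vals = [], []
        for si, s in enumerate(("I", "II", "III", "IV")):
            for i in range(5):
                cols.append(f"{s}_{i}")
                vals.append(10.0 if i < counts[si] else np.nan)
        m = pd.DataFrame([vals], columns=cols, index=["g"])
        labels = pd.Series({c: c.split("_")[0] for c in cols})
        return m, labels

    @pytest.mark.parametrize(
        "counts,expected",
        [((2, 2, 2, 2), True), ((1, 4, 4, 4), False), ((2, 3, 2, 5), True)],
    )
    def test_two_of_four_rule(self, counts, expected):
        m, labels = self._matrix(counts)
        assert stage_filter(m, labels).loc["g"] == expected

    def test_absent_stage_named(self):
        m, labels = self._matrix((2, 2, 2, 2))
        drop = [c for c in m.columns if labels[c] == "IV"]
        with pytest.raises(ValueError, match="IV"):
            stage_filter(m.drop(columns=drop), labels.drop(drop))


class TestOneWayAnova:
    def test_two_groups_equals_squared_pooled_t(self, rng):
        a = rng.normal(size=8)
        b = rng.normal(1.0, 1.0, size=6)
        f, p = one_way_anova({"early": a, "late": b})
        t, pt = sps.ttest_ind(a, b, equal_var=True)
        assert abs(f - t**2) < 1e-10
        assert p == pytest.approx(pt)

    def test_zero_variance_convention(self):
        with pytest.warns(UserWarning, match="zero total variance"):
            f, p = one_way_anova({"I": [2.0, 2.0], "II": [2.0, 2.0]})
        assert (f, p) == (0.0, 1.0)

    def test_null_p_values_uniform(self):
        matrix, labels, _ = simulate_stage_matrix(800, n_per_stage=5, seed=21)
        res = stage_anova(matrix, labels)
        stat, p = sps.kstest(res["p"].to_numpy(), "uniform")
        assert p > 0.01

    def test_power_under_monotone_trend(self):
        hits = 0
        for rep in range(25):
            matrix, labels, flags = simulate_stage_matrix(
                20, n_per_stage=5, trend_fraction=1.0, slope=0.5, sd=0.5, seed=100 + rep
            )
            res = stage_anova(matrix, labels)
            hits += int((res["adj_p"] < 0.05).sum())
        assert hits / (25 * 20) >= 0.8


class TestEarlyLate:
    def test_label_swap_antisymmetry(self):
        matrix, labels, _ = simulate_stage_matrix(20, n_per_stage=4, seed=31)
        res = early_late_test(matrix, labels)
        swapped = labels.map({"I": "III", "II": "IV", "III": "I", "IV": "II"})
        res2 = early_late_test(matrix, swapped)
        assert np.allclose(res["t"], -res2["t"], equal_nan=True)
        assert np.allclose(res["p"], res2["p"], equal_nan=True)

    def test_power_under_late_shift(self):
        matrix, labels, _ = simulate_stage_matrix(50, n_per_stage=10, seed=32)
        late_cols = labels[labels.isin(["III", "IV"])].index
        matrix[late_cols] += 1.0  # +1 log2 shift, sd 0.5
        res = early_late_test(matrix, labels)
        assert float(res["p"].median()) < 1e-4

    def test_degenerate_group_flagged(self):
        matrix, labels, _ = simulate_stage_matrix(3, n_per_stage=3, seed=33)
        matrix.iloc[0] = 5.0
        res = early_late_test(matrix, labels)
        assert res["excluded"].iloc[0] == "degenerate group"
        assert res["excluded"].iloc[1] == ""


class TestPairedT:
    def test_matches_scipy_rel(self, rng):
        m = pd.DataFrame(rng.normal(size=(5, 6)), columns=list("abcdef"))
        pairs = [("a", "b"), ("c", "d"), ("e", "f")]
        res = paired_t_test(m, pairs)
        for i in range(5):
            pre = m.iloc[i][["a", "c", "e"]].to_numpy()
            post = m.iloc[i][["b", "d", "f"]].to_numpy()
            t, p = sps.ttest_rel(post, pre)
            assert res["t"].iloc[i] == pytest.approx(t)
            assert res["p"].iloc[i] == pytest.approx(p)


def oracle_hypergeom_tail(m, k_cat, n_sel, overlap):
    total = math.comb(m, n_sel)
    return sum(
        math.comb(k_cat, k) * math.comb(m - k_cat, n_sel - k)
        for k in range(overlap, min(k_cat, n_sel) + 1)
    ) / total


class TestHypergeomEnrichment:
    def test_exact_enumeration_example(self):
        universe = {f"g{i}" for i in range(10)}
        cat = {f"g{i}" for i in range(4)}
        selected = {f"g{i}" for i in range(5)}  # overlap 4
        res = hypergeom_enrichment(selected, {"T": cat}, universe)
        assert res.loc["T", "p"] == pytest.approx(6 / 252)

    def test_trivial_cases(self):
        universe = {f"g{i}" for i in range(8)}
        res = hypergeom_enrichment({"g0"}, {"empty": set()}, universe)
        assert res.loc["empty", "p"] == 1.0
        res = hypergeom_enrichment(universe, {"T": {"g0", "g1"}}, universe)
        assert res.loc["T", "overlap"] == 2
        assert res.loc["T", "p"] == pytest.approx(1.0)

    def test_matches_enumeration_for_all_small_universes(self, rng):
        for m in range(2, 16):
            universe = {f"g{i}" for i in range(m)}
            for _ in range(5):
                n_sel = int(rng.integers(1, m + 1))
                k_cat = int(rng.integers(0, m + 1))
                selected = set(rng.choice(sorted(universe), size=n_sel, replace=False))
                cat = set(rng.choice(sorted(universe), size=k_cat, replace=False))
                res = hypergeom_enrichment(selected, {"T": cat}, universe)
                expected = oracle_hypergeom_tail(m, k_cat, n_sel, int(res.loc["T", "overlap"]))
                assert res.loc["T", "p"] == pytest.approx(expected, rel=1e-12)

    def test_contract_errors(self):
        with pytest.raises(ValueError, match="universe"):
            hypergeom_enrichment(set(), {}, set())
        with pytest.raises(ValueError, match="subset"):
            hypergeom_enrichment({"x"}, {}, {"y"})
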