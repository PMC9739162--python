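"""Filtering, TMM, log-CPM, moderated t, BH and variance partition."""

import math
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from circsponge.diffexp import (
    CountMatrix,
    NormFactors,
    auto_min_samples,
    bh_adjust,
    cpm,
    estimate_variance_prior,
    filter_by_expression,
    log_cpm,
    moderated_de,
    tmm_factors,
    variance_explained,
)
from circsponge.synthetic import simulate_counts


def _matrix(counts, prefix="f"):
    counts = np.asarray(counts, dtype=float)
    return CountMatrix(
        [f"{prefix}{i}" for i in range(counts.shape[0])],
        [f"s{j}" for j in range(counts.shape[1])],
        counts,
    )


class TestCpm:
    def test_column_scaling(self):
        m = _matrix([[10.0], [90.0]])
        np.testing.assert_allclose(cpm(m), [[1e5], [9e5]])

    def test_equal_columns_identical_cpm(self):
        m = _matrix([[5.0, 5.0], [15.0, 15.0]])
        c = cpm(m)
        np.testing.assert_allclose(c[:, 0], c[:, 1])

    def test_depth_invariance(self):
        m1 = _matrix([[5.0], [15.0]])
        m2 = _matrix([[10.0], [30.0]])
        np.testing.assert_allclose(cpm(m1), cpm(m2))

    def test_zero_library_rejected(self):
        with pytest.raises(ValueError, match="library"):
            cpm(_matrix([[0.0], [0.0]]))


class TestExpressionFilter:
    def test_boundary_feature_kept(self):
        # feature 0 reaches 10 CPM in exactly 2 of 3 samples
        m = _matrix([[2.0, 2.0, 0.5], [99998.0, 99998.0, 99999.0]])
        out = filter_by_expression(m, min_cpm=10, min_samples=2)
        assert "f0" in out.feature_ids
        out3 = filter_by_expression(m, min_cpm=10, min_samples=3)
        assert "f0" not in out3.feature_ids

    def test_min_samples_zero_keeps_all(self):
        m = _matrix([[0.0, 0.0], [1.0, 1.0]])
        assert filter_by_expression(m, min_samples=0).feature_ids == m.feature_ids

    def test_infinite_cpm_threshold_removes_all(self):
        m = _matrix([[1.0, 1.0], [2.0, 2.0]])
        assert filter_by_expression(m, min_cpm=math.inf, min_samples=1).feature_ids == []

    def test_auto_rule_is_seventy_percent_of_smallest_tissue(self):
        meta = pd.DataFrame(
            {"tissue": ["SCC"] * 25 + ["SCT"] * 13, "sample": range(38)}
        )
        assert auto_min_samples(meta) == math.ceil(0.7 * 13)


def _tmm_oracle(counts, trim_m=0.3, trim_a=0.05):
    """Step-by-step recomputation of the doubly-trimmed weighted mean."""
    counts = np.asarray(counts, dtype=float)
    lib = counts.sum(axis=0)
    q75 = np.array([np.percentile(counts[:, j] / lib[j], 75) for j in range(counts.shape[1])])
    ref = int(np.argmin(np.abs(q75 - q75.mean())))
    logf = np.zeros(counts.shape[1])
    for j in range(counts.shape[1]):
        if j == ref:
            continue
        keep = (counts[:, j] > 0) & (counts[:, ref] > 0)
        o, r = counts[keep, j], counts[keep, ref]
        m = np.log2((o / lib[j]) / (r / lib[ref]))
        a = 0.5 * np.log2((o / lib[j]) * (r / lib[ref]))
        w = (lib[j] - o) / (lib[j] * o) + (lib[ref] - r) / (lib[ref] * r)
        n = m.size
        rm, ra = stats.rankdata(m), stats.rankdata(a)
        lo_m, hi_m = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
        lo_a, hi_a = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
        sel = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        logf[j] = np.sum(m[sel] / w[sel]) / np.sum(1.0 / w[sel])
    f = 2.0**logf
    return f / np.exp(np.mean(np.log(f)))


class TestTmm:
    def test_identical_columns_give_unit_factors(self):
        m = _matrix([[10.0, 10.0], [50.0, 50.0], [5.0, 5.0]])
        np.testing.assert_allclose(tmm_factors(m).factors, [1.0, 1.0])

    def test_pure_depth_difference_gives_unit_factors(self):
        col = np.array([10.0, 50.0, 5.0, 100.0, 20.0])
        m = CountMatrix([f"f{i}" for i in range(5)], ["s1", "s2"],
                        np.column_stack([col, 2 * col]))
        np.testing.assert_allclose(tmm_factors(m).factors, [1.0, 1.0], atol=1e-12)

    def test_inflated_column_matches_direct_recomputation(self, rng):
        counts = rng.negative_binomial(5, 0.1, size=(300, 3)).astype(float) + 1
        counts[:90, 2] *= 4  # 30% of features 4-fold inflated in sample 3
        m = _matrix(counts)
        f = tmm_factors(m).factors
        assert f[2] < 1.0
        np.testing.assert_allclose(f, _tmm_oracle(counts), rtol=1e-12)

    def test_geometric_mean_exactly_one_on_random_matrices(self, rng):
        for _ in range(5):
            counts = rng.negative_binomial(3, 0.2, size=(100, 4)).astype(float) + 1
            f = tmm_factors(_matrix(counts)).factors
            assert abs(np.mean(np.log(f))) < 1e-12

    def test_depth_scaling_of_one_column_near_invariant(self, rng):
        # the trimmed set is depth-invariant; the precision weights are not,
        # so invariance holds only approximately
        counts = rng.negative_binomial(5, 0.1, size=(200, 3)).astype(float) + 1
        f1 = tmm_factors(_matrix(counts)).factors
        scaled = counts.copy()
        scaled[:, 1] *= 7.0
        f2 = tmm_factors(_matrix(scaled)).factors
        np.testing.assert_allclose(f1, f2, rtol=0.02)


class TestLogCpm:
    def test_zero_count_is_finite(self):
        m = _matrix([[0.0, 1.0], [10.0, 10.0]])
        assert np.isfinite(log_cpm(m).to_numpy()).all()

    def test_monotone_in_count_within_sample(self):
        m = _matrix([[0.0], [1.0], [5.0], [100.0]])
        vals = log_cpm(m).to_numpy()[:, 0]
        assert np.all(np.diff(vals) > 0)

    def test_matches_plain_cpm_for_large_counts(self):
        m = _matrix([[1e7], [2e7]])
        diff = log_cpm(m).to_numpy() - np.log2(cpm(m))
        assert np.abs(diff).max() < 1e-6


class TestModeratedT:
    def _toy(self, rng, n_feat=60, n=5):
        y = rng.normal(size=(n_feat, 2 * n))
        y[: n_feat // 3, :n] += 1.0
        lcpm = pd.DataFrame(y, index=[f"f{i}" for i in range(n_feat)],
                            columns=[f"s{j}" for j in range(2 * n)])
        return lcpm, ["case"] * n + ["control"] * n

    def test_d0_zero_equals_ordinary_t(self, rng):
        lcpm, groups = self._toy(rng)
        res = moderated_de(lcpm, groups, prior_df=0)
        case = lcpm.to_numpy()[:, :5]
        ctrl = lcpm.to_numpy()[:, 5:]
        t_ref, p_ref = stats.ttest_ind(case, ctrl, axis=1, equal_var=True)
        np.testing.assert_allclose([r.t_mod for r in res], t_ref, rtol=1e-10)
        np.testing.assert_allclose([r.p for r in res], p_ref, rtol=1e-10)

    def test_d0_infinite_pools_all_variances(self, rng):
        lcpm, groups = self._toy(rng)
        res = moderated_de(lcpm, groups, prior_df=math.inf)
        y = lcpm.to_numpy()
        lfc = y[:, :5].mean(axis=1) - y[:, 5:].mean(axis=1)
        # all features share one variance => t proportional to the effect
        ratio = np.array([r.t_mod for r in res]) / lfc
        np.testing.assert_allclose(ratio, ratio[0], rtol=1e-9)

    def test_prior_estimation_recovers_planted_prior(self, rng):
        # s^2 drawn from a scaled-inverse-chi-square with known (d0, s0^2)
        d0, s0_sq, d = 8.0, 0.5, 10
        n = 20000
        s2 = d0 * s0_sq / rng.chisquare(d0, size=n)  # feature-level true variances
        obs = s2 * rng.chisquare(d, size=n) / d
        d0_hat, s0_hat = estimate_variance_prior(obs, d)
        assert abs(d0_hat - d0) / d0 < 0.15
        assert abs(s0_hat - s0_sq) / s0_sq < 0.05

    def test_null_type_one_error_controlled(self):
        rng = np.random.default_rng(77)
        meta = pd.DataFrame(
            {
                "sample": [f"s{i}" for i in range(16)],
                "tissue": ["T"] * 16,
                "condition": ["ALS"] * 8 + ["control"] * 8,
            }
        )
        m = simulate_counts(
            meta, [f"g{i}" for i in range(2000)],
            rng.normal(5.0, 1.5, size=2000), {}, 0.1, rng,
        )
        res = moderated_de(log_cpm(m, tmm_factors(m)),
                           ["case"] * 8 + ["control"] * 8)
        frac = np.mean([r.p < 0.05 for r in res])
        assert 0.035 <= frac <= 0.065

    def test_tiny_group_rejected(self, rng):
        lcpm, _ = self._toy(rng)
        with pytest.raises(ValueError, match="fewer than 2"):
            moderated_de(lcpm, ["case"] + ["control"] * 9)


class TestBH:
    def test_hand_evaluated_step_up(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.3]), [0.3])

    def test_never_decreases_and_caps_at_one(self, rng):
        p = rng.uniform(size=50)
        adj = bh_adjust(p)
        assert np.all(adj >= p) and np.all(adj <= 1.0)

    def test_agrees_with_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=200)
        _, ref, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(bh_adjust(p), ref, rtol=1e-12)

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30),
           st.randoms(use_true_random=False))
    def test_permutation_equivariant(self, p, rnd):
        perm = list(range(len(p)))
        rnd.shuffle(perm)
        adj = bh_adjust(p)
        adj_perm = bh_adjust([p[i] for i in perm])
        np.testing.assert_allclose([adj[i] for i in perm], adj_perm, rtol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestVariancePartition:
    def _covariates(self, rng, n=25):
        return pd.DataFrame(
            {
                "RIN": rng.uniform(4, 9, size=n),
                "PMI": rng.uniform(2, 25, size=n),
                "sex": rng.choice(["M", "F"], size=n),
                "group": rng.integers(0, 2, size=n),
            }
        )

    def test_exact_covariate_response_attributed_fully(self, rng):
        covs = self._covariates(rng)
        y = pd.DataFrame(np.tile(covs["RIN"].to_numpy(), (3, 1)),
                         index=["a", "b", "c"], columns=range(25))
        out = variance_explained(y, covs)
        for part in out.partitions:
            assert part.fraction_by_covariate["RIN"] > 0.95
            assert part.residual < 1e-9

    def test_fractions_sum_to_one(self, rng):
        covs = self._covariates(rng)
        y = pd.DataFrame(rng.normal(size=(40, 25)))
        out = variance_explained(y, covs)
        for part in out.partitions:
            total = sum(part.fraction_by_covariate.values()) + part.residual
            assert abs(total - 1.0) < 1e-9

    def test_pure_noise_has_small_median_fractions(self):
        rng = np.random.default_rng(5)
        covs = self._covariates(rng)
        y = pd.DataFrame(rng.normal(size=(1000, 25)))
        out = variance_explained(y, covs)
        assert all(v < 0.05 for v in out.median_fraction.values())

    def test_planted_group_variance_recovered(self):
        rng = np.random.default_rng(11)
        meta = pd.DataFrame(
            {
                "sample": [f"s{i}" for i in range(30)],
                "tissue": ["T"] * 30,
                "condition": ["ALS"] * 15 + ["control"] * 15,
                "RIN": rng.uniform(4, 9, size=30),
                "PMI": rng.uniform(2, 25, size=30),
                "sex": rng.choice(["M", "F"], size=30),
            }
        )
        m = simulate_counts(
            meta, [f"g{i}" for i in range(600)],
            np.full(600, 5.0), {}, 0.1, rng,
            covariate_effects={"group": 0.3},
        )
        covs = meta[["RIN", "PMI", "sex"]].copy()
        covs["group"] = (meta["condition"] == "ALS").astype(int)
        out = variance_explained(log_cpm(m, tmm_factors(m)), covs)
        assert abs(out.median_fraction["group"] - 0.3) < 0.1

    def test_constant_covariate_warned_and_zero(self, rng):
        covs = self._covariates(rng)
        covs["sex"] = "M"
        y = pd.DataFrame(rng.normal(size=(5, 25)))
        with pytest.warns(UserWarning, match="constant"):
            out = variance_explained(y, covs)
        assert out.median_fraction["sex"] == 0.0


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not available")
def test_tmm_and_moderated_t_match_edger_and_limma(tmp_path, rng):
    """Independent oracle: edgeR's calcNormFactors and limma's eBayes on the
    identical small matrix must agree with the in-package implementations."""
    counts = rng.negative_binomial(10, 0.3, size=(150, 6)).astype(float) + 1
    counts[:45, 3] *= 3
    df = pd.DataFrame(counts, index=[f"g{i}" for i in range(150)],
                      columns=[f"s{j}" for j in range(6)])
    df.to_csv(tmp_path / "counts.tsv", sep="\t")
    script = tmp_path / "oracle.R"
    script.write_text(
        """
        suppressMessages({library(edgeR); library(limma)})
        x <- as.matrix(read.delim(file.path(commandArgs(TRUE)[1], 'counts.tsv'),
                                  row.names=1))
        f <- calcNormFactors(DGEList(counts=x), method='TMM')$samples$norm.factors
        lib <- colSums(x) * f
        lcpm <- log2(t(t(x + 0.5) / (lib + 1)) * 1e6)
        design <- cbind(1, c(1,1,1,0,0,0))
        fit <- eBayes(lmFit(lcpm, design))
        out <- data.frame(factor=f[1:6],
                          t=fit$t[1:6,2], p=fit$p.value[1:6,2])
        write.table(out, file.path(commandArgs(TRUE)[1], 'oracle.tsv'),
                    sep='\\t', row.names=FALSE, quote=FALSE)
        """
    )
    subprocess.run(["Rscript", str(script), str(tmp_path)], check=True,
                   capture_output=True, timeout=240)
    oracle = pd.read_csv(tmp_path / "oracle.tsv", sep="\t")

    m = CountMatrix.from_dataframe(df)
    f = tmm_factors(m)
    np.testing.assert_allclose(f.factors, oracle["factor"], rtol=1e-6)
    res = moderated_de(log_cpm(m, f), ["case"] * 3 + ["control"] * 3)
    np.testing.assert_allclose([r.t_mod for r in res[:6]], oracle["t"], rtol=1e-6)
    np.testing.assert_allclose([r.p for r in res[:6]], oracle["p"], rtol=1e-6)
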