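import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from femr import (SimulationTruth, bh_fdr, filter_genes, minority_rule,
                  normalize, rank_statistic, simulate_cohort)
from femr.dea import DesignSpec, build_design, fit_dea


def bh_oracle(p):
    """Double-loop step-up definition: q_i = min over j with p_j >= p_i of
    m * p_(j) / rank(j)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for pos in range(m):
        cands = [m * p[order[j]] / (j + 1) for j in range(pos, m)]
        q[order[pos]] = min(1.0, min(cands))
    return q


@pytest.fixture(scope="module")
def fitted(small_cohort):
    counts, pheno, geno, truth = small_cohort
    filtered, rep = filter_genes(counts)
    norm = normalize(filtered, rep)
    return counts, filtered, norm, pheno, truth


class TestBhFdr:
    def test_hand_stepup(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_all_equal(self):
        np.testing.assert_allclose(bh_fdr([0.2, 0.2, 0.2]), 0.2)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_matches_double_loop_oracle(self, p):
        np.testing.assert_allclose(bh_fdr(p), bh_oracle(p), rtol=1e-12)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(12)
        p = rng.uniform(size=40)
        perm = rng.permutation(40)
        np.testing.assert_allclose(bh_fdr(p)[perm], bh_fdr(p[perm]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


class TestDesign:
    def test_complete_cases_dropped(self):
        from femr.types import PhenotypeTable
        df = pd.DataFrame({"sample_id": list("abcdef"),
                           "x": [1.0, np.nan, 3.0, 4.0, 2.0, 5.0],
                           "age": [50, 60, 70, np.nan, 55, 48]})
        X, names, e_idx, mask = build_design(
            PhenotypeTable(df), DesignSpec(exposure="x", covariates=("age",)))
        assert mask.sum() == 4
        assert names[e_idx] == "x"

    def test_singular_design_names_alias(self):
        from femr.types import PhenotypeTable
        df = pd.DataFrame({"sample_id": list("abcd"), "x": [1.0, 2, 3, 4],
                           "dup": [1.0, 2, 3, 4]})
        with pytest.raises(ValueError, match="dup"):
            build_design(PhenotypeTable(df),
                         DesignSpec(exposure="x", covariates=("dup",)))

    def test_constant_exposure_errors(self):
        from femr.types import PhenotypeTable
        df = pd.DataFrame({"sample_id": list("abc"), "x": [1.0, 1.0, 1.0]})
        with pytest.raises(ValueError, match="variation"):
            build_design(PhenotypeTable(df), DesignSpec(exposure="x", covariates=()))


class TestFitDea:
    def test_recovers_causal_effect_sign(self, fitted):
        counts, filtered, norm, pheno, truth = fitted
        dea = fit_dea(filtered, norm, pheno, DesignSpec(exposure="bmi"))
        t = dea.set_index("gene_id")
        fe = t.loc[[g for g in truth.fe_gene_ids if g in t.index]]
        assert fe["log2fc"].mean() == pytest.approx(truth.causal_effect_delta, abs=0.15)

    def test_engines_agree_on_significant_genes(self, fitted):
        counts, filtered, norm, pheno, truth = fitted
        nb = fit_dea(filtered, norm, pheno, DesignSpec(exposure="bmi"), engine="nbglm")
        lm = fit_dea(filtered, norm, pheno, DesignSpec(exposure="bmi"), engine="lm_logcpm")
        sig = nb["q"] < 0.1
        assert sig.sum() > 10
        agree = np.sign(nb.loc[sig, "stat"]) == np.sign(lm.loc[sig, "stat"])
        assert agree.mean() >= 0.95

    def test_binary_recode_negates_exactly(self, fitted):
        counts, filtered, norm, pheno, truth = fitted
        df = pheno.data.copy()
        rng = np.random.default_rng(13)
        df["flag"] = rng.integers(0, 2, len(df))
        df["flag_rev"] = 1 - df["flag"]
        ph = type(pheno)(df)
        a = fit_dea(filtered, norm, ph, DesignSpec(exposure="flag"))
        b = fit_dea(filtered, norm, ph, DesignSpec(exposure="flag_rev"))
        np.testing.assert_allclose(a["log2fc"], -b["log2fc"], atol=1e-6)
        np.testing.assert_allclose(a["p"], b["p"], atol=1e-6)

    def test_matches_statsmodels_single_gene(self, fitted):
        import statsmodels.api as sm

        counts, filtered, norm, pheno, truth = fitted
        design = DesignSpec(exposure="bmi")
        dea = fit_dea(filtered, norm, pheno, design)
        X, names, e_idx, mask = build_design(pheno, design)
        offset = np.log(norm.effective_library_sizes[mask])
        from femr.dea import _mom_dispersion
        X0 = np.delete(X, e_idx, axis=1)
        for gi in (0, 7, 42):
            y = filtered.counts[gi, mask].astype(float)
            phi = _mom_dispersion(y[None, :], X0, offset)[0]
            fam = sm.families.NegativeBinomial(alpha=phi)
            fit = sm.GLM(y, X, family=fam, offset=offset).fit()
            assert dea["log2fc"].iloc[gi] == pytest.approx(
                fit.params[e_idx] / np.log(2), rel=1e-4, abs=1e-6)
            assert dea["se"].iloc[gi] == pytest.approx(
                fit.bse[e_idx] / np.log(2), rel=1e-3, abs=1e-6)

    def test_constant_exposure_rejected(self, fitted):
        counts, filtered, norm, pheno, truth = fitted
        df = pheno.data.copy()
        df["const"] = 1.0
        with pytest.raises(ValueError, match="variation"):
            fit_dea(filtered, norm, type(pheno)(df), DesignSpec(exposure="const"))


class TestRankStatistic:
    def _table(self, rows):
        df = pd.DataFrame(rows, columns=["gene_id", "log2fc", "p"])
        df["se"] = 1.0
        df["stat"] = df["log2fc"]
        df["q"] = df["p"]
        df["n_used"] = 10
        df["converged"] = True
        return df

    def test_sign_and_magnitude_ordering(self):
        dea = self._table([("g1", 1.0, 0.01), ("g2", -1.0, 0.01), ("g3", 0.1, 0.9)])
        ranked = rank_statistic(dea, metric="signed_z")
        assert list(ranked.gene_ids) == ["g1", "g3", "g2"]

    def test_logfc_metric(self):
        dea = self._table([("g1", 0.5, 0.5), ("g2", 2.0, 0.9), ("g3", -1.0, 0.01)])
        ranked = rank_statistic(dea, metric="log2fc")
        assert list(ranked.gene_ids) == ["g2", "g1", "g3"]

    def test_deterministic_tie_break(self):
        dea = self._table([("gB", 1.0, 0.5), ("gA", 1.0, 0.5), ("gC", 1.0, 0.5)])
        r1 = rank_statistic(dea)
        r2 = rank_statistic(dea.iloc[::-1].reset_index(drop=True))
        assert list(r1.gene_ids) == ["gA", "gB", "gC"] == list(r2.gene_ids)

    def test_empty_errors(self):
        with pytest.raises(ValueError, match="empty"):
            rank_statistic(self._table([]).iloc[0:0])


class TestMinorityRule:
    @pytest.mark.parametrize("n, minority, expected", [
        (399, 33, True),    # metformin-like: 366 no / 33 yes
        (400, 19, False),   # below the absolute floor of 20
        (100, 20, True),    # 20 >= max(20, 5)
        (1000, 45, False),  # 5% of 1000 = 50 > 45
    ])
    def test_rule(self, n, minority, expected):
        v = np.r_[np.zeros(n - minority), np.ones(minority)]
        assert minority_rule(v) is expected

    def test_nonbinary_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            minority_rule(np.array([0, 1, 2]))
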