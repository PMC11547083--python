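import math

import numpy as np
import pytest
from scipy import stats

from femr.expression import (cpm, filter_genes, inverse_normal, log_cpm,
                             tmm_factors)

from conftest import make_counts


def tmm_oracle(mat, logratio_trim=0.30, abs_trim=0.05):
    """Independent trim-and-weight implementation coded from the algorithm
    definition: per-sample M/A over co-expressed genes, rank-based double
    trim, inverse-variance weighted mean, geometric-mean centering."""
    mat = np.asarray(mat, dtype=float)
    lib = mat.sum(axis=0)
    q75 = np.array([np.quantile(mat[:, j] / lib[j], 0.75) for j in range(mat.shape[1])])
    ref = int(np.argmin(np.abs(q75 - q75.mean())))
    factors = []
    for j in range(mat.shape[1]):
        if j == ref:
            factors.append(1.0)
            continue
        o, r, li, lr = mat[:, j], mat[:, ref], lib[j], lib[ref]
        both = (o > 0) & (r > 0)
        o, r = o[both], r[both]
        m = np.log2((o / li) / (r / lr))
        a = 0.5 * np.log2((o / li) * (r / lr))
        v = (li - o) / (li * o) + (lr - r) / (lr * r)
        if np.max(np.abs(m)) < 1e-6:
            factors.append(1.0)
            continue
        n = m.size
        lo_m, lo_a = math.floor(n * logratio_trim) + 1, math.floor(n * abs_trim) + 1
        hi_m, hi_a = n + 1 - lo_m, n + 1 - lo_a
        rm, ra = stats.rankdata(m), stats.rankdata(a)
        keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        f = np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep])
        if not np.isfinite(f) or abs(f) < 1e-6:
            f = 0.0
        factors.append(2.0 ** f)
    factors = np.asarray(factors)
    return factors / np.exp(np.mean(np.log(factors)))


class TestFilterGenes:
    def test_length_rule_removes_short_genes(self):
        cm = make_counts([[100, 100], [100, 100]], lengths=[250, 500])
        kept, report = filter_genes(cm, min_length_bp=300, min_samples_frac=0.5)
        assert list(kept.gene_ids) == ["G1"]
        assert report.set_index("gene_id").loc["G0", "reason"] == "length"

    def test_required_sample_count_from_fraction(self):
        # 445 samples at fraction 0.225 -> a gene must reach the CPM cutoff
        # in ceil(0.225 * 445) = 101 samples, i.e. more than 100
        assert math.ceil(0.225 * 445) == 101
        rng = np.random.default_rng(0)
        base = rng.integers(100, 200, size=(3, 445))
        counts = np.vstack([base, np.zeros((1, 445), dtype=int)])
        counts[3, :100] = 10_000  # high CPM in exactly 100 samples: removed
        counts[2, :101] = 10_000  # resets row 2: high CPM in exactly 101
        counts[2, 101:] = 0
        cm = make_counts(counts)
        kept, report = filter_genes(cm, min_length_bp=0)
        assert "G2" in list(kept.gene_ids)
        assert "G3" not in list(kept.gene_ids)

    def test_boundary_cpm_retained(self):
        # library size 1e6 and count 1 puts the gene at CPM exactly 1.0 in
        # every sample; removal is strict "less than", so the gene stays
        counts = np.vstack([np.ones(4, dtype=int),
                            np.full(4, 999_999, dtype=int)])
        kept, _ = filter_genes(make_counts(counts), min_length_bp=0,
                               cpm_threshold=1.0, min_samples_frac=1.0)
        assert "G0" in list(kept.gene_ids)

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        cm = make_counts(rng.integers(0, 50, size=(30, 10)))
        once, _ = filter_genes(cm, min_length_bp=0)
        twice, _ = filter_genes(once, min_length_bp=0)
        assert list(once.gene_ids) == list(twice.gene_ids)

    def test_all_removed_raises(self):
        cm = make_counts([[0, 1], [1, 0]])
        with pytest.raises(ValueError, match="relax"):
            filter_genes(cm, min_length_bp=0, cpm_threshold=1e9)


class TestCpm:
    def test_arithmetic(self):
        cm = make_counts([[1, 1], [3, 3]])
        np.testing.assert_allclose(cpm(cm)[:, 0], [250_000, 750_000])

    def test_columns_sum_to_million(self):
        rng = np.random.default_rng(2)
        cm = make_counts(rng.integers(1, 100, size=(20, 5)))
        np.testing.assert_allclose(cpm(cm).sum(axis=0), 1e6)

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(1, 100, size=(20, 3))
        doubled = counts.copy()
        doubled[:, 1] *= 2
        np.testing.assert_allclose(cpm(make_counts(counts))[:, 1],
                                   cpm(make_counts(doubled))[:, 1])

    def test_zero_library_raises(self):
        with pytest.raises(ValueError, match="library"):
            cpm(make_counts([[0, 1], [0, 2]]))

    def test_log_cpm_monotone_in_counts(self):
        cm1 = make_counts([[5, 10], [20, 30]])
        cm2 = make_counts([[6, 10], [20, 30]])
        l1 = log_cpm(cm1, np.ones(2))
        l2 = log_cpm(cm2, np.ones(2))
        assert l2[0, 0] > l1[0, 0]


class TestTmm:
    def test_identical_samples_give_unit_factors(self):
        cm = make_counts(np.tile([[10], [20], [30]], (1, 4)))
        np.testing.assert_allclose(tmm_factors(cm), 1.0)

    def test_pure_depth_difference_cancels(self):
        rng = np.random.default_rng(4)
        base = rng.integers(10, 100, size=(50, 1))
        counts = np.hstack([base, base * 2, base * 3])
        np.testing.assert_allclose(tmm_factors(make_counts(counts)), 1.0)

    def test_per_sample_scale_invariance(self):
        rng = np.random.default_rng(5)
        counts = rng.integers(5, 500, size=(200, 4))
        f1 = tmm_factors(make_counts(counts))
        scaled = counts.copy()
        scaled[:, 2] *= 7
        f2 = tmm_factors(make_counts(scaled))
        np.testing.assert_allclose(f1, f2, atol=5e-2)

    def test_matches_independent_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            counts = rng.negative_binomial(5, 0.1, size=(150, 4)) + 1
            # inflate some genes in one sample to create asymmetry
            idx = rng.choice(150, 15, replace=False)
            counts[idx, 0] *= 8
            got = tmm_factors(make_counts(counts))
            want = tmm_oracle(counts)
            np.testing.assert_allclose(got, want, atol=1e-10)

    def test_single_sample_raises(self):
        with pytest.raises(ValueError, match="2 samples"):
            tmm_factors(make_counts([[1], [2]]))


class TestInverseNormal:
    def test_n3_formula(self):
        out = inverse_normal(np.array([1.0, 5.0, 3.0]))
        want = stats.norm.ppf((np.array([1, 3, 2]) - 0.375) / 3.25)
        np.testing.assert_allclose(out, want)

    def test_standardized_at_large_n(self):
        rng = np.random.default_rng(7)
        out = inverse_normal(rng.exponential(size=1000))
        assert abs(out.mean()) < 0.01
        assert abs(out.std(ddof=1) - 1.0) < 0.02

    def test_order_preserved(self):
        x = np.array([3.0, 1.0, 2.0, 10.0])
        out = inverse_normal(x)
        assert list(np.argsort(out)) == list(np.argsort(x))

    def test_constant_vector_raises(self):
        with pytest.raises(ValueError, match="constant"):
            inverse_normal(np.ones(5))
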