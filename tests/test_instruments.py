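import numpy as np
import pandas as pd
import pytest
from scipy import stats

from femr import (SimulationTruth, build_allele_score, filter_genes,
                  genetic_pcs, instrument_fstat, inverse_normal, normalize,
                  orient_dosage, scan_cis_eqtl, simulate_cohort,
                  target_gene_locus, validate_proxy, validity_screen,
                  weights_from_truth)
from femr.instruments import EqtlProxy, InstrumentWeights
from femr.types import PhenotypeTable

from conftest import make_genotypes


def eqtl_scan_oracle(expr, geno, chrom, pos, window):
    """Exhaustive per-SNP OLS scan, coded independently of the scanner."""
    best = None
    n = len(expr)
    for i in range(geno.n_snps):
        if str(geno.chrom[i]) != str(chrom):
            continue
        if not (pos - window <= geno.pos[i] <= pos + window):
            continue
        if geno.maf[i] < 0.01:
            continue
        d = geno.dosages[i]
        X = np.column_stack([np.ones(n), d])
        beta, *_ = np.linalg.lstsq(X, expr, rcond=None)
        resid = expr - X @ beta
        s2 = resid @ resid / (n - 2)
        se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
        t = beta[1] / se
        p = 2 * stats.t.sf(abs(t), n - 2)
        if best is None or p < best[1]:
            best = (str(geno.snp_ids[i]), p, float(t))
    return best


@pytest.fixture(scope="module")
def eqtl_setup(small_cohort):
    counts, pheno, geno, truth = small_cohort
    filtered, rep = filter_genes(counts)
    norm = normalize(filtered, rep)
    gi = list(filtered.gene_ids).index(truth.target_gene)
    expr = inverse_normal(norm.logcpm[gi])
    return expr, geno, truth


class TestFstat:
    def test_closed_form(self):
        assert instrument_fstat(0.5, 102, 1) == pytest.approx(100.0)
        assert instrument_fstat(0.0, 50) == 0.0

    def test_equals_squared_t(self):
        rng = np.random.default_rng(30)
        d = rng.binomial(2, 0.3, 120).astype(float)
        y = 0.3 * d + rng.normal(size=120)
        res = stats.linregress(d, y)
        f = instrument_fstat(res.rvalue ** 2, 120, 1)
        t = res.slope / res.stderr
        assert f == pytest.approx(t * t, rel=1e-6)

    def test_domain_checks(self):
        with pytest.raises(ValueError):
            instrument_fstat(1.0, 100)
        with pytest.raises(ValueError):
            instrument_fstat(0.5, 2)


class TestScanCisEqtl:
    def test_matches_exhaustive_oracle(self, eqtl_setup):
        expr, geno, truth = eqtl_setup
        proxy = scan_cis_eqtl(expr, geno, target_gene_locus(truth),
                              truth.target_gene)
        want_rsid, want_p, want_t = eqtl_scan_oracle(
            expr, geno, *target_gene_locus(truth), 1_000_000)
        assert proxy.rsid == want_rsid
        assert proxy.p == pytest.approx(want_p, rel=1e-9)
        assert proxy.fstat == pytest.approx(want_t ** 2, rel=1e-9)

    def test_fstat_r2_identity(self, eqtl_setup):
        expr, geno, truth = eqtl_setup
        proxy = scan_cis_eqtl(expr, geno, target_gene_locus(truth))
        want = proxy.r2 * (proxy.n - 2) / (1 - proxy.r2)
        assert proxy.fstat == pytest.approx(want, abs=1e-9)

    def test_recovers_causal_snp(self, eqtl_setup):
        expr, geno, truth = eqtl_setup
        proxy = scan_cis_eqtl(expr, geno, target_gene_locus(truth))
        assert proxy.rsid == truth.eqtl_snp

    def test_weak_flag_threshold(self):
        proxy = EqtlProxy("g", "rs1", "1", 100, "A", "G", True,
                          0.1, 0.05, 0.01, 0.024, 9.99, 400)
        assert proxy.weak
        proxy.fstat = 10.0
        assert not proxy.weak

    def test_empty_window_errors(self, eqtl_setup):
        expr, geno, truth = eqtl_setup
        with pytest.raises(ValueError, match="cis window"):
            scan_cis_eqtl(expr, geno, ("22", 1_000), window_bp=10)


class TestOrientDosage:
    def _proxy(self, eff_is_alt=True):
        return EqtlProxy("g", "rs0", "1", 1000, "G" if eff_is_alt else "A",
                         "A" if eff_is_alt else "G", eff_is_alt,
                         0.4, 0.1, 1e-8, 0.1, 40.0, 3)

    def test_inducer_identity_inhibitor_reflection(self):
        geno = make_genotypes([[0.0, 1.0, 2.0]])
        proxy = self._proxy()
        np.testing.assert_allclose(orient_dosage(proxy, geno, "inducer"), [0, 1, 2])
        np.testing.assert_allclose(orient_dosage(proxy, geno, "inhibitor"), [2, 1, 0])

    def test_ref_effect_allele_flips_first(self):
        geno = make_genotypes([[0.0, 1.0, 2.0]])
        proxy = self._proxy(eff_is_alt=False)
        np.testing.assert_allclose(orient_dosage(proxy, geno, "agonist"), [2, 1, 0])

    def test_double_inhibitor_is_involution(self):
        geno = make_genotypes([[0.0, 1.0, 2.0]])
        proxy = self._proxy()
        once = orient_dosage(proxy, geno, "inhibitor")
        assert np.allclose(2.0 - once, orient_dosage(proxy, geno, "inducer"))

    def test_unknown_action_errors(self):
        geno = make_genotypes([[0.0, 1.0, 2.0]])
        with pytest.raises(ValueError, match="action"):
            orient_dosage(self._proxy(), geno, "modulator")


class TestValidateProxy:
    def _replication(self, beta, seed, n=150):
        rng = np.random.default_rng(seed)
        geno = make_genotypes(rng.binomial(2, 0.3, (1, n)).astype(float),
                              snp_ids=np.array(["rs0"], dtype=object))
        expr = beta * geno.dosages[0] + rng.normal(size=n)
        return inverse_normal(expr), geno

    def _proxy(self):
        return EqtlProxy("g", "rs0", "1", 1000, "G", "A", True,
                         0.4, 0.1, 1e-8, 0.1, 40.0, 150)

    def test_same_sign_replication_validates(self):
        proxy = validate_proxy(self._proxy(), [self._replication(0.5, 31)])
        assert proxy.validated is True

    def test_opposite_sign_not_validated(self):
        proxy = validate_proxy(self._proxy(), [self._replication(-0.5, 32)])
        assert proxy.validated is False

    def test_null_replications_not_validated(self):
        reps = [self._replication(0.0, 33), self._replication(0.0, 34)]
        assert validate_proxy(self._proxy(), reps).validated is False

    def test_absent_snp_untestable(self):
        expr, geno = self._replication(0.5, 35)
        geno = make_genotypes(geno.dosages, snp_ids=np.array(["rsX"], dtype=object))
        assert validate_proxy(self._proxy(), [(expr, geno)]).validated is None


class TestAlleleScore:
    def _weights(self, rsids, eff, oth, beta, ambiguous=None):
        n = len(rsids)
        return InstrumentWeights(
            rsid=np.array(rsids, dtype=object),
            effect_allele=np.array(eff, dtype=object),
            other_allele=np.array(oth, dtype=object),
            beta=np.array(beta, dtype=float),
            ambiguous=np.array(ambiguous if ambiguous is not None else [False] * n),
        )

    def test_linearity(self):
        geno = make_genotypes([[0.0, 1.0, 2.0]])
        w = self._weights(["rs0"], ["G"], ["A"], [0.5])
        score = build_allele_score(geno, w)
        np.testing.assert_allclose(score.values, [0.0, 0.5, 1.0])

    def test_ref_effect_allele_flips_dosage(self):
        geno = make_genotypes([[0.0, 1.0, 2.0]])
        w = self._weights(["rs0"], ["A"], ["G"], [0.5])  # effect = ref allele
        score = build_allele_score(geno, w)
        np.testing.assert_allclose(score.values, [1.0, 0.5, 0.0])

    def test_ambiguous_snp_dropped(self):
        geno = make_genotypes([[0.0, 1.0, 2.0], [2.0, 1.0, 0.0]])
        w = self._weights(["rs0", "rs1"], ["G", "A"], ["A", "T"], [0.5, 9.0],
                          ambiguous=[False, True])
        score = build_allele_score(geno, w)
        assert score.n_dropped_ambiguous == 1
        assert score.n_snps_used == 1
        np.testing.assert_allclose(score.values, [0.0, 0.5, 1.0])

    def test_irreconcilable_alleles_dropped(self):
        geno = make_genotypes([[0.0, 1.0, 2.0]])
        w = self._weights(["rs0"], ["C"], ["T"], [0.5])
        with pytest.raises(ValueError, match="matched"):
            build_allele_score(geno, w)

    def test_snp_order_and_genotype_recoding_invariance(self):
        rng = np.random.default_rng(36)
        dos = rng.binomial(2, 0.4, (3, 50)).astype(float)
        geno = make_genotypes(dos)
        w1 = self._weights(["rs0", "rs1", "rs2"], ["G", "G", "G"],
                           ["A", "A", "A"], [0.2, 0.3, 0.4])
        w2 = self._weights(["rs2", "rs0", "rs1"], ["G", "G", "G"],
                           ["A", "A", "A"], [0.4, 0.2, 0.3])
        s1 = build_allele_score(geno, w1).values
        np.testing.assert_allclose(build_allele_score(geno, w2).values, s1)
        # recode rs1 in the genotype matrix (swap ref/alt, flip dosage):
        # harmonization must undo it, leaving the score unchanged
        dos2 = dos.copy()
        dos2[1] = 2.0 - dos2[1]
        geno2 = make_genotypes(dos2,
                               ref=np.array(["A", "G", "A"], dtype=object),
                               alt=np.array(["G", "A", "G"], dtype=object))
        np.testing.assert_allclose(build_allele_score(geno2, w1).values, s1)

    def test_diagnostics_f_matches_formula(self):
        rng = np.random.default_rng(37)
        geno = make_genotypes(rng.binomial(2, 0.4, (5, 200)).astype(float))
        w = self._weights([f"rs{i}" for i in range(5)], ["G"] * 5, ["A"] * 5,
                          rng.uniform(0.1, 0.5, 5))
        score_only = build_allele_score(geno, w)
        x = score_only.values + rng.normal(0, 1.0, 200)
        score = build_allele_score(geno, w, exposure=x)
        want = instrument_fstat(score.r2_vs_exposure, 200)
        assert score.fstat == pytest.approx(want, rel=1e-9)


class TestGeneticPcs:
    def test_orthogonal_and_deterministic(self):
        rng = np.random.default_rng(38)
        geno = make_genotypes(rng.binomial(2, 0.3, (40, 60)).astype(float))
        pcs = genetic_pcs(geno, n_pcs=5)
        gram = pcs.T @ pcs
        assert np.all(np.abs(gram - np.diag(np.diag(gram))) < 1e-9)
        np.testing.assert_array_equal(pcs, genetic_pcs(geno, n_pcs=5))

    def test_separates_subpopulations(self):
        rng = np.random.default_rng(39)
        n_half = 50
        maf_a = rng.uniform(0.05, 0.5, 80)
        maf_b = np.clip(maf_a + rng.choice([-0.3, 0.3], 80), 0.02, 0.95)
        d = np.hstack([rng.binomial(2, maf_a[:, None], (80, n_half)),
                       rng.binomial(2, maf_b[:, None], (80, n_half))]).astype(float)
        pcs = genetic_pcs(make_genotypes(d), n_pcs=2)
        group = np.r_[np.zeros(n_half), np.ones(n_half)]
        r = np.corrcoef(pcs[:, 0], group)[0, 1]
        assert abs(r) > 0.9

    def test_too_many_pcs_rejected(self):
        geno = make_genotypes(np.zeros((5, 4)) + 1.0)
        with pytest.raises(ValueError, match="n_pcs"):
            genetic_pcs(geno, n_pcs=4)


class TestValidityScreen:
    def test_score_built_for_exposure_is_reliable(self, small_bundle):
        bundle, sig, truth = small_bundle
        geno, pheno = bundle.geno, bundle.pheno
        w = weights_from_truth(truth, geno)
        score = build_allele_score(geno, w,
                                   exposure=pheno.data["bmi"].to_numpy(float),
                                   exposure_name="bmi")
        df = pheno.data.copy()
        rng = np.random.default_rng(40)
        df["unrelated"] = rng.normal(size=len(df))
        table, reliable = validity_screen(score, PhenotypeTable(df),
                                          ["bmi", "unrelated"], "bmi")
        assert reliable
        own_p = table.set_index("variable").loc["bmi", "p"]
        assert own_p < 0.01

    def test_null_instrument_unreliable(self, small_bundle):
        bundle, sig, truth = small_bundle
        rng = np.random.default_rng(41)
        noise = rng.normal(size=len(bundle.pheno))
        table, reliable = validity_screen(noise, bundle.pheno, ["bmi"], "bmi")
        assert not reliable
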