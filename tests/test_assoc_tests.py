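"""Score tests, saddlepoint correction, Firth estimates and Step-2 batching."""

import filecmp

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.stats import binom, norm

from mixedgwas import (GenotypeMatrix, NullModelConfig, PhenotypeTable,
                       SimConfig, SPAWorkspace, TraitManifest, VariantRecord,
                       fit_null_glmm, firth_effect, run_step2, score_test,
                       score_test_batch, simulate_genotypes,
                       simulate_phenotype, spa_pvalue)
from mixedgwas.io_formats import (read_results, save_null_model,
                                  save_variance_ratio, write_manifest,
                                  write_plink)

from conftest import random_operator


def _intercept_only_fit(Y, n, G=None, rng=None):
    pheno = PhenotypeTable([f"s{i}" for i in range(n)], Y, np.ones((n, 1)),
                           "binary", ["intercept"])
    G = G if G is not None else random_operator(
        rng or np.random.default_rng(0), n, 40)
    return fit_null_glmm(pheno, G, NullModelConfig(tol=1e-10, max_outer=60),
                         tau_fixed=0.0)


def cochran_armitage_chi2(g, y):
    """Trend chi^2 from the 2x3 contingency table (independent oracle)."""
    n = len(y)
    table = np.zeros((2, 3))
    for gi, yi in zip(g.astype(int), y.astype(int)):
        table[yi, gi] += 1
    scores = np.array([0.0, 1.0, 2.0])
    col = table.sum(axis=0)
    row = table.sum(axis=1)
    t_obs = (table[1] * scores).sum()
    e = row[1] * (col * scores).sum() / n
    var = row[0] * row[1] / (n - 0) / n * (
        n * (col * scores**2).sum() - ((col * scores).sum())**2) / n
    return (t_obs - e)**2 / var


class TestScoreTest:
    def test_matches_cochran_armitage_trend_chi2(self, rng):
        n = 300
        Y = (rng.random(n) < 0.4).astype(float)
        fit = _intercept_only_fit(Y, n, rng=rng)
        fit.variance_ratio = 1.0
        g = rng.binomial(2, 0.3, size=n).astype(float)
        res = score_test(g, fit)
        chi2 = res.T**2 / res.var
        assert chi2 == pytest.approx(cochran_armitage_chi2(g, Y), rel=1e-8)

    def test_variant_orthogonal_to_residuals_gives_null_score(self, rng):
        n = 200
        Y = (rng.random(n) < 0.5).astype(float)
        fit = _intercept_only_fit(Y, n, rng=rng)
        # polymorphic vector orthogonal to the residuals by construction
        g = rng.standard_normal(n)
        r = fit.residuals
        g = g - (g @ r) / (r @ r) * r
        g = g - g.min()
        res = score_test(g, fit)
        assert res.T == pytest.approx(0.0, abs=1e-8)
        assert res.p_normal == pytest.approx(1.0)

    def test_monomorphic_variant_flagged_untestable(self, rng):
        n = 100
        Y = (rng.random(n) < 0.5).astype(float)
        fit = _intercept_only_fit(Y, n, rng=rng)
        res = score_test(np.full(n, 2.0), fit)
        assert not res.testable
        assert res.p_normal is None and res.p_spa is None

    def test_effect_sign_matches_score_sign(self, rng):
        n = 500
        Y = (rng.random(n) < 0.3).astype(float)
        fit = _intercept_only_fit(Y, n, rng=rng)
        G = rng.binomial(2, rng.uniform(0.1, 0.5, 50), size=(n, 50)).astype(float)
        variants = [VariantRecord("1", j + 1, f"v{j}", "A", "G")
                    for j in range(50)]
        for res in score_test_batch(G, variants, fit):
            if res.testable and res.T != 0:
                assert np.sign(res.beta) == np.sign(res.T)


class TestSPA:
    def _workspace(self, n=500, n_cases=5, n_carriers=10, q_shift=0.0):
        mu = np.full(n, n_cases / n)
        g = np.zeros(n)
        g[:n_carriers] = 1.0
        g_t = g - g.mean()
        q = float(g_t @ mu) + q_shift
        return SPAWorkspace(g_t, mu, q)

    def test_score_at_its_mean_gives_p_one(self):
        ws = self._workspace(q_shift=0.0)
        p, converged = spa_pvalue(ws)
        assert p == 1.0 and converged

    def test_workspace_cgf_identities(self):
        ws = self._workspace()
        assert ws.K(0.0) == pytest.approx(0.0, abs=1e-12)
        assert ws.Kprime(0.0) == pytest.approx(ws.mean, rel=1e-12)
        assert ws.Kpp(0.0) == pytest.approx(ws.var0, rel=1e-12)
        assert ws.var0 > 0

    @staticmethod
    def _exact_score_distribution(n, n_carriers, mu):
        """Exact pmf of S = sum g~_i Y_i by convolving the two binomial
        blocks (carriers at value 1-gbar, non-carriers at -gbar)."""
        gbar = n_carriers / n
        k_car = np.arange(n_carriers + 1)
        k_non = np.arange(n - n_carriers + 1)
        pm_car = binom.pmf(k_car, n_carriers, mu)
        pm_non = binom.pmf(k_non, n - n_carriers, mu)
        support = ((1 - gbar) * k_car[:, None] - gbar * k_non[None, :]).ravel()
        pmf = (pm_car[:, None] * pm_non[None, :]).ravel()
        order = np.argsort(support)
        return support[order], pmf[order]

    def test_matches_exact_convolution_in_far_tail(self):
        """Under 1:99 imbalance the SPA p tracks the exact score
        distribution's mid-p tail (the quantity a continuous approximation
        to a lattice variable targets) to ~10% relative at the 1e-4 level,
        where the normal approximation is off severalfold."""
        n, n_cases, n_carriers = 2000, 20, 500
        mu = n_cases / n
        support, pmf = self._exact_score_distribution(n, n_carriers, mu)
        mean = float(support @ pmf)
        g_t = self._g(n, n_carriers)
        mu_vec = np.full(n, mu)
        checked = 0
        for s_obs in np.unique(np.round(support, 10))[::-1]:
            upper = pmf[support >= s_obs - 1e-9].sum()
            atom = pmf[np.abs(support - s_obs) < 1e-9].sum()
            lower = pmf[support <= 2 * mean - s_obs + 1e-9].sum()
            exact_midp = (upper - 0.5 * atom) + lower
            if not (1e-5 < exact_midp < 1e-3):
                continue
            ws_obs = SPAWorkspace(g_t, mu_vec, s_obs)
            p_spa, converged = spa_pvalue(ws_obs)
            assert converged
            assert p_spa == pytest.approx(exact_midp, rel=0.10)
            # the normal approximation is badly miscalibrated out here
            z = (s_obs - ws_obs.mean) / np.sqrt(ws_obs.var0)
            p_norm = 2 * norm.sf(abs(z))
            assert not (0.5 < p_norm / exact_midp < 2.0)
            checked += 1
        assert checked >= 5

    @staticmethod
    def _g(n, n_carriers):
        g = np.zeros(n)
        g[:n_carriers] = 1.0
        return g - g.mean()

    def test_agrees_with_normal_in_balanced_regime(self):
        n = 2000
        mu = np.full(n, 0.5)
        rng = np.random.default_rng(4)
        g = rng.binomial(2, 0.3, n).astype(float)
        g_t = g - g.mean()
        mean = float(g_t @ mu)
        sd = np.sqrt(float(g_t**2 @ (mu * (1 - mu))))
        q = mean + 2.5 * sd  # moderate deviation
        ws = SPAWorkspace(g_t, mu, q)
        p_spa, converged = spa_pvalue(ws)
        p_norm = 2 * norm.sf(2.5)
        assert converged
        assert abs(p_spa - p_norm) / p_norm < 0.05

    def test_rare_variant_calibration_by_exact_enumeration(self):
        """1:99 imbalance, MAF 0.5%: the exact alpha=0.01 rejection rate of
        the two-sided normal p is inflated (~1.6x) while the SPA p stays
        within (0.005, 0.015).  Computed by full convolution — no
        simulation noise."""
        n, n_cases, maf = 20_000, 200, 0.005
        mu = n_cases / n
        n_het = int(round(2 * maf * (1 - maf) * n))
        g = np.zeros(n)
        g[:n_het] = 1.0  # hom-alt carriers negligible at this MAF
        g_t = g - g.mean()
        support, pmf = self._exact_score_distribution(n, n_het, mu)
        mean = float(support @ pmf)
        sd = np.sqrt(float(((support - mean) ** 2) @ pmf))
        z_crit = norm.isf(0.005)
        rate_norm = pmf[np.abs(support - mean) > z_crit * sd].sum()
        assert rate_norm > 0.014
        mu_vec = np.full(n, mu)
        rate_spa = 0.0
        for s, p_atom in zip(*[a[pmf > 1e-10] for a in (support, pmf)]):
            p_spa, ok = spa_pvalue(SPAWorkspace(g_t, mu_vec, s))
            if ok and p_spa < 0.01:
                rate_spa += p_atom
        assert 0.005 < rate_spa < 0.015

    def test_p_monotone_in_score_deviation(self):
        n = 500
        mu = np.full(n, 0.05)
        g_t = self._g(n, 25)
        mean = float(g_t @ mu)
        sd = np.sqrt(float(g_t**2 @ (mu * (1 - mu))))
        prev = 1.1
        for dev in np.linspace(0.0, 4.0, 17):
            p, _ = spa_pvalue(SPAWorkspace(g_t, mu, mean + dev * sd))
            assert p <= prev + 1e-12
            prev = p


class TestFirth:
    def _penalized_ll(self, theta, D, Y):
        eta = D @ theta
        mu = 1 / (1 + np.exp(-eta))
        w = mu * (1 - mu)
        sign, logdet = np.linalg.slogdet(D.T @ (D * w[:, None]))
        if sign <= 0:
            return -np.inf
        return float(Y @ eta - np.logaddexp(0, eta).sum()) + 0.5 * logdet

    def test_separated_data_yields_finite_estimate(self):
        # complete separation: every carrier is a case
        g = np.array([0.0] * 10 + [1.0] * 5)
        y = np.array([0.0] * 10 + [1.0] * 5)
        X = np.ones((15, 1))
        beta, se, converged = firth_effect(g, X, y)
        assert converged and np.isfinite(beta) and np.isfinite(se)
        # the unpenalized MLE diverges: likelihood increases without bound
        ll = [float(y @ (X[:, 0] * a + g * b) -
                    np.logaddexp(0, X[:, 0] * a + g * b).sum())
              for a, b in [(-2, 5), (-4, 10), (-8, 20), (-16, 40)]]
        assert all(np.diff(ll) > 0)
        assert abs(beta) < 10

    def test_symmetric_data_gives_zero_effect(self):
        # flipping Y and recoding G maps the data to itself
        g = np.array([0.0, 0, 1, 1, 2, 2, 0, 0, 1, 1, 2, 2])
        y = np.array([0.0, 1, 0, 1, 0, 1, 1, 0, 1, 0, 1, 0])
        beta, _, converged = firth_effect(g, np.ones((12, 1)), y)
        assert converged
        assert beta == pytest.approx(0.0, abs=1e-8)

    def test_matches_brute_force_penalized_optimizer(self, rng):
        n = 30
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        g = rng.binomial(2, 0.3, n).astype(float)
        y = (rng.random(n) < 0.4).astype(float)
        beta, _, converged = firth_effect(g, X, y)
        D = np.column_stack([X, g])
        ref = minimize(lambda th: -self._penalized_ll(th, D, y),
                       np.zeros(3), method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12,
                                "maxiter": 5000})
        assert converged
        assert beta == pytest.approx(ref.x[-1], abs=1e-5)


@pytest.fixture(scope="module")
def trait_setup(tmp_path_factory):
    tmp = tmp_path_factory.mktemp("step2")
    cfg = SimConfig(n_samples=400, n_variants=600, trait_type="binary",
                    prevalence=0.2, tau=0.5,
                    family_structure="sib_pairs", seed=31)
    G, _ = simulate_genotypes(cfg)
    paths = {}
    for k, seed in (("t1", 1), ("t2", 2)):
        pheno = simulate_phenotype(G, cfg, rng=np.random.default_rng(seed))
        fit = fit_null_glmm(pheno, G)
        fit.variance_ratio = 0.9
        save_null_model(fit, str(tmp / f"{k}.model.json"))
        save_variance_ratio(0.9, str(tmp / f"{k}.vr.json"))
        paths[k] = (str(tmp / f"{k}.model.json"), str(tmp / f"{k}.vr.json"))
    bed_prefix = str(tmp / "geno")
    write_plink(bed_prefix, G.counts, G.sample_ids, G.variants)
    return tmp, bed_prefix, paths, G


class TestStep2:
    def _manifest(self, tmp, paths, tag):
        out = {k: str(tmp / f"{k}.{tag}.out.tsv") for k in paths}
        manifest = TraitManifest(
            list(paths), [paths[k][0] for k in paths],
            [paths[k][1] for k in paths], [out[k] for k in paths])
        return manifest, out

    def test_chunked_parallel_run_is_byte_identical_to_serial(
            self, trait_setup):
        tmp, bed_prefix, paths, _ = trait_setup
        m1, out1 = self._manifest(tmp, paths, "serial")
        m2, out2 = self._manifest(tmp, paths, "chunked")
        run_step2(m1, ("bed", bed_prefix), chunks=1, workers=1)
        run_step2(m2, ("bed", bed_prefix), chunks=8, workers=4)
        for k in paths:
            assert filecmp.cmp(out1[k], out2[k], shallow=False)

    def test_single_trait_manifest_equals_direct_invocation(
            self, trait_setup):
        tmp, bed_prefix, paths, G = trait_setup
        from mixedgwas.io_formats import load_null_model, load_variance_ratio
        manifest = TraitManifest(["t1"], [paths["t1"][0]], [paths["t1"][1]],
                                 [str(tmp / "single.out.tsv")])
        run_step2(manifest, ("bed", bed_prefix))
        fit = load_null_model(paths["t1"][0])
        fit.variance_ratio = load_variance_ratio(paths["t1"][1])
        from mixedgwas.assoc_tests import load_genotype_source
        variants, D, _ = load_genotype_source(("bed", bed_prefix))
        direct = score_test_batch(D.T, variants, fit)
        tab = read_results(str(tmp / "single.out.tsv"))
        np.testing.assert_allclose(tab["Tstat"].to_numpy(),
                                   [r.T for r in direct], rtol=1e-9)

    def test_spa_trigger_accounting_recounts_from_output(self, trait_setup):
        tmp, bed_prefix, paths, _ = trait_setup
        manifest = TraitManifest(["t1"], [paths["t1"][0]], [paths["t1"][1]],
                                 [str(tmp / "acct.out.tsv")])
        stats = run_step2(manifest, ("bed", bed_prefix), spa_trigger=2.0)[0]
        tab = read_results(str(tmp / "acct.out.tsv"))
        z = np.abs(tab["Tstat"] / np.sqrt(tab["var"]))
        assert stats.n_spa_applied == int((z > 2.0).sum())
        assert stats.n_tested + stats.n_dropped == stats.n_variants

    def test_dosage_source_equals_hard_call_source(self, trait_setup,
                                                   tmp_path):
        """A dosage TSV whose entries equal the (imputed) hard calls yields
        the same association statistics as the bed route."""
        tmp, bed_prefix, paths, G = trait_setup
        from mixedgwas.assoc_tests import load_genotype_source
        from mixedgwas.io_formats import read_dosages, write_dosages
        variants, D, sample_ids = load_genotype_source(("bed", bed_prefix))
        dosage_path = str(tmp_path / "dosages.tsv")
        write_dosages(dosage_path, variants, D, sample_ids)
        back_variants, back_D, back_ids = read_dosages(dosage_path)
        assert back_ids == sample_ids
        np.testing.assert_allclose(back_D, D, rtol=1e-9)
        out_bed = str(tmp_path / "bed.tsv")
        out_dos = str(tmp_path / "dos.tsv")
        run_step2(TraitManifest(["t1"], [paths["t1"][0]], [paths["t1"][1]],
                                [out_bed]), ("bed", bed_prefix))
        run_step2(TraitManifest(["t1"], [paths["t1"][0]], [paths["t1"][1]],
                                [out_dos]), ("dosage", dosage_path))
        t1, t2 = read_results(out_bed), read_results(out_dos)
        np.testing.assert_allclose(t1["Tstat"], t2["Tstat"], rtol=1e-8)
        np.testing.assert_allclose(t1["p_value"], t2["p_value"], rtol=1e-6)

    def test_sample_mismatch_fails_naming_the_trait(self, trait_setup,
                                                    tmp_path):
        tmp, bed_prefix, paths, G = trait_setup
        counts = G.counts[::-1]  # reversed sample order
        other = str(tmp_path / "other")
        write_plink(other, counts, list(reversed(G.sample_ids)), G.variants)
        manifest = TraitManifest(["t1"], [paths["t1"][0]], [paths["t1"][1]],
                                 [str(tmp_path / "x.tsv")])
        with pytest.raises(ValueError, match="t1"):
            run_step2(manifest, ("bed", other))
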