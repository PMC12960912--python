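"""Per-variant association testing against a fitted null model (Step 2).

Each variant gets a score test that reuses the single null fit: the dosage
vector is residualized against the covariates under the null weights,

    g~ = g - X (X'WX)^{-1} X'W g,
    T  = g~' (Y - mu),        var = r * g~' W g~,

where r is the variance ratio calibrating the cheap no-GRM variance to the
full-GRM one.  The normal approximation T / sqrt(var) ~ N(0,1) breaks down
in the far tails under extreme case-control imbalance, so whenever
|T|/sqrt(var) exceeds a trigger (default 2) the p-value is replaced by a
saddlepoint approximation (SPA) to the exact tail of the score, computed
from the cumulant generating function of the weighted Bernoulli sum
S = sum_i g~_i Y_i.  Optional Firth (Jeffreys-prior penalized) logistic
regression provides finite effect estimates under separation.

Variants are split into equal contiguous chunks processed independently
(threads optional); per-trait output is byte-identical regardless of chunk
count or worker count.  A trait manifest drives multi-trait batches.
"""

from __future__ import annotations

import logging
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from scipy.stats import norm

from . import io_formats
from .grm_engine import PartitionPlan
from .io_formats import MISSING, TraitManifest, VariantRecord
from .null_model import NullModelFit

log = logging.getLogger("mixedgwas")

#: residualized variance below this (per sample) is treated as monomorphic
_MONO_TOL = 1e-12


@dataclass
class ScoreTestResult:
    """One tested variant.  ``p_spa == p_normal`` unless SPA was triggered;
    untestable (monomorphic) variants carry no p-values."""

    variant: VariantRecord
    af: float
    n: int
    T: float | None
    var: float | None
    beta: float | None
    se: float | None
    p_normal: float | None
    p_spa: float | None
    spa_applied: bool
    spa_converged: bool
    testable: bool = True


# ---------------------------------------------------------------------------
# Saddlepoint approximation
# ---------------------------------------------------------------------------

class SPAWorkspace:
    """Cumulant generating function of S = sum_i g~_i Y_i with independent
    Y_i ~ Bernoulli(mu_i), plus the observed score q.

    Samples sharing an exact (g~, mu) pair are collapsed to one weighted
    term, so with a constant-mu null and hard calls each CGF evaluation
    costs O(#distinct genotype values) instead of O(N).
    """

    def __init__(self, g_tilde: np.ndarray, mu: np.ndarray, q: float):
        g_tilde = np.asarray(g_tilde, float)
        mu = np.asarray(mu, float)
        pairs, counts = np.unique(g_tilde + 1j * mu, return_counts=True)
        self.v = pairs.real
        self.mu = pairs.imag
        self.c = counts.astype(float)
        self.q = float(q)
        self._logit_mu = np.log(self.mu) - np.log1p(-self.mu)
        self._log1m_mu = np.log1p(-self.mu)
        self.mean = float(np.sum(self.c * self.v * self.mu))
        self.var0 = float(np.sum(self.c * self.v**2 * self.mu * (1 - self.mu)))
        if not self.var0 > 0:
            raise ValueError("score has zero variance; SPA undefined")

    def K(self, t: float) -> float:
        # log(1 - mu + mu e^{vt}) computed as logaddexp for stability
        return float(np.sum(self.c * np.logaddexp(
            self._log1m_mu, np.log(self.mu) + self.v * t)))

    def Kprime(self, t: float) -> float:
        s = expit(self._logit_mu + self.v * t)
        return float(np.sum(self.c * self.v * s))

    def Kpp(self, t: float) -> float:
        s = expit(self._logit_mu + self.v * t)
        return float(np.sum(self.c * self.v**2 * s * (1 - s)))

    @property
    def support(self) -> tuple[float, float]:
        return (float(np.sum(self.c * np.minimum(self.v, 0.0))),
                float(np.sum(self.c * np.maximum(self.v, 0.0))))


def _solve_saddlepoint(ws: SPAWorkspace, q: float,
                       max_iter: int = 100) -> tuple[float, bool]:
    """Root of K'(zeta) = q by safeguarded Newton (bisection fallback on a
    bracketing interval); K' is strictly increasing."""
    if q > ws.mean:
        lo, hi = 0.0, 1.0 / max(np.abs(ws.v).max(), 1e-300)
        for _ in range(200):
            if ws.Kprime(hi) >= q:
                break
            lo, hi = hi, hi * 2
        else:
            return hi, False
    else:
        hi, lo = 0.0, -1.0 / max(np.abs(ws.v).max(), 1e-300)
        for _ in range(200):
            if ws.Kprime(lo) <= q:
                break
            hi, lo = lo, lo * 2
        else:
            return lo, False
    zeta = 0.5 * (lo + hi)
    for _ in range(max_iter):
        f = ws.Kprime(zeta) - q
        if abs(f) <= 1e-10 * (abs(q) + np.sqrt(ws.var0)):
            return zeta, True
        if f > 0:
            hi = zeta
        else:
            lo = zeta
        fp = ws.Kpp(zeta)
        step = f / fp if fp > 0 else np.inf
        cand = zeta - step
        zeta = cand if lo < cand < hi else 0.5 * (lo + hi)
        if hi - lo < 1e-14 * (1 + abs(zeta)):
            return zeta, True
    return zeta, False


def _tail_probability(ws: SPAWorkspace, q: float, upper: bool,
                      zeta_tol: float = 1e-4) -> tuple[float, bool]:
    """Barndorff-Nielsen tail P(S >= q) (upper) or P(S <= q) (lower)."""
    smin, smax = ws.support
    if upper and q > smax:
        return 0.0, True
    if not upper and q < smin:
        return 0.0, True
    zeta, ok = _solve_saddlepoint(ws, q)
    if not ok:
        return np.nan, False
    if abs(zeta) < zeta_tol:  # central region: normal approximation
        z = (q - ws.mean) / np.sqrt(ws.var0)
        return float(norm.sf(z) if upper else norm.cdf(z)), True
    arg = zeta * q - ws.K(zeta)
    w = np.sign(zeta) * np.sqrt(max(2.0 * arg, 0.0))
    v = zeta * np.sqrt(ws.Kpp(zeta))
    if w == 0.0 or v / w <= 0:
        z = (q - ws.mean) / np.sqrt(ws.var0)
        return float(norm.sf(z) if upper else norm.cdf(z)), True
    u = w + np.log(v / w) / w
    return float(norm.sf(u) if upper else norm.cdf(u)), True


def spa_pvalue(ws: SPAWorkspace) -> tuple[float, bool]:
    """Two-sided saddlepoint p-value for the observed score ``ws.q``.

    Each tail is saddlepoint-evaluated separately at the symmetric points
    mean +- |q - mean| and summed (capped at 1).  If the root search fails
    the normal-approximation p is returned with ``converged=False``.
    """
    delta = abs(ws.q - ws.mean)
    z = delta / np.sqrt(ws.var0)
    p_normal = float(2.0 * norm.sf(z))
    if delta <= 1e-12 * np.sqrt(ws.var0):  # score at its null mean
        return 1.0, True
    p_up, ok_up = _tail_probability(ws, ws.mean + delta, upper=True)
    p_lo, ok_lo = _tail_probability(ws, ws.mean - delta, upper=False)
    if not (ok_up and ok_lo):
        return p_normal, False
    return float(min(1.0, p_up + p_lo)), True


# ---------------------------------------------------------------------------
# Score test
# ---------------------------------------------------------------------------

def _residualize(G: np.ndarray, X: np.ndarray, W: np.ndarray) -> np.ndarray:
    """g - X (X'WX)^{-1} X'W g for each column of G."""
    xtwx = X.T @ (X * W[:, None])
    coef = np.linalg.solve(xtwx, X.T @ (G * W[:, None]))
    return G - X @ coef


def score_test_batch(G: np.ndarray, variants, fit: NullModelFit,
                     spa_trigger: float = 2.0) -> list[ScoreTestResult]:
    """Score tests for the columns of the N x k dosage matrix ``G``."""
    G = np.asarray(G, dtype=np.float64)
    if G.ndim == 1:
        G = G[:, None]
    n, k = G.shape
    if n != len(fit.mu):
        raise ValueError("dosage rows disagree with null-model samples")
    r = fit.variance_ratio if fit.variance_ratio is not None else 1.0
    W, resid, mu = fit.W, fit.residuals, fit.mu
    af = G.mean(axis=0) / 2.0
    Gt = _residualize(G, fit.X, W)
    T = Gt.T @ resid
    v_no = np.einsum("ij,ij->j", Gt, Gt * W[:, None])
    testable = v_no > _MONO_TOL * n
    results: list[ScoreTestResult] = []
    for j in range(k):
        variant = variants[j]
        if not testable[j]:
            results.append(ScoreTestResult(
                variant=variant, af=float(af[j]), n=n, T=None, var=None,
                beta=None, se=None, p_normal=None, p_spa=None,
                spa_applied=False, spa_converged=False, testable=False))
            continue
        var = float(r * v_no[j])
        t = float(T[j])
        z = t / np.sqrt(var)
        p_norm = float(2.0 * norm.sf(abs(z)))
        p_spa, applied, spa_ok = p_norm, False, True
        if fit.trait_type == "binary" and abs(z) > spa_trigger:
            ws = SPAWorkspace(Gt[:, j], mu,
                              q=t + float(Gt[:, j] @ mu))
            p_spa, spa_ok = spa_pvalue(ws)
            applied = True
        results.append(ScoreTestResult(
            variant=variant, af=float(af[j]), n=n, T=t, var=var,
            beta=t / var, se=1.0 / np.sqrt(var), p_normal=p_norm,
            p_spa=p_spa, spa_applied=applied, spa_converged=spa_ok))
    return results


def score_test(Gj: np.ndarray, fit: NullModelFit,
               variant: VariantRecord | None = None,
               spa_trigger: float = 2.0) -> ScoreTestResult:
    """Score test for a single length-N dosage vector."""
    if variant is None:
        variant = VariantRecord(chrom="0", pos=1, id="variant", allele1="A",
                                allele2="B")
    return score_test_batch(np.asarray(Gj, float)[:, None], [variant], fit,
                            spa_trigger=spa_trigger)[0]


# ---------------------------------------------------------------------------
# Firth penalized logistic regression
# ---------------------------------------------------------------------------

def firth_effect(Gj: np.ndarray, X: np.ndarray, Y: np.ndarray,
                 max_iter: int = 50, tol: float = 1e-10,
                 ) -> tuple[float, float, bool]:
    """Jeffreys-penalized logistic effect of ``Gj`` adjusting for ``X``.

    Maximizes l(theta) + 0.5 log det I(theta) by Newton with step-halving;
    the penalty keeps estimates finite even under complete separation.
    Returns ``(beta, se, converged)`` for the genotype coefficient.
    """
    D = np.column_stack([X, np.asarray(Gj, float)])
    Y = np.asarray(Y, float)
    theta = np.zeros(D.shape[1])

    def penalized_ll(th: np.ndarray) -> float:
        eta = D @ th
        ll = float(Y @ eta - np.logaddexp(0.0, eta).sum())
        mu = expit(eta)
        w = mu * (1 - mu)
        sign, logdet = np.linalg.slogdet(D.T @ (D * w[:, None]))
        return ll + 0.5 * logdet if sign > 0 else -np.inf

    ll = penalized_ll(theta)
    converged = False
    info = None
    for _ in range(max_iter):
        eta = D @ theta
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), 1e-12, None)
        info = D.T @ (D * w[:, None])
        info_inv = np.linalg.inv(info)
        h = np.einsum("ij,jk,ik->i", D, info_inv, D) * w  # hat diagonal
        score = D.T @ (Y - mu + h * (0.5 - mu))
        step = info_inv @ score
        scale = 1.0
        for _ in range(20):  # step-halving on the penalized likelihood
            cand = theta + scale * step
            ll_new = penalized_ll(cand)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        theta = theta + scale * step
        ll = max(ll_new, ll)
        if np.max(np.abs(scale * step)) < tol * (1 + np.max(np.abs(theta))):
            converged = True
            break
    se = float(np.sqrt(np.linalg.inv(info)[-1, -1]))
    return float(theta[-1]), se, converged


# ---------------------------------------------------------------------------
# Chunked, manifest-driven Step 2
# ---------------------------------------------------------------------------

@dataclass
class Step2Stats:
    trait_id: str
    n_variants: int
    n_tested: int
    n_dropped: int
    n_spa_applied: int


def load_genotype_source(source: tuple[str, str]
                         ) -> tuple[list[VariantRecord], np.ndarray, list[str]]:
    """Load Step-2 dosages: ``("bed", prefix)`` hard calls (missing imputed
    to the variant mean) or ``("dosage", path)`` TSV.  Returns
    ``(variants, D, sample_ids)`` with D of shape (n_variants, N); all
    variants are kept, monomorphic ones surface as untestable rows."""
    kind, path = source
    if kind == "bed":
        counts, sample_ids, variants = io_formats.read_plink(path)
        D = counts.astype(np.float64).T  # M x N
        miss = counts.T == MISSING
        obs = ~miss
        with np.errstate(invalid="ignore"):
            mean = np.where(obs.sum(axis=1) > 0,
                            np.where(obs, D, 0).sum(axis=1) /
                            np.maximum(obs.sum(axis=1), 1), 0.0)
        D[miss] = np.broadcast_to(mean[:, None], D.shape)[miss]
        return variants, D, sample_ids
    if kind == "dosage":
        return io_formats.read_dosages(path)
    raise ValueError(f"unknown genotype source kind {kind!r}")


def _run_one_trait(trait_id: str, fit: NullModelFit, variants, D: np.ndarray,
                   chunks: int, workers: int, spa_trigger: float,
                   out_path: str, firth: bool = False,
                   firth_p_threshold: float = 0.05) -> Step2Stats:
    m = len(variants)
    plan = PartitionPlan.equal_chunks(m, max(1, min(chunks, m)))

    def run_chunk(rng_pair):
        s, e = rng_pair
        return score_test_batch(D[s:e].T, variants[s:e], fit,
                                spa_trigger=spa_trigger)

    if workers > 1 and plan.n_workers > 1:
        with ThreadPoolExecutor(max_workers=workers) as pool:
            chunk_results = list(pool.map(run_chunk, plan.ranges))
    else:
        chunk_results = [run_chunk(rng) for rng in plan.ranges]
    results = [res for chunk in chunk_results for res in chunk]
    if firth and fit.trait_type == "binary":
        # cost-bounded: refit effects only where the score test is small
        Y = fit.mu + fit.residuals
        for j, res in enumerate(results):
            if res.testable and res.p_spa is not None \
                    and res.p_spa < firth_p_threshold:
                beta, se, ok = firth_effect(D[j], fit.X, Y)
                if ok:
                    res.beta, res.se = beta, se
    io_formats.write_results(results, out_path)
    stats = Step2Stats(
        trait_id=trait_id, n_variants=m,
        n_tested=sum(r.testable for r in results),
        n_dropped=sum(not r.testable for r in results),
        n_spa_applied=sum(r.spa_applied for r in results))
    assert stats.n_tested + stats.n_dropped == stats.n_variants
    log.info("stage=step2 trait=%s variants=%d tested=%d dropped=%d "
             "spa_applied=%d spa_fraction=%.4g", trait_id, m, stats.n_tested,
             stats.n_dropped, stats.n_spa_applied,
             stats.n_spa_applied / max(stats.n_tested, 1))
    return stats


def run_step2(manifest: TraitManifest, genotype_source: tuple[str, str],
              chunks: int = 1, workers: int = 1,
              spa_trigger: float = 2.0, firth: bool = False,
              firth_p_threshold: float = 0.05) -> list[Step2Stats]:
    """Run association testing for every trait in the manifest.

    Variants are partitioned into ``chunks`` equal contiguous blocks,
    processed independently, and concatenated in original order; output is
    byte-identical to a single-chunk serial run.  Sample ids in each null
    model must match the genotype sample ids exactly.
    """
    io_formats.check_paths_exist(manifest)
    variants, D, sample_ids = load_genotype_source(genotype_source)
    stats = []
    for trait_id, model_path, vr_path, out_path in manifest.rows():
        fit = io_formats.load_null_model(model_path)
        fit.variance_ratio = io_formats.load_variance_ratio(vr_path)
        if list(fit.sample_ids) != list(sample_ids):
            raise ValueError(
                f"trait {trait_id!r}: null-model samples do not match "
                f"genotype samples")
        stats.append(_run_one_trait(trait_id, fit, variants, D, chunks,
                                    workers, spa_trigger, out_path,
                                    firth=firth,
                                    firth_p_threshold=firth_p_threshold))
    return stats
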