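"""Null-model fitting for mixed-model association (Step 1).

The binary-trait model is the logistic GLMM

    logit(mu_i) = X_i alpha + b_i,        b ~ N(0, tau * psi),

fit under the null hypothesis of no genetic effect; psi is the implicit GRM
from :mod:`.grm_engine`.  Fitting alternates penalized quasi-likelihood
(PQL) working-model updates of (alpha, b) with average-information REML
Newton steps on the variance component tau.  Every solve of the covariance
system

    Sigma x = b,      Sigma = W^{-1} + tau * psi

is matrix-free: Sigma enters only through elementwise division by the PQL
weights W and GRM matvecs, inside a Jacobi (diagonal) preconditioned
conjugate-gradient solver.  Quantitative traits use the gaussian analogue
Y = X alpha + b + eps with Sigma = phi I + tau psi and a joint (phi, tau)
AI-REML update.

The module also estimates the variance ratio r — the mean over a random
marker subset of (full-GRM score variance) / (no-GRM score variance) —
which Step 2 uses to calibrate its cheap test variances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.special import expit

from .grm_engine import GenotypeMatrix

log = logging.getLogger("mixedgwas")


class ConvergenceError(RuntimeError):
    """Raised when the outer fitting loop exhausts its iteration budget.

    Carries the last iterate in ``last_fit`` so callers can inspect it.
    """

    def __init__(self, message: str, last_fit: "NullModelFit | None" = None):
        super().__init__(message)
        self.last_fit = last_fit


@dataclass
class PCGReport:
    iterations: int
    final_relative_residual: float
    converged: bool


@dataclass
class NullModelConfig:
    """Tuning knobs for the null fit; defaults are desk-scale sensible."""

    tol: float = 1e-4            # outer relative-change tolerance on (alpha, tau)
    max_outer: int = 30
    max_inner: int = 20          # PQL working-model iterations per outer step
    pcg_tol: float = 1e-5        # relative residual for each Sigma solve
    pcg_maxit: int = 5000
    exact_trace_n: int = 2000    # dense-psi exact traces up to this N
    hutchinson_probes: int = 30  # Rademacher probes beyond exact_trace_n
    weight_floor: float = 1e-10  # survives quasi-separation
    tau_init: float = 0.1
    mac_min: int = 20            # marker eligibility for the variance ratio
    vr_markers: int = 30


@dataclass
class NullModelFit:
    """Converged null model: everything Step 2 needs, nothing refit."""

    alpha: np.ndarray
    tau: float
    phi: float
    mu: np.ndarray
    W: np.ndarray
    residuals: np.ndarray
    bhat: np.ndarray
    trait_type: str
    sample_ids: list[str]
    covar_names: list[str]
    X: np.ndarray
    converged: bool
    n_iterations: int
    variance_ratio: float | None = None
    tau_history: list[float] = field(default_factory=list)
    pcg_iterations: list[int] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Preconditioned conjugate gradient
# ---------------------------------------------------------------------------

def _sigma_matvec(X: np.ndarray, W: np.ndarray, tau: float,
                  gstd: GenotypeMatrix | None) -> np.ndarray:
    out = X / (W[:, None] if X.ndim == 2 else W)
    if tau > 0:
        A = gstd.std.astype(np.float64, copy=False)
        out = out + tau * (A @ (A.T @ X)) / gstd.n_variants
    return out


def _pcg_block(W: np.ndarray, tau: float, gstd: GenotypeMatrix | None,
               B: np.ndarray, tol: float, maxit: int,
               X0: np.ndarray | None = None) -> tuple[np.ndarray, PCGReport]:
    """Jacobi-preconditioned CG on Sigma X = B for one or more right-hand
    sides simultaneously (shared matvecs, per-column step sizes)."""
    B = np.asarray(B, dtype=np.float64)
    squeeze = B.ndim == 1
    if squeeze:
        B = B[:, None]
    n, k = B.shape
    diag = 1.0 / W + (tau * gstd.diag() if tau > 0 else 0.0)
    bnorm = np.linalg.norm(B, axis=0)
    live = bnorm > 0
    X = np.zeros_like(B) if X0 is None else np.array(X0, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    R = B - _sigma_matvec(X, W, tau, gstd) if X.any() else B.copy()
    Z = R / diag[:, None]
    P = Z.copy()
    rz = np.einsum("ij,ij->j", R, Z)
    relres = np.where(live, np.linalg.norm(R, axis=0) /
                      np.where(live, bnorm, 1.0), 0.0)
    it = 0
    active = relres > tol
    while active.any() and it < maxit:
        it += 1
        AP = _sigma_matvec(P, W, tau, gstd)
        pAp = np.einsum("ij,ij->j", P, AP)
        safe = active & (pAp > 0)
        step = np.where(safe, rz / np.where(pAp > 0, pAp, 1.0), 0.0)
        X += P * step
        R -= AP * step
        relres = np.where(live, np.linalg.norm(R, axis=0) /
                          np.where(live, bnorm, 1.0), 0.0)
        newly_done = active & (relres <= tol)
        active = active & ~newly_done & safe
        if not active.any():
            break
        Z = R / diag[:, None]
        rz_new = np.einsum("ij,ij->j", R, Z)
        beta = np.where(active, rz_new / np.where(rz > 0, rz, 1.0), 0.0)
        P = Z + P * beta
        rz = rz_new
    report = PCGReport(iterations=it,
                       final_relative_residual=float(relres.max(initial=0.0)),
                       converged=bool((relres <= tol).all()))
    return (X[:, 0] if squeeze else X), report


def pcg_solve(W, tau: float, gstd: GenotypeMatrix | None, b: np.ndarray,
              tol: float = 1e-5, maxit: int = 5000,
              x0: np.ndarray | None = None) -> tuple[np.ndarray, PCGReport]:
    """Solve (W^{-1} + tau psi) x = b matrix-free to relative residual ``tol``.

    ``W`` is the strictly positive diagonal weight vector (a scalar is
    broadcast); the Jacobi preconditioner is diag(Sigma) = 1/W + tau psi_ii.
    A diagonal system (tau = 0) converges in a single iteration.  On budget
    exhaustion the report returns ``converged=False`` — never silently.
    """
    b = np.asarray(b, dtype=np.float64)
    W = np.broadcast_to(np.asarray(W, dtype=np.float64), b.shape[:1]).copy()
    if not (W > 0).all():
        raise ValueError("weights W must be strictly positive")
    if tau < 0:
        raise ValueError("tau must be nonnegative")
    if tau > 0 and gstd is None:
        raise ValueError("tau > 0 requires a genotype operator")
    if tau > 0 and gstd.n_samples != b.shape[0]:
        raise ValueError("dimension mismatch between b and genotype operator")
    return _pcg_block(W, tau, gstd, b, tol, maxit, x0)


class SigmaSolver:
    """Shared machinery for repeated solves against one Sigma = W^{-1}+tau psi:
    caches Sigma^{-1} X and the small Gram factor so the REML projection
    P v = Sigma^{-1} v - Sigma^{-1} X (X' Sigma^{-1} X)^{-1} X' Sigma^{-1} v
    costs one PCG solve per new vector."""

    def __init__(self, gstd: GenotypeMatrix | None, W: np.ndarray, tau: float,
                 X: np.ndarray, tol: float = 1e-5, maxit: int = 5000):
        self.gstd, self.tau, self.X = gstd, float(tau), np.asarray(X, float)
        self.W = np.asarray(W, dtype=np.float64)
        self.tol, self.maxit = tol, maxit
        self.total_iterations = 0
        self.SiX, rep = _pcg_block(self.W, self.tau, gstd, self.X, tol, maxit)
        self.total_iterations += rep.iterations
        self._cho = cho_factor(self.X.T @ self.SiX)

    def solve(self, v: np.ndarray) -> np.ndarray:
        out, rep = _pcg_block(self.W, self.tau, self.gstd, v,
                              self.tol, self.maxit)
        self.total_iterations += rep.iterations
        return out

    def project_solved(self, siv: np.ndarray) -> np.ndarray:
        """P v given siv = Sigma^{-1} v."""
        coef = cho_solve(self._cho, self.X.T @ siv)
        return siv - self.SiX @ coef

    def project(self, v: np.ndarray) -> np.ndarray:
        return self.project_solved(self.solve(v))

    def gls_coefficients(self, siy: np.ndarray) -> np.ndarray:
        """(X' Sigma^{-1} X)^{-1} X' Sigma^{-1} y given siy = Sigma^{-1} y."""
        return cho_solve(self._cho, self.X.T @ siy)


# ---------------------------------------------------------------------------
# Traces of P psi
# ---------------------------------------------------------------------------

def trace_p_psi(gstd: GenotypeMatrix, X: np.ndarray, W: np.ndarray,
                tau: float, method: str = "exact", probes: int = 30,
                rng: np.random.Generator | None = None,
                solver: SigmaSolver | None = None) -> float:
    """tr(P psi) with P the REML projection for Sigma = W^{-1} + tau psi.

    ``exact`` forms the dense GRM once (cached on the operator) and uses a
    Cholesky solve; ``hutchinson`` uses seeded Rademacher probe vectors
    z with estimator mean over probes of (P z)' (psi z).
    """
    W = np.broadcast_to(np.asarray(W, float), (gstd.n_samples,))
    if method == "exact":
        psi = gstd.dense_grm()
        sigma = tau * psi + np.diag(1.0 / W)
        c = cho_factor(sigma)
        si_psi = cho_solve(c, psi)
        six = cho_solve(c, X)
        gram = X.T @ six
        corr = np.trace(np.linalg.solve(gram, six.T @ psi @ six))
        return float(np.trace(si_psi) - corr)
    if method == "hutchinson":
        if rng is None:
            rng = np.random.default_rng(0)
        if solver is None:
            solver = SigmaSolver(gstd, W, tau, X)
        total = 0.0
        for _ in range(probes):
            z = rng.integers(0, 2, size=gstd.n_samples) * 2.0 - 1.0
            total += float(solver.project(z) @ gstd.matvec(z))
        return total / probes
    raise ValueError(f"unknown trace method {method!r}")


# ---------------------------------------------------------------------------
# AI-REML variance-component updates
# ---------------------------------------------------------------------------

def ai_reml_step(gstd: GenotypeMatrix, X: np.ndarray, ytilde: np.ndarray,
                 W: np.ndarray, tau: float, *,
                 exact_trace_n: int = 2000, probes: int = 30,
                 rng: np.random.Generator | None = None,
                 pcg_tol: float = 1e-5, pcg_maxit: int = 5000,
                 ) -> tuple[float, dict]:
    """One average-information Newton step on tau (binary-trait path).

    score = (y'P psi P y - tr(P psi)) / 2 and AI = y'P psi P psi P y / 2,
    with P applied via PCG solves; the result is clamped to [0, inf).  A
    nonpositive AI triggers a bounded bisection on the sign of the score.
    """
    solver = SigmaSolver(gstd, W, tau, X, tol=pcg_tol, maxit=pcg_maxit)
    method = "exact" if gstd.n_samples <= exact_trace_n else "hutchinson"

    def score_at(solver_t: SigmaSolver, t: float) -> tuple[float, np.ndarray, np.ndarray]:
        u = solver_t.project(ytilde)          # P y
        w = gstd.matvec(u)                    # psi P y
        tr = trace_p_psi(gstd, X, W, t, method=method, probes=probes,
                         rng=rng, solver=solver_t)
        return 0.5 * (float(u @ w) - tr), u, w

    score, u, w = score_at(solver, tau)
    pw = solver.project(w)
    ai = 0.5 * float(w @ pw)
    info = {"score": score, "ai": ai, "pcg_iterations": solver.total_iterations}
    if np.isfinite(ai) and ai > 0:
        step = score / ai
        return max(0.0, tau + step), info
    # AI degenerate: bisection on the score sign over an expanding bracket
    log.warning("null_model: AI nonpositive (%.3g); bisection fallback", ai)
    lo, s_lo = 0.0, None
    s_lo, *_ = score_at(SigmaSolver(gstd, W, 0.0, X, pcg_tol, pcg_maxit), 0.0)
    if s_lo <= 0:
        return 0.0, info
    hi = max(2 * tau, 0.5)
    for _ in range(8):
        s_hi, *_ = score_at(SigmaSolver(gstd, W, hi, X, pcg_tol, pcg_maxit), hi)
        if s_hi < 0:
            break
        hi *= 2
    else:
        return hi, info
    for _ in range(20):
        mid = 0.5 * (lo + hi)
        s_mid, *_ = score_at(SigmaSolver(gstd, W, mid, X, pcg_tol, pcg_maxit), mid)
        if s_mid > 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-3 * (1 + hi):
            break
    return 0.5 * (lo + hi), info


def _gaussian_ai_step_eigen(Yt: np.ndarray, Xt: np.ndarray, lam: np.ndarray,
                            phi: float, tau: float) -> tuple[float, float]:
    """Joint (phi, tau) AI-REML Newton step in the GRM eigenbasis, with
    step-halving on the restricted log-likelihood."""

    def reml_ll(ph: float, ta: float) -> float:
        d = ph + ta * lam
        if (d <= 0).any():
            return -np.inf
        XtD = Xt / d[:, None]
        gram = Xt.T @ XtD
        sign, logdet_g = np.linalg.slogdet(gram)
        if sign <= 0:
            return -np.inf
        t = Yt / d
        u = t - XtD @ np.linalg.solve(gram, Xt.T @ t)
        return -0.5 * (np.log(d).sum() + logdet_g + float(Yt @ u))

    d = phi + tau * lam
    XtD = Xt / d[:, None]
    gram = Xt.T @ XtD
    cho = cho_factor(gram)
    t = Yt / d

    def papply(wv: np.ndarray) -> np.ndarray:
        tw = wv / d
        return tw - XtD @ cho_solve(cho, Xt.T @ tw)

    u = t - XtD @ cho_solve(cho, Xt.T @ t)     # P y in eigenbasis
    m_i = Xt.T @ (Xt * (1.0 / d**2)[:, None])
    m_psi = Xt.T @ (Xt * (lam / d**2)[:, None])
    tr_p = float((1.0 / d).sum() - np.trace(cho_solve(cho, m_i)))
    tr_ppsi = float((lam / d).sum() - np.trace(cho_solve(cho, m_psi)))
    w_phi, w_tau = u, lam * u
    score = np.array([0.5 * (float(u @ u) - tr_p),
                      0.5 * (float(u @ w_tau) - tr_ppsi)])
    pw_phi, pw_tau = papply(w_phi), papply(w_tau)
    ai = 0.5 * np.array([[float(w_phi @ pw_phi), float(w_phi @ pw_tau)],
                         [float(w_tau @ pw_phi), float(w_tau @ pw_tau)]])
    try:
        step = np.linalg.solve(ai, score)
    except np.linalg.LinAlgError:
        step = score / np.maximum(np.diag(ai), 1e-12)
    ll0 = reml_ll(phi, tau)
    phi_floor = 1e-8 * (phi + tau)
    for _ in range(12):
        phi_new = max(phi + step[0], phi_floor)
        tau_new = max(tau + step[1], 0.0)
        if reml_ll(phi_new, tau_new) >= ll0 - 1e-10:
            return phi_new, tau_new
        step = step / 2.0
    return phi, tau  # no improving step found; outer loop will stop


def _gaussian_ai_step_iterative(gstd: GenotypeMatrix, X: np.ndarray,
                                y: np.ndarray, phi: float, tau: float,
                                probes: int, rng: np.random.Generator,
                                pcg_tol: float, pcg_maxit: int,
                                ) -> tuple[float, float]:
    """(phi, tau) AI step with PCG solves and Hutchinson traces (large N)."""
    n = gstd.n_samples
    W = np.full(n, 1.0 / phi)
    solver = SigmaSolver(gstd, W, tau, X, tol=pcg_tol, maxit=pcg_maxit)
    u = solver.project(y)
    w_tau = gstd.matvec(u)
    tr_p = 0.0
    tr_ppsi = 0.0
    for _ in range(probes):
        z = rng.integers(0, 2, size=n) * 2.0 - 1.0
        pz = solver.project(z)
        tr_p += float(z @ pz)
        tr_ppsi += float(pz @ gstd.matvec(z))
    tr_p /= probes
    tr_ppsi /= probes
    score = np.array([0.5 * (float(u @ u) - tr_p),
                      0.5 * (float(u @ w_tau) - tr_ppsi)])
    pw_phi, pw_tau = solver.project(u), solver.project(w_tau)
    ai = 0.5 * np.array([[float(u @ pw_phi), float(u @ pw_tau)],
                         [float(w_tau @ pw_phi), float(w_tau @ pw_tau)]])
    try:
        step = np.linalg.solve(ai, score)
    except np.linalg.LinAlgError:
        step = score / np.maximum(np.diag(ai), 1e-12)
    phi_new = max(phi + step[0], 1e-8 * (phi + tau))
    tau_new = max(tau + step[1], 0.0)
    return phi_new, tau_new


# ---------------------------------------------------------------------------
# Null GLMM fit
# ---------------------------------------------------------------------------

def _irls_logistic(X: np.ndarray, Y: np.ndarray, floor: float,
                   tol: float = 1e-10, max_iter: int = 100) -> np.ndarray:
    """Plain fixed-effects logistic regression by Newton-Raphson/IRLS."""
    alpha = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ alpha
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), floor, None)
        z = eta + (Y - mu) / w
        xtw = X.T * w
        alpha_new = np.linalg.solve(xtw @ X, xtw @ z)
        if np.max(np.abs(alpha_new - alpha)) < tol * (1 + np.max(np.abs(alpha))):
            return alpha_new
        alpha = alpha_new
    return alpha


def fit_null_glmm(pheno, G, config: NullModelConfig | None = None,
                  tau_fixed: float | None = None, seed: int = 0) -> NullModelFit:
    """Fit the null GLMM (no tested genetic effect) against the implicit GRM.

    Parameters
    ----------
    pheno
        :class:`~.io_formats.PhenotypeTable`; binary traits need both classes.
    G
        :class:`~.grm_engine.GenotypeMatrix` (or a raw count matrix).
    tau_fixed
        Pin the variance component (e.g. 0 reduces the binary path to plain
        logistic regression); ``None`` estimates it by AI-REML.

    Raises
    ------
    ConvergenceError
        If the outer loop exhausts ``config.max_outer``; the exception
        carries the last iterate.
    """
    cfg = config or NullModelConfig()
    gstd = G if isinstance(G, GenotypeMatrix) else GenotypeMatrix(G)
    X = np.asarray(pheno.X, dtype=np.float64)
    Y = np.asarray(pheno.Y, dtype=np.float64)
    n = gstd.n_samples
    if X.shape[0] != n:
        raise ValueError("phenotype rows and genotype rows disagree")
    rng = np.random.default_rng(seed)
    if pheno.trait_type == "binary":
        if len(np.unique(Y)) < 2:
            raise ValueError("binary trait must contain both classes")
        return _fit_binary(X, Y, gstd, cfg, tau_fixed, rng, pheno)
    return _fit_gaussian(X, Y, gstd, cfg, tau_fixed, rng, pheno)


def _relchange(new, old) -> float:
    new, old = np.atleast_1d(new), np.atleast_1d(old)
    return float(np.max(np.abs(new - old) / (np.abs(old) + 1e-6)))


def _fit_binary(X, Y, gstd, cfg, tau_fixed, rng, pheno) -> NullModelFit:
    alpha = _irls_logistic(X, Y, cfg.weight_floor)
    tau = cfg.tau_init if tau_fixed is None else float(tau_fixed)
    b = np.zeros(len(Y))
    eta = X @ alpha
    tau_history, pcg_log = [tau], []
    floored_warned = False
    mu = expit(eta)
    W = np.clip(mu * (1 - mu), cfg.weight_floor, None)
    ytilde = eta
    converged = False
    n_outer = 0
    inner_tol = min(cfg.tol * 1e-2, 1e-6)
    for outer in range(1, cfg.max_outer + 1):
        n_outer = outer
        alpha_prev, tau_prev = alpha.copy(), tau
        for _ in range(cfg.max_inner):
            mu = expit(eta)
            W = mu * (1 - mu)
            if (W < cfg.weight_floor).any() and not floored_warned:
                log.warning("null_model: fitted probabilities near 0/1; "
                            "weights floored at %g", cfg.weight_floor)
                floored_warned = True
            W = np.clip(W, cfg.weight_floor, None)
            ytilde = eta + (Y - mu) / W
            use_grm = tau > 0
            op = gstd if use_grm else None
            sol, rep = _pcg_block(W, tau if use_grm else 0.0, op,
                                  np.column_stack([X, ytilde]),
                                  cfg.pcg_tol, cfg.pcg_maxit)
            pcg_log.append(rep.iterations)
            six, siy = sol[:, :-1], sol[:, -1]
            gram = X.T @ six
            alpha_new = np.linalg.solve(gram, X.T @ siy)
            rvec = siy - six @ alpha_new
            b = tau * gstd.matvec(rvec) if tau > 0 else np.zeros(len(Y))
            eta = X @ alpha_new + b
            delta = _relchange(alpha_new, alpha)
            alpha = alpha_new
            if delta < inner_tol:
                break
        if tau_fixed is None:
            tau, _info = ai_reml_step(
                gstd, X, ytilde, W, tau,
                exact_trace_n=cfg.exact_trace_n, probes=cfg.hutchinson_probes,
                rng=rng, pcg_tol=cfg.pcg_tol, pcg_maxit=cfg.pcg_maxit)
        tau_history.append(tau)
        log.info("stage=step1 outer=%d tau=%.6g max_pcg_iter=%d",
                 outer, tau, max(pcg_log[-cfg.max_inner:], default=0))
        if max(_relchange(alpha, alpha_prev), _relchange(tau, tau_prev)) < cfg.tol:
            converged = True
            break
    # polish (alpha, b) at the final tau with tight solves so the score
    # equation X'(Y - mu) = 0 holds to high precision
    polish_tol = min(cfg.pcg_tol, 1e-7)
    for _ in range(3):
        mu = expit(eta)
        W = np.clip(mu * (1 - mu), cfg.weight_floor, None)
        ytilde = eta + (Y - mu) / W
        sol, rep = _pcg_block(W, tau, gstd if tau > 0 else None,
                              np.column_stack([X, ytilde]), polish_tol,
                              cfg.pcg_maxit)
        pcg_log.append(rep.iterations)
        six, siy = sol[:, :-1], sol[:, -1]
        alpha = np.linalg.solve(X.T @ six, X.T @ siy)
        rvec = siy - six @ alpha
        b = tau * gstd.matvec(rvec) if tau > 0 else np.zeros(len(Y))
        eta = X @ alpha + b
    mu = expit(eta)
    W = np.clip(mu * (1 - mu), cfg.weight_floor, None)
    fit = NullModelFit(
        alpha=alpha, tau=float(tau), phi=1.0, mu=mu, W=W,
        residuals=Y - mu, bhat=b, trait_type="binary",
        sample_ids=list(getattr(pheno, "sample_ids", range(len(Y)))),
        covar_names=list(getattr(pheno, "covar_names", [])),
        X=X, converged=converged, n_iterations=n_outer,
        tau_history=tau_history, pcg_iterations=pcg_log)
    if not converged:
        raise ConvergenceError(
            f"null GLMM did not converge in {cfg.max_outer} outer iterations "
            f"(last tau={tau:.4g})", last_fit=fit)
    return fit


def _fit_gaussian(X, Y, gstd, cfg, tau_fixed, rng, pheno) -> NullModelFit:
    n, p = X.shape
    alpha, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid0 = Y - X @ alpha
    phi = float(resid0 @ resid0) / max(n - p, 1)
    tau = cfg.tau_init if tau_fixed is None else float(tau_fixed)
    use_eigen = n <= cfg.exact_trace_n and tau_fixed is None
    if use_eigen:
        lam, Q = gstd.grm_eigh()
        Yt, Xt = Q.T @ Y, Q.T @ X
    b = np.zeros(n)
    tau_history, pcg_log = [tau], []
    converged = False
    n_outer = 0
    for outer in range(1, cfg.max_outer + 1):
        n_outer = outer
        alpha_prev, tau_prev, phi_prev = alpha.copy(), tau, phi
        W = np.full(n, 1.0 / phi)
        use_grm = tau > 0
        sol, rep = _pcg_block(W, tau if use_grm else 0.0,
                              gstd if use_grm else None,
                              np.column_stack([X, Y]),
                              cfg.pcg_tol, cfg.pcg_maxit)
        pcg_log.append(rep.iterations)
        six, siy = sol[:, :-1], sol[:, -1]
        alpha = np.linalg.solve(X.T @ six, X.T @ siy)
        rvec = siy - six @ alpha
        b = tau * gstd.matvec(rvec) if tau > 0 else np.zeros(n)
        if tau_fixed is None:
            if use_eigen:
                phi, tau = _gaussian_ai_step_eigen(Yt, Xt, lam, phi, tau)
            else:
                phi, tau = _gaussian_ai_step_iterative(
                    gstd, X, Y, phi, tau, cfg.hutchinson_probes, rng,
                    cfg.pcg_tol, cfg.pcg_maxit)
        else:
            # dispersion still profiled when tau is pinned
            r = Y - X @ alpha - b
            phi = float(r @ r) / max(n - p, 1)
        tau_history.append(tau)
        log.info("stage=step1 outer=%d tau=%.6g phi=%.6g pcg_iter=%d",
                 outer, tau, phi, rep.iterations)
        if max(_relchange(alpha, alpha_prev), _relchange(tau, tau_prev),
               _relchange(phi, phi_prev)) < cfg.tol:
            converged = True
            break
    eta = X @ alpha + b
    W = np.full(n, 1.0 / phi)
    fit = NullModelFit(
        alpha=alpha, tau=float(tau), phi=float(phi), mu=eta, W=W,
        residuals=Y - eta, bhat=b, trait_type="quantitative",
        sample_ids=list(getattr(pheno, "sample_ids", range(n))),
        covar_names=list(getattr(pheno, "covar_names", [])),
        X=X, converged=converged, n_iterations=n_outer,
        tau_history=tau_history, pcg_iterations=pcg_log)
    if not converged:
        raise ConvergenceError(
            f"null LMM did not converge in {cfg.max_outer} outer iterations "
            f"(last tau={tau:.4g}, phi={phi:.4g})", last_fit=fit)
    return fit


# ---------------------------------------------------------------------------
# Variance-ratio estimation
# ---------------------------------------------------------------------------

def estimate_variance_ratio(fit: NullModelFit, gstd: GenotypeMatrix,
                            n_markers: int = 30, seed: int = 0,
                            mac_min: int = 20, pcg_tol: float = 1e-8,
                            pcg_maxit: int = 5000) -> float:
    """Mean full-GRM / no-GRM score-variance ratio over a random marker set.

    For each sampled marker g (MAC >= ``mac_min``), residualize against the
    covariates under the fitted weights, g~ = g - X (X'WX)^{-1} X'W g, and
    compute v_full = g~' P g~ (P applied through PCG) and
    v_noGRM = g~' W g~.  With no relatedness (tau = 0) every ratio is 1.
    """
    from .io_formats import MISSING

    counts = gstd.counts
    obs = counts != MISSING
    ac1 = np.where(obs, counts, 0).sum(axis=0, dtype=np.int64)
    mac = np.minimum(ac1, 2 * obs.sum(axis=0) - ac1)
    eligible = np.flatnonzero(mac >= mac_min)
    if len(eligible) == 0:
        raise ValueError(f"no markers with MAC >= {mac_min}")
    if len(eligible) < n_markers:
        log.warning("variance ratio: only %d markers with MAC >= %d "
                    "(requested %d); using all", len(eligible), mac_min,
                    n_markers)
        chosen = eligible
    else:
        rng = np.random.default_rng(seed)
        chosen = rng.choice(eligible, size=n_markers, replace=False)
        chosen.sort()
    X, W = fit.X, fit.W
    g_all = gstd.imputed_counts()[:, chosen]
    xtwx = X.T @ (X * W[:, None])
    coefs = np.linalg.solve(xtwx, X.T @ (g_all * W[:, None]))
    g_res = g_all - X @ coefs
    v_no = np.einsum("ij,ij->j", g_res, g_res * W[:, None])
    solver = SigmaSolver(gstd, W, fit.tau, X, tol=pcg_tol, maxit=pcg_maxit)
    si_g, _ = _pcg_block(W, fit.tau, gstd if fit.tau > 0 else None, g_res,
                         pcg_tol, pcg_maxit)
    pg = si_g - solver.SiX @ cho_solve(solver._cho, X.T @ si_g)
    v_full = np.einsum("ij,ij->j", g_res, pg)
    ratios = v_full / v_no
    r = float(np.mean(ratios))
    log.info("stage=variance_ratio n_markers=%d r=%.6g", len(chosen), r)
    if not r > 0:
        raise ValueError(f"variance ratio must be positive, got {r}")
    return r
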