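"""Synthetic cohorts with known relatedness and phenotypes drawn exactly
from the generative model the engine fits.

Genotypes: founders carry Binomial(2, p_j) hard calls with per-variant
allele frequencies uniform on ``maf_range``; family blocks (sib pairs or
sib quads) are built by Mendelian transmission from stored parental
haplotypes, so siblings have expected kinship 1/4 (GRM expectation 1/2).
Parents are not part of the sample.

Phenotypes: the random effect b is drawn exactly from N(0, tau * psi)
using a symmetric factor of the dense GRM of the simulated markers — the
same markers the fitting step will use, so parameter-recovery experiments
are internally consistent.  Binary traits are Bernoulli(expit(X alpha + b))
with the intercept solved numerically to hit a target prevalence (enabling
the extreme case-control imbalance regime); quantitative traits are
X alpha + b + eps with unit-variance gaussian noise.

All randomness flows from the single ``seed`` in :class:`SimConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .grm_engine import GenotypeMatrix
from .io_formats import PhenotypeTable, VariantRecord

_FAMILY_SIZES = {"unrelated": 1, "sib_pairs": 2, "sib_quads": 4}


@dataclass
class SimConfig:
    """Study-design knobs for one synthetic cohort."""

    n_samples: int = 1000
    n_variants: int = 2000
    maf_range: tuple[float, float] = (0.05, 0.5)
    family_structure: str = "unrelated"  # unrelated | sib_pairs | sib_quads
    tau: float = 1.0
    alpha: tuple[float, ...] = (0.5,)    # effects of the simulated covariates
    prevalence: float = 0.1              # binary traits only
    trait_type: str = "binary"
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo < hi <= 0.5):
            raise ValueError(f"require 0 < maf_low < maf_high <= 0.5, "
                             f"got {self.maf_range}")
        if not (0 < self.prevalence < 1):
            raise ValueError("prevalence must lie in (0, 1)")
        if self.family_structure not in _FAMILY_SIZES:
            raise ValueError(f"unknown family_structure "
                             f"{self.family_structure!r}")
        if self.tau < 0:
            raise ValueError("tau must be nonnegative")
        if self.trait_type not in ("binary", "quantitative"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")


def _sample_ids(n: int) -> list[str]:
    return [f"S{i:06d}" for i in range(n)]


def _variant_records(m: int, rng: np.random.Generator) -> list[VariantRecord]:
    return [VariantRecord(chrom="1", pos=1000 * (j + 1), id=f"V{j:06d}",
                          allele1="A", allele2="G") for j in range(m)]


def simulate_genotypes(cfg: SimConfig) -> tuple[GenotypeMatrix, list[str]]:
    """Generate hard calls and per-sample family labels.

    Returns a :class:`GenotypeMatrix` (monomorphic columns dropped per its
    contract) and one family label per sample (``F000123`` blocks for sibs,
    ``U...`` singletons).
    """
    rng = np.random.default_rng(cfg.seed)
    n, m = cfg.n_samples, cfg.n_variants
    p = rng.uniform(*cfg.maf_range, size=m)
    block = _FAMILY_SIZES[cfg.family_structure]
    n_fam, n_single = divmod(n, block)
    counts = np.empty((n, m), dtype=np.int8)
    labels: list[str] = []
    if block == 1:
        counts[:] = rng.binomial(2, p, size=(n, m)).astype(np.int8)
        labels = [f"U{i:06d}" for i in range(n)]
    else:
        row = 0
        for fam in range(n_fam):
            # each parent is a pair of haplotypes; every child draws one
            # allele per parent per variant (Mendelian transmission)
            mat = (rng.random((2, m)) < p).astype(np.int8)
            pat = (rng.random((2, m)) < p).astype(np.int8)
            pick_m = rng.integers(0, 2, size=(block, m))
            pick_p = rng.integers(0, 2, size=(block, m))
            kids = mat[pick_m, np.arange(m)] + pat[pick_p, np.arange(m)]
            counts[row:row + block] = kids
            labels.extend([f"F{fam:06d}"] * block)
            row += block
        if n_single:
            counts[row:] = rng.binomial(
                2, p, size=(n_single, m)).astype(np.int8)
            labels.extend(f"U{row + i:06d}" for i in range(n_single))
    variants = _variant_records(m, rng)
    G = GenotypeMatrix(counts, variants=variants, sample_ids=_sample_ids(n))
    return G, labels


def _grm_factor(G: GenotypeMatrix) -> np.ndarray:
    """Symmetric factor L with L L' = psi (eigenfactor; psi may be
    rank-deficient when M < N, so a Cholesky is not assumed)."""
    lam, q = G.grm_eigh()
    lam = np.clip(lam, 0.0, None)
    return q * np.sqrt(lam)


def simulate_phenotype(G: GenotypeMatrix, cfg: SimConfig,
                       rng: np.random.Generator | None = None
                       ) -> PhenotypeTable:
    """Draw a phenotype from the mixed model with random effect
    b ~ N(0, tau * psi) on the cohort's own GRM."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    n = G.n_samples
    n_cov = len(cfg.alpha)
    covs = rng.standard_normal((n, n_cov)) if n_cov else np.empty((n, 0))
    fixed = covs @ np.asarray(cfg.alpha, float)
    if cfg.tau > 0:
        b = np.sqrt(cfg.tau) * (_grm_factor(G) @ rng.standard_normal(n))
    else:
        b = np.zeros(n)
    sample_ids = G.sample_ids or _sample_ids(n)
    covar_names = ["intercept"] + [f"cov{j + 1}" for j in range(n_cov)]
    if cfg.trait_type == "quantitative":
        y = fixed + b + rng.standard_normal(n)
        X = np.column_stack([np.ones(n), covs])
        return PhenotypeTable(sample_ids=list(sample_ids), Y=y, X=X,
                              trait_type="quantitative",
                              covar_names=covar_names)
    # binary: solve the intercept so mean(expit(c + fixed + b)) hits the
    # target prevalence
    eta0 = fixed + b

    def excess(c: float) -> float:
        return float(expit(c + eta0).mean() - cfg.prevalence)

    c = brentq(excess, -40.0, 40.0)
    for attempt in range(2):
        y = (rng.random(n) < expit(c + eta0)).astype(float)
        if 0 < y.sum() < n:
            break
        if attempt == 1:
            raise RuntimeError(
                f"could not realize prevalence {cfg.prevalence} "
                f"(degenerate draw after reseed)")
    X = np.column_stack([np.ones(n), covs])
    return PhenotypeTable(sample_ids=list(sample_ids), Y=y, X=X,
                          trait_type="binary", covar_names=covar_names)


def ascertain_case_control(pheno: PhenotypeTable, n_cases: int,
                           n_controls: int, rng: np.random.Generator
                           ) -> np.ndarray:
    """Indices of a case-control subsample (without replacement) from a
    larger simulated pool — the route to extreme imbalance regimes like
    1:99 while keeping the generative model exact."""
    cases = np.flatnonzero(pheno.Y == 1)
    controls = np.flatnonzero(pheno.Y == 0)
    if len(cases) < n_cases or len(controls) < n_controls:
        raise ValueError(
            f"pool has {len(cases)} cases / {len(controls)} controls; "
            f"requested {n_cases}/{n_controls}")
    idx = np.concatenate([rng.choice(cases, n_cases, replace=False),
                          rng.choice(controls, n_controls, replace=False)])
    idx.sort()
    return idx


def subset_phenotype(pheno: PhenotypeTable, idx: np.ndarray
                     ) -> PhenotypeTable:
    return PhenotypeTable(
        sample_ids=[pheno.sample_ids[i] for i in idx], Y=pheno.Y[idx],
        X=pheno.X[idx], trait_type=pheno.trait_type,
        covar_names=list(pheno.covar_names))
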