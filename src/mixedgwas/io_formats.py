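"""File formats touched by the engine.

Step 1 consumes PLINK bed/bim/fam hard calls and a phenotype/covariate TSV;
Step 2 consumes a serialized null model, a variance-ratio file, and either
PLINK hard calls or a simple per-variant dosage TSV, and emits a results
table.  A trait manifest drives batched multi-trait Step-2 runs.

Allele convention (important for effect signs): the bim A1 allele (column 5)
is the *counted* allele.  A hard call of 2 means two copies of allele1, and
every reported allele frequency, dosage and effect size refers to allele1.

The null-model serialization is a single self-describing JSON document (plus
a small variance-ratio sidecar) carrying everything Step 2 needs — fitted
fixed effects, the variance component, per-sample fitted means and weights,
residuals, the covariate matrix and sample ids — so association testing
never refits the null.  It is not interoperable with upstream GMMAT/SAIGE
binary model files.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

#: sentinel for a missing hard call in the raw count matrix (int8 storage)
MISSING = np.int8(-9)

#: PLINK bed magic bytes + SNP-major mode byte
_BED_MAGIC = b"\x6c\x1b"
_BED_SNP_MAJOR = b"\x01"

# 2-bit bed code -> count of allele1 copies
_CODE_TO_COUNT = np.array([2, MISSING, 1, 0], dtype=np.int8)
# count of allele1 copies -> 2-bit bed code (index by count, missing handled apart)
_COUNT_TO_CODE = {2: 0, 1: 2, 0: 3}

RESULTS_COLUMNS = [
    "CHR", "POS", "ID", "Allele1", "Allele2", "AF_Allele1", "N",
    "BETA", "SE", "Tstat", "var", "p_value", "p_value_NA", "is_SPA_converged",
]

#: smallest positive double; p-values are floored here so they never print as 0
_P_FLOOR = float(np.nextafter(0.0, 1.0))


class FormatError(ValueError):
    """Malformed input file (bad magic, missing column, inconsistent sizes)."""


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic variant; ``allele1`` is the counted/effect allele."""

    chrom: str
    pos: int
    id: str
    allele1: str
    allele2: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"variant {self.id!r}: pos must be >= 1, got {self.pos}")
        if not self.id:
            raise ValueError("variant id must be non-empty")
        if self.allele1 == self.allele2:
            raise ValueError(f"variant {self.id!r}: alleles must differ")


@dataclass
class PhenotypeTable:
    """Response and covariates for one trait, row-aligned to ``sample_ids``.

    ``X`` always carries an explicit leading intercept column.
    """

    sample_ids: list[str]
    Y: np.ndarray
    X: np.ndarray
    trait_type: str  # "binary" | "quantitative"
    covar_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        if self.trait_type not in ("binary", "quantitative"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        n = len(self.sample_ids)
        if self.Y.shape != (n,) or self.X.shape[0] != n:
            raise ValueError("sample_ids, Y and X row counts disagree")
        if np.isnan(self.Y).any():
            raise ValueError("missing phenotype values must be filtered before use")
        if self.trait_type == "binary" and not np.isin(self.Y, (0.0, 1.0)).all():
            raise ValueError("binary trait must be coded 0/1")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("covariate matrix X is rank deficient")


@dataclass
class TraitManifest:
    """Batch description for phenome-wide Step 2: one row per trait."""

    trait_ids: list[str]
    null_model_paths: list[str]
    variance_ratio_paths: list[str]
    output_paths: list[str]

    def __len__(self) -> int:
        return len(self.trait_ids)

    def rows(self):
        return zip(self.trait_ids, self.null_model_paths,
                   self.variance_ratio_paths, self.output_paths)


# ---------------------------------------------------------------------------
# PLINK bed/bim/fam
# ---------------------------------------------------------------------------

def read_fam(path: str) -> list[str]:
    fam = pd.read_csv(path, sep=r"\s+", header=None, dtype=str)
    if fam.shape[1] < 2:
        raise FormatError(f"{path}: fam needs >= 2 columns")
    return fam.iloc[:, 1].tolist()


def read_bim(path: str) -> list[VariantRecord]:
    bim = pd.read_csv(path, sep=r"\s+", header=None, dtype=str)
    if bim.shape[1] != 6:
        raise FormatError(f"{path}: bim needs exactly 6 columns, got {bim.shape[1]}")
    return [
        VariantRecord(chrom=r[0], id=r[1], pos=int(r[3]), allele1=r[4], allele2=r[5])
        for r in bim.itertuples(index=False)
    ]


def read_plink(prefix: str) -> tuple[np.ndarray, list[str], list[VariantRecord]]:
    """Read ``prefix``.bed/.bim/.fam into an N x M allele1-count matrix.

    Returns ``(counts, sample_ids, variants)`` where ``counts`` is int8 with
    entries in {0, 1, 2, MISSING}; rows follow fam order, columns bim order.
    """
    sample_ids = read_fam(prefix + ".fam")
    variants = read_bim(prefix + ".bim")
    n, m = len(sample_ids), len(variants)
    with open(prefix + ".bed", "rb") as fh:
        raw = fh.read()
    if raw[:2] != _BED_MAGIC:
        raise FormatError(f"{prefix}.bed: bad magic bytes {raw[:2]!r}")
    if raw[2:3] != _BED_SNP_MAJOR:
        raise FormatError(f"{prefix}.bed: only SNP-major mode 0x01 is supported")
    nbytes = (n + 3) // 4
    expected = 3 + nbytes * m
    if len(raw) != expected:
        raise FormatError(
            f"{prefix}.bed: size {len(raw)} != {expected} expected for "
            f"{n} samples x {m} variants"
        )
    data = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(m, nbytes)
    codes = np.empty((m, nbytes * 4), dtype=np.uint8)
    for k in range(4):  # little-endian 2-bit fields within each byte
        codes[:, k::4] = (data >> (2 * k)) & 0b11
    counts = _CODE_TO_COUNT[codes[:, :n]].T.copy()  # N x M
    return counts, sample_ids, variants


def write_plink(prefix: str, counts: np.ndarray, sample_ids: Sequence[str],
                variants: Sequence[VariantRecord]) -> None:
    """Write hard calls back to bed/bim/fam (inverse of :func:`read_plink`)."""
    counts = np.asarray(counts)
    n, m = counts.shape
    if n != len(sample_ids) or m != len(variants):
        raise ValueError("counts shape disagrees with sample_ids/variants")
    with open(prefix + ".fam", "w") as fh:
        for sid in sample_ids:
            fh.write(f"{sid}\t{sid}\t0\t0\t0\t-9\n")
    with open(prefix + ".bim", "w") as fh:
        for v in variants:
            fh.write(f"{v.chrom}\t{v.id}\t0\t{v.pos}\t{v.allele1}\t{v.allele2}\n")
    nbytes = (n + 3) // 4
    codes = np.zeros((m, nbytes * 4), dtype=np.uint8)
    cm = counts.T  # M x N
    codes[:, :n][cm == 2] = 0
    codes[:, :n][cm == MISSING] = 1
    codes[:, :n][cm == 1] = 2
    codes[:, :n][cm == 0] = 3
    packed = np.zeros((m, nbytes), dtype=np.uint8)
    for k in range(4):
        packed |= codes[:, k::4] << (2 * k)
    with open(prefix + ".bed", "wb") as fh:
        fh.write(_BED_MAGIC + _BED_SNP_MAJOR)
        fh.write(packed.tobytes())


# ---------------------------------------------------------------------------
# Phenotype / covariate TSV
# ---------------------------------------------------------------------------

def read_phenotypes(path: str, pheno_col: str, covar_cols: Sequence[str],
                    trait_type: str, id_col: str = "IID") -> PhenotypeTable:
    """Load a phenotype TSV, drop rows with missing response, add intercept."""
    tab = pd.read_csv(path, sep="\t", dtype={id_col: str})
    for col in [id_col, pheno_col, *covar_cols]:
        if col not in tab.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    tab = tab.dropna(subset=[pheno_col])
    y = tab[pheno_col].to_numpy(dtype=float)
    covs = tab[list(covar_cols)].to_numpy(dtype=float) if covar_cols else \
        np.empty((len(tab), 0))
    X = np.column_stack([np.ones(len(tab)), covs])
    return PhenotypeTable(
        sample_ids=tab[id_col].tolist(), Y=y, X=X, trait_type=trait_type,
        covar_names=["intercept", *covar_cols],
    )


def write_phenotypes(path: str, pheno: PhenotypeTable,
                     pheno_col: str = "pheno", id_col: str = "IID") -> None:
    cols = {id_col: pheno.sample_ids, pheno_col: pheno.Y}
    for j, name in enumerate(pheno.covar_names):
        if name == "intercept":
            continue
        cols[name] = pheno.X[:, j]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Dosage TSV
# ---------------------------------------------------------------------------

def read_dosages(path: str) -> tuple[list[VariantRecord], np.ndarray, list[str]]:
    """Read the dosage TSV dialect: chrom pos id a1 a2 then one column per
    sample in fam order; dosage values lie in [0, 2].

    Returns ``(variants, D, sample_ids)`` with ``D`` of shape (n_variants, N).
    """
    tab = pd.read_csv(path, sep="\t", dtype={"chrom": str, "id": str,
                                             "a1": str, "a2": str})
    meta_cols = ["chrom", "pos", "id", "a1", "a2"]
    for col in meta_cols:
        if col not in tab.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    sample_ids = [c for c in tab.columns if c not in meta_cols]
    variants = [
        VariantRecord(chrom=r.chrom, pos=int(r.pos), id=r.id,
                      allele1=r.a1, allele2=r.a2)
        for r in tab.itertuples(index=False)
    ]
    D = tab[sample_ids].to_numpy(dtype=float)
    if D.size and (D.min() < 0 or D.max() > 2):
        raise FormatError(f"{path}: dosages must lie in [0, 2]")
    return variants, D, sample_ids


def write_dosages(path: str, variants: Sequence[VariantRecord], D: np.ndarray,
                  sample_ids: Sequence[str]) -> None:
    meta = pd.DataFrame({
        "chrom": [v.chrom for v in variants],
        "pos": [v.pos for v in variants],
        "id": [v.id for v in variants],
        "a1": [v.allele1 for v in variants],
        "a2": [v.allele2 for v in variants],
    })
    dose = pd.DataFrame(np.asarray(D), columns=list(sample_ids))
    pd.concat([meta, dose], axis=1).to_csv(path, sep="\t", index=False,
                                           float_format="%.10g")


# ---------------------------------------------------------------------------
# Trait manifest
# ---------------------------------------------------------------------------

def read_manifest(path: str) -> TraitManifest:
    tab = pd.read_csv(path, sep="\t", dtype=str)
    required = ["trait_id", "null_model", "variance_ratio", "output"]
    for col in required:
        if col not in tab.columns:
            raise FormatError(f"{path}: missing manifest column {col!r}")
    ids = tab["trait_id"].tolist()
    if len(set(ids)) != len(ids):
        dupes = sorted({t for t in ids if ids.count(t) > 1})
        raise ValueError(f"{path}: duplicate trait_id(s): {dupes}")
    return TraitManifest(
        trait_ids=ids,
        null_model_paths=tab["null_model"].tolist(),
        variance_ratio_paths=tab["variance_ratio"].tolist(),
        output_paths=tab["output"].tolist(),
    )


def write_manifest(path: str, manifest: TraitManifest) -> None:
    pd.DataFrame({
        "trait_id": manifest.trait_ids,
        "null_model": manifest.null_model_paths,
        "variance_ratio": manifest.variance_ratio_paths,
        "output": manifest.output_paths,
    }).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Association results table
# ---------------------------------------------------------------------------

def _fmt(x, pval: bool = False) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return "NA"
    if pval:
        return f"{max(float(x), _P_FLOOR):.10e}"
    return f"{float(x):.10g}"


def write_results(results, path: str) -> None:
    """Write score-test results as a fixed-header TSV, one row per variant in
    input order.  p-values print in scientific notation, floored at the
    smallest positive double so they never serialize as zero."""
    with open(path, "w") as fh:
        fh.write("\t".join(RESULTS_COLUMNS) + "\n")
        for r in results:
            v = r.variant
            fh.write("\t".join([
                v.chrom, str(v.pos), v.id, v.allele1, v.allele2,
                _fmt(r.af), str(r.n), _fmt(r.beta), _fmt(r.se), _fmt(r.T),
                _fmt(r.var), _fmt(r.p_spa, pval=True),
                _fmt(r.p_normal, pval=True),
                str(bool(r.spa_converged)),
            ]) + "\n")


def read_results(path: str) -> pd.DataFrame:
    tab = pd.read_csv(path, sep="\t", na_values=["NA"],
                      dtype={"CHR": str, "ID": str, "Allele1": str, "Allele2": str})
    if list(tab.columns) != RESULTS_COLUMNS:
        raise FormatError(f"{path}: unexpected results header {list(tab.columns)}")
    return tab


# ---------------------------------------------------------------------------
# Null-model / variance-ratio serialization
# ---------------------------------------------------------------------------

def save_null_model(fit, path: str) -> None:
    """Serialize a fitted null model to one self-describing JSON file."""
    doc = {
        "format": "mixedgwas-null-model",
        "version": 1,
        "trait_type": fit.trait_type,
        "alpha": fit.alpha.tolist(),
        "tau": float(fit.tau),
        "phi": float(fit.phi),
        "mu": fit.mu.tolist(),
        "residuals": fit.residuals.tolist(),
        "W": fit.W.tolist(),
        "bhat": fit.bhat.tolist(),
        "sample_ids": list(fit.sample_ids),
        "covar_names": list(fit.covar_names),
        "X": np.asarray(fit.X).tolist(),
        "converged": bool(fit.converged),
        "n_iterations": int(fit.n_iterations),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_null_model(path: str):
    from .null_model import NullModelFit  # local import: avoid cycle

    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format") != "mixedgwas-null-model":
        raise FormatError(f"{path}: not a mixedgwas null-model file")
    return NullModelFit(
        alpha=np.asarray(doc["alpha"], float),
        tau=float(doc["tau"]),
        phi=float(doc["phi"]),
        mu=np.asarray(doc["mu"], float),
        W=np.asarray(doc["W"], float),
        residuals=np.asarray(doc["residuals"], float),
        bhat=np.asarray(doc["bhat"], float),
        trait_type=doc["trait_type"],
        sample_ids=list(doc["sample_ids"]),
        covar_names=list(doc["covar_names"]),
        X=np.asarray(doc["X"], float),
        converged=bool(doc["converged"]),
        n_iterations=int(doc["n_iterations"]),
    )


def save_variance_ratio(r: float, path: str, n_markers: int | None = None,
                        seed: int | None = None) -> None:
    doc = {"format": "mixedgwas-variance-ratio", "variance_ratio": float(r)}
    if n_markers is not None:
        doc["n_markers"] = int(n_markers)
    if seed is not None:
        doc["seed"] = int(seed)
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_variance_ratio(path: str) -> float:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format") != "mixedgwas-variance-ratio":
        raise FormatError(f"{path}: not a mixedgwas variance-ratio file")
    r = float(doc["variance_ratio"])
    if not r > 0:
        raise ValueError(f"{path}: variance ratio must be positive, got {r}")
    return r


def check_paths_exist(manifest: TraitManifest) -> None:
    missing = [p for p in (*manifest.null_model_paths, *manifest.variance_ratio_paths)
               if not os.path.exists(p)]
    if missing:
        raise FileNotFoundError(f"manifest inputs not found: {missing}")
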