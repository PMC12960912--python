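"""Implicit genetic-relationship-matrix (GRM) operator.

The GRM is psi = (1/M) A A^T where A is the N x M *standardized* genotype
matrix: column j is (g_j - 2 p_j) / sqrt(2 p_j (1 - p_j)) with p_j the
allele1 frequency among non-missing calls and missing calls imputed to the
mean 2 p_j (hence contributing exactly zero).  psi is never materialized for
solver work: every product psi v is computed as two matrix-vector products,
A (A^T v) / M, an O(MN) operation needing only O(N + M) workspace.

The column-partitioned product mirrors a distributed layout in which worker
i owns columns [s_i, e_i) and contributes a partial product; partial results
are reduced in ascending worker order, so the result is reproducible and
agrees with the unpartitioned product up to float reassociation (~1e-8
relative).  The capacity planner converts a matrix footprint at 4 bytes per
entry into the number of accelerator devices of a given memory size needed
to hold it, n_dev = ceil(4 M N / (mem_gb * 10^9)) — decimal gigabytes.

Indexing is 0-based half-open internally; 1-based bim positions exist only
at the file boundary.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .io_formats import MISSING, VariantRecord

log = logging.getLogger("mixedgwas")


class GenotypeMatrix:
    """Raw hard calls plus a lazily standardized view.

    Parameters
    ----------
    counts
        N x M int matrix of allele1 copy counts in {0, 1, 2, MISSING}.
    variants
        Optional variant metadata, filtered alongside the columns.
    dtype
        Storage dtype for the standardized matrix; float32 halves memory
        (4 bytes/entry, matching the planner's assumption) while products
        still accumulate in float64.

    Monomorphic columns (minor-allele count 0 among non-missing calls) and
    all-missing columns are dropped on construction with a logged warning.
    """

    def __init__(self, counts: np.ndarray,
                 variants: list[VariantRecord] | None = None,
                 sample_ids: list[str] | None = None,
                 dtype=np.float64):
        counts = np.asarray(counts)
        if counts.ndim != 2:
            raise ValueError("counts must be 2-D (samples x variants)")
        obs = counts != MISSING
        n_obs = obs.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            ac1 = np.where(obs, counts, 0).sum(axis=0, dtype=np.int64)
            p = np.where(n_obs > 0, ac1 / np.maximum(2 * n_obs, 1), np.nan)
        mac = np.minimum(ac1, 2 * n_obs - ac1)
        keep = (n_obs > 0) & (mac >= 1)
        n_drop = int((~keep).sum())
        if n_drop:
            log.warning("grm_engine: dropped %d monomorphic/all-missing "
                        "variant(s) of %d", n_drop, counts.shape[1])
        self.counts = counts[:, keep]
        self.freqs = p[keep]
        self.kept_indices = np.flatnonzero(keep)
        self.variants = ([variants[i] for i in self.kept_indices]
                         if variants is not None else None)
        self.sample_ids = sample_ids
        self._dtype = np.dtype(dtype)
        self._std: np.ndarray | None = None
        self._diag: np.ndarray | None = None
        self._dense: np.ndarray | None = None
        self._eig: tuple[np.ndarray, np.ndarray] | None = None

    # -- shape ------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_variants(self) -> int:
        return self.counts.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    # -- standardization --------------------------------------------------
    @property
    def std(self) -> np.ndarray:
        """Standardized N x M matrix A (missing entries imputed to 0)."""
        if self._std is None:
            p = self.freqs
            if np.any((p <= 0) | (p >= 1)):
                raise AssertionError("monomorphic column survived filtering")
            scale = np.sqrt(2.0 * p * (1.0 - p))
            a = (self.counts.astype(np.float64) - 2.0 * p) / scale
            a[self.counts == MISSING] = 0.0
            self._std = a.astype(self._dtype, copy=False)
        return self._std

    def imputed_counts(self) -> np.ndarray:
        """Raw counts as float with missing entries set to the mean 2 p_j."""
        g = self.counts.astype(np.float64)
        miss = self.counts == MISSING
        if miss.any():
            g[miss] = np.broadcast_to(2.0 * self.freqs, g.shape)[miss]
        return g

    # -- implicit GRM products --------------------------------------------
    def matvec(self, v: np.ndarray) -> np.ndarray:
        """psi v = A (A^T v) / M without forming the N x N GRM."""
        v = np.asarray(v, dtype=np.float64)
        if v.shape[0] != self.n_samples:
            raise ValueError(
                f"vector length {v.shape[0]} != n_samples {self.n_samples}")
        if not np.all(np.isfinite(v)):
            raise ValueError("matvec input must be finite")
        A = self.std
        # float64 accumulation even when A is stored in float32
        return A @ (A.T @ v) / self.n_variants if A.dtype == np.float64 else (
            A.astype(np.float64) @ (A.T.astype(np.float64) @ v) / self.n_variants)

    def diag(self) -> np.ndarray:
        """Diagonal of psi: entry i is (1/M) sum_j a_ij^2 (nonnegative)."""
        if self._diag is None:
            A = self.std
            self._diag = np.einsum("ij,ij->i", A, A, dtype=np.float64) \
                / self.n_variants
        return self._diag

    def dense_grm(self) -> np.ndarray:
        """Explicit N x N GRM; desk-scale diagnostics and exact traces only."""
        if self._dense is None:
            A = self.std.astype(np.float64, copy=False)
            self._dense = (A @ A.T) / self.n_variants
        return self._dense

    def grm_eigh(self) -> tuple[np.ndarray, np.ndarray]:
        """Cached eigendecomposition of the dense GRM (ascending values)."""
        if self._eig is None:
            lam, q = np.linalg.eigh(self.dense_grm())
            self._eig = (lam, q)
        return self._eig


def grm_matvec(gstd: GenotypeMatrix, v: np.ndarray) -> np.ndarray:
    """Functional alias for :meth:`GenotypeMatrix.matvec`."""
    return gstd.matvec(v)


def grm_diag(gstd: GenotypeMatrix) -> np.ndarray:
    """Functional alias for :meth:`GenotypeMatrix.diag`."""
    return gstd.diag()


# ---------------------------------------------------------------------------
# Column partitioning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PartitionPlan:
    """Disjoint, ordered, covering column ranges [(s_1,e_1),...] over [0, M)."""

    ranges: tuple[tuple[int, int], ...]
    n_columns: int

    def __post_init__(self) -> None:
        if not self.ranges:
            raise ValueError("partition plan needs at least one range")
        prev = 0
        for s, e in self.ranges:
            if s != prev or e <= s:
                raise ValueError(
                    f"ranges must be ordered, disjoint and covering; got "
                    f"{self.ranges} over [0, {self.n_columns})")
            prev = e
        if prev != self.n_columns:
            raise ValueError(
                f"ranges cover [0, {prev}) but matrix has {self.n_columns} columns")

    @property
    def n_workers(self) -> int:
        return len(self.ranges)

    @classmethod
    def equal_chunks(cls, n_columns: int, n_workers: int) -> "PartitionPlan":
        """Split [0, M) into ``n_workers`` near-equal contiguous ranges."""
        if n_columns < 1 or n_workers < 1:
            raise ValueError("n_columns and n_workers must be >= 1")
        n_workers = min(n_workers, n_columns)
        edges = np.linspace(0, n_columns, n_workers + 1).astype(int)
        return cls(tuple(zip(edges[:-1].tolist(), edges[1:].tolist())), n_columns)

    @classmethod
    def from_boundaries(cls, boundaries, n_columns: int) -> "PartitionPlan":
        bnd = [0, *sorted(int(b) for b in boundaries), n_columns]
        return cls(tuple(zip(bnd[:-1], bnd[1:])), n_columns)


def partitioned_grm_matvec(gstd: GenotypeMatrix, v: np.ndarray,
                           plan: PartitionPlan) -> np.ndarray:
    """psi v via independent per-range partial products and an ordered
    (ascending range index) sum-reduction.

    Algebraically identical to :func:`grm_matvec` for any plan; numerically
    equal up to float reassociation across partitions (~1e-8 relative).
    """
    if plan.n_columns != gstd.n_variants:
        raise ValueError(
            f"plan covers {plan.n_columns} columns but matrix has "
            f"{gstd.n_variants}")
    v = np.asarray(v, dtype=np.float64)
    A = gstd.std
    out = np.zeros(gstd.n_samples)
    for s, e in plan.ranges:  # fixed ascending reduction order
        block = A[:, s:e].astype(np.float64, copy=False)
        out += block @ (block.T @ v)
    return out / gstd.n_variants


# ---------------------------------------------------------------------------
# Device-count capacity planner
# ---------------------------------------------------------------------------

def plan_gpus(n_variants: int, n_samples: int, mem_gb: float) -> int:
    """Devices needed to hold an M x N single-precision genotype matrix.

    ``ceil(4 * M * N / (mem_gb * 10^9))``, clamped to at least 1; memory is
    in decimal gigabytes (16 GB = 16e9 bytes) and 4 is the byte size of one
    single-precision float.
    """
    if n_variants < 1 or n_samples < 1:
        raise ValueError("variant and sample counts must be >= 1")
    if not mem_gb > 0:
        raise ValueError("mem_gb must be positive")
    return max(1, math.ceil(4 * n_variants * n_samples / (mem_gb * 1e9)))
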