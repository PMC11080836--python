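"""log2-CPM transformation, leading-log-fold-change MDS, and a permutation
test for dimer-driven batch effects.

The batch-effect question: do sample coordinates in expression space track
the fraction of adapter-dimer reads (a technical variable) rather than
biology?  The test computes the Spearman correlation between per-sample
dimer percentage and each MDS coordinate and calibrates it by permutation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CountMatrix",
    "MDSResult",
    "BatchEffectResult",
    "log_cpm",
    "leading_logfc_mds",
    "dimer_batch_effect_test",
]


@dataclass
class CountMatrix:
    """Feature-by-sample matrix of non-negative integer counts."""

    features: list[str]
    samples: list[str]
    counts: np.ndarray

    def __init__(
        self,
        features: list[str],
        samples: list[str],
        counts: np.ndarray,
        allow_zero_samples: bool = False,
    ) -> None:
        counts = np.asarray(counts)
        if counts.shape != (len(features), len(samples)):
            raise ValueError("counts shape must be (n_features, n_samples)")
        if len(set(features)) != len(features) or len(set(samples)) != len(samples):
            raise ValueError("duplicate feature or sample ids")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        if not allow_zero_samples and (counts.sum(axis=0) == 0).any():
            bad = [s for s, c in zip(samples, counts.sum(axis=0)) if c == 0]
            raise ValueError(f"zero library size for samples: {bad}")
        self.features = list(features)
        self.samples = list(samples)
        self.counts = counts.astype(np.int64)

    @staticmethod
    def from_tsv(path: str | Path) -> "CountMatrix":
        """Read a TSV with feature ids in the first column, samples in the header."""
        frame = pd.read_csv(path, sep="\t", index_col=0)
        return CountMatrix(
            list(frame.index.astype(str)),
            list(frame.columns.astype(str)),
            frame.to_numpy(),
        )

    def to_tsv(self, path: str | Path) -> None:
        frame = pd.DataFrame(self.counts, index=self.features, columns=self.samples)
        frame.index.name = "feature"
        frame.to_csv(path, sep="\t")


@dataclass
class MDSResult:
    """Classical-MDS embedding: samples x k coordinates, eigenvalues
    (descending), and the input distance matrix."""

    coordinates: np.ndarray
    eigenvalues: np.ndarray
    distance_matrix: np.ndarray
    samples: list[str]


@dataclass
class BatchEffectResult:
    """Spearman association of one MDS dimension with dimer percentage,
    with a seeded permutation p-value.  ``dimension`` is 1-based."""

    dimension: int
    spearman_rho: float
    p_perm: float
    n_perm: int
    seed: int


def log_cpm(counts: CountMatrix, prior: float = 2.0) -> np.ndarray:
    """log2 counts-per-million with a pseudo-count prior.

    ``value[f, s] = log2((counts[f, s] + prior) / (libsize_s + 2*prior) * 1e6)``.
    """
    lib = counts.counts.sum(axis=0).astype(float)
    if (lib == 0).any():
        bad = [s for s, c in zip(counts.samples, lib) if c == 0]
        raise ValueError(f"zero library size for samples: {bad}")
    return np.log2((counts.counts + prior) / (lib + 2.0 * prior) * 1e6)


def _leading_logfc_distances(logcpm: np.ndarray, top_n: int) -> np.ndarray:
    F, S = logcpm.shape
    if F < top_n:
        warnings.warn(
            f"only {F} features available; using all instead of top {top_n}",
            stacklevel=3,
        )
        top_n = F
    D = np.zeros((S, S))
    for s in range(S):
        for t in range(s + 1, S):
            diff = np.abs(logcpm[:, s] - logcpm[:, t])
            if top_n < F:
                top = np.partition(diff, F - top_n)[F - top_n :]
            else:
                top = diff
            D[s, t] = D[t, s] = float(np.sqrt(np.mean(top**2)))
    return D


def leading_logfc_mds(
    logcpm: np.ndarray,
    top_n: int = 500,
    k: int = 2,
    samples: list[str] | None = None,
) -> MDSResult:
    """Classical metric MDS on leading-log-fold-change distances.

    The pairwise distance is the root-mean-square of the ``top_n`` largest
    absolute log-CPM differences between two samples (recomputed per pair).
    Embedding is by double-centering of squared distances and
    eigendecomposition; coordinates are the top-k eigenvectors scaled by
    the square root of their (non-negative) eigenvalues, with each axis'
    first nonzero loading made positive so results are reproducible.
    """
    F, S = logcpm.shape
    if S < 3:
        raise ValueError("need at least 3 samples for MDS")
    if not 1 <= k <= S - 1:
        raise ValueError("need 1 <= k <= n_samples - 1")
    D = _leading_logfc_distances(logcpm, top_n)
    J = np.eye(S) - np.ones((S, S)) / S
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    coords = vecs[:, :k] * np.sqrt(np.clip(vals[:k], 0.0, None))
    for axis in range(k):
        col = coords[:, axis]
        nz = np.nonzero(np.abs(col) > 1e-12)[0]
        if len(nz) and col[nz[0]] < 0:
            coords[:, axis] = -col
    return MDSResult(
        coordinates=coords,
        eigenvalues=vals,
        distance_matrix=D,
        samples=list(samples) if samples is not None else [str(i) for i in range(S)],
    )


def dimer_batch_effect_test(
    mds: MDSResult,
    pct_dimer: np.ndarray,
    n_perm: int = 10_000,
    seed: int = 0,
) -> list[BatchEffectResult]:
    """Permutation test of dimer fraction vs. each MDS coordinate.

    ``p_perm = (1 + #{perm : |rho*| >= |rho|}) / (n_perm + 1)`` with the
    dimer vector permuted by a seeded generator; reproducible given the
    seed, and never smaller than ``1/(n_perm+1)``.
    """
    pct_dimer = np.asarray(pct_dimer, dtype=float)
    S, k = mds.coordinates.shape
    if len(pct_dimer) != S:
        raise ValueError("pct_dimer length must match the number of samples")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if np.ptp(pct_dimer) == 0:
        raise ValueError("pct_dimer is constant; Spearman rho is undefined")
    rng = np.random.default_rng(seed)
    rx = stats.rankdata(pct_dimer)
    perm_rows = rng.permuted(np.tile(rx, (n_perm, 1)), axis=1)

    def _corr(rows: np.ndarray, ry: np.ndarray) -> np.ndarray:
        rc = rows - rows.mean(axis=1, keepdims=True)
        yc = ry - ry.mean()
        denom = np.sqrt((rc**2).sum(axis=1) * (yc**2).sum())
        return (rc @ yc) / denom

    out = []
    for d in range(k):
        ry = stats.rankdata(mds.coordinates[:, d])
        if np.ptp(ry) == 0:
            warnings.warn(f"MDS dimension {d + 1} is constant; skipping")
            continue
        rho = float(_corr(rx[None, :], ry)[0])
        rho_perm = _corr(perm_rows, ry)
        exceed = int(np.sum(np.abs(rho_perm) >= abs(rho) - 1e-12))
        out.append(
            BatchEffectResult(
                dimension=d + 1,
                spearman_rho=rho,
                p_perm=(1 + exceed) / (n_perm + 1),
                n_perm=n_perm,
                seed=seed,
            )
        )
    return out
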