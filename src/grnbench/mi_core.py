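"""Discretization and entropy / mutual-information estimation.

Shared substrate of the MI-based inference methods (relevance networks,
CLR, ARACNE, MRNET). Expression is discretized per gene (or over the
global range), and MI is computed as H(X) + H(Y) - H(X, Y) from bin-count
histograms under one of four entropy estimators:

``empirical``
    Plug-in estimator on the observed frequencies.
``mm``
    Miller-Madow: plug-in plus the (m_occupied - 1) / (2n) bias correction.
``shrink``
    Plug-in on James-Stein frequencies shrunk toward the uniform 1/m
    distribution with the closed-form shrinkage intensity.
``sg``
    Plug-in on pseudocount frequencies (n_i + 1/m) / (n + 1)
    (Schuermann-Grassberger Dirichlet prior with parameter 1/m).

All entropies are in nats. Negative MI values arising from the corrected
estimators are clipped to zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulator import ExpressionDataset

ESTIMATORS = ("empirical", "mm", "shrink", "sg")
DISCRETIZATIONS = ("equalwidth", "equalfreq", "globalequalwidth")


@dataclass
class DiscretizedMatrix:
    """Integer bin indices, genes x samples, with the binning method tag."""

    indices: np.ndarray
    bins: int
    method: str
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        if self.bins < 2:
            raise ValueError("bins must be >= 2")
        if self.indices.min(initial=0) < 0 or \
                self.indices.max(initial=0) >= self.bins:
            raise ValueError("bin indices out of range")


@dataclass
class MIMatrix:
    """Symmetric nonnegative genes x genes mutual-information matrix."""

    values: np.ndarray
    gene_ids: list[str]
    estimator: str
    discretization: str = ""
    bins: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        g = len(self.gene_ids)
        if self.values.shape != (g, g):
            raise ValueError("MI matrix must be square over gene_ids")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("MI matrix must be symmetric")
        if (self.values < 0).any():
            raise ValueError("MI values must be nonnegative")
        np.fill_diagonal(self.values, 0.0)


# ---------------------------------------------------------------------------
# Discretization
# ---------------------------------------------------------------------------

def _equalwidth_row(row: np.ndarray, lo: float, hi: float,
                    bins: int) -> np.ndarray:
    if hi <= lo:  # constant input: everything in bin 0
        return np.zeros(row.shape, dtype=np.int64)
    idx = np.floor((row - lo) / (hi - lo) * bins).astype(np.int64)
    # right-close the last bin so the maximum lands in bins-1
    return np.clip(idx, 0, bins - 1)


def discretize(data: ExpressionDataset, method: str = "equalfreq",
               bins: int = 5) -> DiscretizedMatrix:
    """Discretize expression into ``bins`` symbols per gene.

    ``equalwidth`` bins each gene's own [min, max] range into equal-width
    intervals (last bin right-closed); ``equalfreq`` uses per-gene quantile
    cut points with ties assigned to the lower bin; ``globalequalwidth``
    uses equal-width bins over the global [min, max] of the whole matrix.
    """
    if method not in DISCRETIZATIONS:
        raise ValueError(f"unknown discretization {method!r}")
    if bins < 2:
        raise ValueError("bins must be >= 2")
    x = data.values
    if method == "equalfreq" and bins > data.n_samples:
        raise ValueError(
            f"equalfreq requires bins <= samples ({data.n_samples})")

    out = np.empty_like(x, dtype=np.int64)
    if method == "globalequalwidth":
        lo, hi = float(x.min()), float(x.max())
        for i in range(x.shape[0]):
            out[i] = _equalwidth_row(x[i], lo, hi, bins)
    elif method == "equalwidth":
        for i in range(x.shape[0]):
            out[i] = _equalwidth_row(x[i], float(x[i].min()),
                                     float(x[i].max()), bins)
    else:
        qs = np.linspace(0, 1, bins + 1)[1:-1]
        for i in range(x.shape[0]):
            cuts = np.quantile(x[i], qs)
            # side='left': a value equal to a cut point stays in the lower bin
            out[i] = np.searchsorted(cuts, x[i], side="left")
    return DiscretizedMatrix(indices=out, bins=bins, method=method,
                             gene_ids=list(data.gene_ids))


# ---------------------------------------------------------------------------
# Entropy estimators
# ---------------------------------------------------------------------------

def _plugin(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def entropy(counts: np.ndarray, estimator: str = "empirical") -> float:
    """Entropy (nats) of a histogram over m bins under one estimator."""
    counts = np.asarray(counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("counts must be nonnegative")
    n = counts.sum()
    if n < 1:
        raise ValueError("entropy of an all-zero histogram is undefined")
    m = counts.size
    p_hat = counts / n

    if estimator == "empirical":
        return _plugin(p_hat)
    if estimator == "mm":
        occupied = int((counts > 0).sum())
        return _plugin(p_hat) + (occupied - 1) / (2.0 * n)
    if estimator == "shrink":
        target = 1.0 / m
        denom = (n - 1) * ((target - p_hat) ** 2).sum()
        if denom <= 0:
            lam = 1.0
        else:
            lam = float(np.clip((1.0 - (p_hat ** 2).sum()) / denom, 0.0, 1.0))
        return _plugin(lam * target + (1.0 - lam) * p_hat)
    if estimator == "sg":
        p = (counts + 1.0 / m) / (n + 1.0)
        return _plugin(p)
    raise ValueError(f"unknown estimator {estimator!r}")


def _joint_counts(x: np.ndarray, y: np.ndarray, mx: int,
                  my: int) -> np.ndarray:
    return np.bincount(x * my + y, minlength=mx * my).astype(float)


def mutual_information(x_bins: np.ndarray, y_bins: np.ndarray,
                       estimator: str = "empirical",
                       n_bins_x: int | None = None,
                       n_bins_y: int | None = None) -> float:
    """MI(X; Y) = H(X) + H(Y) - H(X, Y) on discretized vectors.

    ``n_bins_x`` / ``n_bins_y`` give the nominal alphabet sizes (used by the
    shrink and sg priors); they default to max(index) + 1.
    """
    x = np.asarray(x_bins, dtype=np.int64)
    y = np.asarray(y_bins, dtype=np.int64)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    mx = n_bins_x or int(x.max()) + 1
    my = n_bins_y or int(y.max()) + 1
    hx = entropy(np.bincount(x, minlength=mx), estimator)
    hy = entropy(np.bincount(y, minlength=my), estimator)
    hxy = entropy(_joint_counts(x, y, mx, my), estimator)
    return max(0.0, hx + hy - hxy)


def mi_matrix(data: ExpressionDataset,
              estimator: str = "empirical",
              discretization: str = "equalfreq",
              bins: int = 5) -> MIMatrix:
    """Pairwise MI over all unordered gene pairs; symmetric, zero diagonal."""
    disc = discretize(data, method=discretization, bins=bins)
    return mi_matrix_from_discretized(disc, estimator)


def mi_matrix_from_discretized(disc: DiscretizedMatrix,
                               estimator: str = "empirical") -> MIMatrix:
    idx = disc.indices
    g = idx.shape[0]
    b = disc.bins
    marg = np.array([entropy(np.bincount(idx[i], minlength=b), estimator)
                     for i in range(g)])
    out = np.zeros((g, g))
    for i in range(g):
        xi = idx[i] * b
        for j in range(i + 1, g):
            hxy = entropy(np.bincount(xi + idx[j], minlength=b * b)
                          .astype(float), estimator)
            out[i, j] = out[j, i] = max(0.0, marg[i] + marg[j] - hxy)
    return MIMatrix(values=out, gene_ids=list(disc.gene_ids),
                    estimator=estimator, discretization=disc.method,
                    bins=b)
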