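"""Unsupervised network-inference methods.

Eight methods, each mapping an expression dataset (or a precomputed MI
matrix) to a matrix of edge scores:

* ``rn``            -- relevance networks: scores are the raw MI values;
* ``clr``           -- context likelihood of relatedness: MI z-scored
  against each gene's background MI distribution;
* ``aracne``        -- MI with data-processing-inequality triangle pruning;
* ``mrnet``         -- maximum-relevance / minimum-redundancy forward
  selection per target;
* ``correlations``  -- absolute Pearson / Spearman / Kendall correlation;
* ``wgcna``         -- soft-threshold adjacency |r|^softpower;
* ``pcit``          -- partial-correlation-and-information-theory trio
  filtering of the correlation matrix;
* ``genie``         -- per-target random-forest feature importances
  (directed).

All methods except ``genie`` produce symmetric score matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.stats
from sklearn.ensemble import RandomForestRegressor

from .mi_core import MIMatrix, mi_matrix
from .simulator import ExpressionDataset

logger = logging.getLogger("grnbench.unsupervised")


@dataclass
class ScoreMatrix:
    """Real-valued genes x genes edge scores with a zero diagonal.

    ``values[i, j]`` scores the (directed) candidate edge gene_i -> gene_j;
    symmetric matrices carry the undirected score in both triangles.
    ``regulators``, when set, restricts the meaningful rows to that subset
    (used by supervised per-TF inference).
    """

    values: np.ndarray
    gene_ids: list[str]
    directed: bool
    method: str
    params: dict = field(default_factory=dict)
    regulators: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        g = len(self.gene_ids)
        if self.values.shape != (g, g):
            raise ValueError("score matrix must be square over gene_ids")
        if not np.isfinite(self.values).all():
            raise ValueError("scores must be finite")
        if not self.directed and not np.allclose(self.values, self.values.T):
            raise ValueError("undirected score matrix must be symmetric")
        np.fill_diagonal(self.values, 0.0)

    def score(self, regulator: str, target: str) -> float:
        i = self.gene_ids.index(regulator)
        j = self.gene_ids.index(target)
        return float(self.values[i, j])


# ---------------------------------------------------------------------------
# MI-based methods
# ---------------------------------------------------------------------------

def rn(mi: MIMatrix) -> ScoreMatrix:
    """Relevance networks: score every pair by its mutual information."""
    return ScoreMatrix(values=mi.values.copy(), gene_ids=list(mi.gene_ids),
                       directed=False, method="rn",
                       params={"estimator": mi.estimator,
                               "discretization": mi.discretization,
                               "bins": mi.bins})


def clr(mi: MIMatrix) -> ScoreMatrix:
    """Context likelihood of relatedness.

    Each MI value is z-scored against the row-wise background distribution
    of both genes (negative z clipped to 0) and the two z-scores combined as
    sqrt(z_i^2 + z_j^2).
    """
    m = mi.values
    g = m.shape[0]
    if g < 3:
        raise ValueError("clr requires at least 3 genes")
    off = ~np.eye(g, dtype=bool)
    mu = np.array([m[i, off[i]].mean() for i in range(g)])
    sd = np.array([m[i, off[i]].std() for i in range(g)])
    z = np.zeros_like(m)
    nz = sd > 0
    z[nz] = (m[nz] - mu[nz, None]) / sd[nz, None]
    z = np.maximum(z, 0.0)
    scores = np.sqrt(z ** 2 + z.T ** 2)
    np.fill_diagonal(scores, 0.0)
    return ScoreMatrix(values=scores, gene_ids=list(mi.gene_ids),
                       directed=False, method="clr",
                       params={"estimator": mi.estimator,
                               "discretization": mi.discretization,
                               "bins": mi.bins})


def aracne(mi: MIMatrix, eps: float = 0.0) -> ScoreMatrix:
    """ARACNE: remove the weakest edge of every fully connected triangle.

    For each triangle (i, j, k) with three positive MI entries, edge (i, j)
    is marked for removal when MI_ij < min(MI_ik, MI_jk) - eps. All marks
    are computed against the original matrix and applied afterwards (no
    cascading), so surviving edges keep their MI score.
    """
    if eps < 0:
        raise ValueError("eps must be >= 0")
    m = mi.values
    g = m.shape[0]
    pos = m > 0
    marked = np.zeros_like(pos)
    for k in range(g):
        col = m[:, k]
        colpos = pos[:, k]
        # min(MI_ik, MI_jk) for every (i, j) with both legs positive
        mins = np.minimum.outer(col, col)
        both = np.outer(colpos, colpos)
        marked |= pos & both & (m < mins - eps)
    np.fill_diagonal(marked, False)
    out = np.where(marked, 0.0, m)
    out = np.minimum(out, out.T)  # marks are symmetric by construction
    return ScoreMatrix(values=out, gene_ids=list(mi.gene_ids),
                       directed=False, method="aracne",
                       params={"eps": eps, "estimator": mi.estimator,
                               "discretization": mi.discretization,
                               "bins": mi.bins})


def mrnet(mi: MIMatrix) -> ScoreMatrix:
    """MRNET: per-target maximum-relevance minimum-redundancy selection.

    For each target Y, predictors are greedily selected maximizing
    u_j = MI(X_j; Y) - mean_{k in selected} MI(X_j; X_k); selection stops
    when the best u is <= 0. A selected pair's directional score is its u
    at selection time; the symmetric score is the max over both directions.
    Ties break toward the lower gene index.
    """
    m = mi.values
    g = m.shape[0]
    directional = np.zeros_like(m)  # directional[x, y]: x predicts y
    for y in range(g):
        candidates = [x for x in range(g) if x != y]
        relevance = m[:, y]
        selected: list[int] = []
        redundancy_sum = np.zeros(g)
        while candidates:
            if selected:
                u = np.array([relevance[x] - redundancy_sum[x] / len(selected)
                              for x in candidates])
            else:
                u = np.array([relevance[x] for x in candidates])
            best = int(np.argmax(u))
            if u[best] <= 0 and selected:
                break
            x = candidates.pop(best)
            if u[best] <= 0:  # first pick with zero relevance: nothing to do
                break
            directional[x, y] = u[best]
            selected.append(x)
            redundancy_sum += m[:, x]
    scores = np.maximum(directional, directional.T)
    return ScoreMatrix(values=scores, gene_ids=list(mi.gene_ids),
                       directed=False, method="mrnet",
                       params={"estimator": mi.estimator,
                               "discretization": mi.discretization,
                               "bins": mi.bins})


# ---------------------------------------------------------------------------
# Correlation-based methods
# ---------------------------------------------------------------------------

def _correlation_matrix(data: ExpressionDataset, kind: str) -> np.ndarray:
    x = data.values
    g = x.shape[0]
    constant = x.std(axis=1) == 0
    if constant.any():
        logger.info("correlations: %d constant genes scored 0",
                    int(constant.sum()))
    if kind == "pearson":
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.corrcoef(x)
    elif kind == "spearman":
        ranks = scipy.stats.rankdata(x, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.corrcoef(ranks)
    elif kind == "kendall":
        r = np.eye(g)
        for i in range(g):
            for j in range(i + 1, g):
                if constant[i] or constant[j]:
                    tau = 0.0
                else:
                    tau = scipy.stats.kendalltau(x[i], x[j]).statistic
                r[i, j] = r[j, i] = 0.0 if np.isnan(tau) else tau
    else:
        raise ValueError(f"unknown correlation kind {kind!r}")
    r = np.nan_to_num(r, nan=0.0)
    np.fill_diagonal(r, 1.0)
    return r


def correlations(data: ExpressionDataset,
                 kind: str = "pearson") -> ScoreMatrix:
    """Absolute correlation as edge score; constant genes score 0."""
    if data.n_samples < 3:
        raise ValueError("correlations require at least 3 samples")
    r = np.abs(_correlation_matrix(data, kind))
    np.fill_diagonal(r, 0.0)
    return ScoreMatrix(values=r, gene_ids=list(data.gene_ids),
                       directed=False, method="correlations",
                       params={"kind": kind})


def wgcna(data: ExpressionDataset, kind: str = "pearson",
          softpower: int = 7, tom: bool = False) -> ScoreMatrix:
    """Soft-threshold co-expression adjacency a = |r|^softpower.

    With ``tom=True`` the topological-overlap transform of the adjacency is
    returned instead (shared-neighbour smoothing of the adjacency).
    """
    if softpower < 1:
        raise ValueError("softpower must be >= 1")
    base = correlations(data, kind=kind)
    a = base.values ** softpower
    np.fill_diagonal(a, 0.0)
    if tom:
        l = a @ a
        k = a.sum(axis=1)
        denom = np.minimum.outer(k, k) + 1.0 - a
        with np.errstate(invalid="ignore", divide="ignore"):
            a = np.where(denom > 0, (l + a) / denom, 0.0)
        np.fill_diagonal(a, 0.0)
        a = (a + a.T) / 2.0
    return ScoreMatrix(values=a, gene_ids=list(data.gene_ids),
                       directed=False, method="wgcna",
                       params={"kind": kind, "softpower": softpower,
                               "tom": tom})


def _first_order_partial(rxy: np.ndarray, rxz: np.ndarray,
                         rzy: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        return (rxy - rxz * rzy) / np.sqrt((1 - rxz ** 2) * (1 - rzy ** 2))


def pcit(data: ExpressionDataset, kind: str = "pearson") -> ScoreMatrix:
    """PCIT: trio-wise partial-correlation significance filtering.

    For every gene trio (x, y, z) the three first-order partial
    correlations are computed; the trio tolerance is the mean of the three
    |partial / direct| ratios, and the (x, y) association is flagged
    non-significant if for some z both |r_xy| <= eps * |r_xz| and
    |r_xy| <= eps * |r_yz|. Surviving edges score |r_xy|. Trios with a
    unit-magnitude direct correlation (degenerate denominator) are skipped.
    """
    if data.n_genes < 3:
        raise ValueError("pcit requires at least 3 genes")
    if data.n_samples < 4:
        raise ValueError("pcit requires at least 4 samples")
    r = _correlation_matrix(data, kind)
    g = r.shape[0]
    absr = np.abs(r)
    flagged = np.zeros((g, g), dtype=bool)
    skipped = 0
    eye = np.eye(g, dtype=bool)
    for z in range(g):
        rxz = r[:, z][:, None]           # column vector over x
        rzy = r[z, :][None, :]           # row vector over y
        pc_xy_z = _first_order_partial(r, rxz, rzy)
        pc_xz_y = _first_order_partial(rxz, r, rzy)   # pair (x,z) given y
        pc_zy_x = _first_order_partial(rzy, rxz, r)   # pair (z,y) given x
        with np.errstate(invalid="ignore", divide="ignore"):
            eps = (np.abs(pc_xy_z) / absr
                   + np.abs(pc_xz_y) / np.abs(rxz)
                   + np.abs(pc_zy_x) / np.abs(rzy)) / 3.0
        valid = np.isfinite(eps)
        valid[z, :] = False
        valid[:, z] = False
        valid &= ~eye
        skipped += int((~np.isfinite(eps) & ~eye).sum())
        cond = valid & (absr <= eps * np.abs(rxz)) \
            & (absr <= eps * np.abs(rzy))
        flagged |= cond
    if skipped:
        logger.info("pcit: skipped %d degenerate trio evaluations", skipped)
    flagged |= flagged.T
    out = np.where(flagged, 0.0, absr)
    np.fill_diagonal(out, 0.0)
    return ScoreMatrix(values=out, gene_ids=list(data.gene_ids),
                       directed=False, method="pcit",
                       params={"kind": kind})


# ---------------------------------------------------------------------------
# Tree-ensemble method
# ---------------------------------------------------------------------------

def genie(data: ExpressionDataset,
          candidate_regulators: list[str] | None = None,
          n_trees: int = 1000,
          k_features: str = "sqrt",
          seed: int = 0) -> ScoreMatrix:
    """GENIE3-style per-target random-forest importance scoring (directed).

    Each gene is regressed in turn on the candidate regulators (itself
    excluded) with a random forest; the score of edge j -> target is the
    impurity-reduction importance of regulator j, normalized so each
    nonconstant target's incoming scores sum to 1.
    """
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    if k_features not in ("sqrt", "all"):
        raise ValueError("k_features must be 'sqrt' or 'all'")
    genes = data.gene_ids
    if data.n_genes < 2:
        raise ValueError("genie requires at least 2 genes")
    reg_ids = list(candidate_regulators) if candidate_regulators else genes
    unknown = set(reg_ids) - set(genes)
    if unknown:
        raise ValueError(f"unknown candidate regulators: {sorted(unknown)}")
    index = {g_: i for i, g_ in enumerate(genes)}
    x = data.values
    g = len(genes)
    scores = np.zeros((g, g))
    rng = np.random.default_rng(seed)
    max_features = "sqrt" if k_features == "sqrt" else 1.0
    for t, target in enumerate(genes):
        preds = [index[r_] for r_ in reg_ids if r_ != target]
        if not preds:
            continue
        y = x[t]
        if y.std() == 0:
            logger.info("genie: constant target %s scored 0", target)
            continue
        forest = RandomForestRegressor(
            n_estimators=n_trees, max_features=max_features,
            random_state=int(rng.integers(2 ** 31 - 1)), n_jobs=1)
        forest.fit(x[preds].T, y)
        imp = forest.feature_importances_
        total = imp.sum()
        if total > 0:
            imp = imp / total
        scores[preds, t] = imp
    return ScoreMatrix(values=scores, gene_ids=list(genes), directed=True,
                       method="genie",
                       params={"n_trees": n_trees, "k_features": k_features,
                               "seed": seed},
                       regulators=reg_ids if candidate_regulators else None)


# ---------------------------------------------------------------------------
# Method registry
# ---------------------------------------------------------------------------

MI_METHODS = {"rn": rn, "clr": clr, "aracne": aracne, "mrnet": mrnet}


def run_method(name: str, data: ExpressionDataset, **params) -> ScoreMatrix:
    """Run one unsupervised method by name on an expression dataset.

    MI-based methods accept ``estimator`` / ``discretization`` / ``bins``
    (and ``eps`` for aracne); correlation-based methods accept ``kind``
    (plus ``softpower`` for wgcna); ``genie`` accepts ``n_trees``,
    ``k_features``, ``seed`` and ``candidate_regulators``.
    """
    if name in MI_METHODS:
        mi = mi_matrix(data,
                       estimator=params.pop("estimator", "empirical"),
                       discretization=params.pop("discretization",
                                                 "equalfreq"),
                       bins=params.pop("bins", 5))
        return MI_METHODS[name](mi, **params)
    if name == "correlations":
        return correlations(data, **params)
    if name == "wgcna":
        return wgcna(data, **params)
    if name == "pcit":
        return pcit(data, **params)
    if name == "genie":
        return genie(data, **params)
    raise ValueError(f"unknown method {name!r}")
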