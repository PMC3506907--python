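"""AUC evaluation, parameter sweeps and statistical method comparison.

Predictions are ranked candidate edge lists; the gold standard is closed
world (absent pairs are negatives). Accuracy is the area under the ROC
curve computed with the tie-aware midrank rank-sum formula: the fraction
of positive-negative pairs ranked concordantly, ties counted one half.
An AUC of 0.5 is random, 1.0 perfect.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.stats
from sklearn.metrics import roc_curve

from .simulator import GeneNetwork
from .unsupervised import ScoreMatrix, run_method

logger = logging.getLogger("grnbench.evaluation")


@dataclass
class EvaluationResult:
    """AUC plus the ROC polyline and the candidate-universe composition."""

    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    n_pos: int
    n_neg: int
    mode: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError("auc must lie in [0, 1]")


@dataclass
class SweepRow:
    params: dict
    result: EvaluationResult | None
    error: str | None = None

    @property
    def auc(self) -> float:
        return self.result.auc if self.result is not None else float("nan")


@dataclass
class SweepResult:
    """One row per parameter configuration; best row = max AUC, first wins ties."""

    method: str
    rows: list[SweepRow] = field(default_factory=list)

    @property
    def best(self) -> SweepRow:
        ok = [r for r in self.rows if r.result is not None]
        if not ok:
            raise ValueError("sweep produced no successful configuration")
        return max(ok, key=lambda r: r.auc)  # max keeps the first of ties

    @property
    def aucs(self) -> list[float]:
        return [r.auc for r in self.rows]


# ---------------------------------------------------------------------------
# AUC
# ---------------------------------------------------------------------------

def _midrank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    pos = labels == 1
    n_pos = int(pos.sum())
    n_neg = labels.size - n_pos
    ranks = scipy.stats.rankdata(scores)  # midranks for ties
    rank_sum = ranks[pos].sum()
    return float((rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def candidate_universe(scores: ScoreMatrix, gold: GeneNetwork,
                       mode: str,
                       exclude_tf_tf: bool = False,
                       exclude_pairs: set[tuple[str, str]] | None = None,
                       restrict_regulators: list[str] | None = None
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Score and label vectors over the candidate edge universe.

    ``directed`` mode enumerates all ordered non-self pairs (restricted to
    the scorer's regulator rows when it declares them); symmetric scorers
    contribute each pair's score in both directions. ``undirected`` mode
    enumerates unordered pairs, collapsing the gold standard by logical OR
    and directed scores by their maximum. ``exclude_pairs`` removes specific
    directed pairs (e.g. training edges) from the universe;
    ``restrict_regulators`` narrows the rows considered, so different
    methods can be compared on an identical universe.
    """
    genes = scores.gene_ids
    missing = set(gold.nodes) - set(genes)
    if missing:
        raise ValueError(f"gold genes missing from scores: {sorted(missing)}")
    index = {g: i for i, g in enumerate(genes)}
    edge_set = gold.edge_set()
    excl = exclude_pairs or set()
    is_tf = {g: gold.tf_flags.get(g, False) for g in genes}
    vals = scores.values

    s_list: list[float] = []
    l_list: list[int] = []
    if mode == "directed":
        rows = scores.regulators if scores.regulators is not None else genes
        if restrict_regulators is not None:
            rows = [r for r in rows if r in set(restrict_regulators)]
        for r in rows:
            i = index[r]
            for j, t in enumerate(genes):
                if i == j or (r, t) in excl:
                    continue
                if exclude_tf_tf and is_tf[r] and is_tf[t]:
                    continue
                s_list.append(vals[i, j])
                l_list.append(1 if (r, t) in edge_set else 0)
    elif mode == "undirected":
        for a, b in itertools.combinations(range(len(genes)), 2):
            ga, gb = genes[a], genes[b]
            if (ga, gb) in excl or (gb, ga) in excl:
                continue
            if exclude_tf_tf and is_tf[ga] and is_tf[gb]:
                continue
            s = vals[a, b] if not scores.directed \
                else max(vals[a, b], vals[b, a])
            s_list.append(s)
            l_list.append(1 if (ga, gb) in edge_set or (gb, ga) in edge_set
                          else 0)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return np.asarray(s_list, dtype=float), np.asarray(l_list, dtype=int)


def default_mode(scores: ScoreMatrix) -> str:
    """Directed evaluation for directed scorers, undirected otherwise."""
    return "directed" if scores.directed else "undirected"


def roc_auc(scores: ScoreMatrix, gold: GeneNetwork,
            mode: str | None = None,
            exclude_tf_tf: bool = False,
            exclude_pairs: set[tuple[str, str]] | None = None,
            restrict_regulators: list[str] | None = None
            ) -> EvaluationResult:
    """Midrank AUC (and ROC points) of a score matrix against a gold standard."""
    mode = mode or default_mode(scores)
    s, labels = candidate_universe(scores, gold, mode,
                                   exclude_tf_tf=exclude_tf_tf,
                                   exclude_pairs=exclude_pairs,
                                   restrict_regulators=restrict_regulators)
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            f"candidate universe needs positives and negatives "
            f"(got {n_pos} / {n_neg})")
    auc = _midrank_auc(s, labels)
    fpr, tpr, _ = roc_curve(labels, s)
    return EvaluationResult(auc=auc, fpr=fpr, tpr=tpr,
                            n_pos=n_pos, n_neg=n_neg, mode=mode)


# ---------------------------------------------------------------------------
# Parameter sweeps
# ---------------------------------------------------------------------------

def canonical_bin_sizes() -> list[int]:
    """The 26 bin counts swept for MI methods: 2-10 step 1, 15-95 step 5."""
    return list(range(2, 11)) + list(range(15, 100, 5))


def mi_method_grid() -> dict[str, list]:
    """4 estimators x 3 discretizations x 26 bin sizes = 312 configurations."""
    return {
        "estimator": ["empirical", "mm", "shrink", "sg"],
        "discretization": ["equalfreq", "equalwidth", "globalequalwidth"],
        "bins": canonical_bin_sizes(),
    }


def wgcna_grid() -> dict[str, list]:
    """3 correlation kinds x softpower 7..17 = 33 configurations."""
    return {
        "kind": ["pearson", "spearman", "kendall"],
        "softpower": list(range(7, 18)),
    }


def correlation_grid() -> dict[str, list]:
    return {"kind": ["pearson", "spearman", "kendall"]}


def enumerate_grid(grid: dict[str, list]) -> list[dict]:
    """Cartesian product of the grid in key-insertion order."""
    if not grid:
        raise ValueError("grid must be nonempty")
    keys = list(grid)
    return [dict(zip(keys, combo))
            for combo in itertools.product(*(grid[k] for k in keys))]


def parameter_sweep(method: str,
                    grid: dict[str, list],
                    data=None,
                    gold: GeneNetwork | None = None,
                    mode: str | None = None,
                    evaluator=None,
                    fixed_params: dict | None = None) -> SweepResult:
    """Evaluate one method over every configuration of a parameter grid.

    ``evaluator``, when given, replaces score computation + AUC with a
    callable ``evaluator(params) -> EvaluationResult`` (used for grid
    bookkeeping and testing). A failing configuration is recorded as an
    error row and the sweep continues.
    """
    result = SweepResult(method=method)
    for params in enumerate_grid(grid):
        full = {**(fixed_params or {}), **params}
        try:
            if evaluator is not None:
                res = evaluator(full)
            else:
                scores = run_method(method, data, **full)
                res = roc_auc(scores, gold, mode=mode)
            result.rows.append(SweepRow(params=params, result=res))
        except Exception as exc:  # noqa: BLE001 - sweep must continue
            logger.warning("sweep %s %s failed: %s", method, params, exc)
            result.rows.append(SweepRow(params=params, result=None,
                                        error=str(exc)))
    return result


def sweep_mi_methods(data, gold: GeneNetwork,
                     methods: list[str] | None = None,
                     grid: dict[str, list] | None = None,
                     mode: str | None = None) -> dict[str, SweepResult]:
    """Sweep several MI-based methods sharing one MI matrix per configuration.

    Computing the MI matrix dominates the cost of rn/clr/aracne/mrnet, so
    sweeping them together over the same (estimator, discretization, bins)
    grid reuses each matrix across methods.
    """
    from .mi_core import mi_matrix
    from .unsupervised import MI_METHODS

    methods = methods or ["rn", "clr", "aracne", "mrnet"]
    grid = grid or mi_method_grid()
    results = {m: SweepResult(method=m) for m in methods}
    for params in enumerate_grid(grid):
        try:
            mi = mi_matrix(data, **params)
        except Exception as exc:  # noqa: BLE001
            for m in methods:
                results[m].rows.append(
                    SweepRow(params=params, result=None, error=str(exc)))
            continue
        for m in methods:
            try:
                res = roc_auc(MI_METHODS[m](mi), gold, mode=mode)
                results[m].rows.append(SweepRow(params=params, result=res))
            except Exception as exc:  # noqa: BLE001
                results[m].rows.append(
                    SweepRow(params=params, result=None, error=str(exc)))
    return results


# ---------------------------------------------------------------------------
# Statistical comparison
# ---------------------------------------------------------------------------

@dataclass
class PairwiseTest:
    group_a: str
    group_b: str
    statistic: float
    p_raw: float
    p_adjusted: float
    significant: bool


def compare_methods(auc_groups: dict[str, list[float]],
                    alpha: float = 0.01) -> list[PairwiseTest]:
    """Two-sided Mann-Whitney U tests for every pair of AUC groups.

    P-values are Bonferroni-adjusted for the number of comparisons;
    significance is called at ``alpha`` on the adjusted values.
    """
    for name, vals in auc_groups.items():
        if len(vals) < 3:
            raise ValueError(f"group {name!r} needs >= 3 values")
    pairs = list(itertools.combinations(sorted(auc_groups), 2))
    n_comp = len(pairs)
    out = []
    for a, b in pairs:
        va, vb = auc_groups[a], auc_groups[b]
        if np.ptp(va) == 0 and np.ptp(vb) == 0 and va[0] == vb[0]:
            stat, p = float(len(va) * len(vb) / 2), 1.0
        else:
            res = scipy.stats.mannwhitneyu(va, vb, alternative="two-sided")
            stat, p = float(res.statistic), float(res.pvalue)
        p_adj = min(1.0, p * n_comp)
        out.append(PairwiseTest(group_a=a, group_b=b, statistic=stat,
                                p_raw=p, p_adjusted=p_adj,
                                significant=p_adj < alpha))
    return out
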