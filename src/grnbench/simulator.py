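"""Benchmark-network and steady-state expression simulation.

Generates directed TF->target networks with controllable topology and
density, attaches Hill-kinetics regulation parameters, and solves for
steady-state expression under three experiment designs:

* ``wildtype``      -- a single unperturbed steady state;
* ``knockdown``     -- one wild-type sample plus one sample per gene with
  that gene clamped to a low level (single-gene knockdown);
* ``multifactorial``-- every sample perturbs all genes' basal activities by
  independent lognormal multipliers, mimicking a cohort in which each
  sample is a different individual.

Two-condition datasets with planted regulator switches (a group of targets
re-assigned from one TF to another) are produced by
:func:`make_condition_pair`; these serve as ground truth for differential
network analysis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

logger = logging.getLogger("grnbench.simulator")

ACTIVATE = "activate"
REPRESS = "repress"

#: Clamp level used for knocked-down genes. A small positive value rather
#: than exactly zero, so that log-scale noise models stay well defined.
KNOCKDOWN_LEVEL = 0.01


class ParameterizationError(ValueError):
    """Raised when requested simulation parameters are infeasible."""


class NonConvergenceError(RuntimeError):
    """Raised when the steady-state iteration fails to converge."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Edge:
    """A directed regulatory interaction regulator -> target."""

    regulator: str
    target: str
    sign: str = ACTIVATE
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.sign not in (ACTIVATE, REPRESS):
            raise ValueError(f"unknown edge sign {self.sign!r}")
        if self.regulator == self.target:
            raise ValueError(f"self-loop on {self.regulator!r} not allowed")


@dataclass
class GeneNetwork:
    """Directed gene network with per-node regulator (TF) designation.

    Serves as source topology, gold standard or prediction. ``negatives``
    optionally records explicitly labelled non-interactions (gold-standard
    rows with label 0).
    """

    nodes: list[str]
    tf_flags: dict[str, bool]
    edges: dict[tuple[str, str], Edge] = field(default_factory=dict)
    negatives: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("node identifiers must be unique")
        node_set = set(self.nodes)
        if set(self.tf_flags) - node_set:
            raise ValueError("tf_flags reference unknown nodes")
        for node in self.nodes:
            self.tf_flags.setdefault(node, False)
        for (reg, tgt), edge in self.edges.items():
            if (reg, tgt) != (edge.regulator, edge.target):
                raise ValueError("edge key does not match edge endpoints")
            if reg not in node_set or tgt not in node_set:
                raise ValueError(f"edge {reg}->{tgt} references unknown gene")
            if not self.tf_flags[reg]:
                raise ValueError(f"edge regulator {reg!r} is not TF-flagged")

    # -- convenience -------------------------------------------------------

    @property
    def tfs(self) -> list[str]:
        return [n for n in self.nodes if self.tf_flags[n]]

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def add_edge(self, edge: Edge) -> None:
        if not self.tf_flags.get(edge.regulator, False):
            raise ValueError(f"regulator {edge.regulator!r} is not a TF")
        self.edges[(edge.regulator, edge.target)] = edge

    def regulators_of(self, gene: str) -> list[str]:
        return [r for (r, t) in self.edges if t == gene]

    def targets_of(self, tf: str) -> list[str]:
        return [t for (r, t) in self.edges if r == tf]

    def edge_set(self) -> set[tuple[str, str]]:
        return set(self.edges)

    def to_digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for edge in self.edges.values():
            g.add_edge(edge.regulator, edge.target,
                       sign=edge.sign, weight=edge.weight)
        return g

    def copy(self) -> "GeneNetwork":
        return GeneNetwork(
            nodes=list(self.nodes),
            tf_flags=dict(self.tf_flags),
            edges=dict(self.edges),
            negatives=set(self.negatives),
        )


@dataclass
class KineticRanges:
    """Uniform sampling ranges for the kinetic parameters.

    Defaults give moderately steep, mid-saturation regulation with a small
    transcriptional leak and mild measurement noise.
    """

    basal: tuple[float, float] = (0.2, 1.0)
    hill_n: tuple[float, float] = (1.0, 10.0)
    hill_K: tuple[float, float] = (0.2, 0.8)
    leak: float = 0.1
    noise_sigma: float = 0.05

    def validate(self) -> None:
        lo, hi = self.basal
        if not (0.0 < lo <= hi <= 1.0):
            raise ParameterizationError("basal range must lie in (0, 1]")
        lo, hi = self.hill_n
        if not (1.0 <= lo <= hi <= 10.0):
            raise ParameterizationError("hill_n range must lie in [1, 10]")
        lo, hi = self.hill_K
        if not (0.0 < lo <= hi < 1.0):
            raise ParameterizationError("hill_K range must lie in (0, 1)")
        if not 0.0 <= self.leak < 1.0:
            raise ParameterizationError("leak must lie in [0, 1)")
        if self.noise_sigma < 0.0:
            raise ParameterizationError("noise_sigma must be >= 0")


@dataclass
class KineticModel:
    """A gene network plus Hill-kinetics parameters; generates steady states.

    Each gene has a basal activity in (0, 1]; each edge carries a Hill
    coefficient ``hill_n`` and half-saturation constant ``hill_K``. The
    ``leak`` floor keeps regulated genes weakly expressed even when their
    activators are off.
    """

    network: GeneNetwork
    basal: dict[str, float]
    hill_n: dict[tuple[str, str], float]
    hill_K: dict[tuple[str, str], float]
    leak: float = 0.1
    noise_sigma: float = 0.05

    def __post_init__(self) -> None:
        genes = set(self.network.nodes)
        if set(self.basal) != genes:
            raise ValueError("basal levels must cover every gene exactly")
        if set(self.hill_n) != set(self.network.edges) or \
                set(self.hill_K) != set(self.network.edges):
            raise ValueError("one (hill_n, hill_K) pair required per edge")
        for g, b in self.basal.items():
            if not (0.0 < b <= 1.0):
                raise ValueError(f"basal[{g}]={b} outside (0, 1]")
        if not 0.0 <= self.leak < 1.0:
            raise ValueError("leak must lie in [0, 1)")
        if self.noise_sigma < 0.0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass
class ExpressionDataset:
    """Genes x samples expression matrix with design metadata.

    ``values`` is a real matrix in [0, 1] oriented genes (rows) by samples
    (columns). ``perturbation_log`` records, per sample, what was done to
    produce it (clamped gene or basal multipliers).
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    design: str = "wildtype"
    condition: list[str] | None = None
    perturbation_log: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples")
        if np.isnan(self.values).any():
            raise ValueError("expression matrix contains missing values")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene identifiers")
        if self.condition is not None and \
                len(self.condition) != len(self.sample_ids):
            raise ValueError("condition labels must match sample count")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


# ---------------------------------------------------------------------------
# Network generation
# ---------------------------------------------------------------------------

def _gene_names(n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def generate_source_network(n_nodes: int,
                            topology: str = "scale_free",
                            tf_fraction: float = 0.25,
                            mean_degree: float = 2.0,
                            seed: int = 0,
                            p_activate: float = 2 / 3,
                            acyclic: bool = True) -> GeneNetwork:
    """Generate a weakly connected directed TF->target source network.

    ``mean_degree`` is the average number of edges per node, so the target
    edge count is ``round(mean_degree * n_nodes)``. Under ``scale_free``
    each edge's regulator is drawn preferentially by current out-degree,
    giving hub TFs; under ``erdos_renyi`` regulators are drawn uniformly.
    A few extra edges may be added afterwards to enforce weak connectivity.

    By default the network is kept free of directed cycles, mirroring the
    predominantly feed-forward structure of curated transcriptional
    networks and guaranteeing a unique stable steady state; pass
    ``acyclic=False`` to allow feedback loops (steep negative feedback can
    then oscillate and the steady-state solver may legitimately fail).
    """
    if n_nodes < 5:
        raise ParameterizationError("n_nodes must be >= 5")
    if not 0.0 < tf_fraction < 1.0:
        raise ParameterizationError("tf_fraction must lie in (0, 1)")
    if mean_degree < 1.0:
        raise ParameterizationError("mean_degree must be >= 1")
    if topology not in ("scale_free", "erdos_renyi"):
        raise ParameterizationError(f"unknown topology {topology!r}")

    rng = np.random.default_rng(seed)
    nodes = _gene_names(n_nodes)
    n_tfs = math.ceil(tf_fraction * n_nodes)
    tfs = nodes[:n_tfs]
    tf_flags = {n: (n in set(tfs)) for n in nodes}

    n_edges = int(round(mean_degree * n_nodes))
    max_edges = n_tfs * (n_nodes - 1)
    if n_edges > max_edges:
        raise ParameterizationError(
            f"cannot place {n_edges} edges with {n_tfs} TFs and "
            f"{n_nodes} nodes (max {max_edges} without self-loops)")

    net = GeneNetwork(nodes=nodes, tf_flags=tf_flags)
    graph = nx.DiGraph()
    graph.add_nodes_from(nodes)
    out_degree = {tf: 0 for tf in tfs}
    attempts = 0
    while net.n_edges < n_edges:
        attempts += 1
        if attempts > 200 * n_edges:
            raise ParameterizationError(
                "edge placement stalled; parameters too dense "
                "(or acyclicity infeasible)")
        if topology == "scale_free":
            w = np.array([out_degree[tf] + 1.0 for tf in tfs])
            reg = tfs[rng.choice(n_tfs, p=w / w.sum())]
        else:
            reg = tfs[rng.integers(n_tfs)]
        tgt = nodes[rng.integers(n_nodes)]
        if tgt == reg or (reg, tgt) in net.edges:
            continue
        if acyclic and nx.has_path(graph, tgt, reg):
            continue
        sign = ACTIVATE if rng.random() < p_activate else REPRESS
        net.add_edge(Edge(reg, tgt, sign=sign))
        graph.add_edge(reg, tgt)
        out_degree[reg] += 1

    _connect_weakly(net, rng, p_activate, acyclic=acyclic)
    return net


def _connect_weakly(net: GeneNetwork, rng: np.random.Generator,
                    p_activate: float, acyclic: bool = False) -> None:
    """Join weakly connected components by adding TF->node bridge edges."""
    g = net.to_digraph()
    comps = sorted(nx.weakly_connected_components(g), key=len, reverse=True)
    if len(comps) <= 1:
        return
    main = set(comps[0])
    tf_pool = list(net.tfs)
    for comp in comps[1:]:
        # prefer a TF inside the detached component regulating into the main
        # component; otherwise bridge from a main-component TF into it.
        comp_tfs = sorted(n for n in comp if net.tf_flags[n])
        if comp_tfs:
            reg = comp_tfs[rng.integers(len(comp_tfs))]
            candidates = sorted(main - {reg})
        else:
            main_tfs = [n for n in tf_pool if n in main]
            reg = main_tfs[rng.integers(len(main_tfs))]
            candidates = sorted(set(comp) - {reg})
        if acyclic:
            candidates = [c for c in candidates if not nx.has_path(g, c, reg)]
        tgt = candidates[rng.integers(len(candidates))]
        if (reg, tgt) not in net.edges:
            sign = ACTIVATE if rng.random() < p_activate else REPRESS
            net.add_edge(Edge(reg, tgt, sign=sign))
            g.add_edge(reg, tgt)
        main |= comp
    logger.debug("added bridge edges to connect %d components", len(comps))


def sample_subnetwork(source: GeneNetwork, size: int,
                      seed: int = 0) -> GeneNetwork:
    """Extract an induced subgraph grown by seeded neighbour addition.

    Starting from a random node, neighbours (ignoring edge direction) are
    added one at a time until ``size`` nodes are collected; if growth stalls
    in a too-small component, a fresh random node outside the current set is
    drawn and growth continues (logged). Denser sources therefore yield
    denser subnetworks of equal node count.
    """
    if not 2 <= size <= len(source.nodes):
        raise ValueError(
            f"size must lie in [2, {len(source.nodes)}], got {size}")
    if size == len(source.nodes):
        return source.copy()

    rng = np.random.default_rng(seed)
    und = source.to_digraph().to_undirected()
    chosen: set[str] = set()
    start = source.nodes[rng.integers(len(source.nodes))]
    chosen.add(start)
    while len(chosen) < size:
        frontier = sorted(
            {nb for n in chosen for nb in und.neighbors(n)} - chosen)
        if not frontier:
            rest = sorted(set(source.nodes) - chosen)
            restart = rest[rng.integers(len(rest))]
            logger.info("subnetwork growth stalled; restarting from %s",
                        restart)
            chosen.add(restart)
            continue
        chosen.add(frontier[rng.integers(len(frontier))])

    nodes = [n for n in source.nodes if n in chosen]
    edges = {k: e for k, e in source.edges.items()
             if k[0] in chosen and k[1] in chosen}
    return GeneNetwork(
        nodes=nodes,
        tf_flags={n: source.tf_flags[n] for n in nodes},
        edges=edges,
    )


# ---------------------------------------------------------------------------
# Kinetics
# ---------------------------------------------------------------------------

def assign_kinetics(network: GeneNetwork,
                    ranges: KineticRanges | None = None,
                    seed: int = 0) -> KineticModel:
    """Sample Hill-kinetics parameters uniformly within ``ranges``."""
    if not network.nodes:
        raise ValueError("cannot assign kinetics to an empty network")
    ranges = ranges or KineticRanges()
    ranges.validate()
    rng = np.random.default_rng(seed)
    basal = {g: float(rng.uniform(*ranges.basal)) for g in network.nodes}
    hill_n = {k: float(rng.uniform(*ranges.hill_n)) for k in network.edges}
    hill_K = {k: float(rng.uniform(*ranges.hill_K)) for k in network.edges}
    return KineticModel(network=network, basal=basal, hill_n=hill_n,
                        hill_K=hill_K, leak=ranges.leak,
                        noise_sigma=ranges.noise_sigma)


def hill_activation(x: np.ndarray, n: np.ndarray, K: np.ndarray) -> np.ndarray:
    """Activating Hill term x^n / (K^n + x^n); equals 1/2 at x = K."""
    xn = np.power(x, n)
    return xn / (np.power(K, n) + xn)


def hill_repression(x: np.ndarray, n: np.ndarray, K: np.ndarray) -> np.ndarray:
    """Repressing Hill term K^n / (K^n + x^n); equals 1/2 at x = K."""
    Kn = np.power(K, n)
    return Kn / (Kn + np.power(x, n))


class _CompiledModel:
    """Index-based arrays for vectorised steady-state iteration."""

    def __init__(self, model: KineticModel):
        net = model.network
        self.genes = net.nodes
        self.index = {g: i for i, g in enumerate(self.genes)}
        self.basal = np.array([model.basal[g] for g in self.genes])
        keys = sorted(net.edges)
        self.src = np.array([self.index[r] for r, _ in keys], dtype=int)
        self.dst = np.array([self.index[t] for _, t in keys], dtype=int)
        self.n = np.array([model.hill_n[k] for k in keys])
        self.K = np.array([model.hill_K[k] for k in keys])
        self.activating = np.array(
            [net.edges[k].sign == ACTIVATE for k in keys])
        self.leak = model.leak


def _regulation_map(cm: _CompiledModel, x: np.ndarray,
                    mult: np.ndarray) -> np.ndarray:
    """Apply the regulation function once: x (genes x cols) -> F(x)."""
    xg = x[cm.src]  # per-edge regulator levels
    term = np.where(cm.activating[:, None],
                    hill_activation(xg, cm.n[:, None], cm.K[:, None]),
                    hill_repression(xg, cm.n[:, None], cm.K[:, None]))
    factors = cm.leak + (1.0 - cm.leak) * term
    prod = np.ones_like(x)
    np.multiply.at(prod, cm.dst, factors)
    return np.minimum(1.0, mult * cm.basal[:, None] * prod)


def _solve(cm: _CompiledModel,
           mult: np.ndarray,
           clamp_idx: np.ndarray,
           clamp_val: np.ndarray,
           clamp_col: np.ndarray,
           damping: float,
           tol: float,
           max_iter: int) -> tuple[np.ndarray, np.ndarray]:
    """Damped synchronous fixed-point iteration over all columns at once.

    Returns the state matrix and a boolean per-column convergence flag.
    Clamped entries (gene ``clamp_idx[i]`` in column ``clamp_col[i]``) are
    held at ``clamp_val[i]`` throughout. Convergence is measured on the
    undamped residual |F(x) - x|, so the criterion does not weaken as the
    damping grows.
    """
    n_cols = mult.shape[1]
    x = np.minimum(1.0, mult * cm.basal[:, None])
    x[clamp_idx, clamp_col] = clamp_val
    converged = np.zeros(n_cols, dtype=bool)
    for _ in range(max_iter):
        fx = _regulation_map(cm, x, mult)
        fx[clamp_idx, clamp_col] = clamp_val
        residual = np.abs(fx - x).max(axis=0)
        x = (1.0 - damping) * fx + damping * x
        converged = residual < tol
        if converged.all():
            break
    return x, converged


def _cycle_hint(model: KineticModel) -> str:
    try:
        cycle = nx.find_cycle(model.network.to_digraph())
        return " -> ".join(u for u, _ in cycle) + f" -> {cycle[-1][1]}"
    except nx.NetworkXNoCycle:
        return "(no directed cycle found)"


def steady_state(model: KineticModel,
                 clamped: dict[str, float] | None = None,
                 basal_multipliers: dict[str, float] | None = None,
                 damping: float = 0.5,
                 tol: float = 1e-8,
                 max_iter: int = 5000) -> dict[str, float]:
    """Solve for one steady-state expression vector.

    Each unclamped gene i relaxes to
    ``x_i = min(1, m_i * b_i * prod_edges (leak + (1-leak) * hill(x_reg)))``
    where the hill term is activating or repressing per the edge sign.
    Genes without regulators sit at ``m_i * b_i``; clamped genes are fixed.
    """
    clamped = clamped or {}
    basal_multipliers = basal_multipliers or {}
    for g, v in clamped.items():
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"clamp level for {g} must lie in [0, 1]")
    for g, m in basal_multipliers.items():
        if m <= 0:
            raise ValueError(f"basal multiplier for {g} must be > 0")

    cm = _CompiledModel(model)
    mult = np.ones((len(cm.genes), 1))
    for g, m in basal_multipliers.items():
        mult[cm.index[g], 0] = m
    cidx = np.array([cm.index[g] for g in clamped], dtype=int)
    cval = np.array(list(clamped.values()), dtype=float)
    ccol = np.zeros(len(clamped), dtype=int)

    x, ok = _solve(cm, mult, cidx, cval, ccol, damping, tol, max_iter)
    if not ok.all():
        raise NonConvergenceError(
            f"steady state did not converge within {max_iter} iterations; "
            f"suspect cycle: {_cycle_hint(model)}")
    return {g: float(x[i, 0]) for g, i in cm.index.items()}


# ---------------------------------------------------------------------------
# Experiment simulation
# ---------------------------------------------------------------------------

def simulate_experiment(model: KineticModel,
                        design: str = "multifactorial",
                        n_samples: int = 100,
                        tau: float = 0.5,
                        seed: int = 0,
                        knockdown_level: float = KNOCKDOWN_LEVEL,
                        condition: str | None = None) -> ExpressionDataset:
    """Simulate a steady-state expression dataset under one design.

    knockdown: one wild-type sample plus one per gene with that gene clamped
    to ``knockdown_level`` (n_genes + 1 samples in total). multifactorial:
    ``n_samples`` samples, each multiplying every gene's basal activity by
    an independent exp(N(0, tau^2)) draw. After solving, multiplicative
    lognormal measurement noise with sigma ``model.noise_sigma`` is applied
    and values are clipped to [0, 1].
    """
    if design not in ("wildtype", "knockdown", "multifactorial"):
        raise ParameterizationError(f"unknown design {design!r}")
    if tau < 0:
        raise ParameterizationError("tau must be >= 0")
    rng = np.random.default_rng(seed)
    cm = _CompiledModel(model)
    genes = cm.genes
    g = len(genes)

    if design == "wildtype":
        n_cols = 1
        mult = np.ones((g, 1))
        cidx = np.array([], dtype=int)
        cval = np.array([], dtype=float)
        ccol = np.array([], dtype=int)
        sample_ids = ["wt"]
        log = [{"kind": "wildtype"}]
    elif design == "knockdown":
        n_cols = g + 1
        mult = np.ones((g, n_cols))
        cidx = np.arange(g)
        cval = np.full(g, knockdown_level)
        ccol = np.arange(1, g + 1)
        sample_ids = ["wt"] + [f"kd_{gene}" for gene in genes]
        log = [{"kind": "wildtype"}] + [
            {"kind": "knockdown", "gene": gene, "level": knockdown_level}
            for gene in genes]
    else:
        if n_samples < 1:
            raise ParameterizationError("n_samples must be >= 1")
        n_cols = n_samples
        mult = np.exp(rng.normal(0.0, tau, size=(g, n_cols)))
        cidx = np.array([], dtype=int)
        cval = np.array([], dtype=float)
        ccol = np.array([], dtype=int)
        sample_ids = [f"mf_{i + 1}" for i in range(n_cols)]
        log = [{"kind": "multifactorial",
                "multipliers": dict(zip(genes, mult[:, i].tolist()))}
               for i in range(n_cols)]

    x, ok = _solve(cm, mult, cidx, cval, ccol, 0.5, 1e-8, 5000)
    if not ok.all():
        # Retry the stubborn columns once with heavier damping: for a local
        # Jacobian eigenvalue lambda the damped map contracts when
        # |d + (1-d) lambda| < 1, so d = 0.9 stabilizes slopes up to ~19
        # (the steepest Hill edges reach ~n / (4 K) ~ 12.5); slow modes
        # near +1 then need many more, cheap, iterations.
        bad = np.flatnonzero(~ok)
        keep = np.isin(ccol, bad)
        x_bad, ok_bad = _solve(cm, mult[:, bad], cidx[keep], cval[keep],
                               np.searchsorted(bad, ccol[keep]),
                               0.9, 1e-8, 100000)
        x[:, bad] = x_bad
        if not ok_bad.all():
            raise NonConvergenceError(
                f"{int((~ok_bad).sum())} samples failed to converge; "
                f"suspect cycle: {_cycle_hint(model)}")

    if model.noise_sigma > 0:
        x = x * np.exp(rng.normal(0.0, model.noise_sigma, size=x.shape))
    x = np.clip(x, 0.0, 1.0)

    return ExpressionDataset(
        values=x, gene_ids=list(genes), sample_ids=sample_ids,
        design=design,
        condition=[condition] * n_cols if condition else None,
        perturbation_log=log)


# ---------------------------------------------------------------------------
# Condition pairs with planted regulator switches
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegulatorSwitch:
    """A planted (or detected) regulator reassignment between conditions."""

    old_tf: str
    new_tf: str
    targets: frozenset[str]

    @property
    def size(self) -> int:
        return len(self.targets)


def make_condition_pair(model: KineticModel,
                        n_switches: int = 1,
                        switch_size: int = 5,
                        seed: int = 0
                        ) -> tuple[KineticModel, KineticModel,
                                   list[RegulatorSwitch]]:
    """Derive two condition models differing only by planted switches.

    For each switch, a group of ``switch_size`` targets regulated solely by
    one TF in condition A has that incoming edge reassigned to a different
    TF in condition B (kinetic parameters carried over). The returned
    manifest lists every planted (old TF, new TF, target set). Target groups
    across switches are disjoint.
    """
    net = model.network
    tfs = net.tfs
    if len(tfs) < 2:
        raise ParameterizationError("network needs at least 2 TFs")
    if n_switches < 0 or switch_size < 1:
        raise ParameterizationError("n_switches >= 0, switch_size >= 1")

    rng = np.random.default_rng(seed)
    model_a = KineticModel(network=net.copy(), basal=dict(model.basal),
                           hill_n=dict(model.hill_n),
                           hill_K=dict(model.hill_K),
                           leak=model.leak, noise_sigma=model.noise_sigma)
    model_b = KineticModel(network=net.copy(), basal=dict(model.basal),
                           hill_n=dict(model.hill_n),
                           hill_K=dict(model.hill_K),
                           leak=model.leak, noise_sigma=model.noise_sigma)
    manifest: list[RegulatorSwitch] = []
    if n_switches == 0:
        return model_a, model_b, manifest

    # eligible targets: exactly one regulator, not themselves TFs (keeps the
    # switch signature clean in expression space)
    sole_reg: dict[str, str] = {}
    for gene in net.nodes:
        regs = net.regulators_of(gene)
        if len(regs) == 1 and not net.tf_flags[gene]:
            sole_reg[gene] = regs[0]

    by_tf: dict[str, list[str]] = {}
    for gene, tf in sole_reg.items():
        by_tf.setdefault(tf, []).append(gene)

    used: set[str] = set()
    for _ in range(n_switches):
        eligible_tfs = [tf for tf in tfs
                        if len([t for t in by_tf.get(tf, [])
                                if t not in used]) >= switch_size]
        if not eligible_tfs:
            raise ParameterizationError(
                f"cannot plant {n_switches} disjoint switches of size "
                f"{switch_size}: not enough singly regulated targets")
        old_tf = eligible_tfs[rng.integers(len(eligible_tfs))]
        pool = [t for t in by_tf[old_tf] if t not in used]
        targets = [pool[i] for i in
                   rng.choice(len(pool), size=switch_size, replace=False)]
        others = [tf for tf in tfs if tf != old_tf]
        new_tf = others[rng.integers(len(others))]
        for tgt in targets:
            if tgt == new_tf or (new_tf, tgt) in model_b.network.edges:
                raise ParameterizationError(
                    f"switch target {tgt} conflicts with new TF {new_tf}")
            old_key = (old_tf, tgt)
            edge = model_b.network.edges.pop(old_key)
            model_b.network.add_edge(replace(edge, regulator=new_tf))
            model_b.hill_n[(new_tf, tgt)] = model_b.hill_n.pop(old_key)
            model_b.hill_K[(new_tf, tgt)] = model_b.hill_K.pop(old_key)
            used.add(tgt)
        manifest.append(RegulatorSwitch(old_tf=old_tf, new_tf=new_tf,
                                        targets=frozenset(targets)))
    return model_a, model_b, manifest
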