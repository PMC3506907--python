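"""File dialects, pipeline configuration and logging plumbing.

All files are plain UTF-8 tab-separated text. Expression matrices are read
and written in two dialects: ``genes_by_samples`` (rows = genes, first
column the gene identifier) and ``dream_rowsamples`` (first row gene
names, subsequent rows samples — the DREAM-challenge layout). Gold
standards are 3-column regulator / target / {0, 1} lists. Networks and
score matrices export as tidy edge tables or Cytoscape SIF.

Gene identifiers are opaque case-sensitive strings; no symbol mapping is
performed.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from .simulator import Edge, ExpressionDataset, GeneNetwork, RegulatorSwitch
from .unsupervised import ScoreMatrix

logger = logging.getLogger("grnbench.io")

EXPRESSION_DIALECTS = ("dream_rowsamples", "genes_by_samples")


class ParseError(ValueError):
    """Raised for malformed input files; the message names the line."""


def configure_logging(level: str = "INFO") -> None:
    """Route package logging to stderr at the requested level."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(
        logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("grnbench")
    root.handlers.clear()
    root.addHandler(handler)
    root.setLevel(level.upper())


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

def write_expression(data: ExpressionDataset, path: str | Path,
                     dialect: str = "genes_by_samples") -> None:
    if dialect not in EXPRESSION_DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.DataFrame(data.values, index=data.gene_ids,
                      columns=data.sample_ids)
    if dialect == "dream_rowsamples":
        df.T.to_csv(path, sep="\t", index=False)
    else:
        df.to_csv(path, sep="\t", index_label="gene")


def read_expression(path: str | Path,
                    dialect: str = "genes_by_samples") -> ExpressionDataset:
    """Read a tab-separated expression table, returning genes x samples.

    The ``dream_rowsamples`` dialect (samples as rows, gene names in the
    header) is transposed on read; gene order is preserved as written.
    """
    if dialect not in EXPRESSION_DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    try:
        if dialect == "dream_rowsamples":
            df = pd.read_csv(path, sep="\t", header=0)
            gene_ids = [str(c) for c in df.columns]
            values = df.to_numpy(dtype=float).T
            sample_ids = [f"s{i + 1}" for i in range(values.shape[1])]
        else:
            df = pd.read_csv(path, sep="\t", header=0, index_col=0)
            gene_ids = [str(i) for i in df.index]
            sample_ids = [str(c) for c in df.columns]
            values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric or ragged table: {exc}") \
            from exc
    if len(set(gene_ids)) != len(gene_ids):
        dupes = sorted({g for g in gene_ids if gene_ids.count(g) > 1})
        raise ParseError(f"{path}: duplicate gene ids {dupes}")
    bad = np.argwhere(np.isnan(values))
    if bad.size:
        i, j = bad[0]
        raise ParseError(
            f"{path}: missing/non-numeric value for gene {gene_ids[i]!r} "
            f"(data line {int(i) + 2})")
    return ExpressionDataset(values=values, gene_ids=gene_ids,
                             sample_ids=sample_ids)


# ---------------------------------------------------------------------------
# Gold standards and training sets
# ---------------------------------------------------------------------------

def write_gold_standard(net: GeneNetwork, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for (r, t) in sorted(net.edges):
            fh.write(f"{r}\t{t}\t1\n")
        for (r, t) in sorted(net.negatives):
            fh.write(f"{r}\t{t}\t0\n")


def read_gold_standard(path: str | Path,
                       universe: list[str]) -> GeneNetwork:
    """Read a 3-column regulator / target / {0,1} edge list.

    Label-1 rows become edges (the regulator is TF-flagged); label-0 rows
    are recorded as explicit negatives. Genes outside ``universe`` and
    self-loop rows are errors.
    """
    path = Path(path)
    uni = set(universe)
    tf_flags = {g: False for g in universe}
    edges: dict[tuple[str, str], Edge] = {}
    negatives: set[tuple[str, str]] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ParseError(
                    f"{path}:{lineno}: expected 3 tab-separated columns")
            reg, tgt, label = parts
            if label not in ("0", "1"):
                raise ParseError(f"{path}:{lineno}: label must be 0 or 1")
            if reg not in uni or tgt not in uni:
                raise ParseError(
                    f"{path}:{lineno}: gene outside universe "
                    f"({reg!r} or {tgt!r})")
            if reg == tgt:
                raise ParseError(f"{path}:{lineno}: self-loop {reg!r}")
            if label == "1":
                tf_flags[reg] = True
                edges[(reg, tgt)] = Edge(reg, tgt)
            else:
                negatives.add((reg, tgt))
    return GeneNetwork(nodes=list(universe), tf_flags=tf_flags,
                       edges=edges, negatives=negatives)


def read_training_set(path: str | Path):
    """Read a 2-column TF / target list into a TrainingSet."""
    from .supervised import TrainingSet

    positives: set[tuple[str, str]] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(
                    f"{path}:{lineno}: expected 2 tab-separated columns")
            positives.add((parts[0], parts[1]))
    tfs = sorted({tf for tf, _ in positives})
    return TrainingSet(positives=positives, tfs=tfs)


# ---------------------------------------------------------------------------
# Networks and score matrices
# ---------------------------------------------------------------------------

def _edge_rows(obj: GeneNetwork | ScoreMatrix,
               condition: str = "", evidence: str = ""):
    if isinstance(obj, GeneNetwork):
        for (r, t), e in sorted(obj.edges.items()):
            yield r, t, e.weight, condition, evidence
    else:
        rows = obj.regulators if obj.regulators is not None else obj.gene_ids
        index = {g: i for i, g in enumerate(obj.gene_ids)}
        for r in rows:
            i = index[r]
            for j, t in enumerate(obj.gene_ids):
                if i == j:
                    continue
                if not obj.directed and i > j:
                    continue
                w = obj.values[i, j]
                if w != 0:
                    yield r, t, float(w), condition, evidence


def write_network(obj: GeneNetwork | ScoreMatrix, path: str | Path,
                  format: str = "tsv_edges",
                  condition: str = "", evidence: str = "") -> None:
    """Write a network or score matrix as a tidy edge table or SIF file."""
    if format == "tsv_edges":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("regulator\ttarget\tweight\tcondition\tevidence\n")
            for r, t, w, c, ev in _edge_rows(obj, condition, evidence):
                fh.write(f"{r}\t{t}\t{w:.10g}\t{c}\t{ev}\n")
    elif format == "sif":
        with open(path, "w", encoding="utf-8") as fh:
            for r, t, _w, _c, _e in _edge_rows(obj, condition, evidence):
                fh.write(f"{r}\treg\t{t}\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_network_tsv(path: str | Path,
                     universe: list[str] | None = None) -> GeneNetwork:
    """Read a tsv_edges file back into a GeneNetwork."""
    df = pd.read_csv(path, sep="\t")
    required = {"regulator", "target", "weight"}
    if not required <= set(df.columns):
        raise ParseError(f"{path}: missing columns {required - set(df.columns)}")
    genes = universe or sorted(set(df["regulator"]) | set(df["target"]))
    tf_flags = {g: False for g in genes}
    edges = {}
    for _, row in df.iterrows():
        r, t = str(row["regulator"]), str(row["target"])
        tf_flags[r] = True
        edges[(r, t)] = Edge(r, t, weight=float(row["weight"]))
    return GeneNetwork(nodes=list(genes), tf_flags=tf_flags, edges=edges)


def write_switch_manifest(switches: list[RegulatorSwitch],
                          path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("old_tf\tnew_tf\ttargets\n")
        for s in switches:
            fh.write(f"{s.old_tf}\t{s.new_tf}\t{','.join(sorted(s.targets))}\n")


def read_switch_manifest(path: str | Path) -> list[RegulatorSwitch]:
    out = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if header.rstrip("\n") != "old_tf\tnew_tf\ttargets":
            raise ParseError(f"{path}: unexpected manifest header")
        for line in fh:
            if not line.strip():
                continue
            old_tf, new_tf, targets = line.rstrip("\n").split("\t")
            out.append(RegulatorSwitch(
                old_tf=old_tf, new_tf=new_tf,
                targets=frozenset(targets.split(","))))
    return out


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Fully resolved run configuration; unknown keys are rejected.

    Parsed from a simple ``key: value`` text file. Every run logs the
    resolved configuration so results can be traced to their settings.
    """

    method: str = "rn"
    estimator: str = "empirical"
    discretization: str = "equalfreq"
    bins: int = 5
    kind: str = "pearson"
    softpower: int = 7
    n_trees: int = 1000
    k_features: str = "sqrt"
    eps: float = 0.0
    folds: int = 3
    min_positives: int = 2
    evaluation_mode: str = ""
    seed: int = 0
    expression_path: str = ""
    gold_path: str = ""
    training_path: str = ""
    out_path: str = ""
    extra: dict = field(default_factory=dict, repr=False)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        known = {f.name: f.type for f in fields(cls) if f.name != "extra"}
        kwargs: dict = {}
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if ":" not in line:
                    raise ParseError(f"{path}:{lineno}: expected 'key: value'")
                key, _, value = line.partition(":")
                key, value = key.strip(), value.strip()
                if key not in known:
                    raise ParseError(f"{path}:{lineno}: unknown key {key!r}")
                current = getattr(cls(), key)
                if isinstance(current, bool):
                    kwargs[key] = value.lower() in ("1", "true", "yes")
                elif isinstance(current, int):
                    kwargs[key] = int(value)
                elif isinstance(current, float):
                    kwargs[key] = float(value)
                else:
                    kwargs[key] = value
        cfg = cls(**kwargs)
        logger.info("resolved config: %s", cfg)
        return cfg

    def method_params(self) -> dict:
        """The parameter subset relevant to the configured method."""
        if self.method in ("rn", "clr", "mrnet"):
            return {"estimator": self.estimator,
                    "discretization": self.discretization, "bins": self.bins}
        if self.method == "aracne":
            return {"estimator": self.estimator,
                    "discretization": self.discretization, "bins": self.bins,
                    "eps": self.eps}
        if self.method in ("correlations", "pcit"):
            return {"kind": self.kind}
        if self.method == "wgcna":
            return {"kind": self.kind, "softpower": self.softpower}
        if self.method == "genie":
            return {"n_trees": self.n_trees, "k_features": self.k_features,
                    "seed": self.seed}
        if self.method == "sirene":
            return {"folds": self.folds, "min_positives": self.min_positives,
                    "seed": self.seed}
        raise ValueError(f"unknown method {self.method!r}")
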