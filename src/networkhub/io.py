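"""Readers and writers for the tab-delimited interchange formats.

Expression tables may arrive samples-in-rows or nodes-in-rows; the
orientation is resolved by matching identifiers against the phenotype
labels.  Networks come as two-column edge lists, optionally accompanied by
a node-definition file mapping a node to a comma-separated list of member
genes, or as a KEGG KGML pathway file.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from lxml import etree

from .scoring import ExpressionMatrix, PhenotypeLabels

logger = logging.getLogger(__name__)

__all__ = [
    "read_labels",
    "read_expression",
    "read_edge_list",
    "read_node_defs",
    "aggregate_multi_gene_nodes",
    "read_kgml",
    "write_table",
    "read_table",
    "write_manifest",
]

_EDGE_HEADERS = {"source", "target", "from", "to", "node1", "node2"}
_FLOAT_FMT = "%.12g"  # 12 significant digits survive a write/read round trip


def read_labels(path) -> PhenotypeLabels:
    """Two-column tab-delimited file: sample id, group label."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two tab-delimited columns")
    df = df.iloc[:, :2].dropna()
    labels = df.iloc[:, 1].unique()
    if len(labels) == 3 and (df.iloc[0, 1] == labels[0]) and (df.iloc[:, 1] == labels[0]).sum() == 1:
        df = df.iloc[1:]  # tolerated header row
        labels = df.iloc[:, 1].unique()
    if len(labels) != 2:
        raise ValueError(f"{path}: exactly two group labels required, found {list(labels)}")
    return PhenotypeLabels(group=dict(zip(df.iloc[:, 0], df.iloc[:, 1])))


def read_expression(path, labels: PhenotypeLabels) -> ExpressionMatrix:
    """Tab-delimited expression matrix with ids in the first row and column.

    Orientation (samples-in-rows vs nodes-in-rows) is auto-detected by
    matching ids against the label file; samples without a label are
    dropped with a logged count.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    samples = set(labels.group)
    if set(df.index) & samples:
        pass  # samples in rows
    elif set(df.columns) & samples:
        df = df.T
    else:
        raise ValueError(f"{path}: no ids overlap the label file in either orientation")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.any().any():
        r, c = np.argwhere(bad.values)[0]
        raise ValueError(
            f"{path}: non-numeric cell {df.values[r, c]!r} at sample "
            f"{df.index[r]!r}, node {df.columns[c]!r}"
        )
    if numeric.isna().any().any():
        r, c = np.argwhere(numeric.isna().values)[0]
        raise ValueError(f"{path}: missing value at sample {df.index[r]!r}, node {df.columns[c]!r}")
    keep = [s in samples for s in df.index]
    dropped = len(df) - sum(keep)
    if dropped:
        logger.info("%s: dropped %d sample(s) absent from the label file", path, dropped)
    numeric = numeric.loc[keep]
    return ExpressionMatrix(
        values=numeric.values.astype(float),
        sample_ids=tuple(str(s) for s in numeric.index),
        node_ids=tuple(str(n) for n in numeric.columns),
    )


def read_edge_list(path) -> list[tuple[str, str]]:
    """Two-column tab-delimited edge list, one edge per line, header optional."""
    edges: list[tuple[str, str]] = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{i + 1}: expected two tab-delimited columns")
            u, v = parts[0].strip(), parts[1].strip()
            if i == 0 and u.lower() in _EDGE_HEADERS and v.lower() in _EDGE_HEADERS:
                continue
            edges.append((u, v))
    if not edges:
        raise ValueError(f"{path}: no edges found")
    return edges


def read_node_defs(path) -> dict[str, tuple[str, ...]]:
    """Node-definition file: node id, then comma-separated member genes."""
    members: dict[str, tuple[str, ...]] = {}
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{i + 1}: expected node id and member list")
            genes = tuple(g.strip() for g in parts[1].split(",") if g.strip())
            if not genes:
                raise ValueError(f"{path}:{i + 1}: node {parts[0]!r} has no members")
            members[parts[0].strip()] = genes
    return members


def aggregate_multi_gene_nodes(
    gene_expr: ExpressionMatrix,
    node_members: dict[str, tuple[str, ...]],
    how: str = "mean",
) -> ExpressionMatrix:
    """Collapse gene-level expression to node level.

    A node's expression is the arithmetic mean (or, with ``how="median"``,
    the median) of its member genes per sample; single-member nodes pass
    through unchanged.  Nodes with no measured member are dropped with a
    warning.
    """
    if how not in ("mean", "median"):
        raise ValueError("how must be 'mean' or 'median'")
    agg = np.mean if how == "mean" else np.median
    gene_idx = {g: i for i, g in enumerate(gene_expr.node_ids)}
    cols, kept = [], []
    for node, genes in node_members.items():
        present = [gene_idx[g] for g in genes if g in gene_idx]
        if not present:
            logger.warning("node %r has no measured member gene; dropped", node)
            continue
        cols.append(agg(gene_expr.values[:, present], axis=1))
        kept.append(node)
    if not kept:
        raise ValueError("no node has any measured member gene")
    return ExpressionMatrix(
        values=np.column_stack(cols),
        sample_ids=gene_expr.sample_ids,
        node_ids=tuple(kept),
    )


def read_kgml(path) -> tuple[list[tuple[str, str]], dict[str, tuple[str, ...]]]:
    """Parse a KEGG KGML pathway into an undirected edge list plus node
    membership.

    Entries of type ``gene`` become single- or multi-gene nodes (all tokens
    of the ``name`` attribute are members; the display name is taken from
    the graphics label when present).  ``group`` entries pool their
    components into one multi-gene node, marked with a trailing ``*``.
    Relations become undirected edges; direction and subtype are discarded.
    This is a best-effort reader, not a byte-compatible port of any
    particular pipeline.
    """
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as e:
        raise ValueError(f"{path}: malformed KGML ({e})") from e
    root = tree.getroot()
    entry_node: dict[str, str] = {}
    entry_members: dict[str, tuple[str, ...]] = {}
    pending_groups: list[tuple[str, list[str]]] = []
    used_names: set[str] = set()

    def display_name(entry) -> str:
        g = entry.find("graphics")
        label = (g.get("name") if g is not None else None) or entry.get("name", "")
        return label.split(",")[0].split()[0] if label.split() else entry.get("id")

    for entry in root.findall("entry"):
        eid = entry.get("id")
        etype = entry.get("type")
        if etype == "group":
            comps = [c.get("id") for c in entry.findall("component")]
            pending_groups.append((eid, comps))
        elif etype in ("gene", "compound", "ortholog"):
            name = display_name(entry)
            if name in used_names:
                name = f"{name}#{eid}"
            used_names.add(name)
            entry_node[eid] = name
            entry_members[eid] = tuple(entry.get("name", name).split()) or (name,)
    for gid, comps in pending_groups:
        members: list[str] = []
        for cid in comps:
            if cid not in entry_node:
                raise ValueError(f"{path}: group {gid} references unknown entry {cid}")
            members.extend(entry_members[cid])
        base = entry_node[comps[0]] if comps else gid
        name = f"{base}*"
        if name in used_names:
            name = f"{name}#{gid}"
        used_names.add(name)
        entry_node[gid] = name
        entry_members[gid] = tuple(dict.fromkeys(members)) or (name,)

    edges: list[tuple[str, str]] = []
    for rel in root.findall("relation"):
        e1, e2 = rel.get("entry1"), rel.get("entry2")
        for e in (e1, e2):
            if e not in entry_node:
                raise ValueError(f"{path}: relation references unknown entry {e}")
        u, v = entry_node[e1], entry_node[e2]
        if u == v:
            logger.warning("%s: relation %s-%s collapses to a self-loop; skipped", path, e1, e2)
            continue
        edges.append((u, v))
    if not entry_node:
        raise ValueError(f"{path}: pathway contains no gene or group entries")
    members_out = {entry_node[eid]: entry_members[eid] for eid in entry_node}
    return edges, members_out


def write_table(df: pd.DataFrame, path) -> None:
    """Tab-delimited output with '.' decimals and 12-significant-digit
    floats, giving byte-identical files across runs."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def plot_scree(result, path, alpha: float = 0.05) -> None:
    """Dual-axis scree plot: sorted influence Q (dots, left axis) against
    -log10 marginal p-values (bars, right axis), with reference lines at
    the nominal level and its per-node Bonferroni division.  Requires
    matplotlib (the ``plot`` extra)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = result.scree_frame()
    fig, ax = plt.subplots(figsize=(max(6, 0.3 * len(df)), 4))
    ax2 = ax.twinx()
    ax2.bar(df["rank"], df["neg_log10_p"], color="0.8", zorder=1)
    ax.plot(df["rank"], df["Q"], "o-", color="tab:blue", zorder=3)
    M = len(df)
    ax2.axhline(-np.log10(alpha), color="red", linestyle="--", linewidth=0.8)
    ax2.axhline(-np.log10(alpha / M), color="red", linewidth=0.8)
    if result.cutoff_index is not None:
        ax.axvline(result.cutoff_index - 0.5, color="tab:green", linestyle=":")
    ax.set_xticks(df["rank"])
    ax.set_xticklabels(df["node_id"], rotation=90, fontsize=7)
    ax.set_ylabel("influence Q")
    ax2.set_ylabel(r"$-\log_{10} p$")
    fig.tight_layout()
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150)
    plt.close(fig)


def write_manifest(manifest: dict, path) -> None:
    """JSON run manifest (scenario, seeds, spec, configuration)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
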