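"""Readers and writers for the pipeline's plain-text formats.

Expression / feature tables are TSV with genes as rows; interaction
networks are 3-column edge lists (gene_a, gene_b, weight — the weight
field may be empty for unweighted edges); drug-target sets use GMT
(drug, description, then one gene per column).
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import pandas as pd

from .simulate import ExpressionMatrix, FeatureTable

__all__ = [
    "write_expression", "read_expression", "write_features", "read_features",
    "write_edgelist", "read_edgelist", "write_gmt", "read_gmt",
    "write_graphml",
]


def write_expression(expr: ExpressionMatrix, expr_path, groups_path):
    expr.values.to_csv(expr_path, sep="\t", index_label="gene")
    expr.groups.rename_axis("sample_id").to_frame().to_csv(groups_path, sep="\t")


def read_expression(expr_path, groups_path) -> ExpressionMatrix:
    values = pd.read_csv(expr_path, sep="\t", index_col=0)
    groups = pd.read_csv(groups_path, sep="\t", index_col=0)["group"]
    bad = set(groups.unique()) - {"tumor", "normal"}
    if bad:
        raise ValueError(f"unknown sample groups: {sorted(bad)}")
    missing = set(values.columns) - set(groups.index)
    if missing:
        raise ValueError(f"{len(missing)} samples lack a group annotation")
    return ExpressionMatrix(values=values, groups=groups.loc[values.columns])


def write_features(ft, path):
    df = ft.matrix if isinstance(ft, FeatureTable) else ft
    df.to_csv(path, sep="\t", index_label="gene")


def read_features(path) -> FeatureTable:
    return FeatureTable(matrix=pd.read_csv(path, sep="\t", index_col=0))


def write_edgelist(g: nx.Graph, path):
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tweight\n")
        for u, v, d in g.edges(data=True):
            w = d.get("weight")
            fh.write(f"{u}\t{v}\t{'' if w is None else w}\n")


def read_edgelist(path):
    """Yield (gene_a, gene_b, weight-or-None) triples; errors carry line numbers."""
    triples = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or (lineno == 1 and line.startswith("gene_a")):
                continue
            parts = line.split("\t")
            if len(parts) == 2:
                parts.append("")
            if len(parts) != 3 or not parts[0] or not parts[1]:
                raise ValueError(f"{path}:{lineno}: malformed edge row: {line!r}")
            w = None
            if parts[2] != "":
                try:
                    w = float(parts[2])
                except ValueError as exc:
                    raise ValueError(
                        f"{path}:{lineno}: bad weight {parts[2]!r}") from exc
                if w < 0:
                    raise ValueError(f"{path}:{lineno}: negative weight {w}")
            triples.append((parts[0], parts[1], w))
    return triples


def write_gmt(drug_targets: dict, path, description: str = "targets"):
    with open(path, "w") as fh:
        for drug in sorted(drug_targets):
            genes = "\t".join(sorted(drug_targets[drug]))
            fh.write(f"{drug}\t{description}\t{genes}\n")


def read_gmt(path) -> dict:
    out = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT rows need id, "
                                 "description and at least one gene")
            out[parts[0]] = set(p for p in parts[2:] if p)
    return out


def write_graphml(g: nx.Graph, path, **node_attrs):
    """GraphML export with optional per-node attribute mappings."""
    out = g.copy()
    for name, mapping in node_attrs.items():
        nx.set_node_attributes(out, {n: mapping.get(n) for n in out.nodes
                                     if mapping.get(n) is not None}, name)
    for u, v, d in out.edges(data=True):
        if d.get("weight") is None:
            d.pop("weight", None)
    nx.write_graphml(out, Path(path))
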