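"""Behavior-model diagram export.

Renders a fitted transition matrix as a directed weighted graph: one node
per behavior, one edge per above-threshold transition probability, with
nodes grouped into dashed stage clusters.  Edge thickness encodes the
probability via the linear map penwidth = 0.5 + 4·p (so p = 1 draws at
width 4.5), and each edge is labelled with the percent to 2 decimals.

DOT output is emitted directly (the grammar is tiny); GraphML goes through
:mod:`networkx` so node/edge attributes are properly typed.
"""

from __future__ import annotations

import networkx as nx

from .ethogram import Ethogram
from .transitions import TransitionMatrix

__all__ = ["behavior_graph", "to_dot", "to_graphml", "PENWIDTH_INTERCEPT", "PENWIDTH_SLOPE"]

PENWIDTH_INTERCEPT = 0.5
PENWIDTH_SLOPE = 4.0


def _check(matrix: TransitionMatrix, ethogram: Ethogram, threshold: float) -> None:
    if not (0.0 <= threshold < 1.0):
        raise ValueError("threshold must be in [0, 1)")
    if not matrix.all_defined:
        raise ValueError("diagram export requires all rows defined")
    if tuple(matrix.states) != ethogram.state_names:
        raise ValueError("matrix states do not match the ethogram")


def behavior_graph(
    matrix: TransitionMatrix, ethogram: Ethogram, threshold: float = 0.0
) -> nx.DiGraph:
    """Directed graph with stage-annotated nodes and probability-weighted
    edges for every p_ij > threshold."""
    _check(matrix, ethogram, threshold)
    g = nx.DiGraph()
    stage_map = ethogram.stage_map
    for state in ethogram.states:
        g.add_node(state.name, label=state.label, stage=stage_map[state.name], index=state.index)
    for i, src in enumerate(ethogram.state_names):
        for j, dst in enumerate(ethogram.state_names):
            p = float(matrix.probs[i, j])
            if p > threshold:
                g.add_edge(src, dst, probability=p)
    return g


def to_dot(matrix: TransitionMatrix, ethogram: Ethogram, threshold: float = 0.0) -> str:
    """DOT text: one dashed cluster per stage, edges weighted by probability."""
    g = behavior_graph(matrix, ethogram, threshold)
    lines = [
        "digraph behavior_model {",
        "  rankdir=LR;",
        '  node [shape=box, style="rounded"];',
    ]
    for stage in ethogram.stages:
        lines.append(f'  subgraph "cluster_{stage.name}" {{')
        lines.append(f'    label="{stage.name}";')
        lines.append("    style=dashed;")
        for name in stage.states:
            label = g.nodes[name]["label"]
            lines.append(f'    "{name}" [label="{label}"];')
        lines.append("  }")
    for src, dst, data in g.edges(data=True):
        p = data["probability"]
        penwidth = PENWIDTH_INTERCEPT + PENWIDTH_SLOPE * p
        lines.append(
            f'  "{src}" -> "{dst}" [label="{p * 100:.2f}", penwidth={penwidth:.3f}];'
        )
    lines.append("}")
    return "\n".join(lines) + "\n"


def to_graphml(matrix: TransitionMatrix, ethogram: Ethogram, threshold: float = 0.0) -> str:
    """GraphML text with probability and stage as typed attributes."""
    g = behavior_graph(matrix, ethogram, threshold)
    return "\n".join(nx.generate_graphml(g)) + "\n"
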