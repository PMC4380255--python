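"""Single-pass trie denoising of flowgrams.

Instead of comparing each read against every cluster center, the read is
threaded into a rooted tree whose edges carry weighted-mean flow values:
at each node the read's next flow value either joins the closest child
edge within the denoising distance (updating that edge's mean) or opens a
new child.  Reads sharing a prefix of similar flow values share a path,
which makes insertion linear in read length — far cheaper than clustering,
at the cost of precision: there is no second iteration, and a value within
distance of several child edges is committed greedily to the closest one.

A read's denoised flowgram is the edge values along its root-to-terminal
path *after all insertions*, so it reflects the final weighted means, like
the clustering module's frozen final centers.  The abundance of a leaf is
the number of reads terminating at it or at any of its ancestors, so leaf
abundances can overcount reads that ended mid-path below several leaves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Optional, Sequence

from .cluster import MissMatrix
from .distances import DistanceModel, distinct
from .sffio import read_flowgrams

log = logging.getLogger(__name__)


class TrieNode:
    __slots__ = ("id", "parent", "edge_value", "edge_count", "terminal_count", "children")

    def __init__(self, node_id: int, parent: Optional["TrieNode"], edge_value: float):
        self.id = node_id
        self.parent = parent
        self.edge_value = edge_value
        self.edge_count = 0
        self.terminal_count = 0
        self.children: list[TrieNode] = []


class FlowTrie:
    """Rooted tree; the root carries no edge."""

    def __init__(self) -> None:
        self.root = TrieNode(0, None, float("nan"))
        self.nodes: list[TrieNode] = [self.root]

    def new_node(self, parent: TrieNode, edge_value: float) -> TrieNode:
        node = TrieNode(len(self.nodes), parent, edge_value)
        self.nodes.append(node)
        parent.children.append(node)
        return node

    def __len__(self) -> int:
        return len(self.nodes)

    def leaves(self) -> Iterator[TrieNode]:
        return (n for n in self.nodes if n is not self.root and not n.children)

    def path_values(self, node_id: int) -> list[float]:
        """Edge values along the root -> node path, at output time."""
        values: list[float] = []
        node = self.nodes[node_id]
        while node.parent is not None:
            values.append(node.edge_value)
            node = node.parent
        values.reverse()
        return values

    @property
    def total_terminals(self) -> int:
        return sum(n.terminal_count for n in self.nodes)


def insert(
    trie: FlowTrie,
    read_flows: Sequence[float],
    model: DistanceModel,
    misses: Optional[MissMatrix] = None,
) -> int:
    """Thread one flowgram into the trie; returns the terminal node id.

    At each step, among children whose edge value is not significantly
    different from the read's value, the closest wins (ties: smaller edge
    value, then older child); its edge mean and count are updated.  Children
    tried and found distinct are recorded as misses.
    """
    if not read_flows:
        raise ValueError("cannot insert an empty flowgram")
    node = trie.root
    for v in read_flows:
        best: Optional[TrieNode] = None
        best_key: Optional[tuple[float, float, int]] = None
        for child in node.children:
            if distinct(model, child.edge_value, v):
                if misses is not None:
                    misses.record(child.edge_value, v)
                continue
            key = (abs(child.edge_value - v), child.edge_value, child.id)
            if best_key is None or key < best_key:
                best, best_key = child, key
        if best is None:
            best = trie.new_node(node, float(v))
        else:
            c = best.edge_count
            best.edge_value = (best.edge_value * c + v) / (c + 1)
        best.edge_count += 1
        node = best
    node.terminal_count += 1
    return node.id


def leaf_abundance(trie: FlowTrie, node_id: int) -> int:
    """Reads terminating at this leaf or any of its ancestors."""
    node = trie.nodes[node_id]
    if node.children:
        raise ValueError(f"node {node_id} is not a leaf")
    total = 0
    cur: Optional[TrieNode] = node
    while cur is not None:
        total += cur.terminal_count
        cur = cur.parent
    return total


@dataclass
class TrieResult:
    trie: FlowTrie
    assignment: dict[str, int]
    misses: MissMatrix
    read_flow_lengths: dict[str, int]
    flow_chars: str = ""
    phase: int = 0
    bin_label: str = ""

    @property
    def node_flowgrams(self) -> dict[int, list[float]]:
        """Final root->terminal edge values for every assigned node."""
        return {nid: self.trie.path_values(nid) for nid in set(self.assignment.values())}


def denoise_reads_trie(
    reads: Sequence[tuple[str, Sequence[float]]],
    model: DistanceModel,
    record_misses: bool = True,
) -> TrieResult:
    trie = FlowTrie()
    misses = MissMatrix()
    recorder = misses if record_misses else None
    assignment = {rid: insert(trie, flows, model, recorder) for rid, flows in reads}
    return TrieResult(
        trie=trie,
        assignment=assignment,
        misses=misses,
        read_flow_lengths={rid: len(flows) for rid, flows in reads},
    )


def denoise_bin_trie(
    flowgram_file: str | Path,
    model: DistanceModel,
    record_misses: bool = True,
) -> TrieResult:
    """Denoise one filtered flowgram bin file with the trie."""
    meta, entries = read_flowgrams(flowgram_file)
    result = denoise_reads_trie(entries, model, record_misses)
    result.flow_chars = meta.get("flow_order", "")
    result.phase = int(meta.get("phase", 0))
    result.bin_label = meta.get("bin", Path(flowgram_file).stem)
    log.info(
        "bin %s: %d reads -> trie of %d nodes (%d misses)",
        result.bin_label, len(entries), len(result.trie) - 1, result.misses.total,
    )
    return result
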