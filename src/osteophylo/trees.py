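"""Phylogeny container, regime maps, and the Brownian-motion covariance.

The package works on rooted trees with branch lengths.  Newick parsing and
writing is delegated to :mod:`dendropy`; internally a tree is flattened to
parent/branch-length arrays in preorder, which makes the recursive trait
simulators and the likelihood code simple and fast.

A :class:`RegimeMap` paints a discrete state (a locomotor habit) onto every
point of every branch as an ordered list of (state, duration) segments per
branch, rootward to tipward, plus the state at the root itself.  Regime maps
are produced by the forward Mk simulator (ground truth) and by stochastic
character mapping (inference), and are consumed by the multi-rate BM and
multi-optimum OU likelihoods.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = ["Phylogeny", "RegimeMap", "phylo_vcv"]


class Phylogeny:
    """A rooted, binary tree with branch lengths, flattened to arrays.

    Nodes are indexed 0..n_nodes-1 in preorder (root = 0).  ``parent[i]``
    is the preorder index of node i's parent (-1 for the root) and
    ``blen[i]`` the length of the branch subtending node i (0 for the
    root).  Tips carry labels; internal nodes are auto-labelled when
    missing so regime maps can be serialized against stable names.
    """

    def __init__(self, parent: np.ndarray, blen: np.ndarray, labels: list[str]):
        self.parent = np.asarray(parent, dtype=int)
        self.blen = np.asarray(blen, dtype=float)
        if np.any(self.blen < 0):
            raise ValueError("negative branch length")
        self.labels = list(labels)
        self.n_nodes = len(self.parent)
        self.children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i in range(1, self.n_nodes):
            self.children[self.parent[i]].append(i)
        self.tip_indices = np.array(
            [i for i in range(self.n_nodes) if not self.children[i]], dtype=int
        )
        self.n_tips = len(self.tip_indices)
        self.tip_labels = [self.labels[i] for i in self.tip_indices]
        # depth of each node = distance from the root
        self.depths = np.zeros(self.n_nodes)
        for i in range(1, self.n_nodes):
            self.depths[i] = self.depths[self.parent[i]] + self.blen[i]

    # ------------------------------------------------------------------ io
    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "Phylogeny":
        nodes = list(tree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        parent = np.empty(len(nodes), dtype=int)
        blen = np.zeros(len(nodes))
        labels = []
        n_internal = 0
        for i, nd in enumerate(nodes):
            parent[i] = -1 if nd.parent_node is None else index[id(nd.parent_node)]
            if nd.parent_node is not None:
                blen[i] = nd.edge.length if nd.edge.length is not None else 0.0
            if nd.is_leaf():
                labels.append(nd.taxon.label if nd.taxon else f"t{i}")
            else:
                lab = nd.label if nd.label else f"nd{n_internal}"
                labels.append(lab)
                n_internal += 1
        return cls(parent, blen, labels)

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        return cls.from_dendropy(tree)

    @classmethod
    def read(cls, path) -> "Phylogeny":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def to_newick(self, internal_labels: bool = False) -> str:
        buf = io.StringIO()

        def write(i: int):
            if self.children[i]:
                buf.write("(")
                for j, c in enumerate(self.children[i]):
                    if j:
                        buf.write(",")
                    write(c)
                buf.write(")")
                if internal_labels:
                    buf.write(self.labels[i])
            else:
                buf.write(self.labels[i].replace(" ", "_"))
            if self.parent[i] >= 0:
                buf.write(f":{self.blen[i]:.10g}")

        write(0)
        buf.write(";")
        return buf.getvalue()

    def write(self, path, internal_labels: bool = False) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick(internal_labels=internal_labels) + "\n")

    # ----------------------------------------------------------- structure
    def preorder(self):
        return range(self.n_nodes)

    def postorder(self):
        return range(self.n_nodes - 1, -1, -1)

    @property
    def height(self) -> float:
        return float(self.depths[self.tip_indices].max())

    def is_ultrametric(self, rel_tol: float = 1e-8) -> bool:
        d = self.depths[self.tip_indices]
        return bool(np.ptp(d) <= rel_tol * max(d.max(), 1.0))

    def tips_below(self) -> list[np.ndarray]:
        """For every node, the tip *positions* (0..n_tips-1) in its clade."""
        pos = {int(t): k for k, t in enumerate(self.tip_indices)}
        below: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i in self.postorder():
            if not self.children[i]:
                below[i] = [pos[i]]
            else:
                for c in self.children[i]:
                    below[i].extend(below[c])
        return [np.array(b, dtype=int) for b in below]

    def vcv(self) -> tuple[np.ndarray, np.ndarray]:
        """BM covariance structure: C[i,j] = shared root-to-MRCA path length.

        Returns (C, T) with T the root-to-tip depths (the diagonal of C).
        Rows/columns follow ``tip_labels`` order.
        """
        below = self.tips_below()
        C = np.zeros((self.n_tips, self.n_tips))
        for i in range(1, self.n_nodes):
            b = below[i]
            C[np.ix_(b, b)] += self.blen[i]
        return C, np.diag(C).copy()

    def path_to_tip(self, tip_pos: int) -> list[int]:
        """Node indices from the root's child down to the tip (branch owners)."""
        i = int(self.tip_indices[tip_pos])
        path = []
        while i != 0:
            path.append(i)
            i = int(self.parent[i])
        return path[::-1]

    def rescale(self, height: float = 1.0) -> "Phylogeny":
        """Return a copy scaled so the deepest tip sits at ``height``."""
        h = self.height
        if h <= 0:
            raise ValueError("tree has zero height")
        return Phylogeny(self.parent, self.blen * (height / h), self.labels)


def phylo_vcv(tree: Phylogeny) -> tuple[np.ndarray, np.ndarray]:
    """Shared-path-length covariance C and tip depths T for ``tree``."""
    return tree.vcv()


@dataclass
class RegimeMap:
    """Piecewise-constant painting of discrete states onto a tree.

    ``segments[i]`` lists (state, duration) pairs for the branch subtending
    node i, ordered rootward to tipward; durations sum to ``tree.blen[i]``.
    The root (which subtends no branch) carries ``root_state``.
    """

    tree: Phylogeny
    segments: list[list[tuple[str, float]]]
    root_state: str

    def __post_init__(self):
        if len(self.segments) != self.tree.n_nodes:
            raise ValueError("one segment list per node required")
        self._cache: dict = {}

    @property
    def states(self) -> list[str]:
        seen = {self.root_state}
        for segs in self.segments:
            seen.update(s for s, _ in segs)
        return sorted(seen)

    def validate(self, atol: float = 1e-9) -> None:
        for i in range(1, self.tree.n_nodes):
            total = sum(d for _, d in self.segments[i])
            if abs(total - self.tree.blen[i]) > atol:
                raise ValueError(
                    f"segments on branch to node {i} sum to {total}, "
                    f"branch length is {self.tree.blen[i]}"
                )
            if any(d < 0 for _, d in self.segments[i]):
                raise ValueError(f"negative segment duration on branch to node {i}")

    def tip_states(self) -> dict[str, str]:
        out = {}
        for pos, i in enumerate(self.tree.tip_indices):
            segs = self.segments[i]
            out[self.tree.tip_labels[pos]] = (
                segs[-1][0] if segs else self._state_above(int(i))
            )
        return out

    def _state_above(self, i: int) -> str:
        while i != 0:
            if self.segments[i]:
                return self.segments[i][-1][0]
            i = int(self.tree.parent[i])
        return self.root_state

    def n_changes(self) -> int:
        count = 0
        for i in range(1, self.tree.n_nodes):
            prev = self._state_above(int(self.tree.parent[i])) if i else self.root_state
            for s, _ in self.segments[i]:
                if s != prev:
                    count += 1
                prev = s
        return count

    def relabel(self, mapping: dict[str, str]) -> "RegimeMap":
        """Collapse states via ``mapping`` (identity for unmapped states).

        Adjacent segments that end up in the same state are merged, e.g.
        folding fossorial and generalist lineages into a shared background
        regime for three-regime models.
        """
        out: list[list[tuple[str, float]]] = [[]]
        for i in range(1, self.tree.n_nodes):
            merged: list[tuple[str, float]] = []
            for s, d in self.segments[i]:
                s = mapping.get(s, s)
                if merged and merged[-1][0] == s:
                    merged[-1] = (s, merged[-1][1] + d)
                else:
                    merged.append((s, d))
            out.append(merged)
        return RegimeMap(self.tree, out, mapping.get(self.root_state, self.root_state))

    # regime-time decompositions used by the likelihoods -----------------
    def shared_times_by_state(self) -> dict[str, np.ndarray]:
        """Per state k, matrix of shared root-to-MRCA time spent in k."""
        if "shared" not in self._cache:
            below = self.tree.tips_below()
            out = {s: np.zeros((self.tree.n_tips, self.tree.n_tips))
                   for s in self.states}
            for i in range(1, self.tree.n_nodes):
                b = below[i]
                for s, d in self.segments[i]:
                    out[s][np.ix_(b, b)] += d
            self._cache["shared"] = out
        return self._cache["shared"]

    def tip_paths(self) -> list[list[tuple[float, float, str]]]:
        """Per tip, (t_start, t_end, state) segments from root to tip."""
        if "paths" not in self._cache:
            paths = []
            for pos in range(self.tree.n_tips):
                t = 0.0
                segs: list[tuple[float, float, str]] = []
                for node in self.tree.path_to_tip(pos):
                    for s, d in self.segments[node]:
                        segs.append((t, t + d, s))
                        t += d
                paths.append(segs)
            self._cache["paths"] = paths
        return self._cache["paths"]

    def tip_path_arrays(self, states: list[str]):
        """Flattened (tip, t0, t1, state-column) arrays for vectorized use."""
        key = ("arrays", tuple(states))
        if key not in self._cache:
            col = {s: j for j, s in enumerate(states)}
            tip, t0, t1, sc = [], [], [], []
            for i, segs in enumerate(self.tip_paths()):
                for a, b, s in segs:
                    tip.append(i); t0.append(a); t1.append(b); sc.append(col[s])
            self._cache[key] = (np.array(tip, dtype=int), np.array(t0),
                                np.array(t1), np.array(sc, dtype=int))
        return self._cache[key]

    # ------------------------------------------------------------------ io
    def to_text(self) -> str:
        lines = [f"#root_state\t{self.root_state}"]
        for i in range(1, self.tree.n_nodes):
            segs = ",".join(f"{s}:{d!r}" for s, d in self.segments[i])
            lines.append(f"{self.tree.labels[i]}\t{segs}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, tree: Phylogeny, text: str) -> "RegimeMap":
        label_to_node = {lab: i for i, lab in enumerate(tree.labels)}
        segments: list[list[tuple[str, float]]] = [[] for _ in range(tree.n_nodes)]
        root_state = None
        for line in text.splitlines():
            line = line.strip()
            if not line:
                continue
            key, _, rest = line.partition("\t")
            if key == "#root_state":
                root_state = rest
                continue
            segs = []
            for part in rest.split(","):
                s, _, d = part.rpartition(":")
                segs.append((s, float(d)))
            segments[label_to_node[key]] = segs
        if root_state is None:
            raise ValueError("regime map text lacks a #root_state line")
        rm = cls(tree, segments, root_state)
        rm.validate(atol=1e-6)
        return rm


def uniform_regime_map(tree: Phylogeny, state: str) -> RegimeMap:
    """Paint the whole tree with a single state (the one-regime painting)."""
    segs = [[] if i == 0 else [(state, float(tree.blen[i]))] for i in range(tree.n_nodes)]
    return RegimeMap(tree, segs, state)
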