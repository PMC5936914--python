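"""Phylogeny containers and covariance bookkeeping.

Trees enter and leave the package as :class:`dendropy.Tree` objects
(Newick/NEXUS I/O, pruning, cloning). All numerical routines consume a
:class:`PhyloData` snapshot, which caches the quantities every Gaussian
trait model needs:

* ``C`` — the shared path-length matrix (``C[i, j]`` = root-to-MRCA
  distance of tips *i* and *j*; diagonal = root-to-tip times),
* ``depths`` — root-to-tip times ``T_i`` (non-ultrametric trees allowed:
  extinct tips simply have smaller depths),
* a lineages-through-time step function, used by the
  diversity-dependent-rate model.

Edge lengths are in Myr throughout.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "PhyloData",
    "as_phylo_data",
    "read_trees",
    "read_tree",
    "prune_to",
    "tree_to_newick",
]


@dataclass(frozen=True)
class PhyloData:
    """Immutable numerical snapshot of a rooted, edge-length phylogeny."""

    labels: tuple[str, ...]
    C: np.ndarray
    depths: np.ndarray
    # lineage count step function: count is ltt_counts[k] on
    # [ltt_times[k], ltt_times[k+1]); ltt_cumint[k] = integral of the
    # count from the root to ltt_times[k]
    ltt_times: np.ndarray = field(repr=False, default=None)
    ltt_counts: np.ndarray = field(repr=False, default=None)
    ltt_cumint: np.ndarray = field(repr=False, default=None)

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def max_depth(self) -> float:
        return float(self.depths.max())

    @property
    def max_lineages(self) -> int:
        return int(self.ltt_counts.max())

    def ltt_integral(self, t):
        """Integral of the lineage count from the root to time(s) ``t``."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.ltt_times, t, side="right") - 1
        idx = np.clip(idx, 0, len(self.ltt_times) - 1)
        return self.ltt_cumint[idx] + self.ltt_counts[idx] * (t - self.ltt_times[idx])

    def lambda_cov(self, lam: float) -> np.ndarray:
        """Pagel-lambda transform of the covariance: off-diagonals
        scaled by lambda, diagonal kept."""
        V = lam * self.C
        np.fill_diagonal(V, self.depths)
        return V

    def lambda_corr(self, lam: float) -> np.ndarray:
        """Pagel-lambda transform of the phylogenetic correlation matrix
        (as in R's corPagel): R_ij = C_ij / sqrt(T_i T_j), off-diagonals
        scaled by lambda, unit diagonal. At lambda = 0 this is the
        identity, so GLS reduces exactly to OLS even on non-ultrametric
        trees."""
        s = np.sqrt(self.depths)
        R = lam * self.C / np.outer(s, s)
        np.fill_diagonal(R, 1.0)
        return R

    @classmethod
    def from_tree(cls, tree: dendropy.Tree) -> "PhyloData":
        root = tree.seed_node
        depth: dict = {root: root.edge.length or 0.0}
        for nd in tree.preorder_node_iter():
            if nd is root:
                continue
            el = nd.edge.length
            if el is None:
                el = 0.0
            if el < 0:
                raise ValueError(f"negative edge length {el} on edge to {nd}")
            depth[nd] = depth[nd.parent_node] + el

        leaves = [nd for nd in tree.leaf_node_iter()]
        labels = []
        for nd in leaves:
            if nd.taxon is not None and nd.taxon.label:
                labels.append(str(nd.taxon.label))
            elif getattr(nd, "label", None):
                labels.append(str(nd.label))
            else:
                raise ValueError("tree has an unlabelled tip")
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate tip labels")
        idx = {nd: i for i, nd in enumerate(leaves)}
        n = len(leaves)

        C = np.zeros((n, n))
        tipsets: dict = {}
        for nd in tree.postorder_node_iter():
            if nd.is_leaf():
                tipsets[nd] = [idx[nd]]
                continue
            groups = [tipsets.pop(ch) for ch in nd.child_nodes()]
            d = depth[nd]
            for a in range(len(groups)):
                for b in range(a + 1, len(groups)):
                    ia = np.asarray(groups[a])
                    ib = np.asarray(groups[b])
                    C[np.ix_(ia, ib)] = d
                    C[np.ix_(ib, ia)] = d
            merged = [i for g in groups for i in g]
            tipsets[nd] = merged
        depths = np.array([depth[nd] for nd in leaves])
        np.fill_diagonal(C, depths)

        # lineages-through-time: +children-1 at each internal node,
        # -1 at each tip; one lineage before the root event
        ev_t, ev_d = [], []
        for nd in tree.preorder_node_iter():
            if nd.is_leaf():
                ev_t.append(depth[nd])
                ev_d.append(-1)
            else:
                ev_t.append(depth[nd])
                ev_d.append(len(nd.child_nodes()) - 1)
        ev_t = np.asarray(ev_t)
        ev_d = np.asarray(ev_d)
        order = np.argsort(ev_t, kind="stable")
        ev_t, ev_d = ev_t[order], ev_d[order]
        times, inv = np.unique(ev_t, return_inverse=True)
        deltas = np.zeros(len(times))
        np.add.at(deltas, inv, ev_d)
        counts = 1 + np.cumsum(deltas)
        if times[0] > 0:
            times = np.concatenate([[0.0], times])
            counts = np.concatenate([[1.0], counts])
        counts = np.maximum(counts, 0.0)
        widths = np.diff(times)
        cumint = np.concatenate([[0.0], np.cumsum(counts[:-1] * widths)])
        return cls(
            labels=tuple(labels),
            C=C,
            depths=depths,
            ltt_times=times,
            ltt_counts=counts,
            ltt_cumint=cumint,
        )

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloData":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        return cls.from_tree(tree)


def as_phylo_data(tree) -> PhyloData:
    """Coerce a dendropy Tree, Newick string, or PhyloData to PhyloData."""
    if isinstance(tree, PhyloData):
        return tree
    if isinstance(tree, dendropy.Tree):
        return PhyloData.from_tree(tree)
    if isinstance(tree, str):
        return PhyloData.from_newick(tree)
    raise TypeError(f"cannot interpret {type(tree)} as a phylogeny")


def _schema_for(path: str, schema: str | None) -> str:
    if schema:
        return schema
    low = str(path).lower()
    if low.endswith((".nex", ".nexus", ".trees")):
        return "nexus"
    return "newick"


def read_trees(path, schema: str | None = None) -> dendropy.TreeList:
    """Read a (possibly multi-tree) Newick or NEXUS file."""
    return dendropy.TreeList.get(path=str(path), schema=_schema_for(path, schema))


def read_tree(path, schema: str | None = None) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema=_schema_for(path, schema))


def prune_to(tree: dendropy.Tree, labels) -> dendropy.Tree:
    """Return a copy of ``tree`` pruned to the given tip labels.

    Path lengths between retained tips are preserved (edges of removed
    unary nodes are concatenated by dendropy).
    """
    labels = set(map(str, labels))
    present = {lf.taxon.label for lf in tree.leaf_node_iter() if lf.taxon}
    keep = labels & present
    if len(keep) < 2:
        raise ValueError("fewer than two requested tips present in tree")
    sub = tree.extract_tree_with_taxa_labels(labels=keep)
    return sub


def tree_to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick").strip()
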