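"""Whole-slide graphs and the graph-convolutional survival encoder.

A slide is represented by its patch grid: nodes carry precomputed patch
embeddings, edges connect patches within a spatial radius (default 1.5 patch
units, i.e. 8-connectivity on the grid), and only the largest connected
component is kept. The encoder stacks neighbour-mean (SAGE) convolutions with
self-attention top-fraction pooling, reads out per-block mean embeddings
through a jumping-knowledge concatenation, and feeds survival / crossmodal
heads. Deep Graph Infomax supplies the contrastive pretraining objective.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse as sp
from scipy.sparse import csgraph
from scipy.spatial import cKDTree

from .nn import MLP, Linear, Module, Tensor, concat, spmm

__all__ = [
    "PatchSet", "WholeSlideGraph", "GCNSpec", "PoolAssignment",
    "build_wsg", "SageConv", "sage_conv", "sag_pool", "jk_readout",
    "GCNSurvivalNet", "DGIHead", "dgi_loss", "gcn_forward",
]


@dataclass
class PatchSet:
    """Patches of one slide: 0-based (row, col) grid coords + embeddings."""

    slide_id: str
    coords: np.ndarray  # n x 2, patch units
    embeddings: np.ndarray  # n x D

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64)
        self.embeddings = np.asarray(self.embeddings, dtype=np.float64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be n x 2")
        if self.embeddings.shape[0] != self.coords.shape[0]:
            raise ValueError("one embedding row per patch required")
        if len(np.unique(self.coords, axis=0)) != len(self.coords):
            raise ValueError("duplicate patch coordinates")


@dataclass
class WholeSlideGraph:
    """Largest-connected-component patch graph of one slide."""

    slide_id: str
    coords: np.ndarray          # n x 2
    features: np.ndarray        # n x D
    edges: np.ndarray           # m x 2, undirected, u < v, no self-loops
    orig_index: np.ndarray      # index of each node in the source PatchSet

    @property
    def n_nodes(self) -> int:
        return len(self.coords)

    def neighbor_mean_matrix(self) -> sp.csr_matrix:
        """Row-normalised adjacency (isolated nodes get an all-zero row)."""
        return _neighbor_mean(self.edges, self.n_nodes)


def _neighbor_mean(edges: np.ndarray, n: int) -> sp.csr_matrix:
    if len(edges) == 0:
        return sp.csr_matrix((n, n))
    rows = np.concatenate([edges[:, 0], edges[:, 1]])
    cols = np.concatenate([edges[:, 1], edges[:, 0]])
    A = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    deg = np.asarray(A.sum(axis=1)).ravel()
    inv = np.divide(1.0, deg, out=np.zeros_like(deg), where=deg > 0)
    return sp.diags(inv) @ A


def build_wsg(patches: PatchSet, radius: float = 1.5) -> WholeSlideGraph:
    """Radius-neighbour graph restricted to its largest connected component.

    Edge (u, v) iff 0 < ||coords_u - coords_v|| <= radius. Component-size ties
    break to the component containing the lowest node index.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    n = len(patches.coords)
    if n == 0:
        raise ValueError("empty patch set")
    tree = cKDTree(patches.coords)
    pairs = tree.query_pairs(r=radius, output_type="ndarray")  # u < v, strict > 0 distance
    if len(pairs):
        adj = sp.csr_matrix((np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    else:
        adj = sp.csr_matrix((n, n))
    n_comp, labels = csgraph.connected_components(adj, directed=False)
    sizes = np.bincount(labels, minlength=n_comp)
    # ties: the component whose lowest member index is smallest wins; since
    # labels are assigned in first-seen order, argmax on sizes already picks
    # the earliest label among equals
    keep_label = int(np.argmax(sizes))
    keep = np.flatnonzero(labels == keep_label)
    remap = -np.ones(n, dtype=np.intp)
    remap[keep] = np.arange(len(keep))
    kept_pairs = pairs[np.isin(pairs[:, 0], keep) & np.isin(pairs[:, 1], keep)] if len(pairs) else pairs
    edges = remap[kept_pairs] if len(kept_pairs) else np.empty((0, 2), dtype=np.intp)
    return WholeSlideGraph(
        slide_id=patches.slide_id,
        coords=patches.coords[keep],
        features=patches.embeddings[keep],
        edges=np.asarray(edges, dtype=np.intp),
        orig_index=keep,
    )


@dataclass
class GCNSpec:
    n_blocks: int = 3
    hidden_dim: int = 128
    pool_ratio: float = 0.5
    jk_mode: str = "cat"
    head_sizes: tuple[int, ...] = (64,)

    def __post_init__(self):
        if not (0 < self.pool_ratio <= 1):
            raise ValueError("pool_ratio must be in (0, 1]")
        if self.n_blocks < 1:
            raise ValueError("need at least one block")


@dataclass
class PoolAssignment:
    """Nodes retained by each pooling step, with their attention scores."""

    retained: list[np.ndarray] = field(default_factory=list)   # original-node indices
    scores: list[np.ndarray] = field(default_factory=list)


class SageConv(Module):
    """h'_v = act(W_self h_v + W_nbr mean_{u in N(v)} h_u + b).

    Isolated nodes receive a zero neighbour term.
    """

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 activation: str = "relu"):
        self.lin_self = Linear(n_in, n_out, rng)
        self.lin_nbr = Linear(n_in, n_out, rng, bias=False)
        self.activation = activation

    def __call__(self, h: Tensor, nbr_mean: sp.csr_matrix) -> Tensor:
        from .nn import ACTIVATIONS
        out = self.lin_self(h) + self.lin_nbr(spmm(nbr_mean, h))
        return ACTIVATIONS[self.activation](out)


def sage_conv(node_feats: np.ndarray, edges: np.ndarray, conv: SageConv) -> np.ndarray:
    """Functional neighbour-mean convolution over an edge list."""
    h = Tensor(np.asarray(node_feats, dtype=np.float64))
    return conv(h, _neighbor_mean(np.asarray(edges, dtype=np.intp), len(node_feats))).data


def sag_pool(node_feats: Tensor, edges: np.ndarray, scores: Tensor, r: float
             ) -> tuple[Tensor, np.ndarray, np.ndarray, np.ndarray]:
    """Self-attention top-fraction pooling.

    Keeps the ceil(r*n) highest-scoring nodes (score ties break to the lower
    node index), scales their features by tanh(score), and induces the edge
    set on the retained nodes. Returns (features', edges', kept_indices,
    kept_scores).
    """
    n = node_feats.shape[0]
    if n == 0:
        raise ValueError("cannot pool an empty graph")
    if not (0 < r <= 1):
        raise ValueError("pool ratio must be in (0, 1]")
    k = math.ceil(r * n)
    s = scores.data.ravel()
    order = np.lexsort((np.arange(n), -s))  # score desc, then index asc
    kept = np.sort(order[:k])
    feats = node_feats.take(kept) * scores.take(kept).reshape(len(kept), 1).tanh()
    remap = -np.ones(n, dtype=np.intp)
    remap[kept] = np.arange(len(kept))
    if len(edges):
        m = np.isin(edges[:, 0], kept) & np.isin(edges[:, 1], kept)
        new_edges = remap[edges[m]]
    else:
        new_edges = np.empty((0, 2), dtype=np.intp)
    return feats, np.asarray(new_edges, dtype=np.intp), kept, s[kept]


def jk_readout(per_block_feats: list[Tensor]) -> Tensor:
    """Jumping-knowledge readout: per-block global mean pooling, concatenated."""
    if not per_block_feats:
        raise ValueError("need at least one block output")
    means = []
    for feats in per_block_feats:
        if feats.shape[0] == 0:
            raise ValueError("block with zero surviving nodes")
        means.append(feats.mean(axis=0))
    return concat(means)


class GCNSurvivalNet(Module):
    """Blocks of (SAGE conv -> attention pool) with JK readout and two heads:
    a scalar log-hazard and a complementary-modality prediction."""

    def __init__(self, in_dim: int, spec: GCNSpec, complement_dim: int,
                 rng: np.random.Generator):
        self.spec = spec
        dims = [in_dim] + [spec.hidden_dim] * spec.n_blocks
        self.convs = [SageConv(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]
        # score convolutions: single-output graph convolution per block
        self.score_convs = [SageConv(spec.hidden_dim, 1, rng, activation="identity")
                            for _ in range(spec.n_blocks)]
        jk_dim = spec.hidden_dim * spec.n_blocks
        self.hazard_head = MLP([jk_dim, *spec.head_sizes, 1], rng)
        self.complement_head = MLP([jk_dim, *spec.head_sizes, complement_dim], rng)

    def node_embeddings(self, wsg: WholeSlideGraph) -> Tensor:
        """Convolution stack without pooling (used for contrastive pretraining)."""
        return self._embed(Tensor(wsg.features), wsg.neighbor_mean_matrix())

    def _embed(self, h: Tensor, nbr: sp.csr_matrix) -> Tensor:
        for conv in self.convs:
            h = conv(h, nbr)
        return h

    def encode(self, wsg: WholeSlideGraph) -> tuple[Tensor, PoolAssignment]:
        h = Tensor(wsg.features)
        edges = wsg.edges
        node_ids = np.arange(wsg.n_nodes)
        pools = PoolAssignment()
        block_outputs: list[Tensor] = []
        for conv, score_conv in zip(self.convs, self.score_convs):
            nbr = _neighbor_mean(edges, h.shape[0])
            h = conv(h, nbr)
            scores = score_conv(h, nbr)
            h, edges, kept, kept_scores = sag_pool(h, edges, scores, self.spec.pool_ratio)
            node_ids = node_ids[kept]
            pools.retained.append(node_ids.copy())
            pools.scores.append(kept_scores.copy())
            block_outputs.append(h)
        return jk_readout(block_outputs), pools

    def __call__(self, wsg: WholeSlideGraph) -> tuple[Tensor, Tensor, Tensor, PoolAssignment]:
        g, pools = self.encode(wsg)
        return self.hazard_head(g), self.complement_head(g), g, pools


def gcn_forward(wsg: WholeSlideGraph, net: GCNSurvivalNet
                ) -> tuple[float, np.ndarray, np.ndarray, PoolAssignment]:
    """(log-hazard, complement prediction, graph embedding, pool trace)."""
    hazard, comp, g, pools = net(wsg)
    return float(hazard.data.ravel()[0]), comp.data, g.data, pools


class DGIHead(Module):
    """Deep Graph Infomax discriminator over a GCN's node-embedding stack."""

    def __init__(self, net: GCNSurvivalNet, rng: np.random.Generator):
        self.net = net
        d = net.spec.hidden_dim
        self.B = Tensor(rng.standard_normal((d, d)) / np.sqrt(d), requires_grad=True)


def dgi_loss(wsg: WholeSlideGraph, head: DGIHead, corruption_seed: int) -> Tensor:
    """Contrastive loss discriminating true node embeddings from corruptions.

    Corruption shuffles node-feature rows on the unchanged topology; the
    summary is s = sigmoid(mean real node embedding); the discriminator is
    D(h, s) = sigmoid(h^T B s); the loss is mean binary cross-entropy with
    real nodes labelled 1 and corrupted nodes 0 (chance level ln 2).
    """
    if wsg.n_nodes < 2:
        raise ValueError("DGI corruption is the identity on a single-node graph")
    nbr = wsg.neighbor_mean_matrix()
    h_real = head.net._embed(Tensor(wsg.features), nbr)
    perm = np.random.default_rng(corruption_seed).permutation(wsg.n_nodes)
    h_fake = head.net._embed(Tensor(wsg.features[perm]), nbr)
    s = h_real.mean(axis=0).sigmoid()
    logits_real = h_real @ (head.B @ s)
    logits_fake = h_fake @ (head.B @ s)
    eps = 1e-12
    p_real = logits_real.sigmoid()
    p_fake = logits_fake.sigmoid()
    bce = -(concat([(p_real + eps).log(), (1.0 - p_fake + eps).log()]).mean())
    return bce
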