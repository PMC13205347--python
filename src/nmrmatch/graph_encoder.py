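"""Hybrid molecular graph encoder.

The encoder combines four stages:

1. multi-head neighborhood-restricted scaled dot-product attention — each
   node attends only over its bonded neighborhood (plus an optional self
   loop); the 8 head outputs are concatenated into a shared representation;
2. three message-passing branches with growing receptive fields: one GCN
   layer (short range), two stacked GCN layers (mid range) and three
   GraphSAGE layers with mean aggregation (long range);
3. a linear fusion layer over the concatenated branches;
4. dual global pooling (per-dimension max and mean over nodes) followed by
   a two-layer projection (widen to 1500, ReLU + dropout, compress to 128).

Graphs are processed as disjoint unions (a :class:`GraphBatch`), so one
forward pass covers a whole minibatch of molecules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat, gather_rows, segment_max, segment_sum
from .molgraph import MolecularGraph
from .nn import BatchNorm1d, Dropout, Linear, Module


class IsolatedNodeError(RuntimeError):
    pass


@dataclass
class GraphEncoderConfig:
    input_dim: int = 24
    heads: int = 8
    head_dim: int = 8            # H(0) width = heads * head_dim
    branch_width: int = 64
    fused_width: int = 384   # budget-fitted (see harness.search_budget)
    proj_hidden: int = 1500
    embed_dim: int = 128
    dropout: float = 0.1
    self_loops: bool = True
    use_attention: bool = True   # multi-head graph attention stage
    use_multiscale: bool = True  # three branches vs. a single GCN stage

    def __post_init__(self):
        if self.input_dim % self.heads:
            raise ValueError(
                f"input_dim {self.input_dim} not divisible by heads {self.heads}")


class GraphBatch:
    """Disjoint union of molecular graphs with precomputed message constants."""

    def __init__(self, graphs: list[MolecularGraph], self_loops: bool = True):
        if not graphs or any(g.num_nodes == 0 for g in graphs):
            raise ValueError("GraphBatch requires nonempty graphs")
        xs, srcs, dsts, gids = [], [], [], []
        offset = 0
        for gi, g in enumerate(graphs):
            n = g.num_nodes
            xs.append(g.node_features)
            ei = g.edge_index()
            srcs.append(ei[0] + offset)
            dsts.append(ei[1] + offset)
            if self_loops:
                loop = np.arange(offset, offset + n, dtype=np.int64)
                srcs.append(loop)
                dsts.append(loop)
            gids.append(np.full(n, gi, dtype=np.int64))
            offset += n
        self.x = np.concatenate(xs).astype(np.float32)
        self.edge_src = np.concatenate(srcs)
        self.edge_dst = np.concatenate(dsts)
        self.graph_ids = np.concatenate(gids)
        self.num_nodes = offset
        self.num_graphs = len(graphs)
        deg = np.bincount(self.edge_dst, minlength=self.num_nodes).astype(np.float32)
        if np.any(deg == 0):
            raise IsolatedNodeError(
                "node with empty neighborhood; enable the self-loop policy "
                "(self_loops=True) to message-pass over isolated nodes")
        # symmetric GCN normalization 1/sqrt(d_i d_j) over the (looped) edges
        self.gcn_norm = (1.0 / np.sqrt(deg[self.edge_src] * deg[self.edge_dst])
                         ).astype(np.float32)[:, None]
        self.inv_deg = (1.0 / deg).astype(np.float32)[:, None]


def _edge_softmax(scores: Tensor, edge_dst: np.ndarray, num_nodes: int) -> Tensor:
    """Softmax of per-edge scores over each destination's incoming edges."""
    # subtract the per-destination max for stability (constant wrt gradient)
    smax = np.full((num_nodes,) + scores.shape[1:], -np.inf, dtype=scores.dtype)
    np.maximum.at(smax, edge_dst, scores.data)
    e = (scores - Tensor(smax[edge_dst])).exp()
    denom = segment_sum(e, edge_dst, num_nodes)
    return e / gather_rows(denom, edge_dst)


class MultiheadGraphAttention(Module):
    """Scaled dot-product attention restricted to graph neighborhoods."""

    def __init__(self, cfg: GraphEncoderConfig, rng: np.random.Generator):
        super().__init__()
        width = cfg.heads * cfg.head_dim
        self.q_proj = Linear(cfg.input_dim, width, rng, bias=False)
        self.k_proj = Linear(cfg.input_dim, width, rng, bias=False)
        self.v_proj = Linear(cfg.input_dim, width, rng, bias=False)
        self.heads, self.head_dim = cfg.heads, cfg.head_dim

    def forward(self, x: Tensor, batch: GraphBatch,
                return_weights: bool = False):
        h, dk = self.heads, self.head_dim
        q = self.q_proj(x).reshape(-1, h, dk)
        k = self.k_proj(x).reshape(-1, h, dk)
        v = self.v_proj(x).reshape(-1, h, dk)
        # per-edge raw scores: <Q_dst, K_src> / sqrt(dk), one per head
        scores = (gather_rows(q, batch.edge_dst) *
                  gather_rows(k, batch.edge_src)).sum(axis=2) * (1.0 / np.sqrt(dk))
        attn = _edge_softmax(scores, batch.edge_dst, batch.num_nodes)
        msg = gather_rows(v, batch.edge_src) * attn.reshape(-1, h, 1)
        out = segment_sum(msg, batch.edge_dst, batch.num_nodes)
        out = out.reshape(-1, h * dk)
        return (out, attn) if return_weights else out


class GCNLayer(Module):
    """Kipf-style graph convolution with symmetric degree normalization."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        super().__init__()
        self.lin = Linear(in_dim, out_dim, rng)

    def forward(self, x: Tensor, batch: GraphBatch) -> Tensor:
        msg = gather_rows(x, batch.edge_src) * Tensor(batch.gcn_norm)
        agg = segment_sum(msg, batch.edge_dst, batch.num_nodes)
        return self.lin(agg)


class SAGELayer(Module):
    """GraphSAGE with mean aggregation and self/neighbor concatenation."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        super().__init__()
        self.lin = Linear(2 * in_dim, out_dim, rng)

    def forward(self, x: Tensor, batch: GraphBatch) -> Tensor:
        msg = gather_rows(x, batch.edge_src)
        mean = segment_sum(msg, batch.edge_dst, batch.num_nodes) * \
            Tensor(batch.inv_deg)
        return self.lin(concat([x, mean], axis=1)).relu()


class GraphEncoder(Module):
    """Molecule -> 128-d embedding; see module docstring for the stages."""

    def __init__(self, cfg: GraphEncoderConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        d = cfg.input_dim
        if cfg.use_attention:
            self.attention = MultiheadGraphAttention(cfg, rng)
            width0 = cfg.heads * cfg.head_dim
        else:
            self.attention = None
            width0 = d
        w = cfg.branch_width
        if cfg.use_multiscale:
            self.gcn_short = GCNLayer(width0, w, rng)
            self.gcn_mid1 = GCNLayer(width0, w, rng)
            self.gcn_mid2 = GCNLayer(w, w, rng)
            self.sage1 = SAGELayer(width0, w, rng)
            self.sage2 = SAGELayer(w, w, rng)
            self.sage3 = SAGELayer(w, w, rng)
            self.fuse = Linear(3 * w, cfg.fused_width, rng)
        else:
            # simplified backbone: a single GCN stage into the fused width
            self.gcn_single = GCNLayer(width0, cfg.fused_width, rng)
        self.proj1 = Linear(2 * cfg.fused_width, cfg.proj_hidden, rng)
        self.drop = Dropout(cfg.dropout, rng)
        self.proj2 = Linear(cfg.proj_hidden, cfg.embed_dim, rng)
        # output calibration: keeps the embedding well-scaled for fusion
        self.out_norm = BatchNorm1d(cfg.embed_dim)

    # staged forwards, exposed so each stage can be checked independently
    def node_embeddings(self, batch: GraphBatch) -> Tensor:
        x = Tensor(batch.x)
        return self.attention(x, batch) if self.attention is not None else x

    def branch_embeddings(self, h0: Tensor, batch: GraphBatch
                          ) -> tuple[Tensor, Tensor, Tensor]:
        h_short = self.gcn_short(h0, batch).relu()
        h_mid = self.gcn_mid2(self.gcn_mid1(h0, batch).relu(), batch).relu()
        h_long = self.sage3(self.sage2(self.sage1(h0, batch), batch), batch)
        return h_short, h_mid, h_long

    def fuse_scales(self, h_short: Tensor, h_mid: Tensor, h_long: Tensor) -> Tensor:
        return self.fuse(concat([h_short, h_mid, h_long], axis=1))

    def pool_and_project(self, h_out: Tensor, batch: GraphBatch) -> Tensor:
        gmax = segment_max(h_out, batch.graph_ids, batch.num_graphs)
        gmean = segment_sum(h_out, batch.graph_ids, batch.num_graphs) * \
            Tensor(1.0 / np.bincount(batch.graph_ids).astype(np.float32)[:, None])
        f_mol = concat([gmax, gmean], axis=1)
        return self.out_norm(self.proj2(self.drop(self.proj1(f_mol).relu())))

    def forward(self, batch: GraphBatch) -> Tensor:
        h0 = self.node_embeddings(batch)
        if self.cfg.use_multiscale:
            h_out = self.fuse_scales(*self.branch_embeddings(h0, batch))
        else:
            h_out = self.gcn_single(h0, batch).relu()
        return self.pool_and_project(h_out, batch)

    def encode(self, graphs: list[MolecularGraph]) -> Tensor:
        return self(GraphBatch(graphs, self_loops=self.cfg.self_loops))
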