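"""Graph encoder: attention, multi-scale branches, fusion, pooling."""

import numpy as np
import pytest

from conftest import random_graph
from nmrmatch.autodiff import Tensor
from nmrmatch.graph_encoder import (GCNLayer, GraphBatch, GraphEncoder,
                                    GraphEncoderConfig, IsolatedNodeError,
                                    MultiheadGraphAttention, SAGELayer)
from nmrmatch.molgraph import MolecularGraph
from oracles import (dense_adjacency, dense_gcn, dense_multihead_attention,
                     dense_sage)


def make_graph(n, edges, X):
    return MolecularGraph(node_features=np.asarray(X, dtype=np.float32),
                          edges=edges, atom_elements=["C"] * n, smiles="")


def batch_of(graph, self_loops=True):
    return GraphBatch([graph], self_loops=self_loops)


# ----------------------------------------------------------------- attention

def test_singleton_neighborhood_gets_weight_one(rng):
    """A node whose only neighbor is itself copies that neighbor's value."""
    cfg = GraphEncoderConfig(input_dim=8, heads=1, head_dim=8)
    att = MultiheadGraphAttention(cfg, rng)
    g = make_graph(2, [(0, 1), (1, 0)], rng.normal(size=(2, 8)))
    batch = GraphBatch([g], self_loops=False)
    out, attn = att(Tensor(batch.x), batch, return_weights=True)
    np.testing.assert_allclose(attn.data, 1.0, atol=1e-6)
    v = batch.x @ att.v_proj.weight.data
    np.testing.assert_allclose(out.data[0], v[1], atol=1e-5)


def test_identical_keys_give_uniform_attention(rng):
    """Equal scores softmax to 1/|N(i)| over the neighborhood."""
    cfg = GraphEncoderConfig(input_dim=8, heads=2, head_dim=4)
    att = MultiheadGraphAttention(cfg, rng)
    X = np.tile(rng.normal(size=(1, 8)), (4, 1))   # all nodes identical
    g = make_graph(4, [(0, 1), (1, 0), (0, 2), (2, 0), (0, 3), (3, 0)], X)
    batch = batch_of(g)
    _, attn = att(Tensor(batch.x), batch, return_weights=True)
    deg = np.bincount(batch.edge_dst)
    expected = np.repeat((1.0 / deg[batch.edge_dst])[:, None], 2, axis=1)
    np.testing.assert_allclose(attn.data, expected, atol=1e-6)


def test_path_graph_attention_matches_dense_oracle(rng):
    """3-node path, 1 head: edge-list path equals dense masked softmax."""
    cfg = GraphEncoderConfig(input_dim=2, heads=1, head_dim=2)
    att = MultiheadGraphAttention(cfg, rng)
    g = make_graph(3, [(0, 1), (1, 0), (1, 2), (2, 1)],
                   [[1.0, 2.0], [0.5, -1.0], [2.0, 0.3]])
    batch = batch_of(g)
    out = att(Tensor(batch.x), batch)
    A = dense_adjacency(3, g.edges, self_loops=True)
    expected = dense_multihead_attention(
        batch.x.astype(np.float64), att.q_proj.weight.data,
        att.k_proj.weight.data, att.v_proj.weight.data, 1, 2, A)
    np.testing.assert_allclose(out.data, expected, atol=1e-5)


def test_attention_equals_dense_oracle_on_small_graphs(rng):
    """All graphs up to 6 nodes, 100 random draws, 8 heads."""
    for trial in range(100):
        n = int(rng.integers(2, 7))
        g = random_graph(rng, n, d=24)
        cfg = GraphEncoderConfig(input_dim=24, heads=8, head_dim=3)
        att = MultiheadGraphAttention(cfg, rng)
        batch = batch_of(g)
        out = att(Tensor(batch.x), batch)
        A = dense_adjacency(n, g.edges)
        expected = dense_multihead_attention(
            batch.x.astype(np.float64), att.q_proj.weight.data,
            att.k_proj.weight.data, att.v_proj.weight.data, 8, 3, A)
        np.testing.assert_allclose(out.data, expected, atol=1e-4)


def test_attention_rows_sum_to_one_and_respect_edges(rng):
    """Softmax weights: normalized per neighborhood, zero off-neighborhood."""
    for _ in range(20):
        n = int(rng.integers(2, 10))
        g = random_graph(rng, n)
        cfg = GraphEncoderConfig()
        att = MultiheadGraphAttention(cfg, rng)
        batch = batch_of(g)
        _, attn = att(Tensor(batch.x), batch, return_weights=True)
        sums = np.zeros((n, cfg.heads))
        np.add.at(sums, batch.edge_dst, attn.data)
        np.testing.assert_allclose(sums, 1.0, atol=1e-6)
        # weights exist only on (looped) edges by construction: the edge
        # list is the only support the implementation ever touches
        assert attn.data.shape[0] == len(batch.edge_src)


def test_isolated_node_without_self_loops_raises():
    g = make_graph(2, [], np.zeros((2, 24)))
    with pytest.raises(IsolatedNodeError, match="self-loop"):
        GraphBatch([g], self_loops=False)


# ------------------------------------------------------------------ branches

def test_single_node_gcn_reduces_to_linear_map(rng):
    """With self-loops only, GCN is a per-node affine map of own features."""
    layer = GCNLayer(6, 4, rng)
    g = make_graph(1, [], rng.normal(size=(1, 6)))
    batch = batch_of(g)
    out = layer(Tensor(batch.x), batch)
    expected = batch.x @ layer.lin.weight.data + layer.lin.bias.data
    np.testing.assert_allclose(out.data, expected, atol=1e-6)


def test_gcn_and_sage_match_dense_oracles_on_cycle(rng):
    """5-node cycle: edge-list propagation equals dense normalized matmul."""
    edges = []
    for i in range(5):
        edges += [(i, (i + 1) % 5), ((i + 1) % 5, i)]
    g = make_graph(5, edges, rng.normal(size=(5, 8)))
    batch = batch_of(g)
    A = dense_adjacency(5, edges)
    gcn = GCNLayer(8, 6, rng)
    out = gcn(Tensor(batch.x), batch)
    np.testing.assert_allclose(
        out.data, dense_gcn(batch.x.astype(np.float64), gcn.lin.weight.data,
                            gcn.lin.bias.data, A), atol=1e-5)
    sage = SAGELayer(8, 6, rng)
    out = sage(Tensor(batch.x), batch)
    np.testing.assert_allclose(
        out.data, dense_sage(batch.x.astype(np.float64), sage.lin.weight.data,
                             sage.lin.bias.data, A), atol=1e-5)


def test_gcn_matches_dense_oracle_on_small_graphs(rng):
    for _ in range(100):
        n = int(rng.integers(1, 7))
        g = random_graph(rng, n, d=8)
        batch = batch_of(g)
        layer = GCNLayer(8, 5, rng)
        out = layer(Tensor(batch.x), batch)
        A = dense_adjacency(n, g.edges)
        np.testing.assert_allclose(
            out.data, dense_gcn(batch.x.astype(np.float64),
                                layer.lin.weight.data, layer.lin.bias.data, A),
            atol=1e-4)


def _hop_distances(n, edges, src):
    import collections

    dist = {src: 0}
    q = collections.deque([src])
    adj = collections.defaultdict(list)
    for i, j in edges:
        adj[i].append(j)
    while q:
        u = q.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                q.append(v)
    return dist


@pytest.mark.parametrize("branch,max_hops", [
    ("short", 2), ("mid", 3), ("long", 4),
])
def test_receptive_field_locality_on_random_trees(rng, branch, max_hops):
    """Perturbing a node beyond the hop bound leaves the branch unchanged.

    The attention stage contributes one hop; GCN layers one each; SAGE
    layers one each — so short/mid/long see at most 2/3/4 hops.
    """
    cfg = GraphEncoderConfig()
    enc = GraphEncoder(cfg, rng).eval()
    for _ in range(5):
        n = 10
        g = random_graph(rng, n, extra_edges=0)   # tree
        dist = _hop_distances(n, g.edges, src=0)
        far = [v for v, d in dist.items() if d > max_hops]
        if not far:
            continue
        v = far[0]

        def branch_rows(graph):
            batch = batch_of(graph)
            h0 = enc.node_embeddings(batch)
            hs, hm, hl = enc.branch_embeddings(h0, batch)
            return {"short": hs, "mid": hm, "long": hl}[branch].data[0]

        base = branch_rows(g)
        g2 = make_graph(n, g.edges, g.node_features.copy())
        g2.node_features[v] += 10.0
        np.testing.assert_allclose(branch_rows(g2), base, atol=1e-4)


# -------------------------------------------------------- fusion and pooling

def test_fuse_scales_selector_zero_and_random_weights(rng):
    cfg = GraphEncoderConfig(branch_width=4, fused_width=4)
    enc = GraphEncoder(cfg, rng)
    hs, hm, hl = (Tensor(rng.normal(size=(3, 4)).astype(np.float32))
                  for _ in range(3))
    # selector of the short branch
    W = np.zeros((12, 4), dtype=np.float32)
    W[:4] = np.eye(4)
    enc.fuse.weight.data = W
    enc.fuse.bias.data[:] = 0.0
    np.testing.assert_allclose(enc.fuse_scales(hs, hm, hl).data, hs.data,
                               atol=1e-6)
    # zero map
    enc.fuse.weight.data = np.zeros_like(enc.fuse.weight.data)
    np.testing.assert_allclose(enc.fuse_scales(hs, hm, hl).data, 0.0)
    # random weights vs hand matmul
    Wr = rng.normal(size=(12, 4)).astype(np.float32)
    br = rng.normal(size=4).astype(np.float32)
    enc.fuse.weight.data, enc.fuse.bias.data = Wr, br
    expected = np.concatenate([hs.data, hm.data, hl.data], axis=1) @ Wr + br
    np.testing.assert_allclose(enc.fuse_scales(hs, hm, hl).data, expected,
                               atol=1e-5)


def test_pooling_constant_features_and_single_node(rng):
    cfg = GraphEncoderConfig()
    enc = GraphEncoder(cfg, rng).eval()
    # constant node rows: max equals mean equals the constant
    c = rng.normal(size=cfg.fused_width).astype(np.float32)
    h = Tensor(np.tile(c, (4, 1)))
    g = random_graph(rng, 4)
    batch = batch_of(g)
    gmax_gmean = np.concatenate([c, c])
    from nmrmatch.autodiff import concat, segment_max, segment_sum

    pooled = concat([segment_max(h, batch.graph_ids, 1),
                     segment_sum(h, batch.graph_ids, 1) * 0.25], axis=1)
    np.testing.assert_allclose(pooled.data[0], gmax_gmean, atol=1e-6)
    # single node: f_mol = [h; h]
    g1 = random_graph(rng, 1, extra_edges=0)
    b1 = batch_of(g1)
    h1 = Tensor(rng.normal(size=(1, cfg.fused_width)).astype(np.float32))
    pooled1 = concat([segment_max(h1, b1.graph_ids, 1),
                      segment_sum(h1, b1.graph_ids, 1)], axis=1)
    np.testing.assert_allclose(pooled1.data[0],
                               np.concatenate([h1.data[0], h1.data[0]]))


def test_projection_widths_are_1500_then_128(rng):
    enc = GraphEncoder(GraphEncoderConfig(), rng)
    assert enc.proj1.out_features == 1500
    assert enc.proj2.out_features == 128
    out = enc.eval()(batch_of(random_graph(rng, 5)))
    assert out.shape == (1, 128)


def test_permutation_invariance_of_molecule_embedding(rng):
    """Relabeling nodes leaves f_final unchanged (within float tolerance)."""
    cfg = GraphEncoderConfig()
    enc = GraphEncoder(cfg, rng).eval()
    for _ in range(5):
        n = int(rng.integers(3, 9))
        g = random_graph(rng, n)
        perm = rng.permutation(n)
        inv = {int(old): int(new) for new, old in enumerate(perm)}
        g_perm = make_graph(n, [(inv[i], inv[j]) for i, j in g.edges],
                            g.node_features[perm])
        out = enc(batch_of(g)).data
        out_perm = enc(batch_of(g_perm)).data
        np.testing.assert_allclose(out, out_perm, atol=1e-3)
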