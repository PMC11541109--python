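"""Cross-channel compression engine for spatially correlated LFP groups.

Local field potentials recorded on nearby electrodes are strongly correlated,
so temporal decorrelation alone leaves redundancy on the table.  This engine
first applies first-order DPCM per channel (``e(i) = s(i) - s(i-1)``), then
predicts each child channel's residuals from a parent channel's residuals:

    e~_c(n) = e_c(n) - gamma * e_r(n)

where the spatial decorrelation factor ``gamma`` is the least-squares
minimizer of the residual energy ``sum(e~_c^2)`` over a training segment:

    gamma = sum(e_c * e_r) / sum(e_r * e_r).

The parent/child chain is a minimum spanning tree over the channel group,
learned in a training pass with per-sample residual energy after the optimal
gamma as edge weight, so the chain can never close a loop.  ``gamma`` is
quantized to Q1.14 fixed point and applied with integer rounding, making
encoder and decoder arithmetic bit-identical — compression is lossless.
The decorrelated residuals are zigzag-mapped and Rice-coded with the same
zero-fraction adaptation as the intra-channel engine.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import breadth_first_order, minimum_spanning_tree

from ._bitio import BitReader, BitstreamError, BitWriter
from .intra_channel_codec import _RiceAdapter, _rice_read, _rice_write, map_from_nonneg, map_to_nonneg
from .recording import Recording

__all__ = [
    "ChannelTree",
    "CceBitstream",
    "temporal_decorrelate",
    "temporal_reconstruct",
    "estimate_gamma",
    "energy",
    "train_channel_tree",
    "cce_compress",
    "cce_decompress",
]

GAMMA_FRAC_BITS = 14  # Q1.14: 1 sign, 1 integer, 14 fraction bits
_GAMMA_SCALE = 1 << GAMMA_FRAC_BITS
MAX_GROUP = 8


def temporal_decorrelate(x: np.ndarray) -> np.ndarray:
    """First-order DPCM: e(0) = x(0), e(i) = x(i) - x(i-1)."""
    x = np.asarray(x, dtype=np.int64)
    if x.size == 0:
        return x.copy()
    e = np.empty_like(x)
    e[0] = x[0]
    np.subtract(x[1:], x[:-1], out=e[1:])
    return e


def temporal_reconstruct(e: np.ndarray) -> np.ndarray:
    """Exact inverse of :func:`temporal_decorrelate` (cumulative sum)."""
    return np.cumsum(np.asarray(e, dtype=np.int64))


def estimate_gamma(e_c: np.ndarray, e_r: np.ndarray, n0: int = 0, N: int | None = None) -> float:
    """Closed-form least-squares spatial decorrelation factor.

    ``gamma = sum(e_c * e_r) / sum(e_r^2)`` over the segment
    ``[n0, n0 + N)``; a zero-energy reference (degenerate parent) yields
    gamma = 0 with a warning.
    """
    e_c = np.asarray(e_c, dtype=np.float64)
    e_r = np.asarray(e_r, dtype=np.float64)
    stop = e_r.size if N is None else min(e_r.size, n0 + N)
    seg_c, seg_r = e_c[n0:stop], e_r[n0:stop]
    denom = float(np.dot(seg_r, seg_r))
    if denom == 0.0:
        warnings.warn("zero-energy reference channel; gamma set to 0", stacklevel=2)
        return 0.0
    return float(np.dot(seg_c, seg_r)) / denom


def energy(e_tilde: np.ndarray) -> float:
    """Residual energy: sum of squared samples."""
    e = np.asarray(e_tilde, dtype=np.float64)
    return float(np.dot(e, e))


def _quantize_gamma(gamma: float) -> int:
    """Round gamma to Q1.14 and clip to the signed 16-bit fixed-point range."""
    q = int(round(gamma * _GAMMA_SCALE))
    return max(-(1 << 15), min((1 << 15) - 1, q))


def _apply_gamma_q(gamma_q: int, e_r: np.ndarray) -> np.ndarray:
    """round-half-away-from-zero of gamma_q * e_r / 2^14, pure integers."""
    p = gamma_q * np.asarray(e_r, dtype=np.int64)
    return np.sign(p) * ((np.abs(p) + (_GAMMA_SCALE >> 1)) >> GAMMA_FRAC_BITS)


@dataclass
class ChannelTree:
    """Trained state of the cross-channel codec.

    ``parent`` maps each non-root channel id to its parent channel id;
    ``gamma_q`` holds the Q1.14-quantized spatial factor per child.
    """

    root: int
    parent: dict[int, int]
    gamma_q: dict[int, int]
    n0: int = 0
    N: int = 0

    def __post_init__(self) -> None:
        nodes = set(self.parent) | {self.root} | set(self.parent.values())
        if len(self.parent) != len(nodes) - 1:
            raise ValueError("parent map must define a spanning tree (n-1 edges)")
        for child in self.parent:
            seen, node = {child}, child
            while node != self.root:
                node = self.parent[node]
                if node in seen:
                    raise ValueError("parent map contains a cycle")
                seen.add(node)

    @property
    def channels(self) -> list[int]:
        return sorted(set(self.parent) | {self.root})

    def topological_order(self) -> list[int]:
        """Channels ordered so every parent precedes its children."""
        children: dict[int, list[int]] = {}
        for c, p in sorted(self.parent.items()):
            children.setdefault(p, []).append(c)
        order, stack = [], [self.root]
        while stack:
            node = stack.pop(0)
            order.append(node)
            stack.extend(children.get(node, []))
        return order

    def to_json(self) -> str:
        return json.dumps(
            {
                "root": self.root,
                "parent": {str(k): v for k, v in self.parent.items()},
                "gamma_q": {str(k): v for k, v in self.gamma_q.items()},
                "n0": self.n0,
                "N": self.N,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ChannelTree":
        d = json.loads(text)
        return cls(
            root=int(d["root"]),
            parent={int(k): int(v) for k, v in d["parent"].items()},
            gamma_q={int(k): int(v) for k, v in d["gamma_q"].items()},
            n0=int(d["n0"]),
            N=int(d["N"]),
        )


def train_channel_tree(group: Recording, n0: int = 0, N: int | None = None) -> ChannelTree:
    """Learn the parent/child chain and per-child gamma from a training segment.

    Builds the complete graph over the 2-8 selected channels with edge
    weight = per-sample residual energy of the child given the parent after
    the optimal gamma (symmetrized by taking the smaller direction), takes
    its minimum spanning tree, and roots it at the smallest channel id.
    """
    n_ch = group.n_channels
    if not 2 <= n_ch <= MAX_GROUP:
        raise ValueError(f"cross-channel training needs 2-{MAX_GROUP} channels, got {n_ch}")
    n_avail = group.n_samples - n0
    if N is None:
        N = min(2000, n_avail)
    if N <= 1 or n_avail < N:
        raise ValueError("training segment is empty or exceeds the recording")

    e = np.stack([temporal_decorrelate(row) for row in group.samples])
    seg = e[:, n0 : n0 + N].astype(np.float64)

    def residual_energy(child: int, ref: int) -> tuple[float, float]:
        g = estimate_gamma(seg[child], seg[ref])
        return energy(seg[child] - g * seg[ref]) / N, g

    weights = np.zeros((n_ch, n_ch))
    for i in range(n_ch):
        for j in range(i + 1, n_ch):
            w_ij, _ = residual_energy(j, i)
            w_ji, _ = residual_energy(i, j)
            # strictly positive weights so the sparse MST keeps every edge
            weights[i, j] = weights[j, i] = min(w_ij, w_ji) + 1e-12

    mst = minimum_spanning_tree(csr_matrix(weights))
    adj = mst + mst.T
    ids = np.asarray(group.channel_ids)
    root_row = int(np.argmin(ids))  # root at the smallest channel id
    order, predecessors = breadth_first_order(adj, i_start=root_row, directed=False)
    parent: dict[int, int] = {}
    gamma_q: dict[int, int] = {}
    for node in order:
        pred = predecessors[node]
        if pred < 0:
            continue
        g = estimate_gamma(seg[node], seg[pred])
        parent[int(ids[node])] = int(ids[pred])
        gamma_q[int(ids[node])] = _quantize_gamma(g)
    return ChannelTree(root=int(ids[root_row]), parent=parent, gamma_q=gamma_q, n0=n0, N=int(N))


@dataclass
class CceBitstream:
    """Golomb-coded payload of an 8-channel group plus its header state."""

    payload: bytes
    payload_bits: int
    n_samples: int
    bit_depth: int
    fs: float
    channel_ids: list[int]
    tree: ChannelTree | None  # None = temporal decorrelation only

    @property
    def header_bits(self) -> int:
        # root + per-child (parent id, gamma_q) + segment bounds + counts
        n = len(self.channel_ids)
        return 8 * (10 + (5 * (n - 1) if self.tree is not None else 0))

    @property
    def total_bits(self) -> int:
        return self.payload_bits + self.header_bits


def cce_compress(group: Recording, tree: ChannelTree | None) -> CceBitstream:
    """Losslessly compress an aligned channel group.

    The root channel codes its temporal residuals only; every child, visited
    in topological order, codes ``e_c - round(gamma_q * e_r / 2^14)``.
    With ``tree=None`` the spatial stage is skipped (temporal-only
    reference mode, useful for paired comparisons).
    """
    ids = [int(c) for c in group.channel_ids]
    if len(ids) > MAX_GROUP:
        raise ValueError(f"group limited to {MAX_GROUP} channels")
    if tree is not None and sorted(tree.channels) != sorted(ids):
        raise ValueError("tree channels do not match the group")

    e_by_id = {cid: temporal_decorrelate(group.channel(cid)) for cid in ids}
    order = tree.topological_order() if tree is not None else ids
    writer = BitWriter()
    for cid in order:
        e_c = e_by_id[cid]
        if tree is not None and cid in tree.parent:
            e_r = e_by_id[tree.parent[cid]]
            values = e_c - _apply_gamma_q(tree.gamma_q[cid], e_r)
        else:
            values = e_c
        adapter = _RiceAdapter()
        for v in map_to_nonneg(values):
            _rice_write(writer, int(v), adapter.k)
            adapter.update(int(v))
    return CceBitstream(
        payload=writer.getvalue(),
        payload_bits=writer.bit_length,
        n_samples=group.n_samples,
        bit_depth=group.bit_depth,
        fs=group.fs,
        channel_ids=ids,
        tree=tree,
    )


def cce_decompress(bits: CceBitstream) -> Recording:
    """Exactly invert :func:`cce_compress`."""
    tree = bits.tree
    order = tree.topological_order() if tree is not None else list(bits.channel_ids)
    reader = BitReader(bits.payload, bits.payload_bits)
    n = bits.n_samples
    e_by_id: dict[int, np.ndarray] = {}
    for cid in order:
        adapter = _RiceAdapter()
        values = np.empty(n, dtype=np.int64)
        for i in range(n):
            v = _rice_read(reader, adapter.k)
            adapter.update(v)
            values[i] = v
        values = np.asarray(map_from_nonneg(values))
        if tree is not None and cid in tree.parent:
            parent_e = e_by_id.get(tree.parent[cid])
            if parent_e is None:
                raise BitstreamError("stream order violates the channel tree")
            values = values + _apply_gamma_q(tree.gamma_q[cid], parent_e)
        e_by_id[cid] = values
    samples = np.stack([temporal_reconstruct(e_by_id[cid]) for cid in bits.channel_ids])
    return Recording(
        samples=samples,
        fs=bits.fs,
        bit_depth=bits.bit_depth,
        channel_ids=np.asarray(bits.channel_ids),
    )
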