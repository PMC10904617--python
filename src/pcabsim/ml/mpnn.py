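"""Message-passing network forward computation.

One message-passing step aggregates, for each vertex v, messages from its
neighbours w over edges (v, w):

    m_v = sum_{w in N(v)} M(h_v, h_w, e_vw)
    h_v <- U(h_v, m_v)

and after T steps a permutation-invariant readout R maps the set of node
states to a scalar prediction.  The default parameterisation is an
edge-conditioned linear message ``M = W_h h_w + W_e e_vw``, an additive
update ``U = h + m``, and a sum readout ``R = w . sum_v h_v + b``; any of
the three maps can be replaced by an arbitrary callable.  Training is out
of scope: weights are supplied, or randomly initialised from a seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .graphs import MolecularGraph

__all__ = ["MPNNModel", "mpnn_forward"]


@dataclass(frozen=True)
class MPNNModel:
    """Weights and step count for the forward pass.

    ``w_in`` projects raw node features into the hidden space.  When
    ``message_fn``/``update_fn``/``readout_fn`` are given they override
    the default linear maps (each receives plain numpy arrays).
    """

    n_steps: int
    w_in: np.ndarray  # (hidden, node_dim)
    w_msg_h: np.ndarray | None = None  # (hidden, hidden)
    w_msg_e: np.ndarray | None = None  # (hidden, edge_dim)
    w_out: np.ndarray | None = None  # (hidden,)
    b_out: float = 0.0
    message_fn: Callable | None = None
    update_fn: Callable | None = None
    readout_fn: Callable | None = None

    def __post_init__(self) -> None:
        if self.n_steps < 0:
            raise ValueError("n_steps must be >= 0")

    @classmethod
    def random(
        cls,
        node_dim: int,
        edge_dim: int,
        hidden_dim: int = 16,
        n_steps: int = 3,
        seed: int = 0,
        scale: float = 0.1,
    ) -> "MPNNModel":
        rng = np.random.default_rng(seed)
        return cls(
            n_steps=n_steps,
            w_in=rng.normal(0, scale, (hidden_dim, node_dim)),
            w_msg_h=rng.normal(0, scale, (hidden_dim, hidden_dim)),
            w_msg_e=rng.normal(0, scale, (hidden_dim, edge_dim)),
            w_out=rng.normal(0, scale, hidden_dim),
            b_out=float(rng.normal(0, scale)),
        )


def mpnn_forward(graph: MolecularGraph, model: MPNNModel) -> float:
    """Deterministic forward pass; invariant to node relabelling."""
    h = graph.node_features @ model.w_in.T
    hidden = h.shape[1]
    adj = graph.neighbours()
    ef = graph.edge_features
    for _ in range(model.n_steps):
        messages = np.zeros_like(h)
        for v in range(graph.n_nodes):
            m = np.zeros(hidden)
            for w, e in adj[v]:
                if model.message_fn is not None:
                    evw = ef[e] if ef is not None else None
                    m = m + model.message_fn(h[v], h[w], evw)
                else:
                    m = m + model.w_msg_h @ h[w]
                    if ef is not None and model.w_msg_e is not None and ef.shape[1]:
                        m = m + model.w_msg_e @ ef[e]
            messages[v] = m
        if model.update_fn is not None:
            h = np.stack(
                [model.update_fn(h[v], messages[v]) for v in range(graph.n_nodes)]
            )
        else:
            h = h + messages
    if model.readout_fn is not None:
        return float(model.readout_fn(h))
    pooled = h.sum(axis=0)
    if model.w_out is None:
        raise ValueError("model has neither w_out nor readout_fn")
    if pooled.shape[0] != model.w_out.shape[0]:
        raise ValueError(
            f"readout dimension mismatch: hidden {pooled.shape[0]} vs "
            f"w_out {model.w_out.shape[0]}"
        )
    return float(model.w_out @ pooled + model.b_out)
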