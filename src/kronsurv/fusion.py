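"""Gated-attention Kronecker trilinear fusion of modality embeddings.

Each modality embedding is projected to a common fusion width, gated on the
other two modalities (a sigmoid attention gate computed from the projected
context), augmented with a constant 1, and combined by a triple outer
product. The appended ones guarantee that every unimodal and bimodal
interaction term appears in the fused vector alongside the trimodal terms.
A feed-forward head maps the fused representation to a scalar log-hazard.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import MLP, Linear, Module, Tensor, concat
from .omics import CrossmodalSurvivalNet
from .wsg import GCNSurvivalNet, WholeSlideGraph

__all__ = [
    "ModalityEmbedding", "FusedRepresentation", "GatedProjection",
    "gate", "kronecker_fuse", "MultimodalSurvivalModel", "multimodal_forward",
]

MODALITIES = ("expression", "methylation", "wsg")


@dataclass
class ModalityEmbedding:
    modality: str
    h: np.ndarray

    def __post_init__(self):
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        self.h = np.asarray(self.h, dtype=np.float64)
        if not np.all(np.isfinite(self.h)):
            raise ValueError("embedding entries must be finite")


@dataclass
class FusedRepresentation:
    f: np.ndarray
    dims: tuple[int, int, int]

    def __post_init__(self):
        d1, d2, d3 = self.dims
        if len(self.f) != (d1 + 1) * (d2 + 1) * (d3 + 1):
            raise ValueError("fused length must be (d1+1)(d2+1)(d3+1)")


class GatedProjection(Module):
    """Projects a target modality and gates it on the other two.

    output = sigmoid(W_g . concat(context projections)) * (W_t . h_target)
    """

    def __init__(self, d_target: int, d_contexts: list[int], width: int,
                 rng: np.random.Generator):
        self.proj_target = Linear(d_target, width, rng)
        self.proj_contexts = [Linear(dc, width, rng) for dc in d_contexts]
        self.gate_lin = Linear(width * len(d_contexts), width, rng)

    def __call__(self, h_target: Tensor, h_contexts: list[Tensor]) -> Tensor:
        if len(h_contexts) != len(self.proj_contexts):
            raise ValueError("context count mismatch")
        ctx = concat([p(h) for p, h in zip(self.proj_contexts, h_contexts)], axis=-1)
        g = self.gate_lin(ctx).sigmoid()
        return g * self.proj_target(h_target)


def gate(h_target: ModalityEmbedding, h_context: list[ModalityEmbedding],
         weights: GatedProjection) -> np.ndarray:
    """Functional gated projection for raw embedding containers."""
    out = weights(Tensor(h_target.h), [Tensor(c.h) for c in h_context])
    return out.data


def kronecker_fuse(e1: Tensor | np.ndarray, e2: Tensor | np.ndarray,
                   e3: Tensor | np.ndarray) -> Tensor:
    """Trilinear Kronecker fusion of three gated vectors.

    Each vector is augmented with a trailing constant 1; the fused vector is
    the vectorised triple outer product with index order
    ``f[(i * (d2+1) + j) * (d3+1) + k] = a_i * b_j * c_k`` where ``a = e1 + [1]``
    etc. Length is exactly (d1+1)(d2+1)(d3+1).
    """
    one = Tensor(np.ones(1))
    a = concat([Tensor._lift(e1), one])
    b = concat([Tensor._lift(e2), one])
    c = concat([Tensor._lift(e3), one])
    d1, d2, d3 = a.shape[0], b.shape[0], c.shape[0]
    prod = a.reshape(d1, 1, 1) * b.reshape(1, d2, 1) * c.reshape(1, 1, d3)
    return prod.reshape(d1 * d2 * d3)


class MultimodalSurvivalModel(Module):
    """Trimodal survival model: unimodal encoders -> gated Kronecker fusion
    -> feed-forward hazard head.

    Penultimate (latent / graph-level) features of the three unimodal nets
    are the modality embeddings; all three modalities must be present.
    """

    def __init__(self, expr_net: CrossmodalSurvivalNet, meth_net: CrossmodalSurvivalNet,
                 wsg_net: GCNSurvivalNet, rng: np.random.Generator,
                 fusion_width: int = 32, head_sizes: tuple[int, ...] = (128, 64)):
        self.expr_net = expr_net
        self.meth_net = meth_net
        self.wsg_net = wsg_net
        self.fusion_width = fusion_width
        d_e = expr_net.encoder.spec.latent_dim
        d_m = meth_net.encoder.spec.latent_dim
        d_w = wsg_net.spec.hidden_dim * wsg_net.spec.n_blocks
        self.gate_expr = GatedProjection(d_e, [d_m, d_w], fusion_width, rng)
        self.gate_meth = GatedProjection(d_m, [d_e, d_w], fusion_width, rng)
        self.gate_wsg = GatedProjection(d_w, [d_e, d_m], fusion_width, rng)
        fused = (fusion_width + 1) ** 3
        self.head = MLP([fused, *head_sizes, 1], rng)

    def encoder_parameters(self):
        """Parameters of the pretrained unimodal encoders (freezable)."""
        return (self.expr_net.parameters() + self.meth_net.parameters()
                + self.wsg_net.parameters())

    def embed(self, x_expr: Tensor, x_meth: Tensor, wsg: WholeSlideGraph
              ) -> tuple[Tensor, Tensor, Tensor]:
        _, h_e = self.expr_net.encoder(x_expr)
        _, h_m = self.meth_net.encoder(x_meth)
        h_w, _ = self.wsg_net.encode(wsg)
        return h_e, h_m, h_w

    def forward_from_embeddings(self, h_e: Tensor, h_m: Tensor, h_w: Tensor) -> Tensor:
        e = self.gate_expr(h_e, [h_m, h_w])
        m = self.gate_meth(h_m, [h_e, h_w])
        w = self.gate_wsg(h_w, [h_e, h_m])
        fused = kronecker_fuse(e, m, w)
        return self.head(fused).reshape(())

    def forward_one(self, x_expr: Tensor, x_meth: Tensor, wsg: WholeSlideGraph) -> Tensor:
        if wsg is None:
            raise ValueError("missing modality: all three are required")
        h_e, h_m, h_w = self.embed(x_expr, x_meth, wsg)
        return self.forward_from_embeddings(h_e, h_m, h_w)

    def hazards(self, X_expr: np.ndarray, X_meth: np.ndarray,
                wsgs: list[WholeSlideGraph], idx=None) -> Tensor:
        idx = np.arange(len(wsgs)) if idx is None else np.asarray(idx)
        outs = [self.forward_one(Tensor(X_expr[i]), Tensor(X_meth[i]), wsgs[i]).reshape(1)
                for i in idx]
        return concat(outs)


def multimodal_forward(x_expr: np.ndarray, x_meth: np.ndarray, wsg: WholeSlideGraph,
                       model: MultimodalSurvivalModel) -> float:
    """Scalar log-hazard for one patient's three modalities."""
    return float(model.forward_one(Tensor(np.asarray(x_expr, dtype=np.float64)),
                                   Tensor(np.asarray(x_meth, dtype=np.float64)), wsg).data)
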