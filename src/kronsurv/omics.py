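"""Sparsely coded (capsule) omics encoders.

Expression and methylation inputs pass through a connectivity-masked layer
whose units ("capsules") correspond to annotated feature groups — genes for
CpG inputs, biological pathways for gene inputs — so each hidden unit has a
biological identity. Two pretraining heads are provided: a variational
autoencoder for self-supervised pretraining, and a joint crossmodal +
survival head that predicts the complementary modality alongside a scalar
log-hazard under a Cox objective.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .nn import MLP, Linear, Module, SparseLinear, Tensor, ACTIVATIONS
from .survival import SurvivalData, cox_loss_tensor

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureAnnotation", "SparseMask", "OmicsEncoderSpec", "VAEOutput",
    "build_sparse_mask", "OmicsEncoder", "OmicsVAE", "CrossmodalSurvivalNet",
    "capsule_forward", "vae_loss", "crossmodal_forward", "crossmodal_loss",
]


@dataclass
class FeatureAnnotation:
    """Feature-to-capsule memberships (e.g. CpG→gene, gene→pathway).

    ``entries`` lists (feature_id, capsule_id) pairs; a feature may belong to
    several capsules. ``feature_order`` / ``capsule_order`` fix canonical
    index orders so masks are deterministic.
    """

    entries: list[tuple[str, str]]
    feature_order: list[str] = field(default_factory=list)
    capsule_order: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.feature_order:
            seen = dict.fromkeys(f for f, _ in self.entries)
            self.feature_order = list(seen)
        if not self.capsule_order:
            seen = dict.fromkeys(c for _, c in self.entries)
            self.capsule_order = list(seen)

    @classmethod
    def from_sets(cls, capsule_to_features: dict[str, list[str]]) -> "FeatureAnnotation":
        entries = [(f, c) for c, feats in capsule_to_features.items() for f in feats]
        return cls(entries=entries, capsule_order=list(capsule_to_features))


@dataclass
class SparseMask:
    """Binary feature-by-capsule connectivity matrix with id bookkeeping."""

    M: np.ndarray
    feature_ids: list[str]
    capsule_ids: list[str]

    def __post_init__(self):
        self.M = np.asarray(self.M, dtype=np.float64)
        if self.M.shape != (len(self.feature_ids), len(self.capsule_ids)):
            raise ValueError("mask shape inconsistent with id lists")
        if np.any(self.M.sum(axis=0) < 1):
            raise ValueError("every capsule needs at least one member feature")

    @property
    def n_features(self) -> int:
        return self.M.shape[0]

    @property
    def n_capsules(self) -> int:
        return self.M.shape[1]


def build_sparse_mask(annotation: FeatureAnnotation, feature_ids: list[str]) -> SparseMask:
    """Deterministic mask over ``feature_ids`` following the canonical orders.

    Features absent from the annotation are dropped from the rows (with a
    logged count); a capsule left without members raises.
    """
    if not feature_ids:
        raise ValueError("feature_ids must be non-empty")
    if not annotation.entries:
        raise ValueError("empty annotation")
    members = set(annotation.entries)
    annotated = {f for f, _ in annotation.entries}
    kept = [f for f in feature_ids if f in annotated]
    dropped = len(feature_ids) - len(kept)
    if dropped:
        logger.info("build_sparse_mask: dropped %d unannotated features", dropped)
    if not kept:
        raise ValueError("no annotated features remain")
    capsules = list(annotation.capsule_order)
    M = np.zeros((len(kept), len(capsules)))
    for i, f in enumerate(kept):
        for j, c in enumerate(capsules):
            if (f, c) in members:
                M[i, j] = 1.0
    empty = [capsules[j] for j in np.flatnonzero(M.sum(axis=0) == 0)]
    if empty:
        raise ValueError(f"capsules with no member features after filtering: {empty[:5]}")
    return SparseMask(M=M, feature_ids=kept, capsule_ids=capsules)


@dataclass
class OmicsEncoderSpec:
    mask: SparseMask
    capsule_activation: str = "tanh"
    hidden_sizes: tuple[int, ...] = (256,)
    latent_dim: int = 128

    def __post_init__(self):
        if self.latent_dim < 1 or any(h < 1 for h in self.hidden_sizes):
            raise ValueError("latent and hidden sizes must be positive")


@dataclass
class VAEOutput:
    mu: Tensor
    logvar: Tensor
    reconstruction: Tensor


class OmicsEncoder(Module):
    """Masked capsule layer followed by a feed-forward stack to the latent."""

    def __init__(self, spec: OmicsEncoderSpec, rng: np.random.Generator):
        self.spec = spec
        self.capsule_layer = SparseLinear(spec.mask.M, rng)
        sizes = [spec.mask.n_capsules, *spec.hidden_sizes, spec.latent_dim]
        self.latent_stack = MLP(sizes, rng, hidden_activation="relu")

    def __call__(self, x: Tensor) -> tuple[Tensor, Tensor]:
        caps = ACTIVATIONS[self.spec.capsule_activation](self.capsule_layer(x))
        return caps, self.latent_stack(caps)

    def latent_from_capsules(self, caps: Tensor) -> Tensor:
        return self.latent_stack(caps)


def capsule_forward(x, spec: OmicsEncoderSpec, encoder: OmicsEncoder) -> tuple[np.ndarray, np.ndarray]:
    """Convenience numpy-in / numpy-out capsule pass for a feature vector."""
    x = np.asarray(x, dtype=np.float64)
    if x.shape[-1] != spec.mask.n_features:
        raise ValueError("input length must equal mask rows")
    caps, latent = encoder(Tensor(x))
    return caps.data, latent.data


class OmicsVAE(Module):
    """Variational autoencoder over an omics encoder (self-supervised head)."""

    def __init__(self, spec: OmicsEncoderSpec, rng: np.random.Generator):
        self.encoder = OmicsEncoder(spec, rng)
        d = spec.latent_dim
        self.mu_head = Linear(d, d, rng)
        self.logvar_head = Linear(d, d, rng)
        rev = [d, *reversed(spec.hidden_sizes), spec.mask.n_features]
        self.decoder = MLP(rev, rng, hidden_activation="relu")

    def __call__(self, x: Tensor, rng: np.random.Generator | None = None) -> VAEOutput:
        _, z = self.encoder(x)
        mu = self.mu_head(z)
        logvar = self.logvar_head(z)
        if rng is not None:
            eps = Tensor(rng.standard_normal(mu.shape))
            z_sample = mu + (logvar * 0.5).exp() * eps
        else:
            z_sample = mu
        return VAEOutput(mu=mu, logvar=logvar, reconstruction=self.decoder(z_sample))


def vae_loss(out: VAEOutput, x: Tensor) -> Tensor:
    """Mean-squared reconstruction error plus the Gaussian KL to N(0, I).

    KL = -0.5 * sum(1 + logvar - mu^2 - exp(logvar)), summed over latent
    dimensions and averaged over any batch axis; the reconstruction term is
    the mean squared error over features (and batch).
    """
    x = x if isinstance(x, Tensor) else Tensor(x)
    if out.reconstruction.shape != x.shape:
        raise ValueError("reconstruction shape mismatch")
    mse = ((out.reconstruction - x) ** 2.0).mean()
    kl_per = (1.0 + out.logvar - out.mu ** 2.0 - out.logvar.exp()).sum(axis=-1) * -0.5
    return mse + kl_per.mean()


class CrossmodalSurvivalNet(Module):
    """Shared capsule encoder with a scalar log-hazard branch and a branch
    predicting selected features of the complementary modality."""

    def __init__(self, spec: OmicsEncoderSpec, complement_dim: int,
                 rng: np.random.Generator, head_hidden: tuple[int, ...] = (64,)):
        self.encoder = OmicsEncoder(spec, rng)
        d = spec.latent_dim
        self.hazard_head = MLP([d, *head_hidden, 1], rng)
        self.complement_head = MLP([d, *head_hidden, complement_dim], rng)

    def __call__(self, x: Tensor) -> tuple[Tensor, Tensor, Tensor, Tensor]:
        caps, latent = self.encoder(x)
        return self.hazard_head(latent), self.complement_head(latent), caps, latent

    # hooks used by the interpretation module (layer-wise attribution)
    def capsule_activations(self, X: np.ndarray) -> np.ndarray:
        caps, _ = self.encoder(Tensor(np.asarray(X, dtype=np.float64)))
        return caps.data

    def hazard_from_capsules(self, caps: Tensor) -> Tensor:
        latent = self.encoder.latent_from_capsules(caps)
        return self.hazard_head(latent).reshape(())


def crossmodal_forward(x, net: CrossmodalSurvivalNet) -> tuple[np.ndarray, np.ndarray]:
    """(log-hazard, complement prediction) for a feature vector or batch."""
    hazard, comp, _, _ = net(Tensor(np.asarray(x, dtype=np.float64)))
    return hazard.data, comp.data


def crossmodal_loss(hazard: Tensor, comp_pred: Tensor, comp_target,
                    surv: SurvivalData, w_cm: float = 1.0) -> Tensor:
    """Joint objective: Cox loss on the hazard branch plus w_cm times the MSE
    of the complementary-modality prediction."""
    target = comp_target if isinstance(comp_target, Tensor) else Tensor(comp_target)
    if comp_pred.shape != target.shape:
        raise ValueError("complement target shape mismatch")
    loss = cox_loss_tensor(hazard, surv)
    if w_cm != 0.0:
        loss = loss + w_cm * ((comp_pred - target) ** 2.0).mean()
    return loss
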