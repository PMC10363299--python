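"""Dataset splitting, Cox training loops, and the pretraining regimes.

Regimes:

* ``uni_self`` — omics encoders pretrained as VAEs (checkpoint grid scanned by
  survival finetuning), WSG GCN trained on survival alone.
* ``uni_cross`` — joint crossmodal + survival training; for the WSG branch a
  Deep Graph Infomax contrastive stage precedes it.
* ``multi_self`` / ``multi_cross`` — gated Kronecker fusion model initialised
  from the corresponding unimodal weights, encoders frozen for the first
  ``freeze_epochs`` epochs.
* ``transfer`` — unimodal + multimodal pretraining on the pooled sub-cohorts,
  then per-sub-cohort finetuning.

Cox risk sets are formed within each gradient-accumulation group: the raw
mini-batches (3–4 patients) are too small to carry stable risk sets, so the
partial likelihood is evaluated over the whole group that an optimiser step
covers (batch_size × accumulation_steps patients).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .fusion import MultimodalSurvivalModel
from .nn import Adam, Module, Tensor
from .omics import (CrossmodalSurvivalNet, OmicsEncoderSpec, OmicsVAE,
                    build_sparse_mask, vae_loss)
from .survival import SurvivalData, concordance_index, cox_loss_tensor, log_rank_test
from .wsg import DGIHead, GCNSpec, GCNSurvivalNet, WholeSlideGraph, build_wsg, dgi_loss

logger = logging.getLogger(__name__)

__all__ = [
    "SplitPlan", "TrainConfig", "ModelConfig", "Checkpoint", "CohortData",
    "make_splits", "prepare_cohort", "train_cox", "run_regime",
]

REGIMES = ("uni_self", "uni_cross", "multi_self", "multi_cross", "transfer")


# ---------------------------------------------------------------------------
# Splitting with survival parity
# ---------------------------------------------------------------------------

@dataclass
class SplitPlan:
    train: np.ndarray
    val: np.ndarray
    test: np.ndarray
    parity_p: dict[str, float]
    seed: int
    attempts: int = 1


def _apportion(stratum_sizes: np.ndarray, total: int) -> np.ndarray:
    """Largest-remainder allocation of ``total`` slots across strata."""
    quota = stratum_sizes * total / stratum_sizes.sum()
    base = np.floor(quota).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(quota - base))
    base[order[:rem]] += 1
    return base


def make_splits(surv: SurvivalData, seed: int, retry_cap: int = 25,
                parity_alpha: float = 0.05) -> SplitPlan:
    """Event-stratified 80/10/10 split with a log-rank parity check.

    If any pairwise log-rank p between partitions falls below
    ``parity_alpha``, the split is redrawn with an incremented seed up to
    ``retry_cap`` times.
    """
    n = len(surv)
    if n < 10:
        raise ValueError("need at least 10 samples to split 80/10/10")
    n_val = round(0.1 * n)
    n_test = round(0.1 * n)
    for attempt in range(retry_cap):
        rng = np.random.default_rng(seed + attempt)
        val_parts, test_parts, train_parts = [], [], []
        strata = [np.flatnonzero(surv.event == e) for e in (0, 1)]
        strata = [s for s in strata if len(s)]
        sizes = np.array([len(s) for s in strata])
        val_alloc = _apportion(sizes, n_val)
        test_alloc = _apportion(sizes, n_test)
        for s, nv, nt in zip(strata, val_alloc, test_alloc):
            perm = rng.permutation(s)
            val_parts.append(perm[:nv])
            test_parts.append(perm[nv:nv + nt])
            train_parts.append(perm[nv + nt:])
        plan = SplitPlan(
            train=np.sort(np.concatenate(train_parts)),
            val=np.sort(np.concatenate(val_parts)),
            test=np.sort(np.concatenate(test_parts)),
            parity_p={}, seed=seed, attempts=attempt + 1)
        ok = True
        for name, (a, b) in {"train_vs_val": (plan.train, plan.val),
                             "train_vs_test": (plan.train, plan.test),
                             "val_vs_test": (plan.val, plan.test)}.items():
            idx = np.concatenate([a, b])
            labels = np.concatenate([np.zeros(len(a), int), np.ones(len(b), int)])
            try:
                _, p = log_rank_test(surv.subset(idx), labels)
            except ValueError:
                p = 1.0
            plan.parity_p[name] = p
            ok &= p >= parity_alpha
        if ok:
            return plan
        logger.info("make_splits: parity failed on attempt %d (%s)", attempt + 1, plan.parity_p)
    raise ValueError(f"no parity-compliant split found in {retry_cap} attempts")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class ModelConfig:
    """Architecture settings shared across regimes."""

    latent_dim: int = 128
    hidden_sizes: tuple[int, ...] = (256,)
    head_sizes: tuple[int, ...] = (64,)
    gcn_blocks: int = 3
    gcn_hidden: int = 128
    pool_ratio: float = 0.5
    fusion_width: int = 32
    fusion_head: tuple[int, ...] = (128, 64)
    top_k_complement: int = 256
    radius: float = 1.5
    w_cm: float = 1.0
    wsg_target: str = "expression"   # complement modality for the WSG branch


@dataclass
class TrainConfig:
    """Optimisation schedule for one regime."""

    regime: str = "uni_cross"
    learning_rate: float = 2e-4
    max_epochs: int = 40
    batch_size: int = 32
    accumulation_steps: int = 1
    freeze_epochs: int = 0
    weight_decay: float = 1e-4
    seed: int = 0
    checkpoint_metric: str = "val_cox_loss"
    decay_mode: str = "weight_decay"      # or "linear_lr" (see docs/methods)
    # stage-specific settings
    vae_epochs: int = 500
    vae_checkpoint_every: int = 100
    vae_lr: float = 0.008
    dgi_epochs: int = 15
    wsg_lr_grid: tuple[float, ...] = (1e-4, 2e-4, 4e-4)
    transfer_pretrain_epochs: int = 10
    transfer_finetune_epochs: int = 40
    transfer_finetune_lr: float = 1e-3
    # optional coarse learning-rate grid for the fusion stage, resolved by
    # validation Cox loss (None: train once at learning_rate)
    lr_grid: tuple[float, ...] | None = None

    def __post_init__(self):
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}")
        if min(self.max_epochs, self.batch_size, self.accumulation_steps) < 1:
            raise ValueError("epochs, batch size and accumulation steps must be >= 1")

    @classmethod
    def for_regime(cls, regime: str, **overrides) -> "TrainConfig":
        base = {
            "uni_self": dict(learning_rate=2e-4, batch_size=32, accumulation_steps=1),
            "uni_cross": dict(learning_rate=2e-4, batch_size=32, accumulation_steps=1),
            "multi_self": dict(learning_rate=1e-4, batch_size=3, accumulation_steps=8,
                               freeze_epochs=10),
            "multi_cross": dict(learning_rate=1e-4, batch_size=3, accumulation_steps=8,
                                freeze_epochs=10),
            "transfer": dict(learning_rate=1e-4, batch_size=3, accumulation_steps=8,
                             freeze_epochs=10),
        }[regime]
        base.update(overrides)
        return cls(regime=regime, **base)

    @property
    def effective_batch(self) -> int:
        return self.batch_size * self.accumulation_steps


@dataclass
class Checkpoint:
    arrays: list[np.ndarray]
    best_epoch: int
    best_val: float
    history: list[dict] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Cohort preparation
# ---------------------------------------------------------------------------

@dataclass
class CohortData:
    """A cohort prepared for training: standardised matrices, graphs, targets."""

    cohort: object
    splits: SplitPlan
    X_expr: np.ndarray
    X_meth: np.ndarray
    wsgs: list[WholeSlideGraph]
    surv: SurvivalData
    expr_complement: np.ndarray     # top-K-variable methylation features
    meth_complement: np.ndarray     # top-K-variable expression features
    expr_mask: object
    meth_mask: object

    def complement_for(self, modality: str) -> np.ndarray:
        if modality == "expression":
            return self.expr_complement
        if modality == "methylation":
            return self.meth_complement
        raise ValueError(modality)


def _standardise(X: np.ndarray, train_idx: np.ndarray) -> np.ndarray:
    mu = X[train_idx].mean(axis=0)
    sd = X[train_idx].std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def _top_k_variable(X: np.ndarray, train_idx: np.ndarray, k: int) -> np.ndarray:
    var = X[train_idx].var(axis=0)
    k = min(k, X.shape[1])
    keep = np.sort(np.argsort(-var, kind="stable")[:k])
    return X[:, keep]


def prepare_cohort(cohort, seed: int, model_cfg: ModelConfig | None = None) -> CohortData:
    """Split, standardise, build graphs, and derive crossmodal targets."""
    model_cfg = model_cfg or ModelConfig()
    splits = make_splits(cohort.survival, seed)
    X_expr = _standardise(cohort.expression, splits.train)
    X_meth = _standardise(cohort.methylation, splits.train)
    wsgs = [build_wsg(ps, radius=model_cfg.radius) for ps in cohort.slides]
    k = model_cfg.top_k_complement
    return CohortData(
        cohort=cohort, splits=splits, X_expr=X_expr, X_meth=X_meth, wsgs=wsgs,
        surv=cohort.survival,
        expr_complement=_top_k_variable(X_meth, splits.train, k),
        meth_complement=_top_k_variable(X_expr, splits.train, k),
        expr_mask=build_sparse_mask(cohort.pathway_annotation, cohort.gene_ids),
        meth_mask=build_sparse_mask(cohort.cpg_annotation, cohort.cpg_ids),
    )


# ---------------------------------------------------------------------------
# Generic Cox training loop
# ---------------------------------------------------------------------------

def train_cox(model: Module, hazard_fn, surv: SurvivalData, train_idx, val_idx,
              cfg: TrainConfig, aux_loss_fn=None, frozen_params=None) -> Checkpoint:
    """Adam training of a hazard model under the Cox partial likelihood.

    ``hazard_fn(idx)`` returns the Tensor of log-hazards for those patients;
    ``aux_loss_fn(idx)`` optionally adds an auxiliary (e.g. crossmodal MSE)
    term. One optimiser step is taken per accumulation group of
    ``batch_size * accumulation_steps`` patients, with the Cox risk set
    spanning the group. Groups without events are skipped (logged). Encoder
    parameters listed in ``frozen_params`` receive no updates while
    ``epoch < freeze_epochs``. The checkpoint with the lowest validation Cox
    loss is restored into the model before returning.
    """
    train_idx = np.asarray(train_idx)
    val_idx = np.asarray(val_idx)
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.learning_rate,
               weight_decay=cfg.weight_decay if cfg.decay_mode == "weight_decay" else 0.0)
    frozen_ids = {id(p) for p in (frozen_params or [])}
    group = cfg.effective_batch
    # the incoming state competes too: finetuning cannot end worse on val
    best = Checkpoint(arrays=model.state_arrays(), best_epoch=-1,
                      best_val=_val_cox(hazard_fn, surv, val_idx))
    step = 0
    for epoch in range(cfg.max_epochs):
        perm = rng.permutation(train_idx)
        epoch_loss, n_groups = 0.0, 0
        for start in range(0, len(perm), group):
            g = perm[start:start + group]
            if surv.event[g].sum() == 0:
                logger.debug("train_cox: skipping accumulation group with no events")
                continue
            loss = cox_loss_tensor(hazard_fn(g), surv.subset(g))
            if aux_loss_fn is not None:
                loss = loss + aux_loss_fn(g)
            opt.zero_grad()
            loss.backward()
            if cfg.decay_mode == "linear_lr":
                opt.lr = cfg.learning_rate * max(0.1, 1.0 - 1e-4 * step)
            opt.step(frozen=frozen_ids if epoch < cfg.freeze_epochs else None)
            step += 1
            epoch_loss += loss.item()
            n_groups += 1
        val = _val_cox(hazard_fn, surv, val_idx)
        best.history.append({"epoch": epoch, "train_loss": epoch_loss / max(n_groups, 1),
                             "val_cox_loss": val})
        if val < best.best_val:
            best.best_val = val
            best.best_epoch = epoch
            best.arrays = model.state_arrays()
    model.load_arrays(best.arrays)
    return best


def _val_cox(hazard_fn, surv: SurvivalData, idx: np.ndarray) -> float:
    try:
        return float(cox_loss_tensor(hazard_fn(idx), surv.subset(idx)).item())
    except ValueError:   # no events in validation fold
        return np.inf


# ---------------------------------------------------------------------------
# Unimodal training
# ---------------------------------------------------------------------------

def _omics_matrix(data: CohortData, modality: str) -> np.ndarray:
    return data.X_expr if modality == "expression" else data.X_meth


def _omics_mask(data: CohortData, modality: str):
    return data.expr_mask if modality == "expression" else data.meth_mask


def _vae_pretrain(spec: OmicsEncoderSpec, X: np.ndarray, train_idx, cfg: TrainConfig,
                  rng: np.random.Generator) -> list[tuple[int, list[np.ndarray]]]:
    """VAE training with a checkpoint grid every ``vae_checkpoint_every`` epochs."""
    vae = OmicsVAE(spec, rng)
    opt = Adam(vae.parameters(), lr=cfg.vae_lr)
    shuffle = np.random.default_rng(cfg.seed + 1)
    checkpoints = []
    for epoch in range(1, cfg.vae_epochs + 1):
        perm = shuffle.permutation(train_idx)
        for start in range(0, len(perm), cfg.batch_size):
            xb = Tensor(X[perm[start:start + cfg.batch_size]])
            out = vae(xb, rng=shuffle)
            loss = vae_loss(out, xb)
            opt.zero_grad()
            loss.backward()
            opt.step()
        if epoch % cfg.vae_checkpoint_every == 0 or epoch == cfg.vae_epochs:
            checkpoints.append((epoch, vae.encoder.state_arrays()))
    return checkpoints


def train_unimodal_omics(data: CohortData, modality: str, regime: str,
                         cfg: TrainConfig, model_cfg: ModelConfig) -> tuple[CrossmodalSurvivalNet, Checkpoint]:
    """Train one omics branch under the ``uni_self`` or ``uni_cross`` scheme."""
    X = _omics_matrix(data, modality)
    comp = data.complement_for(modality)
    spec = OmicsEncoderSpec(mask=_omics_mask(data, modality),
                            hidden_sizes=model_cfg.hidden_sizes,
                            latent_dim=model_cfg.latent_dim)
    surv, tr, va = data.surv, data.splits.train, data.splits.val

    def build_net(seed_offset: int) -> CrossmodalSurvivalNet:
        rng = np.random.default_rng(cfg.seed + seed_offset)
        return CrossmodalSurvivalNet(spec, comp.shape[1], rng,
                                     head_hidden=model_cfg.head_sizes)

    def hazard_fn_of(net):
        return lambda idx: net(Tensor(X[idx]))[0].reshape(len(idx))

    if regime == "uni_self":
        rng = np.random.default_rng(cfg.seed + 10)
        checkpoints = _vae_pretrain(spec, X, tr, cfg, rng)
        best_net, best_ckpt = None, None
        for epoch, enc_arrays in checkpoints:   # scan the VAE checkpoint grid
            net = build_net(20 + epoch)
            net.encoder.load_arrays(enc_arrays)
            ck = train_cox(net, hazard_fn_of(net), surv, tr, va, cfg)
            if best_ckpt is None or ck.best_val < best_ckpt.best_val:
                best_net, best_ckpt = net, ck
        return best_net, best_ckpt
    if regime == "uni_cross":
        net = build_net(30)
        def aux(idx):
            hz, cp, _, _ = net(Tensor(X[idx]))
            return model_cfg.w_cm * ((cp - Tensor(comp[idx])) ** 2.0).mean()
        ck = train_cox(net, hazard_fn_of(net), surv, tr, va, cfg, aux_loss_fn=aux)
        return net, ck
    raise ValueError(f"omics branch does not support regime {regime!r}")


def _dgi_pretrain(net: GCNSurvivalNet, wsgs, train_idx, val_idx, cfg: TrainConfig,
                  rng: np.random.Generator) -> float:
    """Contrastive pretraining; transfers the epoch with lowest validation loss."""
    head = DGIHead(net, rng)
    params = [p for conv in net.convs for p in conv.parameters()] + [head.B]
    opt = Adam(params, lr=1e-3)
    best_val, best_arrays = np.inf, [p.data.copy() for p in params]
    corrupt = np.random.default_rng(cfg.seed + 77)
    for epoch in range(cfg.dgi_epochs):
        for i in rng.permutation(train_idx):
            loss = dgi_loss(wsgs[i], head, int(corrupt.integers(2**31)))
            opt.zero_grad()
            loss.backward()
            opt.step()
        val = float(np.mean([dgi_loss(wsgs[i], head, 12345 + i).item() for i in val_idx]))
        if val < best_val:
            best_val = val
            best_arrays = [p.data.copy() for p in params]
    for p, a in zip(params, best_arrays):
        p.data = a.copy()
    return best_val


def train_unimodal_wsg(data: CohortData, regime: str, cfg: TrainConfig,
                       model_cfg: ModelConfig) -> tuple[GCNSurvivalNet, Checkpoint]:
    """Train the whole-slide-graph branch (``uni_self`` or ``uni_cross``)."""
    # wsg_target names the omics modality the graph branch predicts;
    # meth_complement holds the top-K expression features and vice versa
    comp = (data.meth_complement if model_cfg.wsg_target == "expression"
            else data.expr_complement)
    spec = GCNSpec(n_blocks=model_cfg.gcn_blocks, hidden_dim=model_cfg.gcn_hidden,
                   pool_ratio=model_cfg.pool_ratio, head_sizes=model_cfg.head_sizes)
    in_dim = data.wsgs[0].features.shape[1]
    rng = np.random.default_rng(cfg.seed + 40)
    net = GCNSurvivalNet(in_dim, spec, comp.shape[1], rng)
    surv, tr, va = data.surv, data.splits.train, data.splits.val

    if regime == "uni_cross":
        _dgi_pretrain(net, data.wsgs, tr, va, cfg, rng)

    from .nn import concat

    def hazard_fn(idx):
        return concat([net(data.wsgs[i])[0].reshape(1) for i in idx])

    aux = None
    if regime == "uni_cross":
        def aux(idx):
            preds = concat([net(data.wsgs[i])[1].reshape(1, comp.shape[1]) for i in idx], axis=0)
            return model_cfg.w_cm * ((preds - Tensor(comp[idx])) ** 2.0).mean()

    ck = train_cox(net, hazard_fn, surv, tr, va, cfg, aux_loss_fn=aux)
    return net, ck


# ---------------------------------------------------------------------------
# Multimodal training and regimes
# ---------------------------------------------------------------------------

def train_multimodal(data: CohortData, expr_net, meth_net, wsg_net,
                     cfg: TrainConfig, model_cfg: ModelConfig,
                     train_idx=None, val_idx=None) -> tuple[MultimodalSurvivalModel, Checkpoint]:
    """Fusion training, optionally over a coarse learning-rate grid resolved
    by validation Cox loss. Encoder weights are snapshotted so every grid arm
    starts from the same pretrained state."""
    lrs = cfg.lr_grid or (cfg.learning_rate,)
    if len(lrs) == 1:
        return _train_multimodal_once(data, expr_net, meth_net, wsg_net,
                                      replace(cfg, learning_rate=lrs[0], lr_grid=None),
                                      model_cfg, train_idx, val_idx)
    enc_state = [net.state_arrays() for net in (expr_net, meth_net, wsg_net)]
    best = None
    for lr in lrs:
        for net, arrays in zip((expr_net, meth_net, wsg_net), enc_state):
            net.load_arrays(arrays)
        model, ck = _train_multimodal_once(
            data, expr_net, meth_net, wsg_net,
            replace(cfg, learning_rate=lr, lr_grid=None), model_cfg,
            train_idx, val_idx)
        if best is None or ck.best_val < best[1].best_val:
            best = (model.state_arrays(), ck, lr)
    model.load_arrays(best[0])
    return model, best[1]


def _train_multimodal_once(data: CohortData, expr_net, meth_net, wsg_net,
                           cfg: TrainConfig, model_cfg: ModelConfig,
                           train_idx=None, val_idx=None) -> tuple[MultimodalSurvivalModel, Checkpoint]:
    """Two-phase fusion training: while the pretrained encoders are frozen
    their (constant) embeddings are precomputed and only the gates/head are
    optimised — numerically identical to the frozen forward pass — followed
    by joint finetuning of the whole model."""
    rng = np.random.default_rng(cfg.seed + 50)
    model = MultimodalSurvivalModel(expr_net, meth_net, wsg_net, rng,
                                    fusion_width=model_cfg.fusion_width,
                                    head_sizes=model_cfg.fusion_head)
    tr = data.splits.train if train_idx is None else train_idx
    va = data.splits.val if val_idx is None else val_idx

    history: list[dict] = []
    if cfg.freeze_epochs > 0:
        H_e = model.expr_net.encoder(Tensor(data.X_expr))[1].data
        H_m = model.meth_net.encoder(Tensor(data.X_meth))[1].data
        H_w = np.stack([model.wsg_net.encode(w)[0].data for w in data.wsgs])

        def frozen_hazard_fn(idx):
            from .nn import concat
            outs = [model.forward_from_embeddings(
                Tensor(H_e[i]), Tensor(H_m[i]), Tensor(H_w[i])).reshape(1)
                for i in idx]
            return concat(outs)

        frozen_cfg = replace(cfg, max_epochs=cfg.freeze_epochs, freeze_epochs=0)
        ck0 = train_cox(model, frozen_hazard_fn, data.surv, tr, va, frozen_cfg)
        history = ck0.history

    def hazard_fn(idx):
        return model.hazards(data.X_expr, data.X_meth, data.wsgs, idx)

    joint_cfg = replace(cfg, max_epochs=max(cfg.max_epochs - cfg.freeze_epochs, 0),
                        freeze_epochs=0)
    if joint_cfg.max_epochs > 0:
        ck = train_cox(model, hazard_fn, data.surv, tr, va, joint_cfg)
    else:
        ck = Checkpoint(arrays=model.state_arrays(), best_epoch=-1,
                        best_val=_val_cox(hazard_fn, data.surv, np.asarray(va)))
    ck.history = history + ck.history
    return model, ck


def _test_c(hazards: np.ndarray, surv: SurvivalData, idx: np.ndarray) -> float:
    return concordance_index(hazards[idx], surv.subset(idx))


def run_regime(regime: str, data, cfg: TrainConfig | None = None,
               model_cfg: ModelConfig | None = None) -> dict:
    """Run one full pretraining regime on a prepared cohort.

    ``data`` is a :class:`CohortData` (or a list of them for ``transfer``).
    Returns a dict with trained models, hazards over the full cohort, and
    held-out test concordance.
    """
    model_cfg = model_cfg or ModelConfig()
    cfg = cfg or TrainConfig.for_regime(regime)
    if regime in ("uni_self", "uni_cross"):
        expr_net, _ = train_unimodal_omics(data, "expression", regime, cfg, model_cfg)
        meth_net, _ = train_unimodal_omics(data, "methylation", regime, cfg, model_cfg)
        wsg_cfg = replace(cfg, batch_size=4, accumulation_steps=4)
        wsg_net, _ = train_unimodal_wsg(data, regime, wsg_cfg, model_cfg)
        out = {"expr_net": expr_net, "meth_net": meth_net, "wsg_net": wsg_net}
        out["test_c"] = {
            "expression": _test_c(_omics_hazards(expr_net, data.X_expr), data.surv, data.splits.test),
            "methylation": _test_c(_omics_hazards(meth_net, data.X_meth), data.surv, data.splits.test),
            "wsg": _test_c(_wsg_hazards(wsg_net, data.wsgs), data.surv, data.splits.test),
        }
        return out
    if regime in ("multi_self", "multi_cross"):
        uni_regime = "uni_self" if regime == "multi_self" else "uni_cross"
        uni_cfg = TrainConfig.for_regime(uni_regime, seed=cfg.seed,
                                         max_epochs=cfg.max_epochs,
                                         vae_epochs=cfg.vae_epochs,
                                         vae_checkpoint_every=cfg.vae_checkpoint_every,
                                         dgi_epochs=cfg.dgi_epochs)
        uni = run_regime(uni_regime, data, uni_cfg, model_cfg)
        model, ck = train_multimodal(data, uni["expr_net"], uni["meth_net"],
                                     uni["wsg_net"], cfg, model_cfg)
        hz = model.hazards(data.X_expr, data.X_meth, data.wsgs).data
        return {"model": model, "checkpoint": ck, "unimodal": uni,
                "hazards": hz, "test_c": _test_c(hz, data.surv, data.splits.test)}
    if regime == "transfer":
        return _run_transfer(list(data), cfg, model_cfg)
    raise ValueError(f"unknown regime {regime!r}")


def _omics_hazards(net, X) -> np.ndarray:
    return net(Tensor(X))[0].data.ravel()


def _wsg_hazards(net, wsgs) -> np.ndarray:
    return np.array([float(net(w)[0].data.ravel()[0]) for w in wsgs])


def _pool_cohorts(cohorts: list[CohortData]) -> CohortData:
    """Concatenate prepared sub-cohorts (identical feature spaces required)."""
    off = np.cumsum([0] + [len(c.surv) for c in cohorts[:-1]])
    surv = SurvivalData(np.concatenate([c.surv.time for c in cohorts]),
                        np.concatenate([c.surv.event for c in cohorts]))
    splits = SplitPlan(
        train=np.concatenate([c.splits.train + o for c, o in zip(cohorts, off)]),
        val=np.concatenate([c.splits.val + o for c, o in zip(cohorts, off)]),
        test=np.concatenate([c.splits.test + o for c, o in zip(cohorts, off)]),
        parity_p={}, seed=cohorts[0].splits.seed)
    return CohortData(
        cohort=None, splits=splits,
        X_expr=np.vstack([c.X_expr for c in cohorts]),
        X_meth=np.vstack([c.X_meth for c in cohorts]),
        wsgs=[w for c in cohorts for w in c.wsgs], surv=surv,
        expr_complement=np.vstack([c.expr_complement for c in cohorts]),
        meth_complement=np.vstack([c.meth_complement for c in cohorts]),
        expr_mask=cohorts[0].expr_mask, meth_mask=cohorts[0].meth_mask)


def _run_transfer(cohorts: list[CohortData], cfg: TrainConfig,
                  model_cfg: ModelConfig) -> dict:
    """Pan-cohort pretraining followed by per-cohort finetuning."""
    pooled = _pool_cohorts(cohorts)
    uni_cfg = TrainConfig.for_regime("uni_cross", seed=cfg.seed,
                                     max_epochs=cfg.max_epochs,
                                     dgi_epochs=cfg.dgi_epochs)
    expr_net, _ = train_unimodal_omics(pooled, "expression", "uni_cross", uni_cfg, model_cfg)
    meth_net, _ = train_unimodal_omics(pooled, "methylation", "uni_cross", uni_cfg, model_cfg)
    wsg_cfg = replace(uni_cfg, batch_size=4, accumulation_steps=4)
    wsg_net, _ = train_unimodal_wsg(pooled, "uni_cross", wsg_cfg, model_cfg)
    pre_cfg = replace(cfg, max_epochs=cfg.transfer_pretrain_epochs,
                      freeze_epochs=min(cfg.freeze_epochs, cfg.transfer_pretrain_epochs))
    model, _ = train_multimodal(pooled, expr_net, meth_net, wsg_net, pre_cfg, model_cfg)
    pretrained = model.state_arrays()
    results = []
    for c in cohorts:
        model.load_arrays(pretrained)
        ft_cfg = replace(cfg, learning_rate=cfg.transfer_finetune_lr,
                         max_epochs=cfg.transfer_finetune_epochs, freeze_epochs=0)

        def hazard_fn(idx, c=c):
            return model.hazards(c.X_expr, c.X_meth, c.wsgs, idx)

        ck = train_cox(model, hazard_fn, c.surv, c.splits.train, c.splits.val, ft_cfg)
        hz = model.hazards(c.X_expr, c.X_meth, c.wsgs).data
        results.append({"hazards": hz, "checkpoint": ck,
                        "test_c": _test_c(hz, c.surv, c.splits.test),
                        "state": model.state_arrays()})
    return {"model": model, "per_cohort": results,
            "test_c": [r["test_c"] for r in results]}
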