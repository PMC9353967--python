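"""Pretraining on auxiliary interaction tasks and transfer into the DTA model.

The procedure has three phases:

1. *Pretrain*: a siamese encoder (shared weights on both branches) is trained
   on CCI or PPI pairs through a concatenation + classifier head with binary
   cross-entropy; the encoder parameters at the best validation loss are kept.
2. *Transfer*: those parameters initialise the matching encoder of the DTA
   model (the regression head is always freshly initialised).  Encoders can
   alternatively start from scratch — the baseline arm of the pretrained-vs-
   scratch comparisons — and transferred encoders are fine-tuned by default
   or frozen on request.
3. *Fine-tune*: the assembled model minimises MSE on the DTA training split
   with Adam, selects the epoch by validation loss, and reports test RMSE /
   Pearson / Spearman / concordance index.

Batches encode each distinct entity once and scatter gradients back through
the pair structure, so an epoch costs one encoder pass per unique molecule
or protein rather than one per pair.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .chem_graph import AtomFeatureConfig, smiles_to_graph
from .data_io import PairDataset
from .encoders import (
    EncoderState,
    FlatGraphBatch,
    GinEncoder,
    GinEncoderConfig,
    KmerLookupProvider,
    SequenceEncoder,
    SequenceEncoderConfig,
)
from .interaction_heads import (
    AffinityHead,
    InteractionClassifier,
    PairHeadConfig,
    bce_loss,
    mse_loss,
)
from .nn import Adam
from .splits_metrics import SplitManifest, cold_split, regression_report

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "pretrain_encoder",
    "assemble_dta_model",
    "train_dta",
    "DTAModel",
    "DrugGraphCache",
    "ProteinCountCache",
    "transfer_experiment",
    "ExperimentSettings",
]

ENCODER_MODES = ("from_scratch", "transfer_frozen", "transfer_finetune")


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation recipe for one training phase.

    ``learning_rate`` defaults inside the reference tuning range
    [0.0005, 0.005]; ``batch_size`` of None means full-batch.  ``patience``
    (epochs without validation improvement) enables early stopping; None
    trains the full budget, with the best-validation epoch still selected.
    ``encoder_mode`` governs transferred encoders during DTA fine-tuning.
    """

    learning_rate: float = 0.003
    batch_size: int | None = 256
    epochs: int = 500
    seed: int = 0
    patience: int | None = None
    encoder_mode: str = "transfer_finetune"
    val_fraction: float = 0.1
    deterministic: bool = True
    #: transferred encoders fine-tune at learning_rate * this factor; the
    #: usual transfer recipe protects pretrained features from the large
    #: early gradients of the freshly initialised head
    transfer_lr_scale: float = 0.1
    #: epochs during which transferred encoders stay frozen before
    #: fine-tuning begins (gradual unfreezing)
    transfer_warmup_epochs: int = 0
    #: evaluate the validation loss every N epochs (patience counts
    #: evaluations); 1 = every epoch
    val_every: int = 1

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.encoder_mode not in ENCODER_MODES:
            raise ValueError(
                f"encoder_mode must be one of {ENCODER_MODES}, "
                f"got {self.encoder_mode!r}"
            )


# ---------------------------------------------------------------------------
# entity featurisation caches


class DrugGraphCache:
    """Parsed molecular graphs for a set of chemicals, indexable by id.

    Training consumes flattened (padding-free) sub-batches of the cached
    graphs; each distinct entity is parsed and featurised exactly once.
    """

    def __init__(
        self,
        chemicals: dict[str, str],
        feature_config: AtomFeatureConfig | None = None,
    ) -> None:
        self.ids = list(chemicals)
        self.index = {cid: i for i, cid in enumerate(self.ids)}
        self.graphs = [
            smiles_to_graph(chemicals[cid], feature_config) for cid in self.ids
        ]

    def rows(self, entity_ids) -> np.ndarray:
        return np.asarray([self.index[e] for e in entity_ids], dtype=np.intp)

    def flat_batch(self, rows: np.ndarray) -> FlatGraphBatch:
        return FlatGraphBatch([self.graphs[i] for i in rows])


class TokenCountCache:
    """Token-count matrix for a set of sequences under one provider.

    Works for protein sequences and for SMILES strings alike — whatever the
    provider's tokenizer covers.
    """

    def __init__(self, sequences: dict[str, str], provider: KmerLookupProvider):
        self.ids = list(sequences)
        self.index = {sid: i for i, sid in enumerate(self.ids)}
        self.counts = np.stack(
            [provider.token_counts(sequences[sid]) for sid in self.ids]
        )

    def rows(self, entity_ids) -> np.ndarray:
        return np.asarray([self.index[e] for e in entity_ids], dtype=np.intp)


#: backwards-friendly alias: the common case is a protein cache
ProteinCountCache = TokenCountCache


def _encode_unique(encoder, cache, entity_rows: np.ndarray):
    """Encode each distinct entity once; return per-row encodings + closure.

    The returned ``backward(g_rows)`` scatter-adds per-row output gradients
    onto the unique encodings and backpropagates through the encoder.
    """
    uniq, inv = np.unique(entity_rows, return_inverse=True)
    if isinstance(encoder, GinEncoder):
        out_u, enc_cache = encoder.forward_flat(cache.flat_batch(uniq))
        backprop = encoder.backward_flat
    else:
        out_u, enc_cache = encoder.forward_counts(cache.counts[uniq])
        backprop = encoder.backward
    out = out_u[inv]

    def backward(g_rows: np.ndarray) -> None:
        g_u = np.zeros_like(out_u)
        np.add.at(g_u, inv, g_rows)
        backprop(enc_cache, g_u)

    return out, backward


# ---------------------------------------------------------------------------
# pretraining


def _entity_cache_for(encoder, dataset: PairDataset, provider):
    if isinstance(encoder, GinEncoder):
        if dataset.task != "cci":
            raise ValueError(
                f"a graph encoder pretrains on chemicals (cci), got a "
                f"{dataset.task!r} dataset"
            )
        feat_cfg = AtomFeatureConfig()
        if encoder.config.node_feature_dim != feat_cfg.feature_length:
            raise ValueError(
                "encoder node_feature_dim does not match the atom featuriser"
            )
        return DrugGraphCache(dataset.drugs)
    # sequence encoder: chemicals for cci (SMILES tokens), proteins for ppi
    provider = provider or getattr(encoder, "provider", None)
    if provider is None:
        raise ValueError("sequence pretraining requires a token provider")
    store = dataset.drugs if dataset.task == "cci" else dataset.proteins
    return TokenCountCache(store, provider)


def pretrain_encoder(
    dataset: PairDataset,
    encoder_factory,
    config: TrainConfig,
    provider: KmerLookupProvider | None = None,
    head_config: PairHeadConfig | None = None,
) -> tuple[EncoderState, pd.DataFrame]:
    """Train a siamese encoder on CCI or PPI pairs; return best state + log.

    ``encoder_factory(rng)`` builds the encoder; the classifier head is
    created here (input width = encoder output) unless ``head_config``
    overrides it.  Both pair branches share the one encoder.  Returns the
    parameters at the best validation BCE and a per-epoch log (epoch,
    train_loss, val_loss, val_auc).
    """
    if dataset.task not in ("cci", "ppi"):
        raise ValueError("pretraining expects a cci or ppi dataset")
    if len(dataset) == 0:
        raise ValueError("empty pretraining dataset")
    rng = np.random.default_rng(config.seed)
    encoder = encoder_factory(rng)
    head_config = head_config or PairHeadConfig(
        input_dim=encoder.output_dim, task=dataset.task, hidden_dim=256
    )
    if head_config.input_dim != encoder.output_dim:
        raise ValueError("head input_dim must equal the encoder output width")
    head = InteractionClassifier(head_config, rng)
    cache = _entity_cache_for(encoder, dataset, provider)

    table = dataset.table
    left = cache.rows(table["left_id"])
    right = cache.rows(table["right_id"])
    labels = table["label"].to_numpy(dtype=float)

    n = len(table)
    order = rng.permutation(n)
    n_val = max(1, int(round(config.val_fraction * n))) if n > 1 else 0
    val_idx, train_idx = order[:n_val], order[n_val:]
    if len(train_idx) == 0:
        raise ValueError("no training pairs left after validation split")

    opt_enc = Adam(encoder, lr=config.learning_rate)
    opt_head = Adam(head, lr=config.learning_rate)
    batch = config.batch_size or len(train_idx)

    def predict(idx: np.ndarray) -> np.ndarray:
        out = np.empty(len(idx))
        for s in range(0, len(idx), 4096):
            sl = idx[s : s + 4096]
            el, _ = _encode_unique(encoder, cache, left[sl])
            er, _ = _encode_unique(encoder, cache, right[sl])
            p, _ = head.forward(np.concatenate([el, er], axis=1))
            out[s : s + 4096] = p
        return out

    best = {
        "val_loss": np.inf,
        "epoch": 0,
        "params": encoder.export_params(),
        "head": head.export_params(),
    }
    rows = []
    stale = 0
    for epoch in range(1, config.epochs + 1):
        perm = rng.permutation(len(train_idx))
        epoch_losses = []
        for s in range(0, len(perm), batch):
            sl = train_idx[perm[s : s + batch]]
            encoder.zero_grad()
            head.zero_grad()
            el, back_l = _encode_unique(encoder, cache, left[sl])
            er, back_r = _encode_unique(encoder, cache, right[sl])
            joint = np.concatenate([el, er], axis=1)
            p, head_cache = head.forward(joint)
            y = labels[sl]
            epoch_losses.append(bce_loss(p, y))
            g_joint = head.backward_bce(head_cache, y)
            d = encoder.output_dim
            back_l(g_joint[:, :d])
            back_r(g_joint[:, d:])
            opt_enc.step()
            opt_head.step()
        if n_val:
            pv = predict(val_idx)
            yv = labels[val_idx]
            val_loss = bce_loss(pv, yv)
            val_auc = (
                float(roc_auc_score(yv, pv)) if len(np.unique(yv)) > 1 else np.nan
            )
        else:
            val_loss, val_auc = np.nan, np.nan
        rows.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(epoch_losses)),
                "val_loss": val_loss,
                "val_auc": val_auc,
            }
        )
        if not n_val or val_loss < best["val_loss"]:
            best = {
                "val_loss": val_loss,
                "epoch": epoch,
                "params": encoder.export_params(),
                "head": head.export_params(),
            }
            stale = 0
        else:
            stale += 1
            if config.patience is not None and stale > config.patience:
                logger.info("early stop at epoch %d", epoch)
                break

    encoder.load_params(best["params"])
    log = pd.DataFrame(
        rows, columns=["epoch", "train_loss", "val_loss", "val_auc"]
    )
    state = EncoderState.from_encoder(
        encoder,
        meta={
            "task": dataset.task,
            "best_epoch": int(best["epoch"]),
            "epochs_run": len(rows),
            "seed": config.seed,
        },
    )
    return state, log


# ---------------------------------------------------------------------------
# DTA model assembly and fine-tuning


class DTAModel:
    """Drug encoder + protein encoder + affinity head, with freeze flags.

    The joint representation is [x_protein; x_drug] (protein first), fed to
    the two-affine regression head.
    """

    def __init__(
        self,
        drug_encoder: GinEncoder | SequenceEncoder,
        protein_encoder: SequenceEncoder,
        head: AffinityHead,
        encoder_mode: str = "transfer_finetune",
        transferred: tuple[bool, bool] = (False, False),
    ) -> None:
        self.drug_encoder = drug_encoder
        self.protein_encoder = protein_encoder
        self.head = head
        self.encoder_mode = encoder_mode
        self.transferred = transferred  # (drug, protein)

    def frozen(self, which: str) -> bool:
        idx = 0 if which == "drug" else 1
        return self.encoder_mode == "transfer_frozen" and self.transferred[idx]

    def modules(self):
        return {
            "drug": self.drug_encoder,
            "protein": self.protein_encoder,
            "head": self.head,
        }

    def snapshot(self) -> dict:
        return {k: m.export_params() for k, m in self.modules().items()}

    def restore(self, snap: dict) -> None:
        for k, m in self.modules().items():
            m.load_params(snap[k])

    def predict(
        self, drug_cache, prot_cache, drug_rows, prot_rows, chunk: int = 8192
    ) -> np.ndarray:
        out = np.empty(len(drug_rows))
        for s in range(0, len(drug_rows), chunk):
            xd, _ = _encode_unique(
                self.drug_encoder, drug_cache, drug_rows[s : s + chunk]
            )
            xp, _ = _encode_unique(
                self.protein_encoder, prot_cache, prot_rows[s : s + chunk]
            )
            y, _ = self.head.forward(np.concatenate([xp, xd], axis=1))
            out[s : s + chunk] = y
        return out


def assemble_dta_model(
    drug_state: EncoderState | None,
    protein_state: EncoderState | None,
    *,
    gin_config: GinEncoderConfig | None = None,
    seq_config: SequenceEncoderConfig | None = None,
    head_config: PairHeadConfig | None = None,
    provider: KmerLookupProvider | None = None,
    drug_kind: str = "gin",
    drug_provider: KmerLookupProvider | None = None,
    drug_seq_config: SequenceEncoderConfig | None = None,
    seed: int = 0,
    encoder_mode: str = "transfer_finetune",
) -> DTAModel:
    """Build the affinity model, loading pretrained encoder states if given.

    A ``None`` state leaves that encoder freshly initialised from the seed
    (the from-scratch baseline).  A provided state must match the target
    architecture fingerprint, otherwise assembly refuses and names the
    diverging fields.  The regression head is always fresh.  The drug branch
    is a graph encoder by default; ``drug_kind="sequence"`` uses a SMILES
    token-embedding encoder instead (with ``drug_provider``), completing the
    {graph, sequence} x {pretrained, scratch} grid.
    """
    if encoder_mode not in ENCODER_MODES:
        raise ValueError(f"unknown encoder_mode {encoder_mode!r}")
    rng = np.random.default_rng(seed)
    gin_config = gin_config or GinEncoderConfig()
    seq_config = seq_config or SequenceEncoderConfig()
    if provider is None:
        raise ValueError("a protein token-embedding provider is required")

    if drug_kind == "gin":
        drug_encoder = GinEncoder(gin_config, rng)
    elif drug_kind == "sequence":
        if drug_provider is None:
            raise ValueError("drug_kind='sequence' requires drug_provider")
        drug_encoder = SequenceEncoder(
            drug_seq_config or seq_config, drug_provider, rng
        )
    else:
        raise ValueError(f"unknown drug_kind {drug_kind!r}")
    protein_encoder = SequenceEncoder(seq_config, provider, rng)
    if drug_state is not None:
        drug_state.apply_to(drug_encoder)
    if protein_state is not None:
        protein_state.apply_to(protein_encoder)

    head_config = head_config or PairHeadConfig(
        input_dim=drug_encoder.output_dim, task="dta"
    )
    if head_config.input_dim != drug_encoder.output_dim or (
        drug_encoder.output_dim != protein_encoder.output_dim
    ):
        raise ValueError(
            "head input_dim and both encoder output widths must agree "
            f"(head {head_config.input_dim}, drug {drug_encoder.output_dim}, "
            f"protein {protein_encoder.output_dim})"
        )
    head = AffinityHead(head_config, rng)
    return DTAModel(
        drug_encoder,
        protein_encoder,
        head,
        encoder_mode=encoder_mode,
        transferred=(drug_state is not None, protein_state is not None),
    )


def train_dta(
    model: DTAModel,
    manifest: SplitManifest,
    dataset: PairDataset,
    config: TrainConfig,
    replicate_seeds: tuple[int, ...] | None = None,
) -> dict:
    """Fine-tune the DTA model on the manifest's train split.

    Minimises MSE with Adam, selects the best-validation epoch, and returns
    ``{"metrics": test metrics, "log": per-epoch DataFrame, "best_epoch"}``.
    With ``replicate_seeds`` the whole fit is repeated from fresh snapshots
    per seed and the report carries per-run metrics plus mean and sd
    (the value-(sd) convention of the reference tables).
    """
    if dataset.task != "dta":
        raise ValueError("train_dta expects a dta dataset")
    if replicate_seeds is not None:
        init = model.snapshot()
        runs = []
        for s in replicate_seeds:
            model.restore(init)
            runs.append(
                train_dta(model, manifest, dataset, replace(config, seed=s))
            )
        frame = pd.DataFrame([r["metrics"] for r in runs])
        return {
            "runs": runs,
            "per_seed": frame,
            "mean": frame.mean().to_dict(),
            "sd": frame.std(ddof=1).to_dict(),
        }

    rng = np.random.default_rng(config.seed)
    if isinstance(model.drug_encoder, GinEncoder):
        drug_cache = DrugGraphCache(dataset.drugs)
    else:
        drug_cache = TokenCountCache(dataset.drugs, model.drug_encoder.provider)
    prot_cache = TokenCountCache(dataset.proteins, model.protein_encoder.provider)
    table = dataset.table
    d_rows = drug_cache.rows(table["left_id"])
    p_rows = prot_cache.rows(table["right_id"])
    labels = table["label"].to_numpy(dtype=float)

    tr = manifest.indices("train")
    va = manifest.indices("valid")
    te = manifest.indices("test")
    if len(tr) == 0:
        raise ValueError("empty train split")

    transferred = {"drug": model.transferred[0], "protein": model.transferred[1]}
    opts = {}
    for name, mod in model.modules().items():
        if name in ("drug", "protein") and model.frozen(name):
            continue
        lr = config.learning_rate
        if transferred.get(name) and model.encoder_mode == "transfer_finetune":
            lr *= config.transfer_lr_scale
        opts[name] = Adam(mod, lr=lr)
    batch = config.batch_size or len(tr)
    d_out = model.drug_encoder.output_dim

    def encoder_active(name: str, epoch: int) -> bool:
        if model.frozen(name):
            return False
        if transferred.get(name) and epoch <= config.transfer_warmup_epochs:
            return False
        return True

    best = {"val_loss": np.inf, "epoch": 0, "snap": model.snapshot()}
    rows = []
    stale = 0
    for epoch in range(1, config.epochs + 1):
        perm = rng.permutation(len(tr))
        losses = []
        for s in range(0, len(perm), batch):
            sl = tr[perm[s : s + batch]]
            for m in model.modules().values():
                m.zero_grad()
            xd, back_d = _encode_unique(model.drug_encoder, drug_cache, d_rows[sl])
            xp, back_p = _encode_unique(model.protein_encoder, prot_cache, p_rows[sl])
            joint = np.concatenate([xp, xd], axis=1)
            pred, head_cache = model.head.forward(joint)
            y = labels[sl]
            losses.append(mse_loss(pred, y))
            g_pred = 2.0 * (pred - y) / len(y)
            g_joint = model.head.backward(head_cache, g_pred)
            p_dim = model.protein_encoder.output_dim
            if encoder_active("protein", epoch):
                back_p(g_joint[:, :p_dim])
            if encoder_active("drug", epoch):
                back_d(g_joint[:, p_dim : p_dim + d_out])
            for name, opt in opts.items():
                if name in ("drug", "protein") and not encoder_active(name, epoch):
                    continue
                opt.step()
        evaluate_now = (
            epoch % config.val_every == 0 or epoch == config.epochs
        )
        val_loss = np.nan
        if evaluate_now and len(va):
            val_pred = model.predict(drug_cache, prot_cache, d_rows[va], p_rows[va])
            val_loss = mse_loss(val_pred, labels[va])
        rows.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(losses)),
                "val_loss": val_loss,
            }
        )
        if not evaluate_now:
            continue
        if not len(va) or val_loss < best["val_loss"]:
            best = {"val_loss": val_loss, "epoch": epoch, "snap": model.snapshot()}
            stale = 0
        else:
            stale += 1
            if config.patience is not None and stale > config.patience:
                logger.info("early stop at epoch %d", epoch)
                break

    model.restore(best["snap"])
    test_pred = model.predict(drug_cache, prot_cache, d_rows[te], p_rows[te])
    metrics = regression_report(test_pred, labels[te])
    return {
        "metrics": metrics,
        "log": pd.DataFrame(rows, columns=["epoch", "train_loss", "val_loss"]),
        "best_epoch": int(best["epoch"]),
        "test_predictions": test_pred,
        "test_indices": te,
    }


# ---------------------------------------------------------------------------
# the pretrained-vs-scratch transfer experiment


@dataclass(frozen=True)
class ExperimentSettings:
    """Desk-scale model and optimisation sizes for the transfer experiment.

    Encoder widths are reduced from the reference architecture (which keeps
    d' = 128 for real corpora) so that the full factorial — three regimes x
    {scratch, drug-pretrained, protein-pretrained} x replicate seeds — runs
    in minutes on one CPU.  Depth (5 GIN layers) and every structural choice
    are unchanged; only widths and epoch budgets shrink.
    """

    n_cci: int = 2000
    n_ppi: int = 2000
    n_dta: int = 3000
    #: drug branch: "sequence" (k-mer SMILES encoder, the desk-scale
    #: language-model stand-in) or "gin" (graph encoder)
    drug_encoder_kind: str = "sequence"
    gin_hidden: int = 24
    readout_hidden: int = 48
    output_dim: int = 8
    embed_dim: int = 32
    head_hidden: int = 64
    motif_k: int = 3
    smiles_k: int = 3
    vocab_min_sequences: int = 20
    pretrain_epochs: int = 250
    pretrain_patience: int | None = 40
    pretrain_batch: int | None = 64
    pretrain_lr: float = 0.002
    dta_epochs: int = 200
    dta_patience: int | None = 35
    dta_batch: int | None = 64
    learning_rate: float = 0.001
    transfer_lr_scale: float = 0.1
    transfer_warmup_epochs: int = 15
    cci_channel: str | None = None   # e.g. "experimental" for the ablation
    share_pretraining: bool = True   # one pretraining reused across seeds


def transfer_experiment(
    world_config=None,
    seeds: tuple[int, ...] = tuple(range(10)),
    regimes: tuple[str, ...] = ("cold_drug", "cold_target", "warm"),
    settings: ExperimentSettings | None = None,
) -> pd.DataFrame:
    """Run the pretrained-vs-scratch factorial on one synthetic world.

    For each replicate seed: pretrain the drug encoder on CCI and the
    protein encoder on PPI, then for each regime fit three DTA models from
    identical initialisation — both encoders from scratch, drug encoder
    transferred, protein encoder transferred — on a split drawn with that
    seed.  Returns a tidy frame (seed, regime, arm, rmse, pearson,
    spearman, ci, best_epoch).
    """
    from .synthetic_data import (
        SyntheticWorldConfig,
        generate_world,
        sample_dta_pairs,
        sample_interaction_pairs,
    )

    st = settings or ExperimentSettings()
    wc = world_config or SyntheticWorldConfig()
    world = generate_world(wc)
    cci = sample_interaction_pairs(world, "cci", st.n_cci, seed=101)
    if st.cci_channel is not None:
        cci = cci.filter_channel(st.cci_channel)
    ppi = sample_interaction_pairs(world, "ppi", st.n_ppi, seed=102)
    dta = sample_dta_pairs(world, st.n_dta, seed=103)

    gin_cfg = GinEncoderConfig(
        hidden_dim=st.gin_hidden,
        readout_hidden=st.readout_hidden,
        output_dim=st.output_dim,
    )
    seq_cfg = SequenceEncoderConfig(
        embedding_dim=st.embed_dim, output_dim=st.output_dim
    )
    head_cfg = PairHeadConfig(
        input_dim=st.output_dim, task="dta", hidden_dim=st.head_hidden
    )
    prot_provider_master = KmerLookupProvider.fit(
        world.proteins.values(),
        st.embed_dim,
        k=st.motif_k,
        min_sequences=st.vocab_min_sequences,
        drop_unknown=True,
    )
    if st.drug_encoder_kind == "sequence":
        drug_provider_master = KmerLookupProvider.fit(
            world.chemicals.values(),
            st.embed_dim,
            k=st.smiles_k,
            min_sequences=st.vocab_min_sequences,
            drop_unknown=True,
        )
    elif st.drug_encoder_kind == "gin":
        drug_provider_master = None
    else:
        raise ValueError(f"unknown drug_encoder_kind {st.drug_encoder_kind!r}")

    def pretrain_states(seed: int):
        pre_cfg = TrainConfig(
            learning_rate=st.pretrain_lr,
            batch_size=st.pretrain_batch,
            epochs=st.pretrain_epochs,
            patience=st.pretrain_patience,
            seed=seed,
        )
        if st.drug_encoder_kind == "gin":
            dstate, _ = pretrain_encoder(
                cci, lambda rng: GinEncoder(gin_cfg, rng), pre_cfg
            )
        else:
            dprov = copy.deepcopy(drug_provider_master)
            dstate, _ = pretrain_encoder(
                cci,
                lambda rng: SequenceEncoder(seq_cfg, dprov, rng),
                pre_cfg,
                provider=dprov,
            )
        prot_provider = copy.deepcopy(prot_provider_master)
        pstate, _ = pretrain_encoder(
            ppi,
            lambda rng: SequenceEncoder(seq_cfg, prot_provider, rng),
            pre_cfg,
            provider=prot_provider,
        )
        return dstate, pstate

    # matched arms (the factorial rows of the reference tables):
    #   scratch            — both encoders fresh
    #   protein_pretrained — fresh drug, PPI-pretrained protein
    #   both_pretrained    — CCI-pretrained drug, PPI-pretrained protein
    # drug-encoder effect  = both_pretrained vs protein_pretrained (matched
    # protein branch); protein-encoder effect = protein_pretrained vs
    # scratch (matched drug branch).
    arm_states = lambda d, p: {
        "scratch": (None, None),
        "protein_pretrained": (None, p),
        "both_pretrained": (d, p),
    }
    needed = {
        "cold_drug": ("protein_pretrained", "both_pretrained"),
        "cold_target": ("scratch", "protein_pretrained"),
        "warm": ("scratch", "protein_pretrained", "both_pretrained"),
    }

    shared = pretrain_states(seeds[0]) if st.share_pretraining else None
    rows = []
    for seed in seeds:
        drug_state, prot_state = shared if shared else pretrain_states(seed)
        dta_cfg = TrainConfig(
            learning_rate=st.learning_rate,
            batch_size=st.dta_batch,
            epochs=st.dta_epochs,
            patience=st.dta_patience,
            seed=seed,
            transfer_lr_scale=st.transfer_lr_scale,
            transfer_warmup_epochs=st.transfer_warmup_epochs,
            val_every=2,
        )
        states = arm_states(drug_state, prot_state)
        for regime in regimes:
            manifest = cold_split(dta, regime, seed=seed)
            for arm in needed.get(regime, ()):
                dstate, pstate = states[arm]
                model = assemble_dta_model(
                    dstate,
                    pstate,
                    gin_config=gin_cfg,
                    seq_config=seq_cfg,
                    head_config=head_cfg,
                    provider=copy.deepcopy(prot_provider_master),
                    drug_kind=st.drug_encoder_kind,
                    drug_provider=copy.deepcopy(drug_provider_master)
                    if drug_provider_master is not None
                    else None,
                    seed=seed,
                )
                result = train_dta(model, manifest, dta, dta_cfg)
                rows.append(
                    {
                        "seed": seed,
                        "regime": regime,
                        "arm": arm,
                        **result["metrics"],
                        "best_epoch": result["best_epoch"],
                    }
                )
                logger.info(
                    "seed %s %s %s: rmse %.3f",
                    seed,
                    regime,
                    arm,
                    result["metrics"]["rmse"],
                )
    return pd.DataFrame(rows)


#: (regime, treated arm, baseline arm) for each matched comparison
_COMPARISONS = (
    ("cold_drug", "drug", "both_pretrained", "protein_pretrained"),
    ("warm", "drug", "both_pretrained", "protein_pretrained"),
    ("cold_target", "protein", "protein_pretrained", "scratch"),
    ("warm", "protein", "protein_pretrained", "scratch"),
)


def summarize_transfer(frame: pd.DataFrame) -> dict:
    """Win counts and seed-mean RMSE gaps of the matched comparisons.

    A positive gap means the pretrained arm had lower RMSE than its matched
    baseline for that seed.
    """
    out: dict = {}
    piv = frame.pivot_table(
        index=["seed", "regime"], columns="arm", values="rmse"
    )
    regimes = set(frame["regime"])
    for regime, effect, treated, baseline in _COMPARISONS:
        if regime not in regimes:
            continue
        sub = piv.xs(regime, level="regime")
        if treated not in sub.columns or baseline not in sub.columns:
            continue
        diff = sub[baseline] - sub[treated]       # >0: pretraining wins
        key = f"{regime}.{effect}_effect"
        out[f"{key}.wins"] = int((diff > 0).sum())
        out[f"{key}.n_seeds"] = int(diff.notna().sum())
        out[f"{key}.gap_mean"] = float(diff.mean())
        out[f"{key}.pretrained_rmse_mean"] = float(sub[treated].mean())
        out[f"{key}.baseline_rmse_mean"] = float(sub[baseline].mean())
    return out
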