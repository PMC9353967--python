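"""Pretraining loop mechanics, transfer fidelity, and DTA fine-tuning."""

import copy

import numpy as np
import pytest

from dta_transfer.encoders import (
    EncoderState,
    FingerprintMismatchError,
    GinEncoder,
    GinEncoderConfig,
    KmerLookupProvider,
    SequenceEncoder,
    SequenceEncoderConfig,
)
from dta_transfer.interaction_heads import PairHeadConfig
from dta_transfer.pretrain_transfer import (
    TrainConfig,
    assemble_dta_model,
    pretrain_encoder,
    train_dta,
)
from dta_transfer.splits_metrics import cold_split
from dta_transfer.synthetic_data import (
    SyntheticWorldConfig,
    generate_world,
    sample_dta_pairs,
    sample_interaction_pairs,
)

GIN = GinEncoderConfig(num_layers=2, hidden_dim=8, readout_hidden=8, output_dim=4)
SEQ = SequenceEncoderConfig(embedding_dim=16, output_dim=4)
HEAD = PairHeadConfig(input_dim=4, task="dta", hidden_dim=16)


@pytest.fixture(scope="module")
def tiny_world():
    return generate_world(
        SyntheticWorldConfig(n_chemicals=25, n_proteins=20, seed=21)
    )


@pytest.fixture(scope="module")
def tiny_cci(tiny_world):
    return sample_interaction_pairs(tiny_world, "cci", 120, seed=1)


@pytest.fixture(scope="module")
def tiny_ppi(tiny_world):
    return sample_interaction_pairs(tiny_world, "ppi", 120, seed=2)


@pytest.fixture(scope="module")
def tiny_dta(tiny_world):
    return sample_dta_pairs(tiny_world, 200, seed=3)


def provider_for(world):
    return KmerLookupProvider.fit(world.proteins.values(), 16, k=3)


def test_zero_epochs_returns_initialization(tiny_cci):
    cfg = TrainConfig(epochs=0, seed=5, batch_size=32)
    state, log = pretrain_encoder(tiny_cci, lambda rng: GinEncoder(GIN, rng), cfg)
    fresh = GinEncoder(GIN, np.random.default_rng(5))
    for k, v in fresh.params.items():
        assert np.array_equal(state.params[k], v)
    assert len(log) == 0


def test_identical_seed_identical_training(tiny_cci):
    cfg = TrainConfig(epochs=3, seed=7, batch_size=32, learning_rate=1e-3)
    s1, l1 = pretrain_encoder(tiny_cci, lambda rng: GinEncoder(GIN, rng), cfg)
    s2, l2 = pretrain_encoder(tiny_cci, lambda rng: GinEncoder(GIN, rng), cfg)
    for k in s1.params:
        assert np.array_equal(s1.params[k], s2.params[k])
    assert l1.equals(l2)


def test_one_step_changes_encoder_parameters(tiny_cci):
    """Gradients reach the drug encoder through the siamese head — the
    premise of interaction pretraining."""
    cfg = TrainConfig(epochs=1, seed=3, batch_size=None, learning_rate=1e-2)
    state, _ = pretrain_encoder(tiny_cci, lambda rng: GinEncoder(GIN, rng), cfg)
    fresh = GinEncoder(GIN, np.random.default_rng(3))
    changed = [
        k for k, v in fresh.params.items()
        if not np.array_equal(state.params[k], v)
    ]
    assert changed  # at least some encoder parameters moved


def test_wrong_entity_type_rejected(tiny_ppi):
    cfg = TrainConfig(epochs=1, seed=0)
    with pytest.raises(ValueError, match="cci"):
        pretrain_encoder(tiny_ppi, lambda rng: GinEncoder(GIN, rng), cfg)


def test_sequence_encoder_pretrains_on_ppi(tiny_world, tiny_ppi):
    prov = provider_for(tiny_world)
    cfg = TrainConfig(epochs=2, seed=1, batch_size=32)
    state, log = pretrain_encoder(
        tiny_ppi, lambda rng: SequenceEncoder(SEQ, prov, rng), cfg, provider=prov
    )
    assert state.kind == "sequence"
    assert {"epoch", "train_loss", "val_loss", "val_auc"} <= set(log.columns)


def test_transfer_round_trip_bit_exact(tmp_path, tiny_cci, tiny_world):
    """Parameters leaving pretraining and entering assembly survive the
    checkpoint format unchanged."""
    cfg = TrainConfig(epochs=2, seed=2, batch_size=32)
    state, _ = pretrain_encoder(tiny_cci, lambda rng: GinEncoder(GIN, rng), cfg)
    path = tmp_path / "drug.npz"
    state.save(path)
    loaded = EncoderState.load(path)
    model = assemble_dta_model(
        loaded,
        None,
        gin_config=GIN,
        seq_config=SEQ,
        head_config=HEAD,
        provider=provider_for(tiny_world),
        seed=0,
    )
    for k, v in state.params.items():
        assert np.array_equal(model.drug_encoder.params[k], v)


def test_assemble_modes(tiny_world, tiny_cci):
    prov = provider_for(tiny_world)
    cfg = TrainConfig(epochs=1, seed=4, batch_size=32)
    state, _ = pretrain_encoder(tiny_cci, lambda rng: GinEncoder(GIN, rng), cfg)

    # pretrained drug encoder: parameters match checkpoint, head is fresh
    model = assemble_dta_model(
        state, None, gin_config=GIN, seq_config=SEQ, head_config=HEAD,
        provider=prov, seed=0,
    )
    assert model.transferred == (True, False)

    # no states: everything fresh from the seed
    scratch = assemble_dta_model(
        None, None, gin_config=GIN, seq_config=SEQ, head_config=HEAD,
        provider=prov, seed=0,
    )
    assert scratch.transferred == (False, False)
    assert any(
        not np.array_equal(model.drug_encoder.params[k], scratch.drug_encoder.params[k])
        for k in model.drug_encoder.params
    )

    # fingerprint mismatch refuses the checkpoint
    with pytest.raises(FingerprintMismatchError):
        assemble_dta_model(
            state, None,
            gin_config=GinEncoderConfig(
                num_layers=3, hidden_dim=8, readout_hidden=8, output_dim=4
            ),
            seq_config=SEQ, head_config=HEAD, provider=prov, seed=0,
        )


def test_frozen_vs_finetuned_encoders(tiny_world, tiny_cci, tiny_dta):
    prov = provider_for(tiny_world)
    cfgp = TrainConfig(epochs=1, seed=6, batch_size=32)
    state, _ = pretrain_encoder(tiny_cci, lambda rng: GinEncoder(GIN, rng), cfgp)
    manifest = cold_split(tiny_dta, "warm", seed=0)
    for mode, expect_changed in (("transfer_frozen", False), ("transfer_finetune", True)):
        model = assemble_dta_model(
            state, None, gin_config=GIN, seq_config=SEQ, head_config=HEAD,
            provider=copy.deepcopy(prov), seed=1, encoder_mode=mode,
        )
        before = {k: v.copy() for k, v in model.drug_encoder.params.items()}
        cfg = TrainConfig(
            epochs=2, seed=1, batch_size=64, encoder_mode=mode,
            transfer_lr_scale=1.0, learning_rate=1e-2,
        )
        train_dta(model, manifest, tiny_dta, cfg)
        changed = any(
            not np.array_equal(model.drug_encoder.params[k], before[k])
            for k in before
        )
        assert changed == expect_changed, mode


def test_constant_affinity_converges_to_constant(tiny_world):
    """Degenerate dataset: all affinities equal c. The model should predict
    (approximately) c, so test RMSE is close to the test labels' sd = 0."""
    import pandas as pd
    from dta_transfer.data_io import PairDataset

    rng = np.random.default_rng(0)
    cids = list(tiny_world.chemicals)
    pids = list(tiny_world.proteins)
    table = pd.DataFrame(
        {
            "left_id": rng.choice(cids, 200),
            "right_id": rng.choice(pids, 200),
            "label": np.full(200, 4.2),
        }
    )
    ds = PairDataset("dta", table, drugs=dict(tiny_world.chemicals),
                     proteins=dict(tiny_world.proteins))
    manifest = cold_split(ds, "warm", seed=1)
    model = assemble_dta_model(
        None, None, gin_config=GIN, seq_config=SEQ, head_config=HEAD,
        provider=provider_for(tiny_world), seed=2,
    )
    cfg = TrainConfig(epochs=200, seed=2, batch_size=None, learning_rate=1e-2,
                      patience=None)
    res = train_dta(model, manifest, ds, cfg)
    assert res["metrics"]["rmse"] < 0.1  # labels have zero spread


def test_replicate_reporting(tiny_world, tiny_dta):
    manifest = cold_split(tiny_dta, "warm", seed=2)
    model = assemble_dta_model(
        None, None, gin_config=GIN, seq_config=SEQ, head_config=HEAD,
        provider=provider_for(tiny_world), seed=3,
    )
    cfg = TrainConfig(epochs=2, seed=0, batch_size=64)
    report = train_dta(model, manifest, tiny_dta, cfg, replicate_seeds=(0, 1, 2))
    assert len(report["runs"]) == 3
    assert set(report["mean"]) == {"rmse", "pearson", "spearman", "ci"}
    assert set(report["sd"]) == {"rmse", "pearson", "spearman", "ci"}


def test_empty_train_split_rejected(tiny_world, tiny_dta):
    manifest = cold_split(tiny_dta, "warm", seed=3)
    manifest.record_indices["train"] = []
    model = assemble_dta_model(
        None, None, gin_config=GIN, seq_config=SEQ, head_config=HEAD,
        provider=provider_for(tiny_world), seed=0,
    )
    with pytest.raises(ValueError, match="empty train"):
        train_dta(model, manifest, tiny_dta, TrainConfig(epochs=1, seed=0))
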