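"""Cold-start splitting, leakage audits, and the four evaluation metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dta_transfer.data_io import PairDataset
from dta_transfer.splits_metrics import (
    REGIMES,
    SplitError,
    SplitManifest,
    UndefinedMetricError,
    audit_split,
    cold_split,
    concordance_index,
    pearson,
    rmse,
    spearman,
)


def make_dta(n_drugs, n_prots, n_records, seed):
    rng = np.random.default_rng(seed)
    drugs = {f"D{i}": "CC" for i in range(n_drugs)}
    prots = {f"P{j}": "ACDEFG" for j in range(n_prots)}
    table = pd.DataFrame(
        {
            "left_id": rng.choice(list(drugs), size=n_records),
            "right_id": rng.choice(list(prots), size=n_records),
            "label": rng.normal(size=n_records),
        }
    )
    return PairDataset("dta", table, drugs=drugs, proteins=prots)


def dense_dta(n_drugs, n_prots):
    drugs = {f"D{i}": "CC" for i in range(n_drugs)}
    prots = {f"P{j}": "ACDEFG" for j in range(n_prots)}
    rows = [
        {"left_id": d, "right_id": p, "label": float(i + j)}
        for i, d in enumerate(drugs)
        for j, p in enumerate(prots)
    ]
    return PairDataset("dta", pd.DataFrame(rows), drugs=drugs, proteins=prots)


# ---------------------------------------------------------------------------
# cold_split


def test_cold_drug_five_drugs_partition():
    ds = dense_dta(5, 4)
    man = cold_split(ds, "cold_drug", fractions=(0.6, 0.2, 0.2), seed=0)
    ents = man.entity_ids
    assert len(ents["train"]["drugs"]) == 3
    assert len(ents["valid"]["drugs"]) == 1
    assert len(ents["test"]["drugs"]) == 1
    assert not set(ents["train"]["drugs"]) & set(ents["test"]["drugs"])
    assert not set(ents["train"]["drugs"]) & set(ents["valid"]["drugs"])
    assert audit_split(man, ds)["ok"]


def test_warm_regime_on_dense_matrix_covers_entities():
    ds = dense_dta(8, 6)
    man = cold_split(ds, "warm", seed=3)
    rep = audit_split(man, ds)
    assert rep["ok"] and rep["warm_unseen_records"] == 0


def test_same_seed_reproduces_manifest():
    ds = make_dta(12, 9, 150, seed=5)
    m1 = cold_split(ds, "cold_target", seed=42)
    m2 = cold_split(ds, "cold_target", seed=42)
    assert m1.record_indices == m2.record_indices
    m3 = cold_split(ds, "cold_target", seed=43)
    assert m1.record_indices != m3.record_indices


def test_too_few_entities_is_an_explicit_error():
    ds = make_dta(2, 5, 30, seed=0)
    with pytest.raises(SplitError, match="2"):
        cold_split(ds, "cold_drug", seed=0)


def test_disjointness_audit_across_regimes_and_datasets():
    """Every regime's leakage predicate holds on 20 random datasets."""
    for seed in range(20):
        ds = make_dta(
            n_drugs=6 + seed % 5,
            n_prots=5 + seed % 4,
            n_records=120,
            seed=seed,
        )
        for regime in REGIMES:
            man = cold_split(ds, regime, seed=seed)
            rep = audit_split(man, ds)
            assert rep["covers_dataset"] and rep["records_disjoint"]
            assert rep["no_entity_leakage"], (regime, seed, rep)


def test_manifest_serialization_round_trip(tmp_path):
    ds = make_dta(10, 8, 100, seed=2)
    man = cold_split(ds, "cold_drug", seed=7)
    path = tmp_path / "manifest.json"
    man.save(path)
    loaded = SplitManifest.load(path)
    assert loaded.regime == man.regime
    assert loaded.seed == man.seed
    assert loaded.record_indices == man.record_indices
    assert audit_split(loaded, ds)["ok"]


def test_audit_detects_planted_leakage():
    ds = dense_dta(6, 4)
    man = cold_split(ds, "cold_drug", seed=1)
    # move one test record into train: its drug now leaks
    bad = man.record_indices["test"][0]
    man.record_indices["train"].append(bad)
    man.record_indices["test"] = man.record_indices["test"][1:]
    rep = audit_split(man, ds)
    assert not rep["ok"]


# ---------------------------------------------------------------------------
# metrics


def test_perfect_prediction_metrics():
    p = np.array([1.0, 2.0, 3.0])
    assert rmse(p, p) == 0.0
    assert pearson(p, p) == pytest.approx(1.0)
    assert spearman(p, p) == pytest.approx(1.0)
    assert concordance_index(p, p) == 1.0


def test_rmse_constant_offset():
    assert rmse([1.0, 1.0], [0.0, 0.0]) == 1.0


def test_spearman_single_swap():
    assert spearman([1.0, 3.0, 2.0], [1.0, 2.0, 3.0]) == pytest.approx(0.5)


def test_ci_single_swap_two_thirds():
    assert concordance_index([1.0, 3.0, 2.0], [1.0, 2.0, 3.0]) == pytest.approx(2 / 3)


def test_ci_reversed_is_zero():
    assert concordance_index([3.0, 2.0, 1.0], [1.0, 2.0, 3.0]) == 0.0


def test_degenerate_inputs_signal_undefined():
    with pytest.raises(UndefinedMetricError):
        pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
    with pytest.raises(UndefinedMetricError):
        spearman([1.0, 2.0], [5.0, 5.0])
    with pytest.raises(UndefinedMetricError):
        concordance_index([1.0, 2.0], [3.0, 3.0])


def brute_force_ci(pred, labels):
    """Independent O(n^2) double-loop enumeration with the tie convention."""
    num = den = 0.0
    n = len(pred)
    for i in range(n):
        for j in range(n):
            if labels[i] > labels[j]:
                den += 1
                if pred[i] > pred[j]:
                    num += 1
                elif pred[i] == pred[j]:
                    num += 0.5
    return num / den


def test_ci_agrees_with_brute_force_on_random_instances(rng):
    """200 random instances with ties, n <= 50."""
    for trial in range(200):
        n = int(rng.integers(2, 51))
        labels = rng.integers(0, 6, size=n).astype(float)  # heavy label ties
        pred = np.round(rng.normal(size=n), 1)             # predicted ties too
        if np.all(labels == labels[0]):
            continue
        assert concordance_index(pred, labels) == pytest.approx(
            brute_force_ci(pred, labels)
        )


def test_ci_agrees_with_survival_package(rng):
    """Cross-check against the survival-analysis implementation."""
    from lifelines.utils import concordance_index as lifelines_ci

    for _ in range(25):
        n = int(rng.integers(5, 80))
        labels = rng.normal(size=n)
        pred = rng.normal(size=n)
        assert concordance_index(pred, labels) == pytest.approx(
            lifelines_ci(labels, pred)
        )


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    st.lists(
        st.tuples(
            st.floats(-100, 100, allow_nan=False),
            st.floats(-100, 100, allow_nan=False),
        ),
        min_size=2,
        max_size=40,
    )
)
def test_metric_ranges(pairs):
    pred = np.array([a for a, _ in pairs])
    labels = np.array([b for _, b in pairs])
    assert rmse(pred, labels) >= 0.0
    if np.std(pred) > 0 and np.std(labels) > 0:
        assert -1.0 <= pearson(pred, labels) <= 1.0
        assert -1.0 <= spearman(pred, labels) <= 1.0
    if len(np.unique(labels)) > 1:
        assert 0.0 <= concordance_index(pred, labels) <= 1.0
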