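"""Cold-start (entity-disjoint) splitting and regression metrics.

Cold-drug and cold-target evaluation partitions the *entities* on the cold
axis: every drug (resp. protein) appearing in validation or test is absent
from training, and — following the convention of prior cold-start work —
validation and test entity sets are also disjoint from each other.  The warm
regime splits at pair level, with a repair pass so that (density permitting)
every test/validation entity also occurs in training.

Metrics are RMSE, Pearson, Spearman (average-rank ties) and the concordance
index with the standard tie convention: pairs with tied true labels are
excluded; predicted ties earn half credit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "SplitManifest",
    "cold_split",
    "audit_split",
    "rmse",
    "pearson",
    "spearman",
    "concordance_index",
    "UndefinedMetricError",
    "SplitError",
    "REGIMES",
]

REGIMES = ("cold_drug", "cold_target", "warm")
_PARTS = ("train", "valid", "test")


class SplitError(ValueError):
    """Dataset cannot be split as requested (e.g. too few entities)."""


class UndefinedMetricError(ValueError):
    """Metric has no defined value (e.g. correlation of a constant)."""


# ---------------------------------------------------------------------------
# split manifest


@dataclass
class SplitManifest:
    """Reproducible record-level assignment to train/valid/test.

    Stores explicit record-index lists (enough to reproduce the split
    without the splitter) plus the entity-id lists per partition for audits.
    """

    regime: str
    fractions: tuple[float, float, float]
    seed: int
    record_indices: dict[str, list[int]]
    entity_ids: dict[str, dict[str, list[str]]] = field(default_factory=dict)

    def indices(self, part: str) -> np.ndarray:
        return np.asarray(self.record_indices[part], dtype=np.intp)

    def to_json(self) -> str:
        return json.dumps(
            {
                "regime": self.regime,
                "fractions": list(self.fractions),
                "seed": self.seed,
                "record_indices": self.record_indices,
                "entity_ids": self.entity_ids,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "SplitManifest":
        d = json.loads(text)
        return cls(
            regime=d["regime"],
            fractions=tuple(d["fractions"]),
            seed=d["seed"],
            record_indices={k: list(map(int, v)) for k, v in d["record_indices"].items()},
            entity_ids=d.get("entity_ids", {}),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "SplitManifest":
        with open(path) as fh:
            return cls.from_json(fh.read())


def _partition_sizes(n: int, fractions: tuple[float, float, float]) -> list[int]:
    """Largest-remainder apportionment guaranteeing every part >= 1."""
    raw = [f * n for f in fractions]
    sizes = [int(x) for x in raw]
    while sum(sizes) < n:
        rema = [r - s for r, s in zip(raw, sizes)]
        sizes[int(np.argmax(rema))] += 1
    for i in range(3):
        while sizes[i] == 0:
            j = int(np.argmax(sizes))
            sizes[j] -= 1
            sizes[i] += 1
    return sizes


def cold_split(
    dataset,
    regime: str,
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> SplitManifest:
    """Split a DTA dataset under a named regime.

    cold_drug / cold_target shuffle the entities on the cold axis by seed,
    partition the entity list by the fractions, and let records follow their
    entity.  warm shuffles record indices directly, then repairs: records in
    valid/test whose drug or protein is unseen in train are swapped with
    train records whose entities are covered elsewhere in train.
    """
    if regime not in REGIMES:
        raise ValueError(f"unknown regime {regime!r}; expected one of {REGIMES}")
    if len(fractions) != 3 or min(fractions) <= 0:
        raise ValueError("fractions must be three positive numbers")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)}")

    table = dataset.table
    n_records = len(table)
    drugs = table["left_id"].to_numpy()
    prots = table["right_id"].to_numpy()
    rng = np.random.default_rng(seed)

    if regime in ("cold_drug", "cold_target"):
        axis = drugs if regime == "cold_drug" else prots
        entities = np.unique(axis)
        if len(entities) < 3:
            raise SplitError(
                f"{regime} needs >= 3 distinct entities on the cold axis, "
                f"found {len(entities)}"
            )
        order = rng.permutation(len(entities))
        shuffled = entities[order]
        sizes = _partition_sizes(len(entities), tuple(fractions))
        bounds = np.cumsum(sizes)[:2]
        groups = np.split(shuffled, bounds)
        record_indices = {}
        for part, ents in zip(_PARTS, groups):
            members = np.isin(axis, ents)
            record_indices[part] = np.flatnonzero(members).tolist()
    else:
        order = rng.permutation(n_records)
        sizes = _partition_sizes(n_records, tuple(fractions))
        bounds = np.cumsum(sizes)[:2]
        parts = np.split(order, bounds)
        record_indices = {p: sorted(idx.tolist()) for p, idx in zip(_PARTS, parts)}
        record_indices = _repair_warm(record_indices, drugs, prots, rng)

    manifest = SplitManifest(
        regime=regime,
        fractions=tuple(fractions),
        seed=seed,
        record_indices=record_indices,
        entity_ids={
            part: {
                "drugs": sorted(set(drugs[record_indices[part]])),
                "proteins": sorted(set(prots[record_indices[part]])),
            }
            for part in _PARTS
        },
    )
    for part in _PARTS:
        if not record_indices[part]:
            raise SplitError(
                f"partition {part!r} received no records "
                f"(sizes: { {p: len(record_indices[p]) for p in _PARTS} })"
            )
    return manifest


def _repair_warm(record_indices, drugs, prots, rng) -> dict[str, list[int]]:
    """Move held-out records with train-unseen entities into train.

    A best-effort pass: each offending valid/test record is swapped with a
    random train record that stays safe to release (its entities occur more
    than once in train).  Density permitting, the result satisfies the warm
    invariant exactly.
    """
    train = set(record_indices["train"])
    for part in ("valid", "test"):
        held = list(record_indices[part])
        for idx in held:
            train_drugs = {drugs[i] for i in train}
            train_prots = {prots[i] for i in train}
            if drugs[idx] in train_drugs and prots[idx] in train_prots:
                continue
            # find a train record releasable without uncovering its entities
            from collections import Counter

            d_count = Counter(drugs[i] for i in train)
            p_count = Counter(prots[i] for i in train)
            candidates = [
                i for i in train if d_count[drugs[i]] > 1 and p_count[prots[i]] > 1
            ]
            if not candidates:
                continue  # density does not permit a swap
            swap = candidates[int(rng.integers(len(candidates)))]
            train.remove(swap)
            train.add(idx)
            record_indices[part] = [swap if i == idx else i for i in record_indices[part]]
    record_indices["train"] = sorted(train)
    record_indices["valid"] = sorted(record_indices["valid"])
    record_indices["test"] = sorted(record_indices["test"])
    return record_indices


def audit_split(manifest: SplitManifest, dataset) -> dict:
    """Independently recompute the disjointness predicates for a manifest.

    Deliberately avoids the splitter's internals: reads the record lists,
    rebuilds entity sets from the dataset table, and checks coverage,
    disjointness and the regime-specific leakage predicates.
    """
    table = dataset.table
    n = len(table)
    idx = {p: set(manifest.record_indices[p]) for p in _PARTS}
    report: dict = {"regime": manifest.regime}
    report["covers_dataset"] = (
        sorted(idx["train"] | idx["valid"] | idx["test"]) == list(range(n))
    )
    report["records_disjoint"] = (
        not (idx["train"] & idx["valid"])
        and not (idx["train"] & idx["test"])
        and not (idx["valid"] & idx["test"])
    )
    ent = {
        p: {
            "drugs": {table["left_id"].iloc[i] for i in idx[p]},
            "proteins": {table["right_id"].iloc[i] for i in idx[p]},
        }
        for p in _PARTS
    }
    if manifest.regime == "cold_drug":
        held = ent["valid"]["drugs"] | ent["test"]["drugs"]
        report["no_entity_leakage"] = (
            not (held & ent["train"]["drugs"])
            and not (ent["valid"]["drugs"] & ent["test"]["drugs"])
        )
    elif manifest.regime == "cold_target":
        held = ent["valid"]["proteins"] | ent["test"]["proteins"]
        report["no_entity_leakage"] = (
            not (held & ent["train"]["proteins"])
            and not (ent["valid"]["proteins"] & ent["test"]["proteins"])
        )
    else:  # warm: held-out entities should be seen in train
        unseen = sum(
            1
            for p in ("valid", "test")
            for i in idx[p]
            if table["left_id"].iloc[i] not in ent["train"]["drugs"]
            or table["right_id"].iloc[i] not in ent["train"]["proteins"]
        )
        report["warm_unseen_records"] = unseen
        report["no_entity_leakage"] = True
    report["ok"] = bool(
        report["covers_dataset"]
        and report["records_disjoint"]
        and report["no_entity_leakage"]
    )
    return report


# ---------------------------------------------------------------------------
# metrics


def _check_pair(predictions, labels, min_len: int):
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(labels, dtype=float)
    if p.shape != y.shape or p.ndim != 1:
        raise ValueError("predictions and labels must be equal-length 1-D")
    if len(p) < min_len:
        raise ValueError(f"need at least {min_len} observations")
    return p, y


def rmse(predictions, labels) -> float:
    p, y = _check_pair(predictions, labels, 1)
    return float(np.sqrt(np.mean((p - y) ** 2)))


def pearson(predictions, labels) -> float:
    p, y = _check_pair(predictions, labels, 2)
    if np.std(p) == 0 or np.std(y) == 0:
        raise UndefinedMetricError("pearson undefined for zero-variance input")
    return float(stats.pearsonr(p, y).statistic)


def spearman(predictions, labels) -> float:
    p, y = _check_pair(predictions, labels, 2)
    if np.std(p) == 0 or np.std(y) == 0:
        raise UndefinedMetricError("spearman undefined for zero-variance input")
    return float(stats.spearmanr(p, y).statistic)


def concordance_index(predictions, labels) -> float:
    """Fraction of label-ordered pairs whose predicted order agrees.

    Over all pairs (i, j) with labels_i > labels_j: credit 1 if
    predictions_i > predictions_j, 0.5 if equal, 0 otherwise; tied-label
    pairs enter neither numerator nor denominator.  Computed blockwise in
    O(n^2) time and O(block * n) memory.
    """
    p, y = _check_pair(predictions, labels, 2)
    n = len(p)
    num = 0.0
    den = 0
    block = 512
    for start in range(0, n, block):
        yi = y[start : start + block, None]
        pi = p[start : start + block, None]
        greater = yi > y[None, :]          # label_i > label_j
        den += int(greater.sum())
        num += float(np.where(greater, (pi > p) + 0.5 * (pi == p), 0.0).sum())
    if den == 0:
        raise UndefinedMetricError("concordance undefined: all labels tied")
    return num / den


def regression_report(predictions, labels) -> dict[str, float]:
    """The four benchmark metrics in one dict.

    Individual metrics that are undefined for the given data (zero-variance
    input, all labels tied) are reported as NaN rather than aborting a whole
    evaluation; calling a metric function directly still raises.
    """
    out = {"rmse": rmse(predictions, labels)}
    for name, fn in (
        ("pearson", pearson),
        ("spearman", spearman),
        ("ci", concordance_index),
    ):
        try:
            out[name] = fn(predictions, labels)
        except UndefinedMetricError:
            out[name] = float("nan")
    return out
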