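"""On-disk formats: pair tables, entity stores, FASTA, configs, reports.

Layout mirrors interaction-database corpora: pair files carry entity *ids*
plus a label, and the structures live in separate entity files (SMILES TSV
for chemicals, FASTA for proteins).  Inline structure columns (``smiles_1``,
``sequence_2``...) are also accepted and folded into the stores.

All readers validate as they load: malformed rows are reported with their
line numbers and skipped (counts logged), missing columns are schema errors,
and unresolvable entity references raise with the offending ids.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from .chem_graph import SmilesParseError, smiles_to_graph

logger = logging.getLogger(__name__)

__all__ = [
    "PairDataset",
    "read_pair_table",
    "write_pair_table",
    "read_fasta",
    "write_fasta",
    "read_smiles_table",
    "write_smiles_table",
    "RunConfig",
    "SchemaError",
]

TASKS = ("cci", "ppi", "dta")
EVIDENCE_CHANNELS = ("experimental", "similarity", "text", "other")
STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


class SchemaError(ValueError):
    """Input file does not follow the documented column layout."""


@dataclass
class PairDataset:
    """Labelled entity pairs plus the stores resolving ids to structures.

    ``table`` columns: ``left_id``, ``right_id``, ``label`` and, for CCI,
    an optional ``channel`` evidence tag.  For cci both sides are chemicals,
    for ppi both are proteins, for dta left is the drug and right the
    protein (affinity label is a finite real).
    """

    task: str
    table: pd.DataFrame
    drugs: dict[str, str] = field(default_factory=dict)      # id -> SMILES
    proteins: dict[str, str] = field(default_factory=dict)   # id -> sequence

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}")
        self.validate()

    def __len__(self) -> int:
        return len(self.table)

    @property
    def left_store(self) -> dict[str, str]:
        return self.drugs if self.task in ("cci", "dta") else self.proteins

    @property
    def right_store(self) -> dict[str, str]:
        return self.drugs if self.task == "cci" else self.proteins

    def validate(self) -> None:
        missing_cols = {"left_id", "right_id", "label"} - set(self.table.columns)
        if missing_cols:
            raise SchemaError(f"pair table missing columns: {sorted(missing_cols)}")
        unresolved = sorted(
            set(self.table["left_id"]) - set(self.left_store)
        ) + sorted(set(self.table["right_id"]) - set(self.right_store))
        if unresolved:
            raise SchemaError(
                f"unresolvable entity references ({len(unresolved)}): "
                f"{unresolved[:10]}"
            )
        labels = self.table["label"].to_numpy(dtype=float)
        if self.task in ("cci", "ppi"):
            if not np.all(np.isin(labels, (0.0, 1.0))):
                raise SchemaError(f"{self.task} labels must be 0/1")
        elif not np.all(np.isfinite(labels)):
            raise SchemaError("dta affinities must be finite reals")

    def subset(self, indices) -> "PairDataset":
        return PairDataset(
            task=self.task,
            table=self.table.iloc[np.asarray(indices, dtype=np.intp)].reset_index(
                drop=True
            ),
            drugs=self.drugs,
            proteins=self.proteins,
        )

    def filter_channel(self, channel: str) -> "PairDataset":
        """Restrict CCI records to one evidence channel (ablation switch)."""
        if self.task != "cci":
            raise ValueError("evidence channels only apply to cci datasets")
        if "channel" not in self.table.columns:
            raise SchemaError("cci table has no 'channel' column")
        keep = self.table[self.table["channel"] == channel].reset_index(drop=True)
        return PairDataset("cci", keep, drugs=self.drugs, proteins=self.proteins)


# ---------------------------------------------------------------------------
# readers / writers


def _read_table(path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, dtype={"left_id": str, "right_id": str})
    if df.empty:
        raise SchemaError(f"empty input file: {path}")
    return df


def read_pair_table(
    path,
    task: str,
    drugs: dict[str, str] | None = None,
    proteins: dict[str, str] | None = None,
) -> PairDataset:
    """Load a TSV/CSV pair table into a validated :class:`PairDataset`.

    Required columns: ``left_id``, ``right_id``, ``label`` (ids may instead
    be given inline as ``smiles_1``/``smiles_2``/``smiles``/``sequence``
    columns, which become the stores).  Rows whose SMILES fail to parse or
    whose label is malformed are dropped with a logged line number.
    """
    df = _read_table(path)
    drugs = dict(drugs or {})
    proteins = dict(proteins or {})

    # fold inline structure columns into the stores
    inline = {
        "smiles_1": ("left_id", drugs),
        "smiles_2": ("right_id", drugs),
        "smiles": ("left_id", drugs),
        "sequence": ("right_id", proteins),
        "sequence_1": ("left_id", proteins),
        "sequence_2": ("right_id", proteins),
    }
    for col, (idcol, store) in inline.items():
        if col in df.columns:
            if idcol not in df.columns:
                df[idcol] = df[col].astype(str)
            for eid, structure in zip(df[idcol].astype(str), df[col].astype(str)):
                store.setdefault(eid, structure)

    missing = {"left_id", "right_id", "label"} - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing required columns {sorted(missing)}")

    bad_rows: list[int] = []
    labels = pd.to_numeric(df["label"], errors="coerce")
    for pos, val in enumerate(labels):
        if not np.isfinite(val):
            bad_rows.append(pos)
    left_store = drugs if task in ("cci", "dta") else proteins
    checked: dict[str, bool] = {}
    for pos, eid in enumerate(df["left_id"].astype(str)):
        if task in ("cci", "dta") and eid in left_store:
            if eid not in checked:
                try:
                    smiles_to_graph(left_store[eid])
                    checked[eid] = True
                except SmilesParseError:
                    checked[eid] = False
            if not checked[eid]:
                bad_rows.append(pos)
    if bad_rows:
        # +2: header line and 1-based numbering
        lines = sorted({p + 2 for p in bad_rows})
        logger.warning(
            "%s: dropped %d malformed row(s) at line(s) %s",
            path,
            len(lines),
            lines[:20],
        )
        df = df.drop(df.index[sorted(set(bad_rows))]).reset_index(drop=True)
        if df.empty:
            raise SchemaError(f"{path}: no well-formed rows remain")

    keep = ["left_id", "right_id", "label"] + (
        ["channel"] if "channel" in df.columns else []
    )
    out = df[keep].copy()
    out["left_id"] = out["left_id"].astype(str)
    out["right_id"] = out["right_id"].astype(str)
    out["label"] = pd.to_numeric(out["label"])
    ds = PairDataset(task=task, table=out, drugs=drugs, proteins=proteins)
    logger.info("%s: loaded %d %s pairs", path, len(ds), task)
    return ds


def write_pair_table(dataset: PairDataset, path) -> None:
    dataset.table.to_csv(path, sep="\t", index=False)


def read_fasta(path) -> dict[str, str]:
    """FASTA -> {id: upper-cased sequence}; duplicate ids are an error.

    Ids are the first whitespace-delimited header token.  Non-standard
    residues are mapped to ``X`` with a warning.
    """
    out: dict[str, str] = {}
    duplicates = []
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        if set(seq) - STANDARD_AA:
            logger.warning(
                "sequence %s: non-standard residues mapped to X", record.id
            )
            seq = "".join(c if c in STANDARD_AA else "X" for c in seq)
        if record.id in out:
            duplicates.append(record.id)
        out[record.id] = seq
    if duplicates:
        raise SchemaError(f"duplicate FASTA ids: {sorted(set(duplicates))}")
    if not out:
        raise SchemaError(f"empty FASTA file: {path}")
    return out


def write_fasta(sequences: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for sid, seq in sequences.items():
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def read_smiles_table(path) -> dict[str, str]:
    """Two-column TSV (id, smiles) -> {id: smiles}."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"id", "smiles"} <= set(df.columns):
        raise SchemaError(f"{path}: expected columns 'id' and 'smiles'")
    return dict(zip(df["id"], df["smiles"]))


def write_smiles_table(chemicals: dict[str, str], path) -> None:
    pd.DataFrame(
        {"id": list(chemicals), "smiles": [chemicals[k] for k in chemicals]}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """One YAML document driving a whole run (simulate through evaluate).

    Nested sections are plain dicts mapped onto the dataclass configs by the
    consumers; unknown keys are rejected early so typos fail loudly.  All
    randomness fans out from ``seed``.
    """

    outdir: str = "runs/default"
    seed: int = 0
    world: dict = field(default_factory=dict)
    gin: dict = field(default_factory=dict)
    sequence: dict = field(default_factory=dict)
    head: dict = field(default_factory=dict)
    train: dict = field(default_factory=dict)
    split: dict = field(default_factory=dict)
    paths: dict = field(default_factory=dict)
    verbosity: str = "INFO"

    _SECTIONS = (
        "outdir", "seed", "world", "gin", "sequence",
        "head", "train", "split", "paths", "verbosity",
    )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls._SECTIONS)
        if unknown:
            raise SchemaError(f"unknown config sections: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = {k: getattr(self, k) for k in self._SECTIONS}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    def fingerprint(self) -> str:
        data = {k: getattr(self, k) for k in self._SECTIONS}
        return hashlib.sha256(
            json.dumps(data, sort_keys=True, default=str).encode()
        ).hexdigest()


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
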