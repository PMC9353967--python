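"""Coupled synthetic CCI / PPI / DTA worlds with shared latent structure.

The generator builds molecules from a closed fragment grammar and proteins
from k-mer motifs planted in random background sequence.  Each entity's
latent vector is a deterministic function of its observable structure:

    u_i = (fragment-count composition of chemical i) @ L        (m-dim)
    v_j = (motif-count composition of protein j)    @ M        (m-dim)

with column-centred Gaussian loading matrices L and M.  All three task
datasets are driven by the same latents:

    P(CCI_ij = 1)  = logistic(beta * <u_i, u_j>)      (labels flipped w.p. eta)
    P(PPI_ij = 1)  = logistic(beta * <v_i, v_j>)
    affinity_ij    = a * <u_i, v_j> + b + Normal(0, sigma)

Because the chemical latents that decide CCI also decide binding affinity,
an encoder pretrained on CCI has, by construction, learned features that are
informative for DTA — the transfer premise is true in this world and its
size is controlled by the config.  Default sizes (300 chemicals, 200
proteins, m = 8, sigma = 0.3, balanced 0/1 interaction labels) are chosen so
the whole pipeline trains in seconds on one CPU while leaving enough noise
that the regression is not trivially solvable.

Everything is deterministic per seed; every emitted SMILES is re-parsed
through the graph builder before the world is returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .chem_graph import smiles_to_graph
from .data_io import EVIDENCE_CHANNELS, PairDataset
from .nn import sigmoid

__all__ = [
    "SyntheticWorldConfig",
    "SyntheticWorld",
    "generate_world",
    "sample_interaction_pairs",
    "sample_dta_pairs",
    "DEFAULT_FRAGMENTS",
]

#: Closed fragment grammar: every fragment is a valid inline SMILES chain
#: unit, so any concatenation starting from "C" parses.  Index 0 is the
#: mandatory backbone start; the rest are optional.
DEFAULT_FRAGMENTS: tuple[str, ...] = (
    "C",          # backbone start / methylene
    "CC",
    "CCC",
    "O",
    "N",
    "S",
    "C(=O)",
    "C(C)",
    "C(F)",
    "C(Cl)",
    "CO",
    "CN",
    "c1ccccc1",   # benzene, ortho-substituted inline
    "C1CCCCC1",   # cyclohexane
)

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SyntheticWorldConfig:
    """Sampling parameters of one synthetic world.

    ``beta`` is the steepness of the interaction logistic, ``label_noise``
    the flip probability eta of CCI/PPI labels, ``affinity_noise_sd`` the
    sd sigma of the additive affinity noise, ``loading_scale`` the sd of
    the loading matrices (scaled so latent inner products have spread of
    order one, making beta = 3 a near-separable world).
    """

    n_chemicals: int = 300
    n_proteins: int = 200
    latent_dim: int = 8
    motif_k: int = 3
    n_motifs: int = 12
    min_fragments: int = 3
    max_fragments: int = 8
    min_protein_len: int = 60
    max_protein_len: int = 120
    min_motif_sites: int = 4
    max_motif_sites: int = 14
    beta: float = 3.0
    label_noise: float = 0.05
    affinity_scale: float = 1.0
    affinity_offset: float = 5.0
    affinity_noise_sd: float = 0.3
    loading_scale: float = 2.0
    fragments: tuple[str, ...] = DEFAULT_FRAGMENTS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if not 0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must lie in [0, 0.5)")
        if self.affinity_noise_sd < 0:
            raise ValueError("affinity_noise_sd must be >= 0")


@dataclass
class SyntheticWorld:
    """Generated entities, their latents, and the producing config."""

    config: SyntheticWorldConfig
    chemicals: dict[str, str]                 # id -> SMILES
    proteins: dict[str, str]                  # id -> sequence
    chem_latents: dict[str, np.ndarray]       # id -> u_i
    prot_latents: dict[str, np.ndarray]       # id -> v_j
    fragment_counts: dict[str, np.ndarray] = field(default_factory=dict)
    motif_counts: dict[str, np.ndarray] = field(default_factory=dict)
    motifs: tuple[str, ...] = ()

    @property
    def chem_ids(self) -> list[str]:
        return list(self.chemicals)

    @property
    def prot_ids(self) -> list[str]:
        return list(self.proteins)

    def latent_matrix(self, side: str) -> np.ndarray:
        latents = self.chem_latents if side == "chem" else self.prot_latents
        return np.stack([latents[i] for i in latents])


def _centered_loadings(
    rng: np.random.Generator, n_rows: int, m: int, scale: float
) -> np.ndarray:
    L = rng.normal(0.0, scale, size=(n_rows, m))
    return L - L.mean(axis=0, keepdims=True)


def generate_world(config: SyntheticWorldConfig) -> SyntheticWorld:
    """Build a deterministic world from the config's seed.

    Chemicals are a seeded concatenation of fragment templates (always
    starting from the backbone fragment); every SMILES is re-parsed through
    the graph builder as a validity gate.  Proteins are random background
    sequence with motifs planted at non-overlapping sites; motif counts are
    re-counted from the final sequence so accidental background occurrences
    also contribute, keeping latents a function of the emitted structure.
    """
    c = config
    root = np.random.SeedSequence(c.seed)
    rng_chem, rng_prot, rng_load = (
        np.random.default_rng(s) for s in root.spawn(3)
    )

    n_frag = len(c.fragments)
    L = _centered_loadings(rng_load, n_frag, c.latent_dim, c.loading_scale)

    chemicals: dict[str, str] = {}
    chem_latents: dict[str, np.ndarray] = {}
    fragment_counts: dict[str, np.ndarray] = {}
    for i in range(c.n_chemicals):
        cid = f"CHEM{i:04d}"
        # per-chemical fragment preference -> diverse compositions
        pref = rng_chem.dirichlet(np.full(n_frag - 1, 0.5))
        n_opt = int(rng_chem.integers(c.min_fragments, c.max_fragments + 1))
        picks = rng_chem.choice(n_frag - 1, size=n_opt, p=pref) + 1
        counts = np.zeros(n_frag)
        counts[0] = 1.0
        np.add.at(counts, picks, 1.0)
        smiles = c.fragments[0] + "".join(c.fragments[p] for p in picks)
        graph = smiles_to_graph(smiles)  # validity gate
        assert graph.num_nodes >= 1
        chemicals[cid] = smiles
        fragment_counts[cid] = counts
        chem_latents[cid] = (counts / counts.sum()) @ L

    # distinct k-mer motifs
    motifs: list[str] = []
    while len(motifs) < c.n_motifs:
        m = "".join(rng_prot.choice(list(AA_ALPHABET), size=c.motif_k))
        if m not in motifs:
            motifs.append(m)
    M = _centered_loadings(rng_load, c.n_motifs, c.latent_dim, c.loading_scale)

    proteins: dict[str, str] = {}
    prot_latents: dict[str, np.ndarray] = {}
    motif_counts: dict[str, np.ndarray] = {}
    for j in range(c.n_proteins):
        pid = f"PROT{j:04d}"
        length = int(rng_prot.integers(c.min_protein_len, c.max_protein_len + 1))
        seq = list(rng_prot.choice(list(AA_ALPHABET), size=length))
        pref = rng_prot.dirichlet(np.full(c.n_motifs, 0.5))
        n_sites = int(rng_prot.integers(c.min_motif_sites, c.max_motif_sites + 1))
        placed: list[int] = []
        for _ in range(n_sites):
            which = int(rng_prot.choice(c.n_motifs, p=pref))
            for _attempt in range(20):
                pos = int(rng_prot.integers(0, length - c.motif_k + 1))
                if all(abs(pos - q) >= c.motif_k for q in placed):
                    seq[pos : pos + c.motif_k] = list(motifs[which])
                    placed.append(pos)
                    break
        sequence = "".join(seq)
        counts = np.array(
            [_count_overlapping(sequence, m) for m in motifs], dtype=float
        )
        total = counts.sum()
        comp = counts / total if total > 0 else counts
        proteins[pid] = sequence
        motif_counts[pid] = counts
        prot_latents[pid] = comp @ M

    return SyntheticWorld(
        config=c,
        chemicals=chemicals,
        proteins=proteins,
        chem_latents=chem_latents,
        prot_latents=prot_latents,
        fragment_counts=fragment_counts,
        motif_counts=motif_counts,
        motifs=tuple(motifs),
    )


def _count_overlapping(sequence: str, motif: str) -> int:
    count = start = 0
    while True:
        pos = sequence.find(motif, start)
        if pos < 0:
            return count
        count += 1
        start = pos + 1


def sample_interaction_pairs(
    world: SyntheticWorld,
    task: str,
    n_pairs: int,
    seed: int = 0,
    balanced: bool = True,
    channel_probs: tuple[float, ...] = (0.4, 0.3, 0.2, 0.1),
) -> PairDataset:
    """Draw labelled CCI or PPI pairs from the world's latent logistic.

    Labels are Bernoulli(logistic(beta * <latent_i, latent_j>)) flipped with
    probability eta; with ``balanced`` the 0/1 classes are filled to equal
    quotas by rejection.  CCI records carry a provenance channel tag so the
    experimental-only pretraining ablation is expressible.
    """
    if task not in ("cci", "ppi"):
        raise ValueError("task must be 'cci' or 'ppi'")
    c = world.config
    rng = np.random.default_rng(np.random.SeedSequence((c.seed, seed, 1)))
    ids = world.chem_ids if task == "cci" else world.prot_ids
    latents = world.chem_latents if task == "cci" else world.prot_latents
    lat = np.stack([latents[i] for i in ids])

    want1 = n_pairs // 2 if balanced else n_pairs
    want0 = n_pairs - want1 if balanced else 0
    rows: list[tuple[str, str, int]] = []
    got = {0: 0, 1: 0}
    for _round in range(400):
        if len(rows) >= n_pairs:
            break
        draw = max(2 * n_pairs, 1000)
        i = rng.integers(0, len(ids), size=draw)
        j = rng.integers(0, len(ids), size=draw)
        keep = i != j
        i, j = i[keep], j[keep]
        p = sigmoid(c.beta * np.einsum("ij,ij->i", lat[i], lat[j]))
        labels = (rng.random(len(p)) < p).astype(int)
        flip = rng.random(len(p)) < c.label_noise
        labels[flip] = 1 - labels[flip]
        for a, b, y in zip(i, j, labels):
            if len(rows) >= n_pairs:
                break
            if balanced:
                quota = want1 if y == 1 else want0
                if got[y] >= quota:
                    continue
            rows.append((ids[a], ids[b], int(y)))
            got[int(y)] += 1
    if len(rows) < n_pairs:
        achieved = got[1] / max(1, got[0] + got[1])
        raise RuntimeError(
            f"could not satisfy balance request: collected {len(rows)}/"
            f"{n_pairs} pairs (positive ratio {achieved:.2f})"
        )

    table = pd.DataFrame(rows, columns=["left_id", "right_id", "label"])
    if task == "cci":
        table["channel"] = rng.choice(
            EVIDENCE_CHANNELS, size=len(table), p=channel_probs
        )
        return PairDataset("cci", table, drugs=dict(world.chemicals))
    return PairDataset("ppi", table, proteins=dict(world.proteins))


def sample_dta_pairs(
    world: SyntheticWorld, n_pairs: int, seed: int = 0
) -> PairDataset:
    """Draw (drug, protein, affinity) records from the bilinear model.

    affinity = a * <u_i, v_j> + b + Normal(0, sigma), on a log-dissociation
    -like scale (offset b = 5 by default).  The same latents drive the
    auxiliary interaction tasks, which is what makes pretraining
    transferable in this world.
    """
    c = world.config
    rng = np.random.default_rng(np.random.SeedSequence((c.seed, seed, 2)))
    cids, pids = world.chem_ids, world.prot_ids
    i = rng.integers(0, len(cids), size=n_pairs)
    j = rng.integers(0, len(pids), size=n_pairs)
    U = np.stack([world.chem_latents[cids[a]] for a in i])
    V = np.stack([world.prot_latents[pids[b]] for b in j])
    affinity = (
        c.affinity_scale * np.einsum("ij,ij->i", U, V)
        + c.affinity_offset
        + rng.normal(0.0, c.affinity_noise_sd, size=n_pairs)
    )
    table = pd.DataFrame(
        {
            "left_id": [cids[a] for a in i],
            "right_id": [pids[b] for b in j],
            "label": affinity,
        }
    )
    return PairDataset(
        "dta",
        table,
        drugs=dict(world.chemicals),
        proteins=dict(world.proteins),
    )


def world_with(config: SyntheticWorldConfig | None = None, **overrides):
    """Convenience: default config with overrides applied."""
    base = config or SyntheticWorldConfig()
    return replace(base, **overrides) if overrides else base
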