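"""Drug and protein encoders producing fixed-length representations.

Two encoder families are provided:

* :class:`GinEncoder` — a graph isomorphism network over molecular graphs.
  Each of ``k`` layers updates node features by

      p_v  <-  MLP( (1 + eps) * p_v  +  sum_{u in N(v)} p_u )

  with a trainable scalar ``eps`` per layer and a two-layer MLP (affine,
  ReLU, affine).  After the last layer a coordinate-wise max over nodes pools
  the graph, and two affine readout layers project to the output width
  (ReLU between them by default; a "literal" mode with no activation is
  available since the stacked affines then collapse to one).

* :class:`SequenceEncoder` — a token-embedding encoder: a provider maps a
  sequence to one embedding vector per token, the vectors are averaged over
  the sequence axis, and one affine layer projects the mean to the output
  width.  The provider abstracts pretrained protein/SMILES language models;
  the built-in desk-scale provider is a trainable k-mer lookup table.

Both encoders expose batched forward/backward passes for training and carry
their parameters in a flat named dict so that a pretrained state can be
checkpointed and transferred into the affinity model bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, is_dataclass
from typing import Protocol, runtime_checkable

import numpy as np

from .chem_graph import MoleculeGraph
from .nn import Dense, ParamModule, relu

logger = logging.getLogger(__name__)

CHECKPOINT_FORMAT_VERSION = 1

__all__ = [
    "GinEncoderConfig",
    "SequenceEncoderConfig",
    "TokenEmbeddingProvider",
    "KmerLookupProvider",
    "PrecomputedEmbeddingProvider",
    "GinEncoder",
    "SequenceEncoder",
    "EncoderState",
    "gin_layer",
    "encode_graph",
    "encode_sequence",
    "batch_graphs",
    "config_fingerprint",
]


# ---------------------------------------------------------------------------
# configs and fingerprints


def config_fingerprint(config) -> str:
    """SHA-256 of a config's canonical JSON; identifies an architecture."""
    d = asdict(config) if is_dataclass(config) else dict(config)
    blob = json.dumps(d, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


@dataclass(frozen=True)
class GinEncoderConfig:
    """Architecture of the molecular graph encoder.

    Defaults follow the reference recipe: 5 GIN layers and a 128-wide output
    projection.  ``hidden_dim`` is the per-layer MLP width C(k) (constant
    across layers), ``readout_hidden`` the width between the two readout
    affines, ``epsilon_init`` the initial value of each layer's trainable
    eps.  ``readout_activation`` inserts a ReLU between the two readout
    affines; disabling it gives the literal stacked-affine form.
    """

    node_feature_dim: int = 74
    num_layers: int = 5
    hidden_dim: int = 64
    readout_hidden: int = 128
    output_dim: int = 128
    epsilon_init: float = 0.0
    readout_activation: bool = True

    def __post_init__(self) -> None:
        if self.num_layers < 1:
            raise ValueError("num_layers must be >= 1")
        if self.output_dim < 1:
            raise ValueError("output_dim must be >= 1")


@dataclass(frozen=True)
class SequenceEncoderConfig:
    """Architecture of the token-embedding sequence encoder.

    ``embedding_dim`` (d, default 768) is the provider's per-token width;
    ``output_dim`` (d', default 128) the projected width, required to be
    smaller than d.  External language-model providers are frozen by default
    (``provider_trainable=False`` leaves the token table untouched during
    training); the desk-scale lookup provider is typically trained.
    """

    provider_name: str = "kmer-lookup"
    embedding_dim: int = 768
    output_dim: int = 128
    provider_trainable: bool = True

    def __post_init__(self) -> None:
        if not 1 <= self.output_dim < self.embedding_dim:
            raise ValueError(
                "output_dim must satisfy 1 <= output_dim < embedding_dim "
                f"(got {self.output_dim} vs {self.embedding_dim})"
            )


# ---------------------------------------------------------------------------
# token-embedding providers


@runtime_checkable
class TokenEmbeddingProvider(Protocol):
    """Contract for anything that turns a sequence into per-token vectors.

    ``embed`` must return one row per token, deterministically for fixed
    parameters.  Implementations wrap anything from a lookup table to a
    cached transformer output.
    """

    name: str
    embedding_dim: int

    def tokenize(self, sequence: str) -> list[str]: ...

    def embed(self, sequence: str) -> np.ndarray: ...  # (n_tokens, d)


UNKNOWN_TOKEN = "<unk>"


class KmerLookupProvider:
    """Trainable lookup table over overlapping k-mers of a sequence.

    ``k=1`` gives per-character tokens (SMILES); ``k=3`` gives residue
    triplets, the desk-scale analogue of a contextual protein language model
    (motif content becomes linearly decodable from the mean embedding).
    Tokens outside the fitted vocabulary map to a shared unknown row, with a
    warning.  The table is owned here and registered with a
    :class:`SequenceEncoder` when the encoder is built trainable.
    """

    name = "kmer-lookup"

    def __init__(
        self,
        vocabulary: list[str],
        embedding_dim: int,
        k: int = 1,
        drop_unknown: bool = False,
        rng: np.random.Generator | None = None,
    ) -> None:
        if k < 1:
            raise ValueError("k must be >= 1")
        self.k = k
        self.embedding_dim = embedding_dim
        #: with a pruned vocabulary most tokens are out-of-vocabulary; when
        #: drop_unknown is set they are omitted from the mean instead of
        #: pooling into one shared row that would dominate every embedding
        self.drop_unknown = drop_unknown
        # index 0 is the unknown token
        self.vocab: dict[str, int] = {UNKNOWN_TOKEN: 0}
        for tok in vocabulary:
            if tok not in self.vocab:
                self.vocab[tok] = len(self.vocab)
        # unit-scale rows keep the mean-pooled embedding at a usable
        # magnitude (averaging n tokens shrinks it by ~1/sqrt(n) already)
        rng = rng or np.random.default_rng(0)
        self.table = rng.normal(0.0, 1.0, size=(len(self.vocab), embedding_dim))

    @classmethod
    def fit(
        cls,
        sequences,
        embedding_dim: int,
        k: int = 1,
        min_sequences: int = 1,
        drop_unknown: bool = False,
        rng: np.random.Generator | None = None,
    ) -> "KmerLookupProvider":
        """Build the vocabulary from the k-mers observed in a corpus.

        ``min_sequences`` drops tokens occurring in fewer distinct sequences:
        rare k-mers act as sequence-identity fingerprints, so pruning them
        forces the encoder onto recurring (motif-like) vocabulary that
        generalises to unseen sequences.
        """
        df: dict[str, int] = {}
        for s in sequences:
            for tok in set(_kmers(s, k)):
                df[tok] = df.get(tok, 0) + 1
        kept = sorted(t for t, n in df.items() if n >= min_sequences)
        return cls(kept, embedding_dim, k=k, drop_unknown=drop_unknown, rng=rng)

    @property
    def vocab_size(self) -> int:
        return len(self.vocab)

    def tokenize(self, sequence: str) -> list[str]:
        return _kmers(sequence, self.k)

    def token_indices(self, sequence: str) -> np.ndarray:
        idx = np.asarray(
            [self.vocab.get(tok, 0) for tok in self.tokenize(sequence)],
            dtype=np.intp,
        )
        n_unknown = int((idx == 0).sum())
        if n_unknown:
            logger.debug(
                "%d/%d tokens outside vocabulary mapped to unknown",
                n_unknown,
                len(idx),
            )
        if self.drop_unknown:
            known = idx[idx != 0]
            if known.size == 0:
                # nothing in vocabulary: fall back to the unknown row so the
                # sequence still embeds (rare; logged for audit)
                logger.debug("sequence has no in-vocabulary tokens; kept unknowns")
                return idx
            idx = known
        return idx

    def token_counts(self, sequence: str) -> np.ndarray:
        """Dense count vector over the vocabulary (training fast path)."""
        counts = np.zeros(self.vocab_size)
        np.add.at(counts, self.token_indices(sequence), 1.0)
        return counts

    def embed(self, sequence: str) -> np.ndarray:
        return self.table[self.token_indices(sequence)]


def _kmers(sequence: str, k: int) -> list[str]:
    if len(sequence) == 0:
        raise ValueError("cannot tokenize an empty sequence")
    if len(sequence) < k:
        return [sequence]
    return [sequence[i : i + k] for i in range(len(sequence) - k + 1)]


class PrecomputedEmbeddingProvider:
    """Frozen provider backed by per-sequence embedding matrices on disk.

    Decouples the pipeline from any external language model: whoever computed
    the n x d matrices (ESM, ChemBERTa, anything) is opaque here.
    """

    name = "precomputed"

    def __init__(self, embeddings: dict[str, np.ndarray]) -> None:
        dims = {m.shape[1] for m in embeddings.values()}
        if len(dims) != 1:
            raise ValueError(f"inconsistent embedding widths: {sorted(dims)}")
        self.embedding_dim = dims.pop()
        self._by_sequence = embeddings

    def tokenize(self, sequence: str) -> list[str]:
        return list(sequence)

    def embed(self, sequence: str) -> np.ndarray:
        try:
            return self._by_sequence[sequence]
        except KeyError:
            raise KeyError(
                f"no precomputed embedding for sequence {sequence[:20]!r}..."
            ) from None


# ---------------------------------------------------------------------------
# GIN encoder


def gin_layer(
    node_features: np.ndarray,
    adjacency: np.ndarray,
    epsilon: float,
    mlp=None,
) -> np.ndarray:
    """One sum-aggregation GIN update: MLP((1+eps) * X + A @ X).

    ``mlp`` is any callable on the node-feature matrix; the identity is used
    when omitted.  No degree normalisation is applied — sum aggregation is
    what distinguishes GIN from mean/max message passing.
    """
    x = np.asarray(node_features, dtype=float)
    a = np.asarray(adjacency, dtype=float)
    if a.shape[0] != a.shape[1] or a.shape[0] != x.shape[0]:
        raise ValueError(
            f"adjacency {a.shape} incompatible with features {x.shape}"
        )
    out = (1.0 + epsilon) * x + a @ x
    return out if mlp is None else mlp(out)


def batch_graphs(graphs: list[MoleculeGraph]):
    """Pad a list of graphs into dense (B, N, F), (B, N, N), (B, N) arrays."""
    if not graphs:
        raise ValueError("empty graph batch")
    nmax = max(g.num_nodes for g in graphs)
    feat_dim = graphs[0].node_features.shape[1]
    X = np.zeros((len(graphs), nmax, feat_dim))
    A = np.zeros((len(graphs), nmax, nmax))
    mask = np.zeros((len(graphs), nmax))
    for i, g in enumerate(graphs):
        n = g.num_nodes
        X[i, :n] = g.node_features
        A[i, :n, :n] = g.adjacency
        mask[i, :n] = 1.0
    return X, A, mask


class GinEncoder(ParamModule):
    """Siamese-capable GIN encoder: k GIN layers, masked max-pool, readout."""

    kind = "gin"

    def __init__(self, config: GinEncoderConfig, rng: np.random.Generator) -> None:
        super().__init__()
        self.config = config
        c = config
        self.layers: list[tuple[Dense, Dense]] = []
        width_in = c.node_feature_dim
        for k in range(c.num_layers):
            self.add_param(f"gin{k}.eps", np.asarray(float(c.epsilon_init)))
            d1 = Dense(self, f"gin{k}.mlp1", width_in, c.hidden_dim, rng)
            d2 = Dense(self, f"gin{k}.mlp2", c.hidden_dim, c.hidden_dim, rng)
            self.layers.append((d1, d2))
            width_in = c.hidden_dim
        self.read0 = Dense(self, "readout0", c.hidden_dim, c.readout_hidden, rng)
        self.read1 = Dense(self, "readout1", c.readout_hidden, c.output_dim, rng)

    @property
    def output_dim(self) -> int:
        return self.config.output_dim

    def forward(self, X: np.ndarray, A: np.ndarray, mask: np.ndarray):
        """Batched forward pass; returns (output (B, d'), cache)."""
        if mask.sum(axis=1).min() < 1:
            raise ValueError("graph with zero nodes: max-pool is undefined")
        cache: dict = {"X": X, "A": A, "mask": mask, "layers": []}
        H = X
        m3 = mask[:, :, None]
        for k, (d1, d2) in enumerate(self.layers):
            eps = float(self.params[f"gin{k}.eps"])
            S = (1.0 + eps) * H + A @ H
            Z1 = d1.forward(S)
            H1 = relu(Z1)
            H2 = d2.forward(H1)
            Hout = H2 * m3
            cache["layers"].append({"H_in": H, "S": S, "Z1": Z1, "H1": H1})
            H = Hout
        # masked coordinate-wise max over nodes
        Hm = np.where(m3 > 0, H, -np.inf)
        argmax = Hm.argmax(axis=1)                      # (B, C)
        pooled = np.take_along_axis(Hm, argmax[:, None, :], axis=1)[:, 0, :]
        z0 = self.read0.forward(pooled)
        h0 = relu(z0) if self.config.readout_activation else z0
        out = self.read1.forward(h0)
        cache.update(H_final=H, argmax=argmax, pooled=pooled, z0=z0, h0=h0)
        return out, cache

    def backward(self, cache: dict, g_out: np.ndarray) -> None:
        """Accumulate parameter gradients for one cached forward pass."""
        g_h0 = self.read1.backward(cache["h0"], g_out)
        if self.config.readout_activation:
            g_h0 = g_h0 * (cache["z0"] > 0)
        g_pooled = self.read0.backward(cache["pooled"], g_h0)
        B, N, C = cache["H_final"].shape
        gH = np.zeros((B, N, C))
        b_idx = np.arange(B)[:, None]
        c_idx = np.arange(C)[None, :]
        gH[b_idx, cache["argmax"], c_idx] = g_pooled
        m3 = cache["mask"][:, :, None]
        A = cache["A"]
        for k in range(len(self.layers) - 1, -1, -1):
            d1, d2 = self.layers[k]
            lc = cache["layers"][k]
            gH2 = gH * m3
            gH1 = d2.backward(lc["H1"], gH2)
            gZ1 = gH1 * (lc["Z1"] > 0)
            gS = d1.backward(lc["S"], gZ1)
            eps = float(self.params[f"gin{k}.eps"])
            self.grads[f"gin{k}.eps"] += float(np.sum(gS * lc["H_in"]))
            # d S / d H_in: (1+eps) * I + A  (A symmetric)
            gH = (1.0 + eps) * gS + A @ gS

    def forward_flat(self, flat_batch: "FlatGraphBatch"):
        """Padding-free forward over a :class:`FlatGraphBatch` (training
        fast path; numerically identical to :meth:`forward`)."""
        return _GinFlat.forward(self, flat_batch)

    def backward_flat(self, cache: dict, g_out: np.ndarray) -> None:
        _GinFlat.backward(self, cache, g_out)


class FlatGraphBatch:
    """A set of graphs flattened into one node table (no padding).

    Nodes of each graph are contiguous; ``offsets`` marks segment starts,
    ``graph_ids`` maps nodes to graphs, and the directed edge arrays carry
    both orientations of every bond.
    """

    __slots__ = ("feats", "graph_ids", "offsets", "adjacency", "n_graphs")

    def __init__(self, graphs: list[MoleculeGraph]):
        from scipy import sparse

        if not graphs:
            raise ValueError("empty graph batch")
        sizes = np.array([g.num_nodes for g in graphs])
        self.n_graphs = len(graphs)
        self.offsets = np.concatenate([[0], np.cumsum(sizes)[:-1]]).astype(np.intp)
        self.graph_ids = np.repeat(np.arange(self.n_graphs), sizes)
        self.feats = np.concatenate([g.node_features for g in graphs], axis=0)
        # one block-diagonal sparse adjacency for the whole batch; symmetric,
        # so it serves both the forward aggregation and its adjoint.  The
        # CSR parts are concatenated by hand: scipy's block_diag dominates
        # the training profile if called per batch.
        parts = [_graph_csr_parts(g) for g in graphs]
        indices = np.concatenate(
            [idx + off for (idx, _), off in zip(parts, self.offsets)]
        )
        indptr_chunks = [np.array([0], dtype=np.int64)]
        nnz = 0
        for _, ptr in parts:
            indptr_chunks.append(ptr[1:] + nnz)
            nnz += ptr[-1]
        indptr = np.concatenate(indptr_chunks)
        n = int(sizes.sum())
        self.adjacency = sparse.csr_matrix(
            (np.ones(len(indices)), indices, indptr), shape=(n, n)
        )


def _graph_csr_parts(g: MoleculeGraph):
    """(indices, indptr) of a graph's adjacency, cached on the graph."""
    cached = getattr(g, "_csr_parts", None)
    if cached is None:
        from scipy import sparse

        m = sparse.csr_matrix(g.adjacency)
        cached = (m.indices.astype(np.int64), m.indptr.astype(np.int64))
        g._csr_parts = cached
    return cached


class _GinFlat:
    """Flattened forward/backward for :class:`GinEncoder` (same math as the
    padded path, one dense op per layer instead of per-graph matmuls)."""

    @staticmethod
    def forward(enc: "GinEncoder", fb: FlatGraphBatch):
        cache: dict = {"fb": fb, "layers": []}
        H = fb.feats
        for k, (d1, d2) in enumerate(enc.layers):
            eps = float(enc.params[f"gin{k}.eps"])
            S = (1.0 + eps) * H + fb.adjacency @ H
            Z1 = d1.forward(S)
            H1 = relu(Z1)
            H2 = d2.forward(H1)
            cache["layers"].append({"H_in": H, "S": S, "Z1": Z1, "H1": H1})
            H = H2
        pooled = np.maximum.reduceat(H, fb.offsets, axis=0)
        # first maximal node per (graph, channel), for the pool subgradient
        node_idx = np.arange(H.shape[0])[:, None]
        masked = np.where(
            H == pooled[fb.graph_ids], node_idx, H.shape[0]
        )
        argmax = np.minimum.reduceat(masked, fb.offsets, axis=0)
        z0 = enc.read0.forward(pooled)
        h0 = relu(z0) if enc.config.readout_activation else z0
        out = enc.read1.forward(h0)
        cache.update(H_final=H, argmax=argmax, pooled=pooled, z0=z0, h0=h0)
        return out, cache

    @staticmethod
    def backward(enc: "GinEncoder", cache: dict, g_out: np.ndarray) -> None:
        fb: FlatGraphBatch = cache["fb"]
        g_h0 = enc.read1.backward(cache["h0"], g_out)
        if enc.config.readout_activation:
            g_h0 = g_h0 * (cache["z0"] > 0)
        g_pooled = enc.read0.backward(cache["pooled"], g_h0)
        H = cache["H_final"]
        gH = np.zeros_like(H)
        c_idx = np.arange(H.shape[1])[None, :]
        gH[cache["argmax"], c_idx] = g_pooled
        for k in range(len(enc.layers) - 1, -1, -1):
            d1, d2 = enc.layers[k]
            lc = cache["layers"][k]
            gH1 = d2.backward(lc["H1"], gH)
            gZ1 = gH1 * (lc["Z1"] > 0)
            gS = d1.backward(lc["S"], gZ1)
            eps = float(enc.params[f"gin{k}.eps"])
            enc.grads[f"gin{k}.eps"] += float(np.sum(gS * lc["H_in"]))
            gH = (1.0 + eps) * gS + fb.adjacency @ gS


def encode_graph(graph: MoleculeGraph, encoder: GinEncoder) -> np.ndarray:
    """Fixed-length representation x_d of one molecule."""
    X, A, mask = batch_graphs([graph])
    out, _ = encoder.forward(X, A, mask)
    return out[0]


# ---------------------------------------------------------------------------
# sequence encoder


class SequenceEncoder(ParamModule):
    """Mean-of-token-embeddings encoder with a single affine projection."""

    kind = "sequence"

    def __init__(
        self,
        config: SequenceEncoderConfig,
        provider: TokenEmbeddingProvider,
        rng: np.random.Generator,
    ) -> None:
        super().__init__()
        if provider.embedding_dim != config.embedding_dim:
            raise ValueError(
                f"provider width {provider.embedding_dim} != configured "
                f"embedding_dim {config.embedding_dim}"
            )
        self.config = config
        self.provider = provider
        self.proj = Dense(self, "proj", config.embedding_dim, config.output_dim, rng)
        self._table_trainable = config.provider_trainable and isinstance(
            provider, KmerLookupProvider
        )
        if self._table_trainable:
            # register the provider table so it is trained and checkpointed
            self.params["embed.table"] = provider.table
            self.grads["embed.table"] = np.zeros_like(provider.table)

    @property
    def output_dim(self) -> int:
        return self.config.output_dim

    def forward_mean(self, xbar: np.ndarray):
        """Project precomputed mean-token embeddings (B, d) -> (B, d')."""
        out = self.proj.forward(xbar)
        return out, {"xbar": xbar, "counts_norm": None}

    def forward_counts(self, counts: np.ndarray):
        """Training fast path from token-count vectors (B, vocab).

        The mean token embedding equals (counts / n_tokens) @ table, so the
        per-sequence cost is one matmul and gradients reach the table.
        """
        lengths = counts.sum(axis=1, keepdims=True)
        if np.any(lengths == 0):
            raise ValueError("sequence with zero tokens")
        counts_norm = counts / lengths
        xbar = counts_norm @ self.params["embed.table"]
        out = self.proj.forward(xbar)
        return out, {"xbar": xbar, "counts_norm": counts_norm}

    def backward(self, cache: dict, g_out: np.ndarray) -> None:
        g_xbar = self.proj.backward(cache["xbar"], g_out)
        if self._table_trainable and cache["counts_norm"] is not None:
            self.grads["embed.table"] += cache["counts_norm"].T @ g_xbar


def encode_sequence(
    sequence: str,
    provider: TokenEmbeddingProvider,
    encoder: SequenceEncoder,
) -> np.ndarray:
    """Fixed-length representation of one token sequence.

    The provider emits an (n, d) matrix, the mean over the n axis is taken,
    and the encoder's affine projection maps it to d'.
    """
    if len(sequence) == 0:
        raise ValueError("cannot encode an empty sequence")
    M = provider.embed(sequence)
    if M.ndim != 2 or M.shape[0] == 0:
        raise ValueError("provider must return an (n_tokens, d) matrix")
    xbar = M.mean(axis=0)
    out, _ = encoder.forward_mean(xbar[None, :])
    return out[0]


# ---------------------------------------------------------------------------
# encoder state / checkpoints


class FingerprintMismatchError(ValueError):
    """A checkpoint's architecture does not match the requested config."""


@dataclass
class EncoderState:
    """Transferable snapshot of one encoder's trainable parameters."""

    kind: str                      # "gin" | "sequence"
    params: dict[str, np.ndarray]
    config_dict: dict
    fingerprint: str
    format_version: int = CHECKPOINT_FORMAT_VERSION
    meta: dict = field(default_factory=dict)

    @classmethod
    def from_encoder(cls, encoder, meta: dict | None = None) -> "EncoderState":
        return cls(
            kind=encoder.kind,
            params=encoder.export_params(),
            config_dict=asdict(encoder.config),
            fingerprint=config_fingerprint(encoder.config),
            meta=dict(meta or {}),
        )

    def save(self, path) -> None:
        header = json.dumps(
            {
                "kind": self.kind,
                "config": self.config_dict,
                "fingerprint": self.fingerprint,
                "format_version": self.format_version,
                "meta": self.meta,
            }
        )
        arrays = {f"param::{k}": v for k, v in self.params.items()}
        arrays["__header__"] = np.frombuffer(header.encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "EncoderState":
        with np.load(path) as data:
            header = json.loads(bytes(data["__header__"]).decode())
            if header["format_version"] > CHECKPOINT_FORMAT_VERSION:
                raise ValueError(
                    f"checkpoint format v{header['format_version']} is newer "
                    f"than supported v{CHECKPOINT_FORMAT_VERSION}"
                )
            params = {
                k[len("param::"):]: data[k]
                for k in data.files
                if k.startswith("param::")
            }
        return cls(
            kind=header["kind"],
            params=params,
            config_dict=header["config"],
            fingerprint=header["fingerprint"],
            format_version=header["format_version"],
            meta=header["meta"],
        )

    def check_compatible(self, config) -> None:
        """Refuse transfer into a mismatched architecture, naming the fields."""
        want = config_fingerprint(config)
        if want == self.fingerprint:
            return
        other = asdict(config)
        diverging = sorted(
            k
            for k in set(self.config_dict) | set(other)
            if self.config_dict.get(k) != other.get(k)
        )
        raise FingerprintMismatchError(
            f"checkpoint fingerprint {self.fingerprint[:12]} != target "
            f"{want[:12]}; diverging fields: {diverging}"
        )

    def apply_to(self, encoder) -> None:
        self.check_compatible(encoder.config)
        encoder.load_params(self.params)
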