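"""Per-residue embeddings and the difference encoding of a variation.

A variation on a length-L protein is encoded as the element-wise difference
of two L x d per-residue embedding matrices,

    D = E_wt - E_vt,

which is exactly antisymmetric under swapping wild type and variant: the
same network input encodes a variation and, with flipped sign, its reverse.

Embedders implement a small contract (:class:`Embedder`): given a
:class:`~embddg.sequences.ProteinSequence` they return one embedding row
per residue, with any begin/end special tokens stripped. Two embedders are
provided: a deterministic k-mer-contextual mock used throughout the test
suite and desk-scale experiments, and an adapter to the pretrained ESM2
650M-parameter protein language model (d = 1280) for users with the
optional heavyweight dependencies installed.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import h5py
import numpy as np

from .sequences import ProteinSequence


class Embedder:
    """Contract for per-residue sequence embedders.

    Attributes
    ----------
    name : str
        Identifies the embedder (and keys the on-disk cache).
    d : int
        Embedding dimension.
    deterministic : bool
        Whether the same sequence always yields the same matrix.
    """

    name: str = "base"
    d: int = 0
    deterministic: bool = True
    max_length: int | None = None

    def embed(self, seq: ProteinSequence) -> np.ndarray:
        if self.max_length is not None and len(seq) > self.max_length:
            raise ValueError(
                f"sequence {seq.id!r} has length {len(seq)} > embedder "
                f"maximum {self.max_length}"
            )
        matrix = self._embed(seq)
        if matrix.shape != (len(seq), self.d):
            raise AssertionError(
                f"embedder {self.name!r} returned shape {matrix.shape}, "
                f"expected {(len(seq), self.d)}"
            )
        if not np.all(np.isfinite(matrix)):
            raise ValueError(f"non-finite embedding values for {seq.id!r}")
        return matrix

    def _embed(self, seq: ProteinSequence) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class MockEmbedder(Embedder):
    """Deterministic k-mer-contextual stand-in for a protein language model.

    Row j is a seeded pseudo-random function of the k-mer centred at
    position j (boundary-padded with ``-``), so a point substitution at p
    perturbs exactly the rows within distance (k-1)//2 of p. This mimics the
    essential property of contextual embeddings — a substitution changes
    representations beyond the varied position — without any pretrained
    weights, which is what makes the downstream difference encoding
    non-trivially sparse.

    Parameters
    ----------
    d : int
        Embedding dimension (default 32; real pLMs use much larger d).
    k : int
        Odd context-window width (default 7).
    seed : int
        Base seed; rows are drawn from a generator keyed by a stable hash
        of (seed, d, k-mer), so results are identical across processes.
    """

    deterministic = True

    def __init__(self, d: int = 32, k: int = 7, seed: int = 0):
        if d < 1:
            raise ValueError("embedding dimension d must be >= 1")
        if k < 1 or k % 2 == 0:
            raise ValueError("context window k must be odd and >= 1")
        self.d = int(d)
        self.k = int(k)
        self.seed = int(seed)
        self.name = f"mock-d{d}-k{k}-s{seed}"
        self._row_cache: dict[str, np.ndarray] = {}

    def _row(self, kmer: str) -> np.ndarray:
        row = self._row_cache.get(kmer)
        if row is None:
            key = f"{self.seed}:{self.d}:{self.k}:{kmer}".encode()
            digest = hashlib.blake2b(key, digest_size=8).digest()
            rng = np.random.default_rng(int.from_bytes(digest, "little"))
            row = rng.standard_normal(self.d)
            self._row_cache[kmer] = row
        return row

    def _embed(self, seq: ProteinSequence) -> np.ndarray:
        half = (self.k - 1) // 2
        padded = "-" * half + seq.residues + "-" * half
        return np.stack(
            [self._row(padded[j : j + self.k]) for j in range(len(seq))]
        )


class ESM2Embedder(Embedder):
    """Adapter to the pretrained ESM2 33-layer 650M-parameter model (d = 1280).

    Extracts per-residue representations from a configurable layer (default:
    the final, 33rd) and strips the begin/end special tokens so rows align
    1:1 with residues. Requires the optional ``torch`` and ``fair-esm``
    dependencies (``pip install embddg[esm]``).
    """

    deterministic = True

    def __init__(self, layer: int = 33, max_length: int | None = 1022):
        self.layer = int(layer)
        self.d = 1280
        self.max_length = max_length
        self.name = f"esm2-650M-layer{layer}"
        self._model = None
        self._batch_converter = None

    def _load(self):
        try:
            import esm  # type: ignore
            import torch  # type: ignore
        except ImportError as exc:  # pragma: no cover - exercised via message
            raise ImportError(
                "the ESM2 embedder requires the optional 'torch' and "
                "'fair-esm' packages; install with: pip install embddg[esm]"
            ) from exc
        model, alphabet = esm.pretrained.esm2_t33_650M_UR50D()
        model.eval()
        self._torch = torch
        self._model = model
        self._batch_converter = alphabet.get_batch_converter()

    def _embed(self, seq: ProteinSequence) -> np.ndarray:  # pragma: no cover
        if self._model is None:
            self._load()
        _, _, tokens = self._batch_converter([(seq.id, seq.residues)])
        with self._torch.no_grad():
            out = self._model(tokens, repr_layers=[self.layer])
        rep = out["representations"][self.layer][0]
        # token 0 is BOS; tokens 1..L are residues; strip BOS/EOS.
        return rep[1 : len(seq) + 1].cpu().numpy().astype(np.float64)


def difference_encoding(ewt: np.ndarray, evt: np.ndarray) -> np.ndarray:
    """Element-wise difference D = E_wt - E_vt of two equal-shape matrices.

    A shape mismatch signals an indel or misaligned rows and is an error:
    the encoding is defined only for length-preserving variations.
    """
    ewt = np.asarray(ewt, dtype=np.float64)
    evt = np.asarray(evt, dtype=np.float64)
    if ewt.shape != evt.shape:
        raise ValueError(
            f"embedding shape mismatch {ewt.shape} vs {evt.shape}: the "
            "difference encoding requires a length-preserving variation"
        )
    return ewt - evt


class EmbeddingCache:
    """HDF5-backed store of embedding matrices.

    Layout: one group per embedder name; within it, one float64 dataset of
    shape (L, d) per sequence, row-major, keyed by the SHA1 of the residue
    string (ids are kept as a dataset attribute ``sequence_id``). Cached
    matrices are returned bit-identically for deterministic embedders.
    """

    def __init__(self, path: str | Path):
        self.path = Path(path)

    @staticmethod
    def _key(seq: ProteinSequence) -> str:
        return hashlib.sha1(seq.residues.encode()).hexdigest()

    def get(self, seq: ProteinSequence, embedder: Embedder) -> np.ndarray:
        """Return the cached or freshly computed embedding of ``seq``."""
        key = self._key(seq)
        with h5py.File(self.path, "a") as fh:
            group = fh.require_group(embedder.name)
            if key in group:
                return np.asarray(group[key], dtype=np.float64)
            matrix = embedder.embed(seq)
            dset = group.create_dataset(key, data=matrix, dtype="f8")
            dset.attrs["sequence_id"] = seq.id
            dset.attrs["L"] = len(seq)
            dset.attrs["d"] = embedder.d
            return matrix

    def contains(self, seq: ProteinSequence, embedder: Embedder) -> bool:
        if not self.path.exists():
            return False
        with h5py.File(self.path, "r") as fh:
            return embedder.name in fh and self._key(seq) in fh[embedder.name]
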