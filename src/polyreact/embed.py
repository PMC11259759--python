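"""Per-residue sequence embeddings behind a uniform contract.

Production adapters for pretrained protein language models (AntiBERTy 512-d,
ProtT5 1024-d, ESM2 1280-d) are optional plugins; the default embedder is a
deterministic mock whose rows concatenate a one-hot residue identity, the
Kyte-Doolittle hydropathy, the side-chain charge at pH 7.4, and sinusoidal
position features, tiled or truncated to the requested feature dimension.
The mock carries the real signal the ground-truth rule uses (charge and
hydrophobicity), so downstream training is a genuine recovery problem while
staying download-free.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .errors import DependencyError, LengthError, ValidationError
from .residues import AA_INDEX, AMINO_ACIDS, CHARGE_PH74, KYTE_DOOLITTLE


@dataclass(frozen=True)
class EmbedderSpec:
    name: str
    feature_dim: int
    special_tokens_per_domain: int
    max_input_len: int
    deterministic: bool = True

    def __post_init__(self):
        if self.feature_dim <= 0:
            raise ValidationError("feature_dim must be positive")
        if self.special_tokens_per_domain < 0:
            raise ValidationError("special token count must be >= 0")


#: specs of the external PLM adapters (feature dim, marker rows, input limit)
ANTIBERTY_SPEC = EmbedderSpec("antiberty", 512, 2, 510)
PROTT5_SPEC = EmbedderSpec("prott5", 1024, 1, 4000)
ESM2_SPEC = EmbedderSpec("esm2", 1280, 2, 1022)


class MockEmbedder:
    """Deterministic offline per-residue embedder.

    Row layout before tiling/truncation: 20 one-hot identity channels,
    1 hydropathy channel (Kyte-Doolittle / 4.5), 1 charge channel (pH 7.4),
    then interleaved sin/cos position features.  Special-token rows are fixed
    sentinel vectors (alternating +-0.5), one prepended and one appended when
    ``special_tokens_per_domain`` is 2, appended only when it is 1.
    """

    N_BASE = 22  # one-hot + hydropathy + charge

    def __init__(self, feature_dim: int = 32, special_tokens_per_domain: int = 2,
                 max_input_len: int = 510):
        self.spec = EmbedderSpec(
            name=f"mock{feature_dim}",
            feature_dim=feature_dim,
            special_tokens_per_domain=special_tokens_per_domain,
            max_input_len=max_input_len,
        )

    # -- helpers ----------------------------------------------------------
    def _position_features(self, n_pos: int, n_feat: int) -> np.ndarray:
        if n_feat <= 0:
            return np.zeros((n_pos, 0), dtype=np.float32)
        pos = np.arange(n_pos, dtype=np.float64)[:, None]
        i = np.arange(n_feat, dtype=np.float64)[None, :]
        angle = pos / np.power(10000.0, 2.0 * (i // 2) / max(n_feat, 1))
        feats = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
        return feats.astype(np.float32)

    def _sentinel(self, which: int) -> np.ndarray:
        d = self.spec.feature_dim
        row = 0.5 * np.where(np.arange(d) % 2 == which, 1.0, -1.0)
        return row.astype(np.float32)

    # -- contract ---------------------------------------------------------
    def embed(self, sequence: str) -> np.ndarray:
        """(len + special_tokens, feature_dim) matrix for one sequence."""
        spec = self.spec
        if len(sequence) + spec.special_tokens_per_domain > spec.max_input_len:
            raise LengthError(
                f"sequence of {len(sequence)} residues exceeds the embedder "
                f"input limit of {spec.max_input_len}"
            )
        bad = sorted({c for c in sequence if c not in AA_INDEX})
        if bad:
            raise ValidationError(f"unknown residues {bad} in sequence")
        n = len(sequence)
        idx = np.fromiter((AA_INDEX[c] for c in sequence), dtype=np.int64, count=n)
        onehot = np.zeros((n, len(AMINO_ACIDS)), dtype=np.float32)
        onehot[np.arange(n), idx] = 1.0
        kd = np.array([KYTE_DOOLITTLE[c] / 4.5 for c in sequence],
                      dtype=np.float32)[:, None]
        charge = np.array([CHARGE_PH74[c] for c in sequence],
                          dtype=np.float32)[:, None]
        base = np.concatenate([onehot, kd, charge], axis=1)
        d = spec.feature_dim
        if d <= self.N_BASE:
            body = base[:, :d]
        else:
            body = np.concatenate(
                [base, self._position_features(n, d - self.N_BASE)], axis=1
            )
        rows = [body]
        if spec.special_tokens_per_domain >= 2:
            rows.insert(0, self._sentinel(0)[None, :])
        if spec.special_tokens_per_domain >= 1:
            rows.append(self._sentinel(1)[None, :])
        return np.concatenate(rows, axis=0)


def pool_per_protein(matrix: np.ndarray) -> np.ndarray:
    """Mean over non-padding residue rows -> (feature_dim,) vector.

    Padding rows are all-zero; a matrix with no non-padding row is an error.
    """
    matrix = np.asarray(matrix)
    if matrix.ndim != 2 or matrix.size == 0:
        raise ValidationError("expected a non-empty (rows, features) matrix")
    keep = np.any(matrix != 0, axis=1)
    if not keep.any():
        raise ValidationError("all rows are padding; nothing to pool")
    return matrix[keep].mean(axis=0)


# ---------------------------------------------------------------------------
# cache


class EmbeddingCache:
    """In-memory + NPZ-backed cache keyed by (embedder name, sequence hash)."""

    def __init__(self, embedder) -> None:
        self.embedder = embedder
        self._store: dict[str, np.ndarray] = {}

    @staticmethod
    def _key(name: str, sequence: str) -> str:
        h = hashlib.sha1(sequence.encode()).hexdigest()[:16]
        return f"{name}__{h}"

    def get(self, sequence: str) -> np.ndarray:
        key = self._key(self.embedder.spec.name, sequence)
        if key not in self._store:
            self._store[key] = self.embedder.embed(sequence)
        return self._store[key]

    def save(self, path) -> None:
        """Write the cache as an NPZ archive, byte-reproducibly.

        The zip members carry a fixed timestamp so that reruns with the same
        inputs produce identical archives.
        """
        import io
        import zipfile

        with zipfile.ZipFile(Path(path), "w", zipfile.ZIP_DEFLATED) as zf:
            for key in sorted(self._store):
                buf = io.BytesIO()
                np.lib.format.write_array(buf, self._store[key])
                info = zipfile.ZipInfo(f"{key}.npy", date_time=(1980, 1, 1, 0, 0, 0))
                info.compress_type = zipfile.ZIP_DEFLATED
                zf.writestr(info, buf.getvalue())

    def load(self, path) -> None:
        with np.load(Path(path)) as npz:
            self._store.update({k: npz[k] for k in npz.files})

    def __len__(self) -> int:
        return len(self._store)


# ---------------------------------------------------------------------------
# optional external adapters (never imported by the test suite)


def load_external_embedder(name: str):  # pragma: no cover - needs downloads
    """Instantiate a pretrained-PLM adapter; requires the external package."""
    if name == "antiberty":
        try:
            from antiberty import AntiBERTyRunner
        except ImportError as exc:
            raise DependencyError("antiberty is not installed") from exc
        runner = AntiBERTyRunner()

        class _Antiberty:
            spec = ANTIBERTY_SPEC

            def embed(self, sequence: str) -> np.ndarray:
                (emb,) = runner.embed([sequence])
                return emb.detach().cpu().numpy()

        return _Antiberty()
    if name == "esm2":
        try:
            import esm
        except ImportError as exc:
            raise DependencyError("fair-esm is not installed") from exc
        model, alphabet = esm.pretrained.esm2_t33_650M_UR50D()
        converter = alphabet.get_batch_converter()

        class _ESM2:
            spec = ESM2_SPEC

            def embed(self, sequence: str) -> np.ndarray:
                import torch

                _, _, toks = converter([("x", sequence)])
                with torch.no_grad():
                    out = model(toks, repr_layers=[33])
                return out["representations"][33][0].numpy()

        return _ESM2()
    raise DependencyError(f"no adapter for embedder {name!r}")
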