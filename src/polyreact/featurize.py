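"""Numeric inputs for the classifier.

Four inputs describe one assay point:

* ``input1`` — the per-residue embedding block.  Under the location-matrix
  scheme each of the four var slots occupies a fixed band of
  ``max_domain_len + special_tokens_per_domain`` rows (trailing zero padding),
  giving a residue axis of ``4 * (max_domain_len + special)`` — 536 rows for
  a 132-residue capacity with 2 special tokens, 532 with 1.
* ``input2`` — well coating: BSA -> 0, BVP -> 1.
* ``input3`` — concentration, normalized to [0, 1] as
  ``1 - log(nM) / log(667)`` (667 nM, the assay's top concentration, maps
  to 0; 1 nM maps to 1; values outside [1, 667] nM are clamped).
* ``input4`` — the length-4 location vector (omitted by the G4S scheme,
  which instead fuses same-chain domains with a GGGGS linker).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import LengthError, ValidationError
from .records import CHAIN_SLOTS, VariableDomainSet


@dataclass(frozen=True)
class EncodingConfig:
    scheme: str = "location_matrix"  # or "g4s"
    max_domain_len: int = 132
    n_slots: int = 4
    special_tokens_per_domain: int = 2
    g4s_linker: str = "GGGGS"
    reference_conc_nM: float = 667.0
    #: per-chain capacity for the G4S scheme (not derivable from slot
    #: arithmetic; bounded by the embedder input limit)
    g4s_chain_capacity: int = 510

    def __post_init__(self):
        if self.scheme not in ("location_matrix", "g4s"):
            raise ValidationError(f"unknown encoding scheme {self.scheme!r}")
        if self.max_domain_len <= 0:
            raise ValidationError("max_domain_len must be positive")
        if self.n_slots != 4:
            raise ValidationError("n_slots is fixed at 4")

    @property
    def slot_height(self) -> int:
        return self.max_domain_len + self.special_tokens_per_domain

    @property
    def residue_axis(self) -> int:
        return self.n_slots * self.slot_height


@dataclass
class ModelInputs:
    """Assembled tensors for one assay point (or a batch)."""

    input1: np.ndarray  # (residue_axis, feature_dim, 1)
    input2: float  # coating code
    input3: float  # normalized concentration
    input4: Optional[np.ndarray] = None  # (4,) location vector


def normalize_concentration(conc_nM: float, reference: float = 667.0) -> float:
    """Map concentration (nM) to [0, 1]: 1 - log(c)/log(reference), clamped."""
    if conc_nM <= 0:
        raise ValidationError(f"concentration must be positive, got {conc_nM}")
    x = 1.0 - math.log(conc_nM) / math.log(reference)
    return min(1.0, max(0.0, x))


def encode_coating(coating: str) -> int:
    """BSA -> 0, BVP -> 1 (case-insensitive, whitespace-trimmed)."""
    key = coating.strip().upper()
    if key == "BSA":
        return 0
    if key == "BVP":
        return 1
    raise ValidationError(f"unknown coating {coating!r} (expected BVP or BSA)")


def encode_label(fold_over_control: float, threshold: float = 2.0) -> int:
    """Clean (0) when fold over control <= threshold, polyreactive (1) above."""
    if fold_over_control < 0:
        raise ValidationError(
            f"fold over control must be non-negative, got {fold_over_control}"
        )
    return 0 if fold_over_control <= threshold else 1


def g4s_concatenate(
    domain_set: VariableDomainSet, config: EncodingConfig
) -> list[str]:
    """One sequence per occupied chain; same-chain domains joined by GGGGS.

    Whatever natively connects the domains (engineered linkers, constant
    regions) is discarded.  Output order HC1, LC1, HC2, LC2.
    """
    doms = domain_set.domains()
    out: list[str] = []
    for slot in CHAIN_SLOTS:
        indices = domain_set.per_chain_groups.get(slot)
        if not indices:
            continue
        seq = config.g4s_linker.join(doms[i - 1] for i in indices)
        limit = config.g4s_chain_capacity - config.special_tokens_per_domain
        if len(seq) > limit:
            raise LengthError(
                f"G4S-concatenated chain {slot} has {len(seq)} residues, "
                f"exceeding the capacity of {limit}"
            )
        out.append(seq)
    return out


def build_location_matrix(domain_set: VariableDomainSet) -> np.ndarray:
    """Length-4 integer vector of chain-of-origin codes, zero-padded."""
    return np.asarray(domain_set.location, dtype=np.int64)


def assemble_input1(
    per_domain_embeddings: Sequence[Optional[np.ndarray]],
    config: EncodingConfig,
) -> np.ndarray:
    """Stack up to four per-domain embedding matrices into the input1 block.

    Each domain is right-padded with zero rows to the uniform slot height;
    empty slots are all-zero bands.  Returns (residue_axis, feature_dim, 1).
    """
    mats = [m for m in per_domain_embeddings if m is not None]
    if not mats:
        raise ValidationError("at least one domain embedding is required")
    feature_dim = mats[0].shape[1]
    H = config.slot_height
    out = np.zeros((config.n_slots * H, feature_dim), dtype=np.float32)
    if len(per_domain_embeddings) > config.n_slots:
        raise ValidationError(
            f"at most {config.n_slots} domain embeddings supported"
        )
    for slot, mat in enumerate(per_domain_embeddings):
        if mat is None:
            continue
        if mat.shape[1] != feature_dim:
            raise ValidationError("inconsistent feature dimensions across domains")
        if mat.shape[0] > H:
            raise LengthError(
                f"domain embedding with {mat.shape[0]} rows exceeds the slot "
                f"height of {H} (capacity {config.max_domain_len} + "
                f"{config.special_tokens_per_domain} special tokens)"
            )
        out[slot * H : slot * H + mat.shape[0]] = mat
    return out[:, :, None]


def g4s_residue_axis(config: EncodingConfig, n_chains: int = 2,
                     max_domains_per_chain: int = 2) -> int:
    """Residue axis under the G4S scheme: room for two fused-domain chains."""
    per_chain = (
        max_domains_per_chain * config.max_domain_len
        + (max_domains_per_chain - 1) * len(config.g4s_linker)
        + config.special_tokens_per_domain
    )
    return n_chains * per_chain


@dataclass
class BatchInputs:
    """Batched model inputs (and optionally labels)."""

    x1: np.ndarray  # (N, H, W) embedding blocks
    x2: np.ndarray  # (N,) coating codes
    x3: np.ndarray  # (N,) normalized concentrations
    x4: Optional[np.ndarray] = None  # (N, 4) location vectors
    y: Optional[np.ndarray] = None  # (N,) binary labels

    def __len__(self) -> int:
        return self.x1.shape[0]

    def take(self, idx) -> "BatchInputs":
        return BatchInputs(
            x1=self.x1[idx],
            x2=self.x2[idx],
            x3=self.x3[idx],
            x4=None if self.x4 is None else self.x4[idx],
            y=None if self.y is None else self.y[idx],
        )


def featurize_points(points, domain_sets: dict, embedder,
                     config: Optional[EncodingConfig] = None) -> BatchInputs:
    """Assemble batched model inputs for a list of assay points.

    ``domain_sets`` maps antibody id to its :class:`VariableDomainSet`.
    Embedding blocks are shared between assay points of the same antibody
    (conditions differ only in input2/input3), so each molecule is embedded
    once.
    """
    from .embed import EmbeddingCache  # local import to avoid a cycle

    config = config or EncodingConfig()
    cache = embedder if isinstance(embedder, EmbeddingCache) else EmbeddingCache(embedder)
    block_by_id: dict[str, np.ndarray] = {}

    def block_for(ab_id: str) -> np.ndarray:
        if ab_id not in block_by_id:
            ds = domain_sets[ab_id]
            if config.scheme == "location_matrix":
                mats = [cache.get(d) if d is not None else None
                        for d in ds.domains()]
                block = assemble_input1(mats, config)[:, :, 0]
            else:
                rows = np.concatenate(
                    [cache.get(s) for s in g4s_concatenate(ds, config)], axis=0
                )
                H = g4s_residue_axis(config)
                if rows.shape[0] > H:
                    raise LengthError(
                        f"antibody {ab_id}: G4S block of {rows.shape[0]} rows "
                        f"exceeds the residue axis of {H}"
                    )
                block = np.zeros((H, rows.shape[1]), dtype=np.float32)
                block[: rows.shape[0]] = rows
            block_by_id[ab_id] = block
        return block_by_id[ab_id]

    x1, x2, x3, x4, y = [], [], [], [], []
    for p in points:
        x1.append(block_for(p.antibody.id))
        x2.append(encode_coating(p.coating))
        x3.append(normalize_concentration(p.concentration_nM,
                                          config.reference_conc_nM))
        if config.scheme == "location_matrix":
            x4.append(build_location_matrix(domain_sets[p.antibody.id]))
        y.append(p.label)
    return BatchInputs(
        x1=np.stack(x1).astype(np.float32),
        x2=np.asarray(x2, dtype=np.float32),
        x3=np.asarray(x3, dtype=np.float32),
        x4=np.stack(x4).astype(np.float32) if x4 else None,
        y=np.asarray(y, dtype=np.float32),
    )


def pool_batch(batch: BatchInputs) -> BatchInputs:
    """Convert per-residue blocks to per-protein pooled rows (1D variant)."""
    from .embed import pool_per_protein

    pooled = np.stack([pool_per_protein(b) for b in batch.x1])
    return BatchInputs(
        x1=pooled[:, None, :].astype(np.float32),
        x2=batch.x2, x3=batch.x3, x4=batch.x4, y=batch.y,
    )
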