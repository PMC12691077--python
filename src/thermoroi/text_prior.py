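"""Anatomical text bank and deterministic text-feature encoding.

The detector is text-conditioned: each category is a short anatomical
description rather than a bare one-hot label. The default bank holds five
categories — the two measurement ROIs (LU: lower udder, AA: around the
anus) plus three auxiliary linking regions (RU: rear udder, hind legs,
hind quarters) whose descriptions chain the ROIs into one spatial
structure (LU -> hind legs -> hind quarters enclosing RU and AA). The
spatial prior is therefore data, not code: it lives in the descriptions.

No pretrained language model is bundled; ``encode_text`` is a seeded
hashing bag-of-words embedder, and any callable with the same signature
can be plugged in instead.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "CATEGORIES",
    "TextEntry",
    "TextFeatures",
    "load_text_bank",
    "save_text_bank",
    "encode_text",
    "encode_bank",
    "pool_tokens",
    "tokenize",
]

CATEGORIES = ("LU", "AA", "RU", "hind_legs", "hind_quarters")


@dataclass(frozen=True)
class TextEntry:
    category: str
    description: str
    is_roi: bool

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if not self.description.strip():
            raise ValueError(f"empty description for {self.category}")


@dataclass(frozen=True)
class TextFeatures:
    """Token features (L x D) and their L2-normalised mean pooling (D,)."""

    tokens: np.ndarray
    pooled: np.ndarray


def load_text_bank(path: str | Path | None = None) -> list[TextEntry]:
    """Load a JSON text bank; ``None`` loads the bundled five-category bank."""
    if path is None:
        raw = resources.files("thermoroi.data").joinpath("textbank_default.json").read_text()
    else:
        raw = Path(path).read_text()
    records = json.loads(raw)
    if not isinstance(records, list):
        raise ValueError("text bank must be a JSON array")
    entries = [TextEntry(r["category"], r["description"], bool(r["is_roi"])) for r in records]
    seen = set()
    for e in entries:
        if e.category in seen:
            raise ValueError(f"duplicate category {e.category!r}")
        seen.add(e.category)
    if sum(e.is_roi for e in entries) < 1:
        raise ValueError("text bank must flag at least one ROI category")
    return entries


def save_text_bank(entries: Sequence[TextEntry], path: str | Path) -> None:
    records = [
        {"category": e.category, "description": e.description, "is_roi": e.is_roi}
        for e in entries
    ]
    Path(path).write_text(json.dumps(records, indent=2) + "\n")


def tokenize(text: str) -> list[str]:
    """Lowercase and split on non-alphanumeric runs."""
    return [t for t in re.split(r"[^a-z0-9]+", text.lower()) if t]


def _token_vector(token: str, dim: int, seed: int) -> np.ndarray:
    digest = hashlib.sha256(f"{seed}:{token}".encode()).digest()
    rng = np.random.default_rng(int.from_bytes(digest[:8], "little"))
    return rng.standard_normal(dim)


def encode_text(entry: TextEntry, dim: int = 64, seed: int = 0) -> TextFeatures:
    """Deterministic hashing embedding: one vector per token, mean-pooled.

    Identical (text, dim, seed) always yields bit-identical features; the
    pooled vector is L2-normalised.
    """
    if dim < 8:
        raise ValueError("dim must be >= 8")
    toks = tokenize(entry.description)
    if not toks:
        raise ValueError("description has no tokens")
    mat = np.stack([_token_vector(t, dim, seed) for t in toks])
    pooled = pool_tokens(mat)
    pooled = pooled / np.linalg.norm(pooled)
    return TextFeatures(tokens=mat, pooled=pooled)


def encode_bank(
    entries: Sequence[TextEntry], dim: int = 64, seed: int = 0
) -> np.ndarray:
    """Stacked pooled embeddings, one row per bank entry (K x D)."""
    return np.stack([encode_text(e, dim, seed).pooled for e in entries])


def pool_tokens(tokens: np.ndarray) -> np.ndarray:
    """Arithmetic mean over the token axis of an L x D matrix."""
    tokens = np.asarray(tokens, dtype=float)
    if tokens.ndim != 2 or tokens.shape[0] < 1:
        raise ValueError("tokens must be a non-empty L x D matrix")
    return tokens.mean(axis=0)
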