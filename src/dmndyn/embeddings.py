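"""Vector-space embedding providers for semantic-distance scoring.

Originality scoring is backend-relative: any deterministic token -> vector
mapping can serve.  Two backends are bundled: a hashed random-projection
provider (fully deterministic, no data files, used throughout the tests) and
a loader for pretrained word vectors in the common one-vector-per-line text
format.  The simulator builds a third kind, a frozen vocabulary with planted
cue-response geometry (see :mod:`dmndyn.simulate`).
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Iterable, Protocol, runtime_checkable

import numpy as np

from .errors import FormatError


@runtime_checkable
class EmbeddingProvider(Protocol):
    """Contract: deterministic token lookup with a fixed dimension.

    ``vector`` returns None for out-of-vocabulary tokens; callers decide the
    OOV policy (scoring skips OOV tokens and excludes all-OOV responses).
    """

    name: str
    dim: int

    def vector(self, token: str) -> np.ndarray | None: ...


def sentence_vector(provider: EmbeddingProvider, tokens: Iterable[str]) -> np.ndarray | None:
    """Mean of in-vocabulary token vectors; None if every token is OOV.

    Used for response-vs-response geometry (variability, flexibility), as
    distinct from the multiplicative cue-distance composition in
    :func:`dmndyn.behavior.originality`.
    """
    vecs = [v for v in (provider.vector(t) for t in tokens) if v is not None]
    if not vecs:
        return None
    return np.mean(vecs, axis=0)


class HashedProjectionProvider:
    """Deterministic pseudo-embedding: each token hashes to a Gaussian vector.

    Carries no semantics, but gives reproducible, well-spread unit vectors,
    which is all the scoring pipeline's geometry requires in tests.
    """

    def __init__(self, dim: int = 64, seed: int = 0, name: str = "hashed-projection"):
        self.dim = int(dim)
        self.seed = int(seed)
        self.name = name

    def vector(self, token: str) -> np.ndarray:
        digest = hashlib.blake2b(f"{self.seed}:{token}".encode("utf-8"),
                                 digest_size=8).digest()
        rng = np.random.default_rng(int.from_bytes(digest, "little"))
        v = rng.standard_normal(self.dim)
        return v / np.linalg.norm(v)


class VocabularyProvider:
    """Fixed token -> vector table."""

    def __init__(self, vectors: dict[str, np.ndarray], name: str = "vocabulary"):
        if not vectors:
            raise FormatError("empty vocabulary")
        dims = {len(v) for v in vectors.values()}
        if len(dims) != 1:
            raise FormatError(f"inconsistent vector dimensions: {sorted(dims)}")
        self.vectors = {t: np.asarray(v, dtype=float) for t, v in vectors.items()}
        self.dim = dims.pop()
        self.name = name

    def vector(self, token: str) -> np.ndarray | None:
        return self.vectors.get(token)


def load_word_vectors(path: str | Path, name: str | None = None) -> VocabularyProvider:
    """Read text-format word vectors: one ``token v1 v2 ...`` line per token.

    A first line of two integers (vocab size, dimension) is accepted and
    skipped, matching the common pretrained-vector header convention.
    """
    path = Path(path)
    vectors: dict[str, np.ndarray] = {}
    with open(path, encoding="utf-8") as f:
        for i, line in enumerate(f):
            parts = line.rstrip("\n").split(" ")
            if i == 0 and len(parts) == 2:
                continue
            if len(parts) < 2:
                raise FormatError(f"{path}:{i + 1}: malformed vector line")
            try:
                vectors[parts[0]] = np.array([float(x) for x in parts[1:]])
            except ValueError as exc:
                raise FormatError(f"{path}:{i + 1}: non-numeric vector entry") from exc
    return VocabularyProvider(vectors, name or path.stem)
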