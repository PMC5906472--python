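"""Shared low-level helpers: base encoding and reproducible sub-seeding."""

from __future__ import annotations

import hashlib

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

_DECODER = np.frombuffer(b"ACGT", dtype=np.uint8)
_RC_TABLE = str.maketrans("ACGT", "TGCA")

# ord(base) -> 0..3 lookup; 255 marks a non-ACGT byte
_ENCODER = np.full(256, 255, dtype=np.uint8)
for _b, _i in BASE_INDEX.items():
    _ENCODER[ord(_b)] = _i


def encode(bases: str) -> np.ndarray:
    """Map an ACGT string to a uint8 array with A=0, C=1, G=2, T=3."""
    codes = _ENCODER[np.frombuffer(bases.encode("ascii"), dtype=np.uint8)]
    if codes.size and codes.max() > 3:
        bad = bases[int(np.argmax(codes > 3))]
        raise ValueError(f"non-ACGT character {bad!r} in sequence")
    return codes


def decode(codes: np.ndarray) -> str:
    return _DECODER[np.asarray(codes, dtype=np.uint8)].tobytes().decode("ascii")


def revcomp(bases: str) -> str:
    return bases.translate(_RC_TABLE)[::-1]


def derive_seed(root: int, *tokens) -> int:
    """Stable 31-bit child seed from a root seed plus arbitrary hashable tokens.

    Uses SHA-256 of the repr so that (seed, gene_id, replicate) streams are
    reproducible in isolation, independent of generation order.
    """
    digest = hashlib.sha256(repr((int(root),) + tokens).encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def spawn_rng(root: int, *tokens) -> np.random.Generator:
    return np.random.default_rng(derive_seed(root, *tokens))
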