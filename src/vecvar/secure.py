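"""Backend contract for encryption, SIMD-slot arithmetic and key switching.

The protocol needs only a small algebra over encrypted integer vectors:
chunked encryption under a public key (``ceil(len/l)`` ciphertexts of slot
bound ``l``), slot-wise addition and multiplication (ciphertext-ciphertext
and ciphertext-plaintext), logical slot shifts, and key switching (proxy
re-encryption: converting a ciphertext to a different secret key via a public
switching key, without decryption).

:class:`PlainBackend` is the mandatory, bit-exact plaintext mock: it stores
slot values verbatim, tags every ciphertext with its key id, and refuses
mismatched-key operations — so every protocol error is testable without any
cryptography.  A real homomorphic-encryption adapter can replace it behind
the same contract; nothing above this module may depend on anything but the
contract.  Server-side operations never take a secret key.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DEFAULT_SLOT_BOUND",
    "KeyPair",
    "PublicKey",
    "SecretKey",
    "SwitchKey",
    "CipherVector",
    "KeyMismatchError",
    "ShapeMismatchError",
    "HeadroomError",
    "PlainBackend",
]

#: Default SIMD slot count per ciphertext (typical for the target scheme family).
DEFAULT_SLOT_BOUND = 32768


class KeyMismatchError(ValueError):
    """Operation attempted with a ciphertext/key id pair that does not match."""


class ShapeMismatchError(ValueError):
    """Operands have different logical lengths or slot bounds."""


class HeadroomError(OverflowError):
    """A slot value (or reachable sum) exceeds the backend's representable range."""


@dataclass(frozen=True)
class PublicKey:
    key_id: str


@dataclass(frozen=True)
class SecretKey:
    key_id: str


@dataclass(frozen=True)
class KeyPair:
    key_id: str
    public: PublicKey
    secret: SecretKey


@dataclass(frozen=True)
class SwitchKey:
    """Directional re-encryption key: usable only on from_key ciphertexts."""

    from_key: str
    to_key: str


@dataclass
class CipherVector:
    """Key-tagged sequence of encrypted chunks holding a logical vector."""

    chunks: list[np.ndarray]
    slot_bound: int
    key_id: str
    length: int

    def __post_init__(self):
        if len(self.chunks) != math.ceil(self.length / self.slot_bound):
            raise ShapeMismatchError(
                f"{len(self.chunks)} chunks != ceil({self.length}/{self.slot_bound})"
            )

    @property
    def n_chunks(self) -> int:
        return len(self.chunks)


class PlainBackend:
    """Exact integer-arithmetic mock of the encrypted backend.

    ``max_slot_value`` is the declared headroom contract: encryption refuses
    values whose magnitude exceeds it, so callers must prove their reachable
    sums fit (packed impact values need 2**58; aggregation needs 2*n_G).
    """

    def __init__(self, slot_bound: int = DEFAULT_SLOT_BOUND, max_slot_value: int = 1 << 62):
        if slot_bound < 1:
            raise ValueError("slot bound must be positive")
        self.slot_bound = slot_bound
        self.max_slot_value = max_slot_value
        self._counter = 0

    # -- key management (trusted entity side) -----------------------------
    def keygen(self) -> KeyPair:
        self._counter += 1
        kid = f"key-{self._counter:05d}"
        return KeyPair(key_id=kid, public=PublicKey(kid), secret=SecretKey(kid))

    def gen_switch_key(self, sk_from: SecretKey, sk_to: SecretKey) -> SwitchKey:
        return SwitchKey(from_key=sk_from.key_id, to_key=sk_to.key_id)

    # -- client side -------------------------------------------------------
    def encrypt(self, values, pk: PublicKey) -> CipherVector:
        arr = np.asarray(values, dtype=np.int64)
        if arr.ndim != 1:
            raise ShapeMismatchError("only 1-D vectors are encrypted")
        if arr.size and int(np.abs(arr).max()) > self.max_slot_value:
            raise HeadroomError(
                f"slot value exceeds declared headroom {self.max_slot_value}"
            )
        l = self.slot_bound
        chunks = [arr[i : i + l].copy() for i in range(0, len(arr), l)]
        return CipherVector(chunks=chunks, slot_bound=l, key_id=pk.key_id, length=len(arr))

    def decrypt(self, cv: CipherVector, sk: SecretKey) -> np.ndarray:
        if cv.key_id != sk.key_id:
            raise KeyMismatchError(
                f"ciphertext under {cv.key_id} cannot be decrypted with {sk.key_id}"
            )
        return (
            np.concatenate(cv.chunks) if cv.chunks else np.empty(0, dtype=np.int64)
        )

    # -- server side (no secret keys ever) ---------------------------------
    def _check_pair(self, a: CipherVector, b: CipherVector):
        if a.key_id != b.key_id:
            raise KeyMismatchError(f"mixed keys {a.key_id} / {b.key_id}")
        if a.length != b.length or a.slot_bound != b.slot_bound:
            raise ShapeMismatchError(
                f"length/slot mismatch: {a.length}/{a.slot_bound} vs {b.length}/{b.slot_bound}"
            )

    def _zip_plain(self, cv: CipherVector, plain) -> list[np.ndarray]:
        arr = np.asarray(plain, dtype=np.int64)
        if arr.ndim != 1 or len(arr) != cv.length:
            raise ShapeMismatchError(f"plain length {arr.shape} != {cv.length}")
        l = cv.slot_bound
        return [arr[i : i + l] for i in range(0, len(arr), l)]

    def add(self, a: CipherVector, b: CipherVector) -> CipherVector:
        self._check_pair(a, b)
        return CipherVector(
            [x + y for x, y in zip(a.chunks, b.chunks)], a.slot_bound, a.key_id, a.length
        )

    def mul(self, a: CipherVector, b: CipherVector) -> CipherVector:
        self._check_pair(a, b)
        return CipherVector(
            [x * y for x, y in zip(a.chunks, b.chunks)], a.slot_bound, a.key_id, a.length
        )

    def mul_plain(self, cv: CipherVector, plain) -> CipherVector:
        pchunks = self._zip_plain(cv, plain)
        return CipherVector(
            [x * p for x, p in zip(cv.chunks, pchunks)], cv.slot_bound, cv.key_id, cv.length
        )

    def add_plain(self, cv: CipherVector, plain) -> CipherVector:
        pchunks = self._zip_plain(cv, plain)
        return CipherVector(
            [x + p for x, p in zip(cv.chunks, pchunks)], cv.slot_bound, cv.key_id, cv.length
        )

    def shift(self, cv: CipherVector, k: int) -> CipherVector:
        """Logical shift over the whole vector: result[i] = input[i + k]
        (zero fill outside).  Realized by rotations + masking in a real
        backend; exact here."""
        flat = np.concatenate(cv.chunks) if cv.chunks else np.empty(0, dtype=np.int64)
        out = np.zeros_like(flat)
        n = len(flat)
        if k >= 0:
            if k < n:
                out[: n - k] = flat[k:]
        else:
            if -k < n:
                out[-k:] = flat[: n + k]
        l = cv.slot_bound
        return CipherVector(
            [out[i : i + l] for i in range(0, n, l)], l, cv.key_id, cv.length
        )

    def key_switch(self, cv: CipherVector, swk: SwitchKey) -> CipherVector:
        if cv.key_id != swk.from_key:
            raise KeyMismatchError(
                f"switch key is for {swk.from_key}, ciphertext is under {cv.key_id}"
            )
        return CipherVector(
            [c.copy() for c in cv.chunks], cv.slot_bound, swk.to_key, cv.length
        )
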