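"""Allele-frequency aggregation over (encrypted) genotype matrices.

SNV and insertion-position counts are slot-wise sums over samples,
``f_a(nu) = sum_k G_{a,k}(nu)`` — under encryption this is just a sum of
ciphertexts.  Deletions are aggregated from the 1-bp deletion state matrix
with an exact-span indicator: a sample contributes to the length-``l_d``
count at ``nu`` iff its deletion state is 1 on every position of
``[nu, nu+l_d]`` and 0 at both flanks ``nu-1`` and ``nu+l_d+1`` (flanks
outside the vector, or outside the containing region, read as 0; spans
crossing a stitched region boundary never count — only deletions engulfed in
a target region are aggregated).  Note the printed span convention covers
``l_d + 1`` positions; :func:`aggregate_deletion_span` takes the deleted-base
count instead.

Counts are returned raw; allele frequency = count / (2 * n_G) is a
presentation-layer division so that everything stays integer-exact under
encryption.  Multi-source pooling key-switches every source to a common
(researcher) key before summation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .secure import CipherVector, KeyMismatchError, PlainBackend, PublicKey, SwitchKey
from .targets import TargetRegionSet
from .variants import GenotypeMatrix

__all__ = [
    "FrequencyVector",
    "aggregate_snv",
    "insertion_position_frequency",
    "aggregate_deletion_length",
    "aggregate_deletion_span",
    "encrypt_genotype_columns",
    "aggregate_encrypted",
    "aggregate_deletion_length_encrypted",
    "pool_and_aggregate",
    "write_frequency_tsv",
]


@dataclass
class FrequencyVector:
    """Per-position aggregate allele counts over n_G samples (M sources)."""

    allele: str
    counts: np.ndarray  # int64, length l_T
    n_G: int
    mode: str = "dosage"
    M: int = 1
    span_length: int | None = None  # deleted-base count for deletion-span vectors
    targets: TargetRegionSet | None = field(default=None, repr=False)

    @property
    def max_count(self) -> int:
        return (2 if self.mode == "dosage" else 1) * self.n_G

    def allele_frequency(self) -> np.ndarray:
        return self.counts / float(2 * self.n_G)


def aggregate_snv(G: GenotypeMatrix) -> FrequencyVector:
    """Slot-wise sum over samples (plaintext path)."""
    return FrequencyVector(
        allele=G.allele,
        counts=G.values.sum(axis=1, dtype=np.int64),
        n_G=G.n_G,
        mode=G.mode,
        targets=G.targets,
    )


def insertion_position_frequency(G: GenotypeMatrix) -> FrequencyVector:
    """Positional insertion counts; inserted sequences are not distinguished
    (enumerating them is not supported — a documented limitation)."""
    return aggregate_snv(G)


def _boundary_masks(targets: TargetRegionSet, l_delta: int):
    rid = targets.region_id_vector()
    n = len(rid)
    left = np.zeros(n, dtype=np.int64)
    left[1:] = rid[1:] == rid[:-1]
    right = np.zeros(n, dtype=np.int64)
    d = l_delta + 1
    if d < n:
        right[: n - d] = rid[d:] == rid[: n - d]
    valid = np.zeros(n, dtype=np.int64)
    if l_delta < n:
        valid[: n - l_delta] = rid[l_delta:] == rid[: n - l_delta]
    return left, right, valid


def aggregate_deletion_length(G: GenotypeMatrix, l_delta: int) -> FrequencyVector:
    """Exact-span deletion counts for the printed span convention
    (span = positions [nu, nu + l_delta], i.e. l_delta + 1 deleted bases)."""
    if G.mode != "existence":
        raise ValueError("deletion-span aggregation requires existence encoding")
    if l_delta < 0:
        raise ValueError("l_delta must be >= 0")
    V = G.values.astype(bool)
    n, m = V.shape
    mask_left, mask_right, valid = _boundary_masks(G.targets, l_delta)

    def shifted(a, k):
        out = np.zeros_like(a)
        if k >= 0:
            if k < n:
                out[: n - k] = a[k:]
        else:
            if -k < n:
                out[-k:] = a[: n + k]
        return out

    span_all = np.ones_like(V)
    for l in range(0, l_delta + 1):
        span_all &= shifted(V, l)
    left_ok = ~(shifted(V, -1) & mask_left[:, None].astype(bool))
    right_ok = ~(shifted(V, l_delta + 1) & mask_right[:, None].astype(bool))
    ind = span_all & left_ok & right_ok & valid[:, None].astype(bool)
    return FrequencyVector(
        allele=G.allele,
        counts=ind.sum(axis=1, dtype=np.int64),
        n_G=m,
        mode="existence",
        span_length=l_delta + 1,
        targets=G.targets,
    )


def aggregate_deletion_span(G: GenotypeMatrix, deleted_bases: int) -> FrequencyVector:
    """Exact-span deletion counts parameterized by the number of deleted bases."""
    if deleted_bases < 1:
        raise ValueError("deleted_bases must be >= 1")
    return aggregate_deletion_length(G, deleted_bases - 1)


# -- encrypted paths ------------------------------------------------------


def encrypt_genotype_columns(
    backend: PlainBackend, G: GenotypeMatrix, pk: PublicKey
) -> list[CipherVector]:
    """Encrypt each sample's genotype column as one chunked ciphertext vector."""
    return [backend.encrypt(G.values[:, k].astype(np.int64), pk) for k in range(G.n_G)]


def aggregate_encrypted(backend: PlainBackend, columns: list[CipherVector]) -> CipherVector:
    """Sum of encrypted per-sample vectors (all under one key)."""
    if not columns:
        raise ValueError("no columns to aggregate")
    acc = columns[0]
    for cv in columns[1:]:
        acc = backend.add(acc, cv)
    return acc


def aggregate_deletion_length_encrypted(
    backend: PlainBackend,
    columns: list[CipherVector],
    l_delta: int,
    targets: TargetRegionSet,
) -> CipherVector:
    """Exact-span deletion statistic evaluated under encryption.

    Per sample: product of l_delta+1 shifted copies of the (existence) column
    times the complemented, region-masked flanks, then summed over samples.
    The region-boundary masks are plaintext — the target layout is public.
    """
    if not columns:
        raise ValueError("no columns to aggregate")
    mask_left, mask_right, valid = _boundary_masks(targets, l_delta)
    ones = np.ones(columns[0].length, dtype=np.int64)
    acc = None
    for ct in columns:
        prod = ct
        for l in range(1, l_delta + 1):
            prod = backend.mul(prod, backend.shift(ct, l))
        t_left = backend.mul_plain(backend.shift(ct, -1), mask_left)
        f_left = backend.add_plain(backend.mul_plain(t_left, -ones), ones)
        t_right = backend.mul_plain(backend.shift(ct, l_delta + 1), mask_right)
        f_right = backend.add_plain(backend.mul_plain(t_right, -ones), ones)
        ind = backend.mul_plain(backend.mul(backend.mul(prod, f_left), f_right), valid)
        acc = ind if acc is None else backend.add(acc, ind)
    return acc


def pool_and_aggregate(
    backend: PlainBackend,
    sources: list[tuple[list[CipherVector], str]],
    switch_keys: list[SwitchKey],
    target_key_id: str,
) -> CipherVector:
    """Federated aggregation: key-switch every source's columns to the common
    (researcher) key, then sum everything.

    *sources* is a list of (encrypted columns, source key id); each source
    must come with a switch key to *target_key_id*.  Keys are verified before
    any arithmetic.
    """
    swk_by_from = {}
    for swk in switch_keys:
        swk_by_from[swk.from_key] = swk
    for _cols, kid in sources:
        swk = swk_by_from.get(kid)
        if swk is None or swk.to_key != target_key_id:
            raise KeyMismatchError(
                f"no switch key from {kid} to {target_key_id}"
            )
    acc = None
    for cols, kid in sources:
        swk = swk_by_from[kid]
        for ct in cols:
            if ct.key_id != kid:
                raise KeyMismatchError(
                    f"source declared key {kid} but column is under {ct.key_id}"
                )
            switched = backend.key_switch(ct, swk)
            acc = switched if acc is None else backend.add(acc, switched)
    return acc


def write_frequency_tsv(fv: FrequencyVector, path, include_zeros: bool = False) -> None:
    """Per-position counts as TSV (chrom, pos, element, allele, count, n_G, AF)."""
    targets = fv.targets
    if targets is None:
        raise ValueError("frequency vector has no target set attached")
    allele = fv.allele if fv.span_length is None else f"del[{fv.span_length}bp]"
    with open(path, "w") as fh:
        fh.write("chrom\tpos\telement\tallele\tcount\tn_G\tAF\n")
        nus = np.arange(1, len(fv.counts) + 1) if include_zeros else np.flatnonzero(fv.counts) + 1
        for nu in nus:
            k, chrom, pos = targets.vector_to_genomic(int(nu))
            count = int(fv.counts[nu - 1])
            fh.write(
                f"{chrom}\t{pos}\t{targets.regions[k].element_id}\t{allele}\t"
                f"{count}\t{fv.n_G}\t{count / (2 * fv.n_G):.6g}\n"
            )
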