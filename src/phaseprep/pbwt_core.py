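"""Compact positional Burrows-Wheeler transform with a 32-bit-block rank index.

A PBWT stores, per site, the haplotype alleles permuted so the haplotypes
appear sorted by their reversed prefixes up to that site.  The construction
maintains a permutation array ``a``; scanning the permuted alleles of site
``m`` routes each index into a zero-queue (write cursor starting at 0) or a
one-queue (starting at ``cnt0[m]``, the number of zero alleles at the site),
producing the permutation for site ``m + 1``.

Each permuted row carries an index: one 32-bit integer per 32-bit data
block, the cumulative number of zero bits from the start of the row through
that block inclusive, counting only bits below N.  ``rank0`` then needs at
most one index lookup plus one partial-block popcount.  Padding bits in the
last block are stored as zero and excluded from every count, so the last
index value always equals ``cnt0``.

Binary container (all little-endian)::

    bytes 0-3   magic b"PPWT"
    byte  4     version (1)
    byte  5     direction (0 = forward, 1 = backward)
    bytes 6-9   uint32 M
    bytes 10-13 uint32 N
    then per site: uint32 cnt0, then ceil(N/32) pairs of
    (uint32 data block, uint32 index word), data bits LSB-first.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

PBWT_MAGIC = b"PPWT"
PBWT_VERSION = 1
BLOCK_BITS = 32


@dataclass
class CompactPBWT:
    """Per-site permuted bit rows with zero counts and the block zero-count index."""

    pbwt_rows: np.ndarray  # (M, N) uint8 permuted alleles
    cnt0: np.ndarray  # (M,) int64
    direction: str = "forward"  # "forward" | "backward"
    index: np.ndarray | None = None  # (M, ceil(N/32)) uint32 cumulative zero counts
    final_permutation: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.pbwt_rows = np.ascontiguousarray(self.pbwt_rows, dtype=np.uint8)
        self.cnt0 = np.ascontiguousarray(self.cnt0, dtype=np.int64)
        if self.direction not in ("forward", "backward"):
            raise ValueError("direction must be 'forward' or 'backward'")
        if self.cnt0.shape[0] != self.pbwt_rows.shape[0]:
            raise ValueError("cnt0 length must equal the number of sites")

    @property
    def n_sites(self) -> int:
        return self.pbwt_rows.shape[0]

    @property
    def n_haps(self) -> int:
        return self.pbwt_rows.shape[1]


def _check_rows(rows: np.ndarray) -> np.ndarray:
    try:
        rows = np.ascontiguousarray(rows, dtype=np.uint8)
    except (TypeError, ValueError) as exc:
        raise ValueError("input must be a rectangular bit matrix (ragged rows?)") from exc
    if rows.ndim != 2:
        raise ValueError("input must be a 2-D bit matrix (ragged rows are not allowed)")
    if rows.shape[1] < 1:
        raise ValueError("at least one haplotype is required")
    return rows


def build_pbwt(rows: np.ndarray) -> CompactPBWT:
    """Build the forward compact PBWT of ``M`` bit rows of width ``N``.

    Direct transcription of the queue-based construction: ``a`` starts as
    the identity; per site, scan positions in permuted order, emit the
    allele, and route the index into the zero- or one-queue of the next
    permutation array.  The index is attached afterwards.
    """
    rows = _check_rows(rows)
    m_sites, n = rows.shape
    a = np.arange(n, dtype=np.int64)
    pbwt = np.empty_like(rows)
    cnt0 = np.empty(m_sites, dtype=np.int64)
    for m in range(m_sites):
        permuted = rows[m][a]
        pbwt[m] = permuted
        c0 = int(n - permuted.sum())
        cnt0[m] = c0
        b = np.empty_like(a)
        zero = permuted == 0
        b[: c0] = a[zero]
        b[c0:] = a[~zero]
        a = b
    out = CompactPBWT(pbwt_rows=pbwt, cnt0=cnt0, direction="forward", final_permutation=a)
    return build_index(out)


def build_backward_pbwt(rows: np.ndarray) -> CompactPBWT:
    """Backward PBWT: the forward PBWT of the site-reversed matrix.

    Rows and cnt0 are reported in the reversed site order (row 0 of the
    result corresponds to the last input site).
    """
    rows = _check_rows(rows)
    fwd = build_pbwt(rows[::-1])
    fwd.direction = "backward"
    return fwd


def build_index(pbwt: CompactPBWT) -> CompactPBWT:
    """Attach the cumulative zero-count index: one uint32 per 32-bit block.

    ``index[m][j]`` counts the zero bits of row ``m`` in positions
    ``[0, min(32*(j+1), N))``; padding never contributes.
    """
    m_sites, n = pbwt.pbwt_rows.shape
    n_blocks = max(1, (n + BLOCK_BITS - 1) // BLOCK_BITS)
    index = np.zeros((m_sites, n_blocks), dtype=np.uint32)
    for m in range(m_sites):
        zeros = pbwt.pbwt_rows[m] == 0
        csum = np.cumsum(zeros)
        for j in range(n_blocks):
            end = min(BLOCK_BITS * (j + 1), n)
            index[m, j] = csum[end - 1] if end > 0 else 0
    pbwt.index = index
    return pbwt


def rank0(pbwt: CompactPBWT, site: int, i: int) -> int:
    """Zero bits among ``pbwt_rows[site][0..i)`` via the block index.

    One whole-block index lookup plus a popcount over the partial block.
    """
    n = pbwt.n_haps
    if not 0 <= i <= n:
        raise ValueError(f"position {i} out of range [0, {n}]")
    if pbwt.index is None:
        raise ValueError("index not built; call build_index first")
    block = i // BLOCK_BITS
    base = int(pbwt.index[site, block - 1]) if block > 0 else 0
    start = block * BLOCK_BITS
    partial = int(np.count_nonzero(pbwt.pbwt_rows[site, start:i] == 0))
    return base + partial


def rank1(pbwt: CompactPBWT, site: int, i: int) -> int:
    """Set bits among ``pbwt_rows[site][0..i)``; complement of rank0."""
    return i - rank0(pbwt, site, i)


def invert_pbwt(pbwt: CompactPBWT) -> np.ndarray:
    """Reconstruct the original bit matrix from pbwt_rows and cnt0 alone.

    Replays the construction: the permutation entering each site is
    recoverable by routing, and the permuted row scattered through it
    restores the input row.  For a backward PBWT the rows are returned in
    original site order.
    """
    m_sites, n = pbwt.pbwt_rows.shape
    a = np.arange(n, dtype=np.int64)
    rows = np.empty_like(pbwt.pbwt_rows)
    for m in range(m_sites):
        permuted = pbwt.pbwt_rows[m]
        rows[m][a] = permuted
        c0 = int(pbwt.cnt0[m])
        b = np.empty_like(a)
        zero = permuted == 0
        b[:c0] = a[zero]
        b[c0:] = a[~zero]
        a = b
    if pbwt.direction == "backward":
        rows = rows[::-1]
    return rows


def permutations(pbwt: CompactPBWT) -> np.ndarray:
    """All per-site permutations: row ``m`` is the array entering site ``m``.

    Shape (M+1, N); the final row is the permutation after the last site.
    """
    m_sites, n = pbwt.pbwt_rows.shape
    perms = np.empty((m_sites + 1, n), dtype=np.int64)
    a = np.arange(n, dtype=np.int64)
    perms[0] = a
    for m in range(m_sites):
        permuted = pbwt.pbwt_rows[m]
        c0 = int(pbwt.cnt0[m])
        b = np.empty_like(a)
        zero = permuted == 0
        b[:c0] = a[zero]
        b[c0:] = a[~zero]
        a = b
        perms[m + 1] = a
    return perms


# ---------------------------------------------------------------------------
# serialization


def write_pbwt(pbwt: CompactPBWT, path: str | Path) -> None:
    """Write the documented binary container (index interleaved with data)."""
    if pbwt.index is None:
        build_index(pbwt)
    m_sites, n = pbwt.pbwt_rows.shape
    n_blocks = max(1, (n + BLOCK_BITS - 1) // BLOCK_BITS)
    with open(path, "wb") as fh:
        fh.write(PBWT_MAGIC)
        fh.write(bytes([PBWT_VERSION, 0 if pbwt.direction == "forward" else 1]))
        fh.write(np.uint32(m_sites).tobytes())
        fh.write(np.uint32(n).tobytes())
        for m in range(m_sites):
            fh.write(np.uint32(pbwt.cnt0[m]).tobytes())
            packed = np.packbits(pbwt.pbwt_rows[m], bitorder="little")
            packed = np.pad(packed, (0, 4 * n_blocks - len(packed)))
            blocks = packed.view("<u4")
            for j in range(n_blocks):
                fh.write(blocks[j].tobytes())
                fh.write(np.uint32(pbwt.index[m, j]).tobytes())


def read_pbwt(path: str | Path) -> CompactPBWT:
    """Read a container written by :func:`write_pbwt`."""
    with open(path, "rb") as fh:
        if fh.read(4) != PBWT_MAGIC:
            raise ValueError(f"{path}: not a phaseprep PBWT file")
        version, direction_byte = fh.read(1)[0], fh.read(1)[0]
        if version != PBWT_VERSION:
            raise ValueError(f"{path}: unsupported PBWT container version {version}")
        m_sites = int(np.frombuffer(fh.read(4), dtype="<u4")[0])
        n = int(np.frombuffer(fh.read(4), dtype="<u4")[0])
        n_blocks = max(1, (n + BLOCK_BITS - 1) // BLOCK_BITS)
        rows = np.empty((m_sites, n), dtype=np.uint8)
        cnt0 = np.empty(m_sites, dtype=np.int64)
        index = np.empty((m_sites, n_blocks), dtype=np.uint32)
        for m in range(m_sites):
            cnt0[m] = int(np.frombuffer(fh.read(4), dtype="<u4")[0])
            data = np.empty(n_blocks, dtype="<u4")
            for j in range(n_blocks):
                data[j] = np.frombuffer(fh.read(4), dtype="<u4")[0]
                index[m, j] = np.frombuffer(fh.read(4), dtype="<u4")[0]
            bits = np.unpackbits(data.view(np.uint8), bitorder="little")[:n]
            rows[m] = bits
    return CompactPBWT(
        pbwt_rows=rows,
        cnt0=cnt0,
        direction="forward" if direction_byte == 0 else "backward",
        index=index,
    )
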