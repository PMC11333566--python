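"""Host-side phasing preliminaries: scoring, K-best selection, condensed reference.

A haplotype is *inconsistent* with a target at a site when the target
genotype there is homozygous and the haplotype carries the other allele::

    inc = (is0 AND hap) OR (is2 AND NOT hap)

Heterozygous and missing sites never contribute.  Each reference haplotype
is scored by its total inconsistency count over the homozygous sites; the K
lowest-scoring haplotypes (ties broken toward the lower panel index) form
the working subset for that target.

The *condensed reference* re-expresses the selected haplotypes relative to
one target as ``2C + 1`` alternating bit rows of width ``k_effective``, for
C call (heterozygous) sites: raw allele rows at the call sites, and between
them one row per segment holding the OR of the per-site inconsistency rows
over that segment.  Segments flanked by adjacent call sites (or a call site
at either end of the grid) are explicit all-zero rows, so the alternation
SEGMENT, CALLSITE, ..., SEGMENT is invariant.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from phaseprep.panel_io import HaplotypePanel, TargetGenotypes

DEFAULT_K = 10_000  # default number of reference haplotypes kept per target


class RowKind(Enum):
    SEGMENT = 0
    CALLSITE = 1


@dataclass
class KBestSelection:
    """Bit mask over panel haplotypes marking the K best for one target."""

    mask: np.ndarray  # (N,) uint8
    scores: np.ndarray  # (N,) int64 inconsistency counts

    def __post_init__(self) -> None:
        self.mask = np.ascontiguousarray(self.mask, dtype=np.uint8)
        self.scores = np.ascontiguousarray(self.scores, dtype=np.int64)

    @property
    def k_effective(self) -> int:
        return int(self.mask.sum())

    @property
    def selected_indices(self) -> np.ndarray:
        return np.flatnonzero(self.mask)


@dataclass
class CondensedReference:
    """Alternating segment/call-site rows of width k for one target."""

    rows: np.ndarray  # (2C+1, k) uint8
    row_kind: list[RowKind]
    call_site_index: list[int]  # original 0-based site index per CALLSITE row

    def __post_init__(self) -> None:
        self.rows = np.ascontiguousarray(self.rows, dtype=np.uint8)
        if len(self.row_kind) != self.rows.shape[0]:
            raise ValueError("row_kind length must match row count")
        if self.rows.shape[0] != 2 * len(self.call_site_index) + 1:
            raise ValueError("a condensed reference has exactly 2C+1 rows")

    @property
    def k(self) -> int:
        return self.rows.shape[1]

    @property
    def n_call_sites(self) -> int:
        return len(self.call_site_index)


def inconsistency_bit(is0: int, is2: int, hap: int) -> int:
    """Return 1 iff the haplotype allele contradicts a homozygous genotype."""
    if is0 and is2:
        raise ValueError("is0 and is2 cannot both be set")
    return (is0 & hap) | (is2 & (1 - hap))


def inconsistency_row(is0: int, is2: int, haps: np.ndarray) -> np.ndarray:
    """Vectorised inconsistency over all haplotype bits of one site."""
    if is0 and is2:
        raise ValueError("is0 and is2 cannot both be set")
    haps = np.asarray(haps, dtype=np.uint8)
    if is0:
        return haps.copy()
    if is2:
        return (1 - haps).astype(np.uint8)
    return np.zeros_like(haps)


def score_haplotypes(panel: HaplotypePanel, target: TargetGenotypes) -> np.ndarray:
    """Per-haplotype inconsistency counts of the panel against one target.

    Only homozygous target sites can contribute; an all-missing target
    scores every haplotype zero.
    """
    if panel.n_sites != target.n_sites:
        raise ValueError("panel and target must share the site grid")
    hom0 = target.is0.astype(bool)
    hom2 = target.is2.astype(bool)
    # contributions: hap==1 at is0 sites, hap==0 at is2 sites
    scores = panel.rows[hom0].sum(axis=0, dtype=np.int64)
    scores += (1 - panel.rows[hom2]).sum(axis=0, dtype=np.int64)
    return scores


def select_kbest(scores: np.ndarray, k: int = DEFAULT_K) -> KBestSelection:
    """Select the min(K, N) lowest-scoring haplotypes, ties toward lower index.

    The mask preserves panel order: selection decides membership, not
    ordering, because the downstream mask-compaction is order-preserving.
    """
    if k < 1:
        raise ValueError("K must be at least 1")
    scores = np.asarray(scores, dtype=np.int64)
    n = scores.shape[0]
    k_eff = min(k, n)
    order = np.argsort(scores, kind="stable")  # stable sort = index tie-break
    mask = np.zeros(n, dtype=np.uint8)
    mask[order[:k_eff]] = 1
    return KBestSelection(mask=mask, scores=scores)


def compact_row(row: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Keep the bits of ``row`` at the set positions of ``mask``, in order."""
    row = np.asarray(row, dtype=np.uint8)
    mask = np.asarray(mask, dtype=np.uint8)
    if row.shape != mask.shape:
        raise ValueError("row and mask must have the same width")
    return row[mask.astype(bool)]


def build_condensed(
    panel: HaplotypePanel, target: TargetGenotypes, sel: KBestSelection
) -> CondensedReference:
    """Build the condensed reference for one target over the selected haplotypes.

    With call sites c_1 < ... < c_C, the structure is SEGMENT, CALLSITE,
    SEGMENT, ..., CALLSITE, SEGMENT: segment i ORs the mask-compacted
    inconsistency rows of the sites strictly between c_i and c_{i+1}
    (segment 0 covers the sites before c_1, segment C those after c_C);
    call-site rows carry the mask-compacted raw alleles.  An empty site
    range yields an all-zero segment row.
    """
    if panel.n_sites != target.n_sites:
        raise ValueError("panel and target must share the site grid")
    keep = sel.mask.astype(bool)
    if keep.shape[0] != panel.n_haps:
        raise ValueError("selection mask width must equal the panel haplotype count")
    k = int(keep.sum())
    rows: list[np.ndarray] = []
    kinds: list[RowKind] = []
    call_sites: list[int] = []
    acc = np.zeros(k, dtype=np.uint8)
    for m in range(panel.n_sites):
        if target.call[m]:
            rows.append(acc)
            kinds.append(RowKind.SEGMENT)
            rows.append(panel.rows[m][keep].copy())
            kinds.append(RowKind.CALLSITE)
            call_sites.append(m)
            acc = np.zeros(k, dtype=np.uint8)
        else:
            inc = inconsistency_row(int(target.is0[m]), int(target.is2[m]), panel.rows[m][keep])
            acc = acc | inc
    rows.append(acc)
    kinds.append(RowKind.SEGMENT)
    matrix = np.vstack(rows) if rows else np.zeros((1, k), dtype=np.uint8)
    return CondensedReference(rows=matrix, row_kind=kinds, call_site_index=call_sites)
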