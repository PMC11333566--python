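"""Set-maximal match queries against an indexed compact PBWT.

A *set-maximal match* between a query haplotype and the panel is an
agreement interval ``[start, end)`` with some panel haplotype such that no
panel haplotype agrees with the query on any strict superinterval.  These
are the intervals a PBWT-based imputation step copies from.

The query is swept through the panel's per-site sorted orders by virtual
insertion: an interval ``[f, g)`` of sorted positions tracks exactly the
haplotypes agreeing with the query on ``[e, site)``, advanced with
rank0/rank1 queries on the indexed PBWT rows.  When the interval empties,
the agreeing haplotypes are reported and the sweep re-anchors at the
longest query suffix still present in the panel, located via the query's
insertion position and its sorted-order neighbours.

A deliberately minimal majority-vote allele filler is included so the
primitive is exercisable end to end; it is not an imputation model (no
dosages, no recombination/mutation weighting).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from phaseprep.panel_io import HaplotypePanel
from phaseprep.pbwt_core import CompactPBWT, build_index, invert_pbwt, permutations, rank0, rank1


@dataclass(frozen=True)
class SetMaximalMatch:
    """Agreement interval [start, end) of the query with panel haplotype ``hap``."""

    hap: int
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive


def _extension(pbwt: CompactPBWT, site: int, pos: int, bit: int) -> int:
    """Map sorted position ``pos`` at ``site`` to the next site's order for ``bit``."""
    if bit == 0:
        return rank0(pbwt, site, pos)
    return int(pbwt.cnt0[site]) + rank1(pbwt, site, pos)


def set_maximal_matches(pbwt: CompactPBWT, query: np.ndarray) -> list[SetMaximalMatch]:
    """All set-maximal matches of ``query`` against the panel behind ``pbwt``.

    Matches are returned sorted by (end, start, hap).  The PBWT must be a
    forward transform whose site count equals the query width.
    """
    if pbwt.direction != "forward":
        raise ValueError("set-maximal matching requires a forward PBWT")
    query = np.ascontiguousarray(query, dtype=np.uint8)
    m_sites, n = pbwt.pbwt_rows.shape
    if query.shape[0] != m_sites:
        raise ValueError(f"query width {query.shape[0]} does not match PBWT site count {m_sites}")
    if pbwt.index is None:
        build_index(pbwt)
    haps = invert_pbwt(pbwt)  # (M, N): haplotype h is column h
    perms = permutations(pbwt)  # (M+1, N)

    def agrees(h: int, lo: int, hi: int) -> bool:
        return bool(np.array_equal(haps[lo:hi, h], query[lo:hi]))

    def suffix_start(h: int, end: int) -> int:
        """Smallest s with haps[s:end, h] == query[s:end]."""
        s = end
        while s > 0 and haps[s - 1, h] == query[s - 1]:
            s -= 1
        return s

    matches: list[SetMaximalMatch] = []
    e, f, g = 0, 0, n
    for k in range(m_sites):
        f1 = _extension(pbwt, k, f, int(query[k]))
        g1 = _extension(pbwt, k, g, int(query[k]))
        if f1 < g1:
            f, g = f1, g1
            continue
        # the interval died at site k: [f, g) agreed on [e, k) and none extends
        if k > e:
            for i in range(f, g):
                matches.append(SetMaximalMatch(hap=int(perms[k][i]), start=e, end=k))
        # re-anchor: longest suffix of query[0:k+1] present in the panel,
        # found from the insertion position's sorted neighbours
        t = f1
        order = perms[k + 1]
        e = k + 1  # empty suffix fallback (no haplotype carries query[k] here)
        for nb in (t - 1, t):
            if 0 <= nb < n:
                e = min(e, suffix_start(int(order[nb]), k + 1))
        f, g = t, t
        while f > 0 and agrees(int(order[f - 1]), e, k + 1):
            f -= 1
        while g < n and agrees(int(order[g]), e, k + 1):
            g += 1
    if m_sites > e:
        for i in range(f, g):
            matches.append(SetMaximalMatch(hap=int(perms[m_sites][i]), start=e, end=m_sites))
    matches.sort(key=lambda x: (x.end, x.start, x.hap))
    return matches


def fill_alleles(
    matches: list[SetMaximalMatch],
    panel: HaplotypePanel,
    missing_sites: list[int] | np.ndarray,
) -> dict[int, int | None]:
    """Majority-vote allele per missing site from the covering matches.

    Ties vote reference (0); a site covered by no match maps to ``None``
    (no-call).
    """
    calls: dict[int, int | None] = {}
    for site in (int(s) for s in missing_sites):
        votes = [int(panel.rows[site, mt.hap]) for mt in matches if mt.start <= site < mt.end]
        if not votes:
            calls[site] = None
        else:
            ones = sum(votes)
            calls[site] = 1 if ones * 2 > len(votes) else 0
    return calls
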