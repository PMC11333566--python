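"""Independent naive oracles used to pin down the optimised implementations.

Everything here is deliberately written the slow, obvious way — per-bit
loops, full enumerations, stdlib sorting — and shares no code with the
package paths it checks.
"""

from __future__ import annotations

import numpy as np


def naive_pack(bits, word_width):
    """Per-bit LSB-first packing loop."""
    words = []
    for i, b in enumerate(bits):
        j = i // word_width
        while len(words) <= j:
            words.append(0)
        if b:
            words[j] |= 1 << (i % word_width)
    if not words and len(bits) == 0:
        return []
    return words


def naive_inconsistency(is0, is2, hap):
    if is0 == 1 and hap == 1:
        return 1
    if is2 == 1 and hap == 0:
        return 1
    return 0


def naive_condensed(rows, is0, is2, call, mask):
    """Per-site loop with no bit packing: segment ORs and raw call-site rows.

    Returns (rows list, kinds list) with kinds "S"/"C".
    """
    keep = [i for i, b in enumerate(mask) if b]
    out_rows, kinds = [], []
    seg = [0] * len(keep)
    for m in range(len(rows)):
        if call[m]:
            out_rows.append(seg)
            kinds.append("S")
            out_rows.append([int(rows[m][i]) for i in keep])
            kinds.append("C")
            seg = [0] * len(keep)
        else:
            for j, i in enumerate(keep):
                seg[j] |= naive_inconsistency(int(is0[m]), int(is2[m]), int(rows[m][i]))
    out_rows.append(seg)
    kinds.append("S")
    return out_rows, kinds


def naive_pbwt(rows):
    """Reversed-prefix stable-sort construction.

    At each site m the haplotypes are ordered by their reversed prefixes
    (alleles at sites m-1, m-2, ..., 0); Python's stable sort breaks full
    ties by original haplotype index, matching the identity-initialised
    queue routing.  Returns (pbwt rows, cnt0, final permutation).
    """
    m_sites, n = len(rows), len(rows[0])
    pbwt, cnt0 = [], []
    order = list(range(n))
    for m in range(m_sites):
        order = sorted(range(n), key=lambda h: tuple(int(rows[s][h]) for s in range(m - 1, -1, -1)))
        permuted = [int(rows[m][h]) for h in order]
        pbwt.append(permuted)
        cnt0.append(permuted.count(0))
    final = sorted(
        range(n), key=lambda h: tuple(int(rows[s][h]) for s in range(m_sites - 1, -1, -1))
    )
    return pbwt, cnt0, final


def naive_rank0(row, i):
    return sum(1 for b in row[:i] if b == 0)


def naive_block_index(row, block_bits=32):
    """Cumulative zero counts per block by direct per-bit scanning."""
    n = len(row)
    n_blocks = max(1, (n + block_bits - 1) // block_bits)
    out = []
    for j in range(n_blocks):
        end = min(block_bits * (j + 1), n)
        out.append(naive_rank0(row, end))
    return out


def brute_force_set_maximal(panel_rows, query):
    """O(N·M²)-style enumeration of set-maximal matches.

    Enumerates every per-haplotype maximal agreement interval, then keeps
    those not strictly contained in any other haplotype's interval.
    """
    panel_rows = np.asarray(panel_rows)
    m_sites, n = panel_rows.shape
    maximal = set()
    for h in range(n):
        s = 0
        while s < m_sites:
            if panel_rows[s, h] != query[s]:
                s += 1
                continue
            e = s
            while e < m_sites and panel_rows[e, h] == query[e]:
                e += 1
            maximal.add((h, s, e))
            s = e
    result = set()
    for h, s, e in maximal:
        contained = any(
            (s2 <= s and e <= e2 and (s2, e2) != (s, e)) for (_, s2, e2) in maximal
        )
        if not contained:
            result.add((h, s, e))
    return result
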