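"""Independent brute-force oracles the optimized implementations are
checked against.  Everything here favours obviousness over speed and is
written directly from the definitions, not from the package code."""

import math

import numpy as np


def ehh_pairwise(hap_slice: np.ndarray) -> float:
    """EHH by literal pair counting: fraction of haplotype pairs identical
    over the whole slice."""
    m = hap_slice.shape[0]
    same = 0
    for i in range(m):
        for j in range(i + 1, m):
            if np.array_equal(hap_slice[i], hap_slice[j]):
                same += 1
    return same / (m * (m - 1) / 2)


def ihh_one_side(alleles, positions, core, direction, cutoff=0.05) -> float:
    """Trapezoidal iHH on one side, stopping at the last site with
    EHH >= cutoff (the crossing segment excluded)."""
    L = alleles.shape[1]

    def ehh_at(d):
        a, b = sorted([core, core + direction * d])
        return ehh_pairwise(alleles[:, a : b + 1])

    total = 0.0
    e_prev = ehh_at(0)
    d = 1
    while 0 <= core + direction * d < L:
        e = ehh_at(d)
        if e < cutoff:
            break
        step = abs(positions[core + direction * d] - positions[core + direction * (d - 1)])
        total += 0.5 * (e + e_prev) * step
        e_prev = e
        d += 1
    return total


def xpehh_exhaustive(haps_a, haps_b, positions, cutoff=0.05) -> np.ndarray:
    """Unstandardized XP-EHH per site by exhaustive pair enumeration."""
    L = haps_a.shape[1]
    out = np.full(L, np.nan)
    for j in range(L):
        ia = ihh_one_side(haps_a, positions, j, +1, cutoff) + ihh_one_side(
            haps_a, positions, j, -1, cutoff
        )
        ib = ihh_one_side(haps_b, positions, j, +1, cutoff) + ihh_one_side(
            haps_b, positions, j, -1, cutoff
        )
        if ia > 0 and ib > 0:
            out[j] = math.log(ia / ib)
    return out


def merge_quadratic(intervals):
    """Union of half-open intervals by repeated pairwise merging."""
    items = [list(t) for t in intervals]
    changed = True
    while changed:
        changed = False
        for i in range(len(items)):
            for j in range(i + 1, len(items)):
                a, b = items[i], items[j]
                if a[0] == b[0] and a[1] < b[2] and b[1] < a[2]:
                    items[i] = [a[0], min(a[1], b[1]), max(a[2], b[2])]
                    items.pop(j)
                    changed = True
                    break
            if changed:
                break
    return sorted(tuple(t) for t in items)


def interval_distance(a_start, a_end, b_start, b_end) -> int:
    """bp distance between half-open intervals; 0 when overlapping or
    abutting."""
    return max(0, a_start - b_end, b_start - a_end)


def venn_enumerate(sets: dict):
    """Region counts by per-item membership enumeration."""
    universe = set().union(*sets.values())
    regions = {}
    for item in universe:
        key = frozenset(lab for lab, s in sets.items() if item in s)
        regions[key] = regions.get(key, 0) + 1
    return regions
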