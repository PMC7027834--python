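"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library code paths they check: the quantile
oracle interpolates by hand from a sorted copy, and the labelling oracle is
a breadth-first flood fill.
"""

from collections import deque

import numpy as np


def gap_mask_oracle(counts, ocean, q=0.20):
    """Sort-and-interpolate quantile gap classification."""
    counts = np.asarray(counts)
    ocean = np.asarray(ocean, dtype=bool)
    pos = sorted(int(c) for c in counts[ocean] if c > 0)
    gap = ocean & (counts == 0)
    if pos:
        h = (len(pos) - 1) * q
        lo = int(np.floor(h))
        hi = min(lo + 1, len(pos) - 1)
        thr = pos[lo] + (h - lo) * (pos[hi] - pos[lo])
        gap = gap | (ocean & (counts > 0) & (counts < thr))
    return gap


def flood_fill_components(binary, connectivity=8, wrap=True):
    """BFS connected components; returns list of frozensets of (r, c)."""
    binary = np.asarray(binary, dtype=bool)
    nr, nc = binary.shape
    seen = np.zeros_like(binary)
    if connectivity == 8:
        nbrs = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                if (dr, dc) != (0, 0)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    comps = []
    for r0 in range(nr):
        for c0 in range(nc):
            if not binary[r0, c0] or seen[r0, c0]:
                continue
            comp = set()
            q = deque([(r0, c0)])
            seen[r0, c0] = True
            while q:
                r, c = q.popleft()
                comp.add((r, c))
                for dr, dc in nbrs:
                    rr = r + dr
                    cc = (c + dc) % nc if wrap else c + dc
                    if rr < 0 or rr >= nr or cc < 0 or cc >= nc:
                        continue
                    if binary[rr, cc] and not seen[rr, cc]:
                        seen[rr, cc] = True
                        q.append((rr, cc))
            comps.append(frozenset(comp))
    return comps


def label_sets(labels):
    """Component partition of a labelled raster as a set of frozensets."""
    labels = np.asarray(labels)
    return {frozenset(zip(*np.nonzero(labels == k)))
            for k in np.unique(labels) if k > 0}
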