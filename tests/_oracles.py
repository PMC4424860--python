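"""Independent brute-force oracles used to cross-check the implementation."""

import numpy as np


def flood_fill_clusters(member: np.ndarray, connectivity: int = 6) -> list[frozenset]:
    """Stack-based flood fill returning the set of connected voxel-index sets."""
    offsets = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                order = abs(dx) + abs(dy) + abs(dz)
                if order == 0:
                    continue
                if (connectivity == 6 and order == 1) or \
                   (connectivity == 18 and order <= 2) or connectivity == 26:
                    offsets.append((dx, dy, dz))
    seen = np.zeros_like(member, dtype=bool)
    out = []
    nx, ny, nz = member.shape
    for start in zip(*np.nonzero(member)):
        if seen[start]:
            continue
        stack, comp = [start], set()
        seen[start] = True
        while stack:
            x, y, z = stack.pop()
            comp.add((x, y, z))
            for dx, dy, dz in offsets:
                p = (x + dx, y + dy, z + dz)
                if 0 <= p[0] < nx and 0 <= p[1] < ny and 0 <= p[2] < nz \
                        and member[p] and not seen[p]:
                    seen[p] = True
                    stack.append(p)
        out.append(frozenset(comp))
    return out
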