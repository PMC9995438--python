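"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (python loops, BFS, set arithmetic) and
shares no code with the package paths it verifies.
"""

from __future__ import annotations

from collections import deque
from itertools import product

import numpy as np


def bfs_components(mask: np.ndarray, connectivity: int = 26) -> list[set[tuple[int, int, int]]]:
    """Connected components of a 3-D boolean mask by breadth-first search."""
    if connectivity == 6:
        neigh = [o for o in product((-1, 0, 1), repeat=3) if sum(map(abs, o)) == 1]
    elif connectivity == 18:
        neigh = [o for o in product((-1, 0, 1), repeat=3) if 1 <= sum(map(abs, o)) <= 2]
    else:
        neigh = [o for o in product((-1, 0, 1), repeat=3) if any(o)]
    todo = {tuple(c) for c in np.argwhere(mask)}
    comps = []
    while todo:
        seed = min(todo)  # deterministic start
        comp = {seed}
        todo.discard(seed)
        queue = deque([seed])
        while queue:
            x, y, z = queue.popleft()
            for dx, dy, dz in neigh:
                p = (x + dx, y + dy, z + dz)
                if p in todo:
                    todo.discard(p)
                    comp.add(p)
                    queue.append(p)
        comps.append(comp)
    return comps


def brute_patch(volume: np.ndarray, coord: tuple[int, int, int]) -> list[float]:
    """27 neighborhood values in raster offset order, zeros out of bounds."""
    out = []
    for dx, dy, dz in product((-1, 0, 1), repeat=3):
        x, y, z = coord[0] + dx, coord[1] + dy, coord[2] + dz
        inside = all(0 <= c < n for c, n in zip((x, y, z), volume.shape))
        out.append(float(volume[x, y, z]) if inside else 0.0)
    return out


def set_dsc(a: set, b: set) -> float:
    if not a and not b:
        return 1.0
    return 2.0 * len(a & b) / (len(a) + len(b))


def set_jaccard(a: set, b: set) -> float:
    union = a | b
    if not union:
        return 1.0
    return len(a & b) / len(union)


def mask_to_set(mask: np.ndarray) -> set:
    return {tuple(c) for c in np.argwhere(np.asarray(mask, dtype=bool))}
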