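"""Independent brute-force oracles shared by the test suite.

Everything here is deliberately naive — explicit loops and exhaustive
enumeration — so it cannot share a failure mode with the vectorized
implementations it checks.
"""

import numpy as np

from gliamorph.pipeline import _ball_profile


def rolling_ball_background_oracle(img: np.ndarray, radius: float) -> np.ndarray:
    """Grayscale ball opening by explicit min/max loops (reflect borders)."""
    fp, h = _ball_profile(radius)
    r = fp.shape[0] // 2
    H, W = img.shape
    offs = [(dy, dx) for dy in range(-r, r + 1) for dx in range(-r, r + 1)
            if fp[dy + r, dx + r]]
    pad = np.pad(img.astype(float), r, mode="reflect")
    ero = np.empty((H, W))
    for y in range(H):
        for x in range(W):
            ero[y, x] = min(pad[y + r + dy, x + r + dx] - h[dy + r, dx + r]
                            for dy, dx in offs)
    pad2 = np.pad(ero, r, mode="reflect")
    bg = np.empty((H, W))
    for y in range(H):
        for x in range(W):
            bg[y, x] = max(pad2[y + r + dy, x + r + dx] + h[dy + r, dx + r]
                           for dy, dx in offs)
    return bg


def enumerate_connected_masks(max_cells: int):
    """All translation-normalized 4-connected pixel sets of <= max_cells.

    Yields boolean masks.  Grows sets cell by cell with canonical
    deduplication (the standard fixed-polyomino enumeration).
    """
    def normalize(cells):
        ys = min(y for y, x in cells)
        xs = min(x for y, x in cells)
        return frozenset((y - ys, x - xs) for y, x in cells)

    current = {frozenset({(0, 0)})}
    seen_all = set(current)
    for _ in range(max_cells - 1):
        nxt = set()
        for poly in current:
            for (y, x) in poly:
                for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    cell = (y + dy, x + dx)
                    if cell in poly:
                        continue
                    grown = normalize(poly | {cell})
                    if grown not in seen_all:
                        seen_all.add(grown)
                        nxt.add(grown)
        current = nxt

    for poly in sorted(seen_all, key=len):
        h = 1 + max(y for y, x in poly)
        w = 1 + max(x for y, x in poly)
        mask = np.zeros((h, w), bool)
        for y, x in poly:
            mask[y, x] = True
        yield mask


def random_connected_mask(n_cells: int, rng: np.random.Generator) -> np.ndarray:
    """One random 4-connected mask of exactly n_cells pixels (random growth)."""
    cells = {(0, 0)}
    frontier = [(0, 0)]
    while len(cells) < n_cells:
        y, x = frontier[int(rng.integers(len(frontier)))]
        dy, dx = ((1, 0), (-1, 0), (0, 1), (0, -1))[int(rng.integers(4))]
        cell = (y + dy, x + dx)
        if cell not in cells:
            cells.add(cell)
            frontier.append(cell)
    ys = min(y for y, x in cells)
    xs = min(x for y, x in cells)
    h = 1 + max(y for y, x in cells) - ys
    w = 1 + max(x for y, x in cells) - xs
    mask = np.zeros((h, w), bool)
    for y, x in cells:
        mask[y - ys, x - xs] = True
    return mask
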