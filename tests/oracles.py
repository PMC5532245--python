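"""Independent brute-force oracles used to check the vectorised implementations.

These stay deliberately naive (per-cell double loops, exhaustive distance
computation, hand ledgers) and share no code with the package internals.
"""

from __future__ import annotations

import numpy as np


def brute_change_matrix(c0: np.ndarray, c1: np.ndarray, cell_area: float) -> np.ndarray:
    """Per-cell double-loop tally of class flows (no mmu filtering)."""
    flows = np.zeros((14, 14))
    nrows, ncols = c0.shape
    for r in range(nrows):
        for c in range(ncols):
            a, b = int(c0[r, c]), int(c1[r, c])
            if a != 0 and b != 0:
                flows[a - 1, b - 1] += cell_area
    return flows


def brute_patch_sizes(changed: np.ndarray) -> np.ndarray:
    """4-connected component sizes of a boolean mask via flood fill."""
    visited = np.zeros_like(changed, dtype=bool)
    sizes = np.zeros(changed.shape, dtype=int)
    nrows, ncols = changed.shape
    for r0 in range(nrows):
        for c0 in range(ncols):
            if changed[r0, c0] and not visited[r0, c0]:
                stack, members = [(r0, c0)], []
                visited[r0, c0] = True
                while stack:
                    r, c = stack.pop()
                    members.append((r, c))
                    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < nrows and 0 <= cc < ncols:
                            if changed[rr, cc] and not visited[rr, cc]:
                                visited[rr, cc] = True
                                stack.append((rr, cc))
                for r, c in members:
                    sizes[r, c] = len(members)
    return sizes


def hand_extent_ledger(flows: np.ndarray, managed: set[int]) -> dict[str, dict[int, float]]:
    """Net-mode account entries computed directly from matrix marginals."""
    ledger: dict[str, dict[int, float]] = {
        k: {} for k in ("opening", "expansion", "regression", "closing", "managed")
    }
    for cls in range(1, 15):
        opening = float(flows[cls - 1, :].sum())
        closing = float(flows[:, cls - 1].sum())
        net = closing - opening
        ledger["opening"][cls] = opening
        ledger["expansion"][cls] = max(net, 0.0)
        ledger["regression"][cls] = min(net, 0.0)
        ledger["closing"][cls] = closing
        ledger["managed"][cls] = cls in managed
    return ledger


def brute_nearest_sample(cells: list[tuple[int, int]], samples) -> list:
    """Exhaustive nearest-sample assignment; ties break to lowest sample_id."""
    out = []
    for r, c in cells:
        best = None
        best_d = None
        for s in samples:
            d = (s.row - r) ** 2 + (s.col - c) ** 2
            if best is None or d < best_d or (d == best_d and s.sample_id < best.sample_id):
                best, best_d = s, d
        out.append(best)
    return out


def proportional_crosstab(samples, cover_areas: dict[int, float], classify) -> dict:
    """Spreadsheet-style proportional split of each cover's area."""
    table: dict[tuple[int, str], float] = {}
    for cover, area in cover_areas.items():
        covers = [s for s in samples if s.cover == cover]
        if not covers:
            continue
        for s in covers:
            key = (cover, classify(s))
            table[key] = table.get(key, 0.0) + area / len(covers)
    return table
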