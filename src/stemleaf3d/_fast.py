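"""Numba-accelerated kernels with pure-numpy fallbacks.

Only two inner loops in the package are hot enough to matter: greedy
farthest point sampling and the scatter-add in the gather backward pass.
Both have identical numpy implementations used when numba is unavailable;
results are bit-identical either way (same arithmetic, same order).
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    import numba

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False


def _fps_numpy(positions: np.ndarray, m: int, start: int) -> np.ndarray:
    selected = np.empty(m, dtype=np.int64)
    selected[0] = start
    min_d2 = np.sum((positions - positions[start]) ** 2, axis=1)
    for i in range(1, m):
        idx = int(np.argmax(min_d2))
        selected[i] = idx
        d2 = np.sum((positions - positions[idx]) ** 2, axis=1)
        np.minimum(min_d2, d2, out=min_d2)
    return selected


if _HAVE_NUMBA:

    @numba.njit(cache=False)
    def _fps_kernel(positions, m, start):  # pragma: no cover - jitted
        n = positions.shape[0]
        selected = np.empty(m, dtype=np.int64)
        selected[0] = start
        min_d2 = np.empty(n, dtype=np.float64)
        px, py, pz = positions[start, 0], positions[start, 1], positions[start, 2]
        for j in range(n):
            dx = positions[j, 0] - px
            dy = positions[j, 1] - py
            dz = positions[j, 2] - pz
            min_d2[j] = dx * dx + dy * dy + dz * dz
        for i in range(1, m):
            best = 0
            best_d = min_d2[0]
            for j in range(1, n):
                if min_d2[j] > best_d:
                    best_d = min_d2[j]
                    best = j
            selected[i] = best
            bx, by, bz = positions[best, 0], positions[best, 1], positions[best, 2]
            for j in range(n):
                dx = positions[j, 0] - bx
                dy = positions[j, 1] - by
                dz = positions[j, 2] - bz
                d2 = dx * dx + dy * dy + dz * dz
                if d2 < min_d2[j]:
                    min_d2[j] = d2
        return selected

    def fps_indices(positions: np.ndarray, m: int, start: int) -> np.ndarray:
        return _fps_kernel(np.ascontiguousarray(positions, dtype=np.float64), m, start)

    @numba.njit(cache=False)
    def _scatter_kernel(out, idx, src):  # pragma: no cover - jitted
        r, c = src.shape
        for i in range(r):
            row = idx[i]
            for j in range(c):
                out[row, j] += src[i, j]

    def scatter_add_rows(out: np.ndarray, idx: np.ndarray, src: np.ndarray) -> None:
        """out[idx[i]] += src[i] for all rows i (in place)."""
        _scatter_kernel(out, idx, np.ascontiguousarray(src))

else:  # pragma: no cover

    def fps_indices(positions: np.ndarray, m: int, start: int) -> np.ndarray:
        return _fps_numpy(np.asarray(positions, dtype=np.float64), m, start)

    def scatter_add_rows(out: np.ndarray, idx: np.ndarray, src: np.ndarray) -> None:
        np.add.at(out, idx, src)
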