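"""Low-level tolerance joins on (rt, m/z) coordinate arrays.

Every comparison in the package reduces to the same predicate: two ions match
when both |ΔRt| and |Δm/z| fall within the tolerance window (inclusive).
The helpers here implement that predicate over whole arrays using a sorted
m/z index with a searchsorted candidate window, then an exact |Δ| <= tol
filter, so results are bit-identical to a naive double loop.  The candidate
window is padded slightly beyond the tolerance so that float rounding of
``mz - tol`` / ``mz + tol`` can never exclude a true boundary match.

The predicate carries a guard of ``EPS = 1e-9`` (minutes / daltons): two
values whose printed decimals differ by exactly the tolerance — e.g. m/z
258.08 vs 258.13 at Δm/z = 0.05 — must match even though their binary float
difference can exceed 0.05 by ~1e-11.  EPS is seven orders of magnitude
below any chemically meaningful deviation.
"""

from __future__ import annotations

import numpy as np

__all__ = ["EPS", "SortedIndex", "match_mask", "count_pairs", "pair_indices", "closest_indices"]

#: absolute guard absorbing binary-representation error in |Δ| <= tol
EPS = 1e-9


class SortedIndex:
    """Reference ion set indexed by ascending m/z for window queries."""

    def __init__(self, rt: np.ndarray, mz: np.ndarray) -> None:
        self.order = np.argsort(mz, kind="stable")
        self.rt = np.asarray(rt, dtype=float)[self.order]
        self.mz = np.asarray(mz, dtype=float)[self.order]

    def __len__(self) -> int:
        return len(self.mz)


def _windows(index: SortedIndex, query_mz: np.ndarray, delta_mz: float):
    # pad so that rounding in mz +/- delta never drops an exact-boundary candidate
    pad = delta_mz + 2 * EPS
    lo = np.searchsorted(index.mz, query_mz - pad, side="left")
    hi = np.searchsorted(index.mz, query_mz + pad, side="right")
    return lo, hi


def match_mask(
    query_rt: np.ndarray,
    query_mz: np.ndarray,
    index: SortedIndex,
    delta_rt: float,
    delta_mz: float,
) -> np.ndarray:
    """Boolean mask: does each query ion match >= 1 reference ion."""
    query_rt = np.asarray(query_rt, dtype=float)
    query_mz = np.asarray(query_mz, dtype=float)
    out = np.zeros(len(query_mz), dtype=bool)
    if len(index) == 0:
        return out
    lo, hi = _windows(index, query_mz, delta_mz)
    for i in range(len(query_mz)):
        if lo[i] >= hi[i]:
            continue
        sl = slice(lo[i], hi[i])
        ok = (np.abs(index.mz[sl] - query_mz[i]) <= delta_mz + EPS) & (
            np.abs(index.rt[sl] - query_rt[i]) <= delta_rt + EPS
        )
        out[i] = bool(ok.any())
    return out


def count_pairs(
    query_rt: np.ndarray,
    query_mz: np.ndarray,
    index: SortedIndex,
    delta_rt: float,
    delta_mz: float,
) -> np.ndarray:
    """Per query ion, the number of reference ions it matches."""
    query_rt = np.asarray(query_rt, dtype=float)
    query_mz = np.asarray(query_mz, dtype=float)
    out = np.zeros(len(query_mz), dtype=np.int64)
    if len(index) == 0:
        return out
    lo, hi = _windows(index, query_mz, delta_mz)
    for i in range(len(query_mz)):
        if lo[i] >= hi[i]:
            continue
        sl = slice(lo[i], hi[i])
        ok = (np.abs(index.mz[sl] - query_mz[i]) <= delta_mz + EPS) & (
            np.abs(index.rt[sl] - query_rt[i]) <= delta_rt + EPS
        )
        out[i] = int(np.count_nonzero(ok))
    return out


def pair_indices(
    query_rt: np.ndarray,
    query_mz: np.ndarray,
    index: SortedIndex,
    delta_rt: float,
    delta_mz: float,
) -> list[tuple[int, int]]:
    """All (query index, reference index) matching pairs, reference indices
    reported in the reference set's original (pre-sort) order."""
    query_rt = np.asarray(query_rt, dtype=float)
    query_mz = np.asarray(query_mz, dtype=float)
    pairs: list[tuple[int, int]] = []
    if len(index) == 0:
        return pairs
    lo, hi = _windows(index, query_mz, delta_mz)
    for i in range(len(query_mz)):
        if lo[i] >= hi[i]:
            continue
        sl = np.arange(lo[i], hi[i])
        ok = (np.abs(index.mz[sl] - query_mz[i]) <= delta_mz + EPS) & (
            np.abs(index.rt[sl] - query_rt[i]) <= delta_rt + EPS
        )
        for j in np.sort(index.order[sl[ok]]):
            pairs.append((i, int(j)))
    return pairs


def closest_indices(
    query_rt: np.ndarray,
    query_mz: np.ndarray,
    index: SortedIndex,
    delta_rt: float,
    delta_mz: float,
) -> np.ndarray:
    """Per query ion, the original index of the closest matching reference ion
    (smallest |Δm/z|, ties by smallest |ΔRt|, then lowest original index),
    or -1 when nothing matches."""
    query_rt = np.asarray(query_rt, dtype=float)
    query_mz = np.asarray(query_mz, dtype=float)
    out = np.full(len(query_mz), -1, dtype=np.int64)
    if len(index) == 0:
        return out
    lo, hi = _windows(index, query_mz, delta_mz)
    for i in range(len(query_mz)):
        if lo[i] >= hi[i]:
            continue
        sl = np.arange(lo[i], hi[i])
        dmz = np.abs(index.mz[sl] - query_mz[i])
        drt = np.abs(index.rt[sl] - query_rt[i])
        ok = (dmz <= delta_mz + EPS) & (drt <= delta_rt + EPS)
        if not ok.any():
            continue
        cand = sl[ok]
        key = np.lexsort((index.order[cand], drt[ok], dmz[ok]))
        out[i] = int(index.order[cand[key[0]]])
    return out
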