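"""Sliding-window identity profiles over a multi-island alignment and
two-segment (integration vs cargo) changepoint segmentation.

"% identity" is mean pairwise identity: for every pair of rows and every
column, an indicator that the two bases are equal, with comparisons
involving a gap or N excluded from that pair's denominator.  A large
deletion in a subset of rows therefore does not depress the regional mean.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seqio import MultipleAlignment

DEFAULT_WINDOW = 14

_GAP, _N = ord("-"), ord("N")


@dataclass
class IdentityProfile:
    window: int
    values: np.ndarray        # per window-start column, fraction in [0, 1]
    n_rows: int


@dataclass
class Segmentation:
    boundary_column: int | None   # 0-based first column of the right segment
    left_mean: float
    right_mean: float
    delta: float
    no_changepoint: bool = False


def _pair_counts(msa: MultipleAlignment) -> tuple[np.ndarray, np.ndarray]:
    """Per-column (match_count, valid_pair_count) pooled over all row pairs."""
    m = msa.matrix()
    n, L = m.shape
    ok = (m != _GAP) & (m != _N)
    match = np.zeros(L, dtype=np.int64)
    valid = np.zeros(L, dtype=np.int64)
    for i in range(n):
        for j in range(i + 1, n):
            both = ok[i] & ok[j]
            valid += both
            match += both & (m[i] == m[j])
    return match, valid


def column_identity(msa: MultipleAlignment) -> np.ndarray:
    """Per-column mean pairwise identity; NaN where no valid pair exists."""
    match, valid = _pair_counts(msa)
    with np.errstate(invalid="ignore"):
        return np.where(valid > 0, match / np.maximum(valid, 1), np.nan)


def identity_profile(msa: MultipleAlignment,
                     window: int = DEFAULT_WINDOW) -> IdentityProfile:
    """Sliding-window mean pairwise identity, one value per window start."""
    if window > msa.length:
        raise ValueError(f"window {window} > alignment length {msa.length}")
    match, valid = _pair_counts(msa)
    cm = np.concatenate([[0], np.cumsum(match)])
    cv = np.concatenate([[0], np.cumsum(valid)])
    wm = cm[window:] - cm[:-window]
    wv = cv[window:] - cv[:-window]
    with np.errstate(invalid="ignore"):
        vals = np.where(wv > 0, wm / np.maximum(wv, 1), np.nan)
    return IdentityProfile(window, vals, msa.n_rows)


def region_identity(msa: MultipleAlignment, start: int, end: int) -> float:
    """Mean per-column pairwise identity over columns [start, end)."""
    if not (0 <= start < end <= msa.length):
        raise ValueError(f"bad interval ({start}, {end})")
    ci = column_identity(msa)[start:end]
    ci = ci[~np.isnan(ci)]
    if ci.size == 0:
        raise ValueError("interval has no comparable columns")
    return float(ci.mean())


def segment_two(msa: MultipleAlignment,
                min_segment: int = DEFAULT_WINDOW) -> Segmentation:
    """Least-squares two-segment fit of the per-column identity values.

    The boundary is the column b minimizing the within-segment sum of
    squared deviations of [0, b) and [b, L); ties break to the leftmost
    candidate, and each segment must span at least ``min_segment``
    comparable columns.  A constant profile has no changepoint.
    """
    ci = column_identity(msa)
    usable = ~np.isnan(ci)
    x = ci[usable]
    idx = np.nonzero(usable)[0]
    L = x.size
    if L < 2 * min_segment:
        raise ValueError("alignment shorter than two minimal segments")
    if np.allclose(x, x[0]):
        mean = float(x[0])
        return Segmentation(None, mean, mean, 0.0, no_changepoint=True)
    c1 = np.concatenate([[0.0], np.cumsum(x)])
    c2 = np.concatenate([[0.0], np.cumsum(x * x)])
    best_b, best_sse = None, np.inf
    for b in range(min_segment, L - min_segment + 1):
        sl = c2[b] - c1[b] ** 2 / b
        nr = L - b
        sr = (c2[L] - c2[b]) - (c1[L] - c1[b]) ** 2 / nr
        sse = sl + sr
        if sse < best_sse - 1e-15:
            best_sse, best_b = sse, b
    left = float(x[:best_b].mean())
    right = float(x[best_b:].mean())
    boundary = int(idx[best_b])
    return Segmentation(boundary, left, right, right - left)


def perfect_identity_runs(msa: MultipleAlignment) -> list[tuple[int, int]]:
    """Maximal runs of columns where all rows carry the same A/C/G/T base,
    as (1-based start, length), sorted by length descending."""
    m = msa.matrix()
    ok = ((m != _GAP) & (m != _N)).all(axis=0) & (m == m[0]).all(axis=0)
    runs = []
    start = None
    for j, flag in enumerate(ok):
        if flag and start is None:
            start = j
        elif not flag and start is not None:
            runs.append((start + 1, j - start))
            start = None
    if start is not None:
        runs.append((start + 1, len(ok) - start))
    runs.sort(key=lambda t: (-t[1], t[0]))
    return runs
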