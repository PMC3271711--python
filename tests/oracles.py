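"""Independent brute-force oracles used to check the library's fast paths.

Each oracle is written from the definition of the quantity, with no code
shared with the implementation it checks.
"""

from __future__ import annotations

import math

import numpy as np


def slow_max_run(series, max_gaps: int | None = None) -> int:
    """Transparent O(n^3) run statistic: enumerate every contiguous window
    that starts and ends with a detection and contains no two consecutive
    zeros, and return the most detections any such window holds.

    ``max_gaps`` additionally caps the number of tolerated zeros per window.
    """
    s = [bool(v) for v in series]
    n = len(s)
    best = 0
    for i in range(n):
        if not s[i]:
            continue
        for j in range(i, n):
            if not s[j]:
                continue
            w = s[i : j + 1]
            if any(not w[k] and not w[k + 1] for k in range(len(w) - 1)):
                continue
            n_zero = len(w) - sum(w)
            if max_gaps is not None and n_zero > max_gaps:
                continue
            best = max(best, sum(w))
    return best


def window_enumeration_max_run(series) -> int:
    """Vectorized window enumeration of the same statistic: for every pair
    of detections (i, j) with no double zero strictly inside, count the
    detections in [i, j]."""
    s = np.asarray(series, dtype=bool)
    pos = np.flatnonzero(s)
    if pos.size == 0:
        return 0
    ps = np.concatenate(([0], np.cumsum(s)))
    dz = np.concatenate(([0], np.cumsum(~s[:-1] & ~s[1:]), [0]))[: s.size + 1]
    i, j = np.meshgrid(pos, pos, indexing="ij")
    valid = (i <= j) & (dz[j] - dz[i] == 0)
    counts = ps[j + 1] - ps[i]
    return int(counts[valid].max())


def branch_partition_unifrac(tree, tips_a: set, tips_b: set) -> float:
    """Unweighted UniFrac by explicit branch partition: every branch is
    classified by whether its descendant tips intersect community A, B, or
    both; distance = unique length / occupied length."""
    unique = 0.0
    total = 0.0
    for node in tree.traverse(include_self=False):
        length = node.length or 0.0
        tips = {node.name} if node.is_tip() else {t.name for t in node.tips()}
        in_a = bool(tips & tips_a)
        in_b = bool(tips & tips_b)
        if in_a or in_b:
            total += length
        if in_a != in_b:
            unique += length
    return unique / total if total > 0 else 0.0


def occupancy_core_curve(counts: np.ndarray, thresholds) -> list[float]:
    """Core-curve fractions by direct row scans of an OTU x sample count
    matrix."""
    present = counts > 0
    n_observed = sum(1 for row in present if row.any())
    fractions = []
    for k in thresholds:
        n_core = sum(1 for row in present if int(row.sum()) >= k)
        fractions.append(n_core / n_observed)
    return fractions


def gtest_closed_form(table_2xt) -> tuple[float, int]:
    """Log-likelihood-ratio G and df for a 2 x T table, cell by cell."""
    obs = [list(map(float, row)) for row in table_2xt]
    t_cols = [c for c in range(len(obs[0])) if obs[0][c] + obs[1][c] > 0]
    row_tot = [sum(obs[r][c] for c in t_cols) for r in (0, 1)]
    col_tot = {c: obs[0][c] + obs[1][c] for c in t_cols}
    total = sum(row_tot)
    g = 0.0
    for r in (0, 1):
        for c in t_cols:
            o = obs[r][c]
            if o > 0:
                e = row_tot[r] * col_tot[c] / total
                g += o * math.log(o / e)
    return 2.0 * g, len(t_cols) - 1
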