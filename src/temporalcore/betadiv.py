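"""Phylogenetic beta diversity and its temporal statistics.

Unweighted UniFrac between two communities is the fraction of tree branch
length leading exclusively to tips detected in only one of the two: with
``u(b)`` and ``v(b)`` indicating whether any tip below branch ``b`` is
present in community u or v,

    d(u, v) = sum_b L_b * [u(b) XOR v(b)] / sum_b L_b * [u(b) OR v(b)].

Distances feed classical principal coordinates analysis (Gower double
centering + eigendecomposition), Procrustes superposition with a Monte
Carlo permutation test, Mantel-style paired-distance correlation,
adjacent-timepoint distance series, and within/between-group two-sample
t-tests on pooled distances.

Distance matrices are carried as :class:`skbio.DistanceMatrix`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix, TreeNode

from .tables_io import CountTable, SampleRecord, order_series


# ---------------------------------------------------------------------------
# UniFrac
# ---------------------------------------------------------------------------

def unweighted_unifrac(tree: TreeNode, table: CountTable) -> DistanceMatrix:
    """Pairwise unweighted UniFrac distances between all samples of ``table``.

    Every OTU with a nonzero count anywhere in the table must be a tip of
    ``tree``; presence is count > 0. Branches with no length are treated as
    length zero; the root's stem (if any) never discriminates and is ignored
    via the all-or-nothing union logic.
    """
    presence = table.presence().to_numpy()
    observed = presence.any(axis=1)
    tip_names = {t.name for t in tree.tips()}
    missing = [o for o, obs in zip(table.otu_ids, observed) if obs and o not in tip_names]
    if missing:
        raise ValueError(f"OTUs missing from tree: {missing[:10]}"
                         + ("..." if len(missing) > 10 else ""))
    otu_index = {o: i for i, o in enumerate(table.otu_ids)}
    n_samples = presence.shape[1]

    # per-branch tip-set presence per sample, accumulated in postorder
    branch_presence: list[np.ndarray] = []
    lengths: list[float] = []
    node_presence: dict[int, np.ndarray] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            idx = otu_index.get(node.name)
            pres = (presence[idx] if idx is not None
                    else np.zeros(n_samples, dtype=bool))
        else:
            pres = np.zeros(n_samples, dtype=bool)
            for child in node.children:
                pres = pres | node_presence.pop(id(child))
        node_presence[id(node)] = pres
        if node.parent is not None:
            branch_presence.append(pres)
            lengths.append(node.length or 0.0)

    bp = np.asarray(branch_presence, dtype=float)        # branches x samples
    lens = np.asarray(lengths, dtype=float)
    shared = (bp * lens[:, None]).T @ bp                 # sum L over b in both
    totals = lens @ bp                                   # sum L over b in each
    union = totals[:, None] + totals[None, :] - shared
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = np.where(union > 0, 1.0 - shared / union, 0.0)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, 1.0)
    return DistanceMatrix(dist, ids=table.sample_ids)


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OrdinationResult:
    """Classical-scaling embedding: coordinates on positive-eigenvalue axes."""

    sample_ids: tuple[str, ...]
    coordinates: np.ndarray          # samples x positive axes
    eigenvalues: np.ndarray          # all eigenvalues, descending
    proportion_explained: np.ndarray  # per positive axis, of positive total

    def frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=list(self.sample_ids),
                            columns=cols)


def pcoa(dm: DistanceMatrix | np.ndarray, *, sym_tol: float = 1e-8,
         eig_tol: float = 1e-10) -> OrdinationResult:
    """Principal coordinates analysis by classical scaling.

    Double-centers ``-0.5 * D**2``, eigendecomposes, and scales eigenvectors
    by the square root of their eigenvalues. Negative eigenvalues (from
    non-Euclidean distances) are reported but contribute no coordinates and
    no correction is applied. A plain square array is accepted in place of a
    :class:`skbio.DistanceMatrix`.
    """
    if isinstance(dm, DistanceMatrix):
        d = np.asarray(dm.data, dtype=float)
        ids = tuple(dm.ids)
    else:
        d = np.asarray(dm, dtype=float)
        ids = tuple(str(i) for i in range(d.shape[0]))
    if np.abs(d - d.T).max() > sym_tol:
        raise ValueError("distance matrix is not symmetric")
    n = d.shape[0]
    a = -0.5 * d ** 2
    centering = np.eye(n) - np.ones((n, n)) / n
    b = centering @ a @ centering
    b = (b + b.T) / 2.0
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    scale = max(abs(eigvals[0]), 1.0)
    positive = eigvals > eig_tol * scale
    coords = eigvecs[:, positive] * np.sqrt(eigvals[positive])
    pos_sum = eigvals[positive].sum()
    prop = eigvals[positive] / pos_sum if pos_sum > 0 else eigvals[positive]
    return OrdinationResult(sample_ids=ids, coordinates=coords,
                            eigenvalues=eigvals, proportion_explained=prop)


# ---------------------------------------------------------------------------
# Procrustes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProcrustesResult:
    m_squared: float
    n_permutations: int
    p_value: float


def _standardize(x: np.ndarray) -> np.ndarray:
    x = x - x.mean(axis=0)
    norm = np.linalg.norm(x)
    if norm == 0:
        raise ValueError("degenerate configuration (all points identical)")
    return x / norm


def _m_squared(a_std: np.ndarray, b_std: np.ndarray) -> float:
    """Normalized residual after optimal translation/rotation/scaling of two
    centered, unit-norm configurations: ``1 - (sum of singular values)**2``."""
    s = np.linalg.svd(a_std.T @ b_std, compute_uv=False)
    return float(max(0.0, 1.0 - s.sum() ** 2))


def procrustes_test(coords_a: pd.DataFrame, coords_b: pd.DataFrame,
                    n_axes: int = 3, n_permutations: int = 999,
                    seed: int = 0) -> ProcrustesResult:
    """Procrustes M^2 between two ordinations plus a Monte Carlo test.

    Rows are matched by index (sample id). The null distribution permutes
    the row correspondence of the second configuration; the p-value uses the
    add-one estimator ``(1 + #{M2_perm <= M2_obs}) / (1 + n_permutations)``.
    """
    ids_a = set(coords_a.index)
    if ids_a != set(coords_b.index):
        raise ValueError("configurations must share an identical sample set")
    b = coords_b.loc[coords_a.index]
    if n_axes > coords_a.shape[1] or n_axes > b.shape[1]:
        raise ValueError(f"n_axes={n_axes} exceeds available axes")
    a_std = _standardize(coords_a.to_numpy()[:, :n_axes])
    b_std = _standardize(b.to_numpy()[:, :n_axes])
    m2 = _m_squared(a_std, b_std)
    rng = np.random.default_rng(seed)
    n_le = 0
    for _ in range(n_permutations):
        perm = rng.permutation(b_std.shape[0])
        if _m_squared(a_std, b_std[perm]) <= m2:
            n_le += 1
    p = (1 + n_le) / (1 + n_permutations)
    return ProcrustesResult(m_squared=m2, n_permutations=n_permutations,
                            p_value=p)


# ---------------------------------------------------------------------------
# distance correlations and temporal series
# ---------------------------------------------------------------------------

def paired_distance_correlation(dm_a: DistanceMatrix, dm_b: DistanceMatrix,
                                n_permutations: int = 999,
                                seed: int = 0) -> tuple[float, float]:
    """Pearson r between matched sample-pair distances, with a Mantel-style
    permutation p-value (two-sided on |r|, add-one estimator)."""
    if set(dm_a.ids) != set(dm_b.ids):
        raise ValueError("distance matrices must share a sample set")
    if len(dm_a.ids) < 3:
        raise ValueError("need at least 3 samples")
    b = dm_b.filter(dm_a.ids)
    iu = np.triu_indices(len(dm_a.ids), k=1)
    xa = dm_a.data[iu]
    mat_b = b.data
    xb = mat_b[iu]
    r = float(stats.pearsonr(xa, xb).statistic)
    rng = np.random.default_rng(seed)
    n_ge = 0
    n = len(dm_a.ids)
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        xp = mat_b[np.ix_(perm, perm)][iu]
        if abs(float(stats.pearsonr(xa, xp).statistic)) >= abs(r):
            n_ge += 1
    p = (1 + n_ge) / (1 + n_permutations)
    return r, p


@dataclass(frozen=True)
class DeltaSeries:
    """Distances between adjacent sampling events of one (subject, habitat)."""

    subject: str
    habitat: str
    day_pairs: tuple[tuple[int, int], ...]
    deltas: tuple[float, ...]


def adjacent_delta_series(dm: DistanceMatrix, records: Sequence[SampleRecord],
                          subject: str, habitat: str) -> DeltaSeries:
    """Distance between each pair of consecutive sampling events."""
    series = [r for r in order_series(records, subject, habitat)
              if r.sample_id in set(dm.ids)]
    if len(series) < 2:
        raise ValueError("series must contain at least 2 samples with distances")
    pairs = []
    deltas = []
    for prev, nxt in zip(series, series[1:]):
        pairs.append((prev.day, nxt.day))
        deltas.append(float(dm[prev.sample_id, nxt.sample_id]))
    return DeltaSeries(subject=subject, habitat=habitat,
                       day_pairs=tuple(pairs), deltas=tuple(deltas))


def correlate_delta_series(series_a: DeltaSeries,
                           series_b: DeltaSeries) -> tuple[float, float]:
    """Pearson correlation between two delta series over shared adjacent-day
    pairs (both series sampled at both endpoints); parametric two-sided p."""
    map_a = dict(zip(series_a.day_pairs, series_a.deltas))
    map_b = dict(zip(series_b.day_pairs, series_b.deltas))
    shared = [p for p in series_a.day_pairs if p in map_b]
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared adjacent-day pairs (< 3)")
    xa = np.array([map_a[p] for p in shared])
    xb = np.array([map_b[p] for p in shared])
    res = stats.pearsonr(xa, xb)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    tail: str


def _pool_distances(dm: DistanceMatrix, records: Sequence[SampleRecord],
                    spec: tuple[tuple[str, str], tuple[str, str]] | tuple[str, str],
                    ) -> np.ndarray:
    """Distance entries for a group spec.

    A spec is either ``(subject, habitat)`` — all unordered within-group
    pairs — or a pair of such tuples — all cross pairs between the two
    groups. ``"*"`` matches any subject/habitat.
    """
    by_id = {r.sample_id: r for r in records}
    ids = [i for i in dm.ids if i in by_id]

    def members(group: tuple[str, str]) -> list[int]:
        subject, habitat = group
        return [dm.index(i) for i in ids if by_id[i].matches(subject, habitat)]

    if len(spec) == 2 and isinstance(spec[0], str):
        idx = members(spec)  # type: ignore[arg-type]
        out = [dm.data[i, j] for k, i in enumerate(idx) for j in idx[k + 1:]]
    else:
        idx_a = members(spec[0])  # type: ignore[index]
        idx_b = members(spec[1])  # type: ignore[index]
        overlap = set(idx_a) & set(idx_b)
        if overlap:
            raise ValueError("cross-group spec selects overlapping sample sets")
        out = [dm.data[i, j] for i in idx_a for j in idx_b]
    return np.asarray(out, dtype=float)


def within_between_test(dm: DistanceMatrix, records: Sequence[SampleRecord],
                        group_a_spec, group_b_spec, tail: str = "less",
                        *, equal_var: bool = True) -> TTestResult:
    """One-tailed two-sample t-test comparing two pools of distances.

    ``tail="less"`` tests whether pool A's distances are smaller than pool
    B's (e.g. within-subject < between-subject); ``tail="greater"`` the
    reverse. Pooled-variance statistic by default, Welch via
    ``equal_var=False``.
    """
    if tail not in ("less", "greater"):
        raise ValueError("tail must be 'less' or 'greater'")
    pool_a = _pool_distances(dm, records, group_a_spec)
    pool_b = _pool_distances(dm, records, group_b_spec)
    if pool_a.size == 0 or pool_b.size == 0:
        raise ValueError("both distance pools must be non-empty")
    res = stats.ttest_ind(pool_a, pool_b, equal_var=equal_var, alternative=tail)
    df = (pool_a.size + pool_b.size - 2) if equal_var else int(res.df)
    return TTestResult(t=float(res.statistic), df=int(df),
                       p=float(res.pvalue), tail=tail)


def ordination_trace(result: OrdinationResult, records: Sequence[SampleRecord],
                     subject: str, habitat: str, n_axes: int = 3) -> pd.DataFrame:
    """Time-ordered principal-coordinate trace of one series (for export to
    external animation tools)."""
    coords = pd.DataFrame(
        result.coordinates[:, :n_axes], index=list(result.sample_ids),
        columns=[f"PC{i + 1}" for i in range(min(n_axes, result.coordinates.shape[1]))],
    )
    series = [r for r in order_series(records, subject, habitat)
              if r.sample_id in coords.index]
    out = coords.loc[[r.sample_id for r in series]].copy()
    out.insert(0, "day", [r.day for r in series])
    out.index.name = "sample_id"
    return out
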