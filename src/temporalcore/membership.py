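"""Community-membership analysis of microbiome time series.

Classifies each OTU in a single (subject, habitat) time series as

* **core** — detected at every sampling event;
* **persistent** — detected in >= 20% of timepoints with >= 90% of those
  detections inside one gap-tolerant consecutive stretch (appears and stays);
* **transient** — detected in >= 60% of samples but with <= 75% of detections
  consecutive (appears and disappears repeatedly);
* **other** — everything else.

The consecutive-run statistic tolerates single-timepoint dropouts: a zero
count at one timepoint is counted as part of a continuous stretch when both
neighbouring timepoints have non-zero counts, which guards against a single
bad sample splitting a genuinely continuous residency. Two or more
consecutive zeros always break a stretch.

Group compositions are compared with a G-test (log-likelihood ratio test of
independence) on OTU counts per taxon, and the stability of the persistent
group under re-sequencing depth is probed with a rarefaction jackknife.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .tables_io import CountTable, SampleRecord, TaxonomyMap, order_series, rarefy

LABELS = ("core", "persistent", "transient", "other")


@dataclass(frozen=True)
class MembershipParams:
    """Occupancy thresholds for the persistent / transient rules.

    Defaults: persistent = detected in >= 20% of timepoints with >= 90% of
    detections consecutive; transient = detected in >= 60% of samples with
    <= 75% of detections consecutive. ``0.90 > 0.75`` guarantees the two
    labels are disjoint.
    """

    persistent_min_obs_fraction: float = 0.20
    persistent_min_consecutive_fraction: float = 0.90
    transient_min_obs_fraction: float = 0.60
    transient_max_consecutive_fraction: float = 0.75
    single_gap_per_run: bool = False

    def __post_init__(self):
        for f_ in (self.persistent_min_obs_fraction,
                   self.persistent_min_consecutive_fraction,
                   self.transient_min_obs_fraction,
                   self.transient_max_consecutive_fraction):
            if not 0 <= f_ <= 1:
                raise ValueError("membership fractions must be in [0, 1]")
        if (self.persistent_min_consecutive_fraction
                <= self.transient_max_consecutive_fraction):
            raise ValueError(
                "persistent_min_consecutive_fraction must exceed "
                "transient_max_consecutive_fraction (disjoint categories)"
            )


@dataclass(frozen=True)
class MembershipRecord:
    otu_id: str
    n_timepoints: int
    n_observed: int
    max_run_obs: int
    obs_fraction: float
    consecutive_fraction: float
    median_rel_abundance: float
    label: str


@dataclass(frozen=True)
class GTestResult:
    g: float
    df: int
    p: float


def presence_series(table: CountTable, records: Sequence[SampleRecord],
                    subject: str, habitat: str, otu_id: str) -> np.ndarray:
    """Day-ordered boolean detection vector for one OTU in one series."""
    if otu_id not in table.df.index:
        raise KeyError(f"unknown OTU id {otu_id!r}")
    series = order_series(records, subject, habitat)
    sample_ids = [r.sample_id for r in series if r.sample_id in table.df.columns]
    return (table.df.loc[otu_id, sample_ids].to_numpy() > 0)


def max_gap_tolerant_run(series: np.ndarray, *,
                         single_gap_per_run: bool = False) -> int:
    """Number of detections in the best gap-tolerant consecutive stretch.

    A stretch is a maximal run of detections in which every zero is isolated
    (length one) and flanked by detections; >= 2 consecutive zeros break it.
    Returns the count of detections (True values) inside the best stretch,
    so ``max_run_obs / n_observed <= 1`` always.

    With ``single_gap_per_run`` at most one tolerated zero is allowed per
    stretch (the stricter reading); by default any number of isolated zeros
    may occur within one stretch.
    """
    s = np.asarray(series, dtype=bool)
    pos = np.flatnonzero(s)
    if pos.size == 0:
        return 0
    gaps = np.diff(pos)
    # successive detections belong to one stretch iff separated by <= 2
    # (gap of 2 means exactly one zero in between)
    breaks = np.flatnonzero(gaps > 2)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [pos.size - 1]))  # inclusive
    if not single_gap_per_run:
        return int((ends - starts + 1).max())
    best = 0
    for a, b in zip(starts, ends):
        seg_gaps = gaps[a:b]  # gaps within the stretch, values in {1, 2}
        # longest window of detections containing at most one tolerated zero
        lo = 0
        n_two = 0
        for hi in range(seg_gaps.size):
            if seg_gaps[hi] == 2:
                n_two += 1
            while n_two > 1:
                if seg_gaps[lo] == 2:
                    n_two -= 1
                lo += 1
            best = max(best, hi - lo + 2)
        best = max(best, 1)
    return best


def classify_membership(table: CountTable, records: Sequence[SampleRecord],
                        params: MembershipParams = MembershipParams(),
                        *, subject: str, habitat: str) -> list[MembershipRecord]:
    """Label every OTU observed in the (subject, habitat) series.

    Label precedence: core > persistent > transient > other. Only OTUs with
    a nonzero total count in the series are reported.
    """
    series = order_series(records, subject, habitat)
    sample_ids = [r.sample_id for r in series if r.sample_id in table.df.columns]
    if len(sample_ids) < 2:
        raise ValueError("series must contain at least 2 samples")
    sub = table.df[sample_ids]
    counts = sub.to_numpy()
    n_timepoints = len(sample_ids)
    depths = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(depths > 0, counts / depths, 0.0)
    present = counts > 0

    out: list[MembershipRecord] = []
    for i, otu_id in enumerate(sub.index):
        n_obs = int(present[i].sum())
        if n_obs == 0:
            continue
        run = max_gap_tolerant_run(
            present[i], single_gap_per_run=params.single_gap_per_run
        )
        obs_frac = n_obs / n_timepoints
        consec_frac = run / n_obs
        med_rel = float(np.median(rel[i][present[i]]))
        if n_obs == n_timepoints:
            label = "core"
        elif (obs_frac >= params.persistent_min_obs_fraction
              and consec_frac >= params.persistent_min_consecutive_fraction):
            label = "persistent"
        elif (obs_frac >= params.transient_min_obs_fraction
              and consec_frac <= params.transient_max_consecutive_fraction):
            label = "transient"
        else:
            label = "other"
        out.append(MembershipRecord(
            otu_id=str(otu_id), n_timepoints=n_timepoints, n_observed=n_obs,
            max_run_obs=run, obs_fraction=obs_frac,
            consecutive_fraction=consec_frac,
            median_rel_abundance=med_rel, label=label,
        ))
    return out


def summarize_membership_taxa(membership_records: Sequence[MembershipRecord],
                              taxonomy: TaxonomyMap,
                              rank: str = "class") -> pd.DataFrame:
    """Taxon composition of the persistent and transient groups.

    Returns a long-format frame (label, taxon, n_otus, proportion) where
    proportions sum to one within each non-empty label.
    """
    rows = []
    for label in ("persistent", "transient"):
        otus = [m.otu_id for m in membership_records if m.label == label]
        if not otus:
            continue
        taxa = pd.Series([taxonomy.at_rank(o, rank) for o in otus])
        counts = taxa.value_counts().sort_index()
        for taxon, n in counts.items():
            rows.append({"label": label, "taxon": taxon, "n_otus": int(n),
                         "proportion": n / len(otus)})
    return pd.DataFrame(rows, columns=["label", "taxon", "n_otus", "proportion"])


def group_taxon_counts(membership_records: Sequence[MembershipRecord],
                       taxonomy: TaxonomyMap, label: str,
                       rank: str = "class") -> pd.Series:
    """OTU counts per taxon at ``rank`` for one membership label."""
    otus = [m.otu_id for m in membership_records if m.label == label]
    taxa = pd.Series([taxonomy.at_rank(o, rank) for o in otus], dtype=object)
    return taxa.value_counts().sort_index()


def gtest_independence(counts_a: Sequence[int] | pd.Series,
                       counts_b: Sequence[int] | pd.Series) -> GTestResult:
    """G-test of independence on a 2 x T contingency table of OTU counts.

    ``G = 2 * sum(O * ln(O/E))`` over non-zero observed cells, with expected
    counts from the row/column marginals; degrees of freedom are ``T' - 1``
    where ``T'`` is the number of taxa with a non-zero column total. No
    continuity or Williams correction is applied.
    """
    if isinstance(counts_a, pd.Series) or isinstance(counts_b, pd.Series):
        sa = pd.Series(counts_a, dtype=float)
        sb = pd.Series(counts_b, dtype=float)
        taxa = sorted(set(sa.index) | set(sb.index))
        a = sa.reindex(taxa, fill_value=0).to_numpy()
        b = sb.reindex(taxa, fill_value=0).to_numpy()
    else:
        a = np.asarray(counts_a, dtype=float)
        b = np.asarray(counts_b, dtype=float)
        if a.shape != b.shape:
            raise ValueError("count vectors must share a taxon list")
    if a.sum() == 0 or b.sum() == 0:
        raise ValueError("both groups must have a non-zero total")
    obs = np.vstack([a, b])
    col_tot = obs.sum(axis=0)
    keep = col_tot > 0
    obs = obs[:, keep]
    col_tot = col_tot[keep]
    row_tot = obs.sum(axis=1)
    total = obs.sum()
    expected = np.outer(row_tot, col_tot) / total
    nz = obs > 0
    g = 2.0 * float(np.sum(obs[nz] * np.log(obs[nz] / expected[nz])))
    g = max(g, 0.0)
    df = int(obs.shape[1] - 1)
    p = float(stats.chi2.sf(g, df)) if df > 0 else 1.0
    return GTestResult(g=g, df=df, p=p)


@dataclass
class JackknifeResult:
    """Per-iteration G statistics from the persistent-set stability jackknife."""

    significant_fraction: float
    g_values: list[float] = field(default_factory=list)
    p_values: list[float] = field(default_factory=list)


def compare_persistent_sets(table_full: CountTable,
                            records: Sequence[SampleRecord],
                            taxonomy: TaxonomyMap,
                            *, depth: int, n_iterations: int, seed: int,
                            subject: str, habitat: str,
                            alpha: float = 0.05,
                            rank: str = "class",
                            params: MembershipParams = MembershipParams(),
                            ) -> JackknifeResult:
    """Rarefaction jackknife of the persistent group's taxon composition.

    Each iteration rarefies the full table to ``depth`` (with a per-iteration
    seed derived from ``seed``), re-classifies membership, and G-tests the
    persistent group's taxon composition at ``rank`` against the composition
    obtained on the full data. Returns the fraction of iterations that differ
    significantly at ``alpha``.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    full_members = classify_membership(table_full, records, params,
                                       subject=subject, habitat=habitat)
    full_comp = group_taxon_counts(full_members, taxonomy, "persistent", rank)
    if full_comp.sum() == 0:
        raise ValueError("no persistent OTUs in the full data")
    seeds = np.random.SeedSequence(seed).generate_state(n_iterations) % (2**31)
    g_values: list[float] = []
    p_values: list[float] = []
    n_sig = 0
    for it_seed in seeds:
        rare = rarefy(table_full, depth, int(it_seed))
        if not rare.sample_ids:
            raise ValueError(f"depth {depth} excludes all samples")
        members = classify_membership(rare, records, params,
                                      subject=subject, habitat=habitat)
        comp = group_taxon_counts(members, taxonomy, "persistent", rank)
        if comp.sum() == 0:
            # an empty persistent set is maximally different from the full one
            g_values.append(float("inf"))
            p_values.append(0.0)
            n_sig += 1
            continue
        res = gtest_independence(comp, full_comp)
        g_values.append(res.g)
        p_values.append(res.p)
        if res.p < alpha:
            n_sig += 1
    return JackknifeResult(significant_fraction=n_sig / n_iterations,
                           g_values=g_values, p_values=p_values)


def membership_frame(records: Sequence[MembershipRecord]) -> pd.DataFrame:
    """Tabular view of membership records, one row per OTU."""
    return pd.DataFrame([vars(r) for r in records])
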