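"""Synthetic multi-subject, multi-habitat microbiome time series.

The generator emulates the statistical structure of a dense daily-sampling
study of a few subjects at several body sites: per habitat it plants

* **core** OTUs — present every day at high log-normal relative abundance;
* **persistent** OTUs — non-zero only inside one contiguous window covering
  a sizeable fraction of the series (they appear and remain);
* **transient** OTUs — short presence bursts separated by >= 2 absent days,
  so they occupy most of the series but never form one long stretch;
* **background** OTUs — rare, sporadic (independent Bernoulli occurrence).

Reads are drawn multinomially at a configurable sequencing depth, which
produces realistic depth-driven dropout of low-abundance taxa. Habitat
communities live on disjoint clades of a random bifurcating tree, so they
are phylogenetically distinct; subjects share each habitat's OTU pool only
partially, giving within-subject similarity > between-subject similarity.
Planted habitat-label swaps emulate sample mix-ups for the mislabel
detector. Truth tables record every planted category, window, and swap.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from math import ceil, log

import numpy as np
import pandas as pd
from skbio import TreeNode

from .tables_io import CountTable, SampleRecord, TaxonomyMap, rarefy

CATEGORIES = ("core", "persistent", "transient", "background")


@dataclass(frozen=True)
class SynthParams:
    """Generator configuration.

    Abundance parameters are natural-log mean/sd of an OTU's (unnormalized)
    relative abundance on days it is present; per-day multiplicative noise
    has log-sd ``day_log_sd``. ``subject_overlap`` is the probability that a
    non-core OTU of a habitat pool is carried by a given subject.
    ``palm_coupling`` is the probability that a right-palm OTU reuses the
    presence time-course of its left-palm counterpart, emulating microbial
    exchange between hands. ``class_abundance_sd`` adds a per-taxonomic-class
    log-abundance offset shared by all OTUs of that class, modelling
    systematic abundance differences among higher taxa (this is what makes
    shallow sequencing drop whole portions of a group's taxon composition
    rather than a random subset of its members).
    """

    n_subjects: int = 2
    habitats: tuple[str, ...] = ("gut", "tongue", "left palm", "right palm")
    n_timepoints: int = 130
    seq_depth: int = 5000
    n_core_otus: int = 10
    n_persistent_otus: int = 30
    n_transient_otus: int = 30
    n_background_otus: int = 200
    core_log_mean: float = log(0.02)
    core_log_sd: float = 0.5
    persistent_log_mean: float = log(0.005)
    persistent_log_sd: float = 0.8
    transient_log_mean: float = log(0.005)
    transient_log_sd: float = 0.8
    background_log_mean: float = log(2e-4)
    background_log_sd: float = 1.0
    day_log_sd: float = 0.3
    persistent_window_fraction: float = 0.3
    transient_occurrence_fraction: float = 0.7
    background_occurrence_prob: float = 0.05
    subject_overlap: float = 0.7
    palm_coupling: float = 0.0
    class_abundance_sd: float = 0.0
    overdispersion: float | None = None
    n_planted_mislabels: int = 0
    n_classes: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.n_timepoints < 2:
            raise ValueError("n_timepoints must be >= 2")
        if not 0 < self.persistent_window_fraction <= 1:
            raise ValueError("persistent_window_fraction must be in (0, 1]")
        if ceil(self.persistent_window_fraction * self.n_timepoints) < 1:
            raise ValueError("persistent window shorter than 1 day")
        if self.seq_depth < 1:
            raise ValueError("seq_depth must be >= 1")
        for name in ("n_core_otus", "n_persistent_otus", "n_transient_otus",
                     "n_background_otus", "n_planted_mislabels"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SynthDataset:
    table: CountTable
    records: list[SampleRecord]
    taxonomy: TaxonomyMap
    tree: TreeNode
    otu_truth: pd.DataFrame       # subject, habitat, otu_id, category, window
    mislabel_truth: pd.DataFrame  # sample_id, true_habitat, alleged_habitat
    expected_presence: pd.DataFrame = field(repr=False, default=None)


def _persistent_window(rng: np.random.Generator, n: int,
                       min_frac: float) -> tuple[int, int]:
    """(start, length) of one contiguous presence window; never the full series."""
    hi_frac = max(min(0.85, 1.0 - 1.0 / n), min_frac)
    length = int(ceil(rng.uniform(min_frac, hi_frac) * n))
    length = min(length, n - 1)
    start = int(rng.integers(0, n - length + 1))
    return start, length


def _transient_pattern(rng: np.random.Generator, n: int,
                       target_frac: float) -> np.ndarray:
    """Presence bursts separated by two absent days (anti-clustering).

    Burst lengths of 4-6 days with 2-day separators give an occupancy near
    ``target_frac`` (~0.67-0.75 before dropout) while keeping the longest
    gap-tolerant stretch a small fraction of the observations.
    """
    out = np.zeros(n, dtype=bool)
    i = int(rng.integers(0, 3))
    while i < n:
        k = int(rng.integers(4, 7))
        out[i : i + k] = True
        i += k + 2
    return out


def _random_subtree(rng: np.random.Generator, tip_names: list[str],
                    mean_branch: float = 0.1) -> TreeNode:
    """Random bifurcating tree over ``tip_names`` with exponential branch
    lengths, built by successive random joins."""
    nodes = [TreeNode(name=t, length=float(rng.exponential(mean_branch)))
             for t in tip_names]
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        i, j = (int(i), int(j)) if i < j else (int(j), int(i))
        right = nodes.pop(j)
        left = nodes.pop(i)
        parent = TreeNode(length=float(rng.exponential(mean_branch)),
                          children=[left, right])
        nodes.append(parent)
    return nodes[0]


def _lineage(class_id: int, otu_idx: int) -> tuple[str, ...]:
    return (f"Phylum{class_id % 3}", f"Class{class_id}",
            f"Order{class_id}.{otu_idx % 4}",
            f"Family{class_id}.{otu_idx % 8}", f"Genus{otu_idx}")


def _sanitize(habitat: str) -> str:
    return habitat.replace(" ", "-")


def generate_dataset(params: SynthParams) -> SynthDataset:
    """Generate a complete synthetic dataset with ground truth.

    Identical ``params`` (including seed) yield a bit-identical dataset.
    """
    rng = np.random.default_rng(params.seed)
    n_days = params.n_timepoints
    subjects = [f"S{i + 1}" for i in range(params.n_subjects)]
    days = np.arange(1, n_days + 1)

    # --- habitat OTU pools, taxonomy, tree --------------------------------
    pools: dict[str, list[str]] = {}
    categories: dict[str, str] = {}
    lineages: dict[str, tuple[str, ...]] = {}
    class_ids: dict[str, int] = {}
    class_offsets = params.class_abundance_sd * rng.standard_normal(params.n_classes)
    otu_counter = 0
    per_cat = (("core", params.n_core_otus),
               ("persistent", params.n_persistent_otus),
               ("transient", params.n_transient_otus),
               ("background", params.n_background_otus))
    for habitat in params.habitats:
        pool = []
        for cat, n_cat in per_cat:
            for k in range(n_cat):
                otu_id = f"OTU_{_sanitize(habitat)}_{cat[0]}{k:04d}"
                pool.append(otu_id)
                categories[otu_id] = cat
                class_id = int(rng.integers(0, params.n_classes))
                class_ids[otu_id] = class_id
                lineages[otu_id] = _lineage(class_id, otu_counter)
                otu_counter += 1
        pools[habitat] = pool
    all_otus = [o for h in params.habitats for o in pools[h]]
    otu_index = {o: i for i, o in enumerate(all_otus)}
    taxonomy = TaxonomyMap(lineages)

    subtrees = [_random_subtree(rng, pools[h]) for h in params.habitats]
    for st in subtrees:
        st.length = 1.0  # long stems keep habitat clades phylogenetically distinct
    tree = TreeNode(children=subtrees) if len(subtrees) > 1 else subtrees[0]

    # --- per (subject, habitat) presence patterns and base abundances -----
    log_params = {
        "core": (params.core_log_mean, params.core_log_sd),
        "persistent": (params.persistent_log_mean, params.persistent_log_sd),
        "transient": (params.transient_log_mean, params.transient_log_sd),
        "background": (params.background_log_mean, params.background_log_sd),
    }
    truth_rows = []
    # expected relative abundance per sample, assembled habitat by habitat
    sample_ids: list[str] = []
    records: list[SampleRecord] = []
    probs: list[np.ndarray] = []  # per sample, over all_otus
    expected_presence_cols: dict[str, np.ndarray] = {}

    palm_pair = ("left palm", "right palm")
    has_palms = all(h in params.habitats for h in palm_pair)

    for subject in subjects:
        left_palm_patterns: dict[int, np.ndarray] = {}
        for habitat in params.habitats:
            pool = pools[habitat]
            n_pool = len(pool)
            presence = np.zeros((n_pool, n_days), dtype=bool)
            window_info: list[tuple[int, int] | None] = [None] * n_pool
            carried = np.ones(n_pool, dtype=bool)
            for j, otu_id in enumerate(pool):
                cat = categories[otu_id]
                if cat != "core" and rng.random() > params.subject_overlap:
                    carried[j] = False
                    continue
                if cat == "core":
                    presence[j, :] = True
                elif cat == "persistent":
                    start, length = _persistent_window(
                        rng, n_days, params.persistent_window_fraction)
                    presence[j, start : start + length] = True
                    window_info[j] = (start, length)
                elif cat == "transient":
                    if (has_palms and habitat == palm_pair[1]
                            and rng.random() < params.palm_coupling
                            and j in left_palm_patterns):
                        presence[j] = left_palm_patterns[j]
                    else:
                        presence[j] = _transient_pattern(
                            rng, n_days, params.transient_occurrence_fraction)
                    if has_palms and habitat == palm_pair[0]:
                        left_palm_patterns[j] = presence[j].copy()
                else:  # background
                    if (has_palms and habitat == palm_pair[1]
                            and rng.random() < params.palm_coupling
                            and -j - 1 in left_palm_patterns):
                        presence[j] = left_palm_patterns[-j - 1]
                    else:
                        presence[j] = (rng.random(n_days)
                                       < params.background_occurrence_prob)
                    if has_palms and habitat == palm_pair[0]:
                        left_palm_patterns[-j - 1] = presence[j].copy()

            base = np.exp(np.array([
                log_params[categories[o]][0]
                + log_params[categories[o]][1] * rng.standard_normal()
                + class_offsets[class_ids[o]]
                for o in pool
            ]))
            noise = np.exp(params.day_log_sd
                           * rng.standard_normal((n_pool, n_days)))
            abundance = np.where(presence, base[:, None] * noise, 0.0)
            col_sums = abundance.sum(axis=0)
            col_sums[col_sums == 0] = 1.0
            rel = abundance / col_sums  # normalized within the habitat community

            for j, otu_id in enumerate(pool):
                if not carried[j]:
                    continue
                w = window_info[j]
                truth_rows.append({
                    "subject": subject, "habitat": habitat, "otu_id": otu_id,
                    "category": categories[otu_id],
                    "window_start": w[0] if w else pd.NA,
                    "window_length": w[1] if w else pd.NA,
                })

            offset = otu_index[pool[0]]
            for d_i, day in enumerate(days):
                sid = f"{subject}.{_sanitize(habitat)}.{day}"
                sample_ids.append(sid)
                records.append(SampleRecord(sid, subject, habitat, int(day)))
                p = np.zeros(len(all_otus))
                p[offset : offset + n_pool] = rel[:, d_i]
                probs.append(p)
                expected_presence_cols[sid] = np.concatenate([
                    np.zeros(offset, dtype=bool), presence[:, d_i],
                    np.zeros(len(all_otus) - offset - n_pool, dtype=bool),
                ])

    # --- multinomial read sampling ----------------------------------------
    counts = np.zeros((len(all_otus), len(sample_ids)), dtype=np.int64)
    for s_i, p in enumerate(probs):
        tot = p.sum()
        if tot == 0:
            continue
        p = p / tot
        if params.overdispersion is not None:
            nz = p > 0
            alpha = p[nz] * params.overdispersion
            p = p.copy()
            p[nz] = rng.dirichlet(alpha)
        counts[:, s_i] = rng.multinomial(params.seq_depth, p)
    table = CountTable(pd.DataFrame(counts, index=all_otus, columns=sample_ids))

    # --- planted mislabels (label swaps, uniqueness-preserving) -----------
    mislabel_rows: list[dict] = []
    if params.n_planted_mislabels:
        records, mislabel_rows = _plant_mislabels(
            rng, records, params.n_planted_mislabels)

    otu_truth = pd.DataFrame(
        truth_rows, columns=["subject", "habitat", "otu_id", "category",
                             "window_start", "window_length"])
    mislabel_truth = pd.DataFrame(
        mislabel_rows, columns=["sample_id", "true_habitat", "alleged_habitat"])
    expected_presence = pd.DataFrame(expected_presence_cols, index=all_otus)
    return SynthDataset(table=table, records=records, taxonomy=taxonomy,
                        tree=tree, otu_truth=otu_truth,
                        mislabel_truth=mislabel_truth,
                        expected_presence=expected_presence)


def _merged_class(habitat: str) -> str:
    from .mislabel import habitat_class
    return habitat_class(habitat)


def _plant_mislabels(rng: np.random.Generator, records: list[SampleRecord],
                     n_mislabels: int) -> tuple[list[SampleRecord], list[dict]]:
    """Swap habitat labels within random (subject, day) groups.

    Labels rotate among 2 (or 3, when ``n_mislabels`` is odd) samples from
    habitats with distinct merged classes, so (subject, habitat, day) stays
    unique and every swapped sample's alleged class is wrong.
    """
    by_key: dict[tuple[str, int], list[int]] = {}
    for i, r in enumerate(records):
        by_key.setdefault((r.subject, r.day), []).append(i)
    group_keys = [k for k, v in by_key.items()
                  if len({_merged_class(records[i].habitat) for i in v}) >= 2]
    group_keys = [group_keys[i] for i in rng.permutation(len(group_keys))]
    remaining = n_mislabels
    used: set[int] = set()
    mislabel_rows: list[dict] = []
    new_records = list(records)
    for key in group_keys:
        if remaining <= 0:
            break
        idxs = [i for i in by_key[key] if i not in used]
        by_class: dict[str, int] = {}
        for i in idxs:
            by_class.setdefault(_merged_class(records[i].habitat), i)
        if len(by_class) < 2:
            continue
        k = 3 if (remaining % 2 == 1 and len(by_class) >= 3) else 2
        k = min(k, remaining, len(by_class))
        if k < 2:
            continue
        chosen = [by_class[c] for c in list(by_class)[:k]]
        habs = [records[i].habitat for i in chosen]
        rotated = habs[1:] + habs[:1]
        for i, new_hab in zip(chosen, rotated):
            old = new_records[i]
            new_records[i] = SampleRecord(old.sample_id, old.subject,
                                          new_hab, old.day)
            mislabel_rows.append({"sample_id": old.sample_id,
                                  "true_habitat": old.habitat,
                                  "alleged_habitat": new_hab})
            used.add(i)
        remaining -= k
    if remaining > 0:
        raise ValueError(
            f"could not place {remaining} of {n_mislabels} planted mislabels; "
            "need more (subject, day) groups spanning >= 2 habitat classes")
    return new_records, mislabel_rows


def resample_platforms(table: CountTable, depths: tuple[int, int],
                       seeds: tuple[int, int]) -> tuple[CountTable, CountTable]:
    """Two rarefied views of one table, emulating shallow/deep re-sequencing
    of the same communities (e.g. ~500-read vs ~5,000-read platforms).

    Samples that cannot support the deeper view are dropped from both
    (paired design).
    """
    shallow_depth, deep_depth = depths
    if not shallow_depth < deep_depth:
        raise ValueError("depths must be (shallow, deep) with shallow < deep")
    sums = table.sample_sums()
    kept = [s for s in table.sample_ids if sums[s] >= deep_depth]
    if not kept:
        raise ValueError(f"no sample reaches depth {deep_depth}")
    paired = table.select_samples(kept)
    shallow = rarefy(paired, shallow_depth, seeds[0])
    deep = rarefy(paired, deep_depth, seeds[1])
    return shallow, deep


def truth_labels(dataset: SynthDataset, subject: str,
                 habitat: str) -> pd.Series:
    """Planted category per OTU carried by (subject, habitat), indexed by
    otu_id."""
    t = dataset.otu_truth
    sub = t[(t.subject == subject) & (t.habitat == habitat)]
    return sub.set_index("otu_id")["category"]
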