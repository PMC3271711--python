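"""Detection of mislabeled samples by out-of-bag classifier posteriors.

A bootstrap-aggregated ensemble of decision trees (random feature subsets at
each split) is trained to predict body habitat from the rarefied OTU
abundance matrix. Each sample's posterior probability per habitat is then
estimated **out of bag**: only votes from trees whose bootstrap resample did
not contain that sample are counted, so the posterior is never contaminated
by a tree that saw the sample during training. A sample whose alleged
habitat receives a posterior below the threshold (default 60%) is flagged
as potentially mislabeled.

Left and right palm are merged into a single "skin" class before training,
so classification is at the habitat level (gut / oral / skin).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import BaggingClassifier
from sklearn.tree import DecisionTreeClassifier

from .tables_io import CountTable, SampleRecord, filter_low_prevalence, rarefy

#: default site -> habitat-class merge
HABITAT_CLASSES = {
    "gut": "gut",
    "tongue": "oral",
    "mouth": "oral",
    "oral": "oral",
    "left palm": "skin",
    "right palm": "skin",
    "skin": "skin",
}


def habitat_class(habitat: str) -> str:
    """Merge body sites into the gut / oral / skin habitat classes; unknown
    site names are kept verbatim (they form their own class)."""
    return HABITAT_CLASSES.get(habitat, habitat)


def detect_mislabels(table: CountTable, records: Sequence[SampleRecord],
                     n_trees: int = 2000, depth: int = 500,
                     prevalence: float = 0.01, threshold: float = 0.60,
                     seed: int = 0, *,
                     average_probabilities: bool = False) -> pd.DataFrame:
    """Flag samples whose alleged habitat has a low out-of-bag posterior.

    Pipeline: rarefy to ``depth`` (samples below depth are dropped), remove
    OTUs present in fewer than ``prevalence`` of samples, train ``n_trees``
    bootstrap decision trees (sqrt-features per split, unlimited depth), and
    compute each sample's per-class posterior from its out-of-bag trees
    only — vote fractions by default, averaged class probabilities with
    ``average_probabilities``.

    Returns a frame indexed by sample id with columns ``alleged``,
    ``p_<class>`` per class, ``posterior_alleged``, ``predicted``, and
    ``flagged`` (posterior of the alleged class < ``threshold``).
    """
    rare = rarefy(table, depth, seed)
    rare = filter_low_prevalence(rare, prevalence)
    by_id = {r.sample_id: r for r in records}
    sample_ids = [s for s in rare.sample_ids if s in by_id]
    if len(sample_ids) < len(rare.sample_ids):
        missing = set(rare.sample_ids) - set(sample_ids)
        raise ValueError(f"samples without metadata: {sorted(missing)[:5]}")
    x = rare.df[sample_ids].to_numpy().T          # samples x OTUs
    y = np.array([habitat_class(by_id[s].habitat) for s in sample_ids])
    classes = sorted(set(y))
    if len(classes) < 2:
        raise ValueError("need at least 2 habitat classes")
    for c in classes:
        if (y == c).sum() < 2:
            raise ValueError(f"habitat class {c!r} has < 2 samples after rarefaction")

    forest = BaggingClassifier(
        estimator=DecisionTreeClassifier(max_features="sqrt"),
        n_estimators=n_trees, bootstrap=True, random_state=seed,
    )
    forest.fit(x, y)
    class_index = {c: i for i, c in enumerate(forest.classes_)}

    n = len(sample_ids)
    votes = np.zeros((n, len(forest.classes_)))
    n_oob = np.zeros(n, dtype=int)
    for est, samples in zip(forest.estimators_, forest.estimators_samples_):
        oob = np.ones(n, dtype=bool)
        oob[samples] = False
        if not oob.any():
            continue
        if average_probabilities:
            votes[oob] += est.predict_proba(x[oob])
        else:
            # inner estimators see label-encoded y: predictions index classes_
            pred = np.asarray(est.predict(x[oob]))
            if pred.dtype.kind not in "iu":
                pred = np.array([class_index[p] for p in pred])
            votes[oob, pred.astype(int)] += 1
        n_oob[oob] += 1
    if (n_oob == 0).any():
        bad = [sample_ids[i] for i in np.flatnonzero(n_oob == 0)]
        raise ValueError(
            f"samples with zero out-of-bag trees: {bad}; increase n_trees"
        )
    posteriors = votes / n_oob[:, None]

    alleged = y
    alleged_post = posteriors[np.arange(n), [class_index[a] for a in alleged]]
    predicted = forest.classes_[posteriors.argmax(axis=1)]
    report = pd.DataFrame(
        {
            "alleged": alleged,
            **{f"p_{c}": posteriors[:, class_index[c]] for c in forest.classes_},
            "posterior_alleged": alleged_post,
            "predicted": predicted,
            "flagged": alleged_post < threshold,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return report
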