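"""Temporal core-microbiome curves.

The temporal core at threshold ``k`` is the set of OTUs detected in at least
``k`` of a sample type's samples; sweeping ``k`` from 1 to the number of
samples traces how quickly the core shrinks as the definition tightens. To
compare sample types with unequal series lengths the samples of each type
are first subsampled to a common size (130 in the study design this package
follows), so curves share an x-axis.

The denominator at every threshold is the number of OTUs observed at least
once within the subsampled set, which forces ``fraction_core(1) = 1`` and
makes the curve monotone non-increasing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .tables_io import CountTable, SampleRecord


@dataclass(frozen=True)
class CoreCurve:
    sample_type: str
    n_subsampled: int
    thresholds: tuple[int, ...]
    n_core: tuple[int, ...]
    fraction_core: tuple[float, ...]

    def fraction_at(self, threshold: int) -> float:
        try:
            return self.fraction_core[self.thresholds.index(threshold)]
        except ValueError:
            raise KeyError(f"threshold {threshold} not in curve") from None


def parse_sample_type(spec: str) -> tuple[str, str]:
    """Parse ``"SUBJECT:HABITAT"`` where either side may be ``*`` (all)."""
    subject, _, habitat = spec.partition(":")
    if not subject or not habitat:
        raise ValueError(f"sample type spec must be 'subject:habitat', got {spec!r}")
    return subject, habitat


def subsample_sample_type(records: Sequence[SampleRecord],
                          sample_type_spec: str, n: int, seed: int,
                          *, stratify_by_habitat: bool = False) -> list[str]:
    """Draw exactly ``n`` sample ids uniformly without replacement from the
    samples matching ``sample_type_spec`` (``"M3:gut"``, ``"M3:*"``, ``"*:*"``).

    With ``stratify_by_habitat`` the draw is split as evenly as possible
    across the habitats present in the matching set.
    """
    subject, habitat = parse_sample_type(sample_type_spec)
    matching = [r for r in records if r.matches(subject, habitat)]
    if len(matching) < n:
        raise ValueError(
            f"sample type {sample_type_spec!r} has {len(matching)} samples, "
            f"{n} requested ({n - len(matching)} short)"
        )
    rng = np.random.default_rng(seed)
    if not stratify_by_habitat:
        ids = [r.sample_id for r in matching]
        return list(rng.choice(ids, size=n, replace=False))
    habitats = sorted({r.habitat for r in matching})
    per = np.full(len(habitats), n // len(habitats))
    per[: n % len(habitats)] += 1
    chosen: list[str] = []
    for h, k in zip(habitats, per):
        pool = [r.sample_id for r in matching if r.habitat == h]
        if len(pool) < k:
            raise ValueError(f"habitat {h!r} has {len(pool)} samples, {k} needed "
                             f"for a stratified draw")
        chosen.extend(rng.choice(pool, size=int(k), replace=False))
    return chosen


def core_curve(table: CountTable, sample_ids: Sequence[str],
               thresholds: Sequence[int] | None = None,
               sample_type: str = "") -> CoreCurve:
    """Fraction of observed OTUs present in >= k of ``sample_ids``, per k.

    ``thresholds`` defaults to ``1..len(sample_ids)``.
    """
    if not sample_ids:
        raise ValueError("sample_ids must be non-empty")
    n = len(sample_ids)
    if thresholds is None:
        thresholds = range(1, n + 1)
    thresholds = [int(k) for k in thresholds]
    if any(k < 1 or k > n for k in thresholds):
        raise ValueError(f"thresholds must lie in 1..{n}")
    occupancy = (table.select_samples(sample_ids).df > 0).sum(axis=1).to_numpy()
    n_observed = int((occupancy >= 1).sum())
    if n_observed == 0:
        raise ValueError("no OTU observed in the selected samples")
    n_core = tuple(int((occupancy >= k).sum()) for k in thresholds)
    frac = tuple(c / n_observed for c in n_core)
    return CoreCurve(sample_type=sample_type, n_subsampled=n,
                     thresholds=tuple(thresholds), n_core=n_core,
                     fraction_core=frac)


def core_size_drop(curve: CoreCurve, k_lo: int, k_hi: int) -> tuple[float, float]:
    """Core fractions at a loose and a strict threshold (e.g. 120 vs 130 of
    130 samples), for sensitivity reporting."""
    if not k_lo < k_hi:
        raise ValueError("k_lo must be < k_hi")
    return curve.fraction_at(k_lo), curve.fraction_at(k_hi)
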